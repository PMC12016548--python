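import pytest

from phagecarbon.simulate import FixtureSpec, generate_fixture


@pytest.fixture(scope="session")
def default_bundle():
    """One default fixture shared by read-only tests."""
    return generate_fixture(FixtureSpec(seed=11))


@pytest.fixture(scope="session")
def flat_depth_spec():
    """Default plans but a flat explicit depth plan (every depth >= 10)."""
    spec = FixtureSpec(seed=0)
    depth_plan = {cid: 20.0 for cid in spec.bacterial_ids()}
    depth_plan.update({cid: 15.0 for cid in spec.phage_ids()})
    return FixtureSpec(seed=0, depth_plan=depth_plan)
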