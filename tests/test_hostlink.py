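"""Spacer matching, homology search, host-range merging."""

import numpy as np
import pytest

from phagecarbon._dna import hamming, random_dna, reverse_complement
from phagecarbon.errors import DataValidationError
from phagecarbon.hostlink import (
    CrisprSpacer,
    HostLink,
    SpacerHit,
    homology_links,
    linkage_summary,
    match_spacer,
    merge_links,
    spacer_links,
)
from phagecarbon.simulate import FixtureSpec, HomologyPlan, generate_fixture


def brute_force_spacer_scan(spacer: str, seq: str, max_mismatch: int):
    """Independent oracle: sliding-window Hamming scan on both strands."""
    hits = []
    m = len(spacer)
    for strand, probe in (("+", spacer), ("-", reverse_complement(spacer))):
        for pos in range(len(seq) - m + 1):
            d = hamming(probe, seq[pos : pos + m])
            if d <= max_mismatch:
                hits.append((pos, strand, d))
    return sorted(hits)


def as_tuples(hits):
    return sorted((h.position, h.strand, h.mismatches) for h in hits)


class TestMatchSpacer:
    def test_planted_exact_match(self):
        rng = np.random.default_rng(0)
        phage = random_dna(rng, 2000)
        spacer = random_dna(rng, 32)
        planted = phage[:100] + spacer + phage[132:]
        hits = match_spacer(spacer, planted)
        assert SpacerHit(100, "+", 0) in hits

    def test_two_substitutions_exceed_budget_one(self):
        rng = np.random.default_rng(1)
        phage = random_dna(rng, 2000)
        spacer = random_dna(rng, 32)
        mutated = ("T" if spacer[0] != "T" else "A") + spacer[1:-1] + (
            "T" if spacer[-1] != "T" else "A"
        )
        planted = phage[:100] + mutated + phage[132:]
        positions = [h.position for h in match_spacer(spacer, planted, 1)]
        assert 100 not in positions
        assert 100 in [h.position for h in match_spacer(spacer, planted, 2)]

    def test_spacer_longer_than_phage_gives_empty(self):
        assert match_spacer("ACGT" * 8, "ACGTACGT") == []

    @pytest.mark.parametrize("seed", range(5))
    def test_equals_brute_force_on_random_instances(self, seed):
        rng = np.random.default_rng(seed)
        phage = random_dna(rng, 3000)
        for _ in range(10):
            length = int(rng.integers(20, 41))
            if rng.random() < 0.5:  # random spacer, usually no hit
                spacer = random_dna(rng, length)
            else:  # planted, possibly reverse strand, 0-2 mismatches
                start = int(rng.integers(0, 3000 - length))
                window = phage[start : start + length]
                k = int(rng.integers(0, 3))
                for pos in rng.choice(length, size=k, replace=False):
                    other = [b for b in "ACGT" if b != window[pos]]
                    window = (
                        window[:pos]
                        + other[int(rng.integers(3))]
                        + window[pos + 1 :]
                    )
                spacer = (
                    window if rng.random() < 0.5 else reverse_complement(window)
                )
            budget = int(rng.integers(0, 3))
            assert as_tuples(match_spacer(spacer, phage, budget)) == (
                brute_force_spacer_scan(spacer, phage, budget)
            )

    def test_strand_symmetry_of_link_pairs(self):
        spec = FixtureSpec(seed=3)
        bundle = generate_fixture(spec)
        fwd = spacer_links(bundle.spacers, bundle.phage_contigs)
        rev = spacer_links(
            bundle.spacers,
            {c: reverse_complement(s) for c, s in bundle.phage_contigs.items()},
        )
        pairs = lambda links: {(l.phage_contig, l.bacterial_contig) for l in links}
        assert pairs(fwd) == pairs(rev)

    def test_raising_budget_never_removes_hits(self):
        rng = np.random.default_rng(7)
        phage = random_dna(rng, 2000)
        spacer = phage[500:532]
        prev: set = set()
        for budget in range(4):
            hits = set(as_tuples(match_spacer(spacer, phage, budget)))
            assert prev <= hits
            prev = hits


class TestSpacerLinks:
    def test_no_spacers_no_links(self, default_bundle):
        assert spacer_links([], default_bundle.phage_contigs) == []

    def test_planted_pairs_recovered_exactly(self, default_bundle):
        links = spacer_links(default_bundle.spacers, default_bundle.phage_contigs)
        found = {(l.phage_contig, l.bacterial_contig) for l in links}
        truth = {
            (t.phage_contig, t.bacterial_contig)
            for t in default_bundle.ground_truth.true_links
            if t.mechanism == "spacer"
        }
        assert found == truth

    def test_plant_beyond_budget_is_absent(self):
        from phagecarbon.simulate import SpacerPlan

        spec = FixtureSpec(
            seed=5,
            spacer_plan=(SpacerPlan("B0001", "P0001", length=32, mismatches=2),),
        )
        bundle = generate_fixture(spec)
        links = spacer_links(bundle.spacers, bundle.phage_contigs, max_mismatch=1)
        assert ("P0001", "B0001") not in {
            (l.phage_contig, l.bacterial_contig) for l in links
        }
        links2 = spacer_links(bundle.spacers, bundle.phage_contigs, max_mismatch=2)
        assert ("P0001", "B0001") in {
            (l.phage_contig, l.bacterial_contig) for l in links2
        }


class TestHomology:
    def test_identical_shared_segment(self):
        rng = np.random.default_rng(11)
        segment = random_dna(rng, 1500)
        bact = random_dna(rng, 3000) + segment + random_dna(rng, 3000)
        phage = random_dna(rng, 2000) + segment + random_dna(rng, 2000)
        links = homology_links({"b": bact}, {"p": phage})
        assert len(links) == 1
        detail = links[0].detail
        assert detail.identity >= 0.999
        assert detail.length >= 1500

    def test_segment_below_identity_threshold_is_dropped(self):
        spec = FixtureSpec(
            seed=13,
            spacer_plan=(),
            homology_plan=(HomologyPlan("B0001", "P0001", 1200, 0.85),),
        )
        bundle = generate_fixture(spec)
        links = homology_links(bundle.bacterial_contigs, bundle.phage_contigs)
        assert links == []

    @pytest.mark.parametrize("seed", range(4))
    def test_planted_identity_recovered_within_one_point(self, seed):
        spec = FixtureSpec(
            seed=100 + seed,
            spacer_plan=(),
            homology_plan=(HomologyPlan("B0001", "P0001", 2000, 0.95),),
        )
        bundle = generate_fixture(spec)
        links = homology_links(bundle.bacterial_contigs, bundle.phage_contigs)
        pairs = {(l.phage_contig, l.bacterial_contig) for l in links}
        assert pairs == {("P0001", "B0001")}
        best = max(links, key=lambda l: l.detail.length)
        assert best.detail.identity == pytest.approx(0.95, abs=0.01)
        assert best.detail.length >= 1000

    def test_lowering_thresholds_never_removes_links(self):
        spec = FixtureSpec(seed=17)
        bundle = generate_fixture(spec)
        strict = homology_links(
            bundle.bacterial_contigs,
            bundle.phage_contigs,
            min_identity=0.95,
            min_length=1400,
        )
        relaxed = homology_links(
            bundle.bacterial_contigs,
            bundle.phage_contigs,
            min_identity=0.90,
            min_length=1000,
        )
        pairs = lambda links: {(l.phage_contig, l.bacterial_contig) for l in links}
        assert pairs(strict) <= pairs(relaxed)

    def test_small_k_rejected(self):
        with pytest.raises(DataValidationError, match="k"):
            homology_links({}, {}, k=5)


class TestHostRange:
    def taxonomy(self):
        return {"b1": "Bacteroidota", "b2": "Bacteroidota", "b3": "Bacteroidota",
                "b4": "Actinomycetota"}

    def link(self, phage, bact):
        return HostLink(phage, bact, "spacer", SpacerHit(0, "+", 0))

    def test_three_contigs_one_taxon_is_specialist(self):
        links = [self.link("p1", b) for b in ("b1", "b2", "b3")]
        ranges = merge_links(links, self.taxonomy())
        assert len(ranges) == 1
        assert ranges[0].breadth == "specialist"
        assert ranges[0].host_taxa == {"Bacteroidota"}

    def test_two_taxa_is_generalist(self):
        ranges = merge_links(
            [self.link("p1", "b1"), self.link("p1", "b4")], self.taxonomy()
        )
        assert ranges[0].breadth == "generalist"

    def test_unlinked_phages_are_omitted(self):
        assert merge_links([], self.taxonomy()) == []

    def test_unannotated_contig_becomes_unknown_taxon(self):
        ranges = merge_links([self.link("p1", "bX")], self.taxonomy())
        assert ranges[0].host_taxa == {"unknown"}

    def test_summary_counts_partition_linked_phages(self):
        links = [
            self.link("p1", "b1"),
            self.link("p1", "b4"),
            self.link("p2", "b2"),
            self.link("p3", "b3"),
        ]
        ranges = merge_links(links, self.taxonomy())
        summary = linkage_summary(
            ranges, {"p1": 0.02, "p2": 0.01, "p3": 0.02}
        )
        assert summary["generalist"]["count"] + summary["specialist"]["count"] == 3
        assert summary["specialist"]["cumulative_abundance"] == pytest.approx(0.03)
        assert summary["generalist"]["cumulative_abundance"] == pytest.approx(0.02)

    def test_no_generalists_gives_zero_abundance(self):
        ranges = merge_links([self.link("p1", "b1")], self.taxonomy())
        summary = linkage_summary(ranges, {"p1": 0.5})
        assert summary["generalist"]["count"] == 0
        assert summary["generalist"]["cumulative_abundance"] == 0.0

    def test_missing_abundance_names_phage(self):
        ranges = merge_links([self.link("p9", "b1")], self.taxonomy())
        with pytest.raises(DataValidationError, match="p9"):
            linkage_summary(ranges, {})
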