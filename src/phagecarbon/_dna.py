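"""Small DNA helpers used by the simulator and the matchers."""

from __future__ import annotations

import numpy as np

BASES = "ACGT"
_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")

# fixed byte codes so numpy comparisons work on raw ASCII
_ENC = np.zeros(256, dtype=np.uint8)
for _i, _b in enumerate(BASES):
    _ENC[ord(_b)] = _i
    _ENC[ord(_b.lower())] = _i


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def encode(seq: str) -> np.ndarray:
    """Encode ACGT (case-insensitive) as uint8 codes 0..3."""
    return _ENC[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


_BASE_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def random_dna(rng: np.random.Generator, length: int) -> str:
    codes = rng.integers(0, 4, size=length)
    return _BASE_BYTES[codes].tobytes().decode("ascii")


def mutate_positions(seq: str, positions, rng: np.random.Generator) -> str:
    """Substitute each listed position with a different base."""
    out = list(seq)
    for pos in positions:
        choices = [b for b in BASES if b != out[pos]]
        out[pos] = choices[rng.integers(len(choices))]
    return "".join(out)


def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("hamming distance requires equal-length strings")
    return sum(x != y for x, y in zip(a, b))
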