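"""Phage-host linkage by CRISPR-spacer matching and genome homology.

Two independent lines of evidence connect a phage contig to a candidate
bacterial host:

* a bacterial CRISPR spacer matching a phage protospacer over its full
  length (100% coverage) with at most ``max_mismatch`` substitutions
  (default 1), no indels, both strands searched;
* an ungapped homologous segment of at least ``min_length`` bp (default
  1,000) at identity >= ``min_identity`` (default 0.90), found by k-mer
  seeding (default k = 21) and X-drop diagonal extension.

Links from both mechanisms are merged per phage; a phage whose linked
bacteria span a single taxon is a *specialist*, two or more taxa a
*generalist*.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from phagecarbon._dna import encode, reverse_complement
from phagecarbon.errors import DataValidationError

DEFAULT_MAX_MISMATCH = 1
DEFAULT_MIN_IDENTITY = 0.90
DEFAULT_MIN_LENGTH = 1_000
DEFAULT_SEED_K = 21
_XDROP = 30  # score drop (match +1 / mismatch -1) that ends extension


@dataclass(frozen=True)
class CrisprSpacer:
    """A bacterial CRISPR spacer sequence."""

    spacer_id: str
    bacterial_contig: str
    sequence: str

    def __post_init__(self) -> None:
        if not (20 <= len(self.sequence) <= 60):
            raise DataValidationError(
                f"spacer {self.spacer_id}: length {len(self.sequence)} "
                "outside [20, 60]"
            )
        if set(self.sequence) - set("ACGT"):
            raise DataValidationError(
                f"spacer {self.spacer_id}: sequence must be uppercase ACGT"
            )


@dataclass(frozen=True)
class SpacerHit:
    position: int  # 0-based start on the phage forward strand
    strand: str
    mismatches: int


@dataclass(frozen=True)
class HomologySegment:
    bacterial_start: int
    bacterial_end: int
    phage_start: int
    phage_end: int
    strand: str
    identity: float
    length: int


@dataclass(frozen=True)
class HostLink:
    """One piece of evidence linking a phage contig to a bacterial contig."""

    phage_contig: str
    bacterial_contig: str
    mechanism: str  # "spacer" | "homology"
    detail: SpacerHit | HomologySegment


@dataclass
class PhageHostRange:
    """Aggregated host range of one phage with its breadth call."""

    phage_contig: str
    host_taxa: frozenset[str]
    links: list[HostLink] = field(default_factory=list)

    @property
    def breadth(self) -> str:
        return "specialist" if len(self.host_taxa) == 1 else "generalist"


def match_spacer(
    spacer: CrisprSpacer | str,
    phage_sequence: str,
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> list[SpacerHit]:
    """All full-length spacer matches in a phage sequence.

    Every window of exactly spacer length on either strand with Hamming
    distance <= ``max_mismatch`` is reported (no partial or overhanging
    matches). Positions are on the forward strand of the phage; results
    are sorted by position, then strand ('+' before '-').
    """
    seq = spacer.sequence if isinstance(spacer, CrisprSpacer) else spacer
    m, n = len(seq), len(phage_sequence)
    if m > n:
        return []
    phage_codes = encode(phage_sequence)
    windows = np.lib.stride_tricks.sliding_window_view(phage_codes, m)
    hits: list[SpacerHit] = []
    for strand, probe in (("+", seq), ("-", reverse_complement(seq))):
        mism = (windows != encode(probe)).sum(axis=1)
        for pos in np.nonzero(mism <= max_mismatch)[0]:
            hits.append(SpacerHit(int(pos), strand, int(mism[pos])))
    hits.sort(key=lambda h: (h.position, h.strand))
    return hits


def spacer_links(
    spacers: Iterable[CrisprSpacer],
    phage_contigs: Mapping[str, str],
    max_mismatch: int = DEFAULT_MAX_MISMATCH,
) -> list[HostLink]:
    """One HostLink per spacer hit against every phage contig.

    Duplicate (phage, bacterium) pairs are kept here with their distinct
    hit details; deduplication happens when ranges are merged.
    """
    links: list[HostLink] = []
    for spacer in spacers:
        for phage_id in sorted(phage_contigs):
            for hit in match_spacer(spacer, phage_contigs[phage_id], max_mismatch):
                links.append(
                    HostLink(phage_id, spacer.bacterial_contig, "spacer", hit)
                )
    return links


def _kmer_index(codes: np.ndarray, k: int) -> dict[bytes, list[int]]:
    index: dict[bytes, list[int]] = defaultdict(list)
    data = codes.tobytes()
    for i in range(len(codes) - k + 1):
        index[data[i : i + k]].append(i)
    return index


def _extend_on_diagonal(
    bact: np.ndarray,
    phage: np.ndarray,
    diag: int,
    seed_lo: int,
    seed_hi: int,
) -> tuple[int, int]:
    """X-drop ungapped extension of a seed run on one diagonal.

    ``diag = bact_pos - phage_pos``; ``seed_lo:seed_hi`` are phage
    coordinates of the (exact-match) seed region. Returns the phage
    interval of the maximal-score extension. Score is +1 per match, -1
    per mismatch; extension stops once the running score falls _XDROP
    below its maximum, and the segment is trimmed to the argmax.
    """
    lo_limit = max(0, -diag)
    hi_limit = min(len(phage), len(bact) - diag)
    match = lambda p: bact[p + diag] == phage[p]  # noqa: E731

    best, score, end = 0, 0, seed_hi
    p = seed_hi
    while p < hi_limit:
        score += 1 if match(p) else -1
        p += 1
        if score > best:
            best, end = score, p
        elif best - score > _XDROP:
            break

    best, score, start = 0, 0, seed_lo
    p = seed_lo
    while p > lo_limit:
        p -= 1
        score += 1 if match(p) else -1
        if score > best:
            best, start = score, p
        elif best - score > _XDROP:
            break
    return start, end


def _merge_intervals(intervals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    merged: list[tuple[int, int]] = []
    for lo, hi in sorted(intervals):
        if merged and lo <= merged[-1][1]:
            merged[-1] = (merged[-1][0], max(merged[-1][1], hi))
        else:
            merged.append((lo, hi))
    return merged


def _diagonal_segments(
    bact_codes: np.ndarray,
    phage_codes: np.ndarray,
    k: int,
    min_identity: float,
    min_length: int,
    index: dict[bytes, list[int]] | None = None,
) -> list[tuple[int, int, int, float]]:
    """(phage_start, phage_end, diag, identity) segments on one strand."""
    if len(bact_codes) < k or len(phage_codes) < k:
        return []
    if index is None:
        index = _kmer_index(bact_codes, k)
    by_diag: dict[int, list[tuple[int, int]]] = defaultdict(list)
    data = phage_codes.tobytes()
    for p in range(len(phage_codes) - k + 1):
        for b in index.get(data[p : p + k], ()):
            by_diag[b - p].append((p, p + k))
    segments = []
    for diag, seeds in by_diag.items():
        extended = [
            _extend_on_diagonal(bact_codes, phage_codes, diag, lo, hi)
            for lo, hi in _merge_intervals(seeds)
        ]
        for lo, hi in _merge_intervals(extended):
            length = hi - lo
            if length < min_length:
                continue
            matches = int(
                (bact_codes[lo + diag : hi + diag] == phage_codes[lo:hi]).sum()
            )
            identity = matches / length
            if identity >= min_identity:
                segments.append((lo, hi, diag, identity))
    return segments


def homology_links(
    bacterial_contigs: Mapping[str, str],
    phage_contigs: Mapping[str, str],
    min_identity: float = DEFAULT_MIN_IDENTITY,
    min_length: int = DEFAULT_MIN_LENGTH,
    k: int = DEFAULT_SEED_K,
) -> list[HostLink]:
    """Ungapped homology links between the two contig fractions.

    Matches are seeded by shared k-mers, merged and X-drop extended per
    diagonal, and reported when they reach ``min_length`` bp at identity
    >= ``min_identity``. Segments are reported on the bacterial
    coordinate system; both phage strands are searched.
    """
    if k < 11:
        raise DataValidationError(f"seed size k must be >= 11, got {k}")
    if not (0.0 < min_identity <= 1.0) or min_length <= 0:
        raise DataValidationError("homology thresholds out of range")
    links: list[HostLink] = []
    bact_codes = {bid: encode(seq) for bid, seq in bacterial_contigs.items()}
    bact_index = {
        bid: _kmer_index(codes, k) if len(codes) >= k else {}
        for bid, codes in bact_codes.items()
    }
    for phage_id in sorted(phage_contigs):
        forward = phage_contigs[phage_id]
        plen = len(forward)
        for strand, pseq in (("+", forward), ("-", reverse_complement(forward))):
            pcodes = encode(pseq)
            for bact_id in sorted(bact_codes):
                for lo, hi, diag, ident in _diagonal_segments(
                    bact_codes[bact_id],
                    pcodes,
                    k,
                    min_identity,
                    min_length,
                    index=bact_index[bact_id],
                ):
                    if strand == "+":
                        p_lo, p_hi = lo, hi
                    else:  # map back to forward phage coordinates
                        p_lo, p_hi = plen - hi, plen - lo
                    seg = HomologySegment(
                        bacterial_start=lo + diag,
                        bacterial_end=hi + diag,
                        phage_start=p_lo,
                        phage_end=p_hi,
                        strand=strand,
                        identity=ident,
                        length=hi - lo,
                    )
                    links.append(HostLink(phage_id, bact_id, "homology", seg))
    return links


def merge_links(
    links: Sequence[HostLink],
    taxonomy: Mapping[str, str],
) -> list[PhageHostRange]:
    """Aggregate links per phage into host ranges with breadth calls.

    Multiple links to the same (phage, bacterium) pair are all retained
    as evidence but count once toward the taxon set. Bacterial contigs
    absent from the taxonomy map fall into the "unknown" pseudo-taxon.
    Phages without links are omitted.
    """
    by_phage: dict[str, list[HostLink]] = defaultdict(list)
    for link in links:
        by_phage[link.phage_contig].append(link)
    ranges = []
    for phage_id in sorted(by_phage):
        plinks = by_phage[phage_id]
        taxa = frozenset(
            taxonomy.get(l.bacterial_contig, "unknown") for l in plinks
        )
        ranges.append(PhageHostRange(phage_id, taxa, plinks))
    return ranges


def linkage_summary(
    ranges: Sequence[PhageHostRange],
    phage_abundances: Mapping[str, float],
) -> dict[str, dict[str, float]]:
    """Counts and cumulative relative abundance per breadth class."""
    out = {
        "specialist": {"count": 0, "cumulative_abundance": 0.0},
        "generalist": {"count": 0, "cumulative_abundance": 0.0},
    }
    for rng in ranges:
        if rng.phage_contig not in phage_abundances:
            raise DataValidationError(
                f"missing abundance for linked phage {rng.phage_contig}"
            )
        bucket = out[rng.breadth]
        bucket["count"] += 1
        bucket["cumulative_abundance"] += phage_abundances[rng.phage_contig]
    return out
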