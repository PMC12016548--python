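"""Read-depth, per-gene coverage, RPKM and alpha-diversity statistics.

"Coverage" of a gene is the mean per-base read depth over the gene
interval (pileup convention). Relative gene abundance uses RPKM (reads
per kilobase of gene per million mapped reads). A read overlapping a
gene partially counts fully toward its read count, but only its
overlapping bases contribute to depth.

Alpha diversity (observed richness, bias-corrected Chao1, natural-log
Shannon, Pielou's evenness) delegates to scikit-bio.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam
from skbio.diversity.alpha import chao1 as _skbio_chao1
from skbio.diversity.alpha import pielou_e as _skbio_pielou
from skbio.diversity.alpha import shannon as _skbio_shannon

from phagecarbon.annotation import GeneRecord
from phagecarbon.errors import DataValidationError

ALIGNMENT_COLUMNS = ["read_id", "contig_id", "start", "aligned_length", "strand"]


@dataclass(frozen=True)
class AlignmentRecord:
    """One mapped read: reference, 0-based start, reference span, strand."""

    read_id: str
    contig_id: str
    start: int
    aligned_length: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 0 or self.aligned_length <= 0:
            raise DataValidationError(
                f"read {self.read_id}: invalid interval "
                f"start={self.start} len={self.aligned_length}"
            )

    @property
    def end(self) -> int:
        return self.start + self.aligned_length


@dataclass
class CoverageProfile:
    """Per-gene depth / read count / RPKM for one sample (one fraction)."""

    sample_id: str
    gene_mean_depth: dict[str, float] = field(default_factory=dict)
    gene_read_count: dict[str, int] = field(default_factory=dict)
    total_mapped_reads: int = 0
    gene_rpkm: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class DiversityIndices:
    richness: int
    chao1: float
    shannon: float
    pielou: float | None  # undefined for a single-taxon community


def per_base_depth(
    alignments: Iterable[AlignmentRecord], contig_length: int
) -> np.ndarray:
    """Pileup depth vector: depth[i] = number of reads covering base i."""
    delta = np.zeros(contig_length + 1, dtype=np.int64)
    for aln in alignments:
        if aln.end > contig_length:
            raise DataValidationError(
                f"read {aln.read_id} extends to {aln.end} beyond contig "
                f"length {contig_length}"
            )
        delta[aln.start] += 1
        delta[aln.end] -= 1
    return np.cumsum(delta[:-1])


def gene_coverage(depth: np.ndarray, start: int, end: int) -> float:
    """Mean depth over the gene interval [start, end)."""
    if not (0 <= start < end <= len(depth)):
        raise DataValidationError(
            f"gene interval [{start}, {end}) invalid for contig of "
            f"length {len(depth)}"
        )
    return float(depth[start:end].mean())


def rpkm(read_count: int, gene_length: int, total_mapped_reads: int) -> float:
    """Reads per kilobase of gene per million mapped reads."""
    if gene_length <= 0:
        raise DataValidationError(f"gene_length must be > 0, got {gene_length}")
    if total_mapped_reads <= 0:
        raise DataValidationError(
            "rpkm undefined: total_mapped_reads must be > 0"
        )
    return read_count / (gene_length / 1_000) / (total_mapped_reads / 1_000_000)


def relative_abundance(values: Mapping[str, float]) -> dict[str, float]:
    """Normalise nonnegative values to fractions summing to 1."""
    if any(v < 0 for v in values.values()):
        raise DataValidationError("relative_abundance requires nonnegative values")
    total = sum(values.values())
    if total <= 0:
        raise DataValidationError("relative_abundance undefined for all-zero input")
    return {k: v / total for k, v in values.items()}


def alpha_diversity(counts: Mapping[str, int]) -> DiversityIndices:
    """Alpha-diversity indices of a taxon count table.

    richness = number of taxa with positive count; Shannon uses natural
    log; Chao1 is the bias-corrected estimator
    ``S_obs + F1*(F1-1) / (2*(F2+1))``; Pielou = Shannon / ln(richness),
    reported as missing (None) when richness is 1.
    """
    vec = np.asarray([c for c in counts.values()], dtype=np.int64)
    if vec.size == 0 or (vec < 0).any() or vec.sum() == 0:
        raise DataValidationError(
            "alpha_diversity requires nonnegative counts with at least one "
            "positive taxon"
        )
    richness = int((vec > 0).sum())
    shannon = float(_skbio_shannon(vec, base=math.e))
    chao1 = float(_skbio_chao1(vec, bias_corrected=True))
    pielou = float(_skbio_pielou(vec)) if richness >= 2 else None
    return DiversityIndices(richness, chao1, shannon, pielou)


def compute_coverage(
    alignments: Sequence[AlignmentRecord],
    genes: Sequence[GeneRecord],
    contig_lengths: Mapping[str, int],
    sample_id: str,
) -> CoverageProfile:
    """Per-gene mean depth, read count and RPKM for one sample fraction.

    ``total_mapped_reads`` is the number of alignment records; genes on
    contigs without any mapped read get depth/count/RPKM of zero.
    """
    by_contig: dict[str, list[AlignmentRecord]] = {}
    for aln in alignments:
        if aln.contig_id not in contig_lengths:
            raise DataValidationError(
                f"read {aln.read_id} maps to unknown contig {aln.contig_id}"
            )
        by_contig.setdefault(aln.contig_id, []).append(aln)

    depth_cache = {
        cid: per_base_depth(alns, contig_lengths[cid])
        for cid, alns in by_contig.items()
    }
    total = len(alignments)
    profile = CoverageProfile(sample_id=sample_id, total_mapped_reads=total)
    for gene in genes:
        clen = contig_lengths.get(gene.contig_id)
        if clen is None:
            raise DataValidationError(
                f"gene {gene.gene_id} is on unknown contig {gene.contig_id}"
            )
        if gene.end > clen:
            raise DataValidationError(
                f"gene {gene.gene_id} extends beyond contig {gene.contig_id}"
            )
        depth = depth_cache.get(gene.contig_id)
        if depth is None:
            mean_depth, count = 0.0, 0
        else:
            mean_depth = gene_coverage(depth, gene.start, gene.end)
            count = sum(
                1
                for aln in by_contig[gene.contig_id]
                if aln.start < gene.end and aln.end > gene.start
            )
        profile.gene_mean_depth[gene.gene_id] = mean_depth
        profile.gene_read_count[gene.gene_id] = count
        profile.gene_rpkm[gene.gene_id] = (
            rpkm(count, gene.length, total) if total > 0 and count > 0 else 0.0
        )
    return profile


def read_alignment_tsv(path: str | Path) -> list[AlignmentRecord]:
    """Read the simplified alignment table written by the simulator."""
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ALIGNMENT_COLUMNS if c not in df.columns]
    if missing:
        raise DataValidationError(f"{path}: missing alignment columns {missing}")
    records = []
    for idx, row in enumerate(df.itertuples(index=False)):
        try:
            records.append(
                AlignmentRecord(
                    read_id=row.read_id,
                    contig_id=row.contig_id,
                    start=int(row.start),
                    aligned_length=int(row.aligned_length),
                    strand=row.strand,
                )
            )
        except (ValueError, DataValidationError) as exc:
            raise DataValidationError(f"{path} line {idx + 2}: {exc}") from exc
    return records


def write_alignment_tsv(
    alignments: Iterable[AlignmentRecord], path: str | Path
) -> None:
    rows = [
        {
            "read_id": a.read_id,
            "contig_id": a.contig_id,
            "start": a.start,
            "aligned_length": a.aligned_length,
            "strand": a.strand,
        }
        for a in alignments
    ]
    pd.DataFrame(rows, columns=ALIGNMENT_COLUMNS).to_csv(path, sep="\t", index=False)


def read_sam(path: str | Path) -> list[AlignmentRecord]:
    """Read mapped, primary, non-supplementary records from a SAM file.

    The reference span comes from the CIGAR string (M/=/X/D consume the
    reference; I/S do not), i.e. pysam's ``reference_length``.
    """
    records = []
    with pysam.AlignmentFile(str(path), "r") as sam:
        for aln in sam.fetch(until_eof=True):
            if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                continue
            span = aln.reference_length
            if not span:
                continue
            records.append(
                AlignmentRecord(
                    read_id=aln.query_name,
                    contig_id=aln.reference_name,
                    start=aln.reference_start,
                    aligned_length=span,
                    strand="-" if aln.is_reverse else "+",
                )
            )
    return records


def write_coverage_tsv(profile: CoverageProfile, path: str | Path) -> None:
    """Emit the coverage table: sample_id, gene_id, mean_depth, read_count, rpkm."""
    rows = [
        {
            "sample_id": profile.sample_id,
            "gene_id": gid,
            "mean_depth": profile.gene_mean_depth[gid],
            "read_count": profile.gene_read_count[gid],
            "rpkm": profile.gene_rpkm[gid],
        }
        for gid in sorted(profile.gene_mean_depth)
    ]
    pd.DataFrame(
        rows, columns=["sample_id", "gene_id", "mean_depth", "read_count", "rpkm"]
    ).to_csv(path, sep="\t", index=False)


def read_coverage_tsv(path: str | Path) -> CoverageProfile:
    df = pd.read_csv(path, sep="\t")
    if df.empty:
        raise DataValidationError(f"{path}: empty coverage table")
    sample_id = str(df["sample_id"].iloc[0])
    profile = CoverageProfile(sample_id=sample_id)
    for row in df.itertuples(index=False):
        gid = str(row.gene_id)
        profile.gene_mean_depth[gid] = float(row.mean_depth)
        profile.gene_read_count[gid] = int(row.read_count)
        profile.gene_rpkm[gid] = float(row.rpkm)
    profile.total_mapped_reads = int(df["read_count"].sum())
    return profile
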