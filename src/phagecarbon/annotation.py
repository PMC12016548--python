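"""Gene records and rule-based carbon-metabolism classification.

Carbon-metabolism genes are partitioned into three functional categories:

* **sequestration** — CO2-fixation marker genes (``cbbL``, ``acsA``,
  ``acsB``, ``oorA``, ``nifJ``, ``porA``, ``aclB``), glycosyltransferase
  (GT) CAZy families, and the sequestration-associated phage AMG symbols
  (``aceF``, ``glmS``, ``gltA``, ``GT11``, ``GT2``, ``GT4``, ``GT6``);
* **decomposition** — glycoside hydrolase (GH), polysaccharide lyase
  (PL), carbohydrate esterase (CE) and auxiliary-activity (AA) families,
  plus pectate lyase ``pel``;
* **transformation** — interconversions of organic carbon with the same
  carbon number (``rfbE``, ``wbpD``, ``ugd``, ``pgl``).

Everything else is *unclassified* (non-carbon genes pass through rather
than erroring, since real AMG tables also carry non-carbon entries).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

from phagecarbon.errors import DataValidationError

ANNOTATION_COLUMNS = [
    "gene_id",
    "contig_id",
    "source",
    "start",
    "end",
    "strand",
    "kegg_symbol",
    "cazy_family",
]

#: Minimum length (bp) for a contig to be treated as a phage. The phage
#: definition is "longer than 5,000 bp", i.e. strictly greater, so the
#: smallest retained length is 5,001 bp.
PHAGE_MIN_LENGTH = 5_001


class CarbonCategory(enum.Enum):
    """Three-way carbon-metabolism class, plus the pass-through bucket."""

    SEQUESTRATION = "sequestration"
    TRANSFORMATION = "transformation"
    DECOMPOSITION = "decomposition"
    UNCLASSIFIED = "unclassified"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class GeneRecord:
    """An annotated gene on a contig.

    Coordinates are 0-based half-open. ``source`` says which sequence
    fraction the contig came from ("bacterial" metagenome or "phage"
    virome). ``kegg_symbol`` and ``cazy_family`` are optional labels; a
    classified gene carries at least one.
    """

    gene_id: str
    contig_id: str
    source: str
    start: int
    end: int
    strand: str = "+"
    kegg_symbol: str | None = None
    cazy_family: str | None = None

    def __post_init__(self) -> None:
        if self.source not in ("bacterial", "phage"):
            raise DataValidationError(
                f"gene {self.gene_id}: source must be 'bacterial' or 'phage', "
                f"got {self.source!r}"
            )
        if not (0 <= self.start < self.end):
            raise DataValidationError(
                f"gene {self.gene_id}: invalid interval [{self.start}, {self.end})"
            )
        if self.strand not in ("+", "-"):
            raise DataValidationError(
                f"gene {self.gene_id}: strand must be '+' or '-'"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def symbol(self) -> str | None:
        """The matching key used throughout: KEGG symbol if present,
        otherwise the CAZy family code."""
        return self.kegg_symbol or self.cazy_family


@dataclass(frozen=True)
class AmgRecord:
    """A phage-encoded auxiliary metabolic gene with its category."""

    amg_symbol: str
    phage_contig: str
    category: CarbonCategory
    pathway_label: str = ""

    def __post_init__(self) -> None:
        if not self.amg_symbol:
            raise DataValidationError("amg_symbol must be non-empty")


def cazy_prefix(family: str) -> str:
    """CAZy class prefix = the longest leading alphabetic run.

    ``GT11`` -> ``GT``; ``AA3_2`` -> ``AA``; subfamily suffixes are
    ignored.
    """
    i = 0
    while i < len(family) and family[i].isalpha():
        i += 1
    return family[:i]


@dataclass(frozen=True)
class RuleSet:
    """Classification rules: explicit symbol sets plus a CAZy-prefix map.

    Symbol-set membership takes precedence over the prefix map when both
    apply. The defaults encode the bacterial sequestration marker genes,
    the sequestration-associated AMG symbols, and the transformation /
    decomposition symbols observed across treatments; users may override
    any set via configuration.
    """

    sequestration_kegg: frozenset[str] = frozenset(
        {"cbbL", "acsA", "acsB", "oorA", "nifJ", "porA", "aclB"}
    )
    sequestration_amg: frozenset[str] = frozenset(
        {"aceF", "glmS", "gltA", "GT11", "GT2", "GT4", "GT6"}
    )
    transformation_symbols: frozenset[str] = frozenset(
        {"rfbE", "wbpD", "ugd", "pgl"}
    )
    decomposition_symbols: frozenset[str] = frozenset({"pel"})
    cazy_prefix_map: Mapping[str, CarbonCategory] = field(
        default_factory=lambda: {
            "GT": CarbonCategory.SEQUESTRATION,
            "GH": CarbonCategory.DECOMPOSITION,
            "PL": CarbonCategory.DECOMPOSITION,
            "CE": CarbonCategory.DECOMPOSITION,
            "AA": CarbonCategory.DECOMPOSITION,
        }
    )

    def __post_init__(self) -> None:
        seq = self.sequestration_kegg | self.sequestration_amg
        sets = [seq, self.transformation_symbols, self.decomposition_symbols]
        for i in range(len(sets)):
            for j in range(i + 1, len(sets)):
                overlap = sets[i] & sets[j]
                if overlap:
                    raise DataValidationError(
                        f"rule symbol sets must be pairwise disjoint; "
                        f"shared: {sorted(overlap)}"
                    )
        if set(self.cazy_prefix_map) != {"GT", "GH", "PL", "CE", "AA"}:
            raise DataValidationError(
                "cazy_prefix_map keys must be exactly GT, GH, PL, CE, AA"
            )

    def with_overrides(self, **kwargs) -> "RuleSet":
        """Return a copy with the given sets replaced."""
        frozen = {
            k: (frozenset(v) if k != "cazy_prefix_map" else v)
            for k, v in kwargs.items()
        }
        return replace(self, **frozen)

    def _symbol_category(self, symbol: str) -> CarbonCategory | None:
        if symbol in self.sequestration_kegg or symbol in self.sequestration_amg:
            return CarbonCategory.SEQUESTRATION
        if symbol in self.transformation_symbols:
            return CarbonCategory.TRANSFORMATION
        if symbol in self.decomposition_symbols:
            return CarbonCategory.DECOMPOSITION
        return None


DEFAULT_RULES = RuleSet()


def classify_carbon_gene(gene: GeneRecord, rules: RuleSet = DEFAULT_RULES) -> CarbonCategory:
    """Classify one gene into a carbon-metabolism category.

    Order of evidence: explicit symbol-set membership (KEGG symbol or
    CAZy family code used as a symbol) wins over the CAZy class prefix;
    a gene with no recognised label is unclassified.
    """
    for label in (gene.kegg_symbol, gene.cazy_family):
        if label:
            cat = rules._symbol_category(label)
            if cat is not None:
                return cat
    if gene.cazy_family:
        prefix = cazy_prefix(gene.cazy_family)
        cat = rules.cazy_prefix_map.get(prefix)
        if cat is not None:
            return cat
    return CarbonCategory.UNCLASSIFIED


def filter_phage_contigs(
    contigs: Mapping[str, object], min_length: int = PHAGE_MIN_LENGTH
) -> dict:
    """Retain contigs long enough to be called phages (default > 5 kb).

    ``contigs`` maps contig id to either a sequence (anything with
    ``len``) or an integer length. Retention is ``length >= min_length``;
    with the default threshold a 5,000 bp contig is dropped and a
    5,001 bp contig kept.
    """
    out = {}
    for cid, value in contigs.items():
        length = value if isinstance(value, int) else len(value)
        if length >= min_length:
            out[cid] = value
    return out


def load_annotations(
    path: str | Path, contig_lengths: Mapping[str, int] | None = None
) -> list[GeneRecord]:
    """Read a gene-annotation TSV into :class:`GeneRecord` objects.

    Expected header: ``gene_id contig_id source start end strand
    kegg_symbol cazy_family`` (tab-separated; empty label cells mean "no
    label"). Errors carry the 1-based file line number. If
    ``contig_lengths`` is given, gene intervals are validated against it.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in ANNOTATION_COLUMNS if c not in df.columns]
    if missing:
        raise DataValidationError(
            f"{path}: missing annotation columns {missing}"
        )
    genes: list[GeneRecord] = []
    for idx, row in enumerate(df.itertuples(index=False)):
        line_no = idx + 2  # header is line 1
        try:
            start, end = int(row.start), int(row.end)
        except ValueError as exc:
            raise DataValidationError(
                f"{path} line {line_no}: non-integer coordinates"
            ) from exc
        try:
            gene = GeneRecord(
                gene_id=row.gene_id,
                contig_id=row.contig_id,
                source=row.source,
                start=start,
                end=end,
                strand=row.strand,
                kegg_symbol=row.kegg_symbol or None,
                cazy_family=row.cazy_family or None,
            )
        except DataValidationError as exc:
            raise DataValidationError(f"{path} line {line_no}: {exc}") from exc
        if contig_lengths is not None:
            clen = contig_lengths.get(gene.contig_id)
            if clen is not None and gene.end > clen:
                raise DataValidationError(
                    f"{path} line {line_no}: gene {gene.gene_id} ends at "
                    f"{gene.end} beyond contig {gene.contig_id} ({clen} bp)"
                )
        genes.append(gene)
    return genes


def write_annotations(genes: Iterable[GeneRecord], path: str | Path) -> None:
    """Write GeneRecords back to the annotation TSV format."""
    rows = [
        {
            "gene_id": g.gene_id,
            "contig_id": g.contig_id,
            "source": g.source,
            "start": g.start,
            "end": g.end,
            "strand": g.strand,
            "kegg_symbol": g.kegg_symbol or "",
            "cazy_family": g.cazy_family or "",
        }
        for g in genes
    ]
    pd.DataFrame(rows, columns=ANNOTATION_COLUMNS).to_csv(
        path, sep="\t", index=False
    )


def summarize_carbon_profile(
    genes: Iterable[GeneRecord],
    abundances: Mapping[str, float],
    rules: RuleSet = DEFAULT_RULES,
) -> dict[CarbonCategory, float]:
    """Cumulative relative abundance per carbon category.

    Every gene must have an abundance value; category totals plus the
    unclassified remainder conserve the grand total.
    """
    totals = {cat: 0.0 for cat in CarbonCategory}
    for gene in genes:
        if gene.gene_id not in abundances:
            raise DataValidationError(
                f"missing abundance for gene {gene.gene_id}"
            )
        totals[classify_carbon_gene(gene, rules)] += abundances[gene.gene_id]
    return totals
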