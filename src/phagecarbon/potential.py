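"""Phage:total gene coverage ratio and cumulative carbon-sequestration
potential.

For one AMG symbol in one treatment, the phage:total gene ratio is

    ratio = phage AMG coverage / (phage AMG coverage + bacterial homolog coverage)

where each coverage is the mean read depth summed over all gene copies
bearing that symbol in the respective fraction. The *cumulative carbon
sequestration potential* of an AMG set is the sum of the per-AMG ratios
expressed as percentages; being a sum over genes it can exceed 100%.

A ratio is undefined (0/0) when the symbol has no coverage in either
fraction; undefined entries contribute 0 to cumulative sums and are
flagged in the report.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from phagecarbon.annotation import DEFAULT_RULES, GeneRecord, RuleSet
from phagecarbon.coverage import CoverageProfile
from phagecarbon.errors import DataValidationError

#: Default AMG groupings: the full sequestration-associated AMG list, the
#: treatment-enriched subset, and its complement.
DEFAULT_AMG_SETS: dict[str, tuple[str, ...]] = {
    "all": ("aceF", "glmS", "gltA", "GT11", "GT2", "GT4", "GT6"),
    "enriched": ("GT11", "GT6", "aceF"),
    "non-enriched": ("glmS", "gltA", "GT2", "GT4"),
}


@dataclass(frozen=True)
class RatioEntry:
    """Phage:total coverage ratio for one AMG symbol in one treatment."""

    amg_symbol: str
    treatment: str
    phage_coverage: float
    bacterial_coverage: float

    def __post_init__(self) -> None:
        if self.phage_coverage < 0 or self.bacterial_coverage < 0:
            raise DataValidationError(
                f"{self.amg_symbol}: coverages must be nonnegative"
            )

    @property
    def ratio(self) -> float | None:
        """phage / (phage + bacterial); None when both coverages are 0."""
        total = self.phage_coverage + self.bacterial_coverage
        if total == 0:
            return None
        return self.phage_coverage / total

    @property
    def ratio_percent(self) -> float | None:
        r = self.ratio
        return None if r is None else 100.0 * r


@dataclass
class PotentialReport:
    """Per-AMG ratios and the cumulative potential for one named AMG set."""

    treatment: str
    amg_set_label: str
    member_symbols: tuple[str, ...]
    per_amg: list[RatioEntry]

    @property
    def undefined_symbols(self) -> list[str]:
        return [e.amg_symbol for e in self.per_amg if e.ratio is None]

    @property
    def cumulative_percent(self) -> float:
        return cumulative_potential(self.per_amg)


def phage_total_ratio(phage_coverage: float, bacterial_coverage: float) -> float | None:
    """The phage:total gene coverage ratio as a fraction in [0, 1].

    Returns None (undefined) when both coverages are zero.
    """
    if phage_coverage < 0 or bacterial_coverage < 0:
        raise DataValidationError("coverages must be nonnegative")
    total = phage_coverage + bacterial_coverage
    if total == 0:
        return None
    return phage_coverage / total


def cumulative_potential(entries: Sequence[RatioEntry]) -> float:
    """Sum of ratio percentages over entries of one treatment.

    Undefined (0/0) entries contribute 0. The sum runs over AMG symbols,
    so it may exceed 100%.
    """
    treatments = {e.treatment for e in entries}
    if len(treatments) > 1:
        raise DataValidationError(
            f"cumulative potential mixes treatments: {sorted(treatments)}"
        )
    return sum(e.ratio_percent or 0.0 for e in entries)


def _symbol_coverage(
    profile: CoverageProfile, genes: Sequence[GeneRecord], source: str
) -> dict[str, float]:
    """Coverage per symbol, summed over all gene copies in one fraction."""
    totals: dict[str, float] = {}
    for gene in genes:
        if gene.source != source or gene.symbol is None:
            continue
        depth = profile.gene_mean_depth.get(gene.gene_id)
        if depth is None:
            raise DataValidationError(
                f"no coverage for {source} gene {gene.gene_id}"
            )
        totals[gene.symbol] = totals.get(gene.symbol, 0.0) + depth
    return totals


def build_potential_report(
    phage_profile: CoverageProfile,
    bacterial_profile: CoverageProfile,
    genes: Sequence[GeneRecord],
    rules: RuleSet = DEFAULT_RULES,
    amg_sets: Mapping[str, Sequence[str]] | None = None,
    treatment: str = "sample",
) -> list[PotentialReport]:
    """Per-AMG ratio entries and cumulative potentials for named AMG sets.

    Coverage for a symbol is summed over every gene copy bearing it
    (KEGG symbol, or CAZy family for CAZy-labelled genes) in each
    fraction. Symbols absent from both fractions yield undefined
    entries, flagged in the report. Sets reaching beyond the
    sequestration AMG list are allowed with a warning.
    """
    if amg_sets is None:
        amg_sets = DEFAULT_AMG_SETS
    phage_cov = _symbol_coverage(phage_profile, genes, "phage")
    bact_cov = _symbol_coverage(bacterial_profile, genes, "bacterial")
    reports = []
    for label, symbols in amg_sets.items():
        extra = set(symbols) - set(rules.sequestration_amg)
        if extra:
            warnings.warn(
                f"AMG set {label!r} includes symbols outside the "
                f"sequestration AMG list: {sorted(extra)}",
                stacklevel=2,
            )
        entries = [
            RatioEntry(
                amg_symbol=sym,
                treatment=treatment,
                phage_coverage=phage_cov.get(sym, 0.0),
                bacterial_coverage=bact_cov.get(sym, 0.0),
            )
            for sym in symbols
        ]
        reports.append(
            PotentialReport(
                treatment=treatment,
                amg_set_label=label,
                member_symbols=tuple(symbols),
                per_amg=entries,
            )
        )
    return reports


def write_potential_tsv(
    reports: Sequence[PotentialReport], path: str | Path
) -> None:
    """Per-symbol ratio table; undefined ratios are emitted as empty cells."""
    rows = []
    for rep in reports:
        for e in rep.per_amg:
            rows.append(
                {
                    "treatment": rep.treatment,
                    "amg_set": rep.amg_set_label,
                    "amg_symbol": e.amg_symbol,
                    "phage_coverage": e.phage_coverage,
                    "bacterial_coverage": e.bacterial_coverage,
                    "ratio_percent": (
                        "" if e.ratio_percent is None else repr(e.ratio_percent)
                    ),
                }
            )
    pd.DataFrame(
        rows,
        columns=[
            "treatment",
            "amg_set",
            "amg_symbol",
            "phage_coverage",
            "bacterial_coverage",
            "ratio_percent",
        ],
    ).to_csv(path, sep="\t", index=False)


def write_cumulative_tsv(
    reports: Sequence[PotentialReport], path: str | Path
) -> None:
    rows = [
        {
            "treatment": rep.treatment,
            "amg_set": rep.amg_set_label,
            "cumulative_percent": repr(rep.cumulative_percent),
            "undefined_symbols": ",".join(rep.undefined_symbols),
        }
        for rep in reports
    ]
    pd.DataFrame(
        rows,
        columns=["treatment", "amg_set", "cumulative_percent", "undefined_symbols"],
    ).to_csv(path, sep="\t", index=False)
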