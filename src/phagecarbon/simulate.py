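"""Seeded synthetic metagenome/virome fixtures with planted ground truth.

The generator emulates the inputs of a compost-soil phage AMG study at
desk scale: a bacterial contig fraction carrying carbon-metabolism genes
and CRISPR spacers, a phage fraction (every contig > 5 kb) carrying
auxiliary metabolic genes, spacer<->protospacer correspondences with a
controlled number of mismatches, shared homology segments at a
controlled identity, and single-end reads drawn uniformly along each
contig at a controlled expected depth.

Background sequence is i.i.d. uniform over A/C/G/T so planted signals
dominate; homology segments are copied then point-mutated (no indels,
matching the ungapped downstream matcher); reads are single-end since
only depth matters downstream. Every random draw derives from the
fixture seed, with one child stream per contig in a fixed order, so the
same spec yields byte-identical files and adding a contig does not
perturb earlier ones.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from phagecarbon._dna import mutate_positions, random_dna, reverse_complement
from phagecarbon.annotation import GeneRecord, write_annotations
from phagecarbon.coverage import AlignmentRecord, write_alignment_tsv
from phagecarbon.errors import DataValidationError, SizingError
from phagecarbon.hostlink import CrisprSpacer

_BASES = "ACGT"


@dataclass(frozen=True)
class GenePlan:
    """Plant ``copies`` genes labelled ``symbol`` in one fraction.

    ``kind`` says whether the symbol is a KEGG ortholog symbol or a CAZy
    family code; that controls which annotation column carries it.
    """

    symbol: str
    kind: str  # "kegg" | "cazy"
    source: str  # "bacterial" | "phage"
    copies: int = 1


@dataclass(frozen=True)
class SpacerPlan:
    """Plant a CRISPR spacer on a bacterial contig whose protospacer sits
    on a phage contig, with exactly ``mismatches`` substitutions between
    the two (0-2)."""

    bacterial_contig: str
    phage_contig: str
    length: int = 32  # typical CRISPR spacer lengths are 28-35 bp
    mismatches: int = 0


@dataclass(frozen=True)
class HomologyPlan:
    """Plant a shared segment: copied from the bacterial contig into the
    phage contig, point-mutated down to ``identity``."""

    bacterial_contig: str
    phage_contig: str
    length: int = 1_500
    identity: float = 0.95


#: Default study-like gene plan: bacterial CO2-fixation markers and CAZy
#: genes, plus phage sequestration AMGs with bacterial homologs for the
#: shared symbols.
DEFAULT_GENE_PLAN: tuple[GenePlan, ...] = (
    GenePlan("cbbL", "kegg", "bacterial"),
    GenePlan("oorA", "kegg", "bacterial"),
    GenePlan("nifJ", "kegg", "bacterial"),
    GenePlan("porA", "kegg", "bacterial"),
    GenePlan("GT2", "cazy", "bacterial"),
    GenePlan("GT4", "cazy", "bacterial"),
    GenePlan("GT6", "cazy", "bacterial"),
    GenePlan("GH16", "cazy", "bacterial"),
    GenePlan("CE4", "cazy", "bacterial"),
    GenePlan("pel", "kegg", "bacterial"),
    GenePlan("rfbE", "kegg", "bacterial"),
    GenePlan("ugd", "kegg", "bacterial"),
    GenePlan("GT6", "cazy", "phage"),
    GenePlan("GT11", "cazy", "phage"),
    GenePlan("GT4", "cazy", "phage"),
    GenePlan("aceF", "kegg", "phage"),
)

DEFAULT_SPACER_PLAN: tuple[SpacerPlan, ...] = (
    SpacerPlan("B0001", "P0001", length=32, mismatches=0),
    SpacerPlan("B0002", "P0002", length=33, mismatches=1),
    SpacerPlan("B0003", "P0003", length=30, mismatches=0),
)

DEFAULT_HOMOLOGY_PLAN: tuple[HomologyPlan, ...] = (
    HomologyPlan("B0004", "P0004", length=1_500, identity=0.95),
)

DEFAULT_TAXA: tuple[str, ...] = (
    "Proteobacteria",
    "Actinobacteria",
    "Acidobacteria",
    "Bacteroidetes",
)


@dataclass(frozen=True)
class FixtureSpec:
    """Everything that determines a fixture, including its seed."""

    seed: int = 0
    n_bacterial_contigs: int = 8
    n_phage_contigs: int = 5
    bacterial_length_range: tuple[int, int] = (8_000, 20_000)
    phage_length_range: tuple[int, int] = (6_000, 12_000)
    taxon_labels: tuple[str, ...] = DEFAULT_TAXA
    abundance_concentration: float = 5.0
    gene_plan: tuple[GenePlan, ...] = DEFAULT_GENE_PLAN
    spacer_plan: tuple[SpacerPlan, ...] = DEFAULT_SPACER_PLAN
    homology_plan: tuple[HomologyPlan, ...] = DEFAULT_HOMOLOGY_PLAN
    depth_plan: Mapping[str, float] | None = None
    base_depth: float = 20.0
    read_length: int = 150
    substitution_error_rate: float = 0.001
    gene_length_range: tuple[int, int] = (600, 1_500)

    def validate(self) -> None:
        if self.n_bacterial_contigs < 0 or self.n_phage_contigs < 0:
            raise DataValidationError("contig counts must be nonnegative")
        for lo, hi in (
            self.bacterial_length_range,
            self.phage_length_range,
            self.gene_length_range,
        ):
            if not (0 < lo <= hi):
                raise DataValidationError(f"invalid length range ({lo}, {hi})")
        if self.phage_length_range[0] <= 5_000:
            raise DataValidationError(
                "phage contigs must be longer than 5,000 bp; the lower "
                f"bound {self.phage_length_range[0]} is too small"
            )
        if not (0.0 <= self.substitution_error_rate < 1.0):
            raise DataValidationError("error rate must be in [0, 1)")
        if self.abundance_concentration <= 0:
            raise DataValidationError("abundance_concentration must be > 0")
        if self.read_length <= 0:
            raise DataValidationError("read_length must be positive")
        if self.depth_plan is not None and any(
            d < 0 for d in self.depth_plan.values()
        ):
            raise DataValidationError("depth targets must be >= 0")
        for sp in self.spacer_plan:
            if not (0 <= sp.mismatches <= 2):
                raise DataValidationError("planted spacer mismatches must be 0-2")
            if not (20 <= sp.length <= 60):
                raise DataValidationError("spacer length must be in [20, 60]")
        for hp in self.homology_plan:
            if not (0.0 < hp.identity <= 1.0) or hp.length <= 0:
                raise DataValidationError("invalid homology plan")

    def bacterial_ids(self) -> list[str]:
        return [f"B{i + 1:04d}" for i in range(self.n_bacterial_contigs)]

    def phage_ids(self) -> list[str]:
        return [f"P{i + 1:04d}" for i in range(self.n_phage_contigs)]


@dataclass(frozen=True)
class TrueLink:
    phage_contig: str
    bacterial_contig: str
    mechanism: str  # "spacer" | "homology"
    mismatches: int | None = None
    identity: float | None = None
    length: int | None = None


@dataclass
class GroundTruth:
    """What was actually planted, for parameter-recovery tests."""

    true_links: list[TrueLink] = field(default_factory=list)
    true_gene_coverage: dict[str, float] = field(default_factory=dict)
    true_community: dict[str, float] = field(default_factory=dict)
    true_ratio: dict[str, float] = field(default_factory=dict)

    def link_set(self) -> set[tuple[str, str, str]]:
        return {
            (l.phage_contig, l.bacterial_contig, l.mechanism)
            for l in self.true_links
        }


@dataclass
class FixtureBundle:
    spec: FixtureSpec
    bacterial_contigs: dict[str, str]
    phage_contigs: dict[str, str]
    genes: list[GeneRecord]
    spacers: list[CrisprSpacer]
    alignments: list[AlignmentRecord]
    reads: dict[str, str]
    ground_truth: GroundTruth
    taxonomy: dict[str, str] = field(default_factory=dict)
    depth_plan: dict[str, float] = field(default_factory=dict)

    @property
    def contig_lengths(self) -> dict[str, int]:
        out = {c: len(s) for c, s in self.bacterial_contigs.items()}
        out.update({c: len(s) for c, s in self.phage_contigs.items()})
        return out


def _rng(*key: int) -> np.random.Generator:
    return np.random.default_rng(list(key))


def _place_interval(
    rng: np.random.Generator,
    contig_len: int,
    seg_len: int,
    reserved: list[tuple[int, int]],
    tries: int = 200,
    margin: int = 0,
) -> int | None:
    """A start position for a segment avoiding reserved intervals.

    ``margin`` keeps the segment away from contig ends (used for genes,
    where read-sampling depth falls off near the edges).
    """
    if seg_len + 2 * margin > contig_len:
        return None
    for _ in range(tries):
        start = int(rng.integers(margin, contig_len - seg_len - margin + 1))
        end = start + seg_len
        if all(end <= lo or start >= hi for lo, hi in reserved):
            reserved.append((start, end))
            return start
    return None


def simulate_reads(
    contig_id: str,
    sequence: str,
    mean_depth: float,
    read_length: int,
    error_rate: float,
    rng: np.random.Generator,
) -> tuple[list[AlignmentRecord], dict[str, str]]:
    """Uniform single-end reads at a target expected depth.

    The read count is Poisson with mean ``depth * L / read_length`` so
    realized depth matches the target in expectation; substitution
    errors are applied per base with probability ``error_rate``. The
    returned alignment records are truth (no realignment step).
    """
    length = len(sequence)
    if read_length > length:
        raise SizingError(
            f"contig {contig_id}: read length {read_length} exceeds contig "
            f"length {length}"
        )
    if mean_depth < 0:
        raise DataValidationError("mean_depth must be >= 0")
    n_reads = int(rng.poisson(mean_depth * length / read_length))
    alignments: list[AlignmentRecord] = []
    reads: dict[str, str] = {}
    for j in range(n_reads):
        start = int(rng.integers(0, length - read_length + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        seq = sequence[start : start + read_length]
        if strand == "-":
            seq = reverse_complement(seq)
        if error_rate > 0:
            err_pos = np.nonzero(rng.random(read_length) < error_rate)[0]
            if err_pos.size:
                seq = mutate_positions(seq, err_pos.tolist(), rng)
        read_id = f"{contig_id}_r{j:06d}"
        reads[read_id] = seq
        alignments.append(
            AlignmentRecord(read_id, contig_id, start, read_length, strand)
        )
    return alignments, reads


def _plant_genes(
    spec: FixtureSpec,
    contigs: dict[str, str],
    reserved: dict[str, list[tuple[int, int]]],
    rng: np.random.Generator,
) -> list[GeneRecord]:
    margin = spec.read_length
    by_fraction = {
        "bacterial": spec.bacterial_ids(),
        "phage": spec.phage_ids(),
    }
    cursor = {"bacterial": 0, "phage": 0}
    genes: list[GeneRecord] = []
    gid = 0
    for plan in spec.gene_plan:
        pool = by_fraction[plan.source]
        if not pool:
            raise SizingError(
                f"gene {plan.symbol}: no {plan.source} contigs to host it"
            )
        for _ in range(plan.copies):
            glen = int(rng.integers(*spec.gene_length_range, endpoint=True))
            placed = None
            for attempt in range(len(pool)):
                cid = pool[(cursor[plan.source] + attempt) % len(pool)]
                start = _place_interval(
                    rng, len(contigs[cid]), glen, reserved[cid], margin=margin
                )
                if start is not None:
                    placed = (cid, start)
                    cursor[plan.source] += attempt + 1
                    break
            if placed is None:
                raise SizingError(
                    f"gene {plan.symbol} ({glen} bp): no {plan.source} contig "
                    f"has room (tried {', '.join(pool)})"
                )
            cid, start = placed
            gid += 1
            genes.append(
                GeneRecord(
                    gene_id=f"G{gid:04d}",
                    contig_id=cid,
                    source=plan.source,
                    start=start,
                    end=start + glen,
                    strand="+" if rng.random() < 0.5 else "-",
                    kegg_symbol=plan.symbol if plan.kind == "kegg" else None,
                    cazy_family=plan.symbol if plan.kind == "cazy" else None,
                )
            )
    return genes


def generate_fixture(spec: FixtureSpec) -> FixtureBundle:
    """Build a complete labelled fixture from a :class:`FixtureSpec`.

    Raises :class:`SizingError` (naming the contig) when a contig is too
    short to host a requested gene, spacer or homology segment.
    """
    spec.validate()
    seed = spec.seed

    # 1. contig sequences, one child stream each, fixed order
    contigs: dict[str, str] = {}
    all_ids = spec.bacterial_ids() + spec.phage_ids()
    for idx, cid in enumerate(all_ids):
        stream = _rng(seed, 1, idx)
        lo, hi = (
            spec.bacterial_length_range
            if cid.startswith("B")
            else spec.phage_length_range
        )
        length = int(stream.integers(lo, hi, endpoint=True))
        contigs[cid] = random_dna(stream, length)
    bacterial = {c: contigs[c] for c in spec.bacterial_ids()}
    phage = {c: contigs[c] for c in spec.phage_ids()}
    reserved: dict[str, list[tuple[int, int]]] = {c: [] for c in contigs}

    plant_rng = _rng(seed, 2)
    truth = GroundTruth()

    # 2. genes (coordinates only; background sequence is the gene body)
    genes = _plant_genes(spec, contigs, reserved, plant_rng)

    # 3. homology segments: copy from bacterium into phage, then mutate
    for hp in spec.homology_plan:
        if hp.bacterial_contig not in bacterial or hp.phage_contig not in phage:
            raise DataValidationError(
                f"homology plan names unknown contig "
                f"{hp.bacterial_contig}/{hp.phage_contig}"
            )
        b_seq = contigs[hp.bacterial_contig]
        b_start = _place_interval(
            plant_rng, len(b_seq), hp.length, reserved[hp.bacterial_contig]
        )
        if b_start is None:
            raise SizingError(
                f"contig {hp.bacterial_contig} too short for a {hp.length} bp "
                "homology segment"
            )
        segment = b_seq[b_start : b_start + hp.length]
        n_mut = int(round((1.0 - hp.identity) * hp.length))
        if n_mut:
            pos = plant_rng.choice(hp.length, size=n_mut, replace=False)
            segment = mutate_positions(segment, pos.tolist(), plant_rng)
        p_seq = contigs[hp.phage_contig]
        p_start = _place_interval(
            plant_rng, len(p_seq), hp.length, reserved[hp.phage_contig]
        )
        if p_start is None:
            raise SizingError(
                f"contig {hp.phage_contig} too short for a {hp.length} bp "
                "homology segment"
            )
        contigs[hp.phage_contig] = (
            p_seq[:p_start] + segment + p_seq[p_start + hp.length :]
        )
        phage[hp.phage_contig] = contigs[hp.phage_contig]
        truth.true_links.append(
            TrueLink(
                hp.phage_contig,
                hp.bacterial_contig,
                "homology",
                identity=1.0 - n_mut / hp.length,
                length=hp.length,
            )
        )

    # 4. CRISPR spacers: protospacer read from the phage, spacer written
    #    into the bacterial contig with exactly the planned mismatches
    spacers: list[CrisprSpacer] = []
    for si, sp in enumerate(spec.spacer_plan):
        if sp.bacterial_contig not in bacterial or sp.phage_contig not in phage:
            raise DataValidationError(
                f"spacer plan names unknown contig "
                f"{sp.bacterial_contig}/{sp.phage_contig}"
            )
        p_seq = contigs[sp.phage_contig]
        proto_start = _place_interval(
            plant_rng, len(p_seq), sp.length, reserved[sp.phage_contig]
        )
        if proto_start is None:
            raise SizingError(
                f"contig {sp.phage_contig} too short for a {sp.length} bp "
                "protospacer"
            )
        protospacer = p_seq[proto_start : proto_start + sp.length]
        spacer_seq = protospacer
        if sp.mismatches:
            pos = plant_rng.choice(sp.length, size=sp.mismatches, replace=False)
            spacer_seq = mutate_positions(protospacer, pos.tolist(), plant_rng)
        b_seq = contigs[sp.bacterial_contig]
        b_start = _place_interval(
            plant_rng, len(b_seq), sp.length, reserved[sp.bacterial_contig]
        )
        if b_start is None:
            raise SizingError(
                f"contig {sp.bacterial_contig} too short to carry a "
                f"{sp.length} bp spacer"
            )
        contigs[sp.bacterial_contig] = (
            b_seq[:b_start] + spacer_seq + b_seq[b_start + sp.length :]
        )
        bacterial[sp.bacterial_contig] = contigs[sp.bacterial_contig]
        spacers.append(
            CrisprSpacer(f"S{si + 1:04d}", sp.bacterial_contig, spacer_seq)
        )
        truth.true_links.append(
            TrueLink(
                sp.phage_contig,
                sp.bacterial_contig,
                "spacer",
                mismatches=sp.mismatches,
            )
        )

    # 5. community structure and per-contig depth targets
    taxonomy = {
        cid: spec.taxon_labels[i % len(spec.taxon_labels)]
        for i, cid in enumerate(spec.bacterial_ids())
    }
    if spec.depth_plan is not None:
        depth_plan = dict(spec.depth_plan)
        for cid in contigs:
            depth_plan.setdefault(cid, 0.0)
    else:
        comm_rng = _rng(seed, 3)
        n_tax = len(spec.taxon_labels)
        tax_w = comm_rng.dirichlet([spec.abundance_concentration] * n_tax)
        depth_plan = {}
        for cid in spec.bacterial_ids():
            w = tax_w[spec.taxon_labels.index(taxonomy[cid])]
            depth_plan[cid] = spec.base_depth * w * n_tax
        if spec.n_phage_contigs:
            ph_w = comm_rng.dirichlet(
                [spec.abundance_concentration] * spec.n_phage_contigs
            )
            for i, cid in enumerate(spec.phage_ids()):
                depth_plan[cid] = spec.base_depth * ph_w[i] * spec.n_phage_contigs
    mass = {
        tax: sum(
            depth_plan[cid] * len(contigs[cid])
            for cid in spec.bacterial_ids()
            if taxonomy[cid] == tax
        )
        for tax in spec.taxon_labels
    }
    total_mass = sum(mass.values())
    depth_plan = {c: float(d) for c, d in depth_plan.items()}
    if total_mass > 0:
        truth.true_community = {t: float(m / total_mass) for t, m in mass.items()}

    # 6. reads, one child stream per contig in the same fixed order
    alignments: list[AlignmentRecord] = []
    reads: dict[str, str] = {}
    for idx, cid in enumerate(all_ids):
        alns, rds = simulate_reads(
            cid,
            contigs[cid],
            depth_plan.get(cid, 0.0),
            spec.read_length,
            spec.substitution_error_rate,
            _rng(seed, 4, idx),
        )
        alignments.extend(alns)
        reads.update(rds)

    # 7. remaining ground truth
    for gene in genes:
        truth.true_gene_coverage[gene.gene_id] = depth_plan.get(
            gene.contig_id, 0.0
        )
    symbol_depth: dict[str, dict[str, float]] = {}
    for gene in genes:
        if gene.symbol is None:
            continue
        frac = symbol_depth.setdefault(gene.symbol, {"phage": 0.0, "bacterial": 0.0})
        frac[gene.source] += depth_plan.get(gene.contig_id, 0.0)
    for sym, frac in symbol_depth.items():
        total = frac["phage"] + frac["bacterial"]
        if total > 0:
            truth.true_ratio[sym] = float(frac["phage"] / total)

    return FixtureBundle(
        spec=spec,
        bacterial_contigs=bacterial,
        phage_contigs=phage,
        genes=genes,
        spacers=spacers,
        alignments=alignments,
        reads=reads,
        ground_truth=truth,
        taxonomy=taxonomy,
        depth_plan=depth_plan,
    )


def _write_fasta(records: Mapping[str, str], path: Path) -> None:
    seq_records = [
        SeqRecord(Seq(seq), id=name, description="") for name, seq in records.items()
    ]
    with path.open("w") as handle:
        writer = SeqIO.FastaIO.FastaWriter(handle, wrap=80)
        writer.write_file(seq_records)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def write_fixture(bundle: FixtureBundle, directory: str | Path) -> dict[str, str]:
    """Serialise a fixture to a directory; returns {filename: sha256}.

    Files are written only when they have content; the ground-truth file
    and the manifest are always present. Coordinates are 0-based
    half-open throughout; FASTA is wrapped at 80 columns.
    """
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit(name: str, writer) -> None:
        path = directory / name
        writer(path)
        written.append(path)

    if bundle.bacterial_contigs:
        emit("bacterial.fasta", lambda p: _write_fasta(bundle.bacterial_contigs, p))
    if bundle.phage_contigs:
        emit("phage.fasta", lambda p: _write_fasta(bundle.phage_contigs, p))
    if bundle.reads:
        emit("reads.fasta", lambda p: _write_fasta(bundle.reads, p))
    if bundle.genes:
        emit("genes.tsv", lambda p: write_annotations(bundle.genes, p))
    if bundle.spacers:

        def write_spacers(p: Path) -> None:
            with p.open("w") as fh:
                fh.write("spacer_id\tbacterial_contig\tsequence\n")
                for s in bundle.spacers:
                    fh.write(f"{s.spacer_id}\t{s.bacterial_contig}\t{s.sequence}\n")

        emit("spacers.tsv", write_spacers)
    if bundle.alignments:
        emit("alignments.tsv", lambda p: write_alignment_tsv(bundle.alignments, p))
    if getattr(bundle, "taxonomy", None):

        def write_taxonomy(p: Path) -> None:
            with p.open("w") as fh:
                fh.write("contig_id\ttaxon\n")
                for cid in sorted(bundle.taxonomy):
                    fh.write(f"{cid}\t{bundle.taxonomy[cid]}\n")

        emit("taxonomy.tsv", write_taxonomy)

    truth = bundle.ground_truth
    payload = {
        "true_links": [
            {
                "phage_contig": l.phage_contig,
                "bacterial_contig": l.bacterial_contig,
                "mechanism": l.mechanism,
                "mismatches": l.mismatches,
                "identity": l.identity,
                "length": l.length,
            }
            for l in truth.true_links
        ],
        "true_gene_coverage": truth.true_gene_coverage,
        "true_community": truth.true_community,
        "true_ratio": truth.true_ratio,
        "depth_plan": getattr(bundle, "depth_plan", {}),
    }
    emit(
        "ground_truth.json",
        lambda p: p.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n"),
    )

    manifest = {p.name: _sha256(p) for p in written}
    with (directory / "manifest.tsv").open("w") as fh:
        fh.write("file\tsha256\n")
        for name in sorted(manifest):
            fh.write(f"{name}\t{manifest[name]}\n")
    return manifest


def fixture_from_symbol_coverages(
    symbol_coverages: Mapping[str, tuple[float, float]],
    seed: int = 0,
    kinds: Mapping[str, str] | None = None,
) -> FixtureBundle:
    """A fixture planting one gene per symbol per fraction at set coverages.

    ``symbol_coverages`` maps each gene symbol to its target
    (phage coverage, bacterial coverage); a gene is planted in a
    fraction only when its coverage there is positive, each on its own
    contig whose depth target equals the requested coverage. ``kinds``
    may force "kegg"/"cazy" per symbol; by default CAZy-style codes
    (letters + digits with a known class prefix) are treated as CAZy
    families.
    """
    from phagecarbon.annotation import cazy_prefix

    def kind_of(sym: str) -> str:
        if kinds and sym in kinds:
            return kinds[sym]
        prefix = cazy_prefix(sym)
        if prefix in {"GT", "GH", "PL", "CE", "AA"} and prefix != sym:
            return "cazy"
        return "kegg"

    plans: list[GenePlan] = []
    depth_by_plan: list[float] = []
    for source, col in (("phage", 0), ("bacterial", 1)):
        for sym in sorted(symbol_coverages):
            cov = symbol_coverages[sym][col]
            if cov > 0:
                plans.append(GenePlan(sym, kind_of(sym), source))
                depth_by_plan.append(float(cov))
    n_phage = sum(1 for p in plans if p.source == "phage")
    n_bact = len(plans) - n_phage
    spec = FixtureSpec(
        seed=seed,
        n_bacterial_contigs=max(n_bact, 1),
        n_phage_contigs=max(n_phage, 1),
        gene_plan=tuple(plans),
        spacer_plan=(),
        homology_plan=(),
        depth_plan={},  # filled below; start all-zero
    )
    # single-copy plans place round-robin, so the i-th plan of a fraction
    # lands on that fraction's i-th contig
    depth_plan: dict[str, float] = {
        cid: 0.0 for cid in spec.bacterial_ids() + spec.phage_ids()
    }
    cursors = {"phage": iter(spec.phage_ids()), "bacterial": iter(spec.bacterial_ids())}
    for plan, depth in zip(plans, depth_by_plan):
        depth_plan[next(cursors[plan.source])] = depth
    bundle = generate_fixture(replace(spec, depth_plan=depth_plan))
    planted = {
        (g.symbol, g.source): bundle.depth_plan[g.contig_id] for g in bundle.genes
    }
    for sym, (p_cov, b_cov) in symbol_coverages.items():
        for source, want in (("phage", p_cov), ("bacterial", b_cov)):
            if want > 0 and abs(planted[(sym, source)] - want) > 1e-9:
                raise DataValidationError(
                    f"planted coverage for {sym}/{source} does not match plan"
                )
    return bundle


def profiles_from_truth(bundle: FixtureBundle):
    """Coverage profiles taken from the planted per-gene depths.

    Returns (phage profile, bacterial profile) whose per-gene mean
    depths are the fixture's planted ground-truth coverages — the
    deterministic counterpart of read-level coverage estimation.
    """
    from phagecarbon.coverage import CoverageProfile

    profiles = {}
    for source in ("phage", "bacterial"):
        genes = [g for g in bundle.genes if g.source == source]
        profiles[source] = CoverageProfile(
            sample_id=f"truth.{source}",
            gene_mean_depth={
                g.gene_id: bundle.ground_truth.true_gene_coverage[g.gene_id]
                for g in genes
            },
            gene_read_count={g.gene_id: 1 for g in genes},
            total_mapped_reads=max(len(genes), 1),
            gene_rpkm={g.gene_id: 0.0 for g in genes},
        )
    return profiles["phage"], profiles["bacterial"]


def read_spacer_tsv(path: str | Path) -> list[CrisprSpacer]:
    """Read the spacer table (spacer_id, bacterial_contig, sequence)."""
    spacers = []
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["spacer_id", "bacterial_contig", "sequence"]:
            raise DataValidationError(f"{path}: unexpected spacer header {header}")
        for i, line in enumerate(fh):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 3:
                raise DataValidationError(f"{path} line {i + 2}: malformed row")
            spacers.append(CrisprSpacer(*parts))
    return spacers


def read_fasta(path: str | Path) -> dict[str, str]:
    return {
        rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")
    }


def read_taxonomy_tsv(path: str | Path) -> dict[str, str]:
    taxonomy = {}
    with Path(path).open() as fh:
        header = fh.readline().rstrip("\n").split("\t")
        if header != ["contig_id", "taxon"]:
            raise DataValidationError(f"{path}: unexpected taxonomy header {header}")
        for line in fh:
            cid, taxon = line.rstrip("\n").split("\t")
            taxonomy[cid] = taxon
    return taxonomy


def read_ground_truth(path: str | Path) -> GroundTruth:
    data = json.loads(Path(path).read_text())
    return GroundTruth(
        true_links=[
            TrueLink(
                l["phage_contig"],
                l["bacterial_contig"],
                l["mechanism"],
                mismatches=l.get("mismatches"),
                identity=l.get("identity"),
                length=l.get("length"),
            )
            for l in data["true_links"]
        ],
        true_gene_coverage=data["true_gene_coverage"],
        true_community=data["true_community"],
        true_ratio=data["true_ratio"],
    )
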