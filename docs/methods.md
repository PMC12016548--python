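# Methods

## Scope and model

`phagecarbon` implements the computational core of a paired
metagenome/virome analysis of phage contributions to soil carbon
metabolism. It deliberately starts *after* assembly, gene prediction and
database annotation: contig FASTA, a gene-annotation table (KEGG symbol
and/or CAZy family per gene), read alignments and CRISPR spacer tables
are inputs. Assembly, ORF calling, DIAMOND/eggNOG/CAZy searches, AMG
calling, taxonomy assignment and biomarker (LEfSe) analysis are out of
scope; where their outputs matter (e.g. which AMG symbols are
"enriched"), they enter as configuration.

## Carbon-category classification

A gene's category is decided by, in order: (1) explicit symbol-set
membership — the sequestration marker genes {cbbL, acsA, acsB, oorA,
nifJ, porA, aclB}, the sequestration AMG symbols {aceF, glmS, gltA,
GT11, GT2, GT4, GT6}, the transformation symbols {rfbE, wbpD, ugd,
pgl}, the decomposition symbol {pel}; (2) the CAZy class prefix — GT →
sequestration; GH/PL/CE/AA → decomposition. The prefix is parsed as the
longest leading alphabetic run, so subfamily codes like `AA3_2` resolve
to `AA`. Symbol sets take precedence over the prefix map (irrelevant
with the defaults, which are disjoint by construction and validated as
such). Anything unmatched is *unclassified* and passes through, because
real AMG tables carry non-carbon genes too. All sets are overridable
via configuration; the defaults are pinned by table-driven tests.

*aceF* carries no CAZy family and is classified sequestration purely by
symbol-set membership.

## Phage–host linkage

**Spacer matching.** The operative definition is full-length, ungapped
spacer alignment with a Hamming budget (default ≤ 1 substitution, i.e.
100% coverage, no indels). Stated threshold triplets of the form
"≤1 mismatch, 100% identity, 100% coverage" are internally tense — a
mismatch is not 100% identity — and this package resolves them in the
standard way: coverage is exact, identity is relaxed by the mismatch
budget. Both strands are searched (whether reverse-strand protospacers
were counted in comparable published pipelines is usually unstated; the
strand is recorded in the output so they can be filtered). The matcher
is a vectorised sliding-window comparison and is tested for exact
equality against a brute-force Hamming scan.

**Homology matching.** Ungapped local matches seeded by shared 21-mers,
merged per diagonal, extended with an X-drop rule (+1 match, −1
mismatch, stop 30 below the running maximum, trim to the score argmax),
then thresholded at identity ≥ 0.90 and length ≥ 1,000 bp. Identity of
a reported segment is matches/length over the trimmed interval;
segments are reported in bacterial coordinates and both phage strands
are searched. This is intentionally not a gapped aligner: at ≥ 90%
identity over ≥ 1 kb, ungapped seed-and-extend is deterministic,
dependency-free and recovers planted segments with identity within one
point of truth (verified over seeds). Lowering either threshold or
raising the mismatch budget can only add links (monotonicity is
property-tested).

**Host range.** Links from both mechanisms are pooled per phage.
Repeated (phage, bacterium) evidence is retained in full but counts
once toward the host-taxon set; bacterial contigs without a taxonomy
entry form a single "unknown" pseudo-taxon. Breadth is specialist
(exactly one taxon) vs generalist (two or more). Phages with no links
are omitted from ranges, and summaries report counts and cumulative
relative abundance per breadth class.

## Coverage, abundance, diversity

Per-base depth is a pileup (difference-array cumulative sum; exact
conservation Σ depth = Σ aligned bases is asserted in tests). Gene
coverage is the mean depth over the gene interval. A read partially
overlapping a gene counts fully toward its read count but only its
overlapping bases toward depth; this keeps RPKM integer-count based
while depth remains a per-base quantity. RPKM =
`count / (length/1e3) / (total_mapped/1e6)` with total mapped reads =
all primary mapped records of the fraction. SAM input is restricted to
mapped, primary, non-supplementary records; reference span consumes
M/=/X/D and ignores I/S (delegated to pysam). Relative-abundance
normalisation is emitted per fraction — consumers can renormalise over
any gene subset they care about, since the appropriate denominator
(all genes vs carbon genes) is a reporting choice, not a property of
the data.

Alpha diversity delegates to scikit-bio: observed richness,
bias-corrected Chao1 `S_obs + F1(F1−1)/(2(F2+1))` (robust when F2 = 0;
equals richness when F1 = 0), Shannon with natural log, Pielou
H/ln(S). Pielou for a single-taxon community is reported as missing,
not 0. Closed-form hand checks (even community → H = ln 4, Pielou = 1;
counts {1,1,2,5} → Chao1 = 4.5) serve as the independent oracle.

## Sequestration potential

For one AMG symbol and treatment, coverages are summed over all gene
copies per fraction *before* the ratio (one ratio per symbol per
treatment, matching a one-bar-per-AMG presentation). The ratio is
phage/(phage+bacterial); 0/0 is undefined, contributes 0 to cumulative
sums, and is flagged explicitly — an all-absent AMG set legitimately
reports a cumulative of literally 0. The cumulative potential is the
plain sum of per-symbol percentages, as defined; it may exceed 100% and
no per-pathway averaging is attempted. Matching between fractions is by
symbol (KEGG symbol, else CAZy family); the matching key is whatever
appears in the annotation table for both fractions. Default symbol
sets: all = {aceF, glmS, gltA, GT11, GT2, GT4, GT6}, enriched = {GT11,
GT6, aceF}, non-enriched = {glmS, gltA, GT2, GT4}; since enriched and
non-enriched partition "all", cumulative(all) = cumulative(enriched) +
cumulative(non-enriched) to rounding, which is asserted as an invariant.
Human-readable summaries print one decimal place; machine TSVs keep
full precision. No between-treatment significance test is offered for
this statistic (it is a point estimate by construction).

## Synthetic fixtures

The generator plants every signal the pipeline is supposed to detect:

- **Background**: i.i.d. uniform A/C/G/T, so planted features dominate
  and collision probabilities are calculable (a 21-mer seed collision
  has probability 4⁻²¹ per position pair; spurious ≥1 kb homology is
  effectively impossible).
- **Contigs**: default 8 bacterial (8–20 kb) and 5 phage (6–12 kb,
  respecting the >5 kb phage definition), desk-scale stand-ins for
  assemblies of tens of thousands of contigs.
- **Genes**: coordinates reserved without overlap, lengths 600–1,500 bp,
  kept one read length away from contig ends because uniform read
  placement depresses depth there. The default plan mirrors the study
  system: bacterial CO2-fixation markers, GT/GH/CE families and
  transformation genes; phage copies of GT6, GT11, GT4 and aceF.
- **Spacers**: 28–35 bp (typical CRISPR spacers; lengths are otherwise
  unconstrained by the source system), protospacer read from the phage
  contig, spacer written into the bacterial contig after exactly the
  requested number of substitutions (Hamming distance is brute-force
  verified in tests).
- **Homology**: copy-then-point-mutate to the requested identity; no
  indels, matching the ungapped matcher.
- **Community / depth**: taxa are assigned round-robin to bacterial
  contigs; absent an explicit depth plan, per-taxon Dirichlet weights
  (concentration 5, a moderately uneven soil-like community) scale a
  base depth of 20×. Ground-truth community abundance is
  depth×length mass per taxon, normalised.
- **Reads**: single-end (a 2×150 bp layout adds nothing once alignment
  records are the input — only depth matters downstream), length
  150 bp, substitution errors at 10⁻³/base, count Poisson with mean
  depth·L/ℓ so realized depth is unbiased; alignment records are
  emitted as truth with no realignment step.
- **Determinism**: one child RNG stream per contig, keyed (seed, stage,
  contig index) in a fixed order; same spec + seed ⇒ byte-identical
  files (manifest checksums compared in tests).

What the fixtures do *not* model: FASTQ quality scores, insert-size
structure, chimeras, assembly artefacts, gapped homology, real genome
composition (GC skew, repeats), or distinct free-phage vs induced
prophage fractions (a single phage fraction stands for their pool, and
lifestyle does not modulate depth). Passing recovery tests therefore
demonstrates correctness of the statistics on clean planted signal, not
robustness to misassembly or annotation error in field data.

## Numerical and testing choices

- Coordinates are 0-based half-open everywhere; FASTA wrapped at 80
  columns; tables are TSV with one header line.
- Read-level parameter recovery is stochastic: per-AMG ratios recovered
  from simulated reads are required to sit within 0.05 (absolute, on
  the [0,1] ratio scale) of planted truth after averaging over 10
  seeded fixtures with planted depths ≥ 10×; planted spacer and
  homology links must be recovered with precision = recall = 1 at
  matching thresholds.
- The worked-example reproduction of per-AMG ratio sets is driven
  through the report builder from planted per-gene coverages, which is
  exact and deterministic; read-sampling noise is exercised by the
  recovery tests above, not here.
- Problem sizes throughout (contig counts and lengths, ~24k simulated
  reads per fixture, 10–20 seeds per calibration test) are chosen so
  the whole suite runs in well under a minute on one CPU while keeping
  Poisson counting error an order of magnitude below every tolerance.
- Degenerate inputs fail loudly with typed errors (config vs data
  validation vs sizing), mapped to distinct CLI exit codes (2/3/4);
  empty plans, zero depth, all-zero abundance vectors and single-taxon
  communities are all defined cases with tested behaviour.

## Known limitations

- Symbol-level matching between fractions assumes consistent annotation
  vocabularies across the two assemblies; a homolog annotated to a
  different CAZy subfamily will not pair.
- The homology matcher reports ungapped segments only; true homologs
  with indels longer than the X-drop tolerance are split or missed —
  acceptable at the ≥90%/≥1 kb operating point, not below it.
- Cumulative potential inherits the coverage estimator's bias at very
  low depth; ratios for genes below ~10× depth are noisy and should be
  read with the recovery tolerance in mind.
- Treatment labels are carried, not inferred; replicate-level variance
  modelling is intentionally absent.
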