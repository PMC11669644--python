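# Methods

`momfkit` re-implements, as a tested reusable pipeline, a family of bespoke
procedures used to characterise skin monocyte/macrophage (MOMF) subtypes in
single-cell transcriptomes: detection-rate cluster isolation, signature-based
subtype identity scoring, marker-gate capture analysis, an in-silico coculture
ligand screen, and embedding-proximity pseudobulking for a pan-tissue identity
atlas. This note describes the models and the choices made where the design
was genuinely open.

## Cell QC and the expressed-gene rule

Cells are retained when their detected-gene count (genes with UMI ≥ 1) lies in
[200, 5000] and their mitochondrial UMI fraction is strictly below 10%. The
gene-count bounds are read as inclusive and the mitochondrial bound as strict,
following the literal phrasing of the two rules ("between 200 and 5000",
"less than 10%"). Mitochondrial genes are recognised by the lower-case mouse
prefix `mt-`. A cell with zero total UMI has its fraction defined as 0 and is
removed. QC is idempotent.

A gene is *expressed* in a group when it is detected (UMI ≥ 1) in at least 10%
of the group's cells; the boundary is inclusive (1 detection in 10 cells
qualifies). This rule is monotone in the threshold.

## MOMF cluster isolation

Clustering itself is an input (truth labels in tests, or any standard
graph-clustering result); the package only classifies clusters. A cluster is
MOMF iff the detection rate of *Csf1r* or *Adgre1* exceeds 50%, or *Cd68*
exceeds 60%, or *Cd207* exceeds 40%; all thresholds strict. The *Cd207* arm
can be switched off (`use_cd207=False`) for archived datasets where the
Langerhans-cell marker is unreliable. Detection for classification uses raw
UMI ≥ 1, consistent with the expressed-gene rule. Marker symbols are matched
case-sensitively with a case-insensitive fallback that logs a warning, because
archived matrices vary in capitalisation; a missing marker counts as 0%
detection.

## Subtype identity score

Given disjoint signature gene lists per subtype (S1…S5; any user-supplied set
is accepted), each cell is scored in three steps on log-normalized expression
(counts per `scale_total` = 10⁴, log1p):

1. every signature gene's expression vector is scaled across the whole cell
   population — z-scoring by default, which equalises each gene's
   contribution by standardising its variance (population min-max scaling is
   available via `gene_scaling="minmax"`, and raw-count scoring via the
   normalization step being optional);
2. per cell, the subtype score is the mean of its signature genes' scaled
   values;
3. each subtype's score vector is min-max rescaled over the population to
   [0, 1], so every non-degenerate column attains exactly 0 and exactly 1.

Signature genes absent from the matrix are dropped with a warning (a subtype
losing all of its genes is an error); genes constant across the population
carry no population-relative information and are likewise dropped. A score
column that ends up constant is flagged degenerate and set to 0. Assignment
is the argmax column, with ties broken by the signature order (S1 < S2 < …)
for determinism.

Because the score is population-relative, scores are only comparable within
one scored population: re-scoring a subset of cells changes values. The test
suite asserts this as a property rather than treating it as a bug, and the
intended use is to isolate macrophages inclusively before scoring.

Marker gates select cells on raw UMI: every negative marker at 0 UMI and the
positive markers under an any/all rule (flow notation `Folr2/Cd163+` is
"any"). The capture table reports, per gate, the member count, the fraction of
gated cells assigned to each subtype, and the gate pseudo-bulk's mean subtype
scores — both readings of "capture" so that either can be compared against
published gate percentages.

## In-silico coculture ligand screen

From an annotated ligand-receptor table, a ligand is eligible when at least
one of its receptors is in the macrophage expressed-gene set. Eligible ligand
expression is summarised per cell type as the mean of normalized expression
(detection rate available via `statistic="detection"`). A coculture design's
ligand content is the **sum** of its member types' summaries, so content is
additive over any partition of the members. Contents are compared between
phenotype-inductive and non-inductive designs (at least two of each):
fold-change = mean(inductive)/mean(non-inductive), p-value from Welch's
two-sided two-sample t test, and a ligand is shortlisted iff fold-change > 3,
p < 0.05 and the inductive mean exceeds the non-inductive mean. Welch's
unpaired two-sided variant was chosen as the most conservative reading of an
unspecified "t test"; a zero denominator gets a pseudocount ε = 10⁻⁹ and an
explicit flag; contents constant in both classes give p = 1 and are never
shortlisted.

## UMAP-proximity pseudobulking and atlas integration

Each sample (tissue-condition) is summarised to `n_target` = 100 pseudobulks.
The nominal cells-per-pseudobulk is the pseudobulking factor ⌈n/100⌉. A fixed
size of ⌈n/100⌉ and an exact count of 100 are mutually inconsistent unless
100 divides n; the implementation prioritises the exact pseudobulk count and
uses balanced sizes differing by at most 1 (the larger sizes equal the
factor, so no pseudobulk ever exceeds it). Each iteration draws a random seed
cell uniformly from the not-yet-aggregated cells and pools it with its
nearest unaggregated neighbours by Euclidean distance in the 2-D embedding,
ties broken by cell-index order. The result is a partition of the sample:
transcripts are conserved exactly, and pseudobulk subtype characters are
arithmetic means of member-cell scores (hence bounded by the members' range).
The iteration is deterministic under an explicit RNG seed, which the package
requires. With fewer cells than the target, one pseudobulk per cell is
emitted with a warning.

Atlas integration restricts all samples' pseudobulks to the intersection of
per-sample expressed-gene sets, normalizes (counts-per-10⁴, log1p) and
optionally mean-centres each sample's block. The mean-centring is a
deliberately simple, clearly labelled stand-in at the interface point where a
mutual-nearest-neighbour batch correction would sit; it is off by default.
Atlas re-embedding is delegated to a standard reducer (scanpy neighbors +
UMAP) and its parameters and seed are recorded on the result rather than
reimplemented.

## Synthetic data generator

The generator exists so the pipeline is fully testable with planted ground
truth, and its defaults define the study conditions used throughout the test
suite:

| parameter | default | rationale |
| --- | --- | --- |
| genes | 1500 | enough baseline-expressed genes that healthy cells clear the 200-detected-gene QC floor |
| cell types | 5 MOMF subtypes × 200 cells + fibroblast/keratinocyte/endothelial/T cell | leukocyte-enriched skin with ~⅓ non-hematopoietic cells |
| signature genes | 81 per subtype (405 total), fold-elevation 8 | matches the scale of a 405-gene five-subtype signature |
| baseline mean | 0.2 UMI/gene/cell | sparse droplet-style counts (~18% detection per gene) |
| NB dispersion | 2 (variance = μ + μ²/2) | typical droplet scRNA-seq overdispersion; mean/dispersion parameterisation keeps the dispersion interpretable |
| mito genes | 13 `mt-` genes, per-cell expected fraction U(0.02, 0.08) | mouse mtDNA protein genes; healthy cells mostly below the 10% QC bound, with NB noise pushing a realistic few percent of cells over it |
| MOMF markers | Csf1r/Adgre1/Cd68 ×25 in all subtypes, Cd207 ×25 in S5 only; Folr2/Cd163 ×25 in S1, Ly6c1/2 ×25 in S3 | detection rates well clear of the 50/60/40% rules; gate analyses have real targets |
| ligands | one fibroblast-restricted ligand ×20, receptor ×10 on MOMF; decoys = ½ of planted pairs | a cell-type-specific niche factor strong enough to behave like a real hit; decoy receptors are set to zero in MOMF cells so "absent receptor" is unambiguous |
| samples | 3, conditions cycling healthy/AD, optional per-sample library-size factors | minimal multi-sample structure for the atlas |

Counts are NB draws per gene per cell; the planted elevations are
multiplicative on the baseline mean. The embedding used by unit tests is
simulated from truth (Gaussian blobs on a circle of radius 10), not computed
from counts — this decouples pseudobulking correctness from embedding
quality; integration-style runs can instead delegate to a real reducer.

What the generator does **not** emulate: doublets, ambient RNA, read-level
(FASTQ) structure, gene-gene correlation within a cell beyond the type means,
batch effects beyond library-size shifts, or continuous differentiation
trajectories. Passing tests therefore demonstrate correctness of the
procedures under the stated statistical model, not robustness to every
artefact of real droplet data.

## Problem sizes and numerics

The default test-suite conditions are the generator defaults above
(1500 cells × 1500 genes per run; 20 independent seeds for the recovery
suites; 100 random instances for the conservation/partition suite; 1,000
random ≤10×10 matrices against the brute-force scoring oracle at 1e-10).
Score min-max rescaling is exact in floating point (the extreme cells hit 0
and 1 identically). All RNG flows through `numpy.random.default_rng` seeds
held in configs; re-running any deterministic stage with identical
configuration reproduces byte-identical output files.

## Known limitations

- Cluster labels are always an input; the package ships no clustering.
- The batch-correction stand-in (per-sample mean-centring) is not a
  replacement for mutual-nearest-neighbour correction on real multi-batch
  data.
- Signature discovery is out of scope: signatures are always an input.
- Scores from different scored populations are not comparable (by design of
  the population-relative score).
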