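# Methods

## Study design assumed

The package analyses the pooled-library design used in organoid
stimulation studies: a single bulk RNA-seq library per condition — one
unstimulated 0 h control and one library per (cytokine, duration) for two
pro-inflammatory cytokines (TNFα, IL-1β) at 4 h, 12 h and 36 h. There are
no biological replicates, so all inference is two-library and exact, and
all downstream claims are set-level (DEG lists, pathway memberships,
marker fractions) rather than per-gene effect-size estimates with
uncertainty.

## Differential expression

Fragment counts per library are modelled as Poisson. For a gene with
counts (x, y) and library sizes (N₁, N₂), conditioning on the total
t = x + y removes the nuisance rate: under the null of equal relative
abundance y ~ Binomial(t, N₂/(N₁+N₂)). This is the Audic–Claverie exact
test for comparing two tag/fragment libraries — the standard
replicate-free Poisson test family. Conventions, chosen once and checked
against an exact-rational summation oracle in the tests:

- two-sided p = min(1, 2·min(P(Y ≤ y), P(Y ≥ y))), tails inclusive of the
  observed count; t = 0 gives p = 1. Inclusive doubling makes the test
  slightly conservative at small counts and exactly symmetric under
  swapping (x, N₁) ↔ (y, N₂).
- tails are evaluated via the regularized incomplete beta function (which
  works in log space internally), and p is floored at the smallest
  positive double so the contract p ∈ (0, 1] holds even in deep tails.
- log2FC: counts are rescaled to the geometric mean of the two library
  sizes and 1 pseudocount is added to both before the ratio, giving a
  finite, symmetric fold change for genes absent from one library; at
  equal depth this reduces to log2((y+1)/(x+1)). The pseudocount is
  configurable.
- genes with zero counts in both libraries are untestable and excluded;
  the remaining genes define the detected universe (matching the
  17,000–18,000 detected genes typical of such experiments).
- FDR is Benjamini–Hochberg over all tested genes of one contrast.
- DEG gate: FC ≥ 2.00 and FDR ≤ 0.001, both boundaries inclusive.

Set algebra on DEG lists: *common* DEGs are genes in at least one DEG
list of each cytokine; *cytokine-specific categories* are genes in one
cytokine's lists only, with max |log2FC| strictly above 1.5 at some time
point of that cytokine; *shared fractions* at a time point are
|A∩B|/|A| and |A∩B|/|B| as integer percentages.

## Enrichment

Upper-tail hypergeometric p (inclusive of the observed k), BH-FDR across
the sets of one query, significance at FDR < 0.01. The background
universe defaults to the genes detected in the experiment, not a whole
annotation; this is configurable by supplying a universe to the GMT
reader. Core-pathway selection takes the per-condition top-4 sets ranked
by FDR-adjusted p and keeps sets whose raw p is below 10⁻¹¹ in every
condition where they rank; output is ordered by appearance frequency,
ties broken by best raw p. Overlap percentages between gene sets are
reported with one-decimal rounding, with an explicit denominator choice.

## Boolean time-course clustering

Band split points are 0 and ±2.5 log2 units. Exactly ±2.5 falls in the
strong band (the mild bands are the open intervals (−2.5, 0) and
(0, +2.5)); exactly 0 maps to mild-up — both tie-breaks are documented
contracts, not numerical accidents. Discovery mode clusters genes by
their distinct observed band triplets (every gene assigned, clustered
fraction 100% by construction); definition mode assigns only genes
matching a supplied pattern list and reports the clustered percentage per
cytokine, which is how printed sub-100% clustered fractions arise when a
fixed cluster vocabulary is given. A common DEG lacking a fold change at
some time point (not tested there) contributes 0 at that time point —
using the reported sub-threshold value when present, 0 only when absent.
Cross-cytokine cluster overlap uses the Jaccard denominator (the union of
the two memberships); the count of clusters "below 25%" uses strict
inequality.

The default 22-pattern vocabulary spans sustained, transient, late and
mixed-direction responses in both directions, including the two all-mild
patterns that absorb low-amplitude genes; it is the planting vocabulary
of the generator, so pattern-count recovery is testable exactly.

## Cell-type markers and attribution

Within a region, gene g is a marker of cell type c iff
expr(g, c) ≥ fold · expr(g, c′) for every other cell type c′
(equivalently, against the max of the others), fold = 10 by default, and
expr(g, c) > 0. A mean-of-others mode exists but is not the default: the
per-type comparison is the stricter reading of "ten-fold lower in the
other cell types". Attribution of a DEG list to a cell type is
|markers ∩ DEGs| / |markers| per region, averaged over the regions with a
non-empty marker set. Marker-DEG stability across time points and panel
overlaps use Jaccard and panel-denominator percentages respectively; the
panel/query denominator orientation is explicit because published
percentage reports use both.

## qPCR quantification

Q_x = μ_eff^(ct_min − ct_x) per primer, with ct_min the per-primer
minimum over the samples being compared, so Q ∈ (0, 1] and the most
abundant sample scores 1. μ_eff comes from the plate file per primer;
when absent, 2.0 (perfect doubling) is assumed with a logged warning —
estimating efficiencies from raw fluorescence curves is out of scope.
Technical replicates are averaged on the ct scale before quantification.
Normalization divides by the geometric mean of the reference-gene Qs
(two-gene housekeeping normalizer); fold changes are ratios of condition
means over replicate samples. Agreement with RNA-seq is a one-tailed
Pearson correlation (alternative r > 0), per time point.

## Synthetic-study generator

The generator emulates the statistical structure the analysis assumes,
with ground truth returned for every planted feature:

- **Reference** (genes × cell_type@region): log-normal base expression
  (location 1.0, scale 1.2 on the log scale) with planted marker sets per
  (cell type, region). Marker counts are drawn per region from per-type
  ranges matching a fetal-brain atlas report (e.g. neural progenitors
  39–91, endothelial cells 316–473 per region; the unlabeled population,
  for which no range is reported, uses 80–200). Planted markers are
  boosted to ≥ fold × the max of the other cell types; every non-marker
  gene is clamped strictly below the fold, so noise-free marker
  derivation recovers exactly the planted catalog.
- **Bulk counts**: baseline expected expression is a fixed cell-type
  mixture of the reference (the organoid's composition is not published;
  the default neuron-rich vector is a free parameter). Responses are
  planted on moderately expressed genes (expected control counts roughly
  30–1000): 15 genes per pattern of the 22-pattern vocabulary respond to
  both cytokines (the second cytokine's pattern drawn independently, so
  cross-cytokine cluster overlap is partial), plus 80 cytokine-specific
  genes per cytokine with at least one strong band. Per-time-point
  amplitudes are drawn uniformly inside the planted band intersected with
  the configured effect range (default |log2FC| ∈ [0.5, 5]). Expected
  counts are scaled by 2^log2FC and counts drawn Poisson per library —
  matching the test's model; a gamma overdispersion knob exists, off by
  default, to probe robustness. Planting on moderate expression keeps
  realized library sizes within a few percent of the configured 10M
  depth. Composition renormalization is deliberately *not* applied, so a
  planted log2FC is exactly the expected count ratio; the small resulting
  library-size inflation is realistic and is absorbed by the library-size
  normalization of the test.
- **Gene sets**: three inflammation-signaling-like sets loaded with
  planted responders (TNF- and NFκB-like sets sharing ~25% of members)
  plus 30 random background sets; six panels (three disease-association,
  three inflammation-themed) with graded planted content.
- **qPCR plate**: per primer, efficiency ~ U(1.85, 2.0) and baseline ct ~
  U(20, 28); ct = ct₀ − log2FC/log2(μ_eff) + N(0, 0.15²) cycles, three
  replicate samples per condition; two housekeeping genes (named GAPDH
  and YWHAZ in the synthetic universe) are planted null.

What the generator does **not** emulate: biological replicate variance
beyond Poisson (unless the overdispersion knob is used), correlated
responses within pathways, mappability/length biases, cell-type
composition shifts under stimulation, and single-cell-level counts (the
reference is a mean-expression table). Passing recovery tests therefore
demonstrates correctness of the statistics under the replicate-free
Poisson model, not robustness to biological replication noise — which
the design being emulated cannot estimate either.

## Problem sizes and seeds

The default simulated study is 18,000 genes at 10M fragments per library,
the scale the method targets; the test suite uses 3,000–4,000-gene,
1.5–2M-fragment versions of the same design for per-module checks, and
the full scale for recovery measurements (10 seeds) and null calibration
(50,000 gene pairs at rate 5000 — the deep-coverage regime where the
doubled inclusive tail's discreteness is negligible). All generator
randomness flows through `numpy.random.default_rng` seeded from a single
integer; independent stages use distinct child streams so adding a stage
never perturbs another's draws.

## Known limitations

- The replicate-free test treats the pooled library as the population;
  its p-values quantify counting noise only, and with deep libraries tiny
  fold changes become formally significant — the FC ≥ 2 gate is doing
  real work and must not be dropped.
- Core-pathway selection depends on the supplied gene-set collection and
  universe; with a whole-annotation universe the raw-p cutoff of 10⁻¹¹
  behaves differently than with a detected-gene universe.
- Definition-mode clustering requires the cluster vocabulary as input;
  published vocabularies living in supplementary material must be
  supplied as a pattern file to reproduce printed clustered fractions.
- Real reference atlases, disease panels and expression-panel gene lists
  are user-supplied inputs; the bundled generator only emulates their
  structure.
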