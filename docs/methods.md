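# Methods

This note documents the statistical procedures implemented in `stagenet`,
their assumptions, the tunable parameters, and the design choices made where
a convention had to be fixed.

## Study design and containers

The pipeline operates on a genes × samples expression table (`iohub.
ExpressionMatrix`, raw integer counts or FPKM) together with an ordered
`StageDesign`.  The reference design is eight pre-implantation stages
(oocyte, 2-cell, 4-cell, 8-cell, 16-cell, early morula, compact morula,
blastocyst) with two biological replicates each — sixteen samples.  All
tables are UTF-8 tab-delimited with `#` comments; gene IDs are opaque
strings.  Parsers fail fast: duplicate IDs, negative values and non-integral
counts are rejected with the offending row/column named, never coerced.

## Detection and filtering

A gene is *detected* at a stage when its mean FPKM over the stage's samples
is strictly greater than 0.1.  Before each between-stage test, genes whose
expression sum over the compared samples is not strictly greater than the
25th percentile of all such sums are removed.  The percentile uses linear
interpolation between order statistics (`numpy.percentile`, `method=
"linear"`); the percentile and its base population (all genes by default)
are configurable since other conventions are equally defensible.  All three
decision thresholds in this package family (FPKM > 0.1, sum > 25th
percentile, P < 0.05) are strict inequalities.

## Negative-binomial differential expression

Counts are normalized by median-of-ratios size factors: `s_j = median_g
(k_gj / gm_g)` over genes with positive counts in every sample, where `gm_g`
is the gene's geometric mean; factors are rescaled to geometric mean 1 so
they are pure relative depths.

Per-gene dispersion (`Var = μ + α μ²`):

* *gene-wise*: pooled method-of-moments across both groups — within-group
  variances of normalized counts are pooled, the shot-noise part `ξ·q` is
  subtracted (ξ = mean reciprocal size factor, q = mean normalized count)
  and the excess divided by q².  Pooling is essential at n = 2 per group,
  where per-group estimates are hopeless.
* *trend*: a robust (Huber) linear fit of log α on log q across genes.
* *final*: `α = max(gene-wise, trend)`, floored at 1e-8 — deliberately
  conservative.

The test conditions on the observed total of the rounded normalized group
sums.  Group sums are modeled NB with mean `n_g q` and dispersion `α / n_g`
(a sum of `n_g` like-distributed genes); every split `(a, K−a)` of the total
is enumerated and the p-value is the total probability of splits no more
probable than the observed one.  Consequences: the symmetric modal split
yields p = 1 exactly, an all-zero gene yields p = 1, and the test is
label-symmetric.  On 5,000 simulated null genes (2 vs 2, α = 0.1) the
rejection rate at nominal 0.05 lands within [0.03, 0.07] (checked in the
acceptance suite).  No numerical equivalence with any DESeq release is
claimed, and no multiple-testing correction is applied: genes are flagged at
raw P < 0.05, matching the thresholding convention of the analyses this
package reproduces.

Log2 fold changes use normalized group means with a pseudocount of 0.5.

qRT-PCR support: `relative_expression_ddct` computes 2^−ΔΔCt with ΔCt =
Ct_gene − Ct_reference per sample and ΔΔCt referenced to a calibrator
sample.

## Expression patterns

Sample QC uses Pearson correlation and PCA of log2(x+1) values (components
sign-fixed so the largest-magnitude score is positive).  Pattern discovery
runs K-means (default k = 30, 25 restarts, fixed seed) on z-scored profiles
of the differentially expressed genes.  Each gene is then correlated with
each centroid; the correlation p-value is the two-sided t test with
df = n_samples − 2, Bonferroni-multiplied by genes × k (the full family of
correlations computed; a genes-only family is available).  A gene joins its
best-correlated centroid only when the adjusted p is below 0.05; constant
profiles stay unassigned.  Cluster labels are canonicalized by descending
size, ties broken by smallest member ID, so runs are comparable.

Whether patterns should be correlated against K-means centroids or idealized
stage templates is genuinely open; centroids are the default because they
are data-derived and parameter-free.

Stage-enriched windows (e.g., oocyte-only, oocyte→4-cell, 8-cell→blastocyst,
blastocyst-only): a gene belongs to a contiguous stage window when its mean
FPKM exceeds the detection threshold at every window stage, its mean outside
the window is at most that threshold, and the inside/outside ratio is at
least 5.  The fold and threshold are explicit parameters because the window
concept is qualitative; the defaults make the rule strict enough that a
ubiquitous gene joins no window.

## Co-expression network

Correlation is Pearson on log2(FPKM+1); the network is unsigned
(`a = |r|^β`).  β defaults to the smallest candidate achieving scale-free
topology fit R² ≥ 0.8 on the binned log-log connectivity distribution, with
a logged fallback of 6 when no candidate qualifies — small-sample designs
(n = 16) often cannot reach high scale-free fits, and 6 is the customary
unsigned default.

Topological overlap, distance and eigengenes are as in the README formulas;
`W(i,i) = 1`, an isolated pair is defined to have `W = 0`, and eigengene
signs are aligned with the module's mean standardized profile so
stage-specificity correlations are reproducible.

**Branch cutting.**  Average linkage is applied to `D = 1 − W`.  Modules are
maximal *tight* subtrees: every internal merge, including the subtree root,
lies below `tight_frac` (default 0.9) of the maximum merge height, and the
subtree holds at least `min_module_size` (default 30) genes.  The harvest is
top-down: loose nodes are split and their children re-examined; genes never
captured stay grey.  Degenerate input with all-equal distances has no tight
subtree, so everything is grey.  This is a deliberately simple adaptive
variant of dendrogram branch decomposition; it is controlled by two
transparent parameters rather than the many of the published dynamic
tree-cut algorithms.

**Merging.**  The module pair with the highest eigengene correlation is
fused when that correlation strictly exceeds 0.7, the merged eigengene is
recomputed, and the scan repeats to a fixed point.  Recomputation (rather
than one-pass transitive closure) reflects the eigengene's role as the
module's representative: after a fusion the representative changes, so
remaining decisions must use it.

**Membership pruning.**  Finally each member's kME (correlation with the
module eigengene) is computed and members below 0.3 are dropped, with one
eigengene recomputation.  Dendrogram branches collect stragglers whose
profiles merely brush the branch — in an unsigned network these can even be
anti-correlated with the module consensus — and re-certifying membership
against the eigengene removes them.  0.3 is the customary "weak membership"
boundary; it sits far below the hub threshold (0.9) and far above noise
(|r| ~ 0.2 at n = 16).

## Stage-specific modules and hubs

For each module and stage, the eigengene is correlated with the stage's unit
indicator vector (1 for the stage's samples, 0 otherwise); p-values come
from the t test with df = n_samples − 2, uncorrected by default (a
correction flag exists; with 8 stages the indicator tests are strongly
dependent, so Bonferroni across them is conservative).  The module is
labeled with the single best stage among those with P < 0.05 *and r > 0*:
stage-specificity means over-expression, so negative correlations never
qualify.  Hub genes are members with kME strictly greater than 0.9, ordered
by kME with lexicographic tie-breaks.  The hub-network export ranks the
pairwise TOM weights (adjacency optional) of the top 150 hubs and keeps the
top 200 edges, with deterministic tie-breaking, in a VisANT-loadable
three-column edge list.  Cross-dataset hub validation maps hubs to ortholog
groups and counts a hub as validated when its group recurs among the hubs of
a same-stage module in at least one other dataset.

## Module preservation

Between a reference and a test dataset (ortholog-mapped, restricted to
genes expressed — nonconstant — in both), each module yields four observed
statistics: mean intramodular |correlation| and mean adjacency in the test
data (density), and the ref-vs-test correlations of intramodular
connectivity and of the vectorized correlation matrices (connectivity).
Each is standardized against `n_perm` (default 200) random same-size gene
sets drawn without replacement from the common background excluding the
module's own genes: `Z = (obs − mean_perm) / sd_perm`.  Zdensity and
Zconnectivity are the medians of their pairs, and `Zsummary = (Zdensity +
Zconnectivity) / 2`, with categories strong (≥ 10), weak-to-moderate
([2, 10)) and none (< 2).  This is a compact four-statistic variant of the
published permutation Z battery — the output headers label it as such — and
no numerical equivalence with the WGCNA `modulePreservation` implementation
is claimed.  Modules with fewer than 3 background genes are reported
untestable.  Restricting the background to commonly expressed genes is not
cosmetic: silent genes carry no correlation structure, and leaving them in
the permutation pool deflates the null and manufactures spurious
preservation.

## Cross-species overlap

Module pairs from two species are intersected at the ortholog-group level
over the background of groups expressed in both species.  A module contains
a group when any member gene maps to it (HomoloGene-group semantics for
many-to-many orthologs).  The test is one-sided enrichment: `P = P(X ≥ k)`
for X hypergeometric, floored at 1e-300 before −log10.  One-sided is the
right question — the analysis asks whether overlap exceeds chance — and no
correction is applied across cells by default (a Bonferroni flag exists).

## Synthetic data generator

The generator emulates the reference design so that every downstream claim
is testable against known truth.  Per gene g, sample s (stage t):

    log2 μ_gs = log2(background_mean) + baseline_g
                + amplitude · archetype(t)
                + σ (loading · z_s + sqrt(1 − loading²) · e_gs)

with `z_s` a per-sample latent factor shared within a module (so `loading`
tunes within-module correlation: pairwise r ≈ loading² above the archetype
floor), `e_gs` private noise, `baseline_g ~ N(0, 1)` in log2 units, and
counts NB with `Var = μ + α μ²` scaled by per-sample library sizes.
Archetypes cover the canonical early-embryo dynamics — increasing
(genome-activation), decreasing (maternal decay), transient, constant, and
single-stage peaks.  FPKM is emulated as counts / library size with unit
gene lengths: detection thresholding only needs rank-consistent scaling.

Defaults (the package's reference conditions): 8 stages × 2 replicates,
2,000 genes, five stage-peaked modules of 100 genes (peaks at oocyte,
4-cell, 8-cell, early morula, blastocyst), loading 0.8, amplitude 4 log2,
dispersion 0.1, background mean 50, detected fraction 0.5.  Detectability is
a per-gene property: the silent fraction of background genes is silent at
every stage, calibrated so the expected detected fraction per stage is 0.5.
This mirrors real staged series, where largely the same gene set is detected
stage after stage; per-stage on/off masking would instead plant strong
stage-patterned pseudo-signals in the background.  The sizes above (and the
slightly smaller 500–1,000-gene configurations used in parts of the test
suite) are the package's chosen desk-scale problem sizes.

The sister-species generator renames genes, emits a complete one-group-per-
gene ortholog map, and regenerates each planted module either with its
original archetype/loading (preserved) or with loading and amplitude zero,
which reduces its members to background noise — the named gene set retains
no co-expression structure.  A single seeded `numpy` Generator drives all
sampling, gene-major; identical configuration (including seed) reproduces
outputs byte-identically, which is the reproducibility contract the CLI
manifest checks.

What the generator does *not* model: amplification bias, per-stage dropout
jitter, length-dependent FPKM, correlated background (housekeeping)
structure, and overlapping module membership.  Passing tests therefore
demonstrate correctness of the algorithms under a clean factor model, not
performance on real single-embryo libraries.

## Numerical conventions

* Constant gene profiles: correlations defined as 0 with a warning
  (adjacency), unassignable (patterns), kME 0 (membership).
* NB pmf falls back to Poisson below dispersion 1e-10; permutation sd floors
  at 1e-12; hypergeometric P floors at 1e-300 before −log10.
* All orderings are made deterministic: modules by size then first member,
  hubs by kME then gene ID, edges by weight then lexicographic node pair.
* Exact threshold semantics everywhere: FPKM exactly 0.1 is not detected,
  kME exactly 0.9 is not a hub, eigengene correlation exactly equal to the
  merge threshold does not merge, Zsummary exactly 10 / 2 are strong /
  weak-to-moderate.

## Known limitations

* The preservation Z uses a four-statistic subset, not the full published
  battery (no medianRank).
* The branch cut is a two-parameter tight-subtree rule, not the published
  dynamic hybrid algorithm; on very gradual dendrograms it will be more
  conservative (more grey genes).
* With two replicates per stage, stage-indicator correlation tests have
  df = 14 and limited power; modules with modest eigengene contrast can stay
  unlabeled.
* The NB exact-style test rounds normalized group sums to integers; with
  very small size factors this rounding is a recognized approximation.
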