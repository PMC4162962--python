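# stagenet

Staged-transcriptome co-expression analysis for pre-implantation embryo
series — and for any short, ordered, few-replicate expression design.

During mammalian pre-implantation development (oocyte → 2-cell → 4-cell →
8-cell → 16-cell → early morula → compact morula → blastocyst), maternally
deposited transcripts decay while the embryo's own genome switches on.
Profiling single embryos gives a genes × samples table with very few
replicates per stage (typically two), which calls for a specific analysis
toolkit rather than generic RNA-seq machinery.  `stagenet` implements that
toolkit end to end:

- **Detection and filtering** — a gene counts as detected at a stage when its
  mean FPKM is strictly above 0.1; before each between-stage test, genes whose
  expression sum falls at or below the 25th percentile of all sums are
  dropped.
- **Consecutive-stage differential expression** — an exact-style negative-
  binomial test: size factors by median-of-ratios, per-gene dispersion as the
  maximum of a pooled method-of-moments estimate and a robust mean–dispersion
  trend, then a conditional test that enumerates all splits of the observed
  total between the two stages and sums the probabilities of splits no more
  probable than the observed one.
- **Expression-pattern clusters** — K-means (default k = 30) on standardized
  profiles of the differentially expressed genes; each gene is assigned to
  its best-correlated centroid only when the Bonferroni-adjusted correlation
  p-value (family = genes × k) is below 0.05.
- **Weighted co-expression network** — unsigned soft-threshold adjacency
  `a(i,j) = |cor(i,j)|^β`, topological overlap

      W(i,j) = (l_ij + a_ij) / (min(k_i, k_j) + 1 − a_ij),
      l_ij = Σ_d a_id a_dj  (d ≠ i,j),     k_i = Σ_d a_id,

  distance `D = 1 − W`, average-linkage clustering, an adaptive tight-branch
  cut, eigengene summaries (first principal component of the standardized
  module expression) and iterative merging of modules whose eigengenes
  correlate above 0.7.
- **Stage-specific modules and hubs** — a module is specific to the stage
  whose unit indicator vector correlates positively with its eigengene at
  P < 0.05; hub genes are members with kME (gene–eigengene correlation)
  strictly above 0.9; the top-200 connections of the top-150 hubs export as a
  VisANT-compatible edge list.
- **Module preservation** — permutation Z statistics (density +
  connectivity, 200 permutations) between a reference and a test dataset
  mapped through ortholog groups; Zsummary ≥ 10 is strong preservation,
  2 ≤ Z < 10 weak-to-moderate, Z < 2 none.
- **Cross-species module overlap** — one-sided Fisher (hypergeometric
  upper-tail) enrichment of module pairs over the commonly expressed ortholog
  background, reported as counts and −log10 P.
- **Synthetic data with ground truth** — `stagenet.simdata` generates the
  whole study design (8 stages × 2 replicates, ~50 % of genes detected per
  stage, negative-binomial counts, planted stage-peaked co-expression
  modules, and a sister-species dataset with a controllable fraction of
  preserved modules), so every stage of the pipeline is testable without any
  external download.

## Worked example

```python
from stagenet import simdata, netcore, stagemod, diffexpr

cfg = simdata.default_config(seed=1)          # 8 stages x 2 replicates, 2,000 genes
counts, fpkm, truth = simdata.simulate_dataset(cfg)
design = cfg.design()

de = diffexpr.consecutive_stage_de(counts, design, alpha=0.05)
res = de[("4-cell", "8-cell")]
print(f"4-cell -> 8-cell: {res.n_up()} up, {res.n_down()} down of {len(res.table)} tested")

modules, labels, tom = netcore.detect_modules(fpkm)
stagemod.stage_specific_modules(modules, design)
for mod in modules:
    hubs = stagemod.hub_genes(mod, fpkm)
    print(f"{mod.module_id}: {mod.size} genes, stage={mod.stage}, "
          f"{len(hubs)} hub genes (kME > 0.9)")
```

prints

```
4-cell -> 8-cell: 103 up, 110 down of 1021 tested
M1: 112 genes, stage=oocyte, 63 hub genes (kME > 0.9)
M2: 112 genes, stage=4-cell, 69 hub genes (kME > 0.9)
M3: 111 genes, stage=8-cell, 40 hub genes (kME > 0.9)
M4: 107 genes, stage=blastocyst, 55 hub genes (kME > 0.9)
M5: 106 genes, stage=early_morula, 38 hub genes (kME > 0.9)
```

The five detected modules are exactly the five planted ones: each is called
specific to the stage where its planted profile peaks, and roughly half of
each module's members are tightly enough correlated with the eigengene to
qualify as hubs.  The 4-cell → 8-cell transition carries the largest planted
expression change (the module peaking at 8-cell switches on), mirroring the
genome-activation burst such series are used to locate.

The same walkthrough is available from the shell:

```sh
stagenet all --seed 1 --out run/
```

which writes count/FPKM/design tables, per-transition DE tables, pattern
clusters, the module table with kME and hub flags, hub edge lists,
preservation Z statistics against a simulated sister species, the
cross-species overlap tables and a manifest of parameter and file hashes.

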