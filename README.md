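# trimod

RNA-modification regulator clustering and prognostic scoring for bulk tumour
cohorts.

Writer, reader and eraser enzymes of the three major mRNA methylation marks —
N6-methyladenosine (m6A), 5-methylcytosine (m5C) and N1-methyladenosine
(m1A) — form a 48-gene regulator panel whose coordinated expression
stratifies colon-cancer patients. `trimod` implements that analysis as a
reusable, tested pipeline for anyone with a gene × sample expression matrix
and a clinical follow-up table:

1. **Regulator clusters** — resampling consensus clustering of the 48
   regulators (hierarchical, 1 − Pearson distance), with the number of
   clusters k chosen by the relative change of the area under the consensus
   CDF, `area(k) = ∫₀¹ ECDF_k(t) dt`.
2. **Cluster DEGs** — empirical-Bayes moderated t between every pair of
   clusters (`s̃²_g = (d₀s₀² + d s²_g)/(d₀ + d)`, Benjamini–Hochberg,
   adjusted p < 0.001), intersected across all pairwise contrasts.
3. **Prognostic genes** — univariate Cox proportional-hazards screen of the
   overlap DEGs (Efron ties, Newton–Raphson, raw p < 0.05).
4. **The m6A/m5C/m1A score** — per sample,
   `score_i = PC1_i + PC2_i` of the z-scored prognostic-gene matrix, each
   component sign-oriented so that its Cox coefficient on overall survival
   is ≥ 0 (high score ⇒ higher hazard). Samples split into high/low at the
   median (or at the optimal log-rank cut); the frozen model (loadings,
   signs, cutpoint) projects onto external validation cohorts.
5. **Downstream** — Kaplan–Meier / log-rank survival by cluster, score group
   and tumor mutation burden (TMB, with two-factor stratified curves);
   single-sample gene-set enrichment (ssGSEA, weight exponent α = 0.25) for
   immune-infiltration profiles and score–immune Spearman correlations;
   rank-sum / Kruskal–Wallis / chi-square group comparisons for IPS, MSI and
   checkpoint expression; hypergeometric over-representation of DEGs against
   user-supplied annotation sets; and the 2^−ΔΔCt RT-qPCR fold change.

Because public cohort downloads are out of scope, a first-class synthetic
generator (`trimod.simulate`) produces cohorts with the statistical
structure the analysis assumes — planted regulator-driven clusters, planted
prognostic genes, proportional-hazards survival with tuned censoring,
mutations, MSI and immunophenoscore columns — together with the ground truth
needed for recovery tests.

## Worked example

The numbered scripts under `analysis/` run the whole study on the default
synthetic cohort (300 samples, three planted clusters, planted Cox
coefficient β* = 0.8). Bulky intermediates go to `scratch/`, summary tables
to `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_regulator_clusters.py
```

prints

```
cohort: 2148 genes x 300 samples (TPM)
planted clusters: {1: 105, 2: 97, 3: 98}
censoring fraction: 0.530 (target 0.5)
...
chosen k = 3 (delta areas: {2: 0.457, 3: 0.464, 4: 0.005, ...})
cluster sizes: {'A': 105, 'C': 98, 'B': 97}
ARI vs planted truth: 1.000
cluster survival separation: chi2 = 203.0, p = 8.18e-45
```

The CDF-area rule stops at k = 3 (the last k whose relative area gain
clears 0.10) and the consensus partition matches the planted clusters
exactly (adjusted Rand index 1.0). Continuing,

```bash
python analysis/03_degs_and_prognosis.py
python analysis/04_modification_score.py
python analysis/05_immune_mutation_downstream.py
```

reports 148 overlap DEGs (all 100 planted prognostic genes plus the
48 shifted regulators), all of them passing the Cox screen, and then

```
score = PC1 + PC2 on 148 genes (explained variance 0.76 + 0.16)
high vs low survival: log-rank chi2 = 105.9, p = 7.75e-25
Spearman rho vs planted risk score: 0.952
validation cohort (seed 101): log-rank p = 1.43e-09
...
mutation rates: high = 100.00%, low = 93.33%
top mutated genes (high group): APC, TP53, TTN, KRAS, SYNE1
```

i.e. the PCA score tracks the planted per-sample risk (Spearman 0.95), the
high-score group dies faster in training and in three independently
simulated validation cohorts, and the high-score group carries the heavier
mutation load — the qualitative behaviour the score is designed to surface.

The same pipeline runs end-to-end from a single command or a YAML config:

```bash
trimod run --outdir run1 --seed 7          # default synthetic mode
trimod validate --model run1/score_model.json \
    --expression cohort2.tsv --clinical cohort2_clinical.tsv
```

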