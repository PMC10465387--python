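# Methods

This note documents the models, algorithms and design choices behind
`trimod`, and what the synthetic-cohort tests do and do not demonstrate
about real data.

## Input model and units

Expression enters as a gene × sample matrix of non-negative abundances
tagged FPKM or TPM. FPKM is converted by within-sample renormalisation,
`TPM_gs = FPKM_gs / Σ_g FPKM_gs × 10⁶`, so every column sums to 10⁶ exactly;
a zero column is an error, not a silent NaN. All model fitting (clustering,
differential expression, Cox screening, PCA) runs on `log2(x + 1)`; the
pseudocount is configurable because downstream results are
transform-dependent and the choice must be explicit. Gene identifiers are
matched case-sensitively with no symbol aliasing; merging two cohorts is an
explicit, logged inner join on shared genes with no batch correction.
Missing clinical values stay missing — nothing is imputed.

The bundled regulator panel (`data/regulator_panel_synthetic.tsv`) is a
synthetic reconstruction assembled from published m6A/m5C/m1A regulator
catalogs: 23 m6A, 15 m5C and 10 m1A genes (48 total), each with one
writer/reader/eraser role. To keep gene ids unique, the YTH-domain readers
(YTHDF1/2/3, YTHDC1) are filed under m1A — they recognise both marks — and
the m6A reader slots are filled by IGF2BP1/2/3 and ELAVL1 from the same
catalogs. Users can substitute their own panel TSV.

## Consensus clustering

For each candidate k (default 2–9), `reps` = 100 subsamples of
⌈0.8·n⌉ samples are drawn without replacement and clustered by hierarchical
agglomeration (average linkage) on 1 − Pearson correlation between samples;
genes are z-scored first so high-abundance features cannot dominate the
correlation. The consensus entry M_ij is the fraction of co-samplings in
which i and j co-clustered; pairs never co-sampled (vanishingly rare at
these settings) get 0 with a warning. Final labels cut a hierarchical tree
of 1 − M at k.

k is selected from the empirical CDF of the upper-triangle consensus
entries. The area is computed exactly as `area(k) = ∫₀¹ ECDF_k(t) dt`
(equivalently 1 − mean consensus, which the tests exploit as an independent
closed form): 0 for perfect consensus, 1 for total dissensus, and
non-decreasing in k in practice. The relative gain
`Δ(k) = (area(k) − area(k−1)) / area(k−1)` (absolute area for the first k)
reproduces, as a fixed rule, the analyst's habit of reading the elbow off
the CDF plot: the chosen k is the largest k with Δ(k) ≥ 0.10. The threshold
and a `force_k` override are exposed because elbow reading is ultimately a
judgement call; making the rule explicit keeps reruns reproducible.

The inner clustering engine (hierarchical/average/1 − Pearson) follows the
defaults of the standard consensus-clustering framework and is deterministic
given a resample, which makes the whole run a pure function of the seed.

## Single-sample enrichment (ssGSEA)

Per sample, genes are ranked by expression descending with ties broken by
gene id (platform-independent determinism). With absolute rank r (n for the
top gene) and weight r^α, the enrichment of set S is

ES(S) = Σ_{i=1..n} [P_in(i) − P_out(i)],

where P_in is the cumulative r^α-weighted fraction of members of S
encountered by position i and P_out the cumulative unweighted fraction of
non-members. α = 0.25, the canonical single-sample weighting. The statistic
is rank-based, hence invariant under any monotone per-sample transform. One
enrichment engine serves both the immune-infiltration profiles and any
pathway-activity summaries; the Gaussian-kernel variation-analysis variant
is deliberately not reimplemented — one well-tested statistic with a
documented scope beats two half-tested ones. Min–max normalisation per set
(constant rows to 0, with a warning) makes scores comparable across sets.

## Moderated differential expression

Each pairwise cluster contrast fits, per gene, a two-group comparison on
log2 expression with pooled variance s²_g on d = n_a + n_b − 2 df. The
prior (d₀, s₀²) is estimated by the method of moments on log s²: matching
the mean and variance of `e_g = log s²_g − ψ(d/2) + log(d/2)` against
digamma/trigamma expressions, inverting the trigamma equation by Newton
iteration. When the observed spread of e is no larger than its sampling
spread, d₀ = ∞ and s₀² is the plain mean of the variances (the convention
of the reference implementation, against which one test checks agreement to
1e-8). The moderated t uses s̃²_g = (d₀s₀² + d s²_g)/(d₀ + d) on d₀ + d df;
BH adjusts across genes. Only the two-group moderated t is implemented —
the pipeline needs pairwise cluster contrasts, not general design matrices.

Cluster DEGs are the intersection of the per-contrast calls at adjusted
p < 0.001 across all pairwise contrasts; a Venn "overlap" of cluster
comparisons most naturally means pairwise contrasts, and the threshold is a
config value.

## Survival statistics

* Kaplan–Meier: the product-limit estimator on the unique event-time grid;
  with no censoring it reproduces the empirical survival function exactly.
* Log-rank: the Mantel–Haenszel statistic over ≥ 2 groups with the
  hypergeometric covariance, chi-square on g − 1 df. On two tie-free groups
  it equals the Cox score test at β = 0 (a property test asserts this to
  1e-6). No events ⇒ p = 1 with a warning.
* Cox: univariate Newton–Raphson maximisation of the Efron-tie partial
  likelihood (Breslow by flag, used in oracle cross-checks), step-halving on
  any likelihood decrease, convergence at |Δβ| < 1e-8 within 50 iterations.
  SE comes from the inverse observed information. A constant covariate
  short-circuits to β = 0, p = 1, flagged; a monotone likelihood (perfect
  separation) caps |β| at 50 and flags the fit. Efron is the default tie
  method because it is the less-biased standard. The preprocessed
  survival structure is cached (`CoxData`) so screening hundreds of genes
  against one outcome avoids re-sorting; the prognostic filter keeps genes
  with raw p < 0.05 (configurable and logged — a deliberate screening
  threshold, not a multiplicity-corrected claim).

## The modification score

Prognostic-gene log2 expression is z-scored per gene, and the top two
principal components of the sample × gene matrix are extracted (full SVD,
deterministic). Unscaled PCA would let high-variance genes dominate, so
standardisation is built in. PCA signs are arbitrary, which would make
"high score = poor prognosis" irreproducible across linear-algebra
backends; each component is therefore oriented so its univariate Cox
coefficient on overall survival is ≥ 0, and `score = PC1 + PC2` after
orientation. Groups split at the median (ties to low) by default; an
optimal log-rank cut (each group ≥ 30% of samples) is available and logged
with its cutpoint. The frozen model stores loadings, gene means/sds, signs
and cutpoint; validation cohorts are z-scored on themselves and projected
through the frozen loadings without refitting (projection, not refit, is the
default because it is the stricter test of transferability), with missing
signature genes dropped under a warning down to a floor of 3.

## Synthetic cohorts: what they emulate, and what they do not

`generate_cohort` draws expression as
`x_gs = exp(μ_g + δ_{g,z_s} + ε_gs)`, ε ~ N(0, σ²), columns rescaled to
TPM — log-normal marginals with heavy tails and strict positivity.
Per-cluster log-mean offsets δ are nonzero only for the regulator panel and
the planted prognostic genes: each regulator receives its own random
permutation of the centred pattern `shift · linspace(−1, 1, k)`, while all
prognostic genes share the ascending pattern. The shared pattern is what
gives the planted per-sample risk score — the centred mean of
prognostic-gene log expression — genuine between-sample variance;
independently permuted prognostic offsets would cancel in that mean and no
generative risk axis would exist for the score to recover. Survival is
exponential with hazard `h₀ · exp(β* · score_s)` (defaults h₀ = 0.001/day,
β* = 0.8) under independent Uniform(0, c) censoring with c solved
numerically for the target censoring fraction (default 0.5), keeping the
proportional-hazards assumption intact. Mutations are per-gene Bernoulli
draws at colon-cancer-like frequencies with a score-dependent logit shift;
MSI is a three-level categorical with score-dependent logits (high score
leans MSS); IPS columns are Gaussian with a score-dependent shift. Default
cohort size is 300 samples, 48 regulators, 100 prognostic genes and 2000
background genes; cluster shift 2.0 over noise 0.5 gives clean but not
degenerate separation. The prognostic block is deliberately sizeable —
real analyses of this design screen hundreds of cluster DEGs — and it keeps
the top two principal components dominated by the risk axis rather than by
the orthogonal cluster contrast carried by the regulators.

Passing recovery tests on these cohorts shows that the pipeline's inference
chain is self-consistent: it finds planted cluster numbers, labels, DEGs,
prognostic genes and hazard coefficients when they exist at realistic
effect sizes, and stays calibrated when they do not (null configurations
are part of the suite). It does **not** show robustness to features the
generator omits: batch and platform effects between cohorts, non-log-normal
count noise, censoring that depends on risk, copy-number structure,
read-level artefacts, or gene–gene correlation beyond the planted factors.
Conclusions about any real cohort still require the usual upstream QC.

## Numerical and reproducibility choices

* Seeds: one global seed fans out to per-stage seeds via a stage-name CRC32
  offset mod 2³¹, so skipping a stage never shifts another stage's stream;
  every simulation and resampling consumes a `numpy.random.Generator`.
* Writers emit floats with 17 significant digits (lossless for float64);
  the run manifest records every stage's parameters — including defaulted
  ones — plus SHA-256 digests of all outputs, and two runs with the same
  config and seed are byte-identical.
* Ties: ssGSEA orders by (value desc, gene id asc); the median group split
  sends ties to the low group; Efron handles event-time ties in Cox fits.
* Degenerate inputs fail loudly by design: constant samples in ssGSEA,
  all-identical scores at the cutpoint, empty gene panels, zero TPM
  columns, < 3 usable signature genes. Constant genes before PCA and
  constant enrichment rows degrade gracefully with warnings.
* The rank-sum comparison uses exact enumeration when both groups have
  ≤ 10 untied observations and the tie-corrected normal approximation
  otherwise. TMB is a raw variant count by default (the variant-class
  filter and an optional per-megabase divisor are config), split at the
  median.

## Known limitations

Only univariate Cox is provided (no multivariable adjustment, time-varying
covariates or proportionality diagnostics); the enrichment engine computes
scores, not permutation p-values; over-representation requires user-supplied
annotation sets (no pathway databases are bundled); consensus clustering
reports matrices, areas and labels but not item-consensus scores or the PAC
statistic; and plotting is out of scope — every result is a tidy table or
curve-coordinate file.
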