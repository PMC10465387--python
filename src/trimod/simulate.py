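"""Synthetic tumour cohorts with planted structure for building and testing.

The generator emulates the statistical shape of a bulk RNA-seq tumour cohort:

* log-normal expression on the natural scale, rescaled per sample to TPM;
* ``k_true`` planted sample clusters expressed through the regulator panel
  (each regulator gets its own permuted per-cluster log-mean offset) and
  through a block of planted prognostic genes that share one ascending
  per-cluster offset pattern;
* proportional-hazards overall survival driven by a per-sample risk score —
  the centered mean of planted prognostic-gene log expression — with planted
  log hazard ratio β* and independent uniform censoring tuned numerically to
  a target censoring fraction;
* Bernoulli per-gene somatic mutations with an optional score-dependent
  enrichment, three-level MSI status with score-dependent logits, and four
  immunophenoscore-like columns with a score-dependent Gaussian shift.

Everything is a deterministic function of ``SimConfig`` (including its seed);
identical configs produce byte-identical serialized outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .datasets import MODIFICATIONS, ROLES, load_regulator_catalog
from .io import ExpressionMatrix, GeneSetCollection

#: default per-gene somatic mutation probabilities (colon-cancer-like ranking)
DEFAULT_MUTATION_FREQS = {
    "APC": 0.70, "TP53": 0.50, "TTN": 0.40, "KRAS": 0.35, "PIK3CA": 0.25,
    "SYNE1": 0.30, "MUC16": 0.28, "FAT4": 0.24, "RYR2": 0.20, "OBSCN": 0.20,
    "ZFHX4": 0.18, "DNAH5": 0.16, "LRP1B": 0.15, "FBXW7": 0.12, "CSMD3": 0.12,
}

VARIANT_CLASSES = ("missense_mutation", "nonsense_mutation", "frame_shift_del",
                   "multi_hit", "splice_site")
_VARIANT_PROBS = (0.60, 0.15, 0.10, 0.10, 0.05)


@dataclass
class SimConfig:
    """Study conditions for one synthetic cohort.

    Defaults are the conditions the end-to-end analysis assumes: 300 samples,
    three balanced clusters separated by a 2.0 log-scale shift on the 48
    regulator genes over residual noise of 0.5, 30 planted prognostic genes,
    planted Cox coefficient β* = 0.8 per unit risk score, a baseline hazard of
    0.001/day (median survival ≈ 2 years) and 50% censoring.
    """

    n_samples: int = 300
    n_background_genes: int = 2000
    n_regulators: int = 48
    n_prognostic_genes: int = 100
    k_true: int = 3
    cluster_probs: Sequence[float] | None = None
    cluster_shift: float = 2.0
    noise_sd: float = 0.5
    log_hr_per_unit_score: float = 0.8
    baseline_hazard: float = 0.001
    censor_rate_target: float = 0.5
    mutation_gene_freqs: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_MUTATION_FREQS))
    mutation_score_effect: float = 0.8
    msi_score_effect: float = 0.8
    ips_score_effect: float = 0.8
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        if self.k_true < 2:
            raise ValueError("k_true must be ≥ 2")
        if self.k_true > self.n_samples:
            raise ValueError(f"k_true = {self.k_true} exceeds n_samples = {self.n_samples}")
        if self.n_regulators < 1 or self.n_prognostic_genes < 1 or self.n_background_genes < 1:
            raise ValueError("gene panels must be non-empty")
        if self.cluster_probs is not None:
            p = np.asarray(self.cluster_probs, dtype=float)
            if len(p) != self.k_true:
                raise ValueError("cluster_probs length must equal k_true")
            if abs(p.sum() - 1.0) > 1e-9 or (p < 0).any():
                raise ValueError("cluster_probs must be a probability vector summing to 1")
        if not self.noise_sd > 0:
            raise ValueError("noise_sd must be > 0")
        if self.cluster_shift < 0:
            raise ValueError("cluster_shift must be ≥ 0")
        if not self.baseline_hazard > 0:
            raise ValueError("baseline_hazard must be > 0")
        if not 0 < self.censor_rate_target < 1:
            raise ValueError("censor_rate_target must be in (0, 1)")
        for g, f in self.mutation_gene_freqs.items():
            if not 0 <= f <= 1:
                raise ValueError(f"mutation frequency for {g!r} outside [0, 1]: {f}")

    @property
    def probs(self) -> np.ndarray:
        if self.cluster_probs is None:
            return np.full(self.k_true, 1.0 / self.k_true)
        return np.asarray(self.cluster_probs, dtype=float)


@dataclass
class SyntheticTruth:
    """Ground truth planted by :func:`generate_cohort`."""

    cluster_labels: np.ndarray          # per-sample int in 1..k_true
    prognostic_gene_ids: list[str]
    true_beta: float
    true_score: pd.Series               # per-sample planted risk score


def _sample_ids(n: int) -> list[str]:
    return [f"SAMPLE_{i:04d}" for i in range(1, n + 1)]


def _regulator_genes(config: SimConfig) -> list[str]:
    catalog = load_regulator_catalog()
    genes = list(catalog["gene"])
    if config.n_regulators <= len(genes):
        return genes[: config.n_regulators]
    extra = [f"REG_{i:03d}" for i in range(1, config.n_regulators - len(genes) + 1)]
    return genes + extra


def regulator_catalog_for(config: SimConfig) -> pd.DataFrame:
    """Regulator panel used by the cohort: the bundled catalog, padded or truncated."""
    catalog = load_regulator_catalog()
    if config.n_regulators <= len(catalog):
        return catalog.iloc[: config.n_regulators].reset_index(drop=True)
    rows = [catalog]
    extra = []
    for i in range(config.n_regulators - len(catalog)):
        extra.append({
            "gene": f"REG_{i + 1:03d}",
            "modification": MODIFICATIONS[i % len(MODIFICATIONS)],
            "role": ROLES[i % len(ROLES)],
        })
    rows.append(pd.DataFrame(extra))
    return pd.concat(rows, ignore_index=True)


def _solve_censor_bound(rates: np.ndarray, target: float) -> float:
    """Upper bound c of Uniform(0, c) censoring matching the target censor fraction.

    With T ~ Exp(λ) and C ~ U(0, c), P(censored) = E[(1 − e^{−λc})/(λc)] which
    decreases from 1 to 0 in c; solved by bisection.
    """

    def frac(c: float) -> float:
        lc = rates * c
        return float(np.mean((1.0 - np.exp(-lc)) / lc))

    lo, hi = 1e-9, 1.0
    while frac(hi) - target > 0:
        hi *= 2.0
        if hi > 1e12:
            break
    return brentq(lambda c: frac(c) - target, lo, hi, xtol=1e-10, rtol=1e-12)


def generate_cohort(config: SimConfig) -> tuple[ExpressionMatrix, pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate one cohort: (TPM expression, clinical table, regulator catalog, truth)."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, k = config.n_samples, config.k_true

    reg_genes = _regulator_genes(config)
    prog_genes = [f"PROG_{i:04d}" for i in range(1, config.n_prognostic_genes + 1)]
    bg_genes = [f"BG_{i:05d}" for i in range(1, config.n_background_genes + 1)]
    genes = reg_genes + prog_genes + bg_genes
    n_genes = len(genes)
    samples = _sample_ids(n)

    labels = rng.choice(np.arange(1, k + 1), size=n, p=config.probs)

    mu = rng.normal(2.0, 1.2, size=n_genes)
    # per-cluster log-mean offsets: zero for background genes
    base_pattern = np.linspace(-1.0, 1.0, k) if k > 1 else np.zeros(1)
    delta = np.zeros((n_genes, k))
    for i in range(len(reg_genes)):
        delta[i] = config.cluster_shift * rng.permutation(base_pattern)
    # prognostic genes share one ascending pattern so their mean log expression
    # carries the planted between-sample risk axis
    for i in range(len(reg_genes), len(reg_genes) + len(prog_genes)):
        delta[i] = config.cluster_shift * base_pattern

    log_expr = mu[:, None] + delta[:, labels - 1] + rng.normal(0.0, config.noise_sd, size=(n_genes, n))

    prog_slice = slice(len(reg_genes), len(reg_genes) + len(prog_genes))
    raw_score = log_expr[prog_slice].mean(axis=0)
    true_score = raw_score - raw_score.mean()

    natural = np.exp(log_expr)
    tpm = natural / natural.sum(axis=0, keepdims=True) * 1e6
    expr = ExpressionMatrix(pd.DataFrame(tpm, index=genes, columns=samples), "TPM")

    # proportional-hazards survival on the planted score
    rates = config.baseline_hazard * np.exp(config.log_hr_per_unit_score * true_score)
    event_times = rng.exponential(1.0 / rates)
    c_bound = _solve_censor_bound(rates, config.censor_rate_target)
    censor_times = rng.uniform(0.0, c_bound, size=n)
    os_time = np.minimum(event_times, censor_times)
    os_event = (event_times <= censor_times).astype(int)

    score_std = true_score.std()
    s_std = true_score / score_std if score_std > 0 else np.zeros(n)

    age = np.clip(rng.normal(68.0, 10.0, size=n), 30.0, 95.0)
    sex = rng.choice(["F", "M"], size=n)
    stage = rng.choice([1, 2, 3, 4], size=n, p=[0.18, 0.38, 0.30, 0.14])

    # 3-level MSI with score-dependent logits: high score leans MSS
    msi_logits = np.stack([
        1.0 + config.msi_score_effect * s_std,
        np.full(n, 0.0),
        -0.5 - config.msi_score_effect * s_std,
    ])
    msi_p = np.exp(msi_logits - msi_logits.max(axis=0))
    msi_p /= msi_p.sum(axis=0)
    u = rng.random(n)
    cum = np.cumsum(msi_p, axis=0)
    msi_idx = np.minimum((u[None, :] > cum).sum(axis=0), 2)
    msi = np.array(["MSS", "MSI-L", "MSI-H"])[msi_idx]

    clinical = pd.DataFrame({
        "sample_id": samples,
        "os_time": os_time,
        "os_event": os_event,
        "age": age,
        "sex": sex,
        "stage": stage,
        "msi": msi,
        "cohort": "synthetic",
    })
    # immunophenoscore-like columns: Gaussian, shifted down for high-risk samples
    for col in ("ips_ctla4_pos_pd1_pos", "ips_ctla4_pos_pd1_neg",
                "ips_ctla4_neg_pd1_pos", "ips_ctla4_neg_pd1_neg"):
        clinical[col] = 7.0 - config.ips_score_effect * s_std + rng.normal(0.0, 1.0, size=n)

    truth = SyntheticTruth(
        cluster_labels=labels,
        prognostic_gene_ids=prog_genes,
        true_beta=config.log_hr_per_unit_score,
        true_score=pd.Series(true_score, index=samples, name="true_score"),
    )
    return expr, clinical, regulator_catalog_for(config), truth


def generate_mutations(config: SimConfig, truth: SyntheticTruth) -> pd.DataFrame:
    """MAF-lite mutation table: Bernoulli per (sample, gene) at the configured
    frequencies, with a score-dependent logit shift (high risk → more mutations)."""
    config.validate()
    rng = np.random.default_rng(config.seed + 10_007)
    samples = _sample_ids(config.n_samples)
    s = truth.true_score.to_numpy()
    sd = s.std()
    s_std = s / sd if sd > 0 else np.zeros_like(s)

    rows = []
    for gene, freq in config.mutation_gene_freqs.items():
        if freq <= 0.0:
            continue
        if freq >= 1.0:
            p = np.ones(config.n_samples)
        else:
            p = expit(logit(freq) + config.mutation_score_effect * s_std)
        hit = rng.random(config.n_samples) < p
        classes = rng.choice(VARIANT_CLASSES, size=config.n_samples, p=_VARIANT_PROBS)
        for i in np.flatnonzero(hit):
            rows.append((samples[i], gene, classes[i]))
    return pd.DataFrame(rows, columns=["sample_id", "gene", "variant_class"])


def synthetic_immune_sets(gene_ids: Sequence[str], n_sets: int = 8, set_size: int = 30,
                          seed: int = 0) -> GeneSetCollection:
    """Synthetic immune-cell signatures: random disjoint-ish draws from the cohort genes.

    Stand-ins for published immune signature lists; the enrichment engine is
    signature-agnostic, so tests only need sets with realistic sizes.
    """
    rng = np.random.default_rng(seed)
    pool = list(gene_ids)
    if set_size >= len(pool):
        raise ValueError("set_size must be smaller than the gene universe")
    names = ["activated_CD8_T_cell", "activated_CD4_T_cell", "regulatory_T_cell",
             "natural_killer_cell", "macrophage", "plasmacytoid_dendritic_cell",
             "eosinophil", "type_2_T_helper_cell", "B_cell", "neutrophil"]
    sets, desc = {}, {}
    for i in range(n_sets):
        name = (names[i] if i < len(names) else f"immune_cell_{i:02d}") + "_synthetic"
        members = rng.choice(pool, size=set_size, replace=False)
        sets[name] = set(members.tolist())
        desc[name] = "synthetic immune signature"
    return GeneSetCollection(sets, desc)


def synthetic_annotation_sets(gene_ids: Sequence[str], planted: Sequence[str],
                              n_sets: int = 10, set_size: int = 40,
                              seed: int = 0) -> GeneSetCollection:
    """Synthetic annotation sets for over-representation tests; the first set
    contains the planted genes and should be flagged by ORA."""
    rng = np.random.default_rng(seed)
    pool = [g for g in gene_ids if g not in set(planted)]
    sets = {"planted_pathway_synthetic": set(planted)}
    desc = {"planted_pathway_synthetic": "synthetic annotation set containing the planted genes"}
    for i in range(1, n_sets):
        name = f"pathway_{i:02d}_synthetic"
        sets[name] = set(rng.choice(pool, size=min(set_size, len(pool)), replace=False).tolist())
        desc[name] = "synthetic annotation set"
    return GeneSetCollection(sets, desc)
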