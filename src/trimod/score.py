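"""The m6A/m5C/m1A score: a PCA-based per-sample prognostic signature.

Prognostic-gene log2 expression is z-scored gene-wise, the top two principal
components of the sample × gene matrix are extracted, each component's sign
is oriented so that its univariate Cox coefficient on overall survival is
non-negative (high score ⇒ higher hazard — making the "high score = poor
prognosis" convention reproducible across linear-algebra backends), and

    score_i = PC1_i + PC2_i .

Samples are dichotomised into high/low groups at the median by default, or
at the cut maximising the log-rank statistic. A fitted model can be frozen
(loadings, signs, cutpoint) and projected onto an external validation cohort
without refitting.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .io import ExpressionMatrix
from .survival import cox_univariate, logrank_test

_RANK2_TOL = 1e-12


@dataclass
class ModScore:
    """Fitted per-sample score with everything needed to freeze and re-apply it."""

    scores: pd.Series                # oriented pc1 + pc2
    pc1: pd.Series
    pc2: pd.Series
    loadings: pd.DataFrame           # gene × (pc1, pc2), unoriented
    explained_var: tuple[float, float]
    signs: tuple[int, int]
    cutpoint: float
    groups: pd.Series                # "high" / "low"
    cut_method: str
    gene_means: pd.Series
    gene_sds: pd.Series

    @property
    def genes(self) -> list[str]:
        return list(self.loadings.index)


def _zscore_gene_rows(vals: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    means = vals.mean(axis=1)
    sds = vals.std(axis=1, ddof=0)
    usable = sds > 0
    if not usable.all():
        warnings.warn(f"{int((~usable).sum())} constant gene(s) dropped before PCA")
        vals, means, sds = vals.loc[usable], means[usable], sds[usable]
    z = vals.sub(means, axis=0).div(sds, axis=0)
    return z, means, sds


def compute_score(x: ExpressionMatrix, genes, clinical: pd.DataFrame,
                  cut_method: str = "median") -> ModScore:
    """Fit the PCA score on ``genes`` and dichotomise samples."""
    if x.unit != "LOG2":
        raise ValueError(f"compute_score expects LOG2 expression, got {x.unit}")
    genes = [g for g in x.gene_ids if g in set(genes)]
    if len(genes) < 3:
        raise ValueError(f"need ≥ 3 usable signature genes, got {len(genes)}")
    if len(x.sample_ids) < 3:
        raise ValueError("need ≥ 3 samples")

    z, means, sds = _zscore_gene_rows(x.values.loc[genes])
    if z.shape[0] < 3:
        raise ValueError("fewer than 3 non-constant signature genes")
    A = z.to_numpy().T                      # samples × genes
    pca = PCA(n_components=2, svd_solver="full").fit(A)
    proj = pca.transform(A)
    evr = pca.explained_variance_ratio_
    rank_deficient = pca.explained_variance_[1] <= _RANK2_TOL * max(pca.explained_variance_[0], 1.0)
    if rank_deficient:
        warnings.warn("signature matrix has rank < 2; PC2 set to 0")
        proj[:, 1] = 0.0

    clin = clinical.set_index("sample_id").loc[x.sample_ids]
    t = clin["os_time"].to_numpy()
    e = clin["os_event"].to_numpy()
    signs = []
    for j in range(2):
        beta = cox_univariate(proj[:, j], t, e, name=f"pc{j + 1}").beta
        signs.append(-1 if beta < 0 else 1)
    pc1 = pd.Series(signs[0] * proj[:, 0], index=x.sample_ids, name="pc1")
    pc2 = pd.Series(signs[1] * proj[:, 1], index=x.sample_ids, name="pc2")
    score = (pc1 + pc2).rename("score")

    groups, cut = assign_groups(score, clin.reset_index(), method=cut_method)
    loadings = pd.DataFrame(pca.components_.T, index=z.index, columns=["pc1", "pc2"])
    return ModScore(score, pc1, pc2, loadings, (float(evr[0]), float(evr[1])),
                    (signs[0], signs[1]), cut, groups, cut_method, means, sds)


def assign_groups(scores: pd.Series, clinical: pd.DataFrame | None = None,
                  method: str = "median", min_frac: float = 0.3) -> tuple[pd.Series, float]:
    """Dichotomise scores: ``median`` (ties to low) or ``logrank_opt`` (cut that
    maximises the log-rank statistic with both groups ≥ ``min_frac`` of samples)."""
    scores = pd.Series(scores)
    if len(scores) < 4:
        raise ValueError("need ≥ 4 samples to form groups")
    if scores.nunique() == 1:
        raise ValueError("all scores identical; cannot form groups")
    if method == "median":
        cut = float(scores.median())
    elif method == "logrank_opt":
        if clinical is None:
            raise ValueError("logrank_opt needs the clinical table")
        clin = clinical.set_index("sample_id").loc[scores.index]
        t = clin["os_time"].to_numpy()
        e = clin["os_event"].to_numpy()
        order = np.sort(scores.unique())
        n = len(scores)
        best_cut, best_chi2 = None, -np.inf
        for c in order[:-1]:
            low = scores <= c
            n_low = int(low.sum())
            if n_low < min_frac * n or (n - n_low) < min_frac * n:
                continue
            res = logrank_test(t, e, np.where(low, "low", "high"))
            if res.chi2 > best_chi2:
                best_chi2, best_cut = res.chi2, float(c)
        if best_cut is None:
            raise ValueError(f"no cut leaves both groups ≥ {min_frac:.0%} of samples")
        cut = best_cut
    else:
        raise ValueError(f"unknown cut method {method!r}")
    groups = pd.Series(np.where(scores <= cut, "low", "high"), index=scores.index, name="group")
    if groups.nunique() < 2:
        raise ValueError("cutpoint leaves one group empty")
    return groups, cut


def apply_score(model: ModScore, x_new: ExpressionMatrix) -> pd.DataFrame:
    """Project a new cohort through the frozen loadings and orientation signs.

    The new cohort is z-scored on itself (gene means/sds of the new cohort);
    signature genes missing from the cohort are dropped with a warning, so the
    projection uses the overlapping loading rows only. No refitting.
    """
    if x_new.unit != "LOG2":
        raise ValueError(f"apply_score expects LOG2 expression, got {x_new.unit}")
    overlap = [g for g in model.genes if g in set(x_new.gene_ids)]
    missing = len(model.genes) - len(overlap)
    if len(overlap) < 3:
        raise ValueError(
            f"only {len(overlap)} signature gene(s) present in the new cohort; need ≥ 3 "
            f"(signature: {model.genes[:5]}…)")
    if missing:
        warnings.warn(f"{missing} signature gene(s) absent from the cohort; dropped")
    z, _, _ = _zscore_gene_rows(x_new.values.loc[overlap])
    L = model.loadings.loc[z.index].to_numpy()
    proj = z.to_numpy().T @ L
    pc1 = model.signs[0] * proj[:, 0]
    pc2 = model.signs[1] * proj[:, 1]
    return pd.DataFrame({"pc1": pc1, "pc2": pc2, "score": pc1 + pc2}, index=x_new.sample_ids)


def save_model(model: ModScore, path) -> None:
    payload = {
        "genes": model.genes,
        "loadings_pc1": model.loadings["pc1"].tolist(),
        "loadings_pc2": model.loadings["pc2"].tolist(),
        "gene_means": model.gene_means.loc[model.genes].tolist(),
        "gene_sds": model.gene_sds.loc[model.genes].tolist(),
        "signs": list(model.signs),
        "cutpoint": model.cutpoint,
        "cut_method": model.cut_method,
        "explained_var": list(model.explained_var),
    }
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=1)


def load_model(path) -> ModScore:
    with open(path, encoding="utf-8") as fh:
        payload = json.load(fh)
    genes = payload["genes"]
    loadings = pd.DataFrame({"pc1": payload["loadings_pc1"], "pc2": payload["loadings_pc2"]},
                            index=genes)
    empty = pd.Series(dtype=float)
    return ModScore(
        scores=empty, pc1=empty, pc2=empty, loadings=loadings,
        explained_var=tuple(payload["explained_var"]),
        signs=tuple(payload["signs"]), cutpoint=payload["cutpoint"],
        groups=pd.Series(dtype=object), cut_method=payload["cut_method"],
        gene_means=pd.Series(payload["gene_means"], index=genes),
        gene_sds=pd.Series(payload["gene_sds"], index=genes),
    )
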