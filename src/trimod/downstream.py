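"""Score-stratified downstream analyses.

Tumor mutation burden (raw nonsynonymous counts, median-split), per-group
mutation summaries, two-factor stratified Kaplan–Meier curves, nonparametric
group comparisons (rank-sum / Kruskal–Wallis / chi-square), score–immune
Spearman correlations with BH correction, generic hypergeometric
over-representation against user-supplied annotation sets, and the 2^−ΔΔCt
fold-change formula for RT-qPCR readouts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneSetCollection
from .ssgsea import EnrichmentResult
from .survival import LogrankResult, SurvCurve, km_estimate, logrank_test


@dataclass
class TmbProfile:
    table: pd.DataFrame      # sample_id-indexed: tmb, absent, group
    cutpoint: float
    class_filter: tuple[str, ...] | None = None


@dataclass
class GroupComparison:
    variable: str
    test: str                # wilcoxon | kruskal | chi2
    statistic: float
    p: float
    group_sizes: dict[str, int]


def compute_tmb(mutations: pd.DataFrame, samples, class_filter=None,
                per_mb: float | None = None) -> TmbProfile:
    """Per-sample mutation count (optionally restricted to ``class_filter``
    variant classes, optionally divided by a capture size in Mb), median-split
    into high/low. Samples absent from the table count 0 and are flagged."""
    samples = list(samples)
    if not samples:
        raise ValueError("empty sample list")
    m = mutations
    if class_filter is not None:
        class_filter = tuple(class_filter)
        m = m[m["variant_class"].isin(class_filter)]
    counts = m.groupby("sample_id").size()
    tmb = pd.Series(0.0, index=samples, name="tmb")
    shared = counts.index.intersection(samples)
    tmb.loc[shared] = counts.loc[shared].astype(float)
    if per_mb is not None:
        if not per_mb > 0:
            raise ValueError("per_mb capture size must be > 0")
        tmb = tmb / per_mb
    absent = ~pd.Index(samples).isin(mutations["sample_id"])
    cut = float(tmb.median())
    group = np.where(tmb <= cut, "low", "high")
    table = pd.DataFrame({"tmb": tmb, "absent": absent, "group": group})
    table.index.name = "sample_id"
    return TmbProfile(table, cut, class_filter)


def mutation_summary(mutations: pd.DataFrame, groups: pd.Series,
                     top_n: int = 20) -> dict[str, pd.DataFrame]:
    """Per-group mutation rate, per-gene mutation frequency ranking and
    variant-class tallies. ``groups`` maps sample_id → group label."""
    groups = pd.Series(groups)
    if groups.empty:
        raise ValueError("empty groups")
    rates = []
    gene_rows = []
    class_rows = []
    mutated = set(mutations["sample_id"])
    for label, members in groups.groupby(groups):
        ids = list(members.index)
        if not ids:
            raise ValueError(f"group {label!r} is empty")
        sub = mutations[mutations["sample_id"].isin(ids)]
        rates.append((label, len(ids), len(set(sub["sample_id"])) / len(ids)))
        freq = (sub.groupby("gene")["sample_id"].nunique() / len(ids)).sort_values(ascending=False)
        for rank, (gene, f) in enumerate(freq.head(top_n).items(), start=1):
            gene_rows.append((label, rank, gene, f))
        for vc, cnt in sub["variant_class"].value_counts().items():
            class_rows.append((label, vc, int(cnt)))
    return {
        "rates": pd.DataFrame(rates, columns=["group", "n", "mutation_rate"]),
        "gene_frequency": pd.DataFrame(gene_rows, columns=["group", "rank", "gene", "frequency"]),
        "variant_classes": pd.DataFrame(class_rows, columns=["group", "variant_class", "count"]),
    }


def stratified_km(clinical: pd.DataFrame, factor_a: pd.Series, factor_b: pd.Series
                  ) -> tuple[dict[str, SurvCurve], LogrankResult]:
    """KM per combination of two binary factors plus the overall log-rank
    across the (up to four) strata; empty cells are dropped with a warning."""
    clin = clinical.set_index("sample_id")
    fa = pd.Series(factor_a).reindex(clin.index)
    fb = pd.Series(factor_b).reindex(clin.index)
    if fa.nunique(dropna=True) != 2 or fb.nunique(dropna=True) != 2:
        raise ValueError("both stratification factors must be binary")
    keep = fa.notna() & fb.notna()
    clin, fa, fb = clin[keep], fa[keep], fb[keep]
    strata = fa.astype(str) + "/" + fb.astype(str)
    curves: dict[str, SurvCurve] = {}
    expected = {f"{a}/{b}" for a in fa.unique() for b in fb.unique()}
    for name in sorted(expected):
        mask = strata == name
        if not mask.any():
            warnings.warn(f"stratum {name!r} is empty; dropped")
            continue
        curves[name] = km_estimate(clin.loc[mask, "os_time"], clin.loc[mask, "os_event"])
    if len(curves) < 2:
        raise ValueError("fewer than 2 non-empty strata")
    used = strata.isin(curves)
    res = logrank_test(clin.loc[used, "os_time"], clin.loc[used, "os_event"], strata[used])
    return curves, res


def compare_groups(values, groups, test: str | None = None,
                   variable: str = "value") -> GroupComparison:
    """Nonparametric comparison of a variable across groups.

    Numeric values: rank-sum for 2 groups (exact when both n ≤ 10 and no
    ties, normal approximation with tie/continuity correction otherwise),
    Kruskal–Wallis for ≥ 3. Categorical values (or ``test="chi2"``):
    chi-square on the contingency table.
    """
    values = pd.Series(values).reset_index(drop=True)
    groups = pd.Series(groups).reset_index(drop=True)
    if len(values) != len(groups):
        raise ValueError("values and groups must have equal length")
    keep = values.notna() & groups.notna()
    values, groups = values[keep], groups[keep]
    levels = sorted(groups.unique().tolist(), key=str)
    sizes = {str(l): int((groups == l).sum()) for l in levels}
    if any(s == 0 for s in sizes.values()) or len(levels) < 2:
        raise ValueError("every group needs ≥ 1 observation and ≥ 2 groups are required")

    numeric = pd.api.types.is_numeric_dtype(values)
    if test is None:
        test = "chi2" if not numeric else ("wilcoxon" if len(levels) == 2 else "kruskal")

    if test == "chi2":
        table = pd.crosstab(values, groups)
        stat, p, _, _ = stats.chi2_contingency(table)
        return GroupComparison(variable, "chi2", float(stat), float(p), sizes)
    if not numeric:
        raise ValueError(f"test {test!r} requires numeric values")
    samples = [values[groups == l].to_numpy(dtype=float) for l in levels]
    if test == "wilcoxon":
        if len(levels) != 2:
            raise ValueError("wilcoxon requires exactly 2 groups")
        small = max(len(s) for s in samples) <= 10
        ties = len(np.unique(np.concatenate(samples))) < len(values)
        method = "exact" if (small and not ties) else "asymptotic"
        res = stats.mannwhitneyu(samples[0], samples[1], alternative="two-sided", method=method)
        return GroupComparison(variable, "wilcoxon", float(res.statistic), float(res.pvalue), sizes)
    if test == "kruskal":
        if np.ptp(np.concatenate(samples)) == 0:   # all observations identical
            return GroupComparison(variable, "kruskal", 0.0, 1.0, sizes)
        res = stats.kruskal(*samples)
        return GroupComparison(variable, "kruskal", float(res.statistic), float(res.pvalue), sizes)
    raise ValueError(f"unknown test {test!r}")


def score_immune_correlation(scores: pd.Series, enrichment: EnrichmentResult,
                             min_pairs: int = 5) -> pd.DataFrame:
    """Spearman correlation of the score with every immune-set enrichment row,
    BH-adjusted across sets."""
    scores = pd.Series(scores)
    if scores.nunique() <= 1:
        raise ValueError("constant score vector")
    rows = []
    for name, row in enrichment.scores.iterrows():
        shared = row.index.intersection(scores.index)
        if len(shared) < min_pairs:
            raise ValueError(f"set {name!r}: only {len(shared)} paired samples (< {min_pairs})")
        rho, p = stats.spearmanr(scores.loc[shared], row.loc[shared])
        rows.append((name, float(rho), float(p)))
    out = pd.DataFrame(rows, columns=["set", "rho", "p"]).set_index("set")
    out["adj_p"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def ora_hypergeometric(hit_genes, annotation: GeneSetCollection, universe) -> pd.DataFrame:
    """Over-representation of ``hit_genes`` in each annotation set.

    Raw p is the hypergeometric upper tail P(X ≥ overlap) drawing |hits|
    genes from a universe of size |universe| containing |set ∩ universe|
    successes; BH-adjusted across sets.
    """
    universe = set(universe)
    hits = set(hit_genes)
    if not universe or not hits:
        raise ValueError("empty universe or hit list")
    if not hits <= universe:
        raise ValueError(f"{len(hits - universe)} hit gene(s) outside the universe")
    M, n_draw = len(universe), len(hits)
    rows = []
    for name, members in annotation:
        in_universe = members & universe
        if not in_universe:
            continue
        k = len(in_universe & hits)
        p = float(stats.hypergeom.sf(k - 1, M, len(in_universe), n_draw))
        rows.append((name, k, len(in_universe), p))
    out = pd.DataFrame(rows, columns=["set", "overlap", "set_size", "p"]).set_index("set")
    if len(out):
        out["adj_p"] = multipletests(out["p"], method="fdr_bh")[1]
    return out


def ddct_fold_change(ct_target_case: float, ct_ref_case: float,
                     ct_target_ctrl: float, ct_ref_ctrl: float) -> float:
    """2^−ΔΔCt relative expression:
    ΔΔCt = (Ct_target,case − Ct_ref,case) − (Ct_target,ctrl − Ct_ref,ctrl)."""
    ddct = (ct_target_case - ct_ref_case) - (ct_target_ctrl - ct_ref_ctrl)
    return float(2.0 ** (-ddct))
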