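#!/usr/bin/env python
"""Score-stratified downstream analyses: immune infiltration (ssGSEA and
score–immune Spearman correlations), tumor mutation burden and stratified
survival, mutation summaries, and IPS/MSI/vital-status group comparisons.
"""

from pathlib import Path

import pandas as pd

from trimod.downstream import (compare_groups, compute_tmb, mutation_summary,
                               score_immune_correlation, stratified_km)
from trimod.io import (log2_transform, read_clinical, read_expression,
                       read_gmt, read_mutations)
from trimod.ssgsea import minmax_normalize, ssgsea_scores
from trimod.survival import logrank_test

BASE = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"


def main() -> None:
    expr = read_expression(SCRATCH / "cohort" / "expression_tpm.tsv", "TPM")
    clinical = read_clinical(SCRATCH / "cohort" / "clinical.tsv").set_index("sample_id")
    mutations = read_mutations(SCRATCH / "cohort" / "mutations.tsv")
    immune = read_gmt(SCRATCH / "cohort" / "immune_sets.gmt")
    score_tab = pd.read_csv(BASE / "score" / "score_table.tsv", sep="\t", index_col=0)
    scores, groups = score_tab["score"], score_tab["group"]
    out = BASE / "downstream"
    out.mkdir(parents=True, exist_ok=True)

    enr = minmax_normalize(ssgsea_scores(log2_transform(expr), immune))
    (SCRATCH / "downstream").mkdir(parents=True, exist_ok=True)
    enr.scores.to_csv(SCRATCH / "downstream" / "ssgsea_scores.tsv", sep="\t")
    corr = score_immune_correlation(scores, enr)
    corr.to_csv(out / "score_immune_correlation.tsv", sep="\t")
    print(f"immune sets correlated with the score (BH < 0.05): "
          f"{int((corr['adj_p'] < 0.05).sum())} of {len(corr)}")

    tmb = compute_tmb(mutations, list(scores.index))
    tmb.table.to_csv(out / "tmb.tsv", sep="\t")
    lr_tmb = logrank_test(clinical["os_time"], clinical["os_event"],
                          tmb.table["group"].to_numpy())
    _, lr_strat = stratified_km(clinical.reset_index(), tmb.table["group"], groups)
    print(f"TMB median cut = {tmb.cutpoint:.0f}; TMB log-rank p = {lr_tmb.p:.3g}; "
          f"TMB x score stratified log-rank p = {lr_strat.p:.3g}")

    summary = mutation_summary(mutations, groups)
    for key, df in summary.items():
        df.to_csv(out / f"mutation_{key}.tsv", sep="\t", index=False)
    rates = summary["rates"].set_index("group")["mutation_rate"]
    print(f"mutation rates: high = {rates['high']:.2%}, low = {rates['low']:.2%}")
    top = summary["gene_frequency"].query("group == 'high'").sort_values("rank").head(5)
    print(f"top mutated genes (high group): {', '.join(top['gene'])}")

    comparisons = []
    for col in [c for c in clinical.columns if c.startswith("ips_")]:
        cmp = compare_groups(clinical[col], groups, variable=col)
        comparisons.append((col, cmp.test, cmp.statistic, cmp.p))
    comparisons.append(("score_by_msi",) + tuple(
        getattr(compare_groups(scores, clinical["msi"], variable="score_by_msi"), a)
        for a in ("test", "statistic", "p")))
    comparisons.append(("msi_by_group",) + tuple(
        getattr(compare_groups(clinical["msi"], groups, test="chi2"), a)
        for a in ("test", "statistic", "p")))
    comparisons.append(("score_by_vital_status",) + tuple(
        getattr(compare_groups(scores, clinical["os_event"].map({0: "alive", 1: "dead"})), a)
        for a in ("test", "statistic", "p")))
    cmp_df = pd.DataFrame(comparisons, columns=["variable", "test", "statistic", "p"])
    cmp_df.to_csv(out / "group_comparisons.tsv", sep="\t", index=False)
    print(cmp_df.to_string(index=False, float_format=lambda v: f"{v:.3g}"))
    print(f"outputs in {out}")


if __name__ == "__main__":
    main()
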