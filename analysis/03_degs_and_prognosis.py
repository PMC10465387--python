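#!/usr/bin/env python
"""Differential expression between regulator clusters and the prognostic screen.

Runs the moderated two-group test for every pairwise cluster contrast,
intersects the per-contrast calls (adjusted p < 0.001), tests the overlap for
annotation over-representation, and keeps the genes whose univariate Cox raw
p < 0.05 — the input of the scoring step.
"""

from pathlib import Path

import pandas as pd

from trimod.diffexpr import all_pairwise, overlap_degs
from trimod.downstream import ora_hypergeometric
from trimod.io import log2_transform, read_clinical, read_expression, read_gmt
from trimod.survival import prognostic_filter

BASE = Path(__file__).resolve().parent.parent / "results"
SCRATCH = Path(__file__).resolve().parent.parent / "scratch"


def main() -> None:
    expr = read_expression(SCRATCH / "cohort" / "expression_tpm.tsv", "TPM")
    clinical = read_clinical(SCRATCH / "cohort" / "clinical.tsv")
    labels = pd.read_csv(BASE / "clusters" / "cluster_labels.tsv", sep="\t",
                         index_col=0)["cluster"].loc[expr.sample_ids]
    x = log2_transform(expr)

    results = all_pairwise(x, labels.to_numpy())
    out = BASE / "degs"
    out.mkdir(parents=True, exist_ok=True)
    (SCRATCH / "degs").mkdir(parents=True, exist_ok=True)
    for res in results:
        res.table.to_csv(SCRATCH / "degs" / f"deg_{res.contrast[0]}_vs_{res.contrast[1]}.tsv",
                         sep="\t")
        n_sig = int((res.table["adj_p"] < 0.001).sum())
        print(f"contrast {res.contrast[0]} vs {res.contrast[1]}: {n_sig} DEGs "
              f"(prior df d0 = {res.d0:.3g})")

    overlap = overlap_degs(results, alpha=0.001)
    (out / "overlap_degs.txt").write_text("\n".join(overlap) + "\n")
    print(f"overlap across all contrasts: {len(overlap)} genes")

    annotation = read_gmt(SCRATCH / "cohort" / "annotation_sets.gmt")
    ora = ora_hypergeometric(set(overlap), annotation, x.gene_ids)
    ora.to_csv(out / "ora_overlap_degs.tsv", sep="\t")
    print(f"top over-represented set: {ora['adj_p'].idxmin()} "
          f"(adj p = {ora['adj_p'].min():.3g})")

    passing, table = prognostic_filter(x, clinical, overlap, p_threshold=0.05)
    table.to_csv(out / "prognostic_cox_table.tsv", sep="\t")
    (out / "prognostic_genes.txt").write_text("\n".join(passing) + "\n")
    print(f"prognostic genes (Cox raw p < 0.05): {len(passing)} of {len(overlap)}")
    print(f"outputs in {out}")


if __name__ == "__main__":
    main()
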