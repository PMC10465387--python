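#!/usr/bin/env python
"""Generate the study cohort: a synthetic colon-cancer-like cohort with three
planted regulator-driven sample clusters, 100 planted prognostic genes and
proportional-hazards survival (β* = 0.8, ~50% censoring).

Writes expression (TPM), clinical, mutation, regulator-panel and gene-set
files under results/cohort/ and prints the cohort summary.
"""

import dataclasses
import json
from pathlib import Path

from trimod import simulate
from trimod.io import write_clinical, write_expression, write_gmt, write_mutations

OUT = Path(__file__).resolve().parent.parent / "scratch" / "cohort"
SUMMARY = Path(__file__).resolve().parent.parent / "results"
SEED = 1


def main() -> None:
    cfg = simulate.SimConfig(seed=SEED)
    expr, clinical, catalog, truth = simulate.generate_cohort(cfg)
    mutations = simulate.generate_mutations(cfg, truth)
    immune = simulate.synthetic_immune_sets(expr.gene_ids, seed=SEED)
    annotation = simulate.synthetic_annotation_sets(expr.gene_ids,
                                                    truth.prognostic_gene_ids, seed=SEED)
    OUT.mkdir(parents=True, exist_ok=True)
    write_expression(expr, OUT / "expression_tpm.tsv")
    write_clinical(clinical, OUT / "clinical.tsv")
    write_mutations(mutations, OUT / "mutations.tsv")
    catalog.to_csv(OUT / "regulator_catalog.tsv", sep="\t", index=False)
    write_gmt(immune, OUT / "immune_sets.gmt")
    write_gmt(annotation, OUT / "annotation_sets.gmt")
    (OUT / "sim_config.json").write_text(json.dumps(dataclasses.asdict(cfg), indent=1))
    (OUT / "truth.json").write_text(json.dumps({
        "cluster_labels": truth.cluster_labels.tolist(),
        "prognostic_gene_ids": truth.prognostic_gene_ids,
        "true_beta": truth.true_beta,
        "true_score": truth.true_score.tolist(),
        "sample_ids": list(truth.true_score.index),
    }, indent=1))

    import numpy as np
    sizes = np.bincount(truth.cluster_labels)[1:]
    print(f"cohort: {expr.shape[0]} genes x {expr.shape[1]} samples (TPM)")
    print(f"planted clusters: {dict(enumerate(sizes.tolist(), start=1))}")
    print(f"censoring fraction: {1 - clinical['os_event'].mean():.3f} "
          f"(target {cfg.censor_rate_target})")
    print(f"mutation rows: {len(mutations)} across {mutations['sample_id'].nunique()} samples")
    SUMMARY.mkdir(parents=True, exist_ok=True)
    (SUMMARY / "cohort_summary.json").write_text(json.dumps({
        "n_genes": expr.shape[0], "n_samples": expr.shape[1],
        "planted_cluster_sizes": sizes.tolist(),
        "censoring_fraction": float(1 - clinical["os_event"].mean()),
        "mutation_rows": int(len(mutations)),
    }, indent=1))
    print(f"cohort files in {OUT}; summary in {SUMMARY}")


if __name__ == "__main__":
    main()
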