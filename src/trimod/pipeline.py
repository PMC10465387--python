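"""End-to-end pipeline: orchestration, seeding, manifest and validation.

Stage order mirrors the analysis workflow: input loading (or synthetic
generation) and TPM conversion → log2 transform → consensus clustering of
regulator expression → immune ssGSEA → pairwise moderated DE + overlap →
univariate Cox prognostic filter → consensus gene clusters → PCA score and
group assignment → downstream mutation/immune/clinical analyses.

Every stage writes its outputs as TSV into the run directory and records a
manifest entry (parameters, output digests, wall time, warnings). A single
global seed is fanned out to per-stage seeds through a stage-name CRC32
offset, so reruns with the same config reproduce every digest and skipping a
stage never shifts another stage's stream.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diffexpr, downstream, score, simulate, ssgsea, survival
from .consensus import ConsensusParams, cluster_labels_vs_truth, run_consensus
from .datasets import load_regulator_catalog, read_regulator_catalog
from .io import (ExpressionMatrix, fpkm_to_tpm, log2_transform, read_clinical,
                 read_expression, read_gmt, read_mutations, write_clinical,
                 write_expression, write_gmt, write_mutations)

logger = logging.getLogger(__name__)

_FLOAT_FMT = "%.12g"


class ConfigError(ValueError):
    """Invalid pipeline configuration (CLI exit code 2)."""


class StageError(RuntimeError):
    """A pipeline stage failed (CLI exit code 3)."""

    def __init__(self, stage: str, cause: BaseException):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class ConsensusBlock:
    k_range: tuple[int, ...] = tuple(range(2, 10))
    reps: int = 100
    p_item: float = 0.8
    distance: str = "one_minus_pearson"
    linkage: str = "average"
    delta_area_threshold: float = 0.10
    force_k: int | None = None


@dataclass
class PipelineConfig:
    outdir: str = "trimod_run"
    seed: int = 0
    log_level: str = "INFO"
    # exactly one input mode: synthetic block, or real file paths
    synthetic: simulate.SimConfig | None = None
    expression: str | None = None
    unit: str = "TPM"
    clinical: str | None = None
    mutations: str | None = None
    immune_sets: str | None = None
    annotation_sets: str | None = None
    regulator_panel: str | None = None
    # stage parameter blocks
    consensus: ConsensusBlock = field(default_factory=ConsensusBlock)
    gene_consensus: ConsensusBlock = field(default_factory=ConsensusBlock)
    ssgsea_alpha: float = 0.25
    log2_pseudocount: float = 1.0
    deg_alpha: float = 0.001
    cox_p_threshold: float = 0.05
    cut_method: str = "median"
    tmb_classes: tuple[str, ...] | None = None
    tmb_per_mb: float | None = None

    def validate(self) -> None:
        real = [p for p in (self.expression, self.clinical) if p]
        if self.synthetic is not None and real:
            raise ConfigError("config must declare either a synthetic block or real input paths, not both")
        if self.synthetic is None and not (self.expression and self.clinical):
            raise ConfigError("real-input mode needs both expression and clinical paths")
        if self.synthetic is not None:
            self.synthetic.validate()
        if self.unit not in ("FPKM", "TPM"):
            raise ConfigError(f"input unit must be FPKM or TPM, got {self.unit!r}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        syn = raw.pop("synthetic", None)
        cfg = cls(**{k: v for k, v in raw.items() if k not in ("consensus", "gene_consensus")})
        if syn is not None:
            cfg.synthetic = simulate.SimConfig(**syn)
        for block_name in ("consensus", "gene_consensus"):
            if block_name in raw:
                block = raw[block_name] or {}
                setattr(cfg, block_name, ConsensusBlock(**{**dataclasses.asdict(ConsensusBlock()), **block}))
        if cfg.tmb_classes is not None:
            cfg.tmb_classes = tuple(cfg.tmb_classes)
        return cfg


@dataclass
class StageRecord:
    name: str
    params: dict
    outputs: dict[str, str]
    seconds: float
    warnings: list[str]


@dataclass
class RunManifest:
    config: dict
    stages: list[StageRecord] = field(default_factory=list)
    failed_stage: str | None = None

    def digests(self) -> dict[str, str]:
        out: dict[str, str] = {}
        for rec in self.stages:
            out.update(rec.outputs)
        return out

    def to_json(self, path) -> None:
        payload = {
            "config": self.config,
            "failed_stage": self.failed_stage,
            "stages": [dataclasses.asdict(s) for s in self.stages],
        }
        with open(path, "w", encoding="utf-8") as fh:
            json.dump(payload, fh, indent=1, default=str)


def stage_seed(global_seed: int, stage: str) -> int:
    """Per-stage seed: global seed offset by a stage-name CRC32, mod 2³¹."""
    return (int(global_seed) + zlib.crc32(stage.encode())) % (2**31)


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index=index)


class _Runner:
    def __init__(self, config: PipelineConfig):
        self.config = config
        self.outdir = Path(config.outdir)
        self.outdir.mkdir(parents=True, exist_ok=True)
        self.manifest = RunManifest(config=_config_dict(config))
        self.state: dict = {}

    def run_stage(self, name: str, fn, params: dict) -> None:
        t0 = time.perf_counter()
        before = {p: p.stat().st_mtime_ns for p in self.outdir.rglob("*") if p.is_file()}
        with warnings.catch_warnings(record=True) as caught:
            warnings.simplefilter("always")
            try:
                fn()
            except Exception as exc:
                self.manifest.failed_stage = name
                self.manifest.to_json(self.outdir / "manifest.json")
                raise StageError(name, exc) from exc
        outputs = {}
        for p in sorted(self.outdir.rglob("*")):
            if not p.is_file() or p.name == "manifest.json":
                continue
            if p not in before or p.stat().st_mtime_ns != before[p]:
                outputs[str(p.relative_to(self.outdir))] = _sha256(p)
        rec = StageRecord(name, params, outputs, time.perf_counter() - t0,
                          [str(w.message) for w in caught])
        self.manifest.stages.append(rec)
        logger.info("stage %-22s %6.2fs  %d output file(s)", name, rec.seconds, len(outputs))


def _config_dict(config: PipelineConfig) -> dict:
    d = dataclasses.asdict(config)
    return d


def _consensus_params(block: ConsensusBlock, seed: int) -> ConsensusParams:
    return ConsensusParams(k_range=tuple(block.k_range), reps=block.reps,
                           p_item=block.p_item, distance=block.distance,
                           linkage=block.linkage, seed=seed)


def run_pipeline(config: PipelineConfig) -> RunManifest:
    """Execute every stage in order; returns the manifest (also written to disk)."""
    config.validate()
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    r = _Runner(config)
    out = r.outdir
    st = r.state

    def inputs():
        if config.synthetic is not None:
            expr, clinical, catalog, truth = simulate.generate_cohort(config.synthetic)
            mutations = simulate.generate_mutations(config.synthetic, truth)
            immune = simulate.synthetic_immune_sets(expr.gene_ids,
                                                    seed=stage_seed(config.seed, "immune_sets"))
            annotation = simulate.synthetic_annotation_sets(
                expr.gene_ids, truth.prognostic_gene_ids,
                seed=stage_seed(config.seed, "annotation_sets"))
            st["truth"] = truth
            pd.DataFrame({"sample_id": expr.sample_ids,
                          "true_cluster": truth.cluster_labels,
                          "true_score": truth.true_score.to_numpy()}
                         ).to_csv(out / "truth_samples.tsv", sep="\t", index=False,
                                  float_format=_FLOAT_FMT)
        else:
            expr = read_expression(config.expression, config.unit)
            if expr.unit == "FPKM":
                expr = fpkm_to_tpm(expr)
            clinical = read_clinical(config.clinical)
            clinical = clinical[clinical["sample_id"].isin(expr.sample_ids)].reset_index(drop=True)
            mutations = read_mutations(config.mutations) if config.mutations else None
            immune = read_gmt(config.immune_sets) if config.immune_sets else None
            annotation = read_gmt(config.annotation_sets) if config.annotation_sets else None
            catalog = (read_regulator_catalog(config.regulator_panel)
                       if config.regulator_panel else load_regulator_catalog())
        missing = set(expr.sample_ids) - set(clinical["sample_id"])
        if missing:
            raise ValueError(f"{len(missing)} expression sample(s) missing from the clinical table")
        clinical = clinical.set_index("sample_id").loc[expr.sample_ids].reset_index()
        st.update(expr=expr, clinical=clinical, mutations=mutations,
                  immune=immune, annotation=annotation, catalog=catalog)
        write_expression(expr, out / "expression_tpm.tsv")
        write_clinical(clinical, out / "clinical.tsv")
        catalog.to_csv(out / "regulator_catalog.tsv", sep="\t", index=False)
        if mutations is not None:
            write_mutations(mutations, out / "mutations.tsv")
        if immune is not None:
            write_gmt(immune, out / "immune_sets.gmt")
        if annotation is not None:
            write_gmt(annotation, out / "annotation_sets.gmt")

    r.run_stage("inputs", inputs, {"mode": "synthetic" if config.synthetic else "real",
                                   "unit": config.unit, "seed": config.seed})

    def log2():
        st["log2"] = log2_transform(st["expr"], config.log2_pseudocount)

    r.run_stage("log2_transform", log2, {"pseudocount": config.log2_pseudocount})

    def regulator_clusters():
        panel = set(st["catalog"]["gene"])
        sub = st["log2"].subset_genes(panel)
        if sub.shape[0] < 2:
            raise ValueError("fewer than 2 regulator genes present in the matrix")
        params = _consensus_params(config.consensus, stage_seed(config.seed, "regulator_clusters"))
        run = run_consensus(sub, params, threshold=config.consensus.delta_area_threshold,
                            force_k=config.consensus.force_k)
        st["cluster_run"] = run
        letters = {k: chr(ord("A") + k - 1) for k in range(1, run.chosen_k + 1)}
        labels = pd.Series([letters[l] for l in run.chosen_labels],
                           index=run.sample_ids, name="cluster")
        st["cluster_labels"] = labels
        _write_tsv(pd.DataFrame(run.matrices[run.chosen_k],
                                index=run.sample_ids, columns=run.sample_ids),
                   out / "consensus_matrix_regulators.tsv")
        _write_tsv(pd.DataFrame({"area": run.areas, "delta_area": run.delta_areas}),
                   out / "consensus_areas_regulators.tsv")
        labels.to_frame().to_csv(out / "cluster_labels.tsv", sep="\t")
        clin = st["clinical"]
        lr = survival.logrank_test(clin["os_time"], clin["os_event"], labels.to_numpy())
        report = {"chosen_k": run.chosen_k, "cluster_sizes": labels.value_counts().to_dict(),
                  "logrank_chi2": lr.chi2, "logrank_p": lr.p}
        if "truth" in st:
            report["ari_vs_truth"] = cluster_labels_vs_truth(run.chosen_labels,
                                                             st["truth"].cluster_labels)
        st["cluster_report"] = report
        (out / "cluster_report.json").write_text(json.dumps(report, indent=1, default=str))

    r.run_stage("regulator_clusters", regulator_clusters,
                {**dataclasses.asdict(config.consensus),
                 "seed": stage_seed(config.seed, "regulator_clusters")})

    def immune():
        if st["immune"] is None:
            logger.info("no immune gene sets supplied; skipping ssGSEA")
            return
        res = ssgsea.ssgsea_scores(st["log2"], st["immune"], alpha=config.ssgsea_alpha)
        norm = ssgsea.minmax_normalize(res)
        st["enrichment"] = norm
        _write_tsv(norm.scores, out / "ssgsea_scores.tsv")
        labels = st["cluster_labels"]
        rows = []
        for name, row in norm.scores.iterrows():
            cmp = downstream.compare_groups(row, labels.loc[row.index], variable=name)
            rows.append((name, cmp.test, cmp.statistic, cmp.p))
        _write_tsv(pd.DataFrame(rows, columns=["set", "test", "statistic", "p"]).set_index("set"),
                   out / "immune_by_cluster.tsv")

    r.run_stage("immune_ssgsea", immune, {"alpha": config.ssgsea_alpha})

    def degs():
        labels = st["cluster_labels"].to_numpy()
        results = diffexpr.all_pairwise(st["log2"], labels)
        for res in results:
            _write_tsv(res.table, out / f"deg_{res.contrast[0]}_vs_{res.contrast[1]}.tsv")
        overlap = diffexpr.overlap_degs(results, alpha=config.deg_alpha)
        st["overlap_degs"] = overlap
        (out / "overlap_degs.txt").write_text("\n".join(overlap) + "\n")
        if not overlap:
            raise ValueError(f"no overlap DEGs at adjusted p < {config.deg_alpha}")

    r.run_stage("degs", degs, {"alpha": config.deg_alpha})

    def prognostic():
        passing, table = survival.prognostic_filter(st["log2"], st["clinical"],
                                                    st["overlap_degs"],
                                                    p_threshold=config.cox_p_threshold)
        st["prognostic_genes"] = passing
        _write_tsv(table, out / "prognostic_cox_table.tsv")
        (out / "prognostic_genes.txt").write_text("\n".join(passing) + "\n")
        if len(passing) < 3:
            raise ValueError(f"only {len(passing)} prognostic genes at p < {config.cox_p_threshold}")
        if st["annotation"] is not None:
            ora = downstream.ora_hypergeometric(set(st["overlap_degs"]), st["annotation"],
                                                st["log2"].gene_ids)
            _write_tsv(ora, out / "ora_overlap_degs.tsv")

    r.run_stage("prognostic_filter", prognostic, {"p_threshold": config.cox_p_threshold})

    def gene_clusters():
        sub = st["log2"].subset_genes(st["prognostic_genes"])
        params = _consensus_params(config.gene_consensus, stage_seed(config.seed, "gene_clusters"))
        max_k = sub.shape[1] // 2
        params = ConsensusParams(k_range=tuple(k for k in params.k_range if k <= max_k),
                                 reps=params.reps, p_item=params.p_item,
                                 distance=params.distance, linkage=params.linkage,
                                 seed=params.seed)
        run = run_consensus(sub, params, threshold=config.gene_consensus.delta_area_threshold,
                            force_k=config.gene_consensus.force_k)
        st["gene_cluster_run"] = run
        labels = pd.Series([chr(ord("A") + l - 1) for l in run.chosen_labels],
                           index=run.sample_ids, name="gene_cluster")
        st["gene_cluster_labels"] = labels
        labels.to_frame().to_csv(out / "gene_cluster_labels.tsv", sep="\t")
        _write_tsv(pd.DataFrame({"area": run.areas, "delta_area": run.delta_areas}),
                   out / "consensus_areas_genes.tsv")
        clin = st["clinical"]
        lr = survival.logrank_test(clin["os_time"], clin["os_event"], labels.to_numpy())
        (out / "gene_cluster_report.json").write_text(json.dumps(
            {"chosen_k": run.chosen_k, "sizes": labels.value_counts().to_dict(),
             "logrank_chi2": lr.chi2, "logrank_p": lr.p}, indent=1, default=str))

    r.run_stage("gene_clusters", gene_clusters,
                {**dataclasses.asdict(config.gene_consensus),
                 "seed": stage_seed(config.seed, "gene_clusters")})

    def mod_score():
        model = score.compute_score(st["log2"], st["prognostic_genes"], st["clinical"],
                                    cut_method=config.cut_method)
        st["model"] = model
        tab = pd.DataFrame({"pc1": model.pc1, "pc2": model.pc2,
                            "score": model.scores, "group": model.groups})
        tab.index.name = "sample_id"
        _write_tsv(tab, out / "score_table.tsv")
        score.save_model(model, out / "score_model.json")
        clin = st["clinical"]
        lr = survival.logrank_test(clin["os_time"], clin["os_event"], model.groups.to_numpy())
        report = {"cutpoint": model.cutpoint, "cut_method": model.cut_method,
                  "explained_var": model.explained_var, "signs": model.signs,
                  "group_sizes": model.groups.value_counts().to_dict(),
                  "logrank_chi2": lr.chi2, "logrank_p": lr.p}
        by_cluster = downstream.compare_groups(model.scores, st["cluster_labels"],
                                               variable="score_by_cluster")
        by_gene_cluster = downstream.compare_groups(model.scores, st["gene_cluster_labels"],
                                                    variable="score_by_gene_cluster")
        report["score_by_cluster_p"] = by_cluster.p
        report["score_by_gene_cluster_p"] = by_gene_cluster.p
        if "truth" in st:
            from scipy.stats import spearmanr
            rho, _ = spearmanr(model.scores.to_numpy(),
                               st["truth"].true_score.loc[model.scores.index].to_numpy())
            report["spearman_vs_truth"] = abs(float(rho))
            cox = survival.cox_univariate(model.scores.to_numpy(), clin["os_time"],
                                          clin["os_event"], name="score")
            report["cox_beta_score"] = cox.beta
        st["score_report"] = report
        (out / "score_report.json").write_text(json.dumps(report, indent=1, default=str))

    r.run_stage("score", mod_score, {"cut_method": config.cut_method})

    def downstream_stage():
        clin = st["clinical"].set_index("sample_id")
        model = st["model"]
        groups = model.groups
        results: dict = {}
        # vital status vs score
        cmp_vital = downstream.compare_groups(model.scores, clin["os_event"].map({0: "alive", 1: "dead"}),
                                              variable="score_by_vital_status")
        results["score_by_vital_status_p"] = cmp_vital.p
        # IPS columns
        for col in [c for c in clin.columns if c.startswith("ips_")]:
            cmp = downstream.compare_groups(clin[col], groups, variable=col)
            results[f"{col}_p"] = cmp.p
        # checkpoint expression, only when the genes exist in the matrix
        for gene in ("CD274", "CTLA4"):
            if gene in st["log2"].gene_ids:
                cmp = downstream.compare_groups(st["log2"].values.loc[gene], groups,
                                                variable=f"{gene}_expression")
                results[f"{gene}_expression_p"] = cmp.p
        # MSI
        if "msi" in clin.columns and clin["msi"].notna().any():
            results["score_by_msi_p"] = downstream.compare_groups(
                model.scores, clin["msi"], variable="score_by_msi").p
            results["msi_by_group_chi2_p"] = downstream.compare_groups(
                clin["msi"], groups, test="chi2", variable="msi_by_group").p
        # score–immune correlation
        if "enrichment" in st:
            corr = downstream.score_immune_correlation(model.scores, st["enrichment"])
            _write_tsv(corr, out / "score_immune_correlation.tsv")
        # mutations: TMB, stratified survival, summaries
        if st["mutations"] is not None:
            tmb = downstream.compute_tmb(st["mutations"], list(groups.index),
                                         class_filter=config.tmb_classes,
                                         per_mb=config.tmb_per_mb)
            _write_tsv(tmb.table, out / "tmb.tsv")
            lr_tmb = survival.logrank_test(clin["os_time"], clin["os_event"],
                                           tmb.table["group"].to_numpy())
            results["tmb_logrank_p"] = lr_tmb.p
            _, lr_strat = downstream.stratified_km(st["clinical"],
                                                   tmb.table["group"], groups)
            results["tmb_score_stratified_logrank_p"] = lr_strat.p
            results["tmb_by_group_wilcoxon_p"] = downstream.compare_groups(
                tmb.table["tmb"], groups, variable="tmb_by_group").p
            summary = downstream.mutation_summary(st["mutations"], groups)
            for key, df in summary.items():
                _write_tsv(df, out / f"mutation_{key}.tsv", index=False)
            results["mutation_rates"] = summary["rates"].set_index("group")["mutation_rate"].to_dict()
        st["downstream_report"] = results
        (out / "downstream_report.json").write_text(json.dumps(results, indent=1, default=str))

    r.run_stage("downstream", downstream_stage,
                {"tmb_classes": config.tmb_classes, "tmb_per_mb": config.tmb_per_mb})

    r.manifest.to_json(out / "manifest.json")
    return r.manifest


def validate_external(model_path, expression_path, clinical_path, unit: str = "TPM",
                      outdir=None, log2_pseudocount: float = 1.0) -> dict:
    """Project a frozen score model onto an external cohort and test separation.

    Returns a report with the projected group sizes, the log-rank statistic and
    its p-value; optionally writes the per-sample scores and report.
    """
    model = score.load_model(model_path) if isinstance(model_path, (str, Path)) else model_path
    expr = read_expression(expression_path, unit) if isinstance(expression_path, (str, Path)) \
        else expression_path
    if expr.unit == "FPKM":
        expr = fpkm_to_tpm(expr)
    if expr.unit != "LOG2":
        expr = log2_transform(expr, log2_pseudocount)
    clinical = read_clinical(clinical_path) if isinstance(clinical_path, (str, Path)) else clinical_path
    return validate_cohort(model, expr, clinical, outdir=outdir)


def validate_cohort(model: score.ModScore, expr_log2: ExpressionMatrix,
                    clinical: pd.DataFrame, outdir=None) -> dict:
    projected = score.apply_score(model, expr_log2)
    clin = clinical.set_index("sample_id").loc[projected.index]
    groups = np.where(projected["score"] <= model.cutpoint, "low", "high")
    if len(set(groups)) < 2:
        # frozen cutpoint off-scale for this cohort: fall back to its median, logged
        warnings.warn("frozen cutpoint leaves one empty group; falling back to the cohort median")
        groups = np.where(projected["score"] <= projected["score"].median(), "low", "high")
    lr = survival.logrank_test(clin["os_time"], clin["os_event"], groups)
    report = {
        "n_samples": int(len(projected)),
        "n_signature_genes_used": len([g for g in model.genes if g in set(expr_log2.gene_ids)]),
        "group_sizes": pd.Series(groups).value_counts().to_dict(),
        "logrank_chi2": lr.chi2, "logrank_df": lr.df, "logrank_p": lr.p,
        "cutpoint": model.cutpoint,
    }
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        tab = projected.copy()
        tab["group"] = groups
        tab.index.name = "sample_id"
        _write_tsv(tab, outdir / "validation_scores.tsv")
        (outdir / "validation_report.json").write_text(json.dumps(report, indent=1, default=str))
    return report
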