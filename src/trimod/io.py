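"""Readers, writers and unit conversion for the pipeline's on-disk artifacts.

All tabular artifacts are tab-separated UTF-8 text with a header row:

* expression matrix — first column gene ids, remaining columns one per sample;
* clinical table — one row per sample (``sample_id``, ``os_time`` in days,
  ``os_event`` 0/1, plus optional covariates ``age``, ``sex``, ``stage``,
  ``msi``, ``cohort`` and ``ips_*`` columns);
* MAF-lite mutation table — one row per (sample, gene, variant class);
* gene sets — Broad GMT dialect (set name, description, tab-separated members).

Readers validate and reject malformed input rather than coercing it; every
reader/writer pair round-trips valid data exactly (within float formatting,
which uses 17 significant digits and is therefore lossless for float64).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

VALID_UNITS = ("FPKM", "TPM", "LOG2")

#: Clinical columns that must be present.
CLINICAL_REQUIRED = ("sample_id", "os_time", "os_event")
MUTATION_REQUIRED = ("sample_id", "gene", "variant_class")
MSI_LEVELS = ("MSS", "MSI-L", "MSI-H")

# float format used by every writer; round-trips float64 exactly
_FLOAT_FMT = "%.17g"


@dataclass
class ExpressionMatrix:
    """Gene × sample abundance matrix with an explicit unit tag.

    ``values`` is a DataFrame indexed by gene id with one column per sample.
    ``unit`` is one of FPKM, TPM or LOG2; non-negative values are required
    for the linear-scale units.
    """

    values: pd.DataFrame
    unit: str

    def __post_init__(self) -> None:
        if self.unit not in VALID_UNITS:
            raise ValueError(f"unknown expression unit {self.unit!r}; expected one of {VALID_UNITS}")
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.duplicated().any():
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample ids: {dups[:5]}")
        arr = self.values.to_numpy()
        if not np.isfinite(arr).all():
            raise ValueError("expression values must be finite")
        if self.unit in ("FPKM", "TPM") and (arr < 0).any():
            raise ValueError(f"negative values are not valid {self.unit}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes) -> "ExpressionMatrix":
        """Restrict to ``genes`` present in the matrix, preserving matrix order."""
        keep = [g for g in self.gene_ids if g in set(genes)]
        return ExpressionMatrix(self.values.loc[keep].copy(), self.unit)


@dataclass
class GeneSetCollection:
    """Named, non-empty gene sets with optional descriptions."""

    sets: dict[str, set[str]]
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, members in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} is empty")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets.items())


def read_expression(path, unit: str) -> ExpressionMatrix:
    """Read a gene × sample TSV; duplicate gene rows are collapsed by max (logged)."""
    with open(path, encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")[1:]
    seen = {c for c in header if header.count(c) > 1}
    if seen:
        raise ValueError(f"{path}: duplicate sample ids {sorted(seen)[:5]}")
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    df.index.name = None
    df.columns.name = None
    try:
        vals = df.astype(float)
    except ValueError:
        # locate the offending cell for a useful message
        for gene, row in df.iterrows():
            for col, cell in row.items():
                try:
                    float(cell)
                except (TypeError, ValueError):
                    raise ValueError(
                        f"{path}: non-numeric value {cell!r} at gene {gene!r}, sample {col!r}"
                    ) from None
        raise
    if vals.index.duplicated().any():
        ndup = int(vals.index.duplicated().sum())
        logger.warning("%s: %d duplicated gene rows collapsed by max", path, ndup)
        warnings.warn(f"{path}: {ndup} duplicated gene rows collapsed by max")
        vals = vals.groupby(level=0, sort=False).max()
    vals.index = vals.index.astype(str)
    vals.columns = vals.columns.astype(str)
    return ExpressionMatrix(vals, unit)


def write_expression(x: ExpressionMatrix, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out = x.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def fpkm_to_tpm(x: ExpressionMatrix) -> ExpressionMatrix:
    """Within-sample renormalisation: TPM_gs = FPKM_gs / Σ_g FPKM_gs × 10⁶.

    Every output column sums to 10⁶ (within floating point); a zero column
    has no defined TPM and raises, naming the sample.
    """
    if x.unit != "FPKM":
        raise ValueError(f"fpkm_to_tpm expects FPKM input, got {x.unit}")
    colsum = x.values.sum(axis=0)
    zero = colsum[colsum == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total FPKM: {list(zero.index)[:5]}")
    vals = x.values.div(colsum, axis=1) * 1e6
    return ExpressionMatrix(vals, "TPM")


def log2_transform(x: ExpressionMatrix, pseudocount: float = 1.0) -> ExpressionMatrix:
    """log2(value + pseudocount); the standard pre-analysis transform for TPM-scale data."""
    if x.unit not in ("FPKM", "TPM"):
        raise ValueError(f"log2_transform expects linear-scale input, got {x.unit}")
    if not pseudocount > 0:
        raise ValueError("pseudocount must be > 0")
    return ExpressionMatrix(np.log2(x.values + pseudocount), "LOG2")


def inner_join_genes(a: ExpressionMatrix, b: ExpressionMatrix) -> tuple[ExpressionMatrix, ExpressionMatrix]:
    """Restrict two cohorts to their shared genes (logged); no batch correction."""
    if a.unit != b.unit:
        raise ValueError(f"unit mismatch: {a.unit} vs {b.unit}")
    shared = [g for g in a.gene_ids if g in set(b.gene_ids)]
    if not shared:
        raise ValueError("cohorts share no genes")
    logger.info("inner join on %d shared genes (%d / %d dropped)", len(shared),
                len(a.gene_ids) - len(shared), len(b.gene_ids) - len(shared))
    return a.subset_genes(shared), b.subset_genes(shared)


def validate_clinical(df: pd.DataFrame, source: str = "clinical table") -> pd.DataFrame:
    missing = [c for c in CLINICAL_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{source}: missing required column(s) {missing}")
    if df["sample_id"].duplicated().any():
        dups = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{source}: duplicate sample_id {dups[:5]}")
    bad = df.index[~(df["os_time"].astype(float) > 0)].tolist()
    if bad:
        raise ValueError(f"{source}: os_time must be > 0 (row index {bad[:5]})")
    ev = df["os_event"].astype(float)
    if not ev.isin([0.0, 1.0]).all():
        bad = df.index[~ev.isin([0.0, 1.0])].tolist()
        raise ValueError(f"{source}: os_event must be 0/1 (row index {bad[:5]})")
    msi = df.get("msi")
    if msi is not None:
        known = msi.dropna().isin(MSI_LEVELS)
        if not known.all():
            bad_vals = msi.dropna()[~known].unique().tolist()
            raise ValueError(f"{source}: unknown msi level(s) {bad_vals}")
    out = df.copy()
    out["os_time"] = out["os_time"].astype(float)
    out["os_event"] = out["os_event"].astype(float).astype(int)
    return out


def read_clinical(path) -> pd.DataFrame:
    """Read the clinical table; missing optional values stay NA, never imputed."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return validate_clinical(df, source=str(path))


def write_clinical(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False, float_format=_FLOAT_FMT)


def read_mutations(path) -> pd.DataFrame:
    """Read a MAF-lite TSV (sample_id, gene, variant_class); duplicated rows rejected."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in MUTATION_REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    if df.duplicated().any():
        raise ValueError(f"{path}: {int(df.duplicated().sum())} fully duplicated mutation rows")
    return df


def write_mutations(df: pd.DataFrame, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, sep="\t", index=False)


def read_gmt(path) -> GeneSetCollection:
    """Parse a Broad-dialect GMT file: name, description, tab-separated members."""
    sets: dict[str, set[str]] = {}
    descriptions: dict[str, str] = {}
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: GMT line needs name, description and ≥1 member")
            name, desc, members = parts[0], parts[1], [m for m in parts[2:] if m]
            if name in sets:
                raise ValueError(f"{path}:{lineno}: duplicate gene-set name {name!r}")
            if not members:
                raise ValueError(f"{path}:{lineno}: gene set {name!r} is empty")
            sets[name] = set(members)
            descriptions[name] = desc
    if not sets:
        raise ValueError(f"{path}: no gene sets found")
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in collection.sets.items():
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc] + sorted(members)) + "\n")
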