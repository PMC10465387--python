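"""Bundled reference data: the m6A/m5C/m1A regulator panel.

The shipped panel (``data/regulator_panel_synthetic.tsv``) is a synthetic
reconstruction assembled from the RNA-modification regulator catalogs in the
literature: 23 m6A, 15 m5C and 10 m1A writer/reader/eraser genes (48 in
total), each gene carrying exactly one (modification, role) assignment.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

MODIFICATIONS = ("m6A", "m5C", "m1A")
ROLES = ("writer", "reader", "eraser")


def validate_regulator_catalog(df: pd.DataFrame, source: str = "regulator catalog") -> pd.DataFrame:
    required = ("gene", "modification", "role")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{source}: missing required column(s) {missing}")
    if df["gene"].duplicated().any():
        dups = df.loc[df["gene"].duplicated(), "gene"].tolist()
        raise ValueError(f"{source}: duplicate regulator gene(s) {dups[:5]}")
    bad_mod = df.loc[~df["modification"].isin(MODIFICATIONS), "modification"].unique().tolist()
    if bad_mod:
        raise ValueError(f"{source}: unknown modification(s) {bad_mod}")
    bad_role = df.loc[~df["role"].isin(ROLES), "role"].unique().tolist()
    if bad_role:
        raise ValueError(f"{source}: unknown role(s) {bad_role}")
    return df.reset_index(drop=True)


def load_regulator_catalog() -> pd.DataFrame:
    """Load the bundled 48-gene m6A/m5C/m1A regulator panel."""
    ref = resources.files("trimod").joinpath("data/regulator_panel_synthetic.tsv")
    with resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t")
    return validate_regulator_catalog(df, source="bundled regulator panel")


def read_regulator_catalog(path) -> pd.DataFrame:
    """Read a user-supplied regulator panel TSV (gene, modification, role)."""
    return validate_regulator_catalog(pd.read_csv(path, sep="\t"), source=str(path))


def regulator_counts(df: pd.DataFrame) -> dict[str, int]:
    """Per-modification regulator counts plus the panel total."""
    counts = {m: int((df["modification"] == m).sum()) for m in MODIFICATIONS}
    counts["total"] = int(len(df))
    return counts
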