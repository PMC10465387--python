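"""Single-sample gene-set enrichment (ssGSEA).

For one sample, genes are ranked by expression (descending; ties broken by
gene id for platform-independent determinism) and the enrichment score of a
set S is the summed gap between two cumulative distributions walked down the
ranked list: the rank-weighted ECDF of the members of S (weights r^α, where
r is the absolute rank, n for the top gene) and the unweighted ECDF of the
non-members:

    ES(S) = Σ_{i=1..n} [ P_in(i) − P_out(i) ]

The statistic depends on ranks only, so it is invariant under any monotone
per-sample transform of expression. α defaults to 0.25, the canonical
single-sample weighting.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import ExpressionMatrix, GeneSetCollection


@dataclass
class EnrichmentResult:
    scores: pd.DataFrame        # set × sample
    alpha: float
    normalized: bool = False


def ssgsea_scores(x: ExpressionMatrix, sets: GeneSetCollection, alpha: float = 0.25) -> EnrichmentResult:
    if alpha < 0:
        raise ValueError("alpha must be ≥ 0")
    genes = np.asarray(x.gene_ids)
    n = len(genes)
    gene_pos = {g: i for i, g in enumerate(genes)}

    matched: dict[str, np.ndarray] = {}
    for name, members in sets:
        idx = np.array(sorted(gene_pos[g] for g in members if g in gene_pos), dtype=int)
        if len(idx) < 2:
            warnings.warn(f"gene set {name!r} has < 2 genes in the matrix; dropped")
            continue
        if len(idx) == n:
            raise ValueError(f"gene set {name!r} covers every gene; no non-members to compare against")
        matched[name] = idx
    if not matched:
        raise ValueError("no gene set overlaps the expression matrix")

    vals = x.values.to_numpy(dtype=float)
    # tie-break by gene id: precompute the alphabetical rank of each gene
    gid_rank = np.argsort(np.argsort(genes.astype(str)))
    scores = np.empty((len(matched), vals.shape[1]))

    member_mask = np.zeros((len(matched), n), dtype=bool)
    for si, idx in enumerate(matched.values()):
        member_mask[si, idx] = True

    for j, sample in enumerate(x.sample_ids):
        col = vals[:, j]
        if col.max() == col.min():
            raise ValueError(f"sample {sample!r} has constant expression; ranks undefined")
        order = np.lexsort((gid_rank, -col))        # descending value, gene id ascending on ties
        weights = (np.arange(n, 0, -1, dtype=float)) ** alpha   # absolute rank n..1
        for si in range(len(matched)):
            in_sorted = member_mask[si][order]
            w_in = np.where(in_sorted, weights, 0.0)
            p_in = np.cumsum(w_in) / w_in.sum()
            p_out = np.cumsum(~in_sorted) / (n - in_sorted.sum())
            scores[si, j] = float(np.sum(p_in - p_out))

    frame = pd.DataFrame(scores, index=list(matched), columns=x.sample_ids)
    return EnrichmentResult(frame, alpha=alpha, normalized=False)


def minmax_normalize(res: EnrichmentResult) -> EnrichmentResult:
    """Rescale each set's scores to [0, 1] across samples; constant rows map to 0."""
    if res.scores.shape[1] < 2:
        raise ValueError("min–max normalisation needs ≥ 2 samples")
    lo = res.scores.min(axis=1)
    hi = res.scores.max(axis=1)
    span = hi - lo
    constant = span == 0
    if constant.any():
        warnings.warn(f"{int(constant.sum())} constant enrichment row(s) mapped to 0")
    span = span.mask(constant, 1.0)
    out = res.scores.sub(lo, axis=0).div(span, axis=0)
    out.loc[constant[constant].index] = 0.0
    return EnrichmentResult(out, alpha=res.alpha, normalized=True)
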