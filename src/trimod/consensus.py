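"""Resampling-based consensus clustering with CDF-area selection of k.

For each candidate k, ``reps`` subsamples of ``p_item · n`` samples are drawn
without replacement and clustered hierarchically; the consensus matrix entry
M_ij is the fraction of co-samplings of (i, j) in which the pair landed in the
same cluster. The empirical CDF of the upper-triangle consensus entries is
summarised by its exact area ∫₀¹ ECDF(t) dt, and k is chosen as the largest
value whose relative area gain over k−1 clears a threshold (the reproducible
analogue of reading the elbow off the CDF plot), with a manual override.

Used twice in the pipeline: on regulator expression to define the sample
clusters, and on prognostic-gene expression to define the gene clusters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist, squareform
from sklearn.metrics import adjusted_rand_score

from .io import ExpressionMatrix

_MAX_REDRAWS = 25


@dataclass
class ConsensusParams:
    k_range: tuple[int, ...] = tuple(range(2, 10))
    reps: int = 100
    p_item: float = 0.8
    distance: str = "one_minus_pearson"     # or "euclidean"
    linkage: str = "average"                # or "ward"
    seed: int = 0

    def __post_init__(self) -> None:
        self.k_range = tuple(int(k) for k in self.k_range)
        if not self.k_range or min(self.k_range) < 2:
            raise ValueError("k_range must contain integers ≥ 2")
        if self.reps < 2:
            raise ValueError("reps must be ≥ 2")
        if not 0 < self.p_item <= 1:
            raise ValueError("p_item must be in (0, 1]")
        if self.distance not in ("one_minus_pearson", "euclidean"):
            raise ValueError(f"unknown distance {self.distance!r}")
        if self.linkage not in ("average", "ward"):
            raise ValueError(f"unknown linkage {self.linkage!r}")


@dataclass
class ConsensusRun:
    """Full multi-k consensus result."""

    matrices: dict[int, np.ndarray]
    labels: dict[int, np.ndarray]
    areas: dict[int, float]
    delta_areas: dict[int, float]
    chosen_k: int
    sample_ids: list[str] = field(default_factory=list)

    @property
    def chosen_labels(self) -> np.ndarray:
        return self.labels[self.chosen_k]


def _as_values(x) -> tuple[np.ndarray, list[str]]:
    if isinstance(x, ExpressionMatrix):
        return x.values.to_numpy(dtype=float), x.sample_ids
    arr = np.asarray(x, dtype=float)
    return arr, [str(i) for i in range(arr.shape[1])]


def _zscore_rows(vals: np.ndarray) -> np.ndarray:
    """Z-score each feature (gene) across samples; constant rows map to 0."""
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    return (vals - mean) / sd


def _sample_distance(z: np.ndarray, distance: str) -> np.ndarray:
    """Square distance matrix between sample columns of a feature × sample block."""
    if distance == "one_minus_pearson":
        with np.errstate(invalid="ignore"):
            corr = np.corrcoef(z.T)
        d = 1.0 - corr
        if np.isnan(d).any():
            warnings.warn("constant sample in distance computation; distance set to max (1)")
            d = np.nan_to_num(d, nan=1.0)
        np.fill_diagonal(d, 0.0)
        return np.clip(d, 0.0, None)
    return squareform(pdist(z.T, metric="euclidean"))


def _cut(dist_sq: np.ndarray, k: int, method: str) -> np.ndarray:
    condensed = squareform(dist_sq, checks=False)
    tree = linkage(condensed, method=method)
    return fcluster(tree, k, criterion="maxclust")


def build_consensus(x, k: int, params: ConsensusParams,
                    rng: np.random.Generator | None = None) -> tuple[np.ndarray, np.ndarray]:
    """One consensus matrix and its final labels for a fixed k.

    Returns ``(M, labels)`` with M symmetric, entries in [0, 1] and unit
    diagonal; labels are the k-cut of a hierarchical clustering of 1 − M.
    """
    vals, _ = _as_values(x)
    n = vals.shape[1]
    if k < 2 or k > n:
        raise ValueError(f"k = {k} out of range for n = {n} samples")
    if n < 2 * k:
        raise ValueError(f"need ≥ 2k samples (n = {n}, k = {k})")
    if rng is None:
        rng = np.random.default_rng(params.seed)

    z = _zscore_rows(vals)
    m = int(np.ceil(params.p_item * n))
    hits = np.zeros((n, n))
    tries = np.zeros((n, n))

    for _ in range(params.reps):
        for _attempt in range(_MAX_REDRAWS):
            idx = np.sort(rng.choice(n, size=m, replace=False))
            sub = z[:, idx]
            labels_sub = _cut(_sample_distance(sub, params.distance), k, params.linkage)
            if len(np.unique(labels_sub)) == k:
                break
        else:
            raise RuntimeError(f"could not obtain {k} distinct clusters after {_MAX_REDRAWS} redraws")
        co = (labels_sub[:, None] == labels_sub[None, :]).astype(float)
        grid = np.ix_(idx, idx)
        hits[grid] += co
        tries[grid] += 1.0

    never = tries == 0
    np.fill_diagonal(never, False)
    if never.any():
        warnings.warn(f"{int(never.sum() // 2)} sample pairs never co-sampled; consensus set to 0")
    with np.errstate(invalid="ignore", divide="ignore"):
        M = np.where(tries > 0, hits / np.maximum(tries, 1.0), 0.0)
    np.fill_diagonal(M, 1.0)
    M = (M + M.T) / 2.0

    final = _cut(1.0 - M, k, params.linkage)
    if len(np.unique(final)) != k:
        raise RuntimeError(f"final consensus clustering produced fewer than {k} groups")
    return M, final


def cdf_and_area(M: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Empirical CDF of the upper-triangle consensus entries and its exact area.

    The area is ∫₀¹ ECDF(t) dt computed on the sorted unique-entry grid
    (with 1 appended), so perfect consensus (all entries 1) gives 0 and total
    dissensus (all entries 0) gives 1.
    """
    n = M.shape[0]
    if n < 2:
        raise ValueError("consensus matrix needs ≥ 2 samples")
    entries = M[np.triu_indices(n, k=1)]
    grid, counts = np.unique(entries, return_counts=True)
    cdf = np.cumsum(counts) / counts.sum()
    full_grid = grid if grid[-1] == 1.0 else np.append(grid, 1.0)
    full_cdf = cdf if grid[-1] == 1.0 else np.append(cdf, 1.0)
    # left-height step sum over [c_i, c_{i+1}) — the ECDF is constant there
    area = float(np.sum(np.diff(full_grid) * full_cdf[:-1]))
    return full_grid, full_cdf, area


def select_k(areas: dict[int, float], threshold: float = 0.10,
             force_k: int | None = None) -> int:
    """Largest k whose relative CDF-area gain clears ``threshold``.

    The first k in the range scores its absolute area (so it always qualifies
    for any threshold ≤ area); ``force_k`` overrides the rule entirely.
    """
    if not areas:
        raise ValueError("no areas supplied")
    ks = sorted(areas)
    if force_k is not None:
        if force_k not in areas:
            raise ValueError(f"force_k = {force_k} outside evaluated range {ks}")
        return int(force_k)
    deltas = delta_areas(areas)
    qualifying = [k for k in ks if deltas[k] >= threshold]
    if not qualifying:
        warnings.warn(f"no k cleared the delta-area threshold {threshold}; falling back to k = {ks[0]}")
        return ks[0]
    return max(qualifying)


def delta_areas(areas: dict[int, float]) -> dict[int, float]:
    """Relative area change: area(k_min) for the first k, else (a_k − a_{k−1})/a_{k−1}."""
    ks = sorted(areas)
    out: dict[int, float] = {}
    for i, k in enumerate(ks):
        if i == 0:
            out[k] = areas[k]
        else:
            prev = areas[ks[i - 1]]
            gain = areas[k] - prev
            out[k] = gain / prev if prev > 0 else (np.inf if gain > 0 else 0.0)
    return out


def run_consensus(x, params: ConsensusParams, threshold: float = 0.10,
                  force_k: int | None = None) -> ConsensusRun:
    """Consensus clustering over the whole k range plus CDF-area k selection."""
    vals, sample_ids = _as_values(x)
    rng = np.random.default_rng(params.seed)
    matrices: dict[int, np.ndarray] = {}
    labels: dict[int, np.ndarray] = {}
    areas: dict[int, float] = {}
    for k in params.k_range:
        M, lab = build_consensus(vals, k, params, rng=rng)
        matrices[k] = M
        labels[k] = lab
        areas[k] = cdf_and_area(M)[2]
    chosen = select_k(areas, threshold=threshold, force_k=force_k)
    return ConsensusRun(matrices, labels, areas, delta_areas(areas), chosen, sample_ids)


def cluster_labels_vs_truth(labels, truth_labels) -> float:
    """Adjusted Rand index between a clustering and the planted labels."""
    labels = np.asarray(labels)
    truth_labels = np.asarray(truth_labels)
    if labels.shape != truth_labels.shape:
        raise ValueError(f"length mismatch: {labels.shape} vs {truth_labels.shape}")
    return float(adjusted_rand_score(truth_labels, labels))
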