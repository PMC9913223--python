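"""kNN differential abundance and the neighborhood-overlap readout.

For a pair of samples sharing one embedding, every cell gets a multiscale
score: at each neighborhood size k, the imbalance (f_B - f_A)/(f_B + f_A) of
its k nearest neighbors' labels, with neighbor counts weighted inversely to
label totals so unequal sample sizes do not bias the score; the score is the
mean over k.  A permutation null of the score distribution yields thresholds,
and the overlap is the fraction of the focal sample's cells whose score stays
inside them — cells living in neighborhoods shared by both samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

DEFAULT_K_RANGE = tuple(range(50, 501, 50))


class DAError(ValueError):
    pass


@dataclass
class DAScoreResult:
    scores: np.ndarray            # per-cell mean-over-k score in [-1, 1]
    per_k: np.ndarray             # cells x len(k_range)
    k_range: tuple
    labels: np.ndarray            # per-cell sample label
    pair: tuple                   # (A, B)


@dataclass
class OverlapResult:
    overlap_fraction: float
    lo: float
    hi: float
    n_permutations: int
    alpha: float
    seed: int
    n_cells: int


def _neighbor_graph(coords: np.ndarray, k_max: int) -> np.ndarray:
    nn = NearestNeighbors(n_neighbors=k_max + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    return idx[:, 1:]  # drop self


def _scores_from_graph(neigh_idx: np.ndarray, is_b: np.ndarray,
                       k_range, w_a: float, w_b: float) -> np.ndarray:
    """Per-cell, per-k weighted imbalance from a fixed neighbor graph."""
    nb = is_b[neigh_idx].astype(np.float64)
    cum_b = np.cumsum(nb, axis=1)
    out = np.empty((neigh_idx.shape[0], len(k_range)))
    for j, k in enumerate(k_range):
        b = cum_b[:, k - 1]
        a = k - b
        wb, wa = b * w_b, a * w_a
        out[:, j] = (wb - wa) / (wb + wa)
    return out


def multiscale_score(coords: np.ndarray, labels, pair,
                     k_range=DEFAULT_K_RANGE) -> DAScoreResult:
    """Multiscale kNN imbalance score for every cell of the pair."""
    labels = np.asarray(labels)
    a, b = pair
    sel = np.isin(labels, [a, b])
    if not (labels == a).any() or not (labels == b).any():
        raise DAError(f"both labels of {pair} must be present")
    coords = np.asarray(coords)[sel]
    labels = labels[sel]
    n = len(labels)
    k_range = tuple(k for k in k_range if k < n)
    if not k_range:
        raise DAError("k_range is empty after capping at n_cells - 1")
    is_b = labels == b
    neigh_idx = _neighbor_graph(coords, max(k_range))
    per_k = _scores_from_graph(neigh_idx, is_b, k_range,
                               w_a=1.0 / (~is_b).sum(), w_b=1.0 / is_b.sum())
    return DAScoreResult(scores=per_k.mean(axis=1), per_k=per_k,
                         k_range=k_range, labels=labels, pair=(a, b))


def permutation_null(coords: np.ndarray, labels, pair,
                     k_range=DEFAULT_K_RANGE, n_perm: int = 100,
                     alpha: float = 0.05, seed: int = 0):
    """(lo, hi) score quantiles of the pooled label-permutation null."""
    if n_perm < 20:
        raise DAError("n_perm must be >= 20")
    labels = np.asarray(labels)
    a, b = pair
    sel = np.isin(labels, [a, b])
    coords = np.asarray(coords)[sel]
    labels = labels[sel]
    n = len(labels)
    k_range = tuple(k for k in k_range if k < n)
    if not k_range:
        raise DAError("k_range is empty after capping at n_cells - 1")
    neigh_idx = _neighbor_graph(coords, max(k_range))
    is_b = labels == b
    n_b = int(is_b.sum())
    rng = np.random.default_rng(seed)
    pooled = np.empty((n_perm, n))
    for p in range(n_perm):
        perm_b = np.zeros(n, dtype=bool)
        perm_b[rng.choice(n, size=n_b, replace=False)] = True
        per_k = _scores_from_graph(neigh_idx, perm_b, k_range,
                                   w_a=1.0 / (n - n_b), w_b=1.0 / n_b)
        pooled[p] = per_k.mean(axis=1)
    lo, hi = np.quantile(pooled.ravel(), [alpha / 2.0, 1.0 - alpha / 2.0])
    return float(lo), float(hi)


def overlap_fraction(result: DAScoreResult, thresholds, focal=None,
                     n_permutations: int = 0, alpha: float = 0.05,
                     seed: int = 0) -> OverlapResult:
    """Fraction of the focal sample's cells scoring inside the null band."""
    lo, hi = thresholds
    if lo > hi:
        raise DAError("thresholds must satisfy lo <= hi")
    focal = focal if focal is not None else result.pair[1]
    sel = result.labels == focal
    if not sel.any():
        raise DAError(f"focal sample {focal!r} absent from scored cells")
    inside = (result.scores[sel] >= lo) & (result.scores[sel] <= hi)
    return OverlapResult(overlap_fraction=float(inside.mean()), lo=float(lo),
                         hi=float(hi), n_permutations=n_permutations,
                         alpha=alpha, seed=seed, n_cells=int(sel.sum()))


def pair_overlap(coords: np.ndarray, labels, pair, k_range=DEFAULT_K_RANGE,
                 n_perm: int = 100, alpha: float = 0.05, seed: int = 0,
                 focal=None) -> OverlapResult:
    """Convenience: score, build the permutation null, and take the overlap."""
    scores = multiscale_score(coords, labels, pair, k_range)
    lo, hi = permutation_null(coords, labels, pair, k_range, n_perm, alpha, seed)
    return overlap_fraction(scores, (lo, hi), focal=focal,
                            n_permutations=n_perm, alpha=alpha, seed=seed)
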