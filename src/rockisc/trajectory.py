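"""Single-lineage trajectory inference and principal-curve pseudotime.

Cells of a compared pair of samples are clustered (k = 3, matching the
holoclone / clonogenic / differentiated stages), the cluster richest in
holoclone-assigned cells anchors the lineage, a minimum spanning tree over
cluster centroids orders the clusters, and a principal curve initialized on
the centroid path is iteratively refined (project cells to the curve, smooth
the cell cloud ordered by arc length).  Pseudotime is arc length along the
fitted curve, anchored at the holoclone end; a [0, 1] normalization by total
curve length is reported alongside.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d
from scipy.sparse.csgraph import minimum_spanning_tree
from sklearn.cluster import KMeans

from .preprocess import Embedding


class TrajectoryError(ValueError):
    pass


@dataclass
class ClusterModel:
    labels: np.ndarray
    centroids: np.ndarray
    method: str = "kmeans"

    @property
    def k(self):
        return self.centroids.shape[0]


@dataclass
class LineagePath:
    order: list                   # cluster ids from the start cluster
    edges: list                   # MST edge list (i, j)


@dataclass
class PseudotimeResult:
    pseudotime: np.ndarray        # arc length >= 0
    normalized: np.ndarray        # arc length / total curve length
    curve: np.ndarray             # ordered curve points in embedding space
    total_length: float
    sample: np.ndarray = None     # per-cell sample label
    converged: bool = True
    curve_lengths: list = field(default_factory=list)


def cluster_cells(e_or_coords, k: int = 3, seed: int = 0) -> ClusterModel:
    coords = e_or_coords.coords if isinstance(e_or_coords, Embedding) else np.asarray(e_or_coords)
    if len(coords) < k:
        raise TrajectoryError("fewer cells than clusters")
    for attempt in range(5):
        km = KMeans(n_clusters=k, n_init=10, random_state=seed + attempt).fit(coords)
        if len(np.unique(km.labels_)) == k:
            return ClusterModel(labels=km.labels_, centroids=km.cluster_centers_)
    raise TrajectoryError("k-means produced an empty cluster repeatedly")


def identify_start_cluster(cm: ClusterModel, type_labels) -> int:
    """Cluster with the largest holoclone fraction; ties go to the larger one."""
    type_labels = np.asarray(type_labels, dtype=object)
    if not (type_labels == "holoclone").any():
        raise TrajectoryError("no holoclone-assigned cells available")
    best, best_key = None, None
    for c in range(cm.k):
        sel = cm.labels == c
        size = int(sel.sum())
        frac = float((type_labels[sel] == "holoclone").mean()) if size else 0.0
        key = (frac, size, -c)
        if best_key is None or key > best_key:
            best, best_key = c, key
    return best


def build_lineage(cm: ClusterModel, start: int) -> LineagePath:
    """MST over centroid distances; lineage = traversal from the start cluster,
    longer branches last (ties broken by cluster id)."""
    k = cm.k
    d = np.linalg.norm(cm.centroids[:, None, :] - cm.centroids[None, :, :], axis=2)
    mst = minimum_spanning_tree(d).toarray()
    adj = {i: [] for i in range(k)}
    edges = []
    for i in range(k):
        for j in range(k):
            if mst[i, j] > 0:
                adj[i].append(j)
                adj[j].append(i)
                edges.append((i, j))

    def branch_length(node, parent):
        return max((d[node, c] + branch_length(c, node)
                    for c in adj[node] if c != parent), default=0.0)

    order = []

    def visit(node, parent):
        order.append(node)
        children = sorted((c for c in adj[node] if c != parent),
                          key=lambda c: (d[node, c] + branch_length(c, node), -c))
        for c in children:
            visit(c, node)

    visit(start, None)
    return LineagePath(order=order, edges=edges)


def _extend_ends(curve: np.ndarray, X: np.ndarray) -> np.ndarray:
    """Extrapolate the curve linearly past both ends so boundary cells
    project onto a tangent instead of piling up on the endpoints."""
    for end in (0, -1):
        tangent = curve[1] - curve[0] if end == 0 else curve[-1] - curve[-2]
        norm = np.linalg.norm(tangent)
        if norm == 0:
            continue
        tangent = tangent / norm
        anchor = curve[end]
        # farthest forward projection of any cell beyond this end
        reach = ((X - anchor) @ tangent)
        extent = reach.max() if end == -1 else -reach.min()
        if extent > 0:
            tip = anchor + tangent * extent * (1 if end == -1 else -1)
            curve = (np.vstack([curve, tip]) if end == -1
                     else np.vstack([tip, curve]))
    return curve


def _resample_polyline(points: np.ndarray, n: int) -> np.ndarray:
    seg = np.linalg.norm(np.diff(points, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(seg)])
    if cum[-1] == 0:
        return np.repeat(points[:1], n, axis=0)
    t = np.linspace(0.0, cum[-1], n)
    out = np.empty((n, points.shape[1]))
    for dim in range(points.shape[1]):
        out[:, dim] = np.interp(t, cum, points[:, dim])
    return out


def _project_to_polyline(X: np.ndarray, curve: np.ndarray):
    """Arc-length parameter of each cell's nearest point on the polyline."""
    p0 = curve[:-1]                       # segments x dims
    dvec = curve[1:] - p0
    seg_len2 = np.maximum((dvec ** 2).sum(axis=1), 1e-300)
    seg_len = np.sqrt(seg_len2)
    cum = np.concatenate([[0.0], np.cumsum(seg_len)])
    # cells x segments projection parameter
    t = np.einsum("cd,sd->cs", X, dvec)
    t -= (p0 * dvec).sum(axis=1)[None, :]
    t = np.clip(t / seg_len2[None, :], 0.0, 1.0)
    proj = p0[None, :, :] + t[:, :, None] * dvec[None, :, :]
    d2 = ((X[:, None, :] - proj) ** 2).sum(axis=2)
    best = d2.argmin(axis=1)
    rows = np.arange(len(X))
    lam = cum[best] + t[rows, best] * seg_len[best]
    return lam, float(cum[-1])


def fit_pseudotime(e_or_coords, lineage: LineagePath, cm: ClusterModel,
                   window_frac: float = 0.1, max_iter: int = 15,
                   tol: float = 1e-4, n_curve_points: int = 100) -> PseudotimeResult:
    """Principal-curve pseudotime along the ordered cluster path."""
    X = e_or_coords.coords if isinstance(e_or_coords, Embedding) else np.asarray(e_or_coords)
    n = len(X)
    path_pts = cm.centroids[lineage.order]
    curve = _resample_polyline(_extend_ends(path_pts, X), n_curve_points)
    lam, total = _project_to_polyline(X, curve)
    lengths = [total]
    converged = False
    window = max(5, int(round(window_frac * n))) | 1  # odd: direction-symmetric
    for _it in range(max_iter):
        order = np.argsort(lam, kind="stable")
        smoothed = uniform_filter1d(X[order].astype(float), size=window,
                                    axis=0, mode="nearest")
        curve = _resample_polyline(_extend_ends(smoothed, X), n_curve_points)
        new_lam, total = _project_to_polyline(X, curve)
        lengths.append(total)
        denom = max(total, 1e-12)
        delta = np.abs(new_lam - lam).mean() / denom
        lam = new_lam
        if delta < tol:
            converged = True
            break
    else:
        warnings.warn("principal curve did not converge; returning last iterate")

    # anchor pseudotime 0 at the start-cluster end of the curve
    ends = _project_to_polyline(cm.centroids[[lineage.order[0], lineage.order[-1]]],
                                curve)[0]
    if ends[0] > ends[1]:
        lam = total - lam
        curve = curve[::-1].copy()
    normalized = lam / max(total, 1e-12)
    return PseudotimeResult(pseudotime=lam, normalized=normalized, curve=curve,
                            total_length=float(total), converged=converged,
                            curve_lengths=lengths)


def fit_combined(e: Embedding, pair, type_labels, k: int = 3, seed: int = 0,
                 window_frac: float = 0.1, max_iter: int = 15,
                 tol: float = 1e-4) -> dict:
    """One curve on the union of a sample pair; pseudotimes split per sample.

    Fitting on the union puts both samples' pseudotimes on a common scale so
    their distributions are directly comparable.
    """
    samples = e.cell_meta["sample"].to_numpy()
    sel = np.isin(samples, list(pair))
    for s in pair:
        if not (samples == s).any():
            raise TrajectoryError(f"sample {s!r} is empty")
    coords = e.coords[sel]
    sub_samples = samples[sel]
    sub_types = np.asarray(type_labels, dtype=object)[sel]
    cm = cluster_cells(coords, k=k, seed=seed)
    start = identify_start_cluster(cm, sub_types)
    lineage = build_lineage(cm, start)
    fit = fit_pseudotime(coords, lineage, cm, window_frac=window_frac,
                         max_iter=max_iter, tol=tol)
    fit.sample = sub_samples
    out = {}
    for s in pair:
        in_s = sub_samples == s
        out[s] = PseudotimeResult(
            pseudotime=fit.pseudotime[in_s], normalized=fit.normalized[in_s],
            curve=fit.curve, total_length=fit.total_length,
            sample=sub_samples[in_s], converged=fit.converged,
            curve_lengths=fit.curve_lengths)
    out["combined"] = fit
    return out
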