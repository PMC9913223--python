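"""Normalization and dimensionality reduction.

Counts are variance-stabilized as analytic Pearson residuals of an
offset negative-binomial model: mu_gc = depth_c * (gene total / grand total),
r_gc = (x_gc - mu_gc) / sqrt(mu_gc + mu_gc^2 / theta), clipped to
+/- sqrt(n_cells).  Cell-cycle structure is scored with a binned
control-gene module score and removed by per-gene least-squares regression
on the S-minus-G2M score difference.  Donor (batch) structure is removed in
PCA space by an iterative soft-cluster centroid correction, with a plain
per-donor centering fallback.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans
from sklearn.decomposition import PCA
from sklearn.neighbors import NearestNeighbors

from .matrix import ExpressionMatrix


class NormalizationError(ValueError):
    pass


@dataclass
class NormalizedMatrix:
    """Pearson residuals (genes x cells) with the model's theta and clip bound."""

    residuals: np.ndarray
    gene_symbols: np.ndarray
    barcodes: np.ndarray
    cell_meta: pd.DataFrame
    theta: float
    clip_bound: float

    @property
    def n_genes(self):
        return self.residuals.shape[0]

    @property
    def n_cells(self):
        return self.residuals.shape[1]

    def gene_index(self, symbols):
        lookup = {s: i for i, s in enumerate(self.gene_symbols)}
        return np.asarray([lookup[s] for s in symbols if s in lookup], dtype=int)


@dataclass
class Embedding:
    """PCA (or corrected) coordinates, loadings and explained variance."""

    coords: np.ndarray           # cells x n_components
    loadings: np.ndarray         # genes x n_components
    explained_variance: np.ndarray
    barcodes: np.ndarray
    cell_meta: pd.DataFrame
    hvg: list = None

    @property
    def n_components(self):
        return self.coords.shape[1]

    def with_coords(self, coords) -> "Embedding":
        return Embedding(coords=coords, loadings=self.loadings,
                         explained_variance=self.explained_variance,
                         barcodes=self.barcodes, cell_meta=self.cell_meta,
                         hvg=self.hvg)


def pearson_normalize(m: ExpressionMatrix, theta: float = 100.0) -> NormalizedMatrix:
    """Analytic Pearson residuals with fixed dispersion theta."""
    counts = m.counts.astype(float)
    depth = np.asarray(counts.sum(axis=0)).ravel()
    if (depth == 0).any():
        raise NormalizationError(
            "zero-depth cells present; run QC filters before normalizing")
    gene_tot = np.asarray(counts.sum(axis=1)).ravel()
    grand = gene_tot.sum()
    mu = np.outer(gene_tot / grand, depth)
    with np.errstate(invalid="ignore", divide="ignore"):
        resid = (counts.toarray() - mu) / np.sqrt(mu + mu * mu / theta)
    resid[gene_tot == 0, :] = 0.0
    clip = np.sqrt(m.n_cells)
    np.clip(resid, -clip, clip, out=resid)
    return NormalizedMatrix(residuals=resid, gene_symbols=m.gene_symbols,
                            barcodes=m.barcodes, cell_meta=m.cell_meta,
                            theta=theta, clip_bound=clip)


def log_normalize(m: ExpressionMatrix, scale: float = 1e4) -> np.ndarray:
    """log1p depth-normalized expression (genes x cells, dense)."""
    counts = m.counts.astype(float)
    depth = np.asarray(counts.sum(axis=0)).ravel()
    depth = np.maximum(depth, 1.0)
    return np.log1p(counts.toarray() / depth[None, :] * scale)


def score_gene_set(expr: np.ndarray, gene_symbols, gene_set,
                   n_bins: int = 25, n_ctrl: int = 50,
                   seed: int = 0) -> np.ndarray:
    """Binned control-gene module score per cell.

    score = mean expression over the gene set minus the mean over control
    genes drawn (n_ctrl per set gene) from the same average-expression bins.
    """
    gene_symbols = np.asarray(gene_symbols, dtype=object)
    lookup = {s: i for i, s in enumerate(gene_symbols)}
    set_idx = np.asarray([lookup[g] for g in gene_set if g in lookup], dtype=int)
    if len(set_idx) == 0:
        raise NormalizationError("gene set has no genes in the panel")
    rng = np.random.default_rng(seed)
    avg = expr.mean(axis=1)
    order = np.argsort(avg, kind="stable")
    n_bins = min(n_bins, len(gene_symbols))
    bins = np.empty(len(gene_symbols), dtype=int)
    for b, chunk in enumerate(np.array_split(order, n_bins)):
        bins[chunk] = b
    ctrl_idx = []
    set_mask = np.zeros(len(gene_symbols), dtype=bool)
    set_mask[set_idx] = True
    for g in set_idx:
        pool = np.flatnonzero((bins == bins[g]) & ~set_mask)
        if len(pool) == 0:
            pool = np.flatnonzero(bins == bins[g])
        take = min(n_ctrl, len(pool))
        ctrl_idx.append(rng.choice(pool, size=take, replace=False))
    ctrl_idx = np.concatenate(ctrl_idx)
    return expr[set_idx].mean(axis=0) - expr[ctrl_idx].mean(axis=0)


def cell_cycle_scores(expr: np.ndarray, gene_symbols, s_genes, g2m_genes,
                      n_bins: int = 25, n_ctrl: int = 50,
                      seed: int = 0) -> pd.DataFrame:
    """S and G2M module scores and their difference (the removal covariate)."""
    s = score_gene_set(expr, gene_symbols, s_genes, n_bins, n_ctrl, seed)
    g2m = score_gene_set(expr, gene_symbols, g2m_genes, n_bins, n_ctrl, seed + 1)
    return pd.DataFrame({"s_score": s, "g2m_score": g2m, "cc_difference": s - g2m})


def regress_out(nm: NormalizedMatrix, covariate) -> NormalizedMatrix:
    """Per-gene OLS residualization on [1, covariate]."""
    cov = np.asarray(covariate, dtype=float)
    if not np.isfinite(cov).all():
        raise NormalizationError("covariate must be finite")
    if np.ptp(cov) == 0:
        warnings.warn("constant covariate; regress_out is a no-op")
        return NormalizedMatrix(nm.residuals.copy(), nm.gene_symbols, nm.barcodes,
                                nm.cell_meta, nm.theta, nm.clip_bound)
    X = np.column_stack([np.ones_like(cov), cov])
    beta, *_ = np.linalg.lstsq(X, nm.residuals.T, rcond=None)
    resid = nm.residuals - (X @ beta).T
    return NormalizedMatrix(resid, nm.gene_symbols, nm.barcodes,
                            nm.cell_meta, nm.theta, nm.clip_bound)


def select_hvg(nm: NormalizedMatrix, n: int = 3000) -> list:
    """Top-n genes by residual variance; ties broken lexicographically."""
    if n > nm.n_genes:
        raise NormalizationError(f"requested {n} HVGs from {nm.n_genes} genes")
    var = nm.residuals.var(axis=1)
    order = sorted(range(nm.n_genes),
                   key=lambda i: (-var[i], str(nm.gene_symbols[i])))
    return [nm.gene_symbols[i] for i in order[:n]]


def run_pca(nm: NormalizedMatrix, hvg=None, n_components: int = 50,
            seed: int = 0) -> Embedding:
    """Centered PCA of cells over the (HVG-restricted) residuals."""
    if hvg is None:
        hvg = list(nm.gene_symbols)
    idx = nm.gene_index(hvg)
    X = nm.residuals[idx].T  # cells x genes
    if n_components > min(X.shape):
        raise NormalizationError("n_components exceeds matrix rank bound")
    solver = "full" if min(X.shape) <= 1000 else "randomized"
    pca = PCA(n_components=n_components, svd_solver=solver, random_state=seed)
    coords = pca.fit_transform(X)
    return Embedding(coords=coords, loadings=pca.components_.T,
                     explained_variance=pca.explained_variance_,
                     barcodes=nm.barcodes, cell_meta=nm.cell_meta,
                     hvg=list(hvg))


def integrate_donors(e: Embedding, donors=None, mode: str = "cluster_weighted",
                     n_clusters: int = 10, max_iter: int = 10,
                     tol: float = 1e-4, seed: int = 0) -> Embedding:
    """Remove donor (batch) offsets from the embedding.

    cluster_weighted iterates soft k-means with per-cluster, per-donor
    centroid corrections (the mixture-correction core of batch integration);
    global_center simply recenters each donor on the grand mean.
    """
    if donors is None:
        donors = e.cell_meta["donor"].to_numpy()
    donors = np.asarray(donors)
    uniq = pd.unique(donors)
    if len(uniq) <= 1:
        return e.with_coords(e.coords.copy())
    if n_clusters < 1:
        raise NormalizationError("n_clusters must be >= 1")
    Z = e.coords.copy()
    grand = Z.mean(axis=0)
    if mode == "global_center":
        for d in uniq:
            sel = donors == d
            Z[sel] += grand - Z[sel].mean(axis=0)
        return e.with_coords(Z)
    if mode != "cluster_weighted":
        raise NormalizationError(f"unknown integration mode {mode!r}")

    n_clusters = min(n_clusters, len(Z))
    km = KMeans(n_clusters=n_clusters, n_init=4, random_state=seed).fit(Z)
    centroids = km.cluster_centers_.copy()
    donor_onehot = {d: donors == d for d in uniq}
    for _it in range(max_iter):
        d2 = ((Z[:, None, :] - centroids[None, :, :]) ** 2).sum(axis=2)
        sigma2 = max(np.median(d2.min(axis=1)), 1e-12)
        logr = -d2 / (2.0 * sigma2)
        logr -= logr.max(axis=1, keepdims=True)
        R = np.exp(logr)
        R /= R.sum(axis=1, keepdims=True)
        w_c = R.sum(axis=0)
        mu_c = (R.T @ Z) / np.maximum(w_c[:, None], 1e-12)
        correction = np.zeros_like(Z)
        for d, sel in donor_onehot.items():
            w_cd = R[sel].sum(axis=0)
            mu_cd = (R[sel].T @ Z[sel]) / np.maximum(w_cd[:, None], 1e-12)
            offset = np.where(w_cd[:, None] > 1.0, mu_cd - mu_c, 0.0)
            correction[sel] = R[sel] @ offset
        Z = Z - correction
        new_centroids = (R.T @ Z) / np.maximum(w_c[:, None], 1e-12)
        move = np.linalg.norm(new_centroids - centroids, axis=1).max()
        centroids = new_centroids
        if move < tol:
            break
    return e.with_coords(Z)


def knn_donor_mixing(coords: np.ndarray, donors, k: int = 30) -> float:
    """Mean fraction of a cell's k nearest neighbors from other donors."""
    donors = np.asarray(donors)
    nn = NearestNeighbors(n_neighbors=k + 1).fit(coords)
    _, idx = nn.kneighbors(coords)
    neigh = donors[idx[:, 1:]]
    return float((neigh != donors[:, None]).mean())
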