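"""Normalization, cell-cycle scoring/regression, HVG, PCA, donor integration."""

import numpy as np
import pandas as pd
import pytest
import scipy.linalg
import scipy.sparse as sp

import rockisc as rk
from rockisc import preprocess
from rockisc.matrix import ExpressionMatrix
from rockisc.preprocess import NormalizationError


def build(counts, genes=None, meta=None):
    counts = np.asarray(counts)
    genes = genes or [f"G{i}" for i in range(counts.shape[0])]
    barcodes = [f"B{i}" for i in range(counts.shape[1])]
    return ExpressionMatrix(sp.csr_matrix(counts), genes, barcodes, meta)


def test_pearson_residuals_null_model_centered():
    """Data from the offset model itself leaves near-zero per-gene means."""
    rng = np.random.default_rng(0)
    n_genes, n_cells, theta = 300, 800, 10.0
    base = rng.lognormal(0, 1, n_genes)
    depth = rng.lognormal(0, 0.3, n_cells)
    mu = np.outer(base, depth)
    counts = rng.negative_binomial(theta, theta / (theta + mu))
    nm = rk.pearson_normalize(build(counts), theta=theta)
    mean = nm.residuals.mean(axis=1)
    se = nm.residuals.std(axis=1, ddof=1) / np.sqrt(n_cells)
    frac_ok = (np.abs(mean) < 3 * se).mean()
    assert frac_ok >= 0.95


def test_pearson_residuals_model_exact_gene_is_zero():
    depth_profile = np.array([1, 2, 3, 4], dtype=float)
    counts = np.vstack([10 * depth_profile, 5 * depth_profile])
    nm = rk.pearson_normalize(build(counts))
    assert np.allclose(nm.residuals, 0.0, atol=1e-12)


def test_pearson_residuals_clip_extreme_cell():
    """A cell with an aberrant 10^6 count in an otherwise flat gene hits the
    +sqrt(n_cells) clip bound."""
    counts = np.ones((2, 100))
    counts[1, :] = 1e8       # a dominant housekeeping gene fixes the depths
    counts[0, 0] = 1e6
    nm = rk.pearson_normalize(build(counts))
    assert nm.clip_bound == pytest.approx(10.0)
    assert nm.residuals[0, 0] == pytest.approx(10.0)
    assert np.abs(nm.residuals).max() <= 10.0


def test_pearson_zero_depth_cell_errors():
    counts = np.array([[1, 0], [2, 0]])
    with pytest.raises(NormalizationError, match="QC"):
        rk.pearson_normalize(build(counts))


def test_score_gene_set_self_control_near_zero():
    rng = np.random.default_rng(1)
    expr = rng.normal(0, 1, (200, 50))
    genes = [f"G{i}" for i in range(200)]
    score = rk.score_gene_set(expr, genes, genes[:50], seed=0)
    assert np.abs(score).mean() < 0.2


def test_score_gene_set_detects_active_program(small_config):
    em, gt = rk.simulate_sample(small_config, "Control-6D-")
    logx = rk.log_normalize(em)
    s_genes, _ = rk.syndata.cell_cycle_gene_sets()
    score = rk.score_gene_set(logx, em.gene_symbols, s_genes, seed=0)
    active = (gt["cc_phase"] == "S").to_numpy()
    from scipy.stats import mannwhitneyu
    p = mannwhitneyu(score[active], score[~active], alternative="greater").pvalue
    assert p < 0.01


def test_score_gene_set_deterministic():
    rng = np.random.default_rng(2)
    expr = rng.normal(0, 1, (100, 30))
    genes = [f"G{i}" for i in range(100)]
    s1 = rk.score_gene_set(expr, genes, genes[:10], seed=7)
    s2 = rk.score_gene_set(expr, genes, genes[:10], seed=7)
    assert np.array_equal(s1, s2)


def _toy_nm(resid):
    resid = np.asarray(resid, float)
    return preprocess.NormalizedMatrix(
        residuals=resid, gene_symbols=np.asarray([f"G{i}" for i in range(len(resid))],
                                                 dtype=object),
        barcodes=np.asarray([f"B{i}" for i in range(resid.shape[1])], dtype=object),
        cell_meta=pd.DataFrame(index=range(resid.shape[1])), theta=100.0,
        clip_bound=np.inf)


def test_regress_out_removes_constructed_dependence():
    rng = np.random.default_rng(3)
    cov = rng.normal(0, 1, 500)
    gene = 2.0 * cov + rng.normal(0, 0.1, 500)
    orthogonal = rng.normal(0, 1, 500)
    orthogonal -= np.polyval(np.polyfit(cov, orthogonal, 1), cov)  # exactly orthogonal
    nm = _toy_nm(np.vstack([gene, orthogonal]))
    out = rk.regress_out(nm, cov)
    assert abs(np.corrcoef(out.residuals[0], cov)[0, 1]) < 0.05
    assert np.allclose(out.residuals[1], orthogonal, atol=1e-10)


def test_regress_out_is_idempotent_projection():
    rng = np.random.default_rng(4)
    nm = _toy_nm(rng.normal(0, 1, (20, 100)))
    cov = rng.normal(0, 1, 100)
    once = rk.regress_out(nm, cov)
    twice = rk.regress_out(once, cov)
    assert np.allclose(once.residuals, twice.residuals, atol=1e-10)
    assert (twice.residuals.var(axis=1) <= nm.residuals.var(axis=1) + 1e-12).all()


def test_regress_out_constant_covariate_warns_noop():
    nm = _toy_nm(np.random.default_rng(5).normal(0, 1, (3, 10)))
    with pytest.warns(UserWarning):
        out = rk.regress_out(nm, np.ones(10))
    assert np.array_equal(out.residuals, nm.residuals)


def test_select_hvg_planted_and_ties():
    rng = np.random.default_rng(6)
    resid = rng.normal(0, 1, (500, 200))
    planted = rng.choice(500, size=50, replace=False)
    resid[planted] *= 10
    nm = _toy_nm(resid)
    top = rk.select_hvg(nm, 50)
    assert set(top) == {f"G{i}" for i in planted}
    assert rk.select_hvg(nm, 500) is not None  # full panel allowed
    with pytest.raises(NormalizationError):
        rk.select_hvg(nm, 501)
    # ties resolved lexicographically
    tie = _toy_nm(np.vstack([np.tile([1.0, -1.0], 5)] * 3))
    assert rk.select_hvg(tie, 3) == ["G0", "G1", "G2"]


def test_pca_matches_dense_eigendecomposition():
    rng = np.random.default_rng(7)
    resid = rng.normal(0, 1, (50, 100))
    nm = _toy_nm(resid)
    emb = rk.run_pca(nm, n_components=5, seed=0)
    X = resid.T - resid.T.mean(axis=0)
    w, v = np.linalg.eigh(np.cov(X.T))
    top = v[:, np.argsort(w)[::-1][:5]]
    angles = scipy.linalg.subspace_angles(emb.loadings, top)
    assert np.max(angles) < 1e-6
    assert (np.diff(emb.explained_variance) <= 1e-12).all()
    assert np.allclose(emb.loadings.T @ emb.loadings, np.eye(5), atol=1e-8)


def test_pca_rank_and_reconstruction():
    rng = np.random.default_rng(8)
    low = rng.normal(0, 1, (30, 2)) @ rng.normal(0, 1, (2, 40))
    nm = _toy_nm(low)
    emb = rk.run_pca(nm, n_components=10, seed=0)
    assert emb.explained_variance[2:].max() < 1e-20 * emb.explained_variance[0] + 1e-12
    X = low.T
    recon = emb.coords @ emb.loadings.T + X.mean(axis=0)
    assert np.allclose(recon, X, atol=1e-8)


def _donor_embedding(offset_scale, seed=0, n=600):
    """Three biological blobs shared by three donors plus donor translations."""
    rng = np.random.default_rng(seed)
    blob = rng.integers(0, 3, n)
    donor = rng.integers(0, 3, n)
    centers = np.array([[0, 0], [6, 0], [3, 6]], float)
    offsets = rng.normal(0, offset_scale, (3, 2))
    coords = centers[blob] + offsets[donor] + rng.normal(0, 1, (n, 2))
    meta = pd.DataFrame({"donor": [f"d{d}" for d in donor]})
    emb = preprocess.Embedding(coords=coords, loadings=np.eye(2),
                               explained_variance=np.ones(2),
                               barcodes=np.asarray([f"B{i}" for i in range(n)],
                                                   dtype=object),
                               cell_meta=meta)
    return emb, blob, donor


def test_integrate_single_donor_is_identity():
    emb, *_ = _donor_embedding(0.0)
    emb.cell_meta["donor"] = "d0"
    out = rk.integrate_donors(emb)
    assert np.array_equal(out.coords, emb.coords)


def test_integrate_restores_donor_mixing():
    emb, blob, donor = _donor_embedding(4.0, seed=1)
    clean, _, _ = _donor_embedding(0.0, seed=1)
    mix_clean = preprocess.knn_donor_mixing(clean.coords,
                                            clean.cell_meta["donor"])
    mix_before = preprocess.knn_donor_mixing(emb.coords, emb.cell_meta["donor"])
    out = rk.integrate_donors(emb, n_clusters=3, seed=0)
    mix_after = preprocess.knn_donor_mixing(out.coords, out.cell_meta["donor"])
    assert mix_after > mix_before
    assert abs(mix_after - mix_clean) < 0.1 * max(mix_clean, 1e-9) + 0.05


def test_integrate_preserves_biology():
    from sklearn.metrics import silhouette_score
    emb, blob, _ = _donor_embedding(3.0, seed=2)
    before = silhouette_score(emb.coords, blob)
    out = rk.integrate_donors(emb, n_clusters=3, seed=0)
    after = silhouette_score(out.coords, blob)
    assert after > before - 0.05
    assert out.coords.shape == emb.coords.shape


def test_integrate_zero_effect_small_displacement():
    emb, *_ = _donor_embedding(0.0, seed=3)
    out = rk.integrate_donors(emb, n_clusters=3, seed=0)
    displacement = np.linalg.norm(out.coords - emb.coords, axis=1).mean()
    scale = emb.coords.std()
    assert displacement < 0.1 * scale


def test_global_center_mode():
    emb, *_ = _donor_embedding(5.0, seed=4)
    out = rk.integrate_donors(emb, mode="global_center")
    donors = emb.cell_meta["donor"].to_numpy()
    grand = emb.coords.mean(axis=0)
    for d in np.unique(donors):
        assert np.allclose(out.coords[donors == d].mean(axis=0), grand, atol=1e-9)
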