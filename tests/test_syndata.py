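"""Generator-level checks: determinism, ground-truth structure, noise model."""

import numpy as np
import pytest
from scipy import stats

import rockisc as rk
from rockisc.syndata import (ConfigurationError, PlacementError,
                             shifted_pseudotime_mean, type_from_pseudotime)


def test_fixed_seed_reproduces_counts_exactly():
    cfg = rk.SimulationConfig(n_cells_per_sample=500, n_genes=200, seed=42)
    em1, gt1 = rk.simulate_sample(cfg, "Control-6D-")
    em2, gt2 = rk.simulate_sample(cfg, "Control-6D-")
    assert (em1.counts != em2.counts).nnz == 0
    assert gt1.equals(gt2)


def test_counts_are_nonnegative_integers(control_sample):
    em, _ = control_sample
    assert em.counts.data.min() >= 0
    assert np.issubdtype(em.counts.dtype, np.integer)


def test_zero_contaminant_fraction_has_no_contaminants():
    cfg = rk.SimulationConfig(n_cells_per_sample=300, n_genes=300,
                              contaminant_fraction=0.0, seed=1)
    _, gt = rk.simulate_sample(cfg, "Control-6D-")
    assert not gt["true_type"].isin(["melanocyte", "fibroblast"]).any()
    assert np.isfinite(gt["true_pseudotime"]).all()


def test_contaminants_have_flagged_pseudotime(control_sample):
    _, gt = control_sample
    contam = gt["true_type"].isin(["melanocyte", "fibroblast"])
    assert gt.loc[contam, "true_pseudotime"].isna().all()
    assert np.isfinite(gt.loc[~contam, "true_pseudotime"]).all()


def test_type_is_deterministic_function_of_pseudotime(control_sample):
    _, gt = control_sample
    kera = ~gt["true_type"].isin(["melanocyte", "fibroblast"])
    pt = gt.loc[kera, "true_pseudotime"].to_numpy()
    expect = type_from_pseudotime(pt, (0.33, 0.66))
    assert (gt.loc[kera, "true_type"].to_numpy() == expect).all()


def test_no_effect_null_leaves_signatures_flat():
    """With marker_logfc=0 and no shift, signature means do not differ by type."""
    cfg = rk.SimulationConfig(n_cells_per_sample=2000, n_genes=300,
                              marker_logfc=0.0, gradient_logfc=0.0,
                              pseudotime_shift_treated=0.0,
                              contaminant_fraction=0.0, cellcycle_fraction=0.0,
                              donor_effect_sd=0.0, seed=2)
    em, gt = rk.simulate_sample(cfg, "Control-6D-")
    types = gt["true_type"].to_numpy()
    for sig, genes in rk.syndata.SIGNATURES.items():
        idx = em.gene_index(genes)
        score = np.asarray(em.counts[idx].mean(axis=0)).ravel()
        groups = [score[types == t] for t in rk.syndata.KERATINOCYTE_TYPES]
        for i in range(3):
            for j in range(i + 1, 3):
                assert stats.ttest_ind(groups[i], groups[j]).pvalue > 1e-3


def test_dispersion_matches_moment_estimate():
    """Pure NB config: pooled method-of-moments theta within 20% of truth."""
    theta = 10.0
    cfg = rk.SimulationConfig(n_cells_per_sample=500, n_genes=200,
                              nb_dispersion=theta, depth_lognormal_params=(0.0, 0.0),
                              donor_effect_sd=0.0, marker_logfc=0.0,
                              gradient_logfc=0.0, cellcycle_fraction=0.0,
                              contaminant_fraction=0.0, seed=3)
    em, _ = rk.simulate_sample(cfg, "Control-6D-")
    X = em.counts.toarray().astype(float)
    mean = X.mean(axis=1)
    var = X.var(axis=1, ddof=1)
    ok = (var > mean) & (mean > 0.5)
    est = np.median(mean[ok] ** 2 / (var[ok] - mean[ok]))
    assert abs(est - theta) / theta < 0.2


def test_study_has_four_labeled_samples(small_study):
    assert set(small_study) == set(rk.SAMPLE_CLASSES)
    for cls, (em, gt) in small_study.items():
        assert (gt["sample"] == cls).all()


def test_treated_mean_matches_truncated_shift_oracle():
    shift = 0.2
    cfg = rk.SimulationConfig(n_cells_per_sample=4000, n_genes=300,
                              pseudotime_shift_treated=shift,
                              contaminant_fraction=0.0, seed=4)
    _, gt_c = rk.simulate_sample(cfg, "Control-6D-")
    _, gt_t = rk.simulate_sample(cfg, "ROCKi-6D+")
    props = cfg.type_proportions_per_sample["Control-6D-"]
    expect = shifted_pseudotime_mean(props, cfg.cut_points, shift)
    base = shifted_pseudotime_mean(props, cfg.cut_points, 0.0)
    assert abs(gt_c["true_pseudotime"].mean() - base) < 0.015
    assert abs(gt_t["true_pseudotime"].mean() - expect) < 0.015
    assert expect - base < shift  # clamping at 1 loses part of the shift


def test_withdrawal_samples_share_pseudotime_distribution():
    """ROCKi-6D+6D- and Control-6D-6D- are exchangeable: the KS test rejects
    at the nominal rate only."""
    hits = 0
    n_rep = 50
    for seed in range(n_rep):
        cfg = rk.SimulationConfig(n_cells_per_sample=300, n_genes=300,
                                  contaminant_fraction=0.0, seed=seed)
        _, gt_c = rk.simulate_sample(cfg, "Control-6D-6D-")
        _, gt_r = rk.simulate_sample(cfg, "ROCKi-6D+6D-")
        p = stats.ks_2samp(gt_c["true_pseudotime"], gt_r["true_pseudotime"]).pvalue
        hits += p > 0.05
    assert hits >= 0.9 * n_rep


def test_marker_structure_is_recoverable():
    """Own-type signature score beats the other types in >=95% of cells at
    marker_logfc >= 1.5."""
    cfg = rk.SimulationConfig(n_cells_per_sample=1000, n_genes=400,
                              marker_logfc=1.5, contaminant_fraction=0.0, seed=5)
    em, gt = rk.simulate_sample(cfg, "Control-6D-")
    from rockisc.celltype import score_signatures
    sc = score_signatures(rk.pearson_normalize(em))
    assert (sc.idxmax(axis=1).to_numpy() == gt["true_type"].to_numpy()).mean() >= 0.95


def test_invalid_proportions_raise():
    with pytest.raises(ConfigurationError):
        rk.SimulationConfig(type_proportions_per_sample={
            c: (0.5, 0.5, 0.5) for c in rk.SAMPLE_CLASSES})


def test_plate_image_blank_and_determinism():
    img0, ref0 = rk.simulate_plate_image(0, seed=0, canvas_mm=20)
    assert len(ref0) == 0 and img0.dtype == np.uint8
    img1, _ = rk.simulate_plate_image(5, seed=9, canvas_mm=40)
    img2, _ = rk.simulate_plate_image(5, seed=9, canvas_mm=40)
    assert np.array_equal(img1, img2)


def test_plate_single_disc_geometry():
    img, ref = rk.simulate_plate_image(1, (1.0, 1.0), dpi=600.0, noise_sd=0.0,
                                       seed=0, canvas_mm=10)
    assert ref.loc[0, "area_mm2"] == pytest.approx(np.pi)
    # 600 DPI = 600/25.4 px per mm
    assert ref.loc[0, "radius_mm"] * 600 / 25.4 == pytest.approx(23.622, abs=0.01)
    dark = (img < 135).sum()
    assert dark == pytest.approx(np.pi * 23.622 ** 2, rel=0.05)


def test_plate_overfull_canvas_raises():
    with pytest.raises(PlacementError):
        rk.simulate_plate_image(50, (3.0, 3.0), dpi=600, seed=0, canvas_mm=20)
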