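"""Synthetic single-cell counts and plate scans with known ground truth.

The generator emulates the four-arm keratinocyte study design: a control
culture (Control-6D-), a six-day ROCK-inhibitor-treated culture (ROCKi-6D+),
and the two matched cultures after a further six days without treatment
(Control-6D-6D-, ROCKi-6D+6D-).  Each sample mixes three keratinocyte states
(holoclone-forming, clonogenic, terminally differentiated) laid out along a
single differentiation axis ("true pseudotime" in [0, 1]), plus contaminating
melanocytes and fibroblast-like cells, donor batch shifts and a two-program
(S / G2M) cell-cycle structure.

Counts are negative binomial.  For gene g in cell c the log2 mean is

    log2 mu_gc = log2 baseline_g
               + marker_logfc * 1[g in signature(type_c)]
               + gradient term (smooth in pseudotime, for a subset of genes)
               + cellcycle_logfc * 1[g in program(c)]
               + donor shift
               + log2 depth_c

Treatment acts as a location shift of the pseudotime distribution (clamped to
[0, 1]); withdrawal samples use shift zero, so reversibility is built in by
construction.  Keratinocyte type is always derived from pseudotime through
two fixed cut points, keeping type proportions and pseudotime shifts
mutually consistent.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .matrix import ExpressionMatrix

SAMPLE_CLASSES = ("Control-6D-", "ROCKi-6D+", "Control-6D-6D-", "ROCKi-6D+6D-")
TREATED_CLASS = "ROCKi-6D+"
CONTROL_CLASS = "Control-6D-"
KERATINOCYTE_TYPES = ("holoclone", "clonogenic", "differentiated")

MELANOCYTE_MARKERS = ("MLANA", "PMEL", "MITF")
FIBROBLAST_MARKERS = ("ACTG2", "DLK1", "MTRNR2L6", "MTRNR2L10", "MTRNR2L7",
                      "MTRNR2L1", "PRKAR2B", "NR2F1")
MITO_GENES = ("MT-CO1", "MT-CO2", "MT-CO3", "MT-ND1", "MT-ND2", "MT-ATP6", "MT-CYB")

SIGNATURES = {
    "holoclone": ("ANLN", "AURKB", "CCNA2", "CKAP2L", "FOXM1", "HMGB2", "LMNB1"),
    "clonogenic": ("KRT14", "TP63", "ITGA6", "ITGB1", "BIRC5"),
    "differentiated": ("SERPINB3", "SFN", "KRT10", "TGM1", "IVL", "SPINK5"),
}


class ConfigurationError(ValueError):
    pass


class PlacementError(RuntimeError):
    pass


def _load_gene_list(name: str) -> list[str]:
    text = resources.files("rockisc.data").joinpath(name).read_text()
    return [line.strip() for line in text.splitlines() if line.strip()]


def cell_cycle_gene_sets() -> tuple[list[str], list[str]]:
    """The shipped human S-phase and G2M-phase gene lists."""
    return _load_gene_list("s_genes.txt"), _load_gene_list("g2m_genes.txt")


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic four-sample design.

    Defaults follow the study layout: ~3000 cells loaded per sample, three
    donors, a treated pseudotime shift of 0.2 that vanishes on withdrawal.
    """

    n_cells_per_sample: int = 3000
    n_genes: int = 1000
    n_donors: int = 3
    type_proportions_per_sample: dict = field(default=None)
    pseudotime_shift_treated: float = 0.2
    donor_effect_sd: float = 0.2
    nb_dispersion: float = 10.0
    depth_lognormal_params: tuple = (0.0, 0.3)
    marker_logfc: float = 2.0
    gradient_logfc: float = 1.5
    n_gradient_genes: int = 40
    cellcycle_logfc: float = 1.0
    contaminant_fraction: float = 0.05
    cellcycle_fraction: float = 0.3
    cut_points: tuple = (0.33, 0.66)
    seed: int = 0

    def __post_init__(self):
        if self.type_proportions_per_sample is None:
            base = (0.30, 0.40, 0.30)
            self.type_proportions_per_sample = {c: base for c in SAMPLE_CLASSES}
        self.validate()

    def validate(self):
        if self.n_cells_per_sample <= 0 or self.n_genes <= 0 or self.n_donors <= 0:
            raise ConfigurationError("sizes must be positive")
        if not (0 <= self.contaminant_fraction < 1):
            raise ConfigurationError("contaminant_fraction must be in [0, 1)")
        if not (0 <= self.cellcycle_fraction <= 1):
            raise ConfigurationError("cellcycle_fraction must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ConfigurationError("nb_dispersion must be > 0")
        if self.pseudotime_shift_treated < 0 or self.donor_effect_sd < 0:
            raise ConfigurationError("shift and donor sd must be >= 0")
        for cls, p in self.type_proportions_per_sample.items():
            p = np.asarray(p, dtype=float)
            if p.shape != (3,) or (p < 0).any() or abs(p.sum() - 1.0) > 1e-12:
                raise ConfigurationError(
                    f"type proportions for {cls!r} must be a 3-vector summing to 1")

    def to_json(self, path=None) -> str:
        d = asdict(self)
        text = json.dumps(d, indent=2, default=list)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, text_or_path) -> "SimulationConfig":
        p = Path(str(text_or_path))
        text = p.read_text() if p.exists() else str(text_or_path)
        d = json.loads(text)
        if "depth_lognormal_params" in d:
            d["depth_lognormal_params"] = tuple(d["depth_lognormal_params"])
        if "cut_points" in d:
            d["cut_points"] = tuple(d["cut_points"])
        return cls(**d)


@dataclass
class GenePanel:
    """Deterministic gene panel: symbols, log2 baselines and structural roles."""

    symbols: np.ndarray
    log2_baseline: np.ndarray
    signature_idx: dict          # type -> int array
    gradient_up_idx: np.ndarray
    gradient_down_idx: np.ndarray
    s_idx: np.ndarray
    g2m_idx: np.ndarray
    melanocyte_idx: np.ndarray
    fibroblast_idx: np.ndarray
    vim_idx: int
    mito_idx: np.ndarray


def build_gene_panel(config: SimulationConfig) -> GenePanel:
    """Panel shared by all four samples of a study (a function of the seed)."""
    s_genes, g2m_genes = cell_cycle_gene_sets()
    sig_genes = [g for t in KERATINOCYTE_TYPES for g in SIGNATURES[t]]
    # cell-cycle program boosts never touch signature genes, so marker
    # structure and cell-cycle structure stay separable in the generator
    s_genes = [g for g in s_genes if g not in sig_genes]
    g2m_genes = [g for g in g2m_genes if g not in sig_genes]
    n_grad = config.n_gradient_genes
    grad_up = [f"GRADUP{i:03d}" for i in range(n_grad // 2)]
    grad_down = [f"GRADDN{i:03d}" for i in range(n_grad - n_grad // 2)]
    named = (sig_genes + list(MELANOCYTE_MARKERS) + list(FIBROBLAST_MARKERS)
             + ["VIM"] + list(MITO_GENES) + s_genes + g2m_genes
             + grad_up + grad_down)
    if config.n_genes < len(named):
        raise ConfigurationError(
            f"n_genes must be >= {len(named)} to hold the structured panel")
    filler = [f"GENE{i:04d}" for i in range(config.n_genes - len(named))]
    symbols = np.asarray(named + filler, dtype=object)
    pos = {g: i for i, g in enumerate(symbols)}

    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 11]))
    log2_baseline = rng.normal(np.log2(1.0), 1.0, size=config.n_genes)
    log2_baseline = np.clip(log2_baseline, np.log2(0.05), np.log2(8.0))

    def at(genes):
        return np.asarray([pos[g] for g in genes], dtype=int)

    sig_idx = {t: at(SIGNATURES[t]) for t in KERATINOCYTE_TYPES}
    mel_idx, fib_idx, mito_idx = at(MELANOCYTE_MARKERS), at(FIBROBLAST_MARKERS), at(MITO_GENES)
    # contaminant markers near-silent in keratinocytes; moderate mito content
    log2_baseline[mel_idx] = np.log2(0.005)
    log2_baseline[fib_idx] = np.log2(0.005)
    log2_baseline[mito_idx] = np.log2(2.0)
    log2_baseline[pos["VIM"]] = np.log2(0.3)
    for t in KERATINOCYTE_TYPES:
        log2_baseline[sig_idx[t]] = np.log2(1.0)
    log2_baseline[at(grad_up)] = np.log2(0.5)
    log2_baseline[at(grad_down)] = np.log2(0.5)

    return GenePanel(
        symbols=symbols,
        log2_baseline=log2_baseline,
        signature_idx=sig_idx,
        gradient_up_idx=at(grad_up),
        gradient_down_idx=at(grad_down),
        s_idx=at(s_genes),
        g2m_idx=at(g2m_genes),
        melanocyte_idx=mel_idx,
        fibroblast_idx=fib_idx,
        vim_idx=pos["VIM"],
        mito_idx=mito_idx,
    )


def donor_effects(config: SimulationConfig) -> np.ndarray:
    """Per-donor log2-scale gene shifts, shared across the study's samples."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 13]))
    return rng.normal(0.0, config.donor_effect_sd,
                      size=(config.n_donors, config.n_genes))


def type_from_pseudotime(pt: np.ndarray, cut_points) -> np.ndarray:
    lo, hi = cut_points
    out = np.empty(len(pt), dtype=object)
    out[:] = "clonogenic"
    out[pt < lo] = "holoclone"
    out[pt >= hi] = "differentiated"
    return out


def _draw_base_pseudotime(rng, n, proportions, cut_points):
    """Mixture over the three type intervals, uniform within each interval."""
    edges = np.asarray([0.0, cut_points[0], cut_points[1], 1.0])
    comp = rng.choice(3, size=n, p=np.asarray(proportions, dtype=float))
    return rng.uniform(edges[comp], edges[comp + 1])


def shifted_pseudotime_mean(proportions, cut_points, shift) -> float:
    """Closed-form mean of the clamp-to-1 shifted mixture (testing oracle)."""
    edges = np.asarray([0.0, cut_points[0], cut_points[1], 1.0])
    total = 0.0
    for t in range(3):
        a, b = edges[t] + shift, edges[t + 1] + shift
        w = proportions[t] / (b - a)
        lo, hi = min(a, 1.0), min(b, 1.0)
        total += w * (hi * hi - lo * lo) / 2.0 + w * (b - hi) * 1.0
    return total


def simulate_sample(config: SimulationConfig, sample_class: str):
    """One sample's counts plus ground truth (type, pseudotime, donor, phase)."""
    config.validate()
    if sample_class not in SAMPLE_CLASSES:
        raise ConfigurationError(f"unknown sample class {sample_class!r}")
    panel = build_gene_panel(config)
    donors = donor_effects(config)
    class_i = SAMPLE_CLASSES.index(sample_class)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 17, class_i]))

    n = config.n_cells_per_sample
    n_contam = int(round(config.contaminant_fraction * n))
    n_kera = n - n_contam
    n_mel = n_contam // 2
    n_fib = n_contam - n_mel

    if sample_class == TREATED_CLASS:
        base_props = config.type_proportions_per_sample[CONTROL_CLASS]
        pt = _draw_base_pseudotime(rng, n_kera, base_props, config.cut_points)
        pt = np.minimum(pt + config.pseudotime_shift_treated, 1.0)
    else:
        props = config.type_proportions_per_sample[sample_class]
        pt = _draw_base_pseudotime(rng, n_kera, props, config.cut_points)
    true_type = type_from_pseudotime(pt, config.cut_points)

    cell_type = np.concatenate([
        true_type,
        np.asarray(["melanocyte"] * n_mel + ["fibroblast"] * n_fib, dtype=object),
    ])
    true_pt = np.concatenate([pt, np.full(n_contam, np.nan)])
    donor = rng.integers(0, config.n_donors, size=n)
    phase = np.empty(n, dtype=object)
    phase[:] = "none"
    cycling = np.zeros(n, dtype=bool)
    cycling[:n_kera] = rng.random(n_kera) < config.cellcycle_fraction
    phase[cycling] = rng.choice(["S", "G2M"], size=int(cycling.sum()))

    mu_log, sigma_log = config.depth_lognormal_params
    depth = rng.lognormal(mu_log, sigma_log, size=n)

    log2mu = np.tile(panel.log2_baseline[:, None], (1, n))
    for t in KERATINOCYTE_TYPES:
        cells_t = np.flatnonzero(cell_type == t)
        if len(cells_t):
            log2mu[np.ix_(panel.signature_idx[t], cells_t)] += config.marker_logfc
    kera = np.arange(n_kera)
    if len(kera):
        log2mu[np.ix_(panel.gradient_up_idx, kera)] += config.gradient_logfc * pt
        log2mu[np.ix_(panel.gradient_down_idx, kera)] += config.gradient_logfc * (1.0 - pt)
    s_cells = np.flatnonzero(phase == "S")
    g2m_cells = np.flatnonzero(phase == "G2M")
    if len(s_cells):
        log2mu[np.ix_(panel.s_idx, s_cells)] += config.cellcycle_logfc
    if len(g2m_cells):
        log2mu[np.ix_(panel.g2m_idx, g2m_cells)] += config.cellcycle_logfc
    mel_cells = np.flatnonzero(cell_type == "melanocyte")
    fib_cells = np.flatnonzero(cell_type == "fibroblast")
    if len(mel_cells):
        log2mu[np.ix_(panel.melanocyte_idx, mel_cells)] = np.log2(6.0)
    if len(fib_cells):
        log2mu[np.ix_(panel.fibroblast_idx, fib_cells)] = np.log2(6.0)
        log2mu[panel.vim_idx, fib_cells] = np.log2(6.0)
    log2mu += donors[donor][:, :].T  # donors is (n_donors, n_genes)
    mu = np.exp2(log2mu) * depth[None, :]

    theta = config.nb_dispersion
    counts = rng.negative_binomial(theta, theta / (theta + mu))
    tag = f"S{class_i}"
    barcodes = np.asarray([f"{tag}-{i:05d}" for i in range(n)], dtype=object)
    ground_truth = pd.DataFrame({
        "sample": sample_class,
        "donor": [f"donor{d}" for d in donor],
        "true_type": cell_type,
        "true_pseudotime": true_pt,
        "cc_phase": phase,
    }, index=pd.Index(barcodes, name="barcode"))
    em = ExpressionMatrix(
        counts=sp.csr_matrix(counts),
        gene_symbols=panel.symbols,
        barcodes=barcodes,
        cell_meta=ground_truth,
    )
    return em, ground_truth


def simulate_study(config: SimulationConfig) -> dict:
    """All four samples keyed by sample class."""
    return {cls: simulate_sample(config, cls) for cls in SAMPLE_CLASSES}


# --------------------------------------------------------------------------
# plate scans for the colony-assay module


def simulate_plate_image(n_colonies: int, radius_range_mm=(1.0, 3.0),
                         dpi: float = 600.0, noise_sd: float = 5.0,
                         seed: int = 0, canvas_mm: float = 50.0,
                         allow_overlap: bool = False,
                         margin_mm: float = 1.0):
    """Synthetic 8-bit plate scan of dark quasi-circular colonies.

    Returns the image (uint8, light background) and a reference table with
    true centers (px), radii (mm), areas (mm^2) and circularity 1.0.
    """
    if dpi <= 0:
        raise ConfigurationError("dpi must be > 0")
    if radius_range_mm[0] <= 0 or radius_range_mm[1] < radius_range_mm[0]:
        raise ConfigurationError("invalid radius range")
    rng = np.random.default_rng(seed)
    px_per_mm = dpi / 25.4
    size = int(round(canvas_mm * px_per_mm))
    img = np.full((size, size), 230.0)

    centers, radii = [], []
    for _ in range(n_colonies):
        r_mm = rng.uniform(*radius_range_mm)
        r_px = r_mm * px_per_mm
        placed = False
        for _attempt in range(2000):
            margin = r_px + margin_mm * px_per_mm
            cy = rng.uniform(margin, size - margin)
            cx = rng.uniform(margin, size - margin)
            if allow_overlap or all(
                np.hypot(cy - y0, cx - x0) > (r_px + r0 + 3) for (y0, x0), r0 in
                zip(centers, [rr * px_per_mm for rr in radii])
            ):
                placed = True
                break
        if not placed:
            raise PlacementError(
                f"could not place colony {len(centers) + 1} without overlap")
        centers.append((cy, cx))
        radii.append(r_mm)

    yy, xx = np.mgrid[0:size, 0:size]
    for (cy, cx), r_mm in zip(centers, radii):
        r_px = r_mm * px_per_mm
        d = np.hypot(yy - cy, xx - cx)
        # soft 1-px edge so discs are quasi-circular after thresholding
        img = np.minimum(img, np.where(d <= r_px, 40.0,
                                       np.where(d <= r_px + 1.0,
                                                40.0 + 190.0 * (d - r_px), 230.0)))
    if noise_sd > 0:
        img = img + rng.normal(0.0, noise_sd, size=img.shape)
    img = np.clip(np.round(img), 0, 255).astype(np.uint8)

    reference = pd.DataFrame({
        "center_y_px": [c[0] for c in centers],
        "center_x_px": [c[1] for c in centers],
        "radius_mm": radii,
        "area_mm2": [np.pi * r * r for r in radii],
        "circularity": [1.0] * len(radii),
    })
    return img, reference
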