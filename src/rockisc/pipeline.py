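"""End-to-end study workflow.

One configuration and one seed drive: simulate (or load) the four samples,
QC each, and for each compared pair (control vs treated; control-withdrawal
vs treated-withdrawal) normalize, remove cell-cycle and donor structure,
classify cell types, compare compositions (T) and pseudotime distributions
(D) with bootstrap CIs, optionally quantify neighborhood overlap and
differential expression, and finally form the treatment/withdrawal ratio of
each statistic.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from . import celltype, dabundance, preprocess, qc, revstats, syndata, trajectory
from .matrix import concat_cells, read_mtx_triple
from .syndata import SAMPLE_CLASSES, SimulationConfig

log = logging.getLogger("rockisc")

TREATMENT_PAIR = ("Control-6D-", "ROCKi-6D+")
WITHDRAWAL_PAIR = ("Control-6D-6D-", "ROCKi-6D+6D-")


class PipelineError(RuntimeError):
    pass


@dataclass
class StudyConfig:
    """All knobs of the workflow; synthetic input by default."""

    sim: SimulationConfig = None
    mtx_paths: dict = None               # sample class -> directory, if loading
    qc_thresholds: dict = None           # sample -> QCThresholds (optional)
    theta: float = 100.0
    n_hvg: int = 500
    n_pcs: int = 30
    integrate: str = "cluster_weighted"  # or "global_center" / "none"
    n_boot: int = 1000
    alpha: float = 0.05
    k_range: tuple = dabundance.DEFAULT_K_RANGE
    n_perm: int = 50
    run_overlap: bool = True
    run_de: bool = True
    k_clusters: int = 3
    window_frac: float = 0.1
    seed: int = 0
    outdir: str = None

    def __post_init__(self):
        if self.sim is None and self.mtx_paths is None:
            self.sim = SimulationConfig(seed=self.seed)

    def hash(self) -> str:
        blob = json.dumps(_jsonable(asdict(self)), sort_keys=True)
        return hashlib.sha256(blob.encode()).hexdigest()[:16]


def _jsonable(x):
    if isinstance(x, dict):
        return {str(k): _jsonable(v) for k, v in x.items()}
    if isinstance(x, (list, tuple)):
        return [_jsonable(v) for v in x]
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        v = float(x)
        return v if np.isfinite(v) else str(v)
    if isinstance(x, float) and not np.isfinite(x):
        return str(x)
    return x


@dataclass
class PairResult:
    pair: tuple
    proportions: dict
    T: revstats.ComparisonResult
    D: revstats.ComparisonResult
    overlap: dabundance.OverlapResult = None
    de_summary: dict = None
    pseudotime: dict = None

    def summary(self) -> dict:
        out = {
            "pair": list(self.pair),
            "proportions": {s: list(map(float, p.values))
                            for s, p in self.proportions.items()},
            "T": {"statistic": self.T.statistic, "ci": list(self.T.ci)},
            "D": {"statistic": self.D.statistic, "ci": list(self.D.ci)},
        }
        if self.overlap is not None:
            out["overlap"] = {"fraction": self.overlap.overlap_fraction,
                              "lo": self.overlap.lo, "hi": self.overlap.hi}
        if self.de_summary is not None:
            out["de"] = self.de_summary
        return out


@dataclass
class StudyReport:
    config_hash: str
    seed: int
    qc: dict = field(default_factory=dict)
    pairs: dict = field(default_factory=dict)
    ratio_D: revstats.RatioResult = None
    ratio_T: revstats.RatioResult = None

    def to_dict(self) -> dict:
        out = {
            "config_hash": self.config_hash,
            "seed": self.seed,
            "qc": self.qc,
            "pairs": {"_vs_".join(k): v.summary() for k, v in self.pairs.items()},
        }
        for name, r in (("ratio_D", self.ratio_D), ("ratio_T", self.ratio_T)):
            if r is not None:
                out[name] = {"ratio": r.ratio, "ci": list(r.ci),
                             "undefined": r.undefined}
        return _jsonable(out)

    def to_json(self, path=None) -> str:
        text = json.dumps(self.to_dict(), indent=2, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text


def _load_samples(cfg: StudyConfig) -> dict:
    if cfg.mtx_paths is not None:
        return {cls: read_mtx_triple(path) for cls, path in cfg.mtx_paths.items()}
    data = syndata.simulate_study(cfg.sim)
    return {cls: em for cls, (em, _gt) in data.items()}


def analyze_pair(samples: dict, pair, cfg: StudyConfig, seed: int) -> PairResult:
    """The shared-embedding analysis of one control/treated pair."""
    m = concat_cells([samples[s] for s in pair])
    sample_labels = m.cell_meta["sample"].to_numpy()
    log.info("pair %s: %d cells x %d genes after QC", pair, m.n_cells, m.n_genes)

    nm = preprocess.pearson_normalize(m, theta=cfg.theta)
    logexpr = preprocess.log_normalize(m)
    s_genes, g2m_genes = syndata.cell_cycle_gene_sets()
    cc = preprocess.cell_cycle_scores(logexpr, m.gene_symbols, s_genes, g2m_genes,
                                      seed=seed)
    nm = preprocess.regress_out(nm, cc["cc_difference"].to_numpy())
    hvg = preprocess.select_hvg(nm, n=min(cfg.n_hvg, nm.n_genes))
    emb = preprocess.run_pca(nm, hvg=hvg, n_components=min(cfg.n_pcs, len(hvg)),
                             seed=seed)
    if cfg.integrate != "none" and "donor" in m.cell_meta.columns:
        emb = preprocess.integrate_donors(emb, mode=cfg.integrate, seed=seed)

    assignment = celltype.classify_em(nm, seed=seed)
    props = {s: celltype.proportions(assignment.labels, sample_labels == s)
             for s in pair}
    T = revstats.bootstrap_proportion_T(
        assignment.labels[sample_labels == pair[0]],
        assignment.labels[sample_labels == pair[1]],
        n_boot=cfg.n_boot, alpha=cfg.alpha, seed=seed + 1)

    fits = trajectory.fit_combined(emb, pair, assignment.labels,
                                   k=cfg.k_clusters, seed=seed,
                                   window_frac=cfg.window_frac)
    pt = {s: fits[s].normalized for s in pair}
    D = revstats.bootstrap_quantile_D(pt[pair[0]], pt[pair[1]],
                                      n_boot=cfg.n_boot, alpha=cfg.alpha,
                                      seed=seed + 2)

    overlap = None
    if cfg.run_overlap:
        overlap = dabundance.pair_overlap(emb.coords, sample_labels, pair,
                                          k_range=cfg.k_range, n_perm=cfg.n_perm,
                                          alpha=cfg.alpha, seed=seed + 3,
                                          focal=pair[1])
    de_summary = None
    if cfg.run_de:
        de = revstats.wilcoxon_de(logexpr, m.gene_symbols,
                                  sample_labels == pair[1])
        de_summary = {"n_up": de.n_up, "n_down": de.n_down,
                      "n_called": de.n_up + de.n_down}
    return PairResult(pair=tuple(pair), proportions=props, T=T, D=D,
                      overlap=overlap, de_summary=de_summary, pseudotime=pt)


def run_study(cfg: StudyConfig) -> StudyReport:
    """Execute the full workflow on both pairs; deterministic given the seed."""
    seeds = [int(s.generate_state(1)[0] % (2 ** 31))
             for s in np.random.SeedSequence(cfg.seed).spawn(4)]
    report = StudyReport(config_hash=cfg.hash(), seed=cfg.seed)
    try:
        raw = _load_samples(cfg)
    except Exception as exc:
        raise PipelineError(f"stage simulate/load failed: {exc}") from exc

    samples = {}
    for cls, m in raw.items():
        try:
            thresholds = (cfg.qc_thresholds or {}).get(cls)
            filtered, rep = qc.run_qc(m, thresholds=thresholds)
            samples[cls] = filtered
            report.qc[cls] = rep.stages
            log.info("QC %s: %d -> %d cells", cls, m.n_cells, filtered.n_cells)
        except Exception as exc:
            raise PipelineError(f"stage qc[{cls}] failed: {exc}") from exc

    for i, pair in enumerate((TREATMENT_PAIR, WITHDRAWAL_PAIR)):
        if not all(s in samples for s in pair):
            continue
        try:
            report.pairs[pair] = analyze_pair(samples, pair, cfg, seeds[i])
        except Exception as exc:
            raise PipelineError(f"stage pair{pair} failed: {exc}") from exc

    if TREATMENT_PAIR in report.pairs and WITHDRAWAL_PAIR in report.pairs:
        treat, withdraw = report.pairs[TREATMENT_PAIR], report.pairs[WITHDRAWAL_PAIR]
        report.ratio_D = revstats.ratio_with_ci(treat.D, withdraw.D,
                                                alpha=cfg.alpha, seed=seeds[2])
        report.ratio_T = revstats.ratio_with_ci(treat.T, withdraw.T,
                                                alpha=cfg.alpha, seed=seeds[3])
    if cfg.outdir:
        out = Path(cfg.outdir)
        out.mkdir(parents=True, exist_ok=True)
        report.to_json(out / "study_report.json")
    return report
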