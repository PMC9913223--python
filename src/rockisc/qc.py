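"""Quality control: per-cell metrics, basic and per-sample threshold filters,
and exclusion of contaminating non-keratinocytes by marker expression.

The filter chain order is fixed: basic detection filters, then per-sample
threshold filters, then marker-based exclusion of melanocytes and
mesenchymal-like cells.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .matrix import ExpressionMatrix
from .syndata import MELANOCYTE_MARKERS, FIBROBLAST_MARKERS

# melanocyte markers plus the eight mesenchymal-like cell markers
DEFAULT_EXCLUSION_MARKERS = tuple(MELANOCYTE_MARKERS) + tuple(FIBROBLAST_MARKERS)


class QCConfigurationError(ValueError):
    pass


@dataclass
class QCThresholds:
    """Per-sample bounds on detected genes, total counts and mito fraction."""

    min_genes: int = 0
    max_genes: float = np.inf
    max_counts: float = np.inf
    max_pct_mito: float = 100.0

    def __post_init__(self):
        if self.min_genes > self.max_genes:
            raise QCConfigurationError("min_genes > max_genes")
        if not (0 <= self.max_pct_mito <= 100):
            raise QCConfigurationError("max_pct_mito must be in [0, 100]")


@dataclass
class QCReport:
    stages: list = field(default_factory=list)

    def record(self, stage, cells_in, cells_out, genes_in, genes_out, **extra):
        if cells_out > cells_in or genes_out > genes_in:
            raise QCConfigurationError("a QC stage cannot add cells or genes")
        self.stages.append(dict(stage=stage, cells_in=int(cells_in),
                                cells_out=int(cells_out), genes_in=int(genes_in),
                                genes_out=int(genes_out), **extra))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages)


def compute_qc_metrics(m: ExpressionMatrix) -> pd.DataFrame:
    """Per-cell n_genes (detected), n_counts and percent mitochondrial counts.

    Mitochondrial genes are recognised by the "MT-" symbol prefix
    (case-insensitive).  pct_mito is 0 for empty cells.
    """
    counts = m.counts.tocsc()
    n_counts = np.asarray(counts.sum(axis=0)).ravel()
    n_genes = np.asarray((counts > 0).sum(axis=0)).ravel()
    is_mito = np.asarray([str(g).upper().startswith("MT-") for g in m.gene_symbols])
    mito_counts = (np.asarray(counts[is_mito].sum(axis=0)).ravel()
                   if is_mito.any() else np.zeros(m.n_cells))
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(n_counts > 0, 100.0 * mito_counts / np.maximum(n_counts, 1), 0.0)
    return pd.DataFrame({
        "n_genes": n_genes.astype(int),
        "n_counts": n_counts.astype(int),
        "pct_mito": pct,
    }, index=pd.Index(m.barcodes, name="barcode"))


def filter_basic(m: ExpressionMatrix, min_cells_per_gene: int = 3,
                 min_genes_per_cell: int = 200,
                 report: QCReport = None) -> ExpressionMatrix:
    """Drop genes detected in fewer than 3 cells, then cells with fewer than
    200 detected genes (single pass, in that order)."""
    gene_ncells = np.asarray((m.counts > 0).sum(axis=1)).ravel()
    keep_genes = gene_ncells >= min_cells_per_gene
    out = m.subset_genes(keep_genes)
    cell_ngenes = np.asarray((out.counts > 0).sum(axis=0)).ravel()
    keep_cells = cell_ngenes >= min_genes_per_cell
    out = out.subset_cells(keep_cells)
    if report is not None:
        report.record("basic", m.n_cells, out.n_cells, m.n_genes, out.n_genes)
    return out


def filter_thresholds(m: ExpressionMatrix, thresholds: dict | QCThresholds,
                      report: QCReport = None) -> ExpressionMatrix:
    """Keep cells within their sample's QC bounds.

    *thresholds* is either one QCThresholds applied to all cells or a mapping
    sample -> QCThresholds covering every sample present.
    """
    metrics = compute_qc_metrics(m)
    if isinstance(thresholds, QCThresholds):
        per_sample = {s: thresholds for s in _samples_of(m)}
    else:
        per_sample = thresholds
        missing = [s for s in _samples_of(m) if s not in per_sample]
        if missing:
            raise QCConfigurationError(f"no QC thresholds for samples: {missing}")
    samples = _sample_labels(m)
    keep = np.ones(m.n_cells, dtype=bool)
    for s, t in per_sample.items():
        in_s = samples == s
        ok = ((metrics["n_genes"] >= t.min_genes)
              & (metrics["n_genes"] <= t.max_genes)
              & (metrics["n_counts"] <= t.max_counts)
              & (metrics["pct_mito"] <= t.max_pct_mito)).to_numpy()
        keep[in_s] &= ok[in_s]
    out = m.subset_cells(keep)
    if report is not None:
        report.record("thresholds", m.n_cells, out.n_cells, m.n_genes, out.n_genes)
    return out


def exclude_marked_cells(m: ExpressionMatrix,
                         markers=DEFAULT_EXCLUSION_MARKERS,
                         min_count: int = 2,
                         report: QCReport = None) -> ExpressionMatrix:
    """Remove cells expressing any listed marker at >= min_count counts.

    The default min_count of 2 is the strict reading of a ">1 count"
    exclusion rule.  Missing markers are warned about and skipped.
    """
    if len(markers) == 0:
        warnings.warn("empty marker list: exclusion is a no-op")
        return m.subset_cells(np.ones(m.n_cells, dtype=bool))
    idx = m.gene_index(markers)
    present = [g for g in markers if g in set(m.gene_symbols.tolist())]
    if len(idx) == 0:
        warnings.warn("no exclusion markers found in panel; no cells removed")
        return m.subset_cells(np.ones(m.n_cells, dtype=bool))
    sub = m.counts[idx].toarray()
    hits = sub >= min_count
    removed_per_marker = {g: int(h.sum()) for g, h in zip(present, hits)}
    keep = ~hits.any(axis=0)
    out = m.subset_cells(keep)
    if report is not None:
        report.record("marker_exclusion", m.n_cells, out.n_cells,
                      m.n_genes, out.n_genes, removed_per_marker=removed_per_marker)
    return out


def run_qc(m: ExpressionMatrix, thresholds=None,
           markers=DEFAULT_EXCLUSION_MARKERS,
           min_count: int = 2) -> tuple[ExpressionMatrix, QCReport]:
    """The full fixed-order QC chain with a stage-by-stage report."""
    report = QCReport()
    out = filter_basic(m, report=report)
    if thresholds is not None:
        out = filter_thresholds(out, thresholds, report=report)
    out = exclude_marked_cells(out, markers=markers, min_count=min_count,
                               report=report)
    return out, report


def suggest_thresholds(m: ExpressionMatrix, n_mads: float = 5.0) -> dict:
    """MAD-based per-sample threshold suggestion (never applied silently)."""
    metrics = compute_qc_metrics(m)
    samples = _sample_labels(m)
    out = {}
    for s in pd.unique(samples):
        sub = metrics[samples == s]
        def hi(x):
            med = np.median(x)
            return med + n_mads * np.median(np.abs(x - med)) * 1.4826
        out[s] = QCThresholds(
            min_genes=200,
            max_genes=float(hi(sub["n_genes"])),
            max_counts=float(hi(sub["n_counts"])),
            max_pct_mito=float(min(100.0, hi(sub["pct_mito"]))),
        )
    return out


def _sample_labels(m: ExpressionMatrix) -> np.ndarray:
    if "sample" in m.cell_meta.columns:
        return m.cell_meta["sample"].to_numpy()
    return np.asarray(["__all__"] * m.n_cells, dtype=object)


def _samples_of(m: ExpressionMatrix):
    return pd.unique(_sample_labels(m))
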