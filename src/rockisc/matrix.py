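"""Sparse gene-by-cell count container and 10x-style Matrix Market I/O.

The count matrix is stored genes x cells (the orientation of a 10x
``matrix.mtx``), with unique gene symbols as rows and unique cell barcodes
as columns.  Per-cell annotations (sample class, donor, and optionally the
simulator's ground-truth columns) live in a DataFrame indexed by barcode.
"""

from __future__ import annotations

import gzip
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp


class FormatError(ValueError):
    """Raised when an on-disk matrix triple is internally inconsistent."""


@dataclass
class ExpressionMatrix:
    """Gene x cell counts with gene symbols, barcodes and cell metadata."""

    counts: sp.csr_matrix
    gene_symbols: np.ndarray
    barcodes: np.ndarray
    cell_meta: pd.DataFrame = field(default=None)

    def __post_init__(self):
        self.counts = sp.csr_matrix(self.counts)
        self.gene_symbols = np.asarray(self.gene_symbols, dtype=object)
        self.barcodes = np.asarray(self.barcodes, dtype=object)
        if self.counts.shape != (len(self.gene_symbols), len(self.barcodes)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_symbols)} genes x {len(self.barcodes)} barcodes"
            )
        for name, values in (("gene symbol", self.gene_symbols),
                             ("barcode", self.barcodes)):
            uniq, counts = np.unique(values.astype(str), return_counts=True)
            if (counts > 1).any():
                dup = uniq[counts > 1][0]
                raise FormatError(f"duplicate {name}: {dup!r}")
        if self.counts.nnz and self.counts.data.min() < 0:
            raise FormatError("negative counts")
        if self.cell_meta is None:
            self.cell_meta = pd.DataFrame(index=pd.Index(self.barcodes, name="barcode"))
        else:
            self.cell_meta = self.cell_meta.copy()
            self.cell_meta.index = pd.Index(self.barcodes, name="barcode")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    def gene_index(self, symbols) -> np.ndarray:
        """Row indices of *symbols*; missing symbols are dropped with a warning."""
        lookup = {s: i for i, s in enumerate(self.gene_symbols)}
        idx, missing = [], []
        for s in symbols:
            if s in lookup:
                idx.append(lookup[s])
            else:
                missing.append(s)
        if missing:
            warnings.warn(f"genes not in panel, skipped: {missing}")
        return np.asarray(idx, dtype=int)

    def subset_cells(self, mask) -> "ExpressionMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return ExpressionMatrix(
            counts=self.counts[:, idx],
            gene_symbols=self.gene_symbols,
            barcodes=self.barcodes[idx],
            cell_meta=self.cell_meta.iloc[idx],
        )

    def subset_genes(self, mask) -> "ExpressionMatrix":
        mask = np.asarray(mask)
        if mask.dtype == bool:
            idx = np.flatnonzero(mask)
        else:
            idx = mask
        return ExpressionMatrix(
            counts=self.counts[idx],
            gene_symbols=self.gene_symbols[idx],
            barcodes=self.barcodes,
            cell_meta=self.cell_meta,
        )


def concat_cells(matrices) -> ExpressionMatrix:
    """Concatenate samples cell-wise on the intersection of gene panels."""
    matrices = list(matrices)
    common = set(matrices[0].gene_symbols.tolist())
    for m in matrices[1:]:
        common &= set(m.gene_symbols.tolist())
    genes = [g for g in matrices[0].gene_symbols if g in common]
    blocks, barcodes, metas = [], [], []
    for m in matrices:
        idx = m.gene_index(genes)
        blocks.append(m.counts[idx])
        barcodes.append(m.barcodes)
        metas.append(m.cell_meta)
    return ExpressionMatrix(
        counts=sp.hstack(blocks, format="csr"),
        gene_symbols=np.asarray(genes, dtype=object),
        barcodes=np.concatenate(barcodes),
        cell_meta=pd.concat(metas, axis=0),
    )


def _open_maybe_gz(path: Path):
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def _find(directory: Path, stem: str) -> Path:
    for name in (stem, stem + ".gz"):
        p = directory / name
        if p.exists():
            return p
    raise FileNotFoundError(f"no {stem}[.gz] in {directory}")


def read_mtx_triple(path) -> ExpressionMatrix:
    """Read a 10x-style triple (matrix.mtx, features.tsv, barcodes.tsv).

    An optional ``cells.tsv`` with per-cell columns (sample, donor, ...) is
    picked up as cell metadata.
    """
    path = Path(path)
    with _open_maybe_gz(_find(path, "matrix.mtx")) as fh:
        counts = sp.csr_matrix(scipy.io.mmread(fh))
    with _open_maybe_gz(_find(path, "features.tsv")) as fh:
        genes = np.asarray([line.rstrip("\n").split("\t")[0] for line in fh if line.strip()],
                           dtype=object)
    with _open_maybe_gz(_find(path, "barcodes.tsv")) as fh:
        barcodes = np.asarray([line.strip() for line in fh if line.strip()], dtype=object)
    if counts.shape != (len(genes), len(barcodes)):
        raise FormatError(
            f"matrix is {counts.shape} but features/barcodes give "
            f"({len(genes)}, {len(barcodes)})"
        )
    meta = None
    try:
        cells = _find(path, "cells.tsv")
    except FileNotFoundError:
        cells = None
    if cells is not None:
        meta = pd.read_csv(cells, sep="\t", dtype={"barcode": str}).set_index("barcode")
        meta = meta.reindex(barcodes)
    counts.data = counts.data.astype(np.int64)
    return ExpressionMatrix(counts, genes, barcodes, meta)


def write_mtx_triple(m: ExpressionMatrix, path) -> None:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(path / "matrix.mtx", sp.coo_matrix(m.counts), field="integer")
    (path / "features.tsv").write_text(
        "".join(f"{g}\n" for g in m.gene_symbols))
    (path / "barcodes.tsv").write_text(
        "".join(f"{b}\n" for b in m.barcodes))
    if len(m.cell_meta.columns):
        m.cell_meta.to_csv(path / "cells.tsv", sep="\t")
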