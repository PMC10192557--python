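"""Reading, validation and normalization of single-cell count matrices.

Two on-disk layouts are supported:

* MatrixMarket coordinate integer (``<stem>.mtx``) with a companion gene list
  ``<stem>.genes.tsv`` (one symbol per line) and a separate cell-metadata TSV
  holding at least ``cell_id``, ``species`` and ``cluster`` columns;
* dense CSV with a header row of gene symbols and the first column of cell
  IDs, plus the same metadata TSV.

Orientation on disk (cells-by-genes vs genes-by-cells) is declared by the
caller, never guessed.  Normalization is counts-per-ten-thousand (CP10K)
per cell followed by the natural-log ``log1p`` transform, the standard
variance-stabilizing pipeline for this kind of data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse

CP10K_SCALE = 10_000.0

REQUIRED_META = ("species", "cluster")


@dataclass
class CountMatrix:
    """Raw integer counts, cells x genes, with per-cell annotations."""

    counts: np.ndarray          # (n_cells, n_genes) non-negative integers
    cell_ids: list[str]
    gene_ids: list[str]
    cell_meta: pd.DataFrame     # indexed by cell_id; has species and cluster columns

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        n_cells, n_genes = self.counts.shape
        if len(self.cell_ids) != n_cells or len(self.gene_ids) != n_genes:
            raise ValueError(
                f"ID lists do not match matrix shape {self.counts.shape}: "
                f"{len(self.cell_ids)} cells, {len(self.gene_ids)} genes"
            )
        for kind, ids in (("cell", self.cell_ids), ("gene", self.gene_ids)):
            if len(set(ids)) != len(ids):
                dup = sorted({i for i in ids if ids.count(i) > 1})[:5]
                raise ValueError(f"duplicate {kind} identifiers, e.g. {dup}")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(np.isfinite(self.counts)) or np.any(self.counts % 1 != 0):
                raise ValueError("counts must be finite integers")
            self.counts = self.counts.astype(np.int64)
        if self.counts.min() < 0:
            raise ValueError("counts must be non-negative")
        missing = [c for c in REQUIRED_META if c not in self.cell_meta.columns]
        if missing:
            raise ValueError(f"cell metadata lacks required columns {missing}")
        if list(self.cell_meta.index) != list(self.cell_ids):
            self.cell_meta = self.cell_meta.loc[self.cell_ids]
        clusters = self.cell_meta["cluster"]
        if clusters.isna().any() or (clusters.astype(str).str.len() == 0).any():
            bad = self.cell_meta.index[clusters.isna() | (clusters.astype(str).str.len() == 0)]
            raise ValueError(f"cells with empty cluster label: {list(bad[:5])}")

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    @property
    def clusters(self) -> pd.Series:
        return self.cell_meta["cluster"].astype(str)


@dataclass
class NormalizedMatrix:
    """Real-valued cells x genes matrix with a record of how it was produced."""

    values: np.ndarray
    cell_ids: list[str]
    gene_ids: list[str]
    cell_meta: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    @property
    def clusters(self) -> pd.Series:
        return self.cell_meta["cluster"].astype(str)


# ---------------------------------------------------------------------------
# I/O


def _load_meta(meta_path: Path, n_cells: int, cell_ids: list[str]) -> pd.DataFrame:
    meta = pd.read_csv(meta_path, sep="\t", dtype=str)
    if "cell_id" in meta.columns:
        meta = meta.set_index("cell_id")
    else:
        if len(meta) != n_cells:
            raise ValueError(
                f"metadata rows ({len(meta)}) do not match matrix cells ({n_cells})"
            )
        meta.index = pd.Index(cell_ids)
    if len(meta) != n_cells:
        raise ValueError(
            f"metadata rows ({len(meta)}) do not match matrix cells ({n_cells})"
        )
    missing = set(cell_ids) - set(meta.index)
    if missing:
        raise ValueError(f"metadata missing cells, e.g. {sorted(missing)[:5]}")
    return meta.loc[cell_ids]


def read_counts(matrix_path: str | Path, meta_path: str | Path,
                format: str = "mtx", orientation: str = "cells_by_genes") -> CountMatrix:
    """Read a count matrix plus cell metadata into a validated CountMatrix.

    ``orientation`` declares the on-disk layout; the in-memory result is
    always cells x genes.
    """
    matrix_path, meta_path = Path(matrix_path), Path(meta_path)
    if orientation not in ("cells_by_genes", "genes_by_cells"):
        raise ValueError("orientation must be 'cells_by_genes' or 'genes_by_cells'")
    if format == "mtx":
        mat = scipy.io.mmread(str(matrix_path)).toarray()
        genes_file = matrix_path.parent / (matrix_path.name[: -len(matrix_path.suffix)] + ".genes.tsv")
        if not genes_file.exists():
            raise FileNotFoundError(f"gene list {genes_file} not found next to {matrix_path}")
        gene_ids = genes_file.read_text().split()
        if orientation == "genes_by_cells":
            mat = mat.T
        n_cells = mat.shape[0]
        raw_meta = pd.read_csv(meta_path, sep="\t", dtype=str)
        if "cell_id" in raw_meta.columns:
            cell_ids = list(raw_meta["cell_id"])
        else:
            cell_ids = [f"cell{i}" for i in range(n_cells)]
        if len(cell_ids) != n_cells:
            raise ValueError(
                f"metadata rows ({len(cell_ids)}) do not match matrix cells ({n_cells})"
            )
        meta = _load_meta(meta_path, n_cells, cell_ids)
    elif format == "csv":
        df = pd.read_csv(matrix_path, index_col=0)
        if orientation == "genes_by_cells":
            df = df.T
        mat = df.to_numpy()
        cell_ids = [str(c) for c in df.index]
        gene_ids = [str(g) for g in df.columns]
        meta = _load_meta(meta_path, len(cell_ids), cell_ids)
    else:
        raise ValueError(f"unknown format {format!r}; use 'mtx' or 'csv'")

    if mat.shape[1] != len(gene_ids):
        raise ValueError(
            f"matrix has {mat.shape[1]} genes but gene list has {len(gene_ids)}"
        )
    return CountMatrix(counts=mat, cell_ids=list(cell_ids), gene_ids=list(gene_ids),
                       cell_meta=meta)


def write_counts(m: CountMatrix, matrix_path: str | Path, meta_path: str | Path,
                 format: str = "mtx") -> None:
    """Write a CountMatrix in one of the supported layouts (cells x genes)."""
    matrix_path, meta_path = Path(matrix_path), Path(meta_path)
    meta = m.cell_meta.copy()
    meta.insert(0, "cell_id", m.cell_ids)
    meta.to_csv(meta_path, sep="\t", index=False)
    if format == "mtx":
        scipy.io.mmwrite(str(matrix_path), scipy.sparse.coo_matrix(m.counts), field="integer")
        genes_file = matrix_path.parent / (matrix_path.name[: -len(matrix_path.suffix)] + ".genes.tsv")
        genes_file.write_text("\n".join(m.gene_ids) + "\n")
    elif format == "csv":
        pd.DataFrame(m.counts, index=m.cell_ids, columns=m.gene_ids).to_csv(matrix_path)
    else:
        raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# normalization


def cp10k(m: CountMatrix) -> NormalizedMatrix:
    """Scale each cell's counts to sum to 10,000 (counts per ten thousand)."""
    totals = m.counts.sum(axis=1)
    zero = totals == 0
    if zero.any():
        offenders = [m.cell_ids[i] for i in np.flatnonzero(zero)[:10]]
        raise ValueError(f"cells with zero total counts: {offenders}")
    values = m.counts / totals[:, None] * CP10K_SCALE
    return NormalizedMatrix(
        values=values, cell_ids=list(m.cell_ids), gene_ids=list(m.gene_ids),
        cell_meta=m.cell_meta,
        provenance={"transform": "cp10k", "scale": CP10K_SCALE},
    )


def log1p_transform(m: NormalizedMatrix) -> NormalizedMatrix:
    """Natural-log log1p of non-negative values (0 maps to 0, monotone)."""
    if m.values.min() < 0:
        raise ValueError("log1p input must be non-negative")
    return NormalizedMatrix(
        values=np.log1p(m.values), cell_ids=list(m.cell_ids),
        gene_ids=list(m.gene_ids), cell_meta=m.cell_meta,
        provenance={**m.provenance, "log": "log1p (natural)"},
    )


def lognormalize(m: CountMatrix) -> NormalizedMatrix:
    """CP10K followed by log1p — the standard per-cell normalization."""
    return log1p_transform(cp10k(m))
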