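"""Core data containers and I/O for trajectory differential-expression analysis.

The central container is :class:`CellExperiment`: a sparse genes x cells raw
count matrix together with per-cell pseudotime (a continuous ordering produced
upstream by any trajectory-inference tool) and a categorical branching-path
label.  Normalisation, QC and trajectory inference are out of scope here --
pseudotime and path membership are *inputs*.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.io import mmread, mmwrite

logger = logging.getLogger(__name__)

__all__ = [
    "CellExperiment",
    "load_cell_experiment",
    "RESULT_COLUMNS",
    "validate_result_table",
    "write_results",
    "read_results",
]


@dataclass
class CellExperiment:
    """Genes x cells raw counts plus per-cell pseudotime and path labels.

    Parameters
    ----------
    counts
        Sparse (CSR) matrix of non-negative integer counts, genes as rows.
    gene_ids, cell_ids
        Unique identifiers; lengths must match the matrix dimensions.
    pseudotime
        Per-cell non-negative, finite pseudotime values.
    path
        Per-cell branching-path label (at least one path; two or more for
        branch-aware analysis).
    """

    counts: sp.csr_matrix
    gene_ids: np.ndarray
    cell_ids: np.ndarray
    pseudotime: np.ndarray
    path: np.ndarray

    def __post_init__(self) -> None:
        if not sp.issparse(self.counts):
            self.counts = sp.csr_matrix(np.asarray(self.counts))
        self.counts = self.counts.tocsr()
        self.gene_ids = np.asarray(self.gene_ids, dtype=object)
        self.cell_ids = np.asarray(self.cell_ids, dtype=object)
        self.pseudotime = np.asarray(self.pseudotime, dtype=float)
        self.path = np.asarray(self.path, dtype=object)
        self._validate()

    def _validate(self) -> None:
        n_genes, n_cells = self.counts.shape
        if len(self.gene_ids) != n_genes:
            raise ValueError(
                f"gene_ids length {len(self.gene_ids)} != matrix rows {n_genes}"
            )
        if len(self.cell_ids) != n_cells:
            raise ValueError(
                f"cell_ids length {len(self.cell_ids)} != matrix columns {n_cells}"
            )
        for name, ids in (("gene", self.gene_ids), ("cell", self.cell_ids)):
            if len(set(ids)) != len(ids):
                raise ValueError(f"duplicate {name} identifiers are not allowed")
        if len(self.pseudotime) != n_cells or len(self.path) != n_cells:
            raise ValueError("pseudotime/path length must equal the number of cells")
        if not np.all(np.isfinite(self.pseudotime)):
            raise ValueError("pseudotime must be finite for every cell")
        if np.any(self.pseudotime < 0):
            raise ValueError("pseudotime must be non-negative")
        data = self.counts.data
        if data.size and (np.any(data < 0) or np.any(data != np.round(data))):
            raise ValueError("counts must be non-negative integers")

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_cells(self) -> int:
        return self.counts.shape[1]

    @property
    def paths(self) -> list:
        """Path labels in order of first appearance."""
        return list(pd.unique(self.path))

    def sparsity(self) -> float:
        """Fraction of zero entries in the count matrix."""
        return 1.0 - self.counts.count_nonzero() / (self.n_genes * self.n_cells)

    def write(self, directory: str | Path) -> None:
        """Write counts (MTX), gene/cell ids and cell metadata to a directory."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        mmwrite(str(directory / "matrix.mtx"), self.counts.tocoo(), field="integer")
        (directory / "genes.tsv").write_text(
            "\n".join(str(g) for g in self.gene_ids) + "\n"
        )
        (directory / "barcodes.tsv").write_text(
            "\n".join(str(c) for c in self.cell_ids) + "\n"
        )
        meta = pd.DataFrame(
            {
                "cell_id": self.cell_ids,
                "pseudotime": self.pseudotime,
                "path": self.path,
            }
        )
        meta.to_csv(directory / "cell_metadata.tsv", sep="\t", index=False,
                    float_format="%.17g")


def _read_matrix(matrix_source: str | Path, transpose: bool = False):
    """Read a count matrix from MTX (file or 10x-style directory), delimited
    text, or h5ad.  Returns (sparse counts, gene_ids or None, cell_ids or None).
    """
    src = Path(matrix_source)
    if not src.exists():
        raise FileNotFoundError(f"matrix source not found: {src}")
    gene_ids = cell_ids = None
    if src.is_dir():
        mtx = None
        for name in ("matrix.mtx", "matrix.mtx.gz"):
            if (src / name).exists():
                mtx = src / name
                break
        if mtx is None:
            raise FileNotFoundError(f"no matrix.mtx in directory {src}")
        counts = sp.csr_matrix(mmread(str(mtx)))
        for name in ("genes.tsv", "features.tsv"):
            if (src / name).exists():
                gene_ids = np.loadtxt(src / name, dtype=str, usecols=0, ndmin=1)
                break
        if (src / "barcodes.tsv").exists():
            cell_ids = np.loadtxt(src / "barcodes.tsv", dtype=str, usecols=0, ndmin=1)
    elif src.suffix == ".mtx" or src.name.endswith(".mtx.gz"):
        counts = sp.csr_matrix(mmread(str(src)))
    elif src.suffix == ".h5ad":
        import anndata  # deferred: optional heavy import

        adata = anndata.read_h5ad(src)
        x = adata.X
        counts = sp.csr_matrix(x).T  # AnnData is cells x genes
        gene_ids = np.asarray(adata.var_names)
        cell_ids = np.asarray(adata.obs_names)
    else:
        sep = "," if src.suffix == ".csv" else "\t"
        df = pd.read_csv(src, sep=sep, index_col=0)
        counts = sp.csr_matrix(df.to_numpy())
        gene_ids = np.asarray(df.index.astype(str))
        cell_ids = np.asarray(df.columns.astype(str))
    if transpose:
        counts = counts.T.tocsr()
        gene_ids, cell_ids = cell_ids, gene_ids
    return counts.tocsr(), gene_ids, cell_ids


def load_cell_experiment(
    matrix_source: str | Path,
    cell_metadata_source: str | Path,
    pseudotime_column: str = "pseudotime",
    path_column: str = "path",
    transpose: bool = False,
) -> CellExperiment:
    """Load and validate a :class:`CellExperiment` from disk.

    ``matrix_source`` may be a MatrixMarket file, a 10x-style directory
    (matrix.mtx + genes/features.tsv + barcodes.tsv), a dense CSV/TSV with gene
    rows, or an h5ad file.  ``cell_metadata_source`` is a delimited table with
    one row per cell, aligned with the matrix columns (or matched on a
    ``cell_id`` column when identifiers are available), containing the named
    pseudotime and path columns.  Cells with missing pseudotime or path are
    rejected; the reject count is logged.  Set ``transpose=True`` for
    cells x genes matrices.
    """
    counts, gene_ids, cell_ids = _read_matrix(matrix_source, transpose=transpose)
    sep = "," if str(cell_metadata_source).endswith(".csv") else "\t"
    meta = pd.read_csv(cell_metadata_source, sep=sep)
    for col in (pseudotime_column, path_column):
        if col not in meta.columns:
            raise ValueError(f"cell metadata lacks required column {col!r}")
    if len(meta) != counts.shape[1]:
        raise ValueError(
            f"metadata rows ({len(meta)}) do not match matrix cells ({counts.shape[1]})"
        )
    if cell_ids is not None and "cell_id" in meta.columns:
        order = pd.Index(meta["cell_id"].astype(str))
        if not order.equals(pd.Index([str(c) for c in cell_ids])):
            idx = order.get_indexer([str(c) for c in cell_ids])
            if np.any(idx < 0):
                raise ValueError("metadata cell_id does not match matrix barcodes")
            meta = meta.iloc[idx].reset_index(drop=True)
    if cell_ids is None:
        cell_ids = (
            meta["cell_id"].astype(str).to_numpy()
            if "cell_id" in meta.columns
            else np.array([f"cell{i}" for i in range(counts.shape[1])])
        )
    if gene_ids is None:
        gene_ids = np.array([f"gene{i}" for i in range(counts.shape[0])])

    keep = meta[pseudotime_column].notna() & meta[path_column].notna()
    n_reject = int((~keep).sum())
    if n_reject:
        logger.info("rejecting %d cells with missing pseudotime or path", n_reject)
        counts = counts[:, keep.to_numpy()]
        cell_ids = np.asarray(cell_ids)[keep.to_numpy()]
        meta = meta.loc[keep].reset_index(drop=True)
    return CellExperiment(
        counts=counts,
        gene_ids=gene_ids,
        cell_ids=cell_ids,
        pseudotime=meta[pseudotime_column].to_numpy(dtype=float),
        path=meta[path_column].to_numpy(dtype=object),
    )


# Deterministic column order for gene-level result tables.
RESULT_COLUMNS = [
    "gene",
    "p_value",
    "adjusted_p",
    "converged",
    "selected_terms",
    "term_pvalues",
    "coefficients",
    "r_squared",
    "classification",
]

CLASSIFICATIONS = {"branch-dependent", "time-only", "not significant"}


def validate_result_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check invariants of a gene-level result table and normalise columns."""
    missing = [c for c in RESULT_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"result table missing columns: {missing}")
    p = table["p_value"].to_numpy(dtype=float)
    if np.any((p < 0) | (p > 1) & np.isfinite(p)):
        raise ValueError("p_value outside [0,1]")
    r2 = table["r_squared"].to_numpy(dtype=float)
    ok = np.isfinite(r2)
    if np.any((r2[ok] < 0) | (r2[ok] > 1)):
        raise ValueError("r_squared outside [0,1]")
    bad = set(table["classification"].dropna()) - CLASSIFICATIONS
    if bad:
        raise ValueError(f"unknown classifications: {bad}")
    return table[RESULT_COLUMNS]


def write_results(table: pd.DataFrame, dest: str | Path) -> None:
    """Write a result table as TSV with deterministic column order.

    Floats are written at full precision so a reload reproduces them to
    better than 1e-12; non-float fields round-trip exactly.
    """
    dest = Path(dest)
    if dest.is_dir():
        raise IsADirectoryError(f"destination is a directory: {dest}")
    table = validate_result_table(table)
    table.to_csv(dest, sep="\t", index=False, float_format="%.17g")


def read_results(source: str | Path) -> pd.DataFrame:
    """Reload a result table written by :func:`write_results`."""
    df = pd.read_csv(
        source,
        sep="\t",
        dtype={
            "gene": str,
            "selected_terms": str,
            "term_pvalues": str,
            "coefficients": str,
            "classification": str,
        },
    )
    for col in ("selected_terms", "term_pvalues", "coefficients"):
        if col in df.columns:
            df[col] = df[col].fillna("")
    return validate_result_table(df)
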