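"""Reading and writing count matrices and result tables.

Supported input formats: 10x-style Matrix Market directories or .mtx files
(with features/barcodes sidecars, optionally gzipped), 10x HDF5 gene-barcode
matrices, and dense TSV (cells as rows, genes as columns, first column the
cell barcode).  On-disk gene-major orientations are transposed so that the
in-memory convention is always cells x genes.  Entries must be integral raw
UMIs; fractional values are rejected with the offending coordinate named.
"""

from __future__ import annotations

import gzip
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse as sp

from .containers import CountMatrix

__all__ = [
    "read_count_matrix",
    "write_count_matrix_mtx",
    "write_feature_table",
    "read_feature_table",
]

FEATURE_TABLE_COLUMNS = [
    "gene_id",
    "mean",
    "variance",
    "fano",
    "modified_fano",
    "pvalue",
    "fdr",
    "selected",
    "low_expression",
]


def _check_integral(mat: sp.coo_matrix) -> None:
    bad = np.flatnonzero(mat.data != np.round(mat.data))
    if bad.size:
        b = bad[0]
        raise ValueError(
            f"non-integer entry {mat.data[b]} at (row {int(mat.row[b])}, "
            f"col {int(mat.col[b])}): raw UMI counts are required"
        )


def _find_sidecar(directory: Path, stems) -> Path | None:
    for stem in stems:
        for suffix in ("", ".gz"):
            p = directory / f"{stem}{suffix}"
            if p.exists():
                return p
    return None


def _read_tsv_column(path: Path, column: int = 0) -> np.ndarray:
    opener = gzip.open if path.suffix == ".gz" else open
    with opener(path, "rt") as fh:
        vals = [line.rstrip("\n").split("\t")[column] for line in fh if line.strip()]
    return np.array(vals, dtype=object)


def _detect_format(path: Path) -> str:
    if path.is_dir():
        return "mtx"
    name = path.name.lower()
    if name.endswith((".mtx", ".mtx.gz")):
        return "mtx"
    if name.endswith((".h5", ".hdf5")):
        return "h5"
    if name.endswith((".tsv", ".tsv.gz", ".txt", ".txt.gz", ".csv", ".csv.gz")):
        return "tsv"
    raise ValueError(f"cannot infer format of {path}; pass format explicitly")


def read_count_matrix(path, fmt: str | None = None) -> CountMatrix:
    """Read a raw UMI count matrix as cells x genes.

    ``fmt`` is one of {"mtx", "h5", "tsv"} or None to auto-detect from the
    path.  Matrix Market input follows the 10x convention of genes as rows
    and is transposed; sidecar features/barcodes files, when present, are
    used both for identifiers and to disambiguate orientation.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(str(path))
    fmt = fmt or _detect_format(path)
    if fmt == "mtx":
        return _read_mtx(path)
    if fmt == "h5":
        return _read_10x_h5(path)
    if fmt == "tsv":
        return _read_dense_tsv(path)
    raise ValueError(f"unknown format {fmt!r}")


def _read_mtx(path: Path) -> CountMatrix:
    if path.is_dir():
        mtx = _find_sidecar(path, ["matrix.mtx"])
        if mtx is None:
            raise FileNotFoundError(f"no matrix.mtx[.gz] in {path}")
    else:
        mtx = path
    directory = mtx.parent
    mat = scipy.io.mmread(str(mtx)).tocoo()
    _check_integral(mat)
    features = _find_sidecar(directory, ["features.tsv", "genes.tsv"])
    barcodes = _find_sidecar(directory, ["barcodes.tsv"])
    gene_ids = _read_tsv_column(features) if features else None
    cell_ids = _read_tsv_column(barcodes) if barcodes else None
    n_rows, n_cols = mat.shape
    transpose = True  # 10x convention: genes as rows
    if gene_ids is not None or cell_ids is not None:
        if gene_ids is not None and len(gene_ids) == n_rows:
            transpose = True
        elif gene_ids is not None and len(gene_ids) == n_cols:
            transpose = False
        elif cell_ids is not None and len(cell_ids) == n_cols:
            transpose = True
        elif cell_ids is not None and len(cell_ids) == n_rows:
            transpose = False
        else:
            raise ValueError("sidecar lengths match neither matrix dimension")
    mat = mat.T if transpose else mat
    n_cells, n_genes = mat.shape
    if gene_ids is not None and len(gene_ids) != n_genes:
        raise ValueError("features sidecar length does not match the matrix")
    if cell_ids is not None and len(cell_ids) != n_cells:
        raise ValueError("barcodes sidecar length does not match the matrix")
    return CountMatrix(mat.tocsr(), cell_ids=cell_ids, gene_ids=gene_ids)


def _read_10x_h5(path: Path) -> CountMatrix:
    import h5py

    with h5py.File(path, "r") as fh:
        if "matrix" not in fh:
            raise ValueError(
                "unsupported HDF5 layout: expected a 10x v3 'matrix' group"
            )
        grp = fh["matrix"]
        shape = tuple(grp["shape"][:])  # (genes, cells)
        mat = sp.csc_matrix(
            (grp["data"][:], grp["indices"][:], grp["indptr"][:]), shape=shape
        )
        gene_ids = grp["features"]["id"][:].astype(str)
        cell_ids = grp["barcodes"][:].astype(str)
    coo = mat.tocoo()
    _check_integral(coo)
    return CountMatrix(mat.T.tocsr(), cell_ids=cell_ids, gene_ids=gene_ids)


def _read_dense_tsv(path: Path) -> CountMatrix:
    sep = "," if ".csv" in path.name.lower() else "\t"
    df = pd.read_csv(path, sep=sep, index_col=0)
    values = df.to_numpy()
    bad = np.argwhere(values != np.round(values))
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"non-integer entry {values[i, j]} at (cell {df.index[i]!r}, "
            f"gene {df.columns[j]!r}): raw UMI counts are required"
        )
    return CountMatrix(
        sp.csr_matrix(values.astype(np.int64)),
        cell_ids=df.index.astype(str).to_numpy(dtype=object),
        gene_ids=df.columns.astype(str).to_numpy(dtype=object),
    )


def write_count_matrix_mtx(counts: CountMatrix, directory) -> None:
    """Write a 10x-style Matrix Market directory (genes as rows)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    scipy.io.mmwrite(
        str(directory / "matrix.mtx"), counts.counts.T.tocoo(), field="integer"
    )
    with open(directory / "features.tsv", "w") as fh:
        for g in counts.gene_ids:
            fh.write(f"{g}\t{g}\tGene Expression\n")
    with open(directory / "barcodes.tsv", "w") as fh:
        for b in counts.cell_ids:
            fh.write(f"{b}\n")


def write_feature_table(table: pd.DataFrame, path) -> None:
    """TSV with fixed column order, 6 significant digits, input gene order."""
    out = table.copy()
    for col in FEATURE_TABLE_COLUMNS:
        if col not in out.columns:
            out[col] = False if col in ("selected", "low_expression") else np.nan
    out = out[FEATURE_TABLE_COLUMNS]
    for col in ("selected", "low_expression"):
        out[col] = out[col].map({True: "true", False: "false"})
    out.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_feature_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    for col in ("selected", "low_expression"):
        if col in df.columns and df[col].dtype == object:
            df[col] = df[col].map({"true": True, "false": False})
    return df
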