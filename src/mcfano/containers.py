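"""Core data containers for raw UMI count data.

The package works on unnormalized UMI counts held as a sparse cells x genes
matrix.  All downstream statistics (depth-corrected means, modified corrected
Pearson residuals and Fano factors) are computed from these raw counts; no
normalization is ever applied to the counts themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

__all__ = ["CountMatrix", "DepthCorrectedMeans", "ModelConfig", "ResidualMatrix"]


def _as_string_ids(ids, n: int, prefix: str) -> np.ndarray:
    if ids is None:
        return np.array([f"{prefix}{i}" for i in range(n)], dtype=object)
    out = np.asarray(ids, dtype=object)
    if out.shape != (n,):
        raise ValueError(f"expected {n} {prefix} identifiers, got {out.shape}")
    return out


@dataclass
class CountMatrix:
    """Raw UMI counts for ``n_cells`` cells by ``n_genes`` genes.

    Parameters
    ----------
    counts
        Sparse (or dense, converted on construction) non-negative integer
        matrix, cells as rows and genes as columns.
    cell_ids, gene_ids
        Optional identifier vectors; synthesized if omitted.
    """

    counts: sp.csr_matrix
    cell_ids: np.ndarray = field(default=None)
    gene_ids: np.ndarray = field(default=None)

    def __post_init__(self):
        mat = self.counts
        if not sp.issparse(mat):
            mat = sp.csr_matrix(np.asarray(mat))
        mat = mat.tocsr()
        if mat.ndim != 2:
            raise ValueError("counts must be a 2-D matrix")
        data = mat.data
        if data.size and np.any(data < 0):
            raise ValueError("counts must be non-negative")
        if data.size and not np.allclose(data, np.round(data)):
            raise ValueError("counts must be integer-valued raw UMIs")
        mat.data = np.asarray(np.round(data), dtype=np.int64)
        mat.eliminate_zeros()
        self.counts = mat
        self.cell_ids = _as_string_ids(self.cell_ids, mat.shape[0], "cell_")
        self.gene_ids = _as_string_ids(self.gene_ids, mat.shape[1], "gene_")

    # -- basic geometry ----------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.counts.shape

    # -- margins -----------------------------------------------------------
    def cell_totals(self) -> np.ndarray:
        """Per-cell sequencing depths (row sums), float for downstream math."""
        return np.asarray(self.counts.sum(axis=1)).ravel().astype(float)

    def gene_totals(self) -> np.ndarray:
        """Per-gene total UMI counts (column sums)."""
        return np.asarray(self.counts.sum(axis=0)).ravel().astype(float)

    def grand_total(self) -> float:
        return float(self.counts.sum())

    def gene_means(self) -> np.ndarray:
        """Simple per-gene mean UMI per cell."""
        return self.gene_totals() / self.n_cells

    def cells_expressing(self) -> np.ndarray:
        """Number of cells with a nonzero count, per gene."""
        return np.asarray((self.counts > 0).sum(axis=0)).ravel()

    # -- slicing -----------------------------------------------------------
    def subset_genes(self, index) -> "CountMatrix":
        index = np.asarray(index)
        return CountMatrix(self.counts[:, index], self.cell_ids, self.gene_ids[index])

    def subset_cells(self, index) -> "CountMatrix":
        index = np.asarray(index)
        return CountMatrix(self.counts[index], self.cell_ids[index], self.gene_ids)

    def to_dense(self) -> np.ndarray:
        return np.asarray(self.counts.todense())


@dataclass
class DepthCorrectedMeans:
    """Null expectations mu_ij = d_i * m_j / T stored via their factors.

    d_i is cell i's sequencing depth, m_j gene j's total count and T the grand
    total.  The full n x g matrix is the outer product d m^T / T and is only
    materialized in gene chunks, so memory stays O(n + g) outside of chunked
    passes.  Row sums of mu equal row sums of counts, column sums equal column
    sums, by construction.
    """

    cell_totals: np.ndarray
    gene_totals: np.ndarray
    grand_total: float

    def __post_init__(self):
        self.cell_totals = np.asarray(self.cell_totals, dtype=float)
        self.gene_totals = np.asarray(self.gene_totals, dtype=float)
        self.grand_total = float(self.grand_total)
        if self.grand_total <= 0:
            raise ValueError("grand total of counts must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.cell_totals.size, self.gene_totals.size)

    def block(self, gene_index) -> np.ndarray:
        """Dense mu block for the given gene indices (cells x block)."""
        m = self.gene_totals[gene_index]
        return np.outer(self.cell_totals, m) / self.grand_total

    def column(self, j: int) -> np.ndarray:
        return self.cell_totals * (self.gene_totals[j] / self.grand_total)

    def dense(self) -> np.ndarray:
        return np.outer(self.cell_totals, self.gene_totals) / self.grand_total


@dataclass
class ModelConfig:
    """Numerical settings for the Poisson-lognormal null.

    cv is the consensus coefficient of variation c of underlying biological
    expression (dimensionless); moment_order is how many moments of the null
    distribution of the modified corrected Fano factor are carried into the
    tail estimate; min_cells_expressed is the gene-filtering floor.
    """

    cv: float = 0.5
    moment_order: int = 5
    min_cells_expressed: int = 3

    def __post_init__(self):
        if self.cv < 0:
            raise ValueError("cv must be >= 0")
        if self.moment_order < 2:
            raise ValueError("moment_order must be >= 2")


@dataclass
class ResidualMatrix:
    """Dense residual matrix with a tag for which residual it holds.

    kind is one of ``plain_pearson``, ``corrected_pearson`` (depth-corrected
    mean, Poisson denominator) or ``modified_corrected`` (depth-corrected mean,
    Poisson-lognormal denominator).
    """

    values: np.ndarray
    kind: str

    _KINDS = ("plain_pearson", "corrected_pearson", "modified_corrected")

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.kind not in self._KINDS:
            raise ValueError(f"kind must be one of {self._KINDS}")

    @property
    def n_cells(self) -> int:
        return self.values.shape[0]
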