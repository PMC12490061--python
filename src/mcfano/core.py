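"""Depth-corrected means, Pearson residuals and Fano factors.

Under the null hypothesis every cell draws gene j's transcripts from the same
underlying distribution, so the expected count for gene j in cell i is the
depth-corrected mean mu_ij = d_i * m_j / T (d_i = cell depth, m_j = gene
total, T = grand total).  The modified corrected Pearson residual scales the
deviation from mu_ij by the standard deviation of a Poisson-lognormal count,

    P'_ij = (x_ij - mu_ij) / sqrt(mu_ij * (1 + c^2 * mu_ij)),

where c is the coefficient of variation of biological expression among
equivalent cells.  The modified corrected Fano factor is the mean squared
residual, phi'_j = sum_i P'_ij^2 / (n - 1); its null expectation is ~1
regardless of the underlying expression distribution, because the denominator
is exactly the Poisson-lognormal variance.

All statistics here are computed from raw, unnormalized UMI counts.  For
large matrices phi' is accumulated sparsely: the contribution of zero counts,
(0 - mu)^2 / (mu (1 + c^2 mu)) = mu / (1 + c^2 mu), is summed in gene chunks
from the outer-product structure of mu, so no dense n x g residual matrix is
ever formed.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp

from .containers import CountMatrix, DepthCorrectedMeans, ModelConfig, ResidualMatrix

__all__ = [
    "filter_genes",
    "depth_corrected_means",
    "plain_fano",
    "pearson_residuals",
    "modified_corrected_residuals",
    "modified_corrected_fano",
    "modified_corrected_fano_from_counts",
]

# Gene chunk width for dense mu blocks; bounds peak memory at ~n * chunk doubles.
_CHUNK = 512


class EmptyResultError(ValueError):
    """Raised when a filtering step removes every gene."""


def filter_genes(counts: CountMatrix, min_cells: int = 3) -> CountMatrix:
    """Drop genes detected (count > 0) in fewer than ``min_cells`` cells.

    The cell set and gene order are unchanged.  ``min_cells=0`` is the
    identity.  Raises :class:`EmptyResultError` if no gene survives.
    """
    if min_cells < 0:
        raise ValueError("min_cells must be >= 0")
    if min_cells == 0:
        return counts
    keep = counts.cells_expressing() >= min_cells
    if not keep.any():
        raise EmptyResultError(
            f"no gene is expressed in at least {min_cells} cells"
        )
    return counts.subset_genes(np.flatnonzero(keep))


def depth_corrected_means(counts: CountMatrix) -> DepthCorrectedMeans:
    """Per-cell per-gene null expectations mu_ij = d_i * m_j / T."""
    total = counts.grand_total()
    if total <= 0:
        raise ValueError("count matrix has zero grand total")
    return DepthCorrectedMeans(counts.cell_totals(), counts.gene_totals(), total)


def plain_fano(counts: CountMatrix, return_moments: bool = False):
    """Per-gene Fano factor phi_j = sigma^2_j / mu_j (sample variance, ddof=1).

    Genes with zero mean have an undefined Fano factor and are reported as
    NaN rather than silently 0.  With ``return_moments=True`` the per-gene
    means and variances are returned as well.
    """
    n = counts.n_cells
    if n < 2:
        raise ValueError("at least 2 cells are required for a Fano factor")
    mean = counts.gene_means()
    sq = np.asarray(counts.counts.power(2).sum(axis=0)).ravel()
    var = (sq - n * mean**2) / (n - 1)
    var = np.maximum(var, 0.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        fano = np.where(mean > 0, var / np.where(mean > 0, mean, 1.0), np.nan)
    if return_moments:
        return fano, mean, var
    return fano


def pearson_residuals(counts: CountMatrix) -> ResidualMatrix:
    """Plain Pearson residuals (x_ij - mu_j) / sqrt(mu_j), mu_j the gene mean."""
    mean = counts.gene_means()
    dense = counts.to_dense().astype(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = (dense - mean) / np.sqrt(mean)
    vals[:, mean == 0] = 0.0
    return ResidualMatrix(vals, "plain_pearson")


def modified_corrected_residuals(
    counts: CountMatrix,
    mu: DepthCorrectedMeans | None = None,
    config: ModelConfig | float = 0.0,
) -> ResidualMatrix:
    """Dense modified corrected Pearson residuals P'_ij.

    Intended for modest matrix sizes (tests, small data); the selection
    pipeline uses :func:`modified_corrected_fano_from_counts`, which never
    materializes residuals.  Entries with mu_ij = 0 and x_ij = 0 are defined
    as 0; mu_ij = 0 with x_ij > 0 indicates inconsistent margins and raises.
    """
    cv = config.cv if isinstance(config, ModelConfig) else float(config)
    if cv < 0:
        raise ValueError("cv must be >= 0")
    if mu is None:
        mu = depth_corrected_means(counts)
    if mu.shape != counts.shape:
        raise ValueError("mu dimensions do not match counts")
    dense = counts.to_dense().astype(float)
    mu_dense = mu.dense()
    zero_mu = mu_dense == 0
    if np.any(dense[zero_mu] > 0):
        raise ValueError("mu_ij = 0 where x_ij > 0: margins inconsistent with counts")
    denom = np.sqrt(mu_dense * (1.0 + cv**2 * mu_dense))
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = (dense - mu_dense) / denom
    vals[zero_mu] = 0.0
    return ResidualMatrix(vals, "modified_corrected")


def modified_corrected_fano(residuals: ResidualMatrix) -> np.ndarray:
    """phi'_j = sum_i P'_ij^2 / (n - 1) from a dense residual matrix."""
    if residuals.kind != "modified_corrected":
        raise ValueError("residuals must be of kind 'modified_corrected'")
    n = residuals.n_cells
    if n < 2:
        raise ValueError("at least 2 cells are required")
    return np.sum(residuals.values**2, axis=0) / (n - 1)


def modified_corrected_fano_from_counts(
    counts: CountMatrix,
    cv: float,
    mu: DepthCorrectedMeans | None = None,
    chunk: int = _CHUNK,
) -> np.ndarray:
    """Sparse-first phi'_j directly from raw counts.

    Sum of squared residuals = (zero-count contribution over all entries)
    - (that contribution at nonzero entries) + (actual residual^2 at nonzero
    entries).  The zero-count term mu/(1 + c^2 mu) is accumulated from dense
    mu blocks built gene-chunk by gene-chunk out of the margin vectors.
    """
    if cv < 0:
        raise ValueError("cv must be >= 0")
    n, g = counts.shape
    if n < 2:
        raise ValueError("at least 2 cells are required")
    if mu is None:
        mu = depth_corrected_means(counts)
    c2 = cv * cv
    d = mu.cell_totals
    m = mu.gene_totals
    T = mu.grand_total

    csc = counts.counts.tocsc()
    ss = np.zeros(g)
    for lo in range(0, g, chunk):
        hi = min(lo + chunk, g)
        mu_blk = np.outer(d, m[lo:hi]) / T
        # sum over ALL cells of the zero-count term per gene
        ss[lo:hi] = np.sum(mu_blk / (1.0 + c2 * mu_blk), axis=0)
    # correct the nonzero entries
    indptr, indices, data = csc.indptr, csc.indices, csc.data
    for j in range(g):
        s, e = indptr[j], indptr[j + 1]
        if s == e:
            continue
        mu_j = d[indices[s:e]] * (m[j] / T)
        denom = mu_j * (1.0 + c2 * mu_j)
        x = data[s:e].astype(float)
        ss[j] += np.sum((x - mu_j) ** 2 / denom) - np.sum(mu_j / (1.0 + c2 * mu_j))
    return ss / (n - 1)
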