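"""Consensus coefficient-of-variation estimation.

The only hyperparameter of the null model is c, the coefficient of variation
of underlying biological expression among equivalent cells.  Assuming c is
roughly shared across genes and that most genes are not differentially
expressed, c is identified by the flatness of phi' against expression: when
the supplied c is too small, highly expressed genes show phi' > 1 (their
lognormal variance is under-discounted); too large, phi' < 1.  We therefore
fit c by minimizing the absolute slope of an ordinary least-squares fit of
log10(phi'_j) on log10(mu_j) over genes with mean expression in [0.01, 10].
Genes with phi' = 0 (constant genes) are excluded from the log fit.  Low
expression genes anchor the fit because c barely influences phi' when
mu_ij << 1.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import minimize_scalar

from .containers import CountMatrix
from .core import depth_corrected_means, modified_corrected_fano_from_counts

__all__ = ["CvFitResult", "trend_slope", "fit_consensus_cv"]

DEFAULT_WINDOW = (0.01, 10.0)


@dataclass
class CvFitResult:
    """Outcome of the consensus-c fit."""

    cv: float
    slope: float
    n_genes_used: int
    window: tuple[float, float]


def trend_slope(
    feature_means: np.ndarray,
    modified_fanos: np.ndarray,
    window: tuple[float, float] = DEFAULT_WINDOW,
) -> float:
    """OLS slope of log10(phi') on log10(mean) within the expression window.

    Genes outside the window or with phi' <= 0 are excluded; fewer than two
    usable genes is an error.
    """
    mu = np.asarray(feature_means, dtype=float)
    phi = np.asarray(modified_fanos, dtype=float)
    use = (mu >= window[0]) & (mu <= window[1]) & (phi > 0) & np.isfinite(phi)
    if use.sum() < 2:
        raise ValueError("fewer than 2 usable genes in the fitting window")
    x = np.log10(mu[use])
    y = np.log10(phi[use])
    if np.ptp(x) == 0:
        raise ValueError("all usable genes share one mean; slope undefined")
    slope, _ = np.polyfit(x, y, 1)
    return float(slope)


def fit_consensus_cv(
    counts: CountMatrix,
    window: tuple[float, float] = DEFAULT_WINDOW,
    bounds: tuple[float, float] = (0.0, 3.0),
    grid_points: int = 31,
    xatol: float = 1e-3,
) -> CvFitResult:
    """Fit the consensus c by slope minimization.

    phi'(c) is recomputed for each candidate c on the genes inside the
    fitting window; a coarse grid over ``bounds`` seeds a bounded Brent
    search (the objective is smooth and, in practice, unimodal).  Falls back
    to the grid minimum with a warning if the refinement fails.
    Deterministic given the counts.
    """
    mu_all = counts.gene_means()
    in_window = (mu_all >= window[0]) & (mu_all <= window[1])
    if in_window.sum() < 2:
        raise ValueError("fewer than 2 genes inside the fitting window")
    sub = counts.subset_genes(np.flatnonzero(in_window))
    mu = sub.gene_means()
    dcm = depth_corrected_means(sub)

    def objective(c: float) -> float:
        phi = modified_corrected_fano_from_counts(sub, c, mu=dcm)
        return abs(trend_slope(mu, phi, window))

    grid = np.linspace(bounds[0], bounds[1], grid_points)
    values = np.array([objective(c) for c in grid])
    i = int(np.argmin(values))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, grid_points - 1)]
    best_c, best_val = float(grid[i]), float(values[i])
    try:
        res = minimize_scalar(
            objective, bounds=(lo, hi), method="bounded", options={"xatol": xatol}
        )
        if res.success and res.fun <= best_val:
            best_c, best_val = float(res.x), float(res.fun)
    except Exception as err:  # pragma: no cover - defensive
        warnings.warn(f"scalar refinement failed ({err}); using grid minimum")

    phi = modified_corrected_fano_from_counts(sub, best_c, mu=dcm)
    slope = trend_slope(mu, phi, window)
    n_used = int(np.sum((phi > 0) & np.isfinite(phi)))
    return CvFitResult(cv=best_c, slope=slope, n_genes_used=n_used, window=tuple(window))
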