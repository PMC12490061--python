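"""Moments of the Poisson-lognormal null and tail p-values for phi'.

Null model: the count X for one gene in one cell is Poisson with a
lognormally distributed rate Y, where the lognormal is parametrized by its
ACTUAL mean mu and coefficient of variation c (not the mean/sd of the
underlying normal).  Writing beta = 1 + c^2, the lognormal raw moments are

    E[Y^k] = mu^k * beta^(k(k-1)/2),

and the factorial moments of X equal the raw moments of Y, so raw moments of
X follow from the Stirling-number transform
E[X^r] = sum_j S(r, j) E[Y^j].

The squared modified corrected Pearson residual of one cell is
Q = (X - mu)^2 / v with v = mu (1 + c^2 mu) = Var(X), so E[Q] = 1 exactly.
Raw moments of Q need central moments of X up to order 10.  To avoid the
catastrophic cancellation of forming high-order central moments from raw
moments in floating point, each central moment E[(X - mu)^r] is expressed as
a polynomial in mu whose coefficients are computed once per c in exact
rational arithmetic:

    E[(X - mu)^r] = sum_k C(r,k) E[ m_k^P(Y) * (Y - mu)^(r-k) ],

where m_k^P(lambda) are Poisson central moments (integer-coefficient
polynomials in lambda, from the recurrence m_{k+1} = lambda (dm_k/dlambda
+ k m_{k-1})) and E[Y^p (Y - mu)^s] = mu^(p+s) * g(p, s) with

    g(p, s) = sum_u C(s,u) (-1)^(s-u) beta^((p+u)(p+u-1)/2),

an alternating sum evaluated in exact fractions.  The result is a degree-r
polynomial in mu evaluated vectorized over cells.

phi'_j = sum_i Q_i / (n-1); under the null the Q_i are independent, so
cumulants add:  kappa_r(phi') = sum_i kappa_r(Q_i) / (n-1)^r.  The upper-tail
probability of an observed phi' is read off a Cornish-Fisher expansion in the
first five cumulants, with a monotonicity guard that degrades to the
four-moment expansion and then to a Gaussian tail when the polynomial
quantile function is not monotone over the search bracket.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from fractions import Fraction
from functools import lru_cache
from math import comb

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy.optimize import brentq
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

from .containers import DepthCorrectedMeans

logger = logging.getLogger(__name__)

__all__ = [
    "MomentSet",
    "lognormal_raw_moment",
    "pln_raw_moments",
    "squared_residual_cumulants",
    "fano_null_moments",
    "phi_prime_null_cumulants",
    "tail_pvalue",
    "tail_pvalues",
    "bh_adjust",
]

P_FLOOR = 1e-300  # representability floor for upper-tail probabilities


@dataclass
class MomentSet:
    """First ``order`` raw moments and cumulants of a random variable.

    context distinguishes per-observation quantities (one cell's squared
    residual Q) from the per-gene statistic phi'.
    """

    order: int
    raw_moments: np.ndarray
    cumulants: np.ndarray
    context: str = "per-observation"

    def __post_init__(self):
        self.raw_moments = np.asarray(self.raw_moments, dtype=float)
        self.cumulants = np.asarray(self.cumulants, dtype=float)
        if self.raw_moments.size != self.order or self.cumulants.size != self.order:
            raise ValueError("moment arrays must have length `order`")

    @property
    def mean(self) -> float:
        return float(self.cumulants[0])

    @property
    def variance(self) -> float:
        return float(self.cumulants[1])


# ---------------------------------------------------------------------------
# moment bookkeeping
# ---------------------------------------------------------------------------

def raw_to_cumulants(m: np.ndarray) -> np.ndarray:
    """First five cumulants from the first five raw moments (vectorized)."""
    m1, m2, m3, m4, m5 = m
    k1 = m1
    k2 = m2 - m1**2
    k3 = m3 - 3 * m1 * m2 + 2 * m1**3
    k4 = m4 - 4 * m1 * m3 - 3 * m2**2 + 12 * m1**2 * m2 - 6 * m1**4
    k5 = (
        m5
        - 5 * m1 * m4
        - 10 * m2 * m3
        + 20 * m1**2 * m3
        + 30 * m1 * m2**2
        - 60 * m1**3 * m2
        + 24 * m1**5
    )
    return np.array([k1, k2, k3, k4, k5])


def cumulants_to_raw(k: np.ndarray) -> np.ndarray:
    """First five raw moments from the first five cumulants."""
    k1, k2, k3, k4, k5 = k
    m1 = k1
    m2 = k2 + k1**2
    m3 = k3 + 3 * k2 * k1 + k1**3
    m4 = k4 + 4 * k3 * k1 + 3 * k2**2 + 6 * k2 * k1**2 + k1**4
    m5 = (
        k5
        + 5 * k4 * k1
        + 10 * k3 * k2
        + 10 * k3 * k1**2
        + 15 * k2**2 * k1
        + 10 * k2 * k1**3
        + k1**5
    )
    return np.array([m1, m2, m3, m4, m5])


# ---------------------------------------------------------------------------
# Poisson-lognormal moments
# ---------------------------------------------------------------------------

def lognormal_raw_moment(mean, cv: float, k: int):
    """k-th raw moment of a lognormal with actual mean ``mean`` and CV ``cv``."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if cv < 0:
        raise ValueError("cv must be >= 0")
    mean = np.asarray(mean, dtype=float)
    if np.any(mean <= 0):
        raise ValueError("mean must be > 0")
    out = mean**k * (1.0 + cv * cv) ** (k * (k - 1) / 2)
    return float(out) if out.ndim == 0 else out


@lru_cache(maxsize=None)
def _stirling2(rmax: int) -> tuple:
    """Stirling numbers of the second kind S(r, j), 0 <= j <= r <= rmax."""
    S = [[0] * (rmax + 1) for _ in range(rmax + 1)]
    S[0][0] = 1
    for r in range(1, rmax + 1):
        for j in range(1, r + 1):
            S[r][j] = S[r - 1][j - 1] + j * S[r - 1][j]
    return tuple(tuple(row) for row in S)


def pln_raw_moments(mean, cv: float, max_order: int = 5) -> MomentSet:
    """Raw moments of X ~ Poisson(LogNormal(mean, cv)) up to ``max_order``.

    Uses the factorial-moment identity E[X_(r)] = E[Y^r] (falling factorial)
    and the Stirling transform E[X^r] = sum_j S(r,j) E[Y^j].
    """
    if max_order < 1:
        raise ValueError("max_order must be >= 1")
    if mean <= 0:
        raise ValueError("mean must be > 0")
    beta = 1.0 + cv * cv
    S = _stirling2(max_order)
    raw = np.empty(max_order)
    for r in range(1, max_order + 1):
        raw[r - 1] = sum(
            S[r][j] * mean**j * beta ** (j * (j - 1) / 2) for j in range(1, r + 1)
        )
    cums = np.full(max_order, np.nan)
    if max_order >= 5:
        cums[:5] = raw_to_cumulants(raw[:5])
    else:
        cums[0] = raw[0]
        if max_order >= 2:
            cums[1] = raw[1] - raw[0] ** 2
        if max_order >= 3:
            cums[2] = raw[2] - 3 * raw[0] * raw[1] + 2 * raw[0] ** 3
        if max_order == 4:
            cums[3] = (
                raw[3]
                - 4 * raw[0] * raw[2]
                - 3 * raw[1] ** 2
                + 12 * raw[0] ** 2 * raw[1]
                - 6 * raw[0] ** 4
            )
    return MomentSet(raw.size, raw, cums, "per-observation")


@lru_cache(maxsize=None)
def _poisson_central_coeffs(rmax: int) -> tuple:
    """Integer coefficients of Poisson central moments m_r(lambda).

    Entry [r][p] is the coefficient of lambda^p.  Recurrence:
    m_{r+1} = lambda * (d m_r / d lambda + r * m_{r-1}).
    """
    polys = [[1], [0]]
    for r in range(1, rmax):
        prev, cur = polys[r - 1], polys[r]
        deriv = [p * c for p, c in enumerate(cur)][1:] or [0]
        comb_ = [0] * (max(len(deriv), len(prev)))
        for p, c in enumerate(deriv):
            comb_[p] += c
        for p, c in enumerate(prev):
            comb_[p] += r * c
        polys.append([0] + comb_)  # multiply by lambda
    return tuple(tuple(p) for p in polys)


def _lognormal_g(p: int, s: int, beta: Fraction) -> Fraction:
    """Exact E[Y^p (Y-mu)^s] / mu^(p+s) for the mean/CV-parametrized lognormal."""
    total = Fraction(0)
    for u in range(s + 1):
        m = p + u
        total += comb(s, u) * (-1) ** (s - u) * beta ** (m * (m - 1) // 2)
    return total


@lru_cache(maxsize=None)
def central_moment_polys(cv: float, rmax: int = 10) -> tuple:
    """Polynomial coefficients (in mu, ascending) of E[(X - mu)^r], r=0..rmax.

    Coefficients are assembled in exact rational arithmetic so that the
    cancellation inherent in high-order central moments happens symbolically,
    then converted to float once.
    """
    beta = Fraction(1) + Fraction(cv) * Fraction(cv)
    pois = _poisson_central_coeffs(rmax)
    out = []
    for r in range(rmax + 1):
        coef = [Fraction(0)] * (r + 1)
        for k in range(r + 1):
            s = r - k
            for p, a in enumerate(pois[k]):
                if a == 0:
                    continue
                coef[p + s] += comb(r, k) * a * _lognormal_g(p, s, beta)
        out.append(np.array([float(c) for c in coef]))
    return tuple(out)


def _psi_raw_moments(mu, cv: float, b, order: int = 5):
    """Raw moments 1..order of psi = ((X-mu)^2 - b (X-mu)) / (mu (1+c^2 mu)).

    b = 0 gives the squared residual Q itself (fixed, known mean).  The
    nonzero b used by the estimation-adjusted null is the influence-function
    term accounting for the gene mean being estimated from the same data:
    linearizing phi' in the estimated per-gene rate shows each cell
    contributes Q_i - a (X_i - mu_i) with a gene-level coefficient a
    (b = a * v), because the fitted mean recenters the residuals AND moves
    the variance denominator with them.  Vectorized over mu (b broadcasts).
    """
    polys = central_moment_polys(cv, 2 * order)
    mu = np.asarray(mu, dtype=float)
    b = np.broadcast_to(np.asarray(b, dtype=float), mu.shape)
    v = mu * (1.0 + cv * cv * mu)
    # central moments of X about mu, orders 0..2*order
    M = [np.ones_like(mu), np.zeros_like(mu)] + [
        npoly.polyval(mu, polys[r]) for r in range(2, 2 * order + 1)
    ]
    out = []
    for m_ord in range(1, order + 1):
        tot = np.zeros_like(mu)
        for t in range(m_ord + 1):
            tot = tot + comb(m_ord, t) * (-b) ** (m_ord - t) * M[m_ord + t]
        out.append(tot / v**m_ord)
    return out


def mean_adjustment_coefficient(mu_row: np.ndarray, cv: float):
    """Gene-level coefficient a of the estimation adjustment.

    a = sum_i (1 + 2 c^2 mu_i) / (1 + c^2 mu_i)  /  sum_i mu_i ;
    per-cell b_i = a * mu_i (1 + c^2 mu_i).  With equal cells this reduces
    to b = 1 + 2 c^2 mu, the derivative of the variance function.
    Broadcasts over a trailing gene axis when mu_row is (n, g).
    """
    c2 = cv * cv
    num = np.sum((1.0 + 2 * c2 * mu_row) / (1.0 + c2 * mu_row), axis=0)
    return num / np.sum(mu_row, axis=0)


def squared_residual_cumulants(mu_ij: float, cv: float) -> MomentSet:
    """First 5 cumulants of one cell's squared modified corrected residual."""
    if mu_ij <= 0:
        raise ValueError("mu_ij must be > 0")
    raw = np.array([float(m) for m in _psi_raw_moments(mu_ij, cv, 0.0)])
    return MomentSet(5, raw, raw_to_cumulants(raw), "per-observation")


def fano_null_moments(
    mu_row: np.ndarray, cv: float, n: int, mean_adjusted: bool = False
) -> MomentSet:
    """Cumulants of phi' = sum_i Q_i / (n-1) for one gene under the null.

    mu_row holds the depth-corrected means mu_ij of that gene across the n
    cells.  Cells are independent under the null, so the r-th cumulant of
    phi' is the sum of per-cell r-th cumulants scaled by (n-1)^(-r).  With
    ``mean_adjusted`` the per-cell variable carries the influence term for
    the gene mean being estimated from the same counts (the variant the
    selection pipeline uses); without it the mu_ij are treated as known.
    """
    mu_row = np.asarray(mu_row, dtype=float)
    if n < 2:
        raise ValueError("n must be >= 2")
    if mu_row.size != n:
        raise ValueError("mu_row must have length n")
    if np.any(mu_row <= 0):
        raise ValueError("all mu_ij must be > 0")
    b = 0.0
    if mean_adjusted:
        a = mean_adjustment_coefficient(mu_row, cv)
        b = a * mu_row * (1.0 + cv * cv * mu_row)
    m = _psi_raw_moments(mu_row, cv, b)
    per_cell = raw_to_cumulants(np.array(m))
    scale = (n - 1.0) ** -np.arange(1, 6)
    cums = per_cell.sum(axis=1) * scale
    return MomentSet(5, cumulants_to_raw(cums), cums, "per-gene-statistic")


def phi_prime_null_cumulants(
    mu: DepthCorrectedMeans, cv: float, chunk: int = 256, mean_adjusted: bool = True
) -> np.ndarray:
    """Null cumulants of phi' for every gene, shape (5, n_genes).

    Works gene-chunk by gene-chunk on the outer-product structure of the
    depth-corrected means, so cost is O(n * g) elementary operations and
    memory O(n * chunk).  The estimation adjustment is on by default since
    observed phi' is always computed with per-gene means taken from the
    data.
    """
    n, g = mu.shape
    if n < 2:
        raise ValueError("at least 2 cells are required")
    out = np.empty((5, g))
    scale = (n - 1.0) ** -np.arange(1, 6)
    for lo in range(0, g, chunk):
        hi = min(lo + chunk, g)
        mu_blk = mu.block(np.arange(lo, hi))
        b = 0.0
        if mean_adjusted:
            a = mean_adjustment_coefficient(mu_blk, cv)  # (B,)
            b = a[None, :] * mu_blk * (1.0 + cv * cv * mu_blk)
        m = _psi_raw_moments(mu_blk, cv, b)
        per_cell = raw_to_cumulants(np.array(m))  # (5, n, B)
        out[:, lo:hi] = per_cell.sum(axis=1) * scale[:, None]
    return out


# ---------------------------------------------------------------------------
# tail probabilities
# ---------------------------------------------------------------------------

_Z_LO, _Z_HI = -8.0, 40.0  # search bracket in standardized units


def _cf_poly(g1: float, g2: float, g3: float, order: int) -> np.ndarray:
    """Ascending coefficients of the Cornish-Fisher quantile polynomial w(z).

    order=5 uses standardized cumulants g1 (skew), g2 (excess kurtosis) and
    g3 (5th); order=4 drops the third-order terms; order=2 is the identity
    (Gaussian).
    """
    c = np.zeros(5)
    c[1] = 1.0
    if order >= 4:
        c[0] += -g1 / 6.0
        c[1] += -g2 / 8.0 + 5.0 * g1**2 / 36.0
        c[2] += g1 / 6.0
        c[3] += g2 / 24.0 - g1**2 / 18.0
    if order >= 5:
        c[0] += g3 / 40.0 - g1 * g2 / 12.0 + 17.0 * g1**3 / 324.0
        c[2] += -g3 / 20.0 + 5.0 * g1 * g2 / 24.0 - 53.0 * g1**3 / 324.0
        c[4] += g3 / 120.0 - g1 * g2 / 24.0 + g1**3 / 27.0
    return c


_Z_CORE = -1.0  # the monotone region must at least cover [-1, z_hi]


def _monotone_floor(c: np.ndarray, hi: float = _Z_HI) -> float | None:
    """Left edge of the monotone-increasing region of w that reaches ``hi``.

    Returns the largest real root of w' below ``hi`` (or the unbounded
    bracket edge when w' has no real root there), or None when w is
    decreasing at ``hi`` itself, i.e. the expansion is unusable for the
    upper tail.  Polynomial coefficients are ascending.
    """
    dc = npoly.polyder(c)
    if npoly.polyval(hi, dc) <= 0:
        return None
    if not np.any(dc[1:]):
        return _Z_LO
    roots = np.roots(dc[::-1])
    roots = roots[np.abs(roots.imag) < 1e-9].real
    roots = roots[roots < hi]
    return float(roots.max()) if roots.size else _Z_LO


_Z_REF = 2.0  # representative upper-tail point for the convergence check


def _fifth_term_converged(g1: float, g2: float, g3: float) -> bool:
    """Whether the third-order (fifth-cumulant) correction is perturbative.

    Cornish-Fisher is an asymptotic series; the g3 term only refines the
    quantile when it is small against the first- and second-order terms at
    the working part of the upper tail (z ~ 2).  When it dominates, the
    four-moment expansion is more accurate, not less.
    """
    z = _Z_REF
    h1 = g1 / 6.0 * (z**2 - 1.0)
    h2 = g2 / 24.0 * (z**3 - 3 * z) - g1**2 / 36.0 * (2 * z**3 - 5 * z)
    h3 = (
        g3 / 120.0 * (z**4 - 6 * z**2 + 3.0)
        - g1 * g2 / 24.0 * (z**4 - 5 * z**2 + 2.0)
        + g1**3 / 324.0 * (12 * z**4 - 53 * z**2 + 17.0)
    )
    return abs(h3) <= max(abs(h1) + abs(h2), 0.01)


def tail_pvalue(moments, observed: float) -> float:
    """Upper-tail probability P(phi' >= observed) under the moment null.

    ``moments`` is a MomentSet (or a length-5 cumulant vector).  Uses the
    five-cumulant Cornish-Fisher expansion, falling back to the four-moment
    expansion and then a Gaussian tail if the quantile polynomial is not
    monotone over the bracket.  Result is clamped to [1e-300, 1].
    """
    cums = moments.cumulants if isinstance(moments, MomentSet) else np.asarray(moments)
    if cums.size < 4:
        raise ValueError("at least 4 cumulants are required")
    p, _ = _tail_pvalue_impl(cums, observed)
    return p


def _tail_pvalue_impl(cums: np.ndarray, observed: float) -> tuple[float, int]:
    k1, k2 = cums[0], cums[1]
    if k2 <= 0:
        raise ValueError("cumulant 2 of the null must be positive")
    sd = np.sqrt(k2)
    g1 = cums[2] / sd**3
    g2 = cums[3] / sd**4
    g3 = cums[4] / sd**5 if cums.size >= 5 and np.isfinite(cums[4]) else 0.0
    t = (observed - k1) / sd
    orders = (5, 4, 2) if cums.size >= 5 else (4, 2)
    if orders[0] == 5 and not _fifth_term_converged(g1, g2, g3):
        orders = (4, 2)
    for order in orders:
        c = _cf_poly(g1, g2, g3, order)
        z_floor = _monotone_floor(c)
        if z_floor is None or z_floor > _Z_CORE:
            # quantile polynomial not monotone over the working range
            continue
        z_floor = max(z_floor, _Z_LO)
        w_lo = npoly.polyval(z_floor, c)
        w_hi = npoly.polyval(_Z_HI, c)
        if t <= w_lo:
            # deep in the lower tail of an upper-tail test: p ~ 1
            return float(min(1.0, norm.sf(z_floor))), order
        if t >= w_hi:
            return P_FLOOR, order
        z = brentq(lambda z_: npoly.polyval(z_, c) - t, z_floor, _Z_HI, xtol=1e-10)
        return float(min(1.0, max(P_FLOOR, norm.sf(z)))), order
    # unreachable: order 2 is always monotone
    raise AssertionError("Gaussian stage must be monotone")


def tail_pvalues(cumulants: np.ndarray, observed: np.ndarray) -> np.ndarray:
    """Vectorized upper-tail p-values; cumulants has shape (5, n_genes)."""
    cumulants = np.asarray(cumulants)
    observed = np.asarray(observed, dtype=float)
    g = observed.size
    out = np.empty(g)
    downgrades = {4: 0, 2: 0}
    for j in range(g):
        out[j], order = _tail_pvalue_impl(cumulants[:, j], observed[j])
        if order < 5:
            downgrades[order] += 1
    if downgrades[4] or downgrades[2]:
        logger.warning(
            "tail expansion downgraded for %d genes (4-moment) and %d genes (Gaussian)",
            downgrades[4],
            downgrades[2],
        )
    return out


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues.copy()
    if np.any((pvalues < 0) | (pvalues > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(pvalues, method="fdr_bh")[1]
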