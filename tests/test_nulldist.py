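"""Poisson-lognormal null moments, cumulants and tail probabilities."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import gamma

from mcfano import (
    bh_adjust,
    fano_null_moments,
    lognormal_raw_moment,
    pln_raw_moments,
    squared_residual_cumulants,
    tail_pvalue,
)
from mcfano.nulldist import mean_adjustment_coefficient, raw_to_cumulants


def _pln_draws(rng, mu, cv, size):
    if cv == 0:
        return rng.poisson(mu, size).astype(float)
    s2 = np.log1p(cv * cv)
    y = np.exp(rng.normal(np.log(mu) - s2 / 2, np.sqrt(s2), size))
    return rng.poisson(y).astype(float)


class TestLognormalMoments:
    @pytest.mark.parametrize("cv", [0.0, 0.3, 0.7, 1.5])
    def test_first_moment_is_the_mean(self, cv):
        assert lognormal_raw_moment(3.7, cv, 1) == pytest.approx(3.7)

    def test_closed_form_values(self):
        assert lognormal_raw_moment(2, 0.5, 2) == pytest.approx(5.0)
        assert lognormal_raw_moment(2, 0.5, 3) == pytest.approx(15.625)


class TestPlnRawMoments:
    def test_hand_derived_values(self):
        ms = pln_raw_moments(2.0, 0.5, 3)
        np.testing.assert_allclose(ms.raw_moments, [2.0, 7.0, 32.625])

    def test_first_moment_is_the_mean(self):
        assert pln_raw_moments(0.37, 1.1, 1).raw_moments[0] == pytest.approx(0.37)

    @pytest.mark.parametrize("mu,cv", [(0.5, 0.7), (2.0, 0.5), (5.0, 0.0)])
    def test_matches_monte_carlo_within_3_se(self, mu, cv):
        rng = np.random.default_rng(7)
        reps, batches = 400_000, 20
        x = _pln_draws(rng, mu, cv, reps).reshape(batches, -1)
        ms = pln_raw_moments(mu, cv, 3)
        for r in range(1, 4):
            batch_means = (x**r).mean(axis=1)
            est, se = batch_means.mean(), batch_means.std(ddof=1) / np.sqrt(batches)
            assert abs(ms.raw_moments[r - 1] - est) < 3 * se


class TestSquaredResidualCumulants:
    @pytest.mark.parametrize("mu,cv", [(0.1, 0.0), (1.0, 0.7), (5.0, 0.3), (20.0, 1.0)])
    def test_unit_mean_by_construction(self, mu, cv):
        assert squared_residual_cumulants(mu, cv).cumulants[0] == pytest.approx(1.0)

    def test_poisson_variance_at_unit_mean(self):
        # Var(Q) = E[(X-1)^4] - 1 = (mu + 3 mu^2) - 1 = 3 at mu=1, c=0
        assert squared_residual_cumulants(1.0, 0.0).cumulants[1] == pytest.approx(3.0)

    @pytest.mark.parametrize("mu,cv", [(0.5, 0.7), (2.0, 0.25)])
    def test_matches_monte_carlo_cumulants(self, mu, cv):
        rng = np.random.default_rng(11)
        batches = 20
        x = _pln_draws(rng, mu, cv, (batches, 50_000))
        q = (x - mu) ** 2 / (mu * (1 + cv * cv * mu))
        per_batch = np.array(
            [
                raw_to_cumulants(np.array([np.mean(b**r) for r in range(1, 6)]))
                for b in q
            ]
        )  # (batches, 5)
        pred = squared_residual_cumulants(mu, cv).cumulants
        for r in range(3):
            est = per_batch[:, r].mean()
            se = per_batch[:, r].std(ddof=1) / np.sqrt(batches)
            assert abs(est - pred[r]) < 3 * se, f"cumulant {r + 1}"


class TestFanoNullMoments:
    def test_mean_is_n_over_n_minus_one(self):
        ms = fano_null_moments(np.full(100, 2.0), 0.5, 100)
        assert ms.cumulants[0] == pytest.approx(100 / 99)

    def test_variance_of_equal_poisson_cells(self):
        # per-cell Var(Q) = 2 + 1/mu at c=0; kappa2 = n Var(Q) / (n-1)^2
        ms = fano_null_moments(np.full(2000, 5.0), 0.0, 2000)
        assert ms.cumulants[1] == pytest.approx(2000 * 2.2 / 1999**2, rel=1e-9)

    def test_matches_monte_carlo_distribution(self):
        mu, cv, n, reps = 2.0, 0.7, 100, 10_000
        rng = np.random.default_rng(3)
        x = _pln_draws(rng, mu, cv, (reps, n))
        phi = ((x - mu) ** 2 / (mu * (1 + cv * cv * mu))).sum(axis=1) / (n - 1)
        ms = fano_null_moments(np.full(n, mu), cv, n)
        batches = phi.reshape(20, -1)
        for r, (emp_f, pred) in enumerate(
            [
                (lambda b: b.mean(axis=1), ms.cumulants[0]),
                (lambda b: b.var(axis=1, ddof=1), ms.cumulants[1]),
                (
                    lambda b: np.mean((b - b.mean(axis=1, keepdims=True)) ** 3, axis=1),
                    ms.cumulants[2],
                ),
            ]
        ):
            vals = emp_f(batches)
            se = vals.std(ddof=1) / np.sqrt(20)
            assert abs(vals.mean() - pred) < 3 * se, f"cumulant {r + 1}"

    def test_standardized_cumulants_vanish_with_n(self):
        mu = 2.0
        small = fano_null_moments(np.full(100, mu), 0.7, 100).cumulants
        large = fano_null_moments(np.full(10000, mu), 0.7, 10000).cumulants
        for order in (3, 4):
            g_small = small[order - 1] / small[1] ** (order / 2)
            g_large = large[order - 1] / large[1] ** (order / 2)
            assert abs(g_large) < abs(g_small)
        assert large[1] > 0

    def test_mean_adjustment_reduces_to_variance_slope(self):
        # equal cells: b = a * v must equal d v / d mu = 1 + 2 c^2 mu
        mu, cv = 1.7, 0.6
        a = mean_adjustment_coefficient(np.full(50, mu), cv)
        v = mu * (1 + cv * cv * mu)
        assert a * v == pytest.approx(1 + 2 * cv * cv * mu)

    def test_mu_row_length_must_match_n(self):
        with pytest.raises(ValueError):
            fano_null_moments(np.ones(5), 0.5, 6)


class TestTailPvalue:
    def test_gaussian_median_and_quantile(self):
        cums = np.array([3.0, 4.0, 0.0, 0.0, 0.0])
        assert tail_pvalue(cums, 3.0) == pytest.approx(0.5)
        assert tail_pvalue(cums, 3.0 + 1.959964 * 2.0) == pytest.approx(0.025, rel=1e-4)

    def test_chi_square_mean_against_exact_gamma_tail(self):
        # mean of 50 chi-square(1): kappa_r = 2^(r-1) (r-1)! / 50^(r-1)
        n = 50
        cums = np.array(
            [2.0 ** (r - 1) * math.factorial(r - 1) / n ** (r - 1) for r in range(1, 6)]
        )
        exact = gamma(a=n / 2, scale=2 / n).sf(1.5)
        assert tail_pvalue(cums, 1.5) == pytest.approx(exact, rel=0.10)

    def test_monotone_decreasing_in_observed(self):
        ms = fano_null_moments(np.full(500, 1.0), 0.7, 500)
        obs = np.linspace(0.2, 6.0, 80)
        ps = np.array([tail_pvalue(ms, o) for o in obs])
        assert np.all(np.diff(ps) <= 1e-12)
        assert ps[-1] >= 1e-300 and ps[0] <= 1.0

    def test_extreme_observation_hits_floor_not_zero(self):
        ms = fano_null_moments(np.full(500, 1.0), 0.7, 500)
        p = tail_pvalue(ms, 1e6)
        assert 0 < p <= 1e-300 * 10


class TestBhAdjust:
    def test_single_pvalue_unchanged(self):
        np.testing.assert_allclose(bh_adjust(np.array([0.02])), [0.02])

    def test_textbook_step_up(self):
        np.testing.assert_allclose(bh_adjust(np.array([0.01, 0.02, 0.03])), 0.03)

    def test_ties_are_invariant(self):
        np.testing.assert_allclose(bh_adjust(np.full(7, 0.2)), 0.2)

    @settings(max_examples=50, deadline=None)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_adjusted_at_least_raw_and_capped(self, ps):
        ps = np.array(ps)
        adj = bh_adjust(ps)
        assert np.all(adj <= 1.0 + 1e-12)
        assert np.all(adj >= ps - 1e-12)


def test_pvalue_uniformity_on_null_simulation(null_sim_2k):
    """Raw p-values of well-expressed null genes are near-uniform: the
    fraction below 0.05 lies in [0.03, 0.08]."""
    from mcfano import compute_feature_table

    res = compute_feature_table(null_sim_2k.counts, cv=0.7)
    table = res.table
    keep = table["mean"].to_numpy() >= 0.5
    frac = float(np.mean(table["pvalue"].to_numpy()[keep] < 0.05))
    assert 0.03 <= frac <= 0.08
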