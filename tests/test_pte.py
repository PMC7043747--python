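"""Personalized treatment effects: log HR, survival curves, RMST(d)."""

import numpy as np
import pytest
from scipy import integrate

import credsurv as cs
from credsurv.exceptions import ConfigurationError, ExtrapolationError
from credsurv.model import PosteriorDraws
from credsurv.pte import (
    posterior_log_hr,
    posterior_rmst,
    posterior_rmstd,
    posterior_survival,
)


def _draws(beta, h, cutpoints, n_prog, stratified=False, h1=None):
    beta = np.atleast_2d(np.asarray(beta, dtype=float))
    hd = {0: np.atleast_2d(np.asarray(h, dtype=float))}
    if stratified:
        hd[1] = np.atleast_2d(np.asarray(h1, dtype=float))
    k = beta.shape[1]
    names = tuple(f"b{i}" for i in range(k))
    return PosteriorDraws(
        beta=beta, h=hd, cutpoints=np.asarray(cutpoints, dtype=float),
        column_names=names, n_prognostic=n_prog, stratified=stratified,
        acceptance={"beta": np.ones(k), "h": {0: np.ones(len(cutpoints))}},
        seed=0, burn_in=0, thin=1,
    )


class TestLogHR:
    def test_zero_gamma_gives_zero_everywhere(self, grid):
        d = _draws(np.zeros((4, 3)), np.ones((4, 2)), [1.0, 2.0], n_prog=0)
        p = posterior_log_hr(d, grid)
        assert np.all(p.values == 0.0)

    def test_arithmetic_identity(self):
        d = _draws([[0.5, 1.0, -1.0]], [[1.0]], [1.0], n_prog=0)
        g = cs.CovariateGrid(points=[[1.0, 0.0, 0.0]])
        p = posterior_log_hr(d, g)
        assert p.values[0, 0] == pytest.approx(0.5)

    def test_matches_dot_product_oracle(self, rng):
        beta = rng.normal(size=(4, 5))
        d = _draws(beta, np.ones((4, 3)), [1.0, 2.0, 3.0], n_prog=2)
        pts = rng.normal(size=(3, 3))
        g = cs.CovariateGrid(points=pts)
        p = posterior_log_hr(d, g)
        expected = np.array([[b[2:] @ z for z in pts] for b in beta])
        np.testing.assert_allclose(p.values, expected, atol=1e-12)

    def test_prognostic_block_is_ignored(self, rng):
        beta = rng.normal(size=(5, 4))
        d1 = _draws(beta, np.ones((5, 2)), [1.0, 2.0], n_prog=1)
        beta2 = beta.copy()
        beta2[:, 0] = 99.0
        d2 = _draws(beta2, np.ones((5, 2)), [1.0, 2.0], n_prog=1)
        g = cs.CovariateGrid(points=rng.normal(size=(4, 3)))
        np.testing.assert_array_equal(
            posterior_log_hr(d1, g).values, posterior_log_hr(d2, g).values
        )

    def test_stratified_model_has_no_log_hr(self):
        d = _draws([[0.1]], [[1.0]], [1.0], n_prog=0, stratified=True, h1=[[1.0]])
        with pytest.raises(ConfigurationError, match="stratified"):
            posterior_log_hr(d, cs.CovariateGrid(points=[[1.0]]))


class TestSurvival:
    def test_starts_at_one(self):
        d = _draws([[0.3]], [[0.7, 0.4]], [1.0, 2.0], n_prog=1)
        c = posterior_survival(d, [1.0], [], 0, [0.0, 0.5, 1.0])
        assert c.values[0, 0] == 1.0

    def test_single_interval_closed_form(self):
        d = _draws(np.zeros((1, 0)), [[0.7]], [1.0], n_prog=0)
        c = posterior_survival(d, [], [], 0, [1.0])
        assert c.values[0, 0] == pytest.approx(np.exp(-0.7), abs=1e-12)

    def test_cumulative_sum_oracle_at_cutpoints(self, rng):
        cuts = np.array([0.5, 1.3, 2.0, 4.0])
        h = rng.gamma(1, 0.3, size=(6, 4))
        beta = rng.normal(size=(6, 2))
        d = _draws(beta, h, cuts, n_prog=2)
        x = np.array([0.4, -1.2])
        c = posterior_survival(d, x, [], 0, cuts)
        elp = np.exp(beta @ x)
        expected = elp[:, None] * np.cumsum(h, axis=1)
        np.testing.assert_allclose(-np.log(c.values), expected, rtol=1e-10)

    def test_extrapolation_rejected(self):
        d = _draws(np.zeros((1, 0)), [[0.7]], [1.0], n_prog=0)
        with pytest.raises(ExtrapolationError):
            posterior_survival(d, [], [], 0, [2.0])

    def test_curves_monotone_and_bounded(self, ph_fit):
        _, ds, res = ph_fit
        t = np.linspace(0, res.draws.cutpoints[-1], 40)
        c = res.survival(x=[1.0, 0.5], z=[1.0, 1.0, 0.5], arm=1, times=t)
        assert (np.diff(c.values, axis=1) <= 1e-12).all()
        assert c.values.min() >= 0 and c.values.max() <= 1

    def test_ph_relation_between_arms(self, ph_fit, rng):
        # shared baseline: S1(t) = S0(t)^HR draw by draw
        _, ds, res = ph_fit
        t = np.linspace(0.1, res.draws.cutpoints[-1] * 0.9, 7)
        x = [1.0, 0.3]
        z = [1.0, 1.0, 0.3]
        s0 = res.survival(x, z, 0, t).values
        s1 = res.survival(x, z, 1, t).values
        hr = np.exp(res.draws.gamma @ np.asarray(z))
        np.testing.assert_allclose(s1, s0 ** hr[:, None], rtol=1e-8)


class TestRMST:
    def test_unit_survival_gives_nu(self):
        d = _draws(np.zeros((1, 0)), [[1e-14]], [50.0], n_prog=0)
        c = posterior_survival(d, [], [], 0, [0.0, 25.0, 50.0])
        assert posterior_rmst(c, 30.0)[0] == pytest.approx(30.0, rel=1e-9)

    def test_zero_nu_gives_zero(self):
        d = _draws(np.zeros((1, 0)), [[0.5]], [10.0], n_prog=0)
        c = posterior_survival(d, [], [], 0, [0.0, 10.0])
        assert posterior_rmst(c, 0.0)[0] == 0.0

    def test_constant_hazard_closed_form(self):
        # lambda = 0.01 over a single interval: psi = (1 - e^{-0.3})/0.01
        lam = 0.01
        d = _draws(np.zeros((1, 0)), [[lam * 40.0]], [40.0], n_prog=0)
        c = posterior_survival(d, [], [], 0, [0.0, 40.0])
        expected = (1 - np.exp(-lam * 30.0)) / lam
        assert posterior_rmst(c, 30.0)[0] == pytest.approx(expected, abs=1e-10)

    def test_monotone_in_nu_and_bounded(self, ph_fit):
        _, ds, res = ph_fit
        grid = cs.default_grid(n_z2=3)
        nus = [5.0, 10.0, 20.0]
        vals = [
            res.rmstd(grid, nu=nu).restriction_time for nu in nus
        ]
        assert vals == nus
        c = res.survival([0.0, 0.0], [1.0, 0.0, 0.0], 0,
                         np.linspace(0, 20, 30))
        r = [posterior_rmst(c, nu).mean() for nu in nus]
        assert r[0] < r[1] < r[2] <= nus[2]


class TestRMSTd:
    def test_zero_gamma_shared_baseline_gives_zero(self, rng):
        h = rng.gamma(1, 0.2, size=(5, 3))
        beta = np.c_[rng.normal(size=(5, 1)), np.zeros((5, 2))]
        d = _draws(beta, h, [1.0, 2.0, 3.0], n_prog=1)
        g = cs.CovariateGrid(points=[[1.0, 0.0], [1.0, 1.0]],
                             companion_prognostic=[[0.5], [0.2]])
        p = posterior_rmstd(d, g, nu=2.5)
        np.testing.assert_allclose(p.values, 0.0, atol=1e-14)

    def test_two_interval_segmentwise_oracle(self):
        # oracle: independent numeric integration of the two survival curves
        h = np.array([[0.4, 0.9]])
        cuts = np.array([1.0, 3.0])
        beta = np.array([[0.3, -0.2, 0.5]])  # x-coef, gamma = (-0.2, 0.5)
        d = _draws(beta, h, cuts, n_prog=1)
        g = cs.CovariateGrid(points=[[1.0, -1.0]], companion_prognostic=[[0.8]])
        nu = 2.7
        p = posterior_rmstd(d, g, nu=nu)

        lam = np.array([0.4 / 1.0, 0.9 / 2.0])

        def H0(t):
            return np.where(t < 1.0, lam[0] * t, 0.4 + lam[1] * (t - 1.0))

        e0 = np.exp(0.3 * 0.8)
        e1 = np.exp(0.3 * 0.8 + (-0.2 * 1.0 + 0.5 * -1.0))
        val0 = integrate.quad(lambda t: np.exp(-e0 * H0(t)), 0, nu,
                              points=[1.0], limit=200, epsabs=1e-13)[0]
        val1 = integrate.quad(lambda t: np.exp(-e1 * H0(t)), 0, nu,
                              points=[1.0], limit=200, epsabs=1e-13)[0]
        assert p.values[0, 0] == pytest.approx(val1 - val0, abs=1e-10)

    def test_missing_companion_prognostic_rejected(self):
        d = _draws([[0.1, 0.2]], [[0.5]], [1.0], n_prog=1)
        g = cs.CovariateGrid(points=[[1.0]])
        with pytest.raises(ConfigurationError, match="companion"):
            posterior_rmstd(d, g, nu=0.5)

    def test_nu_beyond_partition_rejected(self):
        d = _draws([[0.1]], [[0.5]], [1.0], n_prog=0)
        g = cs.CovariateGrid(points=[[1.0]], companion_prognostic=[[0.0]])
        with pytest.raises(ExtrapolationError):
            posterior_rmstd(d, g, nu=2.0)

    def test_per_draw_sign_matches_log_hr_under_ph(self, ph_fit, grid):
        """At delta_H = 1 / delta_R = 0 the two PTE measures pick the same
        benefiting draws: z'gamma < 0 iff the RMST difference is positive."""
        _, ds, res = ph_fit
        lh = res.log_hr(grid).values
        rd = res.rmstd(grid).values
        informative = np.abs(lh) > 1e-8
        assert np.array_equal(
            rd[informative] > 0, lh[informative] < 0
        )

    def test_window_restriction_subtracts_head(self, ph_fit, grid):
        _, ds, res = ph_fit
        nu = res.default_nu()
        full = res.rmstd(grid, nu=nu).values
        head = res.rmstd(grid, nu=nu * 0.3).values
        tail = res.rmstd(grid, nu=nu, window_start=nu * 0.3).values
        np.testing.assert_allclose(full, head + tail, atol=1e-9)
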