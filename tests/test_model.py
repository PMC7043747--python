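"""Partition, grouped likelihood and the Gibbs sampler."""

import numpy as np
import pytest
from scipy import integrate

import credsurv as cs
from credsurv import _kernels
from credsurv.exceptions import ConfigurationError, StratificationError
from credsurv.model import (
    CoefficientPrior,
    GammaProcessPrior,
    grouped_log_likelihood,
    partition_time_axis,
)


def _all_events(times, arm=None):
    n = len(times)
    return cs.SurvivalDataset(
        time=np.asarray(times, dtype=float),
        event=np.ones(n, dtype=int),
        arm=np.zeros(n, dtype=int) if arm is None else np.asarray(arm),
        prognostic=np.zeros((n, 0)),
        predictive=np.zeros((n, 0)),
    )


class TestPartition:
    def test_single_interval_contains_everyone(self):
        ds = _all_events([1.0, 2.0, 3.0])
        part = partition_time_axis(ds, 1)
        assert part.J == 1
        assert part.cutpoints[0] >= 3.0
        assert set(part.risk_sets[0]) == {0, 1, 2}
        assert set(part.failure_sets[0]) == {0, 1, 2}

    def test_two_interval_membership_exhaustive(self):
        # oracle: every subject is at risk in each interval up to its exit
        ds = _all_events([1.0, 2.0, 3.0, 4.0, 5.0])
        part = partition_time_axis(ds, 2)
        sizes = [len(f) for f in part.failure_sets]
        assert sum(sizes) == 5
        for i in range(5):
            j_exit = part.exit_interval[i]
            for j in range(part.J):
                assert (i in part.risk_sets[j]) == (j <= j_exit)

    def test_censored_subject_at_cutpoint_not_in_failure_set(self):
        ds = cs.SurvivalDataset(
            time=[1.0, 2.0, 3.0, 2.0],
            event=[1, 1, 1, 0],
            arm=[0, 0, 0, 0],
            prognostic=np.zeros((4, 0)),
            predictive=np.zeros((4, 0)),
        )
        part = partition_time_axis(ds, 2)
        # the censored subject (index 3) exits at a cutpoint: in R_j, not M_j
        j = part.exit_interval[3]
        assert 3 in part.risk_sets[j]
        assert all(3 not in f for f in part.failure_sets)

    def test_too_many_intervals_rejected(self):
        ds = _all_events([1.0, 2.0, 2.0])
        with pytest.raises(ConfigurationError, match="reduce J"):
            partition_time_axis(ds, 5)


class TestGroupedLogLikelihood:
    def test_single_subject_closed_form(self):
        ds = _all_events([1.0])
        part = partition_time_axis(ds, 1)
        ll = grouped_log_likelihood(np.empty(0), [0.5], part, np.zeros((1, 0)))
        assert ll == pytest.approx(np.log(1 - np.exp(-0.5)), abs=1e-12)

    def test_interval_without_failures_is_pure_survival_term(self):
        # two subjects, the second censored in interval 2: interval 2's
        # contribution is -h_2 * sum of risk-set hazards only
        ds = cs.SurvivalDataset(
            time=[1.0, 2.0], event=[1, 0], arm=[0, 0],
            prognostic=np.zeros((2, 0)), predictive=np.zeros((2, 0)),
        )
        part = partition_time_axis(ds, 1)
        # J=1: subject 2 censored at the end; closed form
        h = [0.3]
        ll = grouped_log_likelihood(np.empty(0), h, part, np.zeros((2, 0)))
        expected = -0.3 + np.log(1 - np.exp(-0.3))
        assert ll == pytest.approx(expected, abs=1e-12)

    def test_vanishing_increment_with_failure_diverges_to_minus_inf(self):
        # log(1 - e^{-h}) ~ log h -> -inf as the increment vanishes
        ds = _all_events([1.0])
        part = partition_time_axis(ds, 1)
        lls = [
            grouped_log_likelihood(np.empty(0), [h], part, np.zeros((1, 0)))
            for h in (1e-4, 1e-100, 1e-320)
        ]
        assert lls[0] > lls[1] > lls[2]
        assert lls[2] < -700

    def test_nonpositive_increment_rejected(self):
        ds = _all_events([1.0])
        part = partition_time_axis(ds, 1)
        with pytest.raises(ConfigurationError, match="positive"):
            grouped_log_likelihood(np.empty(0), [0.0], part, np.zeros((1, 0)))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_kernel_agrees_with_reference(self, seed):
        """The fast sampling kernel and the public likelihood must agree."""
        rng = np.random.default_rng(seed)
        n = 40
        ds = cs.SurvivalDataset(
            time=rng.exponential(5, n),
            event=rng.integers(0, 2, n) | (np.arange(n) == 0),
            arm=rng.integers(0, 2, n),
            prognostic=rng.normal(size=(n, 2)),
            predictive=rng.normal(size=(n, 1)),
        )
        d = cs.build_design(ds)
        part = partition_time_axis(ds)
        beta = rng.normal(size=d.p + d.q) * 0.5
        h = rng.gamma(1.0, 0.1, part.J) + 1e-4
        ref = grouped_log_likelihood(beta, h, part, d.combined)
        elp = np.exp(np.clip(d.combined @ beta, -50, 50))
        fast = _kernels.grouped_loglik(
            elp,
            np.arange(n, dtype=np.int64),
            part.exit_interval.astype(np.int64),
            part.event.astype(np.bool_),
            h,
        )
        assert fast == pytest.approx(ref, rel=1e-12)


class TestHazardIncrementSampler:
    def test_single_failure_stationary_matches_quadrature(self):
        """Chain for h with one subject/event targets the exact conditional.

        Oracle: 1-d quadrature of h^(a-1) e^(-b h) (1 - e^(-h)) — first two
        moments within 2%.
        """
        ds = _all_events([1.0])
        prior = GammaProcessPrior.constant_rate(1.0, weight=0.5)
        model = cs.GammaProcessCox(ds, n_intervals=1, hazard_prior=prior)
        res = model.fit(n_iter=21000, burn_in=1000, seed=3)
        h = res.draws.h[0][:, 0]
        a = prior.shape_increments(model.partition.cutpoints)[0]
        b = prior.weight

        def dens(x):
            return x ** (a - 1) * np.exp(-b * x) * (1 - np.exp(-x))

        z, _ = integrate.quad(dens, 0, 200)
        m1 = integrate.quad(lambda x: x * dens(x), 0, 200)[0] / z
        m2 = integrate.quad(lambda x: x * x * dens(x), 0, 200)[0] / z
        assert h.mean() == pytest.approx(m1, rel=0.02)
        assert (h ** 2).mean() == pytest.approx(m2, rel=0.05)

    def test_literal_eq13_switch_runs(self):
        ds = cs.simulate_ph(cs.PHSimConfig(n=60, seed=1))
        res = cs.GammaProcessCox(ds).fit(n_iter=300, burn_in=100, seed=2,
                                         h_update="literal-eq13")
        assert (res.draws.h[0] > 0).all()


class TestGibbs:
    def test_same_seed_bitwise_identical(self):
        ds = cs.simulate_ph(cs.PHSimConfig(n=60, gamma=(1, 1, 1), seed=4))
        r1 = cs.GammaProcessCox(ds).fit(n_iter=400, burn_in=100, seed=9)
        r2 = cs.GammaProcessCox(ds).fit(n_iter=400, burn_in=100, seed=9)
        np.testing.assert_array_equal(r1.draws.beta, r2.draws.beta)
        np.testing.assert_array_equal(r1.draws.h[0], r2.draws.h[0])

    def test_flat_likelihood_recovers_prior(self):
        # all subjects on arm 0: the interaction coefficients never enter the
        # likelihood, so their posterior equals the prior
        rng = np.random.default_rng(0)
        n = 60
        ds = cs.SurvivalDataset(
            time=rng.exponential(5, n), event=np.ones(n, dtype=int),
            arm=np.zeros(n, dtype=int), prognostic=np.zeros((n, 0)),
            predictive=rng.normal(size=(n, 1)),
        )
        prior = CoefficientPrior([0.7, -0.4], np.diag([0.09, 0.04]))
        res = cs.GammaProcessCox(ds, coef_prior=prior).fit(
            n_iter=6000, burn_in=1000, seed=5
        )
        m = res.draws.beta.mean(axis=0)
        s = res.draws.beta.std(axis=0)
        assert m == pytest.approx([0.7, -0.4], abs=0.05)
        assert s == pytest.approx([0.3, 0.2], rel=0.15)

    def test_duplicated_covariate_exchangeable(self):
        rng = np.random.default_rng(1)
        n = 150
        z = rng.normal(size=n)
        ds = cs.SurvivalDataset(
            time=rng.exponential(5, n) * np.exp(-0.3 * z),
            event=np.ones(n, dtype=int),
            arm=rng.integers(0, 2, n),
            prognostic=np.c_[z, z + rng.normal(0, 1e-9, n)],
            predictive=np.zeros((n, 0)),
        )
        res = cs.GammaProcessCox(ds, add_intercept=False).fit(
            n_iter=4000, burn_in=1000, seed=6
        )
        m = res.draws.beta.mean(axis=0)
        s = res.draws.beta.std(axis=0)
        # the two copies carry the same information: symmetric marginals
        assert abs(m[0] - m[1]) < 4 * np.hypot(s[0], s[1]) / np.sqrt(10)

    def test_gamma_recovery_within_three_posterior_sds(self):
        zs = []
        for r in range(10):
            ds = cs.simulate_ph(cs.PHSimConfig(n=500, gamma=(1, 1, 1), seed=100 + r))
            res = cs.GammaProcessCox(ds).fit(seed=200 + r)
            g = res.draws.gamma
            zs.append((g.mean(0) - 1.0) / g.std(0))
        z = np.abs(np.mean(zs, axis=0))
        assert (z < 3).all()

    def test_posterior_sd_shrinks_with_n(self):
        sds = []
        for n in (100, 400, 1600):
            vals = []
            for r in range(4):
                ds = cs.simulate_ph(cs.PHSimConfig(n=n, gamma=(1, 1, 1), seed=50 + r))
                res = cs.GammaProcessCox(ds).fit(n_iter=900, burn_in=300, seed=60 + r)
                vals.append(res.draws.gamma.std(axis=0).mean())
            sds.append(np.mean(vals))
        assert sds[0] > sds[1] > sds[2]

    def test_prior_sensitivity_likelihood_dominates(self):
        ds = cs.simulate_ph(cs.PHSimConfig(n=500, gamma=(1, 1, 1), seed=77))
        model = cs.GammaProcessCox(ds)
        r1 = model.fit(seed=8)
        wide = CoefficientPrior.default(model.k, sd=100.0)
        r2 = cs.GammaProcessCox(ds, coef_prior=wide).fit(seed=8)
        diff = np.abs(r1.draws.gamma.mean(0) - r2.draws.gamma.mean(0))
        assert (diff < 0.5 * r1.draws.gamma.std(0)).all()

    def test_strong_prior_pulls_h_to_base_hazard(self):
        rate = 0.1
        rng = np.random.default_rng(2)
        n = 40
        ds = cs.SurvivalDataset(
            time=rng.exponential(1 / rate, n), event=np.ones(n, dtype=int),
            arm=np.zeros(n, dtype=int), prognostic=np.zeros((n, 0)),
            predictive=np.zeros((n, 0)),
        )
        prior = GammaProcessPrior.constant_rate(rate, weight=1e6)
        res = cs.GammaProcessCox(ds, n_intervals=5, hazard_prior=prior).fit(seed=3)
        cuts = res.draws.cutpoints
        target = np.diff(rate * cuts, prepend=0.0)
        hbar = res.draws.h[0].mean(axis=0)
        np.testing.assert_allclose(hbar, target, rtol=0.05)

    def test_overflow_clipping_is_counted(self):
        # pin the coefficient at 0.5 via a near-degenerate prior; covariate
        # values of +/-300 then push the linear predictor past the clip bound
        rng = np.random.default_rng(9)
        n = 40
        ds = cs.SurvivalDataset(
            time=rng.exponential(5, n), event=np.ones(n, dtype=int),
            arm=np.zeros(n, dtype=int),
            prognostic=rng.uniform(-300, 300, (n, 1)),
            predictive=np.zeros((n, 0)),
        )
        prior = CoefficientPrior([0.5], [[1e-8]])
        res = cs.GammaProcessCox(ds, add_intercept=False, coef_prior=prior).fit(
            n_iter=100, burn_in=20, seed=1
        )
        assert res.diagnostics()["n_clipped"] > 0

    def test_draws_csv_roundtrip(self, tmp_path):
        ds = cs.simulate_ph(cs.PHSimConfig(n=60, seed=10))
        res = cs.GammaProcessCox(ds).fit(n_iter=300, burn_in=100, seed=2)
        res.draws.to_csv(tmp_path / "d.csv", tmp_path / "d.json")
        back = cs.PosteriorDraws.from_csv(tmp_path / "d.csv", tmp_path / "d.json")
        np.testing.assert_allclose(back.beta, res.draws.beta, rtol=1e-12)
        np.testing.assert_allclose(back.h[0], res.draws.h[0], rtol=1e-12)
        assert back.column_names == res.draws.column_names


class TestStratified:
    def test_arm_without_events_rejected(self):
        rng = np.random.default_rng(3)
        n = 40
        ds = cs.SurvivalDataset(
            time=rng.exponential(5, n),
            event=np.r_[np.ones(n // 2, dtype=int), np.zeros(n - n // 2, dtype=int)],
            arm=np.r_[np.zeros(n // 2, dtype=int), np.ones(n - n // 2, dtype=int)],
            prognostic=rng.normal(size=(n, 1)),
            predictive=rng.normal(size=(n, 1)),
        )
        with pytest.raises(StratificationError):
            cs.GammaProcessCox(ds, stratify_by_arm=True)

    def test_ph_data_stratified_agrees_with_shared_baseline(self):
        cfg = cs.PHSimConfig(n=500, gamma=(0.5, 0.5, 0.5), seed=11)
        ds = cs.simulate_ph(cfg)
        grid_s = cs.default_grid(n_z2=5, include_intercept=False)
        grid_u = cs.default_grid(n_z2=5)
        res_u = cs.GammaProcessCox(ds).fit(seed=1)
        res_s = cs.GammaProcessCox(ds, stratify_by_arm=True).fit(seed=2)
        nu = res_u.default_nu()
        ru = res_u.rmstd(grid_u, nu=nu).values.mean(axis=0)
        rs = res_s.rmstd(grid_s, nu=nu).values.mean(axis=0)
        sd = res_u.rmstd(grid_u, nu=nu).values.std(axis=0)
        assert np.all(np.abs(ru - rs) < 4 * sd)

    def test_nonph_rate_ratio_near_one_then_one_tenth(self):
        """With z'gamma = 0, the between-arm hazard-rate ratio implied by the
        posterior cumulative-hazard increments is ~1 before the change point
        and ~1/10 after."""
        cfg = cs.NonPHSimConfig(n=3000, beta=(0, 0), gamma=(0, 0, 0), seed=12)
        ds = cs.simulate_nonph(cfg)
        res = cs.GammaProcessCox(ds, stratify_by_arm=True).fit(seed=4)
        cuts = res.draws.cutpoints
        H1 = res.draws.h[1].mean(axis=0).cumsum()
        H0 = res.draws.h[0].mean(axis=0).cumsum()
        pre = cuts <= 25.0
        i_pre = int(np.flatnonzero(pre)[-1])
        ratio_pre = H1[i_pre] / H0[i_pre]
        lo = np.searchsorted(cuts, 35.0)
        hi = np.searchsorted(cuts, 60.0)
        ratio_post = (H1[hi] - H1[lo]) / (H0[hi] - H0[lo])
        assert 0.7 < ratio_pre < 1.4
        assert 0.05 < ratio_post < 0.2


class TestIntegration:
    def test_standardized_fit_reports_original_scale(self):
        ds = cs.simulate_ph(cs.PHSimConfig(n=300, gamma=(1, 0, 1), seed=31))
        r_raw = cs.GammaProcessCox(ds).fit(seed=3)
        r_std = cs.GammaProcessCox(ds, standardize=True).fit(seed=3)
        m_raw = r_raw.draws.beta.mean(0)
        m_std = r_std.draws.beta.mean(0)
        s = r_raw.draws.beta.std(0)
        assert np.all(np.abs(m_raw - m_std) < 4 * s / np.sqrt(5))

    def test_spline_on_linear_truth_matches_linear_fit(self):
        # df-3 cubic expansion of a covariate whose true effect is linear:
        # the fitted log-HR surface agrees with the unexpanded fit within
        # sampler Monte Carlo error on a probe grid
        from credsurv.data import SplineSpec

        ds = cs.simulate_ph(cs.PHSimConfig(n=400, gamma=(0.5, 0.0, 0.6), seed=32))
        lin = cs.GammaProcessCox(ds).fit(seed=4)
        spl_model = cs.GammaProcessCox(ds, splines=[SplineSpec(covariate_index=1)])
        spl = spl_model.fit(seed=5)
        probe = np.column_stack([np.zeros(9), np.linspace(-2.5, 2.5, 9)])
        g_lin = cs.CovariateGrid(points=np.c_[np.ones(9), probe])
        g_spl = spl_model.design.grid(probe)
        p_lin = lin.log_hr(g_lin)
        p_spl = spl.log_hr(g_spl)
        diff = p_lin.values.mean(0) - p_spl.values.mean(0)
        sd = p_lin.values.std(0)
        assert np.all(np.abs(diff) < 3.5 * sd)

    def test_threshold_design_axes_accepted(self):
        from credsurv.study import StudyCell, run_replicate

        grid = cs.default_grid(n_z2=7)
        for dh in (0.2, 0.5, 2.0):
            cell = StudyCell("c", cs.PHSimConfig(n=60, gamma=(1, 1, 1)),
                             measures=("log_hr",), delta_h=dh)
            rows = run_replicate(cell, grid, 1, 2, n_iter=300, burn_in=100)
            assert rows[0]["total_coverage"] in (0.0, 1.0)
        for dr in (-1.0, 1.0):
            cell = StudyCell("c", cs.PHSimConfig(n=60, gamma=(1, 1, 1)),
                             measures=("rmstd",), delta_r=dr)
            rows = run_replicate(cell, grid, 1, 2, n_iter=300, burn_in=100)
            assert np.isfinite(rows[0]["pair_size"])
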