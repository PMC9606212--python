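"""Trajectory statistics: velocities, densities, tail fits, VACF, profiles."""

import numpy as np
import pytest

from shearwalk import (
    TrajectorySet,
    decorrelation_time,
    exclusion_filter,
    extract_velocities,
    fit_tail,
    fit_vacf_powerlaw,
    log_binned_density,
    mean_abs_velocity,
    vacf,
)
from shearwalk.trajectory_analysis import VacfCurve

DT = 1e-5


def _traj(ys, dt=DT, L=50e-6, ids=None):
    ys = [np.asarray(y, dtype=float) for y in ys]
    ids = ids or [f"p{i}" for i in range(len(ys))]
    return TrajectorySet(
        ids=ids,
        times=[np.arange(y.size) * dt for y in ys],
        y=ys,
        dt_sample=dt,
        L=L,
    )


class TestExtractVelocities:
    def test_two_point_difference(self):
        series, dt_eff = extract_velocities(_traj([[1.0e-6, 1.5e-6]]))
        assert dt_eff == DT
        assert series[0] == pytest.approx([0.05])

    def test_linear_trajectory_gives_constant_velocity(self):
        c = 2.3e-4
        t = np.arange(100) * DT
        series, _ = extract_velocities(_traj([c * t]), stride=1)
        np.testing.assert_allclose(series[0], c, rtol=1e-6)
        series3, dt3 = extract_velocities(_traj([c * t]), stride=3)
        assert dt3 == pytest.approx(3 * DT)
        np.testing.assert_allclose(series3[0], c, rtol=1e-6)

    def test_too_short_record_rejected(self):
        with pytest.raises(ValueError, match="p0"):
            extract_velocities(_traj([[1e-6, 2e-6]]), stride=2)

    def test_non_uniform_sampling_rejected_with_id(self):
        t = np.array([0.0, DT, 3.5 * DT])
        with pytest.raises(ValueError, match="bad_platelet"):
            TrajectorySet(
                ids=["bad_platelet"], times=[t], y=[np.zeros(3)], dt_sample=DT, L=50e-6
            )


class TestMeanAbsVelocity:
    def test_constant(self):
        assert mean_abs_velocity([np.full(10, 3.0), np.full(4, 3.0)]) == 3.0

    def test_record_average_not_pooled(self):
        # unequal lengths: (m1 + m2) / 2, not the sample-weighted mean
        s1 = np.full(100, 1.0)
        s2 = np.full(2, 3.0)
        assert mean_abs_velocity([s1, s2]) == pytest.approx(2.0)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            mean_abs_velocity([])


class TestExclusionFilter:
    def test_band_bounds(self):
        # 50 um domain with 10 um margin keeps only [10, 40] um
        y = np.array([5e-6, 15e-6, 39e-6, 45e-6])
        out = exclusion_filter(_traj([y]), margin=10e-6)
        kept = np.concatenate(out.y)
        assert kept.min() >= 10e-6 and kept.max() <= 40e-6

    def test_in_band_identity(self):
        y = np.linspace(15e-6, 35e-6, 20)
        out = exclusion_filter(_traj([y]), margin=10e-6)
        assert out.n_records == 1
        np.testing.assert_array_equal(out.y[0], y)

    def test_crossing_splits_into_segments(self):
        # out - in - out - in - out: two in-band segments
        y = np.array([1, 15, 20, 5, 2, 25, 30, 45], dtype=float) * 1e-6
        out = exclusion_filter(_traj([y]), margin=10e-6)
        assert out.n_records == 2
        in_band = ((y >= 10e-6) & (y <= 40e-6)).sum()
        assert sum(seg.size for seg in out.y) == in_band

    def test_empty_band_rejected(self):
        with pytest.raises(ValueError):
            exclusion_filter(_traj([[20e-6]]), margin=30e-6)


class TestLogBinnedDensity:
    def test_point_mass_density(self):
        centers, dens = log_binned_density(np.full(50, 2e-3), 8, (1e-3, 1e-2))
        edges = np.geomspace(1e-3, 1e-2, 9)
        i = np.searchsorted(edges, 2e-3) - 1
        assert dens[i] == pytest.approx(1.0 / (edges[i + 1] - edges[i]))
        assert (dens > 0).sum() == 1

    def test_integral_equals_in_range_fraction(self, rng):
        v = rng.exponential(1e-3, size=20000)
        centers, dens = log_binned_density(v, 8, (1e-5, 0.3))
        edges = np.geomspace(1e-5, 0.3, centers.size + 1)
        frac = ((v >= 1e-5) & (v < 0.3)).mean()
        assert np.sum(dens * np.diff(edges)) == pytest.approx(frac, abs=1e-3)

    def test_bad_range_rejected(self):
        with pytest.raises(ValueError):
            log_binned_density([1e-3], 8, (0.0, 0.1))


class TestFitTail:
    def test_exact_pareto_recovery(self, rng):
        # density exponent 4.8 above 5e-3: tail-convention alpha is 3.8
        v = 5e-3 * rng.random(200_000) ** (-1.0 / 3.8)
        fit = fit_tail(v)
        assert fit.alpha_hat == pytest.approx(3.8, abs=0.15)
        # candidate grid starts at the sample median, just above the true
        # threshold, so the optimum sits near its lower end
        assert 5e-3 <= fit.v_min_hat <= 1.5 * 5e-3

    def test_mixed_distribution_recovery(self, dist6):
        v = np.abs(dist6.sample_signed(1_000_000, seed=77))
        fit = fit_tail(v)
        assert 3.6 <= fit.alpha_hat <= 4.0
        assert 5e-3 / 1.5 <= fit.v_min_hat <= 5e-3 * 1.5

    def test_recovery_over_seeds(self, dist6):
        """Median recovery across seeds stays inside the documented band."""
        alphas, vmins = [], []
        for seed in range(10):
            v = np.abs(dist6.sample_signed(300_000, seed=1000 + seed))
            fit = fit_tail(v)
            alphas.append(fit.alpha_hat)
            vmins.append(fit.v_min_hat)
        assert 3.6 <= np.median(alphas) <= 4.0
        assert 5e-3 / 1.5 <= np.median(vmins) <= 5e-3 * 1.5

    def test_exponential_negative_control(self, rng):
        v = rng.exponential(1e-3, size=100_000)
        fit = fit_tail(v)
        assert fit.degenerate

    def test_min_tail_enforced(self, rng):
        with pytest.raises(ValueError, match="min_tail"):
            fit_tail(rng.exponential(1.0, size=60), min_tail=50)


class TestVacf:
    def test_constant_speed_random_signs(self, rng):
        c = 2e-3
        series = [np.full(500, c * s) for s in rng.choice([-1, 1], size=40)]
        curve = vacf(series, DT, np.arange(5) * DT)
        np.testing.assert_allclose(curve.values, c**2, rtol=1e-12)

    def test_iid_steps_decorrelate(self, rng):
        series = [rng.normal(size=2000) for _ in range(50)]
        curve = vacf(series, DT, np.arange(6) * DT)
        assert curve.values[0] == pytest.approx(1.0, abs=0.02)
        # beyond lag 0 the VACF is 0 within 3 standard errors (~1/sqrt(pairs))
        se = 1.0 / np.sqrt(curve.n_pairs[1:])
        assert np.all(np.abs(curve.values[1:]) < 3.5 * se)

    def test_renewal_process_triangular_form(self, rng):
        # piecewise-constant velocities redrawn every m steps: closed form
        # VACF(k) = <v^2> (1 - k/m) for k < m, 0 beyond
        m = 20
        series = []
        for _ in range(300):
            draws = rng.normal(size=30)
            series.append(np.repeat(draws, m))
        lags = np.arange(0, 2 * m) * DT
        curve = vacf(series, DT, lags)
        k = np.arange(2 * m)
        expected = np.clip(1.0 - k / m, 0.0, None)
        assert np.max(np.abs(curve.values / curve.values[0] - expected)) < 0.05

    def test_lags_beyond_series_dropped_with_warning(self):
        series = [np.ones(10)]
        with pytest.warns(UserWarning, match="dropped"):
            curve = vacf(series, DT, np.array([0.0, 5 * DT, 20 * DT]))
        assert curve.lags.size == 2

    def test_non_multiple_lag_rejected(self):
        with pytest.raises(ValueError, match="multiples"):
            vacf([np.ones(10)], DT, np.array([1.5 * DT]))


class TestVacfPowerlawFit:
    def _curve(self, a, b, noise=0.0, seed=0, n=60):
        lags = np.geomspace(1e-5, 1e-3, n)
        vals = a * (lags / 1e-3) ** (-b)
        if noise:
            vals = vals * np.exp(np.random.default_rng(seed).normal(0, noise, n))
        return VacfCurve(lags=lags, values=vals, n_pairs=np.full(n, 1000))

    def test_noiseless_exact_recovery(self):
        fit = fit_vacf_powerlaw(self._curve(1.7e-5, 0.808), (1e-5, 1e-3))
        assert fit.a == pytest.approx(1.7e-5, rel=1e-10)
        assert fit.b == pytest.approx(0.808, abs=1e-10)
        assert fit.sd_b == pytest.approx(0.0, abs=1e-8)

    def test_noisy_recovery_within_two_se(self):
        fit = fit_vacf_powerlaw(self._curve(1.7e-5, 0.808, noise=0.05, seed=3, n=100), (1e-5, 1e-3))
        assert abs(fit.b - 0.808) < 2 * fit.sd_b + 1e-3

    def test_scale_equivariance(self):
        c1 = self._curve(1.7e-5, 0.8, noise=0.05, seed=4)
        c2 = VacfCurve(lags=c1.lags, values=2 * c1.values, n_pairs=c1.n_pairs)
        f1 = fit_vacf_powerlaw(c1, (1e-5, 1e-3))
        f2 = fit_vacf_powerlaw(c2, (1e-5, 1e-3))
        assert f2.a == pytest.approx(2 * f1.a, rel=1e-9)
        assert f2.b == pytest.approx(f1.b, abs=1e-12)

    def test_too_few_positive_points_rejected(self):
        curve = self._curve(1.0, 0.8, n=10)
        bad = VacfCurve(lags=curve.lags, values=-np.abs(curve.values), n_pairs=curve.n_pairs)
        with pytest.raises(ValueError):
            fit_vacf_powerlaw(bad, (1e-5, 1e-3))


class TestDecorrelationTime:
    def _triangular(self, support=0.5e-3, noise=0.02, n=200, seed=0):
        lags = np.arange(n) * DT
        vals = np.clip(1.0 - lags / support, 0.0, None)
        vals = vals + np.random.default_rng(seed).normal(0, noise, n)
        return VacfCurve(lags=lags, values=vals, n_pairs=np.full(n, 1000))

    def test_triangular_memory_time(self):
        res = decorrelation_time(self._triangular())
        assert res.delta_t == pytest.approx(0.5e-3, abs=0.05e-3)

    def test_known_crossing(self):
        lags = np.arange(100) * DT
        vals = np.exp(-lags / 2e-4)
        curve = VacfCurve(lags=lags, values=vals, n_pairs=np.full(100, 10))
        # tail window picks up a floor ~ values there; crossing is deterministic
        res = decorrelation_time(curve, tail_window=(60 * DT, 99 * DT))
        assert res.delta_t == lags[np.argmax(vals <= res.sigma_tail)]

    def test_scale_invariance(self):
        c1 = self._triangular(seed=5)
        c2 = VacfCurve(lags=c1.lags, values=10 * c1.values, n_pairs=c1.n_pairs)
        assert decorrelation_time(c1).delta_t == decorrelation_time(c2).delta_t

    def test_never_crossing_rejected(self):
        lags = np.arange(50) * DT
        curve = VacfCurve(lags=lags, values=np.linspace(2, 1, 50), n_pairs=np.full(50, 10))
        with pytest.raises(ValueError, match="lag range"):
            decorrelation_time(curve)


class TestWallProfiles:
    def test_uniform_constant_velocity(self):
        from shearwalk import wall_profiles

        c = 1e-3
        t = np.arange(200) * DT
        ys = [y0 + c * t for y0 in np.linspace(12e-6, 30e-6, 10)]
        prof = wall_profiles(_traj(ys), bin_width=1e-6, min_freq=0.0)
        np.testing.assert_allclose(prof.mean_v, c, rtol=1e-9)
        np.testing.assert_allclose(prof.var_v, 0.0, atol=1e-12)
        assert prof.global_mean == pytest.approx(c, rel=1e-9)

    def test_homogeneous_ensemble_flat_profile(self, rng):
        from shearwalk import wall_profiles

        # y-independent velocities: per-bin means consistent with the global
        ys = []
        for _ in range(30):
            v = rng.choice([-1e-3, 1e-3], size=600)
            ys.append(25e-6 + np.concatenate([[0.0], np.cumsum(v) * DT]))
        prof = wall_profiles(_traj(ys), bin_width=2e-6, min_freq=1e-3)
        se = np.sqrt(prof.global_var / prof.counts)
        assert np.all(np.abs(prof.mean_v - prof.global_mean) < 4.5 * se)

    def test_rare_bins_masked(self):
        from shearwalk import wall_profiles

        # one sample at 45 um among many near 20 um: below min_freq, masked
        ys = [np.full(1000, 20e-6), np.array([45e-6, 45e-6])]
        prof = wall_profiles(_traj(ys), bin_width=1e-6, min_freq=0.01)
        assert prof.y_centers.max() < 40e-6
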