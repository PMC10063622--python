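"""MSD statistics, piecewise regression, classification and validation tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from spiralmaze import (
    chi2_homogeneity,
    classify_dispersal,
    detection_rate_ci,
    fit_piecewise,
    msd_series,
    per_minute_screen,
    skewness_symmetry_test,
    variance_partition,
    window_average,
)
from spiralmaze.stats import skewness_null


class TestMSD:
    def test_point_mass_and_symmetric_pair(self):
        df = pd.DataFrame({"frame": [0, 0, 1, 1], "s_mm": [0.0, 0.0, 3.0, -3.0]})
        out = msd_series(df)
        assert out.msd_mm2.iloc[0] == 0.0
        assert out.msd_mm2.iloc[1] == pytest.approx(9.0)

    def test_empty_frames_are_missing_not_zero(self):
        df = pd.DataFrame({"frame": [0, 2], "s_mm": [1.0, 2.0]})
        out = msd_series(df)
        assert np.isnan(out.msd_mm2.iloc[1])
        assert out.n.iloc[1] == 0

    def test_slope_tracks_diffusion_coefficient(self):
        rng = np.random.default_rng(0)
        d, n, t_max = 3.0, 300, 240
        steps = rng.normal(0, np.sqrt(2 * d), (t_max, n))
        s = np.cumsum(steps, axis=0)
        rows = [{"frame": t + 1, "s_mm": s[t, i]}
                for t in range(t_max) for i in range(0, n, 1)]
        out = msd_series(pd.DataFrame(rows))
        fit = fit_piecewise(out.t_min.to_numpy(), out.msd_mm2.to_numpy(), 0)
        assert fit.base_slope == pytest.approx(2 * d, rel=0.15)


class TestWindowAverage:
    def test_360_minutes_give_24_points(self):
        t, v = window_average(np.arange(360.0), 15)
        assert len(v) == 24
        assert v[0] == pytest.approx(np.mean(np.arange(15.0)))

    def test_window_one_is_identity(self):
        x = np.array([3.0, 1.0, 4.0, 1.0, 5.0])
        t, v = window_average(x, 1)
        assert np.array_equal(v, x)

    def test_constant_series_and_residual_acf_pass(self):
        t, v = window_average(np.full(60, 7.0), 15)
        assert np.allclose(v, 7.0)
        fit = fit_piecewise(t, v, 0)
        assert fit.segment_acf_significant == (False,)

    def test_window_longer_than_series_rejected(self):
        with pytest.raises(ValueError):
            window_average(np.arange(10.0), 11)

    def test_replicate_average_matches_manual_mean(self):
        t = pd.DataFrame({"frame": [0, 0, 1], "s_mm": [1.0, -1.0, 2.0]})
        u = pd.DataFrame({"frame": [0, 1, 1], "s_mm": [3.0, 0.0, 4.0]})
        from spiralmaze.stats import average_replicate_msd

        out = average_replicate_msd([msd_series(t), msd_series(u)])
        assert out.msd_mm2.iloc[0] == pytest.approx((1.0 + 9.0) / 2)
        assert out.msd_mm2.iloc[1] == pytest.approx((4.0 + 8.0) / 2)

    def test_window_cascade_prefers_whiter_residuals(self):
        from spiralmaze.stats import choose_window

        rng = np.random.default_rng(7)
        t = np.arange(360.0)
        iid = 2 * t + rng.normal(0, 5, 360)
        assert choose_window(iid, times=t) == 2
        # slowly wandering noise (random walk) needs heavier averaging
        wander = 2 * t + np.cumsum(rng.normal(0, 3, 360))
        assert choose_window(wander, times=t) >= 5


def _muggeo_fit(t, y, psis0, n_iter=30):
    """Iterative-linearization breakpoint estimation (the classic segmented
    algorithm): refit the hinge model with an added indicator column per
    breakpoint and update psi <- psi + gamma/delta until converged."""
    psis = np.array(psis0, dtype=float)
    for _ in range(n_iter):
        cols = [np.ones_like(t), t]
        for p in psis:
            cols.append(np.clip(t - p, 0, None))
        for p in psis:
            cols.append(-(t > p).astype(float))
        X = np.stack(cols, axis=-1)
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        k = len(psis)
        delta = beta[2:2 + k]
        gamma = beta[2 + k:]
        with np.errstate(divide="ignore", invalid="ignore"):
            step = np.where(np.abs(delta) > 1e-12, gamma / delta, 0.0)
        new = np.clip(psis + step, t.min() + 1e-6, t.max() - 1e-6)
        new = np.sort(new)
        if np.allclose(new, psis, atol=1e-10):
            psis = new
            break
        psis = new
    cols = [np.ones_like(t), t] + [np.clip(t - p, 0, None) for p in psis]
    X = np.stack(cols, axis=-1)
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    rss = float(np.sum((y - X @ beta) ** 2))
    return psis, rss


class TestPiecewise:
    t = np.arange(1.0, 25.0)

    def test_exact_line(self):
        fit = fit_piecewise(self.t, 2 * self.t + 1, 0)
        assert fit.base_slope == pytest.approx(2.0)
        assert fit.intercept == pytest.approx(1.0)
        assert fit.rss == pytest.approx(0.0, abs=1e-18)

    def test_noiseless_hinge_recovered(self):
        y = np.where(self.t <= 10, self.t, 10 + 3 * (self.t - 10))
        fit = fit_piecewise(self.t, y, 1)
        assert fit.breakpoints[0] == pytest.approx(10.0, abs=0.25)
        assert fit.slopes == pytest.approx((1.0, 3.0), abs=1e-6)
        assert fit.rss == pytest.approx(0.0, abs=1e-12)

    def test_infeasible_segmentation_rejected(self):
        with pytest.raises(ValueError):
            fit_piecewise(np.arange(3.0), np.arange(3.0), 2)

    def test_rss_non_increasing_in_breakpoints(self):
        rng = np.random.default_rng(1)
        for _ in range(5):
            y = rng.normal(0, 1, 24) + 0.5 * self.t
            rss = [fit_piecewise(self.t, y, k).rss for k in (0, 1, 2)]
            assert rss[0] >= rss[1] - 1e-9 >= rss[2] - 2e-9

    def test_noisy_two_breakpoint_recovery_and_iterative_oracle(self):
        """Median breakpoint error <= 2 time units over 100 seeds; the grid
        search matches a 200-restart iterative-linearization oracle RSS."""
        psi_true = (8.0, 16.0)
        sigma = 0.5
        slopes = (0.2, 2.0, 0.5)

        def make(seed):
            rng = np.random.default_rng(seed)
            y = np.piecewise(
                self.t,
                [self.t <= 8, (self.t > 8) & (self.t <= 16), self.t > 16],
                [lambda u: slopes[0] * u,
                 lambda u: slopes[0] * 8 + slopes[1] * (u - 8),
                 lambda u: slopes[0] * 8 + slopes[1] * 8 + slopes[2] * (u - 16)])
            return y + rng.normal(0, sigma, len(self.t))

        errs = []
        for seed in range(100):
            fit = fit_piecewise(self.t, make(seed), 2)
            errs.append(max(abs(fit.breakpoints[0] - psi_true[0]),
                            abs(fit.breakpoints[1] - psi_true[1])))
        assert np.median(errs) <= 2.0

        rng = np.random.default_rng(123)
        for seed in (0, 17, 55):
            y = make(seed)
            grid_rss = fit_piecewise(self.t, y, 2).rss
            best = np.inf
            for _ in range(200):
                p0 = np.sort(rng.uniform(2, 23, 2))
                _, rss = _muggeo_fit(self.t, y, p0)
                best = min(best, rss)
            assert grid_rss <= best * 1.01


class TestClassification:
    t = np.arange(1.0, 25.0)

    def test_linear_noisy_data_is_type1(self):
        hits = sum(
            classify_dispersal(self.t,
                               2 * self.t + np.random.default_rng(s).normal(0, 1, 24)
                               ).label == "type1"
            for s in range(50))
        assert hits >= 45  # >= 90 % of 50 seeded runs

    def test_latency_then_fast_is_type2(self):
        y = np.where(self.t <= 10, 0.2 * self.t, 2 + 2.0 * (self.t - 10))
        assert classify_dispersal(self.t, y).label == "type2"

    def test_slow_fast_slow_is_type3_and_fast_slow_fast_is_other(self):
        y3 = np.piecewise(self.t,
                          [self.t <= 8, (self.t > 8) & (self.t <= 16), self.t > 16],
                          [lambda u: 0.2 * u,
                           lambda u: 1.6 + 2.0 * (u - 8),
                           lambda u: 17.6 + 0.5 * (u - 16)])
        assert classify_dispersal(self.t, y3).label == "type3"
        yf = np.piecewise(self.t,
                          [self.t <= 8, (self.t > 8) & (self.t <= 16), self.t > 16],
                          [lambda u: 2.0 * u,
                           lambda u: 16 + 0.2 * (u - 8),
                           lambda u: 17.6 + 2.0 * (u - 16)])
        assert classify_dispersal(self.t, yf).label == "other"


class TestDetectionRateCI:
    def test_paper_worked_example(self):
        r = detection_rate_ci(1817, 2535)
        assert round(100 * r.rate) == 72
        assert r.ci_low < r.rate < r.ci_high

    def test_zero_successes(self):
        r = detection_rate_ci(0, 50)
        assert r.rate == 0.0 and r.ci_low == 0.0 and r.ci_high > 0

    def test_rate_above_one_flagged(self):
        r = detection_rate_ci(60, 50)
        assert r.rate == pytest.approx(1.2) and r.flagged

    def test_endpoints_match_beta_quantile_bisection(self):
        """Clopper-Pearson bounds vs brute-force bisection on the beta CDF."""

        def bisect(fn, lo, hi, tol=1e-12):
            for _ in range(200):
                mid = (lo + hi) / 2
                if fn(mid) > 0:
                    hi = mid
                else:
                    lo = mid
                if hi - lo < tol:
                    break
            return (lo + hi) / 2

        k, n, a = 1817, 2535, 0.05
        lo = bisect(lambda p: sps.beta.cdf(p, k, n - k + 1) - a / 2, 0, 1)
        hi = bisect(lambda p: sps.beta.cdf(p, k + 1, n - k) - (1 - a / 2), 0, 1)
        r = detection_rate_ci(k, n)
        assert r.ci_low == pytest.approx(lo, abs=1e-6)
        assert r.ci_high == pytest.approx(hi, abs=1e-6)

    def test_manual_zero_rejected(self):
        with pytest.raises(ValueError):
            detection_rate_ci(3, 0)


class TestChi2Homogeneity:
    def test_ten_occupied_bins_give_df_9(self):
        a = [10, 20, 30, 5, 5, 4, 3, 2, 1, 1]
        b = [12, 18, 28, 6, 4, 5, 3, 2, 2, 1]
        stat, df, p = chi2_homogeneity(a, b)
        assert df == 9

    def test_identical_distributions(self):
        stat, df, p = chi2_homogeneity([5, 5, 5], [5, 5, 5])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_statistic_matches_textbook_formula(self):
        rng = np.random.default_rng(3)
        a = rng.integers(1, 40, 5).astype(float)
        b = rng.integers(1, 40, 5).astype(float)
        stat, df, _ = chi2_homogeneity(a, b)
        table = np.stack([a, b])
        expected = (table.sum(1, keepdims=True)
                    * table.sum(0, keepdims=True) / table.sum())
        brute = ((table - expected) ** 2 / expected).sum()
        assert stat == pytest.approx(brute, abs=1e-9)

    def test_empty_bins_dropped_and_all_empty_rejected(self):
        stat, df, _ = chi2_homogeneity([5, 0, 5, 0], [4, 0, 6, 0])
        assert df == 1
        with pytest.raises(ValueError):
            chi2_homogeneity([0, 0], [0, 0])


class TestSkewness:
    def test_symmetric_sample_has_zero_skewness(self):
        b1, p = skewness_symmetry_test([-2.0, -1.0, 0.0, 1.0, 2.0] * 2, seed=0)
        assert b1 == pytest.approx(0.0, abs=1e-12)
        assert p > 0.9

    def test_type_i_error_near_nominal(self):
        """Under a Gaussian null the test rejects at ~5 %; a single shared
        null distribution serves all repetitions (same n)."""
        n = 50
        null = skewness_null(n, n_mc=10_000, seed=1)
        rng = np.random.default_rng(2)
        rejections = 0
        runs = 2000
        for _ in range(runs):
            x = rng.standard_normal(n)
            _, p = skewness_symmetry_test(x, _null=null)
            rejections += p < 0.05
        assert 0.035 <= rejections / runs <= 0.065

    def test_exponential_sample_strongly_rejected(self):
        hits = 0
        for seed in range(20):
            x = np.random.default_rng(seed).exponential(size=200)
            _, p = skewness_symmetry_test(x, n_mc=10_000, seed=seed + 100)
            hits += p < 0.01
        assert hits >= 19  # >= 95 % of seeds

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            skewness_symmetry_test(np.ones(20))
        with pytest.raises(ValueError):
            skewness_symmetry_test(np.arange(5))


class TestPerMinuteScreen:
    def test_identical_groups_all_adjusted_to_one(self):
        rows = []
        for minute in range(10):
            for g in ("levo", "dextro"):
                rows += [{"minute": minute, "group": g, "value": v}
                         for v in (1.0, 2.0, 3.0)]
        out = per_minute_screen(pd.DataFrame(rows), test="anova")
        assert (out.p_adjusted == 1.0).all()

    def test_bonferroni_arithmetic_and_bounds(self):
        rng = np.random.default_rng(4)
        rows = []
        for minute in range(20):
            for g in ("a", "b"):
                rows += [{"minute": minute, "group": g,
                          "value": rng.normal(0 if g == "a" else 2.0, 1.0)}
                         for _ in range(6)]
        out = per_minute_screen(pd.DataFrame(rows), test="anova")
        assert np.all(out.p_adjusted >= out.p_raw)
        assert np.all(out.p_adjusted <= 1.0)
        free = out[out.p_raw * 20 < 1.0]
        assert np.allclose(free.p_adjusted, free.p_raw * 20)

    def test_familywise_error_controlled_under_null(self):
        """Same diffusion in both rotation directions: the Bonferroni screen
        almost never reports any significant minute."""
        rng = np.random.default_rng(5)
        n_families, m = 100, 30
        any_hit = 0
        for _ in range(n_families):
            rows = []
            for minute in range(m):
                for g in ("levo", "dextro"):
                    rows += [{"minute": minute, "group": g,
                              "value": rng.normal(0, 1)} for _ in range(5)]
            out = per_minute_screen(pd.DataFrame(rows), test="anova")
            any_hit += (out.p_adjusted < 0.05).any()
        assert any_hit / n_families <= 0.05 + 0.03

    def test_skewness_screen_runs_per_minute(self):
        rng = np.random.default_rng(6)
        rows = [{"minute": m, "value": v}
                for m in range(3) for v in rng.standard_normal(40)]
        out = per_minute_screen(pd.DataFrame(rows), test="skewness")
        assert len(out) == 3 and np.all(out.p_adjusted >= out.p_raw)


class TestVariancePartition:
    @staticmethod
    def _design(rng, strain_sd2, noise_sd2, n_strains=10, n_reps=10):
        rows = []
        for si in range(n_strains):
            mu = rng.normal(0, np.sqrt(strain_sd2))
            for ri in range(n_reps):
                rows.append({
                    "final_msd": mu + rng.normal(0, np.sqrt(noise_sd2)),
                    "strain": f"s{si}",
                    "replicate_day": ri % 5,
                    "n_detections": int(rng.integers(100, 200)),
                    "orientation": ("levo", "dextro")[ri % 2],
                })
        return pd.DataFrame(rows)

    def test_pure_strain_signal_gives_ratio_one(self):
        rows = [{"final_msd": float(si), "strain": f"s{si}",
                 "replicate_day": ri, "n_detections": 100, "orientation": "levo"}
                for si in range(4) for ri in range(3)]
        ratio = variance_partition(pd.DataFrame(rows),
                                   other_factors=("replicate_day",))
        assert ratio == pytest.approx(1.0, abs=1e-9)

    def test_all_equal_gives_zero(self):
        rows = [{"final_msd": 5.0, "strain": f"s{si}", "replicate_day": ri,
                 "n_detections": 100, "orientation": "levo"}
                for si in range(4) for ri in range(3)]
        assert variance_partition(pd.DataFrame(rows)) == 0.0

    def test_recovers_known_variance_share(self):
        """Strain explains 33 % of variance by construction; the sequential
        ANOVA ratio matches over 100 seeds."""
        ratios = []
        for seed in range(100):
            rng = np.random.default_rng(seed)
            df = self._design(rng, strain_sd2=33.0, noise_sd2=67.0)
            ratios.append(variance_partition(df))
        assert np.mean(ratios) == pytest.approx(0.33, abs=0.05)
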