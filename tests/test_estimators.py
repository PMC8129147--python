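"""Estimator battery: arithmetic examples, independent oracles, properties."""

import numpy as np
import pytest
import statsmodels.api as sm
from scipy import optimize, stats

from twosmr.estimators import (
    DegenerateInputError,
    InsufficientInstrumentsError,
    RatioEstimates,
    contamination_mixture,
    ivw,
    mr_egger,
    mr_presso,
    wald_ratios,
    weighted_median,
    weighted_mode,
    _weighted_mode_point,
)
from twosmr.simulate import SimConfig, simulate_pair
from twosmr.harmonize import harmonize

from conftest import make_harmonized, random_harmonized


def ratios(theta, se):
    theta = np.asarray(theta, dtype=float)
    se = np.asarray(se, dtype=float)
    return RatioEstimates([f"rs{i}" for i in range(len(theta))], theta, se)


class TestWaldRatios:
    def test_arithmetic(self):
        h = make_harmonized([0.5], [0.1], se_y=[0.05])
        r = wald_ratios(h)
        assert r.theta[0] == pytest.approx(0.2)
        assert r.se[0] == pytest.approx(0.1)

    def test_zero_instrument_uncertainty_equates_orders(self):
        h = make_harmonized([1.0, 2.0, -1.5], [0.2, 0.3, 0.1], se_x=[0.0, 0.0, 0.0])
        np.testing.assert_allclose(
            wald_ratios(h, "first").se, wald_ratios(h, "second").se
        )

    def test_second_order_se_dominates_first(self, rng):
        for _ in range(50):
            h = random_harmonized(rng, 12)
            assert np.all(
                wald_ratios(h, "second").se >= wald_ratios(h, "first").se - 1e-15
            )

    def test_zero_beta_x_dropped_and_all_zero_raises(self):
        h = make_harmonized([0.0, 0.5], [0.1, 0.1])
        assert wald_ratios(h).n_snps == 1
        with pytest.raises(DegenerateInputError):
            wald_ratios(make_harmonized([0.0], [0.1]))


class TestIVW:
    def test_single_variant_is_its_wald_ratio(self):
        h = make_harmonized([0.5], [0.1], se_y=[0.05])
        res = ivw(wald_ratios(h))
        assert res.estimate == pytest.approx(0.2)
        assert res.effects_model == "fixed"
        assert np.isnan(res.Q_pval)

    def test_identical_ratios_zero_heterogeneity(self):
        r = ratios([0.3, 0.3, 0.3], [0.1, 0.2, 0.3])
        res = ivw(r)
        assert res.Q == pytest.approx(0.0, abs=1e-20)
        assert res.Q_pval == pytest.approx(1.0)
        assert res.effects_model == "fixed"
        assert res.estimate == pytest.approx(0.3)

    @pytest.mark.parametrize("j", [2, 5, 17, 50])
    def test_matches_wls_through_origin_oracle(self, rng, j):
        """IVW on first-order ratios == WLS of beta_Y on beta_X through origin
        with weights 1/se_Y^2 (estimate and fixed SE, tolerance 1e-10)."""
        h = random_harmonized(rng, j)
        res = ivw(wald_ratios(h), model="fixed")
        t = h.table
        fit = sm.WLS(
            t["beta_y"], t[["beta_x"]], weights=1.0 / t["se_y"] ** 2
        ).fit()
        assert res.estimate == pytest.approx(fit.params.iloc[0], abs=1e-10)
        se_fixed = float(fit.bse.iloc[0]) / np.sqrt(fit.scale)  # unit-scale WLS SE
        assert res.se == pytest.approx(se_fixed, abs=1e-10)

    def test_heterogeneity_switches_to_random_and_inflates_se(self):
        r = ratios([0.0, 0.1, 1.5, -1.0, 0.4], [0.05] * 5)
        auto = ivw(r, "auto")
        fixed = ivw(r, "fixed")
        assert auto.Q_pval < 0.05
        assert auto.effects_model == "random"
        assert auto.se >= fixed.se
        assert auto.se == pytest.approx(fixed.se * np.sqrt(auto.Q / 4))

    def test_random_se_floored_at_fixed(self):
        r = ratios([0.3, 0.3001, 0.2999], [0.1, 0.1, 0.1])
        forced = ivw(r, "random")
        assert forced.se == pytest.approx(ivw(r, "fixed").se)  # Q << J-1

    def test_empty_raises(self):
        with pytest.raises(DegenerateInputError):
            ivw(ratios([], []))


class TestWeightedMedian:
    def test_equal_weights_is_plain_median(self):
        r = ratios([0.1, 0.2, 0.9], [1.0, 1.0, 1.0])
        assert weighted_median(r, n_boot=0).estimate == pytest.approx(0.2)

    def test_dominant_weight_pulls_to_that_variant(self):
        r = ratios([0.1, 0.2, 0.9], [10.0, 10.0, 0.001])
        assert weighted_median(r, n_boot=0).estimate == pytest.approx(0.9, abs=1e-3)

    def test_matches_crossing_point_oracle(self, rng):
        """Root-finding oracle: the interpolated standardized-cumulative-weight
        curve crosses 0.5 exactly at the estimate."""
        for _ in range(20):
            j = int(rng.integers(4, 30))
            th = rng.normal(0.2, 0.5, j)
            se = rng.uniform(0.02, 0.4, j)
            r = ratios(th, se)
            est = weighted_median(r, n_boot=0).estimate
            w = 1.0 / se**2
            order = np.argsort(th)
            ths, ws = th[order], w[order]
            s = (np.cumsum(ws) - ws / 2) / ws.sum()
            f = lambda c: np.interp(c, ths, s) - 0.5
            if f(ths[0]) < 0 < f(ths[-1]):
                root = optimize.brentq(f, ths[0], ths[-1], xtol=1e-12)
                assert est == pytest.approx(root, abs=1e-8)

    def test_bootstrap_se_reproducible_and_positive(self):
        r = ratios([0.1, 0.3, 0.2, 0.5, 0.25], [0.1, 0.1, 0.2, 0.3, 0.1])
        a = weighted_median(r, n_boot=200, seed=7)
        b = weighted_median(r, n_boot=200, seed=7)
        assert a.se == b.se > 0
        assert a.ci95[0] < a.estimate < a.ci95[1]

    def test_needs_three_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            weighted_median(ratios([0.1, 0.2], [0.1, 0.1]))


class TestWeightedMode:
    def test_dominant_mode(self):
        r = ratios([0.3, 0.3, 0.3, 5.0], [1.0, 1.0, 1.0, 1.0])
        assert weighted_mode(r, n_boot=0).estimate == pytest.approx(0.3, abs=0.05)

    def test_tight_cluster_with_symmetric_outliers(self):
        r = ratios([0.5, 0.51, 0.49, 0.5, -3.0, 4.0], [0.05] * 6)
        est = weighted_mode(r, n_boot=0).estimate
        assert 0.45 < est < 0.55

    def test_all_identical_ratios(self):
        r = ratios([0.4, 0.4, 0.4], [0.1, 0.2, 0.1])
        assert weighted_mode(r, n_boot=0).estimate == pytest.approx(0.4)

    def test_matches_refined_grid_oracle(self, rng):
        """The coarse-grid argmax sits within one coarse step of a 10x finer
        independent KDE argmax."""
        for _ in range(10):
            j = int(rng.integers(5, 25))
            th = rng.normal(0.1, 0.4, j)
            se = rng.uniform(0.05, 0.3, j)
            r = ratios(th, se)
            coarse = weighted_mode(r, n_boot=0, n_grid=512).estimate
            w = 1.0 / se**2
            sd = np.std(th, ddof=1)
            iqr = np.subtract(*np.percentile(th, [75, 25]))
            h = 0.9 * min(sd, iqr / 1.34) * j ** (-0.2)
            fine = np.linspace(th.min() - 3 * h, th.max() + 3 * h, 5120)
            dens = (w[None, :] * stats.norm.pdf(fine[:, None], th[None, :], h)).sum(axis=1)
            step = (th.max() - th.min() + 6 * h) / 511
            assert abs(coarse - fine[np.argmax(dens)]) <= step


class TestMREgger:
    def test_recovers_slope_and_intercept_in_noiseless_limit(self, rng):
        j = 30
        bx = rng.uniform(0.05, 0.3, j)
        by = 0.05 + 0.2 * bx  # constant directional pleiotropy
        h = make_harmonized(bx, by, se_y=np.full(j, 0.01))
        res = mr_egger(h)
        assert res.estimate == pytest.approx(0.2, abs=1e-8)
        assert res.extra["intercept"] == pytest.approx(0.05, abs=1e-8)

    def test_matches_wls_normal_equations_oracle(self, rng):
        for _ in range(20):
            h = random_harmonized(rng, 15)
            res = mr_egger(h)
            t = h.table.copy()
            flip = t["beta_x"] < 0
            t.loc[flip, ["beta_x", "beta_y"]] *= -1
            X = sm.add_constant(t["beta_x"])
            fit = sm.WLS(t["beta_y"], X, weights=1.0 / t["se_y"] ** 2).fit()
            assert res.extra["intercept"] == pytest.approx(fit.params.iloc[0], abs=1e-10)
            assert res.estimate == pytest.approx(fit.params.iloc[1], abs=1e-10)

    def test_orientation_invariance(self, rng):
        h = random_harmonized(rng, 10)
        flipped = h.table.copy()
        flipped.loc[::2, ["beta_x", "beta_y"]] *= -1
        h2 = make_harmonized(flipped["beta_x"], flipped["beta_y"],
                             flipped["se_x"], flipped["se_y"])
        assert mr_egger(h).estimate == pytest.approx(mr_egger(h2).estimate)

    def test_intercept_p_calibrated_under_no_pleiotropy(self):
        """With no pleiotropy the intercept test should reject at ~nominal rate."""
        rej = 0
        reps = 200
        for s in range(reps):
            sim = simulate_pair(SimConfig(n_variants=20, theta_true=0.2, seed=50_000 + s))
            h = harmonize(sim.exposure, sim.outcome)
            if mr_egger(h).extra["intercept_pval"] < 0.05:
                rej += 1
        assert 0.01 <= rej / reps <= 0.10

    def test_needs_three_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            mr_egger(make_harmonized([0.1, 0.2], [0.02, 0.04]))


class TestContaminationMixture:
    def test_all_valid_tiny_se(self):
        r = ratios([0.4, 0.401, 0.399, 0.4005], [0.01] * 4)
        res = contamination_mixture(r)
        assert res.estimate == pytest.approx(0.4, abs=0.01)
        assert len(res.extra["ci_intervals"]) == 1
        lo, hi = res.extra["ci_intervals"][0]
        assert lo < 0.4 < hi
        assert all(res.extra["valid_at_max"].values())

    def test_contaminated_fraction_assigned_invalid(self):
        valid = list(np.full(12, 0.3) + np.linspace(-0.01, 0.01, 12))
        contam = list(np.full(8, -0.5) + np.linspace(-0.01, 0.01, 8))
        r = ratios(valid + contam, [0.02] * 20)
        res = contamination_mixture(r)
        assert res.estimate == pytest.approx(0.3, abs=3 * res.se)
        flags = res.extra["valid_at_max"]
        contam_snps = r.snps[12:]
        assert np.mean([not flags[s] for s in contam_snps]) >= 0.9

    def test_grid_refinement_stability(self, rng):
        th = rng.normal(0.2, 0.1, 15)
        se = rng.uniform(0.05, 0.1, 15)
        r = ratios(th, se)
        coarse = contamination_mixture(r, n_grid=1000)
        fine = contamination_mixture(r, n_grid=10000)
        span = coarse.extra["n_grid"]
        pad = 2 * se.max()
        step = (th.max() - th.min() + 2 * pad) / (span - 1)
        assert abs(coarse.estimate - fine.estimate) <= step

    def test_degenerate_grid_rejected(self):
        r = ratios([0.1, 0.2, 0.3], [0.1] * 3)
        with pytest.raises(ValueError, match="grid"):
            contamination_mixture(r, n_grid=2)


class TestMRPresso:
    def test_proportional_data_no_outliers(self, rng):
        j = 12
        bx = rng.uniform(0.05, 0.3, j)
        by = 0.3 * bx + rng.normal(0, 1e-4, j)
        h = make_harmonized(bx, by, se_y=np.full(j, 0.05))
        res = mr_presso(h, n_sim=500, seed=1)
        assert res.global_pval > 0.5
        assert res.outliers() == []

    def test_injected_outlier_detected(self, rng):
        j = 15
        bx = rng.uniform(0.05, 0.3, j)
        se_y = np.full(j, 0.03)
        by = 0.2 * bx + rng.normal(0, se_y)
        by[4] += 10 * se_y[4]
        h = make_harmonized(bx, by, se_y=se_y)
        res = mr_presso(h, n_sim=1000, seed=2)
        assert res.outlier_pval[4] < 0.05
        assert res.global_pval < 0.05

    def test_global_p_stable_when_doubling_nsim(self, rng):
        h = random_harmonized(rng, 10)
        a = mr_presso(h, n_sim=1000, seed=3)
        b = mr_presso(h, n_sim=2000, seed=4)
        p = a.global_pval
        band = 1.96 * np.sqrt(p * (1 - p) / 1000)
        assert abs(a.global_pval - b.global_pval) <= max(band, 0.05)

    def test_reproducible_under_seed(self, rng):
        h = random_harmonized(rng, 8)
        a = mr_presso(h, n_sim=300, seed=9)
        b = mr_presso(h, n_sim=300, seed=9)
        assert a.global_pval == b.global_pval
        np.testing.assert_array_equal(a.outlier_pval, b.outlier_pval)

    def test_empirical_p_bounds_and_length(self, rng):
        h = random_harmonized(rng, 6)
        res = mr_presso(h, n_sim=200, seed=0)
        assert 1 / 201 <= res.global_pval <= 1.0
        assert len(res.outlier_pval) == 6

    def test_needs_four_instruments(self):
        with pytest.raises(InsufficientInstrumentsError):
            mr_presso(make_harmonized([0.1, 0.2, 0.3], [0.02, 0.04, 0.05]))
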