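"""Calibration, accuracy-profile statistics, assay and peak figures of merit."""

import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from alqc import synthetic
from alqc.validation import (
    AccuracyProfile,
    CalibrationModel,
    PeakDescriptor,
    accuracy_profile_from_areas,
    back_calculate,
    build_profile,
    chromatographic_params,
    detect_api,
    fit_calibration,
    level_matrix,
    level_statistics,
    linearity_fit,
    tablet_content,
)


def _areas(rows):
    return pd.DataFrame(rows)


class TestCalibration:
    def test_single_day_factor_is_mean_over_nominal(self):
        df = _areas(
            [{"day": 1, "area": 200.0}, {"day": 1, "area": 200.0}]
        )
        model = fit_calibration(df, 0.10)
        assert model.factor(1) == pytest.approx(2000.0)

    def test_unequal_duplicates_average(self):
        df = _areas([{"day": 1, "area": 190.0}, {"day": 1, "area": 210.0}])
        assert fit_calibration(df, 0.10).factor(1) == pytest.approx(2000.0)

    def test_noise_free_simulation_recovers_true_factor(self):
        truth = synthetic.ValidationTruth(
            compound="artemether",
            true_response_factor=2000.0,
            levels={80: 0.08, 100: 0.10, 120: 0.12},
            relative_bias_per_level={},
            sigma_day=0.0,
            sigma_rep=0.0,
        )
        areas = synthetic.simulate_validation_areas(truth, seed=0)
        model = fit_calibration(areas, 0.10)
        for day in (1, 2, 3):
            assert model.factor(day) == pytest.approx(2000.0)

    def test_back_calculation_inverts_response(self):
        model = CalibrationModel("x", {1: 2000.0})
        df = _areas(
            [
                {"day": 1, "area": 2000.0 * 0.08},
                {"day": 1, "area": 0.0},
            ]
        )
        out = back_calculate(df, model)
        assert out["conc"].tolist() == pytest.approx([0.08, 0.0])

    def test_unknown_day_raises(self):
        model = CalibrationModel("x", {1: 2000.0})
        with pytest.raises(KeyError):
            back_calculate(_areas([{"day": 2, "area": 1.0}]), model)

    def test_nonpositive_areas_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration(_areas([{"day": 1, "area": -5.0}]), 0.10)


class TestLevelStatistics:
    def test_exact_observations_give_degenerate_interval(self):
        x = np.full((3, 3), 0.10)
        s = level_statistics(x, 0.10)
        assert s.relative_bias_pct == pytest.approx(0.0, abs=1e-12)
        assert s.rsd_repeatability_pct == pytest.approx(0.0, abs=1e-12)
        assert s.tolerance_low_pct == pytest.approx(0.0, abs=1e-12)
        assert s.tolerance_high_pct == pytest.approx(0.0, abs=1e-12)

    def test_between_day_variance_clamps_to_zero(self, rng):
        # identical day means, spread within days -> MS_B < MS_W
        x = np.array([[0.09, 0.11, 0.10], [0.11, 0.09, 0.10], [0.10, 0.10, 0.10]])
        s = level_statistics(x, 0.10)
        assert s.sigma_B2 == 0.0
        assert s.sigma_IP2 == pytest.approx(s.sigma_W2)

    def test_interval_contains_bias_and_widens_with_beta(self, rng):
        x = rng.normal(0.10, 0.002, size=(3, 3))
        s90 = level_statistics(x, 0.10, beta=0.90)
        s95 = level_statistics(x, 0.10, beta=0.95)
        assert s90.tolerance_low_pct <= s90.relative_bias_pct <= s90.tolerance_high_pct
        width90 = s90.tolerance_high_pct - s90.tolerance_low_pct
        width95 = s95.tolerance_high_pct - s95.tolerance_low_pct
        assert width95 > width90

    def test_width_shrinks_with_more_replicates(self, rng):
        sigma = 0.002
        x_small = rng.normal(0.10, sigma, size=(3, 3))
        # same per-level variance ratio, larger p*n
        widths = []
        for p, n in ((3, 3), (6, 6)):
            reps = []
            for _ in range(200):
                x = rng.normal(0.10, sigma, size=(p, n))
                s = level_statistics(x, 0.10)
                reps.append(s.tolerance_high_pct - s.tolerance_low_pct)
            widths.append(np.mean(reps))
        assert widths[1] < widths[0]

    def test_bias_and_variance_recovery_monte_carlo(self):
        # MC oracle: mean estimated bias -> true bias; mean sigma_IP^2 -> true
        r = np.random.default_rng(100)
        true_bias, sigma_day, sigma_rep, mu = 0.02, 0.002, 0.0015, 0.10
        biases, ips = [], []
        for _ in range(4000):
            gamma = r.normal(0, sigma_day, size=3)
            x = mu * (1 + true_bias) + gamma[:, None] + r.normal(0, sigma_rep, size=(3, 3))
            s = level_statistics(x, mu)
            biases.append(s.relative_bias_pct)
            ips.append(s.sigma_IP2)
        assert np.mean(biases) == pytest.approx(100 * true_bias, abs=0.1)
        assert np.mean(ips) == pytest.approx(sigma_day**2 + sigma_rep**2, rel=0.05)

    def test_beta_expectation_coverage_monte_carlo(self):
        # fraction of future single observations inside the interval ~ beta
        r = np.random.default_rng(200)
        mu, sigma_day, sigma_rep = 0.10, 0.002, 0.0015
        sigma_tot = math.hypot(sigma_day, sigma_rep)
        reps, futures = 10_000, 40
        inside = []
        for _ in range(reps):
            gamma = r.normal(0, sigma_day, size=3)
            x = mu + gamma[:, None] + r.normal(0, sigma_rep, size=(3, 3))
            s = level_statistics(x, mu, beta=0.90)
            fut_gamma = r.normal(0, sigma_day, size=futures)
            fut = mu + fut_gamma + r.normal(0, sigma_rep, size=futures)
            rel = 100 * (fut - mu) / mu
            inside.append(
                np.mean((rel >= s.tolerance_low_pct) & (rel <= s.tolerance_high_pct))
            )
        assert np.mean(inside) == pytest.approx(0.90, abs=0.02)

    def test_unbalanced_design_rejected(self):
        with pytest.raises(ValueError):
            level_statistics(np.array([0.1, 0.1, 0.1]), 0.10)
        with pytest.raises(ValueError):
            level_statistics(np.full((1, 3), 0.1), 0.10)


class TestLinearity:
    def test_perfect_recovery(self):
        df = pd.DataFrame(
            {"nominal_mgml": [0.08, 0.10, 0.12] * 3, "conc": [0.08, 0.10, 0.12] * 3}
        )
        slope, intercept, r2 = linearity_fit(df)
        assert slope == pytest.approx(1.0)
        assert intercept == pytest.approx(0.0, abs=1e-12)
        assert r2 == pytest.approx(1.0)

    def test_constant_relative_bias_shows_in_slope(self):
        x = np.array([0.08, 0.10, 0.12] * 3)
        df = pd.DataFrame({"nominal_mgml": x, "conc": 1.05 * x})
        slope, intercept, _ = linearity_fit(df)
        assert slope == pytest.approx(1.05)
        assert intercept == pytest.approx(0.0, abs=1e-12)

    def test_matches_polyfit_oracle(self, rng):
        x = np.repeat([0.08, 0.10, 0.12], 9)
        y = x + rng.normal(0, 0.002, size=x.size)
        slope, intercept, r2 = linearity_fit(pd.DataFrame({"nominal_mgml": x, "conc": y}))
        ref = stats.linregress(x, y)
        assert slope == pytest.approx(ref.slope)
        assert intercept == pytest.approx(ref.intercept)
        assert r2 == pytest.approx(ref.rvalue**2)

    def test_degenerate_x_rejected(self):
        df = pd.DataFrame({"nominal_mgml": [0.1, 0.1, 0.1], "conc": [0.1, 0.1, 0.1]})
        with pytest.raises(ValueError):
            linearity_fit(df)


def _stats(level, mu, low, high, beta=0.90):
    from alqc.validation import LevelStats

    return LevelStats(
        level=level, mu_T=mu, grand_mean=mu, relative_bias_pct=(low + high) / 2,
        sigma_W2=0, sigma_B2=0, sigma_IP2=0, rsd_repeatability_pct=0,
        rsd_intermediate_pct=0, R=0, B2=1, nu=5, beta=beta,
        tolerance_low_pct=low, tolerance_high_pct=high,
    )


class TestProfile:
    def test_valid_profile_uses_dosing_range_endpoints(self):
        levels = [
            _stats(80, 0.08, -4, 6),
            _stats(100, 0.10, -3, 3),
            _stats(120, 0.12, -5, 5),
        ]
        profile = build_profile(levels, 10.0)
        assert profile.valid
        assert profile.lloq == 0.08 and profile.uloq == 0.12

    def test_any_breach_invalidates(self):
        levels = [_stats(80, 0.08, -4, 11), _stats(100, 0.10, -3, 3), _stats(120, 0.12, -4, 4)]
        assert not build_profile(levels, 10.0).valid

    def test_interpolated_lloq_matches_hand_solution(self):
        # upper bound 12 at 0.08 and 8 at 0.10 crosses 10 at 0.09
        levels = [_stats(80, 0.08, -4, 12), _stats(100, 0.10, -3, 8), _stats(120, 0.12, -4, 4)]
        profile = build_profile(levels, 10.0)
        assert not profile.valid
        assert profile.lloq == pytest.approx(0.09)
        assert profile.uloq == 0.12

    def test_end_to_end_default_simulation_is_valid(self):
        for compound in (synthetic.ARTEMETHER, synthetic.LUMEFANTRINE):
            truth = synthetic.default_validation_truth(compound)
            areas = synthetic.simulate_validation_areas(truth, seed=5)
            profile = accuracy_profile_from_areas(
                areas, truth.levels[100], compound=compound
            )
            assert profile.valid
            assert profile.lloq == min(truth.levels.values())
            assert profile.uloq == max(truth.levels.values())
            assert profile.slope == pytest.approx(1.0, abs=0.05)
            assert profile.r2 > 0.99


class TestAssayAndDetection:
    def test_full_content_noise_free_is_exactly_100(self):
        areas = synthetic.simulate_assay(1.0, seed=0, sigma_rep=0.0, baseline_sd=0.0)
        contents = tablet_content(areas, synthetic.DEFAULT_RESPONSE_FACTORS)
        for value in contents.values():
            assert value == pytest.approx(100.0)

    def test_dilution_arithmetic_at_95_percent(self):
        areas = synthetic.simulate_assay(0.95, seed=0, sigma_rep=0.0, baseline_sd=0.0)
        contents = tablet_content(areas, synthetic.DEFAULT_RESPONSE_FACTORS)
        for value in contents.values():
            assert value == pytest.approx(95.0)

    def test_licit_range_conformity(self):
        for frac, expected in ((0.95, True), (1.05, True), (0.90, False)):
            areas = synthetic.simulate_assay(frac, seed=1)
            contents = tablet_content(areas, synthetic.DEFAULT_RESPONSE_FACTORS)
            for value in contents.values():
                assert (94.0 <= value <= 106.0) == expected

    def test_falsified_batch_not_detected(self):
        areas = synthetic.simulate_assay(0.0, seed=2)
        contents = tablet_content(areas, synthetic.DEFAULT_RESPONSE_FACTORS)
        assert set(detect_api(contents).values()) == {"not_detected"}

    def test_threshold_boundary_is_closed(self):
        assert detect_api({"x": 1.0}, threshold_pct=1.0) == {"x": "present"}
        assert detect_api({"x": 0.999}, threshold_pct=1.0) == {"x": "not_detected"}


class TestChromatography:
    def test_retention_factor(self):
        peak = PeakDescriptor(t0=1.0, tR=2.0, w_half=0.2, f_5=0.15, w_5=0.30)
        assert chromatographic_params(peak).k == pytest.approx(1.0)

    def test_symmetric_peak_has_unit_tailing(self):
        peak = PeakDescriptor(t0=1.0, tR=3.0, w_half=0.2, f_5=0.15, w_5=0.30)
        assert chromatographic_params(peak).As == pytest.approx(1.0)

    def test_gaussian_pair_resolution_closed_form(self):
        # two Gaussians: w_half = 2 sqrt(2 ln 2) sigma; Rs = dt / (2 (s1+s2))
        def gaussian_peak(tR, sigma):
            w_half = 2 * math.sqrt(2 * math.log(2)) * sigma
            w5 = 2 * math.sqrt(2 * math.log(20)) * sigma
            return PeakDescriptor(t0=1.0, tR=tR, w_half=w_half, f_5=w5 / 2, w_5=w5)

        p1, p2 = gaussian_peak(4.0, 0.10), gaussian_peak(6.0, 0.15)
        out = chromatographic_params(p1, p2)
        expected = (6.0 - 4.0) / (2 * (0.10 + 0.15))
        assert out.Rs == pytest.approx(expected, rel=0.01)  # 1.18/w_half convention
        assert out.As == pytest.approx(1.0)

    def test_invalid_geometry_rejected(self):
        with pytest.raises(ValueError):
            PeakDescriptor(t0=2.0, tR=1.0, w_half=0.1, f_5=0.1, w_5=0.2)
        with pytest.raises(ValueError):
            PeakDescriptor(t0=1.0, tR=2.0, w_half=0.0, f_5=0.1, w_5=0.2)
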