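"""Calibration, peak integration, LOD/LOQ, content, recovery, RSD."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from pmqc.quant import (
    CalibrationCurve,
    Chromatogram,
    SRMTransition,
    dilution_series,
    estimate_lod_loq,
    fit_calibration,
    integrate_srm_peak,
    quantify,
    recovery,
    rsd,
)
from pmqc.simulate import SimConfig, simulate_calibration_points, simulate_chromatogram


def normal_equations_fit(points):
    """Independent oracle: closed-form normal equations."""
    x = np.array([p[0] for p in points])
    y = np.array([p[1] for p in points])
    n = len(x)
    sxx = (x * x).sum() - x.sum() ** 2 / n
    sxy = (x * y).sum() - x.sum() * y.sum() / n
    slope = sxy / sxx
    intercept = y.mean() - slope * x.mean()
    return slope, intercept


def reference_curve(quant_config, analyte):
    ref = quant_config.calibration_reference[analyte]
    return CalibrationCurve(
        analyte, ref["slope"], ref["intercept"], ref["r2"], *ref["range"]
    )


class TestFitCalibration:
    def test_exact_line(self):
        points = [(x, 2.0 * x + 1.0) for x in range(1, 6)]
        curve = fit_calibration(points)
        assert curve.slope == pytest.approx(2.0)
        assert curve.intercept == pytest.approx(1.0)
        assert curve.r2 == pytest.approx(1.0)
        assert (curve.range_low, curve.range_high) == (1.0, 5.0)

    @pytest.mark.parametrize("analyte", ["GA", "EM", "THSG", "EMG"])
    def test_published_lines_recovered_from_noiseless_series(
        self, quant_config, analyte
    ):
        curve = reference_curve(quant_config, analyte)
        levels = quant_config.levels(analyte)
        assert len(levels) == 7
        points = simulate_calibration_points(curve, levels, SimConfig(seed=0))
        fitted = fit_calibration(points, analyte)
        assert fitted.slope == pytest.approx(curve.slope, rel=1e-12)
        assert fitted.intercept == pytest.approx(curve.intercept, rel=1e-9, abs=1e-9)
        assert fitted.r2 == pytest.approx(1.0, abs=1e-12)

    def test_noisy_series_slope_near_generator(self, quant_config):
        curve = reference_curve(quant_config, "GA")
        errors = []
        for seed in range(100):
            points = simulate_calibration_points(
                curve, quant_config.levels("GA"), SimConfig(seed=seed),
                noise_fraction=0.01,
            )
            fitted = fit_calibration(points, "GA")
            assert fitted.r2 >= 0.99
            errors.append(abs(fitted.slope - curve.slope) / curve.slope)
        assert np.mean(errors) <= 0.02

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            x = rng.uniform(0.1, 100.0, size=rng.integers(4, 9))
            y = rng.uniform(10.0, 1e5, size=x.size)
            points = list(zip(x, y))
            curve = fit_calibration(points)
            slope, intercept = normal_equations_fit(points)
            assert curve.slope == pytest.approx(slope, rel=1e-10)
            assert curve.intercept == pytest.approx(intercept, rel=1e-10)

    def test_too_few_levels_rejected(self):
        with pytest.raises(ValueError):
            fit_calibration([(1.0, 2.0), (2.0, 4.0)])
        with pytest.raises(ValueError):
            fit_calibration([(1.0, 2.0), (1.0, 2.1), (1.0, 1.9)])


class TestIntegrateSrmPeak:
    def test_zero_signal(self):
        chrom = Chromatogram(np.linspace(0, 10, 101), np.zeros(101))
        result = integrate_srm_peak(chrom, (4.0, 6.0))
        assert result.area == 0.0 and result.height == 0.0
        assert math.isinf(result.snr) and result.zero_noise

    def test_pure_gaussian_matches_closed_form(self):
        h, sigma = 10.0, 0.05
        chrom = simulate_chromatogram(h, 5.0, sigma, 0.0, SimConfig(seed=0))
        result = integrate_srm_peak(chrom, (4.6, 5.4))
        assert result.area == pytest.approx(h * sigma * math.sqrt(2 * math.pi), rel=0.01)
        assert result.height == pytest.approx(h, rel=0.01)

    def test_snr_tracks_height_over_noise(self):
        snrs = [
            integrate_srm_peak(
                simulate_chromatogram(10.0, 5.0, 0.05, 1.0,
                                      SimConfig(seed=seed)),
                (4.6, 5.4),
            ).snr
            for seed in range(30)
        ]
        assert np.mean(snrs) == pytest.approx(10.0, rel=0.15)

    def test_window_validation(self):
        chrom = Chromatogram(np.linspace(0, 10, 101), np.zeros(101))
        with pytest.raises(ValueError):
            integrate_srm_peak(chrom, (6.0, 4.0))
        with pytest.raises(ValueError):
            integrate_srm_peak(chrom, (-1.0, 5.0))


class TestLodLoq:
    def test_definitional_levels(self):
        result = estimate_lod_loq([(1.0, 1.0), (2.0, 3.0), (5.0, 10.0)])
        assert result.lod == 2.0 and result.loq == 5.0
        assert not result.lod_open_ended

    def test_linear_response_interpolates_exactly(self):
        # snr = conc with unit noise
        levels = [(c, float(c)) for c in (0.5, 1, 2, 4, 8, 16)]
        result = estimate_lod_loq(levels)
        assert result.lod == pytest.approx(3.0)
        assert result.loq == pytest.approx(10.0)

    def test_open_ended_when_threshold_unreached(self):
        result = estimate_lod_loq([(1.0, 0.5), (2.0, 1.0), (4.0, 2.0)])
        assert result.lod_open_ended and result.loq_open_ended
        assert math.isnan(result.lod)

    def test_nonmonotone_series_rejected(self):
        with pytest.raises(ValueError):
            estimate_lod_loq([(1.0, 5.0), (2.0, 3.0), (4.0, 10.0)])

    def test_lod_below_loq_and_noise_monotonicity(self):
        """LOD <= LOQ always; both shrink as noise shrinks."""
        prev_lod, prev_loq = math.inf, math.inf
        for noise in (4.0, 2.0, 1.0, 0.5):
            levels = [(c, c / noise) for c in (0.5, 1, 2, 4, 8, 16, 32, 64)]
            result = estimate_lod_loq(levels)
            assert result.lod <= result.loq
            assert result.lod <= prev_lod and result.loq <= prev_loq
            prev_lod, prev_loq = result.lod, result.loq

    def test_simulated_dilution_series_lod_within_one_step(self, quant_config):
        """Seeded noisy S/N series stays within one two-fold dilution of the
        noiseless answer."""
        rng = np.random.default_rng(11)
        concs = np.array(sorted(dilution_series(64.0)))  # 0.5 .. 32
        ideal = concs / 1.0  # snr = conc / unit noise
        noiseless = estimate_lod_loq(list(zip(concs, ideal)))
        noisy_snr = np.sort(ideal * rng.normal(1.0, 0.05, size=ideal.size))
        noisy = estimate_lod_loq(list(zip(concs, noisy_snr)))
        assert noisy.lod == pytest.approx(noiseless.lod, rel=1.0)
        assert noisy.loq == pytest.approx(noiseless.loq, rel=1.0)


class TestQuantify:
    def test_content_arithmetic(self):
        curve = CalibrationCurve("THSG", 652.2, -5013.2, 0.9997, 1.15, 105.0)
        # extract at 275.44 ug/mL injected after 4x dilution
        area = curve.predict_area(275.44 / 4.0)
        result = quantify(area, curve, dilution_factor=4.0, sample_id="A1")
        assert result.solution_conc == pytest.approx(275.44)
        assert result.content == pytest.approx(34.43)
        assert not result.above_range

    def test_roundtrip_through_fitted_line(self, quant_config):
        curve = reference_curve(quant_config, "EMG")
        for conc in quant_config.levels("EMG"):
            result = quantify(curve.predict_area(conc), curve)
            assert result.solution_conc == pytest.approx(conc, rel=1e-12)

    def test_area_at_intercept_is_zero_content(self):
        curve = CalibrationCurve("GA", 3598.5, 205.82, 0.9997, 0.03, 4.0)
        result = quantify(205.82, curve)
        assert result.content == 0.0

    def test_above_range_flagged(self):
        curve = CalibrationCurve("GA", 3598.5, 205.82, 0.9997, 0.03, 4.0)
        result = quantify(curve.predict_area(8.0), curve)
        assert result.above_range

    def test_negative_backcalculation_clipped(self):
        curve = CalibrationCurve("GA", 3598.5, 205.82, 0.9997, 0.03, 4.0)
        result = quantify(0.0, curve)
        assert result.content == 0.0 and result.clipped

    def test_below_loq_censored(self):
        curve = CalibrationCurve("GA", 3598.5, 205.82, 0.9997, 0.03, 4.0)
        result = quantify(curve.predict_area(0.05), curve, loq=0.10)
        assert result.below_loq


class TestRecoveryRsdDilution:
    def test_recovery_formula_reproduces_validation_table(self):
        """Recomputing recovery from the shipped spike table's printed inputs
        reproduces every printed percentage within the precision lost by
        rounding found and spiked amounts to two decimals: to first order a
        half-ULP (0.005) on each input moves the percentage by
        (100 + recovery) * 0.005 / spiked."""
        from pmqc.quant import load_recovery_table

        table = load_recovery_table()
        assert len(table) == 12
        for _, row in table.iterrows():
            computed = recovery(0.0, row["found_ug_ml"], row["spiked_ug_ml"])
            printed = row["recovery_printed_pct"]
            rounding_bound = (100.0 + printed) * 0.005 / row["spiked_ug_ml"] + 0.005
            assert computed == pytest.approx(printed, abs=rounding_bound), (
                row["analyte"], row["level"]
            )

    def test_recovery_printed_rows(self):
        # spike/recovery arithmetic on printed low-spike inputs
        assert recovery(0.0, 7.17, 7.35) == pytest.approx(97.55, abs=0.005)
        assert recovery(0.0, 22.83, 23.46) == pytest.approx(97.31, abs=0.005)
        assert recovery(1.0, 1.0 + 7.35, 7.35) == pytest.approx(100.0)

    def test_recovery_rejects_nonpositive_spike(self):
        with pytest.raises(ValueError):
            recovery(0.0, 1.0, 0.0)

    def test_rsd(self):
        assert rsd([5.0, 5.0, 5.0]) == 0.0
        assert rsd([9.0, 11.0]) == pytest.approx(14.142135, abs=1e-5)
        values = np.array([0.62, 0.63, 0.64])
        assert rsd(values) == pytest.approx(100 * values.std(ddof=1) / 0.63, rel=1e-9)

    def test_rsd_rejects_degenerate(self):
        with pytest.raises(ValueError):
            rsd([5.0])
        with pytest.raises(ValueError):
            rsd([-1.0, 1.0])

    def test_dilution_series_defaults(self):
        series = dilution_series(228.0)
        assert series[0] == pytest.approx(114.0)
        assert series[-1] == pytest.approx(228.0 / 128.0)
        assert series == sorted(series, reverse=True)
        assert dilution_series(210.0)[0] == pytest.approx(105.0)
        assert dilution_series(50.0, [1.0]) == [50.0]

    def test_dilution_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            dilution_series(0.0)
        with pytest.raises(ValueError):
            dilution_series(10.0, [0.5, -0.25])


class TestTransitions:
    def test_config_ships_four_srm_transitions(self, quant_config):
        pairs = {
            name: (t.precursor_mz, t.product_mz)
            for name, t in quant_config.transitions.items()
        }
        assert pairs == {
            "GA": (169.0, 125.0),
            "EM": (269.0, 225.0),
            "THSG": (405.0, 243.0),
            "EMG": (431.0, 269.0),
        }
        assert all(t.collision_energy == 35.0 for t in quant_config.transitions.values())

    def test_product_below_precursor_enforced(self):
        with pytest.raises(ValueError):
            SRMTransition("bad", 100.0, 200.0)


@settings(derandomize=True, max_examples=40)
@given(
    scale=st.floats(0.01, 1000.0),
    values=st.lists(st.floats(1.0, 100.0), min_size=2, max_size=8),
)
def test_rsd_and_recovery_scale_invariant(scale, values):
    base = rsd(values)
    scaled = rsd([v * scale for v in values])
    assert scaled == pytest.approx(base, rel=1e-6, abs=1e-9)
    assert recovery(0.0, 5.0 * scale, 7.0 * scale) == pytest.approx(
        recovery(0.0, 5.0, 7.0), rel=1e-9
    )
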