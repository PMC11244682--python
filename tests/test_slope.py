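"""Slope statistic, exponential calibrations, and tolerance conversion."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from eslope import (
    CalibrationModel,
    InvalidInputError,
    SlopePoints,
    SlopeReading,
    energy_change_from_slope,
    fit_exponential,
    i50_shift,
    predict,
    ratio_method,
    relative_change,
    slope,
    slope_from_prediction,
    slope_tolerance_for_shift,
    tolerance_entry,
)


class TestSlope:
    def test_flat_secant_is_zero(self):
        assert slope(40.0, 40.0, 1.6, 2.4) == 0.0

    def test_hand_arithmetic(self):
        assert slope(70.0, 30.0, 1.6, 2.4) == pytest.approx(-50.0)

    def test_coincident_depths_rejected(self):
        with pytest.raises(InvalidInputError):
            slope(70.0, 30.0, 2.0, 2.0)

    def test_antisymmetric_under_point_swap(self):
        assert slope(30.0, 70.0, 2.4, 1.6) == slope(70.0, 30.0, 1.6, 2.4)

    def test_baseline_slope_implied_by_energy_calibration(self, energy_model):
        """Inverting E = 32.311*exp(0.0247*M) at 6 MeV gives about -68.2."""
        m6 = slope_from_prediction(energy_model, 6.0)
        assert m6 == pytest.approx(math.log(6.0 / 32.311) / 0.0247, abs=1e-12)
        assert m6 == pytest.approx(-68.2, abs=0.1)

    def test_from_raw_readings_normalizes_to_reference(self):
        points = SlopePoints(d70=1.6, d30=2.4, d_ref=1.0)
        sr = SlopeReading.from_readings(200.0, 140.0, 60.0, points)
        assert sr.ion70 == pytest.approx(70.0)
        assert sr.ion30 == pytest.approx(30.0)
        assert sr.slope_m == pytest.approx(-50.0)


class TestRelativeChange:
    def test_identity_is_zero(self):
        assert relative_change(-50.0, -50.0) == 0.0

    def test_steeper_slope_is_negative(self):
        # same magnitude class as a reported clinical drift
        assert relative_change(-36.06, -34.74) == pytest.approx(-3.80, abs=0.005)

    def test_shallower_slope_is_positive(self):
        m_ref = -50.0
        assert relative_change(0.96 * m_ref, m_ref) == pytest.approx(4.0)

    def test_zero_reference_rejected(self):
        with pytest.raises(InvalidInputError):
            relative_change(-50.0, 0.0)


class TestFitExponential:
    @pytest.mark.parametrize("n", [2, 3, 4, 8])
    @pytest.mark.parametrize("a, b", [(13.714, 0.0246), (32.311, 0.0247)])
    def test_noiseless_recovery_to_six_significant_digits(self, n, a, b):
        slopes = np.linspace(-68.0, -31.0, n)
        targets = a * np.exp(b * slopes)
        model = fit_exponential(slopes, targets)
        assert model.amplitude_a == pytest.approx(a, rel=1e-7)
        assert model.rate_b == pytest.approx(b, rel=1e-7)
        assert model.r_squared == pytest.approx(1.0, abs=1e-12)

    def test_two_points_interpolate_exactly(self):
        model = fit_exponential([-60.0, -30.0], [3.0, 6.0])
        assert predict(model, -60.0) == pytest.approx(3.0, rel=1e-12)
        assert predict(model, -30.0) == pytest.approx(6.0, rel=1e-12)

    def test_multiplicative_noise_recovery(self):
        rng = np.random.default_rng(42)
        a, b = 32.311, 0.0247
        slopes = np.array([-68.0, -52.0, -40.0, -31.0])
        targets = a * np.exp(b * slopes) * (1.0 + 0.005 * rng.standard_normal(4))
        model = fit_exponential(slopes, targets, kind="energy")
        assert model.amplitude_a == pytest.approx(a, rel=0.05)
        assert model.rate_b == pytest.approx(b, rel=0.10)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(InvalidInputError):
            fit_exponential([-50.0], [5.0])
        with pytest.raises(InvalidInputError):
            fit_exponential([-50.0, -40.0], [5.0, -1.0])
        with pytest.raises(InvalidInputError):
            fit_exponential([-50.0, -50.0], [5.0, 6.0])


class TestPredictAndInverse:
    def test_slope_zero_returns_amplitude(self, i50_model):
        assert predict(i50_model, 0.0) == i50_model.amplitude_a

    def test_energy_calibration_closes_round_trip_at_6mev(self, energy_model):
        m = slope_from_prediction(energy_model, 6.0)
        assert predict(energy_model, m) == pytest.approx(6.0, rel=1e-12)

    def test_i50_calibration_hand_evaluation(self, i50_model):
        # 13.714 * exp(0.0246 * -31.06) = 13.714 * exp(-0.764076)
        assert predict(i50_model, -31.06) == pytest.approx(
            13.714 * math.exp(0.0246 * -31.06), rel=1e-12
        )
        assert predict(i50_model, -31.06) == pytest.approx(6.387, abs=2e-3)

    def test_prediction_increases_with_slope(self, i50_model):
        grid = np.linspace(-80.0, -20.0, 50)
        preds = [predict(i50_model, m) for m in grid]
        assert np.all(np.diff(preds) > 0)

    def test_nonpositive_target_rejected(self, i50_model):
        with pytest.raises(InvalidInputError):
            slope_from_prediction(i50_model, 0.0)

    def test_rate_must_be_positive(self):
        with pytest.raises(InvalidInputError):
            CalibrationModel(amplitude_a=10.0, rate_b=-0.02, kind="i50")


class TestI50Shift:
    def test_no_change_no_shift(self, i50_model):
        assert i50_shift(i50_model, -31.0, -31.0) == 0.0

    def test_one_millimetre_round_trip(self, i50_model, energy_model):
        """The slope whose predicted I50 sits 1 mm deeper than baseline must
        convert back to a +1.0 mm shift exactly."""
        m_ref = slope_from_prediction(energy_model, 15.0)
        i50_ref = predict(i50_model, m_ref)
        m = slope_from_prediction(i50_model, i50_ref + 0.1)
        assert i50_shift(i50_model, m_ref, m) == pytest.approx(1.0, rel=1e-9)

    def test_locally_linear_in_slope_change(self, i50_model):
        m_ref = -31.0
        small = i50_shift(i50_model, m_ref, m_ref + 0.05)
        double = i50_shift(i50_model, m_ref, m_ref + 0.10)
        assert double == pytest.approx(2.0 * small, rel=2e-3)


class TestToleranceConversion:
    def test_15mev_levels_round_to_2_and_4_percent(self, i50_model, energy_model):
        m_ref = slope_from_prediction(energy_model, 15.0)
        assert round(slope_tolerance_for_shift(i50_model, m_ref, 1.0)) == 2
        assert round(slope_tolerance_for_shift(i50_model, m_ref, 2.0)) == 4

    def test_12mev_levels_round_to_2_and_4_percent(self, i50_model, energy_model):
        m_ref = slope_from_prediction(energy_model, 12.0)
        assert round(slope_tolerance_for_shift(i50_model, m_ref, 1.0)) == 2
        assert round(slope_tolerance_for_shift(i50_model, m_ref, 2.0)) == 4

    def test_vanishing_shift_gives_vanishing_tolerance(self, i50_model):
        tol = slope_tolerance_for_shift(i50_model, -31.0, 1e-6)
        assert tol == pytest.approx(0.0, abs=1e-5)

    def test_sign_asymmetry_is_small(self, i50_model, energy_model):
        """Deeper and shallower shifts of equal size give tolerances that
        differ only by the local exponential curvature (< 15% relative)."""
        for nominal in (6.0, 9.0, 12.0, 15.0):
            m_ref = slope_from_prediction(energy_model, nominal)
            up = slope_tolerance_for_shift(i50_model, m_ref, 1.0)
            down = slope_tolerance_for_shift(i50_model, m_ref, -1.0)
            assert abs(up - down) / up < 0.15

    def test_shift_below_zero_i50_rejected(self, i50_model):
        with pytest.raises(InvalidInputError):
            slope_tolerance_for_shift(i50_model, -31.0, -70.0)

    def test_entry_rounding_one_decimal(self, i50_model, energy_model):
        m_ref = slope_from_prediction(energy_model, 15.0)
        entry = tolerance_entry(15.0, i50_model, m_ref)
        assert entry.pct_per_1mm == 2.0
        assert entry.pct_per_2mm == 4.0


class TestRatioMethod:
    def test_ratio_at_baseline_is_zero(self):
        assert ratio_method(100.0, 50.0, 2.0) == 0.0

    def test_hand_arithmetic(self):
        assert ratio_method(100.0, 50.0, 2.2) == pytest.approx(-9.0909, abs=1e-3)

    def test_deep_reading_drop_raises_ratio(self):
        base = ratio_method(100.0, 50.0, 2.0)
        lowered = ratio_method(100.0, 45.0, 2.0)
        assert lowered - base == pytest.approx(100.0 * (1 / 0.9 - 1.0), abs=1e-6)

    def test_nonpositive_reading_rejected(self):
        with pytest.raises(InvalidInputError):
            ratio_method(0.0, 50.0, 2.0)


class TestEnergyChangeFromSlope:
    def test_zero_change(self, energy_model):
        assert energy_change_from_slope(energy_model, -31.0, -31.0) == 0.0

    def test_hand_exponential(self, energy_model):
        got = energy_change_from_slope(energy_model, -30.0, -31.32)
        assert got == pytest.approx(100.0 * (math.exp(0.0247 * -1.32) - 1.0), rel=1e-12)
        assert got == pytest.approx(-3.2, abs=0.05)

    def test_first_order_limit(self, energy_model):
        dm = 1e-4
        got = energy_change_from_slope(energy_model, -31.0, -31.0 + dm)
        assert got == pytest.approx(100.0 * energy_model.rate_b * dm, rel=1e-3)


@settings(deadline=None, derandomize=True)
@given(
    m_ref=st.floats(-80.0, -20.0),
    dm=st.floats(-2.0, 2.0).filter(lambda x: abs(x) > 1e-6),
)
def test_relative_change_sign_tracks_energy_direction(m_ref, dm):
    """Steeper slope (more negative) means lower energy and a negative
    relative change; shallower means positive."""
    change = relative_change(m_ref + dm, m_ref)
    assert (change > 0) == (dm > 0)
    assert change == pytest.approx(100.0 * dm / abs(m_ref), rel=1e-9)
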