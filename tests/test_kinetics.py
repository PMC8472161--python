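import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pepfinger import kinetics
from pepfinger.kinetics import (
    KineticsError,
    estimate_bleach_rate,
    estimate_catalytic_efficiency,
    fit_progress_curve,
    fit_vmax_four_point,
    subtract_background,
)

from conftest import TIME_GRID, make_well


def brute_force_vmax(series, t, width=4):
    """Independent oracle: max OLS slope over all 4-point windows, via the
    closed-form covariance/variance ratio."""
    best, best_i = -np.inf, 0
    for i in range(len(series) - width + 1):
        tw, yw = t[i : i + width], series[i : i + width]
        slope = np.sum((tw - tw.mean()) * (yw - yw.mean())) / np.sum(
            (tw - tw.mean()) ** 2
        )
        if slope > best:
            best, best_i = slope, i
    return max(best, 0.0), best_i


class TestSubtractBackground:
    def test_identity_and_zero_control(self):
        w = make_well(np.linspace(0, 120, 13))
        z = make_well(np.zeros(13), well_id="NEG", sample_type="neg_control")
        assert np.allclose(subtract_background(w, w), 0.0)
        assert np.array_equal(subtract_background(w, z), w.fluorescence_au)

    def test_constant_offset_shifts_elementwise(self):
        w = make_well(np.linspace(0, 120, 13))
        neg = make_well(np.full(13, 50.0), well_id="NEG", sample_type="neg_control")
        np.testing.assert_allclose(
            subtract_background(w, neg), w.fluorescence_au - 50.0
        )

    def test_grid_and_substrate_mismatch(self):
        w = make_well(np.zeros(13))
        other = make_well(np.zeros(13), well_id="N", substrate="PepB")
        with pytest.raises(KineticsError, match="substrate"):
            subtract_background(w, other)
        shifted = make_well(np.zeros(13), well_id="N", time_min=TIME_GRID + 1)
        with pytest.raises(KineticsError, match="grid"):
            subtract_background(w, shifted)


class TestVmaxFourPoint:
    def test_exact_linear_series(self):
        fit = fit_vmax_four_point(10.0 * TIME_GRID, TIME_GRID)
        assert fit.vmax_au_per_min == pytest.approx(10.0)
        assert fit.window_start_index == 0  # tie broken to earliest window
        assert fit.r2_window == pytest.approx(1.0)

    def test_constant_series_clamps_to_zero(self):
        fit = fit_vmax_four_point(np.full(13, 42.0), TIME_GRID)
        assert fit.vmax_au_per_min == 0.0
        assert "below_noise" in fit.qc_flags

    def test_saturating_curve_matches_window_oracle(self):
        k = 3.2e-4 * 60.0  # per minute
        series = 200.0 * (1.0 - np.exp(-k * TIME_GRID))
        fit = fit_vmax_four_point(series, TIME_GRID)
        vmax, idx = brute_force_vmax(series, TIME_GRID)
        assert fit.vmax_au_per_min == pytest.approx(vmax, rel=1e-12)
        assert fit.window_start_index == idx == 0  # steepest at the start

    def test_saturated_depletion_flag(self):
        series = 500.0 * (1.0 - np.exp(-0.2 * TIME_GRID))  # flat tail
        fit = fit_vmax_four_point(series, TIME_GRID)
        assert "saturated" in fit.qc_flags

    def test_too_few_points_rejected(self):
        with pytest.raises(KineticsError):
            fit_vmax_four_point(np.zeros(3), TIME_GRID[:3])

    @settings(deadline=None, max_examples=60, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_random_series_agree_with_oracle(self, seed):
        """Vmax always equals the brute-force max over all window slopes and
        is invariant to constant shifts; scaling scales it exactly."""
        r = np.random.default_rng(seed)
        y = r.normal(0, 50, 13).cumsum()
        fit = fit_vmax_four_point(y, TIME_GRID)
        vmax, _ = brute_force_vmax(y, TIME_GRID)
        assert fit.vmax_au_per_min == pytest.approx(vmax, abs=1e-9)
        shifted = fit_vmax_four_point(y + 123.4, TIME_GRID)
        assert shifted.vmax_au_per_min == pytest.approx(fit.vmax_au_per_min, abs=1e-9)
        if vmax > 0:
            c = 3.7
            scaled = fit_vmax_four_point(c * y, TIME_GRID)
            assert scaled.vmax_au_per_min == pytest.approx(c * vmax, rel=1e-12)


class TestBleachRate:
    def test_flat_series_is_zero(self):
        assert estimate_bleach_rate(np.full(13, 80.0), TIME_GRID) == 0.0

    def test_closed_form_decay(self):
        series = 100.0 * np.exp(-0.01 * TIME_GRID)
        assert estimate_bleach_rate(series, TIME_GRID) == pytest.approx(
            0.01, abs=1e-6
        )

    def test_increasing_series_clamped(self):
        assert estimate_bleach_rate(np.linspace(10, 100, 13), TIME_GRID) == 0.0

    def test_nonpositive_values_rejected(self):
        with pytest.raises(KineticsError):
            estimate_bleach_rate(np.linspace(-1, 10, 13), TIME_GRID)


class TestProgressCurve:
    def test_noise_free_recovery(self):
        kobs = 8.5e-4  # s^-1
        series = 200.0 * (1.0 - np.exp(-kobs * 60.0 * TIME_GRID))
        fit = fit_progress_curve(series, TIME_GRID)
        assert fit.kobs_per_s == pytest.approx(kobs, rel=1e-3)
        assert fit.amplitude_au == pytest.approx(200.0, rel=1e-3)

    def test_recovery_with_bleaching(self):
        lam, kobs = 0.004, 3.2e-4
        series = (
            150.0
            * (1.0 - np.exp(-kobs * 60.0 * TIME_GRID))
            * np.exp(-lam * TIME_GRID)
        )
        fit = fit_progress_curve(series, TIME_GRID, bleach_rate_per_min=lam)
        assert fit.kobs_per_s == pytest.approx(kobs, rel=1e-3)

    def test_all_zero_series_flagged(self):
        fit = fit_progress_curve(np.zeros(13), TIME_GRID)
        assert "below_noise" in fit.qc_flags
        assert fit.kobs_per_s == 0.0

    def test_small_rate_limit_matches_four_point_vmax(self):
        """For k_obs * t_max << 1 the initial turnover A*k equals the linear
        four-point Vmax within 5%."""
        kobs = 1e-5  # s^-1 -> k*t_max = 0.036
        series = 5000.0 * (1.0 - np.exp(-kobs * 60.0 * TIME_GRID))
        fit = fit_progress_curve(series, TIME_GRID)
        four_point = fit_vmax_four_point(series, TIME_GRID).vmax_au_per_min
        assert fit.turnover_rate_au_per_min == pytest.approx(four_point, rel=0.05)


class TestCatalyticEfficiency:
    @pytest.mark.parametrize(
        "kobs,conc,expected",
        [
            (3.2e-4, 1e-9, 3.2e5),  # published MMP-2 rate against PepA
            (4.8e-6, 1e-9, 4.8e3),  # published MMP-8 rate against PepE
            (0.0, 1e-9, 0.0),
        ],
    )
    def test_division_is_exact(self, kobs, conc, expected):
        assert estimate_catalytic_efficiency(kobs, conc) == pytest.approx(expected)

    def test_nonpositive_concentration_rejected(self):
        with pytest.raises(KineticsError):
            estimate_catalytic_efficiency(1e-4, 0.0)


def test_fit_well_pipeline_with_background_and_bleach():
    """End-to-end per-well fit: background-subtract, estimate bleach from the
    negative control, recover the generative rate."""
    lam, kobs, baseline = 0.002, 2e-4, 400.0
    signal = (
        baseline * np.exp(-lam * TIME_GRID)
        + 200.0 * (1.0 - np.exp(-kobs * 60 * TIME_GRID)) * np.exp(-lam * TIME_GRID)
    )
    well = make_well(signal)
    neg = make_well(
        baseline * np.exp(-lam * TIME_GRID),
        well_id="NEG",
        sample_type="neg_control",
    )
    fit = kinetics.fit_well(well, neg)
    assert fit.bleach_rate_per_min == pytest.approx(lam, abs=1e-6)
    assert fit.kobs_per_s == pytest.approx(kobs, rel=0.01)
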