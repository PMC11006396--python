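"""Respirometry trace processing: window filter, local slope, conversion."""

import numpy as np
import pytest

from spermscaling import (
    OxygenTrace,
    SlopeEstimate,
    best_local_slope,
    control_corrected_slope,
    saturation_filter,
    slope_to_vo2,
)
from spermscaling.respirometry import process_trace
from spermscaling.synthetic import generate_oxygen_trace

from conftest import naive_best_window


def linear_trace(slope_per_h, start=100.0, duration=40, interval=1.0, **kw):
    t = np.arange(0.0, duration + 1e-9, interval)
    return OxygenTrace(times=t, saturation=start + slope_per_h * t / 60.0, **kw)


class TestSaturationFilter:
    def test_declining_trace_truncated_at_lower_bound(self):
        trace = linear_trace(-60.0, start=100.0, duration=40)  # reaches 60% at t=40
        out = saturation_filter(trace, 100.0, 75.0)
        assert out.saturation[0] == pytest.approx(100.0)
        assert out.saturation[-1] >= 75.0
        assert np.all(out.saturation >= 75.0)
        # next point after the window would be below 75
        assert trace.saturation[len(out)] < 75.0

    def test_trace_within_bounds_unchanged(self):
        trace = linear_trace(-10.0, start=95.0, duration=30)
        out = saturation_filter(trace, 100.0, 75.0)
        assert len(out) == len(trace)
        np.testing.assert_array_equal(out.saturation, trace.saturation)

    def test_depleted_chamber_yields_empty_trace(self):
        """A chamber that began measurement around 60% AS never enters the
        100-75% window and must be excluded."""
        trace = linear_trace(-30.0, start=60.0)
        out = saturation_filter(trace, 100.0, 75.0)
        assert len(out) == 0

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            saturation_filter(linear_trace(-10.0), 75.0, 100.0)


class TestBestLocalSlope:
    def test_noise_free_linear_trace_full_window(self):
        trace = linear_trace(-5.0, start=95.0, duration=40)
        est = best_local_slope(trace)
        assert est.slope == pytest.approx(-5.0, abs=1e-10)
        assert est.window == (0, len(trace))
        assert est.standard_error == pytest.approx(0.0, abs=1e-10)

    def test_piecewise_trace_selects_steep_segment(self):
        """Steep decline then plateau: the selected window must sit in the
        steep part (checked against the exhaustive oracle)."""
        t = np.arange(0.0, 60.0, 1.0)
        sat = np.where(t < 30, 100.0 - 0.5 * t, 85.0)
        rng = np.random.default_rng(42)
        sat = sat + rng.normal(0, 0.05, t.size)
        trace = OxygenTrace(times=t, saturation=sat)
        est = best_local_slope(trace, min_window_fraction=1 / 3)
        assert est.window[1] <= 32  # inside the declining segment
        oracle = naive_best_window(t, sat, max(5, int(np.ceil(t.size / 3))))
        assert est.slope == pytest.approx(oracle[0], rel=1e-9)
        assert est.window == oracle[2]

    def test_pure_noise_flags_instability(self):
        rng = np.random.default_rng(7)
        t = np.arange(0.0, 30.0, 1.0)
        trace = OxygenTrace(times=t, saturation=90.0 + rng.normal(0, 0.5, t.size))
        est = best_local_slope(trace)
        assert est.standard_error / abs(est.slope) > 0.05

    def test_too_few_points_error_names_chamber(self):
        trace = OxygenTrace(times=[0, 1, 2], saturation=[90, 89, 88], chamber_id="A3")
        with pytest.raises(ValueError, match="A3"):
            best_local_slope(trace)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_search(self, seed):
        """The implementation equals a brute-force window search on random
        traces up to 100 points."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(15, 101))
        t = np.cumsum(rng.uniform(0.5, 1.5, n))
        sat = 100.0 - 0.3 * t + rng.normal(0, 0.2, n)
        trace = OxygenTrace(times=t, saturation=sat)
        est = best_local_slope(trace)
        oracle = naive_best_window(t, sat, max(5, int(np.ceil(n / 3))))
        assert est.slope == pytest.approx(oracle[0], rel=1e-9)
        assert est.standard_error == pytest.approx(oracle[1], rel=1e-9, abs=1e-12)
        assert est.window == oracle[2]


class TestControlCorrection:
    def test_zero_controls(self):
        s = SlopeEstimate(-10.0, 0.1, (0, 30), 30)
        ctrl = [SlopeEstimate(0.0, 0.1, (0, 30), 30)] * 2
        assert control_corrected_slope(s, ctrl) == pytest.approx(-10.0)

    def test_drifting_control_subtracted(self):
        s = SlopeEstimate(-10.0, 0.1, (0, 30), 30)
        assert control_corrected_slope(s, [SlopeEstimate(-2.0, 0.1, (0, 30), 30)]) == pytest.approx(-8.0)

    def test_sample_equal_to_control_mean_is_zero(self):
        s = SlopeEstimate(-3.0, 0.1, (0, 30), 30)
        ctrl = [SlopeEstimate(-2.0, 0.1, (0, 30), 30), SlopeEstimate(-4.0, 0.1, (0, 30), 30)]
        assert control_corrected_slope(s, ctrl) == pytest.approx(0.0)

    def test_no_controls_is_an_error(self):
        with pytest.raises(ValueError):
            control_corrected_slope(SlopeEstimate(-1.0, 0.1, (0, 30), 30), [])


class TestSlopeToVo2:
    def test_seawater_unit_conversion(self):
        """10% AS/h in a 750 µl chamber of 21°C seawater is 0.38325 µl O2/h."""
        assert slope_to_vo2(-10.0, 5.11, 750.0) == pytest.approx(0.38325, rel=1e-12)

    def test_zero_slope_zero_rate(self):
        assert slope_to_vo2(0.0, 5.11, 750.0) == 0.0

    def test_linearity_in_volume_and_slope(self):
        base = slope_to_vo2(-10.0, 5.11, 750.0)
        assert slope_to_vo2(-10.0, 5.11, 1500.0) == pytest.approx(2 * base)
        assert slope_to_vo2(-20.0, 5.11, 750.0) == pytest.approx(2 * base)
        assert slope_to_vo2(-10.0, 10.22, 750.0) == pytest.approx(2 * base)

    def test_positive_net_slope_clamps_with_warning(self):
        with pytest.warns(UserWarning):
            assert slope_to_vo2(3.0, 5.11, 750.0) == 0.0

    @pytest.mark.parametrize("cap,vol", [(0, 750), (5.11, -1)])
    def test_domain_errors(self, cap, vol):
        with pytest.raises(ValueError):
            slope_to_vo2(-10.0, cap, vol)


class TestPipelineIdentity:
    @pytest.mark.parametrize("vo2", [0.1, 0.38325, 0.9])
    def test_noise_free_round_trip_recovers_vo2(self, vo2):
        """Simulate → filter → slope → control-correct → convert recovers
        the generating oxygen consumption."""
        sample = generate_oxygen_trace(vo2, volume=750, capacitance=5.11, duration=30)
        controls = [generate_oxygen_trace(0.0, volume=750, capacitance=5.11, duration=30,
                                          is_control=True)]
        _, est_vo2 = process_trace(sample, controls, capacitance=5.11, volume=750)
        assert est_vo2 == pytest.approx(vo2, rel=1e-9)

    def test_drifting_control_is_removed(self):
        vo2, drift = 0.3, -1.5
        sample = generate_oxygen_trace(vo2, control_drift=drift, duration=30)
        controls = [generate_oxygen_trace(0.0, control_drift=drift, duration=30,
                                          is_control=True)]
        _, est_vo2 = process_trace(sample, controls)
        assert est_vo2 == pytest.approx(vo2, rel=1e-9)

    def test_depleted_chamber_is_rejected_downstream(self):
        """A high-concentration chamber whose usable record starts near 60%
        AS is excluded by the saturation window."""
        trace = generate_oxygen_trace(0.5, start_saturation=60.0, duration=30,
                                      chamber_id="hot")
        controls = [generate_oxygen_trace(0.0, duration=30, is_control=True)]
        with pytest.raises(ValueError, match="hot"):
            process_trace(trace, controls)
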