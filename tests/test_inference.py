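"""Signal estimation, corrections, rate inference and error propagation."""

import numpy as np
import pandas as pd
import pytest

from porinflux.calibration import HillFit, SaturationError
from porinflux.inference import (
    SignalEstimate,
    check_sensitivity,
    correct_signal,
    estimate_initial_signal,
    infer_transport_rate,
    propagate_ratio_error,
    relative_transport,
    subtract_control,
)
from porinflux.simulate import simulate_vesicle_trace
from tests.test_simulate import make_system


class TestEstimateInitialSignal:
    def test_slope_on_exact_line(self):
        t = np.arange(0.0, 100.0, 2.0)
        est = estimate_initial_signal(100 + 3 * t, times=t, mode="slope")
        assert est.value == pytest.approx(3.0, rel=1e-12)
        assert est.mode == "slope"

    def test_plateau_on_flat_trace(self):
        t = np.arange(2.0, 300.0, 2.0)
        est = estimate_initial_signal(np.full_like(t, 512.0), times=t, mode="plateau")
        assert est.value == 512.0
        assert est.se == 0.0

    def test_plateau_matches_simulator_steady_state(self):
        """Quasi-steady-state level of a p_inact = 0 glow trace."""
        sys = make_system(p_inact=0.0)
        trace = simulate_vesicle_trace(sys)
        est = estimate_initial_signal(trace.intensities, times=trace.times)
        trimers_in_well = sys.trimers_per_vesicle * sys.vesicles_in_well
        expected = sys.kinetics.baseline + (
            sys.kinetics.eps * sys.k_transport * trimers_in_well)
        assert est.value == pytest.approx(expected, rel=5e-3)

    def test_replicates_give_se(self):
        t = np.arange(2.0, 200.0, 2.0)
        y = np.vstack([np.full_like(t, 100.0), np.full_like(t, 110.0),
                       np.full_like(t, 120.0)])
        est = estimate_initial_signal(y, times=t)
        assert est.value == pytest.approx(110.0)
        assert est.se == pytest.approx(10.0 / np.sqrt(3))
        assert est.replicates_used == 3

    def test_long_format_dataframe(self):
        t = np.arange(2.0, 200.0, 2.0)
        rows = [(rep, ti, 100.0 * rep) for rep in (1, 2) for ti in t]
        df = pd.DataFrame(rows, columns=["replicate", "time_s", "intensity_au"])
        est = estimate_initial_signal(df)
        assert est.value == pytest.approx(150.0)

    def test_nonmonotone_times_rejected(self):
        with pytest.raises(ValueError):
            estimate_initial_signal([1.0, 2.0, 3.0], times=[2.0, 2.0, 4.0])


class TestSubtractControl:
    def s(self, value, se=0.0, mode="plateau"):
        return SignalEstimate(value=value, se=se, mode=mode, window=(2.0, 62.0))

    def test_equal_signals_floored_and_flagged(self):
        out = subtract_control(self.s(100.0), self.s(100.0))
        assert out.value == 0.0
        assert out.floored

    def test_quadrature(self):
        out = subtract_control(self.s(500.0, 10.0), self.s(100.0, 5.0))
        assert out.value == pytest.approx(400.0)
        assert out.se == pytest.approx(np.sqrt(125.0))
        assert out.se == pytest.approx(11.2, rel=1e-2)

    def test_zero_control_is_identity(self):
        out = subtract_control(self.s(500.0, 10.0), self.s(0.0, 0.0))
        assert out.value == 500.0
        assert not out.floored

    def test_negative_floored(self):
        out = subtract_control(self.s(50.0), self.s(100.0))
        assert out.value == 0.0
        assert out.floored

    def test_control_scaling(self):
        out = subtract_control(self.s(500.0, 0.0), self.s(100.0, 4.0), control_scale=2.0)
        assert out.value == pytest.approx(300.0)
        assert out.se == pytest.approx(8.0)

    def test_mode_mismatch_rejected(self):
        with pytest.raises(ValueError):
            subtract_control(self.s(1.0), self.s(1.0, mode="slope"))


class TestCorrectSignal:
    def test_identity(self):
        assert correct_signal(123.0, 1.0, 1.0) == 123.0

    def test_quantum_yield_factor_consistency(self):
        """The CLZ-n factor is the reciprocal of its 7.2% relative yield."""
        assert round(1.0 / 0.072, 1) == 13.9
        assert correct_signal(1.0, 1.0, 13.9) == pytest.approx(1 / 0.072, rel=1e-2)

    def test_linear(self):
        assert correct_signal(2.0, 4.52, 13.9) == pytest.approx(2 * 4.52 * 13.9)

    def test_nonpositive_factors_rejected(self):
        with pytest.raises(ValueError):
            correct_signal(1.0, 0.0, 1.0)


class TestInferTransportRate:
    def test_worked_example(self, reference_hill):
        """c_S = 1.21 uM, N = 2.7 enzymes, 0.20 trimers -> 10.8 s^-1."""
        from porinflux.calibration import hill_rate
        corrected = hill_rate(1.21, reference_hill)
        res = infer_transport_rate(corrected, reference_hill, 2.7, 0.20, porin="OmpF")
        assert res.k_transport == pytest.approx(10.8, rel=0.01)
        assert res.internal_concentration == pytest.approx(1.21, rel=1e-6)
        assert res.within_sensitivity  # 10.8 < 2.7 * 17 = 45.9

    def test_zero_signal_flagged(self, reference_hill):
        res = infer_transport_rate(0.0, reference_hill, 2.7, 0.20)
        assert res.k_transport == 0.0
        assert res.flagged

    def test_saturation_rejected(self, reference_hill):
        with pytest.raises(SaturationError):
            infer_transport_rate(reference_hill.v_max * 1.01, reference_hill, 2.7, 0.2)

    def test_zero_trimers_rejected(self, reference_hill):
        with pytest.raises(ValueError):
            infer_transport_rate(1e6, reference_hill, 2.7, 0.0)

    def test_gauge_invariance(self, reference_hill):
        """Rescaling intensities and v_max jointly leaves k_transport fixed."""
        corrected = 5e6
        base = infer_transport_rate(corrected, reference_hill, 2.7, 0.20)
        for s in (0.1, 3.7, 42.0):
            scaled_fit = HillFit(v_max=reference_hill.v_max * s,
                                 k_half=reference_hill.k_half, h=reference_hill.h)
            res = infer_transport_rate(corrected * s, scaled_fit, 2.7, 0.20)
            assert res.k_transport == pytest.approx(base.k_transport, rel=1e-12)
            assert res.internal_concentration == pytest.approx(
                base.internal_concentration, rel=1e-12)

    def test_monotone_in_signal(self, reference_hill):
        rates = [infer_transport_rate(v, reference_hill, 2.7, 0.2).k_transport
                 for v in (1e5, 1e6, 1e7, 5e7)]
        assert np.all(np.diff(rates) > 0)

    def test_sem_quadrature(self, reference_hill):
        res = infer_transport_rate(5e6, reference_hill, 2.7, 0.2,
                                   rel_errors=(0.3, 0.4))
        assert res.sem == pytest.approx(res.k_transport * 0.5)


class TestRatiosAndSensitivity:
    @pytest.mark.parametrize(
        "x, sx, y, sy, ratio, sem",
        [
            (1.9, 1.1, 2.8, 0.91, 0.68, 0.45),
            (3.3, 1.9, 10.8, 2.9, 0.31, 0.19),
        ],
    )
    def test_ratio_reproduces_published_sems(self, x, sx, y, sy, ratio, sem):
        res = propagate_ratio_error(x, sx, y, sy)
        assert round(res.ratio, 2) == ratio
        assert round(res.sem, 2) == sem

    def test_zero_sems(self):
        assert propagate_ratio_error(2.0, 0.0, 4.0, 0.0).sem == 0.0

    def test_zero_denominator_rejected(self):
        with pytest.raises(ZeroDivisionError):
            propagate_ratio_error(1.0, 0.1, 0.0, 0.1)

    def test_relative_transport(self):
        assert relative_transport(78.0, 10.8) == pytest.approx(7.22, rel=1e-2)
        assert relative_transport(78.0, 10.8) > 7.0
        assert relative_transport(5.0, 5.0) == 1.0
        assert relative_transport(2.2, 2.8) == pytest.approx(0.79, rel=1e-2)
        with pytest.raises(ZeroDivisionError):
            relative_transport(1.0, 0.0)

    def test_sensitivity_strict(self):
        assert check_sensitivity(78.0, 94.0)
        assert check_sensitivity(10.8, 49.0)
        assert not check_sensitivity(68.0, 68.0)
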