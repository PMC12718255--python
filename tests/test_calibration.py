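"""Flash-decay extrapolation and Hill calibration fits."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from sklearn.base import clone

from porinflux.calibration import (
    FlashDecayModel,
    HillCalibrator,
    HillFit,
    SaturationError,
    extrapolate_peak,
    fit_flash_decay,
    fit_hill,
    hill_rate,
    invert_hill,
)
from porinflux.constants import CALIBRATION_CONCENTRATIONS_UM

TRUTH = (1.14e8, 9.8, 1.44)


def hill_points(v_max=TRUTH[0], k_half=TRUTH[1], h=TRUTH[2],
                concs=CALIBRATION_CONCENTRATIONS_UM):
    c = np.asarray(concs, dtype=float)
    return c, v_max * c**h / (k_half**h + c**h)


class TestFlashDecay:
    def test_noiseless_recovery(self, flash_truth):
        t, y, (a, k1, b) = flash_truth
        fit = fit_flash_decay(t, y)
        assert fit.amplitude == pytest.approx(a, rel=1e-6)
        assert fit.decay_rate == pytest.approx(k1, rel=1e-6)
        assert fit.baseline == pytest.approx(b, rel=1e-6)
        assert not fit.unidentifiable

    def test_constant_trace_flagged(self):
        t = np.array([2.0, 4.0, 6.0, 8.0, 10.0])
        fit = fit_flash_decay(t, np.full(5, 114.0))
        assert fit.unidentifiable
        assert fit.amplitude == 0.0
        assert fit.decay_rate == 0.0
        assert fit.baseline == pytest.approx(114.0)

    def test_asymptote_is_baseline(self, flash_truth):
        t, y, (_, _, b) = flash_truth
        fit = fit_flash_decay(t, y)
        assert fit(1e9) == pytest.approx(b, rel=1e-6)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            fit_flash_decay([2.0, 4.0], [10.0, 5.0])

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            fit_flash_decay([2.0, 4.0, 6.0], [10.0, np.nan, 2.0])

    def test_nonmonotone_times_rejected(self):
        with pytest.raises(ValueError):
            fit_flash_decay([2.0, 2.0, 6.0], [10.0, 5.0, 2.0])

    @pytest.mark.parametrize(
        "t_eval, expected",
        [(1.0, 5e5 * np.exp(-0.2) + 114), (0.0, 5e5 + 114)],
    )
    def test_extrapolation(self, flash_truth, t_eval, expected):
        t, y, _ = flash_truth
        fit = fit_flash_decay(t, y)
        assert extrapolate_peak(fit, t_eval) == pytest.approx(expected, rel=1e-6)

    def test_extrapolation_of_flat_fit_returns_baseline(self):
        t = np.array([2.0, 4.0, 6.0, 8.0])
        fit = fit_flash_decay(t, np.full(4, 114.0))
        assert extrapolate_peak(fit) == pytest.approx(114.0)

    def test_anti_drift_property(self):
        """Sampling from t >= 2 s reproduces the true 1 s peak exactly."""
        rng = np.random.default_rng(7)
        for _ in range(5):
            a = rng.uniform(1e4, 1e8)
            k1 = rng.uniform(0.05, 0.5)
            b = rng.uniform(0.0, 200.0)
            t = np.arange(2.0, 11.0, 2.0)
            fit = fit_flash_decay(t, a * np.exp(-k1 * t) + b)
            assert extrapolate_peak(fit, 1.0) == pytest.approx(
                a * np.exp(-k1) + b, rel=1e-6)

    def test_sklearn_api(self, flash_truth):
        t, y, _ = flash_truth
        est = FlashDecayModel(fit_window=(2.0, 10.0))
        assert clone(est).get_params() == est.get_params()
        est.fit(t, y)
        assert np.allclose(est.predict(t), y, rtol=1e-6)


class TestHillFit:
    def test_noiseless_exact_recovery(self):
        c, v = hill_points()
        fit = fit_hill(c, v, n_bootstrap=0)
        assert fit.v_max == pytest.approx(TRUTH[0], rel=1e-6)
        assert fit.k_half == pytest.approx(TRUTH[1], rel=1e-6)
        assert fit.h == pytest.approx(TRUTH[2], rel=1e-6)
        assert fit.r2 == pytest.approx(1.0, abs=1e-9)

    def test_hyperbolic_limit(self):
        """h = 1 truth is recovered: plain saturation kinetics."""
        c, v = hill_points(h=1.0)
        fit = fit_hill(c, v, n_bootstrap=0)
        assert fit.h == pytest.approx(1.0, rel=1e-6)

    @given(h=st.floats(0.5, 4.0), k=st.floats(2.0, 20.0))
    @settings(max_examples=20, deadline=None)
    def test_recovery_across_cooperativity(self, h, k):
        c, v = hill_points(k_half=k, h=h)
        fit = fit_hill(c, v, n_bootstrap=0)
        assert fit.v_max == pytest.approx(TRUTH[0], rel=1e-6)
        assert fit.k_half == pytest.approx(k, rel=1e-6)
        assert fit.h == pytest.approx(h, rel=1e-6)

    def test_bootstrap_ci_contains_estimate_and_covers_truth(self):
        """Each CI brackets its point estimate; across seeds the 95% CIs
        cover the truth most of the time (replicate bootstrap at n = 3
        undercovers somewhat, so majority coverage is the honest bar)."""
        coverage = {name: 0 for name in ("v_max", "k_half", "h")}
        n_seeds = 8
        for seed in range(n_seeds):
            rng = np.random.default_rng(100 + seed)
            c = np.repeat(CALIBRATION_CONCENTRATIONS_UM, 3)
            _, v_true = hill_points(concs=c)
            v = v_true * rng.lognormal(-0.5 * 0.05**2, 0.05, size=c.size)
            fit = fit_hill(c, v, n_bootstrap=150, random_state=seed)
            for name, truth in zip(("v_max", "k_half", "h"), TRUTH):
                lo, hi = fit.ci95[name]
                assert lo <= getattr(fit, name) <= hi
                coverage[name] += lo <= truth <= hi
        for name, hits in coverage.items():
            assert hits >= n_seeds // 2, f"{name} covered only {hits}/{n_seeds}"

    def test_ci_widens_with_noise(self):
        """Bootstrap CI width grows monotonically with the injected CV."""
        widths = []
        c = np.repeat(CALIBRATION_CONCENTRATIONS_UM, 3)
        _, v_true = hill_points(concs=c)
        for cv in (0.02, 0.05, 0.10):
            rng = np.random.default_rng(23)
            v = v_true * rng.lognormal(-0.5 * cv**2, cv, size=c.size)
            fit = fit_hill(c, v, n_bootstrap=200, random_state=5)
            lo, hi = fit.ci95["k_half"]
            widths.append(hi - lo)
        assert widths[0] < widths[1] < widths[2]

    def test_all_zero_intensities_rejected(self):
        with pytest.raises(ValueError):
            fit_hill([1.0, 2.0, 5.0, 10.0], [0.0, 0.0, 0.0, 0.0], n_bootstrap=0)

    def test_too_few_concentrations_rejected(self):
        with pytest.raises(ValueError):
            fit_hill([1.0, 2.0, 5.0], [1.0, 2.0, 3.0], n_bootstrap=0)

    def test_sklearn_api(self):
        c, v = hill_points()
        est = HillCalibrator(n_bootstrap=0)
        est2 = clone(est).set_params(n_bootstrap=10)
        assert est2.get_params()["n_bootstrap"] == 10
        est.fit(c, v)
        assert np.allclose(est.predict(c), v, rtol=1e-6)
        assert est.inverse(est.predict(3.0)) == pytest.approx(3.0, rel=1e-6)


class TestHillRateAndInverse:
    def test_half_saturation_identity(self, reference_hill):
        assert hill_rate(9.8, reference_hill) == pytest.approx(5.7e7, rel=1e-9)
        assert invert_hill(reference_hill.v_max / 2, reference_hill) == pytest.approx(9.8)

    def test_zero(self, reference_hill):
        assert hill_rate(0.0, reference_hill) == 0.0
        assert invert_hill(0.0, reference_hill) == 0.0

    def test_closed_form_value(self, reference_hill):
        assert hill_rate(15.0, reference_hill) == pytest.approx(7.40e7, rel=1e-3)

    def test_monotone_and_bounded(self, reference_hill):
        c = np.linspace(0.01, 200, 500)
        v = hill_rate(c, reference_hill)
        assert np.all(np.diff(v) > 0)
        assert np.all(v < reference_hill.v_max)

    @given(c=st.floats(1e-3, 1e3))
    @settings(max_examples=50, deadline=None)
    def test_roundtrip_identity(self, c):
        fit = HillFit(v_max=1.14e8, k_half=9.8, h=1.44)
        assert invert_hill(hill_rate(c, fit), fit) == pytest.approx(c, rel=1e-9)

    def test_saturation_errors(self, reference_hill):
        with pytest.raises(SaturationError):
            invert_hill(reference_hill.v_max, reference_hill)
        with pytest.raises(ValueError):
            invert_hill(-1.0, reference_hill)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            HillFit(v_max=-1.0, k_half=9.8, h=1.44)
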