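"""Free-enzyme luminescence calibration: flash-decay extrapolation and Hill fit.

The free luciferase shows flash kinetics: a sharp emission peak ~1 s
after substrate injection followed by exponential decay driven by
turnover-coupled inactivation. The plate reader only samples from 2 s,
so each trace is fitted to ``y = a * exp(-k1 * t) + b`` and evaluated at
t = 1 s to recover the true peak. The peak-vs-concentration series is
then fitted to a Hill model

    v(c) = v_max * c^h / (K_0.5^h + c^h)

whose inversion maps a corrected assay intensity back to the substrate
concentration seen by the enzyme.

Both fits are scikit-learn style estimators (``FlashDecayModel``,
``HillCalibrator``); the module-level functions are thin wrappers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit, least_squares
from sklearn.base import BaseEstimator, RegressorMixin

from .constants import PEAK_TIME_S

__all__ = [
    "SaturationError",
    "FlashDecayFit",
    "CalibrationPoint",
    "HillFit",
    "FlashDecayModel",
    "HillCalibrator",
    "fit_flash_decay",
    "extrapolate_peak",
    "fit_hill",
    "hill_rate",
    "invert_hill",
]


class SaturationError(ValueError):
    """Signal at or above the calibration v_max: outside the invertible range."""


@dataclass
class FlashDecayFit:
    """Exponential flash-decay parameters ``a * exp(-k1 t) + b``."""

    amplitude: float
    decay_rate: float
    baseline: float
    fit_window: tuple[float, float]
    rss: float
    unidentifiable: bool = False

    def __call__(self, t):
        return self.amplitude * np.exp(-self.decay_rate * np.asarray(t, float)) + self.baseline


@dataclass
class CalibrationPoint:
    """One calibration concentration with its extrapolated peak intensity."""

    substrate_concentration: float  # uM
    peak_intensity: float  # a.u., extrapolated to t = 1 s
    sd: float = 0.0
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if self.substrate_concentration < 0:
            raise ValueError("concentration must be >= 0")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


@dataclass
class HillFit:
    """Fitted Hill calibration with optional bootstrap 95% CIs."""

    v_max: float
    k_half: float
    h: float
    r2: float = float("nan")
    ci95: dict[str, tuple[float, float]] | None = None
    fit_method: str = "unweighted-nls"
    n_points: int = 0
    residual_sd: float = float("nan")
    extra: dict = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if self.v_max <= 0 or self.k_half <= 0 or self.h <= 0:
            raise ValueError("v_max, k_half and h must all be > 0")

    def to_dict(self) -> dict:
        d = {
            "v_max": float(self.v_max),
            "k_half": float(self.k_half),
            "h": float(self.h),
            "r2": float(self.r2),
            "fit_method": self.fit_method,
            "n_points": int(self.n_points),
        }
        if self.ci95 is not None:
            d["ci95"] = {k: [float(lo), float(hi)] for k, (lo, hi) in self.ci95.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "HillFit":
        ci = d.get("ci95")
        return cls(
            v_max=d["v_max"], k_half=d["k_half"], h=d["h"], r2=d.get("r2", float("nan")),
            ci95={k: (v[0], v[1]) for k, v in ci.items()} if ci else None,
            fit_method=d.get("fit_method", "unweighted-nls"), n_points=d.get("n_points", 0),
        )


def _hill(c, v_max, k_half, h):
    c = np.asarray(c, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        num = np.power(c, h)
        out = v_max * num / (np.power(k_half, h) + num)
    return np.where(c == 0, 0.0, out)


class FlashDecayModel(BaseEstimator, RegressorMixin):
    """Least-squares fit of ``y = a * exp(-k1 t) + b`` to one flash trace.

    Parameters
    ----------
    fit_window : tuple of float, optional
        Time window (s) whose points enter the fit; default is the whole
        trace (the calibration protocol records only the first 10 s).

    Attributes
    ----------
    amplitude_, decay_rate_, baseline_ : float
        Fitted a, k1 (s^-1) and b (a.u.).
    rss_ : float
        Residual sum of squares, a.u.^2.
    unidentifiable_ : bool
        True when the trace is constant (a = 0, k1 = 0, b = mean).
    """

    def __init__(self, fit_window: tuple[float, float] | None = None):
        self.fit_window = fit_window

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).ravel()
        y = np.asarray(y, dtype=float).ravel()
        if t.shape != y.shape:
            raise ValueError("times and intensities must have equal length")
        if not np.all(np.isfinite(y)):
            raise ValueError("non-finite intensities")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.fit_window is not None:
            lo, hi = self.fit_window
            mask = (t >= lo) & (t <= hi)
            t, y = t[mask], y[mask]
        if t.size < 3:
            raise ValueError("need at least 3 points in the fit window")
        window = (float(t[0]), float(t[-1]))

        if np.allclose(y, y[0], rtol=1e-12, atol=1e-9):
            self.amplitude_, self.decay_rate_ = 0.0, 0.0
            self.baseline_ = float(np.mean(y))
            self.rss_ = float(np.sum((y - self.baseline_) ** 2))
            self.unidentifiable_ = True
            self.fit_window_ = window
            return self

        # log-linear initial guess with a provisional baseline below the data
        b0 = max(float(y.min()) - 0.05 * float(np.ptp(y)), 0.0)
        resid = np.clip(y - b0, 1e-12, None)
        slope, intercept = np.polyfit(t, np.log(resid), 1)
        k0 = max(-slope, 1e-6)
        a0 = float(np.exp(intercept))
        res = least_squares(
            lambda p: p[0] * np.exp(-p[1] * t) + p[2] - y,
            x0=(a0, k0, b0), bounds=([0.0, 0.0, 0.0], [np.inf, np.inf, np.inf]),
            x_scale="jac", xtol=1e-13, ftol=1e-10, gtol=None, max_nfev=200,
        )
        self.amplitude_, self.decay_rate_, self.baseline_ = map(float, res.x)
        self.rss_ = float(np.sum((self.predict(t) - y) ** 2))
        self.unidentifiable_ = False
        self.fit_window_ = window
        return self

    def predict(self, X):
        t = np.asarray(X, dtype=float)
        return self.amplitude_ * np.exp(-self.decay_rate_ * t) + self.baseline_

    def peak(self, t_eval: float = PEAK_TIME_S) -> float:
        """Extrapolated intensity at ``t_eval`` (default the 1 s peak), a.u."""
        return float(self.amplitude_ * np.exp(-self.decay_rate_ * t_eval) + self.baseline_)

    def result(self) -> FlashDecayFit:
        return FlashDecayFit(
            amplitude=self.amplitude_, decay_rate=self.decay_rate_,
            baseline=self.baseline_, fit_window=self.fit_window_,
            rss=self.rss_, unidentifiable=self.unidentifiable_,
        )


class HillCalibrator(BaseEstimator, RegressorMixin):
    """Hill calibration ``v = v_max c^h / (K^h + c^h)`` by unweighted NLS.

    Replicate observations at the same concentration are averaged before
    fitting (the model is fitted to the mean response); 95% confidence
    intervals come from a nonparametric bootstrap that resamples
    replicates within each concentration.

    Parameters
    ----------
    n_bootstrap : int
        Bootstrap resamples for the CIs; 0 skips CI computation.
    random_state : int or None
        Seed for the bootstrap.
    h_bounds : tuple
        Box bounds on the Hill coefficient.

    Attributes
    ----------
    v_max_, k_half_, h_ : float
        Point estimates (a.u., uM, dimensionless).
    r2_ : float
        Coefficient of determination against the mean response.
    ci95_ : dict or None
        Percentile bootstrap CIs per parameter.
    """

    _PARAM_NAMES = ("v_max", "k_half", "h")

    def __init__(self, n_bootstrap: int = 1000, random_state: int | None = None,
                 h_bounds: tuple[float, float] = (0.1, 10.0)):
        self.n_bootstrap = n_bootstrap
        self.random_state = random_state
        self.h_bounds = h_bounds

    def fit(self, X, y):
        c = np.asarray(X, dtype=float).ravel()
        v = np.asarray(y, dtype=float).ravel()
        if c.shape != v.shape:
            raise ValueError("concentrations and intensities must have equal length")
        if np.any(c < 0):
            raise ValueError("concentrations must be >= 0")
        if not np.all(np.isfinite(v)):
            raise ValueError("non-finite intensities")
        if np.all(v == 0):
            raise ValueError("all-zero intensities cannot be calibrated")
        uniq = np.unique(c)
        if uniq.size < 4:
            raise ValueError("need >= 4 distinct concentrations")

        means = np.array([v[c == u].mean() for u in uniq])
        self.v_max_, self.k_half_, self.h_ = self._fit_once(uniq, means)
        pred = _hill(uniq, self.v_max_, self.k_half_, self.h_)
        rss = float(np.sum((means - pred) ** 2))
        tss = float(np.sum((means - means.mean()) ** 2))
        self.r2_ = 1.0 - rss / tss if tss > 0 else float("nan")
        self.residual_sd_ = float(np.sqrt(rss / max(uniq.size - 3, 1)))
        self.n_points_ = int(uniq.size)

        self.ci95_ = None
        if self.n_bootstrap and self.n_bootstrap > 0:
            self.ci95_ = self._bootstrap_ci(c, v, uniq)
        return self

    def _fit_once(self, c, v):
        p0 = (1.2 * float(np.max(v)), float(np.median(c[c > 0])), 1.0)
        lo = (1e-12, 1e-12, self.h_bounds[0])
        hi = (np.inf, np.inf, self.h_bounds[1])
        try:
            popt, _ = curve_fit(_hill, c, v, p0=p0, bounds=(lo, hi),
                                maxfev=20000, xtol=1e-14, ftol=1e-14)
        except RuntimeError as err:  # pragma: no cover - diagnostics path
            raise RuntimeError(
                f"Hill fit did not converge (n={c.size}, "
                f"range {c.min()}-{c.max()} uM, max v {v.max():.3g} a.u.): {err}"
            ) from err
        return tuple(map(float, popt))

    def _bootstrap_ci(self, c, v, uniq):
        rng = np.random.default_rng(self.random_state)
        groups = [v[c == u] for u in uniq]
        draws = []
        for _ in range(self.n_bootstrap):
            means = np.array([g[rng.integers(0, g.size, g.size)].mean() for g in groups])
            try:
                draws.append(self._fit_once(uniq, means))
            except RuntimeError:
                continue
        draws = np.asarray(draws)
        lo, hi = np.percentile(draws, [2.5, 97.5], axis=0)
        return {name: (float(lo[i]), float(hi[i])) for i, name in enumerate(self._PARAM_NAMES)}

    def predict(self, X):
        return _hill(np.asarray(X, dtype=float), self.v_max_, self.k_half_, self.h_)

    def inverse(self, v):
        """Substrate concentration (uM) producing calibrated intensity ``v``."""
        return invert_hill(v, self.result())

    def result(self) -> HillFit:
        return HillFit(
            v_max=self.v_max_, k_half=self.k_half_, h=self.h_, r2=self.r2_,
            ci95=self.ci95_, n_points=self.n_points_, residual_sd=self.residual_sd_,
        )


def fit_flash_decay(times, intensities, fit_window=None) -> FlashDecayFit:
    """Fit one flash trace to ``a * exp(-k1 t) + b``; see :class:`FlashDecayModel`."""
    return FlashDecayModel(fit_window=fit_window).fit(times, intensities).result()


def extrapolate_peak(fit: FlashDecayFit, t_eval: float = PEAK_TIME_S) -> float:
    """Evaluate a flash fit at ``t_eval`` (default 1 s, the true peak time)."""
    return float(fit.amplitude * np.exp(-fit.decay_rate * t_eval) + fit.baseline)


def fit_hill(concentrations, intensities, n_bootstrap: int = 1000,
             random_state: int | None = None) -> HillFit:
    """Fit the Hill calibration; see :class:`HillCalibrator`."""
    est = HillCalibrator(n_bootstrap=n_bootstrap, random_state=random_state)
    return est.fit(concentrations, intensities).result()


def hill_rate(c_s, fit: HillFit):
    """Forward Hill evaluation v(c_s); bounded by v_max, zero at zero."""
    c = np.asarray(c_s, dtype=float)
    if np.any(c < 0):
        raise ValueError("concentration must be >= 0")
    out = _hill(c, fit.v_max, fit.k_half, fit.h)
    return float(out) if np.isscalar(c_s) else out


def invert_hill(v, fit: HillFit) -> float:
    """Exact inverse of :func:`hill_rate`: c = K * (v / (v_max - v))^(1/h).

    Raises :class:`SaturationError` for v >= v_max (the signal exceeds
    the calibration range) and ``ValueError`` for negative v.
    """
    v = float(v)
    if v < 0:
        raise ValueError("intensity must be >= 0")
    if v >= fit.v_max:
        raise SaturationError(
            f"intensity {v:.4g} a.u. at or above calibration v_max {fit.v_max:.4g} a.u."
        )
    if v == 0:
        return 0.0
    return float(fit.k_half * (v / (fit.v_max - v)) ** (1.0 / fit.h))
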