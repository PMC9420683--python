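"""Fitting sampled time-enhancement curves.

Two routes from a noisy sampled curve to a maximum slope:

* nonlinear least-squares fit of the Madsen gamma variate (gives the curve
  parameters the two-phase method needs: y_max, t_max, and for the aorta
  the bolus shape alpha);
* a cubic smoothing spline whose first derivative is maximised over the
  upslope (the classical full-curve estimate; smoothing removes ROI noise).

Time zero is the first acquired frame; fits are covariant under a time
shift through t_max, so the injection-to-scan delay needs no modelling here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from numpy.typing import ArrayLike, NDArray
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import curve_fit

from .gamma_model import CLINICAL_ALPHA_RANGE, GammaVariateParams, evaluate_curve

__all__ = [
    "TimeEnhancementCurve",
    "AorticInput",
    "FitResult",
    "estimate_baseline",
    "fit_gamma_variate",
    "fit_spline_max_slope",
    "fit_aortic_input",
    "ALPHA_BOUNDS",
]

#: Search bounds for the bolus-shape parameter during fitting; brackets the
#: clinical range 3-15 with margin on both sides.
ALPHA_BOUNDS: tuple[float, float] = (1.5, 30.0)

MIN_FRAMES_FOR_FIT = 4


@dataclass(frozen=True)
class TimeEnhancementCurve:
    """A sampled ROI time-enhancement curve.

    ``times`` are sample times in seconds (strictly increasing), ``values``
    the ROI median HU per frame. ``baseline_hu`` is the pre-contrast HU
    level; it may be left unset until estimated.
    """

    times: NDArray[np.float64]
    values: NDArray[np.float64]
    baseline_hu: float | None = None

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or v.ndim != 1 or t.size != v.size:
            raise ValueError("times and values must be 1-D arrays of equal length")
        if t.size < 2:
            raise ValueError("a curve needs at least 2 frames")
        if not (np.all(np.isfinite(t)) and np.all(np.isfinite(v))):
            raise ValueError("times and values must be finite")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return int(self.times.size)

    def enhancement(self, baseline_hu: float | None = None) -> NDArray[np.float64]:
        """Baseline-subtracted values (delta-HU)."""
        b = self.baseline_hu if baseline_hu is None else baseline_hu
        if b is None:
            raise ValueError("baseline_hu is not set; estimate or supply it")
        return self.values - b

    def with_baseline(self, baseline_hu: float) -> "TimeEnhancementCurve":
        return TimeEnhancementCurve(self.times, self.values, baseline_hu)


@dataclass(frozen=True)
class FitResult:
    """Outcome of a gamma-variate fit."""

    params: GammaVariateParams
    baseline_hu: float
    rmse: float
    converged: bool


@dataclass(frozen=True)
class AorticInput:
    """Fitted feeding-vessel (aortic) input: peak enhancement and bolus shape."""

    params: GammaVariateParams
    fit: FitResult | None = None

    def __post_init__(self) -> None:
        if self.params.y_max <= 0:
            raise ValueError("aortic peak enhancement must be > 0")

    @property
    def peak_enhancement(self) -> float:
        return self.params.y_max

    @property
    def alpha(self) -> float:
        return self.params.alpha


def estimate_baseline(curve: TimeEnhancementCurve, n_pre: int | str = "auto") -> float:
    """Pre-contrast baseline HU from the initial pre-arrival frames.

    With an integer ``n_pre``, the mean of the first ``n_pre`` frames. In
    ``"auto"`` mode the baseline run is grown from the start while each next
    frame stays within 2 sample standard deviations of the first frame (the
    spread estimated from the run so far); the run always includes at least
    2 frames. Noiseless curves degenerate gracefully: the run extends while
    values equal the first frame exactly.
    """
    v = curve.values
    if n_pre != "auto":
        n = int(n_pre)
        if n < 2 or n > v.size:
            raise ValueError(f"n_pre must be in [2, {v.size}], got {n_pre!r}")
        return float(np.mean(v[:n]))
    if v.size < 2:
        raise ValueError("need at least 2 frames to estimate a baseline")
    end = 2  # minimum run
    while end < v.size:
        run = v[:end]
        sd = float(np.std(run, ddof=1))
        if sd == 0.0:
            ok = v[end] == v[0]
        else:
            ok = abs(v[end] - v[0]) <= 2.0 * sd
        if not ok:
            break
        end += 1
    return float(np.mean(v[:end]))


def _gamma_model(t: NDArray[np.float64], y_max: float, t_max: float, alpha: float):
    tau = t / t_max
    return y_max * tau**alpha * np.exp(alpha * (1.0 - tau))


def fit_gamma_variate(
    curve: TimeEnhancementCurve, baseline: float | None = None
) -> FitResult:
    """Nonlinear least-squares gamma-variate fit of a baseline-subtracted curve.

    Initial values: y_max at the observed maximum enhancement, t_max at the
    earliest maximal frame, alpha = 5; bounds y_max in (0, 3*max],
    t_max in (first time, last time], alpha in [1.5, 30]. A fit whose alpha
    lands on a bound, or that fails to converge, is returned with
    ``converged=False``; an all-baseline (zero-enhancement) curve is rejected.
    """
    if curve.n_frames < MIN_FRAMES_FOR_FIT:
        raise ValueError(f"need at least {MIN_FRAMES_FOR_FIT} frames to fit")
    if baseline is None:
        baseline = (
            curve.baseline_hu
            if curve.baseline_hu is not None
            else estimate_baseline(curve)
        )
    t = curve.times
    enh = curve.values - baseline
    peak = float(np.max(enh))
    if peak <= 0:
        raise ValueError("no enhancement above baseline; nothing to fit")

    i_peak = int(np.argmax(enh))  # earliest maximal frame
    t_peak0 = float(t[i_peak]) if t[i_peak] > 0 else float(t[min(i_peak + 1, t.size - 1)])
    eps = 1e-9
    lo = (eps, max(float(t[0]), eps) + eps, ALPHA_BOUNDS[0])
    hi = (3.0 * peak, float(t[-1]), ALPHA_BOUNDS[1])
    p0 = (
        min(max(peak, lo[0]), hi[0]),
        min(max(t_peak0, lo[1]), hi[1]),
        5.0,
    )
    try:
        popt, _ = curve_fit(
            _gamma_model, t, enh, p0=p0, bounds=(lo, hi), maxfev=20000
        )
        fit_ok = True
    except RuntimeError:
        popt = np.asarray(p0)
        fit_ok = False

    y_max, t_max, alpha = (float(x) for x in popt)
    bound_tol = 1e-6
    alpha_pinned = (
        alpha <= ALPHA_BOUNDS[0] + bound_tol or alpha >= ALPHA_BOUNDS[1] - bound_tol
    )
    params = GammaVariateParams(y_max=y_max, t_max=t_max, alpha=alpha)
    resid = enh - evaluate_curve(params, t)
    rmse = float(np.sqrt(np.mean(resid**2)))
    return FitResult(
        params=params,
        baseline_hu=float(baseline),
        rmse=rmse,
        converged=fit_ok and not alpha_pinned,
    )


def fit_spline_max_slope(
    curve: TimeEnhancementCurve,
    baseline: float,
    smoothing: float | None = None,
) -> tuple[float, float]:
    """Maximum upslope of a smoothing spline through the sampled curve.

    A cubic smoothing spline is fitted to the baseline-subtracted values
    (penalty chosen by generalized cross-validation unless ``smoothing``
    overrides it), its first derivative evaluated on a grid 10x finer than
    the sampling interval and maximised over times up to the observed peak.
    Returns ``(max_slope in HU/s, time of the maximum slope)``. A curve with
    no positive upslope yields 0 with a warning.
    """
    if curve.n_frames < MIN_FRAMES_FOR_FIT:
        raise ValueError(f"need at least {MIN_FRAMES_FOR_FIT} frames to fit")
    t = curve.times
    enh = curve.values - baseline
    spline = make_smoothing_spline(t, enh, lam=smoothing)
    deriv = spline.derivative()

    t_peak = float(t[int(np.argmax(enh))])
    step = float(np.median(np.diff(t))) / 10.0
    if t_peak <= t[0]:
        grid = np.array([float(t[0])])
    else:
        grid = np.arange(float(t[0]), t_peak + 0.5 * step, step)
    slopes = deriv(grid)
    i = int(np.argmax(slopes))
    best = float(slopes[i])
    if best <= 0:
        warnings.warn(
            "curve has no positive upslope; maximum slope reported as 0",
            stacklevel=2,
        )
        return 0.0, float(grid[i])
    return best, float(grid[i])


def fit_aortic_input(curve: TimeEnhancementCurve) -> AorticInput:
    """Fit the aortic ROI curve and expose its peak and bolus shape.

    The fitted y_max is the feeding-vessel peak enhancement and alpha the
    study bolus shape; an alpha below the clinical range (< 3) is flagged
    with a warning as it suggests a tissue-like, not arterial, curve.
    """
    fit = fit_gamma_variate(curve)
    if fit.params.alpha < CLINICAL_ALPHA_RANGE[0]:
        warnings.warn(
            f"fitted aortic alpha {fit.params.alpha:.2f} is below the clinical "
            "range [3, 15]; the ROI may not capture an arterial first pass",
            stacklevel=2,
        )
    return AorticInput(params=fit.params, fit=fit)
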