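"""Closed-form gamma-variate bolus kinetics in the Madsen parameterisation.

Contrast enhancement in a vessel or tissue region after a compact bolus
injection is modelled as

    E(t) = y_max * tau**alpha * exp(alpha * (1 - tau)),   tau = t / t_max

where ``y_max`` is the peak enhancement above baseline (delta-HU), ``t_max``
the time of the peak (s) and ``alpha`` a dimensionless bolus-shape parameter
(steeper bolus for larger alpha; clinical aortic boluses fall in 3-15).
This parameterisation pins the peak at (t_max, y_max) for every alpha, which
is what makes a two-measurement (baseline + peak) perfusion estimate
possible: the maximum upslope is ``y_max * k(alpha) / t_max`` with ``k`` a
pure function of the bolus shape, and maximum-slope perfusion is

    perfusion = maximum tissue upslope / peak feeding-vessel enhancement

in units of (mL/s) per mL of tissue, i.e. 1/s.

Everything in this module is a closed-form, deterministic function of its
arguments; fitting of sampled curves lives in :mod:`ctperf.curve_fitting`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from numpy.typing import ArrayLike, NDArray

__all__ = [
    "GammaVariateParams",
    "InjectionProtocol",
    "PerfusionEstimate",
    "CLINICAL_ALPHA_RANGE",
    "K_LINEAR_INTERCEPT",
    "K_LINEAR_SLOPE",
    "SECONDS_PER_MINUTE",
    "evaluate_curve",
    "curve_slope",
    "inflection_times",
    "k_exact",
    "k_linear",
    "k_factor",
    "max_slope",
    "perfusion_from_curve_params",
    "enhancement_from_perfusion",
    "predict_aortic_peak",
    "perfusion_ratio_from_enhancements",
]

#: Clinical range of the bolus-shape parameter alpha for aortic boluses.
CLINICAL_ALPHA_RANGE: tuple[float, float] = (3.0, 15.0)

#: Coefficients of the linearised maximum-slope factor k(alpha) over the
#: clinical alpha range: k = 1.502 + 0.092016 * alpha.
K_LINEAR_INTERCEPT: float = 1.502
K_LINEAR_SLOPE: float = 0.092016

SECONDS_PER_MINUTE: float = 60.0

#: Default enhancement constant at 120 kVp: HU of blood enhancement per
#: mgI/mL of blood iodine concentration.
HU_PER_MGI_ML_120KVP: float = 26.18


@dataclass(frozen=True)
class GammaVariateParams:
    """Parameters of one Madsen gamma-variate enhancement curve.

    Attributes
    ----------
    y_max :
        Peak enhancement above baseline (delta-HU). Non-negative.
    t_max :
        Time of the peak in seconds. Strictly positive.
    alpha :
        Dimensionless bolus-shape parameter. Must exceed 1 so that the
        curve has an ascending inflection (clinical range 3-15).
    """

    y_max: float
    t_max: float
    alpha: float

    def __post_init__(self) -> None:
        for name in ("y_max", "t_max", "alpha"):
            v = getattr(self, name)
            if not np.isfinite(v):
                raise ValueError(f"{name} must be finite, got {v!r}")
        if self.y_max < 0:
            raise ValueError(f"y_max must be >= 0, got {self.y_max}")
        if self.t_max <= 0:
            raise ValueError(f"t_max must be > 0, got {self.t_max}")
        if self.alpha <= 1:
            raise ValueError(
                f"alpha must be > 1 for a valid bolus shape, got {self.alpha}"
            )


@dataclass(frozen=True)
class InjectionProtocol:
    """Contrast-injection and acquisition parameters for peak prediction.

    The predicted aortic peak assumes the injected contrast is diluted into
    the whole cardiac output before entering the arterial circulation:
    peak delta-HU = flow_rate * iodine_concentration * hu_constant / cardiac_output.

    Attributes
    ----------
    flow_rate :
        Contrast injection rate (mL/s).
    iodine_concentration :
        Iodine concentration of the contrast agent (mgI/mL).
    cardiac_output :
        Cardiac output (mL/s); e.g. 5 L/min is roughly 83 mL/s.
    hu_constant :
        Enhancement per unit blood iodine concentration (HU per mgI/mL);
        defaults to 26.18, valid for 120 kVp acquisitions. Other tube
        voltages need a user-supplied constant.
    """

    flow_rate: float
    iodine_concentration: float
    cardiac_output: float
    hu_constant: float = HU_PER_MGI_ML_120KVP

    def __post_init__(self) -> None:
        for name in ("flow_rate", "iodine_concentration", "cardiac_output", "hu_constant"):
            v = getattr(self, name)
            if not np.isfinite(v) or v < 0:
                raise ValueError(f"{name} must be finite and >= 0, got {v!r}")
        if self.cardiac_output <= 0:
            raise ValueError(f"cardiac_output must be > 0, got {self.cardiac_output}")


@dataclass(frozen=True)
class PerfusionEstimate:
    """A perfusion value together with how it was obtained.

    ``perfusion`` is stored in 1/s, i.e. (mL/s) of blood per mL of tissue;
    :attr:`perfusion_per_min` gives the conventional mL/min/mL presentation.
    ``method`` is ``"spline_full_curve"`` for the classical full-curve
    maximum-slope estimate and ``"gamma_two_phase"`` for the gamma-variate
    two-measurement estimate.
    """

    perfusion: float
    max_slope: float
    aortic_peak: float
    method: str
    extras: dict = field(default_factory=dict, compare=False)

    @property
    def perfusion_per_min(self) -> float:
        """Perfusion in mL/min per mL of tissue."""
        return self.perfusion * SECONDS_PER_MINUTE


def _as_times(times: ArrayLike) -> NDArray[np.float64]:
    t = np.asarray(times, dtype=float)
    if not np.all(np.isfinite(t)):
        raise ValueError("times must be finite")
    if np.any(t < 0):
        raise ValueError("times must be >= 0 (seconds from injection)")
    return t


def evaluate_curve(params: GammaVariateParams, times: ArrayLike) -> NDArray[np.float64]:
    """Evaluate the gamma-variate enhancement curve at times in seconds.

    Returns enhancement above baseline (delta-HU); 0 at t = 0, exactly
    ``y_max`` at ``t_max``, unimodal on [0, inf).
    """
    t = _as_times(times)
    tau = t / params.t_max
    return params.y_max * tau**params.alpha * np.exp(params.alpha * (1.0 - tau))


def curve_slope(params: GammaVariateParams, times: ArrayLike) -> NDArray[np.float64]:
    """First derivative of the enhancement curve in HU/s.

    The Madsen derivative with respect to the dimensionless time tau is
    ``y_max * alpha * (tau**(alpha-1) - tau**alpha) * exp(alpha*(1-tau))``;
    the chain rule contributes 1/t_max to convert to physical HU/s. The
    slope is zero exactly at the peak, positive before, negative after.
    """
    t = _as_times(times)
    tau = t / params.t_max
    a = params.alpha
    dy_dtau = params.y_max * a * (tau ** (a - 1.0) - tau**a) * np.exp(a * (1.0 - tau))
    return dy_dtau / params.t_max


def inflection_times(alpha: float) -> tuple[float, float]:
    """Dimensionless times of the two inflection points, (ascending, descending).

    The second derivative of the gamma variate vanishes at
    tau = (alpha -/+ sqrt(alpha)) / alpha. The ascending root (minus sign)
    lies in (0, 1) and is where the upslope is maximal; the plus root is
    the washout inflection.
    """
    if not np.isfinite(alpha) or alpha <= 1:
        raise ValueError(f"alpha must be > 1, got {alpha!r}")
    s = np.sqrt(alpha) / alpha
    return 1.0 - s, 1.0 + s


def k_exact(alpha: ArrayLike) -> NDArray[np.float64] | float:
    """Exact dimensionless maximum-slope factor k(alpha).

    k is the dimensionless slope of the unit gamma variate at its ascending
    inflection tau = (alpha - sqrt(alpha))/alpha, so that the physical
    maximum upslope is ``y_max * k / t_max``. Monotonically increasing over
    the clinical alpha range.
    """
    a = np.asarray(alpha, dtype=float)
    if not np.all(np.isfinite(a)) or np.any(a <= 1):
        raise ValueError("alpha must be finite and > 1")
    tau = 1.0 - np.sqrt(a) / a
    k = a * (tau ** (a - 1.0) - tau**a) * np.exp(a * (1.0 - tau))
    return float(k) if np.isscalar(alpha) else k


def k_linear(alpha: ArrayLike) -> NDArray[np.float64] | float:
    """Linearised maximum-slope factor k = 1.502 + 0.092016 * alpha.

    A near-perfect linear approximation of :func:`k_exact` over the clinical
    bolus-shape range alpha in [3, 15] (relative error < 2%). Values outside
    that range are computed anyway but trigger a warning, since the linear
    fit is not validated there.
    """
    a = np.asarray(alpha, dtype=float)
    lo, hi = CLINICAL_ALPHA_RANGE
    if np.any(a < lo) or np.any(a > hi):
        warnings.warn(
            f"k_linear is calibrated for alpha in [{lo}, {hi}]; "
            "extrapolating outside that range",
            stacklevel=2,
        )
    k = K_LINEAR_INTERCEPT + K_LINEAR_SLOPE * a
    return float(k) if np.isscalar(alpha) else k


def k_factor(alpha: float, k_mode: str = "linear") -> float:
    """Dispatch on the k evaluation mode: ``"linear"`` or ``"exact"``."""
    if k_mode == "linear":
        return float(k_linear(alpha))
    if k_mode == "exact":
        return float(k_exact(alpha))
    raise ValueError(f"k_mode must be 'linear' or 'exact', got {k_mode!r}")


def max_slope(params: GammaVariateParams, k_mode: str = "linear") -> float:
    """Maximum upslope of the enhancement curve, ``y_max * k(alpha) / t_max`` (HU/s)."""
    return params.y_max * k_factor(params.alpha, k_mode) / params.t_max


def perfusion_from_curve_params(
    params: GammaVariateParams, aortic_peak: float, k_mode: str = "linear"
) -> PerfusionEstimate:
    """Two-phase perfusion from curve parameters and the feeding-vessel peak.

    perfusion = y_max * k(alpha) / t_max / aortic_peak, in 1/s. This is the
    estimate available from just a baseline and a peak-phase measurement
    once the aortic peak and bolus shape are known.
    """
    if not np.isfinite(aortic_peak) or aortic_peak <= 0:
        raise ValueError(f"aortic_peak must be > 0, got {aortic_peak!r}")
    slope = max_slope(params, k_mode)
    return PerfusionEstimate(
        perfusion=slope / aortic_peak,
        max_slope=slope,
        aortic_peak=aortic_peak,
        method="gamma_two_phase",
        extras={"k_mode": k_mode, "alpha": params.alpha, "t_max": params.t_max},
    )


def enhancement_from_perfusion(
    perfusion: float,
    aortic_peak: float,
    t_max: float,
    alpha: float,
    k_mode: str = "linear",
) -> float:
    """Peak tissue enhancement (delta-HU) implied by a perfusion value.

    Inverts the two-phase perfusion equation:
    y_max = perfusion * aortic_peak / (k(alpha) / t_max), with ``perfusion``
    in 1/s. Exact inverse of :func:`perfusion_from_curve_params` for the
    same ``k_mode``.
    """
    if not np.isfinite(aortic_peak) or aortic_peak <= 0:
        raise ValueError(f"aortic_peak must be > 0, got {aortic_peak!r}")
    if not np.isfinite(perfusion) or perfusion < 0:
        raise ValueError(f"perfusion must be >= 0, got {perfusion!r}")
    if t_max <= 0:
        raise ValueError(f"t_max must be > 0, got {t_max!r}")
    return perfusion * aortic_peak * t_max / k_factor(alpha, k_mode)


def predict_aortic_peak(protocol: InjectionProtocol) -> float:
    """Predicted aortic peak enhancement (delta-HU) from the injection protocol.

    Dilution of the injected iodine flux into the cardiac output:
    flow_rate * iodine_concentration * hu_constant / cardiac_output.
    """
    return (
        protocol.flow_rate
        * protocol.iodine_concentration
        * protocol.hu_constant
        / protocol.cardiac_output
    )


def perfusion_ratio_from_enhancements(y_max_1: float, y_max_2: float) -> float:
    """Perfusion ratio of two ROIs sharing a feeding vessel, from peak enhancements.

    With a common aortic input and a common bolus shape the k/t_max factors
    cancel, so the perfusion ratio reduces to the peak-enhancement ratio
    y_max_1 / y_max_2.
    """
    if not np.isfinite(y_max_2) or y_max_2 <= 0:
        raise ValueError(f"y_max_2 must be > 0, got {y_max_2!r}")
    return float(y_max_1) / float(y_max_2)
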