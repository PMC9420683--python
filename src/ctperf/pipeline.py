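"""End-to-end perfusion computation and method-comparison statistics.

Ties the pieces together: the classical full-curve estimate (smoothing
spline maximum slope over the aortic peak), the two-phase estimate (baseline
and peak-phase HU plus the aortic peak and bolus shape), pairwise
perfusion/enhancement ratio tables, linear-regression + Bland-Altman method
comparison, and the SNR/CNR image-quality metrics.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numpy.typing import ArrayLike
from scipy import stats

from .curve_fitting import AorticInput, TimeEnhancementCurve, estimate_baseline, fit_spline_max_slope
from .gamma_model import (
    GammaVariateParams,
    PerfusionEstimate,
    perfusion_from_curve_params,
    perfusion_ratio_from_enhancements,
)

__all__ = [
    "MethodComparison",
    "QualityMetrics",
    "perfusion_full_curve",
    "perfusion_two_phase",
    "compare_methods",
    "quality_metrics",
    "ratio_table",
]

LOA_MULTIPLIER = 1.96  # 95% limits of agreement


@dataclass(frozen=True)
class MethodComparison:
    """Linear regression and Bland-Altman agreement between two estimate vectors.

    The regression is ordinary least squares of method 2 on method 1;
    ``r2`` is the squared Pearson correlation (identical to the OLS R^2
    with intercept). Differences are method2 - method1; the limits of
    agreement are bias -/+ 1.96 times the sample SD of the differences.
    """

    slope: float
    intercept: float
    r2: float
    bias: float
    loa_lower: float
    loa_upper: float
    n: int
    p_value: float
    difference: str = "method2 - method1"


@dataclass(frozen=True)
class QualityMetrics:
    """ROI-based image-quality metrics: signal- and contrast-to-noise ratio."""

    snr: float
    cnr: float


def perfusion_full_curve(
    tissue: TimeEnhancementCurve,
    aorta: AorticInput,
    baseline: float | None = None,
    smoothing: float | None = None,
) -> PerfusionEstimate:
    """Classical maximum-slope perfusion from the full sampled tissue curve.

    The tissue curve is smoothed with a spline, its maximum upslope taken,
    and divided by the fitted aortic peak enhancement.
    """
    if baseline is None:
        baseline = (
            tissue.baseline_hu
            if tissue.baseline_hu is not None
            else estimate_baseline(tissue)
        )
    slope, at_time = fit_spline_max_slope(tissue, baseline, smoothing=smoothing)
    return PerfusionEstimate(
        perfusion=slope / aorta.peak_enhancement,
        max_slope=slope,
        aortic_peak=aorta.peak_enhancement,
        method="spline_full_curve",
        extras={"slope_time_s": at_time, "baseline_hu": float(baseline)},
    )


def perfusion_two_phase(
    baseline_hu: float,
    peak_hu: float,
    t_peak: float,
    aorta: AorticInput,
    k_mode: str = "linear",
) -> PerfusionEstimate:
    """Two-phase perfusion from a baseline scan and a peak-phase scan.

    Only two measurements of the tissue enter: its pre-contrast HU and its
    HU at the enhancement peak (time ``t_peak``). The bolus shape alpha is
    borrowed from the aortic input, whose conservation along the arterial
    tree is the method's central assumption.
    """
    if peak_hu < baseline_hu:
        raise ValueError(
            f"peak_hu ({peak_hu}) must be >= baseline_hu ({baseline_hu})"
        )
    if t_peak <= 0:
        raise ValueError(f"t_peak must be > 0, got {t_peak!r}")
    params = GammaVariateParams(
        y_max=peak_hu - baseline_hu, t_max=t_peak, alpha=aorta.alpha
    )
    return perfusion_from_curve_params(params, aorta.peak_enhancement, k_mode=k_mode)


def compare_methods(x: ArrayLike, y: ArrayLike) -> MethodComparison:
    """Compare two paired estimate vectors: OLS of y on x plus Bland-Altman."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if xv.size < 3:
        raise ValueError("need at least 3 paired estimates")
    if not (np.all(np.isfinite(xv)) and np.all(np.isfinite(yv))):
        raise ValueError("estimates must be finite")
    if np.ptp(xv) == 0:
        raise ValueError("x has zero variance; regression undefined")

    lr = stats.linregress(xv, yv)
    diff = yv - xv
    bias = float(np.mean(diff))
    sd = float(np.std(diff, ddof=1))
    return MethodComparison(
        slope=float(lr.slope),
        intercept=float(lr.intercept),
        r2=float(lr.rvalue**2),
        bias=bias,
        loa_lower=bias - LOA_MULTIPLIER * sd,
        loa_upper=bias + LOA_MULTIPLIER * sd,
        n=int(xv.size),
        p_value=float(lr.pvalue),
    )


def quality_metrics(
    aortic_precontrast_mean: float,
    aortic_roi_sd: float,
    muscle_mean: float,
    muscle_sd: float,
) -> QualityMetrics:
    """SNR and CNR from aortic and paravertebral-muscle ROI statistics.

    SNR = pre-contrast aortic mean HU / aortic ROI SD;
    CNR = (aortic mean HU - muscle mean HU) / muscle HU SD.
    """
    if aortic_roi_sd <= 0 or muscle_sd <= 0:
        raise ValueError("ROI standard deviations must be > 0")
    return QualityMetrics(
        snr=aortic_precontrast_mean / aortic_roi_sd,
        cnr=(aortic_precontrast_mean - muscle_mean) / muscle_sd,
    )


def ratio_table(
    estimates: dict[str, PerfusionEstimate],
    enhancements: dict[str, float],
) -> pd.DataFrame:
    """Pairwise perfusion ratios against peak-enhancement ratios.

    One row per unordered organ pair (in input order), with the perfusion
    ratio organ1/organ2 and the corresponding peak-enhancement ratio. For
    organs sharing the aortic input, t_max and bolus shape, the two columns
    coincide — the feeding-vessel peak and k/t_max cancel in the ratio.
    Pairs whose denominator is zero are skipped with a warning.
    """
    organs = [o for o in estimates if o in enhancements]
    if len(organs) < 2:
        raise ValueError("need at least 2 organs with both estimate and enhancement")
    rows = []
    for o1, o2 in itertools.combinations(organs, 2):
        p2 = estimates[o2].perfusion
        e2 = enhancements[o2]
        if p2 == 0 or e2 <= 0:
            warnings.warn(f"skipping pair {o1}/{o2}: zero denominator", stacklevel=2)
            continue
        rows.append(
            {
                "organ_1": o1,
                "organ_2": o2,
                "perfusion_ratio": estimates[o1].perfusion / p2,
                "enhancement_ratio": perfusion_ratio_from_enhancements(
                    enhancements[o1], e2
                ),
            }
        )
    return pd.DataFrame(rows, columns=["organ_1", "organ_2", "perfusion_ratio", "enhancement_ratio"])
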