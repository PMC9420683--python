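# Methods

## Kinetic model

Tissue and arterial enhancement after a compact contrast bolus are modelled
with the Madsen parameterisation of the gamma-variate,

E(t) = y_max · τ^α · e^{α(1−τ)}, τ = t/t_max,

chosen because it is parameterised directly by the three clinically
accessible quantities: peak enhancement y_max (delta-HU above baseline),
peak time t_max (s), and bolus shape α (dimensionless; steeper bolus for
larger α, aortic boluses typically 3–15). The curve is 0 at t = 0, peaks at
exactly (t_max, y_max) for every α, and is unimodal.

Differentiating with respect to τ and applying the 1/t_max chain factor,
the physical slope is

dE/dt = (y_max α / t_max) · (τ^{α−1} − τ^α) · e^{α(1−τ)}  [HU/s],

with inflections at τ = (α ∓ √α)/α. The ascending root (minus sign) is the
point of maximal upslope; the plus root is the washout inflection. Both are
exposed by `inflection_times`; the maximum-slope factor

k(α) = α (τ^{α−1} − τ^α) e^{α(1−τ)} at τ = (α − √α)/α

is evaluated exactly by `k_exact`, so the maximum upslope is
y_max · k(α)/t_max. Over α ∈ [3, 15], k is nearly linear; `k_linear` uses
k = 1.502 + 0.092016·α, which stays within 2% of the exact value on that
range (an OLS refit of k against α on a 0.1-step grid reproduces these
coefficients and r² ≈ 0.997). The linear form is the package default
(`k_mode="linear"`) because it is the form in which the
perfusion–enhancement relations are usually written and applied; the exact
form is available everywhere and serves as the independent oracle in tests.

## Perfusion

Maximum-slope perfusion is the maximum tissue upslope divided by the peak
feeding-vessel (aortic) enhancement, in units of 1/s (mL/s of blood per mL
of tissue); the conventional mL/min/mL presentation (×60) is provided as an
accessor and is the CLI default. Two estimation routes are implemented:

* **Full-curve** (`perfusion_full_curve`): a cubic smoothing spline through
  all baseline-subtracted frames, its first derivative maximised over the
  upslope, divided by the fitted aortic peak. This is the classical method
  and the reference the two-phase route is validated against.
* **Two-phase** (`perfusion_two_phase`): y_max = peak HU − baseline HU from
  just two measurements, t_max the peak time, and α borrowed from the
  aortic fit; perfusion = y_max·k(α)/t_max / aortic peak. The central
  assumption is that the bolus shape is conserved between the arterial
  input and the tissue curve.

The inverse relation y_max = perfusion · aortic_peak · t_max / k(α)
(`enhancement_from_perfusion`) predicts arterial-phase enhancement from
perfusion; it round-trips with the forward relation to machine precision
for matching k mode. The aortic peak itself can be predicted from the
injection protocol by dilution of the iodine flux into the cardiac output:
peak ΔHU = flow_rate · iodine_concentration · c_kVp / cardiac_output, with
c = 26.18 HU per mgI/mL at 120 kVp. Constants for other tube voltages must
be supplied by the user; no kVp calibration table is bundled.

For two ROIs sharing the feeding vessel and bolus shape, the k/t_max and
aortic-peak factors cancel, so the perfusion ratio equals the
peak-enhancement ratio exactly; `ratio_table` tabulates both sides per
organ pair (one row per unordered pair).

## Fitting sampled curves

* **Baseline** (`estimate_baseline`): mean of the pre-arrival frames. In
  auto mode the initial run is grown while each next frame stays within 2
  sample SDs of the first frame (spread estimated from the run so far),
  minimum 2 frames; a noiseless run degenerates to exact equality with the
  first frame.
* **Gamma-variate fit** (`fit_gamma_variate`): bounded nonlinear least
  squares (scipy `curve_fit`, trust-region reflective) of the
  baseline-subtracted values. Start values: y_max at the observed maximum
  enhancement, t_max at the earliest maximal frame, α = 5. Bounds:
  y_max ∈ (0, 3·max], t_max ∈ (first, last frame time], α ∈ [1.5, 30] — the
  α bracket covers the clinical 3–15 range with margin on both sides. A fit
  whose α lands on a bound or that fails to converge is flagged
  `converged=False`; an all-baseline curve is rejected outright.
* **Spline maximum slope** (`fit_spline_max_slope`): cubic smoothing spline
  (scipy `make_smoothing_spline`) with the penalty chosen by generalized
  cross-validation, overridable. The derivative is evaluated on a grid 10×
  finer than the sampling interval, restricted to times up to the observed
  peak, and maximised. Smoothing attenuates the peak slope slightly, so the
  spline estimate sits at or just below the analytic value (within 2% on
  noiseless data at the standard sampling). A curve with no positive
  upslope reports 0 with a warning rather than an error.

Time zero is the first acquired frame; the injection-to-scan delay is not
modelled in fitting because the estimates depend on the curve only through
t_max, which absorbs any fixed shift.

## Synthetic studies

`generate_study` emulates an abdominal dynamic-CT acquisition: 40 frames at
1.5 s intervals; an aortic ROI with baseline 44 HU and a first-pass bolus
peaking at 350 delta-HU, t_max 14 s, α = 9; and three organ ROIs — pancreas
(1.15 mL/min/mL, t_max 35 s), kidney cortex (2.5 mL/min/mL) and an HCC
focus (0.6 mL/min/mL, a hypovascular-tumour value chosen below normal
parenchyma). Each organ's true y_max is derived from its prescribed
perfusion through the enhancement identity with the shared aortic peak and
bolus shape, so generated studies are exactly model-consistent and carry
their ground truth. ROI noise is the median of `roi_voxels` (default 25)
independent Gaussian voxel draws per frame, voxel SD 20 HU — an aortic SNR
(pre-contrast mean / ROI SD) near 2.2 at the voxel level and roughly 5 HU
of residual frame noise after the median. Noise is independent across
frames and additive on HU; no temporal autocorrelation, beam hardening,
partial-volume or respiratory motion is simulated, and no recirculation
hump is added. Passing recovery tests on these studies therefore
demonstrates correctness of the estimation chain under the kinetic model,
not robustness to the full physics of patient data. A bolus-arrival delay
is available as a pure time offset (`delay_s`, default 0): frames before
arrival sit exactly at baseline.

`recovery_experiment` regenerates the configured study per replicate with
seed `config.seed + r`, runs the complete chain (aortic fit → baseline →
both estimators per organ) and returns a tidy table for `compare_methods`.
The default validation scale — 11 replicates × 3 organs — runs in under a
second; replicate failures are recorded as NaN rows rather than aborting.

## Method comparison

`compare_methods` reports ordinary least squares of method 2 on method 1
(r² as the squared Pearson correlation, identical to OLS R² with an
intercept, plus the slope t-test p-value as supplementary output) and
Bland–Altman agreement. The difference direction is method 2 − method 1;
in the standard validation that is two-phase minus full-curve, so a
slightly lower gamma-based estimate shows as a negative bias. Limits of
agreement are bias ± 1.96 × SD of the differences with the n−1 denominator.
SNR and CNR follow the ROI definitions: SNR = pre-contrast aortic mean HU /
aortic ROI SD; CNR = (aortic mean − muscle mean)/muscle SD.

## Numerical and design notes

* All public slopes are in HU/s; perfusion is stored in 1/s and presented
  in mL/min/mL.
* Argmax tie-break for fit initialisation: the earliest maximal frame.
* `k_linear` outside α ∈ [3, 15] extrapolates but warns.
* Curve CSVs (`time_s,hu`) are written with 12 significant digits; the
  write/read round trip is lossless beyond any HU-relevant precision.
* The α used for the pancreas/kidney enhancement predictions is 9, the
  value that reproduces both reference numbers (≈100 HU at 1.15 mL/min/mL,
  ≈220 HU at 2.5 mL/min/mL) under a 350 delta-HU aortic peak; it also
  serves as the default synthetic bolus shape.
* Brain-type applications (very short t_max ≈ 9 s, grey matter around
  0.72 mL/min/mL) are expressible with the same equations, but the package
  makes no claim about the extra scaling factors such tissues may need
  (e.g. blood-brain-barrier effects on the enhancement scale); with a
  500 HU feeding-vessel peak the plain identity predicts roughly 19–31 ΔHU
  of cortical enhancement over α ∈ [3, 15], noticeably above the 10–15 HU
  sometimes quoted for grey matter, and no attempt is made to reconcile
  the two here.

## Known limitations

Patient DICOM handling, ROI drawing and frame registration are out of
scope: the package starts from ROI time-enhancement tables. Deconvolution
perfusion and whole-organ Fick-principle methods are not implemented. The
synthetic generator is a model-consistent phantom, not a CT physics
simulator, so validation results on it bound the method's behaviour only
under its own kinetic assumptions; collateral or delayed circulation, where
the conserved-bolus-shape assumption fails, is explicitly outside the
model.
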