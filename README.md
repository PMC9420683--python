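# ctperf

CT perfusion estimation from gamma-variate bolus kinetics — including a
**two-phase** method that needs only a baseline scan and a peak-enhancement
scan instead of a full dynamic series.

## The problem

Classical CT perfusion imaging scans the same volume dozens of times during
contrast transit, computes the tissue time-enhancement curve, and applies
the maximum-slope principle:

```
perfusion = maximum upslope of tissue enhancement / peak feeding-vessel enhancement
```

in (mL/s) of blood per mL of tissue. The repeated scanning costs radiation
dose and yields noisy curves. If, however, enhancement follows the Madsen
gamma-variate form

```
E(t) = y_max · τ^α · e^{α(1−τ)},    τ = t / t_max
```

then the whole curve is fixed by three numbers — peak enhancement `y_max`,
peak time `t_max`, and bolus shape `α` — and its maximum upslope has the
closed form `y_max · k(α) / t_max`, where `k(α)` is the dimensionless slope
at the ascending inflection `τ = (α − √α)/α`. Over the clinical bolus-shape
range α ∈ [3, 15], `k` is almost exactly linear: `k ≈ 1.502 + 0.092016·α`.
Because the bolus shape is conserved from the aorta into the branching
arterial tree, α can be taken from the aortic curve (or a bolus test), and
perfusion follows from **two measurements only** — baseline HU and
peak-phase HU:

```
perfusion = (peak − baseline) · k(α) / t_max / aortic peak enhancement
```

The same identity inverted predicts arterial-phase enhancement from
perfusion, and for two ROIs sharing the feeding vessel the perfusion ratio
reduces exactly to the peak-enhancement ratio.

`ctperf` implements both estimation routes — the full-curve route (cubic
smoothing spline through all frames, maximum of its derivative) and the
two-phase gamma-variate route — plus aortic-input fitting, linear-regression
and Bland–Altman method comparison, SNR/CNR image-quality metrics, and a
seeded synthetic dynamic-CT generator (40 frames / 1.5 s, ROI-median noise)
with exact ground truth for validation. It is intended for researchers in
quantitative contrast-enhanced imaging who work with ROI time-enhancement
tables (CSV), not raw DICOM.

## Worked example

From Python:

```python
from ctperf import AorticInput, GammaVariateParams, perfusion_two_phase

aorta = AorticInput(GammaVariateParams(y_max=350.0, t_max=14.0, alpha=9.0))
est = perfusion_two_phase(baseline_hu=40.0, peak_hu=140.0, t_peak=35.0, aorta=aorta)
print(round(est.max_slope, 3), round(est.perfusion_per_min, 3))
# 6.658 1.141
```

A tissue ROI that rises from 40 HU to 140 HU with its peak at 35 s, under a
350 delta-HU aortic peak with bolus shape 9, has a maximum upslope of
6.658 HU/s and a perfusion of 1.141 mL/min/mL — a typical pancreatic value.
The same computation from a shell:

```bash
$ ctperf two-phase 40 140 35 --aortic-peak 350 --alpha 9
{
  "perfusion": 1.1412950204081629,
  ...
}
```

Other subcommands: `simulate` (synthetic study + ground truth), `fit-aorta`
(aortic CSV → peak, α, t_max), `perfusion` (full curve, both methods),
`predict-enhancement`, `predict-aortic-peak`, `compare` (regression +
Bland–Altman), `qa` (SNR/CNR). All emit JSON on stdout; `--units per-s`
switches perfusion to 1/s; exit codes are 0/1/2 for ok / computation error /
usage error.

The `examples/` directory contains short narrative scripts: two-phase
estimation, enhancement prediction from an injection protocol, and an
in-silico comparison of the two methods on 11 synthetic studies (which
prints r² ≈ 0.91 and a bias of −0.04 mL/min/mL between the routes under
realistic ROI noise).

## Layout

- `src/ctperf/gamma_model.py` — closed-form kinetics: curve, derivatives, k(α), conversions
- `src/ctperf/curve_fitting.py` — gamma-variate and smoothing-spline fits of sampled curves
- `src/ctperf/pipeline.py` — both perfusion estimators, ratios, comparison statistics, SNR/CNR
- `src/ctperf/synthetic.py` — seeded synthetic-study generator and recovery experiments
- `src/ctperf/io.py`, `src/ctperf/cli.py` — CSV/config formats and the command-line surface
- `docs/methods.md` — model assumptions, parameter choices, limitations
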