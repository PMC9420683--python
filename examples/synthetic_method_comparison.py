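"""Validate the two-phase method against the full-curve method in silico.

Generates 11 synthetic dynamic-CT studies (40 frames / 1.5 s, aortic SNR
about 2.2), estimates perfusion for pancreas, kidney cortex and an HCC
focus by both routes, and compares them with linear regression and
Bland-Altman statistics.
"""

from ctperf import StudyConfig, compare_methods, recovery_experiment

config = StudyConfig(seed=12345)
table = recovery_experiment(config, n_replicates=11)
print(table.groupby("organ")[["true_perfusion", "spline_estimate", "two_phase_estimate"]]
      .mean().round(3))

c = compare_methods(table["spline_estimate"], table["two_phase_estimate"])
print(f"\nregression : two-phase = {c.intercept:.3f} + {c.slope:.3f} x full-curve")
print(f"r^2        : {c.r2:.3f}")
print(f"bias       : {c.bias:.3f} mL/min/mL  (two-phase minus full-curve)")
print(f"95% LoA    : [{c.loa_lower:.3f}, {c.loa_upper:.3f}] mL/min/mL")
# An r^2 above 0.9 and a bias near zero mean the two-measurement estimate
# tracks the classical full-curve estimate across the perfusion range
# 0.6-2.5 mL/min/mL despite realistic ROI noise.
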