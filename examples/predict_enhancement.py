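"""Predict arterial-phase tissue enhancement from perfusion.

First the aortic peak is predicted from the injection protocol by dilution
into the cardiac output, then the expected peak tissue enhancement follows
from the perfusion-enhancement identity. Inverted, the same identity turns
a measured enhancement back into perfusion.
"""

from ctperf import InjectionProtocol, enhancement_from_perfusion, predict_aortic_peak

protocol = InjectionProtocol(
    flow_rate=3.2,  # mL/s
    iodine_concentration=350.0,  # mgI/mL
    cardiac_output=83.0,  # mL/s (~5 L/min)
    hu_constant=26.18,  # HU per mgI/mL at 120 kVp
)
aortic_peak = predict_aortic_peak(protocol)
print(f"predicted aortic peak: {aortic_peak:.1f} delta-HU")

for organ, perfusion in [("pancreas", 1.15), ("renal cortex", 2.5)]:
    y_max = enhancement_from_perfusion(
        perfusion / 60.0, aortic_peak=350.0, t_max=35.0, alpha=9.0
    )
    print(f"{organ:12s}: {perfusion:.2f} mL/min/mL -> peak enhancement {y_max:.1f} delta-HU")
# With a 350 HU aortic peak, normal pancreatic perfusion implies ~100 HU of
# arterial-phase enhancement and renal-cortex perfusion ~220 HU.
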