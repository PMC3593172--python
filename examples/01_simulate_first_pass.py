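"""Simulate one first-pass experiment on the phantom circuit.

A 0.01 mmol/kg gadobutrol bolus is injected into the circuit at cardiac
output 3 L/min with the left myocardial compartment perfused at
5 mL/mL/min and the right at 10 mL/mL/min; the script prints where the
bolus peaks, how much it is diluted on the way, and how long the open
circuit needs to wash out.
"""

import perftwin as pt

config = pt.reference_circuit(cardiac_output_l_min=3.0,
                              perfusion_right=10.0, perfusion_left=5.0)
protocol = pt.InjectionProtocol(dose_mmol_per_kg=0.01)  # 60 kg subject
curves = pt.simulate_circuit(config, protocol, duration_s=300.0)

print(f"injected mass: {protocol.total_dose_mmol:.2f} mmol "
      f"({protocol.injected_volume_ml:.2f} mL over {protocol.injection_duration_s:.2f} s)")
print(f"stroke volume at 60 bpm: {pt.stroke_volume(3.0, 60)} mL")
print()
print(f"{'location':>12}  {'peak mmol/L':>11}  {'t_peak s':>8}")
for name in ("inlet", "right_atrium", "left_ventricle", "aorta",
             "myo_right", "myo_left"):
    t, p = curves[name].peak()
    print(f"{name:>12}  {p:11.3f}  {t:8.1f}")
print()
for side in ("right", "left"):
    w = pt.washout_time(curves[f"myo_{side}"], 0.01)
    print(f"{side} myocardium washes out (to 1% of peak) at t = {w:.0f} s")
print()
print("The bolus is diluted ~50x between injector and aorta; the slower")
print("compartment peaks later, lower, and needs longer before re-injection.")
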