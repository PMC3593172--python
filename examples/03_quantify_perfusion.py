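"""Dual-bolus Fermi deconvolution against a known gold standard.

Simulates a dual-bolus acquisition (10% prebolus for the AIF, full
0.01 mmol/kg bolus for the myocardium) with the left compartment set to a
gold-standard 7.5 mL/mL/min, adds scanner-like noise, and recovers absolute
perfusion by fitting a Fermi impulse response.
"""

import numpy as np

import perftwin as pt
from perftwin.experiments import acquire_dual_bolus, calibrate_signal_model

GOLD = 7.5  # mL/mL/min
model = calibrate_signal_model()
seq = pt.SequenceParams()
config = pt.reference_circuit(3.0, perfusion_right=10.0, perfusion_left=GOLD)
protocol = pt.InjectionProtocol(0.01)

acq = acquire_dual_bolus(config, protocol, seq, model,
                         sigma=pt.default_noise_sigma(seq, model), seed=7)
res = pt.quantify_dual_bolus(acq, seq, model, roi="myo_left")["myo_left"]
p = res.params

print(f"gold-standard perfusion : {GOLD:.1f} mL/mL/min "
      f"(flow {pt.perfusion_to_flow(GOLD):.3f} L/min over 45 mL)")
print(f"recovered perfusion     : {res.perfusion_ml_ml_min:.2f} mL/mL/min "
      f"({100 * (res.perfusion_ml_ml_min / GOLD - 1):+.1f}%)")
print(f"Fermi parameters        : F = {p.F:.4f}/s, k = {p.k:.3f}/s, "
      f"tau_d = {p.tau_d:.2f} s, tau_0 = {p.tau_0:.2f} s")
print(f"residual rms            : {res.residual_rms:.4f} (concentration units)")
print()
print("F*60 is the impulse-response height at onset, i.e. perfusion; tau_d")
print(f"absorbs the coronary transit delay ({5.8 / (GOLD * 45 / 60):.1f} s at this flow).")
assert np.isfinite(res.perfusion_ml_ml_min)
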