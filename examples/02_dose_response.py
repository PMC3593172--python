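"""Dose response and saturation of the arterial signal.

Calibrates the saturation-recovery signal model against the hardware's
measured arterial peak table, then replays the dose series (0.0005 to
0.1 mmol/kg) and prints the peak SI, the linearly extrapolated expected
peak, and the saturation ratio for each dose.  Ratios near 1 mean the
signal is still linear in concentration; ratios well above 1 mean T1
saturation is flattening the measured peak.
"""

from perftwin.experiments import ExperimentSpec, calibrate_signal_model, run_dose_series

model = calibrate_signal_model()
print(f"calibrated: scale = {model.scale:.0f} au, r1 = {model.r1:.2f} L/mmol/s\n")

result = run_dose_series(ExperimentSpec(base_seed=0), model, quantify=False)
cols = ["dose_mmol_kg", "aif_peak_au", "aif_expected_au", "aif_saturation_ratio",
        "myo_peak_au", "myo_saturation_ratio"]
print(result.table[cols].to_string(
    index=False, float_format=lambda x: f"{x:.2f}",
    formatters={"dose_mmol_kg": lambda d: f"{d:g}"},
))
print()
print("Arterial peaks rise linearly up to ~0.0025 mmol/kg and saturate above;")
print("this is why quantification uses a low-dose prebolus for the AIF and the")
print("full dose only for the (much less enhancing) myocardial curves.")
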