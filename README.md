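# perftwin

A digital twin of a hardware first-pass myocardial perfusion MR phantom.

Quantitative first-pass perfusion MRI estimates myocardial blood flow by
deconvolving the tissue enhancement curve against an arterial input function
(AIF), but validating those estimates requires a gold standard that patients
and most phantoms cannot provide. One validation strategy is a pump-driven
water circuit shaped like the thoracic circulation — vena cava, four cardiac
chambers, pulmonary vessels, aorta, and two independently perfused
"myocardial" compartments — in which flow meters measure true perfusion
while a clinical scanner images a gadolinium bolus. `perftwin` reproduces
that whole measurement chain in software, so acquisition and analysis
choices (doses, dual-bolus protocols, deconvolution settings) can be
replayed end-to-end against known ground-truth flows:

1. **Tracer transport** — the circuit is a cascade of well-mixed chambers
   (`dC/dt = (Q/V)(C_in − C)`) and plug-flow tubes (delay `V/Q`) at cardiac
   output `Q` (2–11 L/min); the myocardial compartment is a single
   well-mixed space with mono-exponential impulse response
   `(F/V_d)·e^{−(F/V_d)t}`, with coronary flows 0.035–0.45 L/min mapping to
   0.8–10 mL/mL/min over the 45 mL distribution volume.
2. **MR signal** — saturation-recovery gradient echo,
   `SI = scale·sin(α)·(1 − e^{−TD·R1})` with `R1 = R10 + r1·c`
   (TD = 120 ms, α = 15°), sampled once per heartbeat at 60 bpm with
   Gaussian noise; `scale` and `r1` are calibrated against the hardware's
   measured arterial peak table.
3. **Quantification** — dual-bolus Fermi deconvolution: a 10% prebolus
   provides the unsaturated AIF, and the tissue curve is fitted with
   `q = c_in ⊛ h`, `h(t) = F(1+e^{−kτ₀})/(1+e^{k(t−τ_d−τ₀)})·θ(t−τ_d)`,
   by bounded Levenberg–Marquardt least squares; absolute perfusion is
   `h` at the delay-corrected onset, `F·60` mL/mL/min.

See `docs/methods.md` for the model assumptions, parameter defaults and
known limitations of the twin relative to the hardware.

## Worked example

`examples/03_quantify_perfusion.py` simulates a noisy dual-bolus acquisition
with the left compartment at a gold-standard 7.5 mL/mL/min and recovers
perfusion by Fermi deconvolution:

```text
gold-standard perfusion : 7.5 mL/mL/min (flow 0.338 L/min over 45 mL)
recovered perfusion     : 7.36 mL/mL/min (-1.9%)
Fermi parameters        : F = 0.1226/s, k = 0.170/s, tau_d = 0.94 s, tau_0 = 0.00 s
residual rms            : 0.0048 (concentration units)
```

`F·60` is the recovered perfusion; `tau_d` has absorbed the ~1 s coronary
transit delay; the −1.9% deviation is within the run-to-run noise of a
single acquisition. The other examples cover circuit simulation and washout
(`01`), dose response and saturation ratios (`02`), cardiac-output
sensitivity and replicate reproducibility (`04`), and image-stack rendering
with ROI extraction (`05`); each prints its numbers with a line on what they
mean.

A thin CLI wraps the same library calls:

```bash
perftwin calibrate --out model.json
perftwin simulate --config run.yaml --seed 1 --out curves/
perftwin quantify --aif curves/aorta.csv --tissue curves/myo_left.csv \
    --config run.yaml --out result.json
perftwin experiment run perfusion --seed 1 --out results/
```

Exit codes: 0 success, 2 validation failure, 3 non-convergence.

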