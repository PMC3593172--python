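# Methods

`perftwin` is a digital twin of a hardware flow phantom used to validate
quantitative first-pass myocardial perfusion MRI. The hardware consists of a
pump-driven water circuit shaped like the thoracic circulation of a 60 kg
subject, with two independently perfused "myocardial" compartments; a
gadolinium bolus injected before the vena cava produces an arterial input
function (AIF) in the aorta and first-pass enhancement curves in the
compartments, while flow meters provide gold-standard perfusion. The twin
reproduces that measurement chain in three stages — tracer transport, MR
signal generation, deconvolution — so quantification can be checked against
known flows.

## Tracer transport: a tanks-and-tubes cascade

The circuit is an ordered cascade

VC (26 mL, tube) → RA (105 mL, box) → RV (120 mL, box) → PA/PV (88 mL, tube)
→ LA (105 mL, box) → LV (120 mL, box) → aorta (36 mL, tube),

driven at cardiac output Q (2–11 L/min; warnings outside this range). Boxes
are ideal well-mixed compartments (continuously stirred tanks),
`dC/dt = (Q/V)(C_in − C)`; tubes are plug-flow delays `V/Q`. An optional
`tube_dispersion_n` splits each tube into serial mixing segments to soften
bolus fronts (default 1, pure delay: dispersion beyond plug-flow transport
is deliberately out of scope). The cascade is solved with an exact
exponential integrator on a 0.05 s grid — fine enough to resolve the
clinical injection pulse (0.6 mL at 4 mL/s lasts 0.15 s) — and the mixed
chambers are first-order IIR filters, so the whole simulation is linear,
time-invariant and mass-conserving to machine precision.

The injector adds `dose × body weight` of agent (gadobutrol, 1 mmol/mL)
through a stopcock at 4 mL/s. With the cascade propagated at constant
cardiac output, mass conservation fixes the inlet pulse amplitude at
`rate × agent concentration / Q`; the pulse is deposited bin-integrated so
the injected mass is exact even when the pulse is shorter than one grid
step. The 20 mL saline flush carries no tracer and is not modelled beyond
the continuing main flow.

**Myocardial compartment and the distribution volume.** The hardware's
gold-standard perfusion is flow per mL of a 45 mL *distribution volume*,
titrated by weighing the myocardial compartment *together with its coronary
vessel*. The twin therefore models the coronary tube (5.8 mL) as a plug
delay traversed at the compartment's perfusion flow — giving the
physiological perfusion-dependent arrival delay — and the well-mixed
myocardial space at 45 − 5.8 = 39.2 mL, so the coronary dead space is not
counted twice. The compartment's impulse response is the mono-exponential
`(F/V) e^{−(F/V)t}`; with gold-standard perfusion defined per 45 mL but
tracer kinetics governed by 39.2 mL, deconvolution reads slightly high at
low rates — the same direction and magnitude the hardware experiments
reported. Perfusion flows 0.035–0.45 L/min map to 0.8–10 mL/mL/min.

## Signal generation: saturation-recovery gradient echo

Concentration maps to longitudinal relaxation linearly, `R1 = R10 + r1·c`,
and to signal through an idealised saturation-recovery preparation with one
readout at the saturation delay TD:

    SI = scale · sin(flip) · (1 − exp(−TD · R1)),   TD = 120 ms, flip = 15°.

TR/TE enter only through the calibrated `scale`; T2* decay, apparent-T1
effects of the readout train and water exchange are outside the model. The
curve is sampled once per RR interval (1 s at the simulated 60 bpm) by
linear interpolation, with additive Gaussian noise on the magnitude signal.
The default noise level gives baseline SNR ≈ 50, chosen so replicate
acquisitions correlate at the R² ≥ 0.99 level the hardware reported;
reproducibility conclusions only need a controllable noise floor, not a
scanner-accurate noise model. Imaging starts 10 s before injection so the
5-sample baseline window is genuinely pre-contrast at any cardiac output.

**Calibration.** The scanner's arbitrary units and the effective relaxivity
are fixed by fitting `scale` (and optionally `r1`; defaults r1 = 5.0
L·mmol⁻¹·s⁻¹, R10 = 0.33 s⁻¹) so that simulated baseline-subtracted aortic
peaks minimise the squared log-error against the hardware's measured peak
table (665 … 17894 au for 0.0005–0.1 mmol/kg). The fitted values are
scale ≈ 6.94·10⁴ au and r1 ≈ 5.46. A peak table proportional to dose makes
`r1` unidentifiable (no curvature information) and raises a dedicated
degenerate-calibration error.

**Known limitation — saturation shape.** Baseline-subtracted peaks of this
model form a two-parameter family `S·(1 − e^{−βd})` in dose `d`. The
hardware shows an abrupt saturation onset (ratio 1.005 at 0.0025 mmol/kg but
1.59 at 0.01) that no member of this family reproduces: the calibrated twin
gives 1.08 and 1.41 at those doses. Likewise the twin's myocardial
concentrations reach about half the aortic peak (a 39 mL mixed volume fed at
up to 0.45 L/min), so its myocardial curves show mild saturation at
0.01 mmol/kg (ratio 1.25) where the hardware measured none — the hardware's
myocardial signal per unit dose is ~10× smaller than aortic, implying an
effective first-pass dilution (slow inter-pipe pathways, partial volume)
that a single well-mixed compartment cannot represent. Tests assert the
regimes the twin does reproduce and document these two divergences rather
than widening bounds.

## Quantification: dual-bolus Fermi deconvolution

By the central volume principle the tissue curve is
`q(t) = c_in(t) ⊛ h(t)` and absolute perfusion is `h` at the
delay-corrected onset, converted to mL/mL/min. The impulse response is
constrained to a delayed Fermi shape

    h(t) = F (1 + e^{−k τ₀}) / (1 + e^{k(t − τ_d − τ₀)})  for t ≥ τ_d,  else 0,

normalised so `h(τ_d) = F`: `k` sets the washout tail, `τ₀` the shoulder
width, `τ_d` the arterial-to-tissue delay.

The full-dose AIF comes from the dual-bolus scheme: a 10% prebolus gives a
saturation-free arterial curve that is rescaled by the dose ratio. Because
the twin's myocardial curves are themselves mildly saturated at the main
dose (see above), the default pipeline first inverts the calibrated signal
model back to concentration for both curves ("linearisation") before
rescaling — a digital twin knows its own signal equation exactly, and
without this step the fitted perfusion at 10 mL/mL/min drops by ~25%.
`linearize=False` reproduces the plain SI-linearity assumption.

**Fitting.** Trust-region least squares with bounds
F ∈ [0, 100/60] s⁻¹, k ∈ [0, 5] s⁻¹, τ_d ∈ [0, 10] s, τ₀ ∈ [0, 20] s;
multi-start over τ_d ∈ {0..4} s crossed with a small grid of k and τ₀
initialisations (single initialisations were observed to strand in local
minima); cost tolerance 1e−8; fit window from injection to 90 s past the
tissue peak. Among starts whose residuals agree to 1e−6 relative, the
smaller fitted τ_d wins (deterministic tie-break).

**Discretisation.** The public `model_tissue` uses the rectangle-rule
convolution on the 1 s imaging grid, `q[i] = Δt Σ aif[j]·h[(i−j)Δt]` (so a
unit impulse returns `h` sampled on the grid, and a brute-force double loop
is its oracle). The fitter evaluates a refined variant: the AIF is linearly
interpolated onto a 0.25 s sub-grid and convolved against the *bin-averaged*
impulse response, computed from the closed-form integral of the Fermi
function. Two reasons: (i) the coarse rule's quadrature error depends
erratically on sub-sample arrival delays (up to −20% perfusion bias at
7.5 mL/mL/min); (ii) point-evaluating a discontinuous response makes the
model exactly invariant to sliding τ_d within one grid cell while F and τ₀
compensate, a spurious degeneracy that the tie-break would resolve towards
low F. Bin averaging is continuous in τ_d, so noiseless self-recovery is
exact.

**Accuracy.** Noiseless end-to-end recovery at gold standards
{1, 2.5, 5, 7.5, 10} mL/mL/min is within ~8% everywhere (two opposing,
well-understood effects: the Fermi family fits a mono-exponential response
~10% low in amplitude, and the 45/39.2 volume convention reads ~15% high,
with rate-dependent mixes). With default noise and six replicates the means
are {1.08, 2.60, 5.04, 7.42, 9.77} and one-way ANOVA separates the rates at
p < 10⁻⁴⁰.

## What the generator does and does not emulate

Emulated: AIF shape/amplitude versus dose and cardiac output (time-rescaled
transit, dilution, heartbeat sampling), single-compartment myocardial
uptake/washout, low-dose signal linearity and high-dose arterial saturation,
open-circuit washout and its monotone dependence on perfusion, replicate
noise. Not emulated: flow-dependent tube dispersion (continuous curves at
different cardiac outputs are exact time-rescalings, so amplitude changes
arise only from finite sampling), the hardware's very large effective
myocardial dilution (see above), pulsatile flow, recirculation kinetics of
the closed-circuit mode (implemented as a config flag but not validated),
k-space/reconstruction effects. Consequently: open-circuit washout to 1% of
peak spans 45–272 s across 1–10 mL/mL/min (a mono-exponential tail needs
ln(100)·V/F), versus the 60–180 s the hardware needed, and the
myocardial-to-aortic peak ratio shifts ~13% between cardiac outputs where
the hardware saw proportionality.

## Numerical choices and degenerate inputs

- Circuit grid 0.05 s; imaging grid 1 s; simulations 240 s (420 s for
  washout studies). Plug delays round to the nearest grid step.
- Washout time = first time after the peak below a threshold fraction of
  peak that stays below; `inf` sentinel when never reached; error on
  curves with no positive peak.
- Zero-variance inputs to correlation, single-group ANOVA, empty curves,
  non-positive flows/volumes/doses all raise typed errors.
- Noise seeds: every stochastic routine takes an explicit seed; replicate
  `i` of an experiment uses `base_seed + i`, with fixed per-ROI offsets, all
  reduced mod 2³¹−1.
- Image stacks render each ROI's SI into disjoint circular masks; extraction
  is the per-frame mask mean, exact to float rounding when noise is off.
  PNG export quantises to 16 bits with a stack-wide scale recorded in the
  JSON sidecar.
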