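"""Digital twin of the perfusion-phantom water circuit.

The hardware being emulated is a cascade of physiologically sized chambers
and tubes (vena cava -> right atrium -> right ventricle -> pulmonary
artery/vein -> left atrium -> left ventricle -> aorta) perfused at a set
cardiac output, with a small coronary tube branching off the aorta into two
myocardial compartments whose flows are regulated independently.  A gadolinium
bolus injected just before the vena cava is progressively mixed and diluted on
its way to the aorta, producing an arterial input function (AIF), and is then
taken up and washed out of the myocardial compartments at the set perfusion
rate.

Chambers (atria, ventricles) are modelled as ideal well-mixed compartments
(continuously stirred tanks); tubes are plug-flow delays, optionally split
into serial mixing segments to soften bolus fronts.  The circuit is linear and
time-invariant, so tracer mass is conserved exactly at every location.

Units: volumes in mL, flows in L/min (converted internally to mL/s), times in
seconds, concentrations in mmol/L.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.signal import lfilter

from .errors import (
    InvalidConfigError,
    InvalidFlowError,
    InvalidProtocolError,
    NoPeakError,
)

__all__ = [
    "CompartmentSpec",
    "CircuitConfig",
    "InjectionProtocol",
    "ConcentrationCurve",
    "reference_circuit",
    "inlet_concentration",
    "propagate",
    "simulate_circuit",
    "myocardial_curve",
    "flow_to_perfusion",
    "perfusion_to_flow",
    "stroke_volume",
    "washout_time",
    "NOT_WASHED_OUT",
]

#: Sentinel returned by :func:`washout_time` when the curve never settles
#: below the threshold within its duration.
NOT_WASHED_OUT = math.inf

_LMIN_TO_MLS = 1000.0 / 60.0


def _to_ml_per_s(flow_l_min: float) -> float:
    return flow_l_min * _LMIN_TO_MLS


@dataclass(frozen=True)
class CompartmentSpec:
    """One segment of the circuit.

    ``kind`` is ``"mixed"`` for a well-mixed chamber (outflow concentration
    equals internal concentration) or ``"plug"`` for a plug-flow tube (pure
    transit delay of volume/flow).
    """

    name: str
    volume_ml: float
    kind: str  # "mixed" | "plug"

    def __post_init__(self) -> None:
        if self.volume_ml <= 0:
            raise InvalidConfigError(
                f"compartment {self.name!r}: volume must be > 0, got {self.volume_ml}"
            )
        if self.kind not in ("mixed", "plug"):
            raise InvalidConfigError(
                f"compartment {self.name!r}: kind must be 'mixed' or 'plug', got {self.kind!r}"
            )


#: Component sizes of the hardware phantom (inner water volumes, mL).
TABLE_VOLUMES_ML = {
    "vena_cava": 26.0,
    "right_atrium": 105.0,
    "right_ventricle": 120.0,
    "pulmonary": 88.0,  # pulmonary artery + vein, one tube
    "left_atrium": 105.0,
    "left_ventricle": 120.0,
    "aorta": 36.0,
    "coronary": 5.8,
}


def _default_cascade() -> tuple[CompartmentSpec, ...]:
    return (
        CompartmentSpec("vena_cava", TABLE_VOLUMES_ML["vena_cava"], "plug"),
        CompartmentSpec("right_atrium", TABLE_VOLUMES_ML["right_atrium"], "mixed"),
        CompartmentSpec("right_ventricle", TABLE_VOLUMES_ML["right_ventricle"], "mixed"),
        CompartmentSpec("pulmonary", TABLE_VOLUMES_ML["pulmonary"], "plug"),
        CompartmentSpec("left_atrium", TABLE_VOLUMES_ML["left_atrium"], "mixed"),
        CompartmentSpec("left_ventricle", TABLE_VOLUMES_ML["left_ventricle"], "mixed"),
        CompartmentSpec("aorta", TABLE_VOLUMES_ML["aorta"], "plug"),
    )


@dataclass(frozen=True)
class CircuitConfig:
    """Geometry and operating point of the water circuit.

    ``distribution_volume_ml`` is the titrated water volume between the AIF
    sampling point and the myocardial imaging plane (45 mL in the hardware).
    It *includes* the coronary tube dead space, so the well-mixed myocardial
    compartment itself is simulated at ``distribution_volume_ml - coronary
    volume``; gold-standard perfusion is nevertheless defined per mL of the
    full distribution volume (:func:`flow_to_perfusion`).
    """

    cascade: tuple[CompartmentSpec, ...] = field(default_factory=_default_cascade)
    coronary: CompartmentSpec = CompartmentSpec(
        "coronary", TABLE_VOLUMES_ML["coronary"], "plug"
    )
    cardiac_output_l_min: float = 3.0
    perfusion_flow_right_l_min: float = 0.45
    perfusion_flow_left_l_min: float = 0.45
    distribution_volume_ml: float = 45.0
    mode: str = "open"  # "open" | "closed"
    reservoir_volume_ml: float = 1000.0  # closed mode only
    tube_dispersion_n: int = 1
    dt_s: float = 0.05

    def __post_init__(self) -> None:
        names = [c.name for c in self.cascade] + [self.coronary.name]
        if len(set(names)) != len(names):
            raise InvalidConfigError(f"compartment names not unique: {names}")
        if self.mode not in ("open", "closed"):
            raise InvalidConfigError(f"mode must be 'open' or 'closed', got {self.mode!r}")
        if self.dt_s <= 0:
            raise InvalidConfigError("dt_s must be positive")
        if self.tube_dispersion_n < 1:
            raise InvalidConfigError("tube_dispersion_n must be >= 1")
        if self.distribution_volume_ml <= self.coronary.volume_ml:
            raise InvalidConfigError(
                "distribution volume must exceed the coronary tube volume"
            )
        if not 2.0 <= self.cardiac_output_l_min <= 11.0:
            warnings.warn(
                f"cardiac output {self.cardiac_output_l_min} L/min outside the "
                "pump's 2-11 L/min operating range",
                stacklevel=2,
            )
        for side, f in (
            ("right", self.perfusion_flow_right_l_min),
            ("left", self.perfusion_flow_left_l_min),
        ):
            if f <= 0:
                raise InvalidFlowError(f"{side} perfusion flow must be > 0, got {f}")
            if not 0.035 <= f <= 0.45:
                warnings.warn(
                    f"{side} perfusion flow {f} L/min outside the roller pump's "
                    "0.035-0.45 L/min range",
                    stacklevel=2,
                )
        if (
            self.perfusion_flow_right_l_min + self.perfusion_flow_left_l_min
            >= self.cardiac_output_l_min
        ):
            raise InvalidConfigError(
                "total myocardial flow must be smaller than cardiac output"
            )

    @property
    def mixing_volume_ml(self) -> float:
        """Well-mixed myocardial volume: distribution volume minus coronary dead space."""
        return self.distribution_volume_ml - self.coronary.volume_ml


def reference_circuit(
    cardiac_output_l_min: float = 3.0,
    perfusion_right: float = 10.0,
    perfusion_left: float = 10.0,
    **kwargs,
) -> CircuitConfig:
    """Circuit at the hardware's reference geometry.

    Perfusion rates are given in mL/mL/min (the unit the experiments are
    described in) and converted to coronary line flows over the 45 mL
    distribution volume.
    """
    vd = kwargs.pop("distribution_volume_ml", 45.0)
    return CircuitConfig(
        cardiac_output_l_min=cardiac_output_l_min,
        perfusion_flow_right_l_min=perfusion_to_flow(perfusion_right, vd),
        perfusion_flow_left_l_min=perfusion_to_flow(perfusion_left, vd),
        distribution_volume_ml=vd,
        **kwargs,
    )


@dataclass(frozen=True)
class InjectionProtocol:
    """Contrast injection programme of the power injector."""

    dose_mmol_per_kg: float
    body_weight_kg: float = 60.0
    agent_concentration_mmol_per_ml: float = 1.0  # gadobutrol
    injection_rate_ml_per_s: float = 4.0
    flush_volume_ml: float = 20.0
    prebolus_fraction: float = 0.10
    inter_bolus_gap_s: float = 240.0

    def __post_init__(self) -> None:
        if self.dose_mmol_per_kg < 0:
            raise InvalidProtocolError(
                f"dose must be >= 0, got {self.dose_mmol_per_kg}"
            )
        if self.injection_rate_ml_per_s <= 0:
            raise InvalidProtocolError("injection rate must be > 0")
        if not 0.0 <= self.prebolus_fraction <= 1.0:
            raise InvalidProtocolError("prebolus fraction must lie in [0, 1]")
        if self.body_weight_kg <= 0:
            raise InvalidProtocolError("body weight must be > 0")
        if self.agent_concentration_mmol_per_ml <= 0:
            raise InvalidProtocolError("agent concentration must be > 0")

    @property
    def total_dose_mmol(self) -> float:
        return self.dose_mmol_per_kg * self.body_weight_kg

    @property
    def injected_volume_ml(self) -> float:
        return self.total_dose_mmol / self.agent_concentration_mmol_per_ml

    @property
    def injection_duration_s(self) -> float:
        return self.injected_volume_ml / self.injection_rate_ml_per_s

    def prebolus(self) -> "InjectionProtocol":
        """The diluted prebolus: same programme at ``prebolus_fraction`` of the dose."""
        return replace(self, dose_mmol_per_kg=self.dose_mmol_per_kg * self.prebolus_fraction)


@dataclass
class ConcentrationCurve:
    """Gadolinium concentration versus time at a named circuit location.

    ``times`` is a uniform, strictly increasing grid in seconds; ``values``
    are concentrations in mmol/L.
    """

    location: str
    times: np.ndarray
    values: np.ndarray

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.ndim != 1 or self.times.shape != self.values.shape:
            raise InvalidConfigError("times and values must be 1-D arrays of equal length")
        if len(self.times) < 2:
            raise InvalidConfigError("curve needs at least two samples")
        steps = np.diff(self.times)
        if np.any(steps <= 0) or not np.allclose(steps, steps[0], rtol=1e-9, atol=1e-12):
            raise InvalidConfigError("times must be strictly increasing and uniform")
        if np.any(self.values < -1e-9):
            raise InvalidConfigError("concentrations must be non-negative")
        self.values = np.maximum(self.values, 0.0)

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def mass_mmol(self, flow_l_min: float) -> float:
        """Tracer mass transported past this location, ``integral C*Q dt``.

        Values are bin averages over ``[t_i, t_i + dt)``, so the integral is
        the rectangle sum (exact for the bin-deposited injection pulse).
        """
        q_l_per_s = flow_l_min / 60.0
        return float(np.sum(self.values) * self.dt * q_l_per_s)

    def peak(self) -> tuple[float, float]:
        """(time, value) of the maximum sample."""
        i = int(np.argmax(self.values))
        return float(self.times[i]), float(self.values[i])

    def scaled(self, factor: float, location: str | None = None) -> "ConcentrationCurve":
        return ConcentrationCurve(
            location or self.location, self.times.copy(), self.values * factor
        )


def inlet_concentration(
    protocol: InjectionProtocol,
    config: CircuitConfig,
    duration_s: float = 240.0,
    start_s: float = 0.0,
) -> ConcentrationCurve:
    """Concentration pulse at the vena-cava entry produced by the injector.

    The injector pushes ``injected_volume`` of agent at ``injection_rate``
    through a three-way stopcock into the main flow.  With the cascade
    propagated at constant cardiac output, mass conservation fixes the pulse
    amplitude at ``rate * agent_conc / Q_main``; the pulse lasts
    ``injected_volume / rate`` seconds (0.15 s for 0.01 mmol/kg in a 60 kg
    subject).  The pulse is deposited bin-integrated so the injected mass is
    exact even when it is shorter than one grid step.  ``start_s`` delays the
    injection, leaving a pre-contrast baseline segment (acquisitions normally
    start imaging several beats before the injector fires).
    """
    dt = config.dt_s
    q_main = _to_ml_per_s(config.cardiac_output_l_min)
    times = np.arange(0.0, duration_s, dt)
    values = np.zeros_like(times)
    dur = protocol.injection_duration_s
    if dur > 0.0:
        amp = (
            protocol.injection_rate_ml_per_s
            * protocol.agent_concentration_mmol_per_ml
            / q_main
            * 1000.0  # mmol/mL -> mmol/L
        )
        # fraction of each dt bin covered by the rectangular pulse
        overlap = np.clip(
            np.minimum(times + dt, start_s + dur) - np.maximum(times, start_s), 0.0, dt
        )
        values = amp * overlap / dt
        # exactness guard against float edge effects
        values *= dur / (values.sum() * dt / amp) if values.sum() > 0 else 1.0
    return ConcentrationCurve("inlet", times, values)


def _mixed_outflow(values: np.ndarray, volume_ml: float, q_ml_s: float, dt: float) -> np.ndarray:
    """Exact exponential-integrator solution of dC/dt = (Q/V)(Cin - C), C(0)=0,
    for piecewise-constant input (first-order IIR filter)."""
    f = math.exp(-q_ml_s / volume_ml * dt)
    # out[i] = f*out[i-1] + (1-f)*in[i-1]
    driven = lfilter([0.0, 1.0 - f], [1.0, -f], values)
    return driven


def _plug_outflow(values: np.ndarray, volume_ml: float, q_ml_s: float, dt: float) -> np.ndarray:
    delay = volume_ml / q_ml_s
    n = int(round(delay / dt))
    out = np.zeros_like(values)
    if n < len(values):
        out[n:] = values[: len(values) - n]
    return out


def propagate(
    curve: ConcentrationCurve,
    comp: CompartmentSpec,
    flow_l_min: float,
    tube_dispersion_n: int = 1,
) -> ConcentrationCurve:
    """Transport a concentration curve through one compartment.

    Well-mixed chambers obey the stirred-tank equation
    ``dC/dt = (Q/V)(C_in - C)``; plug tubes delay the input by ``V/Q``.
    ``tube_dispersion_n > 1`` splits a plug tube into that many serial mixing
    segments, softening the bolus front while preserving the mean transit
    time.  Tracer mass (the time integral at fixed flow) is conserved.
    """
    if flow_l_min <= 0:
        raise InvalidFlowError(f"flow must be > 0, got {flow_l_min}")
    q = _to_ml_per_s(flow_l_min)
    dt = curve.dt
    vals = curve.values
    if comp.kind == "mixed":
        out = _mixed_outflow(vals, comp.volume_ml, q, dt)
    elif tube_dispersion_n > 1:
        out = vals
        seg = comp.volume_ml / tube_dispersion_n
        for _ in range(tube_dispersion_n):
            out = _mixed_outflow(out, seg, q, dt)
    else:
        out = _plug_outflow(vals, comp.volume_ml, q, dt)
    return ConcentrationCurve(comp.name, curve.times.copy(), out)


def simulate_circuit(
    config: CircuitConfig,
    protocol: InjectionProtocol,
    duration_s: float = 240.0,
    injection_start_s: float = 0.0,
) -> dict[str, ConcentrationCurve]:
    """Run the bolus through the full cascade.

    Returns concentration curves at every cascade location plus:

    ``"aorta"``
        the AIF, sampled in the proximal aorta before the coronary take-off;
    ``"myo_inflow_right"`` / ``"myo_inflow_left"``
        the aortic curve after transit through the coronary tube at each
        compartment's perfusion flow (a perfusion-dependent arrival delay);
    ``"myo_right"`` / ``"myo_left"``
        the well-mixed myocardial compartment concentrations at the imaging
        plane (:func:`myocardial_curve` at the circuit's mixing volume).

    In closed mode the distal outflow is recirculated into the vena cava
    through a well-mixed reservoir (untested against hardware data).
    """
    curve = inlet_concentration(protocol, config, duration_s, injection_start_s)
    curves: dict[str, ConcentrationCurve] = {"inlet": curve}
    q_main = config.cardiac_output_l_min

    if config.mode == "closed":
        curve = _simulate_closed_cascade(config, curve)
        curves.update({"aorta": curve})
    else:
        for comp in config.cascade:
            curve = propagate(curve, comp, q_main, config.tube_dispersion_n)
            curves[comp.name] = curve
        curves["aorta"] = curve  # last cascade element is the proximal aorta

    aorta = curves["aorta"]
    for side, perf_flow in (
        ("right", config.perfusion_flow_right_l_min),
        ("left", config.perfusion_flow_left_l_min),
    ):
        inflow = propagate(aorta, config.coronary, perf_flow, config.tube_dispersion_n)
        inflow.location = f"myo_inflow_{side}"
        curves[f"myo_inflow_{side}"] = inflow
        myo = myocardial_curve(inflow, perf_flow, config.mixing_volume_ml)
        myo.location = f"myo_{side}"
        curves[f"myo_{side}"] = myo
    return curves


def _simulate_closed_cascade(
    config: CircuitConfig, inlet: ConcentrationCurve
) -> ConcentrationCurve:
    """Closed-circuit recirculation: distal aorta -> reservoir -> vena cava.

    Solved by time-stepping all mixed compartments jointly with the
    recirculation feedback; plug tubes are integer-step delay lines.
    """
    dt = config.dt_s
    q = _to_ml_per_s(config.cardiac_output_l_min)
    comps = list(config.cascade) + [
        CompartmentSpec("reservoir", config.reservoir_volume_ml, "mixed")
    ]
    n = len(inlet.values)
    states = [0.0] * len(comps)
    delays = [
        np.zeros(max(int(round(c.volume_ml / q / dt)), 1)) if c.kind == "plug" else None
        for c in comps
    ]
    aorta_out = np.zeros(n)
    feedback = 0.0
    for i in range(n):
        x = inlet.values[i] + feedback
        for j, comp in enumerate(comps):
            if comp.kind == "mixed":
                f = math.exp(-q / comp.volume_ml * dt)
                states[j] = states[j] * f + x * (1 - f)
                x = states[j]
            else:
                buf = delays[j]
                out = buf[-1]
                buf[1:] = buf[:-1]
                buf[0] = x
                x = out
            if comp.name == "aorta":
                aorta_out[i] = x
        feedback = x
    return ConcentrationCurve("aorta", inlet.times.copy(), aorta_out)


def myocardial_curve(
    myo_inflow: ConcentrationCurve,
    perfusion_flow_l_min: float,
    v_d_ml: float,
) -> ConcentrationCurve:
    """Concentration inside a myocardial compartment at the imaging plane.

    The compartment is a single well-mixed space of volume ``v_d_ml`` perfused
    at ``perfusion_flow_l_min``; its impulse response is the mono-exponential
    ``(F/V) * exp(-(F/V) t)``, which is the system's ground-truth tissue
    residue model.
    """
    if perfusion_flow_l_min <= 0:
        raise InvalidFlowError(
            f"perfusion flow must be > 0, got {perfusion_flow_l_min}"
        )
    if v_d_ml <= 0:
        raise InvalidConfigError(f"distribution volume must be > 0, got {v_d_ml}")
    q = _to_ml_per_s(perfusion_flow_l_min)
    out = _mixed_outflow(myo_inflow.values, v_d_ml, q, myo_inflow.dt)
    return ConcentrationCurve("myocardium", myo_inflow.times.copy(), out)


def flow_to_perfusion(flow_l_min: float, v_d_ml: float) -> float:
    """Coronary line flow -> perfusion rate in mL of perfusate per mL of
    distribution volume per minute (0.45 L/min over 45 mL -> 10)."""
    if v_d_ml <= 0:
        raise InvalidConfigError(f"distribution volume must be > 0, got {v_d_ml}")
    return flow_l_min * 1000.0 / v_d_ml


def perfusion_to_flow(perfusion_ml_ml_min: float, v_d_ml: float = 45.0) -> float:
    """Inverse of :func:`flow_to_perfusion` (returns L/min)."""
    if v_d_ml <= 0:
        raise InvalidConfigError(f"distribution volume must be > 0, got {v_d_ml}")
    return perfusion_ml_ml_min * v_d_ml / 1000.0


def stroke_volume(cardiac_output_l_min: float, heart_rate_bpm: float) -> int:
    """Stroke volume in mL at the simulated heart rate (4 L/min at 60 bpm -> 67)."""
    if heart_rate_bpm <= 0:
        raise InvalidConfigError(f"heart rate must be > 0, got {heart_rate_bpm}")
    return int(round(cardiac_output_l_min * 1000.0 / heart_rate_bpm))


def washout_time(curve: ConcentrationCurve, threshold_fraction: float = 0.01) -> float:
    """First time after the peak at which the curve falls below
    ``threshold_fraction * peak`` and stays below.

    Returns :data:`NOT_WASHED_OUT` (``inf``) if the curve never settles below
    the threshold within its duration.  Raises :class:`NoPeakError` for a
    curve with no positive peak.
    """
    if not 0.0 < threshold_fraction <= 1.0:
        raise InvalidConfigError("threshold fraction must lie in (0, 1]")
    t_peak, peak = curve.peak()
    if peak <= 0.0:
        raise NoPeakError(f"curve at {curve.location!r} has no positive peak")
    if threshold_fraction >= 1.0:
        return t_peak
    i_peak = int(np.argmax(curve.values))
    below = curve.values[i_peak:] < threshold_fraction * peak
    if not below.any():
        return NOT_WASHED_OUT
    above = np.where(~below)[0]
    last_above = above[-1] if len(above) else -1
    j = last_above + 1
    if j >= len(below):
        return NOT_WASHED_OUT
    return float(curve.times[i_peak + j])
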