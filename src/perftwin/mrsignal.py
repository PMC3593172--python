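"""Saturation-recovery gradient-echo signal model.

Concentration curves from the circuit twin are converted into signal
intensity (SI, arbitrary units) the way the scanner sees them: a linear
relaxivity model maps gadolinium concentration to the longitudinal relaxation
rate, an idealised saturation-recovery preparation with a single readout at
the saturation delay maps R1 to SI, and the continuous curve is sampled once
per heartbeat with additive Gaussian noise.

    R1(c) = R10 + r1 * c
    SI(R1) = scale * sin(flip) * (1 - exp(-TD * R1))

TE/T2* decay and apparent-T1 effects of the fast readout train are outside
the model; they enter only through the calibrated ``scale``.  The model is
monotone and concave in concentration, which is what produces the
saturation-ratio behaviour of high-dose arterial curves.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import InvalidConfigError, NoPeakError

__all__ = [
    "SequenceParams",
    "SignalModelParams",
    "SignalCurve",
    "concentration_to_R1",
    "sr_signal",
    "signal_from_concentration",
    "concentration_from_signal",
    "sample_and_noise",
    "default_noise_sigma",
    "peak_si",
    "expected_peak",
    "saturation_ratio",
]


@dataclass(frozen=True)
class SequenceParams:
    """Saturation-recovery gradient-echo sequence settings."""

    tr_ms: float = 3.0
    te_ms: float = 1.0
    flip_deg: float = 15.0
    sr_delay_ms: float = 120.0
    rr_s: float = 1.0  # cardiac trigger interval (60 bpm)

    def __post_init__(self) -> None:
        for name in ("tr_ms", "te_ms", "flip_deg", "sr_delay_ms", "rr_s"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be positive")

    @property
    def sr_delay_s(self) -> float:
        return self.sr_delay_ms / 1000.0


@dataclass(frozen=True)
class SignalModelParams:
    """Relaxometry and scanner calibration.

    ``r1`` is the gadobutrol longitudinal relaxivity (L mmol^-1 s^-1), ``r10``
    the baseline relaxation rate of water, and ``scale`` the arbitrary-unit
    calibration constant of the receive chain (fitted against a measured peak
    table by the experiments module).
    """

    r1: float = 5.0
    r10: float = 0.33
    scale: float = 1.0

    def __post_init__(self) -> None:
        if self.r1 <= 0 or self.r10 <= 0 or self.scale <= 0:
            raise InvalidConfigError("r1, r10 and scale must all be positive")


@dataclass
class SignalCurve:
    """Signal intensity versus time at a named region of interest.

    ``baseline_window`` is the (start, stop) sample range of the pre-contrast
    segment used for baseline subtraction.
    """

    roi: str
    times: np.ndarray
    values: np.ndarray
    baseline_window: tuple[int, int] = (0, 5)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.times.shape != self.values.shape or self.times.ndim != 1:
            raise InvalidConfigError("times and values must be 1-D arrays of equal length")
        if len(self.times) == 0:
            raise InvalidConfigError("signal curve is empty")
        if np.any(self.values < 0):
            raise InvalidConfigError("signal intensities must be non-negative")
        b0, b1 = self.baseline_window
        if not 0 <= b0 < b1:
            raise InvalidConfigError("baseline window must be a non-empty forward range")

    @property
    def dt(self) -> float:
        if len(self.times) < 2:
            raise InvalidConfigError("single-sample curve has no sampling interval")
        return float(self.times[1] - self.times[0])

    def baseline(self) -> float:
        b0, b1 = self.baseline_window
        return float(np.mean(self.values[b0:min(b1, len(self.values))]))

    def baseline_subtracted(self) -> np.ndarray:
        return self.values - self.baseline()


def concentration_to_R1(c, params: SignalModelParams):
    """Linear relaxivity model, R1 = R10 + r1*c (s^-1)."""
    c = np.asarray(c, dtype=float)
    if np.any(c < 0):
        raise InvalidConfigError("concentration must be non-negative")
    return params.r10 + params.r1 * c


def sr_signal(R1, seq: SequenceParams, params: SignalModelParams):
    """SI after an ideal saturation pulse with recovery delay TD.

    ``SI = scale * sin(flip) * (1 - exp(-TD * R1))`` — strictly increasing and
    saturating towards ``scale * sin(flip)`` as R1 grows.
    """
    R1 = np.asarray(R1, dtype=float)
    td = seq.sr_delay_s
    return params.scale * math.sin(math.radians(seq.flip_deg)) * (1.0 - np.exp(-td * R1))


def signal_from_concentration(curve, seq: SequenceParams, params: SignalModelParams,
                              roi: str | None = None) -> SignalCurve:
    """Map a ConcentrationCurve through the full signal model (no sampling)."""
    si = sr_signal(concentration_to_R1(curve.values, params), seq, params)
    return SignalCurve(roi or curve.location, curve.times.copy(), np.asarray(si))


def concentration_from_signal(si, seq: SequenceParams, params: SignalModelParams):
    """Invert the signal model back to concentration (mmol/L).

    Exact inverse of the monotone SR-GRE equation; values are clipped just
    below the saturation plateau for numerical safety and the result floored
    at zero.
    """
    si = np.asarray(si, dtype=float)
    plateau = params.scale * math.sin(math.radians(seq.flip_deg))
    x = np.clip(1.0 - si / plateau, 1e-12, None)
    R1 = -np.log(x) / seq.sr_delay_s
    return np.maximum((R1 - params.r10) / params.r1, 0.0)


def sample_and_noise(
    curve: SignalCurve,
    seq: SequenceParams,
    sigma: float = 0.0,
    seed: int | None = None,
) -> SignalCurve:
    """Sample a continuous SI curve once per RR interval and add Gaussian noise.

    The trigger fires at t = 0, RR, 2RR, ...; values are linearly interpolated
    from the input grid.  Noise is additive Gaussian on the magnitude signal
    (sigma in au), reproducible for a given seed, floored at zero.
    """
    if sigma < 0:
        raise InvalidConfigError("sigma must be >= 0")
    t_end = float(curve.times[-1])
    t_samp = np.arange(0.0, t_end + 1e-9, seq.rr_s)
    vals = np.interp(t_samp, curve.times, curve.values)
    if sigma > 0:
        rng = np.random.default_rng(seed)
        vals = vals + rng.normal(0.0, sigma, size=vals.shape)
    return SignalCurve(curve.roi, t_samp, np.maximum(vals, 0.0),
                       baseline_window=curve.baseline_window)


def default_noise_sigma(seq: SequenceParams, params: SignalModelParams,
                        snr: float = 50.0) -> float:
    """Noise level giving the requested baseline SNR (default ~50)."""
    baseline = float(sr_signal(params.r10, seq, params))
    return baseline / snr


def peak_si(curve: SignalCurve) -> float:
    """Maximum of the baseline-subtracted signal (au)."""
    if len(curve.values) == 0:
        raise NoPeakError("empty signal curve")
    return float(np.max(curve.baseline_subtracted()))


def expected_peak(reference_peak: float, reference_dose: float, dose: float) -> float:
    """Linear extrapolation of a non-saturating reference peak to another dose."""
    if reference_dose <= 0:
        raise InvalidConfigError(f"reference dose must be > 0, got {reference_dose}")
    return reference_peak * dose / reference_dose


def saturation_ratio(expected: float, observed: float) -> float:
    """Expected / observed peak SI, rounded to two decimals.

    Ratios above 1 quantify T1-saturation flattening of the measured peak.
    """
    if observed <= 0:
        raise InvalidConfigError(f"observed peak must be > 0, got {observed}")
    return round(expected / observed, 2)
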