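"""Exception hierarchy for the perfusion-phantom twin."""


class PerfTwinError(Exception):
    """Base class for all package errors."""


class InvalidProtocolError(PerfTwinError, ValueError):
    """Injection protocol violates its contract (e.g. negative dose)."""


class InvalidFlowError(PerfTwinError, ValueError):
    """A volumetric flow is non-positive where positive flow is required."""


class InvalidConfigError(PerfTwinError, ValueError):
    """A circuit / sequence / run configuration violates an invariant."""


class NoPeakError(PerfTwinError, ValueError):
    """Curve has no usable peak (e.g. identically zero)."""


class CurveFormatError(PerfTwinError, ValueError):
    """Malformed curve or config file; message names the offending line/field."""


class UndefinedCorrelationError(PerfTwinError, ValueError):
    """Correlation requested between inputs with zero variance."""


class CalibrationError(PerfTwinError, RuntimeError):
    """Signal-model calibration failed; carries the residual report."""


class DegenerateCalibrationError(CalibrationError):
    """Relaxivity unidentifiable: the peak table is consistent with a purely
    linear signal model, so r1 is unbounded."""


class NotConvergedError(PerfTwinError, RuntimeError):
    """Deconvolution did not converge; carries fit diagnostics."""
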