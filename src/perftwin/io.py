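"""File formats: curve CSV, run configuration YAML/JSON, result JSON.

Curves travel as two-column CSV (``time_s,<value column>``) with ``#``-prefixed
metadata lines (location/ROI, config hash, seed).  Run configurations bundle
the circuit, injection, sequence, signal-model and noise settings under a
versioned schema; every artifact written by the package carries the
configuration hash and the seed that produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

import numpy as np
import yaml

from .circuit import CircuitConfig, CompartmentSpec, ConcentrationCurve, InjectionProtocol
from .errors import CurveFormatError, InvalidConfigError
from .mrsignal import SequenceParams, SignalCurve, SignalModelParams

__all__ = [
    "RunConfig",
    "config_hash",
    "write_curve",
    "read_curve",
    "write_config",
    "read_config",
    "write_result",
]

SCHEMA_ID = "perftwin/run-config/v1"


@dataclass
class RunConfig:
    """Complete, serialisable description of one simulated acquisition."""

    circuit: CircuitConfig = field(default_factory=CircuitConfig)
    injection: InjectionProtocol = field(default_factory=lambda: InjectionProtocol(0.01))
    sequence: SequenceParams = field(default_factory=SequenceParams)
    signal_model: SignalModelParams = field(default_factory=SignalModelParams)
    noise_sigma_au: float = 0.0
    seed: int = 0
    duration_s: float = 240.0
    schema: str = SCHEMA_ID

    def to_dict(self) -> dict:
        d = asdict(self)
        d["circuit"]["cascade"] = [asdict(c) for c in self.circuit.cascade]
        d["circuit"]["coronary"] = asdict(self.circuit.coronary)
        return d


def config_hash(config: RunConfig | dict) -> str:
    """Short stable hash of a configuration for provenance headers."""
    d = config.to_dict() if isinstance(config, RunConfig) else config
    blob = json.dumps(d, sort_keys=True, default=float).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# curves


def write_curve(curve: ConcentrationCurve | SignalCurve, path: str | Path,
                meta: dict | None = None) -> None:
    path = Path(path)
    is_signal = isinstance(curve, SignalCurve)
    label = curve.roi if is_signal else curve.location
    col = "si_au" if is_signal else "conc_mmol_per_L"
    lines = [
        f"# {'roi' if is_signal else 'location'}: {label}",
        f"# kind: {'signal' if is_signal else 'concentration'}",
    ]
    if is_signal:
        lines.append(f"# baseline_window: {curve.baseline_window[0]} {curve.baseline_window[1]}")
    for k, v in (meta or {}).items():
        lines.append(f"# {k}: {v}")
    lines.append(f"time_s,{col}")
    for t, v in zip(curve.times, curve.values):
        lines.append(f"{t:.17g},{v:.17g}")
    path.write_text("\n".join(lines) + "\n")


def read_curve(path: str | Path) -> ConcentrationCurve | SignalCurve:
    path = Path(path)
    meta: dict[str, str] = {}
    times, values = [], []
    header_seen = False
    for ln, raw in enumerate(path.read_text().splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            body = line[1:].strip()
            if ":" in body:
                k, v = body.split(":", 1)
                meta[k.strip()] = v.strip()
            continue
        if not header_seen:
            header_seen = True  # column header line
            if not line.startswith("time_s"):
                raise CurveFormatError(f"{path}:{ln}: expected 'time_s,...' header, got {line!r}")
            continue
        parts = line.split(",")
        if len(parts) != 2:
            raise CurveFormatError(f"{path}:{ln}: expected two comma-separated values")
        try:
            times.append(float(parts[0]))
            values.append(float(parts[1]))
        except ValueError as exc:
            raise CurveFormatError(f"{path}:{ln}: non-numeric value: {exc}") from exc
    if not times:
        raise CurveFormatError(f"{path}: no data rows")
    t = np.asarray(times)
    v = np.asarray(values)
    if meta.get("kind") == "signal":
        bw = meta.get("baseline_window", "0 5").split()
        return SignalCurve(meta.get("roi", "unknown"), t, v,
                           baseline_window=(int(bw[0]), int(bw[1])))
    return ConcentrationCurve(meta.get("location", "unknown"), t, v)


# ---------------------------------------------------------------------------
# config


_REQUIRED = {
    "circuit": CircuitConfig,
    "injection": InjectionProtocol,
    "sequence": SequenceParams,
    "signal_model": SignalModelParams,
}


def write_config(config: RunConfig, path: str | Path) -> None:
    path = Path(path)
    d = config.to_dict()
    d["config_hash"] = config_hash(config)
    text = (
        json.dumps(d, indent=2)
        if path.suffix.lower() == ".json"
        else yaml.safe_dump(d, sort_keys=False)
    )
    path.write_text(text)


def _build(cls, d: dict, context: str):
    names = {f.name for f in fields(cls)}
    unknown = set(d) - names
    if unknown:
        raise InvalidConfigError(f"{context}: unknown field(s) {sorted(unknown)}")
    try:
        return cls(**d)
    except TypeError as exc:
        raise InvalidConfigError(f"{context}: {exc}") from exc


def read_config(path: str | Path) -> RunConfig:
    path = Path(path)
    raw = path.read_text()
    data = json.loads(raw) if path.suffix.lower() == ".json" else yaml.safe_load(raw)
    if not isinstance(data, dict):
        raise InvalidConfigError(f"{path}: config root must be a mapping")
    schema = data.pop("schema", SCHEMA_ID)
    if schema != SCHEMA_ID:
        raise InvalidConfigError(f"{path}: unsupported schema {schema!r} (expected {SCHEMA_ID})")
    data.pop("config_hash", None)
    kwargs = {}
    for key, cls in _REQUIRED.items():
        if key not in data:
            raise InvalidConfigError(f"{path}: missing required section {key!r}")
        section = dict(data.pop(key))
        if key == "circuit":
            if "cardiac_output_l_min" not in section:
                raise InvalidConfigError(f"{path}: circuit section missing field 'cardiac_output_l_min'")
            if "cascade" in section:
                section["cascade"] = tuple(
                    _build(CompartmentSpec, c, f"{path}: circuit.cascade")
                    for c in section["cascade"]
                )
            if "coronary" in section:
                section["coronary"] = _build(
                    CompartmentSpec, section["coronary"], f"{path}: circuit.coronary"
                )
        kwargs[key] = _build(cls, section, f"{path}: section {key!r}")
    for key in ("noise_sigma_au", "seed", "duration_s"):
        if key in data:
            kwargs[key] = data.pop(key)
    if data:
        raise InvalidConfigError(f"{path}: unknown top-level field(s) {sorted(data)}")
    return RunConfig(schema=schema, **kwargs)


def write_result(result: dict, path: str | Path, config: RunConfig | None = None,
                 seed: int | None = None) -> None:
    """Write a result JSON with provenance (config hash and seed)."""
    out = dict(result)
    if config is not None:
        out.setdefault("config_hash", config_hash(config))
        seed = config.seed if seed is None else seed
    if seed is not None:
        out.setdefault("seed", int(seed))
    Path(path).write_text(json.dumps(out, indent=2, default=float) + "\n")
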