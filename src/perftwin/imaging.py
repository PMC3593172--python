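"""Synthetic dynamic image rendering and ROI extraction.

The hardware phantom is imaged in a single transverse plane showing the
aorta, both myocardial compartments and the large vessels at once.  This
module renders per-ROI signal curves into a dynamic image stack (one frame
per heartbeat, circular ROIs on a flat background) and extracts per-frame
mean-intensity curves back out of labelled masks — the synthetic counterpart
of the segmentation/export step of the image-analysis workflow.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .errors import InvalidConfigError
from .mrsignal import SignalCurve

__all__ = [
    "RoiSpec",
    "PhantomImageStack",
    "default_layout",
    "render_image_series",
    "extract_roi",
    "write_stack",
    "read_stack",
]


@dataclass(frozen=True)
class RoiSpec:
    """Circular ROI: centre (row, col) and radius, in pixels."""

    name: str
    center: tuple[float, float]
    radius: float


def default_layout() -> tuple[RoiSpec, ...]:
    """Transverse imaging plane: aorta centred between the two myocardial
    cylinders, vena cava and pulmonary vessel in the lower half."""
    return (
        RoiSpec("aorta", (26.0, 48.0), 7.0),
        RoiSpec("myo_right", (44.0, 22.0), 13.0),
        RoiSpec("myo_left", (44.0, 74.0), 13.0),
        RoiSpec("vena_cava", (76.0, 34.0), 5.0),
        RoiSpec("pulmonary", (76.0, 62.0), 5.0),
    )


@dataclass
class PhantomImageStack:
    """Dynamic frame stack with labelled ROI masks.

    ``frames`` has shape (n_frames, height, width); ``roi_map`` maps ROI name
    to a boolean mask of the frame shape.  All frames share one shape and the
    masks are pairwise disjoint.
    """

    frames: np.ndarray
    roi_map: dict[str, np.ndarray]
    times: np.ndarray
    pixel_size_mm: float = 1.2
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3:
            raise InvalidConfigError("frames must be a (n, h, w) array")
        shape = self.frames.shape[1:]
        taken = np.zeros(shape, dtype=bool)
        for name, mask in self.roi_map.items():
            if mask.shape != shape:
                raise InvalidConfigError(f"ROI {name!r} mask shape differs from frames")
            if (taken & mask).any():
                raise InvalidConfigError(f"ROI {name!r} overlaps another ROI")
            taken |= mask
        if len(self.times) != len(self.frames):
            raise InvalidConfigError("one timestamp per frame required")


def _disk_mask(shape: tuple[int, int], roi: RoiSpec) -> np.ndarray:
    rr, cc = np.ogrid[: shape[0], : shape[1]]
    return (rr - roi.center[0]) ** 2 + (cc - roi.center[1]) ** 2 <= roi.radius**2


def render_image_series(
    curves: dict[str, SignalCurve],
    layout: tuple[RoiSpec, ...] | None = None,
    shape: tuple[int, int] = (96, 96),
    background: float = 0.0,
    noise_sigma: float = 0.0,
    seed: int | None = None,
    pixel_size_mm: float = 1.2,
) -> PhantomImageStack:
    """Paint each ROI's signal curve into a dynamic frame stack.

    All curves must share their time grid; every pixel of a ROI takes that
    ROI's SI value in each frame (plus optional per-pixel Gaussian noise),
    the background is constant.
    """
    layout = layout or default_layout()
    names = [r.name for r in layout if r.name in curves]
    missing = set(curves) - {r.name for r in layout}
    if missing:
        raise InvalidConfigError(f"no layout entry for curve(s): {sorted(missing)}")
    ref = curves[names[0]]
    for n in names[1:]:
        if len(curves[n].times) != len(ref.times) or not np.allclose(
            curves[n].times, ref.times
        ):
            raise InvalidConfigError("all curves must share one time grid")
    masks = {r.name: _disk_mask(shape, r) for r in layout if r.name in curves}
    taken = np.zeros(shape, dtype=bool)
    for name, m in masks.items():
        if (taken & m).any():
            raise InvalidConfigError(f"ROI {name!r} overlaps another ROI")
        taken |= m
    n_frames = len(ref.times)
    frames = np.full((n_frames, *shape), background, dtype=float)
    for name in names:
        frames[:, masks[name]] = curves[name].values[:, None]
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        frames = np.maximum(frames + rng.normal(0.0, noise_sigma, frames.shape), 0.0)
    return PhantomImageStack(
        frames=frames,
        roi_map=masks,
        times=ref.times.copy(),
        pixel_size_mm=pixel_size_mm,
        meta={"noise_sigma": noise_sigma, "seed": seed},
    )


def extract_roi(stack: PhantomImageStack, roi: str) -> SignalCurve:
    """Per-frame mean intensity over the named ROI mask."""
    if roi not in stack.roi_map:
        raise InvalidConfigError(
            f"unknown ROI {roi!r}; available: {sorted(stack.roi_map)}"
        )
    mask = stack.roi_map[roi]
    if not mask.any():
        raise InvalidConfigError(f"ROI {roi!r} has an empty mask")
    vals = stack.frames[:, mask].mean(axis=1)
    return SignalCurve(roi, stack.times.copy(), np.maximum(vals, 0.0))


def write_stack(stack: PhantomImageStack, directory: str | Path) -> None:
    """Persist a stack as 16-bit PNG frames plus a JSON sidecar.

    Intensities are scaled to the uint16 range frame-stack-wide; the scale
    factor, ROI geometry and timing go into ``stack.json``.
    """
    import imageio.v3 as iio

    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    vmax = float(stack.frames.max()) or 1.0
    scale = 65535.0 / vmax
    for i, frame in enumerate(stack.frames):
        iio.imwrite(
            directory / f"frame_{i:04d}.png",
            np.round(frame * scale).astype(np.uint16),
        )
    sidecar = {
        "n_frames": len(stack.frames),
        "shape": list(stack.frames.shape[1:]),
        "times_s": stack.times.tolist(),
        "pixel_size_mm": stack.pixel_size_mm,
        "intensity_scale": scale,
        "rois": {
            name: {"pixels": np.argwhere(mask).tolist()}
            for name, mask in stack.roi_map.items()
        },
        "meta": stack.meta,
    }
    (directory / "stack.json").write_text(json.dumps(sidecar))


def read_stack(directory: str | Path) -> PhantomImageStack:
    """Load a stack written by :func:`write_stack` (intensities are restored
    up to the 16-bit quantisation of the PNG frames)."""
    import imageio.v3 as iio

    directory = Path(directory)
    sidecar = json.loads((directory / "stack.json").read_text())
    frames = np.stack(
        [
            iio.imread(directory / f"frame_{i:04d}.png").astype(float)
            / sidecar["intensity_scale"]
            for i in range(sidecar["n_frames"])
        ]
    )
    shape = tuple(sidecar["shape"])
    roi_map = {}
    for name, spec in sidecar["rois"].items():
        mask = np.zeros(shape, dtype=bool)
        idx = np.array(spec["pixels"], dtype=int)
        if len(idx):
            mask[idx[:, 0], idx[:, 1]] = True
        roi_map[name] = mask
    return PhantomImageStack(
        frames=frames,
        roi_map=roi_map,
        times=np.asarray(sidecar["times_s"], dtype=float),
        pixel_size_mm=sidecar["pixel_size_mm"],
        meta=sidecar.get("meta", {}),
    )
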