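"""Core data containers and I/O for dynamic PET analysis.

Defines the frame schedule, 4D dynamic image, time-activity curve (TAC),
mask and parametric-map types that every pipeline in :mod:`rsdpet`
consumes, together with NIfTI read/write helpers and the shared numeric
utilities (cumulative time integration, weighted-least-squares frame
weights).

Conventions
-----------
* Time is in minutes throughout; activity in kBq/mL.
* Images are indexed ``(x, y, z, frame)`` with 0-based voxel indices.
* Frame values represent duration-averaged activity; model equations are
  evaluated at frame mid-times.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "FrameSchedule",
    "DynamicImage",
    "TAC",
    "Mask",
    "ParametricMap",
    "ScheduleError",
    "FormatError",
    "EmptyRegionError",
    "ConfigError",
    "load_dynamic_image",
    "save_dynamic_image",
    "load_mask",
    "save_map",
    "extract_tacs",
    "reference_tac",
    "cumulative_integral",
    "frame_weights",
]


class ScheduleError(ValueError):
    """Frame timing inconsistent with the image or internally invalid."""


class FormatError(ValueError):
    """Input file is not in the expected format (e.g. not 4D)."""


class EmptyRegionError(ValueError):
    """A mask/label selects no voxels."""


class ConfigError(ValueError):
    """Unknown option value."""


# ---------------------------------------------------------------------------
# Frame timing
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FrameSchedule:
    """Start times and durations (minutes) of the dynamic frames.

    Frames must be non-overlapping and in increasing order. Mid-frame
    times, at which all kinetic models are evaluated, are derived as
    ``start + duration / 2``.
    """

    start_times: np.ndarray
    durations: np.ndarray

    def __post_init__(self) -> None:
        st = np.asarray(self.start_times, dtype=float)
        du = np.asarray(self.durations, dtype=float)
        object.__setattr__(self, "start_times", st)
        object.__setattr__(self, "durations", du)
        if st.ndim != 1 or du.shape != st.shape or st.size == 0:
            raise ScheduleError("start_times and durations must be equal-length 1D arrays")
        if np.any(du <= 0):
            raise ScheduleError("frame durations must be positive")
        if np.any(np.diff(st) <= 0):
            raise ScheduleError("frame start times must be strictly increasing")
        if np.any(st[1:] < (st[:-1] + du[:-1]) - 1e-9):
            raise ScheduleError("frames overlap")

    @property
    def n_frames(self) -> int:
        return self.start_times.size

    @property
    def mid_times(self) -> np.ndarray:
        return self.start_times + self.durations / 2.0

    @property
    def end_times(self) -> np.ndarray:
        return self.start_times + self.durations

    @property
    def scan_end(self) -> float:
        return float(self.end_times[-1])

    # -- constructors -------------------------------------------------

    @classmethod
    def uniform(cls, n_frames: int, frame_minutes: float = 1.0, start: float = 0.0) -> "FrameSchedule":
        """Equal-duration frames, e.g. the default 75 x 1-min protocol."""
        starts = start + frame_minutes * np.arange(n_frames)
        return cls(starts, np.full(n_frames, float(frame_minutes)))

    @classmethod
    def from_csv(cls, path: str | Path) -> "FrameSchedule":
        """Two-column CSV with headers ``start_min,duration_min``."""
        df = pd.read_csv(path)
        if not {"start_min", "duration_min"} <= set(df.columns):
            raise FormatError(f"{path}: expected columns start_min,duration_min")
        return cls(df["start_min"].to_numpy(float), df["duration_min"].to_numpy(float))

    @classmethod
    def from_json(cls, path: str | Path) -> "FrameSchedule":
        """Sidecar JSON with ``start_min`` and ``duration_min`` lists."""
        with open(path) as fh:
            obj = json.load(fh)
        return cls(np.asarray(obj["start_min"], float), np.asarray(obj["duration_min"], float))

    def to_csv(self, path: str | Path) -> None:
        pd.DataFrame({"start_min": self.start_times, "duration_min": self.durations}).to_csv(
            path, index=False
        )


# ---------------------------------------------------------------------------
# Containers
# ---------------------------------------------------------------------------


@dataclass
class DynamicImage:
    """4D dynamic PET image: activity (kBq/mL) on a 3D grid x frames."""

    voxels: np.ndarray
    voxel_size: tuple[float, float, float]
    schedule: FrameSchedule
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 4:
            raise FormatError("DynamicImage requires a 4D array (x, y, z, frame)")
        if self.voxels.shape[3] != self.schedule.n_frames:
            raise ScheduleError(
                f"frame axis length {self.voxels.shape[3]} != schedule length {self.schedule.n_frames}"
            )
        if any(v <= 0 for v in self.voxel_size):
            raise ValueError("voxel_size must be positive")
        if not np.all(np.isfinite(self.voxels)):
            raise ValueError("activity values must be finite")
        if self.affine is None:
            self.affine = np.diag([*self.voxel_size, 1.0])

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape[:3]

    @property
    def n_frames(self) -> int:
        return self.voxels.shape[3]


@dataclass
class TAC:
    """A single time-activity curve sampled on a frame schedule."""

    values: np.ndarray
    schedule: FrameSchedule
    weights: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.schedule.n_frames,):
            raise ScheduleError("TAC length inconsistent with schedule")
        if self.weights is None:
            self.weights = np.ones_like(self.values)
        else:
            self.weights = np.asarray(self.weights, dtype=float)
            if self.weights.shape != self.values.shape:
                raise ScheduleError("weights length inconsistent with TAC")
            if np.any(self.weights < 0) or not np.any(self.weights > 0):
                raise ValueError("weights must be nonnegative and not all zero")

    @property
    def mid_times(self) -> np.ndarray:
        return self.schedule.mid_times


@dataclass
class Mask:
    """Integer label volume aligned with a DynamicImage grid."""

    labels: np.ndarray
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if self.labels.ndim != 3:
            raise FormatError("Mask requires a 3D label array")
        if np.any(self.labels < 0):
            raise ValueError("labels must be >= 0")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.labels.shape

    def indices(self, label: int | None = None) -> np.ndarray:
        """Lexicographically ordered (N, 3) voxel indices of a label (any nonzero if None)."""
        sel = self.labels > 0 if label is None else self.labels == label
        return np.argwhere(sel)


@dataclass
class ParametricMap:
    """Scalar statistic per voxel inside a mask; NaN outside."""

    values: np.ndarray
    statistic_name: str
    mask: Mask

    VALID = ("beta", "gamma", "F", "pOcc", "t", "p", "R1", "k2", "k2a", "BPND0")

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != self.mask.shape:
            raise FormatError("map shape must match mask shape")
        if self.statistic_name not in self.VALID:
            raise ConfigError(f"unknown statistic {self.statistic_name!r}")
        inside = self.mask.labels > 0
        if not np.all(np.isfinite(self.values[inside & np.isfinite(self.values)])):
            raise ValueError("non-finite values inside mask")

    def masked_values(self) -> np.ndarray:
        """Values at in-mask voxels in lexicographic voxel order."""
        idx = self.mask.indices()
        return self.values[idx[:, 0], idx[:, 1], idx[:, 2]]


# ---------------------------------------------------------------------------
# NIfTI I/O
# ---------------------------------------------------------------------------


def _resolve_schedule(timing, n_frames: int) -> FrameSchedule:
    if isinstance(timing, FrameSchedule):
        sched = timing
    else:
        p = Path(timing)
        sched = FrameSchedule.from_json(p) if p.suffix == ".json" else FrameSchedule.from_csv(p)
    if sched.n_frames != n_frames:
        raise ScheduleError(f"timing has {sched.n_frames} frames, image has {n_frames}")
    return sched


def load_dynamic_image(path: str | Path, timing) -> DynamicImage:
    """Load a 4D NIfTI volume plus frame timing (FrameSchedule, CSV or JSON path)."""
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj).astype(float)
    if data.ndim != 4:
        raise FormatError(f"{path}: expected 4D image, got {data.ndim}D")
    sched = _resolve_schedule(timing, data.shape[3])
    zooms = img.header.get_zooms()[:3]
    return DynamicImage(data, tuple(float(z) for z in zooms), sched, affine=img.affine)


def save_dynamic_image(image: DynamicImage, path: str | Path, timing_path: str | Path | None = None) -> None:
    """Write a DynamicImage to NIfTI (+ optional timing CSV sidecar)."""
    nii = nib.Nifti1Image(np.asarray(image.voxels), image.affine)
    nii.header.set_zooms((*image.voxel_size, 1.0))
    nib.save(nii, str(path))
    if timing_path is not None:
        image.schedule.to_csv(timing_path)


def load_mask(path: str | Path) -> Mask:
    img = nib.load(str(path))
    data = np.asanyarray(img.dataobj)
    if data.ndim != 3:
        raise FormatError(f"{path}: expected 3D mask, got {data.ndim}D")
    return Mask(np.rint(data).astype(int), affine=img.affine)


def save_map(pmap: ParametricMap, path: str | Path, affine: np.ndarray | None = None) -> None:
    aff = affine if affine is not None else (pmap.mask.affine if pmap.mask.affine is not None else np.eye(4))
    nib.save(nib.Nifti1Image(pmap.values.astype(np.float32), aff), str(path))


# ---------------------------------------------------------------------------
# TAC extraction
# ---------------------------------------------------------------------------


def extract_tacs(image: DynamicImage, mask: Mask, label: int) -> Iterator[tuple[tuple[int, int, int], TAC]]:
    """Yield (voxel index, TAC) for every voxel with the given label.

    Order is deterministic (lexicographic in the voxel index).
    """
    if mask.shape != image.shape:
        raise FormatError("mask not aligned with image")
    idx = mask.indices(label)
    if idx.shape[0] == 0:
        raise EmptyRegionError(f"label {label} selects no voxels")
    for i, j, k in idx:
        yield (int(i), int(j), int(k)), TAC(image.voxels[i, j, k, :], image.schedule)


def voxel_matrix(image: DynamicImage, mask: Mask, label: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """All in-mask voxel TACs as a (V, T) matrix plus their (V, 3) indices."""
    if mask.shape != image.shape:
        raise FormatError("mask not aligned with image")
    idx = mask.indices(label)
    if idx.shape[0] == 0:
        raise EmptyRegionError("mask selects no voxels")
    Y = image.voxels[idx[:, 0], idx[:, 1], idx[:, 2], :].astype(float)
    return Y, idx


def reference_tac(image: DynamicImage, mask: Mask, label: int | None = None) -> TAC:
    """Frame-wise mean TAC over a (reference region) mask."""
    Y, _ = voxel_matrix(image, mask, label)
    return TAC(Y.mean(axis=0), image.schedule)


# ---------------------------------------------------------------------------
# Numerics
# ---------------------------------------------------------------------------


def cumulative_integral_values(values: np.ndarray, mid_times: np.ndarray) -> np.ndarray:
    """Running integral of frame-sampled series (trapezoid on mid-times).

    A leading triangle from (0, 0) to the first mid-time accounts for the
    initial segment (zero activity at injection). Works on any array whose
    last axis is the frame axis. Exact for piecewise-linear inputs.
    """
    v = np.asarray(values, dtype=float)
    t = np.asarray(mid_times, dtype=float)
    out = np.empty_like(v)
    out[..., 0] = 0.5 * v[..., 0] * t[0]
    if v.shape[-1] > 1:
        seg = 0.5 * (v[..., 1:] + v[..., :-1]) * np.diff(t)
        out[..., 1:] = out[..., :1] + np.cumsum(seg, axis=-1)
    return out


def cumulative_integral(tac: TAC) -> np.ndarray:
    """Integral of a TAC from time 0 to each frame mid-time (kBq*min/mL)."""
    return cumulative_integral_values(tac.values, tac.mid_times)


def frame_weights(schedule: FrameSchedule, mode: str = "uniform") -> np.ndarray:
    """Per-frame WLS weights: all-ones, or proportional to frame duration.

    Duration weights are normalized to mean 1 so that weighted and
    unweighted residual sums are on the same scale.
    """
    if mode == "uniform":
        return np.ones(schedule.n_frames)
    if mode == "duration":
        w = schedule.durations / schedule.durations.mean()
        return w
    raise ConfigError(f"unknown weight mode {mode!r}")
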