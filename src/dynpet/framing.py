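"""Frame-timing model, dynamic-image container and NIfTI/JSON I/O.

A dynamic PET acquisition is a contiguous sequence of frames of varying
duration.  The lung protocol modelled throughout this package partitions a
65-minute chest acquisition into 28 frames (6 x 10 s, 4 x 30 s, 4 x 60 s,
4 x 120 s, 10 x 300 s).  Schedules are stored in seconds at the I/O
boundary; all kinetic mathematics runs in minutes (rate constants in
min^-1), so :class:`FrameSchedule` exposes minute-based views.

Images are assumed decay-corrected to injection time with voxel values in
kBq/ml, the standard output of clinical reconstruction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np

__all__ = [
    "FrameSchedule",
    "TimeActivityCurve",
    "DynamicImage",
    "build_frame_schedule",
    "DEFAULT_PROTOCOL",
    "load_dynamic",
    "save_dynamic",
    "combine_frames",
    "tac_to_csv",
]

#: 65-min chest protocol: 28 frames.
DEFAULT_PROTOCOL: tuple[tuple[int, float], ...] = (
    (6, 10.0),
    (4, 30.0),
    (4, 60.0),
    (4, 120.0),
    (10, 300.0),
)


class ValidationError(ValueError):
    """Raised when inputs violate a documented precondition."""


@dataclass(frozen=True)
class FrameSchedule:
    """Acquisition timing grid: per-frame start time and duration, seconds.

    Frames must be contiguous, non-overlapping and start at increasing
    times.  Minute-based views (``mid_min``, ``duration_min``) back the
    kinetic layer.
    """

    frame_start: np.ndarray
    frame_duration: np.ndarray

    def __post_init__(self) -> None:
        start = np.asarray(self.frame_start, dtype=float)
        dur = np.asarray(self.frame_duration, dtype=float)
        object.__setattr__(self, "frame_start", start)
        object.__setattr__(self, "frame_duration", dur)
        if start.ndim != 1 or dur.shape != start.shape or start.size == 0:
            raise ValidationError("frame_start/frame_duration must be equal-length 1D arrays")
        if np.any(dur <= 0):
            raise ValidationError("all frame durations must be > 0")
        if np.any(np.diff(start) <= 0):
            raise ValidationError("frame starts must be strictly increasing")
        if not np.allclose(start[1:], start[:-1] + dur[:-1], rtol=0, atol=1e-6):
            raise ValidationError("frames must be contiguous and non-overlapping")

    @property
    def n_frames(self) -> int:
        return int(self.frame_start.size)

    @property
    def total_duration(self) -> float:
        """Scan length in seconds."""
        return float(self.frame_start[-1] + self.frame_duration[-1])

    @property
    def frame_end(self) -> np.ndarray:
        return self.frame_start + self.frame_duration

    @property
    def mid_s(self) -> np.ndarray:
        return self.frame_start + self.frame_duration / 2.0

    # minute views used by the kinetics layer
    @property
    def start_min(self) -> np.ndarray:
        return self.frame_start / 60.0

    @property
    def end_min(self) -> np.ndarray:
        return self.frame_end / 60.0

    @property
    def mid_min(self) -> np.ndarray:
        return self.mid_s / 60.0

    @property
    def duration_min(self) -> np.ndarray:
        return self.frame_duration / 60.0


@dataclass
class TimeActivityCurve:
    """Per-frame activity concentration (kBq/ml) for a region or voxel.

    Negative values are permitted (reconstruction noise) but flagged via
    :attr:`has_negatives`.
    """

    schedule: FrameSchedule
    values: np.ndarray
    decay_corrected: bool = True

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.schedule.n_frames,):
            raise ValidationError(
                f"TAC length {self.values.size} != n_frames {self.schedule.n_frames}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValidationError("TAC values must be finite")

    @property
    def has_negatives(self) -> bool:
        return bool(np.any(self.values < 0))


@dataclass
class DynamicImage:
    """4D activity grid (x, y, z, frame) in kBq/ml with spatial metadata.

    ``meta`` may carry ``injected_dose_MBq`` and ``body_weight_kg``; SUV
    operations refuse to run when either is missing.
    """

    voxels: np.ndarray
    spacing: tuple[float, float, float]
    affine: np.ndarray
    schedule: FrameSchedule
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels, dtype=float)
        if self.voxels.ndim != 4:
            raise ValidationError("DynamicImage requires a 4D array (x,y,z,frame)")
        if self.voxels.shape[3] != self.schedule.n_frames:
            raise ValidationError(
                f"4th dimension {self.voxels.shape[3]} != n_frames {self.schedule.n_frames}"
            )
        if any(s <= 0 for s in self.spacing):
            raise ValidationError("voxel spacing must be positive on all axes")
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValidationError("affine must be 4x4")

    @property
    def shape3d(self) -> tuple[int, int, int]:
        return self.voxels.shape[:3]

    def voxel_tac(self, i: int, j: int, k: int) -> TimeActivityCurve:
        return TimeActivityCurve(self.schedule, self.voxels[i, j, k, :])


def build_frame_schedule(spec: Sequence[tuple[int, float]]) -> FrameSchedule:
    """Build a contiguous schedule from ``[(count, duration_s), ...]`` blocks.

    ``build_frame_schedule(DEFAULT_PROTOCOL)`` yields the 28-frame, 3900-s
    chest protocol.
    """
    if not spec:
        raise ValidationError("empty frame specification")
    durations: list[float] = []
    for count, dur in spec:
        if int(count) < 1:
            raise ValidationError(f"frame count must be >= 1, got {count}")
        if dur <= 0:
            raise ValidationError(f"frame duration must be > 0, got {dur}")
        durations.extend([float(dur)] * int(count))
    dur_arr = np.asarray(durations)
    starts = np.concatenate([[0.0], np.cumsum(dur_arr)[:-1]])
    return FrameSchedule(starts, dur_arr)


def save_dynamic(img: DynamicImage, image_path: str | Path, sidecar_path: str | Path) -> None:
    """Write a 4D NIfTI-1 volume plus a BIDS-PET style JSON timing sidecar."""
    nii = nib.Nifti1Image(img.voxels.astype(np.float32), img.affine)
    nii.header.set_zooms((*img.spacing, 1.0))
    nib.save(nii, str(image_path))
    sidecar = {
        "FrameTimesStart": img.schedule.frame_start.tolist(),
        "FrameDuration": img.schedule.frame_duration.tolist(),
    }
    for key in ("injected_dose_MBq", "body_weight_kg"):
        if key in img.meta:
            sidecar[key] = img.meta[key]
    Path(sidecar_path).write_text(json.dumps(sidecar, indent=1))


def load_dynamic(image_path: str | Path, sidecar_path: str | Path) -> DynamicImage:
    """Load a 4D NIfTI volume and its frame-timing sidecar.

    The sidecar must contain ``FrameTimesStart`` and ``FrameDuration``
    (seconds) matching the image's 4th dimension; dose/weight keys are
    optional and carried through to ``meta``.
    """
    nii = nib.load(str(image_path))
    data = np.asarray(nii.get_fdata(), dtype=float)
    if data.ndim != 4:
        raise ValidationError(f"expected 4D NIfTI, got {data.ndim}D")
    sidecar = json.loads(Path(sidecar_path).read_text())
    try:
        starts = np.asarray(sidecar["FrameTimesStart"], dtype=float)
        durs = np.asarray(sidecar["FrameDuration"], dtype=float)
    except KeyError as exc:
        raise ValidationError(f"sidecar missing required key: {exc}") from exc
    if starts.size != data.shape[3]:
        raise ValidationError(
            f"sidecar has {starts.size} frames but image has {data.shape[3]}"
        )
    schedule = FrameSchedule(starts, durs)  # validates contiguity/overlap
    zooms = nii.header.get_zooms()[:3]
    meta = {k: sidecar[k] for k in ("injected_dose_MBq", "body_weight_kg") if k in sidecar}
    return DynamicImage(
        voxels=data,
        spacing=tuple(float(z) for z in zooms),
        affine=np.asarray(nii.affine),
        schedule=schedule,
        meta=meta,
    )


def combine_frames(img: DynamicImage, window: tuple[float, float]) -> np.ndarray:
    """Duration-weighted mean of all frames fully inside ``window`` (seconds).

    The early composite used for aorta ROI placement is
    ``combine_frames(img, (0, 60))``: the mean of the six 10-s frames.
    """
    t0, t1 = float(window[0]), float(window[1])
    if t1 <= t0:
        raise ValidationError("window must satisfy t0 < t1")
    s = img.schedule
    inside = (s.frame_start >= t0 - 1e-9) & (s.frame_end <= t1 + 1e-9)
    if not np.any(inside):
        raise ValidationError(f"no complete frame inside window ({t0}, {t1}) s")
    w = s.frame_duration[inside]
    sub = img.voxels[..., inside]
    return np.tensordot(sub, w / w.sum(), axes=([3], [0]))


def tac_to_csv(tac: TimeActivityCurve, path: str | Path) -> None:
    """Export a TAC as CSV (frame_start_s, frame_duration_s, value_kBq_ml)."""
    import pandas as pd

    pd.DataFrame(
        {
            "frame_start_s": tac.schedule.frame_start,
            "frame_duration_s": tac.schedule.frame_duration,
            "value_kBq_ml": tac.values,
        }
    ).to_csv(path, index=False)
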