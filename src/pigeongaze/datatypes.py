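"""Core in-memory containers shared by the pipeline stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

HEAD_MARKERS = ("h1", "h2", "h3", "h4")
BACKPACK_MARKERS = ("b1", "b2", "b3", "b4")

CONDITIONS = ("test", "control")


class DataError(ValueError):
    """Raised for malformed or internally inconsistent input data."""


class CalibrationError(ValueError):
    """Raised for degenerate eye/beak/template calibration geometry."""


@dataclass
class BirdTracks:
    """Raw marker tracks for one bird: 4 head markers + backpack markers."""

    head: np.ndarray  # (n_frames, 4, 3) m, world frame; NaN where missing
    head_valid: np.ndarray  # (n_frames, 4) bool
    backpack: np.ndarray  # (n_frames, k, 3)
    backpack_valid: np.ndarray  # (n_frames, k)

    @property
    def n_frames(self) -> int:
        return self.head.shape[0]

    def backpack_centroid(self) -> np.ndarray:
        """Per-frame centroid of valid backpack markers; NaN when none valid."""
        pts = np.where(self.backpack_valid[..., None], self.backpack, np.nan)
        with np.errstate(invalid="ignore"):
            return np.nanmean(pts, axis=1)


@dataclass
class MarkerTimeSeries:
    """Per-frame 3D marker coordinates for a flock, with validity masks."""

    frame_rate: float
    birds: dict[str, BirdTracks]

    @property
    def n_frames(self) -> int:
        return next(iter(self.birds.values())).n_frames if self.birds else 0

    @property
    def bird_ids(self) -> list[str]:
        return list(self.birds)

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise DataError("frame_rate must be > 0")
        lengths = {b.n_frames for b in self.birds.values()}
        if len(lengths) > 1:
            raise DataError(f"birds have differing frame counts: {sorted(lengths)}")


@dataclass
class HeadCalibration:
    """Per-bird eye/beak positions and the 4-marker rigid template, all
    expressed in the head-marker rigid-body (template) frame.

    ``head_up`` is the head-up reference direction recorded at calibration:
    the unit vector normal to the eye axis closest to world-up in the
    calibration posture. It fixes the roll of the head frame so the frame is
    rig-independent.
    """

    left_eye: np.ndarray  # (3,) m
    right_eye: np.ndarray
    beak_tip: np.ndarray
    template: np.ndarray  # (4, 3) head-marker template
    head_up: np.ndarray | None = None

    def __post_init__(self) -> None:
        for name in ("left_eye", "right_eye", "beak_tip"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.template = np.asarray(self.template, dtype=float)
        if self.template.shape != (4, 3):
            raise CalibrationError("template must be 4 markers x 3 coordinates")
        eye_axis = self.right_eye - self.left_eye
        if np.linalg.norm(eye_axis) < 1e-9:
            raise CalibrationError("eyes coincide")
        mid = 0.5 * (self.left_eye + self.right_eye)
        beak_dir = self.beak_tip - mid
        nb = np.linalg.norm(beak_dir)
        if nb < 1e-9:
            raise CalibrationError("beak tip coincides with eye midpoint")
        cross = np.cross(eye_axis / np.linalg.norm(eye_axis), beak_dir / nb)
        if np.linalg.norm(cross) < 1e-6:
            raise CalibrationError("beak tip collinear with the eye axis")
        centered = self.template - self.template.mean(axis=0)
        if np.linalg.matrix_rank(centered, tol=1e-9) < 3:
            raise CalibrationError("marker template degenerate (rank < 3)")
        if self.head_up is not None:
            self.head_up = np.asarray(self.head_up, dtype=float)


@dataclass
class HeadPoseSeries:
    """Smoothed per-frame head pose for one bird.

    ``origin`` is the eye midpoint in world coordinates; ``rot`` maps
    head-local to world coordinates (columns = head X, Y, Z axes in world),
    orthonormal with determinant +1 on valid frames.
    """

    frame_rate: float
    origin: np.ndarray  # (n, 3)
    rot: np.ndarray  # (n, 3, 3), world <- head
    valid: np.ndarray  # (n,) bool

    @property
    def n_frames(self) -> int:
        return self.origin.shape[0]


@dataclass
class BehaviorMask:
    """Per-frame saccade/grooming flags for one bird (defined on valid-pose
    frames; False elsewhere)."""

    saccade: np.ndarray  # (n,) bool
    grooming: np.ndarray  # (n,) bool

    @property
    def excluded(self) -> np.ndarray:
        return self.saccade | self.grooming


@dataclass(frozen=True)
class LookBout:
    """A maximal >= fixation-minimum episode of one bird's gaze cone
    intersecting one ROI sphere. Frames are [start_frame, end_frame)
    half-open; duration is (end - start) / frame_rate."""

    bird: str
    roi: str
    cone: str  # cone label holding the majority of hit frames
    start_frame: int
    end_frame: int
    duration_ms: float

    def overlaps_frames(self, flags: np.ndarray) -> bool:
        return bool(flags[self.start_frame : self.end_frame].any())


SCHEDULE_COLUMNS = [
    "trial_id",
    "presentation_index",
    "condition",
    "presentation_location",
    "demonstrator_side",
    "start_frame",
    "end_frame",
    "experiment_id",
]


@dataclass
class PresentationSchedule:
    """Validated table of object presentations (one row each)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.table
        if len(df) == 0:
            raise DataError("schedule is empty")
        missing = [c for c in SCHEDULE_COLUMNS if c not in df.columns]
        if missing:
            raise DataError(f"schedule missing columns: {missing}")
        bad_cond = set(df["condition"]) - set(CONDITIONS)
        if bad_cond:
            raise DataError(f"unknown condition labels: {sorted(bad_cond)}")
        if (df["start_frame"] >= df["end_frame"]).any():
            raise DataError("schedule rows must satisfy start_frame < end_frame")
        if (df["presentation_index"] < 1).any():
            raise DataError("presentation_index must be >= 1")
        self.table = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.table)

    def __iter__(self):
        return (row for _, row in self.table.iterrows())


def bouts_to_frame(bouts: list[LookBout]) -> pd.DataFrame:
    cols = ["bird", "roi", "cone", "start_frame", "end_frame", "duration_ms"]
    if not bouts:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame([b.__dict__ for b in bouts])[cols]
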