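"""Scene configuration: geometry of the arena, gaze-cone definitions and
all detection thresholds.

Every constant of the analysis (cone azimuths, cone half-angle, ROI radius,
minimum fixation duration, saccade-speed threshold, smoothing parameters)
lives here so that nothing is hard-coded in the pipeline stages and every
threshold is visible and overridable from one structured file.

Units: meters for lengths, degrees for angles, Hz for rates, milliseconds
for durations. World frame is Z-up.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import yaml

FOVEA_AZIMUTH_DEG = 75.0  # lateral foveal projection, either side
DEFAULT_CONE_HALF_ANGLE_DEG = 10.0
DEFAULT_ROI_RADIUS_M = 0.25  # 50 cm diameter sphere around a window
DEFAULT_FIXATION_MIN_MS = 300.0
DEFAULT_SACCADE_THRESHOLD_DEG_S = 300.0


class ConfigError(ValueError):
    """Raised when a configuration file violates an invariant."""


@dataclass(frozen=True)
class GazeConeSpec:
    """One gaze cone in the head-local frame.

    Azimuth is measured from the forward (+Y) axis toward the bird's right
    (+X); elevation from the horizontal (XY) plane toward head-up (+Z).
    Negative azimuth therefore denotes the left fovea.
    """

    label: str  # left_fovea | right_fovea | binocular
    azimuth_deg: float
    elevation_deg: float
    half_angle_deg: float = DEFAULT_CONE_HALF_ANGLE_DEG

    def __post_init__(self) -> None:
        if not 0.0 < self.half_angle_deg < 90.0:
            raise ConfigError(
                f"cone {self.label!r}: half_angle must be in (0, 90), "
                f"got {self.half_angle_deg}"
            )

    @property
    def is_foveal(self) -> bool:
        return self.label.endswith("fovea")


def default_cone_specs(half_angle_deg: float = DEFAULT_CONE_HALF_ANGLE_DEG) -> list[GazeConeSpec]:
    """The three cones of the analysis: two lateral foveas and the frontal
    binocular field. The lower-frontal field deliberately has no cone."""
    return [
        GazeConeSpec("left_fovea", -FOVEA_AZIMUTH_DEG, 0.0, half_angle_deg),
        GazeConeSpec("right_fovea", +FOVEA_AZIMUTH_DEG, 0.0, half_angle_deg),
        GazeConeSpec("binocular", 0.0, 0.0, half_angle_deg),
    ]


@dataclass(frozen=True)
class RoiSphere:
    """Spherical region of interest around a stimulus window."""

    label: str  # presentation location, e.g. "top" / "bottom"
    center: tuple[float, float, float]
    radius_m: float = DEFAULT_ROI_RADIUS_M

    def __post_init__(self) -> None:
        if self.radius_m <= 0:
            raise ConfigError(f"ROI {self.label!r}: radius must be > 0")

    @property
    def center_arr(self) -> np.ndarray:
        return np.asarray(self.center, dtype=float)


@dataclass(frozen=True)
class TableRegion:
    """Axis-aligned box for one of the two pigeon tables (side A or B)."""

    label: str
    lo: tuple[float, float, float]
    hi: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not all(a < b for a, b in zip(self.lo, self.hi)):
            raise ConfigError(f"table {self.label!r}: lo must be < hi on every axis")

    def contains(self, points: np.ndarray) -> np.ndarray:
        """Vectorized membership test for an (..., 3) array of points."""
        p = np.asarray(points, dtype=float)
        lo = np.asarray(self.lo)
        hi = np.asarray(self.hi)
        return np.all((p >= lo) & (p <= hi), axis=-1)

    def overlaps(self, other: "TableRegion") -> bool:
        return all(
            a_lo < b_hi and b_lo < a_hi
            for a_lo, a_hi, b_lo, b_hi in zip(self.lo, self.hi, other.lo, other.hi)
        )


@dataclass
class SceneConfig:
    """Full scene + detection configuration for one experiment."""

    frame_rate: float
    roi_centers: dict[str, tuple[float, float, float]]
    roi_radius_m: float = DEFAULT_ROI_RADIUS_M
    table_regions: list[TableRegion] = field(default_factory=list)
    cone_specs: list[GazeConeSpec] = field(default_factory=default_cone_specs)
    saccade_threshold_deg_s: float = DEFAULT_SACCADE_THRESHOLD_DEG_S
    saccade_smooth_frames: int = 5  # median differentiator window for angular speed
    fixation_min_ms: float = DEFAULT_FIXATION_MIN_MS
    # smoothing
    max_gap_frames: int = 10
    lowpass_cutoff_hz: float = 10.0
    lowpass_order: int = 2
    # grooming heuristic (stand-in defaults; the original detector is a
    # companion-pipeline algorithm)
    grooming_pitch_threshold_deg: float = -45.0
    grooming_backpack_dist_m: float = 0.15
    grooming_min_ms: float = 300.0

    def __post_init__(self) -> None:
        if self.frame_rate <= 0:
            raise ConfigError("frame_rate must be > 0")
        if self.roi_radius_m <= 0:
            raise ConfigError("roi_radius must be > 0")
        if len(self.table_regions) != 2:
            raise ConfigError("exactly two table regions (sides A and B) required")
        if self.table_regions[0].overlaps(self.table_regions[1]):
            raise ConfigError("table regions must be disjoint")

    @property
    def fixation_min_frames(self) -> int:
        """Smallest number of frames a run must span to count as a fixation."""
        return int(np.ceil(self.fixation_min_ms * self.frame_rate / 1000.0))

    def rois(self) -> list[RoiSphere]:
        return [
            RoiSphere(label, tuple(center), self.roi_radius_m)
            for label, center in self.roi_centers.items()
        ]

    # ------------------------------------------------------------------ io

    def to_dict(self) -> dict:
        d = asdict(self)
        d["cone_specs"] = [asdict(c) for c in self.cone_specs]
        d["table_regions"] = [asdict(t) for t in self.table_regions]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SceneConfig":
        d = dict(d)
        d["cone_specs"] = [GazeConeSpec(**c) for c in d.get("cone_specs", [])] or default_cone_specs()
        d["table_regions"] = [
            TableRegion(t["label"], tuple(t["lo"]), tuple(t["hi"]))
            for t in d.get("table_regions", [])
        ]
        d["roi_centers"] = {k: tuple(v) for k, v in d["roi_centers"].items()}
        return cls(**d)

    def save(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def load(cls, path: str | Path) -> "SceneConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, dict):
            raise ConfigError(f"config file {path} is not a mapping")
        try:
            return cls.from_dict(d)
        except (KeyError, TypeError) as exc:
            raise ConfigError(f"invalid config file {path}: {exc}") from exc


def default_scene_config(frame_rate: float = 60.0) -> SceneConfig:
    """The synthetic arena: two parallel tables either side of the tube
    structure, top and bottom window ROIs at x = 0 between them."""
    return SceneConfig(
        frame_rate=frame_rate,
        roi_centers={"top": (0.0, 0.0, 1.7), "bottom": (0.0, 0.0, 0.35)},
        table_regions=[
            TableRegion("A", (-1.05, 0.8, 0.4), (1.05, 1.6, 1.3)),
            TableRegion("B", (-1.05, -1.6, 0.4), (1.05, -0.8, 1.3)),
        ],
    )
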