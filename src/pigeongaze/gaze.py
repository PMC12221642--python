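"""Gaze-cone reprojection, cone-sphere ROI intersection and bout ("look")
segmentation.

A bird's gaze is proxied by head orientation: each visual-field cone (left
fovea at -75 deg azimuth, right fovea at +75 deg, binocular field straight
ahead, all with a 10 deg half-angle by default) is carried into world
coordinates by the head pose. "Looking" at a region of interest is defined
as any cone crossing the ROI sphere; frame-wise hits are filtered by the
saccade and grooming masks, and maximal runs of at least the minimum
fixation duration (default 300 ms) become LookBouts.
"""

from __future__ import annotations

import numpy as np

from .config import GazeConeSpec, RoiSphere, SceneConfig
from .datatypes import BehaviorMask, HeadPoseSeries, LookBout


def head_direction(azimuth_deg: float, elevation_deg: float) -> np.ndarray:
    """Unit vector in the head frame at the given azimuth/elevation.

    Azimuth is measured from forward (+Y) toward the right (+X); elevation
    from the XY plane toward head-up (+Z).
    """
    az = np.deg2rad(azimuth_deg)
    el = np.deg2rad(elevation_deg)
    return np.array(
        [np.sin(az) * np.cos(el), np.cos(az) * np.cos(el), np.sin(el)]
    )


def cone_axis_world(pose_rot: np.ndarray, spec: GazeConeSpec) -> np.ndarray:
    """World-frame center-line direction(s) of a gaze cone.

    ``pose_rot`` may be a single (3, 3) rotation or a stack (n, 3, 3); the
    result has matching shape (3,) or (n, 3) and unit norm.
    """
    d = head_direction(spec.azimuth_deg, spec.elevation_deg)
    return np.asarray(pose_rot) @ d


def cone_hits_sphere(
    apex: np.ndarray, axis: np.ndarray, half_angle_deg: float, roi: RoiSphere
) -> bool | np.ndarray:
    """Whether a cone (apex, unit axis, half-angle) intersects an ROI sphere.

    True iff the apex lies inside the sphere, or the angle between the axis
    and the apex-to-center direction is at most
    ``half_angle + arcsin(min(1, radius / distance))`` — the half-angle
    subtended by the sphere widens the cone acceptance. Vectorized over
    leading dimensions of ``apex``/``axis``.
    """
    if not 0.0 < half_angle_deg < 90.0:
        raise ValueError("half_angle must be in (0, 90) degrees")
    apex = np.asarray(apex, dtype=float)
    axis = np.asarray(axis, dtype=float)
    to_center = roi.center_arr - apex
    dist = np.linalg.norm(to_center, axis=-1)
    inside = dist <= roi.radius_m
    with np.errstate(invalid="ignore", divide="ignore"):
        cosang = np.sum(axis * to_center, axis=-1) / np.where(dist > 0, dist, np.inf)
        offset = np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0)))
        widen = np.degrees(np.arcsin(np.minimum(1.0, roi.radius_m / np.where(dist > 0, dist, np.inf))))
    hit = inside | (offset <= half_angle_deg + widen)
    return bool(hit) if hit.ndim == 0 else hit


def cone_hit_frames(
    poses: HeadPoseSeries, spec: GazeConeSpec, roi: RoiSphere
) -> np.ndarray:
    """Per-frame hit mask of one cone against one ROI (False on invalid
    frames)."""
    hits = np.zeros(poses.n_frames, dtype=bool)
    v = poses.valid
    if not v.any():
        return hits
    axes = cone_axis_world(poses.rot[v], spec)
    hits[v] = cone_hits_sphere(poses.origin[v], axes, spec.half_angle_deg, roi)
    return hits


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    idx = np.flatnonzero(mask)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    stops = np.concatenate([idx[breaks] + 1, [idx[-1] + 1]])
    return list(zip(starts.tolist(), stops.tolist()))


def detect_looks(
    poses: dict[str, HeadPoseSeries],
    masks: dict[str, BehaviorMask],
    config: SceneConfig,
    windows: list[tuple[int, int]] | None = None,
    rois: list[RoiSphere] | None = None,
) -> list[LookBout]:
    """Segment filtered gaze-cone hits into LookBouts.

    Per bird and ROI the frame-wise hit is the OR over all cones, AND-ed
    with pose validity and NOT-saccade, NOT-grooming. Maximal runs at least
    ``fixation_min_ms`` long become one bout each — simultaneous hits by
    several cones are a single look, labeled with the cone holding the
    majority of hit frames (ties resolved in favor of a fovea). Saccade or
    grooming frames break runs outright. When presentation ``windows``
    (half-open frame ranges) are given, hits are evaluated within each
    window separately, clipping bouts to window boundaries.
    """
    rois = config.rois() if rois is None else rois
    min_frames = config.fixation_min_frames
    bouts: list[LookBout] = []
    for bird, pose in poses.items():
        mask = masks[bird]
        ok = pose.valid & ~mask.saccade & ~mask.grooming
        for roi in rois:
            per_cone = {
                spec.label: cone_hit_frames(pose, spec, roi) for spec in config.cone_specs
            }
            any_hit = np.logical_or.reduce(list(per_cone.values())) & ok
            frame_windows = windows if windows is not None else [(0, pose.n_frames)]
            for w0, w1 in frame_windows:
                clipped = np.zeros_like(any_hit)
                clipped[w0:w1] = any_hit[w0:w1]
                for s, e in _runs(clipped):
                    if e - s < min_frames:
                        continue
                    counts = {lbl: int(h[s:e].sum()) for lbl, h in per_cone.items()}
                    best = max(counts.values())
                    tied = [lbl for lbl, c in counts.items() if c == best]
                    label = next(
                        (lbl for lbl in tied if lbl.endswith("fovea")), tied[0]
                    )
                    bouts.append(
                        LookBout(
                            bird=bird,
                            roi=roi.label,
                            cone=label,
                            start_frame=int(s),
                            end_frame=int(e),
                            duration_ms=1000.0 * (e - s) / pose.frame_rate,
                        )
                    )
    return bouts


def classify_field_usage(bouts: list[LookBout]) -> dict[str, float] | None:
    """Fraction of bouts using foveal vs binocular vision.

    Returns ``{"foveal": f, "binocular": 1 - f}`` or None when there are no
    bouts (the proportion is undefined, reported as absent).
    """
    if not bouts:
        return None
    n_fov = sum(1 for b in bouts if b.cone.endswith("fovea"))
    f = n_fov / len(bouts)
    return {"foveal": f, "binocular": 1.0 - f}
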