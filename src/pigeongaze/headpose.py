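"""Head-pose reconstruction from rigid 4-marker sets.

Each frame's observed head markers are rigidly aligned to the per-bird
calibration template (Kabsch, proper rotation). The calibrated eye and beak
positions are carried into world coordinates by that transform and turned
into the head-local coordinate system: origin at the eye midpoint, forward
(+Y) axis pointing at the horizon, defined as 30 degrees above the
origin-to-beak-tip direction in elevation. X points toward the right eye,
Z = X x Y is head-up, right-handed — so negative azimuth is the bird's left.

The module also produces the per-frame behavior masks used to filter gaze
data: head-saccade frames (geodesic angular speed above threshold, because
avian visual processing is suppressed during rapid head rotations) and
grooming frames (head pitched far down and close to the bird's own back).
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import median_filter
from scipy.signal import butter, filtfilt
from scipy.spatial.transform import Rotation, Slerp

from .config import SceneConfig
from .datatypes import (
    BehaviorMask,
    BirdTracks,
    CalibrationError,
    HeadCalibration,
    HeadPoseSeries,
    MarkerTimeSeries,
)

HORIZON_ELEVATION_DEG = 30.0  # horizon sits 30 deg above the origin-beak line


def rigid_align(
    observed: np.ndarray, template: np.ndarray, valid: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, float] | None:
    """Least-squares rigid transform (Kabsch) mapping template -> observed.

    Parameters
    ----------
    observed, template : (k, 3) arrays of corresponding points.
    valid : optional (k,) bool mask of usable observed points.

    Returns ``(R, t, rmsd)`` with ``observed ~= template @ R.T + t`` and
    ``det(R) = +1`` (reflections are never returned), or ``None`` when fewer
    than 3 valid markers remain — the frame is simply unusable, not an error.
    """
    obs = np.asarray(observed, dtype=float)
    tpl = np.asarray(template, dtype=float)
    if valid is None:
        valid = np.all(np.isfinite(obs), axis=1)
    if valid.sum() < 3:
        return None
    obs = obs[valid]
    tpl = tpl[valid]
    mu_o = obs.mean(axis=0)
    mu_t = tpl.mean(axis=0)
    h = (tpl - mu_t).T @ (obs - mu_o)
    u, _, vt = np.linalg.svd(h)
    d = np.sign(np.linalg.det(vt.T @ u.T))
    rot = vt.T @ np.diag([1.0, 1.0, d]) @ u.T
    t = mu_o - rot @ mu_t
    resid = obs - (tpl @ rot.T + t)
    rmsd = float(np.sqrt(np.mean(np.sum(resid**2, axis=1))))
    return rot, t, rmsd


def build_head_frame(
    left_eye: np.ndarray,
    right_eye: np.ndarray,
    beak_tip: np.ndarray,
    head_up_hint: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Construct the head-local coordinate system from eye/beak positions.

    All inputs in one common frame; returns ``(origin, R)`` with R's columns
    the head X/Y/Z axes in that frame. Y is the origin-to-beak direction
    rotated up by 30 degrees elevation within the plane spanned by the beak
    direction and the head-up direction; consequently the beak direction has
    exactly -30 degrees elevation and 0 azimuth in the head frame. X points
    toward the right eye, Z = X x Y.

    ``head_up_hint`` resolves the roll: the head-up used is the unit vector
    normal to the beak direction closest to the hint (default: the component
    of world-up normal to the eye axis, the calibration-posture convention).
    """
    left_eye = np.asarray(left_eye, dtype=float)
    right_eye = np.asarray(right_eye, dtype=float)
    beak_tip = np.asarray(beak_tip, dtype=float)
    origin = 0.5 * (left_eye + right_eye)
    beak_dir = beak_tip - origin
    nb = np.linalg.norm(beak_dir)
    if nb < 1e-12:
        raise CalibrationError("beak tip coincides with the eye midpoint")
    b = beak_dir / nb
    eye_axis = right_eye - left_eye
    ne = np.linalg.norm(eye_axis)
    if ne < 1e-12:
        raise CalibrationError("eyes coincide")
    e = eye_axis / ne
    if head_up_hint is None:
        # component of world-up normal to the eye axis
        z = np.array([0.0, 0.0, 1.0])
        hint = z - (z @ e) * e
        if np.linalg.norm(hint) < 1e-9:
            raise CalibrationError("eye axis parallel to world-up; supply head_up_hint")
    else:
        hint = np.asarray(head_up_hint, dtype=float)
    w = hint - (hint @ b) * b
    nw = np.linalg.norm(w)
    if nw < 1e-9:
        raise CalibrationError("head-up direction collinear with beak direction")
    w = w / nw
    c = np.cos(np.deg2rad(HORIZON_ELEVATION_DEG))
    s = np.sin(np.deg2rad(HORIZON_ELEVATION_DEG))
    y_axis = c * b + s * w
    z_axis = c * w - s * b  # completes the (b, w) plane; beak elevation = -30 exactly
    x_axis = np.cross(y_axis, z_axis)
    rot = np.column_stack([x_axis, y_axis, z_axis])
    if x_axis @ e < 1e-6:
        raise CalibrationError(
            "degenerate geometry: eye axis has no rightward component in the "
            "constructed frame (beak collinear with the eye axis?)"
        )
    return origin, rot


def calibration_head_up(calib: HeadCalibration) -> np.ndarray:
    """Head-up reference in the template frame (recorded or the default
    world-up-normal-to-eye-axis convention evaluated in template coords)."""
    if calib.head_up is not None:
        return calib.head_up
    e = calib.right_eye - calib.left_eye
    e = e / np.linalg.norm(e)
    z = np.array([0.0, 0.0, 1.0])
    hint = z - (z @ e) * e
    if np.linalg.norm(hint) < 1e-9:
        raise CalibrationError("eye axis parallel to template-up; record head_up")
    return hint / np.linalg.norm(hint)


def reconstruct_poses(
    tracks: BirdTracks, calib: HeadCalibration, frame_rate: float
) -> HeadPoseSeries:
    """Per-frame head pose from raw marker tracks.

    Frames with fewer than 3 valid head markers are marked invalid. The
    alignment maps the calibration template onto the observed markers; eyes,
    beak and the recorded head-up direction ride along, and the head frame
    is rebuilt in world coordinates each frame.
    """
    n = tracks.n_frames
    origin = np.full((n, 3), np.nan)
    rot = np.full((n, 3, 3), np.nan)
    valid = np.zeros(n, dtype=bool)
    head_up_t = calibration_head_up(calib)
    for i in range(n):
        res = rigid_align(tracks.head[i], calib.template, tracks.head_valid[i])
        if res is None:
            continue
        r_wt, t_wt, _ = res
        le = r_wt @ calib.left_eye + t_wt
        re = r_wt @ calib.right_eye + t_wt
        bk = r_wt @ calib.beak_tip + t_wt
        hint = r_wt @ head_up_t
        origin[i], rot[i] = build_head_frame(le, re, bk, head_up_hint=hint)
        valid[i] = True
    return HeadPoseSeries(frame_rate=frame_rate, origin=origin, rot=rot, valid=valid)


def _valid_runs(valid: np.ndarray) -> list[tuple[int, int]]:
    """Half-open [start, stop) index ranges of consecutive True values."""
    idx = np.flatnonzero(valid)
    if idx.size == 0:
        return []
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[idx[0]], idx[breaks + 1]])
    stops = np.concatenate([idx[breaks] + 1, [idx[-1] + 1]])
    return list(zip(starts.tolist(), stops.tolist()))


def _interpolate_gaps(poses: HeadPoseSeries, max_gap: int) -> HeadPoseSeries:
    origin = poses.origin.copy()
    rot = poses.rot.copy()
    valid = poses.valid.copy()
    runs = _valid_runs(poses.valid)
    for (s0, e0), (s1, _) in zip(runs[:-1], runs[1:]):
        gap = s1 - e0
        if gap == 0 or gap > max_gap:
            continue
        t0, t1 = e0 - 1, s1
        frac = (np.arange(e0, s1) - t0) / (t1 - t0)
        origin[e0:s1] = (1 - frac)[:, None] * origin[t0] + frac[:, None] * origin[t1]
        slerp = Slerp([0.0, 1.0], Rotation.from_matrix(rot[[t0, t1]]))
        rot[e0:s1] = slerp(frac).as_matrix()
        valid[e0:s1] = True
    return HeadPoseSeries(poses.frame_rate, origin, rot, valid)


def smooth_poses(poses: HeadPoseSeries, config: SceneConfig) -> HeadPoseSeries:
    """Gap-fill and low-pass the pose series.

    Gaps up to ``max_gap_frames`` are interpolated (positions linearly,
    rotations by spherical interpolation); longer gaps stay invalid. A
    zero-phase Butterworth low-pass is then applied per contiguous valid run
    to positions and to orientations (via quaternion components with sign
    continuity, renormalized afterwards, which re-orthonormalizes the
    rotations).
    """
    poses = _interpolate_gaps(poses, config.max_gap_frames)
    nyq = poses.frame_rate / 2.0
    cutoff = config.lowpass_cutoff_hz
    if cutoff <= 0 or cutoff >= nyq:
        return poses
    b, a = butter(config.lowpass_order, cutoff / nyq)
    padlen = 3 * (max(len(a), len(b)) - 1)
    origin = poses.origin.copy()
    rot = poses.rot.copy()
    for s, e in _valid_runs(poses.valid):
        if e - s <= padlen + 1:
            continue  # run too short to filter; keep raw
        origin[s:e] = filtfilt(b, a, poses.origin[s:e], axis=0)
        quat = Rotation.from_matrix(poses.rot[s:e]).as_quat()
        flips = np.cumsum(np.sum(quat[1:] * quat[:-1], axis=1) < 0) % 2
        quat[1:][flips == 1] *= -1
        quat = filtfilt(b, a, quat, axis=0)
        quat /= np.linalg.norm(quat, axis=1, keepdims=True)
        rot[s:e] = Rotation.from_quat(quat).as_matrix()
    return HeadPoseSeries(poses.frame_rate, origin, rot, poses.valid.copy())


def median_orientation(poses: HeadPoseSeries, window: int = 5) -> HeadPoseSeries:
    """Running median of the orientation track (per valid run, componentwise
    on sign-continuous quaternions, renormalized).

    This is the differentiator pre-filter for angular-speed estimation: a
    median suppresses frame-to-frame marker-noise jitter without smearing a
    genuine orientation step across neighboring frames the way a linear
    low-pass does, so the saccade detector flags a tight interval around the
    true jump.
    """
    if window <= 1:
        return poses
    rot = poses.rot.copy()
    for s, e in _valid_runs(poses.valid):
        if e - s < 2:
            continue
        quat = Rotation.from_matrix(poses.rot[s:e]).as_quat()
        flips = np.cumsum(np.sum(quat[1:] * quat[:-1], axis=1) < 0) % 2
        quat[1:][flips == 1] *= -1
        med = median_filter(quat, size=(window, 1), mode="nearest")
        med /= np.linalg.norm(med, axis=1, keepdims=True)
        rot[s:e] = Rotation.from_quat(med).as_matrix()
    return HeadPoseSeries(poses.frame_rate, poses.origin.copy(), rot, poses.valid.copy())


def angular_speed(poses: HeadPoseSeries) -> np.ndarray:
    """Geodesic angular speed (deg/s) at each frame relative to the previous
    valid frame; NaN on invalid frames and on the first frame of each run."""
    n = poses.n_frames
    speed = np.full(n, np.nan)
    for s, e in _valid_runs(poses.valid):
        if e - s < 2:
            continue
        rel = Rotation.from_matrix(poses.rot[s : e - 1]).inv() * Rotation.from_matrix(
            poses.rot[s + 1 : e]
        )
        ang = np.rad2deg(rel.magnitude())
        speed[s + 1 : e] = ang * poses.frame_rate
    return speed


def detect_saccades(poses: HeadPoseSeries, threshold_deg_s: float) -> np.ndarray:
    """Flag frames whose angular speed from the previous valid pose exceeds
    the threshold. The first frame of each valid run is never flagged."""
    if threshold_deg_s <= 0:
        raise ValueError("saccade threshold must be > 0")
    speed = angular_speed(poses)
    with np.errstate(invalid="ignore"):
        return np.nan_to_num(speed, nan=0.0) > threshold_deg_s


def head_pitch_deg(poses: HeadPoseSeries) -> np.ndarray:
    """Elevation of the forward (Y) axis above the world horizontal, deg."""
    fwd_z = poses.rot[:, 2, 1]  # world-Z component of head-Y column
    return np.rad2deg(np.arcsin(np.clip(fwd_z, -1.0, 1.0)))


def detect_grooming(
    poses: HeadPoseSeries,
    backpack_centroid: np.ndarray,
    config: SceneConfig,
    external_mask: np.ndarray | None = None,
) -> np.ndarray:
    """Grooming mask for one bird.

    Reference heuristic: a frame is grooming when the head pitch is below
    ``grooming_pitch_threshold_deg`` AND the eye midpoint sits within
    ``grooming_backpack_dist_m`` of the backpack centroid, sustained for at
    least ``grooming_min_ms``. An externally supplied mask (e.g. from a
    dedicated detector) is passed through verbatim instead.
    """
    if external_mask is not None:
        mask = np.asarray(external_mask, dtype=bool)
        if mask.shape[0] != poses.n_frames:
            raise ValueError("external grooming mask length mismatch")
        return mask & poses.valid
    pitch = head_pitch_deg(poses)
    with np.errstate(invalid="ignore"):
        dist = np.linalg.norm(poses.origin - backpack_centroid, axis=1)
        raw = (
            poses.valid
            & (pitch < config.grooming_pitch_threshold_deg)
            & (dist < config.grooming_backpack_dist_m)
        )
    min_frames = int(np.ceil(config.grooming_min_ms * poses.frame_rate / 1000.0))
    mask = np.zeros_like(raw)
    for s, e in _valid_runs(raw):
        if e - s >= min_frames:
            mask[s:e] = True
    return mask


def compute_masks(
    poses: HeadPoseSeries,
    tracks: BirdTracks,
    config: SceneConfig,
    grooming_mask: np.ndarray | None = None,
    saccade_poses: HeadPoseSeries | None = None,
) -> BehaviorMask:
    """Saccade + grooming masks for one bird (masks are subsets of
    valid-pose frames by construction).

    ``saccade_poses`` lets the saccade detector run on an unsmoothed pose
    series: the zero-phase low-pass smears a rapid rotation across
    neighboring frames, so detecting on the raw (gap-filled) series keeps
    the flagged interval tight around the true jump.
    """
    sp = poses if saccade_poses is None else saccade_poses
    sacc = detect_saccades(sp, config.saccade_threshold_deg_s) & poses.valid
    groom = detect_grooming(
        poses, tracks.backpack_centroid(), config, external_mask=grooming_mask
    )
    return BehaviorMask(saccade=sacc, grooming=groom & poses.valid)


def process_bird(
    tracks: BirdTracks,
    calib: HeadCalibration,
    config: SceneConfig,
    frame_rate: float,
    grooming_mask: np.ndarray | None = None,
) -> tuple[HeadPoseSeries, BehaviorMask]:
    """Full per-bird pose stage: reconstruct, gap-fill, smooth, mask.

    Saccades are detected on the gap-filled but unsmoothed series; the
    smoothed series is what gaze projection uses.
    """
    raw = reconstruct_poses(tracks, calib, frame_rate)
    raw = _interpolate_gaps(raw, config.max_gap_frames)
    smoothed = smooth_poses(raw, config)
    mask = compute_masks(
        smoothed,
        tracks,
        config,
        grooming_mask=grooming_mask,
        saccade_poses=median_orientation(raw, config.saccade_smooth_frames),
    )
    return smoothed, mask


def reconstruct_flock(
    markers: MarkerTimeSeries,
    calibrations: dict[str, HeadCalibration],
    config: SceneConfig,
    smooth: bool = True,
) -> dict[str, HeadPoseSeries]:
    """Reconstruct (and optionally smooth) head poses for every bird."""
    poses: dict[str, HeadPoseSeries] = {}
    for bird, tracks in markers.birds.items():
        if bird not in calibrations:
            raise CalibrationError(f"no calibration for bird {bird!r}")
        p = reconstruct_poses(tracks, calibrations[bird], markers.frame_rate)
        poses[bird] = smooth_poses(p, config) if smooth else p
    return poses
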