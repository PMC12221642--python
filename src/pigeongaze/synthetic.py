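"""Synthetic flock scenarios and response tables with known ground truth.

Two generators make every pipeline stage testable without recorded data:

* ``generate_flock_trajectories`` emits raw marker-level motion-capture data
  for a flock of rigid 4-marker heads standing on the two tables. Head
  orientation follows avian head-saccade dynamics: piecewise-constant
  fixations separated by instantaneous saccade jumps. Scheduled LookEvents
  aim a designated gaze cone's center line exactly at an ROI center;
  wandering fixations keep every cone at least 30 degrees away from every
  ROI direction so no spurious look can arise. Grooming bouts pitch the head
  steeply down next to the backpack. Marker noise and dropout are applied
  last. The emitted ground truth (events, grooming, saccade boundaries,
  table sides, schedule) is what the recovery tests compare against.

* ``generate_response_table`` is the statistical twin of the presentation
  tables: binary looks ~ Bernoulli(logit^-1(eta)) and look counts ~
  Poisson(exp(eta)) with eta = intercept + beta_cond * condition +
  beta_dem * z(count) [+ beta_dem2 * z(count)^2] + per-individual random
  intercepts and slopes, at stated effect sizes.

All randomness flows from a single seed through named child generators, so
identical seeds give byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import SceneConfig, default_scene_config
from .datatypes import (
    BirdTracks,
    HeadCalibration,
    MarkerTimeSeries,
    PresentationSchedule,
)
from .gaze import head_direction

HEAD_HEIGHT_M = 0.25  # eye midpoint above the table surface when standing
GROOM_PITCH_DEG = -60.0
GROOM_HEAD_OFFSET = np.array([0.0, 0.05, 0.07])  # head drops toward the back
BACKPACK_OFFSET = np.array([0.0, 0.0, 0.02])
WANDER_MARGIN_DEG = 30.0  # wandering cones stay this far from all ROIs
MIN_SACCADE_JUMP_DEG = 25.0  # consecutive fixations differ at least this much
FOVEAL_EVENT_FRACTION = 0.92  # share of scheduled looks using a fovea


def default_calibration() -> HeadCalibration:
    """Eye/beak/template geometry of a pigeon-sized head, expressed directly
    in the head frame (eye midpoint at the origin, forward = +Y): the
    template-to-head transform is then the identity, which makes the
    generator's poses exactly recoverable."""
    return HeadCalibration(
        left_eye=np.array([-0.010, 0.0, 0.0]),
        right_eye=np.array([0.010, 0.0, 0.0]),
        beak_tip=0.02 * np.array([0.0, np.cos(np.deg2rad(30.0)), -np.sin(np.deg2rad(30.0))]),
        template=np.array(
            [
                [0.015, 0.010, 0.022],
                [-0.015, 0.010, 0.020],
                [0.013, -0.014, 0.012],
                [-0.011, -0.013, 0.030],
            ]
        ),
        head_up=np.array([0.0, 0.0, 1.0]),
    )


@dataclass(frozen=True)
class LookEvent:
    """Ground-truth scheduled gaze event."""

    bird: str
    roi: str
    cone: str
    start_frame: int
    end_frame: int

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


@dataclass(frozen=True)
class GroomBout:
    bird: str
    start_frame: int
    end_frame: int


@dataclass
class SyntheticScenario:
    """Everything that defines one simulated session."""

    n_birds: int
    schedule: PresentationSchedule
    sides: dict[tuple, dict[str, str]]  # (trial, pres) -> bird -> side label
    look_events: list[LookEvent]
    groom_bouts: list[GroomBout]
    switchers: list[tuple[str, object, int]] = field(default_factory=list)
    flyoffs: list[tuple[str, object, int]] = field(default_factory=list)
    marker_noise_sd: float = 0.0005  # m, per coordinate
    dropout_prob: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.marker_noise_sd < 0:
            raise ValueError("marker noise sd must be >= 0")
        if not 0.0 <= self.dropout_prob <= 1.0:
            raise ValueError("dropout probability must be in [0, 1]")
        windows = {
            (p["trial_id"], p["presentation_index"]): (
                int(p["start_frame"]),
                int(p["end_frame"]),
            )
            for p in self.schedule
        }
        for ev in self.look_events:
            if not any(lo <= ev.start_frame and ev.end_frame <= hi for lo, hi in windows.values()):
                raise ValueError(f"look event {ev} lies outside every presentation window")

    @property
    def bird_ids(self) -> list[str]:
        return [f"p{i:02d}" for i in range(self.n_birds)]

    @property
    def n_frames(self) -> int:
        return int(self.schedule.table["end_frame"].max()) + 30


# ----------------------------------------------------------- orientation


def orientation_for_direction(
    head_dir: np.ndarray, world_dir: np.ndarray, up: np.ndarray | None = None
) -> np.ndarray:
    """Rotation R with R @ head_dir = world_dir, roll chosen so the head-up
    (+Z) axis stays as close to world-up as the constraint allows."""
    d = np.asarray(head_dir, dtype=float)
    d = d / np.linalg.norm(d)
    u = np.asarray(world_dir, dtype=float)
    u = u / np.linalg.norm(u)
    up = np.array([0.0, 0.0, 1.0]) if up is None else np.asarray(up, dtype=float)
    axis = np.cross(d, u)
    na = np.linalg.norm(axis)
    c = float(np.clip(d @ u, -1.0, 1.0))
    if na < 1e-12:
        r0 = np.eye(3) if c > 0 else _rotation_about(_any_perp(d), np.pi)
    else:
        r0 = _rotation_about(axis / na, np.arccos(c))
    v = r0 @ np.array([0.0, 0.0, 1.0])
    v_par = (v @ u) * u
    v_perp = v - v_par
    if np.linalg.norm(v_perp) < 1e-12:
        return r0
    phi = np.arctan2(up @ np.cross(u, v_perp), up @ v_perp)
    return _rotation_about(u, phi) @ r0


def _rotation_about(axis: np.ndarray, angle: float) -> np.ndarray:
    axis = np.asarray(axis, dtype=float)
    x, y, z = axis
    k = np.array([[0, -z, y], [z, 0, -x], [-y, x, 0]])
    return np.eye(3) + np.sin(angle) * k + (1 - np.cos(angle)) * (k @ k)


def _any_perp(v: np.ndarray) -> np.ndarray:
    w = np.array([1.0, 0.0, 0.0]) if abs(v[0]) < 0.9 else np.array([0.0, 1.0, 0.0])
    p = np.cross(v, w)
    return p / np.linalg.norm(p)


def _geodesic_deg(r1: np.ndarray, r2: np.ndarray) -> float:
    c = (np.trace(r1.T @ r2) - 1.0) / 2.0
    return float(np.degrees(np.arccos(np.clip(c, -1.0, 1.0))))


# ------------------------------------------------------ schedule builders


def make_schedule(
    pattern: str,
    window_frames: int,
    gap_frames: int,
    trial_id: object = 1,
    experiment_id: int = 3,
    start_frame: int = 30,
    locations: list[str] | None = None,
    demonstrator_side: str = "A",
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Schedule rows for one trial from a T/C pattern string such as
    "TCCTTCTC" (separators like '-' are ignored). Presentation locations
    alternate top/bottom unless given or randomized via ``rng``."""
    pattern = pattern.replace("-", "").upper()
    rows = []
    frame = start_frame
    for i, ch in enumerate(pattern):
        if ch not in "TC":
            raise ValueError(f"bad pattern character {ch!r}")
        if locations is not None:
            loc = locations[i]
        elif rng is not None:
            loc = rng.choice(["top", "bottom"])
        else:
            loc = "top" if i % 2 == 0 else "bottom"
        rows.append(
            {
                "trial_id": trial_id,
                "presentation_index": i + 1,
                "condition": "test" if ch == "T" else "control",
                "presentation_location": loc,
                "demonstrator_side": demonstrator_side,
                "start_frame": frame,
                "end_frame": frame + window_frames,
                "experiment_id": experiment_id,
            }
        )
        frame += window_frames + gap_frames
    return pd.DataFrame(rows)


# ------------------------------------------------------- random scenario


def random_scenario(
    config: SceneConfig | None = None,
    n_birds: int = 10,
    pattern: str = "TCCTTCTC",
    window_s: float = 8.0,
    gap_s: float = 2.0,
    events_per_demonstrator: tuple[int, int] = (0, 2),
    events_per_observer: tuple[int, int] = (0, 2),
    event_ms: tuple[float, float] = (360.0, 1000.0),
    n_sub_threshold: int = 0,
    sub_threshold_ms: float = 200.0,
    groom_prob: float = 0.25,
    seed: int = 0,
    marker_noise_sd: float = 0.0005,
    dropout_prob: float = 0.01,
) -> SyntheticScenario:
    """A randomized but fully ground-truthed session.

    Birds are shuffled between table sides at each presentation.
    Demonstrator-side birds schedule looks at the target ROI; observer-side
    birds schedule looks at target or distractor. Event counts per bird are
    uniform in the given ranges; durations uniform in ``event_ms``. Cone
    labels follow the foveal/binocular usage split (92% / 8%).
    ``n_sub_threshold`` adds deliberately too-short events (recorded as
    sub-threshold ground truth that must yield no bout).
    """
    config = default_scene_config() if config is None else config
    rng = np.random.default_rng(np.random.SeedSequence([seed, 101]))
    fr = config.frame_rate
    sched = make_schedule(
        pattern,
        window_frames=int(round(window_s * fr)),
        gap_frames=int(round(gap_s * fr)),
        rng=rng,
    )
    schedule = PresentationSchedule(sched)
    birds = [f"p{i:02d}" for i in range(n_birds)]
    roi_labels = list(config.roi_centers)
    sides: dict[tuple, dict[str, str]] = {}
    events: list[LookEvent] = []
    grooms: list[GroomBout] = []
    occupied: dict[str, list[tuple[int, int]]] = {b: [] for b in birds}

    def place(bird: str, lo: int, hi: int, n_fr: int) -> tuple[int, int] | None:
        for _ in range(40):
            if hi - lo <= n_fr + 4:
                return None
            s = int(rng.integers(lo + 2, hi - n_fr - 2))
            e = s + n_fr
            if all(e + 2 <= s0 or s >= e0 + 2 for s0, e0 in occupied[bird]):
                occupied[bird].append((s, e))
                return s, e
        return None

    def pick_cone() -> str:
        if rng.random() < FOVEAL_EVENT_FRACTION:
            return rng.choice(["left_fovea", "right_fovea"])
        return "binocular"

    sub_left = n_sub_threshold
    for pres in schedule:
        key = (pres["trial_id"], pres["presentation_index"])
        lo, hi = int(pres["start_frame"]), int(pres["end_frame"])
        target = pres["presentation_location"]
        demo_side = pres["demonstrator_side"]
        max_demo = n_birds - 1  # always leave at least one observer
        n_demo = (
            int(rng.integers(min(2, max_demo - 1), max_demo)) if max_demo > 1 else 1
        )
        shuffled = list(rng.permutation(birds))
        assignment = {
            b: (demo_side if i < n_demo else ("B" if demo_side == "A" else "A"))
            for i, b in enumerate(shuffled)
        }
        sides[key] = assignment
        for b in birds:
            is_demo = assignment[b] == demo_side
            n_lo, n_hi = events_per_demonstrator if is_demo else events_per_observer
            n_ev = int(rng.integers(n_lo, n_hi + 1))
            for _ in range(n_ev):
                if is_demo and pres["condition"] != "test":
                    continue  # control: no window, demonstrators see nothing
                roi = target if is_demo else str(rng.choice(roi_labels))
                dur = float(rng.uniform(*event_ms))
                n_fr = max(2, int(round(dur * fr / 1000.0)))
                spot = place(b, lo, hi, n_fr)
                if spot is None:
                    continue
                events.append(LookEvent(b, roi, pick_cone(), spot[0], spot[1]))
            if sub_left > 0 and rng.random() < 0.3:
                n_fr = max(2, int(round(sub_threshold_ms * fr / 1000.0)))
                spot = place(b, lo, hi, n_fr)
                if spot is not None:
                    roi = target if is_demo else str(rng.choice(roi_labels))
                    events.append(LookEvent(b, roi, pick_cone(), spot[0], spot[1]))
                    sub_left -= 1
            if rng.random() < groom_prob:
                n_fr = int(round(rng.uniform(500, 1200) * fr / 1000.0))
                spot = place(b, lo, hi, n_fr)
                if spot is not None:
                    grooms.append(GroomBout(b, spot[0], spot[1]))
    return SyntheticScenario(
        n_birds=n_birds,
        schedule=schedule,
        sides=sides,
        look_events=events,
        groom_bouts=grooms,
        marker_noise_sd=marker_noise_sd,
        dropout_prob=dropout_prob,
        seed=seed,
    )


# ------------------------------------------------- trajectory generation


@dataclass
class GroundTruth:
    """Tables emitted alongside the generated markers."""

    events: pd.DataFrame  # bird, roi, cone, start/end_frame, sub_threshold
    grooming: pd.DataFrame  # bird, start_frame, end_frame
    saccade_frames: dict[str, np.ndarray]
    sides: dict[tuple, dict[str, str]]
    schedule: PresentationSchedule


def _table_spot(region, rng: np.random.Generator) -> np.ndarray:
    lo = np.asarray(region.lo)
    hi = np.asarray(region.hi)
    margin = 0.08
    spot = rng.uniform(lo + margin, hi - margin)
    spot[2] = lo[2] + 0.35  # standing height of the body above the table floor box
    return spot


def _wander_rotation(
    origin: np.ndarray,
    config: SceneConfig,
    rng: np.random.Generator,
    prev_rot: np.ndarray | None,
) -> np.ndarray:
    """Random fixation orientation with every cone >= WANDER_MARGIN_DEG away
    from every ROI direction and a supra-threshold jump from the previous
    fixation."""
    roi_dirs = []
    for roi in config.rois():
        v = roi.center_arr - origin
        roi_dirs.append(v / np.linalg.norm(v))
    cone_dirs = [
        head_direction(s.azimuth_deg, s.elevation_deg) for s in config.cone_specs
    ]
    cos_margin = np.cos(np.deg2rad(WANDER_MARGIN_DEG))
    for _ in range(200):
        yaw = rng.uniform(0, 2 * np.pi)
        pitch = np.deg2rad(np.clip(rng.normal(0, 15), -40, 40))
        fwd = np.array(
            [np.sin(yaw) * np.cos(pitch), np.cos(yaw) * np.cos(pitch), np.sin(pitch)]
        )
        rot = orientation_for_direction(np.array([0.0, 1.0, 0.0]), fwd)
        ok = all(
            (rot @ d) @ rd < cos_margin for d in cone_dirs for rd in roi_dirs
        )
        if ok and prev_rot is not None:
            ok = _geodesic_deg(rot, prev_rot) >= MIN_SACCADE_JUMP_DEG
        if ok:
            return rot
    raise RuntimeError("could not sample a wandering orientation; check scene geometry")


def _event_rotation(
    spec, world_dir: np.ndarray, origin: np.ndarray, target_roi: str, config: SceneConfig
) -> np.ndarray:
    """Orientation for a scheduled look: the designated cone's center line
    points exactly along ``world_dir``; the free roll about that line is
    chosen to keep head-up near world-up while no *other* cone/ROI pair
    comes within its acceptance angle (otherwise the pipeline would — by
    construction correctly — report an unscheduled second look)."""
    d = head_direction(spec.azimuth_deg, spec.elevation_deg)
    u = np.asarray(world_dir, dtype=float)
    u = u / np.linalg.norm(u)
    base = orientation_for_direction(d, u)
    others = []
    for roi in config.rois():
        v = roi.center_arr - origin
        dist = np.linalg.norm(v)
        accept = np.deg2rad(5.0) + np.arcsin(min(1.0, roi.radius_m / dist))
        for cs in config.cone_specs:
            if roi.label == target_roi and cs.label == spec.label:
                continue
            others.append(
                (
                    head_direction(cs.azimuth_deg, cs.elevation_deg),
                    v / dist,
                    np.cos(np.deg2rad(cs.half_angle_deg) + accept),
                )
            )
    best = None
    for phi in np.deg2rad(np.arange(0.0, 360.0, 3.0)):
        rot = _rotation_about(u, phi) @ base
        if all((rot @ cd) @ rd < cos_lim for cd, rd, cos_lim in others):
            upness = (rot @ np.array([0.0, 0.0, 1.0]))[2]
            if best is None or upness > best[0]:
                best = (upness, rot)
    if best is None:
        return base  # no clear roll exists from this vantage; accept overlap
    return best[1]


def generate_flock_trajectories(
    scenario: SyntheticScenario,
    calib: HeadCalibration | None = None,
    config: SceneConfig | None = None,
) -> tuple[MarkerTimeSeries, GroundTruth]:
    """Emit marker-level data plus ground truth for a scenario.

    During each LookEvent the designated cone's center line, as recovered by
    the head-pose and gaze stages from the emitted markers, passes through
    the ROI center exactly (up to marker noise). Events shorter than the
    fixation minimum are recorded with a sub-threshold flag.
    """
    config = default_scene_config() if config is None else config
    calib = default_calibration() if calib is None else calib
    n = scenario.n_frames
    fr = config.frame_rate
    root = np.random.SeedSequence([scenario.seed, 7])
    regions = {r.label: r for r in config.table_regions}
    rois = {r.label: r for r in config.rois()}
    windows = {
        (p["trial_id"], p["presentation_index"]): (int(p["start_frame"]), int(p["end_frame"]))
        for p in scenario.schedule
    }
    birds_out: dict[str, BirdTracks] = {}
    sacc_truth: dict[str, np.ndarray] = {}
    ev_by_bird: dict[str, list[LookEvent]] = {}
    for ev in scenario.look_events:
        ev_by_bird.setdefault(ev.bird, []).append(ev)
    gr_by_bird: dict[str, list[GroomBout]] = {}
    for g in scenario.groom_bouts:
        gr_by_bird.setdefault(g.bird, []).append(g)

    for bi, bird in enumerate(scenario.bird_ids):
        rng = np.random.default_rng(np.random.SeedSequence([scenario.seed, 7, bi]))
        body = np.zeros((n, 3))
        # piecewise-constant body position: one spot per presentation window,
        # held through the following gap
        spot = None
        cursor = 0
        for key, (lo, hi) in sorted(windows.items(), key=lambda kv: kv[1][0]):
            side = scenario.sides[key].get(bird)
            new_spot = _table_spot(regions[side], rng) if side else (
                spot if spot is not None else _table_spot(regions["A"], rng)
            )
            if spot is None:
                spot = new_spot
            body[cursor:lo] = spot
            seg = np.tile(new_spot, (hi - lo, 1))
            # scripted departures happen past the window midpoint so the
            # median position (hence the reported side) stays the start side
            if (bird, key[0], key[1]) in scenario.switchers:
                other = [r for r in regions.values() if r.label != side][0]
                dest = _table_spot(other, rng)
                cut = (6 * (hi - lo)) // 10
                seg[cut:] = dest
                new_spot = dest
            if (bird, key[0], key[1]) in scenario.flyoffs:
                away = np.array([0.0, 0.0, 2.5])  # above the arena, off both tables
                cut = (6 * (hi - lo)) // 10
                seg[cut:] = away
                new_spot = away
            body[lo:hi] = seg
            spot = new_spot
            cursor = hi
        body[cursor:] = spot

        origin = body + np.array([0.0, 0.0, HEAD_HEIGHT_M])
        rot = np.empty((n, 3, 3))
        # segment plan: look events and grooming override wandering
        seg_rot: dict[int, np.ndarray] = {}
        for g in gr_by_bird.get(bird, []):
            origin[g.start_frame : g.end_frame] = (
                body[g.start_frame : g.end_frame] + GROOM_HEAD_OFFSET
            )
            yaw = rng.uniform(0, 2 * np.pi)
            d = np.array(
                [
                    np.sin(yaw) * np.cos(np.deg2rad(GROOM_PITCH_DEG)),
                    np.cos(yaw) * np.cos(np.deg2rad(GROOM_PITCH_DEG)),
                    np.sin(np.deg2rad(GROOM_PITCH_DEG)),
                ]
            )
            seg_rot[g.start_frame] = orientation_for_direction(
                np.array([0.0, 1.0, 0.0]), d
            )
        cone_by_label = {s.label: s for s in config.cone_specs}
        for ev in ev_by_bird.get(bird, []):
            spec = cone_by_label[ev.cone]
            u = rois[ev.roi].center_arr - origin[ev.start_frame]
            seg_rot[ev.start_frame] = _event_rotation(
                spec, u, origin[ev.start_frame], ev.roi, config
            )
        # scheduled spans (looks + grooming) partition the rest into wander
        sched_spans = sorted(
            [(ev.start_frame, ev.end_frame) for ev in ev_by_bird.get(bird, [])]
            + [(g.start_frame, g.end_frame) for g in gr_by_bird.get(bird, [])]
        )
        segments: list[tuple[int, int, np.ndarray | None]] = []
        cursor = 0
        for s, e in sched_spans:
            if s > cursor:
                segments.append((cursor, s, None))
            segments.append((s, e, seg_rot[s]))
            cursor = e
        if cursor < n:
            segments.append((cursor, n, None))
        # split wander stretches into random fixation lengths, additionally
        # breaking wherever the body teleports (table shuffles between
        # presentations): an orientation sampled from the old vantage point
        # may otherwise aim a cone at an ROI after the jump
        jumps = set((np.flatnonzero(np.linalg.norm(np.diff(body, axis=0), axis=1) > 1e-9) + 1).tolist())
        final: list[tuple[int, int, np.ndarray | None]] = []
        for s, e, r in segments:
            if r is not None:
                final.append((s, e, r))
                continue
            cuts = sorted({s, e} | {j for j in jumps if s < j < e})
            for a, bnd in zip(cuts[:-1], cuts[1:]):
                c = a
                while c < bnd:
                    dur = int(round(rng.uniform(0.35, 0.9) * fr))
                    final.append((c, min(c + dur, bnd), None))
                    c += dur
        prev = None
        starts = []
        for s, e, r in final:
            if r is None:
                r = _wander_rotation(origin[s], config, rng, prev)
            rot[s:e] = r
            if prev is not None and _geodesic_deg(prev, r) > 1e-6:
                starts.append(s)
            prev = r
        sacc_truth[bird] = np.array(starts, dtype=int)

        # markers: head template rides on the pose; backpack sits on the body
        head = origin[:, None, :] + np.einsum("nij,mj->nmi", rot, calib.template)
        bp_offsets = np.array(
            [[0.03, 0.03, 0.0], [-0.03, 0.03, 0.0], [0.03, -0.03, 0.0], [-0.03, -0.03, 0.0]]
        ) + BACKPACK_OFFSET
        backpack = body[:, None, :] + bp_offsets[None, :, :]
        if scenario.marker_noise_sd > 0:
            head = head + rng.normal(0, scenario.marker_noise_sd, head.shape)
            backpack = backpack + rng.normal(0, scenario.marker_noise_sd, backpack.shape)
        head_valid = rng.random((n, 4)) >= scenario.dropout_prob
        bp_valid = rng.random((n, 4)) >= scenario.dropout_prob
        head = np.where(head_valid[..., None], head, np.nan)
        backpack = np.where(bp_valid[..., None], backpack, np.nan)
        birds_out[bird] = BirdTracks(
            head=head, head_valid=head_valid, backpack=backpack, backpack_valid=bp_valid
        )

    min_frames = config.fixation_min_frames
    ev_df = pd.DataFrame(
        [
            {
                "bird": ev.bird,
                "roi": ev.roi,
                "cone": ev.cone,
                "start_frame": ev.start_frame,
                "end_frame": ev.end_frame,
                "sub_threshold": int(ev.n_frames < min_frames),
            }
            for ev in scenario.look_events
        ],
        columns=["bird", "roi", "cone", "start_frame", "end_frame", "sub_threshold"],
    )
    gr_df = pd.DataFrame(
        [
            {"bird": g.bird, "start_frame": g.start_frame, "end_frame": g.end_frame}
            for g in scenario.groom_bouts
        ],
        columns=["bird", "start_frame", "end_frame"],
    )
    truth = GroundTruth(
        events=ev_df,
        grooming=gr_df,
        saccade_frames=sacc_truth,
        sides=scenario.sides,
        schedule=scenario.schedule,
    )
    return MarkerTimeSeries(frame_rate=fr, birds=birds_out), truth


# ---------------------------------------------------- response-table twin


@dataclass
class EffectSpec:
    """Generating effect sizes for the statistical twin of the analysis
    table. Coefficients are on the z-scored predictor scale, matching how
    the models are reported."""

    baseline: float = -0.3  # intercept: log-odds (binomial) / log-rate (poisson)
    beta_cond: float = 0.425
    beta_dem: float = 0.324
    beta_dem2: float = 0.0
    re_intercept_sd: float = 0.5
    re_slope_sd: float = 0.2
    n_individuals: int = 70
    n_presentations: int = 21  # rows per individual
    max_demonstrators: int = 9

    def __post_init__(self) -> None:
        if self.re_intercept_sd < 0 or self.re_slope_sd < 0:
            raise ValueError("random-effect sds must be >= 0")
        if self.n_individuals < 2:
            raise ValueError("need >= 2 individuals")


def generate_response_table(
    spec: EffectSpec, seed: int = 0
) -> tuple[pd.DataFrame, dict]:
    """Draw a presentation-level response table with known effects.

    Returns (table, truth). The table carries both response flavors —
    ``looked_target`` (Bernoulli through the logit link) and
    ``n_looks_target`` (Poisson through the log link) — from the same
    linear predictor structure, plus the control-predictor columns the
    models expect (all with zero true effect).
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 29]))
    n_ind, n_pres = spec.n_individuals, spec.n_presentations
    n = n_ind * n_pres
    ind = np.repeat(np.arange(n_ind), n_pres)
    b0 = rng.normal(0, spec.re_intercept_sd, n_ind)
    b_cond = rng.normal(0, spec.re_slope_sd, n_ind)
    b_dem = rng.normal(0, spec.re_slope_sd, n_ind)
    cond = rng.integers(0, 2, n)
    dem = rng.binomial(spec.max_demonstrators, 0.5, n)
    zdem = (dem - dem.mean()) / dem.std(ddof=1)
    eta = (
        spec.baseline
        + (spec.beta_cond + b_cond[ind]) * cond
        + (spec.beta_dem + b_dem[ind]) * zdem
        + spec.beta_dem2 * zdem**2
        + b0[ind]
    )
    eta = np.clip(eta, -30, 30)
    looked = rng.binomial(1, 1.0 / (1.0 + np.exp(-eta)))
    n_looks = rng.poisson(np.exp(eta))
    table = pd.DataFrame(
        {
            "observer_id": [f"p{i:02d}" for i in ind],
            "experiment_id": 3,
            "trial_id": np.tile(np.arange(n_pres) // 8 + 1, n_ind),
            "presentation_index": np.tile(np.arange(n_pres) % 8 + 1, n_ind),
            "condition": np.where(cond == 1, "test", "control"),
            "presentation_location": rng.choice(["top", "bottom"], n),
            "n_demonstrators": np.minimum(dem + rng.integers(0, 2, n), spec.max_demonstrators),
            "n_actual_demonstrators": dem,
            "looked_target": looked,
            "n_looks_target": n_looks,
        }
    )
    truth = {
        "baseline": spec.baseline,
        "beta_cond": spec.beta_cond,
        "beta_dem": spec.beta_dem,
        "beta_dem2": spec.beta_dem2,
        "re_intercept_sd": spec.re_intercept_sd,
        "re_slope_sd": spec.re_slope_sd,
        "zdem_scaling": (float(dem.mean()), float(dem.std(ddof=1))),
    }
    return table, truth
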