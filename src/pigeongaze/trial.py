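"""From look bouts to the per-observer, per-presentation analysis table.

Each object presentation splits the flock into demonstrators (birds on the
table side facing the stimulus window) and observers (the other side). One
analysis row is one observer during one presentation: whether and how often
it looked at the target and distractor locations, which it looked at first,
and how many demonstrators provided a gaze cue — the "actual number of
demonstrators", i.e. demonstrator-side birds with at least one target bout
not falling entirely within the observer's own grooming (a look the
observer could not have seen does not count).

Exclusion rules: observers that flew off, switched tables or were untracked
during the presentation window are dropped, as are all rows of test
presentations in which no demonstrator ever looked at the target (that rule
is a property of the presentation, evaluated before observer-grooming
filtering, and does not apply to control presentations).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SceneConfig, TableRegion
from .datatypes import BehaviorMask, DataError, LookBout, PresentationSchedule

PRESENTATION_COLUMNS = [
    "experiment_id",
    "trial_id",
    "presentation_index",
    "condition",
    "presentation_location",
    "observer_id",
    "looked_target",
    "n_looks_target",
    "looked_distractor",
    "n_looks_distractor",
    "first_look",
    "n_demonstrators",
    "n_actual_demonstrators",
    "mean_demonstrators_looking",
    "excluded",
    "exclusion_reason",
]


@dataclass(frozen=True)
class SideAssignment:
    """One bird's table side during one presentation window."""

    side: str | None  # region label, or None when untracked
    flew_off: bool
    switched: bool
    untracked: bool

    @property
    def usable(self) -> bool:
        return not (self.flew_off or self.switched or self.untracked)


def assign_sides(
    positions: dict[str, np.ndarray],
    table_regions: list[TableRegion],
) -> dict[str, SideAssignment]:
    """Assign each bird to the table region containing its median position.

    ``positions`` maps bird -> (n_window_frames, 3) world positions during
    the presentation window (NaN rows = untracked frames). Flags:
    ``flew_off`` when any tracked position lies outside both regions,
    ``switched`` when region membership changes within the window,
    ``untracked`` when no frame is tracked.
    """
    out: dict[str, SideAssignment] = {}
    for bird, pos in positions.items():
        pos = np.asarray(pos, dtype=float)
        tracked = np.all(np.isfinite(pos), axis=-1)
        if not tracked.any():
            out[bird] = SideAssignment(None, False, False, True)
            continue
        p = pos[tracked]
        membership = np.full(len(p), -1)
        for i, region in enumerate(table_regions):
            membership[region.contains(p)] = i
        flew_off = bool((membership == -1).any())
        seen = membership[membership >= 0]
        switched = bool(seen.size > 0 and not np.all(seen == seen[0]))
        median = np.median(p, axis=0)
        side = None
        for region in table_regions:
            if region.contains(median):
                side = region.label
                break
        if side is None and seen.size > 0:
            # median fell between tables (e.g. mid-switch); majority region
            counts = np.bincount(seen, minlength=len(table_regions))
            side = table_regions[int(np.argmax(counts))].label
        out[bird] = SideAssignment(side, flew_off, switched, False)
    return out


def _bout_frames(bout: LookBout, lo: int, hi: int) -> np.ndarray:
    mask = np.zeros(hi - lo, dtype=bool)
    s = max(bout.start_frame, lo)
    e = min(bout.end_frame, hi)
    if e > s:
        mask[s - lo : e - lo] = True
    return mask


def count_actual_demonstrators(
    demonstrator_target_bouts: dict[str, list[LookBout]],
    observer_grooming: np.ndarray,
    window: tuple[int, int],
) -> int:
    """Observer-specific count of demonstrators that provided a gaze cue.

    A demonstrator counts if at least one of its target bouts overlaps at
    least one frame in which the observer is not grooming (demonstrator
    looks are excluded when the observer grooms; the any-overlap rule).
    """
    lo, hi = window
    groom = np.asarray(observer_grooming, dtype=bool)[lo:hi]
    n = 0
    for bouts in demonstrator_target_bouts.values():
        for bout in bouts:
            if (_bout_frames(bout, lo, hi) & ~groom).any():
                n += 1
                break
    return n


def _mean_demonstrators_looking(
    demonstrator_target_bouts: dict[str, list[LookBout]], window: tuple[int, int]
) -> float:
    """Average over window frames of the number of demonstrators with an
    ongoing target bout (optional covariate, unused by the default models)."""
    lo, hi = window
    counts = np.zeros(hi - lo)
    for bouts in demonstrator_target_bouts.values():
        bird_mask = np.zeros(hi - lo, dtype=bool)
        for bout in bouts:
            bird_mask |= _bout_frames(bout, lo, hi)
        counts += bird_mask
    return float(counts.mean()) if hi > lo else 0.0


def build_presentation_table(
    bouts: list[LookBout],
    schedule: PresentationSchedule,
    sides: dict[tuple, dict[str, SideAssignment]],
    masks: dict[str, BehaviorMask],
    n_frames: int,
) -> pd.DataFrame:
    """One row per observer-side bird per presentation.

    ``sides`` maps (trial_id, presentation_index) -> per-bird side
    assignments for that window. The target ROI is the presentation's
    location; the distractor is the other location visible to the observer.
    """
    rows = []
    for pres in schedule:
        key = (pres["trial_id"], pres["presentation_index"])
        if key not in sides:
            raise DataError(f"no side assignments for presentation {key}")
        lo, hi = int(pres["start_frame"]), int(pres["end_frame"])
        if hi > n_frames:
            raise DataError(
                f"presentation {key}: window [{lo}, {hi}) outside tracked frames"
            )
        assignment = sides[key]
        demo_side = pres["demonstrator_side"]
        target = pres["presentation_location"]
        window_bouts = [
            b for b in bouts if b.start_frame >= lo and b.start_frame < hi
        ]
        demonstrators = [
            b for b, a in assignment.items() if a.side == demo_side and a.usable
        ]
        observers = [
            b for b, a in assignment.items() if a.side is not None and a.side != demo_side
        ]
        demo_target_bouts = {
            d: [b for b in window_bouts if b.bird == d and b.roi == target]
            for d in demonstrators
        }
        mean_demo = _mean_demonstrators_looking(demo_target_bouts, (lo, hi))
        for obs in observers:
            a = assignment[obs]
            obs_bouts = [b for b in window_bouts if b.bird == obs]
            by_roi: dict[str, list[LookBout]] = {}
            for b in obs_bouts:
                by_roi.setdefault(b.roi, []).append(b)
            n_target = len(by_roi.get(target, []))
            distractor_bouts = [b for b in obs_bouts if b.roi != target]
            n_distr = len(distractor_bouts)
            first = "none"
            t_on = min((b.start_frame for b in by_roi.get(target, [])), default=None)
            d_on = min((b.start_frame for b in distractor_bouts), default=None)
            if t_on is not None and (d_on is None or t_on < d_on):
                first = "target"
            elif d_on is not None and (t_on is None or d_on < t_on):
                first = "distractor"
            # identical onsets (possible with two foveas) stay "none"
            n_actual = count_actual_demonstrators(
                demo_target_bouts, masks[obs].grooming, (lo, hi)
            )
            reason = ""
            if a.untracked:
                reason = "untracked"
            elif a.flew_off:
                reason = "flew_off"
            elif a.switched:
                reason = "switched"
            rows.append(
                {
                    "experiment_id": pres["experiment_id"],
                    "trial_id": pres["trial_id"],
                    "presentation_index": pres["presentation_index"],
                    "condition": pres["condition"],
                    "presentation_location": target,
                    "observer_id": obs,
                    "looked_target": int(n_target > 0),
                    "n_looks_target": n_target,
                    "looked_distractor": int(n_distr > 0),
                    "n_looks_distractor": n_distr,
                    "first_look": first,
                    "n_demonstrators": len(demonstrators),
                    "n_actual_demonstrators": n_actual,
                    "mean_demonstrators_looking": mean_demo,
                    "excluded": int(bool(reason)),
                    "exclusion_reason": reason,
                    "_any_demo_looked": int(
                        any(len(v) > 0 for v in demo_target_bouts.values())
                    ),
                }
            )
    return pd.DataFrame(rows, columns=PRESENTATION_COLUMNS + ["_any_demo_looked"])


def apply_exclusions(table: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Drop excluded rows and report counts by reason.

    Rows are dropped when (a) the observer flew off, switched tables or was
    untracked, or (b) the row belongs to a test presentation in which no
    demonstrator looked at the target (evaluated on demonstrator bouts
    before observer-grooming filtering). Returns (filtered table, report
    with columns reason/count).
    """
    table = table.copy()
    reasons = table["exclusion_reason"].copy()
    no_demo = (table["condition"] == "test") & (table["_any_demo_looked"] == 0)
    reasons[no_demo & (reasons == "")] = "no_demonstrator_looked"
    drop = reasons != ""
    report = (
        reasons[drop]
        .value_counts()
        .rename_axis("reason")
        .reset_index(name="count")
        .sort_values("reason")
        .reset_index(drop=True)
    )
    kept = table[~drop].drop(columns=["_any_demo_looked"]).reset_index(drop=True)
    kept["excluded"] = 0
    kept["exclusion_reason"] = ""
    return kept, report
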