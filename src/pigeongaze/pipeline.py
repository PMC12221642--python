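"""End-to-end orchestration: markers -> poses -> bouts -> table -> models."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import SceneConfig
from .datatypes import (
    BehaviorMask,
    HeadCalibration,
    HeadPoseSeries,
    LookBout,
    MarkerTimeSeries,
    PresentationSchedule,
    bouts_to_frame,
)
from .gaze import classify_field_usage, detect_looks
from .headpose import process_bird
from .stats import GlmmResult, GlmmSpec, fit_glmm
from .trial import apply_exclusions, assign_sides, build_presentation_table


@dataclass
class PipelineResult:
    poses: dict[str, HeadPoseSeries]
    masks: dict[str, BehaviorMask]
    bouts: list[LookBout]
    table: pd.DataFrame  # filtered analysis table
    raw_table: pd.DataFrame  # before exclusions
    exclusion_report: pd.DataFrame
    field_usage: dict[str, float] | None

    @property
    def bout_table(self) -> pd.DataFrame:
        return bouts_to_frame(self.bouts)


def presentation_windows(schedule: PresentationSchedule) -> list[tuple[int, int]]:
    return [
        (int(p["start_frame"]), int(p["end_frame"])) for p in schedule
    ]


def compute_sides(
    markers: MarkerTimeSeries,
    schedule: PresentationSchedule,
    config: SceneConfig,
) -> dict[tuple, dict]:
    """Per-presentation table-side assignment from backpack positions."""
    centroids = {
        bird: tracks.backpack_centroid() for bird, tracks in markers.birds.items()
    }
    sides = {}
    for pres in schedule:
        lo, hi = int(pres["start_frame"]), int(pres["end_frame"])
        positions = {bird: c[lo:hi] for bird, c in centroids.items()}
        sides[(pres["trial_id"], pres["presentation_index"])] = assign_sides(
            positions, config.table_regions
        )
    return sides


def run_pipeline(
    markers: MarkerTimeSeries,
    calibrations: dict[str, HeadCalibration],
    schedule: PresentationSchedule,
    config: SceneConfig,
    grooming_masks: dict[str, np.ndarray] | None = None,
) -> PipelineResult:
    """Run every stage from raw markers to the filtered analysis table."""
    poses: dict[str, HeadPoseSeries] = {}
    masks: dict[str, BehaviorMask] = {}
    for bird, tracks in markers.birds.items():
        poses[bird], masks[bird] = process_bird(
            tracks,
            calibrations[bird],
            config,
            markers.frame_rate,
            grooming_mask=(grooming_masks or {}).get(bird),
        )
    bouts = detect_looks(poses, masks, config, windows=presentation_windows(schedule))
    sides = compute_sides(markers, schedule, config)
    raw = build_presentation_table(bouts, schedule, sides, masks, markers.n_frames)
    table, report = apply_exclusions(raw)
    return PipelineResult(
        poses=poses,
        masks=masks,
        bouts=bouts,
        table=table,
        raw_table=raw,
        exclusion_report=report,
        field_usage=classify_field_usage(bouts),
    )


DEFAULT_CONTROLS = ["trial_id", "presentation_index", "presentation_location"]


def fit_standard_models(
    table: pd.DataFrame,
    main_predictor: str = "condition",
    controls: list[str] | None = None,
    structure: str = "correlated",
) -> dict[str, GlmmResult]:
    """The two headline models: likelihood of looking (binomial) and number
    of looks (Poisson), with the usual control predictors."""
    controls = DEFAULT_CONTROLS if controls is None else controls
    controls = [c for c in controls if table[c].nunique() > 1]
    if main_predictor != "condition":
        table = table[table["condition"] == "test"]
    out = {}
    for family, response in (
        ("binomial", "looked_target"),
        ("poisson", "n_looks_target"),
    ):
        spec = GlmmSpec(
            family=family,
            response=response,
            main_predictor=main_predictor,
            control_predictors=controls,
            structure=structure,
        )
        out[f"{family}:{response}"] = fit_glmm(spec, table)
    return out
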