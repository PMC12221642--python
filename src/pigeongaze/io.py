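"""Readers and writers for the on-disk CSV formats.

Marker CSV dialect: a ``frame`` column followed by ``<bird>_<marker>_<axis>``
columns (markers h1..h4 for the head, b1..b4 for the backpack; axes x/y/z;
units meters, world frame Z-up). Missing samples are empty fields and become
invalid-masked entries, never zeros.
"""

from __future__ import annotations

import itertools
from pathlib import Path

import numpy as np
import pandas as pd

from .datatypes import (
    BACKPACK_MARKERS,
    BirdTracks,
    DataError,
    HEAD_MARKERS,
    HeadCalibration,
    LookBout,
    MarkerTimeSeries,
    PresentationSchedule,
    SCHEDULE_COLUMNS,
    bouts_to_frame,
)

AXES = ("x", "y", "z")


class FormatError(DataError):
    """Raised when a file's structure (header, columns) is malformed."""


def _parse_marker_column(col: str) -> tuple[str, str, str]:
    parts = col.rsplit("_", 2)
    if len(parts) != 3 or parts[2] not in AXES:
        raise FormatError(f"malformed marker column {col!r}: expected <bird>_<marker>_<axis>")
    return parts[0], parts[1], parts[2]


def read_mocap_csv(path: str | Path, frame_rate: float) -> MarkerTimeSeries:
    """Read a wide marker CSV into a MarkerTimeSeries.

    The frame column must be strictly increasing. Every bird appearing in
    the header is present in the result; cells left empty are masked
    invalid.
    """
    df = pd.read_csv(path)
    if df.shape[1] == 0 or df.columns[0] != "frame":
        raise FormatError(f"{path}: first column must be 'frame'")
    frames = df["frame"].to_numpy()
    if len(frames) == 0:
        raise DataError(f"{path}: no data rows")
    if not np.all(np.diff(frames) > 0):
        raise DataError(f"{path}: frame column is not strictly increasing")
    layout: dict[str, dict[str, dict[str, str]]] = {}
    for col in df.columns[1:]:
        bird, marker, axis = _parse_marker_column(col)
        layout.setdefault(bird, {}).setdefault(marker, {})[axis] = col
    n = len(df)
    birds: dict[str, BirdTracks] = {}
    for bird, markers in layout.items():
        head_names = [m for m in HEAD_MARKERS if m in markers]
        if len(head_names) != 4:
            raise FormatError(
                f"{path}: bird {bird!r} must declare 4 head markers h1..h4, "
                f"found {head_names}"
            )
        back_names = [m for m in BACKPACK_MARKERS if m in markers]

        def stack(names: list[str]) -> np.ndarray:
            if not names:
                return np.empty((n, 0, 3))
            cols = [[markers[m][ax] for ax in AXES] for m in names]
            return np.stack(
                [df[c].to_numpy(dtype=float) for c in itertools.chain(*cols)], axis=1
            ).reshape(n, len(names), 3)

        head = stack(head_names)
        back = stack(back_names)
        birds[bird] = BirdTracks(
            head=head,
            head_valid=np.all(np.isfinite(head), axis=2),
            backpack=back,
            backpack_valid=np.all(np.isfinite(back), axis=2),
        )
    return MarkerTimeSeries(frame_rate=frame_rate, birds=birds)


def write_mocap_csv(path: str | Path, series: MarkerTimeSeries) -> None:
    """Write a MarkerTimeSeries in the wide CSV dialect (empty = missing)."""
    n = series.n_frames
    data: dict[str, np.ndarray] = {"frame": np.arange(n)}
    for bird, tracks in series.birds.items():
        for j, m in enumerate(HEAD_MARKERS):
            for k, ax in enumerate(AXES):
                col = tracks.head[:, j, k].copy()
                col[~tracks.head_valid[:, j]] = np.nan
                data[f"{bird}_{m}_{ax}"] = col
        for j in range(tracks.backpack.shape[1]):
            for k, ax in enumerate(AXES):
                col = tracks.backpack[:, j, k].copy()
                col[~tracks.backpack_valid[:, j]] = np.nan
                data[f"{bird}_{BACKPACK_MARKERS[j]}_{ax}"] = col
    pd.DataFrame(data).to_csv(path, index=False, float_format="%.9g")


def read_schedule(path: str | Path) -> PresentationSchedule:
    """Read and validate a presentation schedule CSV."""
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise DataError(f"{path}: empty schedule file") from exc
    if len(df) == 0:
        raise DataError(f"{path}: schedule has no rows")
    return PresentationSchedule(df)


def write_schedule(path: str | Path, schedule: PresentationSchedule) -> None:
    schedule.table[SCHEDULE_COLUMNS].to_csv(path, index=False)


def read_calibrations(path: str | Path) -> dict[str, HeadCalibration]:
    """Read per-bird calibration CSV with columns bird,point,x,y,z.

    Points: left_eye, right_eye, beak_tip, m1..m4 (the marker template) and
    optionally head_up (a direction, not a position).
    """
    df = pd.read_csv(path)
    required = {"bird", "point", "x", "y", "z"}
    if not required.issubset(df.columns):
        raise FormatError(f"{path}: calibration needs columns {sorted(required)}")
    out: dict[str, HeadCalibration] = {}
    for bird, grp in df.groupby("bird"):
        pts = {row["point"]: np.array([row["x"], row["y"], row["z"]]) for _, row in grp.iterrows()}
        try:
            template = np.stack([pts[f"m{i}"] for i in range(1, 5)])
            out[str(bird)] = HeadCalibration(
                left_eye=pts["left_eye"],
                right_eye=pts["right_eye"],
                beak_tip=pts["beak_tip"],
                template=template,
                head_up=pts.get("head_up"),
            )
        except KeyError as exc:
            raise FormatError(f"{path}: bird {bird!r} missing point {exc}") from exc
    return out


def write_calibrations(path: str | Path, calibs: dict[str, HeadCalibration]) -> None:
    rows = []
    for bird, c in calibs.items():
        named = {"left_eye": c.left_eye, "right_eye": c.right_eye, "beak_tip": c.beak_tip}
        for i in range(4):
            named[f"m{i + 1}"] = c.template[i]
        if c.head_up is not None:
            named["head_up"] = c.head_up
        for point, v in named.items():
            rows.append({"bird": bird, "point": point, "x": v[0], "y": v[1], "z": v[2]})
    pd.DataFrame(rows).to_csv(path, index=False)


def write_bouts(path: str | Path, bouts: list[LookBout], extra: pd.DataFrame | None = None) -> None:
    df = bouts_to_frame(bouts)
    if extra is not None:
        df = pd.concat([df, extra], axis=1)
    df.to_csv(path, index=False)


def read_bouts(path: str | Path) -> list[LookBout]:
    df = pd.read_csv(path)
    return [
        LookBout(
            bird=str(r.bird),
            roi=str(r.roi),
            cone=str(r.cone),
            start_frame=int(r.start_frame),
            end_frame=int(r.end_frame),
            duration_ms=float(r.duration_ms),
        )
        for r in df.itertuples()
    ]
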