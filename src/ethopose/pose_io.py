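"""Reading, writing and pre-processing of keypoint track files.

Pose tracks are exchanged as long-format CSV with columns
``individual, frame, time_s, node, x, y, score`` (one row per detected
keypoint), the tabular export dialect common to pose-estimation tools.
In memory a track is a wide per-frame table: one row per frame with
``<node>_x/<node>_y/<node>_score`` columns and NaN for missing
detections.  The image coordinate convention is y-down (origin at the
top-left of the frame).

Pre-processing mirrors what a tracking pipeline does before per-second
analysis: down-sampling the frame rate (keep the first frame of each
output bin) and removal of duplicate tracks that follow the same animal.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .classifier import KEYPOINTS, AnnotationSeries


class PoseFormatError(ValueError):
    """Raised when a pose CSV violates the expected format."""


class UnsupportedRateError(ValueError):
    """Raised when a frame-rate conversion is not an integer decimation."""


_WIDE_COLUMNS = ["frame", "time_s"] + [
    f"{node}_{axis}" for node in KEYPOINTS for axis in ("x", "y", "score")
]


@dataclass
class PoseTrack:
    """Time-ordered keypoint coordinates for one individual.

    ``df`` has columns ``frame, time_s`` plus ``<node>_x``,
    ``<node>_y``, ``<node>_score`` for each of nose, head, shoulder,
    hip; NaN marks an absent detection.
    """

    individual: str
    df: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in _WIDE_COLUMNS if c not in self.df.columns]
        if missing:
            raise PoseFormatError(f"track missing columns: {missing}")
        t = self.df["time_s"].to_numpy()
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise PoseFormatError(f"non-monotone time_s for individual {self.individual!r}")
        coords = self.df[[f"{n}_{a}" for n in KEYPOINTS for a in ("x", "y")]].to_numpy(float)
        if np.isinf(coords).any():
            raise PoseFormatError("non-finite keypoint coordinates")

    def __len__(self) -> int:
        return len(self.df)

    @property
    def duration_s(self) -> float:
        if len(self.df) == 0:
            return 0.0
        t = self.df["time_s"]
        return float(t.iloc[-1] - t.iloc[0]) + 1.0

    def mean_score(self) -> float:
        scores = self.df[[f"{n}_score" for n in KEYPOINTS]].to_numpy(float)
        return float(np.nanmean(scores)) if np.isfinite(scores).any() else float("nan")


def _empty_wide() -> pd.DataFrame:
    return pd.DataFrame({c: pd.Series(dtype=float) for c in _WIDE_COLUMNS})


def read_pose_csv(path: str | Path) -> list[PoseTrack]:
    """Read a long-format pose CSV into one :class:`PoseTrack` per individual.

    Unknown node names and non-monotone frame times raise
    :class:`PoseFormatError` naming the offending row/individual.
    """
    raw = pd.read_csv(path)
    required = {"individual", "frame", "time_s", "node", "x", "y"}
    missing = required - set(raw.columns)
    if missing:
        raise PoseFormatError(f"pose CSV missing columns: {sorted(missing)}")
    if "score" not in raw.columns:
        raw["score"] = np.nan
    bad = ~raw["node"].isin(KEYPOINTS)
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise PoseFormatError(
            f"unknown node {raw['node'].iloc[row]!r} at data row {row} "
            f"(expected one of {KEYPOINTS})"
        )
    tracks: list[PoseTrack] = []
    for individual, grp in raw.groupby("individual", sort=True):
        wide = grp.pivot_table(
            index=["frame", "time_s"], columns="node", values=["x", "y", "score"]
        )
        wide.columns = [f"{node}_{axis}" for axis, node in wide.columns]
        wide = wide.reset_index()
        for col in _WIDE_COLUMNS:
            if col not in wide.columns:
                wide[col] = np.nan
        wide = wide[_WIDE_COLUMNS].sort_values("frame").reset_index(drop=True)
        order = grp.sort_index()["time_s"].to_numpy()
        if np.any(np.diff(order) < 0):
            raise PoseFormatError(f"non-monotone time_s for individual {individual!r}")
        tracks.append(PoseTrack(individual=str(individual), df=wide))
    return tracks


def write_pose_csv(tracks: list[PoseTrack], path: str | Path) -> None:
    """Write tracks in the long CSV dialect; absent keypoints are skipped."""
    rows = []
    for track in tracks:
        for rec in track.df.to_dict("records"):
            for node in KEYPOINTS:
                x, y = rec[f"{node}_x"], rec[f"{node}_y"]
                if np.isnan(x) or np.isnan(y):
                    continue
                rows.append(
                    {
                        "individual": track.individual,
                        "frame": int(rec["frame"]),
                        "time_s": rec["time_s"],
                        "node": node,
                        "x": x,
                        "y": y,
                        "score": rec[f"{node}_score"],
                    }
                )
    cols = ["individual", "frame", "time_s", "node", "x", "y", "score"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def downsample(track: PoseTrack, from_fps: int, to_fps: int) -> PoseTrack:
    """Reduce the frame rate by keeping the first frame of each output bin.

    ``from_fps`` must be an integer multiple of ``to_fps``; the result
    has ``ceil(n * to_fps / from_fps)`` frames.  Picking the first frame
    (rather than averaging) keeps each output frame an actual observed
    pose, matching per-second snapshot semantics.
    """
    if from_fps <= 0 or to_fps <= 0:
        raise UnsupportedRateError("frame rates must be positive")
    if from_fps % to_fps != 0:
        raise UnsupportedRateError(
            f"cannot down-sample {from_fps} -> {to_fps} fps: not an integer decimation"
        )
    step = from_fps // to_fps
    df = track.df.iloc[::step].reset_index(drop=True)
    return PoseTrack(individual=track.individual, df=df)


def to_seconds(track: PoseTrack) -> PoseTrack:
    """Re-index a 1-fps track to integer seconds starting from its first frame."""
    df = track.df.copy()
    if len(df):
        start = int(np.floor(df["time_s"].iloc[0]))
        df["time_s"] = start + np.arange(len(df))
    return PoseTrack(individual=track.individual, df=df)


def _pair_distance(a: PoseTrack, b: PoseTrack) -> float:
    """Mean keypoint distance over co-visible times (inf when never co-visible)."""
    merged = a.df.merge(b.df, on="time_s", suffixes=("_a", "_b"))
    dists = []
    for node in KEYPOINTS:
        dx = merged[f"{node}_x_a"] - merged[f"{node}_x_b"]
        dy = merged[f"{node}_y_a"] - merged[f"{node}_y_b"]
        dists.append(np.hypot(dx, dy))
    all_d = np.concatenate([d.to_numpy(float) for d in dists]) if dists else np.array([])
    all_d = all_d[np.isfinite(all_d)]
    return float(all_d.mean()) if all_d.size else float("inf")


def dedupe_tracks(tracks: list[PoseTrack], overlap_threshold_px: float = 50.0) -> list[PoseTrack]:
    """Drop duplicate tracks that follow the same animal.

    Two tracks are duplicates when their mean keypoint distance over
    co-visible seconds falls below ``overlap_threshold_px``; the one
    with the lower mean detection score (or, on a tie, the shorter
    duration) is removed.  Idempotent.
    """
    alive = list(tracks)
    while True:
        worst = None
        for i, j in itertools.combinations(range(len(alive)), 2):
            if _pair_distance(alive[i], alive[j]) < overlap_threshold_px:
                worst = (i, j)
                break
        if worst is None:
            return alive
        i, j = worst
        a, b = alive[i], alive[j]
        sa, sb = a.mean_score(), b.mean_score()
        # NaN scores compare as equal quality; fall back to duration
        if np.isnan(sa) and np.isnan(sb):
            drop = i if a.duration_s <= b.duration_s else j
        elif np.isnan(sa) or sa < sb:
            drop = i
        elif np.isnan(sb) or sb < sa:
            drop = j
        else:
            drop = i if a.duration_s <= b.duration_s else j
        alive.pop(drop)


# --- annotation and tracking-point CSV dialects -------------------------------


def write_annotations_csv(series_list: list[AnnotationSeries], path: str | Path) -> None:
    """Write annotation series as CSV (individual, time_s, behavior)."""
    rows = [
        {"individual": s.individual, "time_s": int(t), "behavior": lab}
        for s in series_list
        for t, lab in s.labels.items()
    ]
    pd.DataFrame(rows, columns=["individual", "time_s", "behavior"]).to_csv(path, index=False)


def read_annotations_csv(
    path: str | Path, categories: tuple[str, ...] | None = None
) -> list[AnnotationSeries]:
    """Read per-second annotations, one series per individual."""
    raw = pd.read_csv(path)
    out = []
    for individual, grp in raw.groupby("individual", sort=True):
        grp = grp.sort_values("time_s")
        labels = pd.Series(
            grp["behavior"].to_numpy(object), index=grp["time_s"].astype(int).to_numpy()
        )
        cats = categories or tuple(dict.fromkeys(labels))
        out.append(AnnotationSeries(individual=str(individual), labels=labels, categories=cats))
    return out


def write_tracking_points(points: pd.DataFrame, path: str | Path) -> None:
    """Write blueprint tracking points as CSV (individual, period, time_s, x, y)."""
    cols = ["individual", "period", "time_s", "x", "y"]
    points[cols].to_csv(path, index=False)


def read_tracking_points(path: str | Path) -> pd.DataFrame:
    raw = pd.read_csv(path)
    missing = {"individual", "period", "time_s", "x", "y"} - set(raw.columns)
    if missing:
        raise PoseFormatError(f"tracking-point CSV missing columns: {sorted(missing)}")
    return raw
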