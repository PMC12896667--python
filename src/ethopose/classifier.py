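"""Per-second behavior classification from four-keypoint geometry.

Each observed second is assigned exactly one of five categories —
Standing, Lying Down, Foraging/Feeding, Locomotion, Not Labeled — from
the pixel coordinates of the nose, head, shoulder and hip keypoints.
The rules are geometric:

* **Lying Down** — hip or shoulder falls inside a fixed rectangular
  resting zone (boundaries inclusive).
* **Foraging/Feeding** — the head is at least ``head_drop_px`` below the
  shoulder, or the nose at least ``nose_drop_px`` below it.  Image
  coordinates grow downward, so "below" means larger *y*.
* **Locomotion** — a second whose static label is Standing is relabeled
  when the hip/shoulder displacement since the previous second exceeds
  ``locomotion_fraction`` of a body length (hip-to-shoulder distance).
* **Standing** — the default when no other rule fires.
* **Not Labeled** — hip and shoulder are both missing (e.g. occlusion),
  so no rule can be evaluated.

Rule precedence is Lying Down before Foraging/Feeding: a lying animal's
head is typically low, and zone membership is the stronger cue.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

if TYPE_CHECKING:  # pragma: no cover
    from .pose_io import PoseTrack

KEYPOINTS = ("nose", "head", "shoulder", "hip")

STANDING = "Standing"
LYING = "Lying Down"
FORAGING = "Foraging/Feeding"
LOCOMOTION = "Locomotion"
NOT_LABELED = "Not Labeled"

#: The five labels the automated classifier can emit.
AUTO_CATEGORIES = (STANDING, LYING, FORAGING, LOCOMOTION, NOT_LABELED)

#: Rectangle (x_min, x_max, y_min, y_max) of the default resting zone,
#: in pixels of a 1920x1080 frame.
DEFAULT_LYING_ZONE = (1080.0, 1720.0, 270.0, 400.0)


@dataclass(frozen=True)
class RuleConfig:
    """Thresholds of the geometric classification rules.

    Parameters
    ----------
    head_drop_px, nose_drop_px
        Minimum vertical drop (pixels, y-down) of head/nose below the
        shoulder for Foraging/Feeding; comparisons are ``>=``.
    locomotion_fraction
        Fraction of a body length the hip/shoulder displacement must
        *exceed* (strict ``>``) between consecutive seconds.
    lying_zone
        Resting-zone rectangle ``(x_min, x_max, y_min, y_max)``;
        boundaries inclusive.
    displacement_rule
        How the hip and shoulder displacements are combined before the
        locomotion threshold: ``"mean"`` (default), ``"max"``, or
        ``"both"`` (each must exceed).
    """

    head_drop_px: float = 60.0
    nose_drop_px: float = 90.0
    locomotion_fraction: float = 0.5
    lying_zone: tuple[float, float, float, float] = DEFAULT_LYING_ZONE
    displacement_rule: str = "mean"

    def __post_init__(self) -> None:
        if self.head_drop_px <= 0 or self.nose_drop_px <= 0:
            raise ValueError("drop thresholds must be positive")
        if not self.locomotion_fraction > 0:
            raise ValueError("locomotion_fraction must be positive")
        x0, x1, y0, y1 = self.lying_zone
        if not (x0 < x1 and y0 < y1):
            raise ValueError(f"invalid lying_zone {self.lying_zone!r}")
        if self.displacement_rule not in ("mean", "max", "both"):
            raise ValueError(f"unknown displacement_rule {self.displacement_rule!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RuleConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "lying_zone" in raw:
            raw["lying_zone"] = tuple(float(v) for v in raw["lying_zone"])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = {
            "head_drop_px": self.head_drop_px,
            "nose_drop_px": self.nose_drop_px,
            "locomotion_fraction": self.locomotion_fraction,
            "lying_zone": list(self.lying_zone),
            "displacement_rule": self.displacement_rule,
        }
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    def with_(self, **kwargs) -> "RuleConfig":
        return replace(self, **kwargs)


@dataclass
class AnnotationSeries:
    """Per-second behavior labels for one individual.

    ``labels`` is a string Series indexed by integer second; the index
    must be contiguous over the observed window and every label must
    belong to ``categories``.
    """

    individual: str
    labels: pd.Series
    categories: tuple[str, ...]

    def __post_init__(self) -> None:
        self.labels = pd.Series(self.labels, dtype=object)
        idx = self.labels.index.to_numpy()
        if len(idx) and not np.array_equal(idx, np.arange(idx[0], idx[0] + len(idx))):
            raise ValueError("annotation seconds must be contiguous")
        bad = set(self.labels) - set(self.categories)
        if bad:
            raise ValueError(f"labels outside declared category set: {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.labels)

    @classmethod
    def from_labels(
        cls,
        labels: Iterable[str],
        individual: str = "",
        categories: tuple[str, ...] | None = None,
        start_s: int = 0,
    ) -> "AnnotationSeries":
        labels = list(labels)
        if categories is None:
            categories = tuple(dict.fromkeys(labels))
        series = pd.Series(labels, index=np.arange(start_s, start_s + len(labels)))
        return cls(individual=individual, labels=series, categories=categories)


def _xy(frame: Mapping, node: str) -> tuple[float, float] | None:
    """Coordinates of a keypoint, or None when absent (NaN/missing)."""
    x = frame.get(f"{node}_x", math.nan)
    y = frame.get(f"{node}_y", math.nan)
    if x is None or y is None:
        return None
    x, y = float(x), float(y)
    if math.isnan(x) or math.isnan(y):
        return None
    return x, y


def body_length(frame: Mapping) -> float:
    """Hip-to-shoulder Euclidean distance in pixels.

    Raises ``ValueError`` when either keypoint is absent.
    """
    shoulder = _xy(frame, "shoulder")
    hip = _xy(frame, "hip")
    if shoulder is None or hip is None:
        raise ValueError("body length undefined: hip or shoulder keypoint missing")
    return math.hypot(hip[0] - shoulder[0], hip[1] - shoulder[1])


def _in_zone(pt: tuple[float, float], zone: tuple[float, float, float, float]) -> bool:
    x0, x1, y0, y1 = zone
    return x0 <= pt[0] <= x1 and y0 <= pt[1] <= y1


def classify_static(frame: Mapping, config: RuleConfig | None = None) -> str:
    """Classify a single second from keypoint positions alone.

    Locomotion cannot be decided from one frame; it is applied in a
    second pass by :func:`apply_locomotion`.  A second with neither hip
    nor shoulder detected is Not Labeled.  When head and nose are
    missing but hip/shoulder are present, the foraging rule simply
    cannot fire and the second falls through to Standing.
    """
    config = config or RuleConfig()
    shoulder = _xy(frame, "shoulder")
    hip = _xy(frame, "hip")
    if shoulder is None and hip is None:
        return NOT_LABELED
    for pt in (hip, shoulder):
        if pt is not None and _in_zone(pt, config.lying_zone):
            return LYING
    if shoulder is not None:
        head = _xy(frame, "head")
        nose = _xy(frame, "nose")
        if head is not None and head[1] - shoulder[1] >= config.head_drop_px:
            return FORAGING
        if nose is not None and nose[1] - shoulder[1] >= config.nose_drop_px:
            return FORAGING
    return STANDING


def _displacements(prev: Mapping, cur: Mapping) -> tuple[float, float] | None:
    """Hip and shoulder displacement between two frames, or None if any
    of the four keypoints is absent."""
    pts = {}
    for frame, tag in ((prev, "p"), (cur, "c")):
        for node in ("hip", "shoulder"):
            pt = _xy(frame, node)
            if pt is None:
                return None
            pts[(tag, node)] = pt
    d_hip = math.dist(pts[("p", "hip")], pts[("c", "hip")])
    d_sh = math.dist(pts[("p", "shoulder")], pts[("c", "shoulder")])
    return d_hip, d_sh


def apply_locomotion(
    static_labels: AnnotationSeries,
    track: "PoseTrack",
    config: RuleConfig | None = None,
) -> AnnotationSeries:
    """Relabel Standing seconds as Locomotion based on displacement.

    Second *t* becomes Locomotion iff its static label is Standing, the
    track has hip and shoulder at both *t-1* and *t*, and the combined
    hip/shoulder displacement between the two seconds exceeds
    ``locomotion_fraction`` x body length (taken from frame *t*).  The
    first observed second can never be Locomotion.  A zero body length
    means the rule cannot fire.
    """
    config = config or RuleConfig()
    df = track.df
    labels = static_labels.labels.copy()
    rows = df.to_dict("records")
    time_s = df["time_s"].to_numpy() if len(df) else np.array([], dtype=int)
    for i in range(1, len(rows)):
        t = int(time_s[i])
        if int(time_s[i - 1]) != t - 1 or labels.get(t) != STANDING:
            continue
        disp = _displacements(rows[i - 1], rows[i])
        if disp is None:
            continue
        d_hip, d_sh = disp
        if body_length(rows[i]) == 0.0:
            continue  # degenerate pose: half a body length is meaningless
        if config.displacement_rule == "mean":
            fired = (d_hip + d_sh) / 2.0 > config.locomotion_fraction * body_length(rows[i])
        elif config.displacement_rule == "max":
            fired = max(d_hip, d_sh) > config.locomotion_fraction * body_length(rows[i])
        else:  # both
            thr = config.locomotion_fraction * body_length(rows[i])
            fired = d_hip > thr and d_sh > thr
        if fired:
            labels.loc[t] = LOCOMOTION
    return AnnotationSeries(
        individual=static_labels.individual,
        labels=labels,
        categories=AUTO_CATEGORIES,
    )


def classify_track(track: "PoseTrack", config: RuleConfig | None = None) -> AnnotationSeries:
    """Full per-second classification of a 1-fps track.

    Composition of :func:`classify_static` over every frame followed by
    the :func:`apply_locomotion` pass; every second of the track
    receives exactly one of the five categories.
    """
    config = config or RuleConfig()
    df = track.df
    static = [classify_static(row, config) for row in df.to_dict("records")]
    series = AnnotationSeries(
        individual=track.individual,
        labels=pd.Series(static, index=df["time_s"].astype(int).to_numpy(), dtype=object),
        categories=AUTO_CATEGORIES,
    )
    return apply_locomotion(series, track, config)
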