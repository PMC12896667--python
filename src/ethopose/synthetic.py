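"""Synthetic inputs with known ground truth for every pipeline stage.

Real pose-estimation studies rarely deposit raw tracks, so the package
ships generators that emulate the statistical structure the analysis
assumes:

* a semi-Markov behavior sequence (geometric dwell times per behavior,
  one state per second),
* keypoint tracks whose geometry realises each behavior's
  classification rule exactly and violates the others by a safety
  margin, with optional Gaussian coordinate jitter and whole-frame
  occlusion,
* an imperfect manual observer (random category flips, out-of-sight
  seconds),
* per-day behavior-proportion tables for two periods (control/test)
  drawn from Dirichlet distributions with configurable effect sizes,
* 2-D tracking-point clouds from Gaussian mixtures on the enclosure
  blueprint, so density shifts toward a scent location can be planted.

Everything is deterministic given the seed carried in its config.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .classifier import (
    FORAGING,
    KEYPOINTS,
    LOCOMOTION,
    LYING,
    STANDING,
    AnnotationSeries,
)
from .pose_io import PoseTrack, _WIDE_COLUMNS

OUT_OF_SIGHT = "Out of Sight"

_CORE_BEHAVIORS = (STANDING, LYING, FORAGING, LOCOMOTION)

#: Default mean dwell times (seconds) per behavior.  No field estimates
#: exist for captive pygmy hippos at per-second resolution; these are
#: order-of-magnitude placeholders (long rests, short travel bouts).
DEFAULT_MEAN_DWELL = {STANDING: 20.0, LYING: 120.0, FORAGING: 40.0, LOCOMOTION: 5.0}


def _uniform_jump_matrix(k: int) -> np.ndarray:
    m = np.full((k, k), 1.0 / (k - 1))
    np.fill_diagonal(m, 0.0)
    return m


@dataclass(frozen=True)
class SimConfig:
    """Conditions for one synthetic focal-observation bout.

    ``transition_matrix`` (row-stochastic over ``behaviors``) governs
    which behavior follows which; dwell in each behavior is geometric
    with mean ``mean_dwell_s`` (memoryless, the simplest model
    consistent with per-second sampling).  ``margin_px`` is the
    geometric safety margin by which non-active rules are violated; it
    must exceed ``jitter_px`` for noise-proof classification.
    """

    duration_s: int = 600
    behaviors: tuple[str, ...] = _CORE_BEHAVIORS
    transition_matrix: tuple[tuple[float, ...], ...] | None = None
    mean_dwell_s: Mapping[str, float] | None = None
    jitter_px: float = 0.0
    miss_prob: float = 0.0
    lying_zone: tuple[float, float, float, float] = (1080.0, 1720.0, 270.0, 400.0)
    body_length_px: float = 200.0
    margin_px: float = 40.0
    frame_size: tuple[int, int] = (1920, 1080)
    start_behavior: str = STANDING
    seed: int = 0

    def __post_init__(self) -> None:
        if self.duration_s < 0:
            raise ValueError("duration_s must be non-negative")
        if not set(_CORE_BEHAVIORS) <= set(self.behaviors):
            raise ValueError(f"behaviors must include {_CORE_BEHAVIORS}")
        if not 0.0 <= self.miss_prob <= 1.0:
            raise ValueError("miss_prob must lie in [0, 1]")
        if self.jitter_px < 0:
            raise ValueError("jitter_px must be non-negative")
        x0, x1, y0, y1 = self.lying_zone
        if not (x0 < x1 and y0 < y1):
            raise ValueError(f"invalid lying_zone {self.lying_zone!r}")
        if self.body_length_px <= 0:
            raise ValueError("body_length_px must be positive")
        if self.start_behavior not in self.behaviors:
            raise ValueError(f"unknown start_behavior {self.start_behavior!r}")
        t = self.jump_matrix()  # validates stochasticity
        assert t.shape == (len(self.behaviors),) * 2
        for b, mean in self.dwell().items():
            if mean < 1.0:
                raise ValueError(f"mean dwell for {b!r} must be >= 1 second, got {mean}")

    def dwell(self) -> dict[str, float]:
        dwell = dict(DEFAULT_MEAN_DWELL)
        if self.mean_dwell_s:
            dwell.update(self.mean_dwell_s)
        return {b: float(dwell.get(b, 30.0)) for b in self.behaviors}

    def jump_matrix(self) -> np.ndarray:
        """Validated row-stochastic matrix over behaviors (may include
        self-transitions; the diagonal is re-absorbed into dwell)."""
        k = len(self.behaviors)
        if self.transition_matrix is None:
            return _uniform_jump_matrix(k)
        t = np.asarray(self.transition_matrix, dtype=float)
        if t.shape != (k, k):
            raise ValueError(f"transition_matrix must be {k}x{k}")
        if (t < -1e-12).any() or np.abs(t.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValueError("transition_matrix rows must be non-negative and sum to 1")
        return np.clip(t, 0.0, None)

    def with_(self, **kwargs) -> "SimConfig":
        return replace(self, **kwargs)


def effective_transition_matrix(config: SimConfig) -> np.ndarray:
    """Per-second transition matrix of the semi-Markov chain.

    From state *i* the chain stays with probability ``1 - 1/mean_i``
    and otherwise jumps according to the off-diagonal part of the
    transition matrix (renormalised); a fully self-transitioning row is
    absorbing.  Geometric dwell with the configured mean follows.
    """
    behaviors = config.behaviors
    t = config.jump_matrix()
    dwell = config.dwell()
    k = len(behaviors)
    eff = np.zeros((k, k))
    for i, b in enumerate(behaviors):
        leave = 1.0 / dwell[b]
        off = t[i].copy()
        off[i] = 0.0
        total = off.sum()
        if total <= 0:  # absorbing state
            eff[i, i] = 1.0
            continue
        eff[i] = leave * off / total
        eff[i, i] = 1.0 - leave
    return eff


def simulate_behavior_sequence(config: SimConfig) -> AnnotationSeries:
    """Per-second ground-truth behavior labels from the semi-Markov model."""
    rng = np.random.default_rng(config.seed)
    behaviors = list(config.behaviors)
    eff = effective_transition_matrix(config)
    state = behaviors.index(config.start_behavior)
    labels = []
    for _ in range(config.duration_s):
        labels.append(behaviors[state])
        state = int(rng.choice(len(behaviors), p=eff[state]))
    return AnnotationSeries.from_labels(
        labels, individual="sim", categories=tuple(config.behaviors)
    )


# --- keypoint realisation -----------------------------------------------------


def _pose(anchor: np.ndarray, behavior: str, config: SimConfig) -> dict[str, float]:
    """Keypoint coordinates for one behavior, shoulder at ``anchor``."""
    length = config.body_length_px
    ax, ay = float(anchor[0]), float(anchor[1])
    if behavior == FORAGING:
        head_dy = 60.0 + config.margin_px + 20.0
        nose_dy = 90.0 + config.margin_px + 20.0
    else:
        head_dy = -0.1 * length  # head above shoulder: drop rules safely violated
        nose_dy = -0.05 * length
    rec = {
        "shoulder_x": ax,
        "shoulder_y": ay,
        "hip_x": ax + length,
        "hip_y": ay,
        "head_x": ax - 0.15 * length,
        "head_y": ay + head_dy,
        "nose_x": ax - 0.3 * length,
        "nose_y": ay + nose_dy,
    }
    for node in KEYPOINTS:
        rec[f"{node}_score"] = 1.0
    return rec


def _anchor_ok(anchor: np.ndarray, config: SimConfig) -> bool:
    """Shoulder and hip in-frame and clear of the lying zone by the margin."""
    length = config.body_length_px
    w, h = config.frame_size
    x0, x1, y0, y1 = config.lying_zone
    pad = config.margin_px
    for pt in (anchor, anchor + np.array([length, 0.0])):
        if not (pad <= pt[0] <= w - pad and pad <= pt[1] <= h - pad):
            return False
        if (x0 - pad) < pt[0] < (x1 + pad) and (y0 - pad) < pt[1] < (y1 + pad):
            return False
    return True


def realize_keypoints(
    sequence: AnnotationSeries, config: SimConfig
) -> tuple[PoseTrack, AnnotationSeries]:
    """Emit a 1-fps keypoint track whose geometry realises the sequence.

    For each second the four keypoints satisfy exactly the rule of the
    ground-truth behavior and violate the others by at least
    ``margin_px`` (image convention: y grows downward).  Locomotion
    seconds displace the hip/shoulder anchor by 0.75 body lengths,
    safely above the half-body-length rule; transitions that must stay
    sub-threshold (e.g. rising from the lying zone into Standing) move
    by well under half a body length.  Jitter and occlusion are applied
    after the geometry.  Returns the track and its ground-truth labels.
    """
    if config.jitter_px > 0 and config.margin_px <= config.jitter_px:
        warnings.warn(
            "geometry margin does not exceed coordinate jitter: "
            "classification rules may flip under noise",
            stacklevel=2,
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    x0, x1, y0, y1 = config.lying_zone
    lying_anchor = np.array([x0 + 120.0, y1 - 10.0])
    exit_dy = (y1 - lying_anchor[1]) + config.margin_px + 1.0
    anchor = np.array([400.0, 700.0])
    direction = np.array([1.0, 0.0])
    step = 0.75 * config.body_length_px

    labels = sequence.labels
    records = []
    prev_behavior: str | None = None
    for t, behavior in labels.items():
        if behavior == LYING:
            anchor = lying_anchor.copy()
        elif behavior == LOCOMOTION:
            if prev_behavior == LYING:
                # leave the zone downward; any >0.5 L jump is fine here
                anchor = anchor + np.array([0.0, step])
                direction = np.array([0.0, 1.0])
            else:
                moved = False
                for _ in range(4):
                    candidate = anchor + step * direction
                    if _anchor_ok(candidate, config):
                        anchor = candidate
                        moved = True
                        break
                    direction = np.array([-direction[1], direction[0]])  # rotate 90 deg
                if not moved:  # pragma: no cover - geometry always leaves an exit
                    anchor = anchor + step * direction
        elif prev_behavior == LYING:
            # rise out of the zone with a sub-threshold step
            anchor = anchor + np.array([0.0, exit_dy])
        rec = _pose(anchor, str(behavior), config)
        rec["frame"] = int(t)
        rec["time_s"] = int(t)
        records.append(rec)
        prev_behavior = str(behavior)

    df = pd.DataFrame(records, columns=_WIDE_COLUMNS) if records else pd.DataFrame(
        {c: pd.Series(dtype=float) for c in _WIDE_COLUMNS}
    )
    coord_cols = [f"{n}_{a}" for n in KEYPOINTS for a in ("x", "y")]
    if len(df):
        if config.jitter_px > 0:
            df[coord_cols] += rng.normal(0.0, config.jitter_px, size=(len(df), len(coord_cols)))
        if config.miss_prob > 0:
            missed = rng.random(len(df)) < config.miss_prob
            df.loc[missed, coord_cols + [f"{n}_score" for n in KEYPOINTS]] = np.nan
    track = PoseTrack(individual=sequence.individual or "sim", df=df)
    truth = AnnotationSeries(
        individual=track.individual, labels=labels.copy(), categories=sequence.categories
    )
    return track, truth


def simulate_observer(
    truth: AnnotationSeries,
    error_rate: float = 0.0,
    out_of_sight_rate: float = 0.0,
    seed: int = 0,
) -> AnnotationSeries:
    """Imperfect manual coder: random flips and out-of-sight seconds.

    Each second is independently recorded as Out of Sight with
    probability ``out_of_sight_rate``, or replaced by a uniformly
    random *different* category with probability ``error_rate``
    (out-of-sight takes precedence; the two probabilities may sum to at
    most 1).
    """
    for name, rate in (("error_rate", error_rate), ("out_of_sight_rate", out_of_sight_rate)):
        if not 0.0 <= rate <= 1.0:
            raise ValueError(f"{name} must lie in [0, 1]")
    if error_rate + out_of_sight_rate > 1.0 + 1e-12:
        raise ValueError("error_rate + out_of_sight_rate must not exceed 1")
    rng = np.random.default_rng(seed)
    cats = list(truth.categories)
    u = rng.random(len(truth.labels))
    out = truth.labels.copy()
    for pos, (t, lab) in enumerate(truth.labels.items()):
        if u[pos] < out_of_sight_rate:
            out.loc[t] = OUT_OF_SIGHT
        elif u[pos] < out_of_sight_rate + error_rate:
            others = [c for c in cats if c != lab]
            out.loc[t] = others[int(rng.integers(len(others)))]
    categories = tuple(cats) + ((OUT_OF_SIGHT,) if OUT_OF_SIGHT not in cats else ())
    return AnnotationSeries(individual=truth.individual, labels=out, categories=categories)


# --- study-level tables -------------------------------------------------------

PERIODS = ("control", "test")

#: Default manual-ethogram categories for study tables.
STUDY_CATEGORIES = ("Inactive", "Activity in Water", "Locomotion", "Foraging", "Scenting")

#: Baseline Dirichlet concentrations: mostly inactive, little scenting.
DEFAULT_CONCENTRATION = (8.0, 4.0, 3.0, 4.0, 1.0)


@dataclass(frozen=True)
class StudySimConfig:
    """Conditions for a two-period multi-individual enrichment study.

    Each (individual, period) cell draws one proportion vector per day
    from a Dirichlet with the cell's concentration vector; identical
    concentrations across periods give a null (no-effect) study.
    """

    individuals: tuple[str, ...] = ("male", "female", "calf")
    n_days_per_period: int = 8
    categories: tuple[str, ...] = STUDY_CATEGORIES
    concentrations: Mapping[tuple[str, str], Sequence[float]] | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_days_per_period < 1:
            raise ValueError("n_days_per_period must be >= 1")
        if len(self.individuals) < 1:
            raise ValueError("need at least one individual")
        for cell, alpha in self.cell_concentrations().items():
            if len(alpha) != len(self.categories) or np.any(np.asarray(alpha) <= 0):
                raise ValueError(f"invalid concentration vector for {cell}")

    def cell_concentrations(self) -> dict[tuple[str, str], np.ndarray]:
        base = np.asarray(DEFAULT_CONCENTRATION[: len(self.categories)], dtype=float)
        if len(base) < len(self.categories):
            base = np.concatenate([base, np.full(len(self.categories) - len(base), 2.0)])
        out = {}
        for ind in self.individuals:
            for period in PERIODS:
                out[(ind, period)] = base.copy()
        if self.concentrations:
            for cell, alpha in self.concentrations.items():
                out[cell] = np.asarray(alpha, dtype=float)
        return out

    def with_effect(self, category: str, shift: float, period: str = "test") -> "StudySimConfig":
        """Copy with concentration mass moved onto ``category`` in ``period``."""
        idx = self.categories.index(category)
        conc = {}
        for cell, alpha in self.cell_concentrations().items():
            alpha = alpha.copy()
            if cell[1] == period:
                alpha[idx] += shift
            conc[cell] = tuple(alpha)
        return replace(self, concentrations=conc)


def simulate_study_table(config: StudySimConfig) -> pd.DataFrame:
    """Daily behavior-proportion table (individual, period, day, category, proportion).

    Each day's proportions are one Dirichlet draw from the cell's
    concentration vector (independent, hence exchangeable, across
    days); per-day proportions sum to 1.
    """
    rng = np.random.default_rng(config.seed)
    conc = config.cell_concentrations()
    rows = []
    for ind in config.individuals:
        for period in PERIODS:
            draws = rng.dirichlet(conc[(ind, period)], size=config.n_days_per_period)
            for day in range(1, config.n_days_per_period + 1):
                for cat, p in zip(config.categories, draws[day - 1]):
                    rows.append(
                        {
                            "individual": ind,
                            "period": period,
                            "day": day,
                            "category": cat,
                            "proportion": float(p),
                        }
                    )
    return pd.DataFrame(rows, columns=["individual", "period", "day", "category", "proportion"])


# --- spatial point clouds -----------------------------------------------------


def simulate_tracking_points(
    n_points: int,
    components: Sequence[tuple[float, Sequence[float], Sequence[Sequence[float]] | float]],
    seed: int = 0,
    bounds: tuple[float, float] = (1920.0, 1080.0),
    individual: str = "sim",
    period: str = "control",
    interval_s: int = 15,
) -> pd.DataFrame:
    """Blueprint tracking points from a 2-D Gaussian mixture.

    ``components`` is a list of ``(weight, mean_xy, cov)`` where ``cov``
    may be a full 2x2 matrix or a scalar standard deviation; weights
    must sum to 1.  Points are clipped to the blueprint bounds and get
    synthetic timestamps every ``interval_s`` seconds.
    """
    weights = np.array([w for w, _, _ in components], dtype=float)
    if len(weights) == 0 or abs(weights.sum() - 1.0) > 1e-9 or (weights < 0).any():
        raise ValueError("component weights must be non-negative and sum to 1")
    rng = np.random.default_rng(seed)
    if n_points == 0:
        return pd.DataFrame(columns=["individual", "period", "time_s", "x", "y"])
    assignment = rng.choice(len(components), size=n_points, p=weights)
    xy = np.empty((n_points, 2))
    for k, (_, mean, cov) in enumerate(components):
        sel = assignment == k
        if not sel.any():
            continue
        mean = np.asarray(mean, dtype=float)
        cov_m = np.asarray(cov, dtype=float)
        if cov_m.ndim == 0:
            cov_m = np.eye(2) * float(cov_m) ** 2
        xy[sel] = rng.multivariate_normal(mean, cov_m, size=int(sel.sum()))
    xy[:, 0] = np.clip(xy[:, 0], 0.0, bounds[0])
    xy[:, 1] = np.clip(xy[:, 1], 0.0, bounds[1])
    return pd.DataFrame(
        {
            "individual": individual,
            "period": period,
            "time_s": np.arange(n_points) * interval_s,
            "x": xy[:, 0],
            "y": xy[:, 1],
        }
    )
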