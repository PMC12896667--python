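"""Geometric classification rules: static postures, locomotion, composition."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from ethopose import (
    AUTO_CATEGORIES,
    FORAGING,
    KEYPOINTS,
    LOCOMOTION,
    LYING,
    NOT_LABELED,
    STANDING,
    PoseTrack,
    RuleConfig,
    SimConfig,
    body_length,
    classify_static,
    classify_track,
    realize_keypoints,
    simulate_behavior_sequence,
)
from ethopose.pose_io import _WIDE_COLUMNS


def frame(**kp):
    """Build a frame mapping from keypoint (x, y) pairs; others absent."""
    rec = {f"{n}_{a}": math.nan for n in KEYPOINTS for a in ("x", "y", "score")}
    for node, (x, y) in kp.items():
        rec[f"{node}_x"], rec[f"{node}_y"] = x, y
        rec[f"{node}_score"] = 1.0
    return rec


def make_track(frames, individual="t"):
    rows = []
    for t, rec in enumerate(frames):
        rec = dict(rec)
        rec["frame"] = t
        rec["time_s"] = t
        rows.append(rec)
    df = pd.DataFrame(rows, columns=_WIDE_COLUMNS) if rows else pd.DataFrame(
        {c: pd.Series(dtype=float) for c in _WIDE_COLUMNS}
    )
    return PoseTrack(individual=individual, df=df)


class TestBodyLength:
    def test_three_four_five(self):
        assert body_length(frame(shoulder=(0, 0), hip=(3, 4))) == 5.0

    def test_coincident_points(self):
        assert body_length(frame(shoulder=(7, 7), hip=(7, 7))) == 0.0

    def test_matches_direct_formula(self, rng):
        for _ in range(50):
            sx, sy, hx, hy = rng.uniform(0, 1920, 4)
            expected = math.sqrt((hx - sx) ** 2 + (hy - sy) ** 2)
            assert body_length(frame(shoulder=(sx, sy), hip=(hx, hy))) == pytest.approx(expected)

    def test_missing_keypoint_raises(self):
        with pytest.raises(ValueError, match="undefined"):
            body_length(frame(shoulder=(0, 0)))


class TestStaticRules:
    def test_head_drop_fires_foraging(self):
        f = frame(shoulder=(500, 300), head=(500, 370), hip=(600, 300))
        assert classify_static(f) == FORAGING  # drop 70 >= 60

    def test_nose_drop_fires_foraging(self):
        f = frame(shoulder=(500, 300), nose=(480, 395), hip=(600, 300))
        assert classify_static(f) == FORAGING  # drop 95 >= 90

    def test_drop_threshold_is_inclusive(self):
        f = frame(shoulder=(500, 300), head=(500, 360), hip=(600, 300))
        assert classify_static(f) == FORAGING  # "at least" 60

    def test_lying_zone_beats_foraging(self):
        # shoulder inside the resting zone: Lying Down regardless of head
        f = frame(shoulder=(1400, 300), head=(1400, 500), hip=(900, 300))
        assert classify_static(f) == LYING

    def test_zone_boundary_inclusive(self):
        f = frame(shoulder=(900, 900), hip=(1080, 400))
        assert classify_static(f) == LYING

    def test_all_keypoints_absent(self):
        assert classify_static(frame()) == NOT_LABELED

    def test_head_nose_missing_falls_to_standing(self):
        # hip/shoulder present but foraging rule cannot be evaluated
        f = frame(shoulder=(500, 300), hip=(600, 300))
        assert classify_static(f) == STANDING

    @given(
        st.lists(
            st.tuples(
                st.sampled_from(KEYPOINTS),
                st.floats(0, 1920),
                st.floats(0, 1080),
            ),
            max_size=4,
            unique_by=lambda t: t[0],
        )
    )
    def test_every_frame_gets_exactly_one_category(self, kps):
        f = frame(**{n: (x, y) for n, x, y in kps})
        assert classify_static(f) in AUTO_CATEGORIES

    @given(
        st.floats(100, 900),
        st.floats(100, 1000),
        st.floats(60, 200),
        st.floats(90, 300),
    )
    def test_raising_thresholds_never_adds_foraging(self, sx, sy, head_drop, nose_drop):
        f = frame(shoulder=(sx, sy), head=(sx, sy + 80), nose=(sx, sy + 110), hip=(sx + 50, sy))
        low = classify_static(f, RuleConfig())
        high = classify_static(f, RuleConfig(head_drop_px=head_drop, nose_drop_px=nose_drop))
        if low != FORAGING:
            assert high != FORAGING


class TestLocomotion:
    @staticmethod
    def standing_frame(x, y=700):
        return frame(shoulder=(x, y), hip=(x + 200, y), head=(x - 30, y - 20))

    def test_stationary_track_has_no_locomotion(self):
        track = make_track([self.standing_frame(400)] * 10)
        labels = classify_track(track).labels
        assert (labels == STANDING).all()

    def test_exact_half_body_length_stays_standing(self):
        # body length 200, displacement exactly 100: "exceeded" is strict
        track = make_track([self.standing_frame(400), self.standing_frame(500)])
        assert list(classify_track(track).labels) == [STANDING, STANDING]

    def test_above_half_body_length_fires(self):
        track = make_track([self.standing_frame(400), self.standing_frame(501)])
        assert list(classify_track(track).labels) == [STANDING, LOCOMOTION]

    def test_first_second_never_locomotion(self):
        track = make_track([self.standing_frame(400)])
        assert list(classify_track(track).labels) == [STANDING]

    def test_zero_body_length_cannot_fire(self):
        f0 = frame(shoulder=(400, 700), hip=(400, 700))
        f1 = frame(shoulder=(900, 700), hip=(900, 700))
        track = make_track([f0, f1])
        assert list(classify_track(track).labels) == [STANDING, STANDING]

    def test_missing_previous_keypoints_block_locomotion(self):
        track = make_track([frame(), self.standing_frame(900)])
        assert list(classify_track(track).labels) == [NOT_LABELED, STANDING]

    def test_infinite_fraction_kills_locomotion(self):
        track = make_track([self.standing_frame(200 + 400 * i) for i in range(5)])
        config = RuleConfig(locomotion_fraction=1e9)
        assert LOCOMOTION not in set(classify_track(track, config).labels)

    def test_displacement_rule_variants(self):
        # body length 200 at t; hip moves 160, shoulder 60: mean 110 > 100
        # fires, "both" does not (shoulder alone stays below threshold)
        f0 = frame(shoulder=(400, 700), hip=(500, 700))
        f1 = frame(shoulder=(460, 700), hip=(660, 700))
        track = make_track([f0, f1])
        assert classify_track(track, RuleConfig(displacement_rule="mean")).labels.iloc[1] == LOCOMOTION
        assert classify_track(track, RuleConfig(displacement_rule="both")).labels.iloc[1] == STANDING
        assert classify_track(track, RuleConfig(displacement_rule="max")).labels.iloc[1] == LOCOMOTION


class TestClassifyTrack:
    def test_empty_track_empty_series(self):
        assert len(classify_track(make_track([]))) == 0

    def test_occluded_middle_second_isolated(self):
        good = TestLocomotion.standing_frame(400)
        track = make_track([good, frame(), good])
        assert list(classify_track(track).labels) == [STANDING, NOT_LABELED, STANDING]

    def test_matches_independent_reimplementation(self):
        """A straight-line re-implementation of the rules agrees on 1000 s."""
        sim = SimConfig(duration_s=1000, jitter_px=3.0, miss_prob=0.05, margin_px=40.0, seed=42)
        track, _ = realize_keypoints(simulate_behavior_sequence(sim), sim)
        config = RuleConfig()

        def oracle(df):
            x0, x1, y0, y1 = config.lying_zone
            recs = df.to_dict("records")
            out = []
            for i, r in enumerate(recs):
                pts = {
                    n: (r[f"{n}_x"], r[f"{n}_y"])
                    for n in KEYPOINTS
                    if not (np.isnan(r[f"{n}_x"]) or np.isnan(r[f"{n}_y"]))
                }
                if "hip" not in pts and "shoulder" not in pts:
                    out.append(NOT_LABELED)
                    continue
                lying = any(
                    x0 <= pts[n][0] <= x1 and y0 <= pts[n][1] <= y1
                    for n in ("hip", "shoulder")
                    if n in pts
                )
                if lying:
                    out.append(LYING)
                    continue
                label = STANDING
                if "shoulder" in pts:
                    if "head" in pts and pts["head"][1] - pts["shoulder"][1] >= 60:
                        label = FORAGING
                    elif "nose" in pts and pts["nose"][1] - pts["shoulder"][1] >= 90:
                        label = FORAGING
                out.append(label)
            for i in range(1, len(recs)):
                if out[i] != STANDING:
                    continue
                prev, cur = recs[i - 1], recs[i]
                ok = all(
                    not np.isnan(f[f"{n}_{a}"])
                    for f in (prev, cur)
                    for n in ("hip", "shoulder")
                    for a in ("x", "y")
                )
                if not ok:
                    continue
                d_hip = math.hypot(cur["hip_x"] - prev["hip_x"], cur["hip_y"] - prev["hip_y"])
                d_sh = math.hypot(
                    cur["shoulder_x"] - prev["shoulder_x"],
                    cur["shoulder_y"] - prev["shoulder_y"],
                )
                bl = math.hypot(
                    cur["hip_x"] - cur["shoulder_x"], cur["hip_y"] - cur["shoulder_y"]
                )
                if (d_hip + d_sh) / 2 > 0.5 * bl:
                    out[i] = LOCOMOTION
            return out

        assert list(classify_track(track, config).labels) == oracle(track.df)


class TestRuleConfig:
    def test_invalid_zone_rejected(self):
        with pytest.raises(ValueError):
            RuleConfig(lying_zone=(100, 50, 0, 10))

    def test_yaml_round_trip(self, tmp_path):
        config = RuleConfig(head_drop_px=70, lying_zone=(1.0, 2.0, 3.0, 4.0))
        path = tmp_path / "rules.yaml"
        config.to_yaml(path)
        assert RuleConfig.from_yaml(path) == config
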