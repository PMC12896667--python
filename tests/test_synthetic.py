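"""Generators: behavior sequences, keypoint realisation, observer, study tables."""

import numpy as np
import pandas as pd
import pytest

from ethopose import (
    FORAGING,
    LOCOMOTION,
    LYING,
    NOT_LABELED,
    STANDING,
    AnnotationSeries,
    SimConfig,
    StudySimConfig,
    classify_track,
    effective_transition_matrix,
    realize_keypoints,
    simulate_behavior_sequence,
    simulate_observer,
    simulate_study_table,
    simulate_tracking_points,
)
from ethopose.synthetic import OUT_OF_SIGHT

BEHAVIORS = (STANDING, LYING, FORAGING, LOCOMOTION)


def identity_matrix():
    return tuple(tuple(1.0 if i == j else 0.0 for j in range(4)) for i in range(4))


class TestBehaviorSequence:
    def test_absorbing_identity_chain(self):
        config = SimConfig(duration_s=50, transition_matrix=identity_matrix(), seed=1)
        seq = simulate_behavior_sequence(config)
        assert set(seq.labels) == {STANDING}

    def test_zero_duration_empty_sequence(self):
        assert len(simulate_behavior_sequence(SimConfig(duration_s=0))) == 0

    def test_non_stochastic_matrix_rejected(self):
        bad = tuple(tuple(0.3 for _ in range(4)) for _ in range(4))
        with pytest.raises(ValueError, match="sum to 1"):
            SimConfig(transition_matrix=bad)

    def test_reproducible_given_seed(self):
        a = simulate_behavior_sequence(SimConfig(duration_s=300, seed=9))
        b = simulate_behavior_sequence(SimConfig(duration_s=300, seed=9))
        assert a.labels.equals(b.labels)

    def test_empirical_frequencies_match_stationary_distribution(self):
        """Uniform 4-state chain: state frequencies sit within 3 standard
        errors of the stationary distribution found by eigen-analysis."""
        dwell = {b: 2.0 for b in BEHAVIORS}
        config = SimConfig(duration_s=10000, mean_dwell_s=dwell, seed=5)
        seq = simulate_behavior_sequence(config)

        # independent construction of the per-second chain + eigen-analysis
        k = len(BEHAVIORS)
        eff = np.full((k, k), (1.0 / 2.0) / (k - 1))
        np.fill_diagonal(eff, 1.0 - 1.0 / 2.0)
        assert np.allclose(eff, effective_transition_matrix(config))
        vals, vecs = np.linalg.eig(eff.T)
        pi = np.real(vecs[:, np.argmax(np.real(vals))])
        pi = pi / pi.sum()

        counts = seq.labels.value_counts()
        n = len(seq)
        # effective sample size shrunk by the geometric dwell (mean 2 s)
        n_eff = n / (2 * 2.0)
        for i, b in enumerate(BEHAVIORS):
            freq = counts.get(b, 0) / n
            se = np.sqrt(pi[i] * (1 - pi[i]) / n_eff)
            assert abs(freq - pi[i]) < 3 * se


class TestRealizeKeypoints:
    def test_foraging_geometry_by_construction(self):
        seq = AnnotationSeries.from_labels([FORAGING] * 5, categories=BEHAVIORS)
        track, _ = realize_keypoints(seq, SimConfig(duration_s=5))
        drop = track.df["head_y"] - track.df["shoulder_y"]
        assert (drop >= 60).all()

    def test_lying_geometry_by_construction(self):
        seq = AnnotationSeries.from_labels([LYING] * 5, categories=BEHAVIORS)
        config = SimConfig(duration_s=5)
        track, _ = realize_keypoints(seq, config)
        x0, x1, y0, y1 = config.lying_zone
        inside = (
            track.df["hip_x"].between(x0, x1) & track.df["hip_y"].between(y0, y1)
        ) | (
            track.df["shoulder_x"].between(x0, x1) & track.df["shoulder_y"].between(y0, y1)
        )
        assert inside.all()

    def test_total_occlusion_means_all_not_labeled(self):
        config = SimConfig(duration_s=20, miss_prob=1.0, seed=3)
        track, _ = realize_keypoints(simulate_behavior_sequence(config), config)
        labels = classify_track(track).labels
        assert set(labels) == {NOT_LABELED}

    def test_margin_not_exceeding_jitter_warns(self):
        seq = AnnotationSeries.from_labels([STANDING] * 3, categories=BEHAVIORS)
        with pytest.warns(UserWarning, match="margin"):
            realize_keypoints(seq, SimConfig(duration_s=3, jitter_px=50.0, margin_px=40.0))

    def test_bit_reproducible(self):
        config = SimConfig(duration_s=200, jitter_px=2.0, miss_prob=0.1, seed=21)
        seq = simulate_behavior_sequence(config)
        t1, _ = realize_keypoints(seq, config)
        t2, _ = realize_keypoints(seq, config)
        pd.testing.assert_frame_equal(t1.df, t2.df)

    def test_noise_free_round_trip_is_exact(self):
        """End-to-end oracle: clean tracks classify to ground truth exactly."""
        config = SimConfig(duration_s=3000, seed=17)
        track, truth = realize_keypoints(simulate_behavior_sequence(config), config)
        predicted = classify_track(track)
        assert (predicted.labels.to_numpy() == truth.labels.to_numpy()).all()


class TestObserver:
    def truth(self, n=100):
        config = SimConfig(duration_s=n, seed=2)
        return simulate_behavior_sequence(config)

    def test_perfect_observer_is_identity(self):
        truth = self.truth()
        out = simulate_observer(truth, error_rate=0.0, out_of_sight_rate=0.0, seed=1)
        assert out.labels.equals(truth.labels)

    def test_forced_flip_with_two_categories(self):
        truth = AnnotationSeries.from_labels(["A", "B", "A", "B"], categories=("A", "B"))
        out = simulate_observer(truth, error_rate=1.0, seed=1)
        assert list(out.labels) == ["B", "A", "B", "A"]

    def test_disagreement_fraction_binomial(self):
        truth = self.truth(5000)
        out = simulate_observer(truth, error_rate=0.2, seed=0)
        frac = (out.labels != truth.labels).mean()
        se = np.sqrt(0.2 * 0.8 / 5000)
        assert abs(frac - 0.2) < 3 * se

    def test_out_of_sight_rate(self):
        truth = self.truth(5000)
        out = simulate_observer(truth, out_of_sight_rate=0.3, seed=8)
        frac = (out.labels == OUT_OF_SIGHT).mean()
        assert abs(frac - 0.3) < 3 * np.sqrt(0.3 * 0.7 / 5000)

    def test_invalid_rates_rejected(self):
        truth = self.truth(10)
        with pytest.raises(ValueError):
            simulate_observer(truth, error_rate=0.7, out_of_sight_rate=0.5)


class TestStudyTable:
    def test_one_day_per_period_counts(self):
        config = StudySimConfig(individuals=("a", "b"), n_days_per_period=1, seed=1)
        table = simulate_study_table(config)
        for ind in ("a", "b"):
            cell = table[table["individual"] == ind]
            assert set(zip(cell["period"], cell["day"])) == {("control", 1), ("test", 1)}

    def test_daily_proportions_sum_to_one(self):
        table = simulate_study_table(StudySimConfig(seed=4))
        sums = table.groupby(["individual", "period", "day"])["proportion"].sum()
        assert np.allclose(sums, 1.0, atol=1e-9)

    def test_shifted_concentration_orders_medians(self):
        config = StudySimConfig(individuals=("a",), n_days_per_period=30, seed=6)
        config = config.with_effect("Scenting", shift=30.0)
        table = simulate_study_table(config)
        by = table[table["category"] == "Scenting"].groupby("period")["proportion"].median()
        assert by["test"] > by["control"]

    def test_reproducible_given_seed(self):
        a = simulate_study_table(StudySimConfig(seed=3))
        b = simulate_study_table(StudySimConfig(seed=3))
        pd.testing.assert_frame_equal(a, b)

    def test_days_exchangeable_within_cell(self):
        """Same Dirichlet for every day of a cell: per-day means are
        statistically indistinguishable (a permutation-flavored sanity check)."""
        config = StudySimConfig(individuals=tuple(f"i{k}" for k in range(40)), seed=9)
        table = simulate_study_table(config)
        sub = table[(table["period"] == "control") & (table["category"] == "Inactive")]
        day_means = sub.groupby("day")["proportion"].mean()
        grand = sub["proportion"].mean()
        se = sub["proportion"].std() / np.sqrt(len(sub) / config.n_days_per_period)
        assert (np.abs(day_means - grand) < 4 * se).all()


class TestTrackingPoints:
    def test_degenerate_component_collapses_to_mean(self):
        pts = simulate_tracking_points(50, [(1.0, (500.0, 400.0), 0.0)], seed=1)
        assert np.allclose(pts["x"], 500.0) and np.allclose(pts["y"], 400.0)

    def test_zero_points_empty(self):
        pts = simulate_tracking_points(0, [(1.0, (0, 0), 1.0)], seed=1)
        assert len(pts) == 0

    def test_component_occupancy_matches_weights(self):
        pts = simulate_tracking_points(
            10000,
            [(0.8, (300.0, 300.0), 20.0), (0.2, (1600.0, 900.0), 20.0)],
            seed=11,
        )
        near_first = np.hypot(pts["x"] - 300, pts["y"] - 300) < 300
        se = np.sqrt(0.8 * 0.2 / 10000)
        assert abs(near_first.mean() - 0.8) < 3 * se

    def test_points_clipped_to_bounds(self):
        pts = simulate_tracking_points(
            2000, [(1.0, (0.0, 0.0), 500.0)], seed=2, bounds=(1920.0, 1080.0)
        )
        assert pts["x"].between(0, 1920).all() and pts["y"].between(0, 1080).all()

    def test_bad_weights_rejected(self):
        with pytest.raises(ValueError, match="weights"):
            simulate_tracking_points(10, [(0.5, (0, 0), 1.0)], seed=1)
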