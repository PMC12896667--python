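"""Simulate a focal-observation bout and classify it from keypoint geometry.

Generates 10 minutes of semi-Markov behavior for one animal, realises a
1-fps four-keypoint track with mild coordinate jitter and occlusion,
classifies every second with the geometric rules, and prints per-second
agreement with the known ground truth plus both time budgets.
"""

import ethopose as ep

sim = ep.SimConfig(duration_s=600, jitter_px=2.0, miss_prob=0.03, seed=42)
sequence = ep.simulate_behavior_sequence(sim)
track, truth = ep.realize_keypoints(sequence, sim)
predicted = ep.classify_track(track)

agreement = (predicted.labels.to_numpy() == truth.labels.to_numpy()).mean()
print(f"per-second agreement with ground truth: {agreement:.1%}")
print("\nseconds per behavior (truth vs automated):")
truth_budget = ep.cumulative_budget(truth, truth.categories)
auto_budget = ep.cumulative_budget(predicted, predicted.categories)
for category in predicted.categories:
    print(f"  {category:<20} {truth_budget.get(category, 0):>5}  {auto_budget[category]:>5}")
print(
    "\nDisagreements come only from occluded frames (classified Not Labeled)"
    " and jitter at rule boundaries; with jitter and occlusion at zero the"
    " agreement is exactly 100%."
)
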