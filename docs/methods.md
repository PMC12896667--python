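# Methods

## Scope and model

`ethopose` post-processes four-keypoint pose tracks (nose, head,
shoulder, hip; pixel coordinates, y-down image convention) into
per-second behavior labels and runs the downstream comparisons a
behavioral-enrichment study needs.  The classifier is deliberately
rule-based rather than learned: with so few keypoints, the terrestrial
behaviors of a large, slow-moving animal are separable by explicit
geometry, and explicit rules keep every decision auditable.

### Classification rules and conventions

Rules are evaluated per second in fixed precedence:

| order | label | condition | default thresholds |
|---|---|---|---|
| 1 | Not Labeled | hip **and** shoulder undetected | — |
| 2 | Lying Down | hip **or** shoulder inside the resting-zone rectangle | (1080, 1720, 270, 400) px, boundaries inclusive |
| 3 | Foraging/Feeding | head ≥ 60 px **or** nose ≥ 90 px below the shoulder | comparisons are `≥` ("at least") |
| 4 | Standing | none of the above (default behavior) | — |
| 5 | Locomotion | static label Standing, and combined hip/shoulder displacement since *t−1* **>** `0.5 × L` | strict `>` ("exceeded"); `L` = hip-to-shoulder distance at *t* |

Decisions that the rule statement leaves open, fixed here:

* **Precedence** Lying Down is tested before Foraging/Feeding: a lying
  animal's head is typically low, and zone membership is the stronger
  cue.  Foraging-vs-lying co-firing is therefore resolved in favor of
  Lying Down.
* **"Displacement of hip and shoulder"** means the arithmetic mean of
  the two keypoint displacements; `max` and `both-exceed` variants are
  available via `RuleConfig.displacement_rule`.
* **Body length** is taken from the current frame; a zero body length
  disables the locomotion rule (the fraction is meaningless).
* **Missing keypoints** void a second only when hip and shoulder are
  both absent.  If head and nose are missing but hip/shoulder present,
  the foraging rule simply cannot fire and the second falls through to
  Standing — partial information is used, not discarded.
* The first observed second can never be Locomotion (no predecessor),
  and a gap or occluded predecessor blocks the rule for that second.
* The zone constants assume a 1920×1080 frame; both are configurable.

### Evaluation

The confusion matrix counts predicted (rows) against manual (columns)
labels over co-observed seconds.  The manual "Out of View"/"Out of
Sight" category and the automated "Not Labeled" both mean "no behavior
scorable that second" and are paired as a single axis category.
Per-class metrics are one-vs-rest; 0/0 ratios are reported as NaN, never
as 0.  Golden-value tests reproduce a published 5×5 validation matrix's
full metric table at 3 decimals (half-up rounding, matching the printed
precision).

Kendall's W uses mid-ranks and the tie-corrected denominator; with
five distinct cumulative durations ties are rare but must not crash the
statistic.  Significance uses the large-sample χ² approximation
`m(n−1)W` on `n−1` df — the only approximation consistent with the
reference p-values (for χ² with 4 df the closed form
`p = e^(−x/2)(1 + x/2)` maps W = 0.95, m = 2 to p = 0.107 and W = 0.50
to p = 0.406 only when n = 5 items are ranked, i.e. the four behaviors
plus the out-of-view pairing; this inference is encoded as a regression
test).  Exact permutation p-values are out of scope.

### Non-parametric statistics

Daily behavior proportions (after excluding out-of-sight time) are the
sampling unit; daily medians damp within-day autocorrelation.  The
tests delegate to scipy behind this module's surface: Mann–Whitney U
with tie and continuity corrections under the normal approximation
(the common software default even at n = 8 days; exact p behind a
flag), Pearson χ² without Yates correction on 2×k second-count tables
(full-distribution design by default, one-vs-rest 2×2 per behavior as
the pairwise option), and Fligner–Killeen normal-scores dispersion.
Each is verified against a from-the-definition brute-force oracle in
the test suite.  No multiple-testing correction is applied by default
(raw p-values are the reporting convention); Benjamini–Hochberg is
available as `adjust_pvalues`.

### Heat maps

Tracking points (one per 15 s of visibility) are binned on a 64×36
grid over the 1920×1080 blueprint (30 px cells), smoothed with a
Gaussian kernel (default σ = 2 cells = 60 px) using reflecting
boundaries — which conserve total mass for a symmetric kernel — and
normalised to unit mass.  Histogram-plus-smoothing was chosen over
kernel density estimation for exact mass control and speed; difference
maps subtract two normalised grids and sum to zero.  Boundary points
are clipped to edge cells.  Maps are qualitatively, not numerically,
comparable to manually produced study figures, whose estimator and
bandwidth are unknown.

## Synthetic data: what it emulates, what it does not

The generators exist so that every pipeline stage can be tested against
known ground truth.

* **Behavior sequences** follow a semi-Markov chain: geometric
  (memoryless) dwell per behavior — the simplest model consistent with
  per-second sampling — with the mean dwell encoded as a per-second
  self-transition probability, and jumps drawn from the off-diagonal
  part of the transition matrix.  Default dwell means (Standing 20 s,
  Lying 120 s, Foraging 40 s, Locomotion 5 s) are order-of-magnitude
  placeholders — long rests, brief travel bouts — not field estimates;
  no per-second dwell statistics for captive pygmy hippos exist to
  calibrate against.  Sequences start in Standing by default; a
  first-second Locomotion label would be unexpressable (no predecessor
  frame to displace from).
* **Keypoint realisation** places poses so each second satisfies
  exactly its behavior's rule and violates the others by a margin
  (default 40 px, against the default body length of 200 px):
  locomotion steps are 0.75 L (vs. the 0.5 L threshold), transitions
  that must stay sub-threshold (rising from the resting zone into
  Standing) move ≈ 0.25 L, and standing head posture sits 80 px clear
  of the foraging threshold.  Gaussian jitter and whole-frame occlusion
  (all four keypoints dropped jointly; partial dropout is off by
  default) are applied after the geometry, so with zero noise the
  classifier must agree with ground truth on 100% of seconds — the
  end-to-end oracle.  A margin ≤ jitter triggers a warning.
* **The simulated observer** flips each second to a uniformly random
  different category with probability `error_rate` or records Out of
  Sight with probability `out_of_sight_rate` (out-of-sight takes
  precedence; the rates may sum to at most 1).
* **Study tables** draw one proportion vector per day from a
  per-(individual, period) Dirichlet (baseline concentration
  (8, 4, 3, 4, 1) over Inactive, Activity in Water, Locomotion,
  Foraging, Scenting — mostly inactive, little scenting; two periods of
  8 days, three individuals).  Identical concentrations across periods
  give an exact null for type-I-error checks; `with_effect` shifts
  concentration mass onto one category to plant an effect.
* **Tracking points** come from 2-D Gaussian mixtures clipped to the
  blueprint; a weight shift toward a scent coordinate plants a
  recoverable density change.

None of this emulates real pose-estimation error structure (confusion
between visually similar postures, identity swaps, systematic
occlusion by enclosure furniture) or real behavioral rhythms
(diurnality, autocorrelated dwell).  Passing round-trip tests therefore
demonstrates internal consistency of generator + classifier + statistics,
not field performance of any pose model.

## Pre-processing conventions

Down-sampling keeps the first frame of each output-rate bin (an actual
observed pose, matching per-second snapshot semantics) and requires an
integer rate ratio; composing two down-samplings equals the single
composed one.  Duplicate tracks — multiple tracks following one
animal — are detected by mean inter-track keypoint distance over
co-visible seconds (the rule is an automated surrogate for what is
usually a manual review); the lower-scoring, then shorter, track is
dropped, and the operation is idempotent.  Times are integer seconds
after down-sampling; sub-second alignment is out of scope.

## Problem sizes and numerical conventions

Round-trip checks use 12 000-second tracks; the type-I-error experiment
uses 1000 replicate single-individual 8-day studies; spatial recovery
uses 100 replicates of 3000 points per period.  These sizes put the
Monte-Carlo standard error well inside the asserted tolerances (e.g.
±0.7% on a 5% rejection rate) while keeping the default suite fast.
All generators take explicit integer seeds and are bit-reproducible;
the pipeline derives stage seeds by fixed offsets from the run seed, so
a seeded run is byte-identical.  Statistical tolerances in tests are
stated as multiples of the relevant binomial/stationary standard error.

## Known limitations

* Only terrestrial behaviors are classified; water-based and social
  behaviors need different cues than a fixed zone and vertical drops.
* The resting-zone rule is camera- and enclosure-specific by
  construction; reusing it requires re-deriving the rectangle.
* The Mann–Whitney normal approximation is slightly conservative at
  n = 8 days (empirical type-I ≈ 4%).
* Kendall's W with n = 5 items has low power; non-significance at high
  W is expected behavior of the approximation, not a defect.
* The CLI is a thin convenience layer; the library API is the primary
  interface.
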