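# Methods

`dyadkin` quantifies mother–infant interaction from two synchronised 3D
skeleton streams ("interaction imaging"): each partner is tracked by her
own RGB-D sensor during a short tabletop play session, the two sensor
streams are placed in one spatial frame and on one clock, and a fixed
17-element vector of individual and dyadic motion features is extracted
and validated against expert interaction ratings (CIB composites) and a
group label. This note documents the models, the parameters that matter,
the synthetic-data generator, and the numerical and design choices.

## Data model

A `SkeletonStream` is one partner's time-stamped joint trajectories
(metres) plus a face-forward head-orientation unit vector, in a named
coordinate frame. Missing data are first-class: every joint carries a
per-frame validity mask, readers never drop invalid frames, and every
downstream operation propagates the masks. Units are metres and seconds
throughout; timestamps are absolute session seconds. Gaps up to
`max_gap` (default 0.33 s, about 10 frames at the 30 Hz default rate)
are linearly interpolated during resampling; longer gaps remain invalid.
Orientation vectors are re-normalised after interpolation, falling back
to the nearest valid sample when interpolated vectors cancel.

## Co-registration

**Space.** The transform between the two sensors is rigid (rotation +
translation, no scale), fitted by the SVD-based least-squares solution
(Kabsch/Umeyama) to corresponding 3D points such as chessboard corners
seen by both sensors. Rigid rather than projective is appropriate
because both sensors deliver metric 3D points. Reflections are excluded
by the usual sign correction; fewer than 3 correspondences or collinear
points raise a degenerate-geometry error, since the rotation about the
common axis is then unconstrained.

**Time.** The clock offset is the arg-max of the normalised
cross-correlation of two 1-D synchronisation envelopes (hand claps
recorded by both microphones), searched over ±`max_lag` (default 2 s).
The discrete peak is refined to sub-sample precision by a parabola
through its two neighbours; refinement is skipped when either flank is
non-positive (an isolated impulse has no meaningful curvature and the
discrete lag is already exact). Whether sub-frame alignment is wanted is
exposed as an option (`subsample_offset`).

`align_dyad` maps the infant stream through the rigid transform, shifts
its timestamps onto the mother clock, and resamples both streams onto a
shared uniform grid over their temporal overlap (at least 1 s required).

## Motion features

Let `p_j[i]` be joint `j` at frame `i` and `dt` the frame interval.

- **Quantity of movement (QoM)**: `qom[i] = Σ_j ‖p_j[i] − p_j[i−1]‖ / dt`
  over the configured joints (default head + both hands when present;
  else all available). A frame is valid only if every requested joint is
  valid at both ends of the difference.
- **Motion activity**: `qom > threshold` (default 0.05 m/s on the summed
  head+hands speed — well above tracker jitter, well below deliberate
  tabletop movement), then a morphological closing followed by opening
  with window `min_duration` (default 0.25 s), so neither flickers nor
  sub-perceptual blips count as state changes. The morphology runs on
  the validity-compressed sequence: a tracking dropout is a
  non-observation, not stillness, so it neither splits a bout nor lets a
  short flanked fragment be deleted. A single-frame series has no time
  base and is returned unsmoothed. **Activity ratio** is the moving
  fraction of valid frames.
- **Heads distance**: per-frame inter-head Euclidean distance (mean/sd
  over jointly valid frames). **Contributions**: head displacements are
  projected on the previous frame's inter-head axis; to first order the
  two projections sum to the distance change. Shares aggregate approach
  and withdrawal symmetrically via absolute values and sum to 1; a fully
  static pair is (0.5, 0.5) by convention.
- **Face-to-face ratio**: fraction of jointly valid frames where *each*
  partner's head orientation is within 30° (default) of the other's
  head. **Task ratio** (per partner): same test against a configured 3D
  task point (the table centre; it is configuration, not auto-detected).
  Frames with coincident head and target are skipped as undefined.
- **Synchrony ratio** (directional): the fraction of one partner's
  movement onsets (still→moving edges on the validity-compressed state)
  answered by an onset of the other within `(0, window]` (default 3 s).
  `sync_parent_to_infant` is the mother's response rate to infant
  initiations. Onset-based rather than windowed-correlation-based; with
  no leader onsets the ratio is NaN (undefined, not an error), with no
  responder onsets it is 0.
- **Overlap / pause ratio**: fraction of jointly valid frames where both
  move / neither moves. Overlap + pause + exactly-one-moving = 1 on
  every session.

The canonical 17-vector is: 4 QoM mean/sd + 2 activity ratios + 2
heads-distance mean/sd + 2 contributions + face-to-face + 2 task ratios
+ 2 directional synchrony ratios + overlap + pause. QoM and distance
standard deviations use the sample convention (ddof = 1; 0 when fewer
than two valid frames). All features are invariant under a global rigid
transform of the common frame (with the task point transformed along)
and under time translation.

## Validation statistics

- **Spearman's rho** is the Pearson correlation of mid-ranks. The
  two-sided p-value uses the exact permutation distribution for n ≤ 10
  and the t approximation (n − 2 df) above.
- **Holm step-down** controls family-wise error. The family is, by
  default, each composite's 17 tests (`per_composite`), with a 136-test
  `global` option; cells with a constant or too-short series are NaN and
  leave the family.
- **Group tests**: Mann–Whitney/Wilcoxon rank-sum (W reported in the
  Mann–Whitney U convention of `x`; exact for combined n ≤ 20 without
  ties, else normal approximation with tie correction) and Fisher's
  exact test (two-sided hypergeometric summation; conditional-ML odds
  ratio). A published 6/4 vs 4/6 sex table is sometimes quoted with
  p = 0.82 and OR = 1.81; the standard exact test on that table gives
  p = 0.6563, and this package follows the standard definition.
- **Classification**: rows are shuffled by the seed, split by stratified
  k-fold, and per fold standardised (training statistics only) and fit
  with a linear-kernel SVM (C = 1). Reported: per-fold accuracies,
  pooled held-out accuracy, whole-data training accuracy, pooled 2×2
  confusion matrix. The default k = 15 follows the published protocol's
  "15 cross-validation", which is under-specified for 20 dyads: with 10
  per group, stratified folds beyond k = 10 must miss a class, and the
  implementation raises with advice to lower k. Cohort-level analyses in
  this package therefore use k = 10, the largest stratified choice a
  10-per-group cohort admits.

## Synthetic dyads

The generator emulates the study envelope — 4-minute sessions at 30 Hz,
two partners at a small table — with the minimal latent structure whose
ground truth maps one-to-one onto the features:

- **Activity**: a two-state Markov chain per partner; on-rate α
  (still→moving) and off-rate β give stationary activity α/(α+β).
  Defaults α = 0.10/s, β = 0.15/s (activity 0.4, mean bouts 6.7 s
  moving / 10 s still — unhurried tabletop play).
- **Response coupling**: with probability `p_respond_mother`, an infant
  onset schedules a mother onset after a uniform lag in `(0, window]`.
  The response is realised as ~0.35 s of forced stillness followed by a
  forced bout, so every coupled response is observable as an onset
  event; without this, responses arriving while the mother already
  moved would be invisible and the planted coupling unidentifiable from
  the raw synchrony ratio.
- **Kinematics**: while moving, each joint's deviation from a resting
  pose integrates an Ornstein–Uhlenbeck velocity (correlation 0.3 s,
  mean speed `speed_scale` = 0.15 m/s per joint) with a weak spring to
  the pose; while still the pose is frozen. Temporally correlated
  measurement jitter (sd 0.5 mm, correlation 1 s) is always added, and
  frames are dropped per partner with probability 0.02.
- **Gaze**: exponential-duration bouts (mean 2 s) directed at the
  partner, the task, or elsewhere (the "elsewhere" direction is sampled
  at least 40° away from both targets, keeping the per-partner
  face/task ratios identifiable).
- **Cohorts**: two group presets differ in maternal activity, maternal
  responsiveness and mutual gaze, in the directions of the reported
  feature–composite correlation profile (the at-risk preset: more
  maternal movement, higher movement responsiveness, less mutual gaze,
  less joint pausing). CIB-like composites are clamped-to-[1,5]
  monotone functions of the true generator parameters (z-scored,
  combined with documented signs, e.g. reciprocity increasing in joint
  stillness, avoidance decreasing in mutual gaze) plus Gaussian noise
  (gain 0.7, sd 0.25).

**What the generator does not emulate**: biomechanics and posture,
object manipulation, facial expression and speech, heavy-tailed or
non-stationary activity, rater idiosyncrasies in the composites, and
correlated sensor failures. Passing recovery tests therefore shows the
*estimators* are correct and identifiable under the stated generative
model — not that the feature set captures everything about real dyads.

### Recovery-test operating points

Parameter-recovery tolerances interact with the switching rates through
the occupancy variance `2 a(1−a) τ / T` (τ = 1/(α+β), T the session
length) and the chance-response rate `λ = (1−a)·α` within the response
window. Two operating points are used, chosen from these expressions:

- occupancy recovery at α = 0.4, β = 0.6 (per-session sd ≈ 0.036, so a
  4-minute session identifies activity within ±0.05);
- coupling recovery at α = 0.05, β = 0.075 (analytic chance-response
  level 1 − exp(−λ·3 s) ≈ 0.086, so the raw synchrony ratio identifies
  a planted response probability within ±0.1).

At the defaults, the same quantities are 0.09 and 0.165: a single
4-minute session simply does not pin the occupancy that tightly, and a
busier responder raises the chance floor — which is a property of the
measurement, not of the estimator.

## Numerical choices and degenerate inputs

File round-trips are written with 12 significant digits (round-trip
error ≤ 1e-9 m). Resampled grids are exactly `t0 + k/rate`; resampling
a uniformly sampled stream at its own rate is the identity on valid
frames. The angle thresholds are inclusive. Equal-magnitude opposite
orientations interpolating to zero fall back to the nearest valid
sample. Static dyads yield zero QoM/activity/overlap, pause 1 and
undefined (NaN) synchrony; the classifier refuses NaN features
explicitly rather than imputing silently. All randomness in simulation
and classification flows from explicit integer seeds, and identical
seeds give bit-identical outputs.

## Known limitations

- The feature definitions are explicit reconstructions of briefly named
  quantities; alternative readings (windowed-correlation synchrony,
  jointly-defined task orientation) are possible and the config exposes
  the knobs that would matter.
- The Holm family composition ("per composite" vs "global") changes
  which cells survive; both are implemented, neither is canonical.
- With 10 dyads per group, held-out accuracy has a granularity of 0.05
  and a wide null distribution; the null-cohort check bounds it only
  loosely.
- The CSV/XML schemas are this package's own; no claim is made of
  reading any vendor's native export.
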