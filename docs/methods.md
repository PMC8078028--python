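# Methods

`smtgaze` re-implements, as a tested pipeline, the analysis chain of an
eye-tracked Search-and-Match (match-3) task used as an adjunct cognitive
marker in older adults: single-solution puzzle boards, 120 Hz binocular
gaze and mouse streams, constraint-based fixation/saccade extraction,
target/distractor area-of-interest (AOI) metrics, and rank correlations
against neuropsychological assessment scores. Raw participant recordings
from the original pilot were stored locally and never deposited, so the
package pairs the analysis chain with (a) packaged per-subject tables
(13 assessment records; 8 eye-movement metric rows) from which the
published statistics are recomputed exactly, and (b) a synthetic-data
generator with known ground truth against which every processing stage
is validated.

## Puzzle boards

A board is a `height x width` grid (both 4–8) of 4–8 tile types. A valid
initial board contains no line of three identical tiles, and exactly one
pair of orthogonally adjacent tiles whose swap creates such a line (the
*target pattern*); every other swap is a false move that bounces back.
`enumerate_solving_swaps` tries each adjacent swap exhaustively and is
the solvability oracle; a swap can only create lines through its two
cells, so detection is restricted to those windows (an optimisation that
does not change the result, and the tests re-verify boards with a fully
naive oracle that copies the grid per swap).

Uniform rejection sampling is not viable for generation: random
run-free boards at 8x8 with few tile types have on the order of 15–25
solving swaps, so the probability of exactly one is essentially zero.
`generate_board` instead (1) plants a target configuration — two tiles
of the match line in place, the third arriving via the solving swap —
and protects those cells; (2) fills the remaining cells in row-major
order, choosing uniformly among tile types that do not complete a run of
three; (3) repairs the board by re-typing one tile of a randomly chosen
unwanted solving swap's post-swap match line until the planted swap is
the only solution, restarting from a fresh fill if a repair destroys the
planted solution. The result is re-checked with the exhaustive oracle
before being returned. Identical seeds give identical boards. Median
repair counts range from ~10 (small boards, many types) to ~1500 (8x8
with 4 types); the pairing of the largest boards with the fewest tile
types is the hard corner and can exhaust the retry budget, which raises
a `GenerationError` rather than silently degrading. Difficulty levels in
practice pair larger boards with more tile types, and the default
12-level test set does so.

*Distractor patterns* are operationalised as the minimal configurations
that visually suggest a near-match: same-type adjacent pairs and gapped
(`X.X`) pairs in a row or column, excluding patterns lying entirely
inside the target's AOI. They are recorded per board, not controlled.

A session is 3 fixed training levels of incremental difficulty —
(width, height, tiles) = (4,4,4), (5,5,5), (6,6,6) — followed by 12 test
levels in seeded random order, 4 boards per level. The original study
did not publish its 12 test-level triples; the default set covers the
eight board sizes for which per-set-size metrics were reported plus four
larger boards, and is overridable.

Screen geometry defaults to a 1920x1080 px display with the board
centered and 100 px square tiles; grid coordinates are 0-based
(row, col) with row 0 at top, and tile rectangles are half-open pixel
intervals with a top-left origin, matching gaze-sample conventions.

## Fixation extraction

Candidate fixations are grown by greedy temporal chaining over the
combined (left/right mean) gaze point of each valid sample: a sample
joins the open cluster while it is within 64 px of the *immediately
preceding sample* of the cluster (chain distance, not distance to the
running centroid — the literal reading that keeps the rule well defined
online) and within 3 nominal sample periods (25 ms) of it. Invalid or
dropped samples do not break a cluster by themselves; only the time gap
does. A closed cluster is retained iff all five selection constraints
hold: duration >= 100 ms (first to last member timestamp), >= 5 samples,
every chain step < 64 px, left-eye centroid within 100 px of the
right-eye centroid, and position scatter <= 100 px. Scatter is computed
as the root of the mean of the per-axis population variances of the
combined points about their centroid — one scalar in pixels. All five
thresholds are parameters of `FixationParams`.

Whether the original implementation clustered each eye's stream
separately before merging is unknown; clustering the combined point is
symmetric in the eyes (the output is invariant under swapping left/right
labels, which is property-tested) and matches the convention that a
fixation's center is the mean of its included data points.

Saccades are defined between consecutive retained fixations: duration is
the start of the current fixation minus the end of the previous one;
distance is the Euclidean separation of their combined centroids. With
sparse retained fixations these inter-fixation gaps can be long —
saccade "durations" of seconds are gaps between usable fixations, not
physiological saccade flight times.

Subjects whose session yields fewer than `min_fixations` (default 10,
configurable; the original cutoff was described only qualitatively) are
excluded with a per-subject reason, mirroring the pilot's 13 -> 8
attrition from calibration problems and corrective glasses.

## AOI classification and game metrics

A fixation credits one hit per *target* tile whose rectangle intersects
the disc of radius `edge_tol` (default 5 px) around the fixation
centroid; a centroid on the shared edge of two target tiles therefore
counts as two fixations on targets. The tolerance disc is our geometric
operationalisation of the published edge rule, which states the outcome
but not the rule. A fixation with no target hit counts once on
distractors if the disc touches any distractor-pattern tile, else it is
"other". Consequently the total fixation count can exceed the sum of
target and distractor hits (fixations on other tiles) or fall short of
it (edge double counts) — both directions occur and are asserted in
tests.

* **Visual search time**: board initiation to the start timestamp of the
  first target-labelled fixation; missing when a board has none (boards
  where no fixation on the target was recorded are reported as
  unavailable rather than zero).
* **Effective search time**: accumulated mouse-movement time. An
  inter-sample interval counts as movement when displacement exceeds
  2 px/sample *or the button is held down*: a click-held drag is
  purposeful movement even when slow, and slow drags between adjacent
  tiles (100 px over 0.4–0.8 s at 120 Hz ≈ 1–2 px/sample) would
  otherwise be invisible to a pure displacement threshold. Accumulation
  ends at the completing drag's release.
* **Board completion time**: initiation to correct-move completion
  (mouse release); summed over boards this is the game completion time.

Per-subject summaries report means and sample SDs over boards (SD of a
single value is reported as 0; missing values propagate and means use
available boards only). Per-set-size summaries group by `WxH` label.
Multiple subsequent target fixations before the move are all counted.
Fixation ellipses for rendering use the member-point mean as center,
twice the per-axis SD as width/height, and an opacity increasing with
duration, clipped to (0, 1].

## Synthetic data generator

The generator emulates the *statistical structure* of a recorded
session, not eye physiology. Per board, the scanpath follows the
inefficient-serial-search account: `k ~ Poisson(exec_slowness * n_distractors)`
distractor dwells (cells sampled without immediate repetition, excluding
tiles shared with the target AOI so every dwell has an unambiguous
label), then one or more target-AOI dwells, the last always on the
target. `exec_slowness` is the latent subject parameter standing in for
the executive-function component that drives fixation counts; cohort
profiles couple it linearly (plus Gaussian noise) to a synthetic
Trail-Making-B score so the end-to-end pipeline's direction-recovery can
be tested. Dwell durations are truncated normal (default mean 250 ms,
SD 80 ms) floored at 120 ms so that every ground-truth dwell is
detectable under the 100 ms selection threshold; saccadic gaps are
20–80 ms.

Rendering emits 120 Hz samples on a grid anchored at board initiation:
during a dwell, both eyes sit on the tile center, separated horizontally
by `inter_eye_offset` and perturbed by per-eye isotropic Gaussian noise;
samples are dropped i.i.d. at `dropout_rate`. Saccades are rendered
ballistically: at 120 Hz a saccade's traverse (peak velocities of
hundreds of deg/s) fits within about one sample period, so gap samples
sit on the departing tile for the first half of the gap and on the
arriving tile for the second half. Ground truth records the *landing*
time (gap midpoint) as the first-target time, which is what any
sample-level detector can see. The mouse idles on the advance button in
the bottom-right screen corner, repositions to the swap's first tile
(0.3–0.6 s), pauses, then drags to the second tile (0.4–0.8 s) with the
button held; the release ends the board.

Not modelled: smooth pursuit, pupil dynamics, blink kinematics (blinks
appear only as dropout), calibration drift, and any spatial bias of
search order. Passing recovery tests therefore shows the pipeline is
correct on data matching its assumptions, not that it is robust to every
real-world artefact; the degradation knobs (dropout, large inter-eye
disagreement) exercise the exclusion rules but are simple i.i.d.
mechanisms.

## Statistics

Spearman's coefficient is computed as the Pearson correlation of
mid-ranks (ties receive average ranks), with two-sided p-values from the
t approximation (`t = rho * sqrt((n-2)/(1-rho^2))`); an exact permutation
p-value over all n! orderings is available for the tiny cohort sizes
where it is feasible. Missing values are deleted pairwise, so each
variable pair reports its own n. First-order partial correlation uses
`r_xy.z = (r_xy - r_xz r_yz) / sqrt((1-r_xz^2)(1-r_yz^2))` with the
pairwise coefficients computed rank-based or product-moment, p from the
t approximation with n-3 df; it matches an explicit
residual-regression oracle to 1e-10 in tests. Significance is flagged at
p < .05 with deliberately no multiple-testing adjustment (exploratory
analysis). Descriptives report means, sample SDs (n-1) and ranges with
column-wise missing exclusion.

The Cramér-V companion is an interpretation: a correlation has no unique
contingency-table equivalent, and published V values of 0.2 next to
rho ≈ 0.83–0.87 at n = 8 are not reproduced by any standard formula we
know. We derive chi-squared = n·rho² with one degree of freedom, giving
V = |rho|; the computation is isolated in one overridable function,
monotone in |rho| and zero at independence, and never alters rho or p.
Covariate-controlled coefficients for the published age-controlled
analysis are likewise not reproduced: the original report mixes rank and
product-moment notation and repeats a row with conflicting values, so
the partial-correlation operation is provided without asserting those
numbers.

Known data discrepancies, recorded rather than patched: the published
cohort age summary (mean 70.67, SD 4.75) does not match recomputation
from the tabulated ages (70.85, 4.60), and the published TMT-B range
(47.05–128.74 s) excludes one subject's 173.00 s even though the mean
includes it. The packaged fixtures transcribe the tables as printed; the
recomputed age summary is reported without a comparison value.

## Problem sizes and determinism

Acceptance-style checks run at these sizes: 1000 generated boards (40
per width x height combination, tile counts 4–8 with at least 5 on
boards of 40+ cells), ~4000 candidate clusters for the
constraint-completeness check, 80 noiseless boards for ground-truth
recovery, 400 random vectors (n <= 10, tie-heavy and continuous) plus 50
triples for the statistical oracles, and 200 replicates of an
8-subject, 4-board cohort for direction recovery. All randomness flows
from explicit seeds (`random.Random` for board search, numpy
`default_rng` elsewhere); per-subject generator seeds are recorded in
session metadata. Timestamps are seconds since session start on one
shared clock (no epoch is defined for the original recordings).

## Limitations

The generator's scanpath is memoryless within a board (no inhibition of
return beyond immediate-repetition avoidance, no systematic grid
scanning). The fixation chain rule inherits the known I-DT-style
sensitivity to slow drift (a sub-threshold drift accumulates into one
high-scatter cluster, which the position-SD constraint then discards
wholesale). Effective search time depends on the mouse sampling being
dense and the drag being flagged; streams without click flags fall back
to pure displacement thresholding. Board generation at 8x8 with 4 tile
types is slow (~1 s) and can fail within its budget; callers needing
that corner should raise `max_repair_iters`.
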