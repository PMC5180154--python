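# Methods

This note documents the models, conventions and numerical choices behind
shoaltrack, and what the synthetic-data tests do and do not demonstrate.

## Coordinate frame and cleaning chain

Raw tracker tables are in pixels; all analysis happens in centimetres
with the arena centre at (0, 0). The default calibration is 0.029 cm per
pixel (a 29 cm arena spanning 1000 px). Some set-ups quote 0.03 cm/px for
a 30 cm arena; both numbers are configurable (`ArenaGeometry.pixel_scale`,
`radius_cm`) and the 29 cm/1000 px pair is the default because the
normalised video, not the physical dish, defines the data's scale. The
nominal 15 cm physical radius still matters in one place: the 3 cm edge
zone is 20% of it.

Cleaning runs in a fixed order, once:

1. **Out-of-arena deletion.** Any point with radial distance > R becomes
   missing. These are overwhelmingly mirror reflections of fish swimming
   against the wall, picked up by the tracker as detections outside the
   dish.
2. **Speed filter.** A point is deleted when the displacement from the
   previous *present* frame exceeds v_max/f (default 91 cm/s at 25 Hz →
   3.64 cm/frame). Only the later point of the offending pair is removed,
   and the scan is sequential, so a single identity-swap teleport costs
   one point rather than invalidating its neighbours. Whether the
   original published analyses removed one or both endpoints is generally
   unstated; one-endpoint deletion is the minimal-loss choice.
3. **Gap interpolation.** A gap qualifies when it is strictly shorter
   than one second (at 25 Hz: at most 24 missing frames) and the five
   frames on each side are all present. x(t) and y(t) are then fitted
   independently by a least-squares cubic over the ten flanking frames
   and evaluated inside the gap. A single best-fitting cubic — rather
   than a shape-preserving spline such as PCHIP — is used deliberately:
   it reproduces straight-line and cubic paths exactly (the properties
   the unit tests pin down), it is the natural reading of "the polynomial
   which best approximates the missing values", and its occasional
   overshoot is bounded by the fourth derivative of the path over a ≤1.4 s
   window. Filled points that land outside the disc are radially clamped
   to R, which keeps the arena invariant; the five-frame context is used
   both as the eligibility condition and as the fitting window.

After the chain, no point lies outside the arena and no per-frame speed
exceeds v_max; re-running the chain is a no-op (verified by test).
Downstream metrics ignore whatever is still missing — no further
imputation.

## Behavioural variables

* **Stillness** is defined at the pixel scale: displacement < 0.029 cm
  per frame. Restated per second that is 0.725 cm/s, conventionally
  quoted as 0.7 cm/s.
* **Exploration grid.** 1 × 1 cm squares, corner-aligned on the arena
  centre. Under the default `intersects_disc` convention a cell belongs
  to the arena when its nearest point lies *strictly* inside the disc
  (the strict inequality is what makes a radius-1 arena have exactly
  4 cells rather than also counting the tangent ones). For R = 14.5 cm
  this yields 724 cells. Published grid counts for nominally similar
  arenas differ (e.g. 788), because the grid's alignment and the
  in-disc rule are rarely stated; the convention here is explicit,
  logged, and configurable (`centre_in_disc` as the alternative), and
  all fractions are relative to the package's own cell count.
* **Exploration threshold.** "Explore 10%" means ⌈0.10 · n_cells⌉
  distinct cells, so the target is attainable by whole cells; the time
  is the first frame at which the count is reached, in seconds, and is
  missing (reported NaN) if never reached.
* **Neighbour radius.** The local-neighbour proportion counts group-mates
  within the dataset-wide median of all pairwise inter-fish distances,
  pooled over frames, pairs and trials. When no pooled radius is supplied
  the documented fallback default is 6.9 cm. Frames in which the focal
  fish is missing are excluded from its denominators; pairs with a
  missing member contribute nothing to distance pools, and missing
  conspecifics are simply not "within radius".
* **Analysis units.** Profiles are per fish by default (ten rows per
  trial); `MetricsConfig(per_trial=True)` aggregates to one row per trial
  (pooled medians for speed and nearest-neighbour distance, means for the
  bounded proportions). Group-living fish are not independent, so
  condition-level inference in the acceptance script uses trial-level
  rows; fish-level rows are appropriate for the real-versus-null contrast
  where the question is about the population of individuals.

## Null model

Each simulated fish is an independent correlated random walk:

    x(t+1) = x(t) + v(t) cos(θ(t) + ω(t))
    y(t+1) = y(t) + v(t) sin(θ(t) + ω(t))
    θ(t+1) = θ(t) + ω(t)

with v (cm/frame) and ω (rad/frame) drawn uniformly with replacement from
pools harvested from cleaned trajectories: v is every valid per-frame
displacement; ω is the wrapped difference of successive step headings,
contributed only when both displacements are at least one pixel (sub-pixel
moves have no defined direction). The heading recursion θ ← θ + ω is the
only reading under which ω is an angular *speed*.

Steps leaving the arena are replaced by the radial mirror r → 2R − r at
the same polar angle. By default the heading is *not* altered by
reflection: the next ω draw is independent anyway, so the extra mechanism
would be invisible in distribution. The exception is degenerate
diagnostics (ω ≡ 0), where an unturning fish would otherwise point
outward forever and chatter at the wall; `reflect_heading=True` mirrors
the heading at the wall and produces the expected straight
billiard chords (median realised speed exactly the coded v). Points
beyond 2R cannot be mirrored inside and are clamped to the centre with a
warning — unreachable while every pooled v is below R.

Initial conditions (not derivable from the published descriptions of such
models): positions uniform over the disc, headings uniform on (−π, π].
The synthetic school generator uses the same initialisation so that
school-versus-null comparisons are not confounded by the transient.
Reproducibility: one master seed spawns an independent substream per
replicate.

Pools are pooled across all fish and trials (not per condition); the
real-versus-null contrast then asks what the *population's* kinematics
fail to explain.

## Statistics

* z-scoring uses ddof = 1; zero-variance columns raise, naming the
  variable.
* PCA is the eigendecomposition of the correlation matrix of the z-scored
  7-variable matrix. The top k = 3 components (a fixed, configurable
  retention choice) are varimax-rotated with Kaiser normalisation
  (SVD algorithm, tolerance 1e−8, ≤1000 iterations). Rotation preserves
  communalities and the total retained variance; per-component shares are
  reattributed. Sign convention: each rotated component is flipped so its
  largest-magnitude loading is positive (signs are otherwise arbitrary).
  Scores use the regression method, W = R⁻¹L. Orthogonally rotated scores
  are not guaranteed uncorrelated, so the score correlation matrix is
  reported rather than asserted diagonal.
* Condition models: per-component score ~ condition (treatment-coded
  against "ambient") with a random intercept for experiment number
  (batches of arenas recorded simultaneously). p-values are Wald-z
  (normal approximation) from statsmodels MixedLM; with trial- or
  fish-level sample sizes in this design the normal approximation is
  adequate, and its calibration is verified empirically (type-I error
  within the binomial band over 500 simulated null cohorts). Singular
  fits are reported with a flag, not raised.
* Fish that never reach the 10% exploration threshold have their time
  imputed as the trial duration — censoring at the recording length,
  conservative in the direction of "slow" — and the imputation count is
  carried in the matrix metadata.
* Real-versus-null comparison: for the five variables not coded into the
  simulation, an ordinary linear model on data type (real = 1), plus a
  median-centred (Brown–Forsythe) Levene test per variable.

## Synthetic schooling generator

The generator exists so every stage is testable without any real videos;
it is a minimal kernel designed to produce controllable, qualitatively
correct contrasts, not a validated schooling model. Per frame, each
fish's heading change is

    ω = noise + a · wrap(bearing-to-centroid − θ) + w · wrap(bearing-to-ring − θ)

with wrapped-normal noise (σ = 0.6 rad/frame by default), centroid
attraction gain a (sociability), and steering gain w toward a thigmotaxis
target that blends the wall tangent (in the sense closest to the current
heading) with a radial correction toward a preference ring at
R − `wall_preference_inset_cm`. Per-frame speed is 0 with the stillness
probability, otherwise exponential with mean `speed_scale`, capped at
3.5 cm/frame so clean kinematics always pass the 91 cm/s filter.
Positions reflect at the boundary like the null model.

The ring-target formulation (rather than steering at the bare wall
tangent) is a deliberate design choice: pure tangent steering entangles
boldness with cohesion — strong tangential steering disperses a school
along the rim, while a cohesive school averages away individual heading
noise and locks onto the wall — and that entanglement destroys the
independent-axes structure the planted-cohort tests require.

Defaults (the package's standing study conditions, chosen once from
design sweeps of the kernel): a = 0.02, w = 0.12, inset 1.5 cm, stillness
0.30, speed scale 0.18 cm/frame, σ = 0.6. At these values a 10-fish,
6-minute trial shows a pooled median inter-fish distance near 7 cm,
moderate wall use, and median speeds of 1–2 cm/s — the right order for
juvenile shoaling fish in a 29 cm dish. Trial length defaults to 9 000
frames (6 min); the full 60-minute recording is one parameter away.

**Artifact injection** corrupts a clean trial into tracker-style pixel
output: missed-detection gaps (rate per fish-frame; lengths 1–40 frames),
mirror-reflection spikes at radius (R, 1.2 R], and identity swaps
(25–250-frame windows exchanged between two fish). A ground-truth ledger
records every corruption, so tests can require, e.g., that out-of-arena
deletions equal injected spikes exactly, and that eligible gaps are
refilled to < 0.1 cm on smooth paths.

**Planted three-factor cohort** (`generate_cohort_for_pca`): 26 trials
draw three independent latents — sociability → attraction gain
(0.03–0.12), boldness → preferred wall offset (5.5 → 2.0 cm inset at
fixed gain 0.25), activity → speed scale (0.14–0.16 cm/frame) with
inversely tied stillness (0.34 → 0.30). Boldness maps to the preferred
*offset*, not the steering gain, because gain variation couples edge use
to realized cohesion and coverage; offset variation yields an edge-use
axis empirically orthogonal to the other two (established by regressing
trial-level metrics on the planted latents). The latent draws use a
correlation-reduced Latin-hypercube design so the axes are independent
in-sample, not merely in expectation — at n = 26, chance correlations of
|r| ≈ 0.2 would otherwise leak across blocks.

**Heterogeneous cohort** (`HETEROGENEOUS_LATENT_SD`): across-trial latent
spread (attraction sd 0.012, wall gain sd 0.06, stillness sd 0.08, speed
sd 0.04) representing the group-to-group variability of real fish; used
for real-versus-null comparisons, where greater real-arm variance is
itself part of the expected signal.

## What the synthetic tests do and do not show

Passing tests show the *pipeline* is correct: metrics equal brute-force
recomputations, cleaning recovers known corruption, the simulator obeys
its physics, the PCA/rotation machinery recovers structure that is truly
present, and the mixed models are calibrated under their own assumptions.
They do not show that real fish have three behavioural axes, nor validate
the schooling kernel as a model of fish — the kernel's interactions are
deliberately minimal, it has no body size, vision cone, burst-and-coast
gait, or depth, and its artifact model is a caricature of real tracker
failure modes. Quantities estimated from real recordings (e.g. the 6.9 cm
neighbour radius of one published dataset) will differ from synthetic
values; the package recomputes all dataset-dependent quantities from the
data at hand.

Block-structure recovery at the study's own scale (26 trials) is subject
to cohort-level sampling noise: the coverage variables (% explored and
time-to-10%) share school-level path randomness, and in roughly half of
random cohorts the % explored off-block loading edges slightly above the
0.3 criterion used in the fixed-seed test. The test pins the package's
default seed; the robustness margin, not just the point result, is the
honest summary.

## Problem sizes and runtime choices

Test-suite and acceptance runs use 6-minute (9 000-frame) trials, the
full 26-trial × 10-fish design, 500-replicate mixed-model calibration at
fish-level size, and 10⁴-frame simulator invariant runs. These sizes were
chosen so the whole suite completes in about a minute while every check
operates at the design's real group structure; all are parameters, and
nothing in the code depends on the reduced durations.

## Known limitations

* The LMM p-values are normal-approximation Wald tests; no Satterthwaite
  or Kenward–Roger correction (calibration is verified by simulation for
  the design actually used).
* Gap interpolation can, in principle, overshoot on sharply curving paths
  within a one-second window; the radial clamp bounds but does not remove
  this.
* The tracker reader is convention-tolerant (delimiters, optional header,
  optional frame column) but does not parse every historical idTracker
  sidecar format; metadata travel in a YAML sidecar instead.
* Bayesian or equivalence-testing (TOST) treatments of "no condition
  difference" are out of scope.
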