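# Methods

This note documents the models, algorithms and design choices behind
`tmtgaze`, in the order data flows through the pipeline.

## Coordinate conversion

Gaze arrives in screen pixels (origin top-left, y downward). Angular
coordinates use a per-axis arctangent about the screen center:
θ = atan((p − c) · pitch / d), with pitch the physical pixel size and d
the viewing distance. This is exact at all on-screen eccentricities
(no small-angle linearization), trivially invertible (round-trip
< 1e-9 px), and distances are Euclidean in (θx, θy). The default
geometry is a 36 × 27 cm display at 1024 × 768 px viewed from 71 cm,
the standard chin-rest desktop-tracker setup.

## Event detection

Saccades are runs of samples whose angular speed exceeds 30 °/s **or**
whose acceleration exceeds 8000 °/s²; sub-threshold runs are fixations.
Speed is the central difference of position over a configurable window
(default 3 samples at 1000 Hz); acceleration is the central difference
of that scalar speed; edge samples copy their nearest interior value so
every sample is labelled. Event intervals abut (each event's offset is
the next event's onset within a valid segment), so durations partition
the recorded span exactly.

Commercial trackers' online parsers are proprietary; this detector is
faithful to the published thresholds but not guaranteed
sample-identical to any vendor's output. Velocity-model differences are
confined to the window parameter, which is exposed and documented.

Blink handling is conservative: runs of ≥ 2 invalid samples become
blink intervals that terminate any open event; events are never
interpolated across blinks. An isolated single invalid sample is
bridged by linear interpolation, since one lost sample at 1000 Hz does
not evidence an eyelid closure.

Fixations whose centroids are closer than 1° merge iteratively
left-to-right (duration-weighted centroid, re-checked against the next
fixation until stable), and the saccade between two merged fixations is
absorbed. There is no minimum fixation duration by default
(`min_fix_dur = 0`, configurable).

## Trial scoring

Eight measures per completed trial. Classification of a fixation uses a
3.25°-diameter circle (AOI) around each target center: *guiding* if it
contains the fixation and the target is the one pending at the
fixation's **onset** (a fixation cannot be guided by a target that
becomes current only after it starts); *searching* if the fixation
falls in any other target's AOI (nearest center wins, ties to the
current target); *unassigned* otherwise. Unassigned fixations count in
`n_fixations` but in neither subtype (so the subtypes need not sum to
the total; a flag restricts the total to classified fixations).

The eye-hand span of target k is the hit-click time minus the onset of
the *first* guiding fixation on k that begins after k became current.
Targets never fixated this way yield missing spans — never zero, which
would bias the mean. Spans are strictly positive and bounded by the
trial duration. Scanpath length is the summed Euclidean angular
distance between consecutive fixation centroids (robust to raw-sample
noise, standard in the scanpath literature; not the raw-sample path or
the saccade-amplitude sum). Trial duration runs from the start signal
to the final hit; missed clicks (which do not advance the sequence) are
part of the trial.

## Synthetic data

The generator exists so every downstream stage is testable; its
distributional choices are scaffolding with the right qualitative
structure, not claims about any particular dataset.

- **Layouts**: each target takes a distinct field of a 5×5 screen grid,
  displaced by uniform jitter (default ±1°), rejection-sampled until
  all pairwise distances reach `min_sep` (default 2°, at least the
  1.35° target circle). 25 targets for the test, 8 for training;
  part B relabels to the alternating number/letter sequence. Layouts
  are *not* matched across test halves by default (matching is a flag,
  for studying the layout confound).
- **Trials**: per target, a Poisson number of searching fixations on
  other targets, then guiding fixation(s) on the current target held
  until the click. The click lands around the target center with
  condition-dependent precision and must fall inside the 1.35° circle;
  misses re-click after a delay. The eye-hand span is drawn log-normal;
  longer holds spawn guiding re-fixations at ~1/s. Condition
  multipliers encode the trade-off: speed emphasis scales searching
  counts by 0.65 and spans by 1.35/1.95 (so simulated part-A means land
  near ~70 s under accuracy and ~28 s faster under speed); part B
  scales searching by 1.5 and adds 0.3 s to spans. Defaults: 160 ms
  median fixation duration, 1.95 s accuracy-emphasis span, 2 searching
  fixations per target, 0.3° fixation scatter.
- **Ground-truth recoverability**: fixation landing offsets are
  truncated at min(3 SD, 95% of the AOI radius, 95% of half the minimum
  target separation), and consecutive fixations are re-drawn to sit
  beyond the merge distance when the scatter allows it. Consequently
  the emitted role labels are recovered exactly by AOI classification,
  and rendered raw samples (position held per fixation, linear ~300 °/s
  ramps between fixations) survive detection + merging with the
  fixation count intact. This also means the generator under-represents
  two features of real data: ambiguous fixations between AOIs and
  oculomotor dynamics (no main sequence, no drift/tremor). Passing
  tests therefore certify the pipeline's bookkeeping and statistics,
  not detector performance on noisy biological signals.
- **Score tables**: `simulate_scores` draws directly from the
  random-intercept model y = Xβ + u_j + ε for the 2×2 design. Defaults
  follow the trial-duration structure (β = (72.55, 22.97, −28.18,
  14.20) s, subject SD 17.22 s, residual SD 20.9 s, 58 subjects).
- All randomness flows from one seed through `numpy` `SeedSequence`
  spawning.

## Mixed models

One random intercept per subject. With λ = σ_u²/σ_e², both β (GLS) and
σ_e² have closed forms given λ, and the restricted likelihood reduces
to a 1-D profiled deviance
`(n−p)·log(r'V⁻¹r/(n−p)) + log|V| + log|X'V⁻¹X| + const`,
minimized over log λ on [−23, 18.4] by bounded scalar search
(tolerance 1e-8), with the λ = 0 boundary checked explicitly so
no-subject-variance data collapse exactly to OLS. Grouped structure
makes each evaluation O(J p²) via Sherman–Morrison
(V_j⁻¹ = I − λ/(1+λn_j)·11'). REML is the default; ML is available for
likelihood comparisons.

Fixed effects are dummy-coded with reference levels part A and
accuracy. Wald 95% intervals use z = 1.96 — an approximation to profile
intervals, with correspondingly small discrepancies expected in small
samples. p-values are de-emphasized: the default uses residual degrees
of freedom; a Satterthwaite variant derives per-coefficient df from the
numerically-differentiated REML information of (σ_u², σ_e²). Transforms
use the natural log; the count/span/path measures (n_fixations,
n_searching, eye-hand span, scanpath length) are modelled on that
scale. Missing responses are dropped per measure (complete case), with
the fitted group and observation counts always reported.

## Dominance analysis

Within one test half the design leaves instruction as the only fixed
factor, so the per-half models are: fixed-only (instruction contrasts),
random-only (subject indicators), and intercept-only. Bayes factors use
the Zellner–Siow formulation for ANOVA designs: the grand mean gets a
flat prior, σ² a Jeffreys prior, and standardized effects a common g
per block with g ~ scaled-inverse-χ²(1, r²) — a Cauchy scale on effect
size. Fixed factors are projected onto orthonormal (a−1)-dimensional
contrasts with r = 0.5; the subject block keeps its full indicator
columns with r = 1.0 (the usual "nuisance" scale). Both scales are
configurable and recorded in every result. These defaults follow the
convention of the reference Bayesian-ANOVA software; agreement with any
specific package is approximate (same order of magnitude or better),
as it depends on that package's internal contrast standardization.

After integrating mean, σ² and effects analytically, the BF against the
null reduces to a 1-D integral over g, computed by deterministic
quadrature on a log grid: a coarse scan (401 points over g ∈ [1e-15,
1e15]) locates the integrand's mass, a dense trapezoid (4097 points)
refines the region within e⁻⁴⁶ of the peak, all in log space. Results
are reproducible to ~1e-6 relative tolerance and match brute-force
dense integration to well under 1% on small tables. The BF is exactly
location-scale invariant in the response.

The quotient BF_fixed / BF_random exceeds 1 iff the fixed-effects model
beats the random-effects model against the common null; the verdict
threshold sits at 1 (qualitative reading). Marginal and conditional R²
come from the variance decomposition of the random-intercept fit:
R²m = var(Xβ̂)/(var(Xβ̂)+σ̂_u²+σ̂_e²), R²c adds σ̂_u² to the numerator
(population variance of the fixed-effect predictions). Their 95%
intervals are percentile cluster bootstraps resampling **subjects**
with replacement (preserving within-subject dependence; the resampling
unit was an open choice, and the subject is the exchangeable unit
here), B = 1000 by default; failed refits are dropped and counted.

## Problem sizes and numerical choices

Study-scale checks in the test suite use 58 subjects with the
trial-duration variance structure: 500 replicates for SE recovery,
200+200 for dominance direction, and 200 outer replications × B = 1000
bootstrap replicates for R² interval coverage — sizes chosen so the
whole suite completes in minutes on one core while keeping Monte-Carlo
error well inside the asserted tolerances. Degenerate inputs fail
loudly: zero-variance responses (BF), zero total variance (R²),
rank-deficient designs (empty cells), non-monotone timestamps, and
incomplete trials each raise a specific error rather than propagating
garbage.

## Known limitations

- The detector is threshold-faithful, not tracker-identical; real
  recordings should expect small boundary differences against vendor
  event streams.
- Wald intervals and residual-df p-values are approximations; profile
  or bootstrap intervals for β are out of scope.
- The BF implementation covers the fixed-only / random-only /
  intercept-only comparison the dominance procedure needs, not general
  model-averaged Bayesian ANOVA.
- Random slopes, crossed random effects and generalized mixed models
  are out of scope; so are error-count norms, pupillometry and binocular
  data.
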