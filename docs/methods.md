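# Methods

## Model and objective

Fixations are 2D points in raw pixel coordinates on the stimulus
canvas (default 700×500, origin top-left). Each class-conditional
density is a Gaussian kernel density estimate with bandwidth `h`
(pixels) and normalization `c_d = (2π)^(−d/2)`, `d = 2`; **both class
densities divide by the full training-set size N**, not the class
subset size, so that the signed difference

    q(x) = p̂(x|X⁺) − p̂(x|X⁻) = (c_d / N h^d) · Σᵢ yᵢ k(x, xᵢ)

is proportional to the label-weighted kernel sum with a single shared
constant. `c_d` cancels in the supervised mean-shift vector and only
sets the absolute density scale. The word-quality surface is |q(x)|;
its extrema are the candidate dictionary words. The discrete word
quality is purity × coverage = |n⁺ − n⁻|, which |q| approximates when
words are locally compact.

Coordinates are never standardized: bandwidths stay interpretable in
pixels against the stimulus, and both axes share the same unit.

## Dual mode seeking

The supervised mean-shift iteration `x ← x + m(x)` with
`m(x) = Σ yᵢ k xᵢ / Σ yᵢ k − x` ascends q where the positive class
dominates and descends it where the negative class dominates; in both
cases |q| increases, so one iteration handles both signs without
branching. Unlike classic mean shift, monotone progress is not
automatic (the denominator carries negative terms), so:

- **Acceptance rule.** A proposed step is accepted when it does not
  decrease |q| — acceptance is evaluated on the absolute difference
  (the true objective), not the signed one, which keeps backtracking
  well-defined on both sides of the zero level-set. Acceptance is
  non-strict: a zero-change step at a fixed point is accepted and then
  terminates via the displacement test. (A strict rule can reject the
  final sub-tolerance step and desynchronize the single-class
  reduction from classic mean shift.)
- **Backtracking.** A rejected step is halved (`step_shrink = 0.5`) up
  to `max_backtracks = 20` times; if no scale improves |q| the kernel
  is frozen at its current position and treated as converged.
- **Balanced-density fallback.** Where |Σ yᵢ k| falls below
  `eps_den = 1e−12` × (largest single kernel weight at x), the shift
  vector is numerically meaningless; the kernel instead takes a step of
  length `tol` along the analytic gradient of |q| (sign-corrected), or
  freezes if the gradient also vanishes.
- **Termination.** A kernel stops when its accepted displacement falls
  below `tol = 1e−3·h` or after `max_rounds = 30` accepted rounds (the
  round count matches the reference protocol; both are configurable).
- **Isolation guard.** A query whose total kernel mass underflows
  (beyond ~38 h from every training point) is frozen rather than
  producing NaNs.

Classic mean shift runs through the same engine with all labels +1, so
the single-class reduction is exact to the bit. The density-ratio mode
(the "discriminative mode seeking via density ratio" baseline) ascends
`p̂(x|X⁺)/(p̂(x|X⁻) + ε)` with `ε = 1e−8 ×` the largest negative-class
density over training points, stepping along `h²∇log` of the guarded
ratio; its known pathologies (no coverage weighting, noise-chasing over
sparse negative regions) are intentionally left in place — they are
what the baseline represents.

All kernels in a batch are driven simultaneously (vectorized kernel
sums, per-kernel backtracking masks); seeking is deterministic given
its inputs.

## Dictionary, encoding, evaluation

`learn_dictionary` seeds kernels with a seeded uniform subsample
(without replacement, default rate 1/20) of the training fixations,
shifts them, and clusters the converged positions with k-means (Lloyd,
10 seeded restarts, best inertia). Near-duplicate converged kernels
are *not* merged first; k-means handles the collapse. Centroids are
ordered by word quality (descending, ties by x then y) so feature
columns are reproducible; any fixed order is equivalent downstream.
Class-wise learners split K as ⌈K/2⌉/⌊K/2⌋ between classes and use a
distinct derived sub-seed per class (identical class inputs would
otherwise produce exactly duplicated centroids, which the dictionary
contract forbids).

Fixations are assigned to the nearest centroid (Euclidean, ties to the
lowest word index). Each subject-image sequence becomes an
L1-normalized K-bin histogram — frequencies are the stated semantics
and keep features bounded for the RBF SVM.

Evaluation is leave-one-subject-out: per fold the dictionary is learned
from training-subject fixations only, an `SVC(kernel="rbf")` is fit on
training-image histograms, and the held-out subject's score is the mean
signed decision value over their images (decision values rather than
calibrated probabilities; calibration is never part of the protocol).
Accuracy is reported at the global threshold maximizing LOSO accuracy
and hyperparameters (K ∈ {35..70}, γ ∈ 2⁻⁶..2⁰, C ∈ 2⁶..2¹⁶, h) are
searched on the same LOSO loop — both selections are optimistically
biased, which the result object records; AUC (rank-based
Mann–Whitney, ties ½) is threshold-free. The bandwidth grid has no
canonical published range and defaults to a single 30 px cell.

## Synthetic cohorts

The generator emulates the statistical structure the method assumes:
five isotropic Gaussian attention regions (left eye, right eye, nose,
mouth, off-face background) on the 700×500 canvas, base mixing weights
(0.25, 0.25, 0.20, 0.20, 0.10), region sd 30 px by default. The
positive class sheds δ/2 from each eye onto nose and background, so the
total-variation distance between class weight vectors is exactly δ.
Subject heterogeneity is a Dirichlet draw centered on the class weights
(concentration 50 by default) — without it every subject is
exchangeable and LOSO is trivially easy. Fixations are i.i.d. within
an image (the method uses only the spatial marginal, so no saccade
dynamics are modeled) and clipped to the canvas to keep counts exact.
Defaults: 30+30 subjects × 6 images × 40 fixations.

An analytic oracle evaluates the *population* smoothed density
difference (a component with sd s convolved with the kernel is Gaussian
with variance s²+h²) on a 0.5 px grid and reports its extrema; it
anchors the mode-seeking tests independently of the implementation.

Benchmark sizes used by the test suite and `scripts/acceptance.py`:
the null cohort uses the full 60-subject default; the moderate-gap
(δ = 0.3) comparisons use 15+15 subjects × 5 images × 30 fixations and
the strong-gap (δ = 0.4, sd 15, concentration 200) cohort 12+12
subjects × 4 images × 40 fixations — sizes chosen as compact designs
that still leave the expected effects clearly measurable.

## What passing tests do and do not show

The synthetic cohorts validate the machinery — identities of the
gradient and the signed kernel sum, monotone convergence, mode
recovery against exhaustive search, chance-level behavior without
signal, near-perfect behavior with strong signal, and the ordering of
proposed vs. class-blind dictionaries under moderate signal. They do
not certify performance on real eye-tracking cohorts: real gaze
densities are far more multimodal, subject effects are not Dirichlet,
and fixation counts vary per image.

## Known limitations

- **Purity profiles on synthetic data are noise-dominated.** Under the
  five-region model the population absolute purity is capped at
  δ/(w⁺+w⁻) ≈ 0.43 for δ = 0.3, while mean-shift-style pipelines
  collapse kernels onto a handful of modes and k-means then produces
  sliver words covering 0–6 fixations whose purity is sampling noise
  (often exactly 1.0). Top-5 purity comparisons between methods are
  therefore unreliable on these cohorts — the corresponding check in
  the acceptance suite fails by design of the generator, not of the
  seeker — whereas on real multimodal gaze data purity profiles are
  informative. Coverage-weighted quality is the robust diagnostic here.
- Bandwidth is global and isotropic; no adaptive or per-region h.
- The threshold/hyperparameter selection reports the protocol's
  optimistic "best performance"; unbiased error estimation would need
  a nested loop, deliberately out of scope.
- Fixation order, duration and saccade geometry are ignored by design.
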