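# Methods

This note documents the models and procedures implemented in `szeeg`,
the defaults and why they were chosen, what the synthetic generator does
and does not emulate, and the numerical choices made where the design
was genuinely open.

## Synthetic cohort model

Each subject's channel is a sum of three sources, mixed across channels
by a near-identity random full-rank matrix and scaled to a microvolt
range:

1. **1/f^β colored noise** (spectral shaping of white Gaussian noise,
   unit variance). β defaults to 1.2 for both classes.
2. **A chaotic component** — a standardized logistic-map orbit at
   r = 3.99 (r slightly below 4 avoids the map's numerically absorbing
   states on long orbits) — mixed in with fraction `chaotic_mix`
   (default 0.05).
3. **Band-limited oscillations**: weak 10 Hz (alpha) and 20 Hz (beta)
   sinusoids with random phases.

`effect_size` shifts only the schizophrenia class: β decreases by 0.25
and the chaotic fraction increases by 0.15 per unit effect size. Whiter
noise plus a larger chaotic fraction raises sample entropy and LZ
complexity and lowers the DFA exponent, so the two classes differ in
exactly the statistics the pipeline measures, monotonically in
`effect_size`; at 0 the classes are identical in law. The direction of
the shift is an arbitrary modelling choice that creates separation — it
carries no clinical claim, and the generator makes no attempt to
reproduce real schizophrenia EEG morphology (no artifacts, no
non-stationarity, no topographic structure, no medication effects).
Consequently, passing end-to-end tests demonstrates the *mechanics* of
the pipeline (no leakage, sensible metrics, optimizers that find
separating weights), not clinical performance.

Defaults mirror the study geometry the package emulates: 14 subjects
per class, 19 channels in the 10–20 montage, 15 minutes per recording.
The sampling rate is never stated alongside that geometry; 225,000
samples over 15 minutes implies 250 Hz, which is the default. Per-subject
seeds are `SeedSequence(master_seed, (class_index, subject_index))`,
stable across runs and platforms.

Segmentation cuts each channel into non-overlapping, contiguous
5000-sample segments (45 per default channel); a trailing partial
segment is discarded.

## Feature extractors

All extractors operate on 1-D windows. Tolerances and thresholds are
relative to the window's own SD/mean/median, making sample entropy and
the LZ-based measures invariant under affine rescaling.

* **DFA**: integrate the mean-removed series, detrend per window
  (order 1), fit log F(s) vs log s over 10 log-spaced scales in
  [4, n/4]. Scales above n/4 are rejected.
* **R/S Hurst**: blocks are powers of two in [8, n/4]. The raw slope
  estimator carries a well-known upward small-sample bias (≈ +0.10 at
  H = 0.3, n = 4096), so the default applies the Anis–Lloyd–Peters
  correction H = 1/2 + slope of (log R/S − log E[R/S_iid]); the exact
  iid expectation uses the gamma-function form below b = 340 and the
  asymptotic form above. `corrected=False` restores the raw slope.
* **RQA**: embedding m = 3, delay τ = first autocorrelation zero
  crossing capped at 10, Theiler window = τ, radius ε = 0.2 × SD of all
  embedded pairwise distances (Euclidean metric, `<=` comparison so a
  constant signal recurs fully). Determinism counts recurrent points in
  diagonal runs of length ≥ 2.
* **Sample entropy**: Richman–Moorman convention — both template
  lengths m and m+1 use the same n − m start indices, pairs i < j,
  Chebyshev distance, r = 0.2·SD. A constant window returns 0 (every
  template matches); A = 0 returns the +inf sentinel (flagged and
  median-imputed at the matrix level). This convention makes a strict
  alternation score exactly 0.
* **Katz dimension**: D = log₁₀L / log₁₀d with unit abscissa spacing;
  L is the summed point-to-point length and d the farthest Euclidean
  distance from the first sample. A ramp gives exactly 1; an
  all-constant window is degenerate (every point identical up to the
  unit abscissa) and is flagged.
* **LZ76 phrase count**: greedy exhaustive parsing with
  copy-with-overlap; the trailing component that is still reproducible
  when the sequence ends does **not** open a phrase, so a constant
  string counts exactly 1 phrase. Kolmogorov proxy binarizes at the
  mean and returns c·log₂n/n; LZ complexity binarizes at the median and
  returns c/(n/log₂n). The two binarization rules keep the two features
  distinct. Note the standard convention is implemented: *higher* LZC
  means *less* repetitive signal.
* **Hjorth**: activity = var, mobility = sqrt(var Δx / var x) (≈ the
  dominant angular frequency for a dense sine), complexity =
  mobility(Δx)/mobility(x) (≈ 1 for a pure sine).
* **Largest Lyapunov exponent**: Rosenstein-style nearest-neighbor
  divergence. Neighbors must be separated in time by more than the mean
  period (estimated from mean crossings); λ₁ is the least-squares slope
  of the mean log divergence over steps 1–8. The default fit range ends
  before the divergence curve saturates for the map benchmarks used in
  the tests; both range and temporal-exclusion window are parameters.

**Feature matrices.** Per method and channel, each 5000-sample segment
is split into 10 sub-windows of 500 samples (default), and the method is
evaluated per sub-window under a 10-column variant grid — the single
most salient parameter of each method is varied (scale range for
DFA/R-S, tolerance for SampEn, radius for RQA, analysis-window fraction
for the window-local statistics). A `dense` mode instead slides a
reflect-padded stride-1 window across the segment, producing one row
per sample (the segment-length × 10 layout); it is provided for
completeness and is only practical for the cheap extractors. Cells
whose sub-window violates a method's preconditions (constant input, too
few embedded points, non-finite sentinel) are flagged and imputed by
their column median, with the count recorded, so a pathological
sub-window cannot sink a whole run.

## Metaheuristic optimizers

All four maximize over an axis-aligned box, count every fitness call,
abort on non-finite fitness, and retain the best position ever
evaluated (elitism), which makes the best-so-far history monotone — the
basis of a shared contract test.

* **Artificial Flora** (N = 10 plants × B = 5 branches, 100
  iterations): propagation distance d_h = d1·rand·c1 + d2·rand·c2 with
  c1 = c2 = 0.8; the grandparent distance inherits the parent's
  (d1′ = d2) and the parent distance becomes the RMS offspring
  displacement. Offspring are Gaussian around the parent with standard
  deviation d_h: d_h is a *distance*, and reading it as a variance
  (dimensionally inconsistent) freezes the spread dynamics at ≈1
  because the RMS displacement of N(0, σ²=d) is √d; the
  `spread_is_variance` flag keeps that literal reading available. The
  survival rule l = (F/F_max)·P_y^(h·m−1) (P_y = 0.5) depends on the
  plant and seed indices; originals are sorted best-first each
  generation so the index penalty acts as rank-based selection
  pressure. Survivors are roulette-sampled into the next generation,
  topped up by roulette over non-survivors, and a new plant replaces
  its slot only when it improves on the old one. Fitness is shifted
  positive within each generation so the ratio F/F_max is well defined
  for negative objectives.
* **Glowworm swarm** (40 worms, 500 iterations): luciferin
  f ← (1−ρ)f + γH with ρ = 0.4, γ = 0.6, initial luciferin 5; step
  st = 0.01 × box diagonal; decision range starts at the box diagonal
  and is nudged by β = 0.08 toward a neighborhood of i_n = 5. These are
  standard values from the GSO literature. A worm with no brighter
  neighbor in range stays put, which preserves separated peaks.
* **Black hole** (30 stars, 500 iterations): per-coordinate
  Y ← Y + rand·(Y_bh − Y); the event-horizon radius R = G_bh / ΣG_j is
  computed from raw fitness values (Σ = 0 guarded to R = 0). With
  negative-fitness objectives R is negative and absorption simply never
  triggers; the contraction step alone still converges.
* **Monkey search** (10 monkeys, 20 outer iterations): climb by the
  sign of the two-point pseudogradient with step s = 0.005 × diagonal
  for 30 steps; watch-jump samples uniformly within the eyesight box
  (0.05 × diagonal, 5 attempts, accept on improvement); somersault
  reflects through the population mean with θ ~ U[−1, 1]. Infeasible
  somersault proposals are redrawn up to 20 times, then clipped to the
  box.

Default budgets were chosen so that all four reliably solve 2-D and 5-D
sphere benchmarks to within 0.05 of the optimum; the selection stage of
the pipeline uses smaller documented budgets (`SELECTION_BUDGETS`)
because its 10-dimensional Fisher-ratio fitness is cheap and easy.

**Selection objective.** How a rows × 10 feature matrix becomes a
single selected column is the largest open design point in this family
of analyses; here the optimizers search weight vectors w ∈ [0,1]¹⁰
maximizing the Fisher ratio of the weighted column combination, and the
winning w is renormalized to sum 1. The objective is isolated behind
`ObjectiveSpec` so alternatives (e.g. classifier-wrapper fitness) can be
swapped in without touching the optimizers.

## Classifiers and evaluation

ANN = one hidden layer of 50 logistic units (LBFGS, 2000-iteration cap,
tolerance 1e-6 — a practical stand-in for training to zero MSE); QDA
unregularized except a 1e-6 stability guard; SVM uses the RBF kernel
only with C = 1 and the 1/(p·var) bandwidth heuristic (the reference
accuracies cannot pin these down, so they stay configurable); logistic
regression with defaults; FLDA is the closed form W = S_W⁻¹(m₁ − m₂)
with a ridge guard for singular scatter and a midpoint threshold on the
projected class means; KNN uses K = 4 with an even vote broken by the
single nearest neighbor.

Splits are 70/30, stratified by class, **subject-wise** (all instances
of a subject land on one side): segment-level instances within a
subject are correlated, and instance-level splitting would inflate
accuracy through subject leakage. Whether the original study split
subject-wise is not stated; subject-wise is the defensible default, and
instance-level behavior is recovered by giving each instance its own
group id. Five repetitions with per-repetition derived seeds.

Features fed to classifiers are standardized using training-set
statistics only.

## Pipeline

Instances are segments: per repetition, selection weights are fitted on
the training subjects' rows only (per optimizer × method), all rows are
projected, the selected column is averaged within each segment, and the
per-method values are stacked into a 9-dimensional instance. Metrics
are computed per repetition and then averaged (matching the "average"
captioning of the report tables), never by averaging counts first. Per
class, one-vs-rest counts feed sensitivity/specificity/accuracy/PI/GDR;
MSE is computed between the classifier's real-valued scores and the
0/1 labels, since the error definition leaves the observed/target
series otherwise unbound. The pooled performance tables report an
error rate of 100 − PC%, the interpretation that makes the error and
perfect-classification entries complementary.

The end-to-end behavioral checks use the *pooled overall accuracy*
(total correct / total test instances) per optimizer × classifier cell:
the per-class (sens+spec)/2 quantity assigns 75 to a degenerate
always-one-class predictor on the predicted class and 0 on the other,
so it cannot serve as a chance-band leakage guard, while pooled
accuracy is 50 for any constant or random predictor on balanced
classes. The report tables still carry the per-class quantity.

Moment summaries use sample variance (ddof = 1) and the *excess*
kurtosis convention (Gaussian → 0), matching the near-zero and negative
reference values for oscillatory features. The first canonical
correlation is computed from the SVD of Sxx^{-1/2} Sxy Syy^{-1/2} with a
trace-scaled ridge of 1e-9 on the within-set covariances; tests
cross-check it against an independent eigenvalue formulation.

## Problem sizes used in the shipped checks

The synthetic study defaults (14 + 14 subjects × 19 channels × 225,000
samples) define the data model, but the shipped end-to-end checks run a
deliberately scaled-down instance of the same design: 24 subjects per
class, 1 channel, 16 s recordings (4000 samples), 1000-sample segments
in 4 sub-windows of 250 samples, with the full 4-optimizer ×
6-classifier grid on the null cohort (10 repetitions) and a
5-repetition separable cohort. The cohort size and repetition count
were sized so that a null-cohort cell's standard error is about 2
accuracy points — small cohorts make all cells fluctuate together with
the cohort's spurious finite-sample class difference, and a guard band
is only meaningful when that fluctuation is well inside it. These sizes
retain every moving part of the analysis while keeping a full run in
the minutes range on one CPU; the parameter-recovery checks (fGn Hurst,
logistic-map λ₁) run at n = 4096 and n = 2000 respectively.

## Known limitations

* The generator's subjects are exchangeable within class (no
  between-subject parameter variability beyond noise realizations);
  real cohorts have subject-level effects that make subject-wise
  splitting even more important than the tests demonstrate.
* With small cohorts, null-cohort cell accuracies fluctuate together at
  the cohort level (a finite sample of subjects can carry a spurious
  class difference); the chance-band checks are calibrated to the
  shipped problem sizes.
* The dense feature-matrix mode is computationally impractical for the
  quadratic-cost extractors (SampEn, RQA, LLE) at full segment length.
* No preprocessing beyond segmentation is applied; an ICA step in the
  emulated design is unspecified (no algorithm or rejection rule), so
  the pipeline exposes a pass-through hook in its place: supply
  pre-cleaned CSV/EDF recordings via `input_cohort`.
* EDF export is not implemented (recordings are stored as CSV +
  manifest); EDF reading requires the optional `mne` dependency.
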