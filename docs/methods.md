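# Methods

## Model

Each brain region's activity `X_a` (one value per repetition time,
TR = 0.72 s) is modelled as a network ODE in discrete time (one step per
sample):

```
X_a[t+1] - X_a[t] = λ·X_a[t] + Σ_b Σ_{n=1..p} Ξ[a,b,n]·X_b[t]^n + η[t]
```

The library contains pure monomials only (no interaction terms): each
directed edge is a scalar polynomial of the source region, and a region's
derivative is the sum over its incoming edges plus a linear decay. No
symmetry is imposed; the b→a and a→b edges are fitted independently.

**The decay constraint.** The first-order self-coefficient is fixed, not
estimated. A region's derivative confounds two simultaneous processes —
return to baseline and network input — and an unconstrained regression
splits them arbitrarily, producing unstructured connectivity. The value is
anchored in hemodynamics: sampling the canonical double-gamma HRF
(peak-delay 6 s, undershoot-delay 16 s, ratio 1/6) at the TR and fitting a
log-linear decay to the falling limb from the peak down to 10 % of peak
gives λ = −0.222 per sample. The 10 % stop is principled, not cosmetic:
below it the undershoot lobe dominates and the response is no longer
single-exponential (fitting the full positive limb gives −0.29, fitting to
20 % gives −0.20; the procedure and its window are therefore stated
explicitly and exposed as an argument). Higher-order diagonal terms remain
free, so self-edges may still be sigmoidal.

**Fitting.** Per target region: subtract `λ·X_a` from the target
derivative, drop the first-order diagonal column from the design, solve
ridge (`(ΘᵀΘ + αI)β = Θᵀy`), then iterate sequential thresholding (zero
every |Ξ| < threshold, re-solve over survivors, at most `n_iter` rounds),
and reinstate the diagonal. Defaults: α = 1e-2, threshold = 1e-3,
`n_iter` = 10, polynomial order capped at 7. An L1 optimizer is
deliberately not offered: pure-lasso solutions are too sparse to track the
dynamics. Adjusted R² uses the standard sample-size/parameter-count
correction over the pooled training residuals.

## Derivative estimation

Three estimators are provided, and the choice matters more than is usually
appreciated:

* `forward` — one-step forward differences. For data generated (or well
  approximated) by an Euler–Maruyama step, the increment over [t, t+1) is
  exactly the drift at t plus noise independent of the state at t, so drift
  regression and drift-prediction scoring are unbiased. This is the default
  in the recovery and evaluation studies.
* `spectral` — multiplication by i2πf in the Fourier domain, after
  removing the endpoint-matching linear trend and applying a Tukey(0.05)
  taper to suppress wrap-around (the trend slope is added back). Exact for
  band-limited periodic content; errors scale down rapidly with record
  length.
* `smoothed_finite_difference` — Savitzky–Golay smoothing (window 7, order
  3) followed by central differences; robust to white noise and the
  appropriate choice when the analysis treats the signal as a smooth
  (hemodynamically filtered) curve.

A pitfall documented here because it cost real debugging time: centered or
smoothed estimators mix in *past* noise increments, which are positively
correlated with the current state; for an Ornstein–Uhlenbeck-like process
this partially cancels the decay term and collapses pointwise
drift-prediction correlations (median r ≈ 0.06 versus ≈ 0.36 for the
forward difference at the default noise level). The separation pipeline
uses one estimator (smoothed finite difference) for *both* the model fits
and the trial windows: the background subtraction compares a model
prediction against a measured derivative, and mixing estimators with
different frequency responses de-calibrates that subtraction.

Pointwise derivative prediction on held-out runs is bounded by the
drift/noise power ratio, not by model quality: at the default dynamics
noise (sd 0.1/sample against drift sd ≈ 0.04) the ceiling is ≈ 0.36, and
the fitted models reach it (while their predicted drift correlates with the
true drift at r > 0.99). Reported held-out medians of ~0.35 should be read
against that ceiling, not against 1.

## Preprocessing

Band-pass plus z-score, per ROI row. The filter is an FFT brick-wall
projection (coefficients outside [low, high] zeroed) rather than an IIR
design: a projection is exactly idempotent, so repeated preprocessing is
harmless, and step-like transition bands are standard practice in fMRI
band-passing. Default band 0.008–0.15 Hz; the upper edge sits below the
0.15–0.3 Hz respiratory/cardiac range and is configurable. Constant rows
(z-score undefined) return as zeros with a logged warning. The synthetic
studies skip band-passing: the generator produces stationary zero-mean
signals, and filtering would distort the one-step Euler pairing that the
recovery oracles rely on.

## The synthetic ground truth

`make_ground_truth` samples a two-hemisphere network: intrahemispheric
edges positive (lognormal magnitudes, density 0.4), every contralateral
homologue pair positive, remaining interhemispheric edges negative
(density 0.3, half scale). Coupling is `w·tanh(gain·x)`; weights are
rescaled so the largest eigenvalue real part of the rest linearization is
−0.05 per sample — stable but slow, like resting fMRI. Runs are integrated
with Euler–Maruyama at one step per TR with white dynamics noise
(sd 0.1/sample).

Task runs differ from rest in three ways, all tied to the premise that a
task engages a sub-network of the rest processes:

* task-mask edges (a 4-region-per-hemisphere sub-network by default) are
  multiplied by `task_elevation` (default 1.25);
* the remaining rest edges are attenuated by `offtask_attenuation`
  (default 0.5) — during a task the unrelated rest processes lose
  structure, which is what makes the fitted task model a *sub-network* of
  the rest model rather than a superset;
* each trial injects a triangular input (3 samples up, 3 down; per-trial
  amplitude ~ N(0.3, 0.1), floored near 0) into four stimulus regions, and
  the same triangular profile multiplies the task-edge gain
  (`stimulus_gain_coupling`, default 1), so part of the trial response is
  carried by the engaged network processes themselves rather than by the
  additive input alone.

Reaction time is an affine, noisy function of the trial amplitude
(1000 − 500·amp + N(0, 40) ms, floored at 100 ms). This link is a test
scaffold — real behavior has no known generative law — chosen so the
RT–amplitude correlation ceiling is ≈ 0.8.

What the generator does *not* emulate: hemodynamic convolution (the ODE
lives in measurement space), measurement noise distinct from dynamics
noise, spatial autocorrelation of parcels, head motion or physiological
artifacts, individual differences in decay rate, and non-stationarity
across a run. Passing tests therefore demonstrate that the estimators
recover the structures this model family can express, not that real
recordings satisfy the model.

## Study conditions and problem sizes

Chosen once as a desk-scale stand-in for the full-size recordings (84
regions, ~half a million training samples) and used by the analysis
scripts, the acceptance tests and `scripts/acceptance.py`:

* 16 regions; 20,000-sample rest runs for model identification;
* 500-trial training task runs and 300-trial test runs, trials every
  21.6 s (30 samples), 14.4 s / 20-sample windows;
* separation-framework effects reported as medians over 12 seeded
  replicates; the (c1, c2) sweep (c1 ∈ [−1, 3], c2 ∈ [−3, 1], step 0.5) on
  4 of them;
* two-task embedding study: 50 individuals per task, 6 trials each,
  per-individual multiplicative lognormal connectivity jitter (σ = 0.5),
  two task sub-networks sharing 6 of 8 regions with a weaker contrast
  (elevation 1.15, attenuation 0.85) — without inter-individual variability
  and overlap the unseparated FCs are already perfectly classifiable and
  the comparison is uninformative.

## Separation and behavior

Windows resample the 14.4 s after each completed onset onto 20 points by
linear interpolation (identity when onsets fall on the TR grid; half-open
window, sample 0 at onset). The background derivative is evaluated on the
*measured* window states (the printed integrand), not on the evolving
separated state; the feedback variant would make the operation nonlinear
in (c1, c2) and is intentionally not used. Integration is a left-rectangle
cumulative sum with a one-sample step, matching the model convention.
Incomplete trials are excluded from all RT analyses; completion flags are
retained for per-individual outcome prediction.

The Elastic-Net RT model uses the concatenated flattened signal and
derivative windows, standardized within training folds only, with
α = 1, l1_ratio = 0.95, and 10 repeats of a seeded 80/20 shuffle split
(reading the common "10-fold … 80/20" idiom as repeated shuffle splits).
R² is reported as the *squared Pearson correlation* between predicted and
held-out RT — explained variance, not the coefficient of determination;
note this metric has a positive chance bias of roughly 1/(n_test − 1).
Per-individual outcome prediction uses α = 5, l1_ratio = 0.01 on the
vectorized FC upper triangle; trial classification uses a 200-tree random
forest. FC embedding uses UMAP (n_neighbors = 100 clamped to n − 1,
min_dist = 0.1, 2 components, correlation metric, seeded) and an RBF SVM
(C = 1, scale gamma) on the 2-D coordinates with a stratified 20 % test
split; cluster distances are computed in the embedded space (a native-space
option exists).

EC–SC correlations use signed coefficients within the intra- and
interhemispheric classes (the sign structure is the finding of interest)
and magnitudes for the "all" class, since tract counts are unsigned; both
views are available. The Pareto operating rule flags grid rows with
adjusted R² > 0.1 and first-order EC–SC correlation > 0.4; on the synthetic
fixture the adjusted R² peaks at the true decay rate.

## Numerical choices and degenerate inputs

* Ridge solves use the normal equations; a singular Gram matrix at α = 0
  raises a numerical error with a remedy hint.
* Thresholding that removes every term leaves a decay-only model and logs
  a warning.
* Zero-variance rows yield missing (NaN) correlations, logged, never
  silent zeros.
* Model persistence is HDF5 (tensors, written without timestamps) plus a
  JSON sidecar; round-trips are bit-exact. Experiment manifests hash array
  *content*, so reruns with equal seeds verify bitwise.
* All randomness flows through `numpy.random.SeedSequence` children of one
  master seed; child seeds are kept below 2³¹.

## Known limitations

* The elastic-net ΔR² comparison between separation frameworks is at the
  seed-noise floor at this problem size: a sparse linear aggregator over
  the same window features can partially learn the background subtraction
  itself, so the median ΔR² for the ACM and rest-baseline frameworks is
  small (±0.005 across seeds) even though the max-correlation ordering is
  decisive (ACM positive in ~95–100 % of seeds, baselines negative in
  ~90–100 %). The full-scale regime (thousands of features against a few
  hundred training trials) is more under-determined and favours explicit
  separation more strongly.
* The derivative-space FC decomposition shows the expected ordering
  (residual < measured) but with small magnitudes, because white dynamics
  noise dominates derivative variance at this noise level.
* STLSQ is a greedy heuristic; no optimality guarantee, and with heavy
  thresholds whole regions can reduce to decay-only models.
* UMAP is seeded but not deterministic across library versions or thread
  counts; tests compare medians over replicates rather than coordinates.
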