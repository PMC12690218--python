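# Methods

## Path reconstruction

Two optical sensors view an air-suspended ball at 90°; each reports one
axis of ball rotation as integer displacements in dots (394 dots/cm). The
two per-trial CSV files may hold cumulative positions or per-frame deltas —
acquisition software differs — so the dialect is a mandatory input, never
guessed: cumulative streams are first-differenced, delta streams pass
through. The two boards stop independently, so streams are truncated to a
common length and aligned *by sample index*; timestamp interpolation is
deliberately avoided because the boards' clocks are not synchronised. The
sampling rate is estimated per trial as (n − 1)/(t_last − t_first), with
the nominal 60 Hz as fallback. An optional batch mode trims every trial in
a study to the global minimum sample count, making all trials cover the
same number of measurements at the cost of coupling unrelated trials;
per-trial trimming is the default.

Which sensor channel measures forward vs lateral ball rotation depends on
the rig, so the mapping is a configurable `AxisMap` (default: sensor A's x
channel → forward/y, sensor B's x channel → lateral/x, signs +). The
`calibration_check` diagnostic quantifies the lateral/forward RMS ratio of
a pure-forward push, which should be ≈ 0 under a correct map.

## Smoothing and the movement variables

Sensor quantization at 60 Hz produces fine-scale jitter, so the cumulative
coordinates are smoothed with a centred rolling mean (default window 30
samples ≈ 0.5 s) and then re-differenced. Default edge handling is
`valid` (the window − 1 incomplete edge samples are dropped — statistically
clean); a `shrink` mode averaging over available samples preserves length.
Smoothing the cumulative coordinates rather than the increments keeps the
operation a linear filter of the path itself; both are supported.

Increments are converted to cm and reduced to six variables (see README
for formulas). Two definitional choices deserve note:

* **Non-movement threshold.** After smoothing, exact zeros are rare, so an
  increment counts as movement only when its 2-D displacement magnitude
  exceeds `zero_tolerance`, default half a dot (0.5/394 cm). The same
  threshold governs the velocity mean and heading definition, so the two
  metrics are consistent. The criterion is the 2-D magnitude, not "both
  components individually nonzero": requiring both would discard all
  axis-aligned motion, which cannot be intended physically.
* **Unsigned rotation.** Heading changes are wrapped into [0, π]
  (|Δθ| > π ⇒ 2π − |Δθ|: within 1/60 s the animal is assumed to turn the
  short way round), and their *absolute* values are summed. Total rotation
  is therefore nonnegative and straightness (cm/rad) well defined; signed
  net turning is intentionally not computed. Degenerate trials report NaN
  with flags (`no_movement`, `zero_rotation`) instead of infinities.

## Repeatability

The random-intercept Gaussian model y_ij = μ + a_i + e_ij is fitted with no
fixed effects beyond the intercept. The ANOVA path uses the one-way moment
estimator with the standard unbalanced correction
n₀ = (N − Σnᵢ²/N)/(g − 1) and truncation of negative among-individual
variance to zero. The REML path profiles the restricted likelihood down to
the variance ratio λ = V_among/V_within:

f(λ) = (N − 1)·log Q(λ) + Σᵢ log(1 + nᵢλ) + log Σᵢ wᵢ,
wᵢ = nᵢ/(1 + nᵢλ), Q = SSW + Σᵢ wᵢ(ȳᵢ − μ̂)², μ̂ the w-weighted mean,

minimised by golden-section search on log λ over [−35, 35] (≈90 iterations,
bracket ≪ any practical tolerance) with the λ = 0 boundary checked
explicitly; then V_within = Q/(N − 1), V_among = λ·V_within. For balanced
data this optimum coincides exactly with the truncated ANOVA estimator
(the interior stationarity condition reduces to 1 + nλ = MS_among /
MS_within), which the test suite verifies to 1e−6 against 100 random
balanced datasets and, on unbalanced data, against an independent
general-purpose mixed-model REML fitter. The objective is evaluated
vectorised over a batch axis, so a 1000-replicate parametric bootstrap
refits in milliseconds.

Confidence intervals are percentile parametric bootstrap: datasets are
simulated from the fitted V_among/V_within on the observed group structure
and re-estimated with the same method; seeds are mandatory arguments so
every interval is reproducible. Two degenerate regimes are handled exactly:
zero within-individual variance gives r = 1 with a collapsed CI [1, 1], and
a constant response flags r as undefined. Because r is truncated at 0, the
null (true R = 0) estimator is positively biased — simulations at the
30 × 2 design put the mean estimate near 0.05 — which is why a CI excluding
zero, not the point estimate, is the significance criterion.

Response transformations (√, natural log, arcsine-√) are applied before
fitting where the raw metric violates Gaussian-model assumptions; the
shipped defaults transform total distance (√), rotational velocity (ln) and
sinuosity (arcsine-√). Rank-based between-trial Spearman correlations are
reported alongside, since no transformation fixes every diagnostic.
Spearman point estimates are Pearson correlations of mid-ranks (delegated
to scipy); their CIs are nonparametric pairs-bootstrap percentiles, with
degenerate (constant-rank) resamples dropped.

## The synthetic generator

`simulate_path` is a discrete-time correlated random walk at 60 steps/s:
per step the walker pauses with probability `pause_prob`; otherwise it
draws a gamma step length (shape from mean/sd) and turns by a zero-centred
von Mises angle with concentration κ (κ = ∞ is the straight-walking limit,
κ = 0 uniform turning). Defaults — mean speed 3.5 cm/s, speed sd 1.5 cm/s,
κ = 4 (turn sd ≈ 0.5 rad/step), pause probability 0.2, 600-s trials — give
an expected unsmoothed distance of 3.5 × 0.8 × 600 = 1680 cm per trial,
in the range such assays report for actively walking ground beetles, with
per-step turns well below π so heading unwrapping is untested only where
it should be.

Rendering converts the forward/lateral increments to dots, optionally adds
Gaussian sensor noise, and quantizes by rounding the *cumulative* dot count
and differencing, so the integrated rendered path never drifts more than
half a dot per axis from the truth (the property tests assert this bound at
every sample). Optional uniform timestamp jitter (< half a sample period)
exercises the empirical-rate estimator.

Populations place Gaussian among- and within-individual variation on a
latent parameter — log mean speed by default (keeping speeds positive and
distances approximately lognormal); log turning concentration and logit
pause probability are also available — so the latent structure is *exactly*
the random-intercept model the estimators assume, with true
R = among_sd²/(among_sd² + within_sd²) known by construction. Defaults
(30 individuals × 2 trials, among_sd = within_sd = 0.2, R = 0.5) mirror a
realistic single-study design.

What the generator does not emulate: ball inertia and slippage, bout
structure beyond i.i.d. pauses, gait-scale periodicity, heavy-tailed turns,
and drift or dropout in the sensors. Passing recovery tests therefore
demonstrate correctness of the *processing and estimation*, not that real
trackball data meet these assumptions.

## Validation design and problem sizes

* Elementary operations are pinned to closed forms (3-4-5 increments,
  semicircle sinuosity 2/π, unwrap at |Δ| = 3π/2, a toy balanced ANOVA with
  r = 0.9459…) and to brute-force oracles (windowed means, mid-rank
  Spearman on exhaustive permutations for n ≤ 5 plus tied cases to n = 8).
* Metric recovery runs full-length trials (600 s, 36 000 steps) rendered
  noiselessly and re-measured with smoothing disabled, since the stated
  tolerances (distance within n/394 cm, sinuosity ±0.02, rotation ±5 %)
  are quantization slack; the 30-sample smoother is validated separately
  against its brute-force definition. Measured errors are far inside the
  tolerances (rotation ≈ 0.3 %).
* Estimator recovery uses the generator's latent layer directly — the
  estimator's sampling distribution depends only on the Gaussian structure —
  at 500 replicates per true R ∈ {0, 0.35, 0.5, 0.8}; CI coverage uses 200
  replicates × 500 bootstrap draws. The sensor-level end-to-end check runs
  150 replicate populations of 60-s trials (a paired comparison of
  pipeline-estimated vs latent-value repeatability, which cancels most
  Monte-Carlo noise); trial length is immaterial there because metric
  measurement error at 3600 steps is negligible against the within-
  individual variance.
* The full test suite runs in well under a minute on one CPU.

## Known limitations

* Repeatability is unadjusted (no fixed-effect conditioning) and Gaussian
  only; proportion/count responses would need link-scale methods.
* The ANOVA path's n₀ correction and the REML fit both accept unbalanced
  data, but individuals contribute no within-information from single
  trials.
* Percentile bootstrap CIs (both flavours) are first-order accurate only;
  at n = 30 individuals their coverage in simulations is within a few
  points of nominal, consistent with their known behaviour.
* The axis map and CSV dialect cannot be inferred from data; misdeclaring
  them produces silently wrong paths — use `calibration_check` with a
  pure-forward push when configuring a rig.
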