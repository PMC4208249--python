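# Methods

This note documents the models, conventions and numerical choices behind
`enosekit`: a pipeline that turns raw resistance recordings from a
large-scale conducting-polymer chemiresistor array into odour-class
predictions, plus a synthetic array simulator used to exercise the pipeline
without the physical device.

## Problem setting

A large-scale electronic nose reads N sensors (the reference device:
16,384 conducting-polymer chemiresistors over ~24 polymer classes) at 1 Hz.
One measurement exposes the array to an analyte or binary mixture between a
clean-air baseline (samples 0–100) and a clean-air purge (after sample 650),
giving a T × N resistance grid. A campaign of M measurements (tens) is tiny
compared with N — the "many sensors, few samples" regime that drives every
design choice below.

## Preprocessing

1. **Savitzky–Golay smoothing** of each sensor trace: local least-squares
   polynomial fit, degree k = 2 over a frame of f = 101 samples (~100 s of
   context at 1 Hz). Unlike a moving average it preserves the height and
   shape of the response plateau; polynomials up to the fit degree pass
   through exactly. Implemented with `scipy.signal.savgol_filter`; edges are
   filled by evaluating a polynomial fitted to the terminal window
   (`mode="interp"`), so output length equals input length.
2. **Fractional response** ΔR/R = (R − R₀)/R₀ per sensor, with R₀ the mean
   over the baseline window (default: the whole pre-stimulus interval) and
   R the mean over a steady-state window (default: the last 100 samples of
   the stimulus phase, where first-order kinetics have plateaued). Window
   means are used instead of single samples for noise robustness; length-1
   windows recover single-sample semantics. The ratio form suppresses
   multiplicative drift. The package also provides the live-display quantity
   Rs% = 100·(Rs − R₀)/Rs (note the denominator is the current reading).
3. **Autoscaling**: per-sensor z-score across the M measurements, population
   variance convention (divide by M). Zero-variance columns are set to zero
   and flagged rather than dropped, preserving the sensor-to-material
   layout. The scaling statistics are stored so held-out measurements can be
   mapped with training-fold statistics only.

## EigenOdour decomposition (snapshot PCA)

The N × N response covariance C = (1/M) Σ Φᵢ Φᵢᵀ (Φᵢ = yᵢ − Ψ, Ψ the mean
measurement) has rank ≤ M − 1, so its nonzero spectrum is computed from the
M × M Gram matrix L, L_mn = Φₘᵀ Φₙ — the snapshot trick familiar from the
eigenface method. Gram eigenvectors v are lifted to sensor space as
u = Σₖ v_k Φₖ and renormalized to unit length, yielding an orthonormal basis
(EigenOdours) in descending variance order.

Conventions:

- L is eigendecomposed without the 1/M factor; reported eigenvalues are
  divided by M so they equal covariance eigenvalues and variance fractions
  are unaffected.
- Component retention: either an explicit count p, or the smallest p whose
  cumulative variance reaches a fraction (default 0.90, the operating point
  at which the reference campaign kept its first 15 components). Cumulative
  variance is always computed over the full positive spectrum, so it does
  not depend on how many components were retained.
- Eigenvector sign is fixed so each component's largest-magnitude
  coefficient is positive, making serialized models reproducible.
- Eigenvalues below 1e−10 of the leading one are treated as rank noise.

## Two-stage discriminant (PCA + LDA)

Fisher LDA needs an invertible within-class scatter S_W, but in sensor
space rank(S_W) ≤ M − c. The remedy (as in the Fisherface method): project
onto p ≤ M − c EigenOdours first — the directions maximizing total scatter —
then solve the generalized eigenproblem S_B w = λ S_W w in that subspace and
keep the q ≤ c − 1 leading eigenvectors. The composed map
W_opt = W_pca W_lda takes raw measurements directly to discriminant
coordinates.

- Default p = min(M − c, components reaching 90% variance); requesting
  p > M − c raises a singularity error citing the rank bound.
- Default q = c − 1 (the rank bound of S_B).
- The generalized problem is solved by symmetric reduction
  (`scipy.linalg.eigh(S_B, S_W)`); if S_W fails Cholesky, a jitter of
  1e−10 · max(tr S_W, tr S_B, 1)/p is added — scaling the floor by the total
  scatter keeps the problem conditioned even when within-class scatter
  vanishes entirely (e.g. duplicated measurements in a noise-free check).
- Discriminant columns are renormalized to unit Euclidean length. `eigh`
  returns S_W-normalized vectors, whose length diverges as S_W degenerates;
  only the direction carries information, and unit norm keeps downstream
  score scales bounded. Scores are *not* re-standardized before the SVM.
- Ties in the generalized spectrum are broken by `eigh`'s deterministic
  ordering plus the same sign rule as the EigenOdour basis.

## Crammer–Singer multiclass SVM

All c class functions are trained in one joint optimization

    min 1/2 Σₘ ‖wₘ‖² + C Σᵢ ξᵢ
    s.t. w_{yᵢ}·φ(xᵢ) − wₘ·φ(xᵢ) ≥ eᵢᵐ − ξᵢ,   eᵢᵐ = 1 − δ_{yᵢ,m}

whose dual has per-example blocks constrained by Σₘ αᵢᵐ = 0 and
αᵢᵐ ≤ C·δ_{yᵢ,m}. The solver is block-coordinate descent over examples with
an exact analytic solution of each c-variable subproblem (clipped
water-filling via sorted breakpoints), a deterministic cyclic visiting
order, and termination when the largest per-example KKT violation falls
below 1e−6. Only kernel values enter, so linear and RBF kernels share one
code path. Prediction is argmax over classes of Σᵢ αᵢᵐ K(xᵢ, x); exact ties
go to the lowest class index.

Two choices matter in practice:

- **Intercepts.** The formulation has no bias term; homogeneous linear
  score functions through the origin cannot let a "middle" class win when
  clusters are centered and nearly collinear — exactly the geometry of LDA
  scores for an ordered mixture series. The linear kernel is therefore
  inhomogeneous, K(x, y) = x·y + b, equivalent to a constant appended
  feature; b defaults to the mean squared training-point norm so the
  implied (regularized) intercept stays expressive at any feature scale.
  `bias=0` restores the strictly homogeneous machine.
- **Penalty.** C defaults to 1; in the well-separated LDA geometry results
  are insensitive to it over orders of magnitude.

Degenerate subproblems with K(xᵢ,xᵢ) ≈ 0 are solved analytically (true-class
variable at its cap, remainder spread evenly).

## Evaluation

Confusion matrices use rows = estimated labels, columns = known labels.
Per-class precision is diagonal/row-sum, recall diagonal/column-sum; macro
scores are unweighted class means. Two rounding modes exist for the macro
computation: `exact` (default), and `paper`, which truncates each
*non-terminating* per-class ratio to two decimals before averaging — the
hand-calculation convention in which 7/9 contributes 0.77 while 5/8
contributes 0.625, making the reference matrix's macro recall 0.879 rather
than the exact 0.880556. (Terminating decimals are detected exactly via the
reduced denominator's prime factors.)

Cross-validation is stratified k-fold (default k = 10) with seed-controlled
shuffling: each class's indices are dealt round-robin from a rotating
offset, so 8–9-member classes survive in every training split. Autoscaling
statistics, the EigenOdour basis, the LDA projection and the SVM are fitted
per training split only; a `global_scaling` switch reproduces the laxer
protocol of scaling once on all data. A never-predicted class gets
precision 0 with a warning; a class absent from the known labels makes
recall undefined and raises. Folds whose removal would empty a class out of
training are merged with a neighbour (with a warning).

## Synthetic sensor array

The simulator is a structural stand-in, not a chemistry model: its job is
to reproduce the data regime (M ≪ N, material- and analyte-dependent
responses, sparsity, noise, delivery variability) so pipeline claims can be
tested end to end. Per sensor n of material m:

    Rₙ(t) = R₀ₙ · (1 + aₙ·g(t)) · (1 + ε(t)),
    aₙ = Σ_analytes s(m, analyte) · concentration_ppm

with g(t) first-order rise (τ_rise) from stimulus onset and exponential
recovery (τ_rec) after the purge, and ε multiplicative Gaussian read noise.

Defaults (fixed once; all configurable):

| parameter | default | rationale |
|---|---|---|
| n_sensors | 1024 | desk-scale stand-in for 16,384 (supported, slower) |
| n_materials | 24 | responsive polymer classes of the reference device |
| sensitivities | log-uniform 1e−6..3e−5 ΔR/R per ppm | plateau responses ~1–60% at the campaign's ppm levels, the order conducting polymers show for alcohols/ketones |
| τ_rise / τ_rec | 60 s / 120 s | plateau well developed within the 550 s exposure; visible recovery tail |
| noise_sd | 0.002 | ~0.2% relative read noise per sample |
| dead_fraction | 0.3 | sizeable non-responding population ("sparse" array) |
| baseline_range | 1e4–1e6 Ω log-uniform | heterogeneous polymer film resistances |
| concentration_jitter | 5% | measurement-to-measurement delivery variability |

Material layout, sensitivities and the dead-sensor set derive from the
configuration seed (fixed array properties); baselines, jitter and read
noise derive from (seed, measurement index), so campaigns are bit-for-bit
reproducible. Two stock campaigns mirror the reference designs: a
41-measurement varying-ratio butanone/ethanol series (8/8/9/8/8 over five
compositions) and a 20-measurement butanone-step series over a constant
ethanol background.

What the simulator does *not* emulate — and hence what passing tests do not
show about real data: sensor drift over days, humidity/temperature
coupling, asynchronous response kinetics across materials, correlated
sensor noise, and nonlinear (saturating) concentration response. Perfect
cross-validated recovery on synthetic campaigns demonstrates the pipeline's
correctness in the intended regime, not field performance of a device.

## Problem sizes and determinism

Tests run the pipeline at 96–256 sensors; the end-to-end recovery check and
the reproduction script use the full default configuration (41
measurements × 1024 sensors, 750 samples, 10-fold CV), which completes in
well under a minute on one core. Every stochastic step (simulation,
fold assignment) is seed-controlled; fits themselves are deterministic
(cyclic SVM visiting order, fixed eigenvector sign conventions), so reports
are byte-reproducible for a given configuration and seed.

## Known limitations

- The pipeline is linear end to end (by design); strongly nonlinear
  sensor–analyte relations would need the RBF kernel or a different
  reduction.
- `paper` rounding mode exists solely to reproduce by-hand truncated
  arithmetic; use `exact` for anything quantitative.
- With fewer than ~2 measurements per class, stratified 10-fold CV
  degenerates; the fold-merging fallback warns but cannot conjure data.
- The N × N covariance is never formed, but the N × p basis is dense; at
  N = 16,384 and p ≈ 40 this is still only ~5 MB.
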