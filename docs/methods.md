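# Methods

## Model and procedure

`fcshrink` predicts each subject's second-session seed-based connectivity
map from first-session data. The analysis scale is Fisher-Z: with
`V_ij(v) = arctanh(W_ij(v))` for subject *i*, session *j* ∈ {1, 2}, ROI
voxel *v*, the classical measurement-error model for a replication study is

    V_ij(v) = X_i(v) + U_ij(v),
    X_i(v) ~ (μ_x(v), σ²_x),  U_ij(v) ~ (0, σ²_u),  all independent.

Under this model the best linear unbiased predictor of `X_i(v)` given one
noisy replicate is the convex combination of the subject's own map and the
group mean,

    V̂_i2(v) = λ(v)·V̄_1(v) + (1 − λ(v))·V_i1(v),
    λ(v) = Var{U}(v) / (Var{X}(v) + Var{U}(v)) = 1 − ICC(v),

so λ = 0 when the raw map is noiseless (no shrinkage) and λ = 1 when it
carries no subject signal (collapse to the mean). The intraclass
correlation ICC(v) — the test–retest reliability of the voxel — is reported
alongside as 1 − λ. Predictions are mapped back to the correlation scale
with `tanh`.

Variance components are voxelwise moment estimators built from the session
differences `D_i = V_i2 − V_i1`:

    Var{U} = ½ · (1/(I−1)) Σ_i (D_i − D̄)²
    Var{V} = (1/J) Σ_j (1/(I−1)) Σ_i (V_ij − V̄_j)²      (pooled over sessions)
    Var{X} = max(Var{V} − Var{U}, 0)

`E[Var{V}] = σ²_x + σ²_u` under the model, which makes the subtraction a
coherent estimator of σ²_x. Scoring uses the per-subject MSE over ROI
voxels against the observed session-2 map, on the Fisher scale by default
(the correlation scale is available via `scale="correlation"`), with
percent reduction relative to the raw predictor.

## Assumptions

* Exactly two sessions; every subject has both. The session error is
  homoscedastic across subjects and sessions and independent of `X`.
* λ estimation uses both sessions of the same dataset being evaluated —
  the same circularity as the analysis this package operationalises. An
  externally estimated `LambdaMap` can be plugged into `shrink()` to break
  it in methodological experiments.
* The seed time course averages **all** ROI voxels, including the voxel
  being correlated. The induced self-correlation inflation (of order
  `(1 − ρ²)/|S|`) is part of the definition and is visible in simulations
  with small ROIs.

## Parameters that matter

| parameter | units | default | why |
|---|---|---|---|
| `sigma2_x` | Fisher-Z² | 0.04 | between-subject variance; with `sigma2_u = 0.01` gives λ = 0.2, a moderately reliable voxel (ICC 0.8) |
| `sigma2_u` | Fisher-Z² | 0.01 | session-error variance (time-series mode: the session-effect variance, to which `1/(T−3)` sampling variance adds) |
| `mu_x` | Fisher-Z | 0.3 | mean true connectivity, a typical within-ROI seed correlation (~0.29 on the r scale) |
| `n_subjects`, `n_timepoints` | — | 21, 74 | the study design the package emulates: a short two-session paediatric resting-state protocol |
| `fixed_lambda` | — | 0.1 | published rule-of-thumb near the average voxel reliability, used when λ is not estimated and as the fallback for unestimable voxels |
| `ar1` | — | 0 | temporal autocorrelation of the synthetic noise; whiteness keeps the Fisher sampling variance exactly `1/(T−3)` |

## What the generators emulate — and what they do not

The model-level generator (`generate_fisher_panel`) samples the
measurement-error model exactly, so both variance components are known and
parameter recovery can be asserted tightly. The time-series generator
(`generate_timeseries_panel`) draws a white standard-normal driver per
scan, gives each voxel the signal `ρ·s(t) + √(1−ρ²)·ε(v,t)` with
`ρ = tanh(X_i(v) + B_ij(v))`, the session effect `B` added on the Fisher
scale, and `ρ` clipped to |ρ| ≤ 0.999; the realised Fisher maps then carry
measurement error ≈ `sigma2_u + 1/(T−3)`.

Neither generator simulates motion, drift, physiological noise, spatial
autocorrelation, or realistic haemodynamics, and the time-series noise is
temporally white by default. Passing tests therefore demonstrate that the
estimator chain is correct under its own model, not that the model captures
every feature of real BOLD data. Real data enter through the `fit` stage
(NIfTI scans + manifest + ROI mask) with the Athena-style preprocessing
assumed done upstream.

## Numerical choices

* Correlations are clipped to |W| ≤ 1 − 1e−7 before `arctanh`; the Fisher
  round trip is then an identity to ≤ 1e−12 for |W| ≤ 0.999.
* Zero-variance (degenerate) voxels give NaN maps; NaNs are excluded
  pairwise from means, variance components (with per-voxel effective-I
  logging) and MSE averages, the only convention that cannot silently bias
  λ. A voxel with fewer than 2 complete subjects takes the fixed fallback
  λ = 0.1.
* Negative `Var{X}` estimates are clamped to 0 (⇒ λ = 1) and flagged —
  the standard treatment of a negative variance component.
* Both components zero (e.g. a constant panel) gives λ = 1 by convention:
  the raw map then adds nothing beyond the mean.
* Masks threshold at 0.5 so binary and resampled probabilistic masks both
  work; voxel enumeration is ascending (x, y, z) in 0-based indices and is
  identical across all operations. Background voxels of output maps are
  NaN, not 0.
* All computation is double precision; TSV outputs store full precision
  with display rounding (half-up, 2 decimals) confined to `*_display`
  columns. Quartiles use the median-exclusive convention so the Tukey
  outlier count is deterministic.
* One master seed drives a dedicated substream per (subject, session)
  via seed-sequence spawning, so panels are bit-reproducible regardless of
  generation order.

## Design choices where the design was open

* **λ orientation.** The two limiting cases (λ = 1 ⇒ mean, λ = 0 ⇒ raw)
  and the BLUE property force λ = Var{U}/(Var{X}+Var{U}); the package
  reports ICC = 1 − λ alongside so both readings are available.
* **Var{V} estimator.** Implemented as the pooled within-session
  between-subject sample variance — the moment estimator whose expectation
  is σ²_x + σ²_u, keeping `Var{X} = Var{V} − Var{U}` coherent.
* **Headline MSE scale.** Fisher-Z, where the predictor is linear and the
  closed forms hold; the correlation scale is computed on request.
* **Time-series construction.** No canonical generative model exists for
  "time series whose correlations follow the measurement-error model"; the
  driver-plus-noise construction was chosen because it makes the target
  correlation explicit and the Fisher sampling variance exactly `1/(T−3)`
  under whiteness.
* **Within-mask analysis.** Maps are computed for ROI voxels only; a
  whole-brain variant is a matter of supplying a larger target mask.

## Problem sizes used in the checks

Monte-Carlo checks run at I = 200, V = 500 for λ recovery (tolerance 0.03
on the voxel-averaged weight), 10 000 (i, j, v) cells at T = 74 for the
Fisher sampling variance (±10% of 1/71), and I = 50, V = 2000 for the
closed-form MSE comparison (±10%); the end-to-end determinism check uses a
10-subject, 200-voxel, T = 74 study. These sizes put the Monte-Carlo
standard errors comfortably inside the stated tolerances while keeping any
single check under a few seconds.

## Known limitations

* Requires J = 2 sessions with labels "1" and "2"; more general replication
  designs are out of scope.
* λ is estimated per voxel with no spatial smoothing or regularisation;
  at small I the per-voxel weights are noisy (only their average is
  accurate), which is why the fixed-λ mode exists.
* The benchmark table bundled in `fcshrink.datasets` carries two
  internally inconsistent printed rows (subjects 7 and 14, where the
  printed reductions disagree with the printed MSE cells at the ~2 pp
  level); statistics recomputed from the per-subject cells can differ from
  the source's own summary row in the fourth decimal.
* Real-data ingestion assumes preprocessed, spatially aligned NIfTI scans;
  no registration or resampling is performed, and grid mismatches are
  errors by design.
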