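# Methods

## Model and assumptions

`bimr` implements two-sample Mendelian randomization: the causal effect
θ of an exposure X on an outcome Y is estimated from per-SNP summary
associations measured in two non-overlapping cohorts. Each instrument j
is assumed to (1) associate with X, (2) be independent of confounders
of the X–Y relationship, and (3) affect Y only through X (no horizontal
pleiotropy). Under these assumptions every Wald ratio
θ̂ⱼ = β̂_Yj / β̂_Xj estimates θ; the estimators differ in how they
behave when assumption (3) fails for some instruments.

Per-SNP ratio SEs use the first-order delta method, σ_Yj/|β̂_Xj|,
ignoring exposure-side noise. This is the standard two-sample
convention; it is accurate when instruments are strong (the relative
error of β̂_Xj is O(1/√F)), which the selection pipeline enforces and
the generator reproduces.

### Estimators

- **IVW.** Closed-form inverse-variance-weighted mean of the ratios with
  w_j = β̂²_Xj/σ²_Yj, algebraically identical to the zero-intercept
  weighted regression of β̂_Y on β̂_X with weights 1/σ²_Yj (both code
  paths exist and are cross-asserted to 1e-12 in the tests). The default
  effects model is multiplicative random effects: the fixed-effect SE
  (Σw)^(−1/2) is multiplied by max(1, √(Q/(J−1))). The floor makes the
  estimator reduce exactly to the fixed-effect model when there is no
  excess heterogeneity and makes the test mildly conservative otherwise
  (measured null rejection ≈ 0.036 at nominal 0.05); the underlying
  GWAS reports do not name an effects model, so the common default was
  chosen. Normal-quantile 95% CIs.
- **MR-Egger.** Every pair is first oriented so β̂_Xj ≥ 0 — the Egger
  fit is not invariant to per-SNP allele sign conventions and
  orientation-to-positive is the canonical choice. Weighted regression
  with a free intercept, weights 1/σ²_Yj; the covariance uses
  multiplicative overdispersion floored at 1 (residual variance scaling
  never shrinks SEs below the homoskedastic value); inference and CIs
  are t-based on J−2 df. The intercept estimates the average directional
  pleiotropy per instrument and is consistent under InSIDE (pleiotropic
  effects independent of instrument strength).
- **Weighted median.** Ratios are ordered; with normalized weights p_j,
  the cumulative midpoints s_j = Σ_{k≤j} p_k − p_j/2 define a piecewise
  linear quantile function, and the estimate interpolates to s = 0.5.
  Consistent while valid instruments carry more than half the weight.
- **Simple / weighted mode.** Normal-kernel density over the ratios,
  evaluated at the ratios themselves; the estimate is the argmax
  (first index on exact ties). Bandwidth
  h = φ · 0.9 · min(sd, IQR/1.349) · J^(−1/5) with φ = 1 by default,
  using weighted sd and weighted quantiles for the weighted mode; if the
  IQR is zero the sd alone sets the bandwidth, and if all ratios
  coincide that common value is returned. The bandwidth is re-derived
  inside every bootstrap replicate.
- Bootstrap SEs (weighted median and modes) are parametric: each θ̂ⱼ is
  resampled from N(θ̂ⱼ, se²ⱼ) and the estimator recomputed, n_boot =
  1000 by default, seeded everywhere. A set with a single instrument
  falls back to the Wald ratio in place of IVW.

### Sensitivity diagnostics

- **Cochran's Q / I².** About the fixed-effect IVW estimate (J−1 df) or
  the Egger fit (J−2 df), with I² = max(0, (Q−df)/Q). The IVW-reference
  Q is also validated against the regression-residual formulation.
- **Egger intercept test.** Two-sided t test, J−2 df.
- **MR-PRESSO.** Observed statistic RSS = Σⱼ (β̂_Yj − θ̂₍₋ⱼ₎β̂_Xj)²/σ²_Yj
  with θ̂₍₋ⱼ₎ the leave-one-out IVW estimate. The null distribution comes
  from parametric simulation (β̂*_X ~ N(β̂_X, σ_X), β̂*_Y ~
  N(θ̂₍₋ⱼ₎β̂_X, σ_Y), statistic recomputed per replicate); global and
  per-SNP p-values use the add-one rule (1+k)/(1+n_sim) so Monte-Carlo
  p is never zero, and per-SNP outliers are flagged at the Bonferroni
  level α/J. Because the simulation re-draws exposure noise around
  already-noisy observed effects, the global p is mildly conservative
  under the null (measured mean ≈ 0.54, rejection ≈ 0.026 at 0.05);
  this is a property of the published resampling scheme itself, not of
  this implementation, and the calibration tests bound it accordingly.
  The distortion test is not implemented — only the global test and
  outlier detection are within scope.
- **Leave-one-out.** J IVW re-fits omitting one SNP each; a row is
  flagged influential when its CI excludes the full-set point estimate.

## Instrument selection and harmonization

Selection runs significance filter (strict p < threshold, matching the
printed "P < 5 × 10⁻⁸" convention), confounder exclusion list, greedy
LD clumping (accept by ascending p-value; pairs outside the window or
on other chromosomes count r² = 0; within-window pairs missing from the
user-supplied LD table count 0 with a warning), then the F ≥ 10 screen
(F exactly 10 is kept: the rule removes F *less than* ten). Analyses
with fewer than five instruments are skipped with a recorded reason
rather than estimated. LD always comes from a user-supplied table —
never a remote panel — so runs are deterministic and desk-scale.

Harmonization aligns outcome records to the exposure's effect allele:
identical orientation (no action), swapped alleles (negate β, EAF →
1−EAF), strand complement (relabel only), or both. Palindromic A/T and
C/G pairs cannot be resolved by strand; two policies exist. `drop_all`
removes every palindromic instrument (the forward-analysis behaviour);
`drop_intermediate` (default) removes them only when either EAF lies in
the ambiguity window, else orients by EAF agreement (both frequencies
on the same side of 0.5). The window defaults to (0.42, 0.58), the
conventional choice; no published value pins it down, so it is
configurable. Instruments absent from the outcome dataset are dropped
into the audit (no proxy lookup). Every removal at every stage appears
in exactly one audit row, and counts are conserved.

## Synthetic data generator

The generator emulates post-clumping two-sample summary data: J
independent instruments plus optional null background SNPs, effect
allele frequencies uniform on `maf_range`, and standard errors
1/√(2·EAF·(1−EAF)·N) — the sampling counterpart of the
variance-explained formula — with independent exposure and outcome
noise (non-overlapping cohorts). Defaults encode the target study's
geometry: J = 15, N_exposure = 21,758 (the serum-protein GWAS
meta-analysis), N_outcome = 127,442 (the disease GWAS), θ = 0.

True exposure effects are |N(0, 0.15²)| floored so each instrument's
true F reaches `min_true_f` = 80. Two consequences are deliberate.
First, instruments are genuinely strong, as real post-screening
instrument sets are, which keeps the delta-method approximation
accurate and calibration honest. Second, the effect allele is coded as
the exposure-increasing allele. With symmetric-signed exposure effects,
directional pleiotropy would cancel after Egger's positive-orientation
step (the intercept would estimate E[sign(b)·a] = 0), so the textbook
directional regime requires a fixed coding; allele-sign handling is
exercised instead through injected strand flips, allele swaps, and
joint-negation invariance tests. Pleiotropic outcome effects a_j ~
N(mean, sd²) are drawn independently of the exposure effects with
probability `pleiotropy_prob`, so InSIDE holds by construction.
Palindromic allele pairs, strand-flipped and allele-swapped outcome
encodings, and null SNPs are injected at configurable fractions and
logged in the ground-truth record. Identical configurations produce
byte-identical output.

What the generator does **not** emulate — and what passing tests
therefore do not establish about real data: LD between instruments
(simulated instruments are independent; the LD table path is tested
separately with constructed panels), winner's curse in instrument
selection, sample overlap between cohorts, case-control ascertainment
in binary-trait SEs (the same frequency-based SE formula is used for
both trait types), population stratification, and InSIDE violations.

## Pipeline, seeds, determinism

`run_direction` chains selection → harmonization → five estimators →
sensitivity; `run_bidirectional` repeats it with roles swapped,
redoing selection from scratch per direction. Per-analysis seeds derive
from the master seed by CRC-32 hashing of the (exposure, outcome) ids,
kept below 2³¹. The Bonferroni denominator defaults to the number of
analyses in the batch and can be pinned (e.g. to 25) in the config.
Reports are plain TSV plus a sorted, indented `summary.json` whose
bytes are a pure function of inputs, config and seed.

## Problem sizes in tests and the acceptance script

Calibration checks use 4000 null replicates (Monte-Carlo SE ≈ 0.003 on
a rejection rate, so the 0.03–0.07 acceptance band is resolved by the
estimand rather than batch noise); recovery uses 500 replicates at the
OR-0.92 geometry; robustness orderings 200–300 replicates; PRESSO
uniformity 300 replicates at 400 simulations each. Replicate batches
use a light estimation path (IVW, Egger, weighted-median point
estimate, Q) without bootstrap SEs or PRESSO; full-pipeline behaviour
is covered by the dedicated pipeline and determinism tests. The whole
suite runs in well under a minute on one CPU.

## Known limitations

- Exposure-side noise is ignored in ratio SEs (no second-order
  correction, no MR-RAPS-style adjustment).
- No Steiger direction filtering, no multivariable MR, no proxy-SNP
  lookup, no distortion test, no remote data access.
- Continuous-trait effect sizes are treated as SD units (rank-normal
  transformed traits); binary-trait effects as log-odds. Mixed or
  unscaled inputs are the caller's responsibility.
- In a merged bidirectional scenario, instruments of trait A can reach
  genome-wide significance for trait B through a strong causal effect;
  the reverse analysis will then include them. This mirrors the genuine
  reverse-causation hazard of the design rather than hiding it.
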