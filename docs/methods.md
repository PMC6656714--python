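# Methods

## Signal models

Each voxel's diffusion-weighted magnitude signal is modelled two ways:

* **Kurtosis model.** `S(b) = S0 · exp(−b·D_app + (1/6)·b²·D_app²·K_app)`,
  with b in s/mm², D_app in mm²/s (so b·D is dimensionless) and K_app
  unitless. K_app is the apparent excess kurtosis of the water displacement
  distribution; K_app = 0 recovers Gaussian diffusion. This is the
  trace-weighted (isotropic) form — no directional kurtosis tensor is
  modelled.
* **Mono-exponential model.** `S(b) = S0 · exp(−b·ADC)`, fitted only over a
  low-b subset (default 100, 500, 900 s/mm²) where the quadratic term is
  small, as done in routine clinical ADC mapping.

The kurtosis expansion is not monotone in b for all parameters: the decay
turns around at b = 3/(D_app·K_app). With tissue-like values
(D ≈ 1.4 × 10⁻³ mm²/s, K ≈ 0.7) that turning point sits near 3000 s/mm²,
safely above the default grid's maximum of 1700 s/mm², so generated and
fitted signals are strictly decreasing over the acquisition range.
The default b grid (100, 500, 900, 1300, 1700 s/mm²) has no b = 0 volume;
S0 is always an extrapolated free parameter of the fit, never read from the
data.

## Estimation

**Kurtosis fit.** Bound-constrained nonlinear least squares on the *raw*
signal (`scipy.optimize.least_squares`, trust-region reflective, analytic
Jacobian). Fitting in the linear signal domain rather than on log-signal
avoids amplifying the noise at high b, where the signal is smallest.
Defaults:

| parameter | bounds | rationale |
|---|---|---|
| S0 | (0, 2·max signal] | magnitude scale; the factor 2 allows extrapolation above the b=100 sample |
| D_app | [1 × 10⁻⁵, 4 × 10⁻³] mm²/s | physiological range up to free water |
| K_app | [0, 3] | non-negative kurtosis; 3 is well above solid-tumour values |

Initialisation is ordinary least squares of ln S on (1, −b, b²), whose
coefficients map exactly onto (ln S0, D_app, D_app²·K_app/6); on noiseless
model data the initial point *is* the solution, which is why noiseless
round-trips recover parameters to ~1e−15 relative. Degenerate starts
(non-positive or non-finite diffusivity) fall back to (median signal,
1 × 10⁻³ mm²/s, 0.5) before clipping into bounds. Convergence tolerance is
1e−10 on parameters and cost with at most 500 function evaluations;
non-convergence is recorded per voxel (qc code), never silently accepted.
Setting the two kurtosis bounds equal pins K and reduces the problem to a
constrained two-parameter mono-exponential fit. Standard errors come from
the Gauss-Newton covariance `rss/dof · (JᵀJ)⁻¹` at the solution.

An optional noise-floor offset replaces the forward model by
`sqrt(model² + floor²)` to approximate the Rician plateau at low SNR; it is
off by default, i.e. the default fit applies no Rician bias correction.

**ADC fit.** Log-linear OLS of ln S on −b over the configured subset. A
nonlinear variant would differ only under noise; the log-linear choice is
the common clinical convention and is exact on mono-exponential data.

**Grid oracle.** `grid_oracle_fit` evaluates the residual sum of squares
exhaustively over a finite (S0, D, K) grid and returns the arg-min. It
exists to bound the solver in tests (the solver must never return a larger
RSS than any grid point); it is not a production fitter.

**Volume fitting and quality control.** Only voxels with a positive mask
label are fitted. qc codes: 0 fitted, 1 outside mask, 2 non-positive
signal, 3 solver did not converge; metric maps hold NaN wherever qc ≠ 0.
Fitting is fully deterministic.

## VOI summaries

All of a patient's lesion ROIs are pooled (set union) into a single VOI and
each metric map is reduced over the VOI's qc-clean voxels to one value per
patient. The default reduction is the voxel-weighted mean — equivalent to
the count-weighted average of per-lesion means, an identity the tests check
— with the median available as a policy for skew-robust summaries. Excluded
(failed-fit) voxels are counted and reported.

## Cohort statistics

* **Response dichotomisation.** RECIST v1.1 categories collapse to
  responder (CR, PR) vs non-responder (SD, PD); a missing category is
  "unclassified" and excluded from group comparisons but retained for
  correlations.
* **Two-group comparison.** Shapiro-Wilk per group at alpha = 0.05 (the
  gate's alpha is a convention, applied independently per group); Student's
  two-sample t only if both groups pass, otherwise two-sided Mann-Whitney
  U. The Mann-Whitney p is exact (full null distribution) when the pooled
  sample is tie-free and n ≤ 25 — which covers a 5-vs-10 cohort — and
  otherwise uses mid-ranks with tie-corrected variance and continuity
  correction. Constant groups are routed to the rank test.
* **Correlations.** Mid-rank Spearman with the t-approximation p-value; an
  exact permutation p (all n! rank assignments) is available for n ≤ 10.
* **Observer agreement.** ICC in the two-way random-effects,
  absolute-agreement, single-rater form by default (consistency form
  selectable), with the 95% CI from the F-distribution construction;
  computed via pingouin. Absolute agreement is the right default for
  "would a second reader get the same number", since a constant reader
  offset should (and does) lower it while leaving the consistency form at 1.
* No multiple-testing correction is applied; p = 0.05 is the cut-off.

## Synthetic data generator

The generator emulates the statistical structure the analysis assumes, at
desk scale:

* **Phantom.** Ellipsoidal lesions on a 48 × 48 × 12 default grid (two
  lesions by default), per-voxel (S0, D, K) drawn from truncated normals
  (K ≥ 0, D ≥ 1 × 10⁻⁵ mm²/s; truncation rather than rejection keeps cost
  deterministic), signal synthesised exactly through the kurtosis model.
  Background is a low-signal (S0 = 100) free-water-like mono-exponential
  compartment. A configurable fraction of each lesion becomes a
  necrotic/cystic core — K = 0, D ∈ [2.5, 3.2] × 10⁻³ mm²/s — labelled
  negatively in the ground truth and *excluded* from the ROI mask,
  mirroring the analyst's exclusion of non-solid tissue when outlining
  tumour.
* **Noise.** Rician magnitude noise `sqrt((S+ε₁)² + ε₂²)`, the standard
  model for magnitude MR images; it exercises the fitter's noise-floor
  behaviour at the highest b-value. The default sigma of 17 gives an SNR of
  ~50 at b = 100 for the default lesion S0 of 1000; SNR is a free parameter
  of any real acquisition, so it is exposed in the phantom config.
* **Cohorts.** Per-patient VOI-level metrics drawn from group
  distributions. The defaults encode the study conditions this package
  targets: 5 responders with K_app 0.69 ± 0.13, D_app 1.44 ± 0.30 × 10⁻³,
  ADC 1.22 ± 0.24 × 10⁻³, versus 10 non-responders with 0.51 ± 0.11,
  1.51 ± 0.32 × 10⁻³ and 1.30 ± 0.27 × 10⁻³, plus optionally 2 unclassified
  (adjuvant-arm) patients drawn from the mixture.
* **Histology covariates.** Cellularity (cells/µm², log-normal marginal,
  median 0.006) and Ki-67 (%, logistic marginal, median 40) are attached
  through a Gaussian copula against the K_app ranks (default rank
  correlations 0.49 and 0.53). Because the K_app margin enters as fixed
  normal scores, the copula is calibrated against the *exact finite-n
  expectation* of the sample Spearman coefficient for that construction
  (expected ranks via the normal CDF of score differences), inverted
  numerically. The asymptotic `(6/π)·asin(r/2)` correction alone would
  leave a bias of ~0.05 at n = 17; the finite-n calibration brings the mean
  sample rho within ~0.002 of target.

Every stochastic operation is a pure function of (inputs, explicit integer
seed); there is no global random state, and the CLI pipeline's outputs are
byte-identical across runs at a fixed (config, seed).

What the generator does **not** emulate: anatomy, partial-volume and
motion/distortion artefacts, T2/TE dependence, spatial noise correlation,
and intra-VOI spatial texture. Tests passing on this generator therefore
validate the estimators and the inference chain, not robustness to
real-acquisition confounds.

## Problem sizes

The test suite and acceptance checks run at desk scale: phantoms of
20 × 20 × 6 to 48 × 48 × 12 voxels (~10²–10³ lesion voxels), 10⁴ single
voxels for the noise-recovery regression, 200 simulated cohorts for the
power ordering, and 10⁴ seeds for the copula calibration — sizes chosen so
the full suite completes in a few minutes on one CPU while keeping
Monte-Carlo standard errors well below the asserted tolerances.

## Known limitations

* **Per-voxel kurtosis precision at moderate SNR is intrinsically poor.**
  For the five-point grid with SNR 50 at S0 (sigma = S0/50), the Cramér–Rao
  bound at (D = 1.3 × 10⁻³, K = 0.6) gives sd(K̂) ≥ ~0.22 and
  sd(D̂) ≥ ~1.3 × 10⁻⁴ — a median per-voxel relative error around 24% for K
  and 7% for D for *any* unbiased estimator. The solver sits essentially on
  this bound and is centred on the truth (the median recovered K across
  10⁴ voxels is within ~1% of the generating value), so VOI-level means
  over hundreds of voxels are precise even though single-voxel estimates
  are noisy. K_app maps should be read accordingly.
* The isotropic kurtosis form ignores diffusion anisotropy; no IVIM
  (perfusion) compartment is modelled, which can bias D_app upward when
  very low b-values are included (the default grid starts at 100 s/mm²
  partly to suppress perfusion effects).
* Masks must share the series' voxel grid exactly; no registration or
  resampling is provided.
* The exact Mann-Whitney branch requires tie-free data; with ties the
  approximation is used even at small n.
* The exact Spearman permutation p is limited to n ≤ 10 (n! enumeration).
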