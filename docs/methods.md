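# Methods

This note documents the models, the synthetic-data calibration, the
numerical choices, and the limits of what the test suite shows.

## Acquisition models and estimators

### Saturation-recovery T1 and ECV

T1 maps come from a 13-point saturation-recovery series (TRs 82.9–8000 ms).
The recovery model is `S(TR) = M0·(1 − eff·exp(−TR/T1))` with the
saturation efficiency `eff ∈ (0, 2]` free: a three-parameter form that
absorbs imperfect saturation and the flip-angle variation of a surface
transceiver coil without committing to a specific flip-angle model. The fit
is bounded nonlinear least squares with four T1 starting values
(200/800/1650/3000 ms); non-convergence is flagged, not raised. ECV is the
ratio of gadolinium-induced R1 changes in muscle and plasma; the plasma
change must be positive (contrast must have arrived) and a voxelwise map
variant propagates invalid voxels as NaN.

### EPG dictionary T2 mapping

The MSME protocol (5.15 ms spacing, 32 echoes) is simulated with a
single-compartment extended-phase-graph recursion: ideal 90° excitation
under the CPMG phase condition, then per echo period relax(esp/2) → dephase
one configuration order → B1·180° refocusing → dephase → relax(esp/2), with
T1 recovery feeding the zero-order longitudinal state and configuration
orders truncated at `n_echoes + 1`. Crushers are assumed ideal (pure EPG, no
diffusion term). At B1 = 1 the train reduces exactly to `exp(−k·esp/T2)`;
for all B1 the implementation agrees with an independent isochromat-ensemble
(rotation-matrix) simulation to 1e−10 (see `tests/test_epg.py`).

The dictionary covers T2 = 5–80 ms in 0.1 ms steps and B1 = 0.4–1.2 in 0.02
steps with tissue T1 fixed at 1650 ms (the native-muscle scale; matching is
insensitive to T1 at these train lengths). Steps were chosen well below the
reported group IQRs; both grids are configurable. Echo trains are
unit-normalized and voxels are matched by maximum normalized inner product;
all-zero or non-finite voxels are flagged missing rather than matched.

### CPMG spectra and model-order selection

ISIS-CPMG decays (1 ms spacing, 200 echoes) are fitted with discrete 1-, 2-
or 3-component nonnegative exponential models. Initialization peels
components from slow to fast via log-linear tail estimates, then adds a
geometric-spread fallback and six jittered restarts; the lowest-RSS solution
wins and components are reported sorted by T2 with normalized fractions.
Nested fits are compared with sequential F-tests
(`F = ((RSS_s − RSS_c)/Δp)/(RSS_c/(n − p_c))`, α = 0.05, simple → complex);
equal-parameter candidates (the two bi-exponential UTE variants) are decided
by lower RSS, which is equivalent to the higher F against the accepted
simpler model. A zero complex RSS yields F = ∞ and acceptance, flagged.
The selection property (order 1 on mono data, order 3 on well-separated
tri-exponential data) holds at finite noise; on *noiseless* data any
overparameterized model attains RSS ≈ 0 and the F-test is undefined, so the
selection tests operate at SNR 200.

### UTE T2*

The oscillatory model is fitted as the magnitude of the complex signal to
the amplitude decay at the 16 protocol echo times, with the 970 Hz chemical
shift fixed (not fitted). The default TE list has 16 values; the protocol
text lists 16 values, and the list is configurable.
Amplitudes are bounded nonnegative; short/long components are ordered by
construction and a post-fit swap.

### ASL perfusion

Quantification uses the single-compartment saturation model with
λ = 0.75, T1m = 2 s, T1a = 2.2 s, tT = 0.2 s; with T1m in minutes and a
×100 factor the output is ml/min/100 g (tissue density 1 g/ml). Samples at
or past the model singularity (`r ≥ exp(−tT/T1a)`) are flagged NaN with a
warning. The paradigm summary defines **total perfusion** as the
baseline-subtracted trapezoidal integral of flow over the reperfusion
window, flooring per-sample negative excursions at zero, with the baseline
the median rest flow. This "volume repaid" definition is the only one
consistent with the reported control totals (≈50 ml/100 g, far below a
non-subtracted integral of rest flow over 10.7 min); it is applied
identically in the generator and the pipeline.

## Synthetic cohort calibration

Marginals are log-normal matched to the reference pooled-group median (IQR)
(`μ = ln(median)`, `σ = asinh(IQR/(2·median))/z₀.₇₅`), reflecting positive,
right-skewed metrics reported as median (IQR); skewness, which can be
negative, uses a normal marginal. Dependence on collagen fraction is a
Gaussian copula with one latent factor per muscle: the total-collagen
latent, an endomysial latent correlated with it at Spearman 0.92, and each
metric loading `2·sin(π·ρ_s/6)` on the latent of its primary reference
correlation (vs total collagen where reported, else vs endomysial).
The factor structure is positive semidefinite by construction; infeasible
user-supplied targets are rejected naming the offending pair. Realized
within-group rank correlations are unbiased for their targets with
Monte-Carlo error ≈ 0.034 at n = 500 (so single-draw checks at the 0.05
band fail for ~20% of seeds; the convergence test averages over seeds).
Pooled injured+control correlations additionally carry between-group
separation, as in the real paired design.

Values without reference medians required choices, made once:

- CPMG tri-exponential presets: T2 = 10/40/140 ms, fractions 0.10/0.75/0.15
  (injured) and 0.08/0.80/0.12 (control) — field-realistic skeletal-muscle
  values (macromolecular-interface, myofibrillar and interstitial pools).
- Perfusion curve shape: triangular hyperaemic overshoot starting at the
  first 20-s sample of reperfusion, decaying linearly over 360 s (injured)
  or 80 s (control), with the rest baseline solved from
  `total = (peak − baseline)·decay/2` (7.3 and 5.9 ml/min/100 g — plausible
  resting muscle flows). Breakpoints lie on the sampling grid so the
  trapezoidal summary reproduces the calibrated total exactly.
- Strain-specific presets differ from the pooled ones only in their
  collagen medians (the only strain-resolved reference values available).
- Texture energy: the reference presentation ("×10³") exceeds the Σp² ≤ 1
  bound of the definition and its binning is not stated; energy medians are
  set to 0.111/0.095 on the raw Σp² scale, preserving ordering and
  discriminability. Energy is not a recovery target.
- Ordinal scores are coded 0 = absent … 3 = severe and drawn from
  group-specific distributions (injured: mostly mild-to-moderate
  inflammation, frequent centronucleation, occasional calcification in
  line with the model's phenotype; controls mostly 0). Rank-based
  statistics use only their order.
- Shear moduli at 40°/60° interpolate monotonically between SM0 and SM80
  (fractions 0.45/0.75 of the SMi rise); only SM0/SM80 enter any statistic.
- The texture generator contaminates a Gaussian ROI with a shifted
  component (injured 6%, control 1%, −4 sd shift). Mixture kurtosis
  increases with contamination only in the dilute regime (it peaks near
  3.5% for a −4 sd shift before bimodality pulls it down); the
  monotonicity test covers 0–3%.

## What the synthetic data do not emulate

No k-space/reconstruction artifacts, partial-volume or motion effects,
anatomically structured images (texture ROIs are pixel samples; a 2-D
writer exists only for I/O tests), no dystrophic pathology (fat
infiltration, necrosis), no strain differences beyond collagen levels, and
metric noise is modality-independent given the latents. Passing recovery
tests therefore shows the estimators invert their stated forward models and
the statistics behave as specified — not that the pipeline is robust to
real-scanner artifacts.

## Statistics layer

Paired Wilcoxon uses the exact null for ≤ 25 nonzero differences (zeros
discarded; the classic convention) and the tie-corrected normal
approximation otherwise; Bonferroni multiplies by the metric-family size,
capped at 1. Partial Spearman rank-transforms all columns (mid-ranks),
residualizes on an intercept plus covariate ranks by OLS, and tests the
residual Pearson correlation with df = n − 2 − k; with no covariates it
equals plain Spearman exactly, and a variable entirely explained by the
covariates returns r = 0 rather than an error. Collinear covariates are
rejected. AUC is the Mann-Whitney pair-count statistic with half credit for
ties; the 95% CI uses the DeLong structural-components variance
(implemented here; cross-checked against exhaustive pair counting and
scikit-learn). The composite index robust-standardizes each panel metric by
median/IQR across samples (median-based, consistent with median (IQR)
reporting; mean/SD is not offered as the default), orients its sign by the
univariate AUC ≥ 0.5 rule, deduplicates the panel, excludes zero-IQR
metrics with a warning, and averages with equal weights. Missing values are
handled pairwise-complete per test, with n reported alongside every
statistic. The Bonferroni family is the per-analysis metric family (14
metrics in the pipeline report).

## Problem sizes and determinism

The analysis drivers use the 18-animal paired design; calibration and
convergence checks use cohorts of 200–4000 animals and a few seeds, sizes
at which Monte-Carlo error is comfortably below the tested tolerances.
Every generator takes an explicit seed and regenerates bit-identically;
the pipeline report is deterministic given its seed.

## Interfaces

The package is an analysis library plus numbered driver scripts; no shell
CLI is shipped, as the intended entry points are Python functions
(`run_pipeline`, the generators and estimators) and the `analysis/`
drivers. Cohort tables and signals are CSV; parameter maps and ROI masks
are NIfTI (nonzero = member) via nibabel; reports are JSON. Voxel-grid
alignment between maps and masks is required (no registration).

## Known limitations

Discrete 1–3 component T2 models (no regularized NNLS spectra); no
complex-valued UTE fitting or fat-suppression modeling; no B1 mapping
beyond dictionary co-estimation; no transit-time fitting or
multi-compartment ASL kinetics; the exact standardization and Bonferroni
family of the original analysis are unstated, so the defaults here are
declared and configurable.
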