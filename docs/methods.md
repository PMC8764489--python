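# Methods

This note documents the models implemented in `fmriverse`, the defaults
and why they were chosen, what the synthetic data do and do not emulate,
and the numerical choices a maintainer should know about.

## The synthetic study

Every analysis in the package runs on data from `fmriverse.synthetic`.
A bundle emulates a small preprocessed task-fMRI study:

- **Scale.** 16×16×16 voxel grid, TR 2 s, 160 volumes, 15 subjects.
  These sizes keep a full workflow ladder runnable in seconds while
  leaving enough voxels (4096) and frames for stable autocorrelation and
  cluster statistics. Fifteen subjects mirrors a small single-site study.
- **Task designs.** An event-related design emits, per trial, a unit
  `task_average` event and a `task_modulated` event at the same onset
  whose modulation column carries a response-time-like value drawn from
  U(0.8, 2.5) s; this is the structure that makes modulated-versus-average
  orthogonalization meaningful. A block design alternates two conditions
  in 10 s blocks. A multi-basis repeated-measures design can be generated
  but its group stage is intentionally unsupported (below).
- **Signal.** `effect_map × (HRF ⊛ task regressor)`, scaled per subject
  by a response gain drawn from N(1, 0.3²) truncated at zero. The gain is
  the between-subject variance component; without it, group t statistics
  at true voxels become unrealistically large because the only
  between-subject variability would be estimation noise. The default
  effect map holds six cubic blobs with amplitudes
  (1.0, 0.7, 0.5, 0.35, 0.08, 0.055) in innovation-SD units: the strong
  blobs sit firmly above the group detection threshold, the two weak ones
  straddle it. Marginal clusters are deliberate — they are what makes
  cluster-survival flips and thresholding amplification observable.
- **Drift.** Cosine components with periods 240 s and 480 s (amplitudes
  0.5 and 0.3, per-voxel loading U(0.5, 1.5)). Scanner drift is
  predominantly very low frequency; these periods are within reach of all
  three drift-model emulations, so drift-model interchange is benign by
  construction — matching the regime the package is meant to reproduce.
- **Motion nuisance.** Six smoothed random walks (the "motion
  parameters", returned with the bundle and used as nuisance regressors)
  coupled into the data through fixed spatially smooth loading maps.
- **Noise.** Stationary AR(1) in time with innovation SD 1 and lag-1
  coefficient 0.4 (typical of 2 s-TR data), independent across voxels.
- **Determinism.** Every generator is a pure function of its config and
  seed; subject seeds are drawn once from the config seed and recorded in
  the ground-truth sidecar.

What the generator does *not* emulate: spatial noise correlation,
physiological noise, susceptibility distortion, slice timing,
registration error, or any acquisition physics. Passing tests therefore
show that the *statistical machinery* behaves as designed under its
stated assumptions — not that real preprocessed data satisfy those
assumptions.

Correlated z-map ensembles are built as
`z_i = sqrt(ρ̄)·shared + sqrt(1−ρ̄)·unique_i + effect`, which is exactly
equicorrelated at ρ̄ with unit null variance, and trivially verifiable.

## First-level model

**HRF presets.** Three named difference-of-gammas presets stand in for
the canonical shapes of the major packages. Each kernel is
`g(t; delay/disp, disp) − ratio · g(t; u_delay/u_disp, u_disp)` (gamma
densities parameterized by mean `delay` and scale `disp`), normalized to
unit peak:

| style | peak delay | peak disp | undershoot delay | undershoot disp | ratio |
|-------|-----------|-----------|------------------|-----------------|-------|
| `S`   | 6 | 1 | 16 | 1 | 1/6 |
| `F`   | 6 | 1.5 | 16 | 0.5625 | 1/6 |
| `A`   | 5.6 | 0.9 | 12.2 | 0.9 | 0.08 |

`S` is the classic canonical double gamma; `F` matches a mean-6/SD-3 and
mean-16/SD-3 gamma pair; `A` peaks earlier with a weak undershoot. These
are *emulations* exposed in config, not reproductions of any package's
code; what matters for the variability analyses is that they differ the
way package families differ (peak time, width, undershoot).

**Signal regressors.** Condition boxcars (impulses for zero-duration
events) on a 16×-oversampled grid, heights given by mean-centered
modulation values where present, convolved with the kernel and resampled
at the frame times. Mean-centering before convolution is the standard
identifiability convention separating a modulated regressor from its
paired average-activity regressor. A condition whose centered modulation
is identically zero is rejected by name. Temporal derivatives (numerical
derivative of the convolved regressor) are optional and off by default.

**Orthogonalization.** `serial_preceding` residualizes each signal column
on all preceding signal columns in event-table order (automatic SPM-style
behaviour, scoped to signal columns); `pairwise_explicit` residualizes
named targets on named references (FSL-style); `none` is the AFNI-style
default. Orthogonalization never changes the design span — the hat matrix
is invariant (tested to 1e−8) — it only redistributes shared variance
among the signal coefficients.

**Drift models.** `dct_basis` uses `floor(2T/cutoff)` discrete cosine
columns (periods ≥ cutoff); `polynomial_basis` uses discretely
orthonormalized polynomials (QR of the Vandermonde matrix, so exact
orthogonality on the grid); `highpass_residualization` returns a
projection recipe over the same DCT basis which the GLM applies to both
data and design, with the consumed basis dimensions discounted from the
degrees of freedom. In the workflow engine all three styles default to an
effective ~128 s high-pass scale (`A` → polynomial degree 4, `F` →
residualization at 128 s, `S` → DCT at 128 s): the styles differ in basis
family and mechanism, not in how aggressively they filter, which is the
regime in which drift-model interchange is a minor contributor to
pipeline variability. The cutoffs and degrees are ordinary config fields
for anyone wanting to study cutoff mismatch instead.

**Noise models and prewhitening.** The fit is a two-pass prewhitened GLM:
OLS residuals → autocorrelation estimate → GLS on whitened data and
design. Four styles span the pooled-vs-voxelwise and AR-vs-ARMA axes
along which packages differ: `ols` (no whitening), `ar1_pooled` (one φ
averaged over the mask), `ar1_voxelwise` (per-voxel φ, vectorized via
closed-form whitened cross-products quadratic in φ), and
`arma11_voxelwise` (per-voxel (φ, θ) by method of moments on lags 1–2,
whitened through a Cholesky factor of the Toeplitz correlation matrix,
cached on a 0.02 parameter grid).

Residuals of a least-squares fit understate the noise autocorrelation
because the design projection absorbs part of it — materially so when the
design contains smooth drift regressors. The estimators therefore invert
the *expected* residual autocorrelation under the design's
residual-forming matrix M: with A_k = M S_k M (S_k the symmetrized lag-k
pattern), the expected residual lag-k autocorrelation under noise
correlation R is tr(A_k R)/tr(A_0 R), computable per candidate parameter
from diagonal sums in O(n). AR(1) styles invert this curve on a φ grid
(step 0.01); the ARMA style does a nearest-neighbour lookup on a
(φ, θ) grid (step 0.05). This correction is what keeps the voxelwise
type-I error at its nominal level (measured 0.050–0.053 at α = 0.05 on
AR(1) noise with the default design; OLS on the same data rejects at
~0.15, reproducing the mechanism behind noise-model-driven pipeline
variability). Prewhitening is two-pass, not iterated; degrees of freedom
are n − rank(design) (minus the high-pass basis dimension when drift is
handled by residualization), with no Satterthwaite-style correction.

## Group stage

One-sample t across subject effect (COPE) maps, df = n−1; the analysis
mask keeps voxels finite in all subjects and excludes zero-variance
voxels. t→z conversion is the probit of the Student CDF, evaluated on the
log scale so extreme statistics stay finite; one convention is applied
uniformly to all pipelines.

Cluster-extent FWE is always calibrated against the sign-flip permutation
distribution of the maximum supra-threshold cluster size. For n ≤ 12
subjects (or when the requested permutation count exceeds 2ⁿ) all sign
patterns are enumerated, making the p-values exact; the identity pattern
is always included, so no p-value can be zero. The null records the
maximum extent of *positive* clusters per pattern; by the sign symmetry
of the flip distribution the same null applies to negative clusters, so
control is per sign — the convention of the packages' one-sided
permutation tools, and what makes the smallest achievable p equal
1/2ⁿ. The cluster-forming cutoff is the one-sided Student quantile
applied to each sign separately. A "parametric"-branch workflow is
thresholded against the same permutation null (random-field and
simulation-based cluster p-values are deliberately out of scope; the
branch is kept as metadata so the pipeline space enumerates correctly).
Default connectivity is 26 (configurable to 6 or 18; packages disagree
and nothing here depends on the choice).

Per-dataset-kind inference settings: cluster-forming p < .01 (`ds1_like`),
p < .005 (`ds109_like`), p < .001 (`ds120_like`), all with clusterwise
FWE p < .05.

Voxelwise FDR is one-sided Benjamini–Hochberg within the mask, used by
the consensus stage.

## Comparison statistics

Pearson r is computed over the *intersection* of the two analysis masks
(union-with-zeros would bias r; mask disagreement is already quantified
by spill-over). Dice is per sign, `|A∩B|/((|A|+|B|)/2)`; when exactly one
mask is empty Dice is 0, and when both are empty it is reported missing
(NaN) rather than 1 — agreement on "nothing survived" is not evidence of
overlap. Spill-over is the percentage of one map's activation outside the
other's analysis mask, missing when there is no activation.

## Consensus meta-analysis

The consensus statistic is `mean(z_i) / sqrt((1+(k−1)ρ̄)/k)`, standard
normal under an exchangeable equicorrelated null. ρ̄ is the mean of the
k(k−1)/2 pairwise in-mask correlations, estimated by default over the
whole shared mask; a config hook restricts estimation to a presumed-null
voxel mask, and the estimator itself is pluggable. ρ̄ is clipped below at
−1/(k−1) to keep the variance correction positive (unreachable in
practice for pipelines sharing data). Whole-mask estimation slightly
*over*-estimates ρ̄ in the presence of shared true signal, which is
conservative for the consensus. Inference is two independent one-sided
BH-FDR procedures at q = 0.05; an empty negative side is an expected
outcome, not an error.

## Workflow engine

A pipeline spec fixes the style at five points — preprocessing, signal,
drift, noise, group — plus the inference branch. The noise style is also
the executing package, since one package's noise model cannot run inside
another; signal and drift interchange is literal column exchange in the
design matrix. Ladders walk from the all-secondary workflow (rung 1) to
the all-reference workflow (rung 7) flipping one stage per transition:
preprocessing→common surrogate, group, noise, drift, signal,
preprocessing→reference. The transition order is a property of the
scheme descriptor, not hard-coded. Rung labels (`1A`, `4AF`, `7F`, …)
follow the ladder convention; nonparametric-branch ids carry a `-np`
suffix. The two ladders of a dataset share their all-reference endpoint,
which is emitted once — hence 13 parametric workflows per ladder dataset,
26 with both branches, 7 for the single-ladder repeated-measures dataset,
59 in total.

At desk scale the four preprocessing styles map onto the generator's
single preprocessed output with a per-style spatial smoothing surrogate
(σ = 0 / 0.3 / 0.5 / 0.7 voxels for fMRIPrep-like / A / S / F): real
preprocessing is out of scope, but the surrogate keeps preprocessing
rungs non-degenerate so the enumeration and reporting logic traverses
them meaningfully. The repeated-measures (`ds120_like`) group stage
raises "unsupported group model": its multi-basis F-test group models are
intentionally not implemented, mirroring the fact that not every group
model is portable across packages; the workflow engine enumerates those
specs but will not execute them.

The variability report computes the full pairwise comparison matrices,
attributes adjacent-pair differences to the single stage that changed,
and runs the consensus across all completed workflows.

## Numerical and interface choices

- Voxel indices are 0-based; all volumes share one grid, no resampling;
  volumes are written as NIfTI-1 with identity affine; events as
  BIDS-style TSV (`trial_type` column); ground truth as a JSON sidecar.
- Rank deficiency of an assembled design is an error naming the collinear
  columns (QR diagonal test at 1e−8 relative).
- Noise parameter clips: φ ∈ [−0.99, 0.99] (AR), grid bounds
  φ ∈ [−0.3, 0.9], θ ∈ [−0.6, 0.6] (ARMA).
- Ties and degenerate inputs: empty supra-threshold sets yield valid
  empty thresholded maps; zero-variance voxels are excluded from masks
  with a logged count; constant maps make correlations undefined and are
  rejected by position.
- Test problem sizes (10⁴-voxel calibration grids, 200-ensemble null
  batches, 15-subject recovery bundles) were chosen to keep Monte-Carlo
  error comfortably inside the asserted tolerances while the whole suite
  runs in well under a minute.

## Known limitations

- The package styles are emulations of model *families*; none of the
  numerical idiosyncrasies of the real packages (tapered autocovariance
  estimators, restricted maximum likelihood pooling, specific basis
  implementations) are reproduced.
- Group modelling is a one-sample t surrogate for every group style;
  between-package group-model differences are represented in the
  enumeration but not in execution (except the unsupported
  repeated-measures stage).
- Spatially independent noise means cluster-extent nulls are small
  compared with smoothed real data; cluster-level conclusions transfer
  qualitatively, not quantitatively.
- The consensus correction assumes exchangeable equicorrelation; a full
  correlation-matrix weighting is not implemented (the estimator hook is
  the extension point).
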