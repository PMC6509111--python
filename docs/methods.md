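# Methods

This note documents the models, algorithms, parameter choices and known
limitations of `stategrain`, in the order data flows through the
package.

## Synthetic neural data

Each subject's condition set is the cross of target people (any subset
of self / close / far) and mental states.  The generator
(`stategrain.synth`) draws, per subject:

- a **target mean map** m_T per target, i.i.d. N(0, 1) across voxels
  (the unit spatial scale all other magnitudes are relative to);
- a **state latent map** z_s per state, i.i.d. N(0, 1), *shared across
  targets* — so "the same state for two targets" is a meaningful
  correspondence, as required by cross-target state-space alignment;
- the beta volume for condition (T, s):

      beta_Ts(v) = m_T(v) + disp_T(v) · z_s(v) + ε,   ε ~ N(0, noise_sd²)

  where disp_T(v) equals `dispersion_by_target[T]` inside the
  designated effect region and `baseline_dispersion` elsewhere.

Within a searchlight, the spatial correlation between two of target
T's states is approximately σ²_m / (σ²_m + disp_T² + noise²), so larger
dispersion ⇒ lower within-target pattern correlation ⇒ higher
correlation-distance distinctiveness.  Planting dispersions
(self, close, far) = (1.0, 0.6, 0.2) therefore plants the ordering
self > close > far in the statistic under test.  These values, with
`baseline_dispersion = 0.3` and `noise_sd = 0.3` (moderate noise:
comparable to the smallest planted dispersion), are the package's
standard planted-effect conditions; null conditions set both targets'
dispersion to 0.5 everywhere.  The default grid is 12×12×12 voxels at
2 mm — large enough for a radius-4 searchlight to have full interior
spheres, small enough for simulation studies on one CPU.

Per-subject randomness comes from `SeedSequence([master_seed,
subject_id])`, so any subject can be regenerated independently and all
generators are bit-reproducible.

What the generator does **not** emulate: BOLD autocorrelation,
physiological noise, scanner drift beyond the linear trends the GLM
removes, anatomical structure, or inter-subject spatial misalignment.
Passing recovery tests therefore demonstrates correctness of the
estimators under the assumed signal model, not robustness to real
acquisition artifacts.

### Trial designs

`generate_trial_design` produces either all C(n,2) unordered state
pairs per target (the rating task: 15 states × 3 targets → 315 trials;
10 states × 2 targets → 90 trials) or one trial per (target, state) per
run (the scanner task), with per-seed randomization.  Blocked designs
group trials by target within run (block order and within-block order
randomized); intermixed designs shuffle targets freely.  Scanner-task
onsets use a 4.2 s trial and jitter drawn in 1.4 s increments from a
truncated Poisson (mean 1.4 s, max 4.2 s).

## First-level GLM

The design matrix has one boxcar per condition convolved with the
canonical double-gamma HRF (response peak 6 s, undershoot 16 s, unit
dispersions, peak:undershoot 6, 32 s support — the de-facto standard
parameterization), computed on a 16× oversampled grid and sampled at
scan times; plus per-run intercepts, per-run centered linear trends,
and optional per-run-centered motion covariates.  Estimation is
ordinary least squares per voxel.  No prewhitening is applied: the
synthetic noise is white by construction, and real-data reanalysis
(which would need an AR model and a high-pass filter) is out of scope.
Rank-deficient designs raise an error naming the collinear columns
(pivoted-QR detection).

`design_induced_similarity` returns the correlation matrix of the
condition beta *estimators* implied by (XᵀX)⁻¹ — in blocked designs,
conditions sharing a block have structurally correlated estimators.
`correct_block_structure` removes this leakage by regressing the
off-diagonal measured pattern similarities on the induced estimator
correlations (with intercept) across condition pairs and keeping the
residuals; with an orthogonal design this reduces to centering.  The
residualization is deliberately isolated in one function so an
alternative correction can be swapped in.

## RSA distinctiveness

`compute_rdm` forms d = 1 − Pearson r between all condition pattern
pairs.  Distances are averaged directly (equivalently, raw correlations
are averaged) rather than Fisher-z transformed; averaging r is the
common convention for summarizing similarity matrices and keeps Δr
interpretable as a difference of mean correlations.  Per-target
distinctiveness is the mean of the within-target lower triangle only —
cross-target entries never contribute.

Searchlights are integer-lattice spheres (radius in voxel units;
radius 4 ⇒ 257 voxels) intersected with the analysis mask.
Neighborhoods with fewer than 30 in-mask voxels are undefined (NaN) and
excluded from group maps.  Constant (zero-variance) patterns cannot
enter a correlation: the affected condition is dropped from that
neighborhood (logged), and neighborhoods losing more than 10% of
conditions are skipped entirely.  The searchlight engine computes all
neighborhood sums through one sparse neighborhood-indicator matrix, and
the test suite verifies it is entry-for-entry identical to explicitly
building each neighborhood's RDM.

## Group inference

Per-subject distinctiveness maps are smoothed **before** group testing
(6 mm FWHM separable Gaussian, σ = FWHM / (2√(2 ln 2)) per axis,
reflective boundaries, which preserve total mass; NaN voxels are
handled by normalized convolution and stay NaN).

Voxelwise statistics are the paired t (df = n−1) for two targets and
the one-way repeated-measures F (df = (k−1), (k−1)(n−1)) for three.
TFCE integrates e(h)^E · h^H · dh over thresholds with E = 0.5, H = 2,
26-connectivity and dh = max/100 — the field-standard values.  FWE
control is by maximal-statistic permutation: per-subject sign flips of
the difference maps (paired t) or independent within-subject target
relabelings (ANOVA), always including the identity; requesting more
permutations than exist triggers exhaustive enumeration with a warning.
Each voxel's corrected p is the fraction of permutations whose
image-wide maximum enhanced statistic reaches that voxel's observed
enhanced value.  Two-sided paired tests enhance the positive and
negative tails separately and Bonferroni-combine them (×2), following
the package-wide two-sided convention; the ANOVA tail is one-sided by
nature.

Two implementation details matter for speed and are covered by
equivalence tests: (i) random sign-flip sets are generated
negation-closed (antithetic pairs), which makes the negative-tail null
maximum distribution exactly equal to the positive-tail one, so only
one tail needs enhancing; (ii) the permutation null is enhanced in one
batch by normalizing every map to unit peak (TFCE is homogeneous of
degree H+1 when dh = max/n_steps) and labeling all maps jointly with a
structure that never connects different permutations.

ROI-level comparisons report the paired t, two-sided p, paired Cohen's
d = mean(diff)/sd(diff), Δr (the same contrast on the mean-correlation
scale r̄ = 1 − D, so Δr = −Δdistance), and Bonferroni-adjusted p over
the number of target pairs.

## Rating mixed model

`simulate_ratings` generates rating = grand mean (3.5, scale midpoint)
+ b·code + participant intercept/slope + pair intercept/slope +
residual.  The default random-effect SDs (0.6 / 0.3 participant
intercept/slope, 0.3 / 0.1 pair intercept/slope, residual 1.0) make the
random structure absorb roughly a third of total variance, typical of
such rating tasks.  Ratings are continuous by default; optional
rounding/clipping to 1–6 is available but attenuates b (a Likert
response cannot be both Gaussian and integer), so recovery studies use
the continuous form.  The default target coding is 0 for the first
target and 1 for the rest — self-vs-other when self is present, close
(0) vs far (1) otherwise — so b is the far−close mean difference in the
two-target design.

The fitter (`stategrain.lmm`) implements profiled REML with the
standard Cholesky decomposition of the mixed-model equations (dense
q×q, adequate for the few hundred random-effect levels these designs
produce), L-BFGS-B over the relative-covariance factors with diagonal
entries bounded at zero.  Fixed-effect df use the Satterthwaite
approximation: df = 2·Var(c'β̂)² / Var̂(Var(c'β̂)), with the gradient of
the contrast variance and the curvature of the REML deviance both
obtained by central finite differences in (θ, σ).  Against lme4 +
lmerTest on a frozen fixture, estimates, standard errors, variance
components and Satterthwaite df agree to at least four significant
digits (see `tests/test_lmm.py`).

The maximal structure — correlated intercept+slope for participant and
for state pair — falls back on singular fits or non-convergence by
dropping correlations, then the pair slope, then the participant slope;
each step is logged in the result.  A fit is singular when any relative
Cholesky diagonal is below 10⁻⁴.  Standardized β comes from refitting
with z-scored response and predictor; marginal/conditional R² follow
the Nakagawa variance decomposition, with each term's random variance
computed as the mean observation-level quadratic form of its fitted
covariance.  Post-hoc least-squares means refit with the target factor
dummy coded (same coding in the random slopes) and report all pairwise
contrasts with Satterthwaite df; in balanced designs these equal raw
target means.  The social-distance composite is the arithmetic mean of
raw similarity, familiarity and closeness scores (a z-scored-entry
option exists), with the mean pairwise correlation among the three
reported alongside; the continuous-distance model z-scores the
composite across participant × target cells because its coefficient is
reported standardized.

## State-space geometry

Per-target 2-D embeddings use classical (Torgerson) MDS — double-center
the squared-distance matrix, take the top two eigendirections —
deterministic and seed-free, with axis signs fixed by convention.
Non-reference targets are rotated/reflected onto the self (first)
target's configuration by orthogonal Procrustes *without scaling*, so
each target's circle radius (its mean within-target dissimilarity)
remains comparable across targets.  Alignment provably preserves
within-target pairwise distances (tested to 1e-10).

## Validation studies and problem sizes

All validation studies live in `stategrain.experiments` and are seeded
end to end.

- **Null FWER** (`null_fwer_experiment`): both targets share dispersion
  0.5, so any significant voxel is a false positive.  The full study —
  200 datasets × 12 subjects, 12³ grid, 2 targets × 8 states, 500
  sign-flip permutations — runs in `scripts/acceptance.py`; the test
  suite runs 60 datasets and checks that the Clopper–Pearson 95% CI of
  the empirical FWER contains or falls below 0.05.
- **Planted-effect recovery** (`planted_recovery_experiment`): 20
  cohorts of 20 subjects with dispersions (1.0, 0.6, 0.2); the ROI
  pairwise differences must carry the planted signs in ≥95% of cohorts,
  and for three cohorts the full searchlight map must show a larger
  group self-vs-far difference inside the planted region than outside.
- **Mixed-model recovery** (`lmm_recovery_experiment`): two-target
  rating studies with planted b = 0.23.  The test suite runs 100
  replicates at 60 participants × 10 states (the same crossed design at
  reduced width; CI coverage and test calibration are properties of the
  estimator, not the sample size) requiring ≥90% CI coverage, and 100
  null replicates requiring empirical type-I error ≤ 0.07 at nominal
  0.05.
- **TFCE oracle**: the fast implementation must match a pure-Python
  flood-fill enumeration on 50 random 8³ maps within one threshold
  step's contribution.

## Numerical choices and degenerate inputs

- Pearson correlations are clipped to [−1, 1] before distancing;
  RDM symmetry/zero-diagonal/range are enforced at construction.
- A pattern counts as constant when its centered sum of squares is
  below 10⁻¹⁰ of its raw sum of squares.
- Zero-variance paired differences make a voxel's t undefined (NaN,
  logged, excluded from permutation maxima); identical ROI scalars
  return t = 0, p = 1, while constant *nonzero* differences raise.
- TFCE thresholds are exact fractions of the map peak so the top
  threshold includes the peak voxel; explicit dh values use plain
  multiples.
- The REML optimizer starts at unit relative SDs with zero
  correlations; Satterthwaite falls back to residual df if the deviance
  Hessian is numerically singular (flagged by a warning).

## Known limitations

- Real-data adapters stop at NIfTI/TSV/CSV ingestion; motion
  parameters must be supplied, and no preprocessing (realignment,
  normalization, slice timing) is provided or planned.
- The block-design correction is a linear residualization; nonlinear
  leakage of design structure into pattern similarity would survive it.
- Crossvalidated distance estimators (crossnobis, Mahalanobis) are
  deliberately out of scope: the pipeline measures plain Pearson
  distance, whose positive bias under noise cancels in between-target
  contrasts but not in absolute distinctiveness values.
- The mixed-model engine targets the rating-study design family
  (crossed intercept+slope structures, a few hundred levels); it is not
  a general-purpose sparse LMM solver.
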