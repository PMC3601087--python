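# Methods

## Scientific setting

`gmtraj` analyses cross-sectional voxel-based morphometry (VBM) data from a
two-group design: abstinent cocaine-dependent (CD) subjects with known weeks of
abstinence and years of prior use, and drug-naive controls. The response at
each voxel is the modulated, smoothed grey-matter (GM) value — a partial-volume
estimate multiplied by the Jacobian of the nonlinear warp to common space, so
values represent local GM volume. The package does not perform segmentation,
registration or modulation; it starts where preprocessing ends.

The analysis chain is:

1. **Voxelwise Huber robust regression** of GM on
   `[intercept, abstinence_weeks, years_use, age]` across the CD group only
   (age is a nuisance; covariates stay in natural units so downstream
   crossover points come out in weeks/years). With n = 43 CD subjects and
   p = 4 columns, the t maps carry 39 residual degrees of freedom.
2. **Sign splitting**: each term's t map is split into positive- and
   negative-coefficient maps, thresholded two-tailed at |t| >= t_crit with
   t_crit the upper 1 - p/2 Student-t quantile (p = 0.005, df = 39 → 2.976).
3. **Monte-Carlo cluster-extent correction**: smooth Gaussian null fields on
   the analysis mask calibrate the distribution of the largest suprathreshold
   cluster; surviving clusters must meet a minimum size chosen so the
   family-wise false-positive probability is 5%.
4. **Crossover analysis**: per surviving cluster, mean GM is extracted per
   subject; a Huber line is fit to CD values against the cluster's covariate,
   and the crossover point is where it meets the arithmetic control mean:
   `crossover = (control_mean - intercept) / slope`. CD subjects strictly
   beyond the crossover are compared to controls with a Welch t-test, and
   cross-term specificity is checked by regressing each cluster's ROI means on
   the *other* covariate (age nuisance, uncorrected p < 0.05).

## Huber IRLS details

The M-estimator uses tuning constant k = 1.345 (95% Gaussian efficiency).
Residual scale is re-estimated every iteration as the median absolute residual
about zero divided by Φ⁻¹(3/4) ≈ 0.6745, floored at
`1e-12 * (1 + |median(y)|)` so voxels with an exact linear fit do not divide
by zero (they reduce to OLS, which is the correct limit). Iteration starts
from OLS and stops when `max|Δβ| / (1 + max|β|) < 1e-8` (cap 50 iterations;
non-convergence is flagged per voxel and counted, never raised). Standard
errors use the Huber (1973) "H1" estimator with the small-sample correction
factor `c = 1 + (p/n)·var(ψ')/mean(ψ')²`:

    cov(β) = c² · [Σψ(r/s)²·s²/(n-p)] / [mean ψ'(r/s)]² · (XᵀX)⁻¹

This is the default covariance of the widely used reference implementation in
statsmodels (`RLM(..., M=HuberT()).fit(scale_est="mad", cov="H1")`), and the
test suite verifies agreement of coefficients and standard errors to 1e-6 on
random contaminated problems — so the voxelwise engine is interchangeable with
the reference at single-fit granularity while being vectorized across all mask
voxels (batched 4×4 weighted normal equations), which is what makes
whole-mask fits take seconds rather than hours.

A consequence of the MAD scale worth knowing: in very small samples a single
gross outlier inflates the scale enough that no residual exceeds k·scale, and
the Huber fit *is* the OLS fit (e.g. y = [0,1,2,10] on x = [0,1,2,3] gives
slope 3.1 in this package, statsmodels, and MASS::rlm alike). Robustness
claims therefore hold asymptotically, not at n = 4.

## Monte-Carlo cluster-extent null

Each null iteration draws a white Gaussian field on the full grid, smooths it
with the Gaussian kernel matching the assumed data smoothness (default FWHM
4.7 mm, the data-smoothing kernel σ = 2 mm), standardizes it to zero mean and
unit variance within the mask, applies the two-sided *Gaussian* quantile for
the voxel p (simulated fields are Gaussian by construction; observed t maps
use the Student-t critical value), labels each sign separately, and records
the maximum cluster size over both signs — the max-statistic construction that
gives two-sided family-wise protection. The extent threshold is the smallest
size whose estimated null exceedance probability is strictly below alpha;
resolving a tie at exactly alpha upward keeps the realized FWE at or below the
nominal level. Survival requires `size >= threshold`.

Connectivity is 6 (faces) by default, with 18 and 26 available. Labeling
delegates to `scipy.ndimage.label`; tests verify the partition against
`skimage.measure.label` as an independent oracle. Smoothness is a
configuration input, not estimated from residuals.

Calibration is verified empirically: with the default phantom mask
(40×48×40 at 2 mm, ellipsoid support, ~20,600 voxels), a threshold calibrated
on 1,000 iterations holds the FWE of 400 fresh null datasets inside the 95%
binomial band around 0.05 ([0.028, 0.078]).

## Synthetic phantom cohorts

The generator emulates the *output* of preprocessing, not a brain:

- Support is a centered ellipsoid (semi-axes 0.4× the grid extent); cluster
  inference only needs a connected mask of realistic volume, not anatomy.
  Default grid 40×48×40 at 2 mm isotropic keeps runs desk-scale while a
  360 µl cluster still spans a meaningful 45 voxels.
- Covariates are sampled uniformly within the study population's ranges
  (abstinence 1–102 weeks, years of use 0.3–24, age 20–55). Only ranges and
  means are published for the real cohort; uniform is the least-committal
  choice, and it will not reproduce the published means — that is documented,
  not asserted.
- Each effect is a sphere where CD maps receive
  `cd_offset + slope·covariate(subject)`; controls stay at baseline
  (default 0.5) everywhere. `cd_offset` lets the CD trajectory start below
  the control mean so the crossover point `-cd_offset/slope` is a nontrivial
  ground truth; the canonical recovery phantom uses slope 0.002 GM/week and
  offset −0.05 (true crossover 25 weeks).
- Noise is white Gaussian (default sd 0.03 before smoothing), smoothed with
  the same σ as the data smoothing, masked to the support, and added before
  the final clip at zero — matching the smoothness assumption the Monte-Carlo
  null uses. The post-smoothing voxel sd is checked in tests against a
  brute-force convolution oracle.
- Ground-truth effect masks are returned with the maps so recovery tests never
  re-derive them.

What passing phantom tests does **not** show: robustness to registration
error, anatomy-dependent smoothness, non-Gaussian physiological noise,
covariate measurement error, or correlated covariates — real VBM data have
all of these. The phantom establishes that the statistical machinery is
correct under its own assumptions, nothing more.

## Degenerate inputs and numerical conventions

- Zero-variance response: slopes 0, intercept = the constant (median).
- Zero or sub-floor ROI slope: the crossover is flagged invalid (NaN), never
  an exception; an optional plausibility window flags but still reports
  out-of-range crossovers.
- "Beyond crossover" means strictly greater covariate value; fewer than two
  CD subjects beyond (or two controls) makes the Welch test "not testable".
- ROI trend fits exclude nuisances by default (enable with
  `roi_nuisance=("age",)`); with nuisances, the reported intercept is
  re-centered to the nuisance sample means so the line stays in natural units.
- Cluster center of mass is the unweighted mean of member voxel centers mapped
  through the affine; coordinates are RAS+ (0-based voxel indices; mm only
  ever come from the affine).
- The analysis mask rule is `mean GM across subjects > 0.05` (configurable).
- Welch tests on raw values use `scipy.stats.ttest_ind(equal_var=False)`;
  demographic Welch t and Satterthwaite df are computed from published
  mean/SEM/n summaries; the gender test is the Yates-corrected chi-square.

## Problem sizes used by tests and the acceptance script

Phantom recovery uses 20 cohorts of 43+43 subjects on the default grid with
one abstinence effect; family-wise calibration uses 1,000 calibration
iterations plus 400 fresh null datasets; IRLS reference agreement uses 100
random n = 50, p = 4 problems. These sizes give stable estimates at desk
scale (the full acceptance run takes about a minute on one CPU). Production
analyses should raise `n_iterations` to the 10,000 default.

## Known limitations

- ROI trend lines are fit to clusters selected by the same data (selection
  circularity inflates apparent correlations); the package reports the fits
  as-is and leaves correction to the analyst.
- Robust residual degrees of freedom are debated; t maps use df = n − p.
- No residual-based smoothness estimation; the null smoothness is an input.
- The generator's uniform covariates and single-sphere effects are idealized;
  see above for what that does and does not validate.
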