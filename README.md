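# gmtraj — grey-matter trajectory analysis

`gmtraj` is a tested pipeline for asking how regional grey-matter (GM) volume
changes with drug-use history and abstinence duration in voxel-based
morphometry (VBM) data. It is aimed at neuroimaging researchers who have
modulated, smoothed GM maps in a common space (one 3D NIfTI per subject) plus
a covariate table, and who want the classic robust-regression /
cluster-correction / trajectory-crossover analysis with every step unit-tested
and reproducible — including a synthetic phantom generator for validating the
whole chain against known ground truth.

## The model

For each voxel v inside the analysis mask, the GM values of the
cocaine-dependent (CD) group are modeled as

    GM_i(v) = β₀(v) + β₁(v)·abstinence_weeksᵢ + β₂(v)·years_useᵢ + β₃(v)·ageᵢ + εᵢ(v)

fit by the **Huber M-estimator** (k = 1.345, MAD/0.6745 residual scale,
iteratively reweighted least squares), which keeps single aberrant subjects
from driving voxelwise slopes. With n = 43 subjects and p = 4 columns the
t = β/SE maps have 39 degrees of freedom; voxels pass at two-tailed p = 0.005
(|t| ≥ 2.98) after splitting each term's map by coefficient sign.

Family-wise error across the mask is controlled by **Monte-Carlo
cluster-extent thresholding**: smooth Gaussian null fields (default FWHM
4.7 mm, matching the data smoothing σ = 2 mm) are thresholded the same way,
and the largest null cluster per iteration calibrates the minimum cluster size
whose chance probability is below 5%.

For each surviving cluster, the per-subject mean GM is extracted and a robust
line against the cluster's covariate is intersected with the control-group
mean to give the **crossover point**

    x* = (mean_control − intercept) / slope ,

the abstinence duration (or years of use) at which the CD trajectory reaches
normal volumes. Welch t-tests compare CD subjects beyond the crossover with
controls, and cross-term regressions check that abstinence and use effects
occupy distinct regions.

## Worked example

Simulate a phantom cohort (43 CD + 43 controls on a 40×48×40 grid at 2 mm)
carrying one spherical effect where CD grey matter starts 0.05 below the
control baseline and rises 0.002 GM-units per week of abstinence — a true
crossover at 25 weeks — then run the full analysis:

```python
from gmtraj import RunConfig, run_full_analysis
from gmtraj.synth import CohortConfig, default_abstinence_effect
from gmtraj.cluster_mc import ClusterParams

cfg = RunConfig(
    cohort=CohortConfig(effects=(default_abstinence_effect(),), seed=7),
    cluster=ClusterParams(n_iterations=1000),
    seed=7,
)
res = run_full_analysis(cfg)
```

Printing the key results:

```
voxel threshold |t| >= 2.976, extent >= 24 voxels = 192 ul
cluster: term=abstinence_weeks polarity=positive size=257 vox (2056 ul),
         center of mass (1.0, 1.0, 1.0) mm, peak |t|=136.8
trend: slope=0.00199 GM/week, intercept=0.450, control mean=0.500
crossover at 24.9 weeks of abstinence
Welch test beyond crossover: t=9.87, df=31.1, p=4.32e-11
cross-term (years_use) p=0.59
```

Reading this: the Monte-Carlo null says any cluster of ≥ 24 voxels (192 µl)
of |t| ≥ 2.98 voxels is significant at 5% family-wise; exactly one such
cluster survives, centered on the planted sphere (grid center, 1 mm off due
to the even grid). The robust ROI trend recovers the generating slope
(0.00199 vs 0.002) and intercept (0.450), so the fitted line crosses the
control mean at 24.9 weeks versus the true 25. Subjects abstinent longer than
the crossover have significantly higher GM than controls, and the cluster
shows no years-of-use effect (p = 0.59), as constructed.

The same run from the shell:

```bash
gmtraj run --out results/demo --seed 7     # writes clusters.tsv, crossovers.tsv, report.md
gmtraj stats welch 37.5 1.2 43 38.7 1.6 43 # Welch t from group summaries
gmtraj stats chi2 41 2 36 7                # Yates chi-square on a 2x2 table
```

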