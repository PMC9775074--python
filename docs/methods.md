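# Methods

This note records the model underlying each module, the default parameters
with units and rationale, and the numerical choices that affect results.

## 1. Diffusion phantom (`synthetic_data.PhantomSpec`)

A rectangular grid (default 20×20×20 voxels of 2×2×2.5 mm) with an
axis convention of x = left-right (LR), y = anterior-posterior (AP),
z = cranio-caudal (CC) — the geometry at the lateral-ventricle body where
the ALPS ROIs are placed. Two fiber slabs sit at the same x/z position
("parallel to" each other in the LR/CC plane) and are separated along y:

- **projection region** (anterior slab): base tensor diag(0.6, 0.6, 1.7)
  ×10⁻³ mm²/s — principal axis CC;
- **association region** (posterior slab): diag(0.6, 1.7, 0.6)×10⁻³ —
  principal axis AP;
- **background / subcortical_other**: isotropic 0.8×10⁻³.

Diffusivity magnitudes are typical white-matter values (axial ≈1.7,
radial ≈0.6×10⁻³ mm²/s). The perivascular contribution is a single scalar
`pvs_axis_boost` (default 0.46×10⁻³) added to Dxx in both fiber regions,
giving a ground-truth ALPS of (0.6+0.46)/0.6 ≈ 1.767, a typical
healthy-control value. `wmh_scale` multiplies every tensor uniformly,
modelling a global free-water diffusivity change; the ALPS index is exactly
invariant to it. All base tensors are validated symmetric positive definite.

## 2. DWI forward model and tensor fit (`synthetic_data.generate_dwi`, `dti`)

Signals follow the monoexponential tensor model S = S₀·exp(−b·gᵀDg).
Gradient directions come from a deterministic Fibonacci-sphere scheme
(`make_gradient_scheme`; default b = 1000 s/mm², one leading b0). Noise is
Rician: independent Gaussians of sd `noise_sigma·S₀` on the real and
imaginary channels before the magnitude, so SNR on b0 equals
1/`noise_sigma`. Simulation accepts any scheme; the *fit* requires ≥6
non-collinear diffusion directions (`GradientSchemeError` otherwise).

Fitting is ordinary log-linear least squares: −ln(S/S₀) = B·d with the
6-column design b·(gx², gy², gz², 2gxgy, 2gxgz, 2gygz), one shared
pseudoinverse applied to all voxels. Multiple b0 frames are averaged.
Voxels with any non-positive signal are masked out. Eigenvalues are clamped
at zero for derived maps (FA, directional diffusivities); the number of
clamped voxels is reported (`n_clamped`). On noiseless data the fit is exact
to machine precision (round-trip error ~10⁻¹⁵ relative).

## 3. ALPS measurement (`alps`)

The index uses tensor **diagonal elements** in scanner axes (Dxx, Dyy, Dzz),
not eigenvalues, from two ROIs:

ALPS = mean(Dxx_proj, Dxx_asso) / mean(Dyy_proj, Dzz_asso).

ROIs are "spherical" 12-voxel neighborhoods: the N voxels nearest the center
by squared physical distance, ties broken lexicographically on voxel index,
so placement is fully deterministic. Centers whose neighborhood would leave
the volume raise `RoiPlacementError` rather than silently truncating.
`suggest_roi_centers` automates placement from the color-FA map: the
projection ROI maximizes blue×FA (CC-oriented fibers, FA floor 0.2) and the
association ROI maximizes green×FA on the same LR/CC line, mirroring how the
ROIs are drawn on directional-encoded color maps in practice. A zero
denominator raises `DegenerateMeasurementError`.

## 4. Cohort generator (`synthetic_data.CohortSpec`)

Four groups — NC (n=52), CSVD-non-CI (56), CSVD-MCI (52), CSVD-VaD (29) —
with demographics, vascular risk factors, imaging markers
(white-matter-hyperintensity volume lognormal; lacunes and microbleeds
zero-inflated Poisson; basal-ganglia enlarged perivascular spaces Bernoulli),
screening scores (MMSE, MoCA, CDR, ADL) consistent with the group label
except for a small `label_noise` fraction (default 2%), and ten raw
neuropsychological tests loading on a latent memory factor (loading 0.7).

The scientific core is a within-group mediation chain on group-centered
variables:

- alps = group mean + a·log-WMH + (age effect)·age + ε₁, a = −0.30
- memory = group mean + b·alps + c′·log-WMH + ε₂, b = 0.50, c′ = −0.05

Effect sizes are moderate by design: the indirect effect is reliably
detectable in large samples and near the detection limit in a single
52-subject subgroup. `orthogonalize_residuals` (default off) projects the
residual draws orthogonal to the within-group regressors so that OLS
recovers the generating paths *exactly*; it exists because a literally
noiseless chain makes the outcome regression collinear (M is then an exact
linear function of X), so exact-recovery tests need orthogonalized noise
rather than no noise. These defaults are study conditions, fixed before the
calibration experiments below were run.

Reference contingency tables and group moments for gender, basal-ganglia
EPVS, age and education ship as `REFERENCE_*` constants; they reproduce the
published group statistics (χ² 0.106 and 25.293; F 12.88 vs printed 12.87
and 21.83 vs 21.75 — the residual gap comes from the inputs being printed
to two decimals).

## 5. Scoring and classification (`cohort_scoring`)

Timed tests (TMT-A/B, Stroop B/C) are inverted by negation (default) so
higher always means better; a reciprocal mode exists for sensitivity checks.
Scores are z-standardized against the whole sample (default) or the NC
group, and five domain composites are pairwise means of z-scores: episodic
memory (WMS visual reproduction delayed, AVLT delayed), language (BNT,
category fluency), processing speed (TMT-A, Stroop B), executive (TMT-B,
Stroop C), visuospatial (clock drawing, VRT). Missing constituents propagate
to NaN; a zero-variance reference is an error.

Education-adjusted cutoffs: MMSE dementia threshold ≤17 / ≤20 / ≤24 for
0 / 1–6 / >6 years; MoCA normal threshold >13 / >19 / >24 for 0 / 1–6 /
≥7 years. The MoCA rule is specified for 7–12 years; applying it above 12
years triggers a one-time warning. Classification: VaD = MMSE at/below
cutoff with CDR ≥1; MCI = MMSE above cutoff, MoCA at/below cutoff, CDR 0.5,
ADL 8; non-CI = both above cutoff, CDR 0, ADL 8; anything else is
unclassifiable rather than silently assigned. Imaging markers are
transformed log₁₀(x+1); EPVS is coded 0/1.

## 6. Group statistics (`group_stats`)

Thin, tested wrappers over scipy/statsmodels with one addition:
`anova_from_summary` computes one-way ANOVA from group (n, mean, sd) via
SSB = Σnᵢ(mᵢ−m̄)², SSW = Σ(nᵢ−1)sᵢ², which is algebraically identical to
raw-data ANOVA (property-tested to 10⁻¹⁰) and lets published group moments
be re-analyzed without raw data. Chi-square uses no Yates correction (the
reference values reproduce only without it); expected-count adequacy is
reported. Fisher's exact test is restricted to 2×2. The covariate-adjusted
GLM tests the group factor by a nested-model F and reports
Bonferroni-corrected pairwise contrasts (m = k(k−1)/2). Partial correlation
residualizes both variables on the covariates and tests r on n−2−q degrees
of freedom; a variable lying in the covariate span (relative residual sd
≤10⁻¹²) is rejected as degenerate. Normality screening uses Shapiro-Wilk on
group-centered residuals at α = 0.05.

## 7. Mediation (`mediation`)

PROCESS-style model 4 with OLS paths: a from M~X+Z, b and c′ from Y~X+M+Z,
c from Y~X+Z; indirect = a·b, and c = c′ + a·b holds exactly for OLS (tested
to 10⁻¹⁰). Inference is a nonparametric case-resampling bootstrap,
vectorized via batched normal equations (einsum Gram matrices +
`np.linalg.solve`); resamples with a rank-deficient design are redrawn and
counted. Intervals: percentile, or bias-corrected (default) with
z₀ = Φ⁻¹(proportion of resamples below the point estimate) clipped to
[1/(k+1), k/(k+1)] and percentile levels Φ(2z₀+z_α). Default k = 5000;
k < 100 is refused unless forced. Calibration (fixed seeds, part of the
acceptance suite): 95% percentile intervals cover the true indirect effect
in 94.1% of 1000 simulated 137-subject cohorts at k = 1000; ANOVA,
Kruskal-Wallis and partial-correlation type-I error over 10 000 null
replicates is 0.049 / 0.048 / 0.049; mean ALPS bias at SNR 30 over 200
noisy phantom realizations is 0.02%.

## 8. Pipeline (`pipeline`, `cli`)

`run_full_analysis` chains imaging (optional), scoring, demographic and
marker tables, covariate-adjusted cognition contrasts, correlation tables
(pooled CSVD and per-group, Pearson and partial) and mediation into a
`report.json` plus TSVs, each stamped with a 12-hex-digit SHA-256 hash of
the analysis-relevant configuration (paths to outputs excluded). Skipped
analyses (e.g., a degenerate correlate in one group) are recorded in an
explicit `skip_log`, never silently dropped. Reruns on the same inputs are
byte-identical. `validate_inputs` returns an itemized failure list (missing
columns, unresolvable covariates, non-unit gradient vectors, …) and backs
the `validate` CLI command.

## Scope and limitations

The phantom is a geometric idealization: uniform tensors per region, no
partial volume, no eddy/motion effects, no susceptibility distortion — it
isolates the estimator chain, not acquisition artifacts. The cohort
generator reproduces group-level moments and one mediation chain; it does
not model item-level test responses, longitudinal change, or missingness
mechanisms beyond complete-case deletion. Rician noise is the only noise
model. The tensor fit is unweighted log-linear least squares, adequate at
the simulated SNRs but biased at very low SNR where weighted or nonlinear
fits would be preferred.
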