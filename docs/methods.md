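# Methods

This note documents the models and procedures implemented in `tslniche`,
the assumptions behind them, the choices made where the design was open,
and what the synthetic-data generators do and do not emulate.

## Image preprocessing

**Spillover compensation.** The mixing convention is
`observed = S · true`, with the rows of `S` indexed by detection channels —
the same convention as cytometry compensation matrices. Compensation solves
the linear system per voxel and clamps negative unmixed intensities to
zero, because every downstream statistic (masked means, densities) assumes
non-negative intensities. The matrix is user-supplied data (CSV with
channel names on both axes); the package does not estimate it.

**Depth attenuation.** Signal loss along z is modelled as a single global
exponential, `I(z) = I0·exp(−z/λ)` with z the slice depth in µm.
λ is fitted by ordinary least squares on the log of per-slice medians of
the reference channel's nonzero voxels; every channel slice is then divided
by `exp(−z/λ)`. The median (not mean) is used because sparse bright
structures would otherwise dominate the per-slice statistic. A flat or
inverted profile yields λ = ∞ (no-op) or a warning plus no-op respectively;
a single-slice volume is a no-op with λ undefined. The correction is
idempotent up to fit noise: a second application fits an essentially flat
profile. A per-channel fit mode is deliberately not provided — one
reference channel (typically the structurally dense XCR1 channel) is
assumed representative of the optical path.

## Per-cell quantification

**Membrane masks.** Nuclear labels are expanded by a nearest-label rule:
every background voxel within Euclidean distance `radius` of its nearest
nucleus takes that nucleus's label. This is collision-free by construction
(each voxel has exactly one nearest nucleus), unlike independent per-label
dilation, which double-assigns voxels in dense tissue. Exact distance ties
go to the lower label id, for determinism. The membrane/cytoplasmic mask is
the expansion minus the nuclei; with radius 0 it is empty. The radius is
interpreted in voxel units on the native anisotropic grid by default
(`radius=6` means 6 voxels in every axis direction, i.e. a physically
anisotropic shell when the z step exceeds the xy pixel size); a µm-unit
mode (`physical_units=True`) uses the voxel dimensions as the distance
metric instead.

**Feature table.** Per cell and channel, the masked mean is the sum of
masked voxel intensities divided by the mask voxel count; centroids are
mean nuclear voxel indices (0-based, (z, y, x) order) and their world
counterparts are the elementwise product with the voxel dimensions
(origin at the centre of voxel (0, 0, 0)). Cells whose membrane mask is
empty report missing (NaN) membrane means, never 0.

## Histocytometry

Gates are named 2D polygons on feature pairs with a parent hierarchy;
membership is the even-odd point-in-polygon test with boundary and vertex
points counting as inside (the `covers` convention of the geometry
library), intersected with the parent's membership. Boundary-inclusiveness
is a convention choice made for determinism and portability of gate files;
it is observable only for events exactly on a gate edge.

The heatmap matrix standardizes each parameter to a per-cell z-score using
the population SD (ddof = 0), mapping zero-spread columns to all-zero with
a warning, and sorts rows by the given subset order. Population rather than
sample SD is used because the z-score is taken over the entire imaged cell
population, not a sample; a `ddof` switch is exposed. The same population-SD
choice applies to the cDC1-density^high threshold (mean + 1 SD of
max-normalised densities, strict >) and to affinity standardization.

TCF-1 normalisation to naive T cells divides cell means by the mean
intensity of a user-chosen naive-dense reference patch; the high gate is
strict (`> 0.7` by default), so a cell exactly at the threshold is not
flagged.

## Spatial statistics

**cDC1 density.** A unit-sum 2D Gaussian (σ default 3.6 µm, converted to
pixels with the xy voxel size, reflective boundary) is applied to the XCR1
channel independently per z-slice; a cell's density is the mean of the
filtered volume under its nuclear mask. Per-slice (2D) filtering means
signal in a neighbouring slice contributes nothing — a deliberate match to
the anisotropic acquisition geometry (2 µm z steps vs 0.361 µm xy pixels).
Two σ calibrations circulate for this statistic (3.6 µm = 10 px, and
3.27 µm); 3.6 µm is the default and σ is an ordinary argument, so either is
reachable. Reflective boundaries avoid artificial density loss at volume
edges; the mode is configurable.

**NFAT translocation.** The cell's largest cross-section (the z-slice with
the maximal nuclear-mask area; ties to the lowest z) is selected, and the
ratio of nuclear to membrane mean NFAT intensity on that slice classifies
the cell as nuclear (ratio ≥ 1) or membrane (< 1). The boundary at exactly
1.0 is assigned to the nuclear class — the natural fixed point given that
"positive" localization means nuclear accumulation; the threshold is a
parameter. Cells whose whole-cell NFAT mean falls below a low-expression
threshold are excluded as likely false positives; the default threshold is
the 10th percentile of whole-cell means, since no principled absolute
value exists without staining calibration. A zero membrane mean with
nuclear signal yields a +∞ ratio sentinel, class nuclear, flagged.

**Weighted KDE.** Density maps use an exact isotropic 3D Gaussian sum,

`density(g) = Σᵢ wᵢ (2πσ²)^(−3/2) exp(−‖g − pᵢ‖²/2σ²)`,

evaluated on a regular grid (σ default 6 µm, spacing 10 µm) spanning the
point bounding box padded by 4σ, with the grid origin snapped to the
spacing lattice so shifted point sets produce in-phase grids. The kernel is
separable, so the sum is computed from per-axis factors with an einsum;
evaluation is exact, with no tree approximation — at the point counts of
per-volume cell tables (10³–10⁵) the exact sum is cheap and removes an
error knob. Weights are min-max normalised marker expressions in [0, 1]
(constant input maps to all-ones with a warning). The 2D visualisation map
is a plain node sum over a z slab (80 µm default) without division by slab
thickness: the map is a relative-density visual, not a volume-normalised
quantity, so the constant factor is omitted.

## Imputed TCR affinity

The index is tetramer staining over CD3 staining per cell — tetramer
binding normalised to surface TCR level. Because tetramer staining varies
by batch and incubation, log indices are z-standardized within each
experimental cohort against the pooled control-IgG SLAMF6+ T_SL events of
that cohort (population SD); the reference pool itself therefore has mean 0
and SD 1 per cohort. The normalised mean ratio divides each
(mouse, subset, treatment) mean index by the pooled cohort reference mean.
When any index is non-positive, the pooled cohort indices are first
translated by `1 − min(pooled)`, making the minimum exactly 1 and every
log-index non-negative; the translation is rank-preserving. Quantile
binning ranks events by ascending index with ties broken by event id
(a documented, stable rule — real instruments rarely produce exact ties)
and cuts at ⌈i·n/k⌉, giving exactly n/k events per bin when k divides n.

## Hierarchical Bayesian models

Both models share one likelihood and sampler. The response (cellular
z(log affinity), or standardized log counts per mouse × state) is regressed
on cell state, treatment and their interaction (dummy coding; reference
levels SLAMF6+ T_SL and IgG by default) with per-mouse random intercepts
and per-mouse random slopes for each non-reference state. Random-slope
variances are independent per state (diagonal covariance) — slope
correlations are not identifiable at typical mouse counts and are not
asserted. Priors are weakly informative and fully conjugate on the
standardized scales: β ~ N(0, 5²I), σ², τ² ~ Inverse-Gamma(2, 1).

The sampler is blocked Gibbs with (β, u) drawn **jointly** as a single
Gaussian block given the variances, then the variances from their
inverse-gamma conditionals. Joint sampling matters: updating β and u in
separate blocks mixes pathologically slowly because the fixed intercept and
the mean of the mouse intercepts are strongly confounded; the joint block
removes that autocorrelation (observed split-R-hat drops from ≈1.5 to
≈1.00 on the recovery fixture). All cross-products of the combined design
are precomputed once, so each iteration costs one Cholesky factorisation of
a (p + J·(1+S−1)) square matrix. Defaults are 4 chains × 4,000 iterations
with 1,000 burn-in; the test suite and acceptance script run 2 chains ×
450 iterations (150 burn-in), which the diagnostics show is ample for
these problem sizes (bulk ESS in the hundreds). Split-R-hat and bulk ESS
are computed per parameter via ArviZ; R-hat above 1.05 is recorded as a
warning on the result object, never silently dropped.

Population-level prediction draws `ŷ = x'β + N(0, σ²)` per posterior draw
with the mouse effects removed, isolating state and treatment. The expected
high-affinity count per (state, treatment) multiplies the per-draw fraction
of predictive affinity above threshold 0 (the control-reference mean on the
standardized scale) by the per-draw expected total count, obtained by
inverting the stored log-count standardization and exponentiating the
count-model linear predictor; the point estimate is the posterior mean
(not median) of the per-draw product, with intervals from the joint per-draw
products. A lognormal half-variance correction on the back-transform is
deliberately omitted: the quantity reported is the count implied by the
typical (median) mouse, which is the interpretable scale here; adding
σ²/2 would change point estimates by a common factor without affecting any
of the contrasts the analysis reads out.

**Degenerate inputs.** Unobserved (state, treatment) cells make the design
rank deficient and raise an error naming the aliased columns. Zero counts
cannot be log-transformed and raise rather than being silently offset
(+1 offsets change small-count contrasts; if needed, the offset belongs in
the caller's hands). Constant log-counts make standardization undefined and
raise.

## Synthetic data

**Imaging.** The generator emulates a cleared tdLN tile at the target
acquisition geometry (0.361 µm xy, 2 µm z). The cDC1 network is a set of
persistent random-walk filaments rasterised and Gaussian-smoothed, scaled
to [0, 1] and given a constant autofluorescence floor (the floor keeps
per-slice nonzero medians comparable, which is what the attenuation fit
uses; it also makes the DC channel realistic — tissue is never zero).
T cells are non-overlapping axis-aligned ellipsoidal nuclei (radii uniform
in a configured µm range; rejection sampling with bounded retries and an
explicit crowding error) with a membrane shell; nuclei **and shells** are
kept mutually disjoint so that painted marker intensities never leak
between neighbours and noise-free masked means are exact. A configurable
fraction of cells is placed uniformly within a ball of `cluster_radius`
around random skeleton voxels (niche-resident truth), the rest uniformly
(dispersed truth). Nuclear markers are painted as constants inside nuclei
(so noise-free nuclear means equal the configured phenotype means exactly),
membrane markers on the shell, and NFAT1 is routed nucleus-high or
shell-high per a truth flag tied to clustering. Optional depth attenuation
(`exp(−z·Δz/λ)`), spillover mixing and clamped additive Gaussian noise
exercise preprocessing. Geometry defaults (filament count/length, cluster
radius, nuclear radii) are plausible placeholders exposed in the
parameters, not calibrated to any measured niche geometry.

What the generator does **not** emulate: PSF/optics, clearing artefacts,
segmentation errors (the label masks are ground truth), multi-round
registration, and realistic marker covariance structure. Passing tests
therefore demonstrate correctness of the measurement machinery on inputs
with known truth, not robustness to real microscopy noise.

**Cytometry.** Events are drawn exactly from the hierarchical model the
downstream analysis assumes: `log(tetramer/CD3) = μ(subset, treatment) +
u0_mouse + u1_mouse,subset + ε`, with lognormal CD3 staining and the
tetramer derived from it, mouse effects Gaussian (slopes only for
non-reference subsets, matching the model), and multinomial subset
assignment per treatment arm. The monoclonal flag multiplies **both**
tetramer and CD3 by a downregulation factor on blockade arms, so the index
is invariant by construction — the in-silico analogue of the TCR-transgenic
control that separates receptor-level changes from affinity changes.
Default condition sizes (6 mice per arm, 500 events per mouse, residual SD
0.5, mouse SDs 0.15/0.10) are typical of the tdLN tetramer panels this
pipeline targets. Accessory markers (TCF-1, SLAMF6, PD-1, CD8) are
independent lognormals per subset — sufficient for gating plumbing, not a
model of real marker correlations.

## Problem sizes and numerical tolerances

The test suite and `scripts/acceptance.py` use reduced problem sizes chosen
to exercise every code path with meaningful statistical power on one CPU:
interval calibration uses 100 replicates of 20 mice × 200 events with
2 × 450 Gibbs iterations; direction recovery uses 20 end-to-end runs of
12 mice × 150 events; imaging checks use tiles up to 40 × 224 × 224 voxels
and 200 cells. Oracle comparisons are exact where the arithmetic is exact
(masked means accumulate in the same order as the oracle; point-in-polygon
off the boundary), 1e−8 against dense convolution for the per-slice
Gaussian (separable vs direct ordering differences only), 1e−10 for the
closed-form KDE peak, and 1% for the KDE Riemann mass (the lattice-sum
error of a Gaussian at spacing/σ = 10/6 is ≈0.2% per axis).

## Known limitations

- The attenuation model is one global exponential; depth-dependent
  scattering that varies laterally is not captured.
- Gate vertex coordinates are user data; the package ships the gating
  machinery, not calibrated subset gates.
- The KDE map's z-slab sum is a visualisation, not a density with units.
- The Gibbs sampler is specialised to the state × treatment design with
  mouse intercept/slope effects; it is not a general mixed-model engine.
- Expected-count back-transforms report the typical-mouse scale (no
  half-variance correction); see above.
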