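# Methods

## The measurement model

Each voxel's diffusion-weighted signal follows the mono-exponential tensor
model S_i = S0 · exp(−b g_iᵀ D g_i), with D a symmetric positive 3×3 tensor
(mm²/s), b the diffusion weighting (0 or 800 s/mm²) and g_i a unit gradient
direction. Nerve tissue is modelled as axially symmetric: eigenvalues
(AD, RD, RD) with the principal axis along the local nerve tangent; the
defaults AD = 1.85×10⁻³ and RD = 1.12×10⁻³ mm²/s give MD = 1.363×10⁻³ and
FA = 0.2997, typical of healthy cervical roots. Background tissue is
isotropic with MD = 2.0×10⁻³ mm²/s (CSF-weighted neighbourhood average) and
60% of the nerve's S0 — the exact background values only need to provide
contrast; none of the reported statistics depend on them.

Magnitude noise is Rician: M = √((S+n₁)² + n₂²) with n₁, n₂ ~ N(0, σ²) and
σ = S0_nerve / SNR_target per acquisition. The emulated protocol acquires 6
signal averages (magnitude-averaged), matching the scan protocol the phantom
mirrors; the SNR target of 21 refers to a single average, which is also how
the noise-only (RF-off) σ estimate is validated against the Rayleigh mean
identity mean|n| = σ√(π/2).

## Phantom geometry

Nerve centerlines are cubic splines through hand-placed coronal control
points: roots exit the "spine" at descending heights and converge laterally
and inferiorly toward an Erb's-point-like confluence, both sides, ≥ 40 mm
each. Only tangent smoothness and length matter — per-0.45 mm tangent
rotation stays well under 14° at the `low` curvature level, and the `high`
level splices a 1.2 mm-radius detour into C7 (≈ 21° per 0.45 mm) to exercise
angular stopping. The default grid is 64×48×32 voxels at 3 mm isotropic
(smaller than a clinical matrix, chosen to keep simulations fast; the grid is
configurable and the geometry scales with it).

Voxelisation is binary: a voxel is nerve iff its center lies within the tube
radius of a centerline; no sub-voxel mixing is simulated. The tube radius
defaults to 6 mm. This is wider than a real root (~2–3 mm radius) and is a
deliberate trade: with 3 mm voxels, a narrower tube leaves no "interior"
voxels whose trilinear neighbourhood is purely nerve, so even a noiseless
pipeline would carry several percent of partial-volume bias and no criterion
could separate algorithmic error from geometric contamination. With radius
6 mm and mid-nerve seeding the noiseless pipeline reproduces the tissue
parameters to < 0.5% (interpolation error only), so any larger error seen
under noise is attributable to noise.

The 15 gradient directions are a fixed, antipodally symmetric
electrostatic-repulsion set (minimum pairwise angle ≈ 37°), shipped as a
constant; any well-spread 15-direction scheme is equivalent for these
purposes.

## Estimation chain

* **Rician correction**: the moment-based map M → √(max(M²−2σ², 0)), applied
  with the known (or Rayleigh-estimated) σ divided by √NSA. It is optional
  (`rician_correction` flag); more elaborate filters are out of scope.
* **Registration**: `identity` mode is a strict pass-through (phantoms are
  motion-free). `rigid` mode estimates one rotation+translation per weighted
  volume by Powell search over a normalized-cross-correlation cost (NCC is
  contrast-insensitive, needed when matching b=800 to b=0), evaluated on an
  interior region after light Gaussian smoothing so boundary fill-in cannot
  anchor the optimum at the identity. Each recovered rotation is conjugated
  into the stored b-matrix (g → Rᵀg, equivalently B → R B Rᵀ), and the test
  suite verifies on a physically consistent synthetic rotation (tensors
  rotated with the anatomy) that omitting this step leaves a ~5° axis error.
* **WLLS**: per voxel, ln S_i = ln S0 − Σ B_ijk D_jk is solved twice — OLS on
  log-signals, then weighted least squares with w_i = Ŝ_i² from the first
  pass. Non-positive signals are clamped to 10⁻⁶ × the voxel's maximum signal
  and the voxel flagged. The design matrix is built from the (possibly
  rotated) per-volume b-matrices, so registration corrections propagate.
* **Scalar maps**: eigenvalues sorted descending; FA by the normalized
  deviatoric norm. Negative eigenvalues are retained (not clipped) but
  counted in QC, matching common DTI practice.

## Tractography

Deterministic fixed-step Euler integration, bidirectional from each seed,
step 0.15 × mean voxel edge (0.45 mm at 3 mm voxels). The principal
eigenvector is trilinearly interpolated with per-corner sign alignment to the
previous direction (the field is axial, not vector-valued); FA for the
stopping test is interpolated the same way. Halting: FA outside [0.1, 0.8],
per-step turning > 14°, grid exit, or the step cap. Fibers shorter than
30 mm are discarded. Seeds are placed on a jittered stratified grid within
the ROI plane so that the count equals round(area × density) exactly and is
reproducible under the seed.

Two discretization consequences are documented rather than hidden: (i) the
tracked polyline loses up to one partial step at each free end, so a tube of
extent L is recovered to within 2 × 0.45 mm, not one step overall; terminal
segments are not clipped to the boundary because streamlines guarantee
constant inter-point spacing. (ii) with trilinear interpolation at 3 mm
voxels, per-step turning exceeds 14° only where adjacent-voxel directions
differ by ≈ 90°; continuous curvature sharp enough to trigger the rule is
inherently sub-voxel, so the angular-stopping tests use a two-region field
with an 88° bend.

In the phantom pipeline, seed ROIs are the labelled sagittal-plane voxels at
18% of each root's arc (just distal to the "ganglion"), restricted to voxels
within 0.35 × radius of the centerline — the mid-nerve placement an operator
makes on MD maps, which keeps seeds out of edge voxels.

## Along-tract analysis

Fibers are consistently oriented (sign of the endpoint displacement against
the bundle's dominant axis), resampled to K = 100 equidistant points, and
averaged point-wise into the mean path. Outlier fibers (mean distance to the
mean path > 5 mm ≈ 1.7 voxels, configurable) are dropped once and the mean
path recomputed. Fibers are cut to the retained segment — arc-length
fractions (default 8%–92%) on phantoms, where the excluded ends stand in for
the ganglion and the region past Erb's point; user-supplied planes enter
through the same interface. The mean-path arc is divided into n equal
sections (C5/C6: 8, C7: 6, C8: 4); each fiber point joins the section of its
nearest-arc-length projection; a section's value is the mean of the scalar
maps interpolated at its fiber points; and the per-nerve mean weights the
sections equally regardless of point count, so the dense region near the
seed cannot dominate.

## Statistics

For paired series (session 1 vs 2, rater 1 vs 2) with differences d:
Bland–Altman mean(d) ± 1.96·SD(d) (sample SD); CV = 100·SD(d)/mean with the
denominator defaulting to the grand mean over both members (configurable to
the mean of pair means — identical for complete pairs); MDD = 1.96·SD(d), so
MDD ≡ 1.96·(CV/100)·mean exactly. ICC(A,1) uses the two-way ANOVA mean
squares (MSR − MSE)/(MSR + (k−1)MSE + k(MSC − MSE)/n) with the conventional
poor/fair/good/excellent bands at 0.40/0.60/0.75.

The repeated-measures ANOVA is the univariate contrast-score formulation:
for each within-subject effect (side: 1 contrast; root: 3; interaction: 3),
orthonormal contrast scores Z are regressed on the between-subject design
(intercept + mean-centered entered covariates); F = (tr H/df₁)/(tr E/df₂)
with df₂ = q_eff·(n − q). Mauchly's W and the Greenhouse–Geisser ε come from
the contrast-score covariance; the GG-corrected P is used when Mauchly
rejects at 0.05. This univariate-ε framework (rather than REML mixed models)
is the natural reading of a Mauchly/GG analysis; the implementation matches
pingouin's F, P and ε to 8 digits in the cross-check tests and its side-test
type-I error calibrates to 0.046 over 500 null simulations.

Stepwise forward covariate entry tests each candidate on the between-subject
component (OLS of subject-cell means on intercept + entered + candidate);
the smallest-P candidate below 0.05 enters, repeating until none qualifies.
Collinear candidates surface with P = NaN rather than being dropped
silently. Sex is coded 0/1; body surface area is an input column, computed
by the Du Bois formula when generated.

## Cohort generator calibration

Per subject, weight ~ U(47, 103) kg; AD and RD are linear in weight (slopes
−4.40×10⁻⁶ and −3.03×10⁻⁶ mm²/s per kg, intercepts 2.17×10⁻³ and
1.34×10⁻³), which implies the MD relation (slope −3.49×10⁻⁶, intercept
1.617×10⁻³) through MD = (AD+2RD)/3. Between-subject residuals for (AD, RD)
are bivariate normal with SDs (9.94, 10.47)×10⁻⁵ mm²/s and correlation 0.49
— the unique calibration for which the session-averaged weight regressions
land at R² ≈ 0.26 (MD), 0.31 (AD) and 0.17 (RD) simultaneously; independent
residuals cannot satisfy all three because MD is a linear combination of AD
and RD. Within-subject (session/rater) noise SDs are set from the observed
repeatability the generator emulates (CVs ≈ 16/12/11/14% for FA/MD/AD/RD).
The summary-level generator (`simulate_cohort_table`) draws nerve means
directly from this model for statistics validation at scale; the full-image
generator (`make_cohort`) runs the same model through DWI synthesis.

What passing tests on this generator do **not** show: robustness to
distortion, fat contamination, motion, partial volume at realistic nerve
calibres, or rater-dependent ROI placement — the phantom has none of these.

## Known limitations

* A stepwise bodyweight-vs-BMI selection experiment at R² ≈ 0.26 and n = 30
  is power-limited: the probability that the weight slope is significant at
  α = 0.05 is ≈ 0.86, and with cor(weight, BMI) ≈ 0.9 the chance that weight
  also beats BMI brings clean selection to ≈ 0.65–0.72. Single-cohort
  selection outcomes at this effect size are fragile by nature.
* Registration is rigid, single-resolution and NCC-based; eddy-current
  affine terms and susceptibility unwarping are out of scope.
* Sections are assigned by nearest-arc-length projection; strongly fanning
  bundles may project non-uniquely.
* Problem sizes in tests and the acceptance script (64×48×32 grid, 5 noise
  realisations, 200 cohorts, 500 null simulations) were chosen to make the
  whole suite run in minutes on one core while keeping Monte-Carlo standard
  errors well inside the asserted tolerances.
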