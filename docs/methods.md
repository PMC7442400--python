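# Methods

## Texture model

The package summarises the micro-pattern of a segmented volume of interest
(VOI) by gray-level co-occurrence statistics. All computation happens on
the acquired voxel lattice: no resampling, reorientation or world-space
geometry is involved, and the physical voxel spacing (recorded on the
volume) deliberately plays no role in the texture itself — displacements
are integer lattice steps, as in standard lattice-offset GLCM practice,
even though sagittal spine acquisitions are strongly anisotropic
(≈0.8 × 0.8 × 3 mm).

**Quantization.** In-mask intensities are binned to Ng equal-width levels
over the in-mask range: `level = min(Ng, floor((v − vmin)·Ng/(vmax −
vmin)) + 1)`. This is range-relative, so the features are exactly
invariant to adding a constant to all intensities (and to any positive
affine rescaling). A VOI whose in-mask range is below 1e-12 (relative) is
treated as constant and maps entirely to level 1. Ng defaults to 32, a
common radiomics compromise between co-occurrence-matrix sparsity and
discriminability; it is configurable.

**Co-occurrence.** For each of the 13 canonical directions — the
26-neighbourhood of a voxel with each direction and its negation
identified — and each distance d ∈ {1..5}, ordered in-mask voxel pairs
(v, v + direction·d) are counted into an Ng×Ng matrix; by default the
transpose is added (symmetric counting, which is what the
antipodally-deduplicated direction set implies) and the matrix is
normalized to probabilities. Displacements for which no valid pair exists
are skipped with a logged warning rather than failing the VOI; only if
*every* matrix is empty is the VOI rejected as degenerate.

**Attributes.** Twenty-two scalar attributes are computed per matrix
(autocorrelation, the three cluster moments, contrast, correlation,
difference entropy, dissimilarity, energy, entropy, two homogeneities, two
information measures of correlation, IDMN, IDN, inverse variance, maximum
probability, sum average/entropy/variance, variance). Entropy terms use
log base 2 by default (natural log selectable); 0·log 0 ≡ 0 everywhere.
Degenerate-value policy: correlation and IMC1 fall back to 0 when their
denominators vanish, the IMC2 radicand is clamped at 0, and inverse
variance sums off-diagonal cells only — so a constant-texture VOI yields a
finite, testable feature vector (energy 1, entropy 0, contrast 0).
Sum variance is taken as the second moment of the cross-sum distribution
about the sum average; the literature also contains a variant centred on
sum entropy, which is not implemented. The "variance" attribute centres on
the mean of the in-matrix level mass, which equals the marginal mean for
symmetric matrices.

**Aggregation.** The 65 per-matrix attribute values are reduced to one
value per attribute by an unweighted mean over all non-empty matrices
(default), with mean-over-directions-then-distances selectable. With the
default configuration the aggregate is exactly invariant under 90°
rotations of volume+mask about any axis, because the direction multiset
(after antipodal identification) is closed under these rotations.

## Statistical models

**Association.** `TextureAssociation` fits, per attribute, model 1
(BMD ~ attribute, ordinary least squares; slope, two-sided p from the t
distribution with n−2 df, Pearson r) and model 2 (BMD ~ attribute + age +
BMI; adjusted slope and its p-value, n−4 df). Covariates with zero
variance are dropped before fitting — they are absorbed by the intercept,
and the fit then coincides with model 1 — while any remaining rank
deficiency (e.g. the attribute duplicating a covariate) is a hard
collinearity error. No multiple-testing correction is applied by default:
the report flags raw p < α over the 22 attributes, which mirrors how such
exploratory radiomics associations are conventionally reported; a
Benjamini–Hochberg column is available behind an explicit switch.

**Concordance.** `lin_ccc` uses the original 1/n (biased) moment
estimator ρ_c = 2s_xy/(s_x² + s_y² + (x̄−ȳ)²). The confidence interval
applies the inverse-hyperbolic-tangent transform with the asymptotic
variance of the transformed estimator, written in terms of c = ρ_c/r so
it remains finite as r → 0, and back-transforms the bounds; |ρ_c| = 1
(within 1e-12) yields a degenerate interval at the point estimate.
Constant input sequences make the coefficient (and its CI) undefined and
raise an error naming the offending attribute. Strength labels use the
conventional agreement ranges with boundaries belonging to the upper
label (0.20 → fair, 0.80 → almost perfect); negative coefficients are
labelled poor.

**Group comparison.** `compare_groups` is one-way ANOVA; with two groups
it equals the pooled-variance two-sided t-test (F = t²). All-identical
data return p = 1; zero within-group variance with distinct means returns
p = 0.

## Synthetic data

The phantom generator emulates what the pipeline needs from a vertebral
MRI — a spatially correlated, trabecular-like texture inside a segmented
VOI — and nothing more. It is not a biophysical bone model and does not
simulate MRI physics (no bias field, no Rician noise, no partial-volume
effects); conclusions from passing tests are about the pipeline's
correctness and statistical behaviour, not about real-bone effect sizes.

**Field.** White Gaussian noise is smoothed with an isotropic Gaussian
kernel of scale ℓ (the coarseness knob) applied in the Fourier domain,
z-scored, and independent voxel noise of standard deviation `noise_sd`
(default 0.1) is added. The Fourier-domain kernel makes the large-ℓ limit
degenerate cleanly: once every non-constant mode underflows, the field is
exactly constant (a sub-1e-12 standard deviation is treated as zero), so
the constant-texture limit (energy → 1) is reachable exactly. The field
is then mapped through the Gaussian CDF of its theoretical scale and
linearly placed in [100, 1000]. The CDF mapping, rather than min–max
rescaling, is deliberate: with min–max the quantized marginal histogram
depends on the number of effective samples in the grid, which rises as ℓ
shrinks, and this confound empirically destroys the monotone relation
between coarseness and aggregate entropy. With the CDF mapping the
marginal is stable across ℓ and the texture ladder behaves as intended:
entropy decreases and energy increases monotonically in ℓ.

**Geometry.** Grids default to 32×32×16 voxels at 0.8×0.8×3.0 mm,
emulating a sagittal fast-spin-echo acquisition; the VOI is the ellipsoid
inscribed in the grid minus a margin (default 2 voxels, ≈4200 voxels), and
specs whose mask would fall below 100 voxels are rejected.

**Second rater.** `perturb_mask` emulates a second manual segmentation by
patchwise boundary perturbation: a smoothed unit-variance random field
partitions the grid, the mask is dilated (up to `jitter` voxels) where the
field exceeds +0.7, eroded where it falls below −0.7, and left untouched
elsewhere. The ±0.7 threshold leaves roughly half of the boundary
unmodified, keeping jitter-1 Dice overlap above 0.85 even for ~1000-voxel
masks — a realistic degree of inter-rater disagreement for a
well-delineated vertebral body.

**Cohort.** Per subject, ℓ is drawn uniformly from `ell_range` (default
1–3 voxels), and true BMD is `bmd_mean + coupling · z(ℓ) + N(0, bmd_sd)`
with defaults 1.0 ± 0.13 g/cm² and coupling 0.05 g/cm² per SD of
coarseness — numbers chosen so that a 49-subject cohort lands in the
r ≈ |0.2–0.4| correlation regime typical of this kind of study. z(ℓ) uses
the *theoretical* uniform moments of `ell_range`, so a subject's true BMD
is independent of cohort size. Age (20–68), BMI (18–25) and sex (59%
female) are drawn to match a healthy eutrophic adult cohort. BMD is
coupled to the coarseness parameter rather than to any specific attribute,
so end-to-end recovery tests cannot tautologically encode an attribute
formula: the texture side of the recovery regression uses the
sign-oriented standardized entropy as a coarseness proxy (entropy
decreases monotonically in ℓ), which attenuates the recovered slope by the
proxy's imperfect correlation with ℓ (measured ≈0.90 at the default
noise) — well inside the 3-standard-error recovery band at n = 200.

**Randomness.** Everything descends from one integer seed through
`numpy.random.SeedSequence` spawning: cohort-level draws and each
subject's phantom and mask-perturbation seeds are independent streams, so
outputs are bit-reproducible and insensitive to evaluation order.

## Problem sizes and numerical choices

Default problem sizes used by the test suite and the acceptance script —
32×32×16 phantoms (≈4200-voxel VOIs), cohorts of 49 (the study scale) for
reproducibility and 200 for parameter recovery, 1000 replicates for the
type-I calibration, and a brute-force oracle sweep over ≤5×5×5 grids with
Ng ≤ 4 — were chosen as the smallest scales at which each property is
meaningfully exercised; each extraction runs in ~50 ms, so the whole suite
stays interactive. Reports fix float formatting at 12 significant digits,
making reruns byte-identical while round-tripping far below 1e-9.

## Known limitations

* Texture ignores voxel anisotropy; attributes from strongly anisotropic
  acquisitions mix in-plane and through-plane correlation scales.
* The aggregation of 65 matrices to one feature vector is a convention
  (unweighted mean), not a derived quantity; both it and Ng, symmetry and
  log base materially affect absolute attribute values, so comparisons
  across configurations are not meaningful.
* Lin's CI is asymptotic; at very small n (≲10) its coverage is
  approximate.
* The phantom's single coarseness knob cannot represent directional
  trabecular anisotropy, marrow heterogeneity, or acquisition artifacts.
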