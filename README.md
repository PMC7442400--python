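# bonetexture

Quantitative texture analysis of trabecular bone from routine MRI.

Bone mineral density (BMD) from dual-energy X-ray absorptiometry is the
clinical standard for osteoporosis assessment, but it misses much of what
makes bone fragile — in particular the trabecular microarchitecture.
`bonetexture` implements the radiomics pipeline used to probe that
microarchitecture from ordinary sagittal T2-weighted spine MRI: 3-D
gray-level co-occurrence matrix (GLCM) texture attributes are extracted
from a segmented vertebral-body volume of interest (VOI), associated with
BMD by simple and age/BMI-adjusted linear regression, and checked for
interobserver reproducibility with Lin's concordance correlation
coefficient (CCC). It is aimed at musculoskeletal-imaging researchers who
want a tested, scriptable version of this analysis, including a synthetic
phantom cohort so every stage can be exercised without patient data.

## The method

**Texture.** The VOI intensities are quantized to Ng equal-width gray
levels over the in-mask range (default Ng = 32). For a displacement vector
**d** = direction × distance, the co-occurrence matrix holds the joint
probabilities

&nbsp;&nbsp;&nbsp;&nbsp;p(i, j) = Pr[ I(**x**) = i and I(**x** + **d**) = j ], both voxels inside the VOI,

counted symmetrically. With the 13 canonical lattice orientations (the
26-neighbourhood with opposite directions identified) and distances 1–5
voxels this yields 65 matrices per VOI. From each matrix 22 classical
attributes are computed — energy Σp², entropy −Σp log₂ p, contrast
Σ(i−j)²p, homogeneity, cluster moments, information measures of
correlation, sum/difference statistics, and so on — and averaged over the
65 matrices into one feature vector.

**Association.** For each attribute *t*, model 1 fits BMD = β₀ + β₁t by
ordinary least squares (slope, two-sided t-test p-value, Pearson r);
model 2 adds age and BMI as covariates and reports the adjusted attribute
slope.

**Agreement.** For two raters' feature columns x, y, Lin's CCC

&nbsp;&nbsp;&nbsp;&nbsp;ρ_c = 2·s_xy / (s_x² + s_y² + (x̄ − ȳ)²)

(1/n moments) measures agreement; a 95% CI comes from the Fisher-z
transform with the asymptotic variance, and values are labelled poor /
fair / moderate / substantial / almost perfect at the conventional
0.20/0.40/0.60/0.80 boundaries.

**Phantoms.** Synthetic vertebral phantoms are stationary Gaussian random
fields with a tunable correlation length ℓ ("coarseness"), an ellipsoidal
VOI, and an optional second-rater mask produced by patchwise boundary
erosion/dilation. Simulated cohorts couple true BMD to ℓ with a known
slope, so recovery of the coupling through the texture pipeline can be
tested end to end.

## Worked example

```python
from bonetexture import PhantomSpec, generate_phantom, extract, perturb_mask

vol, mask, ell = generate_phantom(PhantomSpec(correlation_length=2.0, seed=7))
fv = extract(vol, mask)                 # 65 matrices -> 22 attributes
print(fv.n_matrices, fv["entropy"], fv["energy"])
```

prints `65 9.498951... 0.001685...`: a medium-coarseness phantom VOI of
4160 voxels has aggregate entropy 9.50 bits and energy 0.0017. A rougher
phantom (ℓ = 1, same seed) gives entropy 9.76 — finer texture means a more
dispersed co-occurrence distribution. Re-extracting with a jitter-1
perturbed mask (a simulated second rater) shifts entropy only to 9.4761,
the kind of stability the concordance analysis quantifies.

The same analysis from the shell, on a full simulated cohort:

```sh
bonetexture simulate --n 49 --seed 1 --out demo
bonetexture extract --manifest demo/manifest.csv --out demo/features_a.csv
bonetexture extract --manifest demo/manifest.csv --rater b --out demo/features_b.csv
bonetexture associate --features demo/features_a.csv --cohort demo/cohort.csv --out demo/association.csv
bonetexture concordance --a demo/features_a.csv --b demo/features_b.csv --out demo/concordance.csv
```

With seed 1 this reports `7 significant at alpha=0.05` among the 22
attributes — e.g. entropy with slope −0.103 g/cm² per bit, p = 0.042,
r = −0.29 — and interobserver agreement `almost perfect` for all 22
attributes (smallest CCC 0.973). Because the simulated coupling runs
through the coarseness parameter, smoother (coarser) texture goes with
higher BMD, so entropy correlates negatively with BMD in this cohort.

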