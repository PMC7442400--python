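"""Synthetic vertebral phantoms, rater-perturbed masks and cohorts.

The generator emulates the measurement situation of the study — a
trabecular-like textured vertebral body segmented on sagittal MRI, with a
DXA-scale BMD covariate — without any biophysical bone model.  Texture is a
stationary Gaussian random field: white noise smoothed with an isotropic
Gaussian kernel of scale ``correlation_length`` (the coarseness knob ℓ),
plus independent voxel noise, rescaled to a fixed positive intensity range.
BMD is coupled to ℓ, not to any specific texture attribute, so downstream
recovery tests do not tautologically encode a feature formula.

All randomness descends from a single integer seed through
``numpy.random.SeedSequence`` spawning, so every output is reproducible.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterator

import numpy as np
import pandas as pd
import scipy.ndimage
import scipy.special

from .errors import DegenerateVoiError, PhantomSpecError
from .io import ImageVolume, VoiMask, write_mask, write_volume

__all__ = [
    "PhantomSpec",
    "CohortSimSpec",
    "generate_phantom",
    "perturb_mask",
    "simulate_subjects",
    "generate_cohort",
]


@dataclass(frozen=True)
class PhantomSpec:
    """Specification of one synthetic vertebral phantom.

    Defaults emulate a sagittal fast-spin-echo acquisition: 0.8 mm
    in-plane, 3.0 mm slices, on a grid just large enough to hold a
    vertebral-body-like ellipsoidal VOI.
    """

    shape: tuple[int, int, int] = (32, 32, 16)
    spacing: tuple[float, float, float] = (0.8, 0.8, 3.0)
    correlation_length: float = 2.0  # voxels; trabecular coarseness knob
    noise_sd: float = 0.1  # relative to the unit-variance smoothed field
    voi_margin: int = 2  # voxels of border excluded from the mask
    seed: int = 0

    def __post_init__(self) -> None:
        if self.correlation_length <= 0:
            raise PhantomSpecError("correlation_length must be > 0")
        if self.noise_sd < 0:
            raise PhantomSpecError("noise_sd must be >= 0")
        if len(self.shape) != 3 or any(int(n) < 1 for n in self.shape):
            raise PhantomSpecError(f"invalid shape {self.shape}")
        if self.voi_margin < 0:
            raise PhantomSpecError("voi_margin must be >= 0")


@dataclass(frozen=True)
class CohortSimSpec:
    """Specification of a simulated cohort with a known texture–BMD coupling.

    Per subject, the coarseness ℓ is drawn uniformly from ``ell_range`` and
    the true BMD is ``bmd_mean + coupling * z(ℓ) + N(0, bmd_sd)``, where
    z standardizes ℓ with the theoretical moments of its uniform sampling
    range (so a subject's BMD does not depend on cohort size).  Defaults
    mirror the study cohort scale: 49 subjects, BMD about 1.0 ± 0.13 g/cm²,
    ages 20–68, BMI 18–25, about 59% female.
    """

    n: int = 49
    coupling: float = 0.05  # g/cm² per SD of coarseness
    bmd_mean: float = 1.0
    bmd_sd: float = 0.13
    ell_range: tuple[float, float] = (1.0, 3.0)
    age_range: tuple[float, float] = (20.0, 68.0)
    bmi_range: tuple[float, float] = (18.0, 25.0)
    female_fraction: float = 29.0 / 49.0
    rater_jitter: int = 1
    phantom: PhantomSpec = field(default_factory=PhantomSpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 3:
            raise PhantomSpecError("cohort size must be >= 3")
        if self.bmd_sd <= 0:
            raise PhantomSpecError("bmd_sd must be > 0")
        if not (0 < self.ell_range[0] < self.ell_range[1]):
            raise PhantomSpecError(f"invalid ell_range {self.ell_range}")


def _gaussian_random_field(shape, sigma, rng) -> np.ndarray:
    """Unit-variance periodic Gaussian random field with smoothing scale sigma.

    Smoothing is applied in the Fourier domain, so the large-sigma limit
    degenerates cleanly: once every non-constant mode underflows, the field
    is exactly constant and is returned as zeros rather than amplifying
    numerical dust through the variance normalization.
    """
    white = rng.standard_normal(shape)
    spectrum = scipy.ndimage.fourier_gaussian(np.fft.rfftn(white), sigma=sigma)
    smooth = np.fft.irfftn(spectrum, s=shape, axes=tuple(range(len(shape))))
    sd = smooth.std()
    if sd < 1e-12:
        return np.zeros(shape)
    return (smooth - smooth.mean()) / sd


def _ellipsoid_mask(shape, margin) -> np.ndarray:
    center = [(n - 1) / 2.0 for n in shape]
    semi = [max((n - 1) / 2.0 - margin, 0.5) for n in shape]
    grids = np.ogrid[tuple(slice(0, n) for n in shape)]
    dist2 = sum(((g - c) / a) ** 2 for g, c, a in zip(grids, center, semi))
    return dist2 <= 1.0


def generate_phantom(spec: PhantomSpec) -> tuple[ImageVolume, VoiMask, float]:
    """Generate one phantom volume, its ellipsoidal VOI mask and coarseness.

    Returns ``(volume, mask, coarseness)`` where coarseness is the
    correlation length actually used (the cohort-level covariate).
    Intensities are rescaled to a fixed positive range; texture features are
    range-relative, so the absolute scale is cosmetic.
    """
    rng = np.random.default_rng(spec.seed)
    base = _gaussian_random_field(spec.shape, spec.correlation_length, rng)
    field_ = base + spec.noise_sd * rng.standard_normal(spec.shape)
    if np.ptp(field_) < 1e-12:
        data = np.full(spec.shape, 500.0)
    else:
        # Map through the Gaussian CDF of the field's theoretical scale: a
        # monotone rescaling to a fixed positive range whose quantized
        # marginal stays stable across coarseness values.  (Plain min-max
        # rescaling makes the marginal histogram — and hence entropy —
        # depend on the number of effective samples, confounding the
        # coarseness ladder.)
        uniform = scipy.special.ndtr(field_ / np.sqrt(1.0 + spec.noise_sd**2))
        data = 100.0 + 900.0 * uniform
    mask = _ellipsoid_mask(spec.shape, spec.voi_margin)
    if mask.sum() < 100:
        raise PhantomSpecError(
            f"VOI has only {int(mask.sum())} voxels (< 100); "
            f"enlarge shape or reduce voi_margin"
        )
    return (
        ImageVolume(data=data, spacing=spec.spacing),
        VoiMask(data=mask),
        float(spec.correlation_length),
    )


def perturb_mask(mask: VoiMask, jitter: int, seed: int = 0) -> VoiMask:
    """Simulate a second rater by patchwise boundary erosion/dilation.

    A smooth random field partitions the grid into patches: where the field
    exceeds +0.7 the mask is dilated by up to ``jitter`` voxels, where it
    falls below −0.7 it is eroded, and elsewhere the boundary is left
    untouched — emulating locally over- and under-inclusive manual
    segmentation.  ``jitter = 0`` returns the mask unchanged.
    """
    if jitter < 0:
        raise ValueError("jitter must be >= 0")
    if jitter == 0:
        return VoiMask(mask.data.copy())
    rng = np.random.default_rng(seed)
    field_ = scipy.ndimage.gaussian_filter(rng.standard_normal(mask.shape), sigma=3.0)
    sd = field_.std()
    if sd > 0:
        field_ = field_ / sd
    grown = scipy.ndimage.binary_dilation(mask.data, iterations=jitter)
    shrunk = scipy.ndimage.binary_erosion(mask.data, iterations=jitter)
    out = mask.data.copy()
    out[field_ > 0.7] = grown[field_ > 0.7]
    out[field_ < -0.7] = shrunk[field_ < -0.7]
    if not out.any():
        raise DegenerateVoiError("mask perturbation emptied the VOI")
    return VoiMask(data=out)


@dataclass(frozen=True)
class SimulatedSubject:
    """One simulated subject: covariates plus in-memory images."""

    id: str
    age: float
    sex: str
    bmi: float
    bmd: float
    ell_true: float
    volume: ImageVolume
    mask_a: VoiMask
    mask_b: VoiMask


def simulate_subjects(spec: CohortSimSpec) -> Iterator[SimulatedSubject]:
    """Yield the subjects of a simulated cohort, fully in memory.

    Deterministic for a given ``spec.seed``: cohort-level draws and every
    per-subject phantom descend from one spawned seed sequence.
    """
    root = np.random.SeedSequence(spec.seed)
    cohort_ss, *subject_ss = root.spawn(spec.n + 1)
    rng = np.random.default_rng(cohort_ss)
    lo, hi = spec.ell_range
    ell_mean = (lo + hi) / 2.0
    ell_sd = (hi - lo) / np.sqrt(12.0)
    width = len(str(spec.n))
    for k in range(spec.n):
        ell = float(rng.uniform(lo, hi))
        age = float(np.round(rng.uniform(*spec.age_range), 1))
        sex = "F" if rng.random() < spec.female_fraction else "M"
        bmi = float(np.round(rng.uniform(*spec.bmi_range), 1))
        z = (ell - ell_mean) / ell_sd
        bmd = spec.bmd_mean + spec.coupling * z + rng.normal(0.0, spec.bmd_sd)
        bmd = float(max(bmd, 0.05))  # BMD is physically positive
        sub_rng = np.random.default_rng(subject_ss[k])
        phantom_seed = int(sub_rng.integers(2**31 - 1))
        jitter_seed = int(sub_rng.integers(2**31 - 1))
        pspec = replace(spec.phantom, correlation_length=ell, seed=phantom_seed)
        volume, mask_a, _ = generate_phantom(pspec)
        mask_b = perturb_mask(mask_a, spec.rater_jitter, seed=jitter_seed)
        yield SimulatedSubject(
            id=f"sub{k + 1:0{width}d}",
            age=age,
            sex=sex,
            bmi=bmi,
            bmd=bmd,
            ell_true=ell,
            volume=volume,
            mask_a=mask_a,
            mask_b=mask_b,
        )


def generate_cohort(spec: CohortSimSpec, outdir: str | os.PathLike) -> pd.DataFrame:
    """Write a simulated cohort directory and return its manifest.

    Layout: ``volumes/<id>.nii.gz``, ``masks_a/<id>.nii.gz``,
    ``masks_b/<id>.nii.gz``, ``cohort.csv`` (id, age, sex, bmi, bmd,
    ell_true) and ``manifest.csv`` (id plus relative file paths).
    """
    out = Path(outdir)
    for sub in ("volumes", "masks_a", "masks_b"):
        (out / sub).mkdir(parents=True, exist_ok=True)
    records, manifest = [], []
    for subject in simulate_subjects(spec):
        vol_path = Path("volumes") / f"{subject.id}.nii.gz"
        a_path = Path("masks_a") / f"{subject.id}.nii.gz"
        b_path = Path("masks_b") / f"{subject.id}.nii.gz"
        write_volume(subject.volume, out / vol_path)
        write_mask(subject.mask_a, out / a_path, spacing=subject.volume.spacing)
        write_mask(subject.mask_b, out / b_path, spacing=subject.volume.spacing)
        records.append(
            {
                "id": subject.id,
                "age": subject.age,
                "sex": subject.sex,
                "bmi": subject.bmi,
                "bmd": subject.bmd,
                "ell_true": subject.ell_true,
            }
        )
        manifest.append(
            {
                "id": subject.id,
                "volume": str(vol_path),
                "mask_a": str(a_path),
                "mask_b": str(b_path),
            }
        )
    cohort = pd.DataFrame.from_records(records)
    cohort.to_csv(out / "cohort.csv", index=False, float_format="%.12g", lineterminator="\n")
    manifest_frame = pd.DataFrame.from_records(manifest)
    manifest_frame.to_csv(out / "manifest.csv", index=False, lineterminator="\n")
    return manifest_frame
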