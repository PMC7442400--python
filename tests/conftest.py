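"""Shared fixtures and the independent brute-force co-occurrence oracle."""

import numpy as np
import pandas as pd
import pytest

from bonetexture.io import ImageVolume, VoiMask


def brute_force_glcm(levels, mask, offset, n_levels, symmetric=True):
    """Independent oracle: enumerate every voxel pair with triple loops.

    Returns (p, n_pairs) exactly as the production path defines them, or
    (None, 0) when no in-mask pair exists for the displacement.
    """
    counts = np.zeros((n_levels, n_levels))
    nx, ny, nz = levels.shape
    n_pairs = 0
    for x in range(nx):
        for y in range(ny):
            for z in range(nz):
                if not mask[x, y, z]:
                    continue
                x2, y2, z2 = x + offset[0], y + offset[1], z + offset[2]
                if 0 <= x2 < nx and 0 <= y2 < ny and 0 <= z2 < nz and mask[x2, y2, z2]:
                    counts[levels[x, y, z] - 1, levels[x2, y2, z2] - 1] += 1
                    n_pairs += 1
    if n_pairs == 0:
        return None, 0
    if symmetric:
        counts = counts + counts.T
    return counts / counts.sum(), n_pairs


def random_voi(shape, n_levels, seed, mask_density=0.8):
    """A random quantized test volume with a random (nonempty) mask."""
    rng = np.random.default_rng(seed)
    levels = rng.integers(1, n_levels + 1, size=shape).astype(np.int32)
    mask = rng.random(shape) < mask_density
    if mask.sum() < 2:
        mask[:] = True
    levels = np.where(mask, levels, 0)
    return levels, mask


def make_volume(data, spacing=(1.0, 1.0, 1.0)):
    return ImageVolume(data=np.asarray(data, dtype=float), spacing=spacing)


def full_mask(shape):
    return VoiMask(data=np.ones(shape, dtype=bool))


@pytest.fixture(scope="session")
def small_cohort_dir(tmp_path_factory):
    """A tiny simulated cohort on disk, shared by the pipeline tests."""
    from bonetexture.synthetic import CohortSimSpec, generate_cohort

    out = tmp_path_factory.mktemp("cohort")
    generate_cohort(CohortSimSpec(n=6, seed=42), out)
    return out


@pytest.fixture()
def cohort_frame():
    """A well-formed covariate table of 49 subjects built in memory."""
    rng = np.random.default_rng(0)
    n = 49
    return pd.DataFrame(
        {
            "id": [f"s{i:02d}" for i in range(n)],
            "age": rng.uniform(20, 68, n).round(1),
            "sex": np.where(rng.random(n) < 0.6, "F", "M"),
            "bmi": rng.uniform(18, 25, n).round(1),
            "bmd": rng.normal(1.0, 0.13, n).round(4).clip(0.5),
        }
    )
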