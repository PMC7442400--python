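"""3-D gray-level co-occurrence matrices (GLCM) and Haralick-style attributes.

The texture of a segmented volume of interest (VOI) is summarised by the
joint distribution of quantized gray-level pairs at fixed voxel
displacements.  For each of 13 lattice orientations (the 26-neighbourhood
with opposite directions identified) and each displacement distance 1–5
voxels a co-occurrence matrix is accumulated — 65 matrices with the default
configuration — and 22 scalar attributes are computed per matrix and
averaged into one feature vector per VOI.

Conventions
-----------
* Gray levels are quantized to ``n_levels`` equal-width bins over the
  in-mask intensity range (range-relative, so features are invariant to
  adding a constant to all intensities); levels run 1..Ng.
* Matrices are symmetric by default: each ordered pair is counted in both
  orders, which is what the antipodally-deduplicated direction set implies.
* Displacements are ``direction * distance`` in integer voxel steps;
  physical voxel anisotropy is deliberately ignored (lattice-offset GLCM
  practice).  Spacing is carried on the volume but unused here.
* Entropy terms use log base 2 by default (configurable to natural log);
  0·log 0 is 0 throughout.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np

from .errors import DegenerateVoiError, EmptyMatrixError
from .io import ImageVolume, VoiMask

logger = logging.getLogger(__name__)

__all__ = [
    "ATTRIBUTE_NAMES",
    "GlcmConfig",
    "QuantizedVoi",
    "Glcm",
    "GlcmDerived",
    "FeatureVector",
    "direction_set",
    "quantize",
    "compute_glcm",
    "glcm_derived",
    "compute_features",
    "extract",
]

#: Canonical names (and report order) of the 22 texture attributes.
ATTRIBUTE_NAMES: tuple[str, ...] = (
    "autocorrelation",
    "cluster_prominence",
    "cluster_shade",
    "cluster_tendency",
    "contrast",
    "correlation",
    "difference_entropy",
    "dissimilarity",
    "energy",
    "entropy",
    "homogeneity1",
    "homogeneity2",
    "imc1",
    "imc2",
    "idmn",
    "idn",
    "inverse_variance",
    "max_probability",
    "sum_average",
    "sum_entropy",
    "sum_variance",
    "variance",
)

# The 13 unique directions of the 26-neighbourhood with each antipodal pair
# counted once, in canonical order.
_DIRECTIONS_13: tuple[tuple[int, int, int], ...] = (
    (1, 0, 0),
    (0, 1, 0),
    (0, 0, 1),
    (1, 1, 0),
    (1, -1, 0),
    (1, 0, 1),
    (1, 0, -1),
    (0, 1, 1),
    (0, 1, -1),
    (1, 1, 1),
    (1, 1, -1),
    (1, -1, 1),
    (1, -1, -1),
)


def direction_set() -> list[tuple[int, int, int]]:
    """The 13 canonical 3-D co-occurrence directions.

    These are the 26-neighbourhood offsets with opposite directions
    identified (symmetric matrices make a direction and its negation
    equivalent), covering every combination of in-plane angle θ and
    through-plane angle φ on the voxel lattice.
    """
    return [tuple(d) for d in _DIRECTIONS_13]


@dataclass(frozen=True)
class GlcmConfig:
    """Configuration of the co-occurrence computation.

    Parameters
    ----------
    n_levels : int
        Number of gray-level bins Ng (default 32, a common radiomics
        choice balancing matrix sparsity against discriminability).
    distances : tuple of int
        Displacement distances in voxels (default 1..5).
    directions : tuple of 3-int tuples
        Lattice directions; default is the canonical 13-orientation set.
    symmetric : bool
        Count each voxel pair in both orders (default True).
    log_base : float
        Base of the logarithm in entropy terms: 2 or e (default 2).
    aggregation : str
        How the per-matrix attributes are reduced to one value:
        ``mean_over_matrices`` (unweighted mean over all non-empty
        matrices, the default) or ``mean_over_directions_then_distances``.
    """

    n_levels: int = 32
    distances: tuple[int, ...] = (1, 2, 3, 4, 5)
    directions: tuple[tuple[int, int, int], ...] = _DIRECTIONS_13
    symmetric: bool = True
    log_base: float = 2.0
    aggregation: str = "mean_over_matrices"

    def __post_init__(self) -> None:
        if self.n_levels < 2:
            raise ValueError("n_levels must be >= 2")
        if not self.distances or any(int(d) < 1 for d in self.distances):
            raise ValueError("distances must be positive integers")
        if not self.directions:
            raise ValueError("directions must be nonempty")
        seen: set[tuple[int, int, int]] = set()
        for d in self.directions:
            t = tuple(int(c) for c in d)
            if t == (0, 0, 0):
                raise ValueError("the zero vector is not a valid direction")
            neg = tuple(-c for c in t)
            if t in seen or neg in seen:
                raise ValueError(f"direction {t} duplicates or negates another")
            seen.add(t)
        if self.aggregation not in (
            "mean_over_matrices",
            "mean_over_directions_then_distances",
        ):
            raise ValueError(f"unknown aggregation {self.aggregation!r}")
        base = float(self.log_base)
        if not (base == 2.0 or abs(base - math.e) < 1e-12):
            raise ValueError("log_base must be 2 or e")


@dataclass(frozen=True)
class QuantizedVoi:
    """A VOI quantized to integer gray levels 1..Ng (0 outside the mask)."""

    levels: np.ndarray
    mask: VoiMask
    n_levels: int


@dataclass(frozen=True)
class Glcm:
    """A normalized co-occurrence probability matrix for one displacement.

    ``p[i-1, j-1]`` is the probability of the gray-level pair (i, j);
    ``offset`` is the generating displacement (direction × distance);
    ``n_pairs`` the raw directed pair count before symmetrization and
    normalization.
    """

    p: np.ndarray
    offset: tuple[int, int, int]
    n_pairs: int


@dataclass(frozen=True)
class GlcmDerived:
    """Marginal and entropy summaries of one co-occurrence matrix.

    ``p_plus[k-2]`` holds the cross-sum mass P_{x+y}(k) for k = 2..2Ng and
    ``p_minus[k]`` the cross-difference mass P_{x-y}(k) for k = 0..Ng-1.
    ``hxy1 = -Σ p(i,j) log(px(i) py(j))`` and
    ``hxy2 = -Σ px(i) py(j) log(px(i) py(j))`` are the cross entropies
    feeding the information measures of correlation.
    """

    px: np.ndarray
    py: np.ndarray
    mu_x: float
    mu_y: float
    sigma_x: float
    sigma_y: float
    p_plus: np.ndarray
    p_minus: np.ndarray
    hx: float
    hy: float
    hxy: float
    hxy1: float
    hxy2: float
    log_base: float = 2.0


@dataclass(frozen=True)
class FeatureVector:
    """The 22 aggregated texture attributes of one VOI."""

    values: dict[str, float]
    n_matrices: int = 0
    n_constructed: int = 0

    def __post_init__(self) -> None:
        if tuple(self.values.keys()) != ATTRIBUTE_NAMES:
            missing = set(ATTRIBUTE_NAMES) - set(self.values)
            extra = set(self.values) - set(ATTRIBUTE_NAMES)
            raise ValueError(
                f"feature vector must carry the canonical 22 attributes in "
                f"order (missing {sorted(missing)}, extra {sorted(extra)})"
            )

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def to_array(self) -> np.ndarray:
        return np.array([self.values[k] for k in ATTRIBUTE_NAMES])


def quantize(volume: ImageVolume, mask: VoiMask, n_levels: int = 32) -> QuantizedVoi:
    """Quantize in-mask intensities to equal-width bins 1..Ng.

    ``level = min(Ng, floor((v - vmin) * Ng / (vmax - vmin)) + 1)`` over the
    in-mask range; a constant VOI maps everything to level 1.
    """
    if volume.shape != mask.shape:
        raise DegenerateVoiError(
            f"mask shape {mask.shape} does not match volume shape {volume.shape}"
        )
    if n_levels < 2:
        raise ValueError("n_levels must be >= 2")
    inside = mask.data
    values = volume.data[inside]
    if values.size < 2:
        raise DegenerateVoiError(
            f"VOI must contain at least 2 voxels, got {values.size}"
        )
    vmin = float(values.min())
    vmax = float(values.max())
    levels = np.zeros(volume.shape, dtype=np.int32)
    # relative tolerance guards float dust from degrading a constant VOI
    if vmax - vmin <= 1e-12 * max(1.0, abs(vmax)):
        levels[inside] = 1
    else:
        binned = np.floor((values - vmin) * n_levels / (vmax - vmin)).astype(np.int64)
        levels[inside] = np.clip(binned + 1, 1, n_levels)
    return QuantizedVoi(levels=levels, mask=mask, n_levels=int(n_levels))


def _pair_views(shape, offset):
    """Slices selecting source and destination voxels for one displacement."""
    src, dst = [], []
    for n, o in zip(shape, offset):
        if abs(o) >= n:
            return None
        if o >= 0:
            src.append(slice(0, n - o))
            dst.append(slice(o, n))
        else:
            src.append(slice(-o, n))
            dst.append(slice(0, n + o))
    return tuple(src), tuple(dst)


def compute_glcm(
    qvoi: QuantizedVoi,
    direction: tuple[int, int, int],
    distance: int,
    symmetric: bool = True,
) -> Glcm:
    """Accumulate the co-occurrence matrix for one direction and distance.

    Counts every ordered in-mask voxel pair ``(v, v + direction*distance)``;
    with ``symmetric`` the transpose is added before normalizing to a
    probability matrix.
    """
    offset = tuple(int(c) * int(distance) for c in direction)
    ng = qvoi.n_levels
    views = _pair_views(qvoi.levels.shape, offset)
    if views is None:
        raise EmptyMatrixError(f"displacement {offset} exceeds the grid")
    src, dst = views
    valid = qvoi.mask.data[src] & qvoi.mask.data[dst]
    i = qvoi.levels[src][valid] - 1
    j = qvoi.levels[dst][valid] - 1
    n_pairs = int(i.size)
    if n_pairs == 0:
        raise EmptyMatrixError(f"no in-mask voxel pair for displacement {offset}")
    counts = np.bincount(i * ng + j, minlength=ng * ng).reshape(ng, ng).astype(float)
    if symmetric:
        counts = counts + counts.T
    return Glcm(p=counts / counts.sum(), offset=offset, n_pairs=n_pairs)


def _log(x: np.ndarray | float, base: float):
    return np.log2(x) if base == 2.0 else np.log(x)


def _entropy(p: np.ndarray, base: float) -> float:
    nz = p[p > 0]
    return float(-(nz * _log(nz, base)).sum())


def glcm_derived(g: Glcm, log_base: float = 2.0) -> GlcmDerived:
    """Marginals, cross-sum/difference distributions and entropies of a GLCM."""
    p = g.p
    ng = p.shape[0]
    levels = np.arange(1, ng + 1, dtype=float)
    px = p.sum(axis=1)
    py = p.sum(axis=0)
    mu_x = float(levels @ px)
    mu_y = float(levels @ py)
    sigma_x = float(np.sqrt(((levels - mu_x) ** 2) @ px))
    sigma_y = float(np.sqrt(((levels - mu_y) ** 2) @ py))
    ii, jj = np.meshgrid(np.arange(1, ng + 1), np.arange(1, ng + 1), indexing="ij")
    p_plus = np.bincount((ii + jj).ravel(), weights=p.ravel(), minlength=2 * ng + 1)[2:]
    p_minus = np.bincount(np.abs(ii - jj).ravel(), weights=p.ravel(), minlength=ng)[:ng]
    pxpy = np.outer(px, py)
    mask_p = p > 0
    hxy1 = float(-(p[mask_p] * _log(pxpy[mask_p], log_base)).sum())
    return GlcmDerived(
        px=px,
        py=py,
        mu_x=mu_x,
        mu_y=mu_y,
        sigma_x=sigma_x,
        sigma_y=sigma_y,
        p_plus=p_plus,
        p_minus=p_minus,
        hx=_entropy(px, log_base),
        hy=_entropy(py, log_base),
        hxy=_entropy(p, log_base),
        hxy1=hxy1,
        hxy2=_entropy(pxpy.ravel(), log_base),
        log_base=log_base,
    )


def compute_features(g: Glcm, dv: GlcmDerived, log_base: float = 2.0) -> dict[str, float]:
    """The 22 co-occurrence attributes of one matrix.

    Degenerate cases take defined fallbacks: correlation and IMC1 are 0 when
    their denominators vanish, the IMC2 radicand clamps at 0, and inverse
    variance skips the diagonal — so a constant-texture VOI stays finite.
    """
    p = g.p
    ng = p.shape[0]
    ii, jj = np.meshgrid(
        np.arange(1, ng + 1, dtype=float), np.arange(1, ng + 1, dtype=float), indexing="ij"
    )
    gap = ii - jj
    abs_gap = np.abs(gap)
    k = np.arange(2, 2 * ng + 1, dtype=float)

    autocorrelation = float((ii * jj * p).sum())
    mu_sum = dv.mu_x + dv.mu_y
    cluster = ii + jj - mu_sum
    sig = dv.sigma_x * dv.sigma_y
    correlation = 0.0 if sig <= 0 else float((autocorrelation - dv.mu_x * dv.mu_y) / sig)
    denom_imc1 = max(dv.hx, dv.hy)
    imc1 = 0.0 if denom_imc1 == 0 else float((dv.hxy - dv.hxy1) / denom_imc1)
    imc2 = float(np.sqrt(max(0.0, 1.0 - np.exp(-2.0 * (dv.hxy2 - dv.hxy)))))
    sum_average = float(k @ dv.p_plus)
    off_diag = ~np.eye(ng, dtype=bool)
    inv_var = float((p[off_diag] / gap[off_diag] ** 2).sum()) if ng > 1 else 0.0
    mu_all = 0.5 * (dv.mu_x + dv.mu_y)  # equals mu_x for symmetric matrices

    return {
        "autocorrelation": autocorrelation,
        "cluster_prominence": float((cluster**4 * p).sum()),
        "cluster_shade": float((cluster**3 * p).sum()),
        "cluster_tendency": float((cluster**2 * p).sum()),
        "contrast": float((gap**2 * p).sum()),
        "correlation": correlation,
        "difference_entropy": _entropy(dv.p_minus, log_base),
        "dissimilarity": float((abs_gap * p).sum()),
        "energy": float((p**2).sum()),
        "entropy": _entropy(p, log_base),
        "homogeneity1": float((p / (1.0 + abs_gap)).sum()),
        "homogeneity2": float((p / (1.0 + gap**2)).sum()),
        "imc1": imc1,
        "imc2": imc2,
        "idmn": float((p / (1.0 + gap**2 / ng**2)).sum()),
        "idn": float((p / (1.0 + abs_gap / ng)).sum()),
        "inverse_variance": inv_var,
        "max_probability": float(p.max()),
        "sum_average": sum_average,
        "sum_entropy": _entropy(dv.p_plus, log_base),
        "sum_variance": float(((k - sum_average) ** 2) @ dv.p_plus),
        "variance": float(((ii - mu_all) ** 2 * p).sum()),
    }


def extract(
    volume: ImageVolume, mask: VoiMask, cfg: GlcmConfig | None = None
) -> FeatureVector:
    """Quantize a VOI, build all co-occurrence matrices and aggregate.

    One matrix is built per (distance, direction) pair — 65 with the
    defaults.  Displacements with no valid in-mask pair are skipped with a
    logged warning; the per-matrix attributes of the rest are reduced to one
    value each according to ``cfg.aggregation``.
    """
    if cfg is None:
        cfg = GlcmConfig()
    qvoi = quantize(volume, mask, cfg.n_levels)
    per_matrix: list[tuple[int, dict[str, float]]] = []
    n_constructed = 0
    for d_idx, distance in enumerate(cfg.distances):
        for direction in cfg.directions:
            n_constructed += 1
            try:
                g = compute_glcm(qvoi, direction, distance, cfg.symmetric)
            except EmptyMatrixError:
                logger.warning(
                    "skipping empty co-occurrence matrix for direction %s distance %d",
                    direction,
                    distance,
                )
                continue
            dv = glcm_derived(g, cfg.log_base)
            per_matrix.append((d_idx, compute_features(g, dv, cfg.log_base)))
    if not per_matrix:
        raise DegenerateVoiError("every co-occurrence matrix is empty for this VOI")

    if cfg.aggregation == "mean_over_matrices":
        agg = {
            name: float(np.mean([f[name] for _, f in per_matrix]))
            for name in ATTRIBUTE_NAMES
        }
    else:  # mean over directions within a distance, then over distances
        by_distance: dict[int, list[dict[str, float]]] = {}
        for d_idx, feats in per_matrix:
            by_distance.setdefault(d_idx, []).append(feats)
        agg = {
            name: float(
                np.mean(
                    [np.mean([f[name] for f in group]) for group in by_distance.values()]
                )
            )
            for name in ATTRIBUTE_NAMES
        }
    return FeatureVector(
        values={name: agg[name] for name in ATTRIBUTE_NAMES},
        n_matrices=len(per_matrix),
        n_constructed=n_constructed,
    )
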