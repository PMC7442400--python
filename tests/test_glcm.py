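"""Unit and property tests for quantization, GLCM construction and attributes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bonetexture.errors import DegenerateVoiError, EmptyMatrixError
from bonetexture.glcm import (
    ATTRIBUTE_NAMES,
    Glcm,
    GlcmConfig,
    compute_features,
    compute_glcm,
    direction_set,
    extract,
    glcm_derived,
    quantize,
)
from bonetexture.io import VoiMask

from conftest import full_mask, make_volume


class TestDirectionSet:
    def test_thirteen_unique_directions(self):
        dirs = direction_set()
        assert len(dirs) == 13
        assert len(set(dirs)) == 13

    def test_no_antipodal_pair(self):
        dirs = set(direction_set())
        for d in dirs:
            assert tuple(-c for c in d) not in dirs

    def test_axis_aligned_units_present(self):
        dirs = set(direction_set())
        assert {(1, 0, 0), (0, 1, 0), (0, 0, 1)} <= dirs

    def test_covers_26_neighbourhood(self):
        covered = set()
        for d in direction_set():
            covered.add(d)
            covered.add(tuple(-c for c in d))
        assert len(covered) == 26


class TestGlcmConfig:
    def test_defaults(self):
        cfg = GlcmConfig()
        assert cfg.n_levels == 32
        assert cfg.distances == (1, 2, 3, 4, 5)
        assert len(cfg.directions) == 13

    @pytest.mark.parametrize(
        "kwargs",
        [
            {"n_levels": 1},
            {"distances": ()},
            {"distances": (0,)},
            {"directions": ()},
            {"directions": ((0, 0, 0),)},
            {"directions": ((1, 0, 0), (-1, 0, 0))},
            {"aggregation": "median"},
            {"log_base": 10},
        ],
    )
    def test_invalid_configs_rejected(self, kwargs):
        with pytest.raises(ValueError):
            GlcmConfig(**kwargs)


class TestQuantize:
    def test_constant_voi_all_level_one(self):
        vol = make_volume(np.full((3, 3, 3), 7.0))
        q = quantize(vol, full_mask((3, 3, 3)), 8)
        assert (q.levels[q.mask.data] == 1).all()

    def test_range_endpoints_hit_extreme_levels(self):
        data = np.full((2, 2, 2), 5.0)
        data[0, 0, 0] = 1.0
        data[1, 1, 1] = 9.0
        q = quantize(make_volume(data), full_mask((2, 2, 2)), 4)
        assert q.levels[0, 0, 0] == 1
        assert q.levels[1, 1, 1] == 4

    def test_ramp_binning_formula(self):
        # equal-width bins over [0, 255]: value 16 -> floor(16*32/256)+1 = 3
        data = np.arange(256, dtype=float).reshape(4, 8, 8)
        q = quantize(make_volume(data), full_mask((4, 8, 8)), 32)
        flat = q.levels.ravel()
        assert flat[16] == 3
        assert flat[0] == 1
        assert flat[255] == 32

    def test_singleton_mask_rejected(self):
        mask = np.zeros((3, 3, 3), dtype=bool)
        mask[1, 1, 1] = True
        with pytest.raises(DegenerateVoiError):
            quantize(make_volume(np.zeros((3, 3, 3))), VoiMask(mask), 4)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(shift=st.floats(-1e4, 1e4, allow_nan=False), seed=st.integers(0, 50))
    def test_intensity_shift_invariance(self, shift, seed):
        rng = np.random.default_rng(seed)
        data = rng.uniform(0, 100, size=(4, 4, 4))
        mask = full_mask((4, 4, 4))
        q0 = quantize(make_volume(data), mask, 8)
        q1 = quantize(make_volume(data + shift), mask, 8)
        np.testing.assert_array_equal(q0.levels, q1.levels)


class TestComputeGlcm:
    def test_column_hand_enumeration(self):
        # levels [1,1,2,2] along z, displacement (0,0,1): ordered pairs
        # (1,1),(1,2),(2,2); plus transpose -> [[2,1],[1,2]]/6
        data = np.array([1.0, 1.0, 2.0, 2.0]).reshape(1, 1, 4)
        q = quantize(make_volume(data), full_mask((1, 1, 4)), 2)
        g = compute_glcm(q, (0, 0, 1), 1, symmetric=True)
        np.testing.assert_allclose(g.p, [[2 / 6, 1 / 6], [1 / 6, 2 / 6]])
        assert g.n_pairs == 3

    def test_asymmetric_counts(self):
        data = np.array([1.0, 1.0, 2.0, 2.0]).reshape(1, 1, 4)
        q = quantize(make_volume(data), full_mask((1, 1, 4)), 2)
        g = compute_glcm(q, (0, 0, 1), 1, symmetric=False)
        np.testing.assert_allclose(g.p, [[1 / 3, 1 / 3], [0, 1 / 3]])

    def test_constant_voi_single_cell(self):
        q = quantize(make_volume(np.ones((3, 3, 3))), full_mask((3, 3, 3)), 4)
        g = compute_glcm(q, (1, 0, 0), 1, symmetric=True)
        assert g.p[0, 0] == 1.0
        assert g.p.sum() == 1.0

    def test_displacement_without_pairs_raises(self):
        data = np.zeros((2, 2, 2))
        q = quantize(make_volume(np.random.default_rng(0).random((2, 2, 2))), full_mask((2, 2, 2)), 2)
        with pytest.raises(EmptyMatrixError):
            compute_glcm(q, (0, 0, 1), 5, symmetric=True)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 100), sym=st.booleans())
    def test_normalization_and_symmetry(self, seed, sym):
        rng = np.random.default_rng(seed)
        data = rng.random((4, 4, 4))
        q = quantize(make_volume(data), full_mask((4, 4, 4)), 5)
        g = compute_glcm(q, (1, 1, 0), 1, symmetric=sym)
        assert g.p.sum() == pytest.approx(1.0, abs=1e-12)
        assert (g.p >= 0).all()
        if sym:
            np.testing.assert_allclose(g.p, g.p.T)


class TestGlcmDerived:
    def test_checker_matrix_marginals(self):
        g = Glcm(p=np.array([[0.0, 0.5], [0.5, 0.0]]), offset=(0, 0, 1), n_pairs=2)
        dv = glcm_derived(g)
        np.testing.assert_allclose(dv.px, [0.5, 0.5])
        np.testing.assert_allclose(dv.py, [0.5, 0.5])
        # p_plus index k runs 2..2Ng; all mass at i+j=3
        np.testing.assert_allclose(dv.p_plus, [0.0, 1.0, 0.0])
        np.testing.assert_allclose(dv.p_minus, [0.0, 1.0])

    def test_point_mass(self):
        g = Glcm(p=np.array([[1.0]]), offset=(1, 0, 0), n_pairs=1)
        dv = glcm_derived(g)
        assert dv.hxy == 0.0
        assert dv.mu_x == 1.0
        assert dv.mu_y == 1.0

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 100), ng=st.integers(2, 6))
    def test_distribution_sums_and_entropy_order(self, seed, ng):
        rng = np.random.default_rng(seed)
        raw = rng.random((ng, ng))
        raw = raw + raw.T
        g = Glcm(p=raw / raw.sum(), offset=(1, 0, 0), n_pairs=ng)
        dv = glcm_derived(g)
        for dist in (dv.px, dv.py, dv.p_plus, dv.p_minus):
            assert dist.sum() == pytest.approx(1.0, abs=1e-12)
        assert dv.hx >= 0 and dv.hy >= 0 and dv.hxy >= 0
        assert dv.hxy1 >= dv.hxy - 1e-12


class TestComputeFeatures:
    def test_checker_closed_forms(self):
        g = Glcm(p=np.array([[0.0, 0.5], [0.5, 0.0]]), offset=(0, 0, 1), n_pairs=2)
        f = compute_features(g, glcm_derived(g))
        assert f["energy"] == pytest.approx(0.5)
        assert f["contrast"] == pytest.approx(1.0)
        assert f["dissimilarity"] == pytest.approx(1.0)
        assert f["max_probability"] == pytest.approx(0.5)
        assert f["entropy"] == pytest.approx(1.0)  # log base 2
        assert f["autocorrelation"] == pytest.approx(2.0)

    def test_point_mass_fallbacks(self):
        g = Glcm(p=np.array([[1.0]]), offset=(1, 0, 0), n_pairs=1)
        f = compute_features(g, glcm_derived(g))
        assert f["energy"] == 1.0
        assert f["entropy"] == 0.0
        assert f["contrast"] == 0.0
        assert f["correlation"] == 0.0  # sigma_x*sigma_y = 0 fallback
        assert f["imc1"] == 0.0

    def test_transpose_invariance_of_symmetric_features(self):
        rng = np.random.default_rng(3)
        raw = rng.random((5, 5))
        raw = raw + raw.T
        g = Glcm(p=raw / raw.sum(), offset=(1, 0, 0), n_pairs=10)
        f = compute_features(g, glcm_derived(g))
        gt = Glcm(p=g.p.T.copy(), offset=(1, 0, 0), n_pairs=10)
        ft = compute_features(gt, glcm_derived(gt))
        for name in ATTRIBUTE_NAMES:
            assert f[name] == pytest.approx(ft[name], abs=1e-12)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(seed=st.integers(0, 100), ng=st.integers(2, 8))
    def test_homogeneity_ordering_and_bounds(self, seed, ng):
        rng = np.random.default_rng(seed)
        raw = rng.random((ng, ng))
        g = Glcm(p=raw / raw.sum(), offset=(1, 0, 0), n_pairs=ng)
        f = compute_features(g, glcm_derived(g))
        assert f["homogeneity1"] >= f["homogeneity2"] - 1e-12
        assert f["homogeneity1"] <= 1.0 + 1e-12
        assert f["homogeneity2"] <= 1.0 + 1e-12
        assert 0.0 < f["energy"] <= 1.0
        assert f["entropy"] >= 0.0
        assert f["contrast"] >= 0.0


class TestExtract:
    def test_default_config_counts(self):
        rng = np.random.default_rng(0)
        vol = make_volume(rng.random((8, 8, 8)))
        fv = extract(vol, full_mask((8, 8, 8)))
        assert fv.n_constructed == 65
        assert fv.n_matrices == 65
        assert tuple(fv.values.keys()) == ATTRIBUTE_NAMES
        assert len(fv.values) == 22

    def test_constant_voi_aggregate(self):
        fv = extract(make_volume(np.full((6, 6, 6), 3.0)), full_mask((6, 6, 6)))
        assert fv["energy"] == pytest.approx(1.0)
        assert fv["entropy"] == pytest.approx(0.0)

    def test_aggregation_modes_agree_when_all_nonempty(self):
        # with every matrix non-empty the two reductions are identical means
        rng = np.random.default_rng(1)
        vol = make_volume(rng.random((8, 8, 8)))
        mask = full_mask((8, 8, 8))
        f1 = extract(vol, mask, GlcmConfig(aggregation="mean_over_matrices"))
        f2 = extract(vol, mask, GlcmConfig(aggregation="mean_over_directions_then_distances"))
        for name in ATTRIBUTE_NAMES:
            assert f1[name] == pytest.approx(f2[name], rel=1e-12)

    def test_sparse_voi_skips_empty_matrices(self):
        # two voxels adjacent along x: only direction (1,0,0) distance 1 pairs
        mask = np.zeros((8, 8, 8), dtype=bool)
        mask[0, 0, 0] = mask[1, 0, 0] = True
        rng = np.random.default_rng(2)
        fv = extract(make_volume(rng.random((8, 8, 8))), VoiMask(mask))
        assert fv.n_constructed == 65
        assert fv.n_matrices == 1

    def test_all_matrices_empty_raises(self):
        mask = np.zeros((16, 16, 16), dtype=bool)
        mask[0, 0, 0] = mask[15, 15, 15] = True  # no displacement links them
        rng = np.random.default_rng(2)
        with pytest.raises(DegenerateVoiError):
            extract(make_volume(rng.random((16, 16, 16))), VoiMask(mask))
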