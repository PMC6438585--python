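import math

import numpy as np
import pytest
from conftest import random_dvoi, sphere_spec

import oracles
from pettex import (
    DiscretizationConfig,
    IneligibleVOIError,
    PETVolume,
    TEXTURE_FEATURES,
    VOIMask,
    build_glcm,
    build_glrlm,
    build_glzlm,
    build_ngldm,
    discretize_absolute,
    extract_features,
    generate_phantom,
    glcm_indices,
    glrlm_indices,
    glzlm_indices,
    ngldm_indices,
    normalize_glcm,
    tumor_support,
)
from pettex.texture import DiscretizedVOI, discretize_values


def line_dvoi(levels_1d, n_levels=4):
    """A 1D strip of levels along x, embedded in a 3D grid."""
    arr = np.asarray(levels_1d, dtype=np.int64)
    levels = np.zeros((len(arr), 1, 1), dtype=np.int64)
    levels[:, 0, 0] = arr
    return DiscretizedVOI(levels=levels, mask=levels > 0, n_levels=n_levels,
                          spacing=(1.0, 1.0, 1.0))


def constant_dvoi(shape=(3, 3, 3), level=5, n_levels=8):
    levels = np.full(shape, level, dtype=np.int64)
    return DiscretizedVOI(levels=levels, mask=np.ones(shape, bool),
                          n_levels=n_levels, spacing=(1.0, 1.0, 1.0))


class TestDiscretization:
    @pytest.mark.parametrize(
        "suv,expected",
        [(0.0, 1), (30.0, 64), (35.0, 64), (15.0, 33), (10.0, 22),
         (29.9999, 64), (0.468, 1), (0.46875, 2)],
    )
    def test_absolute_resampling_levels(self, suv, expected, disc64):
        assert discretize_values(np.array([suv]), disc64)[0] == expected

    def test_levels_always_in_range(self, disc64):
        rng = np.random.default_rng(0)
        v = rng.uniform(-5, 60, size=1000)
        lv = discretize_values(v, disc64)
        assert lv.min() >= 1 and lv.max() <= 64

    def test_discretize_absolute_matches_mask(self, disc64):
        rng = np.random.default_rng(1)
        vol = PETVolume(rng.uniform(0, 40, (6, 6, 6)), spacing=(1, 1, 1))
        mask = VOIMask(rng.random((6, 6, 6)) < 0.5, spacing=(1, 1, 1))
        dvoi = discretize_absolute(vol, mask, disc64)
        assert dvoi.n_voxels == mask.n_voxels
        assert np.all(dvoi.levels[dvoi.mask] >= 1)
        assert np.all(dvoi.levels[~dvoi.mask] == 0)

    def test_coarser_binning_never_increases_entropy(self):
        """Halving the number of levels merges co-occurrence cells, which
        can only lower the matrix entropy."""
        rng = np.random.default_rng(2)
        vol = PETVolume(rng.uniform(0, 30, (5, 5, 5)), spacing=(1, 1, 1))
        mask = VOIMask(np.ones((5, 5, 5), bool), spacing=(1, 1, 1))
        entropies = {}
        for n in (64, 32, 16):
            dvoi = discretize_absolute(vol, mask, DiscretizationConfig(n_levels=n))
            p = normalize_glcm(build_glcm(dvoi))
            entropies[n] = glcm_indices(p)["Entropy"]
        assert entropies[32] <= entropies[64] + 1e-12
        assert entropies[16] <= entropies[32] + 1e-12


class TestGLCM:
    def test_collinear_triplet_counts_and_indices(self):
        """[1, 1, 2] along x: ordered pair counts (1,1):2, (1,2):1, (2,1):1
        and the six indices computed by hand from p = (0.5, .25, .25)."""
        dvoi = line_dvoi([1, 1, 2])
        counts = build_glcm(dvoi)
        assert counts[0, 0] == 2 and counts[0, 1] == 1 and counts[1, 0] == 1
        assert counts.sum() == 4
        idx = glcm_indices(normalize_glcm(counts))
        assert idx["Homogeneity"] == pytest.approx(0.75)
        assert idx["Energy"] == pytest.approx(0.375)
        assert idx["Contrast_glcm"] == pytest.approx(0.5)
        assert idx["Dissimilarity"] == pytest.approx(0.5)
        assert idx["Entropy"] == pytest.approx(1.5)

    def test_constant_voi_all_mass_on_diagonal(self):
        dvoi = constant_dvoi(level=5)
        p = normalize_glcm(build_glcm(dvoi))
        assert p[4, 4] == pytest.approx(1.0)
        idx = glcm_indices(p)
        assert idx["Homogeneity"] == pytest.approx(1.0)
        assert idx["Energy"] == pytest.approx(1.0)
        assert idx["Entropy"] == pytest.approx(0.0)
        assert idx["Contrast_glcm"] == pytest.approx(0.0)
        assert math.isnan(idx["Correlation"])

    def test_single_voxel_is_degenerate(self):
        dvoi = line_dvoi([3])
        with pytest.raises(ValueError, match="degenerate"):
            normalize_glcm(build_glcm(dvoi))

    def test_homogeneity_at_most_one(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            dvoi = random_dvoi(rng)
            counts = build_glcm(dvoi)
            if counts.sum() == 0:
                continue
            idx = glcm_indices(normalize_glcm(counts))
            assert idx["Homogeneity"] <= 1.0 + 1e-12
            assert 0 < idx["Energy"] <= 1.0 + 1e-12


class TestGLRLM:
    def test_collinear_triplet_runs(self):
        counts = build_glrlm(line_dvoi([1, 1, 2]))
        # along x: one run (level 1, len 2), one (level 2, len 1);
        # the other 12 directions contribute three runs of length 1
        assert counts[0, 1] == 1
        assert counts[0, 0] == 12 * 2  # level-1 voxels, 12 off-axis directions
        assert counts[1, 0] == 12 + 1

    def test_run_mass_conserved_per_direction(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            dvoi = random_dvoi(rng, shape=(3, 3, 3))
            counts = build_glrlm(dvoi)
            lengths = np.arange(1, counts.shape[1] + 1)
            assert (counts * lengths).sum() == 13 * dvoi.n_voxels

    def test_single_run_formulas(self):
        # one run of level 2, length 4 fed straight into the formulas
        counts = np.zeros((4, 6), dtype=np.int64)
        counts[1, 3] = 1
        idx = glrlm_indices(counts, n_voxels=4)
        assert idx["SRE"] == pytest.approx(1 / 16)
        assert idx["LRE"] == pytest.approx(16)
        assert idx["LGRE"] == pytest.approx(1 / 4)
        assert idx["HGRE"] == pytest.approx(4)
        assert idx["RP"] == pytest.approx(1 / (13 * 4))

    def test_maximally_fragmented_runs(self):
        counts = np.zeros((4, 3), dtype=np.int64)
        counts[0, 0] = 13 * 5  # five level-1 voxels, all runs length 1
        idx = glrlm_indices(counts, n_voxels=5)
        assert idx["SRE"] == 1.0
        assert idx["LRE"] == 1.0
        assert idx["RP"] == 1.0


class TestNGLDM:
    def test_constant_cube_center_dependence_26(self):
        dvoi = constant_dvoi(level=3)
        res = build_ngldm(dvoi)
        assert res.q[2, 26] == 1  # the center voxel sees all 26 neighbors
        assert res.q.sum() == 27
        idx = ngldm_indices(res)
        assert math.isnan(idx["Busyness"])
        assert idx["Contrast"] == 0.0
        assert idx["Coarseness"] > 1e6  # uniform region: near-infinite coarseness

    def test_checkerboard_strip_has_zero_dependence(self):
        dvoi = line_dvoi([1, 2, 1, 2, 1, 2])
        res = build_ngldm(dvoi)
        assert np.all(res.q[:, 1:] == 0)
        assert res.q[:, 0].sum() == 6


class TestGLZLM:
    def test_collinear_triplet_zones(self):
        counts = build_glzlm(line_dvoi([1, 1, 2]))
        assert counts[0, 1] == 1  # level 1, size 2
        assert counts[1, 0] == 1  # level 2, size 1
        sizes = np.arange(1, counts.shape[1] + 1)
        assert (counts * sizes).sum() == 3
        idx = glzlm_indices(counts, n_voxels=3)
        assert idx["SZE"] == pytest.approx(0.625)
        assert idx["LZE"] == pytest.approx(2.5)
        assert idx["LGZE"] == pytest.approx(0.625)
        assert idx["HGZE"] == pytest.approx(2.5)
        assert idx["ZP"] == pytest.approx(2 / 3)

    def test_connected_constant_voi_single_zone(self):
        dvoi = constant_dvoi(shape=(3, 3, 3), level=2)
        counts = build_glzlm(dvoi)
        assert counts.sum() == 1
        assert counts[1, 26] == 1

    def test_single_zone_formulas(self):
        counts = np.zeros((4, 9), dtype=np.int64)
        counts[0, 8] = 1  # level 1, size 9
        idx = glzlm_indices(counts, n_voxels=9)
        assert idx["LZLGE"] == pytest.approx(81)
        assert idx["SZE"] == pytest.approx(1 / 81)
        assert idx["ZP"] == pytest.approx(1 / 9)


@pytest.fixture(scope="module")
def random_cases():
    rng = np.random.default_rng(20240101)
    cases = []
    for _ in range(120):
        shape = tuple(rng.integers(2, 6, size=3))
        cases.append(random_dvoi(rng, shape=shape,
                                 n_levels=int(rng.integers(2, 7)),
                                 mask_p=float(rng.uniform(0.4, 1.0))))
    return cases


class TestOracleEquivalence:
    """All four builders against literal nested-loop enumerations on random
    small masked level maps."""

    def test_glcm_matches_brute_force(self, random_cases):
        for dvoi in random_cases:
            expected = oracles.glcm_brute(dvoi.levels, dvoi.mask, dvoi.n_levels)
            np.testing.assert_array_equal(build_glcm(dvoi), expected)

    def test_glrlm_matches_brute_force(self, random_cases):
        for dvoi in random_cases:
            got = build_glrlm(dvoi)
            expected = oracles.glrlm_brute(dvoi.levels, dvoi.mask,
                                           dvoi.n_levels, got.shape[1])
            np.testing.assert_array_equal(got, expected)

    def test_ngldm_matches_brute_force(self, random_cases):
        for dvoi in random_cases:
            got = build_ngldm(dvoi)
            q, s, n_i = oracles.ngldm_brute(dvoi.levels, dvoi.mask, dvoi.n_levels)
            np.testing.assert_array_equal(got.q, q)
            np.testing.assert_allclose(got.s, s, atol=1e-9)
            np.testing.assert_array_equal(got.n_i, n_i)

    def test_glzlm_matches_brute_force(self, random_cases):
        for dvoi in random_cases:
            got = build_glzlm(dvoi)
            expected = oracles.glzlm_brute(dvoi.levels, dvoi.mask, dvoi.n_levels)
            np.testing.assert_array_equal(got, expected[:, :got.shape[1]])
            assert expected[:, got.shape[1]:].sum() == 0


class TestExtractFeatures:
    def _eligible_voi(self, heterogeneity=0.4, seed=7):
        spec = sphere_spec(20.0, heterogeneity_amp=heterogeneity, seed=seed)
        vol = generate_phantom(spec)
        mask = VOIMask(tumor_support(spec), spacing=spec.spacing)
        return vol, mask

    def test_sub_floor_voi_rejected(self):
        vol, _ = self._eligible_voi()
        m = np.zeros(vol.shape, dtype=bool)
        m[20:23, 20:23, 20:27] = True  # 63 voxels
        with pytest.raises(IneligibleVOIError):
            extract_features(vol, VOIMask(m, spacing=vol.spacing))

    def test_eligible_voi_yields_31_texture_indices(self):
        vol, mask = self._eligible_voi()
        fv = extract_features(vol, mask)
        assert len(TEXTURE_FEATURES) == 31
        texture = {k: v for k, v in fv.values.items() if k in TEXTURE_FEATURES}
        assert len(texture) == 31
        assert set(fv.values) - set(TEXTURE_FEATURES) == {"SUVmax", "MTV"}

    def test_constant_voi_uniform_limit(self):
        vals = np.ones((10, 10, 10)) * 12.0
        vol = PETVolume(vals, spacing=(4.07, 4.07, 2.0))
        m = np.zeros((10, 10, 10), dtype=bool)
        m[2:7, 2:7, 2:6] = True  # 100 voxels, single cluster
        fv = extract_features(vol, VOIMask(m, spacing=vol.spacing))
        assert fv.values["Homogeneity"] == pytest.approx(1.0)
        assert fv.values["Energy"] == pytest.approx(1.0)
        assert fv.values["Entropy"] == pytest.approx(0.0)
        assert fv.values["Contrast_glcm"] == pytest.approx(0.0)
        assert fv.values["Dissimilarity"] == pytest.approx(0.0)
        assert math.isnan(fv.values["Correlation"])
        assert math.isnan(fv.values["Busyness"])
        assert fv.values["GLNUz"] == pytest.approx(1.0)  # single zone

    def test_disconnected_mask_rejected(self):
        vol, _ = self._eligible_voi()
        m = np.zeros(vol.shape, dtype=bool)
        m[2:6, 2:6, 2:6] = True
        m[20:24, 20:24, 20:24] = True
        with pytest.raises(ValueError, match="connected"):
            extract_features(vol, VOIMask(m, spacing=vol.spacing))

    def test_noise_lowers_homogeneity_raises_entropy(self):
        """Uncorrelated voxel noise fragments the co-occurrence structure."""
        homog, entro = [], []
        for seed in range(20):
            spec = sphere_spec(15.0, sbr=20.0, noise_sd=0.0, seed=seed)
            noisy = sphere_spec(15.0, sbr=20.0, noise_sd=1.0, seed=seed)
            mask = VOIMask(tumor_support(spec), spacing=spec.spacing)
            f0 = extract_features(generate_phantom(spec), mask)
            f1 = extract_features(generate_phantom(noisy), mask)
            homog.append(f1.values["Homogeneity"] - f0.values["Homogeneity"])
            entro.append(f1.values["Entropy"] - f0.values["Entropy"])
        assert np.mean(homog) < 0
        assert np.mean(entro) > 0
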