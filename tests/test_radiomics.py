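import math

import numpy as np
import pytest

import _oracles as orc
from fmisodyn import (FEATURE_NAMES, DiscretizedVolume, RadiomicsConfig,
                      build_matrices, delta_features, discretize_equal_probability,
                      discretize_fixed, feature_vector, glcm_correlation, lgze,
                      wavelet_bandpass)
from fmisodyn.radiomics import (FeatureVector, glcm_features, glrlm_features,
                                glszm_features, ngtdm_features)

from conftest import make_mask, make_volume, sphere_mask


def disc_from_levels(levels):
    levels = np.asarray(levels, dtype=np.int32)
    mask = levels > 0
    return DiscretizedVolume(levels, mask, int(levels.max()), "fixed_bin_width", 0.01)


def random_level_grid(rng, shape, n_levels, density=0.8):
    levels = rng.integers(1, n_levels + 1, size=shape).astype(np.int32)
    levels[rng.random(shape) > density] = 0
    if not (levels > 0).any():
        levels.flat[0] = 1
    return levels


class TestDiscretization:
    def test_constant_region_is_single_level(self):
        vol = make_volume(np.full((4, 4, 4), 1.3))
        disc = discretize_fixed(vol, make_mask(np.ones((4, 4, 4))))
        assert disc.n_levels == 1
        assert (disc.levels[disc.mask] == 1).all()

    def test_fixed_bin_floor_arithmetic(self):
        vals = np.zeros((1, 1, 3))
        vals[0, 0] = [1.00, 1.005, 1.02]
        disc = discretize_fixed(make_volume(vals), make_mask(np.ones((1, 1, 3))),
                                bin_width=0.01)
        assert list(disc.levels[0, 0]) == [1, 1, 3]

    def test_halving_bin_width_never_loses_levels(self, rng):
        vals = rng.uniform(1.0, 2.0, (5, 5, 5))
        mask = make_mask(np.ones((5, 5, 5)))
        for w in (0.2, 0.1, 0.05):
            coarse = discretize_fixed(make_volume(vals), mask, bin_width=w)
            fine = discretize_fixed(make_volume(vals), mask, bin_width=w / 2)
            assert fine.n_levels >= coarse.n_levels

    def test_equal_probability_exact_quartiles(self, rng):
        vals = rng.permutation(np.linspace(1, 2, 100)).reshape((4, 5, 5))
        disc = discretize_equal_probability(make_volume(vals),
                                            make_mask(np.ones((4, 5, 5))), n_levels=4)
        counts = np.bincount(disc.levels[disc.mask])[1:]
        assert list(counts) == [25, 25, 25, 25]

    def test_all_equal_values_collapse_to_one_level(self):
        disc = discretize_equal_probability(make_volume(np.full((3, 3, 3), 2.0)),
                                            make_mask(np.ones((3, 3, 3))), n_levels=8)
        occupied = np.unique(disc.levels[disc.mask])
        assert len(occupied) == 1

    def test_equalization_raises_entropy_on_skewed_sample(self, rng):
        vals = rng.exponential(0.2, (6, 6, 6)) + 1.0
        mask = make_mask(np.ones((6, 6, 6)))
        vol = make_volume(vals)

        def entropy(levels):
            p = np.bincount(levels[levels > 0])
            p = p[p > 0] / p.sum()
            return -(p * np.log2(p)).sum()

        fixed = discretize_fixed(vol, mask, bin_width=np.ptp(vals) / 16)
        equal = discretize_equal_probability(vol, mask, n_levels=16)
        assert entropy(equal.levels) >= entropy(fixed.levels)


class TestWaveletBandpass:
    def test_constant_volume_unchanged(self):
        vol = make_volume(np.full((12, 12, 12), 1.7))
        mask = sphere_mask((12, 12, 12), (6, 6, 6), 4)
        out = wavelet_bandpass(vol, mask)
        np.testing.assert_allclose(out.values[mask.values], 1.7, atol=1e-10)

    def test_textured_phantom_changes_and_not_a_projection(self, rng):
        vol = make_volume(1.0 + rng.uniform(0, 1, (12, 12, 12)))
        mask = make_mask(np.ones((12, 12, 12)))
        once = wavelet_bandpass(vol, mask)
        assert not np.allclose(once.values, vol.values)
        twice = wavelet_bandpass(once, mask)
        assert not np.allclose(twice.values, once.values)

    def test_region_below_filter_support_rejected(self):
        vol = make_volume(np.ones((8, 8, 8)))
        tiny = np.zeros((8, 8, 8), dtype=bool)
        tiny[2:5, 2:5, 2:5] = True
        with pytest.raises(ValueError, match="filter support"):
            wavelet_bandpass(vol, make_mask(tiny))


class TestMatricesAgainstOracle:
    """Vectorised matrices must equal brute-force enumeration on small grids."""

    def grids(self):
        rng = np.random.default_rng(7)
        yield np.array([[[1, 1], [2, 2]]], dtype=np.int32)        # hand case
        yield np.ones((1, 1, 1), dtype=np.int32)                  # single voxel
        for shape in ((3, 3, 3), (4, 3, 2), (5, 5, 5)):
            for n_levels in (2, 4):
                yield random_level_grid(rng, shape, n_levels)

    def test_all_matrices_match(self):
        for levels in self.grids():
            disc = disc_from_levels(levels)
            mats = build_matrices(disc)
            ng = disc.n_levels
            np.testing.assert_array_equal(mats.glcm, orc.glcm_brute(levels, ng))
            brute_rlm = orc.glrlm_brute(levels, ng)
            np.testing.assert_array_equal(
                mats.glrlm[:, : brute_rlm.shape[1]], brute_rlm)
            assert mats.glrlm[:, brute_rlm.shape[1]:].sum() == 0
            brute_szm = orc.glszm_brute(levels, ng, disc.n_voxels)
            np.testing.assert_array_equal(mats.glszm, brute_szm)
            s, n = orc.ngtdm_brute(levels, ng)
            np.testing.assert_allclose(mats.ngtdm_s, s, atol=1e-10)
            np.testing.assert_array_equal(mats.ngtdm_n, n)

    def test_single_voxel_degenerate_matrices(self):
        mats = build_matrices(disc_from_levels(np.ones((1, 1, 1), dtype=np.int32)))
        assert mats.glcm.sum() == 0
        assert mats.glszm.sum() == 1          # one zone of size 1
        assert mats.glszm[1, 1] == 1

    def test_two_zone_hand_case(self):
        mats = build_matrices(disc_from_levels([[[1, 1], [2, 2]]]))
        assert mats.glszm[1, 2] == 1
        assert mats.glszm[2, 2] == 1
        assert mats.glszm.sum() == 2

    def test_glcm_totals_count_neighbor_pairs_twice(self):
        levels = np.ones((3, 3, 3), dtype=np.int32)
        mats = build_matrices(disc_from_levels(levels))
        # 27 voxels: count ordered in-bounds neighbour pairs by enumeration
        pairs = orc.glcm_brute(levels, 1).sum()
        assert mats.glcm.sum() == pairs
        assert pairs % 2 == 0


class TestFeatureFormulasAgainstOracle:
    def test_texture_features_match_brute_force(self):
        rng = np.random.default_rng(11)
        for shape, n_levels in (((4, 4, 4), 3), ((5, 5, 5), 4), ((5, 4, 3), 2)):
            levels = random_level_grid(rng, shape, n_levels)
            disc = disc_from_levels(levels)
            mats = build_matrices(disc)
            checks = [
                (glcm_features(mats.glcm), orc.glcm_features_brute(mats.glcm)),
                (glrlm_features(mats.glrlm, mats.n_voxels),
                 orc.glrlm_features_brute(mats.glrlm, mats.n_voxels)),
                (glszm_features(mats.glszm, mats.n_voxels),
                 orc.glszm_features_brute(mats.glszm, mats.n_voxels)),
                (ngtdm_features(mats.ngtdm_s, mats.ngtdm_n, mats.n_voxels),
                 orc.ngtdm_features_brute(mats.ngtdm_s, mats.ngtdm_n, mats.n_voxels)),
            ]
            for impl, brute in checks:
                assert set(impl) == set(brute)
                for name in impl:
                    if math.isnan(brute[name]):
                        assert math.isnan(impl[name])
                    else:
                        assert impl[name] == pytest.approx(brute[name], rel=1e-6), name

    def test_lgze_hand_values(self):
        m = np.zeros((3, 3))
        m[1, 1] = 4                       # four zones at level 1
        assert lgze(m) == pytest.approx(1.0)
        m10 = np.zeros((11, 2))
        m10[10, 1] = 3                    # all zones at level 10
        assert lgze(m10) == pytest.approx(0.01)
        m2 = np.zeros((3, 2))
        m2[1, 1] = 1
        m2[2, 1] = 1
        assert lgze(m2) == pytest.approx(0.625)

    def test_glcm_correlation_hand_cases(self):
        banded = np.zeros((4, 4))
        banded[1, 1] = banded[2, 2] = banded[3, 3] = 5
        assert glcm_correlation(banded) == pytest.approx(1.0)
        marg = np.array([0.0, 0.2, 0.5, 0.3])
        independent = np.outer(marg, marg) * 100
        assert glcm_correlation(independent) == pytest.approx(0.0, abs=1e-12)
        single = np.zeros((3, 3))
        single[2, 2] = 7
        assert math.isnan(glcm_correlation(single))


class TestInvariants:
    def test_glszm_conserves_voxel_count(self, rng):
        levels = random_level_grid(rng, (6, 6, 6), 4)
        mats = build_matrices(disc_from_levels(levels))
        sizes = np.arange(mats.glszm.shape[1])
        assert (mats.glszm * sizes).sum() == (levels > 0).sum()

    def test_lgze_bounds_and_monotonicity(self):
        base = np.zeros((5, 4))
        base[1, 1] = 2
        base[2, 1] = 1
        low = lgze(base)
        assert 0 < low <= 1
        raised = np.zeros((5, 4))
        raised[1, 1] = 1
        raised[4, 1] = 1                 # one zone's level raised 2 → 4
        raised[2, 1] = 1
        assert lgze(raised) < low

    def test_glcm_normalization_and_correlation_bounds(self, rng):
        for _ in range(5):
            levels = random_level_grid(rng, (5, 5, 5), 5)
            mats = build_matrices(disc_from_levels(levels))
            if mats.glcm.sum() == 0:
                continue
            p = mats.glcm / mats.glcm.sum()
            assert p.sum() == pytest.approx(1.0)
            c = glcm_features(mats.glcm)["correlation"]
            if not math.isnan(c):
                assert -1.0 <= c <= 1.0 + 1e-12

    def test_rotation_invariance_of_merged_texture_features(self, rng):
        levels = random_level_grid(rng, (5, 5, 5), 4, density=1.0)
        ref_mats = build_matrices(disc_from_levels(levels))
        ref_glcm = glcm_features(ref_mats.glcm)
        ref_glrlm = glrlm_features(ref_mats.glrlm, ref_mats.n_voxels)
        for k in (1, 2, 3):
            rot = np.rot90(levels, k=k, axes=(0, 1))
            mats = build_matrices(disc_from_levels(rot))
            for name, val in glcm_features(mats.glcm).items():
                assert val == pytest.approx(ref_glcm[name], rel=1e-9, nan_ok=True)
            for name, val in glrlm_features(mats.glrlm, mats.n_voxels).items():
                assert val == pytest.approx(ref_glrlm[name], rel=1e-9, nan_ok=True)


class TestFeatureVector:
    def test_full_vector_has_130_stable_names(self, rng):
        vol = make_volume(1.0 + rng.uniform(0, 1, (14, 14, 14)))
        mask = sphere_mask((14, 14, 14), (7, 7, 7), 5)
        fv = feature_vector(vol, mask)
        assert list(fv.values) == list(FEATURE_NAMES)
        assert len(fv) == 130
        assert np.isfinite(fv["LGZE"])
        assert np.isfinite(fv["C_CM"])

    def test_homogeneous_sphere_single_zone_and_round_shape(self):
        vol = make_volume(np.full((16, 16, 16), 1.8))
        mask = sphere_mask((16, 16, 16), (8, 8, 8), 5)
        fv = feature_vector(vol, mask)
        assert fv["LGZE"] == pytest.approx(1.0)   # one zone at level 1
        assert fv["sphericity"] == pytest.approx(1.0, abs=0.15)
        assert math.isnan(fv["C_CM"])             # single level: flagged missing

    def test_subset_extraction(self, rng):
        vol = make_volume(1.0 + rng.uniform(0, 1, (12, 12, 12)))
        mask = sphere_mask((12, 12, 12), (6, 6, 6), 4)
        fv = feature_vector(vol, mask, RadiomicsConfig(features=("LGZE", "C_CM")))
        assert set(fv.values) == {"glszm_lgze", "glcm_correlation"}

    def test_frozen_catalogue_file_matches_module(self):
        import yaml
        from importlib import resources
        payload = yaml.safe_load(
            resources.files("fmisodyn").joinpath("features_v1.yaml").read_text())
        assert tuple(payload["features"]) == FEATURE_NAMES


class TestDeltaFeatures:
    def test_identical_vectors_give_zero(self, rng):
        vol = make_volume(1.0 + rng.uniform(0, 1, (12, 12, 12)))
        mask = sphere_mask((12, 12, 12), (6, 6, 6), 4)
        fv = feature_vector(vol, mask)
        deltas = delta_features(fv, fv)
        finite = [v for v in deltas.values.values() if np.isfinite(v)]
        assert finite and all(v == 0.0 for v in finite)

    def test_worked_lgze_ratio(self):
        fv0 = FeatureVector({"glszm_lgze": 0.05}, "W0")
        fv2 = FeatureVector({"glszm_lgze": 0.01}, "W2")
        assert delta_features(fv0, fv2)["LGZE"] == pytest.approx(-0.8)

    def test_antisymmetric_in_swap(self):
        fv0 = FeatureVector({"glszm_lgze": 0.04}, "W0")
        fv2 = FeatureVector({"glszm_lgze": 0.06}, "W2")
        fwd = delta_features(fv0, fv2)["LGZE"]
        # swapping the scans flips the sign of the numerator
        assert np.sign(delta_features(fv2, fv0)["LGZE"]) == -np.sign(fwd)

    def test_zero_baseline_flagged_missing(self):
        fv0 = FeatureVector({"glszm_lgze": 0.0}, "W0")
        fv2 = FeatureVector({"glszm_lgze": 0.01}, "W2")
        assert math.isnan(delta_features(fv0, fv2)["LGZE"])
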