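"""Radiomics tests: geometry, first-order and GLCM against brute-force oracles."""

import numpy as np
import pytest

from ramrad.mri_radiomics import (
    DIRECTIONS_13,
    CoRegistration,
    EmptyRoiError,
    MriVolume,
    RoiSample,
    discretize,
    feature_identifiers,
    first_order_features,
    glcm_features,
    glcm_matrix,
    map_trus_to_mri,
    radiomics_vector,
    spherical_roi,
)

# ---------------------------------------------------------------------------
# Independent brute-force oracles (literal formulas, no vectorization)
# ---------------------------------------------------------------------------


def sphere_count_brute(spacing, radius):
    """Enumerate lattice points with ||idx * spacing|| <= radius around 0."""
    bound = [int(np.ceil(radius / s)) + 1 for s in spacing]
    count = 0
    for i in range(-bound[0], bound[0] + 1):
        for j in range(-bound[1], bound[1] + 1):
            for k in range(-bound[2], bound[2] + 1):
                d2 = (i * spacing[0]) ** 2 + (j * spacing[1]) ** 2 + (k * spacing[2]) ** 2
                if d2 <= radius**2:
                    count += 1
    return count


def glcm_brute(levels, mask, n_levels, offset):
    P = np.zeros((n_levels, n_levels))
    ni, nj, nk = levels.shape
    for i in range(ni):
        for j in range(nj):
            for k in range(nk):
                if not mask[i, j, k]:
                    continue
                i2, j2, k2 = i + offset[0], j + offset[1], k + offset[2]
                if 0 <= i2 < ni and 0 <= j2 < nj and 0 <= k2 < nk and mask[i2, j2, k2]:
                    P[levels[i, j, k] - 1, levels[i2, j2, k2] - 1] += 1
    P = P + P.T
    total = P.sum()
    return P / total if total else P


def glcm_features_brute(P):
    n = P.shape[0]
    mu_i = sum((i + 1) * P[i, j] for i in range(n) for j in range(n))
    mu_j = sum((j + 1) * P[i, j] for i in range(n) for j in range(n))
    var_i = sum(((i + 1) - mu_i) ** 2 * P[i, j] for i in range(n) for j in range(n))
    var_j = sum(((j + 1) - mu_j) ** 2 * P[i, j] for i in range(n) for j in range(n))
    sig = np.sqrt(var_i) * np.sqrt(var_j)
    auto = sum((i + 1) * (j + 1) * P[i, j] for i in range(n) for j in range(n))
    shade = sum(((i + 1) + (j + 1) - mu_i - mu_j) ** 3 * P[i, j] for i in range(n) for j in range(n))
    contrast = sum((i - j) ** 2 * P[i, j] for i in range(n) for j in range(n))
    correlation = 1.0 if sig == 0 else (auto - mu_i * mu_j) / sig
    inv_diff = sum(P[i, j] / (1 + abs(i - j)) for i in range(n) for j in range(n))
    p_diff = np.zeros(n)
    for i in range(n):
        for j in range(n):
            p_diff[abs(i - j)] += P[i, j]
    diff_ent = -sum(p * np.log2(p) for p in p_diff if p > 0)
    joint_ent = -sum(P[i, j] * np.log2(P[i, j]) for i in range(n) for j in range(n) if P[i, j] > 0)
    joint_en = sum(P[i, j] ** 2 for i in range(n) for j in range(n))
    return {
        "Auto correlation": auto,
        "Cluster shade": shade,
        "Contrast": contrast,
        "Correlation": correlation,
        "Inverse difference": inv_diff,
        "Difference entropy": diff_ent,
        "Joint entropy": joint_ent,
        "Joint energy": joint_en,
    }


def first_order_brute(x, voxel_volume, bin_width):
    x = np.asarray(x, dtype=float)
    levels = np.floor((x - x.min()) / bin_width).astype(int) + 1
    p = np.array([(levels == l).mean() for l in range(1, levels.max() + 1)])
    pnz = p[p > 0]
    mean = x.mean()
    return {
        "Energy": (x**2).sum(),
        "Total energy": voxel_volume * (x**2).sum(),
        "Entropy": -(pnz * np.log2(pnz)).sum(),
        "Mean": mean,
        "Median": np.median(x),
        "Standard deviation": np.sqrt(((x - mean) ** 2).mean()),
        "Mean absolute deviation": np.abs(x - mean).mean(),
        "Uniformity": (p**2).sum(),
    }


def _volume(shape=(20, 20, 20), spacing=(1.0, 1.0, 1.0), seed=0, modality="T2"):
    rng = np.random.default_rng(seed)
    return MriVolume(
        modality=modality,
        intensities=100 + 20 * rng.standard_normal(shape),
        spacing_mm=np.array(spacing),
        origin_mm=np.zeros(3),
    )


# ---------------------------------------------------------------------------
# Co-location
# ---------------------------------------------------------------------------


class TestTrusToMri:
    def test_identity_and_translation(self):
        p = np.array([1.0, 2.0, 3.0])
        np.testing.assert_allclose(map_trus_to_mri(p, CoRegistration(np.eye(4))), p)
        t = np.eye(4)
        t[:3, 3] = [5.0, -1.0, 2.0]
        np.testing.assert_allclose(map_trus_to_mri(p, CoRegistration(t)), p - [5, -1, 2])

    def test_random_affine_round_trip(self):
        rng = np.random.default_rng(42)
        for _ in range(20):
            mat = np.eye(4)
            mat[:3, :3] = rng.standard_normal((3, 3)) + 3 * np.eye(3)
            mat[:3, 3] = rng.uniform(-30, 30, 3)
            reg = CoRegistration(mat)
            p = rng.uniform(-50, 50, 3)
            np.testing.assert_allclose(map_trus_to_mri(reg.apply(p), reg), p, atol=1e-9)

    def test_singular_transform_rejected(self):
        mat = np.eye(4)
        mat[0, 0] = 0.0
        mat[0, 1] = 0.0
        mat[0, 2] = 0.0
        with pytest.raises(ValueError, match="singular"):
            CoRegistration(mat)


# ---------------------------------------------------------------------------
# Spherical ROI
# ---------------------------------------------------------------------------


class TestSphericalRoi:
    def test_isotropic_5mm_sphere_has_515_voxels(self):
        vol = _volume(shape=(21, 21, 21))
        roi = spherical_roi(vol, center_mm=np.array([10.0, 10.0, 10.0]), radius_mm=5.0)
        assert len(roi.intensities) == sphere_count_brute((1, 1, 1), 5.0) == 515

    @pytest.mark.parametrize("spacing", [(1.8, 1.8, 4.0), (2.6, 2.6, 5.0)])
    def test_anisotropic_count_matches_bruteforce(self, spacing):
        vol = _volume(shape=(15, 15, 9), spacing=spacing)
        center = np.array([7, 7, 4]) * np.array(spacing)
        roi = spherical_roi(vol, center, radius_mm=5.0)
        assert len(roi.intensities) == sphere_count_brute(spacing, 5.0)

    def test_tiny_radius_keeps_single_voxel(self):
        vol = _volume()
        roi = spherical_roi(vol, np.array([10.0, 10.0, 10.0]), radius_mm=0.4)
        assert len(roi.intensities) == 1

    def test_center_outside_volume_raises(self):
        vol = _volume()
        with pytest.raises(EmptyRoiError):
            spherical_roi(vol, np.array([500.0, 500.0, 500.0]), radius_mm=5.0)


class TestDiscretize:
    def test_hand_examples_and_shift_invariance(self):
        levels, n = discretize(np.array([0.0, 25.0, 50.0]), 25.0)
        np.testing.assert_array_equal(levels, [1, 2, 3])
        assert n == 3
        levels_c, _ = discretize(np.full(7, 3.0), 25.0)
        np.testing.assert_array_equal(levels_c, np.ones(7, dtype=int))
        x = np.array([2.0, 31.0, 64.0, 90.0])
        l1, _ = discretize(x, 25.0)
        l2, _ = discretize(x + 1234.5, 25.0)
        np.testing.assert_array_equal(l1, l2)


# ---------------------------------------------------------------------------
# Feature formulas vs oracles
# ---------------------------------------------------------------------------


class TestFirstOrder:
    def test_constant_roi_degenerate_values(self):
        roi = RoiSample(np.zeros((9, 3), dtype=int), np.full(9, 7.0), 2.0)
        f = first_order_features(roi)
        assert f["Entropy"] == 0.0
        assert f["Uniformity"] == 1.0
        assert f["Standard deviation"] == 0.0
        assert f["Mean absolute deviation"] == 0.0

    def test_hand_arithmetic(self):
        roi = RoiSample(np.zeros((4, 3), dtype=int), np.array([1.0, 2.0, 2.0, 3.0]), 1.0)
        f = first_order_features(roi, bin_width=1.0)
        assert f["Energy"] == 18.0
        assert f["Mean"] == 2.0
        assert f["Median"] == 2.0
        assert f["Mean absolute deviation"] == 0.5

    def test_two_equal_bins_entropy_one_bit(self):
        roi = RoiSample(np.zeros((4, 3), dtype=int), np.array([0.0, 0.0, 30.0, 30.0]), 1.0)
        f = first_order_features(roi, bin_width=25.0)
        assert abs(f["Entropy"] - 1.0) < 1e-12
        assert abs(f["Uniformity"] - 0.5) < 1e-12

    def test_random_rois_match_bruteforce(self):
        rng = np.random.default_rng(9)
        for _ in range(100):
            n = rng.integers(3, 60)
            x = rng.uniform(0, 200, n)
            vv = float(rng.uniform(0.5, 15))
            bw = float(rng.uniform(5, 40))
            got = first_order_features(RoiSample(np.zeros((n, 3), dtype=int), x, vv), bw)
            want = first_order_brute(x, vv, bw)
            for name, val in want.items():
                np.testing.assert_allclose(got[name], val, atol=1e-9, err_msg=name)


class TestGlcm:
    def test_constant_block_concentrates_mass(self):
        grid = np.ones((2, 2, 1), dtype=int)
        mask = np.ones((2, 2, 1), dtype=bool)
        mats = glcm_matrix(grid, mask, n_levels=1)
        for P in mats.values():
            assert P.shape == (1, 1)
            assert abs(P.sum() - 1.0) < 1e-12
        f = glcm_features(mats)
        assert f["Contrast"] == 0.0
        assert f["Joint energy"] == 1.0
        assert f["Joint entropy"] == 0.0
        assert f["Cluster shade"] == 0.0
        assert f["Inverse difference"] == 1.0
        assert f["Correlation"] == 1.0  # degenerate single level

    def test_alternating_strip_hand_count(self):
        # 1-D strip [1,2,1,2] along x: symmetric P = [[0,.5],[.5,0]]
        grid = np.array([1, 2, 1, 2]).reshape(4, 1, 1)
        mask = np.ones((4, 1, 1), dtype=bool)
        mats = glcm_matrix(grid, mask, n_levels=2, directions=((1, 0, 0),))
        P = mats[(1, 0, 0)]
        np.testing.assert_allclose(P, [[0.0, 0.5], [0.5, 0.0]])
        f = glcm_features(mats)
        assert abs(f["Contrast"] - 1.0) < 1e-12
        assert abs(f["Joint energy"] - 0.5) < 1e-12
        assert abs(f["Joint entropy"] - 1.0) < 1e-12

    def test_random_grids_match_bruteforce(self):
        rng = np.random.default_rng(10)
        for _ in range(25):
            shape = tuple(rng.integers(3, 6, size=3))
            n_levels = int(rng.integers(2, 6))
            grid = rng.integers(1, n_levels + 1, size=shape)
            mask = rng.random(shape) < 0.8
            if not mask.any():
                mask[0, 0, 0] = True
            try:
                mats = glcm_matrix(grid, mask, n_levels)
            except ValueError:
                continue
            feats = glcm_features(mats)
            oracle_per_dir = []
            for d, P in mats.items():
                P_brute = glcm_brute(grid, mask, n_levels, d)
                np.testing.assert_allclose(P, P_brute, atol=1e-12)
                oracle_per_dir.append(glcm_features_brute(P_brute))
            for name in feats:
                oracle_mean = np.mean([o[name] for o in oracle_per_dir])
                np.testing.assert_allclose(feats[name], oracle_mean, atol=1e-9, err_msg=name)

    def test_no_valid_pairs_raises(self):
        grid = np.ones((1, 1, 1), dtype=int)
        mask = np.ones((1, 1, 1), dtype=bool)
        with pytest.raises(ValueError, match="pair"):
            glcm_matrix(grid, mask, n_levels=1)


# ---------------------------------------------------------------------------
# 48-feature vector
# ---------------------------------------------------------------------------


def _triplet(seed=0):
    return {
        "T2": _volume(shape=(40, 40, 40), spacing=(1, 1, 1), seed=seed, modality="T2"),
        "ADC": _volume(shape=(23, 23, 10), spacing=(1.8, 1.8, 4.0), seed=seed + 1, modality="ADC"),
        "b2000": _volume(shape=(16, 16, 8), spacing=(2.6, 2.6, 5.0), seed=seed + 2, modality="b2000"),
    }


class TestRadiomicsVector:
    def test_identifier_grid_layout(self):
        ids = feature_identifiers()
        assert len(ids) == 48
        assert ids["r1"] == ("T2", "First order", "Energy")
        assert ids["r17"] == ("ADC", "First order", "Energy")
        assert ids["r46"] == ("b2000", "GLCM", "Difference entropy")
        assert ids["r44"] == ("b2000", "GLCM", "Correlation")
        assert ids["r32"] == ("ADC", "GLCM", "Joint energy")

    def test_full_vector_and_modality_attribution(self):
        vols = _triplet()
        reg = CoRegistration(np.eye(4))
        point = np.array([20.0, 20.0, 20.0])
        vec = radiomics_vector(point, vols, reg)
        assert sorted(vec) == sorted(f"r{i}" for i in range(1, 49))
        adc_roi = spherical_roi(vols["ADC"], point, 5.0)
        assert vec["r17"] == first_order_features(adc_roi, 25.0)["Energy"]
        b2000_roi = spherical_roi(vols["b2000"], point, 5.0)
        from ramrad.mri_radiomics import _roi_glcm_features

        assert vec["r46"] == _roi_glcm_features(vols["b2000"], b2000_roi, 25.0)["Difference entropy"]

    def test_translation_of_world_frame_leaves_features_unchanged(self):
        vols = _triplet(seed=5)
        shift = np.array([13.0, -4.0, 7.0])
        shifted = {
            m: MriVolume(v.modality, v.intensities, v.spacing_mm, v.origin_mm + shift)
            for m, v in vols.items()
        }
        reg = CoRegistration(np.eye(4))
        p = np.array([20.0, 20.0, 20.0])
        a = radiomics_vector(p, vols, reg)
        b = radiomics_vector(p + shift, shifted, reg)
        for key in a:
            np.testing.assert_allclose(a[key], b[key], rtol=1e-12, err_msg=key)

    def test_roi_outside_one_volume_names_the_modality(self):
        vols = _triplet()
        reg = CoRegistration(np.eye(4))
        # z = 40.5 mm: within reach of T2 (z <= 39) and ADC (z <= 36) voxel
        # centers but > 5 mm past the last b2000 plane (z = 35)
        with pytest.raises(EmptyRoiError, match="b2000"):
            radiomics_vector(np.array([20.0, 20.0, 40.5]), vols, reg)
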