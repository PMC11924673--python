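"""Texture matrices and features against brute-force oracles and worked examples."""

import numpy as np
import pytest

from t1tex.features import families
from t1tex.features.catalog import FAMILY_NAMES, FAMILY_SIZES
from t1tex.features.firstorder import firstorder_features
from t1tex.features.matrices import (
    GLCM_OFFSETS,
    compute_glcm,
    compute_gldm,
    compute_glrlm,
    compute_glszm,
    compute_ngtdm,
)
from t1tex.features.shape2d import shape2d_features

import oracles
from conftest import random_level_image

FULL2 = np.ones((2, 2), bool)


class TestGlcmExamples:
    def test_constant_image_concentrates_on_diagonal(self):
        levels = np.ones((3, 3), dtype=int)
        glcm = compute_glcm(levels, np.ones((3, 3), bool))
        for p in glcm.matrices:
            assert p[0, 0] == pytest.approx(1.0)
        assert families.glcm_idmn(glcm) == pytest.approx(1.0)
        assert families.glcm_sum_entropy(glcm) == pytest.approx(0.0)

    def test_two_by_two_pair_enumeration(self):
        levels = np.array([[1, 2], [1, 2]])
        glcm = compute_glcm(levels, FULL2)
        # horizontal angle: ordered pairs (1,2),(1,2) -> symmetric 0.5/0.5
        p_h = glcm.matrices[0]
        assert p_h[0, 1] == pytest.approx(0.5)
        assert p_h[1, 0] == pytest.approx(0.5)
        assert p_h[0, 0] == p_h[1, 1] == 0.0

    def test_idmn_off_diagonal_arithmetic(self):
        # all mass at |i-j|=1 with Ng=2: IDMN = 1/(1 + 1/4) = 0.8
        levels = np.array([[1, 2], [1, 2]])
        glcm = compute_glcm(levels, FULL2)
        horizontal_only = type(glcm)(matrices=[glcm.matrices[0]], n_levels=2)
        assert families.glcm_idmn(horizontal_only) == pytest.approx(0.8)

    def test_sum_entropy_worked_examples(self):
        levels = np.array([[1, 2], [1, 2]])
        glcm = compute_glcm(levels, FULL2)
        horizontal_only = type(glcm)(matrices=[glcm.matrices[0]], n_levels=2)
        # p_{x+y}(3) = 1 -> zero entropy
        assert families.glcm_sum_entropy(horizontal_only) == pytest.approx(0.0)
        # uniform 2x2 GLCM: p_{x+y} = (1/4, 1/2, 1/4) -> 1.5 bits
        uniform = type(glcm)(matrices=[np.full((2, 2), 0.25)], n_levels=2)
        assert families.glcm_sum_entropy(uniform) == pytest.approx(1.5)

    def test_idmn_decreases_when_mass_moves_off_diagonal(self):
        ng = 4
        diag = np.eye(ng) / ng
        moved = diag.copy()
        moved[0, 0] -= 1 / ng
        moved[0, ng - 1] += 1 / (2 * ng)
        moved[ng - 1, 0] += 1 / (2 * ng)
        glcm_d = compute_glcm(np.ones((2, 2), int), FULL2)
        d = families._glcm_single(diag, ng)["Idmn"]
        m = families._glcm_single(moved, ng)["Idmn"]
        assert d == pytest.approx(1.0)
        assert m < d


class TestGlszmExamples:
    def test_constant_region_single_zone(self):
        levels = np.ones((4, 4), dtype=int)
        z = compute_glszm(levels, np.ones((4, 4), bool))
        assert z.n_zones == 1
        assert families.glszm_zone_percentage(z) == pytest.approx(1 / 16)

    def test_two_column_zones(self):
        levels = np.array([[1, 2], [1, 2]])
        z = compute_glszm(levels, FULL2)
        assert z.n_zones == 2
        assert families.glszm_zone_percentage(z) == pytest.approx(0.5)

    def test_checkerboard_every_pixel_its_own_zone_is_false_with_8conn(self):
        # 8-connectivity joins diagonal same-level pixels
        levels = np.indices((4, 4)).sum(axis=0) % 2 + 1
        z = compute_glszm(levels, np.ones((4, 4), bool))
        assert z.n_zones == 2


class TestFirstOrderExamples:
    def test_constant_entropy_zero_rms_abs(self):
        img = np.full((3, 3), -4.0)
        lv = np.ones((3, 3), dtype=int)
        f = firstorder_features(img, np.ones((3, 3), bool), lv)
        assert f["Entropy"] == pytest.approx(0.0)
        assert f["RootMeanSquared"] == pytest.approx(4.0)

    def test_two_level_entropy_one_bit(self):
        img = np.array([[0.0, 1.0], [0.0, 1.0]])
        lv = np.array([[1, 2], [1, 2]])
        f = firstorder_features(img, FULL2, lv)
        assert f["Entropy"] == pytest.approx(1.0)

    def test_rms_direct_arithmetic(self):
        img = np.array([[3.0, 4.0]])
        lv = np.array([[1, 2]])
        f = firstorder_features(img, np.ones((1, 2), bool), lv)
        assert f["RootMeanSquared"] == pytest.approx(np.sqrt(12.5))

    def test_entropy_bounded_by_log_levels(self):
        rng = np.random.default_rng(2)
        img = rng.normal(size=(20, 20))
        from t1tex.image_prep import discretize

        d = discretize(img, np.ones((20, 20), bool), 16)
        f = firstorder_features(img, d.mask, d.levels)
        assert 0.0 <= f["Entropy"] <= np.log2(16)
        assert 0.0 < f["Uniformity"] <= 1.0


class TestShape2D:
    def test_circle_elongation_near_one(self):
        rr, cc = np.mgrid[0:41, 0:41]
        disk = (rr - 20) ** 2 + (cc - 20) ** 2 <= 15**2
        f = shape2d_features(disk, (1.0, 1.0))
        assert f["Elongation"] == pytest.approx(1.0, abs=0.05)
        assert f["Sphericity"] == pytest.approx(1.0, abs=0.1)
        assert f["PixelSurface"] == pytest.approx(np.pi * 15**2, rel=0.05)

    def test_annulus_counts_both_boundaries(self):
        rr, cc = np.mgrid[0:41, 0:41]
        d2 = (rr - 20) ** 2 + (cc - 20) ** 2
        ring = (d2 <= 15**2) & (d2 >= 8**2)
        f = shape2d_features(ring, (1.0, 1.0))
        assert f["Perimeter"] == pytest.approx(2 * np.pi * (15 + 8), rel=0.1)
        assert f["MeshSurface"] == pytest.approx(np.pi * (15**2 - 8**2), rel=0.1)

    def test_spacing_scales_lengths(self):
        rr, cc = np.mgrid[0:21, 0:21]
        disk = (rr - 10) ** 2 + (cc - 10) ** 2 <= 7**2
        f1 = shape2d_features(disk, (1.0, 1.0))
        f2 = shape2d_features(disk, (2.0, 2.0))
        assert f2["Perimeter"] == pytest.approx(2 * f1["Perimeter"])
        assert f2["MeshSurface"] == pytest.approx(4 * f1["MeshSurface"])


@pytest.fixture(scope="module")
def instances():
    rng = np.random.default_rng(314159)
    return [random_level_image(rng) for _ in range(200)]


class TestMatrixOracles:
    """Every matrix-based feature equals a brute-force oracle on random images."""

    def test_glcm_matrices_and_features(self, instances):
        for levels, mask in instances:
            ng = int(levels[mask].max())
            try:
                glcm = compute_glcm(levels, mask)
            except ValueError:
                continue  # no valid pair anywhere; oracle agrees trivially
            kept = [
                off
                for off in GLCM_OFFSETS
                if oracles.glcm_oracle(levels, mask, off, ng).sum() > 0
            ]
            assert len(kept) == len(glcm.matrices)
            for off, p in zip(kept, glcm.matrices):
                p_oracle = oracles.glcm_oracle(levels, mask, off, ng)
                np.testing.assert_allclose(p, p_oracle, atol=1e-12)
                ours = families._glcm_single(p, ng)
                theirs = oracles.glcm_features_oracle(p_oracle.tolist(), ng)
                for name in ours:
                    assert ours[name] == pytest.approx(theirs[name], abs=1e-9), name

    def test_glrlm_matrices_and_features(self, instances):
        for levels, mask in instances:
            ng = int(levels[mask].max())
            glrlm = compute_glrlm(levels, mask)
            max_run = max(levels.shape)
            oracle_mats = [
                oracles.glrlm_oracle(levels, mask, d, ng, max_run) for d in GLCM_OFFSETS
            ]
            for ours_m, oracle_m in zip(glrlm.matrices, oracle_mats):
                np.testing.assert_allclose(ours_m, oracle_m)
            ours = families.glrlm_features(glrlm)
            per_angle = [
                oracles.sizezone_features_oracle(m, int(mask.sum()), "glrlm")
                for m in oracle_mats
            ]
            for name in ours:
                expect = np.mean([a[name] for a in per_angle])
                assert ours[name] == pytest.approx(expect, abs=1e-9), name

    def test_glszm_zones_and_features(self, instances):
        for levels, mask in instances:
            ng = int(levels[mask].max())
            glszm = compute_glszm(levels, mask)
            zones = oracles.glszm_zones_oracle(levels, mask, ng)
            assert glszm.n_zones == len(zones)
            # every in-mask pixel belongs to exactly one zone
            assert sum(s for _, s in zones) == int(mask.sum())
            max_zone = max(s for _, s in zones)
            z_oracle = np.zeros((ng, max_zone))
            for g, s in zones:
                z_oracle[g - 1, s - 1] += 1
            np.testing.assert_allclose(glszm.z, z_oracle)
            ours = families.glszm_features(glszm)
            theirs = oracles.sizezone_features_oracle(z_oracle, int(mask.sum()), "glszm")
            for name in ours:
                assert ours[name] == pytest.approx(theirs[name], abs=1e-9), name

    def test_gldm_matrices_and_features(self, instances):
        for levels, mask in instances:
            ng = int(levels[mask].max())
            gldm = compute_gldm(levels, mask)
            d_oracle = oracles.gldm_oracle(levels, mask, ng)
            np.testing.assert_allclose(gldm.d, d_oracle)
            ours = families.gldm_features(gldm)
            theirs = oracles.sizezone_features_oracle(d_oracle, int(mask.sum()), "gldm")
            for name in ours:
                assert ours[name] == pytest.approx(theirs[name], abs=1e-9), name

    def test_ngtdm_and_features(self, instances):
        for levels, mask in instances:
            ng = int(levels[mask].max())
            ngtdm = compute_ngtdm(levels, mask)
            s_o, n_o = oracles.ngtdm_oracle(levels, mask, ng)
            np.testing.assert_allclose(ngtdm.s, s_o, atol=1e-9)
            np.testing.assert_allclose(ngtdm.n, n_o)
            if n_o.sum() == 0:
                continue
            ours = families.ngtdm_features(ngtdm)
            theirs = oracles.ngtdm_features_oracle(s_o, n_o, ng)
            for name in ours:
                assert ours[name] == pytest.approx(theirs[name], abs=1e-7), name


class TestInvariants:
    def test_family_cardinalities(self):
        assert FAMILY_SIZES == {
            "shape2d": 9,
            "firstorder": 18,
            "glcm": 24,
            "gldm": 14,
            "glrlm": 16,
            "glszm": 16,
            "ngtdm": 5,
        }
        for fam, names in FAMILY_NAMES.items():
            assert len(set(names)) == len(names), fam

    def test_glcm_features_invariant_to_rotation(self):
        rng = np.random.default_rng(21)
        levels = rng.integers(1, 5, size=(7, 7)).astype(int)
        mask = np.ones((7, 7), bool)
        f1 = families.glcm_features(compute_glcm(levels, mask))
        f2 = families.glcm_features(compute_glcm(np.rot90(levels).copy(), mask))
        for name in f1:
            assert f1[name] == pytest.approx(f2[name], abs=1e-10), name

    def test_bounded_features(self):
        rng = np.random.default_rng(5)
        for _ in range(25):
            levels, mask = random_level_image(rng)
            try:
                glcm = compute_glcm(levels, mask)
            except ValueError:
                continue
            idmn = families.glcm_idmn(glcm)
            assert 0.0 < idmn <= 1.0 + 1e-12
            zp = families.glszm_zone_percentage(compute_glszm(levels, mask))
            assert 0.0 < zp <= 1.0
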