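"""Texture panel: hand-computed examples, brute-force matrix oracles,
degenerate-ROI conventions, invariances."""

import numpy as np
import pytest

from heamlrad.preprocess import DiscretizedRoi
from heamlrad.texture import (
    DIRECTIONS, channel_feature_set, compute_glcm, compute_glrlm,
    compute_glszm, compute_ngtdm, first_order_features, glcm_features,
    glrlm_features, glszm_features, ngtdm_features,
)

from oracles import brute_glcm, brute_glrlm, brute_glszm, brute_ngtdm, random_roi


def roi_of(levels, n_bins=None):
    lv = np.asarray(levels, dtype=np.int32)
    return DiscretizedRoi(levels=lv, n_bins=n_bins or int(lv.max()))


class TestFirstOrder:
    def test_constant_roi(self):
        f = first_order_features(roi_of(np.ones((3, 3))))
        assert f["variance"] == 0 and f["entropy"] == 0 and f["uniformity"] == 1
        assert f["skewness"] == 0 and f["kurtosis"] == 0

    def test_two_level_half_half(self):
        lv = np.array([[1, 2], [1, 2]])
        f = first_order_features(roi_of(lv))
        assert f["entropy"] == pytest.approx(1.0)   # 1 bit
        assert f["uniformity"] == pytest.approx(0.5)
        assert f["mean"] == pytest.approx(1.5)

    def test_exactly_seven(self):
        assert len(first_order_features(roi_of([[1, 2], [3, 0]], 4))) == 7


class TestGlcm:
    def test_constant_single_cell(self):
        m = compute_glcm(roi_of(np.ones((3, 3))))
        assert m.p[0, 0] == pytest.approx(1.0)
        f = glcm_features(m)
        assert f["contrast"] == 0 and f["energy"] == 1 and f["entropy"] == 0
        assert f["homogeneity"] == 1 and f["correlation"] == 1

    def test_2x2_hand_enumeration(self):
        roi = roi_of([[1, 2], [1, 2]])
        m = compute_glcm(roi)
        expected = brute_glcm(roi.levels, 2, DIRECTIONS)
        np.testing.assert_allclose(m.p, expected)

    def test_checkerboard_contrast_matches_oracle(self):
        lv = np.indices((6, 6)).sum(axis=0) % 2 + 1
        roi = roi_of(lv)
        f = glcm_features(compute_glcm(roi))
        p = brute_glcm(lv, 2, DIRECTIONS)
        i, j = np.meshgrid([1, 2], [1, 2], indexing="ij")
        assert f["contrast"] == pytest.approx(np.sum(p * (i - j) ** 2))
        assert f["sum_average"] == pytest.approx(np.sum(p * (i + j)))

    def test_symmetry_random(self, rng):
        for _ in range(50):
            lv, nb = random_roi(rng)
            m = compute_glcm(DiscretizedRoi(lv, nb))
            np.testing.assert_allclose(m.p, m.p.T)

    def test_no_pairs_raises(self):
        lv = np.zeros((3, 3), dtype=np.int32)
        lv[0, 0] = 1  # isolated pixel, no in-mask neighbour
        with pytest.raises(ValueError):
            compute_glcm(DiscretizedRoi(lv, 2))


class TestGlrlm:
    def test_single_row_runs(self):
        roi = roi_of([[1, 1, 1, 2]])
        m = compute_glrlm(roi, directions=((0, 1),))
        assert m.counts[0, 2] == 1 and m.counts[1, 0] == 1
        assert m.counts.sum() == 2
        f = glrlm_features(m)
        assert f["rp"] == pytest.approx(2 / 4)

    def test_constant_row_closed_form(self):
        n = 6
        roi = roi_of([[1] * n])
        f = glrlm_features(compute_glrlm(roi, directions=((0, 1),)))
        assert f["sre"] == pytest.approx(1 / n**2)
        assert f["lre"] == pytest.approx(n**2)

    def test_thirteen_features(self):
        f = glrlm_features(compute_glrlm(roi_of([[1, 2], [2, 1]])))
        assert len(f) == 13


class TestGlszm:
    def test_constant_single_zone(self):
        roi = roi_of(np.ones((3, 3)))
        m = compute_glszm(roi)
        assert m.counts[0, 8] == 1 and m.counts.sum() == 1
        f = glszm_features(m)
        assert f["zp"] == pytest.approx(1 / 9)

    def test_two_single_pixel_zones(self):
        lv = np.zeros((3, 3), dtype=np.int32)
        lv[0, 0], lv[2, 2] = 1, 2
        # two isolated single-pixel zones of different levels... but note
        # diagonal adjacency joins equal levels only, so these stay separate
        f = glszm_features(compute_glszm(DiscretizedRoi(lv, 2)))
        assert f["zp"] == pytest.approx(1.0)
        assert f["sze"] == pytest.approx(1.0)

    def test_mass_conservation_random(self, rng):
        """sum(size x count) equals the in-mask pixel count, always."""
        for _ in range(100):
            lv, nb = random_roi(rng)
            m = compute_glszm(DiscretizedRoi(lv, nb))
            sizes = np.arange(1, m.counts.shape[1] + 1)
            assert np.sum(m.counts * sizes) == (lv > 0).sum()


class TestNgtdm:
    def test_constant_roi_conventions(self):
        f = ngtdm_features(compute_ngtdm(roi_of(np.ones((3, 3)))))
        assert f["coarseness"] == pytest.approx(1e6)  # 1 / epsilon
        assert f["contrast"] == 0 and f["busyness"] == 0

    def test_center_pixel_hand_computation(self):
        lv = np.ones((3, 3), dtype=np.int32)
        lv[1, 1] = 2
        t = compute_ngtdm(DiscretizedRoi(lv, 2))
        p, s, n = brute_ngtdm(lv, 2)
        np.testing.assert_allclose(t.p, p)
        np.testing.assert_allclose(t.s, s)
        assert t.n_valid == n == 9
        # the center sees eight 1s: s_2 = |2 - 1| = 1; each edge pixel sees
        # the 2 in its neighborhood
        assert t.s[1] == pytest.approx(1.0)
        f = ngtdm_features(t)
        assert len(f) == 5
        assert f["contrast"] > 0

    def test_matches_bruteforce_random(self, rng):
        for _ in range(50):
            lv, nb = random_roi(rng)
            try:
                t = compute_ngtdm(DiscretizedRoi(lv, nb))
            except ValueError:
                continue
            p, s, n = brute_ngtdm(lv, nb)
            np.testing.assert_allclose(t.p, p, atol=1e-12)
            np.testing.assert_allclose(t.s, s, atol=1e-10)


class TestMatrixOracles:
    """Every texture matrix equals independent brute-force enumeration on
    random small ROIs (>= 100 instances across families)."""

    def test_glcm_random(self, rng):
        for _ in range(100):
            lv, nb = random_roi(rng)
            try:
                m = compute_glcm(DiscretizedRoi(lv, nb))
            except ValueError:
                continue
            np.testing.assert_allclose(m.p, brute_glcm(lv, nb, DIRECTIONS), atol=1e-12)

    def test_glrlm_random(self, rng):
        for _ in range(100):
            lv, nb = random_roi(rng)
            m = compute_glrlm(DiscretizedRoi(lv, nb))
            expected = brute_glrlm(lv, nb, DIRECTIONS)
            np.testing.assert_allclose(m.counts[:, :expected.shape[1]], expected)
            assert m.counts[:, expected.shape[1]:].sum() == 0

    def test_glszm_random(self, rng):
        for _ in range(100):
            lv, nb = random_roi(rng)
            m = compute_glszm(DiscretizedRoi(lv, nb))
            expected = brute_glszm(lv, nb)
            np.testing.assert_allclose(m.counts[:, :expected.shape[1]], expected)


class TestChannelPanel:
    def test_47_features_stable_order(self, rng):
        lv, nb = random_roi(rng, max_side=8)
        f1 = channel_feature_set(DiscretizedRoi(lv, nb), "original")
        f2 = channel_feature_set(DiscretizedRoi(lv.copy(), nb), "original")
        assert len(f1) == 47
        assert list(f1) == list(f2) and f1 == f2
        assert all(np.isfinite(v) for v in f1.values())

    def test_rotation_invariance_90deg(self, rng):
        """GLSZM/NGTDM are rotation invariant; the direction-summed
        GLCM/GLRLM features are invariant because the direction set is
        closed under 90-degree rotation."""
        for _ in range(10):
            lv, nb = random_roi(rng, max_side=6)
            if not (np.rot90(lv) > 0).sum() or (lv > 0).sum() < 4:
                continue
            try:
                f = channel_feature_set(DiscretizedRoi(lv, nb), "c")
                g = channel_feature_set(DiscretizedRoi(np.rot90(lv).copy(), nb), "c")
            except ValueError:
                continue
            for k in f:
                assert f[k] == pytest.approx(g[k], rel=1e-9), k

    def test_invariant_to_out_of_mask_values(self, rng):
        lv, nb = random_roi(rng)
        roi = DiscretizedRoi(lv, nb)
        f = channel_feature_set(roi, "c")
        # out-of-mask pixels are already 0 by construction; embedding the ROI
        # in a larger frame must not change anything
        big = np.zeros((lv.shape[0] + 4, lv.shape[1] + 4), dtype=np.int32)
        big[2:-2, 2:-2] = lv
        g = channel_feature_set(DiscretizedRoi(big, nb), "c")
        for k in f:
            assert f[k] == pytest.approx(g[k], rel=1e-12), k
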