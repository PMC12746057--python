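"""Discretization, first-order, shape and texture features: hand-computed
examples and small property checks (full brute-force oracle equivalence
lives in the acceptance suite)."""

import numpy as np
import pytest

from vsgrowth import radiomics as R

from oracles import ORACLES


def volume_1d(values):
    """Embed a 1D level sequence as a (1, 1, n) volume with full mask."""
    arr = np.asarray(values, dtype=np.int64)[None, None, :]
    return arr, np.ones_like(arr, dtype=bool)


class TestDiscretize:
    def test_constant_roi_maps_to_level_one(self):
        img = np.full((3, 3, 3), 7.0)
        mask = np.ones((3, 3, 3), bool)
        disc = R.discretize(img, mask, 0.5)
        assert (disc[mask] == 1).all()

    def test_hand_example(self):
        img = np.array([0.0, 0.9, 1.0, 2.5])[None, None, :]
        mask = np.ones_like(img, bool)
        disc = R.discretize(img, mask, 1.0)
        assert disc.ravel().tolist() == [1, 1, 2, 3]

    def test_shift_invariance(self):
        rng = np.random.default_rng(0)
        img = rng.normal(size=(4, 4, 4))
        mask = rng.random((4, 4, 4)) < 0.8
        a = R.discretize(img, mask, 0.3)
        b = R.discretize(img + 17.3, mask, 0.3)
        assert np.array_equal(a, b)

    def test_no_clipping_of_extremes(self):
        img = np.array([0.0, 100.0])[None, None, :]
        mask = np.ones_like(img, bool)
        assert R.discretize(img, mask, 1.0).max() == 101


class TestBinWidths:
    def test_single_patient(self):
        rule = R.fit_bin_widths({"t2": [np.array([0.0, 32.0])]}, 32)
        assert rule.widths["t2"] == pytest.approx(1.0)

    def test_mean_over_training_patients(self):
        rule = R.fit_bin_widths(
            {"t2": [np.array([0.0, 10.0]), np.array([5.0, 35.0])]}, 10)
        assert rule.widths["t2"] == pytest.approx(2.0)  # (10+30)/2/10

    def test_nonpositive_range_rejected(self):
        with pytest.raises(ValueError):
            R.fit_bin_widths({"t2": [np.array([3.0, 3.0])]}, 10)

    def test_n_bins_floor(self):
        with pytest.raises(ValueError):
            R.fit_bin_widths({"t2": [np.array([0.0, 1.0])]}, 1)


class TestFirstOrder:
    def test_hand_statistics(self):
        x = np.array([1.0, 2.0, 3.0])
        d = np.array([1, 2, 3])
        fo = R.first_order_features(x, d)
        assert fo["Mean"] == 2.0
        assert fo["Range"] == 2.0
        assert fo["Variance"] == pytest.approx(2.0 / 3.0)

    def test_robust_mad_of_constant_is_zero(self):
        x = np.full(10, 4.2)
        fo = R.first_order_features(x, np.ones(10, dtype=int))
        assert fo["RobustMeanAbsoluteDeviation"] == pytest.approx(0.0,
                                                                  abs=1e-12)

    def test_percentile_matches_sort_based_oracle(self):
        x = np.arange(1.0, 101.0)
        fo = R.first_order_features(x, np.ones(100, dtype=int))
        xs = np.sort(x)
        rank = 0.10 * (len(xs) - 1)
        lo = int(np.floor(rank))
        oracle = xs[lo] + (rank - lo) * (xs[lo + 1] - xs[lo])
        assert fo["Percentile10"] == pytest.approx(oracle)

    def test_entropy_uniformity_from_histogram(self):
        x = np.array([1.0, 1.0, 2.0, 2.0])
        d = np.array([1, 1, 2, 2])
        fo = R.first_order_features(x, d)
        assert fo["Entropy"] == pytest.approx(1.0)
        assert fo["Uniformity"] == pytest.approx(0.5)


class TestShape:
    def test_cube_volume_and_elongation(self):
        mask = np.zeros((14, 14, 14), bool)
        mask[2:12, 2:12, 2:12] = True
        sf = R.shape_features(mask, (1.0, 1.0, 1.0))
        assert sf["VoxelVolume"] == pytest.approx(1000.0)
        assert sf["Elongation"] == pytest.approx(1.0, abs=1e-9)
        assert sf["Flatness"] == pytest.approx(1.0, abs=1e-9)

    def test_ball_sphericity_near_one(self):
        r = 10
        g = np.mgrid[-12:13, -12:13, -12:13]
        mask = (g**2).sum(axis=0) <= r**2
        sf = R.shape_features(mask, (1.0, 1.0, 1.0))
        assert sf["Sphericity"] == pytest.approx(1.0, abs=0.05)
        assert sf["Maximum3DDiameter"] == pytest.approx(2 * r, rel=0.07)

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            R.shape_features(np.zeros((3, 3, 3), bool))


class TestGlcm:
    def test_single_direction_hand_enumeration(self):
        """[[1,1],[2,2]] along the within-row direction: two (1,2) pairs,
        symmetrised -> p(1,2)=p(2,1)=1/2, contrast = 1."""
        levels = np.array([[1, 1], [2, 2]])[:, :, None]
        p = R._glcm_single(levels, 2, (1, 0, 0))
        assert np.allclose(p, [[0.0, 0.5], [0.5, 0.0]])
        levels2 = levels.transpose(1, 0, 2)  # pairs (1,1) and (2,2)
        p2 = R._glcm_single(levels2, 2, (1, 0, 0))
        assert np.allclose(p2, [[0.5, 0.0], [0.0, 0.5]])

    def test_constant_image_degenerate_limits(self):
        levels = np.ones((3, 3, 3), dtype=np.int64)
        mask = np.ones((3, 3, 3), bool)
        f = R.glcm_features(levels, mask)
        assert f["Contrast"] == 0.0
        assert f["Id"] == 1.0
        assert f["Correlation"] == 1.0  # single-level convention

    def test_cluster_prominence_matches_direct_summation(self):
        rng = np.random.default_rng(2)
        levels = rng.integers(1, 4, (5, 5, 5))
        mask = np.ones((5, 5, 5), bool)
        f = R.glcm_features(levels, mask)
        oracle = ORACLES["glcm"](levels, mask)
        assert f["ClusterProminence"] == pytest.approx(
            oracle["ClusterProminence"], rel=1e-12)


class TestGlrlm:
    def test_runs_on_1d_row(self):
        levels, _ = volume_1d([1, 1, 1, 2])
        mat = R._run_length_matrix(levels, 2, (0, 0, 1))
        # runs: level 1 length 3, level 2 length 1
        assert mat[0, 2] == 1 and mat[1, 0] == 1 and mat.sum() == 2

    def test_constant_volume_single_run_per_line(self):
        levels = np.ones((1, 1, 7), dtype=np.int64)
        mat = R._run_length_matrix(levels, 1, (0, 0, 1))
        assert mat.sum() == 1 and mat[0, 6] == 1

    def test_srlgle_hand_value(self):
        levels, mask = volume_1d([1, 1, 2])
        feats = R._rlm_features_single(
            R._run_length_matrix(levels, 2, (0, 0, 1)), 3)
        # runs (g=1,l=2), (g=2,l=1): [1/(1*4) + 1/(4*1)] / 2 = 0.25
        assert feats["ShortRunLowGrayLevelEmphasis"] == pytest.approx(0.25)


class TestGlszm:
    def test_two_singleton_zones_glnn(self):
        levels = np.zeros((3, 3, 3), dtype=np.int64)
        mask = np.zeros((3, 3, 3), bool)
        levels[0, 0, 0], mask[0, 0, 0] = 1, True
        levels[2, 2, 2], mask[2, 2, 2] = 2, True
        f = R.glszm_features(levels, mask)
        assert f["GrayLevelNonUniformityNormalized"] == pytest.approx(0.5)

    def test_single_zone_glnn_is_one(self):
        levels = np.ones((2, 2, 2), dtype=np.int64)
        f = R.glszm_features(levels, np.ones((2, 2, 2), bool))
        assert f["GrayLevelNonUniformityNormalized"] == pytest.approx(1.0)

    def test_zone_count_matches_flood_fill_oracle(self):
        from oracles import flood_fill_zones

        rng = np.random.default_rng(9)
        for _ in range(5):
            levels = rng.integers(1, 4, (6, 6, 6))
            mask = rng.random((6, 6, 6)) < 0.6
            lv = np.where(mask, levels, 0)
            if not mask.any():
                continue
            mat = R._size_zone_matrix(lv, int(lv.max()))
            assert mat.sum() == len(flood_fill_zones(lv, mask))


class TestNgtdm:
    def test_constant_volume_capped_coarseness_zero_contrast(self):
        levels = np.ones((3, 3, 3), dtype=np.int64)
        f = R.ngtdm_features(levels, np.ones((3, 3, 3), bool))
        assert f["Coarseness"] == R.COARSENESS_CAP
        assert f["Contrast"] == 0.0

    def test_neighbourhood_sums_match_hand_enumeration(self):
        levels = np.array([[1, 1, 2], [2, 2, 2], [1, 1, 1]])[:, :, None]
        mask = np.ones_like(levels, dtype=bool)
        f = R.ngtdm_features(levels, mask)
        # hand-enumerate s(i) = sum over voxels of |level - mean(neighbours)|
        s = {1: 0.0, 2: 0.0}
        for i in range(3):
            for j in range(3):
                nbrs = [levels[a, b, 0]
                        for a in range(max(0, i - 1), min(3, i + 2))
                        for b in range(max(0, j - 1), min(3, j + 2))
                        if (a, b) != (i, j)]
                g = levels[i, j, 0]
                s[int(g)] += abs(g - sum(nbrs) / len(nbrs))
        n1 = int((levels == 1).sum())
        n2 = int((levels == 2).sum())
        p1, p2 = n1 / 9, n2 / 9
        coarse = 1.0 / (p1 * s[1] + p2 * s[2])
        assert f["Coarseness"] == pytest.approx(coarse, rel=1e-12)


class TestGldm:
    def test_constant_cube_dependences_equal_neighbour_counts(self):
        levels = np.ones((3, 3, 3), dtype=np.int64)
        mask = np.ones((3, 3, 3), bool)
        f = R.gldm_features(levels, mask)
        # every voxel depends on all its in-volume 26-neighbours:
        # 8 corners (7), 12 edge mids (11), 6 face mids (17), 1 centre (26)
        counts = {7: 8, 11: 12, 17: 6, 26: 1}
        lde = sum(n * (c + 1) ** 2 for c, n in counts.items()) / 27
        assert f["LargeDependenceEmphasis"] == pytest.approx(lde)

    def test_single_voxel_has_zero_dependence(self):
        levels = np.zeros((3, 3, 3), dtype=np.int64)
        mask = np.zeros((3, 3, 3), bool)
        levels[1, 1, 1], mask[1, 1, 1] = 1, True
        f = R.gldm_features(levels, mask)
        assert f["SmallDependenceEmphasis"] == pytest.approx(1.0)  # j = 1
        assert f["LargeDependenceEmphasis"] == pytest.approx(1.0)


class TestExtractVector:
    @pytest.fixture()
    def patient(self, cohort20):
        return cohort20[0]

    def _rule(self, patient):
        vals = {ch: [img[patient.roi_mask]]
                for ch, img in {"t2": patient.t2_image,
                                "ktrans": patient.maps.ktrans,
                                "ve": patient.maps.ve,
                                "vp": patient.maps.vp}.items()}
        return R.fit_bin_widths(vals, 32)

    def test_vector_has_404_named_elements(self, patient):
        rule = self._rule(patient)
        vec = R.extract_vector({"t2": patient.t2_image,
                                "ktrans": patient.maps.ktrans,
                                "ve": patient.maps.ve,
                                "vp": patient.maps.vp},
                               patient.roi_mask, rule, patient.spacing_mm)
        assert list(vec) == R.feature_names()
        assert len(vec) == 404
        assert all(np.isfinite(v) for v in vec.values())

    def test_missing_channel_listed_in_error(self, patient):
        rule = self._rule(patient)
        with pytest.raises(ValueError, match="ktrans"):
            R.extract_vector({"t2": patient.t2_image,
                              "ve": patient.maps.ve,
                              "vp": patient.maps.vp},
                             patient.roi_mask, rule)

    def test_determinism_bit_for_bit(self, patient):
        rule = self._rule(patient)
        chans = {"t2": patient.t2_image, "ktrans": patient.maps.ktrans,
                 "ve": patient.maps.ve, "vp": patient.maps.vp}
        v1 = R.extract_vector(chans, patient.roi_mask, rule,
                              patient.spacing_mm)
        v2 = R.extract_vector(chans, patient.roi_mask, rule,
                              patient.spacing_mm)
        assert v1 == v2

    def test_texture_features_shift_invariant(self, patient):
        rule = self._rule(patient)
        chans = {"t2": patient.t2_image, "ktrans": patient.maps.ktrans,
                 "ve": patient.maps.ve, "vp": patient.maps.vp}
        shifted = dict(chans, t2=chans["t2"] + 5.0)
        v1 = R.extract_vector(chans, patient.roi_mask, rule,
                              patient.spacing_mm)
        v2 = R.extract_vector(shifted, patient.roi_mask, rule,
                              patient.spacing_mm)
        for fam in ("glcm", "glrlm", "glszm", "ngtdm", "gldm"):
            for name in dict(R.FAMILIES)[fam]:
                assert v1[f"t2_{fam}_{name}"] == v2[f"t2_{fam}_{name}"]
        assert v2["t2_firstorder_Mean"] == pytest.approx(
            v1["t2_firstorder_Mean"] + 5.0)
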