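import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from skimage.draw import ellipse

from nucleoscore import features as F
from nucleoscore import segmentation


def _rgb(value, shape=(5, 5)):
    return np.full((*shape, 3), value, dtype=np.uint8)


class TestGrayscale:
    @pytest.mark.parametrize(
        "pixel,expected",
        [((255, 255, 255), 255.0), ((0, 0, 0), 0.0), ((100, 100, 100), 100.0)],
    )
    def test_reference_points(self, pixel, expected):
        img = np.zeros((1, 1, 3), dtype=np.uint8)
        img[0, 0] = pixel
        assert F.to_grayscale(img)[0, 0] == pytest.approx(expected)


class TestRingZones:
    def test_three_by_three_square(self):
        z = F.ring_zones(np.ones((3, 3), dtype=bool))
        sizes = [(z == i).sum() for i in (1, 2, 3)]
        assert sizes == [3, 3, 3]
        assert z[1, 1] == 3  # deepest pixel is in the center zone

    def test_zone_sizes_balanced_on_disks(self):
        for radius in (4, 7, 10, 13):
            mask = np.zeros((30, 30), dtype=bool)
            rr, cc = ellipse(15, 15, radius, radius)
            mask[rr, cc] = True
            z = F.ring_zones(mask)
            sizes = sorted((z == i).sum() for i in (1, 2, 3))
            assert sizes[-1] - sizes[0] <= 1
            assert sum(sizes) == mask.sum()

    def test_depth_ordering_on_disk(self):
        mask = np.zeros((25, 25), dtype=bool)
        rr, cc = ellipse(12, 12, 10, 10)
        mask[rr, cc] = True
        z = F.ring_zones(mask)
        from scipy.ndimage import distance_transform_edt

        dist = distance_transform_edt(np.pad(mask, 1))[1:-1, 1:-1]
        means = [dist[z == i].mean() for i in (1, 2, 3)]
        assert means[0] < means[1] < means[2]  # border < middle < center

    def test_tiny_mask_rejected(self):
        with pytest.raises(ValueError):
            F.ring_zones(np.array([[True, True]]))


class TestColorFeatures:
    def test_constant_nucleus(self):
        mask = np.zeros((7, 7), dtype=bool)
        mask[1:6, 1:6] = True
        out = F.color_features(_rgb(100, (7, 7)), mask)
        assert len(out) == 23
        assert set(out) == set(F.COLOR_FEATURES)
        for c in ("r", "g", "b", "gray"):
            assert out[f"std_{c}"] == 0.0
            assert out[f"ratio_border_middle_{c}"] == 1.0
            assert out[f"ratio_border_center_{c}"] == 1.0
        assert out["shannon_entropy"] == pytest.approx(0.0)
        assert out["glcm_contrast"] == 0.0
        assert out["glcm_correlation"] == 0.0  # defined for single-valued crops

    def test_two_level_histogram(self):
        crop = np.stack([np.array([[0, 0], [255, 255]], dtype=np.uint8)] * 3, axis=-1)
        out = F.color_features(crop, np.ones((2, 2), dtype=bool))
        assert out["shannon_entropy"] == pytest.approx(1.0)
        assert out["mean_gray"] == pytest.approx(127.5)

    def test_only_masked_pixels_enter_statistics(self, rng):
        crop = rng.integers(0, 255, (9, 9, 3)).astype(np.uint8)
        mask = np.zeros((9, 9), dtype=bool)
        mask[2:7, 2:7] = True
        poisoned = crop.copy()
        poisoned[~mask] = 255  # out-of-mask pixels must not matter
        a = F.color_features(crop, mask)
        b = F.color_features(poisoned, mask)
        for k in F.COLOR_FEATURES:
            assert a[k] == pytest.approx(b[k], abs=1e-12)

    def test_zone_ratios_scale_invariant(self, rng):
        crop = rng.integers(10, 120, (15, 15, 3)).astype(np.uint8)
        mask = np.zeros((15, 15), dtype=bool)
        mask[2:13, 2:13] = True
        a = F.color_features(crop, mask)
        b = F.color_features((crop.astype(int) * 2).astype(np.uint8), mask)
        for k in (k for k in F.COLOR_FEATURES if k.startswith("ratio")):
            assert a[k] == pytest.approx(b[k], abs=1e-9)


class TestShapeFeatures:
    def test_disk_is_round_and_solid(self):
        mask = np.zeros((40, 40), dtype=bool)
        rr, cc = ellipse(20, 20, 10, 10)
        mask[rr, cc] = True
        out = F.shape_features(mask)
        assert len(out) == 4
        assert out["eccentricity"] < 0.1
        assert out["solidity"] > 0.95
        assert out["area"] == mask.sum()

    def test_two_to_one_ellipse_eccentricity(self):
        mask = np.zeros((120, 120), dtype=bool)
        rr, cc = ellipse(60, 60, 40, 20)
        mask[rr, cc] = True
        out = F.shape_features(mask)
        assert out["eccentricity"] == pytest.approx(np.sqrt(1 - 0.25), abs=0.02)

    def test_single_pixel_degenerate(self):
        mask = np.zeros((3, 3), dtype=bool)
        mask[1, 1] = True
        out = F.shape_features(mask)
        assert out["eccentricity"] == 0.0
        assert out["solidity"] == 1.0
        assert np.isfinite(out["perimeter"])


class TestSpatialFeatures:
    def test_mean_radius_unit_disk(self):
        assert F.mean_radius([np.pi]) == pytest.approx(1.0)

    def test_mean_radius_two_disks(self):
        assert F.mean_radius([np.pi, 4 * np.pi]) == pytest.approx(1.5)

    def test_mean_radius_matches_loop_oracle(self, rng):
        areas = rng.uniform(10, 900, size=100)
        acc = 0.0
        for a in areas:  # direct summation oracle
            acc += np.sqrt(a / np.pi)
        assert F.mean_radius(areas) == pytest.approx(acc / 100, abs=1e-12)

    def test_single_nucleus_crowding_zero(self):
        assert (F.crowding([(5.0, 5.0)], 2.0) == 0).all()

    def test_two_nuclei_radius_bracketing(self):
        counts = F.crowding([(0, 0), (0, 10)], r_mean=1.0)
        by_x = dict(zip(F.CROWDING_MULTIPLIERS, counts[0]))
        assert by_x[9] == 0 and by_x[15] == 1
        assert (counts[0] == counts[1]).all()

    def test_crowding_matches_brute_force(self, rng):
        pts = rng.uniform(0, 200, size=(60, 2))
        r_mean = 4.0
        counts = F.crowding(pts, r_mean)
        for i in range(len(pts)):
            for j, x in enumerate(F.CROWDING_MULTIPLIERS):
                brute = sum(
                    1
                    for k in range(len(pts))
                    if k != i and np.hypot(*(pts[k] - pts[i])) <= x * r_mean
                )
                assert counts[i, j] == brute

    @settings(deadline=None, max_examples=30)
    @given(
        st.lists(
            st.tuples(
                st.floats(0, 100, allow_nan=False), st.floats(0, 100, allow_nan=False)
            ),
            min_size=1,
            max_size=15,
        )
    )
    def test_crowding_monotone_in_radius(self, pts):
        counts = F.crowding(pts, r_mean=2.5)
        assert (np.diff(counts, axis=1) >= 0).all()

    def test_nn_distance_345(self):
        assert F.nn_distance([(0, 0), (3, 4)]) == pytest.approx([5.0, 5.0])

    def test_nn_distance_collinear(self):
        out = F.nn_distance([(0, 0), (0, 1), (0, 10)])
        assert out == pytest.approx([1.0, 1.0, 9.0])

    def test_nn_distance_matches_brute_force(self, rng):
        pts = rng.uniform(0, 500, size=(200, 2))
        out = F.nn_distance(pts)
        for i in range(200):
            d = [np.hypot(*(pts[j] - pts[i])) for j in range(200) if j != i]
            assert out[i] == pytest.approx(min(d), abs=1e-9)

    def test_single_nucleus_nn_is_na(self):
        assert np.isnan(F.nn_distance([(1.0, 1.0)]))[()]


class TestExtractAll:
    def test_canonical_36_columns(self, single_image):
        img, lm = single_image
        seg = segmentation.extract_nuclei(img, lm)
        table = F.extract_all(seg, img)
        assert list(table.columns) == ["nucleus_id", *F.ALL_FEATURES]
        assert len(F.ALL_FEATURES) == 36
        assert len(F.COLOR_FEATURES) == 23
        assert len(F.SHAPE_FEATURES) == 4
        assert len(F.SPATIAL_FEATURES) == 9

    def test_deterministic(self, single_image):
        img, lm = single_image
        seg = segmentation.extract_nuclei(img, lm)
        a = F.extract_all(seg, img)
        b = F.extract_all(seg, img)
        assert a.equals(b)

    def test_translation_invariance(self, single_image):
        img, lm = single_image
        seg = segmentation.extract_nuclei(img, lm)
        a = F.extract_all(seg, img)
        pimg = np.pad(img, ((13, 0), (7, 0), (0, 0)), constant_values=240)
        plm = np.pad(lm, ((13, 0), (7, 0)))
        b = F.extract_all(segmentation.extract_nuclei(pimg, plm), pimg)
        va = a[list(F.ALL_FEATURES)].to_numpy()
        vb = b[list(F.ALL_FEATURES)].to_numpy()
        assert np.allclose(va, vb, atol=1e-9, equal_nan=True)

    def test_rotation_invariant_subset(self, single_image):
        # GLCM props survive 90-degree rotation only because the four
        # principal offset directions are averaged
        img, lm = single_image
        a = F.extract_all(segmentation.extract_nuclei(img, lm), img)
        rimg, rlm = np.rot90(img).copy(), np.rot90(lm).copy()
        b = F.extract_all(segmentation.extract_nuclei(rimg, rlm), rimg)
        cols = (
            ["area", "solidity", "shannon_entropy", "nn_distance"]
            + [f"crowd_x{x}" for x in F.CROWDING_MULTIPLIERS]
            + [c for c in F.COLOR_FEATURES if c.startswith("glcm")]
        )
        va = a.sort_values("nucleus_id")[cols].to_numpy()
        vb = b.sort_values("nucleus_id")[cols].to_numpy()
        assert np.allclose(va, vb, atol=1e-9, equal_nan=True)

    def test_empty_segmentation_gives_empty_table(self):
        img = np.zeros((10, 10, 3), dtype=np.uint8)
        seg = segmentation.extract_nuclei(img, np.zeros((10, 10), np.int64))
        table = F.extract_all(seg, img)
        assert len(table) == 0
        assert list(table.columns) == ["nucleus_id", *F.ALL_FEATURES]


class TestClassSeparation:
    def test_ptc_class_larger_and_less_solid(self, nucleus_table, small_dataset):
        labels = {
            p.patient_id: p.class_label.value for p in small_dataset.patients
        }
        grp = nucleus_table.assign(
            cls=nucleus_table["patient_id"].map(labels)
        )
        ptc = grp[grp["cls"] == "PTC"]
        non = grp[grp["cls"] == "nonPTC"]
        assert len(ptc) >= 50 and len(non) >= 50
        t_area = stats.ttest_ind(ptc["area"], non["area"], equal_var=False)
        t_sol = stats.ttest_ind(non["solidity"], ptc["solidity"], equal_var=False)
        assert ptc["area"].mean() > non["area"].mean()
        assert ptc["solidity"].mean() < non["solidity"].mean()
        assert t_area.pvalue < 0.01
        assert t_sol.pvalue < 0.01
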