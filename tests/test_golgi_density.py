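"""Cell-culture Golgi-density workflow: primitives vs brute-force oracles
and end-to-end behaviour on planted ground truth."""

import numpy as np
import pytest

from grasptools import golgi_density as gd
from grasptools import synthetic as syn
from grasptools.datatypes import CalibratedImage

import oracles


@pytest.fixture
def two_channel_image():
    chans = {
        "dapi": np.pad(np.full((4, 4), 500.0), 2),
        "golgi": np.pad(np.full((2, 2), 900.0), 3),
    }
    return CalibratedImage(chans, pixel_size_um=0.1)


class TestSplitChannels:
    def test_split_returns_arrays_unmodified(self, two_channel_image):
        out = gd.split_channels(two_channel_image)
        assert set(out) == {"dapi", "golgi"}
        np.testing.assert_array_equal(out["dapi"], two_channel_image.channel("dapi"))

    def test_missing_channel_lists_available(self, two_channel_image):
        with pytest.raises(KeyError, match="dapi"):
            gd.split_channels(two_channel_image, "gm130")

    def test_round_trip_restack(self, two_channel_image):
        out = gd.split_channels(two_channel_image)
        rebuilt = CalibratedImage(out, two_channel_image.pixel_size_um)
        for name in out:
            np.testing.assert_array_equal(
                rebuilt.channel(name), two_channel_image.channel(name)
            )


class TestMedianSmooth:
    def test_constant_image_unchanged(self):
        img = np.full((9, 9), 7.0)
        np.testing.assert_array_equal(gd.median_smooth(img), img)

    def test_hot_pixel_removed(self):
        img = np.full((9, 9), 10.0)
        img[4, 4] = 10_000.0
        assert gd.median_smooth(img, 3)[4, 4] == 10.0

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError, match="odd"):
            gd.median_smooth(np.zeros((5, 5)), kernel_px=4)

    @pytest.mark.parametrize("kernel", [3, 5])
    def test_matches_naive_sliding_window(self, kernel):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 1000, (32, 32))
        np.testing.assert_allclose(
            gd.median_smooth(img, kernel), oracles.naive_median_filter(img, kernel)
        )


class TestBinarize:
    def test_bimodal_exact(self):
        img = np.zeros((10, 10))
        img[2:5, 2:5] = 1000.0
        np.testing.assert_array_equal(gd.binarize_golgi(img), img == 1000.0)

    def test_constant_rejected(self):
        with pytest.raises(ValueError, match="constant"):
            gd.binarize_golgi(np.full((5, 5), 3.0))
        with pytest.raises(ValueError, match="constant"):
            gd.binarize_nucleus(np.full((5, 5), 3.0))

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_otsu_matches_exhaustive_search(self, seed):
        rng = np.random.default_rng(seed)
        img = np.concatenate(
            [rng.normal(100, 20, 600), rng.normal(700, 50, 400)]
        ).reshape(40, 25)
        from skimage.filters import threshold_otsu

        t_pkg = threshold_otsu(img, nbins=256)
        t_ref = oracles.exhaustive_otsu(img, nbins=256)
        # both thresholds must achieve the exhaustive-search maximum of the
        # between-class variance (the criterion can plateau over empty bins,
        # so thresholds inside the plateau are equivalent)
        v_pkg = oracles.pixel_between_class_variance(img, t_pkg)
        v_ref = oracles.pixel_between_class_variance(img, t_ref)
        assert v_pkg == pytest.approx(v_ref, rel=1e-9)
        np.testing.assert_array_equal(gd.binarize_golgi(img), img > t_pkg)

    def test_inverted_image_complementary_mask(self):
        rng = np.random.default_rng(3)
        img = np.concatenate([rng.normal(100, 10, 500), rng.normal(900, 10, 500)]).reshape(25, 40)
        m = gd.binarize_golgi(img)
        m_inv = gd.binarize_golgi(img.max() - img)
        # complementary up to pixels landing on threshold-bin ties
        disagreement = np.mean(m == m_inv)
        assert disagreement < 0.01

    def test_nucleus_floor_threshold_is_strict(self):
        img = np.full((6, 6), 10.0)
        img[2:4, 2:4] = 500.0
        mask = gd.binarize_nucleus(img)
        assert mask.sum() == 4
        assert not mask[0, 0]

    def test_floor_mask_contains_otsu_mask(self):
        rng = np.random.default_rng(4)
        img = np.concatenate([rng.uniform(0, 50, 500), rng.uniform(500, 900, 500)]).reshape(25, 40)
        assert np.all(gd.binarize_golgi(img) <= gd.binarize_nucleus(img))


class TestFillHoles:
    def test_interior_hole_filled(self):
        mask = np.zeros((14, 14), dtype=bool)
        mask[2:12, 2:12] = True
        mask[6:8, 6:8] = False
        filled = gd.fill_holes(mask)
        assert filled.sum() == 100

    def test_border_concavity_untouched(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[3:7, 0:8] = True
        mask[4:6, 0:5] = False  # notch open to the border
        np.testing.assert_array_equal(gd.fill_holes(mask), mask)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3])
    def test_matches_flood_fill_oracle(self, seed):
        rng = np.random.default_rng(seed)
        mask = rng.random((32, 32)) < 0.45
        np.testing.assert_array_equal(gd.fill_holes(mask), oracles.flood_fill_holes(mask))


class TestAssignment:
    def test_single_cell(self):
        nuc = np.zeros((20, 20), dtype=bool)
        nuc[2:6, 2:6] = True
        gol = np.zeros((20, 20), dtype=bool)
        gol[8:10, 8:10] = True
        _, _, cells = gd.assign_golgi_to_cells(gol, nuc)
        assert cells.tolist() == [1]

    def test_no_nuclei_error(self):
        with pytest.raises(ValueError, match="nucleus"):
            gd.assign_golgi_to_cells(np.ones((5, 5), bool), np.zeros((5, 5), bool))

    def test_nearest_centroid_brute_force(self):
        rng = np.random.default_rng(5)
        nuc = np.zeros((60, 60), dtype=bool)
        centers = [(10, 10), (10, 50), (50, 30)]
        for r, c in centers:
            nuc[r - 2 : r + 3, c - 2 : c + 3] = True
        gol = np.zeros((60, 60), dtype=bool)
        spots = [(20, 12), (18, 45), (40, 28), (55, 55)]
        for r, c in spots:
            gol[r, c] = True
        from skimage.measure import label, regionprops

        _, nuc_labels, cells = gd.assign_golgi_to_cells(gol, nuc)
        nuc_centroids = {p.label: np.array(p.centroid) for p in regionprops(nuc_labels)}
        gol_labels = label(gol, connectivity=2)
        for p, assigned in zip(regionprops(gol_labels), cells):
            dists = {
                lab: np.linalg.norm(np.array(p.centroid) - cen)
                for lab, cen in nuc_centroids.items()
            }
            assert assigned == min(dists, key=dists.get)


class TestComputeDensity:
    def test_solid_golgi_density_one(self):
        mask = np.zeros((10, 10), dtype=bool)
        mask[2:8, 2:8] = True
        rec = gd.compute_density(mask, mask, nucleus_area_um2=10.0, pixel_size_um=0.1)
        assert rec.density == 1.0

    def test_ratio_96_over_100(self):
        filled = np.zeros((20, 20), dtype=bool)
        filled[0:10, 0:10] = True
        stack = filled.copy()
        stack[4:6, 4:6] = False
        rec = gd.compute_density(stack, filled, 10.0, 0.1)
        assert rec.density == pytest.approx(0.96)
        assert rec.golgi_to_nucleus_ratio == pytest.approx(100 * 0.01 / 10.0)

    def test_empty_golgi_flagged_invalid_not_nan(self):
        empty = np.zeros((5, 5), dtype=bool)
        rec = gd.compute_density(empty, empty, 10.0, 0.1)
        assert not rec.valid
        assert np.isfinite(rec.density)


class TestCompareGroups:
    def test_identical_groups(self):
        assert gd.compare_groups([1, 2, 3], [1, 2, 3]) == (0.0, 1.0)

    def test_clear_separation(self):
        t, p = gd.compare_groups([1.0, 2.0, 3.0], [11.0, 12.0, 13.0])
        assert abs(t) > 8
        assert p < 0.001

    def test_matches_textbook_pooled_formula(self):
        a, b = (2.1, 2.5, 2.3), (1.1, 1.4, 1.2)
        t, p = gd.compare_groups(a, b)
        t_ref, dof = oracles.pooled_t_statistic(a, b)
        assert t == pytest.approx(t_ref, abs=1e-12)
        assert dof == 4

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError, match="two"):
            gd.compare_groups([1.0], [1.0, 2.0])


class TestPipeline:
    def test_solid_fragment_density_one_and_area_recovered(self):
        img, gt = syn.gen_cell_image(3, 1, 4.0, 0.1, noise_sd=0.0, seed=11)
        records = gd.analyze_image(img)
        assert len(records) == 3
        planted = gt.per_fragment_area_um2[0]
        for rec in records:
            assert rec.density == 1.0
            assert abs(rec.golgi_total_area_um2 - planted) / planted < 0.10

    def test_density_decreases_with_fragmentation(self):
        means = []
        for frags in (1, 4, 16):
            densities = []
            for seed in range(10):
                img, _ = syn.gen_cell_image(2, frags, 4.0 / frags, 0.1, seed=seed)
                densities += [r.density for r in gd.analyze_image(img)]
            assert len(densities) >= 20
            means.append(np.mean(densities))
        assert means[0] > means[1] > means[2]

    def test_intensity_scaling_invariance(self):
        img, _ = syn.gen_cell_image(2, 4, 1.0, 0.1, noise_sd=20.0, seed=13)
        scaled = CalibratedImage(
            {"dapi": img.channel("dapi"), "golgi": img.channel("golgi") * 3.7},
            img.pixel_size_um,
        )
        rec_a = gd.analyze_image(img)
        rec_b = gd.analyze_image(scaled)
        assert [r.density for r in rec_a] == pytest.approx([r.density for r in rec_b])

    def test_measured_areas_equal_brute_force_pixel_counts(self):
        img, _ = syn.gen_cell_image(2, 2, 2.0, 0.1, seed=17)
        smoothed = gd.median_smooth(img.channel("golgi"))
        filled = gd.fill_holes(gd.binarize_golgi(smoothed))
        from skimage.measure import label, regionprops

        areas_pkg = sorted(p.area for p in regionprops(label(filled, connectivity=2)))
        assert areas_pkg == oracles.component_areas_bruteforce(filled)
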