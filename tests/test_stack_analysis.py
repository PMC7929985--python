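"""Tests of the image-processing chain: thresholding, cleaning, nucleus
detection, internuclear distances and thickness estimation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import spearmanr

from ccm3d import (
    ImageStack,
    StackSpec,
    binarize_stack,
    coefficient_of_variation,
    cv_percent,
    detect_nuclei,
    estimate_thickness,
    min_internuclear_distances,
    remove_small_areas,
)
from ccm3d.synthetic import _sample_centers

from conftest import brute_force_min_distances


def _stack(vox, px=1.0, dz=1.0, channel="nuclei"):
    return ImageStack(voxels=np.asarray(vox, dtype=float), pixel_size_um=px,
                      z_step_um=dz, channel=channel)


class TestBinarize:
    def test_two_level_image_fixed_threshold(self):
        vox = np.full((2, 4, 4), 10.0)
        vox[0, 1, 1] = 200.0
        mask, thr = binarize_stack(_stack(vox), 100.0)
        assert thr == 100.0
        assert mask.sum() == 1 and mask[0, 1, 1]

    def test_all_zero_stack_fixed_threshold(self):
        mask, _ = binarize_stack(_stack(np.zeros((3, 5, 5))), 1.0)
        assert not mask.any()

    def test_constant_stack_automatic_threshold_errors(self):
        with pytest.raises(ValueError, match="constant"):
            binarize_stack(_stack(np.full((2, 4, 4), 7.0)), "otsu")

    def test_unknown_policy_errors(self):
        with pytest.raises(ValueError, match="unknown threshold policy"):
            binarize_stack(_stack(np.zeros((1, 2, 2))), "quantile")

    def test_otsu_recovers_sphere_volume_on_synthetic_stack(self, small_stack):
        spec, nuclei, _, truth = small_stack
        mask, _ = binarize_stack(nuclei, "otsu")
        # ground-truth foreground volume: voxels within one radius of a centre
        nz, ny, nx = nuclei.shape
        zz = np.arange(nz)[:, None, None] * spec.z_step_um
        yy = np.arange(ny)[None, :, None] * spec.pixel_size_um
        xx = np.arange(nx)[None, None, :] * spec.pixel_size_um
        true_vox = np.zeros(nuclei.shape, dtype=bool)
        for cx, cy, cz in truth.centroids_um:
            true_vox |= (
                (zz - cz) ** 2 + (yy - cy) ** 2 + (xx - cx) ** 2
            ) <= spec.nucleus_radius_um**2
        assert mask.sum() == pytest.approx(true_vox.sum(), rel=0.20)


class TestRemoveSmallAreas:
    def test_small_square_removed_large_kept(self):
        sl = np.zeros((1, 12, 12), dtype=bool)
        sl[0, 1:3, 1:3] = True    # 2x2, area 4
        sl[0, 5:9, 5:9] = True    # 4x4, area 16
        out = remove_small_areas(sl, min_area_px=9)
        assert out.sum() == 16
        assert out[0, 5:9, 5:9].all()

    def test_boundary_area_exactly_nine_is_kept(self):
        sl = np.zeros((1, 10, 10), dtype=bool)
        sl[0, 2:5, 2:5] = True    # exactly 9 px
        assert remove_small_areas(sl, min_area_px=9).sum() == 9

    def test_empty_mask_identity(self):
        empty = np.zeros((3, 6, 6), dtype=bool)
        assert not remove_small_areas(empty, 9).any()

    def test_cleaning_is_per_slice(self):
        # a 3x3 column spanning 2 slices: each slice has area 9, both kept
        vol = np.zeros((2, 8, 8), dtype=bool)
        vol[:, 2:5, 2:5] = True
        assert remove_small_areas(vol, 9).sum() == 18
        # per-slice area 4 removed even though 3D volume is 8
        vol2 = np.zeros((2, 8, 8), dtype=bool)
        vol2[:, 2:4, 2:4] = True
        assert not remove_small_areas(vol2, 9).any()


class TestDetectNuclei:
    def test_single_sphere_centroid_within_one_voxel(self):
        spec = StackSpec(
            field_size_um=100, pixel_size_um=0.5, slab_thickness_um=100,
            n_nuclei=0, noise_sd=0.0, z_margin_um=10.0, seed=0,
        )
        # build one noise-free sphere at (50, 50, 60) um by hand
        nz = int(round(120 / spec.z_step_um))
        n = int(round(100 / 0.5))
        zz = np.arange(nz)[:, None, None] * 1.0
        yy = np.arange(n)[None, :, None] * 0.5
        xx = np.arange(n)[None, None, :] * 0.5
        vox = 100.0 * (((zz - 60) ** 2 + (yy - 50) ** 2 + (xx - 50) ** 2) <= 25.0)
        ns = detect_nuclei(vox > 50, 0.5, 1.0)
        assert len(ns) == 1
        assert np.allclose(ns.centroids_um[0], (50, 50, 60), atol=1.0)

    def test_recovers_all_generated_nuclei(self, small_stack):
        spec, nuclei, _, truth = small_stack
        mask, thr = binarize_stack(nuclei, "otsu")
        mask = remove_small_areas(mask, 9)
        ns = detect_nuclei(mask, spec.pixel_size_um, spec.z_step_um, source_threshold=thr)
        assert len(ns) == spec.n_nuclei
        # greedy match: each detection within 1 um of a distinct truth centre
        from scipy.spatial.distance import cdist

        d = cdist(ns.centroids_um, truth.centroids_um)
        assert d.min(axis=1).max() < 1.0
        assert len(np.unique(d.argmin(axis=1))) == spec.n_nuclei

    def test_touching_spheres_merge_into_one_component(self):
        vol = np.zeros((9, 21, 21), dtype=bool)
        zz = np.arange(9)[:, None, None]
        yy = np.arange(21)[None, :, None]
        xx = np.arange(21)[None, None, :]
        # two overlapping spheres, separation < 2r
        for cx in (8, 13):
            vol |= ((zz - 4) ** 2 + (yy - 10) ** 2 + (xx - cx) ** 2) <= 16
        ns = detect_nuclei(vol, 1.0, 1.0)
        assert len(ns) == 1  # documented limitation: no watershed splitting

    def test_empty_mask_gives_empty_set(self):
        ns = detect_nuclei(np.zeros((4, 5, 5), dtype=bool), 1.0, 1.0)
        assert len(ns) == 0
        assert ns.per_depth_counts.tolist() == [0, 0, 0, 0]

    def test_per_depth_counts_by_centroid_slice(self):
        vol = np.zeros((6, 10, 10), dtype=bool)
        vol[1, 2:4, 2:4] = True      # centroid in slice 1
        vol[3:6, 6:8, 6:8] = True    # centroid in slice 4
        ns = detect_nuclei(vol, 1.0, 1.0)
        assert ns.per_depth_counts.tolist() == [0, 1, 0, 0, 1, 0]
        assert ns.per_depth_counts.sum() == len(ns)

    def test_doubling_pixel_size_doubles_xy_components(self):
        vol = np.zeros((4, 10, 10), dtype=bool)
        vol[1, 2:5, 3:6] = True
        a = detect_nuclei(vol, 0.5, 1.0).centroids_um[0]
        b = detect_nuclei(vol, 1.0, 1.0).centroids_um[0]
        assert b[0] == pytest.approx(2 * a[0]) and b[1] == pytest.approx(2 * a[1])
        assert b[2] == pytest.approx(a[2])

    def test_invalid_connectivity(self):
        with pytest.raises(ValueError, match="connectivity"):
            detect_nuclei(np.zeros((2, 2, 2), dtype=bool), 1.0, 1.0, connectivity=4)


class TestMinDistances:
    def test_two_points(self):
        s = min_internuclear_distances(np.array([[0, 0, 0], [10, 0, 0]], float))
        assert np.allclose(s.min_distances_um, [10, 10])
        assert s.median_um == 10

    def test_three_collinear_points(self):
        s = min_internuclear_distances(np.array([[0, 0, 0], [10, 0, 0], [25, 0, 0]], float))
        assert np.allclose(np.sort(s.min_distances_um), [10, 10, 15])
        assert s.median_um == 10

    def test_matches_brute_force_oracle_on_random_points(self):
        pts = np.random.default_rng(42).uniform(0, 200, size=(500, 3))
        s = min_internuclear_distances(pts)
        assert np.allclose(s.min_distances_um, brute_force_min_distances(pts), atol=0)

    def test_fewer_than_two_points_errors(self):
        with pytest.raises(ValueError, match="at least 2"):
            min_internuclear_distances(np.array([[1.0, 2.0, 3.0]]))

    def test_by_depth_medians(self):
        pts = np.array([[0, 0, 2], [3, 0, 2], [0, 0, 15], [4, 0, 15]], float)
        s = min_internuclear_distances(pts, z_bin_um=10)
        assert s.by_depth[5.0] == 3.0
        assert s.by_depth[15.0] == 4.0

    def test_all_entries_positive(self, small_stack):
        _, _, _, truth = small_stack
        s = min_internuclear_distances(truth.centroids_um)
        assert (s.min_distances_um > 0).all()
        assert len(s.min_distances_um) == len(truth.centroids_um)


class TestThickness:
    def test_noise_free_slab(self):
        vox = np.full((141, 8, 8), 5.0)
        vox[10:130] = 80.0   # 120 slices of signal
        est = estimate_thickness(_stack(vox, channel="collagen"))
        assert abs(est.thickness_um - 120.0) <= 1.0
        assert est.z_low_um == pytest.approx(10.0, abs=1.0)

    def test_uniform_signal_full_extent(self):
        vox = np.full((50, 6, 6), 30.0)
        est = estimate_thickness(_stack(vox, channel="collagen"))
        assert est.thickness_um == 50.0

    def test_noisy_slab_within_two_slices(self, small_stack):
        spec, _, collagen, truth = small_stack
        est = estimate_thickness(collagen)
        assert abs(est.thickness_um - spec.slab_thickness_um) <= 2 * spec.z_step_um

    def test_no_detectable_signal_errors(self):
        rng = np.random.default_rng(0)
        vox = np.clip(10 + rng.normal(0, 1, size=(30, 8, 8)), 0, None)
        with pytest.raises(ValueError, match="detectability"):
            estimate_thickness(_stack(vox, channel="collagen"))


class TestCV:
    @pytest.mark.parametrize(
        "mean,sd,expected", [(880.0, 21.0, 2.4), (359.0, 95.0, 26.5)]
    )
    def test_summary_worked_examples(self, mean, sd, expected):
        assert round(cv_percent(mean, sd), 1) == expected

    def test_constant_list_zero_cv(self):
        assert coefficient_of_variation([5, 5, 5]) == 0.0

    def test_errors(self):
        with pytest.raises(ValueError):
            coefficient_of_variation([5.0])
        with pytest.raises(ValueError):
            coefficient_of_variation([-3.0, 1.0])
        with pytest.raises(ValueError):
            cv_percent(0.0, 1.0)

    @given(
        st.lists(st.floats(1.0, 1e4), min_size=2, max_size=20),
        st.floats(1e-3, 1e3),
    )
    @settings(deadline=None, max_examples=50)
    def test_scale_invariance(self, values, scale):
        base = coefficient_of_variation(values)
        scaled = coefficient_of_variation([v * scale for v in values])
        assert scaled == pytest.approx(base, rel=1e-9, abs=1e-9)


def test_uniform_placement_has_no_depth_trend():
    """Per-depth counts of uniformly placed nuclei show no monotone z-trend
    (aggregate over 20 seeded replicates)."""
    spec = StackSpec(n_nuclei=100, seed=0)
    nz = int(round((spec.slab_thickness_um + 2 * spec.z_margin_um) / spec.z_step_um))
    counts = np.zeros(nz)
    for seed in range(20):
        centers = _sample_centers(
            StackSpec(n_nuclei=100, seed=seed), np.random.default_rng(seed)
        )
        idx = np.clip(np.rint(centers[:, 2] / spec.z_step_um).astype(int), 0, nz - 1)
        np.add.at(counts, idx, 1)
    interior = slice(
        int(spec.z_margin_um / spec.z_step_um) + 1,
        nz - int(spec.z_margin_um / spec.z_step_um) - 1,
    )
    rho, p = spearmanr(np.arange(nz)[interior], counts[interior])
    assert p > 0.05


def test_image_stack_validation():
    with pytest.raises(ValueError, match="3D"):
        ImageStack(voxels=np.zeros((4, 4)), pixel_size_um=1.0, z_step_um=1.0)
    with pytest.raises(ValueError, match="positive"):
        ImageStack(voxels=np.zeros((1, 4, 4)), pixel_size_um=0.0, z_step_um=1.0)
    with pytest.raises(ValueError, match="non-negative"):
        ImageStack(voxels=np.full((1, 2, 2), -1.0), pixel_size_um=1.0, z_step_um=1.0)
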