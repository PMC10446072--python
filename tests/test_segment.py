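import numpy as np
import pytest

from pseudoislet3d import (
    LabelMap,
    VoxelGeometry,
    detect_spots,
    detect_surfaces,
    label_components,
    measure_objects,
    place_cells,
    render,
    size_filter,
    threshold_manual,
    threshold_otsu,
    watershed_split,
)

import oracles
from conftest import clean_sim_config


def sphere_mask(shape, centre, radius):
    zz, yy, xx = np.mgrid[: shape[0], : shape[1], : shape[2]]
    return ((zz - centre[0]) ** 2 + (yy - centre[1]) ** 2
            + (xx - centre[2]) ** 2) <= radius**2


class TestThresholding:
    def test_bimodal_grid_split_exactly(self, rng):
        grid = np.zeros((10, 10, 10))
        hot = rng.random((10, 10, 10)) < 0.1
        grid[hot] = 1.0
        binary = threshold_otsu(grid, mode="global")
        np.testing.assert_array_equal(binary, hot)

    def test_shift_invariance(self, rng):
        grid = rng.normal(size=(12, 12, 12)) ** 2
        np.testing.assert_array_equal(
            threshold_otsu(grid, "global"), threshold_otsu(grid + 37.0, "global")
        )

    def test_positive_affine_invariance(self, rng):
        grid = rng.random((10, 10, 10))
        np.testing.assert_array_equal(
            threshold_otsu(grid, "global"), threshold_otsu(3.0 * grid + 2.0, "global")
        )

    def test_global_threshold_matches_exhaustive_variance_maximisation(self, rng):
        mixture = np.concatenate([
            rng.normal(0.2, 0.05, 1000), rng.normal(0.8, 0.05, 400)
        ]).reshape(10, 10, 14)
        # quantise to 256 levels so both routes optimise over the same grid
        grid = np.clip(mixture * 255, 0, 255).round().astype(np.int64)
        binary = threshold_otsu(grid, "global")
        thr = oracles.exhaustive_otsu_discrete(grid.astype(int))
        np.testing.assert_array_equal(binary, grid > thr)

    def test_constant_grid_is_error(self):
        with pytest.raises(ValueError):
            threshold_otsu(np.ones((4, 4, 4)))

    def test_adaptive_tracks_local_contrast(self, rng):
        # two halves with very different brightness: one global threshold
        # swallows the dim half, the clamped adaptive map keeps both
        grid = rng.random((8, 16, 32)) * 0.05
        grid[:, :, :16] += np.where(rng.random((8, 16, 16)) < 0.2, 1.0, 0.0)
        grid[:, :, 16:] += np.where(rng.random((8, 16, 16)) < 0.2, 0.45, 0.0)
        adaptive = threshold_otsu(grid, "adaptive", block=8)
        dim_fraction = adaptive[:, :, 16:].mean()
        assert 0.1 < dim_fraction < 0.3  # dim spots recovered

    def test_manual_threshold_edges(self, rng):
        grid = rng.random((4, 4, 4))
        assert threshold_manual(grid, grid.min()).all()
        assert not threshold_manual(grid, grid.max() + 1).any()


class TestLabelComponents:
    def test_face_neighbours_are_one_object(self, iso_geometry):
        binary = np.zeros((3, 3, 3), bool)
        binary[1, 1, 0] = binary[1, 1, 1] = True
        for conn in (6, 18, 26):
            assert label_components(binary, conn, iso_geometry).n_objects == 1

    def test_corner_neighbours_depend_on_connectivity(self, iso_geometry):
        binary = np.zeros((2, 2, 2), bool)
        binary[0, 0, 0] = binary[1, 1, 1] = True
        assert label_components(binary, 26, iso_geometry).n_objects == 1
        assert label_components(binary, 6, iso_geometry).n_objects == 2

    @pytest.mark.parametrize("connectivity", [6, 18, 26])
    def test_matches_flood_fill_oracle_on_random_binaries(self, connectivity,
                                                          iso_geometry):
        rng = np.random.default_rng(connectivity)
        for _ in range(70):
            binary = rng.random((12, 12, 12)) < 0.35
            got = label_components(binary, connectivity, iso_geometry).labels
            want = oracles.flood_fill_label(binary, connectivity)
            assert oracles.same_partition(got, want)


class TestSizeFilter:
    def test_exactly_250_voxels_removed_under_strict_rule(self, iso_geometry):
        labels = np.zeros((10, 10, 10), np.int32)
        labels.ravel()[:250] = 1
        out = size_filter(LabelMap(labels, iso_geometry), min_voxels=250)
        assert out.n_objects == 0
        labels.ravel()[250] = 1  # 251 voxels survives "> 250"
        out = size_filter(LabelMap(labels, iso_geometry), min_voxels=250)
        assert out.n_objects == 1

    def test_zero_thresholds_are_identity(self, rng, iso_geometry):
        labels = (rng.random((8, 8, 8)) < 0.3).astype(np.int32)
        labels = label_components(labels > 0, 26, iso_geometry).labels
        out = size_filter(LabelMap(labels, iso_geometry), 0, 0.0)
        np.testing.assert_array_equal(out.labels, labels)

    def test_survivors_match_brute_force_measurement(self, rng, iso_geometry):
        binary = rng.random((12, 12, 12)) < 0.3
        lm = label_components(binary, 6, iso_geometry)
        min_voxels, min_area = 5, 1.2
        out = size_filter(lm, min_voxels, min_area, iso_geometry)
        ref = oracles.brute_measurements(lm.labels, np.ones(binary.shape),
                                         iso_geometry.spacing_zyx)
        expected_survivors = {
            lab for lab, m in ref.items()
            if m["voxel_count"] > min_voxels and m["max_slice_area"] >= min_area
        }
        assert out.n_objects == len(expected_survivors)
        surviving_mask = out.labels > 0
        want_mask = np.isin(lm.labels, list(expected_survivors))
        np.testing.assert_array_equal(surviving_mask, want_mask)

    def test_never_increases_object_count(self, rng, iso_geometry):
        binary = rng.random((10, 10, 10)) < 0.25
        lm = label_components(binary, 26, iso_geometry)
        out = size_filter(lm, 3, 0.5, iso_geometry)
        assert out.n_objects <= lm.n_objects


class TestWatershedSplit:
    def test_single_sphere_stays_whole(self, iso_geometry):
        binary = sphere_mask((24, 24, 24), (12, 12, 12), 8)
        out = watershed_split(binary, 8.0, iso_geometry)
        assert out.n_objects == 1

    def test_two_fused_spheres_split_at_midplane(self, iso_geometry):
        # 8 µm spheres (8 voxel radius at 0.5 µm) overlapping by ~25 %
        c1, c2 = (16, 16, 12), (16, 16, 24)
        binary = sphere_mask((32, 32, 40), c1, 8) | sphere_mask((32, 32, 40), c2, 8)
        out = watershed_split(binary, 8.0, iso_geometry)
        assert out.n_objects == 2
        boundary_x = []
        lab = out.labels
        for x in range(39):
            if (lab[16, 16, x] != 0 and lab[16, 16, x + 1] != 0
                    and lab[16, 16, x] != lab[16, 16, x + 1]):
                boundary_x.append(x + 0.5)
        assert boundary_x and abs(boundary_x[0] - 18.0) <= 1.0

    def test_three_sphere_chain_splits_into_three(self, iso_geometry):
        shape = (28, 28, 56)
        binary = np.zeros(shape, bool)
        for cx in (12, 28, 44):
            binary |= sphere_mask(shape, (14, 14, cx), 8)
        out = watershed_split(binary, 8.0, iso_geometry)
        assert out.n_objects == 3

    def test_never_decreases_component_count(self, rng, iso_geometry):
        binary = rng.random((14, 14, 14)) < 0.3
        before = label_components(binary, 26, iso_geometry).n_objects
        after = watershed_split(binary, 3.0, iso_geometry).n_objects
        assert after >= before


class TestDetectSpots:
    def test_empty_grid_gives_empty_table(self, iso_geometry):
        assert len(detect_spots(np.zeros((8, 8, 8)), 6.0, None, iso_geometry)) == 0

    def test_recovers_rendered_nuclei_within_one_voxel(self, iso_geometry):
        cfg = clean_sim_config(n_cells=5, aggregate_radius=14.0, seed=4)
        truth = place_cells(cfg)
        stack = render(truth, cfg, iso_geometry)
        spots = detect_spots(stack["nuclei"].astype(float), 6.0, None, iso_geometry)
        assert len(spots) == 5
        shape = stack.shape
        offset = np.array([shape[2], shape[1], shape[0]]) * 0.5 / 2.0
        truth_xyz = truth[["centre_x_um", "centre_y_um", "centre_z_um"]].to_numpy() + offset
        got_xyz = spots[["centroid_x_um", "centroid_y_um", "centroid_z_um"]].to_numpy()
        for t in truth_xyz:
            d = np.sqrt(((got_xyz - t) ** 2).sum(1)).min()
            assert d <= 0.5 * np.sqrt(3) + 1e-6  # within one voxel diagonal

    def test_threshold_above_max_response_kills_all_spots(self, iso_geometry):
        cfg = clean_sim_config(n_cells=5, aggregate_radius=14.0, seed=4)
        stack = render(place_cells(cfg), cfg, iso_geometry)
        spots = detect_spots(stack["nuclei"].astype(float), 6.0, 1e9, iso_geometry)
        assert len(spots) == 0


class TestDetectSurfaces:
    def test_two_separated_cells_give_two_surfaces(self, iso_geometry):
        grid = np.zeros((24, 24, 48))
        grid[sphere_mask(grid.shape, (12, 12, 12), 6)] = 1.0
        grid[sphere_mask(grid.shape, (12, 12, 36), 6)] = 1.0
        out = detect_surfaces(grid, 0.6, 16.0, None, iso_geometry,
                              split_diameter=8.0)
        assert out.n_objects == 2

    def test_all_zero_grid_gives_empty_map(self, iso_geometry):
        out = detect_surfaces(np.zeros((8, 8, 8)), 0.6, 16.0, None, iso_geometry)
        assert out.n_objects == 0

    def test_deterministic(self, rng, iso_geometry):
        grid = rng.random((10, 16, 16))
        a = detect_surfaces(grid, 0.6, 8.0, None, iso_geometry, split_diameter=4.0)
        b = detect_surfaces(grid, 0.6, 8.0, None, iso_geometry, split_diameter=4.0)
        np.testing.assert_array_equal(a.labels, b.labels)


class TestMeasureObjects:
    def test_single_voxel_centroid_is_voxel_centre(self, aniso_geometry):
        labels = np.zeros((4, 4, 5), np.int32)
        labels[1, 2, 3] = 1
        table = measure_objects(LabelMap(labels, aniso_geometry),
                                np.ones(labels.shape))
        row = table.iloc[0]
        assert row["centroid_x_um"] == pytest.approx(3 * 0.5)
        assert row["centroid_y_um"] == pytest.approx(2 * 0.5)
        assert row["centroid_z_um"] == pytest.approx(1 * 0.8)

    def test_cube_volume(self, iso_geometry):
        labels = np.zeros((4, 4, 4), np.int32)
        labels[1:3, 1:3, 1:3] = 1
        table = measure_objects(LabelMap(labels, iso_geometry), np.ones((4, 4, 4)))
        assert table.iloc[0]["volume_um3"] == pytest.approx(8 * 0.125)

    def test_matches_brute_force_accumulation(self, rng, iso_geometry):
        binary = rng.random((9, 9, 9)) < 0.3
        lm = label_components(binary, 26, iso_geometry)
        intensity = rng.random((9, 9, 9)) * 10
        table = measure_objects(lm, intensity)
        ref = oracles.brute_measurements(lm.labels, intensity,
                                         iso_geometry.spacing_zyx)
        assert len(table) == len(ref)
        for _, row in table.iterrows():
            want = ref[int(row["object_id"])]
            assert row["voxel_count"] == want["voxel_count"]
            assert row["volume_um3"] == pytest.approx(want["volume"])
            assert row["max_slice_area_um2"] == pytest.approx(want["max_slice_area"])
            assert row["mean_intensity"] == pytest.approx(want["mean_intensity"])
            got_xyz = (row["centroid_x_um"], row["centroid_y_um"], row["centroid_z_um"])
            np.testing.assert_allclose(got_xyz, want["centroid_xyz"], atol=1e-9)
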