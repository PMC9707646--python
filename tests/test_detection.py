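"""Focus detection: DoG, Otsu, labelling, volumes, compartments, cell records."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from foci3d import (
    DetectionParams,
    FocusObject,
    ImageStack,
    NuclearLabels,
    SceneParams,
    VoxelGeometry,
    assign_cells,
    assign_compartment,
    build_cell_table,
    classify_clusters,
    compute_spot_threshold,
    detect_foci,
    dog_filter,
    generate_scene,
    label_objects,
    nuclear_fraction,
    threshold_otsu,
    volume_um3,
)
from foci3d.core import DEFAULT_GEOMETRY
from foci3d.segmentation import stack_histogram

# ---------------------------------------------------------------------------
# independent oracles


def _direct_kernel(sigma):
    radius = int(4.0 * sigma + 0.5)
    x = np.arange(-radius, radius + 1, dtype=float)
    k = np.exp(-(x**2) / (2 * sigma**2))
    return k / k.sum()


def _flood_fill_components(binary, connectivity):
    """Brute-force connected components by explicit flood fill."""
    binary = np.asarray(binary, dtype=bool)
    offsets = []
    for dz in (-1, 0, 1):
        for dy in (-1, 0, 1):
            for dx in (-1, 0, 1):
                if (dz, dy, dx) == (0, 0, 0):
                    continue
                order = abs(dz) + abs(dy) + abs(dx)
                if connectivity == 6 and order > 1:
                    continue
                if connectivity == 18 and order > 2:
                    continue
                offsets.append((dz, dy, dx))
    seen = np.zeros_like(binary, dtype=bool)
    comps = []
    for start in zip(*np.nonzero(binary)):
        if seen[start]:
            continue
        stack, comp = [start], []
        seen[start] = True
        while stack:
            v = stack.pop()
            comp.append(v)
            for off in offsets:
                w = tuple(v[i] + off[i] for i in range(3))
                if any(c < 0 or c >= binary.shape[i] for i, c in enumerate(w)):
                    continue
                if binary[w] and not seen[w]:
                    seen[w] = True
                    stack.append(w)
        comps.append(frozenset(comp))
    return set(comps)


def _otsu_variance(hist, centers, threshold):
    """Between-class variance induced by a threshold (binarize with >=)."""
    hist = np.asarray(hist, dtype=float)
    below = centers < threshold
    w0, w1 = hist[below].sum(), hist[~below].sum()
    if w0 == 0 or w1 == 0:
        return 0.0
    mu0 = (hist[below] * centers[below]).sum() / w0
    mu1 = (hist[~below] * centers[~below]).sum() / w1
    return w0 * w1 * (mu0 - mu1) ** 2


def _assert_otsu_optimal(hist, edges, threshold):
    """Exhaustive-oracle check: no split beats the returned threshold, and the
    induced class partition matches the best brute-force split.  Thresholds
    are compared through their partitions because every split across an empty
    histogram gap is an equally valid maximizer."""
    hist = np.asarray(hist, dtype=float)
    centers = 0.5 * (edges[:-1] + edges[1:])
    ours = _otsu_variance(hist, centers, threshold)
    best = max(_otsu_variance(hist, centers, e) for e in edges[1:-1])
    assert ours >= best * (1 - 1e-9)


# ---------------------------------------------------------------------------


class TestDog:
    def test_constant_annihilated(self):
        out = dog_filter(np.full((3, 32, 32), 4321.0))
        assert np.all(out == 0)

    def test_single_voxel_matches_two_kernel_convolution(self):
        data = np.zeros((3, 51, 51), dtype=np.float32)
        data[1, 25, 25] = 20000.0
        out = dog_filter(data, 2.0, 4.0)
        k1, k2 = _direct_kernel(2.0), _direct_kernel(4.0)
        r1, r2 = len(k1) // 2, len(k2) // 2
        narrow = np.zeros((51, 51))
        narrow[25 - r1 : 25 + r1 + 1, 25 - r1 : 25 + r1 + 1] = 20000.0 * np.outer(k1, k1)
        wide = np.zeros((51, 51))
        wide[25 - r2 : 25 + r2 + 1, 25 - r2 : 25 + r2 + 1] = 20000.0 * np.outer(k2, k2)
        expected = np.maximum(np.rint(narrow) - np.rint(wide), 0.0)
        np.testing.assert_allclose(out[1], expected, atol=1.0 + 1e-6)
        assert out[1, 25, 25] > 0

    def test_broad_plateau_interior_zero_edges_positive(self):
        data = np.zeros((1, 40, 200), dtype=np.float32)
        data[0, :, 50:150] = 10000.0
        out = dog_filter(data)
        assert np.all(out[0, 20, 90:110] == 0)  # interior far from edges
        assert out[0, 20, 48:52].max() > 0  # rising edge responds

    def test_sigma_order_enforced(self):
        with pytest.raises(ValueError):
            dog_filter(np.zeros((1, 8, 8)), 4.0, 2.0)


class TestOtsu:
    def test_two_equal_spikes_tie_breaks_low(self):
        values = np.r_[np.full(500, 50.0), np.full(500, 200.0)]
        hist, edges = stack_histogram(values)
        t = threshold_otsu(hist, edges)
        # every split between the spikes maximizes the criterion; the
        # contract picks the lowest maximizing bin edge
        assert t == pytest.approx(edges[1])
        assert 50.0 < t < 200.0

    @given(st.integers(0, 10_000))
    def test_matches_exhaustive_split_search(self, seed):
        rng = np.random.default_rng(seed)
        a = rng.normal(800, 150, size=3000)
        b = rng.normal(rng.uniform(3000, 9000), 500, size=rng.integers(100, 3000))
        hist, edges = stack_histogram(np.r_[a, b])
        _assert_otsu_optimal(hist, edges, threshold_otsu(hist, edges))

    def test_matches_reference_implementation(self):
        skimage_filters = pytest.importorskip("skimage.filters")
        rng = np.random.default_rng(3)
        values = np.r_[rng.normal(800, 150, 3000), rng.normal(6000, 500, 800)]
        hist, edges = stack_histogram(values)
        centers = 0.5 * (edges[:-1] + edges[1:])
        ref = skimage_filters.threshold_otsu(hist=(hist.astype(np.int64), centers))
        assert abs(threshold_otsu(hist, edges) - ref) <= 2 * (edges[1] - edges[0])

    def test_single_occupied_bin_errors(self):
        hist, edges = stack_histogram(np.full(10, 5.0))
        with pytest.raises(ValueError):
            threshold_otsu(hist, edges)


class TestSpotThreshold:
    def test_manual_cap_wins_when_otsu_high(self):
        """Spot-rich grid: Otsu sits in the thousands, the 250 cap wins."""
        rng = np.random.default_rng(0)
        filtered = np.abs(rng.normal(0, 120, size=(4, 64, 64))).astype(np.float32)
        spots = rng.random(filtered.shape) < 0.02
        filtered[spots] = rng.uniform(4000, 9000, size=int(spots.sum()))
        hist, edges = stack_histogram(filtered)
        assert threshold_otsu(hist, edges) > 250.0
        assert compute_spot_threshold(filtered) == 250.0

    def test_otsu_wins_when_below_manual(self):
        filtered = np.zeros((4, 64, 64), dtype=np.float32)
        filtered[:, :10, :10] = 120.0
        t = compute_spot_threshold(filtered)
        assert t < 250.0
        assert 0.0 < t <= 120.0

    def test_degenerate_filtered_grid_falls_back_to_manual(self):
        assert compute_spot_threshold(np.zeros((2, 8, 8), dtype=np.float32)) == 250.0

    def test_blank_scene_yields_zero_objects(self):
        """Noise-only simulated field: nothing survives detection."""
        p = SceneParams(image_shape=(31, 256, 256), n_cells=0, seed=17)
        bundle, _ = generate_scene(p)
        result = detect_foci(bundle["HsHTT"])
        assert result.objects == []


class TestLabelObjects:
    def test_solid_cube_counts(self):
        grid = np.zeros((7, 7, 7), dtype=bool)
        grid[2:5, 2:5, 2:5] = True
        objs = label_objects(grid, 26, 25)
        assert len(objs) == 1
        assert objs[0][1] == 27

    def test_24_voxel_object_rejected_25_kept(self):
        grid = np.zeros((4, 6, 6), dtype=bool)
        grid[1, 1:5, 1:4] = True  # 12
        grid[2, 1:5, 1:4] = True  # 24 total
        assert label_objects(grid, 26, 25) == []
        grid[3, 1, 1] = True  # 25th voxel, corner-adjacent
        objs = label_objects(grid, 26, 25)
        assert len(objs) == 1 and objs[0][1] == 25

    def test_corner_touch_connectivity(self):
        grid = np.zeros((2, 2, 2), dtype=bool)
        grid[0, 0, 0] = grid[1, 1, 1] = True
        assert len(label_objects(grid, 26, 1)) == 1
        assert len(label_objects(grid, 6, 1)) == 2

    @given(
        hnp.arrays(bool, st.tuples(st.integers(1, 6), st.integers(1, 6), st.integers(1, 6))),
        st.sampled_from([6, 18, 26]),
    )
    def test_matches_flood_fill_oracle(self, grid, connectivity):
        ours = {
            frozenset(map(tuple, coords)) for coords, _, _ in label_objects(grid, connectivity, 1)
        }
        assert ours == _flood_fill_components(grid, connectivity)

    def test_centroid_of_symmetric_object(self):
        grid = np.zeros((5, 5, 5), dtype=bool)
        grid[1:4, 1:4, 1:4] = True
        (coords, count, centroid), = label_objects(grid, 26, 1)
        assert centroid == (2.0, 2.0, 2.0)


class TestVolumes:
    def test_cluster_cutoff_voxel_conversion(self, geometry):
        assert volume_um3(274, geometry) == pytest.approx(0.6004, abs=1e-4)
        assert volume_um3(274, geometry) >= 0.6
        assert volume_um3(273, geometry) < 0.6

    def test_min_size_floor_volume(self, geometry):
        assert volume_um3(25, geometry) == pytest.approx(0.0548, abs=1e-4)
        assert volume_um3(0, geometry) == 0.0

    def test_negative_count_rejected(self, geometry):
        with pytest.raises(ValueError):
            volume_um3(-1, geometry)


def _obj(volume, geometry, coords=None, compartment=None):
    count = int(round(volume / geometry.voxel_volume_um3))
    return FocusObject(
        object_id=0,
        channel="c",
        voxel_count=count,
        volume_um3=volume,
        centroid=(0.0, 0.0, 0.0),
        peak_intensity=1.0,
        coords=coords if coords is not None else np.zeros((1, 3), dtype=int),
        compartment=compartment,
    )


class TestClusters:
    def test_inclusive_boundary(self, geometry):
        objs = [
            _obj(volume_um3(273, geometry), geometry),
            _obj(volume_um3(274, geometry), geometry),
            _obj(0.6, geometry),
            _obj(5.0, geometry),
        ]
        classify_clusters(objs, 0.6)
        assert [o.is_cluster for o in objs] == [False, True, True, True]


def _labels_grid():
    grid = np.zeros((4, 10, 10), dtype=np.int32)
    grid[1:3, 1:4, 1:4] = 1
    grid[1:3, 6:9, 6:9] = 2
    counts = np.array([(grid == 1).sum(), (grid == 2).sum()])
    cents = np.array([[1.5, 2.0, 2.0], [1.5, 7.0, 7.0]])
    return NuclearLabels(grid=grid, voxel_counts=counts, centroids=cents)


class TestCompartmentAndCells:
    def test_single_voxel_overlap_is_nuclear(self):
        labels = _labels_grid()
        inside = _obj(0.1, DEFAULT_GEOMETRY, coords=np.array([[1, 2, 2]]))
        touching = _obj(0.1, DEFAULT_GEOMETRY, coords=np.array([[0, 0, 0], [1, 3, 3]]))
        outside = _obj(0.1, DEFAULT_GEOMETRY, coords=np.array([[3, 5, 5]]))
        assign_compartment([inside, touching, outside], labels)
        assert inside.compartment == "nuclear"
        assert touching.compartment == "nuclear"  # one shared voxel suffices
        assert outside.compartment == "cytoplasmic"

    def test_out_of_grid_coordinates_error(self):
        labels = _labels_grid()
        rogue = _obj(0.1, DEFAULT_GEOMETRY, coords=np.array([[9, 2, 2]]))
        with pytest.raises(ValueError):
            assign_compartment([rogue], labels)

    def test_nuclear_majority_overlap_and_cyto_nearest(self):
        labels = _labels_grid()
        geometry = VoxelGeometry(0.5, 0.5, 0.5)  # easy distances
        nuc = _obj(
            0.1,
            geometry,
            coords=np.array([[1, 3, 3], [1, 2, 2], [1, 2, 3], [3, 5, 5]]),
            compartment="nuclear",
        )
        cyto_near = _obj(0.1, geometry, compartment="cytoplasmic")
        cyto_near.centroid = (1.5, 3.5, 3.5)  # ~1 um from nucleus 1 centroid
        cyto_far = _obj(0.1, geometry, compartment="cytoplasmic")
        cyto_far.centroid = (3.0, 9.0, 9.0)  # >= 1.6 um from either nucleus
        assign_cells([nuc, cyto_near, cyto_far], labels, geometry, max_distance_um=1.2)
        assert nuc.cell_id == 1
        assert cyto_near.cell_id == 1
        assert cyto_far.cell_id is None  # beyond max distance: unassigned


class TestNuclearFraction:
    @pytest.mark.parametrize(
        "n, c, expected",
        [(8, 8, 0.5), (19, 10, 19 / 29), (0, 5, 0.0), (5, 0, 1.0)],
    )
    def test_values(self, n, c, expected):
        assert nuclear_fraction(n, c) == pytest.approx(expected, abs=5e-4)

    def test_undefined_when_no_foci(self):
        assert np.isnan(nuclear_fraction(0, 0))

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            nuclear_fraction(-1, 0)


class TestCellTable:
    def test_counts_fraction_and_flags(self):
        labels = _labels_grid()
        geometry = DEFAULT_GEOMETRY
        objs = []
        for i, (comp, cell, cluster) in enumerate(
            [
                ("nuclear", 1, False),
                ("nuclear", 1, False),
                ("nuclear", 1, True),
                ("cytoplasmic", 1, False),
                ("cytoplasmic", 1, False),
            ]
        ):
            o = _obj(1.0 if cluster else 0.1, geometry, compartment=comp)
            o.object_id = i
            o.cell_id = cell
            o.is_cluster = cluster
            objs.append(o)
        cells = build_cell_table({"c": objs}, labels)
        row1 = cells[(cells["cell_id"] == 1)].iloc[0]
        assert row1["n_nuclear"] == 3 and row1["n_cytoplasmic"] == 2
        assert row1["nuclear_fraction"] == pytest.approx(0.6)
        assert bool(row1["has_nuclear_cluster"]) is True
        assert bool(row1["has_cytoplasmic_cluster"]) is False
        row2 = cells[(cells["cell_id"] == 2)].iloc[0]
        assert row2["n_nuclear"] == 0 and row2["n_cytoplasmic"] == 0
        assert np.isnan(row2["nuclear_fraction"])
        assert not row2["has_nuclear_cluster"]


class TestEndToEndInvariants:
    def test_threshold_monotonicity(self, small_scene):
        """A higher threshold never yields more objects or larger ones."""
        bundle, _ = small_scene
        filtered = dog_filter(bundle["HsHTT"].data)
        lo = label_objects(filtered >= 250.0, 26, 25)
        hi = label_objects(filtered >= 500.0, 26, 25)
        assert len(hi) <= len(lo)
        assert sum(c for _, c, _ in hi) <= sum(c for _, c, _ in lo)

    def test_object_conservation(self, small_result):
        """Each object has exactly one compartment and at most one cell;
        per-cell counts plus unassigned add up to the total."""
        for channel, objs in small_result.objects.items():
            assert all(o.compartment in ("nuclear", "cytoplasmic") for o in objs)
            cells = small_result.cells
            sub = cells[cells["channel"] == channel]
            assigned = int(sub["n_nuclear"].sum() + sub["n_cytoplasmic"].sum())
            unassigned = sum(1 for o in objs if o.cell_id is None)
            assert assigned + unassigned == len(objs)

    def test_invalid_params(self):
        with pytest.raises(ValueError):
            DetectionParams(sigma1=4, sigma2=2)
        with pytest.raises(ValueError):
            DetectionParams(min_voxels=0)
        with pytest.raises(ValueError):
            DetectionParams(connectivity=10)
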