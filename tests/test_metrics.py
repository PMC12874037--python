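"""Skeleton morphometry: thinning, graph, lengths, branch points, maps."""

import numpy as np
import pytest

import octvessel as ov
from octvessel.metrics import MetricsParams, build_graph, prune_spurs, skeletonize
from octvessel.topology import betti_numbers

from conftest import random_blob_mask, tube_network_spec


class TestSkeletonize:
    def test_cylinder_skeleton_near_axis_no_junctions(self, cylinder_mask):
        skel = skeletonize(cylinder_mask)
        vox = np.argwhere(skel)
        assert np.abs(vox[:, 1] - 31.5).max() <= 1.0
        assert np.abs(vox[:, 2] - 15.5).max() <= 1.0
        g = build_graph(prune_spurs(skel, 3), (1, 1, 1))
        assert ov.count_branch_points(g) == 0

    def test_single_voxel_is_its_own_skeleton(self):
        m = np.zeros((9, 9, 9), bool)
        m[4, 4, 4] = True
        assert np.array_equal(skeletonize(m), m)

    def test_even_width_bar_keeps_a_line(self):
        # a 2x2 bar has no central voxel plane; thinning must still leave a path
        m = np.zeros((8, 8, 30), bool)
        m[3:5, 3:5, 2:28] = True
        skel = skeletonize(m)
        assert skel.sum() >= 20
        assert betti_numbers(skel)[0] == 1

    def test_y_fixture_three_endpoints(self, y_fixture):
        _, mask, _ = y_fixture
        skel = prune_spurs(skeletonize(mask), 3)
        g = build_graph(skel, (1, 1, 1))
        endpoints = [n for n, d in g.graph.nodes(data=True) if d["kind"] == "endpoint"]
        assert len(endpoints) == 3

    def test_skeleton_subset_and_topology_preserved(self):
        rng = np.random.default_rng(17)
        for _ in range(10):
            m = random_blob_mask(rng)
            skel = skeletonize(m)
            assert not (skel & ~m).any()
            assert betti_numbers(m)[:2] == betti_numbers(skel)[:2]

    def test_2d_mask_routed_to_2d_thinning(self):
        m = np.zeros((20, 20), bool)
        m[5:15, 8:12] = True
        skel = skeletonize(m)
        assert skel.ndim == 2 and 0 < skel.sum() < m.sum()


class TestPruneSpurs:
    def test_clean_path_unchanged(self):
        m = np.zeros((20, 5, 5), bool)
        m[2:18, 2, 2] = True
        assert np.array_equal(prune_spurs(m, 3), m)

    def test_short_terminal_spur_removed(self):
        m = np.zeros((20, 8, 3), bool)
        m[2:18, 2, 1] = True
        m[10, 3, 1] = m[10 + 1, 4, 1] = True  # 2-voxel spur off the path
        pruned = prune_spurs(m, 3)
        g = build_graph(pruned, (1, 1, 1))
        assert ov.count_branch_points(g) == 0
        assert pruned.sum() == 16

    def test_component_count_preserved(self):
        rng = np.random.default_rng(23)
        for _ in range(5):
            m = random_blob_mask(rng, shape=(24, 24, 24))
            skel = skeletonize(m)
            assert betti_numbers(prune_spurs(skel, 3))[0] == betti_numbers(skel)[0]


class TestBuildGraph:
    def test_straight_path_length(self):
        m = np.zeros((60, 5, 5), bool)
        m[5:56, 2, 2] = True  # 51 voxels
        g = build_graph(m, (1, 1, 1))
        assert g.graph.number_of_edges() == 1
        assert ov.total_vessel_length(g) == pytest.approx(50.0)

    def test_diagonal_staircase_isotropic(self):
        m = np.zeros((15, 15, 3), bool)
        for i in range(11):
            m[2 + i, 2 + i, 1] = True
        g = build_graph(m, (1, 1, 1))
        assert ov.total_vessel_length(g) == pytest.approx(10 * np.sqrt(2), rel=1e-9)

    def test_diagonal_staircase_anisotropic(self):
        m = np.zeros((15, 15, 3), bool)
        for i in range(11):
            m[2 + i, 2 + i, 1] = True
        g = build_graph(m, (2, 1, 1))
        assert ov.total_vessel_length(g) == pytest.approx(10 * np.sqrt(5), rel=1e-9)

    def test_sum_of_edges_equals_total(self, y_fixture):
        _, mask, _ = y_fixture
        g = build_graph(prune_spurs(skeletonize(mask), 3), (1, 1, 1))
        assert ov.total_vessel_length(g) == pytest.approx(
            sum(d["length_um"] for _, _, d in g.graph.edges(data=True))
        )

    def test_empty_graph_zero_with_warning(self):
        g = build_graph(np.zeros((5, 5, 5), bool), (1, 1, 1))
        with pytest.warns(UserWarning, match="empty"):
            assert ov.total_vessel_length(g) == 0.0


class TestBranchPoints:
    def test_straight_tube_zero(self, cylinder_mask):
        res = ov.compute_metrics(cylinder_mask)
        assert res.branch_points == 0

    def test_y_fixture_one(self, y_fixture):
        _, mask, _ = y_fixture
        res = ov.compute_metrics(mask)
        assert res.branch_points == 1

    def test_y_branch_count_invariant_under_axis_permutation(self, y_fixture):
        _, mask, _ = y_fixture
        for perm in [(0, 1, 2), (1, 2, 0), (2, 0, 1), (0, 2, 1)]:
            res = ov.compute_metrics(np.transpose(mask.mask, perm), (1.0, 1.0, 1.0))
            assert res.branch_points == 1

    @pytest.mark.parametrize("seed", range(6))
    def test_random_tree_counts_match_generator(self, seed):
        spec = tube_network_spec(100 + seed)
        truth = ov.generate_network(spec)
        mask = ov.rasterize(truth, spec.grid_shape, spec.voxel_spacing)
        res = ov.compute_metrics(mask)
        assert res.branch_points == truth.n_bifurcations


class TestThicknessAndVI:
    def test_empty_column_zero(self):
        m = np.zeros((4, 4, 10), bool)
        m[1, 1, 2:7] = True
        t = ov.thickness_map(m, (1, 1, 1))
        assert t.values[0, 0] == 0.0
        assert t.values[1, 1] == 5.0

    def test_cylinder_max_thickness_is_diameter(self, cylinder_mask):
        t = ov.thickness_map(cylinder_mask)
        assert t.values.max() in (9.0, 10.0, 11.0)

    def test_longest_run_not_sum(self):
        m = np.zeros((3, 3, 30), bool)
        m[1, 1, 2:7] = True  # 5-run
        m[1, 1, 10:22] = True  # 12-run
        t = ov.thickness_map(m, (1, 1, 1))
        assert t.values[1, 1] == 12.0
        t2 = ov.thickness_map(m, (1, 1, 1), definition="column_count")
        assert t2.values[1, 1] == 17.0

    def test_vi_empty_full_and_cylinder(self, cylinder_mask):
        assert ov.vascularity_index(np.zeros((4, 4, 4), bool)) == 0.0
        assert ov.vascularity_index(np.ones((4, 4, 4), bool)) == 1.0
        band = np.zeros((64, 64, 64), bool)
        band[:, :, 16:48] = cylinder_mask.mask[:, :, :32]
        vi = ov.vascularity_index(band)
        assert vi == pytest.approx(np.pi * 25 * 64 / 64**3, rel=0.02)

    def test_vi_additive_over_disjoint_masks(self):
        rng = np.random.default_rng(3)
        a = np.zeros((10, 10, 10), bool)
        b = np.zeros((10, 10, 10), bool)
        a[:5] = rng.random((5, 10, 10)) < 0.3
        b[5:] = rng.random((5, 10, 10)) < 0.3
        assert ov.vascularity_index(a | b) == pytest.approx(
            ov.vascularity_index(a) + ov.vascularity_index(b)
        )


class TestComputeMetrics:
    def test_empty_mask_all_zero(self):
        res = ov.compute_metrics(np.zeros((8, 8, 8), bool), (1, 1, 1))
        assert (res.vascularity_index, res.mean_thickness_um, res.total_length_um,
                res.branch_points) == (0.0, 0.0, 0.0, 0)

    def test_y_fixture_all_metrics_positive(self, y_fixture):
        _, mask, _ = y_fixture
        res = ov.compute_metrics(mask)
        assert res.branch_points == 1
        assert res.vascularity_index > 0
        assert res.mean_thickness_um > 0
        assert res.total_length_um > 0

    def test_deterministic_on_repeat(self):
        spec = tube_network_spec(42, n_seed_vessels=3)
        mask = ov.rasterize(ov.generate_network(spec), spec.grid_shape, spec.voxel_spacing)
        a = ov.compute_metrics(mask)
        b = ov.compute_metrics(mask)
        assert (a.vascularity_index, a.mean_thickness_um, a.total_length_um, a.branch_points) == (
            b.vascularity_index, b.mean_thickness_um, b.total_length_um, b.branch_points
        )

    def test_scaling_spacing_scales_lengths_only(self, y_fixture):
        _, mask, _ = y_fixture
        a = ov.compute_metrics(mask.mask, (1.0, 1.0, 1.0))
        b = ov.compute_metrics(mask.mask, (2.0, 2.0, 2.0))
        assert b.total_length_um == pytest.approx(2 * a.total_length_um)
        assert b.mean_thickness_um == pytest.approx(2 * a.mean_thickness_um)
        assert b.vascularity_index == a.vascularity_index
        assert b.branch_points == a.branch_points

    def test_y_total_length_within_5pct(self, y_fixture):
        _, mask, truth_length = y_fixture
        res = ov.compute_metrics(mask)
        assert res.total_length_um == pytest.approx(truth_length, rel=0.05)

    def test_disjoint_tubes_lengths_add(self):
        from octvessel.phantom import VesselSegment

        segs = [
            VesselSegment((5, 10, 10), (45, 10, 10), 2.5),
            VesselSegment((5, 30, 10), (45, 30, 10), 2.5),
        ]
        mask = ov.rasterize(segs, (50, 40, 20), (1, 1, 1))
        both = ov.compute_metrics(mask)
        one = ov.compute_metrics(ov.rasterize(segs[:1], (50, 40, 20), (1, 1, 1)))
        assert both.total_length_um == pytest.approx(2 * one.total_length_um, rel=0.02)


class TestTopologyOracle:
    def test_betti_numbers_of_known_shapes(self):
        solid = np.zeros((8, 8, 8), bool)
        solid[2:6, 2:6, 2:6] = True
        assert betti_numbers(solid) == (1, 0, 0)
        ring = solid.copy()
        ring[3:5, 3:5, :] = False  # a through-hole -> one loop
        assert betti_numbers(ring) == (1, 1, 0)
        shell = solid.copy()
        shell[3:5, 3:5, 3:5] = False  # enclosed cavity
        assert betti_numbers(shell) == (1, 0, 1)
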