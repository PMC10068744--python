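"""Skeletonization, radii, morphometry, connectivity domains, SWC export."""

from collections import deque

import numpy as np
import pytest

from vesselseg.phantom import PhantomSpec, rasterize, generate_tree
from vesselseg.vasc_analysis import (
    VesselSkeleton,
    connectivity_domains,
    estimate_radii,
    export_swc,
    morphometry,
    read_swc,
    skeletonize,
)

from conftest import make_cylinder_tree


def solid_cylinder(radius=4.0, length=50, axis=0, shape=(64, 64, 64), center=32.0):
    spec = PhantomSpec(shape=shape, n_trees=1, seed=0, hollow_radius_um=1e9)
    tree = make_cylinder_tree(radius, length=length, axis=axis, center=center)
    _, truth = rasterize(tree, spec)
    return truth.voxels


class TestSkeletonize:
    def test_cylinder_gives_simple_path(self):
        mask = solid_cylinder(radius=4.0, length=50, axis=0)
        skel = skeletonize(mask)
        deg = skel.degrees()
        # a simple path: exactly two endpoints, everything else degree 2
        assert (deg == 1).sum() == 2
        assert (deg >= 3).sum() == 0
        assert abs(skel.n_nodes - 51) <= 4

    def test_skeleton_inside_mask(self, small_phantom):
        _, _, truth, _ = small_phantom
        skel = skeletonize(truth.voxels)
        assert truth.voxels[tuple(skel.positions.T)].all()

    def test_two_tubes_two_components(self):
        a = solid_cylinder(radius=3.0, axis=0)
        b = solid_cylinder(radius=3.0, axis=2, center=50.0)
        mask = (a | b).astype(np.uint8)
        assert not (a & b).any()
        skel = skeletonize(mask)
        assert connectivity_domains(skel).max() == 2

    def test_empty_mask_empty_skeleton(self):
        skel = skeletonize(np.zeros((8, 8, 8), np.uint8))
        assert skel.n_nodes == 0 and len(skel.edges) == 0

    def test_component_count_preserved(self, small_phantom):
        from scipy import ndimage

        _, _, truth, _ = small_phantom
        _, n_mask = ndimage.label(truth.voxels, structure=np.ones((3, 3, 3)))
        skel = skeletonize(truth.voxels)
        assert connectivity_domains(skel).max() == n_mask

    def test_diagonal_line_interior_degree_two(self):
        mask = np.zeros((16, 16, 16), np.uint8)
        for i in range(12):
            mask[i + 2, i + 2, i + 2] = 1
        skel = skeletonize(mask)
        deg = skel.degrees()
        assert (deg == 1).sum() == 2 and (deg > 2).sum() == 0


class TestRadii:
    def test_cylinder_radius_recovered(self):
        mask = solid_cylinder(radius=4.0, axis=0)
        skel = estimate_radii(mask, skeletonize(mask), 1.0)
        interior = skel.radii_um[5:-5]
        assert 3.5 <= interior.mean() <= 4.5

    def test_thin_line_radius_below_one_voxel(self):
        mask = np.zeros((16, 16, 16), np.uint8)
        mask[8, 8, 2:14] = 1
        skel = estimate_radii(mask, skeletonize(mask), 1.0)
        assert (skel.radii_um <= 1.0 + 1e-6).all()

    def test_voxel_size_scales_radii(self):
        mask = solid_cylinder(radius=4.0, axis=0)
        s1 = estimate_radii(mask, skeletonize(mask), 1.0)
        s2 = estimate_radii(mask, skeletonize(mask), 2.0)
        np.testing.assert_allclose(s2.radii_um, 2 * s1.radii_um)

    def test_node_outside_mask_rejected(self):
        mask = np.zeros((8, 8, 8), np.uint8)
        mask[2:5, 2:5, 2:5] = 1
        bad = VesselSkeleton(np.array([[7, 7, 7]]), np.zeros((0, 2), int))
        with pytest.raises(ValueError):
            estimate_radii(mask, bad, 1.0)


class TestMorphometry:
    def test_single_path_length_density(self):
        # 100-voxel path in a 100^3 um^3 region: 0.1 mm / 1e-3 mm^3 = 100 mm/mm^3
        positions = np.array([[50, 50, z] for z in range(101)])
        edges = np.array([[i, i + 1] for i in range(100)])
        skel = VesselSkeleton(positions, edges, np.full(101, 2.0), (1.0, 1.0, 1.0))
        region = np.ones((100, 100, 100), bool)
        rep = morphometry(skel, region_mask=region, voxel_size_um=1.0)
        assert rep.total_length_mm == pytest.approx(0.1)
        assert rep.length_density_mm_per_mm3 == pytest.approx(100.0, rel=0.05)
        assert rep.n_bifurcations == 0

    def test_y_tree_single_bifurcation(self):
        spec = PhantomSpec(shape=(96, 96, 96), n_trees=1, seed=0, hollow_radius_um=1e9)
        # a Y: trunk along z, two arms leaving from its top
        trunk = np.stack([np.arange(10, 50.0), np.full(40, 48.0), np.full(40, 48.0)], 1)
        arm1 = np.stack([np.arange(49, 75.0), np.arange(49, 75.0), np.full(26, 48.0)], 1)
        arm2 = np.stack([np.arange(49, 75.0), np.full(26, 48.0), np.arange(49, 75.0)], 1)
        from vesselseg.phantom import VesselTree

        tree = VesselTree(
            polylines=[(trunk, np.full(40, 3.0)), (arm1, np.full(26, 3.0)),
                       (arm2, np.full(26, 3.0))],
            parents=[None, (0, 39), (0, 39)],
        )
        _, truth = rasterize(tree, spec)
        skel = estimate_radii(truth.voxels, skeletonize(truth.voxels), 1.0)
        rep = morphometry(skel, region_mask=np.ones(spec.shape, bool), voxel_size_um=1.0)
        assert rep.n_bifurcations == 1
        assert rep.n_connectivity_domains == 1

    def test_empty_skeleton_zero_densities(self):
        skel = VesselSkeleton(np.zeros((0, 3), int), np.zeros((0, 2), int), np.zeros(0))
        rep = morphometry(skel, region_mask=np.ones((10, 10, 10), bool), voxel_size_um=1.0)
        assert rep.total_length_mm == 0.0
        assert rep.bifurcation_density_per_mm3 == 0.0

    def test_empty_region_rejected(self):
        skel = VesselSkeleton(np.zeros((0, 3), int), np.zeros((0, 2), int))
        with pytest.raises(ValueError):
            morphometry(skel, region_mask=np.zeros((4, 4, 4), bool), voxel_size_um=1.0)

    def test_histogram_sums_to_node_count(self):
        mask = solid_cylinder(radius=4.0, axis=0)
        skel = estimate_radii(mask, skeletonize(mask), 1.0)
        rep = morphometry(skel, region_mask=np.ones(mask.shape, bool), voxel_size_um=1.0)
        assert sum(rep.radius_histogram.values()) == skel.n_nodes

    def test_axis_aligned_and_oblique_length_accuracy(self):
        mask = solid_cylinder(radius=3.0, length=50, axis=0)
        skel = skeletonize(mask)
        length = skel.edge_lengths_um().sum()
        assert abs(length - 50) / 50 < 0.05
        # 45-degree oblique tube in the y-x plane
        spec = PhantomSpec(shape=(64, 64, 64), n_trees=1, seed=0, hollow_radius_um=1e9)
        n = 40
        pts = np.stack([np.full(n, 32.0), 10 + np.arange(n, dtype=float),
                        10 + np.arange(n, dtype=float)], 1)
        from vesselseg.phantom import VesselTree

        _, truth = rasterize(VesselTree([(pts, np.full(n, 3.0))], [None]), spec)
        oblique = skeletonize(truth.voxels).edge_lengths_um().sum()
        true_len = (n - 1) * np.sqrt(2)
        assert abs(oblique - true_len) / true_len < 0.10


class TestConnectivityDomains:
    def test_ids_ordered_by_size(self):
        big = solid_cylinder(radius=3.0, length=50, axis=0)
        small = np.zeros_like(big)
        small[5:11, 55:60, 55:60] = 1
        skel = skeletonize((big | small).astype(np.uint8))
        labels = connectivity_domains(skel)
        n1 = (labels == 1).sum()
        n2 = (labels == 2).sum()
        assert n1 > n2 > 0

    def test_matches_bfs_oracle(self, small_phantom):
        _, _, truth, _ = small_phantom
        skel = skeletonize(truth.voxels)
        labels = connectivity_domains(skel)
        adj = {i: set() for i in range(skel.n_nodes)}
        for a, b in skel.edges:
            adj[a].add(b)
            adj[b].add(a)
        seen = set()
        comps = []
        for start in range(skel.n_nodes):
            if start in seen:
                continue
            comp = {start}
            seen.add(start)
            q = deque([start])
            while q:
                v = q.popleft()
                for nb in adj[v]:
                    if nb not in seen:
                        seen.add(nb)
                        comp.add(nb)
                        q.append(nb)
            comps.append(comp)
        expect_sets = {frozenset(c) for c in comps}
        got_sets = {frozenset(np.flatnonzero(labels == i).tolist())
                    for i in range(1, labels.max() + 1)}
        assert got_sets == expect_sets


class TestSwc:
    @pytest.fixture()
    def cylinder_skeleton(self):
        mask = solid_cylinder(radius=3.0, axis=0)
        return estimate_radii(mask, skeletonize(mask), 1.0)

    def test_line_count_equals_nodes(self, cylinder_skeleton, tmp_path):
        path = tmp_path / "out.swc"
        export_swc(cylinder_skeleton, path)
        lines = [l for l in path.read_text().splitlines() if l and not l.startswith("#")]
        assert len(lines) == cylinder_skeleton.n_nodes

    def test_parents_precede_children(self, cylinder_skeleton, tmp_path):
        path = tmp_path / "out.swc"
        export_swc(cylinder_skeleton, path)
        _, _, parents = read_swc(path)
        for i, p in enumerate(parents, start=1):
            assert p == -1 or p < i

    def test_round_trip_positions_and_radii(self, cylinder_skeleton, tmp_path):
        path = tmp_path / "out.swc"
        export_swc(cylinder_skeleton, path)
        positions, radii, _ = read_swc(path)
        got = {tuple(p) for p in positions.astype(int)}
        expect = {tuple(p) for p in cylinder_skeleton.positions}
        assert got == expect
        assert radii.min() > 0

    def test_cycle_broken_at_lowest_radius_edge(self, tmp_path):
        # a 4-node square cycle with one weak (small-radius) corner
        positions = np.array([[0, 0, 0], [0, 0, 1], [0, 1, 1], [0, 1, 0]])
        edges = np.array([[0, 1], [1, 2], [2, 3], [3, 0]])
        radii = np.array([5.0, 5.0, 1.0, 5.0])
        skel = VesselSkeleton(positions, edges, radii)
        n_broken = export_swc(skel, tmp_path / "c.swc")
        assert n_broken == 1
        _, _, parents = read_swc(tmp_path / "c.swc")
        assert (parents == -1).sum() == 1  # still a single connected tree
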