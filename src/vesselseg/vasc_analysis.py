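"""Vascular reconstruction and morphometry on binary vessel masks.

The mask (lumens filled by post-processing) is thinned to a one-voxel-wide
medial-axis skeleton; skeleton voxels become graph nodes connected by
26-adjacency, with redundant "triangle" shortcut edges removed so a clean
tube yields interior nodes of degree 2 and bifurcations of degree >= 3.
Per-node radii come from the Euclidean distance transform of the mask.  On
top of the skeleton graph the module computes the classic morphometric
summaries — total centerline length, length density (mm of vessel per mm^3
of region), bifurcation count and density, a radius histogram — plus a
connectivity-domain labeling (connected components of the skeleton graph,
largest first), and exports the skeleton in tree-structured SWC format.

Vascular loops are legal in the graph; SWC export breaks each cycle at its
lowest-radius edge and notes the break count in a header comment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx
import numpy as np
from scipy import ndimage
from skimage.morphology import skeletonize as _sk_skeletonize

__all__ = [
    "VesselSkeleton", "MorphometryReport",
    "skeleton_mask", "skeletonize", "estimate_radii",
    "morphometry", "connectivity_domains", "export_swc", "read_swc",
]

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)

# the 13 "forward" neighbor offsets: each 26-neighbor pair visited once
_HALF_NEIGHBORS = [
    (dz, dy, dx)
    for dz in (-1, 0, 1)
    for dy in (-1, 0, 1)
    for dx in (-1, 0, 1)
    if (dz, dy, dx) > (0, 0, 0)
]


@dataclass
class VesselSkeleton:
    """Centerline graph: node positions (voxels), radii (um), 26-adjacency edges."""

    positions: np.ndarray                 # (N, 3) int, (z, y, x)
    edges: np.ndarray                     # (E, 2) int node indices
    radii_um: np.ndarray | None = None    # (N,)
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0)

    @property
    def n_nodes(self) -> int:
        return len(self.positions)

    def graph(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(range(self.n_nodes))
        g.add_edges_from(map(tuple, self.edges))
        return g

    def degrees(self) -> np.ndarray:
        deg = np.zeros(self.n_nodes, dtype=int)
        for a, b in self.edges:
            deg[a] += 1
            deg[b] += 1
        return deg

    def edge_lengths_um(self) -> np.ndarray:
        if len(self.edges) == 0:
            return np.zeros(0)
        vs = np.asarray(self.voxel_size_um)
        delta = (self.positions[self.edges[:, 0]] - self.positions[self.edges[:, 1]]) * vs
        return np.linalg.norm(delta, axis=1)


@dataclass
class MorphometryReport:
    total_length_mm: float
    length_density_mm_per_mm3: float
    n_bifurcations: int
    bifurcation_density_per_mm3: float
    radius_histogram: dict[str, int]      # "[lo,hi)" um bins -> node counts
    n_connectivity_domains: int
    region_volume_mm3: float

    def to_dict(self) -> dict:
        return {
            "total_length_mm": self.total_length_mm,
            "length_density_mm_per_mm3": self.length_density_mm_per_mm3,
            "n_bifurcations": self.n_bifurcations,
            "bifurcation_density_per_mm3": self.bifurcation_density_per_mm3,
            "radius_histogram": self.radius_histogram,
            "n_connectivity_domains": self.n_connectivity_domains,
            "region_volume_mm3": self.region_volume_mm3,
        }

    def to_csv(self, path) -> None:
        """One-row CSV of the scalar summaries (histogram stays in the JSON)."""
        cols = ["total_length_mm", "length_density_mm_per_mm3", "n_bifurcations",
                "bifurcation_density_per_mm3", "n_connectivity_domains",
                "region_volume_mm3"]
        d = self.to_dict()
        Path(path).write_text(
            ",".join(cols) + "\n" + ",".join(str(d[c]) for c in cols) + "\n"
        )


def skeleton_mask(mask: np.ndarray) -> np.ndarray:
    """3D medial-axis thinning (Lee) of a binary mask, as a boolean volume.

    Guarantees one skeleton component per mask component: thinning of small
    even-width objects (e.g. a 2x2 bar, which has no center plane) can erase
    them entirely, so any mask component left without skeleton voxels is
    represented by its deepest voxel (maximal distance transform).
    """
    binary = np.asarray(mask) > 0
    if not binary.any():
        return np.zeros_like(binary)
    skel = _sk_skeletonize(binary) > 0
    labels, n = ndimage.label(binary, structure=_STRUCT_26)
    have = np.zeros(n + 1, dtype=bool)
    have[np.unique(labels[skel])] = True
    lost = [i for i in range(1, n + 1) if not have[i]]
    if lost:
        edt = ndimage.distance_transform_edt(binary)
        for i in lost:
            comp = labels == i
            depth = np.where(comp, edt, -1.0)
            skel[np.unravel_index(np.argmax(depth), depth.shape)] = True
    return skel


def _prune_triangle_edges(positions: np.ndarray, edges: list[tuple[int, int]]) -> np.ndarray:
    """Drop diagonal shortcut edges whose endpoints share a strictly closer 2-path.

    In a raw 26-adjacency graph a straight staircase of voxels carries extra
    diagonal edges that inflate node degrees; removing an edge of squared
    length 2 or 3 whenever a common neighbor joins its endpoints by two
    strictly shorter steps restores degree 2 on simple paths without ever
    disconnecting the graph.
    """
    adj: dict[int, set[int]] = {}
    for a, b in edges:
        adj.setdefault(a, set()).add(b)
        adj.setdefault(b, set()).add(a)

    def sq(a: int, b: int) -> int:
        d = positions[a] - positions[b]
        return int(d @ d)

    keep = []
    for a, b in edges:
        l2 = sq(a, b)
        if l2 > 1:
            common = adj.get(a, set()) & adj.get(b, set())
            if any(sq(a, c) < l2 and sq(c, b) < l2 for c in common):
                continue
        keep.append((a, b))
    return np.array(keep, dtype=int).reshape(-1, 2)


def skeletonize(
    mask: np.ndarray,
    voxel_size_um: float | Sequence[float] = 1.0,
    prune_triangles: bool = True,
) -> VesselSkeleton:
    """Thin a binary mask to a centerline skeleton graph (radii unset).

    Thinning preserves topology: the skeleton has the same number of
    connected components as the mask.  Edges connect 26-neighboring
    skeleton voxels; redundant triangle edges are pruned by default.
    """
    vs = (voxel_size_um,) * 3 if np.isscalar(voxel_size_um) else tuple(voxel_size_um)
    skel = skeleton_mask(mask)
    coords = np.argwhere(skel)
    if len(coords) == 0:
        return VesselSkeleton(coords.reshape(0, 3), np.zeros((0, 2), dtype=int), None, vs)
    index = {tuple(c): i for i, c in enumerate(coords)}
    edges: list[tuple[int, int]] = []
    for i, c in enumerate(coords):
        for off in _HALF_NEIGHBORS:
            nb = (c[0] + off[0], c[1] + off[1], c[2] + off[2])
            j = index.get(nb)
            if j is not None:
                edges.append((i, j))
    edge_arr = _prune_triangle_edges(coords, edges) if prune_triangles else \
        np.array(edges, dtype=int).reshape(-1, 2)
    return VesselSkeleton(coords, edge_arr, None, vs)


def estimate_radii(
    mask: np.ndarray,
    skeleton: VesselSkeleton,
    voxel_size_um: float | Sequence[float] = 1.0,
) -> VesselSkeleton:
    """Set each node's radius to the mask's Euclidean distance transform (um)."""
    binary = np.asarray(mask) > 0
    vs = (voxel_size_um,) * 3 if np.isscalar(voxel_size_um) else tuple(voxel_size_um)
    if skeleton.n_nodes and not binary[tuple(skeleton.positions.T)].all():
        raise ValueError("skeleton node outside the mask: skeleton does not match this mask")
    edt = ndimage.distance_transform_edt(binary, sampling=vs)
    radii = edt[tuple(skeleton.positions.T)] if skeleton.n_nodes else np.zeros(0)
    return VesselSkeleton(skeleton.positions, skeleton.edges, np.asarray(radii, dtype=float), vs)


def connectivity_domains(skeleton: VesselSkeleton) -> np.ndarray:
    """Label each node with its connected component id, 1 = largest domain."""
    if skeleton.n_nodes == 0:
        return np.zeros(0, dtype=int)
    comps = sorted(nx.connected_components(skeleton.graph()), key=lambda c: (-len(c), min(c)))
    labels = np.zeros(skeleton.n_nodes, dtype=int)
    for domain_id, comp in enumerate(comps, start=1):
        labels[list(comp)] = domain_id
    return labels


def morphometry(
    skeleton: VesselSkeleton,
    region_mask: np.ndarray | None = None,
    voxel_size_um: float | Sequence[float] = 1.0,
    region_volume_mm3: float | None = None,
) -> MorphometryReport:
    """Length/bifurcation densities and radius histogram over a region.

    Total length is the sum of Euclidean edge lengths.  A bifurcation is a
    branch *point*: a connected cluster of skeleton nodes of degree >= 3
    (thinning often leaves two or three adjacent high-degree voxels at one
    anatomical junction, which must not be double-counted).  Densities
    divide by the region volume — the voxel count of ``region_mask`` times
    the voxel volume, or an explicit ``region_volume_mm3``.  Radius bins
    are [0,1), [1,2), ... um; counts sum to the node count.
    """
    vs = (voxel_size_um,) * 3 if np.isscalar(voxel_size_um) else tuple(voxel_size_um)
    voxel_mm3 = float(np.prod(vs)) * 1e-9
    if region_volume_mm3 is None:
        if region_mask is None:
            raise ValueError("need region_mask or region_volume_mm3")
        region_volume_mm3 = float(np.count_nonzero(region_mask)) * voxel_mm3
    if region_volume_mm3 <= 0:
        raise ValueError("region volume is zero: densities undefined")
    total_len_mm = float(skeleton.edge_lengths_um().sum()) * 1e-3
    deg = skeleton.degrees()
    branch_nodes = np.flatnonzero(deg >= 3)
    if len(branch_nodes):
        sub = skeleton.graph().subgraph(branch_nodes.tolist())
        n_bif = nx.number_connected_components(sub)
    else:
        n_bif = 0
    hist: dict[str, int] = {}
    if skeleton.radii_um is not None and skeleton.n_nodes:
        radii = np.asarray(skeleton.radii_um)
        top = int(math.floor(radii.max())) + 1
        counts, _ = np.histogram(radii, bins=np.arange(0, top + 1))
        hist = {f"[{lo},{lo + 1})": int(c) for lo, c in enumerate(counts)}
    n_domains = int(connectivity_domains(skeleton).max(initial=0))
    return MorphometryReport(
        total_length_mm=total_len_mm,
        length_density_mm_per_mm3=total_len_mm / region_volume_mm3,
        n_bifurcations=n_bif,
        bifurcation_density_per_mm3=n_bif / region_volume_mm3,
        radius_histogram=hist,
        n_connectivity_domains=n_domains,
        region_volume_mm3=region_volume_mm3,
    )


SWC_VESSEL_TYPE = 7  # "custom" type code, used here for vessels


def export_swc(skeleton: VesselSkeleton, path: str | Path) -> int:
    """Write the skeleton as standard 7-column SWC; returns cycle-break count.

    SWC is tree-structured, so each graph cycle is broken at its
    lowest-radius edge (a maximum-spanning-forest over min-endpoint-radius
    edge weights); the number of broken edges is recorded in a header
    comment.  Coordinates are micrometres in (x, y, z) order; each
    connectivity domain contributes one root with parent -1, and every
    parent id precedes its children.
    """
    g = skeleton.graph()
    radii = skeleton.radii_um if skeleton.radii_um is not None else np.ones(skeleton.n_nodes)
    for a, b in g.edges:
        g.edges[a, b]["weight"] = float(min(radii[a], radii[b]))
    # maximum_spanning_tree returns a spanning forest on disconnected graphs
    forest = nx.maximum_spanning_tree(g) if g.number_of_edges() else g
    n_broken = g.number_of_edges() - forest.number_of_edges()
    vs = np.asarray(skeleton.voxel_size_um)
    lines = [
        "# SWC export of a vessel centerline skeleton",
        f"# nodes {skeleton.n_nodes}  cycle_edges_broken {n_broken}",
        "# id type x y z radius parent   (coordinates in um)",
    ]
    swc_id = np.full(skeleton.n_nodes, -1, dtype=int)
    next_id = 1
    comps = sorted(nx.connected_components(forest), key=lambda c: (-len(c), min(c)))
    for comp in comps:
        root = min(comp)
        for parent, child in [(None, root)] + list(nx.bfs_edges(forest, root)):
            swc_id[child] = next_id
            z, y, x = skeleton.positions[child] * vs
            pid = -1 if parent is None else swc_id[parent]
            lines.append(
                f"{next_id} {SWC_VESSEL_TYPE} {x:.3f} {y:.3f} {z:.3f} {radii[child]:.3f} {pid}"
            )
            next_id += 1
    Path(path).write_text("\n".join(lines) + "\n")
    return n_broken


def read_swc(path: str | Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Parse an SWC file: positions (N,3) um in (z,y,x), radii (N,), parents (N,)."""
    positions, radii, parents = [], [], []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split()
        if len(parts) != 7:
            raise ValueError(f"malformed SWC line: {line!r}")
        _, _, x, y, z, r, parent = parts
        positions.append((float(z), float(y), float(x)))
        radii.append(float(r))
        parents.append(int(parent))
    return np.array(positions), np.array(radii), np.array(parents, dtype=int)
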