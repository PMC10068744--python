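"""Synthetic vascular phantoms with known ground truth.

Emulates the appearance of a fluorescence vessel channel in which only the
endothelial wall is labeled: large vessels render as bright tubes with a
dark central lumen (wall-only shell), capillaries as dim solid tubes with
complex branching, on a diffuse noisy background peppered with isolated
fluorescent specks.  Geometry is a seeded random-walk branching tree —
controllable, not anatomically derived — which is sufficient because the
downstream modules depend only on appearance and topology, not on realistic
vascular statistics.

The ground-truth mask always contains the *filled* vessel (lumen included),
matching the annotation convention used for training: the network is asked
to recover the lumen of hollow vessels from wall context, and the
morphological post-processing stage fills whatever closed cavities remain.

All randomness flows through one explicit `numpy.random.Generator`; an
identical seed yields bit-identical volumes.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from vesselseg.volio import VolumeStack, write_stack

__all__ = [
    "PhantomSpec", "VesselTree", "PhantomDataset",
    "generate_tree", "rasterize", "corrupt", "generate_phantom",
    "make_dataset", "hdfmost_like_specs",
]


class InvalidSpecError(ValueError):
    """The phantom specification is degenerate or inconsistent."""


@dataclass(frozen=True)
class PhantomSpec:
    """Generative description of a synthetic vascular volume.

    Intensities are in the units of the output dtype (uint8 by default);
    all geometric quantities are in micrometres with isotropic voxels.
    """

    shape: tuple[int, int, int] = (64, 64, 64)
    voxel_size_um: float = 1.0
    n_trees: int = 2
    radius_range_um: tuple[float, float] = (2.0, 20.0)
    hollow_radius_um: float = 6.0       # at/above this radius only the wall is lit
    wall_thickness_um: float = 2.0
    branch_prob: float = 0.10           # per-step bifurcation probability
    step_len_um: float = 3.0
    tortuosity: float = 0.25            # std of per-step direction perturbation
    n_steps: int = 150                  # growth-step budget per tree
    child_radius_ratio: float = 0.8
    intensity_large: float = 200.0
    intensity_small: float = 70.0
    background_mean: float = 20.0
    background_sd: float = 6.0
    n_speckles: int = 10
    speckle_size_range: tuple[int, int] = (3, 20)
    psf_sigma_um: float = 0.7
    seed: int = 0
    dtype: str = "uint8"

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise InvalidSpecError("n_trees must be >= 1")
        if len(self.shape) != 3 or any(s < 32 for s in self.shape):
            raise InvalidSpecError(f"shape must be >= (32,32,32), got {self.shape}")
        if not (self.intensity_large > self.intensity_small > self.background_mean):
            raise InvalidSpecError(
                "need intensity_large > intensity_small > background_mean "
                f"(got {self.intensity_large}, {self.intensity_small}, {self.background_mean})"
            )
        rmin, rmax = self.radius_range_um
        if rmin < self.voxel_size_um:
            raise InvalidSpecError(f"min radius {rmin} um below one voxel ({self.voxel_size_um} um)")
        if rmax < rmin:
            raise InvalidSpecError("radius_range_um must be (min, max)")
        if not 0.0 <= self.branch_prob <= 1.0:
            raise InvalidSpecError("branch_prob must be in [0, 1]")
        if self.n_steps < 1 or self.step_len_um <= 0:
            raise InvalidSpecError("need n_steps >= 1 and step_len_um > 0")
        if np.dtype(self.dtype) not in (np.dtype("uint8"), np.dtype("uint16")):
            raise InvalidSpecError("dtype must be uint8 or uint16")


@dataclass
class VesselTree:
    """A branching centerline: polylines in voxel coordinates with per-point radii.

    ``polylines[i]`` is a (points, radii) pair — points (N, 3) float (z, y, x)
    voxels, radii (N,) in um.  ``parents[i]`` is None for the root or a
    (polyline index, point index) pair giving the attachment point, so the
    tree is a single connected network.
    """

    polylines: list[tuple[np.ndarray, np.ndarray]]
    parents: list[tuple[int, int] | None]

    @property
    def n_nodes(self) -> int:
        return sum(len(p) for p, _ in self.polylines)

    def all_points(self) -> np.ndarray:
        return np.concatenate([p for p, _ in self.polylines], axis=0)


def _as_rng(rng_state: int | np.random.Generator | None) -> np.random.Generator:
    if isinstance(rng_state, np.random.Generator):
        return rng_state
    return np.random.default_rng(rng_state)


def _unit(v: np.ndarray) -> np.ndarray:
    n = float(np.linalg.norm(v))
    return v / n if n > 0 else np.array([0.0, 0.0, 1.0])


def _perturb(direction: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    return _unit(direction + rng.normal(0.0, sd, size=3))


def generate_tree(spec: PhantomSpec, rng_state: int | np.random.Generator | None = None) -> VesselTree:
    """Grow one random branching vessel tree inside the volume bounds.

    The root radius is drawn from the upper half of ``radius_range_um`` and
    each bifurcation scales both daughters by ``child_radius_ratio`` (never
    below the minimum radius), so radii are non-increasing from root to tip.
    Growth reflects off the volume walls to stay inside bounds.
    """
    rng = _as_rng(rng_state if rng_state is not None else spec.seed)
    rmin, rmax = spec.radius_range_um
    dims = np.array(spec.shape, dtype=float)
    root_r = float(rng.uniform((rmin + rmax) / 2.0, rmax))

    def margin_for(r_um: float) -> np.ndarray:
        m = r_um / spec.voxel_size_um + 1.0
        return np.minimum(m, dims / 2.0 - 1.0)

    m0 = margin_for(root_r)
    pos0 = rng.uniform(m0, dims - 1.0 - m0)
    dir0 = _unit(rng.normal(size=3))

    step_vox = spec.step_len_um / spec.voxel_size_um
    polylines: list[list[tuple[np.ndarray, float]]] = [[(pos0.copy(), root_r)]]
    parents: list[tuple[int, int] | None] = [None]
    # active branch tips: (polyline idx, position, direction, radius)
    tips: list[list] = [[0, pos0.copy(), dir0, root_r]]
    budget = spec.n_steps
    while budget > 0 and tips:
        tip = tips.pop(0)
        poly_idx, pos, direction, radius = tip
        direction = _perturb(direction, spec.tortuosity, rng)
        nxt = pos + direction * step_vox
        m = margin_for(radius)
        for ax in range(3):  # reflect off the walls
            if nxt[ax] < m[ax] or nxt[ax] > dims[ax] - 1.0 - m[ax]:
                direction[ax] = -direction[ax]
        nxt = np.clip(pos + direction * step_vox, m, dims - 1.0 - m)
        polylines[poly_idx].append((nxt.copy(), radius))
        budget -= 1
        if rng.uniform() < spec.branch_prob:
            child_r = max(radius * spec.child_radius_ratio, rmin)
            point_idx = len(polylines[poly_idx]) - 1
            child_dir = _perturb(direction, max(spec.tortuosity, 0.5), rng)
            polylines.append([(nxt.copy(), child_r)])
            parents.append((poly_idx, point_idx))
            tips.append([len(polylines) - 1, nxt.copy(), child_dir, child_r])
            radius = child_r  # symmetric bifurcation: both daughters shrink
        tips.append([poly_idx, nxt, direction, radius])
    out_polys = [
        (np.array([p for p, _ in pl], dtype=float), np.array([r for _, r in pl], dtype=float))
        for pl in polylines
    ]
    return VesselTree(polylines=out_polys, parents=parents)


def _stamp_tree(
    tree: VesselTree,
    spec: PhantomSpec,
    surf: np.ndarray,
    dist: np.ndarray,
    rad: np.ndarray,
) -> None:
    """Update per-voxel nearest-tube fields with one tree's densely sampled centerline.

    surf: min over samples of (distance - radius), voxels (signed surface distance)
    dist/rad: centerline distance and radius (voxels) of the argmin sample
    """
    dims = np.array(spec.shape)
    vs = spec.voxel_size_um
    for points, radii in tree.polylines:
        samples = [(points[0], radii[0])]
        for i in range(len(points) - 1):
            seg = points[i + 1] - points[i]
            seg_len = float(np.linalg.norm(seg))
            n_sub = max(1, int(math.ceil(seg_len / 0.5)))
            for t in range(1, n_sub + 1):
                f = t / n_sub
                samples.append((points[i] + f * seg, radii[i] + f * (radii[i + 1] - radii[i])))
        for p, r_um in samples:
            r = r_um / vs
            h = int(math.ceil(r)) + 2
            lo = np.maximum(np.floor(p).astype(int) - h, 0)
            hi = np.minimum(np.floor(p).astype(int) + h + 1, dims)
            if np.any(lo >= hi):
                continue
            zz = np.arange(lo[0], hi[0], dtype=np.float32) - p[0]
            yy = np.arange(lo[1], hi[1], dtype=np.float32) - p[1]
            xx = np.arange(lo[2], hi[2], dtype=np.float32) - p[2]
            d = np.sqrt(
                zz[:, None, None] ** 2 + yy[None, :, None] ** 2 + xx[None, None, :] ** 2
            )
            cand = d - np.float32(r)
            box = (slice(lo[0], hi[0]), slice(lo[1], hi[1]), slice(lo[2], hi[2]))
            better = cand < surf[box]
            surf[box] = np.where(better, cand, surf[box])
            dist[box] = np.where(better, d, dist[box])
            rad[box] = np.where(better, np.float32(r), rad[box])


def rasterize(
    tree: VesselTree | Sequence[VesselTree],
    spec: PhantomSpec,
) -> tuple[VolumeStack, VolumeStack]:
    """Render trees into a noise-free image and a filled binary truth mask.

    The truth is the union of filled tubes (lumen included).  In the image,
    tubes with radius >= ``hollow_radius_um`` show only an annular wall of
    ``wall_thickness_um`` at ``intensity_large`` — the lumen stays at
    background level — while thinner tubes are solid at ``intensity_small``.
    The image is then blurred with an isotropic Gaussian of
    ``psf_sigma_um``.  Background voxels are zero; :func:`corrupt` adds the
    background offset and noise.
    """
    trees = [tree] if isinstance(tree, VesselTree) else list(tree)
    surf = np.full(spec.shape, np.inf, dtype=np.float32)
    dist = np.zeros(spec.shape, dtype=np.float32)
    rad = np.zeros(spec.shape, dtype=np.float32)
    for t in trees:
        _stamp_tree(t, spec, surf, dist, rad)
    truth = surf <= 0.0
    vs = spec.voxel_size_um
    hollow_vox = spec.hollow_radius_um / vs
    wall_vox = spec.wall_thickness_um / vs
    image = np.zeros(spec.shape, dtype=np.float32)
    solid = truth & (rad < hollow_vox)
    hollow = truth & (rad >= hollow_vox)
    image[solid] = spec.intensity_small
    wall = hollow & (dist >= rad - wall_vox)
    image[wall] = spec.intensity_large  # lumen voxels stay at background level
    if spec.psf_sigma_um > 0:
        image = ndimage.gaussian_filter(image, sigma=spec.psf_sigma_um / vs)
    vs3 = (vs, vs, vs)
    return (
        VolumeStack(image, vs3),
        VolumeStack(truth.astype(np.uint8), vs3),
    )


def _place_speckles(
    protect: np.ndarray,
    spec: PhantomSpec,
    rng: np.random.Generator,
    max_tries: int = 60,
) -> tuple[np.ndarray, int]:
    """Grow ``n_speckles`` random connected blobs disjoint from ``protect``.

    Returns (speckle mask, number successfully placed).  Blobs keep a
    2-voxel clearance from the protected mask and from each other so they
    remain isolated connected components after a mild blur.
    """
    shape = spec.shape
    clearance = 2 + int(math.ceil(spec.psf_sigma_um / spec.voxel_size_um))
    forbidden = ndimage.binary_dilation(protect > 0, iterations=clearance) if protect.any() else np.zeros(shape, bool)
    mask = np.zeros(shape, dtype=bool)
    placed = 0
    neigh = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]])
    for _ in range(spec.n_speckles):
        size = int(rng.integers(spec.speckle_size_range[0], spec.speckle_size_range[1] + 1))
        ok = False
        for _try in range(max_tries):
            seed_vox = rng.integers(1, np.array(shape) - 1)
            if forbidden[tuple(seed_vox)] or mask[tuple(seed_vox)]:
                continue
            blob = {tuple(seed_vox)}
            frontier = [tuple(seed_vox)]
            while len(blob) < size and frontier:
                base = frontier[int(rng.integers(len(frontier)))]
                step = neigh[int(rng.integers(6))]
                cand = tuple(np.array(base) + step)
                if any(c < 1 or c >= s - 1 for c, s in zip(cand, shape)):
                    continue
                if forbidden[cand]:
                    break
                if cand not in blob:
                    blob.add(cand)
                    frontier.append(cand)
            if len(blob) < spec.speckle_size_range[0]:
                continue
            idx = tuple(np.array(sorted(blob)).T)
            if forbidden[idx].any():
                continue
            mask[idx] = True
            # keep future blobs (and the blur) from merging with this one
            forbidden |= ndimage.binary_dilation(mask, iterations=clearance)
            placed += 1
            ok = True
            break
        if not ok:
            warnings.warn(
                f"speckle placement failed after {max_tries} tries; placed {placed} of {spec.n_speckles}",
                stacklevel=2,
            )
    return mask, placed


def corrupt(
    image: VolumeStack,
    spec: PhantomSpec,
    rng_state: int | np.random.Generator | None = None,
    truth: VolumeStack | np.ndarray | None = None,
) -> VolumeStack:
    """Add background offset, Gaussian noise, and isolated fluorescent specks.

    Speckles are rejection-sampled away from the vessel mask (``truth`` if
    given, else the nonzero support of the clean image) so they form
    components disjoint from the vasculature.  The result is clipped and
    cast to the spec dtype.  The number of speckles actually placed is
    reported in ``meta['n_speckles_placed']``.
    """
    if tuple(image.shape) != tuple(spec.shape):
        raise InvalidSpecError(f"image shape {image.shape} != spec shape {spec.shape}")
    rng = _as_rng(rng_state if rng_state is not None else spec.seed + 1)
    img = image.voxels.astype(np.float32)
    if truth is not None:
        protect = (truth.voxels if isinstance(truth, VolumeStack) else np.asarray(truth)) > 0
    else:
        protect = img > max(1.0, 0.05 * spec.intensity_small)
    placed = 0
    if spec.n_speckles > 0:
        speckle_mask, placed = _place_speckles(protect, spec, rng)
        layer = np.zeros(spec.shape, dtype=np.float32)
        layer[speckle_mask] = rng.uniform(
            spec.intensity_small, spec.intensity_large, size=int(speckle_mask.sum())
        ).astype(np.float32)
        if spec.psf_sigma_um > 0:
            layer = ndimage.gaussian_filter(layer, sigma=spec.psf_sigma_um / spec.voxel_size_um)
        img = img + layer
    img = img + spec.background_mean
    if spec.background_sd > 0:
        img = img + rng.normal(0.0, spec.background_sd, size=spec.shape).astype(np.float32)
    info = np.iinfo(np.dtype(spec.dtype))
    out = np.clip(np.rint(img), info.min, info.max).astype(spec.dtype)
    vs = image.voxel_size_um
    return VolumeStack(out, vs, meta={"n_speckles_placed": placed})


def generate_phantom(
    spec: PhantomSpec,
    rng_state: int | np.random.Generator | None = None,
) -> tuple[VolumeStack, VolumeStack, list[VesselTree]]:
    """Generate a complete phantom: corrupted image, filled truth, and the trees."""
    rng = _as_rng(rng_state if rng_state is not None else spec.seed)
    trees = [generate_tree(spec, rng) for _ in range(spec.n_trees)]
    clean, truth = rasterize(trees, spec)
    image = corrupt(clean, spec, rng, truth=truth)
    return image, truth, trees


@dataclass
class PhantomDataset:
    """Cropped (image, truth) block pairs partitioned into train/val/test."""

    blocks: list[dict]          # keys: index, split, image, truth
    block_shape: tuple[int, int, int]
    split_fractions: tuple[float, float, float]

    def split(self, name: str) -> list[tuple[np.ndarray, np.ndarray]]:
        return [(b["image"], b["truth"]) for b in self.blocks if b["split"] == name]

    def split_sizes(self) -> dict[str, int]:
        out: dict[str, int] = {}
        for b in self.blocks:
            out[b["split"]] = out.get(b["split"], 0) + 1
        return out

    def write(self, dir_path: str | Path, compress: bool = True) -> Path:
        """Write each block as paired TIFF stacks plus a manifest TSV."""
        root = Path(dir_path)
        root.mkdir(parents=True, exist_ok=True)
        lines = ["#block\tsplit\timage_dir\ttruth_dir"]
        for b in self.blocks:
            img_dir = root / f"block_{b['index']:04d}" / "image"
            tr_dir = root / f"block_{b['index']:04d}" / "truth"
            write_stack(b["image"], img_dir, compress=compress)
            write_stack(b["truth"], tr_dir, compress=compress)
            lines.append(f"{b['index']}\t{b['split']}\t{img_dir}\t{tr_dir}")
        manifest = root / "manifest.tsv"
        manifest.write_text("\n".join(lines) + "\n")
        return manifest


def _split_counts(n: int, fractions: Sequence[float]) -> list[int]:
    fr = np.asarray(fractions, dtype=float)
    if abs(fr.sum() - 1.0) > 1e-9:
        raise InvalidSpecError(f"split fractions must sum to 1, got {fractions}")
    raw = fr * n
    counts = np.floor(raw).astype(int)
    # hand remaining blocks to the largest fractional parts (ties: earlier split)
    order = np.argsort(-(raw - counts), kind="stable")
    for i in range(n - counts.sum()):
        counts[order[i % len(counts)]] += 1
    return counts.tolist()


def hdfmost_like_specs(
    shape: tuple[int, int, int] = (96, 96, 96),
    seed: int = 0,
) -> list[PhantomSpec]:
    """Study-condition phantoms emulating a 1 um vessel-channel block mix.

    Real vessel-channel data is capillary-dominated — most vessels are
    capillaries with radii of 2-3 um and only a few percent of the volume is
    vessel — with occasional penetrating arterioles/venules (diameters up to
    ~20 um) that are wall-labeled and show a dark lumen.  Three volume
    recipes, cycled per generated volume: two capillary fields (thin, dim,
    branched trees) and one mixed volume that adds larger hollow vessels.
    Rare trunk vessels wider than ~20 um diameter are not emulated.
    """
    cap = PhantomSpec(
        shape=shape, n_trees=4, radius_range_um=(2.0, 4.0),
        branch_prob=0.15, n_steps=180, seed=seed,
    )
    mixed = PhantomSpec(
        shape=shape, n_trees=3, radius_range_um=(2.0, 10.0),
        branch_prob=0.12, n_steps=160, seed=seed,
    )
    return [cap, replace(cap, seed=seed + 1), mixed]


def make_dataset(
    spec: PhantomSpec | Sequence[PhantomSpec],
    n_blocks: int,
    block_shape: Sequence[int] = (64, 64, 64),
    split: Sequence[float] = (0.7, 0.15, 0.15),
    seed: int | None = None,
    background_fraction: float = 47.0 / 179.0,
    crops_per_volume: int = 4,
) -> PhantomDataset:
    """Randomly crop (image, truth) blocks from fresh phantoms and partition them.

    ``spec`` may be a single recipe or a sequence of recipes cycled over the
    generated volumes (see :func:`hdfmost_like_specs`).  A
    ``background_fraction`` of the blocks contains background only (noise
    and speckles, empty truth), mirroring training sets that keep their
    vessel-free crops.  The split is disjoint and exhaustive; a fixed seed
    reproduces the full dataset bit-for-bit.
    """
    if n_blocks < 1:
        raise InvalidSpecError("n_blocks must be >= 1")
    specs = [spec] if isinstance(spec, PhantomSpec) else list(spec)
    if not specs:
        raise InvalidSpecError("need at least one phantom spec")
    bs = tuple(int(v) for v in block_shape)
    for s in specs:
        if any(b > d for b, d in zip(bs, s.shape)):
            raise InvalidSpecError(f"block_shape {bs} larger than phantom shape {s.shape}")
    rng = _as_rng(seed if seed is not None else specs[0].seed)
    n_bg = int(round(n_blocks * background_fraction))
    n_fg = n_blocks - n_bg
    pairs: list[tuple[np.ndarray, np.ndarray]] = []
    min_fg_voxels = max(64, int(0.001 * np.prod(bs)))
    vol_idx = 0
    while len(pairs) < n_fg:
        vspec = specs[vol_idx % len(specs)]
        vol_idx += 1
        image, truth, _ = generate_phantom(vspec, rng)
        got = 0
        attempts = 0
        while got < crops_per_volume and len(pairs) < n_fg and attempts < 40:
            attempts += 1
            o = [int(rng.integers(0, s - b + 1)) for s, b in zip(vspec.shape, bs)]
            sl = tuple(slice(v, v + b) for v, b in zip(o, bs))
            if truth.voxels[sl].sum() < min_fg_voxels:
                continue
            pairs.append((image.voxels[sl].copy(), truth.voxels[sl].copy()))
            got += 1
    bg_spec = replace(specs[0], shape=bs)
    for _ in range(n_bg):
        empty = VolumeStack(np.zeros(bs, dtype=np.float32), (bg_spec.voxel_size_um,) * 3)
        noisy = corrupt(empty, bg_spec, rng, truth=np.zeros(bs, dtype=np.uint8))
        pairs.append((noisy.voxels, np.zeros(bs, dtype=np.uint8)))
    order = rng.permutation(n_blocks)
    counts = _split_counts(n_blocks, split)
    names = ["train"] * counts[0] + ["val"] * counts[1] + ["test"] * counts[2]
    blocks = []
    for rank, block_idx in enumerate(order):
        img, tr = pairs[int(block_idx)]
        blocks.append({"index": rank, "split": names[rank], "image": img, "truth": tr})
    return PhantomDataset(blocks=blocks, block_shape=bs, split_fractions=tuple(split))
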