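"""Volume I/O and blockwise decomposition.

Volumes are stored on disk as ordered stacks of 2D TIFF slices, one file per
z-plane, which is the native layout of serial-sectioning microscopes.  In
memory a volume is a :class:`VolumeStack`: a (z, y, x)-indexed array plus
voxel-size metadata.  Large volumes are decomposed into fixed-size blocks
with a guaranteed overlap so each block can be segmented independently and
the binary results merged back with a voxelwise OR; :func:`plan_blocks`,
:func:`extract_blocks` and :func:`fuse_blocks` implement that round trip
exactly (fusion of unmodified blocks reproduces the input volume).

Conventions: coordinates are 0-based (z, y, x); block extents are half-open
[origin, origin + shape); binary masks are written as uint8 {0, 255}.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import tifffile

__all__ = [
    "VolumeStack", "BlockSpec", "BlockGrid",
    "read_stack", "write_stack", "resample",
    "plan_blocks", "extract_blocks", "fuse_blocks", "plan_sections",
    "write_block_coords", "read_block_coords",
]

DEFAULT_BLOCK = 192
DEFAULT_OVERLAP = 32


class StackFormatError(ValueError):
    """A slice stack is malformed (mixed shapes/dtypes, empty directory...)."""


@dataclass
class VolumeStack:
    """A 3D scalar image indexed (z, y, x) with voxel-size metadata."""

    voxels: np.ndarray
    voxel_size_um: tuple[float, float, float] = (1.0, 1.0, 1.0)
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"expected a 3D array, got ndim={self.voxels.ndim}")
        vs = tuple(float(v) for v in self.voxel_size_um)
        if len(vs) != 3 or any(v <= 0 for v in vs):
            raise ValueError(f"voxel_size_um must be 3 positive floats, got {self.voxel_size_um}")
        self.voxel_size_um = vs

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def dtype(self) -> np.dtype:
        return self.voxels.dtype

    def is_binary(self) -> bool:
        u = np.unique(self.voxels)
        return bool(np.isin(u, (0, 1, 255)).all())


@dataclass(frozen=True)
class BlockSpec:
    """One block of a :class:`BlockGrid`: integer id, voxel origin, shape."""

    index: int
    origin: tuple[int, int, int]
    shape: tuple[int, int, int]


@dataclass
class BlockGrid:
    """Decomposition of a volume into equal-sized overlapped blocks."""

    volume_shape: tuple[int, int, int]
    block_shape: tuple[int, int, int]
    overlap: int
    blocks: list[BlockSpec]

    def __len__(self) -> int:
        return len(self.blocks)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, BlockGrid):
            return NotImplemented
        return (
            tuple(self.volume_shape) == tuple(other.volume_shape)
            and tuple(self.block_shape) == tuple(other.block_shape)
            and self.overlap == other.overlap
            and self.blocks == other.blocks
        )


_TIFF_RE = re.compile(r".*\.tiff?$", re.IGNORECASE)


def _slice_files(dir_path: str | Path) -> list[Path]:
    d = Path(dir_path)
    if not d.is_dir():
        raise FileNotFoundError(f"not a directory: {d}")
    files = sorted(p for p in d.iterdir() if _TIFF_RE.match(p.name))
    if not files:
        raise FileNotFoundError(f"no TIFF slices found in {d}")
    return files


def read_stack(dir_path: str | Path, voxel_size_um: Sequence[float] = (1.0, 1.0, 1.0)) -> VolumeStack:
    """Assemble the TIFF slices of a directory (filename order) into a volume.

    Raises :class:`StackFormatError` naming the offending file if slice
    shapes or dtypes are inconsistent, FileNotFoundError if the directory
    holds no TIFF files.
    """
    files = _slice_files(dir_path)
    first = tifffile.imread(files[0])
    if first.ndim != 2:
        raise StackFormatError(f"{files[0]}: expected a 2D slice, got ndim={first.ndim}")
    out = np.empty((len(files),) + first.shape, dtype=first.dtype)
    out[0] = first
    for z, f in enumerate(files[1:], start=1):
        sl = tifffile.imread(f)
        if sl.shape != first.shape:
            raise StackFormatError(f"{f}: slice shape {sl.shape} != {first.shape} of {files[0]}")
        if sl.dtype != first.dtype:
            raise StackFormatError(f"{f}: slice dtype {sl.dtype} != {first.dtype} of {files[0]}")
        out[z] = sl
    return VolumeStack(out, tuple(voxel_size_um))


def write_stack(
    volume: VolumeStack | np.ndarray,
    dir_path: str | Path,
    compress: bool = True,
    prefix: str = "img_",
) -> list[Path]:
    """Write one 2D TIFF per z-slice (``img_0000.tif`` ...), LZW-compressed on request.

    Boolean or {0, 1} masks are widened to uint8 {0, 255} so the files open
    in any image tool.
    """
    arr = volume.voxels if isinstance(volume, VolumeStack) else np.asarray(volume)
    if arr.ndim != 3:
        raise ValueError("write_stack expects a 3D volume")
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    elif arr.dtype == np.uint8 and arr.max(initial=0) <= 1:
        arr = arr * 255
    d = Path(dir_path)
    d.mkdir(parents=True, exist_ok=True)
    compression = "lzw" if compress else None
    paths = []
    for z in range(arr.shape[0]):
        p = d / f"{prefix}{z:04d}.tif"
        tifffile.imwrite(p, arr[z], compression=compression)
        paths.append(p)
    return paths


def resample(volume: VolumeStack, factor: Sequence[int]) -> VolumeStack:
    """Integer-factor downsampling: block-mean for images, majority for masks.

    Each output voxel is the mean of a ``factor``-shaped cell of input
    voxels; for binary masks the cell majority decides, with exact ties
    going to foreground.  Trailing voxels that do not fill a whole cell are
    dropped.  The voxel size is multiplied by the factor.
    """
    f = tuple(int(v) for v in factor)
    if len(f) != 3 or any(v < 1 for v in f):
        raise ValueError(f"unsupported resampling factor {factor}: need 3 integers >= 1")
    if any(int(v) != float(v0) for v, v0 in zip(f, factor)):
        raise ValueError(f"unsupported resampling factor {factor}: non-integer")
    arr = volume.voxels
    if f == (1, 1, 1):
        return VolumeStack(arr.copy(), volume.voxel_size_um)
    binary = volume.is_binary()
    work = arr.astype(np.float64)
    if binary:
        work = (work > 0).astype(np.float64)
    crop = tuple(s - s % v for s, v in zip(arr.shape, f))
    work = work[: crop[0], : crop[1], : crop[2]]
    nz, ny, nx = (c // v for c, v in zip(crop, f))
    work = work.reshape(nz, f[0], ny, f[1], nx, f[2]).mean(axis=(1, 3, 5))
    if binary:
        out = (work >= 0.5).astype(np.uint8)  # ties -> foreground
    else:
        out = np.rint(work).astype(arr.dtype)
    vs = tuple(v * s for v, s in zip(f, volume.voxel_size_um))
    return VolumeStack(out, vs)


def _axis_origins(dim: int, b: int, stride: int) -> list[int]:
    if dim <= b:
        return [0]
    origins = list(range(0, dim - b + 1, stride))
    if origins[-1] + b < dim:
        origins.append(dim - b)  # clamp the last block to the edge
    return origins


def plan_blocks(
    volume_shape: Sequence[int],
    block_shape: int | Sequence[int] = DEFAULT_BLOCK,
    overlap: int = DEFAULT_OVERLAP,
) -> BlockGrid:
    """Plan an overlapped block decomposition of a volume.

    Per axis, block origins run 0, s, 2s, ... with stride s = B - overlap;
    a final block that would overrun is clamped to ``dim - B`` (gaining extra
    overlap), and an axis shorter than B gets a single block at 0 whose
    extraction is zero-padded.  Blocks are ordered by (z, y, x) origin.
    """
    shape = tuple(int(v) for v in volume_shape)
    if isinstance(block_shape, (int, np.integer)):
        bs = (int(block_shape),) * 3
    else:
        bs = tuple(int(v) for v in block_shape)
    if len(shape) != 3 or len(bs) != 3:
        raise ValueError("volume_shape and block_shape must be 3D")
    if not all(b > overlap >= 0 for b in bs):
        raise ValueError(f"need block > overlap >= 0, got block={bs}, overlap={overlap}")
    per_axis = [_axis_origins(d, b, b - overlap) for d, b in zip(shape, bs)]
    blocks = []
    idx = 0
    for z in per_axis[0]:
        for y in per_axis[1]:
            for x in per_axis[2]:
                blocks.append(BlockSpec(index=idx, origin=(z, y, x), shape=bs))
                idx += 1
    return BlockGrid(volume_shape=shape, block_shape=bs, overlap=overlap, blocks=blocks)


def extract_blocks(
    volume: VolumeStack | np.ndarray,
    grid: BlockGrid,
    coord_path: str | Path | None = None,
) -> list[tuple[BlockSpec, np.ndarray]]:
    """Copy each planned block out of the volume (zero-padding short axes).

    Optionally writes the plain-text coordinate record via
    :func:`write_block_coords`.
    """
    arr = volume.voxels if isinstance(volume, VolumeStack) else np.asarray(volume)
    if arr.shape != tuple(grid.volume_shape):
        raise ValueError(f"volume shape {arr.shape} != grid volume_shape {grid.volume_shape}")
    out = []
    for spec in grid.blocks:
        sl = tuple(
            slice(o, min(o + b, d)) for o, b, d in zip(spec.origin, spec.shape, arr.shape)
        )
        chunk = arr[sl]
        if chunk.shape != spec.shape:
            pad = [(0, b - c) for b, c in zip(spec.shape, chunk.shape)]
            chunk = np.pad(chunk, pad, mode="constant")
        else:
            chunk = chunk.copy()
        out.append((spec, chunk))
    if coord_path is not None:
        write_block_coords(grid, coord_path)
    return out


def write_block_coords(grid: BlockGrid, path: str | Path) -> None:
    """Write the block coordinate record: one TAB-separated line per block."""
    lines = ["#index\tz\ty\tx\tbz\tby\tbx"]
    for b in grid.blocks:
        lines.append(
            f"{b.index}\t{b.origin[0]}\t{b.origin[1]}\t{b.origin[2]}"
            f"\t{b.shape[0]}\t{b.shape[1]}\t{b.shape[2]}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_block_coords(
    path: str | Path,
    volume_shape: Sequence[int] | None = None,
    overlap: int = DEFAULT_OVERLAP,
) -> BlockGrid:
    """Parse a coordinate record back into a :class:`BlockGrid`."""
    blocks = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = [int(v) for v in line.split("\t")]
        if len(parts) != 7:
            raise ValueError(f"malformed coordinate line: {line!r}")
        blocks.append(BlockSpec(index=parts[0], origin=tuple(parts[1:4]), shape=tuple(parts[4:7])))
    if not blocks:
        raise ValueError(f"no blocks in coordinate file {path}")
    bs = blocks[0].shape
    if volume_shape is None:
        volume_shape = tuple(
            max(min(b.origin[i] + b.shape[i], 10**9) for b in blocks) for i in range(3)
        )
    return BlockGrid(volume_shape=tuple(volume_shape), block_shape=bs, overlap=overlap,
                     blocks=sorted(blocks, key=lambda b: b.index))


def fuse_blocks(
    blocks: Sequence[tuple[BlockSpec, np.ndarray]],
    grid: BlockGrid,
    volume_shape: Sequence[int] | None = None,
) -> VolumeStack:
    """OR-merge segmented blocks back into a full binary volume.

    Every grid cell must be present; padding added at extraction (axes
    shorter than the block) is trimmed before merging so it can never leak
    foreground.  Overlap voxels take the logical OR of all covering blocks,
    making the result independent of block order.
    """
    shape = tuple(volume_shape) if volume_shape is not None else tuple(grid.volume_shape)
    have = {spec.index for spec, _ in blocks}
    missing = sorted(b.index for b in grid.blocks if b.index not in have)
    if missing:
        raise ValueError(f"fuse_blocks: missing segmented blocks for grid indices {missing}")
    out = np.zeros(shape, dtype=bool)
    for spec, chunk in sorted(blocks, key=lambda t: t[0].index):
        chunk = np.asarray(chunk)
        if chunk.shape != tuple(spec.shape):
            raise ValueError(f"block {spec.index}: shape {chunk.shape} != spec {spec.shape}")
        ext = tuple(min(o + b, d) - o for o, b, d in zip(spec.origin, spec.shape, shape))
        sl_out = tuple(slice(o, o + e) for o, e in zip(spec.origin, ext))
        sl_in = tuple(slice(0, e) for e in ext)
        out[sl_out] |= chunk[sl_in] > 0
    return VolumeStack(out.astype(np.uint8), (1.0, 1.0, 1.0))


def plan_sections(n_slices: int, n_workers: int, halo: int = DEFAULT_OVERLAP) -> list[tuple[int, int]]:
    """Split [0, n_slices) into near-equal contiguous z-sections for workers.

    Consecutive sections share at least ``halo`` slices (clipped at the
    volume end).  With more workers than slices, fewer non-empty sections
    are returned.  Deterministic for fixed inputs.
    """
    if n_workers < 1:
        raise ValueError("n_workers must be >= 1")
    n_sections = min(n_workers, n_slices) or 1
    bounds = np.linspace(0, n_slices, n_sections + 1).astype(int)
    sections = []
    start = 0
    for i in range(n_sections):
        stop = int(bounds[i + 1])
        stop_h = min(n_slices, stop + (halo if i < n_sections - 1 else 0))
        sections.append((start, stop_h))
        # start the next section so the shared halo is >= `halo` even when
        # the extension above was clipped at the volume end
        start = max(0, min(stop, stop_h - halo))
    return sections
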