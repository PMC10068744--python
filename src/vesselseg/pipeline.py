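"""End-to-end orchestration: blocking -> block prediction -> fusion -> clean-up.

The pipeline expresses parallelism as a deterministic map over independent
work items (z-sections for reading, blocks for prediction) merged in fixed
index order, so the output is bit-identical for any worker count.  Block
prediction may be backed by a trained network checkpoint or by any
pointwise predictor callable (e.g. a global threshold), which makes the
blocking/fusion machinery testable in isolation.

Morphological post-processing runs once on the fused whole volume rather
than per worker section: the plane-wise fill is a global operation along
each axis, so only whole-volume application guarantees results independent
of how the volume was partitioned.  Each run writes a JSON manifest
recording the configuration actually used, per-stage timings, and block and
component counts, so runs are auditable.
"""

from __future__ import annotations

import json
import logging
import os
import threading
import time
from concurrent.futures import ThreadPoolExecutor
from dataclasses import dataclass, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import tifffile
import yaml
from scipy import ndimage

from vesselseg import net as net_mod
from vesselseg import volio
from vesselseg.metrics import cl_dice, hausdorff, overlap_metrics
from vesselseg.postprocess import postprocess_mask
from vesselseg.vasc_analysis import estimate_radii, morphometry, skeletonize
from vesselseg.volio import VolumeStack

__all__ = ["PipelineConfig", "segment_volume", "run_experiment", "threshold_predictor"]

logger = logging.getLogger("vesselseg.pipeline")

_STRUCT_26 = np.ones((3, 3, 3), dtype=bool)


@dataclass
class PipelineConfig:
    """Everything a segmentation run needs; YAML-serializable."""

    input_dir: str = ""
    output_dir: str = ""
    checkpoint: str | None = None
    block_shape: int = volio.DEFAULT_BLOCK
    overlap: int = volio.DEFAULT_OVERLAP
    resample_factor: tuple[int, int, int] = (1, 1, 1)
    threshold: float = 0.5
    min_component: int = 100
    connectivity: int = 26
    skip_fill: bool = False
    skip_remove: bool = False
    n_workers: int = 1
    seed: int = 0
    compress: bool = True
    block_cache_dir: str | None = None

    def __post_init__(self) -> None:
        if self.block_shape <= self.overlap:
            raise ValueError(f"block_shape {self.block_shape} must exceed overlap {self.overlap}")
        if self.n_workers < 1:
            raise ValueError("n_workers must be >= 1")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        if "resample_factor" in data:
            data["resample_factor"] = tuple(data["resample_factor"])
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["resample_factor"] = list(d["resample_factor"])
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))


def threshold_predictor(threshold: float) -> Callable[[np.ndarray], np.ndarray]:
    """A pointwise stand-in predictor: global intensity threshold, no learning."""

    def predict(block: np.ndarray) -> np.ndarray:
        return (block > threshold).astype(np.uint8)

    return predict


def _read_volume_parallel(input_dir: str | Path, n_workers: int) -> VolumeStack:
    files = volio._slice_files(input_dir)
    first = tifffile.imread(files[0])
    out = np.empty((len(files),) + first.shape, dtype=first.dtype)
    out[0] = first

    def read_one(z: int) -> None:
        sl = tifffile.imread(files[z])
        if sl.shape != first.shape or sl.dtype != first.dtype:
            raise volio.StackFormatError(f"{files[z]}: inconsistent slice")
        out[z] = sl

    if n_workers > 1 and len(files) > 1:
        with ThreadPoolExecutor(max_workers=n_workers) as pool:
            list(pool.map(read_one, range(1, len(files))))
    else:
        for z in range(1, len(files)):
            read_one(z)
    return VolumeStack(out)


def _predict_blocks(
    blocks: Sequence[tuple[volio.BlockSpec, np.ndarray]],
    predictor: Callable[[np.ndarray], np.ndarray],
    n_workers: int,
    cache_dir: str | Path | None = None,
) -> list[tuple[volio.BlockSpec, np.ndarray]]:
    cache = Path(cache_dir) if cache_dir else None
    if cache:
        cache.mkdir(parents=True, exist_ok=True)
    # workers overlap file I/O; the numerical prediction itself is serialized
    # so results are bit-identical for any worker count (concurrent BLAS use
    # can leave threads with diverging floating-point behavior)
    compute_lock = threading.Lock()

    def run_one(item: tuple[volio.BlockSpec, np.ndarray]) -> tuple[volio.BlockSpec, np.ndarray]:
        spec, block = item
        if cache:
            f = cache / f"block_{spec.index:05d}.tif"
            if f.exists():
                return spec, (tifffile.imread(f) > 0).astype(np.uint8)
        with compute_lock:
            mask = (np.asarray(predictor(block)) > 0).astype(np.uint8)
        if mask.shape != block.shape:
            raise ValueError(f"predictor changed block shape: {mask.shape} vs {block.shape}")
        if cache:
            tmp = cache / f".block_{spec.index:05d}.tif.tmp"
            tifffile.imwrite(tmp, mask * 255, compression="lzw")
            os.replace(tmp, cache / f"block_{spec.index:05d}.tif")  # content-complete or absent
        return spec, mask

    if n_workers > 1:
        with ThreadPoolExecutor(max_workers=n_workers) as pool:
            results = list(pool.map(run_one, blocks))
    else:
        results = [run_one(b) for b in blocks]
    return sorted(results, key=lambda t: t[0].index)


def segment_volume(
    cfg: PipelineConfig,
    predictor: Callable[[np.ndarray], np.ndarray] | None = None,
) -> dict:
    """Run the full pipeline on a TIFF slice stack; returns the RunManifest dict.

    Stages: parallel slice reading over z-sections, optional integer
    resampling, overlapped blocking with a coordinate record, block
    prediction over the worker pool, OR-fusion, plane-wise hole filling,
    small-component removal, LZW TIFF output.  Fails fast (before heavy
    compute) on unreadable inputs or a missing checkpoint.
    """
    t_start = time.time()
    in_dir, out_dir = Path(cfg.input_dir), Path(cfg.output_dir)
    if not in_dir.is_dir():
        raise FileNotFoundError(f"[read] input stack not found: {in_dir}")
    if predictor is None:
        if cfg.checkpoint is None:
            raise ValueError("[predict] need a checkpoint or an explicit predictor")
        if not Path(cfg.checkpoint).exists():
            raise FileNotFoundError(f"[predict] checkpoint not found: {cfg.checkpoint}")
        network = net_mod.load_checkpoint(cfg.checkpoint)
        predictor = lambda block: net_mod.predict_block(network, block, cfg.threshold)
    timings: dict[str, float] = {}

    t0 = time.time()
    volume = _read_volume_parallel(in_dir, cfg.n_workers)
    sections = volio.plan_sections(volume.shape[0], cfg.n_workers, halo=cfg.overlap)
    timings["read_s"] = time.time() - t0
    logger.info("[read] %s slices from %s (%d sections, %d workers)",
                volume.shape[0], in_dir, len(sections), cfg.n_workers)

    if tuple(cfg.resample_factor) != (1, 1, 1):
        t0 = time.time()
        volume = volio.resample(volume, cfg.resample_factor)
        timings["resample_s"] = time.time() - t0

    t0 = time.time()
    grid = volio.plan_blocks(volume.shape, cfg.block_shape, cfg.overlap)
    out_dir.mkdir(parents=True, exist_ok=True)
    blocks = volio.extract_blocks(volume, grid, coord_path=out_dir / "block_coords.txt")
    timings["blocking_s"] = time.time() - t0
    logger.info("[blocking] %d blocks of %s, overlap %d", len(grid), grid.block_shape, cfg.overlap)

    t0 = time.time()
    predicted = _predict_blocks(blocks, predictor, cfg.n_workers, cfg.block_cache_dir)
    timings["predict_s"] = time.time() - t0

    t0 = time.time()
    fused = volio.fuse_blocks(predicted, grid, volume.shape)
    timings["fuse_s"] = time.time() - t0

    t0 = time.time()
    labels_before = int(ndimage.label(fused.voxels > 0, structure=_STRUCT_26)[1])
    mask = postprocess_mask(
        fused.voxels,
        min_size=cfg.min_component,
        connectivity=cfg.connectivity,
        skip_fill=cfg.skip_fill,
        skip_remove=cfg.skip_remove,
    )
    labels_after = int(ndimage.label(mask > 0, structure=_STRUCT_26)[1])
    timings["postprocess_s"] = time.time() - t0
    logger.info("[postprocess] threshold=%s min_component=%d connectivity=%d: "
                "%d -> %d components", cfg.threshold, cfg.min_component,
                cfg.connectivity, labels_before, labels_after)

    t0 = time.time()
    volio.write_stack(mask, out_dir / "mask", compress=cfg.compress)
    timings["write_s"] = time.time() - t0

    from vesselseg import __version__

    manifest = {
        "version": __version__,
        "config": {**asdict(cfg), "resample_factor": list(cfg.resample_factor)},
        "volume_shape": list(volume.shape),
        "n_sections": len(sections),
        "n_blocks": len(grid),
        "components_before_removal": labels_before,
        "components_after_removal": labels_after,
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "total_s": round(time.time() - t_start, 3),
    }
    tmp = out_dir / ".manifest.json.tmp"
    tmp.write_text(json.dumps(manifest, indent=2))
    os.replace(tmp, out_dir / "manifest.json")  # atomic at run end
    return manifest


def run_experiment(
    pred_dir: str | Path,
    truth_dir: str | Path,
    out_csv: str | Path | None = None,
    out_json: str | Path | None = None,
    voxel_size_um: float = 1.0,
    region_mask: np.ndarray | None = None,
) -> dict:
    """Evaluate a prediction stack against truth, then run morphometry on it.

    Produces the six Table-style metric columns (precision, recall, dice,
    jaccard, cldice, hd) as one CSV row and the morphometry report as JSON.
    The morphometry region defaults to the full volume extent.
    """
    pred = volio.read_stack(pred_dir)
    truth = volio.read_stack(truth_dir)
    m = overlap_metrics(pred.voxels, truth.voxels)
    m["cldice"] = cl_dice(pred.voxels, truth.voxels)
    try:
        m["hd"] = hausdorff(pred.voxels, truth.voxels)
    except ValueError:
        m["hd"] = float("nan")
    skel = skeletonize(pred.voxels, voxel_size_um)
    skel = estimate_radii(pred.voxels, skel, voxel_size_um)
    region = region_mask if region_mask is not None else np.ones(pred.shape, dtype=bool)
    report = morphometry(skel, region_mask=region, voxel_size_um=voxel_size_um)
    result = {"metrics": m, "morphometry": report.to_dict()}
    if out_csv is not None:
        cols = ["precision", "recall", "dice", "jaccard", "cldice", "hd"]
        lines = [",".join(cols), ",".join(f"{m[c]:.6f}" for c in cols)]
        Path(out_csv).write_text("\n".join(lines) + "\n")
    if out_json is not None:
        Path(out_json).write_text(json.dumps(result["morphometry"], indent=2))
    return result
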