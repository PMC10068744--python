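"""Volume I/O, resampling, overlapped blocking and OR-fusion."""

import numpy as np
import pytest
import tifffile
from hypothesis import given, settings, strategies as st

from vesselseg.volio import (
    BlockGrid,
    StackFormatError,
    extract_blocks,
    fuse_blocks,
    plan_blocks,
    plan_sections,
    read_block_coords,
    read_stack,
    resample,
    write_block_coords,
    write_stack,
    VolumeStack,
)


class TestStackIO:
    def test_round_trip_is_byte_identical(self, tmp_path):
        rng = np.random.default_rng(0)
        vol = rng.integers(0, 255, size=(16, 12, 10), dtype=np.uint8)
        write_stack(VolumeStack(vol), tmp_path / "a", compress=True)
        back = read_stack(tmp_path / "a")
        np.testing.assert_array_equal(back.voxels, vol)
        write_stack(back, tmp_path / "b", compress=False)
        np.testing.assert_array_equal(read_stack(tmp_path / "b").voxels, vol)

    def test_one_file_per_slice(self, tmp_path):
        vol = np.zeros((64, 32, 16), dtype=np.uint8)
        paths = write_stack(VolumeStack(vol), tmp_path / "s")
        assert len(paths) == 64
        assert tifffile.imread(paths[0]).shape == (32, 16)

    def test_binary_mask_written_as_0_255(self, tmp_path):
        mask = (np.random.default_rng(1).random((8, 8, 8)) > 0.5).astype(np.uint8)
        write_stack(mask, tmp_path / "m")
        vals = np.unique(read_stack(tmp_path / "m").voxels)
        assert set(vals.tolist()) <= {0, 255}

    def test_mixed_shape_raises_naming_file(self, tmp_path):
        d = tmp_path / "bad"
        d.mkdir()
        tifffile.imwrite(d / "img_0000.tif", np.zeros((8, 8), np.uint8))
        tifffile.imwrite(d / "img_0001.tif", np.zeros((8, 9), np.uint8))
        with pytest.raises(StackFormatError, match="img_0001"):
            read_stack(d)

    def test_empty_directory_raises(self, tmp_path):
        d = tmp_path / "empty"
        d.mkdir()
        with pytest.raises(FileNotFoundError):
            read_stack(d)


class TestResample:
    def test_identity_factor(self):
        vol = VolumeStack(np.arange(64).reshape(4, 4, 4).astype(np.uint8))
        out = resample(vol, (1, 1, 1))
        np.testing.assert_array_equal(out.voxels, vol.voxels)

    def test_constant_volume_any_factor(self):
        vol = VolumeStack(np.full((8, 8, 8), 7, dtype=np.uint8))
        for f in [(2, 2, 2), (4, 2, 1), (8, 8, 8)]:
            assert np.all(resample(vol, f).voxels == 7)

    def test_checkerboard_mean(self):
        # 8^3 checkerboard of 0/100 -> every 2^3 cell averages to 50
        z, y, x = np.indices((8, 8, 8))
        board = (((z + y + x) % 2) * 100).astype(np.uint8)
        out = resample(VolumeStack(board), (2, 2, 2))
        assert np.all(out.voxels == 50)
        assert out.voxel_size_um == (2.0, 2.0, 2.0)

    def test_binary_majority_ties_to_foreground(self):
        vol = np.zeros((2, 2, 2), dtype=np.uint8)
        vol[0, 0, 0] = vol[0, 0, 1] = vol[0, 1, 0] = vol[1, 1, 1] = 1  # exactly half
        out = resample(VolumeStack(vol), (2, 2, 2))
        assert out.voxels[0, 0, 0] == 1

    def test_non_integer_factor_rejected(self):
        with pytest.raises(ValueError):
            resample(VolumeStack(np.zeros((4, 4, 4), np.uint8)), (1.5, 1, 1))


class TestPlanBlocks:
    def test_512_gives_27_blocks(self):
        grid = plan_blocks((512, 512, 512), 192, 32)
        assert len(grid) == 27
        origins = sorted({b.origin[0] for b in grid.blocks})
        assert origins == [0, 160, 320]

    def test_exact_fit_single_block(self):
        grid = plan_blocks((192, 192, 192), 192, 32)
        assert len(grid) == 1 and grid.blocks[0].origin == (0, 0, 0)

    def test_clamped_last_block(self):
        grid = plan_blocks((200, 192, 192), 192, 32)
        z_origins = sorted({b.origin[0] for b in grid.blocks})
        assert z_origins == [0, 8]

    def test_invalid_overlap_rejected(self):
        with pytest.raises(ValueError):
            plan_blocks((64, 64, 64), 32, 32)

    def test_origins_sorted_and_unique(self):
        grid = plan_blocks((300, 250, 200), 96, 16)
        origins = [b.origin for b in grid.blocks]
        assert origins == sorted(origins)
        assert len(set(origins)) == len(origins)

    def test_coverage_and_overlap_invariants(self):
        grid = plan_blocks((300, 250, 200), 96, 16)
        cover = np.zeros((300, 250, 200), dtype=np.uint8)
        for b in grid.blocks:
            sl = tuple(slice(o, o + s) for o, s in zip(b.origin, b.shape))
            cover[sl] = 1
        assert cover.all()


class TestExtractFuse:
    def test_extract_fuse_identity(self):
        rng = np.random.default_rng(3)
        mask = (rng.random((100, 80, 70)) > 0.5).astype(np.uint8)
        grid = plan_blocks(mask.shape, 48, 8)
        blocks = extract_blocks(mask, grid)
        fused = fuse_blocks(blocks, grid, mask.shape)
        np.testing.assert_array_equal(fused.voxels > 0, mask > 0)

    def test_voxel_conservation(self):
        grid = plan_blocks((100, 80, 70), 48, 8)
        blocks = extract_blocks(np.ones((100, 80, 70), np.uint8), grid)
        total = sum(b.size for _, b in blocks)
        assert total == len(grid) * 48 ** 3

    def test_overlap_voxels_equal_in_both_blocks(self):
        rng = np.random.default_rng(4)
        vol = rng.integers(0, 255, (100, 64, 64), dtype=np.uint8)
        grid = plan_blocks(vol.shape, 64, 28)  # z origins 0 and 36
        blocks = dict((spec.index, (spec, arr)) for spec, arr in extract_blocks(vol, grid))
        (s0, a0), (s1, a1) = blocks[0], blocks[1]
        assert s0.origin == (0, 0, 0) and s1.origin == (36, 0, 0)
        np.testing.assert_array_equal(a0[36:64], a1[0:28])

    def test_overlap_or_semantics(self):
        grid = plan_blocks((10, 10, 16), 10, 4)
        assert len(grid) == 2
        b0 = np.zeros((10, 10, 10), np.uint8)
        b1 = np.zeros((10, 10, 10), np.uint8)
        b0[5, 5, 8] = 1  # inside the shared overlap, only one block votes 1
        fused = fuse_blocks([(grid.blocks[0], b0), (grid.blocks[1], b1)], grid)
        assert fused.voxels[5, 5, 8] > 0

    def test_fusion_order_independent(self):
        rng = np.random.default_rng(5)
        mask = (rng.random((64, 64, 80)) > 0.8).astype(np.uint8)
        grid = plan_blocks(mask.shape, 48, 16)
        blocks = extract_blocks(mask, grid)
        f1 = fuse_blocks(blocks, grid, mask.shape)
        f2 = fuse_blocks(list(reversed(blocks)), grid, mask.shape)
        np.testing.assert_array_equal(f1.voxels, f2.voxels)

    def test_missing_block_reported(self):
        grid = plan_blocks((64, 64, 64), 48, 16)
        blocks = extract_blocks(np.zeros((64, 64, 64), np.uint8), grid)
        with pytest.raises(ValueError, match="missing"):
            fuse_blocks(blocks[:-1], grid)

    def test_padding_never_leaks_foreground(self):
        # a volume thinner than the block along y: fused result keeps shape
        mask = np.ones((48, 20, 48), np.uint8)
        grid = plan_blocks(mask.shape, 48, 8)
        blocks = [(spec, np.ones(spec.shape, np.uint8)) for spec, _ in extract_blocks(mask, grid)]
        fused = fuse_blocks(blocks, grid, mask.shape)
        assert fused.voxels.shape == mask.shape

    @settings(max_examples=15, deadline=None)
    @given(st.integers(0, 2 ** 30))
    def test_property_extract_fuse_inverse(self, seed):
        rng = np.random.default_rng(seed)
        shape = tuple(int(rng.integers(20, 70)) for _ in range(3))
        mask = (rng.random(shape) > rng.uniform(0.3, 0.95)).astype(np.uint8)
        b = int(rng.integers(8, 40))
        o = int(rng.integers(0, b // 2))
        grid = plan_blocks(shape, b, o)
        fused = fuse_blocks(extract_blocks(mask, grid), grid, shape)
        np.testing.assert_array_equal(fused.voxels > 0, mask > 0)


class TestCoordRecord:
    def test_line_count_and_round_trip(self, tmp_path):
        grid = plan_blocks((512, 512, 512), 192, 32)
        path = tmp_path / "coords.txt"
        write_block_coords(grid, path)
        lines = [l for l in path.read_text().splitlines() if not l.startswith("#")]
        assert len(lines) == 27
        back = read_block_coords(path, volume_shape=(512, 512, 512), overlap=32)
        assert back == grid


class TestPlanSections:
    def test_single_worker_whole_range(self):
        assert plan_sections(100, 1, 32) == [(0, 100)]

    def test_four_workers_overlap_and_coverage(self):
        secs = plan_sections(100, 4, 32)
        assert len(secs) == 4
        assert secs[0][0] == 0 and max(s[1] for s in secs) == 100
        covered = set()
        for a, b in secs:
            covered.update(range(a, b))
        assert covered == set(range(100))
        for (a0, b0), (a1, b1) in zip(secs, secs[1:]):
            assert b0 - a1 >= 32

    def test_more_workers_than_slices(self):
        secs = plan_sections(3, 8, 1)
        assert all(b > a for a, b in secs)
        assert max(b for _, b in secs) == 3

    def test_deterministic(self):
        assert plan_sections(1000, 7, 32) == plan_sections(1000, 7, 32)
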