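import numpy as np
import pytest
from PIL import Image

from cytoblock import image_prep as ip


def _write_png(path, array):
    Image.fromarray(np.asarray(array, dtype=np.uint8)).save(path)
    return path


class TestLoadAndResize:
    def test_forces_target_shape_regardless_of_source(self, tmp_path):
        rng = np.random.default_rng(0)
        src = rng.integers(0, 256, (486, 648, 3))  # 2592×1944 aspect, scaled down
        img = ip.load_and_resize(_write_png(tmp_path / "a.png", src))
        assert img.shape == (800, 1000)
        assert img.original_size == (486, 648)

    def test_identity_when_already_working_size(self, tmp_path):
        rng = np.random.default_rng(1)
        src = rng.integers(0, 256, (800, 1000, 3)).astype(np.uint8)
        img = ip.load_and_resize(_write_png(tmp_path / "b.png", src))
        np.testing.assert_array_equal(img.pixels, src)

    def test_resampling_preserves_constant_color(self, tmp_path):
        src = np.full((1600, 2000, 3), (12, 200, 77), dtype=np.uint8)
        img = ip.load_and_resize(_write_png(tmp_path / "c.png", src))
        assert img.shape == (800, 1000)
        assert (img.pixels == (12, 200, 77)).all()

    def test_grayscale_input_rejected(self, tmp_path):
        path = tmp_path / "gray.png"
        Image.fromarray(np.zeros((50, 50), dtype=np.uint8), mode="L").save(path)
        with pytest.raises(ValueError, match="[Cc]hannel"):
            ip.load_and_resize(path)

    def test_unreadable_file_raises_oserror(self, tmp_path):
        bad = tmp_path / "not_an_image.png"
        bad.write_text("this is not a PNG")
        with pytest.raises(OSError):
            ip.load_and_resize(bad)


class TestTile:
    def test_working_image_gives_80_blocks(self):
        img = ip.from_array(np.zeros((800, 1000, 3), dtype=np.uint8))
        grid = ip.tile(img)
        assert (grid.n_rows, grid.n_cols, grid.n_blocks) == (8, 10, 80)
        assert all(block.shape == (100, 100, 3) for _, block in grid)

    def test_coordinate_convention_and_coverage(self):
        rng = np.random.default_rng(2)
        pixels = rng.integers(0, 256, (800, 1000, 3)).astype(np.uint8)
        grid = ip.tile(ip.from_array(pixels))
        np.testing.assert_array_equal(grid.block(0, 0)[0, 0], pixels[0, 0])
        np.testing.assert_array_equal(grid.block(3, 7), pixels[300:400, 700:800])
        # reassembling the tiles reproduces the image bit-exactly
        np.testing.assert_array_equal(ip.assemble(grid), pixels)

    def test_twelve_images_give_960_blocks(self):
        total = sum(
            ip.tile(ip.from_array(np.zeros((800, 1000, 3), dtype=np.uint8))).n_blocks
            for _ in range(12)
        )
        assert total == 960

    def test_non_divisible_dimensions_rejected(self):
        img = ip.from_array(np.zeros((850, 1000, 3), dtype=np.uint8))
        with pytest.raises(ValueError, match="divisible"):
            ip.tile(img)


class TestColorPlanes:
    def test_gray_weights_sum_to_one_on_white(self):
        block = np.full((100, 100, 3), 255, dtype=np.uint8)
        planes = ip.to_color_planes(block)
        np.testing.assert_allclose(planes.gray, 255.0)
        np.testing.assert_allclose(planes.intensity, 1.0)

    def test_intensity_is_channel_mean_rescaled(self):
        block = np.zeros((100, 100, 3), dtype=np.uint8)
        block[...] = (30, 60, 90)
        planes = ip.to_color_planes(block)
        np.testing.assert_allclose(planes.intensity, 60 / 255)
        np.testing.assert_allclose(planes.r_channel, 30.0)

    def test_gray_kept_as_float(self):
        block = np.zeros((100, 100, 3), dtype=np.uint8)
        block[..., 0] = 255
        planes = ip.to_color_planes(block)
        np.testing.assert_allclose(planes.gray, 0.299 * 255)  # 76.245, unrounded

    def test_planes_bounded_by_block_channel_range(self):
        rng = np.random.default_rng(3)
        block = rng.integers(0, 256, (100, 100, 3)).astype(np.uint8)
        planes = ip.to_color_planes(block)
        assert planes.gray.min() >= block.min() - 1e-9
        assert planes.gray.max() <= block.max() + 1e-9
        assert 0 <= planes.intensity.min() <= planes.intensity.max() <= 1


class TestMedianFilter:
    def test_constant_plane_unchanged(self):
        plane = np.full((20, 20), 7.5)
        np.testing.assert_array_equal(ip.median_filter(plane), plane)

    def test_single_impulse_removed(self):
        plane = np.zeros((21, 21))
        plane[10, 10] = 200.0
        assert ip.median_filter(plane).max() == 0.0

    def test_checkerboard_becomes_window_majority(self):
        i, j = np.mgrid[0:20, 0:20]
        plane = np.where((i + j) % 2 == 0, 5.0, 9.0)
        out = ip.median_filter(plane, 5)
        # brute-force median per 5×5 window with edge replication
        padded = np.pad(plane, 2, mode="edge")
        expected = np.empty_like(plane)
        for a in range(20):
            for b in range(20):
                expected[a, b] = np.median(padded[a : a + 5, b : b + 5])
        np.testing.assert_array_equal(out, expected)

    def test_never_introduces_new_values(self):
        rng = np.random.default_rng(4)
        plane = rng.integers(0, 10, (15, 15)).astype(float)
        out = ip.median_filter(plane, 3)
        assert set(np.unique(out)) <= set(np.unique(plane))

    @pytest.mark.parametrize("window", [2, 4, 1, 0])
    def test_even_or_small_window_rejected(self, window):
        with pytest.raises(ValueError):
            ip.median_filter(np.zeros((10, 10)), window)


class TestHSI:
    def test_ranges_and_intensity_definition(self):
        rng = np.random.default_rng(5)
        block = rng.integers(0, 256, (32, 32, 3)).astype(np.uint8)
        h, s, i = ip.hsi(block)
        assert (h >= 0).all() and (h <= 360).all()
        assert (s >= 0).all() and (s <= 1 + 1e-9).all()
        np.testing.assert_allclose(i, block.sum(axis=2) / 3 / 255)

    def test_achromatic_pixels_have_zero_saturation(self):
        block = np.full((4, 4, 3), 120, dtype=np.uint8)
        h, s, i = ip.hsi(block)
        np.testing.assert_allclose(s, 0.0)
        np.testing.assert_allclose(h, 0.0)
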