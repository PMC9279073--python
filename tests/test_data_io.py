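"""Raster round-trips, splits, patching, augmentation and stitching."""

import imageio.v3 as iio
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from vesselfuse.data_io import (DataError, ImagePair, augment, binarize,
                                extract_patches, load_image_pair,
                                load_pairs_from_manifest, split_dataset,
                                stitch_predictions, write_image_pair,
                                write_manifest)


def _write_pair_files(tmp_path, h=64, w=64, mask_format="png"):
    rng = np.random.default_rng(0)
    img = (rng.random((h, w, 3)) * 255).astype(np.uint8)
    mask = (rng.random((h, w)) > 0.8).astype(np.uint8) * 255
    ip = tmp_path / "img.png"
    mp = tmp_path / f"mask.{mask_format}"
    iio.imwrite(ip, img)
    iio.imwrite(mp, mask)
    return ip, mp, img, mask


class TestLoadImagePair:
    def test_png_gif_round_trip(self, tmp_path):
        ip, mp, img, mask = _write_pair_files(tmp_path, mask_format="gif")
        pair = load_image_pair(ip, mp)
        np.testing.assert_allclose(pair.image, img / 255.0, atol=1e-7)
        np.testing.assert_array_equal(pair.mask, (mask > 127).astype(np.uint8))

    def test_mask_binarized_to_unit_values(self, tmp_path):
        ip, mp, _, _ = _write_pair_files(tmp_path)
        pair = load_image_pair(ip, mp)
        assert set(np.unique(pair.mask)) <= {0, 1}

    def test_grayscale_image_replicated_to_rgb(self, tmp_path):
        gray = (np.eye(16) * 255).astype(np.uint8)
        iio.imwrite(tmp_path / "g.png", gray)
        iio.imwrite(tmp_path / "m.png", gray)
        pair = load_image_pair(tmp_path / "g.png", tmp_path / "m.png")
        assert pair.image.shape == (16, 16, 3)
        assert (pair.image[..., 0] == pair.image[..., 1]).all()

    def test_size_mismatch_rejected(self, tmp_path):
        ip, _, _, _ = _write_pair_files(tmp_path)
        small = (np.zeros((32, 32)) * 255).astype(np.uint8)
        iio.imwrite(tmp_path / "small.png", small)
        with pytest.raises(DataError, match="does not match"):
            load_image_pair(ip, tmp_path / "small.png")

    def test_manifest_round_trip(self, tmp_path, small_phantom):
        rec = write_image_pair(tmp_path, small_phantom)
        rec["split"] = "train"
        write_manifest(tmp_path / "manifest.json", [rec])
        pairs = load_pairs_from_manifest(tmp_path / "manifest.json",
                                         split="train")
        assert len(pairs) == 1
        np.testing.assert_array_equal(pairs[0].mask, small_phantom.mask)
        np.testing.assert_array_equal(pairs[0].fov, small_phantom.fov)


class TestSplitDataset:
    def test_stare_first_ten_train(self):
        ids = [f"im{i:04d}" for i in range(1, 21)]
        train, test = split_dataset("STARE", ids)
        assert train == ids[:10] and test == ids[10:]

    def test_drive_official_division(self):
        ids = [f"{i:02d}" for i in range(1, 41)]
        train, test = split_dataset("DRIVE", ids)
        assert len(train) == len(test) == 20
        assert train == ids[20:] and test == ids[:20]

    def test_wrong_cardinality_rejected(self):
        with pytest.raises(DataError, match="20"):
            split_dataset("STARE", [str(i) for i in range(19)])

    def test_split_is_pure_function_of_ids(self):
        ids = [f"x{i}" for i in range(20)]
        shuffled = list(reversed(ids))
        assert split_dataset("STARE", ids) == split_dataset("STARE", shuffled)


class TestExtractPatches:
    def test_degenerate_grid_single_patch(self):
        pair = ImagePair(image=np.zeros((64, 64, 3)),
                         mask=np.zeros((64, 64), dtype=np.uint8))
        ps = extract_patches(pair, strategy="grid", n_or_stride=64)
        assert len(ps) == 1 and (ps.patches[0].row, ps.patches[0].col) == (0, 0)

    def test_grid_lattice_count(self):
        pair = ImagePair(image=np.zeros((128, 128, 3)),
                         mask=np.zeros((128, 128), dtype=np.uint8))
        ps = extract_patches(pair, strategy="grid", n_or_stride=64)
        assert len(ps) == 4

    def test_random_is_seeded(self, small_phantom):
        a = extract_patches(small_phantom, strategy="random", n_or_stride=20,
                            seed=5)
        b = extract_patches(small_phantom, strategy="random", n_or_stride=20,
                            seed=5)
        assert [(p.row, p.col) for p in a] == [(p.row, p.col) for p in b]

    def test_patches_fully_inside_and_coregistered(self, small_phantom):
        ps = extract_patches(small_phantom, strategy="random", n_or_stride=30,
                             seed=2)
        h, w = small_phantom.shape
        for p in ps:
            assert 0 <= p.row <= h - 64 and 0 <= p.col <= w - 64
            np.testing.assert_array_equal(
                p.mask, small_phantom.mask[p.row:p.row + 64, p.col:p.col + 64])

    def test_image_smaller_than_patch_rejected(self):
        pair = ImagePair(image=np.zeros((32, 32, 3)),
                         mask=np.zeros((32, 32), dtype=np.uint8))
        with pytest.raises(DataError, match="smaller"):
            extract_patches(pair)


class TestAugment:
    @pytest.mark.parametrize("op", ["hflip", "vflip"])
    def test_flip_is_involution(self, rng, op):
        img, mask = rng.random((8, 8, 3)), (rng.random((8, 8)) > 0.5)
        i2, m2 = augment(*augment(img, mask, [op]), [op])
        np.testing.assert_array_equal(i2, img)
        np.testing.assert_array_equal(m2, mask)

    def test_rot90_four_times_is_identity(self, rng):
        img, mask = rng.random((8, 8, 3)), (rng.random((8, 8)) > 0.5)
        i2, m2 = img, mask
        for _ in range(4):
            i2, m2 = augment(i2, m2, ["rot90"])
        np.testing.assert_array_equal(i2, img)

    def test_flips_and_rotations_preserve_histogram(self, rng):
        img, mask = rng.random((8, 8, 3)), (rng.random((8, 8)) > 0.5)
        for op in ("hflip", "vflip", "rot90", "rot180", "rot270"):
            i2, m2 = augment(img, mask, [op])
            np.testing.assert_array_equal(np.sort(i2.ravel()),
                                          np.sort(img.ravel()))
            assert m2.sum() == mask.sum()

    def test_translate_loses_shifted_out_foreground(self, rng):
        mask = np.ones((8, 8), dtype=np.uint8)
        img = rng.random((8, 8, 3))
        i2, m2 = augment(img, mask, [("translate", 2, 3)])
        assert m2.sum() == (8 - 2) * (8 - 3)
        assert m2.sum() <= mask.sum()
        assert set(np.unique(m2)) <= {0, 1}

    def test_unknown_op_rejected(self, rng):
        with pytest.raises(DataError, match="unknown"):
            augment(rng.random((4, 4, 3)), np.zeros((4, 4)), ["swirl"])


class TestStitch:
    def test_single_full_tile_is_identity(self, rng):
        tile = rng.random((16, 16))
        out, cov = stitch_predictions([(tile, (0, 0))], (16, 16))
        np.testing.assert_array_equal(out, tile)
        assert cov.all()

    def test_overlapping_tiles_average(self):
        a, b = np.full((8, 8), 0.2), np.full((8, 8), 0.8)
        out, _ = stitch_predictions([(a, (0, 0)), (b, (0, 0))], (8, 8))
        np.testing.assert_allclose(out, 0.5)

    def test_matches_accumulate_count_oracle(self, rng):
        tiles = [(rng.random((4, 4)),
                  (int(rng.integers(0, 5)), int(rng.integers(0, 5))))
                 for _ in range(7)]
        out, cov = stitch_predictions(tiles, (8, 8))
        acc = np.zeros((8, 8))
        cnt = np.zeros((8, 8))
        for t, (r, c) in tiles:
            acc[r:r + 4, c:c + 4] += t
            cnt[r:r + 4, c:c + 4] += 1
        expect = np.where(cnt > 0, acc / np.maximum(cnt, 1), 0.0)
        np.testing.assert_allclose(out, expect)
        np.testing.assert_array_equal(cov, (cnt > 0).astype(np.uint8))

    def test_out_of_bounds_tile_rejected(self):
        with pytest.raises(DataError, match="bounds"):
            stitch_predictions([(np.zeros((8, 8)), (60, 60))], (64, 64))

    def test_grid_tile_then_stitch_reproduces_mask(self, small_phantom):
        """Identity prediction through the tiler is lossless."""
        ps = extract_patches(small_phantom, strategy="grid", n_or_stride=32)
        tiles = [(p.mask.astype(float), (p.row, p.col)) for p in ps]
        out, cov = stitch_predictions(tiles, small_phantom.shape)
        assert cov.all()
        np.testing.assert_allclose(out, small_phantom.mask.astype(float))


class TestBinarize:
    def test_threshold_is_strict(self):
        assert (binarize(np.full((3, 3), 0.5)) == 0).all()
        assert (binarize(np.full((3, 3), 0.6)) == 1).all()

    @given(st.integers(0, 10_000))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_matches_elementwise_comparison(self, seed):
        prob = np.random.default_rng(seed).random((6, 6))
        np.testing.assert_array_equal(binarize(prob, 0.3),
                                      (prob > 0.3).astype(np.uint8))
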