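"""Patch tiling and gray-tone sampling at the prime mask."""

import numpy as np
import pytest

from ulameeg.features import (
    extract_patch_features,
    feature_length,
    patchify,
    segment_features,
)
from ulameeg.timefreq import TFImage
from ulameeg.ulam_sg import sg_count, sg_mask, ulam_spiral


def gray(img):
    return TFImage(pixels=np.asarray(img, dtype=np.uint8))


class TestPatchify:
    def test_225_by_15_gives_225_patches(self):
        rng = np.random.default_rng(0)
        grid = patchify(gray(rng.integers(0, 256, (225, 225))), 15)
        assert len(grid.patches) == 225
        assert grid.rows_of_patches == grid.cols_of_patches == 15

    def test_small_example_row_major(self):
        img = np.arange(81).reshape(9, 9)
        grid = patchify(img, 3)
        assert len(grid.patches) == 9
        assert np.array_equal(grid.patches[0], img[:3, :3])
        assert np.array_equal(grid.patches[1], img[:3, 3:6])  # row-major
        assert np.array_equal(grid.patches[3], img[3:6, :3])

    def test_every_pixel_in_exactly_one_patch(self):
        img = np.arange(45 * 45).reshape(45, 45)
        grid = patchify(img, 9)
        seen = np.concatenate([p.ravel() for p in grid.patches])
        assert sorted(seen.tolist()) == list(range(45 * 45))

    def test_nondivisor_rejected(self):
        with pytest.raises(ValueError, match="10"):
            patchify(gray(np.zeros((225, 225))), 10)


class TestExtract:
    def test_zero_patch(self):
        mask = sg_mask(3)
        assert extract_patch_features(np.zeros((3, 3)), mask).tolist() == [0, 0, 0]

    def test_constant_patch(self):
        assert extract_patch_features(np.full((3, 3), 7), sg_mask(3)).tolist() == [7, 7, 7]

    def test_spiral_valued_patch_reads_back_its_primes(self):
        """A patch holding its own spiral values returns the SG primes."""
        for n in (3, 9, 15):
            patch = ulam_spiral(n).grid
            got = extract_patch_features(patch, sg_mask(n))
            assert got.tolist() == list(sg_mask(n).values)

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError):
            extract_patch_features(np.zeros((5, 5)), sg_mask(3))


class TestSegmentFeatures:
    def test_reference_configuration_length(self):
        rng = np.random.default_rng(1)
        imgs = [gray(rng.integers(0, 256, (225, 225))) for _ in range(19)]
        fv = segment_features(imgs, 15)
        assert fv.values.shape == (64125,)
        assert feature_length(19, 225, 15) == 64125

    def test_single_channel_small(self):
        img = gray(np.random.default_rng(2).integers(0, 256, (9, 9)))
        fv = segment_features([img], 3)
        assert len(fv.values) == 27  # 9 patches x 3 SG primes

    def test_duplicate_channel_duplicates_block(self):
        img = gray(np.random.default_rng(3).integers(0, 256, (45, 45)))
        fv = segment_features([img, img], 15)
        half = len(fv.values) // 2
        assert np.array_equal(fv.values[:half], fv.values[half:])

    def test_length_formula_matches_bruteforce_double_loop(self):
        rng = np.random.default_rng(4)
        for channels, size, n in [(3, 45, 9), (2, 45, 15), (1, 27, 3), (2, 9, 9)]:
            imgs = [gray(rng.integers(0, 256, (size, size))) for _ in range(channels)]
            fv = segment_features(imgs, n)
            mask = sg_mask(n)
            expected = []
            for img in imgs:
                for pi in range(size // n):
                    for pj in range(size // n):
                        patch = img.pixels[pi * n:(pi + 1) * n, pj * n:(pj + 1) * n]
                        for (r, c) in mask.coords:
                            expected.append(patch[r, c])
            assert fv.values.tolist() == expected
            assert len(expected) == feature_length(channels, size, n)

    def test_only_masked_pixels_are_read(self):
        rng = np.random.default_rng(5)
        pix = rng.integers(0, 256, (9, 9)).astype(np.uint8)
        fv1 = segment_features([gray(pix)], 9)
        mask = sg_mask(9)
        masked = set(mask.coords)
        pix2 = pix.copy()
        for r in range(9):
            for c in range(9):
                if (r, c) not in masked:
                    pix2[r, c] = (int(pix2[r, c]) + 101) % 256
        fv2 = segment_features([gray(pix2)], 9)
        assert np.array_equal(fv1.values, fv2.values)
        # but perturbing a masked pixel does change the vector
        pix3 = pix.copy()
        r, c = mask.coords[0]
        pix3[r, c] = (int(pix3[r, c]) + 1) % 256
        assert not np.array_equal(fv1.values, segment_features([gray(pix3)], 9).values)

    def test_whole_image_mode(self):
        img = gray(np.random.default_rng(6).integers(0, 256, (45, 45)))
        fv = segment_features([img], 45)
        assert len(fv.values) == sg_count(45)

    def test_heterogeneous_sizes_rejected(self):
        a = gray(np.zeros((9, 9)))
        b = gray(np.zeros((45, 45)))
        with pytest.raises(ValueError, match="heterogeneous"):
            segment_features([a, b], 3)
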