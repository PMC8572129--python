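"""LBP codes, histograms, entropy, and the error metrics built on them."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from hypothesis.extra import numpy as hnp

from respireg import (
    DegenerateInputError,
    describe_slice,
    entropy_error,
    lbp_error,
    lbp_histogram,
    lbp_mask,
    shannon_entropy,
)
from respireg.descriptors import NEIGHBOR_OFFSETS


def lbp_loop_oracle(image: np.ndarray) -> np.ndarray:
    """Direct per-pixel evaluation of the LBP definition (the test oracle)."""
    img = image.astype(int)
    out = np.zeros(img.shape, dtype=np.uint8)
    for r in range(1, img.shape[0] - 1):
        for c in range(1, img.shape[1] - 1):
            code = 0
            for dr, dc in NEIGHBOR_OFFSETS:
                code = (code << 1) | int(img[r, c] >= img[r + dr, c + dc])
            out[r, c] = code
    return out


class TestLbpMask:
    def test_constant_image_gives_all_255(self):
        codes = lbp_mask(np.full((5, 7), 93, dtype=np.uint8))
        assert np.all(codes[1:-1, 1:-1] == 255)

    def test_strict_minimum_center_gives_0(self):
        img = np.full((3, 3), 200, dtype=np.uint8)
        img[1, 1] = 10
        assert lbp_mask(img)[1, 1] == 0

    def test_matches_per_pixel_oracle_on_random_images(self, rng):
        for _ in range(10):
            img = rng.integers(0, 256, size=(16, 16), dtype=np.uint8)
            np.testing.assert_array_equal(lbp_mask(img), lbp_loop_oracle(img))

    def test_rejects_too_small_images(self):
        with pytest.raises(ValueError):
            lbp_mask(np.zeros((2, 5), dtype=np.uint8))

    def test_border_codes_are_zero(self, rng):
        codes = lbp_mask(rng.integers(1, 256, size=(6, 6), dtype=np.uint8))
        assert not codes[0].any() and not codes[-1].any()
        assert not codes[:, 0].any() and not codes[:, -1].any()


class TestLbpHistogram:
    def test_constant_image_is_bin_255_indicator(self):
        hist = lbp_histogram(lbp_mask(np.full((8, 8), 7, dtype=np.uint8)))
        assert hist[255] == 1.0
        assert hist.sum() == pytest.approx(1.0)

    def test_normalization(self, rng):
        img = rng.integers(0, 256, size=(20, 20), dtype=np.uint8)
        assert lbp_histogram(lbp_mask(img)).sum() == pytest.approx(1.0, abs=1e-12)

    def test_mask_changes_histogram(self, small_dataset):
        img = small_dataset.volume.data[0, 12]
        lung = small_dataset.lung_masks[0, 12]
        codes = lbp_mask(img)
        assert lbp_error(lbp_histogram(codes, lung), lbp_histogram(codes)) > 0

    def test_empty_region_raises(self):
        codes = lbp_mask(np.zeros((5, 5), dtype=np.uint8))
        with pytest.raises(DegenerateInputError):
            lbp_histogram(codes, np.zeros((5, 5), dtype=bool))

    def test_disjoint_halves_combine_to_full_histogram(self, rng):
        """Count-weighted average of half-mask histograms equals the full one."""
        img = rng.integers(0, 256, size=(12, 18), dtype=np.uint8)
        codes = lbp_mask(img)
        full = np.ones(img.shape, dtype=bool)
        left = full.copy()
        left[:, 9:] = False
        right = full & ~left
        interior = np.zeros(img.shape, dtype=bool)
        interior[1:-1, 1:-1] = True
        n_l = (left & interior).sum()
        n_r = (right & interior).sum()
        combined = (
            n_l * lbp_histogram(codes, left) + n_r * lbp_histogram(codes, right)
        ) / (n_l + n_r)
        np.testing.assert_allclose(combined, lbp_histogram(codes, full), atol=1e-12)


class TestLbpError:
    def test_identical_histograms(self, rng):
        h = lbp_histogram(lbp_mask(rng.integers(0, 256, (10, 10), dtype=np.uint8)))
        assert lbp_error(h, h) == 0.0

    def test_disjoint_indicators(self):
        h1 = np.zeros(256)
        h2 = np.zeros(256)
        h1[0] = 1.0
        h2[1] = 1.0
        assert lbp_error(h1, h2) == pytest.approx(2.0)

    def test_matches_direct_summation(self, rng):
        h1 = rng.dirichlet(np.ones(256))
        h2 = rng.dirichlet(np.ones(256))
        direct = sum((a - b) ** 2 for a, b in zip(h1, h2))
        assert lbp_error(h1, h2) == pytest.approx(direct, rel=1e-12)

    def test_rejects_wrong_length(self):
        with pytest.raises(ValueError):
            lbp_error(np.zeros(255), np.zeros(255))

    @given(
        hnp.arrays(np.float64, 256, elements=st.floats(0, 1)),
        hnp.arrays(np.float64, 256, elements=st.floats(0, 1)),
    )
    def test_pseudometric_properties(self, h1, h2):
        assert lbp_error(h1, h2) >= 0
        assert lbp_error(h1, h2) == pytest.approx(lbp_error(h2, h1))
        assert lbp_error(h1, h1) == 0.0


class TestEntropy:
    @pytest.mark.parametrize(
        "image, expected",
        [
            (np.full((10, 10), 42, dtype=np.uint8), 0.0),
            (np.repeat([0, 255], 50).astype(np.uint8).reshape(10, 10), 1.0),
            (np.arange(256, dtype=np.uint8).reshape(16, 16), 8.0),
        ],
        ids=["constant", "two-level", "uniform-256"],
    )
    def test_closed_form_values(self, image, expected):
        assert shannon_entropy(image) == pytest.approx(expected)

    def test_entropy_error_is_absolute_difference(self):
        assert entropy_error(3.2, 3.2) == 0.0
        assert entropy_error(1.0, 3.5) == pytest.approx(2.5)
        assert entropy_error(3.5, 1.0) == pytest.approx(2.5)

    def test_empty_mask_raises(self):
        with pytest.raises(DegenerateInputError):
            shannon_entropy(np.zeros((4, 4), dtype=np.uint8), np.zeros((4, 4), bool))

    def test_bounded_by_8_bits(self, rng):
        img = rng.integers(0, 256, size=(32, 32), dtype=np.uint8)
        assert 0.0 <= shannon_entropy(img) <= 8.0


class TestDescribeSlice:
    def test_constant_slice(self):
        desc = describe_slice(np.full((9, 9), 5, dtype=np.uint8))
        assert desc.lbp_histogram[255] == 1.0
        assert desc.entropy == 0.0
        assert desc.n_pixels == 49

    def test_composition_matches_components(self, small_dataset):
        img = small_dataset.volume.data[0, 12]
        lung = small_dataset.lung_masks[0, 12]
        desc = describe_slice(img, lung, region="lung")
        np.testing.assert_array_equal(
            desc.lbp_histogram, lbp_histogram(lbp_mask(img), lung)
        )
        assert desc.entropy == shannon_entropy(img, lung)
        assert desc.region == "lung"

    def test_empty_mask_raises(self):
        with pytest.raises(DegenerateInputError):
            describe_slice(np.zeros((5, 5), dtype=np.uint8), np.zeros((5, 5), bool))


def test_bit_rotation_preserves_matching(small_dataset):
    """Rotating the LBP bit start changes codes but not which slice matches."""
    from respireg.descriptors import lbp_histogram as hist, lbp_mask as mask

    vol = small_dataset.volume
    lungs = small_dataset.lung_masks
    target_p, k = 3, 12
    for rotation in (0, 3):
        h_t = hist(mask(vol.data[target_p, k], rotation=rotation), lungs[target_p, k])
        errors = {
            j: lbp_error(h_t, hist(mask(vol.data[0, j], rotation=rotation), lungs[0, j]))
            for j in range(8, 18)
        }
        best = min(errors, key=errors.get)
        if rotation == 0:
            reference = best
        else:
            assert best == reference
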