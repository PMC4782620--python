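"""Line-SE bank construction and grayscale morphology operators."""

import numpy as np
import pytest

from mcdetect import (
    GrayImage,
    generate_line_ses,
    grayscale_opening,
    multi_se_enhance,
    tophat,
)
from mcdetect.errors import ParameterError

from conftest import naive_opening


class TestGenerateLineSEs:
    def test_default_bank_has_eight_distinct_centred_lines(self):
        ses = generate_line_ses(15, 8)
        assert len(ses) == 8
        assert ses.footprint_px == 15
        masks = [se.mask.tobytes() for se in ses]
        assert len(set(masks)) == 8
        for se in ses:
            assert se.mask[7, 7]  # anchor set
            assert se.n_pixels == 15  # thickness-1 line of length 15

    def test_point_symmetry_about_anchor(self):
        for se in generate_line_ses(15, 8):
            assert np.array_equal(se.mask, se.mask[::-1, ::-1])

    def test_horizontal_line_matches_bruteforce_rasterization(self):
        # orientation 0: all 15 pixels in the anchor row
        se = generate_line_ses(15, 8).elements[0]
        expected = np.zeros((15, 15), dtype=bool)
        expected[7, :] = True
        assert np.array_equal(se.mask, expected)

    def test_vertical_line_in_anchor_column(self):
        ses = generate_line_ses(15, 8)
        vertical = next(se for se in ses if se.orientation_deg == 90.0)
        expected = np.zeros((15, 15), dtype=bool)
        expected[:, 7] = True
        assert np.array_equal(vertical.mask, expected)

    def test_trivial_footprint_collapses_to_identity_se(self):
        ses = generate_line_ses(1, 8)
        assert len(ses) == 1
        assert ses.elements[0].mask.shape == (1, 1)

    def test_even_footprint_rejected(self):
        with pytest.raises(ParameterError):
            generate_line_ses(14, 8)

    def test_physical_extent(self, se_bank):
        assert se_bank.physical_extent_mm(0.05) == pytest.approx(0.75)

    def test_json_dump_roundtrips_offsets(self, se_bank):
        d = se_bank.to_json_dict()
        assert d["footprint_px"] == 15
        assert len(d["elements"]) == 8
        assert all(len(e["offsets"]) == 15 for e in d["elements"])


class TestOpening:
    def test_constant_image_invariant(self, se_bank):
        img = GrayImage(np.full((20, 20), 0.4))
        for se in se_bank:
            out = grayscale_opening(img, se)
            np.testing.assert_array_equal(out.pixels, img.pixels)

    def test_single_bright_pixel_removed(self, se_bank):
        a = np.zeros((21, 21))
        a[10, 10] = 1.0
        for se in se_bank:
            out = grayscale_opening(GrayImage(a), se)
            np.testing.assert_array_equal(out.pixels, np.zeros_like(a))

    @pytest.mark.parametrize("border", ["reflect", "replicate", "constant", "clip"])
    def test_matches_naive_oracle_all_ses(self, se_bank, rng, border):
        f = rng.uniform(size=(12, 12))
        img = GrayImage(f)
        for se in se_bank:
            got = grayscale_opening(img, se, border=border).pixels
            exp = naive_opening(f, se.mask, border=border)
            np.testing.assert_array_equal(got, exp)

    @pytest.mark.parametrize("border", ["reflect", "replicate", "constant", "clip"])
    def test_anti_extensive(self, se_bank, random_image, border):
        for se in se_bank:
            once = grayscale_opening(random_image, se, border=border)
            assert np.all(once.pixels <= random_image.pixels)

    def test_idempotent_exactly_under_clip(self, se_bank, random_image):
        # the clipped-window convention forms an adjunction on the image
        # domain, so its opening is exactly idempotent for every SE
        for se in se_bank:
            once = grayscale_opening(random_image, se, border="clip")
            twice = grayscale_opening(once, se, border="clip")
            np.testing.assert_array_equal(once.pixels, twice.pixels)

    def test_idempotent_in_interior_under_reflect(self, se_bank, rng):
        # reflective extension commutes with the opening only away from
        # the borders for oblique SEs; the interior is exact
        img = GrayImage(rng.uniform(size=(60, 60)))
        for se in se_bank:
            once = grayscale_opening(img, se)
            twice = grayscale_opening(once, se)
            m = 28  # beyond twice the SE extent
            np.testing.assert_array_equal(
                once.pixels[m:-m or None, m:-m or None],
                twice.pixels[m:-m or None, m:-m or None],
            )

    def test_unknown_border_rejected(self, se_bank, random_image):
        with pytest.raises(ParameterError):
            grayscale_opening(random_image, se_bank.elements[0], border="wrap")


class TestTophat:
    def test_constant_image_gives_zeros(self, se_bank):
        img = GrayImage(np.full((18, 18), 0.7))
        out = tophat(img, se_bank.elements[0])
        np.testing.assert_allclose(out.pixels, 0.0)

    def test_narrow_ridge_returned_at_full_amplitude(self, se_bank):
        # a 3-px-wide vertical ridge cannot contain the horizontal 15-px line
        a = np.full((31, 31), 0.1)
        a[:, 14:17] = 0.5
        horizontal = se_bank.elements[0]
        out = tophat(GrayImage(a), horizontal)
        np.testing.assert_allclose(out.pixels[:, 14:17], 0.4)

    def test_nonnegative_on_random_input(self, se_bank, random_image):
        for se in se_bank:
            assert np.all(tophat(random_image, se).pixels >= 0)


class TestMultiSEEnhance:
    def test_constant_image_gives_zeros(self, se_bank):
        img = GrayImage(np.full((20, 20), 0.3))
        np.testing.assert_allclose(multi_se_enhance(img, se_bank).pixels, 0.0)

    def test_isolated_small_blob_fully_enhanced(self, se_bank):
        # no 15-px line fits inside a 3x3 blob: full contrast survives
        a = np.full((41, 41), 0.1)
        a[19:22, 19:22] = 0.5
        E = multi_se_enhance(GrayImage(a), se_bank).pixels
        np.testing.assert_allclose(E[19:22, 19:22], 0.4)
        outside = a == 0.1
        np.testing.assert_allclose(E[outside], 0.0)

    def test_large_square_fully_removed(self, se_bank):
        # the horizontal SE fits everywhere inside a 31x31 bright square,
        # so structures larger than the footprint are not enhanced
        a = np.full((63, 63), 0.1)
        a[16:47, 16:47] = 0.6
        E = multi_se_enhance(GrayImage(a), se_bank).pixels
        np.testing.assert_allclose(E[17:46, 17:46], 0.0, atol=1e-15)

    def test_equals_min_of_tophats(self, se_bank, random_image):
        E = multi_se_enhance(random_image, se_bank).pixels
        min_tophat = np.min(
            [tophat(random_image, se).pixels for se in se_bank], axis=0
        )
        np.testing.assert_array_equal(E, min_tophat)

    def test_empty_se_set_rejected(self, random_image):
        with pytest.raises(ParameterError):
            multi_se_enhance(random_image, [])

    def test_translation_equivariance_in_interior(self, se_bank, rng):
        f = np.zeros((40, 40))
        f[15:20, 15:20] = rng.uniform(0.2, 0.8, (5, 5))
        shifted = np.roll(f, (3, 2), axis=(0, 1))
        e1 = multi_se_enhance(GrayImage(f), se_bank).pixels
        e2 = multi_se_enhance(GrayImage(shifted), se_bank).pixels
        np.testing.assert_array_equal(
            np.roll(e1, (3, 2), axis=(0, 1))[10:30, 10:30], e2[10:30, 10:30]
        )
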