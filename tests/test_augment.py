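"""Mixed-sample operators: identities, oracles and invariants."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import oracles
import usmixaug as ux
from conftest import random_pair
from usmixaug.types import BinaryMask, GrayImage, LabeledSample, MixParams

ALL_OPS = (ux.pixmix, ux.segmix2, ux.lesionblend, ux.lesionblend2, ux.pixmix2)


def _const_sample(image_value, mask_value, size=16):
    image = GrayImage(np.full((size, size), float(image_value)), source_id="L")
    mask = BinaryMask(np.full((size, size), int(mask_value)))
    return LabeledSample(image=image, mask=mask, source_id="L")


def _const_unlabeled(value, size=16):
    return GrayImage(np.full((size, size), float(value)), source_id="U")


class TestSmoothMask:
    def test_constant_masks_are_fixed_points(self):
        ones = ux.smooth_mask(BinaryMask(np.ones((16, 16), np.uint8)), sigma=3.0)
        zeros = ux.smooth_mask(BinaryMask(np.zeros((16, 16), np.uint8)), sigma=3.0)
        np.testing.assert_allclose(ones.pixels, 1.0, atol=1e-12)
        np.testing.assert_array_equal(zeros.pixels, 0.0)

    def test_center_delta_matches_discrete_kernel_peak(self):
        m = np.zeros((33, 33), np.uint8)
        m[16, 16] = 1
        soft = ux.smooth_mask(BinaryMask(m), sigma=2.0)
        k1 = oracles.gaussian_kernel_1d(2.0)
        assert soft.pixels[16, 16] == pytest.approx(k1[len(k1) // 2] ** 2, abs=1e-15)

    def test_nonpositive_sigma_rejected(self):
        with pytest.raises(ValueError):
            ux.smooth_mask(BinaryMask(np.ones((16, 16), np.uint8)), sigma=0.0)

    def test_mass_conservation_away_from_borders(self):
        m = np.zeros((64, 64), np.uint8)
        m[28:36, 28:36] = 1
        soft = ux.smooth_mask(BinaryMask(m), sigma=2.0)
        assert soft.pixels.sum() == pytest.approx(m.sum(), rel=1e-10)


@pytest.mark.parametrize(
    "op,labeled_val,unlabeled_val,mask_val,params,expected",
    [
        # pixmix is the identity at alpha=1
        (ux.pixmix, 0.37, 0.9, 1, MixParams(alpha=1.0, beta=0.0), 0.37),
        # pixmix of constants is the convex combination
        (ux.pixmix, 1.0, 0.5, 1, MixParams(alpha=0.8, beta=0.2), 0.9),
        # segmix2 with an all-zero mask returns the unlabeled image
        (ux.segmix2, 0.3, 0.6, 0, MixParams(), 0.6),
        # segmix2 with gamma=1 and an all-ones mask returns the labeled image
        (ux.segmix2, 0.3, 0.6, 1, MixParams(gamma=1.0), 0.3),
        # lesionblend keeps the labeled image where the soft mask is 1
        (ux.lesionblend, 0.25, 0.75, 1, MixParams(), 0.25),
        (ux.lesionblend, 0.25, 0.75, 0, MixParams(), 0.75),
        # lesionblend2 is its complement
        (ux.lesionblend2, 0.25, 0.75, 0, MixParams(), 0.25),
        (ux.lesionblend2, 0.25, 0.75, 1, MixParams(), 0.75),
        # pixmix2 of two constants renormalizes to zero (degenerate range)
        (ux.pixmix2, 0.4, 0.3, 1, MixParams(), 0.0),
    ],
)
def test_constant_input_identities(op, labeled_val, unlabeled_val, mask_val, params, expected):
    labeled = _const_sample(labeled_val, mask_val)
    out = op(labeled, _const_unlabeled(unlabeled_val), params)
    np.testing.assert_allclose(out.image.pixels, expected, atol=1e-12)
    np.testing.assert_array_equal(out.mask.pixels, labeled.mask.pixels)


def test_pixmix2_with_zero_partner_recovers_full_range_image(rng):
    pixels = rng.uniform(size=(16, 16))
    pixels[0, 0], pixels[-1, -1] = 0.0, 1.0
    labeled = LabeledSample(
        image=GrayImage(pixels),
        mask=BinaryMask(np.zeros((16, 16), np.uint8)),
        source_id="L",
    )
    out = ux.pixmix2(labeled, _const_unlabeled(0.0))
    np.testing.assert_allclose(out.image.pixels, pixels, atol=1e-15)


def test_pixmix2_clip_mode(rng):
    labeled, unlabeled = random_pair(rng)
    out = ux.pixmix2(labeled, unlabeled, MixParams(pixmix2_overflow="clip"))
    expected = np.minimum(labeled.image.pixels + unlabeled.pixels, 1.0)
    np.testing.assert_array_equal(out.image.pixels, expected)


@pytest.mark.parametrize("trials", [50])
def test_operators_match_per_pixel_loop_oracles(rng, trials):
    params = MixParams(alpha=0.8, beta=0.2, gamma=0.5, sigma=2.0)
    for _ in range(trials):
        labeled, unlabeled = random_pair(rng)
        il, iu = labeled.image.pixels, unlabeled.pixels
        soft = ux.smooth_mask(labeled.mask, params.sigma).pixels
        expected = {
            ux.pixmix: oracles.pixmix_loop(il, iu, params.alpha, params.beta),
            ux.segmix2: oracles.segmix2_loop(il, iu, soft, params.gamma),
            ux.lesionblend: oracles.lesionblend_loop(il, iu, soft),
            ux.lesionblend2: oracles.lesionblend2_loop(il, iu, soft),
            ux.pixmix2: oracles.pixmix2_loop(il, iu),
        }
        for op, want in expected.items():
            got = op(labeled, unlabeled, params).image.pixels
            np.testing.assert_array_equal(got, want, err_msg=op.__name__)


@given(seed=st.integers(0, 2**31 - 1))
def test_mask_invariance_and_range_safety(seed):
    """All five strategies return the source mask bit-identically and an
    image inside [0, 1]."""
    rng = np.random.default_rng(seed)
    labeled, unlabeled = random_pair(rng)
    for op in ALL_OPS:
        out = op(labeled, unlabeled, MixParams(sigma=2.0))
        assert np.array_equal(out.mask.pixels, labeled.mask.pixels)
        assert out.image.pixels.min() >= 0.0
        assert out.image.pixels.max() <= 1.0


@given(seed=st.integers(0, 2**31 - 1))
def test_convex_operators_stay_within_input_envelope(seed):
    rng = np.random.default_rng(seed)
    labeled, unlabeled = random_pair(rng)
    lo = np.minimum(labeled.image.pixels, unlabeled.pixels)
    hi = np.maximum(labeled.image.pixels, unlabeled.pixels)
    for op in (ux.pixmix, ux.lesionblend, ux.lesionblend2):
        out = op(labeled, unlabeled, MixParams(sigma=2.0)).image.pixels
        assert np.all(out >= lo - 1e-12)
        assert np.all(out <= hi + 1e-12)


@given(seed=st.integers(0, 2**31 - 1))
def test_lesionblend_pair_sums_to_input_sum(seed):
    """lesionblend + lesionblend2 = I_L + I_U pixelwise (complementarity)."""
    rng = np.random.default_rng(seed)
    labeled, unlabeled = random_pair(rng)
    params = MixParams(sigma=2.0)
    a = ux.lesionblend(labeled, unlabeled, params).image.pixels
    b = ux.lesionblend2(labeled, unlabeled, params).image.pixels
    np.testing.assert_allclose(
        a + b, labeled.image.pixels + unlabeled.pixels, atol=1e-12
    )


def test_swapping_soft_mask_swaps_the_blends(rng):
    """lesionblend2 equals lesionblend with the soft mask complemented."""
    labeled, unlabeled = random_pair(rng)
    soft = ux.smooth_mask(labeled.mask, 2.0).pixels
    via_blend2 = ux.lesionblend2(labeled, unlabeled, MixParams(sigma=2.0))
    manual = np.clip(
        (1.0 - soft) * labeled.image.pixels + soft * unlabeled.pixels, 0.0, 1.0
    )
    np.testing.assert_array_equal(via_blend2.image.pixels, manual)


def test_segmix2_sigma_limit_is_hard_copy_paste(rng):
    """gamma=1 with vanishing smoothing reduces to copy-pasting the lesion."""
    labeled, unlabeled = random_pair(rng, size=32)
    out = ux.segmix2(labeled, unlabeled, MixParams(gamma=1.0, sigma=0.01))
    hard = np.where(labeled.mask.pixels == 1, labeled.image.pixels, unlabeled.pixels)
    np.testing.assert_allclose(out.image.pixels, hard, atol=1.0 / 255.0)


def test_operators_are_deterministic(rng):
    labeled, unlabeled = random_pair(rng)
    for op in ALL_OPS:
        first = op(labeled, unlabeled, MixParams(sigma=2.0))
        second = op(labeled, unlabeled, MixParams(sigma=2.0))
        np.testing.assert_array_equal(first.image.pixels, second.image.pixels)
        np.testing.assert_array_equal(first.mask.pixels, second.mask.pixels)


def test_dimension_mismatch_rejected(rng):
    labeled, _ = random_pair(rng, size=16)
    other = GrayImage(rng.uniform(size=(24, 24)), source_id="U")
    for op in ALL_OPS:
        with pytest.raises(ValueError, match="dimensions differ"):
            op(labeled, other, MixParams())


def test_provenance_recorded(rng):
    labeled, unlabeled = random_pair(rng)
    out = ux.pixmix(labeled, unlabeled, MixParams(alpha=0.7, beta=0.3))
    assert out.labeled_source_id == "L"
    assert out.unlabeled_source_id == "U"
    assert out.params == {"alpha": 0.7, "beta": 0.3}


def test_alpha_beta_must_sum_to_one():
    with pytest.raises(ValueError, match="alpha"):
        MixParams(alpha=0.8, beta=0.3)
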