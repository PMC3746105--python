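import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from irisqtl.colorimetry import (
    ColorSummary,
    IrisImage,
    filter_pixels,
    lab_to_srgb,
    read_image,
    read_summaries,
    srgb_to_lab,
    summarize_iris,
    white_balance,
    write_summaries,
)

CORNERS = np.array(
    [[0, 0, 0], [255, 0, 0], [0, 255, 0], [0, 0, 255],
     [255, 255, 0], [255, 0, 255], [0, 255, 255], [255, 255, 255]],
    dtype=float,
)


def test_srgb_to_lab_matches_skimage_oracle():
    from skimage.color import rgb2lab

    rng = np.random.default_rng(0)
    rgb = np.vstack([CORNERS, rng.integers(0, 256, size=(200, 3))]).astype(float)
    ours = srgb_to_lab(rgb)
    ref = rgb2lab((rgb / 255.0)[None, :, :])[0]
    assert np.max(np.abs(ours - ref)) < 0.01


def test_known_reference_values():
    # canonical published sRGB->Lab conversions (D65, 2 degrees)
    lab_red = srgb_to_lab([255, 0, 0])
    assert np.allclose(lab_red, [53.24, 80.09, 67.20], atol=0.01)
    assert np.allclose(srgb_to_lab([255, 255, 255]), [100.0, 0.0, 0.0], atol=1e-6)
    assert np.allclose(srgb_to_lab([0, 0, 0]), [0.0, 0.0, 0.0], atol=1e-6)


def test_gray_axis_is_exactly_achromatic():
    grays = np.stack([np.arange(256)] * 3, axis=-1)
    lab = srgb_to_lab(grays)
    assert np.max(np.abs(lab[:, 1:])) < 1e-6
    # L* strictly increasing along the gray axis
    assert np.all(np.diff(lab[:, 0]) > 0)


def test_round_trip_inversion():
    rng = np.random.default_rng(1)
    rgb = rng.uniform(0, 255, size=(500, 3))
    back = lab_to_srgb(srgb_to_lab(rgb))
    assert np.max(np.abs(back - rgb)) < 1e-8


def test_lab_to_srgb_out_of_gamut():
    with pytest.raises(ValueError, match="gamut"):
        lab_to_srgb([50.0, 120.0, -120.0])
    clipped = lab_to_srgb([50.0, 120.0, -120.0], clip=True)
    assert clipped.min() >= 0 and clipped.max() <= 255


def test_srgb_to_lab_input_validation():
    with pytest.raises(ValueError):
        srgb_to_lab([300.0, 0.0, 0.0])
    with pytest.raises(ValueError):
        srgb_to_lab([[1.0, 2.0]])


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 255), st.integers(0, 255), st.integers(0, 255))
def test_lab_lightness_bounds_property(r, g, b):
    lab = srgb_to_lab([r, g, b])
    assert -1e-9 <= lab[0] <= 100 + 1e-9
    assert np.all(np.isfinite(lab))


def _toy_image(pixels):
    px = np.asarray(pixels, dtype=np.uint8).reshape(1, -1, 3)
    mask = np.ones(px.shape[:2], dtype=bool)
    return IrisImage(px, mask, image_id="toy")


def test_filter_pixels_all_rule_keeps_saturated_blue():
    im = _toy_image(
        [
            [120, 140, 200],   # normal pixel
            [255, 255, 255],   # highlight: all > 250
            [252, 251, 253],   # highlight
            [5, 3, 8],         # shadow: all < 10
            [0, 0, 255],       # saturated blue survives the "all" rule
        ]
    )
    kept = filter_pixels(im)
    assert kept.shape == (2, 3)
    assert [0, 0, 255] in kept.tolist()


def test_filter_pixels_any_rule_is_stricter():
    im = _toy_image([[120, 140, 200], [0, 0, 255], [255, 10, 10]])
    kept = filter_pixels(im, channel_rule="any")
    assert kept.tolist() == [[120, 140, 200]]
    with pytest.raises(ValueError):
        filter_pixels(im, channel_rule="bogus")


def test_filter_pixels_boundary_values_retained():
    # thresholds are strict: exactly 250 and exactly 10 are retained
    im = _toy_image([[250, 250, 250], [10, 10, 10]])
    assert filter_pixels(im).shape == (2, 3)


def test_filter_pixels_failure_modes():
    im = _toy_image([[255, 255, 255], [1, 1, 1]])
    with pytest.raises(ValueError, match="no usable iris pixels"):
        filter_pixels(im)
    px = np.full((2, 2, 3), 100, dtype=np.uint8)
    empty = IrisImage(px, np.zeros((2, 2), dtype=bool))
    with pytest.raises(ValueError, match="mask selects no pixels"):
        filter_pixels(empty)


def test_summarize_iris_even_median_mean_of_middle_two():
    # four chromatic pixels: medians must equal the mean of middle two
    px = [[100, 120, 180], [110, 130, 190], [90, 100, 170], [120, 140, 210]]
    im = _toy_image(px)
    s = summarize_iris(im)
    lab = srgb_to_lab(np.asarray(px, dtype=float))
    assert s.median_a == pytest.approx(np.median(lab[:, 1]))
    assert s.median_b == pytest.approx(np.median(lab[:, 2]))
    assert s.n_pixels_total == 4 and s.n_pixels_kept == 4


def test_summarize_iris_is_pixel_order_invariant(rng):
    px = rng.integers(30, 220, size=(1, 40, 3)).astype(np.uint8)
    mask = np.ones((1, 40), dtype=bool)
    a = summarize_iris(IrisImage(px, mask))
    perm = rng.permutation(40)
    b = summarize_iris(IrisImage(px[:, perm], mask))
    assert a.median_a == pytest.approx(b.median_a)
    assert a.median_b == pytest.approx(b.median_b)


def test_white_balance_equalizes_channel_means():
    rng = np.random.default_rng(3)
    px = np.clip(
        rng.normal([140, 100, 80], 20, size=(32, 32, 3)), 0, 255
    ).astype(np.uint8)
    mask = np.zeros((32, 32), dtype=bool)
    mask[8:24, 8:24] = True
    balanced = white_balance(IrisImage(px, mask))
    means = balanced.pixels.reshape(-1, 3).astype(float).mean(axis=0)
    # equal to within the rounding granularity of 8-bit storage
    assert np.ptp(means) < 1.0
    assert balanced.mask.shape == mask.shape


def test_white_balance_background_reference():
    px = np.full((4, 4, 3), 100, dtype=np.uint8)
    px[..., 0] = 200  # red cast
    mask = np.zeros((4, 4), dtype=bool)
    mask[1:3, 1:3] = True
    out = white_balance(IrisImage(px, mask), reference="background")
    means = out.pixels.reshape(-1, 3).astype(float).mean(axis=0)
    assert np.ptp(means) < 1.0
    with pytest.raises(ValueError):
        white_balance(IrisImage(px, mask), reference="nope")


def test_white_balance_degenerate_image():
    px = np.zeros((2, 2, 3), dtype=np.uint8)
    with pytest.raises(ValueError, match="degenerate"):
        white_balance(IrisImage(px, np.ones((2, 2), dtype=bool)))


def test_iris_image_validation():
    with pytest.raises(ValueError):
        IrisImage(np.zeros((2, 2)), np.zeros((2, 2), dtype=bool))
    with pytest.raises(ValueError):
        IrisImage(np.zeros((2, 2, 3)), np.zeros((3, 3), dtype=bool))


def test_color_summary_validation():
    with pytest.raises(ValueError):
        ColorSummary("x", 0.0, 0.0, n_pixels_total=4, n_pixels_kept=0)
    with pytest.raises(ValueError):
        ColorSummary("x", np.nan, 0.0, n_pixels_total=4, n_pixels_kept=2)


def test_image_and_summary_io_round_trip(tmp_path):
    from PIL import Image

    rng = np.random.default_rng(4)
    px = rng.integers(20, 230, size=(16, 16, 3)).astype(np.uint8)
    mask = np.zeros((16, 16), dtype=bool)
    mask[4:12, 4:12] = True
    Image.fromarray(px).save(tmp_path / "a.png")
    Image.fromarray((mask * 255).astype(np.uint8)).save(tmp_path / "a.mask.png")
    im = read_image(tmp_path / "a.png", tmp_path / "a.mask.png", image_id="a")
    assert np.array_equal(im.pixels, px)
    assert np.array_equal(im.mask, mask)

    s = summarize_iris(im)
    write_summaries([s], tmp_path / "pheno.tsv")
    df = read_summaries(tmp_path / "pheno.tsv")
    assert df.loc[0, "individual_id"] == "a"
    assert df.loc[0, "median_b"] == pytest.approx(s.median_b)
    assert df.loc[0, "n_kept"] == s.n_pixels_kept
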