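"""Photograph-based iris colorimetry.

Converts masked iris pixels of a white-balanced photograph into a
per-individual quantitative phenotype: the median CIE a* (green-magenta
axis) and median CIE b* (blue-yellow axis) over iris pixels, after
excluding achromatic highlight (reflection) and shadow pixels.  L* is
computed but never summarized because it tracks lighting conditions
rather than pigmentation.

The sRGB -> CIE L*a*b* conversion follows the IEC 61966-2-1 piecewise
sRGB companding, the standard sRGB -> XYZ matrix (D65, 2 degree
observer), and the CIE piecewise cube-root Lab formulas.  The reference
white is taken as the image of (1, 1, 1) under the sRGB matrix, so the
gray axis maps exactly onto a* = b* = 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from PIL import Image

__all__ = [
    "IrisImage",
    "ColorSummary",
    "srgb_to_lab",
    "lab_to_srgb",
    "white_balance",
    "filter_pixels",
    "summarize_iris",
    "read_image",
    "read_mask",
    "write_summaries",
    "read_summaries",
]

# Standard sRGB (linear) -> XYZ matrix, D65 white, 2 degree observer.
_SRGB_TO_XYZ = np.array(
    [
        [0.4124564, 0.3575761, 0.1804375],
        [0.2126729, 0.7151522, 0.0721750],
        [0.0193339, 0.1191920, 0.9503041],
    ]
)
_XYZ_TO_SRGB = np.linalg.inv(_SRGB_TO_XYZ)
# Reference white = matrix image of RGB (1,1,1); equals D65 to ~1e-7 and
# makes grays exactly achromatic.
_WHITE = _SRGB_TO_XYZ.sum(axis=1)

_DELTA = 6.0 / 29.0


@dataclass
class IrisImage:
    """A decoded RGB photograph plus a boolean iris-region selection.

    Parameters
    ----------
    pixels : (H, W, 3) uint8-compatible array of RGB values in [0, 255].
    mask : (H, W) boolean array, True on iris pixels.
    image_id : identifier carried through to the phenotype table.
    encoding_tag : free text recording the source encoding
        (e.g. ``"RAW-derived"``, ``"JPEG"``) so parallel analyses of
        differently processed photographs can be kept apart.
    """

    pixels: np.ndarray
    mask: np.ndarray
    image_id: str = ""
    encoding_tag: str = ""

    def __post_init__(self):
        self.pixels = np.asarray(self.pixels)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an (H, W, 3) RGB array")
        if self.mask.shape != self.pixels.shape[:2]:
            raise ValueError("mask shape must match pixel grid shape")
        if self.pixels.min() < 0 or self.pixels.max() > 255:
            raise ValueError("channel values must lie in [0, 255]")


@dataclass
class ColorSummary:
    """Median iris color of one photograph (the quantitative phenotype)."""

    individual_id: str
    median_a: float
    median_b: float
    n_pixels_total: int
    n_pixels_kept: int
    encoding_tag: str = ""

    def __post_init__(self):
        if self.n_pixels_kept < 1 or self.n_pixels_kept > self.n_pixels_total:
            raise ValueError("need 1 <= n_pixels_kept <= n_pixels_total")
        if not (np.isfinite(self.median_a) and np.isfinite(self.median_b)):
            raise ValueError("medians must be finite")


def _srgb_companding_inverse(v: np.ndarray) -> np.ndarray:
    """Decode 0-1 sRGB values to linear light (IEC 61966-2-1)."""
    return np.where(v <= 0.04045, v / 12.92, ((v + 0.055) / 1.055) ** 2.4)


def _srgb_companding(v: np.ndarray) -> np.ndarray:
    """Encode linear light to 0-1 sRGB values."""
    v = np.asarray(v)
    return np.where(v <= 0.0031308, 12.92 * v, 1.055 * v ** (1 / 2.4) - 0.055)


def _lab_f(t: np.ndarray) -> np.ndarray:
    return np.where(t > _DELTA**3, np.cbrt(t), t / (3 * _DELTA**2) + 4.0 / 29.0)


def _lab_f_inverse(t: np.ndarray) -> np.ndarray:
    return np.where(t > _DELTA, t**3, 3 * _DELTA**2 * (t - 4.0 / 29.0))


def srgb_to_lab(rgb) -> np.ndarray:
    """Convert 8-bit sRGB values to CIE L*a*b* (D65, 2 degree observer).

    Parameters
    ----------
    rgb : array-like, shape (..., 3)
        Integer (or float) channel values in [0, 255].

    Returns
    -------
    ndarray, shape (..., 3)
        ``(L*, a*, b*)`` per input pixel.  L* is in [0, 100] for
        in-gamut input; a* and b* are signed chromaticity axes.
    """
    rgb = np.asarray(rgb, dtype=float)
    if rgb.shape[-1] != 3:
        raise ValueError("expected (..., 3) RGB input")
    if rgb.min() < 0 or rgb.max() > 255:
        raise ValueError("channel values out of range [0, 255]")
    linear = _srgb_companding_inverse(rgb / 255.0)
    xyz = linear @ _SRGB_TO_XYZ.T
    f = _lab_f(xyz / _WHITE)
    lab = np.empty_like(f)
    lab[..., 0] = 116.0 * f[..., 1] - 16.0
    lab[..., 1] = 500.0 * (f[..., 0] - f[..., 1])
    lab[..., 2] = 200.0 * (f[..., 1] - f[..., 2])
    return lab


def lab_to_srgb(lab, clip: bool = False) -> np.ndarray:
    """Invert :func:`srgb_to_lab`, returning float RGB in [0, 255].

    Raises ``ValueError`` for out-of-gamut colors unless ``clip`` is set.
    """
    lab = np.asarray(lab, dtype=float)
    fy = (lab[..., 0] + 16.0) / 116.0
    fx = fy + lab[..., 1] / 500.0
    fz = fy - lab[..., 2] / 200.0
    xyz = np.stack([_lab_f_inverse(fx), _lab_f_inverse(fy), _lab_f_inverse(fz)], axis=-1)
    linear = (xyz * _WHITE) @ _XYZ_TO_SRGB.T
    if linear.min() < -1e-9 or linear.max() > 1 + 1e-9:
        if not clip:
            raise ValueError("color outside the sRGB gamut")
    linear = np.clip(linear, 0.0, 1.0)
    return 255.0 * _srgb_companding(linear)


def white_balance(image: IrisImage, reference: str = "image") -> IrisImage:
    """Gray-world white balance.

    Each channel is rescaled so that channel means over the reference
    pixels are equal (to their common mean), emulating an automatic
    white-balance adjustment in a documented, deterministic way.

    Parameters
    ----------
    image : IrisImage
    reference : {"image", "background"}
        Pixels over which channel means are computed: the whole image
        (default) or only non-iris pixels.  The scaling is always
        applied to the whole image.
    """
    px = image.pixels.astype(float)
    if reference == "image":
        ref = px.reshape(-1, 3)
    elif reference == "background":
        ref = px[~image.mask]
        if ref.size == 0:
            ref = px.reshape(-1, 3)
    else:
        raise ValueError(f"unknown reference {reference!r}")
    means = ref.mean(axis=0)
    if np.all(means == 0):
        raise ValueError("degenerate image: all channels zero")
    if np.any(means == 0):
        raise ValueError("degenerate image: a channel is uniformly zero")
    scale = means.mean() / means
    balanced = np.clip(np.rint(px * scale), 0, 255).astype(image.pixels.dtype)
    return IrisImage(balanced, image.mask, image.image_id, image.encoding_tag)


def filter_pixels(
    image: IrisImage,
    low: int = 10,
    high: int = 250,
    channel_rule: str = "all",
) -> np.ndarray:
    """Return mask-true pixels with highlights and shadows excluded.

    A pixel is classified as a specular highlight when its channels
    exceed ``high`` and as a shadow when they fall below ``low``; under
    the default ``channel_rule="all"`` the classification requires all
    three channels to do so (achromatic extremes only, so saturated
    blue iris pixels survive), while ``"any"`` excludes on any single
    channel.

    Returns
    -------
    (n, 3) ndarray of retained RGB pixels (order follows row-major mask
    order, but downstream summaries are order-invariant).

    Raises
    ------
    ValueError
        If the mask is empty or no pixel survives filtering — the
        latter signals the photograph should be excluded from analysis.
    """
    if not image.mask.any():
        raise ValueError("mask selects no pixels")
    px = image.pixels[image.mask].astype(int)
    if channel_rule == "all":
        highlight = (px > high).all(axis=1)
        shadow = (px < low).all(axis=1)
    elif channel_rule == "any":
        highlight = (px > high).any(axis=1)
        shadow = (px < low).any(axis=1)
    else:
        raise ValueError(f"unknown channel_rule {channel_rule!r}")
    kept = px[~(highlight | shadow)]
    if kept.shape[0] == 0:
        raise ValueError("no usable iris pixels: photograph should be excluded")
    return kept


def summarize_iris(
    image: IrisImage,
    low: int = 10,
    high: int = 250,
    channel_rule: str = "all",
    individual_id: str | None = None,
) -> ColorSummary:
    """Median CIE a* and b* over retained iris pixels.

    Even-length medians use the mean-of-middle-two convention.  L* is
    computed as part of the conversion but deliberately not summarized.
    """
    kept = filter_pixels(image, low=low, high=high, channel_rule=channel_rule)
    lab = srgb_to_lab(kept)
    return ColorSummary(
        individual_id=individual_id if individual_id is not None else image.image_id,
        median_a=float(np.median(lab[:, 1])),
        median_b=float(np.median(lab[:, 2])),
        n_pixels_total=int(image.mask.sum()),
        n_pixels_kept=int(kept.shape[0]),
        encoding_tag=image.encoding_tag,
    )


# ---------------------------------------------------------------------------
# File I/O


def read_image(path, mask_path, image_id: str = "", encoding_tag: str = "") -> IrisImage:
    """Read a PNG/TIFF photograph and its mask into an :class:`IrisImage`.

    The mask is a single-channel image where nonzero marks iris pixels.
    """
    with Image.open(path) as im:
        pixels = np.asarray(im.convert("RGB"))
    mask = read_mask(mask_path)
    return IrisImage(pixels, mask, image_id=image_id or str(path), encoding_tag=encoding_tag)


def read_mask(path) -> np.ndarray:
    with Image.open(path) as im:
        return np.asarray(im.convert("L")) > 0


def write_summaries(summaries, path) -> None:
    """Write ColorSummary rows as a TSV phenotype table."""
    import pandas as pd

    pd.DataFrame(
        [
            {
                "individual_id": s.individual_id,
                "median_a": s.median_a,
                "median_b": s.median_b,
                "n_total": s.n_pixels_total,
                "n_kept": s.n_pixels_kept,
                "encoding_tag": s.encoding_tag,
            }
            for s in summaries
        ]
    ).to_csv(path, sep="\t", index=False)


def read_summaries(path):
    import pandas as pd

    return pd.read_csv(path, sep="\t")
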