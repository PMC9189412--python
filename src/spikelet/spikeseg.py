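"""Spike extraction: saturation channel, Otsu thresholding, binary mask.

The spike sits on a near-neutral board, so its HSV saturation is high while
the board's is close to zero.  Binarizing the S channel at the Otsu cut,
keeping the largest 8-connected component and filling enclosed holes yields
a single clean spike silhouette (1 = spike, 0 = background).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage as ndi

from .types import CanonicalImage, GrayImage, SpikeMask

__all__ = [
    "saturation_channel",
    "otsu_threshold",
    "binarize",
    "spike_mask",
    "saturation_of_rgb",
    "largest_component",
]


def saturation_of_rgb(rgb: np.ndarray) -> np.ndarray:
    """HSV saturation of an 8-bit RGB array, rescaled to uint8 [0, 255].

    S = 0 where max(R,G,B) = 0, else (max - min) / max.
    """
    arr = np.asarray(rgb, dtype=np.float64)
    cmax = arr.max(axis=-1)
    cmin = arr.min(axis=-1)
    with np.errstate(invalid="ignore", divide="ignore"):
        s = np.where(cmax > 0, (cmax - cmin) / np.where(cmax > 0, cmax, 1), 0.0)
    return np.rint(s * 255.0).astype(np.uint8)


def saturation_channel(img: CanonicalImage) -> GrayImage:
    """S component of a canonical image as an 8-bit gray image."""
    return GrayImage(saturation_of_rgb(img.pixels), channel_name="S")


def otsu_threshold(gray: GrayImage | np.ndarray) -> int:
    """Otsu's threshold over the 256-bin histogram of an 8-bit image.

    Returns the integer cut ``t`` maximizing between-class variance, where
    the classes are ``<= t`` and ``> t``; ties break toward the smallest t.

    Raises
    ------
    ValueError
        If the image is constant ("degenerate histogram").
    """
    pixels = gray.pixels if isinstance(gray, GrayImage) else np.asarray(gray)
    hist = np.bincount(pixels.ravel().astype(np.uint8), minlength=256).astype(np.float64)
    total = hist.sum()
    if np.count_nonzero(hist) < 2:
        raise ValueError("degenerate histogram: image has fewer than 2 distinct values")
    levels = np.arange(256, dtype=np.float64)
    w0 = np.cumsum(hist)  # pixels <= t
    m0 = np.cumsum(hist * levels)  # first moment <= t
    mu_total = m0[-1]
    w1 = total - w0
    with np.errstate(invalid="ignore", divide="ignore"):
        mean0 = m0 / w0
        mean1 = (mu_total - m0) / w1
        sigma_b = w0 * w1 * (mean0 - mean1) ** 2
    sigma_b = np.where((w0 > 0) & (w1 > 0), sigma_b, -np.inf)
    return int(np.argmax(sigma_b))  # argmax takes the smallest index on ties


def binarize(gray: np.ndarray, threshold: int) -> np.ndarray:
    """Foreground = pixels strictly above the threshold (uint8 0/1)."""
    return (np.asarray(gray) > threshold).astype(np.uint8)


_STRUCT8 = np.ones((3, 3), dtype=bool)  # 8-connectivity


def largest_component(binary: np.ndarray) -> np.ndarray:
    """Keep only the largest 8-connected foreground component (uint8 0/1)."""
    labels, n = ndi.label(binary, structure=_STRUCT8)
    if n == 0:
        raise ValueError("empty mask: no foreground component")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    keep = int(np.argmax(counts))
    return (labels == keep).astype(np.uint8)


def spike_mask(img: CanonicalImage) -> SpikeMask:
    """Binary spike mask of a canonical image.

    Binarizes the saturation channel at the Otsu threshold with the spike on
    the high-saturation side, keeps the largest 8-connected component, and
    fills enclosed holes.
    """
    sat = saturation_channel(img).pixels
    t = otsu_threshold(sat)
    fg = binarize(sat, t)
    # Polarity guard: the spike is the high-saturation class. With fg defined
    # as "> t" this holds by construction, but an inverted scene (saturated
    # board, neutral spike) would silently flip it — check and correct.
    if fg.any() and (~fg.astype(bool)).any():
        if sat[fg == 1].mean() < sat[fg == 0].mean():
            fg = 1 - fg
    if not fg.any():
        raise ValueError("empty mask: no pixels above Otsu threshold")
    fg = largest_component(fg)
    fg = ndi.binary_fill_holes(fg).astype(np.uint8)
    return SpikeMask(fg, threshold_used=t)
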