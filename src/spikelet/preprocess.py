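"""Region-of-interest cropping and bicubic resampling to the canonical frame.

Raw spike photos are large (the motivating capture setup produces
4,000 x 3,000 px frames) and mostly board.  The coarse spike criterion —
Otsu on the saturation channel at full resolution, largest 8-connected
component — locates the spike; the crop is its tight bounding rectangle
expanded by a pad, and the crop is then resampled (bicubic) to the fixed
canonical frame of 256 x 1,021 so downstream area thresholds live at a
single scale.
"""

from __future__ import annotations

import numpy as np
from PIL import Image

from . import spikeseg
from .types import CANONICAL_HEIGHT, CANONICAL_WIDTH, CanonicalImage, RawImage

__all__ = ["extract_roi", "resample_canonical", "preprocess_image"]

DEFAULT_PAD = 20


def coarse_foreground(raw: RawImage) -> np.ndarray:
    """Coarse spike mask at raw resolution (Otsu on S, largest component)."""
    sat = spikeseg.saturation_of_rgb(raw.pixels)
    try:
        t = spikeseg.otsu_threshold(sat)
    except ValueError as exc:
        raise ValueError("empty ROI: degenerate image") from exc
    fg = spikeseg.binarize(sat, t)
    if fg.any() and (~fg.astype(bool)).any():
        if sat[fg == 1].mean() < sat[fg == 0].mean():
            fg = 1 - fg
    if not fg.any():
        raise ValueError("empty ROI: no foreground found")
    return spikeseg.largest_component(fg)


def extract_roi(raw: RawImage, pad: int = DEFAULT_PAD) -> tuple[RawImage, tuple[int, int]]:
    """Crop the tight bounding rectangle of the coarse spike, plus ``pad``.

    Returns the cropped :class:`RawImage` and the (row, col) origin of the
    crop in the raw frame.  The crop is clipped to image bounds; every
    coarse-foreground pixel lies inside it.

    Raises
    ------
    ValueError
        "empty ROI" when no foreground exists (e.g. a constant image).
    """
    if pad < 0:
        raise ValueError("pad must be non-negative")
    fg = coarse_foreground(raw)
    rows = np.flatnonzero(fg.any(axis=1))
    cols = np.flatnonzero(fg.any(axis=0))
    r0 = max(int(rows[0]) - pad, 0)
    r1 = min(int(rows[-1]) + 1 + pad, raw.height)
    c0 = max(int(cols[0]) - pad, 0)
    c1 = min(int(cols[-1]) + 1 + pad, raw.width)
    crop = RawImage(
        raw.pixels[r0:r1, c0:c1].copy(),
        image_id=raw.image_id,
        wheat_line=raw.wheat_line,
    )
    return crop, (r0, c0)


def resample_canonical(
    cropped: RawImage,
    canonical_size: tuple[int, int] = (CANONICAL_WIDTH, CANONICAL_HEIGHT),
    roi_offset: tuple[int, int] = (0, 0),
) -> CanonicalImage:
    """Bicubic resample of a crop to ``canonical_size`` (width, height)."""
    width, height = canonical_size
    if width < 1 or height < 1:
        raise ValueError("canonical size must be positive")
    if (cropped.width, cropped.height) == (width, height):
        pixels = cropped.pixels.copy()
    else:
        im = Image.fromarray(cropped.pixels, mode="RGB")
        pixels = np.asarray(im.resize((width, height), Image.BICUBIC))
    scale = (height / cropped.height, width / cropped.width)
    return CanonicalImage(
        pixels,
        source_id=cropped.image_id,
        wheat_line=cropped.wheat_line,
        roi_offset=roi_offset,
        scale=scale,
    )


def preprocess_image(
    raw: RawImage,
    pad: int = DEFAULT_PAD,
    canonical_size: tuple[int, int] = (CANONICAL_WIDTH, CANONICAL_HEIGHT),
) -> CanonicalImage:
    """ROI crop followed by bicubic resampling to the canonical frame."""
    crop, offset = extract_roi(raw, pad=pad)
    return resample_canonical(crop, canonical_size, roi_offset=offset)
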