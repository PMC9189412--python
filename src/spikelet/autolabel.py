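"""Unsupervised spikelet labeling: Cb channel + h-minima watershed + MER filter.

Spikelet glumes have lower blue-chroma (Cb) values than the pixels at the
boundaries between spikelets, so on the Cb relief each spikelet body is a
catchment basin.  The labeling pipeline is:

    Cb channel -> bilateral contrast enhancement -> zero the background
    (spike mask) -> h-minima suppression (depth < h are removed, avoiding
    over-segmentation) -> marker-controlled watershed restricted to the
    spike -> per-basin area + minimum enclosed rectangle (MER) -> keep
    regions with area in [1000, 5000] px and MER long/short side ratio in
    [1, 2.5].

The surviving MERs, in reading order, are the candidate spikelet labels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage as ndi
from skimage.morphology import local_minima, reconstruction
from skimage.restoration import denoise_bilateral
from skimage.segmentation import watershed

from . import spikeseg
from .types import Annotation, Box, CandidateRegion, CanonicalImage, GrayImage, SpikeMask

__all__ = [
    "AutolabelParams",
    "cb_channel",
    "bilateral_enhance",
    "mask_background",
    "suppress_shallow_minima",
    "hmin_watershed",
    "extract_regions",
    "filter_regions",
    "autolabel_image",
]


@dataclass(frozen=True)
class AutolabelParams:
    """Tunable constants of the labeling pipeline.

    ``h_min`` is the minima-depth ("local minimum") threshold of the
    h-minima transform; basins shallower than this merge into their
    neighbors.  ``area_min``/``area_max`` bound the basin pixel count and
    ``ratio_min``/``ratio_max`` the MER side ratio (long/short); both
    intervals are inclusive.  ``bilateral`` is (window diameter px,
    range sigma in gray levels, spatial sigma px).
    """

    h_min: int = 3
    area_min: int = 1000
    area_max: int = 5000
    ratio_min: float = 1.0
    ratio_max: float = 2.5
    bilateral: tuple[int, float, float] = (9, 50.0, 5.0)

    def __post_init__(self) -> None:
        if not (0 < self.area_min < self.area_max):
            raise ValueError("need 0 < area_min < area_max")
        if not (1.0 <= self.ratio_min <= self.ratio_max):
            raise ValueError("need 1 <= ratio_min <= ratio_max")
        if self.h_min < 1:
            raise ValueError("h_min must be >= 1")


# Full-range ITU-R BT.601 blue-chroma coefficients.
_CB_R, _CB_G, _CB_B = 0.168736, 0.331264, 0.5


def cb_channel(img: CanonicalImage) -> GrayImage:
    """Blue-chroma (Cb) component: 128 - 0.169 R - 0.331 G + 0.5 B."""
    arr = img.pixels.astype(np.float64)
    cb = 128.0 - _CB_R * arr[..., 0] - _CB_G * arr[..., 1] + _CB_B * arr[..., 2]
    return GrayImage(
        np.clip(np.rint(cb), 0, 255).astype(np.uint8), channel_name="Cb"
    )


def bilateral_enhance(
    gray: GrayImage, bilateral: tuple[int, float, float] = AutolabelParams.bilateral
) -> GrayImage:
    """Edge-preserving bilateral smoothing of the Cb image.

    Smooths within spikelet bodies while keeping the body/boundary edges
    sharp, which deepens the basins relative to residual texture.
    """
    diameter, range_sigma, spatial_sigma = bilateral
    out = denoise_bilateral(
        gray.pixels.astype(np.float64) / 255.0,
        win_size=int(diameter),
        sigma_color=range_sigma / 255.0,
        sigma_spatial=spatial_sigma,
        mode="edge",  # constant-pad would drag border values toward 0
    )
    return GrayImage(
        np.clip(np.rint(out * 255.0), 0, 255).astype(np.uint8),
        channel_name=gray.channel_name,
    )


def mask_background(gray: GrayImage, mask: SpikeMask) -> GrayImage:
    """Pixel-wise product: background to 0, spike values unchanged."""
    if gray.shape != mask.shape:
        raise ValueError(f"dimension mismatch: {gray.shape} vs {mask.shape}")
    return GrayImage(gray.pixels * mask.pixels, channel_name=gray.channel_name)


def suppress_shallow_minima(surface: np.ndarray, h: float) -> np.ndarray:
    """h-minima transform: fill every regional minimum of dynamic depth < h.

    Implemented as grayscale reconstruction-by-erosion of ``surface + h``
    above ``surface``.  Idempotent: applying it twice equals applying it
    once.
    """
    surface = np.asarray(surface, dtype=np.float64)
    return reconstruction(surface + h, surface, method="erosion")


def hmin_watershed(
    gray: GrayImage, mask: SpikeMask, h_min: int = 3
) -> np.ndarray:
    """Marker-controlled watershed of the Cb relief inside the spike mask.

    Regional minima of dynamic depth < ``h_min`` are removed by grayscale
    reconstruction (the h-minima transform); the surviving minima seed the
    flood.  Returns an int32 label raster: 0 = background or watershed ridge
    line, k >= 1 = basin.  Basins are 8-connected, pairwise disjoint, and
    confined to ``mask == 1``.
    """
    if h_min < 1:
        raise ValueError("h_min must be >= 1")
    if gray.shape != mask.shape:
        raise ValueError(f"dimension mismatch: {gray.shape} vs {mask.shape}")
    inside = mask.pixels.astype(bool)
    if not inside.any():
        raise ValueError("empty mask")
    # Work in float and push the background to a ceiling so that no regional
    # minimum (and no basin) can live outside the spike.
    surface = gray.pixels.astype(np.float64)
    ceiling = 256.0 + float(h_min)
    surface[~inside] = ceiling
    filled = suppress_shallow_minima(surface, h_min)
    minima = local_minima(filled, connectivity=2) & inside
    markers, n = ndi.label(minima, structure=np.ones((3, 3), dtype=bool))
    if n == 0:  # single plateau covering the whole mask
        markers = inside.astype(np.int32)
    labels = watershed(
        filled, markers=markers, mask=inside, connectivity=2, watershed_line=True
    )
    return labels.astype(np.int32)


def extract_regions(labels: np.ndarray) -> list[CandidateRegion]:
    """Per-basin area and tight axis-aligned MER, ordered by label id."""
    labels = np.asarray(labels)
    n = int(labels.max())
    if n == 0:
        return []
    objects = ndi.find_objects(labels, max_label=n)
    areas = np.bincount(labels.ravel(), minlength=n + 1)
    regions: list[CandidateRegion] = []
    for lid, sl in enumerate(objects, start=1):
        if sl is None:
            continue
        rs, cs = sl
        regions.append(
            CandidateRegion(
                label_id=lid,
                area=int(areas[lid]),
                box=Box(
                    x=int(cs.start),
                    y=int(rs.start),
                    w=int(cs.stop - cs.start),
                    h=int(rs.stop - rs.start),
                ),
            )
        )
    return regions


def filter_regions(
    regions: list[CandidateRegion], params: AutolabelParams = AutolabelParams()
) -> list[Box]:
    """Keep regions passing the area and MER side-ratio tests (inclusive).

    Area is the basin pixel count, not the box area.  Survivors are
    returned in reading order (top-to-bottom, then left-to-right) for
    deterministic output.
    """
    kept = [
        r.box
        for r in regions
        if params.area_min <= r.area <= params.area_max
        and params.ratio_min <= r.box.aspect_ratio <= params.ratio_max
    ]
    return sorted(kept, key=lambda b: (b.y, b.x))


def autolabel_image(
    img: CanonicalImage, params: AutolabelParams = AutolabelParams()
) -> Annotation:
    """Full unsupervised labeling of one canonical spike image."""
    mask = spikeseg.spike_mask(img)
    cb = cb_channel(img)
    enhanced = bilateral_enhance(cb, params.bilateral)
    masked = mask_background(enhanced, mask)
    labels = hmin_watershed(masked, mask, params.h_min)
    boxes = filter_regions(extract_regions(labels), params)
    return Annotation(
        image_id=img.source_id,
        wheat_line=img.wheat_line,
        image_size=(img.width, img.height),
        boxes=boxes,
        source="watershed",
    )
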