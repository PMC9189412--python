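"""Synthetic single-spike images with exact ground truth.

The generator renders what the labeling pipeline assumes about a real
photo: one near-vertical spike on a uniform, nearly neutral board, with

* paired elliptical spikelets on both sides of a vertical rachis plus an
  apical spikelet on top — all strongly saturated, so Otsu on the S channel
  separates spike from board;
* spikelet bodies whose blue-chroma (Cb) values dip well below the rachis
  and inter-spikelet boundary levels, so each body is one catchment basin
  of the Cb relief (body-vs-boundary contrast is kept at least ``h_min + 2``
  gray levels, far above the minima-suppression depth);
* a shallow Cb dip on each rachis segment *between* spikelet rows, which
  gives those segments their own small basins — they are later discarded by
  the area filter instead of inflating a spikelet's rectangle;
* optional thin awn strokes (width <= 2 px) rendered just off the spike
  body, and an optional small sterile basal spikelet that is flagged and
  too small to pass the area filter.

Every geometric element is recorded, so ground-truth boxes (canonical
coordinates) and the foreground mask are exact.  All randomness flows from
one seeded generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import line as draw_line

from .counteval import CountComparison
from .types import (
    CANONICAL_HEIGHT,
    CANONICAL_WIDTH,
    Box,
    CanonicalImage,
    RawImage,
)

__all__ = [
    "LinePalette",
    "WHEAT_LINE_PALETTES",
    "SyntheticSpikeParams",
    "SyntheticSample",
    "generate_spike",
    "generate_count_study",
]


def _cb_of(rgb: tuple[int, int, int]) -> float:
    r, g, b = rgb
    return 128.0 - 0.168736 * r - 0.331264 * g + 0.5 * b


@dataclass(frozen=True)
class LinePalette:
    """Colors of one wheat-line preset.

    ``body_center``/``body_edge`` shade the spikelet ellipse radially (the
    center is the basin floor); ``rachis`` is the high-Cb ridge level and
    ``rachis_dip`` the slightly lower level of inter-row segments; ``awn``
    colors the bristle strokes; ``board`` is the background.
    """

    body_center: tuple[int, int, int]
    body_edge: tuple[int, int, int]
    rachis: tuple[int, int, int]
    rachis_dip: tuple[int, int, int]
    awn: tuple[int, int, int]
    board: tuple[int, int, int]

    def check_contrast(self, h_min: int) -> None:
        """Basin floor must sit at least h_min + 2 Cb levels below the
        boundary (rachis) level, and the rachis dip must be a real minimum."""
        body = _cb_of(self.body_edge)
        ridge = _cb_of(self.rachis)
        dip = _cb_of(self.rachis_dip)
        if not body <= ridge - (h_min + 2):
            raise ValueError("palette: body Cb too close to boundary Cb")
        if not (body < dip < ridge and ridge - dip >= h_min):
            raise ValueError("palette: rachis dip must lie between body and ridge")


# Four presets mirroring wheat lines that differ in hue and brightness;
# the "liangxing99"-style preset is the most uniform in color.
WHEAT_LINE_PALETTES: dict[str, LinePalette] = {
    "line_a": LinePalette(  # warm golden, high contrast
        body_center=(210, 170, 40),
        body_edge=(190, 160, 55),
        rachis=(115, 135, 60),
        rachis_dip=(170, 150, 62),
        awn=(150, 140, 70),
        board=(200, 200, 204),
    ),
    "line_b": LinePalette(  # paler straw yellow
        body_center=(220, 190, 60),
        body_edge=(200, 180, 75),
        rachis=(125, 145, 70),
        rachis_dip=(180, 160, 72),
        awn=(165, 155, 85),
        board=(205, 205, 208),
    ),
    "line_c": LinePalette(  # uniform light gold, smallest internal spread
        body_center=(205, 175, 50),
        body_edge=(195, 170, 58),
        rachis=(120, 140, 65),
        rachis_dip=(172, 152, 64),
        awn=(152, 142, 72),
        board=(198, 198, 202),
    ),
    "line_d": LinePalette(  # darker bronze
        body_center=(185, 145, 35),
        body_edge=(170, 140, 50),
        rachis=(105, 125, 55),
        rachis_dip=(150, 130, 52),
        awn=(138, 128, 65),
        board=(202, 202, 206),
    ),
}


@dataclass(frozen=True)
class SyntheticSpikeParams:
    """Generator configuration; defaults give 19 countable spikelets.

    ``spikelet_axes`` are the ellipse semi-axes (major = vertical, minor =
    horizontal) in canonical pixels, sized so body regions carry 1,000 to
    5,000 px; ``boundary_gap`` is the vertical clearance between adjacent
    spikelet rows; ``awn_density`` counts awn strokes per spikelet.
    """

    n_pairs: int = 9
    include_apical: bool = True
    include_sterile_basal: bool = False
    spikelet_axes: tuple[int, int] = (28, 18)
    boundary_gap: int = 39
    awn_density: int = 2
    wheat_line: str = "line_a"
    noise_sigma: float = 0.0
    raw_scale: int = 3
    raw_margin: int = 120
    seed: int = 0
    h_min: int = 3  # contrast the palette must clear

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.wheat_line not in WHEAT_LINE_PALETTES:
            raise ValueError(f"unknown wheat line preset {self.wheat_line!r}")
        a, b = self.spikelet_axes
        if a < 4 or b < 4:
            raise ValueError("spikelet axes too small")
        if self.boundary_gap < 1:
            raise ValueError("boundary_gap must be >= 1")
        WHEAT_LINE_PALETTES[self.wheat_line].check_contrast(self.h_min)


@dataclass
class SyntheticSample:
    """A rendered spike with its exact ground truth.

    ``gt_boxes`` and ``gt_mask`` are in the coordinates of ``canonical``;
    ``image`` is the same scene at raw (pre-ROI) scale.  ``sterile_flags``
    marks the non-countable basal spikelet when present.
    """

    image: RawImage
    canonical: CanonicalImage
    gt_boxes: list[Box]
    gt_mask: np.ndarray
    sterile_flags: list[bool] = field(default_factory=list)

    @property
    def countable_boxes(self) -> list[Box]:
        return [b for b, s in zip(self.gt_boxes, self.sterile_flags) if not s]


def _layout(params: SyntheticSpikeParams) -> dict:
    """Scene geometry in canonical coordinates (row, col)."""
    a, b = params.spikelet_axes
    pitch = 2 * a + params.boundary_gap
    cx = CANONICAL_WIDTH // 2
    rachis_half = 4
    # ellipses touch the rachis strip so the spike is one component
    offset = rachis_half + b - 1
    top = 62 + a
    centers: list[tuple[int, int, bool]] = []  # (row, col, sterile)
    if params.include_apical:
        centers.append((top, cx, False))
        first_pair = top + pitch
    else:
        first_pair = top
    for k in range(params.n_pairs):
        y = first_pair + k * pitch
        centers.append((y, cx - offset, False))
        centers.append((y, cx + offset, False))
    base = first_pair + (params.n_pairs - 1) * pitch + a + 12
    if params.include_sterile_basal:
        sa, sb = max(a // 2, 4), max(b // 2, 4)
        centers.append((base + sa - 2, cx - rachis_half - sb + 1, True))
        base = base + 2 * sa
    if base + 6 > CANONICAL_HEIGHT:
        raise ValueError(
            "layout overflows the canonical frame; reduce n_pairs or axes"
        )
    return {
        "centers": centers,
        "axes": (a, b),
        "cx": cx,
        "rachis_half": rachis_half,
        "rachis_top": top,
        "rachis_base": base,
        "pitch": pitch,
    }


def _check_overlap(layout: dict, params: SyntheticSpikeParams) -> None:
    from .detecteval import iou

    a, b = layout["axes"]
    boxes = [
        Box(x=c - b, y=r - a, w=2 * b + 1, h=2 * a + 1)
        for r, c, sterile in layout["centers"]
        if not sterile
    ]
    for i in range(len(boxes)):
        for j in range(i + 1, len(boxes)):
            if iou(boxes[i], boxes[j]) >= 0.3:
                raise ValueError("countable spikelets overlap (IoU >= 0.3)")


def _render(
    layout: dict,
    params: SyntheticSpikeParams,
    scale: int,
    shape: tuple[int, int],
    origin: tuple[int, int],
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Paint the scene at an integer scale; returns (rgb float64, mask)."""
    pal = WHEAT_LINE_PALETTES[params.wheat_line]
    h, w = shape
    r0, c0 = origin
    img = np.empty((h, w, 3), dtype=np.float64)
    img[:] = np.asarray(pal.board, dtype=np.float64)
    mask = np.zeros((h, w), dtype=np.uint8)
    a, b = layout["axes"]
    cx = layout["cx"]
    half = layout["rachis_half"]

    def put(rr, cc, color):
        ok = (rr >= 0) & (rr < h) & (cc >= 0) & (cc < w)
        img[rr[ok], cc[ok]] = color
        mask[rr[ok], cc[ok]] = 1

    # rachis strip (ridge level)
    rt, rb = layout["rachis_top"] * scale + r0, layout["rachis_base"] * scale + r0
    ct0, ct1 = (cx - half) * scale + c0, (cx + half + 1) * scale + c0
    img[rt:rb, ct0:ct1] = np.asarray(pal.rachis, dtype=np.float64)
    mask[rt:rb, ct0:ct1] = 1
    # shallow dips on inter-row rachis segments: their own (small) basins
    centers = layout["centers"]
    rows = sorted({r for r, _, st in centers if not st})
    for y0, y1 in zip(rows[:-1], rows[1:]):
        lo = (y0 + a + 4) * scale + r0
        hi = (y1 - a - 4) * scale + r0
        if hi > lo:
            img[lo:hi, ct0:ct1] = np.asarray(pal.rachis_dip, dtype=np.float64)
    # spikelet bodies, shaded center -> edge so each has one clear minimum
    cc_center = np.asarray(pal.body_center, dtype=np.float64)
    cc_edge = np.asarray(pal.body_edge, dtype=np.float64)
    for r, c, sterile in centers:
        ra = (a // 2 if sterile else a) * scale
        rb_ = (b // 2 if sterile else b) * scale
        rr, cc = draw_ellipse(r * scale + r0, c * scale + c0, ra, rb_, shape=(h, w))
        # radial shade: t = normalized squared distance from the center
        t = ((rr - (r * scale + r0)) / ra) ** 2 + ((cc - (c * scale + c0)) / rb_) ** 2
        color = cc_center[None, :] * (1 - t[:, None]) + cc_edge[None, :] * t[:, None]
        img[rr, cc] = color
        mask[rr, cc] = 1
    # awns: thin strokes starting a little off the body so they stay
    # disconnected from the spike component (the mask post-processing then
    # discards them, as the MER filters discard real awn regions)
    if params.awn_density > 0:
        awn = np.asarray(pal.awn, dtype=np.float64)
        for r, c, sterile in centers:
            if sterile:
                continue
            for _ in range(params.awn_density):
                ang = rng.uniform(-0.9, 0.9)  # radians from vertical
                length = rng.integers(16, 28)
                sr = r - a - 4
                sc = c + int(np.round(np.sin(ang) * 6))
                er = sr - int(np.round(np.cos(ang) * length))
                ec = sc + int(np.round(np.sin(ang) * length))
                rr, cc = draw_line(
                    sr * scale + r0, sc * scale + c0, er * scale + r0, ec * scale + c0
                )
                for d in range(max(scale // 2, 1)):
                    put(np.clip(rr, 0, h - 1), np.clip(cc + d, 0, w - 1), awn)
    return img, mask


def generate_spike(params: SyntheticSpikeParams = SyntheticSpikeParams()) -> SyntheticSample:
    """Render one synthetic spike at raw and canonical scales.

    Raises ``ValueError`` if the requested geometry makes countable
    spikelets overlap (pairwise IoU >= 0.3) or overflow the frame.
    """
    layout = _layout(params)
    _check_overlap(layout, params)
    rng = np.random.default_rng(params.seed)
    a, b = layout["axes"]

    # canonical-scale render
    canon_rgb, canon_mask = _render(
        layout, params, 1, (CANONICAL_HEIGHT, CANONICAL_WIDTH), (0, 0),
        np.random.default_rng(params.seed),
    )
    # raw-scale render of the same scene (same stroke randomness)
    s, m = params.raw_scale, params.raw_margin
    raw_shape = (CANONICAL_HEIGHT * s + 2 * m, CANONICAL_WIDTH * s + 2 * m)
    raw_rgb, _ = _render(
        layout, params, s, raw_shape, (m, m), np.random.default_rng(params.seed)
    )
    if params.noise_sigma > 0:
        canon_rgb = canon_rgb + rng.normal(0, params.noise_sigma, canon_rgb.shape)
        raw_rgb = raw_rgb + rng.normal(0, params.noise_sigma, raw_rgb.shape)
    canon_u8 = np.clip(np.rint(canon_rgb), 0, 255).astype(np.uint8)
    raw_u8 = np.clip(np.rint(raw_rgb), 0, 255).astype(np.uint8)

    boxes: list[Box] = []
    flags: list[bool] = []
    for r, c, sterile in layout["centers"]:
        ra = a // 2 if sterile else a
        rb_ = b // 2 if sterile else b
        boxes.append(Box(x=c - rb_, y=r - ra, w=2 * rb_ + 1, h=2 * ra + 1))
        flags.append(sterile)

    image_id = f"synthetic_{params.wheat_line}_{params.seed:04d}"
    return SyntheticSample(
        image=RawImage(raw_u8, image_id=image_id, wheat_line=params.wheat_line),
        canonical=CanonicalImage(
            canon_u8, source_id=image_id, wheat_line=params.wheat_line
        ),
        gt_boxes=boxes,
        gt_mask=canon_mask,
        sterile_flags=flags,
    )


def generate_count_study(
    n_images: int,
    count_error_model: dict | None = None,
    seed: int = 0,
    count_range: tuple[int, int] = (17, 23),
    wheat_lines: tuple[str, ...] = tuple(WHEAT_LINE_PALETTES),
) -> CountComparison:
    """Paired manual/automatic counts under a stated integer error model.

    True ("manual") counts are drawn uniformly from ``count_range``
    (inclusive), matching typical per-spike spikelet numbers.  The error
    model perturbs them into automatic counts:

    * ``{"kind": "none"}`` — automatic equals manual (default);
    * ``{"kind": "pm1", "p": q}`` — with probability q the count is off by
      one (sign equiprobable), so RMSE -> sqrt(q) for large n;
    * ``{"kind": "shift", "delta": k}`` — deterministic offset k.
    """
    if n_images < 2:
        raise ValueError("need at least 2 images")
    model = count_error_model or {"kind": "none"}
    rng = np.random.default_rng(seed)
    lo, hi = count_range
    manual = rng.integers(lo, hi + 1, size=n_images)
    kind = model["kind"]
    if kind == "none":
        automatic = manual.copy()
    elif kind == "pm1":
        p = float(model["p"])
        hit = rng.random(n_images) < p
        sign = rng.choice([-1, 1], size=n_images)
        automatic = manual + hit * sign
    elif kind == "shift":
        automatic = manual + int(model["delta"])
    else:
        raise ValueError(f"unknown error model {kind!r}")
    lines = [wheat_lines[i % len(wheat_lines)] for i in range(n_images)]
    return CountComparison(
        manual=manual,
        automatic=np.maximum(automatic, 0),
        image_ids=[f"count_{i:04d}" for i in range(n_images)],
        wheat_lines=lines,
    )
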