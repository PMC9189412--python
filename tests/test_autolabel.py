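"""Cb channel, bilateral filter, h-minima watershed, and MER filtering."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from spikelet.autolabel import (
    AutolabelParams,
    autolabel_image,
    bilateral_enhance,
    cb_channel,
    extract_regions,
    filter_regions,
    hmin_watershed,
    mask_background,
    suppress_shallow_minima,
)
from spikelet.detecteval import iou
from spikelet.types import Box, CandidateRegion, CanonicalImage, GrayImage, SpikeMask


def _gray(arr):
    return GrayImage(np.asarray(arr, dtype=np.uint8))


def _mask(arr):
    return SpikeMask(np.asarray(arr, dtype=np.uint8), threshold_used=0)


# ---------------------------------------------------------------- Cb channel

@pytest.mark.parametrize(
    "rgb,expected",
    [
        ((0, 0, 0), 128),
        ((200, 200, 200), 128),  # any gray -> chroma offset
        ((0, 0, 255), 255),  # 128 + 127.5 clipped after rounding
        ((255, 0, 0), 85),  # round(128 - 0.168736*255)
        ((0, 255, 0), 44),  # round(128 - 0.331264*255)
    ],
)
def test_cb_formula(rgb, expected):
    img = CanonicalImage(np.full((2, 2, 3), rgb, dtype=np.uint8))
    assert cb_channel(img).pixels[0, 0] == expected


# ---------------------------------------------------------------- bilateral

def test_bilateral_preserves_constant():
    g = _gray(np.full((40, 40), 100))
    out = bilateral_enhance(g)
    assert np.all(out.pixels == 100)


def test_bilateral_range_bounded(rng):
    g = _gray(rng.integers(40, 200, (50, 50)))
    out = bilateral_enhance(g)
    assert out.pixels.min() >= g.pixels.min()
    assert out.pixels.max() <= g.pixels.max()


def test_bilateral_keeps_step_edge_location():
    g = np.full((40, 60), 50, dtype=np.uint8)
    g[:, 30:] = 200
    out = bilateral_enhance(_gray(g)).pixels.astype(int)
    grad_in = np.abs(np.diff(g.astype(int), axis=1)).sum(axis=0)
    grad_out = np.abs(np.diff(out, axis=1)).sum(axis=0)
    assert np.argmax(grad_out) == np.argmax(grad_in) == 29


def test_bilateral_reduces_noise_variance(rng):
    g = np.clip(100 + rng.normal(0, 5, (60, 60)), 0, 255).astype(np.uint8)
    out = bilateral_enhance(_gray(g))
    assert out.pixels.astype(float).var() <= g.astype(float).var()


# ---------------------------------------------------------------- masking

def test_mask_background_zeroes_exactly_background(rng):
    g = _gray(rng.integers(1, 255, (20, 20)))
    m = np.zeros((20, 20), dtype=np.uint8)
    m[:, :10] = 1
    out = mask_background(g, _mask(m))
    assert np.array_equal(out.pixels[:, :10], g.pixels[:, :10])
    assert np.all(out.pixels[:, 10:] == 0)


def test_mask_background_dimension_mismatch():
    with pytest.raises(ValueError, match="mismatch"):
        mask_background(_gray(np.zeros((5, 5))), _mask(np.ones((4, 4))))


# ------------------------------------------------------------- h-minima

def _two_pit_surface(ridge_level):
    """Vertical profile: pit(50) | ridge | pit(50) on an 80-level base."""
    surf = np.full((40, 30), 100, dtype=np.uint8)
    surf[5:15, 5:25] = 50
    surf[15:25, 5:25] = ridge_level
    surf[25:35, 5:25] = 50
    mask = np.ones_like(surf)
    return _gray(surf), _mask(mask)


def test_two_pits_with_high_ridge_give_two_basins():
    g, m = _two_pit_surface(ridge_level=80)  # ridge 30 above pit floors
    labels = hmin_watershed(g, m, h_min=3)
    assert labels.max() == 2


def test_two_pits_with_shallow_ridge_merge():
    g, m = _two_pit_surface(ridge_level=52)  # only 2 above the floors
    labels = hmin_watershed(g, m, h_min=3)
    assert labels.max() == 1


def test_single_pit_single_basin():
    surf = np.full((30, 30), 90, dtype=np.uint8)
    surf[10:20, 10:20] = 40
    labels = hmin_watershed(_gray(surf), _mask(np.ones_like(surf)), 3)
    assert labels.max() == 1


def test_hmin_watershed_empty_mask_errors():
    g = _gray(np.zeros((10, 10)))
    with pytest.raises(ValueError, match="empty mask"):
        hmin_watershed(g, _mask(np.zeros((10, 10))), 3)


def test_watershed_partition_is_disjoint_and_inside_mask(noisy_sample):
    from spikelet.spikeseg import spike_mask

    img = noisy_sample.canonical
    m = spike_mask(img)
    g = mask_background(bilateral_enhance(cb_channel(img)), m)
    labels = hmin_watershed(g, m, 3)
    assert np.all(labels[m.pixels == 0] == 0)  # basins confined to mask
    regions = extract_regions(labels)
    assert sum(r.area for r in regions) <= m.area  # ridges unassigned
    assert labels.min() == 0


def test_suppression_properties(rng):
    from scipy import ndimage as ndi
    from skimage.morphology import local_minima

    s8 = np.ones((3, 3))
    for _ in range(5):
        surf = rng.integers(0, 100, (40, 40)).astype(np.float64)
        filled = suppress_shallow_minima(surf, 3)
        # relief is only raised, and by at most h
        assert np.all(filled >= surf)
        assert np.all(filled <= surf + 3 + 1e-9)
        # suppression never creates minima
        n_before = ndi.label(local_minima(surf, connectivity=2), structure=s8)[1]
        n_after = ndi.label(local_minima(filled, connectivity=2), structure=s8)[1]
        assert n_after <= n_before


def test_suppression_depth_rule():
    # a pit shallower than h vanishes; a deeper one survives
    from skimage.morphology import local_minima

    base = np.full((20, 40), 100.0)
    shallow = base.copy()
    shallow[8:12, 10:20] = 98  # depth 2 < 3
    deep = base.copy()
    deep[8:12, 25:35] = 90  # depth 10 >= 3
    assert local_minima(suppress_shallow_minima(shallow, 3)).sum() == 0
    filled = suppress_shallow_minima(deep, 3)
    assert local_minima(filled)[8:12, 25:35].all()


# ------------------------------------------------------------- regions

def test_extract_regions_rectangle():
    labels = np.zeros((100, 100), dtype=np.int32)
    labels[10:60, 20:60] = 1  # 50 rows x 40 cols at (y=10, x=20)
    (r,) = extract_regions(labels)
    assert r.area == 2000
    assert r.box == Box(x=20, y=10, w=40, h=50)


def test_extract_regions_empty():
    assert extract_regions(np.zeros((5, 5), dtype=np.int32)) == []


def _region(area, w, h, x=0, y=0, label_id=1):
    return CandidateRegion(label_id=label_id, area=area, box=Box(x, y, w, h))


@pytest.mark.parametrize(
    "area,w,h,kept",
    [
        (2000, 50, 30, True),  # inside both intervals
        (800, 30, 30, False),  # below area_min
        (5001, 70, 71, False),  # above area_max
        (3000, 90, 30, False),  # ratio 3.0 > 2.5
        (1000, 25, 25, True),  # area at lower bound, ratio 1.0
        (5000, 20, 50, True),  # area at upper bound, ratio exactly 2.5
    ],
)
def test_filter_region_boundaries(area, w, h, kept):
    boxes = filter_regions([_region(area, w, h)])
    assert (len(boxes) == 1) == kept


def test_filter_orders_reading_order():
    regions = [
        _region(2000, 30, 30, x=50, y=100, label_id=1),
        _region(2000, 30, 30, x=10, y=100, label_id=2),
        _region(2000, 30, 30, x=90, y=5, label_id=3),
    ]
    boxes = filter_regions(regions)
    assert [(b.y, b.x) for b in boxes] == [(5, 90), (100, 10), (100, 50)]


@given(
    shrink_lo=st.integers(0, 500),
    shrink_hi=st.integers(0, 2000),
    ratio_hi=st.floats(1.0, 2.5),
)
def test_filter_anti_monotone_in_constraints(shrink_lo, shrink_hi, ratio_hi):
    rng = np.random.default_rng(7)
    regions = [
        _region(int(a), int(w), int(h), label_id=i + 1)
        for i, (a, w, h) in enumerate(
            zip(
                rng.integers(500, 6000, 30),
                rng.integers(10, 100, 30),
                rng.integers(10, 100, 30),
            )
        )
    ]
    wide = AutolabelParams()
    narrow = AutolabelParams(
        area_min=wide.area_min + shrink_lo,
        area_max=wide.area_max - shrink_hi,
        ratio_max=ratio_hi,
    )
    assert len(filter_regions(regions, narrow)) <= len(filter_regions(regions, wide))


# ------------------------------------------------------------- end to end

def test_autolabel_recovers_synthetic_ground_truth(clean_sample):
    ann = autolabel_image(clean_sample.canonical)
    assert len(ann.boxes) >= 15
    matched_gt = 0
    for g in clean_sample.countable_boxes:
        if any(iou(g, b) >= 0.5 for b in ann.boxes):
            matched_gt += 1
    assert matched_gt == len(clean_sample.countable_boxes)
    # boxes stay inside the frame
    for b in ann.boxes:
        assert 0 <= b.x and 0 <= b.y
        assert b.x2 <= clean_sample.canonical.width
        assert b.y2 <= clean_sample.canonical.height


def test_autolabel_on_blank_board_errors():
    img = CanonicalImage(np.full((1021, 256, 3), 200, dtype=np.uint8))
    with pytest.raises(ValueError):
        autolabel_image(img)
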