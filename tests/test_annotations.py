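"""VOC XML round-trips, dataset splitting, relabel filtering, count tables."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from spikelet.annotations import (
    apply_corrections,
    count_table_from_cells,
    filter_by_confidence,
    read_voc_xml,
    split_dataset,
    summarize_counts,
    write_voc_xml,
)
from spikelet.types import Annotation, Box, Detection


def _ann(n_boxes, image_id="img0", line="line_a", size=(256, 1021)):
    rng = np.random.default_rng(hash(image_id) % (2**31))
    boxes = []
    for _ in range(n_boxes):
        w, h = int(rng.integers(1, 60)), int(rng.integers(1, 60))
        x = int(rng.integers(0, size[0] - w))
        y = int(rng.integers(0, size[1] - h))
        boxes.append(Box(x, y, w, h))
    return Annotation(image_id=image_id, wheat_line=line, image_size=size, boxes=boxes)


# ------------------------------------------------------------------- XML

def test_voc_coordinate_convention(tmp_path):
    ann = Annotation("a", "l", (20, 20), [Box(0, 0, 10, 10)])
    path = write_voc_xml(ann, tmp_path / "a.xml")
    text = path.read_text()
    for tag, val in [("xmin", 1), ("ymin", 1), ("xmax", 10), ("ymax", 10)]:
        assert f"<{tag}>{val}</{tag}>" in text


@given(st.integers(0, 12), st.integers(0, 2**31 - 1))
def test_xml_round_trip(n_boxes, ident):
    import tempfile, os

    ann = _ann(n_boxes, image_id=f"img{ident}")
    with tempfile.TemporaryDirectory() as d:
        back = read_voc_xml(write_voc_xml(ann, os.path.join(d, "x.xml")))
    assert back.image_id == ann.image_id
    assert back.wheat_line == ann.wheat_line
    assert back.image_size == ann.image_size
    assert back.boxes == ann.boxes
    assert back.source == ann.source


def test_read_rejects_malformed_box(tmp_path):
    p = tmp_path / "bad.xml"
    p.write_text(
        "<annotation><filename>f</filename>"
        "<size><width>50</width><height>50</height></size>"
        "<object><bndbox><xmin>20</xmin><ymin>5</ymin>"
        "<xmax>10</xmax><ymax>8</ymax></bndbox></object></annotation>"
    )
    with pytest.raises(ValueError, match="object 0"):
        read_voc_xml(p)


def test_read_rejects_missing_size(tmp_path):
    p = tmp_path / "nosize.xml"
    p.write_text("<annotation><filename>f</filename></annotation>")
    with pytest.raises(ValueError, match="size"):
        read_voc_xml(p)


def test_read_rejects_out_of_bounds_box(tmp_path):
    p = tmp_path / "oob.xml"
    p.write_text(
        "<annotation><filename>f</filename>"
        "<size><width>10</width><height>10</height></size>"
        "<object><bndbox><xmin>5</xmin><ymin>5</ymin>"
        "<xmax>20</xmax><ymax>9</ymax></bndbox></object></annotation>"
    )
    with pytest.raises(ValueError, match="object 0"):
        read_voc_xml(p)


# ------------------------------------------------------------------ split

def test_split_100_into_80_20():
    anns = [_ann(3, image_id=f"im{i}", line="L1") for i in range(100)]
    split = split_dataset(anns, 0.8, seed=1)
    assert len(split.train) == 80
    assert len(split.validation) == 20


def test_split_floor_rule_and_partition():
    anns = [_ann(1, image_id=f"im{i}") for i in range(10)]
    split = split_dataset(anns, 0.8, seed=0)
    assert len(split.train) == 8 and len(split.validation) == 2
    ids = {a.image_id for a in split.train} | {a.image_id for a in split.validation}
    assert len(ids) == 10


def test_split_deterministic_per_seed():
    anns = [_ann(1, image_id=f"im{i}", line=f"L{i % 3}") for i in range(30)]
    a = split_dataset(anns, 0.8, seed=9)
    b = split_dataset(anns, 0.8, seed=9)
    c = split_dataset(anns, 0.8, seed=10)
    assert [x.image_id for x in a.train] == [x.image_id for x in b.train]
    assert [x.image_id for x in a.train] != [x.image_id for x in c.train]


def test_split_is_per_line():
    anns = [_ann(1, image_id=f"a{i}", line="L1") for i in range(10)] + [
        _ann(1, image_id=f"b{i}", line="L2") for i in range(10)
    ]
    split = split_dataset(anns, 0.8, seed=4)
    for line in ("L1", "L2"):
        assert sum(a.wheat_line == line for a in split.train) == 8
        assert sum(a.wheat_line == line for a in split.validation) == 2


def test_split_empty_errors():
    with pytest.raises(ValueError):
        split_dataset([], 0.8, seed=0)


# ------------------------------------------------------------- confidence

def test_confidence_cut_is_strict():
    dets = [
        Detection(Box(0, 0, 5, 5), 0.9),
        Detection(Box(0, 0, 5, 5), 0.75),
        Detection(Box(0, 0, 5, 5), 0.76),
    ]
    kept = filter_by_confidence(dets, 0.75)
    assert [d.score for d in kept] == [0.9, 0.76]


@given(st.lists(st.floats(0, 1), max_size=20), st.floats(0, 1))
def test_confidence_output_is_subsequence(scores, threshold):
    dets = [Detection(Box(0, 0, 2, 2), s) for s in scores]
    kept = filter_by_confidence(dets, threshold)
    it = iter(dets)
    assert all(any(k is d for d in it) for k in kept)


# ------------------------------------------------------------ corrections

def test_corrections_arithmetic():
    ann = _ann(10)
    out = apply_corrections(ann, removals=[0, 5], additions=[Box(0, 0, 3, 3)] * 3)
    assert len(out.boxes) == 11
    assert out.source == "corrected"
    assert len(ann.boxes) == 10  # original untouched


def test_corrections_noop_changes_only_source():
    ann = _ann(4)
    out = apply_corrections(ann)
    assert out.boxes == ann.boxes and out.source == "corrected"


def test_corrections_invalid_index():
    with pytest.raises(ValueError, match="out of range"):
        apply_corrections(_ann(3), removals=[3])
    with pytest.raises(ValueError, match="duplicate"):
        apply_corrections(_ann(3), removals=[1, 1])


# ----------------------------------------------------------- count table

def test_summarize_counts_hand_sum():
    anns = [_ann(3, image_id="a"), _ann(4, image_id="b")]
    for a in anns:
        a.boxes = a.boxes[: 3 if a.image_id == "a" else 4]
    table = summarize_counts({"training": anns})
    assert table.loc["line_a", "training"] == 7
    assert table.loc["SUM", "SUM"] == 7


def test_summarize_counts_empty():
    table = summarize_counts({"training": [], "validation": []})
    assert table.loc["SUM", "SUM"] == 0


def test_count_table_margins_are_sums():
    table = count_table_from_cells(
        ["L1", "L2"], {"training": [10, 20], "validation": [1, 2]}
    )
    body = table.drop(index="SUM").drop(columns="SUM")
    assert (table.loc["SUM"].drop("SUM") == body.sum(axis=0)).all()
    assert (table["SUM"].drop("SUM") == body.sum(axis=1)).all()
    assert table.loc["SUM", "SUM"] == body.to_numpy().sum()
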