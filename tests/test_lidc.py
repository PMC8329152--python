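"""Annotation parsing, even-odd rasterization, and box extraction."""

import io

import numpy as np
import pytest

from nodulefuse.exceptions import (
    AnnotationParseError,
    ExtractionError,
    GeometryError,
)
from nodulefuse.lidc import (
    GridGeometry,
    NoduleAnnotation,
    extract_box,
    parse_annotations,
    polygon_interior,
    rasterize_mask,
)

TWO_NODULE_XML = """<?xml version="1.0" encoding="UTF-8"?>
<LidcReadMessage>
  <readingSession>
    <unblindedReadNodule>
      <noduleID>n1</noduleID>
      <characteristics>
        <subtlety>4</subtlety><internalStructure>1</internalStructure>
        <calcification>6</calcification><sphericity>4</sphericity>
        <margin>4</margin><lobulation>2</lobulation>
        <spiculation>1</spiculation><texture>5</texture>
        <malignancy>2</malignancy>
      </characteristics>
      <roi>
        <imageZposition>2.0</imageZposition>
        <edgeMap><xCoord>2</xCoord><yCoord>2</yCoord></edgeMap>
        <edgeMap><xCoord>2</xCoord><yCoord>7</yCoord></edgeMap>
        <edgeMap><xCoord>7</xCoord><yCoord>7</yCoord></edgeMap>
        <edgeMap><xCoord>7</xCoord><yCoord>2</yCoord></edgeMap>
      </roi>
    </unblindedReadNodule>
    <unblindedReadNodule>
      <noduleID>n2</noduleID>
      <characteristics>
        <subtlety>5</subtlety><internalStructure>1</internalStructure>
        <calcification>3</calcification><sphericity>3</sphericity>
        <margin>2</margin><lobulation>4</lobulation>
        <spiculation>5</spiculation><texture>5</texture>
        <malignancy>5</malignancy>
      </characteristics>
      <roi>
        <imageZposition>3.0</imageZposition>
        <edgeMap><xCoord>1</xCoord><yCoord>1</yCoord></edgeMap>
        <edgeMap><xCoord>1</xCoord><yCoord>4</yCoord></edgeMap>
        <edgeMap><xCoord>4</xCoord><yCoord>4</yCoord></edgeMap>
      </roi>
      <roi>
        <imageZposition>4.0</imageZposition>
        <edgeMap><xCoord>1</xCoord><yCoord>1</yCoord></edgeMap>
        <edgeMap><xCoord>1</xCoord><yCoord>5</yCoord></edgeMap>
        <edgeMap><xCoord>5</xCoord><yCoord>5</yCoord></edgeMap>
        <edgeMap><xCoord>5</xCoord><yCoord>1</yCoord></edgeMap>
      </roi>
    </unblindedReadNodule>
  </readingSession>
</LidcReadMessage>
"""

NO_MALIGNANCY_XML = TWO_NODULE_XML.replace(
    "<malignancy>5</malignancy>", "", 1
)


def _square_annotation(lo: int, hi: int, z: float = 0.0) -> NoduleAnnotation:
    pts = (
        [(lo, y) for y in range(lo, hi + 1)]
        + [(x, hi) for x in range(lo + 1, hi + 1)]
        + [(hi, y) for y in range(hi - 1, lo - 1, -1)]
        + [(x, lo) for x in range(hi - 1, lo, -1)]
    )
    return NoduleAnnotation("sq", [(z, pts)], {})


class TestParseAnnotations:
    def test_hand_written_fixture_point_counts(self):
        anns = parse_annotations(io.BytesIO(TWO_NODULE_XML.encode()))
        assert [a.nodule_id for a in anns] == ["n1", "n2"]
        assert [len(pts) for _, pts in anns[0].contours] == [4]
        assert [len(pts) for _, pts in anns[1].contours] == [3, 4]
        assert anns[0].characteristics["malignancy"] == 2
        assert anns[1].characteristics["int_structure"] == 1

    def test_missing_characteristic_excludes_nodule(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING, logger="nodulefuse.lidc"):
            anns = parse_annotations(io.BytesIO(NO_MALIGNANCY_XML.encode()))
        assert [a.nodule_id for a in anns] == ["n1"]
        assert any("incomplete" in r.message for r in caplog.records)

    def test_malformed_xml_raises_parse_error(self):
        with pytest.raises(AnnotationParseError):
            parse_annotations(io.BytesIO(b"<LidcReadMessage><oops>"))


class TestRasterizeMask:
    def test_square_outline_fills_interior_only(self):
        # 6x6 outline -> 4x4 interior, outline pixels excluded
        ann = _square_annotation(2, 7, z=0.0)
        mask = rasterize_mask(ann, GridGeometry((12, 12, 1)))
        assert mask.sum() == 16
        assert mask[3:7, 3:7, 0].all()

    def test_collinear_contour_warns_and_fills_nothing(self):
        ann = NoduleAnnotation("line", [(0.0, [(1, 1), (1, 2), (1, 3)])], {})
        with pytest.warns(UserWarning, match="empty interior"):
            mask = rasterize_mask(ann, GridGeometry((6, 6, 1)))
        assert mask.sum() == 0

    def test_contour_outside_grid_rejected(self):
        ann = _square_annotation(2, 7)
        with pytest.raises(GeometryError):
            rasterize_mask(ann, GridGeometry((6, 6, 1)))

    def test_z_matching_respects_slice_tolerance(self):
        ann = _square_annotation(1, 4, z=10.0)
        with pytest.raises(GeometryError):
            rasterize_mask(ann, GridGeometry((6, 6, 2), spacing_mm=(1, 1, 1)))

    def test_matches_brute_force_even_odd_oracle(self):
        # random simple polygons (convex hulls, <= 12 vertices) vs per-pixel
        # ray casting written independently here
        rng = np.random.default_rng(42)
        from scipy.spatial import ConvexHull

        for _ in range(20):
            pts = rng.uniform(1, 14, size=(12, 2))
            hull = ConvexHull(pts)
            poly = [tuple(p) for p in pts[hull.vertices]]
            fast = polygon_interior(poly, (16, 16))
            slow = np.zeros((16, 16), dtype=bool)
            for px in range(16):
                for py in range(16):
                    inside = False
                    n = len(poly)
                    for i in range(n):
                        x1, y1 = poly[i]
                        x2, y2 = poly[(i + 1) % n]
                        if (y1 <= py) != (y2 <= py):
                            if px < x1 + (py - y1) * (x2 - x1) / (y2 - y1):
                                inside = not inside
                    slow[px, py] = inside
            assert (fast == slow).all()

    def test_sphere_round_trip_voxel_error_under_5pct(self):
        from nodulefuse.synthetic import _slice_contours

        shape = (24, 24, 24)
        c = (np.arange(24) - 11.5)
        xx, yy, zz = np.meshgrid(c, c, c, indexing="ij")
        sphere = xx**2 + yy**2 + zz**2 <= 8.0**2
        contours = []
        for z in range(24):
            if sphere[:, :, z].any():
                for chain in _slice_contours(sphere[:, :, z]):
                    contours.append((float(z), [(int(x), int(y)) for x, y in chain]))
        ann = NoduleAnnotation("sphere", contours, {})
        mask = rasterize_mask(ann, GridGeometry(shape))
        rel_err = abs(int(mask.sum()) - int(sphere.sum())) / sphere.sum()
        assert rel_err < 0.05


class TestExtractBox:
    def test_centered_nodule_yields_central_block(self):
        rng = np.random.default_rng(0)
        grid = rng.normal(size=(64, 64, 32)).astype(np.float32)
        ann = _square_annotation(28, 35, z=16.0)
        vol, mask = extract_box(grid, ann, (32, 32, 16))
        assert vol.shape == (32, 32, 16) and mask.shape == (32, 32, 16)
        # centroid of the filled 29..34 square is (31.5, 31.5) at z=16
        center = np.rint([31.5, 31.5, 16.0]).astype(int)
        lo = center - np.array([16, 16, 8])
        expect = grid[lo[0]:lo[0] + 32, lo[1]:lo[1] + 32, lo[2]:lo[2] + 16]
        assert (vol == expect).all()

    def test_edge_nodule_zero_padded(self):
        grid = np.ones((40, 40, 20), dtype=np.float32)
        ann = _square_annotation(1, 7, z=10.0)  # centroid at x=y=4
        vol, mask = extract_box(grid, ann, (32, 32, 16))
        assert vol.shape == (32, 32, 16)
        # box spans x, y in [-12, 20): 12 zero-padded planes on the low sides
        assert (vol[:12] == 0).all() and (vol[:, :12] == 0).all()
        assert (vol[12:, 12:, :] == 1).all()
        assert not mask[:12].any()

    def test_output_shape_fixed(self, default_cohort):
        grid = np.zeros((48, 48, 24), dtype=np.float32)
        ann = _square_annotation(20, 27, z=12.0)
        vol, mask = extract_box(grid, ann)
        assert vol.shape == (32, 32, 16)

    def test_centroid_lands_near_box_center(self):
        grid = np.zeros((64, 64, 32), dtype=np.float32)
        ann = _square_annotation(10, 21, z=9.0)
        _, mask = extract_box(grid, ann, (32, 32, 16))
        centroid = np.array([c.mean() for c in np.nonzero(mask)])
        center = np.array([16, 16, 8])
        assert (np.abs(centroid - center) <= 1.0).all()

    def test_empty_mask_rejected(self):
        ann = NoduleAnnotation("line", [(0.0, [(1, 1), (1, 2), (1, 3)])], {})
        grid = np.zeros((32, 32, 16), dtype=np.float32)
        with pytest.raises(ExtractionError), pytest.warns(UserWarning):
            extract_box(grid, ann, (32, 32, 16))

    def test_grid_smaller_than_box_rejected(self):
        ann = _square_annotation(1, 4)
        with pytest.raises(GeometryError):
            extract_box(np.zeros((16, 16, 8), dtype=np.float32), ann, (32, 32, 16))
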