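"""LIDC-style XML annotation parsing, contour rasterization, box extraction.

The reader consumes per-nodule annotations in the LIDC XML dialect: each
nodule carries 9 ordinal characteristic scores and one or more per-slice
``<roi>`` elements holding a z-position (mm) and an ``<edgeMap>`` contour of
(x, y) integer pixel coordinates.  Contour pixels follow the LIDC
convention of lying at the first pixel *outside* the nodule, so
rasterization fills the contour interior excluding the outline pixels
themselves.

Coordinate convention: 0-based voxel indices, (x, y) within an axial slice
(the first two axes of the (X, Y, Z) grid), z by slice position; contour
points are voxel centers.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from lxml import etree

from .data import BIOMARKER_NAMES, DEFAULT_BOX_SHAPE
from .exceptions import AnnotationParseError, ExtractionError, GeometryError

logger = logging.getLogger(__name__)

#: Mapping from record field names to LIDC XML characteristic tag names.
CHARACTERISTIC_TAGS = {
    "subtlety": "subtlety",
    "int_structure": "internalStructure",
    "calcification": "calcification",
    "sphericity": "sphericity",
    "margin": "margin",
    "lobulation": "lobulation",
    "spiculation": "spiculation",
    "texture": "texture",
    "malignancy": "malignancy",
}


@dataclass
class NoduleAnnotation:
    """One parsed nodule: contours per slice plus the 9 ordinal scores."""

    nodule_id: str
    #: list of (z_position_mm, [(x, y), ...]) contours
    contours: list[tuple[float, list[tuple[int, int]]]]
    characteristics: dict[str, int]

    def __post_init__(self) -> None:
        if len(self.contours) < 1:
            raise ValueError(f"nodule {self.nodule_id}: needs at least one contour")
        for z, pts in self.contours:
            if len(pts) < 3:
                raise ValueError(
                    f"nodule {self.nodule_id}: contour at z={z} has < 3 points"
                )


@dataclass
class GridGeometry:
    """Shape and physical geometry of the intensity grid contours map into."""

    shape: tuple[int, int, int]
    spacing_mm: tuple[float, float, float] = (1.0, 1.0, 1.0)
    origin_z_mm: float = 0.0

    def z_index(self, z_mm: float) -> int:
        """Nearest slice index for a z position, within half a slice spacing."""
        sz = self.spacing_mm[2]
        idx = int(round((z_mm - self.origin_z_mm) / sz))
        if not 0 <= idx < self.shape[2]:
            raise GeometryError(f"z position {z_mm} mm outside grid")
        if abs(z_mm - (self.origin_z_mm + idx * sz)) > sz / 2.0 + 1e-9:
            raise GeometryError(f"z position {z_mm} mm matches no slice")
        return idx


def parse_annotations(xml_source) -> list[NoduleAnnotation]:
    """Parse a LIDC-style XML file into :class:`NoduleAnnotation` objects.

    Nodules missing any of the 9 characteristics (the <3 mm convention) or
    having only degenerate contours are excluded with a logged warning.
    Malformed XML raises :class:`AnnotationParseError` with line context.
    """
    try:
        tree = etree.parse(xml_source)
    except etree.XMLSyntaxError as exc:
        raise AnnotationParseError(f"malformed annotation XML: {exc}") from exc
    root = tree.getroot()
    annotations = []
    for nod in root.iter("unblindedReadNodule"):
        nid_el = nod.find("noduleID")
        nid = nid_el.text if nid_el is not None else "<unnamed>"
        chars_el = nod.find("characteristics")
        characteristics = {}
        complete = chars_el is not None
        if complete:
            for name, tag in CHARACTERISTIC_TAGS.items():
                val_el = chars_el.find(tag)
                if val_el is None or val_el.text is None:
                    complete = False
                    break
                characteristics[name] = int(val_el.text)
        if not complete:
            logger.warning("nodule %s: incomplete characteristics, excluded", nid)
            continue
        contours = []
        for roi in nod.iter("roi"):
            z_el = roi.find("imageZposition")
            if z_el is None:
                raise AnnotationParseError(
                    f"nodule {nid}: roi missing imageZposition (line {roi.sourceline})"
                )
            pts = [
                (int(e.find("xCoord").text), int(e.find("yCoord").text))
                for e in roi.iter("edgeMap")
            ]
            if len(pts) < 3:
                logger.warning(
                    "nodule %s: degenerate contour (%d pts) at z=%s skipped",
                    nid, len(pts), z_el.text,
                )
                continue
            contours.append((float(z_el.text), pts))
        if not contours:
            logger.warning("nodule %s: no usable contours, excluded", nid)
            continue
        annotations.append(NoduleAnnotation(nid, contours, characteristics))
    return annotations


def polygon_interior(
    points: list[tuple[float, float]], shape: tuple[int, int]
) -> np.ndarray:
    """Even-odd interior of a closed polygon, sampled at integer pixel centers.

    Crossing-number test with a +x ray and the half-open edge rule in y,
    vectorized over the pixel grid.  Pixels lying exactly on the outline are
    not guaranteed a side here; callers exclude outline pixels explicitly.
    """
    pts = np.asarray(points, dtype=float)
    X, Y = np.meshgrid(np.arange(shape[0]), np.arange(shape[1]), indexing="ij")
    inside = np.zeros(shape, dtype=bool)
    nxt = np.roll(pts, -1, axis=0)
    for (x1, y1), (x2, y2) in zip(pts, nxt):
        if y1 == y2:
            continue  # horizontal edge: no +x-ray crossing under half-open rule
        crosses = (y1 <= Y) != (y2 <= Y)
        x_at = x1 + (Y - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (X < x_at)
    return inside


def rasterize_mask(annotation: NoduleAnnotation, geometry: GridGeometry) -> np.ndarray:
    """Rasterize per-slice contours into a 3-D boolean mask.

    Each contour interior is filled per slice (even-odd rule) with the
    outline pixels themselves EXCLUDED, matching the convention that the
    outline sits at the first pixel outside the nodule.  Slices are stacked
    by nearest z position.
    """
    mask = np.zeros(geometry.shape, dtype=bool)
    sx, sy = geometry.shape[0], geometry.shape[1]
    for z_mm, pts in annotation.contours:
        zi = geometry.z_index(z_mm)
        arr = np.asarray(pts)
        if (arr < 0).any() or (arr[:, 0] >= sx).any() or (arr[:, 1] >= sy).any():
            raise GeometryError(
                f"contour at z={z_mm} mm falls outside the {geometry.shape} grid"
            )
        interior = polygon_interior(pts, (sx, sy))
        interior[arr[:, 0], arr[:, 1]] = False  # outline pixels are outside
        if not interior.any():
            warnings.warn(
                f"contour at z={z_mm} mm has empty interior (degenerate polygon)",
                stacklevel=2,
            )
        mask[:, :, zi] |= interior
    return mask


def extract_box(
    intensity_grid: np.ndarray,
    annotation: NoduleAnnotation,
    box_shape: tuple[int, int, int] = DEFAULT_BOX_SHAPE,
    geometry: GridGeometry | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Cut a fixed-size box + mask centered at the nodule's mask centroid.

    The box is centered at the rounded centroid of the rasterized mask and
    zero-padded wherever it overruns the grid; the mask is cropped with the
    same window.
    """
    grid = np.asarray(intensity_grid)
    if geometry is None:
        geometry = GridGeometry(grid.shape)
    if grid.shape != tuple(geometry.shape):
        raise GeometryError(
            f"grid shape {grid.shape} != geometry shape {geometry.shape}"
        )
    if any(g < b for g, b in zip(grid.shape, box_shape)):
        raise GeometryError(f"grid {grid.shape} smaller than box {box_shape}")
    mask = rasterize_mask(annotation, geometry)
    if not mask.any():
        raise ExtractionError(f"nodule {annotation.nodule_id}: empty rasterized mask")
    centroid = np.array([c.mean() for c in np.nonzero(mask)])
    center = np.rint(centroid).astype(int)

    vol_box = np.zeros(box_shape, dtype=grid.dtype)
    mask_box = np.zeros(box_shape, dtype=bool)
    lo = center - np.array(box_shape) // 2
    hi = lo + np.array(box_shape)
    src_lo = np.maximum(lo, 0)
    src_hi = np.minimum(hi, grid.shape)
    dst_lo = src_lo - lo
    dst_hi = dst_lo + (src_hi - src_lo)
    src = tuple(slice(a, b) for a, b in zip(src_lo, src_hi))
    dst = tuple(slice(a, b) for a, b in zip(dst_lo, dst_hi))
    vol_box[dst] = grid[src]
    mask_box[dst] = mask[src]
    return vol_box, mask_box
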