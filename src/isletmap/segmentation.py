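"""Islet object construction from co-registered stain masks.

Islets are connected components of the union of six defining stains
(CHGA, ProINS, INS, GCG, SST, PPY), hole-filled, size-filtered at
1,000 µm², and removed when within 10 µm of the tissue border.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from shapely.geometry import Polygon
from skimage import measure

from .core import (
    DEFINING_6,
    MIN_ISLET_AREA_UM2,
    IsletObject,
    RegistrationError,
    StainMask,
    TissueSection,
    points_in_polygon,
)

# 8-connectivity: diagonally touching stained pixels belong to one region
_STRUCT8 = np.ones((3, 3), dtype=bool)


def polygonize_component(mask: np.ndarray, pixel_size_um: float) -> Polygon:
    """Trace the outer contour of a single connected component.

    Marching squares at the 0.5 level; vertices returned in physical µm
    with pixel centres at (index + 0.5) * pixel size.
    """
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        raise ValueError("no contour found in component mask")
    best = max(contours, key=len)
    # (row, col) index space -> (x, y) physical µm; subtract the pad offset
    xy = np.column_stack([best[:, 1] - 1 + 0.5, best[:, 0] - 1 + 0.5]) * pixel_size_um
    poly = Polygon(xy)
    if not poly.is_valid:
        poly = poly.buffer(0)
    return poly


def segment_stained_regions(
    mask: StainMask, min_region_area_um2: float = 50.0
) -> list[Polygon]:
    """Connected-component polygons with pixel area >= ``min_region_area_um2``.

    Mirrors the low-resolution threshold step that finds all stained
    regions of at least 50 µm² in a single channel.
    """
    if mask.pixel_size_um is None:
        raise ValueError("mask pixel size is required")
    labeled, n = ndimage.label(mask.data, structure=_STRUCT8)
    if n == 0:
        return []
    px_area = mask.pixel_area_um2
    counts = np.bincount(labeled.ravel())[1:]
    polys: list[Polygon] = []
    slices = ndimage.find_objects(labeled)
    for lab, (count, sl) in enumerate(zip(counts, slices), start=1):
        if count * px_area < min_region_area_um2:
            continue
        sub = labeled[sl] == lab
        poly = polygonize_component(sub, mask.pixel_size_um)
        # shift back to global coordinates
        dx = sl[1].start * mask.pixel_size_um
        dy = sl[0].start * mask.pixel_size_um
        poly = Polygon(np.asarray(poly.exterior.coords) + [dx, dy])
        polys.append(poly)
    return polys


def build_islets(
    channel_masks: dict[str, StainMask],
    tissue: TissueSection,
    min_islet_area_um2: float = MIN_ISLET_AREA_UM2,
    border_margin_um: float = 10.0,
) -> list[IsletObject]:
    """Merge the six defining channels into disjoint islet objects."""
    try:
        masks = [channel_masks[c] for c in DEFINING_6]
    except KeyError as exc:
        raise KeyError(f"missing defining channel {exc.args[0]!r}") from exc
    ref = masks[0]
    for m in masks[1:]:
        if not ref.same_grid(m):
            raise RegistrationError("stain masks are not on a common pixel grid")

    union = np.zeros(ref.data.shape, dtype=bool)
    for m in masks:
        union |= m.data
    union = ndimage.binary_fill_holes(union)

    labeled, n = ndimage.label(union, structure=_STRUCT8)
    islets: list[IsletObject] = []
    next_id = 0
    boundary = tissue.boundary.exterior
    slices = ndimage.find_objects(labeled)
    for lab in range(1, n + 1):
        sl = slices[lab - 1]
        sub = labeled[sl] == lab
        sub = ndimage.binary_fill_holes(sub)
        poly = polygonize_component(sub, ref.pixel_size_um)
        dx = sl[1].start * ref.pixel_size_um
        dy = sl[0].start * ref.pixel_size_um
        poly = Polygon(np.asarray(poly.exterior.coords) + [dx, dy])
        if poly.area < min_islet_area_um2:
            continue
        if poly.distance(boundary) < border_margin_um or not tissue.boundary.covers(poly):
            continue
        islets.append(IsletObject(id=next_id, polygon=poly))
        next_id += 1
    return islets


def shape_descriptors(polygon: Polygon) -> tuple[float, float, float, float, float]:
    """(area, perimeter, circularity, solidity, aspect_ratio) of a polygon.

    circularity = 4π·area / perimeter²; solidity = area / convex-hull area;
    aspect_ratio = short over long side of the minimum rotated bounding
    rectangle (a caliper-width ratio: 1 for squares and circles, 0.5 for a
    2:1 rectangle).  All three clamped to (0, 1].
    """
    if polygon.is_empty or polygon.area <= 0:
        raise ValueError("degenerate polygon: zero area")
    area = float(polygon.area)
    perim = float(polygon.length)
    circ = min(1.0, 4.0 * np.pi * area / perim**2)
    sol = min(1.0, area / polygon.convex_hull.area)
    rect = polygon.minimum_rotated_rectangle
    coords = np.asarray(rect.exterior.coords)
    if len(coords) < 4:  # degenerate rectangle (collinear points)
        ar = 1.0
    else:
        e1 = float(np.hypot(*(coords[1] - coords[0])))
        e2 = float(np.hypot(*(coords[2] - coords[1])))
        long, short = max(e1, e2), min(e1, e2)
        ar = min(1.0, short / long) if long > 0 else 1.0
    return area, perim, circ, sol, ar


def equivalent_diameter_volume(area_um2: float) -> tuple[float, float]:
    """Circle-equivalent diameter and sphere-equivalent volume of an islet.

    diameter = 2·sqrt(area/π); volume = (π/6)·diameter³.  The 1,000 µm²
    minimum islet area maps to a ~36 µm diameter (~10 cells).
    """
    if area_um2 < 0:
        raise ValueError("area must be non-negative")
    diameter = 2.0 * float(np.sqrt(area_um2 / np.pi))
    volume = (np.pi / 6.0) * diameter**3
    return diameter, float(volume)


def islet_cell_density(islet: IsletObject, nuclei_xy: np.ndarray) -> float:
    """Nuclei inside the islet polygon per mm² of islet area.

    Boundary-point containment is closed: a nucleus exactly on the islet
    outline is counted as inside.
    """
    nuclei_xy = np.asarray(nuclei_xy, float).reshape(-1, 2)
    count = int(points_in_polygon(nuclei_xy, islet.polygon).sum())
    return count / (islet.area_um2 / 1e6)
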