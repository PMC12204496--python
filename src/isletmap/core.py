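"""Core domain types shared across the pipeline.

All coordinates are physical micrometres (µm), origin at the tissue
bounding-box corner, y-axis pointing down (raster convention).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
from shapely.geometry import Polygon

#: The nine quantified stain channels (proinsulin is captured twice:
#: total staining plus a nested high-intensity mask).
CHANNELS_9 = (
    "CHGA",
    "ProINS_total",
    "ProINS_hi",
    "INS",
    "IAPP",
    "ProGCG",
    "GCG",
    "SST",
    "PPY",
)

#: The eight hormone stains whose union defines the endocrine area and
#: over which pairwise overlap statistics are computed.
HORMONES_8 = (
    "CHGA",
    "ProINS_total",
    "INS",
    "IAPP",
    "ProGCG",
    "GCG",
    "SST",
    "PPY",
)

#: The six stains merged to delineate islet objects.
DEFINING_6 = ("CHGA", "ProINS_total", "INS", "GCG", "SST", "PPY")

#: Major cluster vocabulary; "null" marks unclustered islets.
MAJOR_CLUSTERS = ("I", "II", "III", "IV", "V-A", "V-BC")

STAGES = ("Ctrl", "AAb", "T1DS", "T1DL")
REGIONS = ("PT", "PH")

#: Minimum islet area in µm² (~10 cells, ~36 µm equivalent diameter).
MIN_ISLET_AREA_UM2 = 1000.0


class MissingChannelError(KeyError):
    """A required stain channel is absent from the input set."""


class RegistrationError(ValueError):
    """Stain masks do not share a common pixel grid."""


@dataclass
class TissueSection:
    """Polygonal tissue/parenchyma boundary plus section metadata."""

    boundary: Polygon
    region: str = "PT"
    donor_id: str = ""
    stage: str = "Ctrl"
    pancreas_region_weight_g: float | None = None

    def __post_init__(self) -> None:
        if not self.boundary.is_valid or self.boundary.area <= 0:
            raise ValueError("tissue boundary must be a simple polygon with area > 0")
        if self.region not in REGIONS:
            raise ValueError(f"region must be one of {REGIONS}, got {self.region!r}")
        if self.stage not in STAGES:
            raise ValueError(f"stage must be one of {STAGES}, got {self.stage!r}")

    @property
    def parenchymal_area_um2(self) -> float:
        return float(self.boundary.area)

    @property
    def parenchymal_area_mm2(self) -> float:
        return float(self.boundary.area) / 1e6


@dataclass
class StainMask:
    """Binary raster for one stain channel, co-registered to the section.

    Pixel (row, col) covers the physical square
    [col*px, (col+1)*px) x [row*px, (row+1)*px) with px = ``pixel_size_um``.
    """

    data: np.ndarray
    pixel_size_um: float
    channel: str = ""

    def __post_init__(self) -> None:
        if self.pixel_size_um is None or not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be a positive real")
        self.data = np.asarray(self.data, dtype=bool)
        if self.data.ndim != 2:
            raise ValueError("mask must be a 2-D array")

    @property
    def pixel_area_um2(self) -> float:
        return self.pixel_size_um**2

    def same_grid(self, other: "StainMask") -> bool:
        return (
            self.data.shape == other.data.shape
            and np.isclose(self.pixel_size_um, other.pixel_size_um)
        )


@dataclass
class IsletObject:
    """One segmented islet with geometry and shape descriptors."""

    id: int
    polygon: Polygon
    area_um2: float = field(init=False)
    perimeter_um: float = field(init=False)
    centroid: tuple[float, float] = field(init=False)
    circularity: float = field(init=False)
    solidity: float = field(init=False)
    aspect_ratio: float = field(init=False)
    equivalent_diameter_um: float = field(init=False)
    nuclei_count: int = 0
    cell_density_per_mm2: float = 0.0

    def __post_init__(self) -> None:
        from .segmentation import shape_descriptors  # local: avoid cycle

        poly = self.polygon
        if poly.interiors:
            poly = Polygon(poly.exterior)
            self.polygon = poly
        area, perim, circ, sol, ar = shape_descriptors(poly)
        if area < MIN_ISLET_AREA_UM2:
            raise ValueError(
                f"islet area {area:.1f} µm² below the {MIN_ISLET_AREA_UM2:.0f} µm² minimum"
            )
        self.area_um2 = area
        self.perimeter_um = perim
        self.circularity = circ
        self.solidity = sol
        self.aspect_ratio = ar
        c = poly.centroid
        self.centroid = (float(c.x), float(c.y))
        self.equivalent_diameter_um = 2.0 * float(np.sqrt(area / np.pi))


def as_point_array(x_um, y_um) -> np.ndarray:
    """Stack coordinate columns into an (n, 2) float array."""
    return np.column_stack([np.asarray(x_um, float), np.asarray(y_um, float)])


def points_in_polygon(points: np.ndarray, polygon: Polygon) -> np.ndarray:
    """Closed point-in-polygon test (points on the boundary count as inside)."""
    if len(points) == 0:
        return np.zeros(0, dtype=bool)
    geoms = shapely.points(points)
    return shapely.covers(polygon, geoms)
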