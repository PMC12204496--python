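"""File formats: islet tables (CSV with WKT polygons), tissue GeoJSON,
stain-mask rasters with JSON sidecars, and cell CSVs.

CSV dialect is UTF-8, comma-separated, "." decimal, mandatory header.
All coordinates are physical µm (y-axis down, raster convention).
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import Polygon, mapping, shape

from .core import StainMask, TissueSection


class TableError(ValueError):
    """A tabular input failed validation; the message names file/column/row."""


def write_islet_table(islets: pd.DataFrame, path) -> None:
    islets.to_csv(path, index=False)


def read_islet_table(path, require_polygons: bool = False) -> pd.DataFrame:
    """Read an islet CSV; unknown columns are preserved.

    Polygon WKT strings are validated row by row; malformed entries are
    reported with their row numbers.
    """
    df = pd.read_csv(path)
    if "islet_id" not in df.columns:
        raise TableError(f"{path}: missing required column 'islet_id'")
    if "polygon_wkt" in df.columns:
        bad = []
        for i, w in enumerate(df["polygon_wkt"]):
            if not isinstance(w, str):
                if require_polygons:
                    bad.append(i)
                continue
            try:
                shapely.from_wkt(w)
            except shapely.errors.GEOSException:
                bad.append(i)
        if bad:
            raise TableError(
                f"{path}: malformed WKT in column 'polygon_wkt' at row(s) {bad[:20]}"
            )
    elif require_polygons:
        raise TableError(f"{path}: missing required column 'polygon_wkt'")
    return df


def read_cells(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("x_um", "y_um", "class"):
        if col not in df.columns:
            raise TableError(f"{path}: missing required column {col!r}")
    return df


def write_tissue_geojson(tissue: TissueSection, path) -> None:
    doc = {
        "type": "Feature",
        "geometry": mapping(tissue.boundary),
        "properties": {
            "coordinate_unit": "um",
            "region": tissue.region,
            "donor_id": tissue.donor_id,
            "stage": tissue.stage,
            "pancreas_region_weight_g": tissue.pancreas_region_weight_g,
        },
    }
    Path(path).write_text(json.dumps(doc))


def read_tissue_geojson(path) -> TissueSection:
    doc = json.loads(Path(path).read_text())
    if doc.get("type") == "FeatureCollection":
        doc = doc["features"][0]
    props = doc.get("properties") or {}
    geom = shape(doc["geometry"])
    if not isinstance(geom, Polygon):
        raise TableError(f"{path}: tissue geometry must be a Polygon")
    return TissueSection(
        boundary=geom,
        region=props.get("region", "PT"),
        donor_id=props.get("donor_id", ""),
        stage=props.get("stage", "Ctrl"),
        pancreas_region_weight_g=props.get("pancreas_region_weight_g"),
    )


def write_masks(masks: dict[str, StainMask], out_dir) -> None:
    """One PNG per channel plus a JSON sidecar carrying the pixel size."""
    import imageio.v3 as iio

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    for ch, m in masks.items():
        iio.imwrite(out_dir / f"{ch}.png", (m.data.astype(np.uint8) * 255))
        (out_dir / f"{ch}.json").write_text(
            json.dumps({"pixel_size_um": m.pixel_size_um, "channel": ch})
        )


def read_masks(mask_dir) -> dict[str, StainMask]:
    import imageio.v3 as iio

    mask_dir = Path(mask_dir)
    masks = {}
    for png in sorted(mask_dir.glob("*.png")):
        sidecar = png.with_suffix(".json")
        if not sidecar.exists():
            raise TableError(f"{png}: missing JSON sidecar with pixel size")
        meta = json.loads(sidecar.read_text())
        data = iio.imread(png) > 0
        masks[meta.get("channel", png.stem)] = StainMask(
            data=data, pixel_size_um=meta["pixel_size_um"], channel=meta.get("channel", png.stem)
        )
    return masks
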