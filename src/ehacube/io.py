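"""Raster and vector I/O.

Rasters are single-band GeoTIFFs written through :mod:`tifffile` with the
standard GeoTIFF georeferencing tags (ModelPixelScale, ModelTiepoint) plus
the GDAL nodata convention; the CRS is carried as a free-text tag because
the package works on local metric grids and performs no geodesy. Vector
layers (protected areas, plantation features, roads) are GeoJSON handled
with :mod:`shapely` geometries.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import tifffile
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113

#: CRS tag used by the synthetic generator: a local metric (x east, y north)
#: grid with no geodetic datum.
LOCAL_METRIC_CRS = "LOCAL_METRIC"


@dataclass(frozen=True)
class GridTransform:
    """Affine georeferencing of a north-up, square-pixel grid.

    ``origin_x, origin_y`` locate the *outer corner* of pixel (0, 0); rows
    increase southward (y decreases), columns increase eastward.
    """

    origin_x: float
    origin_y: float
    cell_size: float  # metres per pixel, > 0

    def __post_init__(self) -> None:
        if self.cell_size <= 0:
            raise ValueError(f"cell_size must be > 0, got {self.cell_size}")

    def centroid(self, row, col):
        """Map (row, col) pixel indices to centroid (x, y) coordinates."""
        row = np.asarray(row, dtype=float)
        col = np.asarray(col, dtype=float)
        x = self.origin_x + (col + 0.5) * self.cell_size
        y = self.origin_y - (row + 0.5) * self.cell_size
        return x, y

    def coarsen(self, factor: int) -> "GridTransform":
        """Transform of the grid aggregated by an integer block factor."""
        return GridTransform(self.origin_x, self.origin_y,
                             self.cell_size * factor)


def write_geotiff(path, values: np.ndarray, transform: GridTransform,
                  crs_tag: str = LOCAL_METRIC_CRS, nodata=None) -> None:
    """Write a single-band georeferenced TIFF.

    Multi-band (T-band) arrays of shape (bands, rows, cols) are accepted for
    per-time-step layers such as Gi* z-scores.
    """
    values = np.asarray(values)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3,
         (transform.cell_size, transform.cell_size, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6,
         (0.0, 0.0, 0.0, transform.origin_x, transform.origin_y, 0.0)),
    ]
    if nodata is not None:
        nd = str(int(nodata)) if np.issubdtype(values.dtype, np.integer) \
            else repr(float(nodata))
        extratags.append((_TAG_GDAL_NODATA, "s", len(nd) + 1, nd))
    meta = {"crs_tag": crs_tag}
    tifffile.imwrite(path, values, description=json.dumps(meta),
                     extratags=extratags)


def read_geotiff(path):
    """Read a TIFF written by :func:`write_geotiff`.

    Returns ``(values, transform, crs_tag, nodata)``. Files without the
    georeferencing tags are rejected: every raster in this pipeline is
    spatial and distances are meaningless without a cell size.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        tags = page.tags
        if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
            raise ValueError(
                f"{path}: missing GeoTIFF georeferencing tags "
                "(ModelPixelScale/ModelTiepoint)")
        scale = tags[_TAG_MODEL_PIXEL_SCALE].value
        tiepoint = tags[_TAG_MODEL_TIEPOINT].value
        transform = GridTransform(origin_x=float(tiepoint[3]),
                                  origin_y=float(tiepoint[4]),
                                  cell_size=float(scale[0]))
        nodata = None
        if _TAG_GDAL_NODATA in tags:
            raw = tags[_TAG_GDAL_NODATA].value
            nodata = float(raw) if ("." in raw or "e" in raw) else int(raw)
        crs_tag = LOCAL_METRIC_CRS
        desc = tags.get("ImageDescription")
        if desc is not None:
            try:
                crs_tag = json.loads(desc.value).get("crs_tag", crs_tag)
            except (json.JSONDecodeError, AttributeError):
                pass
        values = tif.asarray()
    return values, transform, crs_tag, nodata


def write_geojson(path, features: Iterable[dict]) -> None:
    """Write a GeoJSON FeatureCollection.

    Each feature dict carries a shapely ``geometry`` plus arbitrary
    JSON-serialisable properties under any other keys.
    """
    out = []
    for feat in features:
        props = {k: v for k, v in feat.items() if k != "geometry"}
        out.append({"type": "Feature",
                    "geometry": mapping(feat["geometry"]),
                    "properties": props})
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": out}, fh)


def read_geojson(path) -> list[dict]:
    """Read a GeoJSON FeatureCollection into feature dicts with shapely
    geometries (inverse of :func:`write_geojson`)."""
    with open(path) as fh:
        data = json.load(fh)
    feats = []
    for f in data.get("features", []):
        d = dict(f.get("properties") or {})
        d["geometry"] = shape(f["geometry"])
        feats.append(d)
    return feats


def geometry_list(features: Sequence[dict] | Sequence[BaseGeometry]):
    """Extract bare geometries from feature dicts or pass geometries through."""
    geoms = []
    for f in features:
        geoms.append(f["geometry"] if isinstance(f, dict) else f)
    return geoms
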