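"""Protected-area overlay of the category map.

Locations are assigned to a protected area when their bin centroid falls
inside the polygon (no fractional-area weighting: categories live on the
cube's location grid, and splitting bins would invent sub-bin
information). Overlapping PAs resolve to the first-listed polygon.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union

from ehacube.classify import CATEGORIES, CATEGORY_CODES, CategoryMap, NONE_CATEGORY
from ehacube.simulate import IUCN_CATEGORIES

_SHARE_CATEGORIES = list(CATEGORIES) + [NONE_CATEGORY]


@dataclass
class ProtectedArea:
    """A named protected-area polygon with its IUCN management category."""

    geometry: BaseGeometry
    name: str
    iucn_category: str = "Not reported"

    def __post_init__(self) -> None:
        if not self.geometry.is_valid:
            self.geometry = self.geometry.buffer(0)  # standard repair
        if self.geometry.area <= 0:
            raise ValueError(f"protected area {self.name!r} has zero area")
        if self.iucn_category not in IUCN_CATEGORIES:
            raise ValueError(
                f"unknown IUCN category {self.iucn_category!r}; "
                f"valid: {', '.join(IUCN_CATEGORIES)}")


def as_protected_areas(features) -> list[ProtectedArea]:
    """Coerce GeoJSON-style feature dicts (or ProtectedArea instances) to
    ProtectedArea objects."""
    out = []
    for i, f in enumerate(features):
        if isinstance(f, ProtectedArea):
            out.append(f)
        else:
            out.append(ProtectedArea(
                geometry=f["geometry"], name=f.get("name", f"PA-{i + 1}"),
                iucn_category=f.get("iucn_category", "Not reported")))
    return out


def rasterize_pa(pa_collection, category_map: CategoryMap,
                 pa_crs_tag: str | None = None,
                 map_crs_tag: str | None = None) -> np.ndarray:
    """Per-location PA index grid: 0 = no PA, i+1 = i-th protected area.

    Membership is a point-in-polygon test of the bin centroid; overlaps
    resolve to the first-listed PA. If both CRS tags are supplied they
    must match — the overlay is meaningless across reference systems.
    """
    if (pa_crs_tag is not None and map_crs_tag is not None
            and pa_crs_tag != map_crs_tag):
        raise ValueError(f"CRS mismatch: protected areas {pa_crs_tag!r} vs "
                         f"category map {map_crs_tag!r}")
    pas = as_protected_areas(pa_collection)
    rows, cols = category_map.category.shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    x, y = category_map.transform.centroid(rr, cc)
    pa_grid = np.zeros((rows, cols), dtype=np.int32)
    for i, pa in enumerate(pas):
        inside = shapely.contains_xy(pa.geometry, x, y)
        pa_grid[(pa_grid == 0) & inside] = i + 1
    return pa_grid


def pa_category_shares(category_map: CategoryMap, pa_raster: np.ndarray,
                       pa_collection) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Category composition per PA and the island-level inside/outside split.

    Returns ``(shares, island)``:

    - ``shares``: one row per PA x category with the percentage of the
      PA's masked locations in that category (none included; per-PA shares
      sum to 100). A PA covering no masked locations reports NaN shares —
      undefined, not zero.
    - ``island``: per category, counts of masked locations inside any PA
      and outside all PAs.
    """
    pas = as_protected_areas(pa_collection)
    mask = category_map.mask
    cat = category_map.category
    rows = []
    for i, pa in enumerate(pas):
        member = mask & (pa_raster == i + 1)
        total = int(member.sum())
        for name in _SHARE_CATEGORIES:
            count = int((cat[member] == CATEGORY_CODES[name]).sum())
            share = 100.0 * count / total if total > 0 else np.nan
            rows.append({"pa_name": pa.name,
                         "iucn_category": pa.iucn_category,
                         "category": name, "n_locations": count,
                         "share_pct": share})
    shares = pd.DataFrame(rows)

    inside = mask & (pa_raster > 0)
    outside = mask & (pa_raster == 0)
    island_rows = []
    for name in _SHARE_CATEGORIES:
        code = CATEGORY_CODES[name]
        island_rows.append({"category": name,
                            "inside_pa": int((cat[inside] == code).sum()),
                            "outside_pa": int((cat[outside] == code).sum())})
    island = pd.DataFrame(island_rows)
    return shares, island


def boundary_distance_profile(category_map: CategoryMap, pa_collection,
                              ring_width: float,
                              max_distance: float | None = None) -> pd.DataFrame:
    """Category counts by signed distance to the nearest PA boundary.

    Distances are negative inside a PA, positive outside; locations are
    binned into rings of ``ring_width`` metres. Useful for the
    neighborhood-leakage question: are within-PA hotspots concentrated
    near the boundary?
    """
    if ring_width <= 0:
        raise ValueError("ring_width must be > 0")
    pas = as_protected_areas(pa_collection)
    union = unary_union([p.geometry for p in pas])
    boundary = union.boundary
    mask = category_map.mask
    cat = category_map.category
    rr, cc = np.nonzero(mask)
    x, y = category_map.transform.centroid(rr, cc)
    pts = shapely.points(np.column_stack([x, y]))
    d = shapely.distance(pts, boundary)
    inside = shapely.contains_xy(union, x, y)
    signed = np.where(inside, -d, d)
    if max_distance is not None:
        signed = np.clip(signed, -max_distance, max_distance - 1e-9)
    ring = np.floor(signed / ring_width).astype(int)
    frame = pd.DataFrame({"ring": ring,
                          "category": [next(k for k, v in CATEGORY_CODES.items()
                                            if v == c)
                                       for c in cat[rr, cc]]})
    out = (frame.groupby(["ring", "category"]).size()
           .unstack(fill_value=0).reset_index())
    out["ring_lo_m"] = out["ring"] * ring_width
    out["ring_hi_m"] = (out["ring"] + 1) * ring_width
    return out
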