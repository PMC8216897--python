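"""Loss-year rasters and the space-time cube.

The raw input is a first-loss-year raster in the Global Forest Change
convention: 0 means the pixel was never lost, ``v`` in ``1..T`` means the
pixel was first lost in year ``2000 + v``. The cube aggregates pixels into
square analysis bins and holds, per bin and per year, the count of newly
lost pixels — the ``x_j`` on which the Gi* statistic operates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import json
import numpy as np
import pandas as pd

from ehacube.io import GridTransform, LOCAL_METRIC_CRS, read_geotiff, write_geotiff


@dataclass
class LossYearRaster:
    """Georeferenced integer grid of first-loss year codes."""

    values: np.ndarray  # 2-D int, 0 = no loss, 1..n_years = first-loss year
    transform: GridTransform
    n_years: int
    crs_tag: str = LOCAL_METRIC_CRS
    nodata: int | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        if self.values.ndim != 2:
            raise ValueError("loss raster must be a single 2-D band")
        if not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError("loss raster must be integer-coded")
        self._validate_codes()

    def _validate_codes(self) -> None:
        vals = self.values
        valid = (vals >= 0) & (vals <= self.n_years)
        if self.nodata is not None:
            valid |= vals == self.nodata
        if not valid.all():
            r, c = np.argwhere(~valid)[0]
            raise ValueError(
                f"loss code {vals[r, c]} at pixel ({r}, {c}) outside "
                f"[0, {self.n_years}]"
                + (f" ∪ {{{self.nodata}}}" if self.nodata is not None else ""))

    @property
    def data_mask(self) -> np.ndarray:
        """Boolean grid of valid-data pixels (nodata excluded)."""
        if self.nodata is None:
            return np.ones(self.values.shape, dtype=bool)
        return self.values != self.nodata

    @property
    def pixel_area_m2(self) -> float:
        return self.transform.cell_size ** 2

    def write(self, path) -> None:
        write_geotiff(path, self.values, self.transform,
                      crs_tag=self.crs_tag, nodata=self.nodata)


def read_loss_raster(path, n_years: int = 18) -> LossYearRaster:
    """Read and validate a loss-year GeoTIFF.

    Rejects rasters with codes outside ``[0, n_years]`` (plus the declared
    nodata value) or without georeferencing.
    """
    values, transform, crs_tag, nodata = read_geotiff(path)
    nd = int(nodata) if nodata is not None else None
    return LossYearRaster(values=values.astype(np.int64), transform=transform,
                          n_years=n_years, crs_tag=crs_tag, nodata=nd)


@dataclass
class SpaceTimeCube:
    """Per-bin annual counts of newly lost pixels.

    ``counts[r, c, t-1]`` is the number of pixels in spatial bin (r, c)
    first lost in year index ``t`` (1-based, year 2000+t). ``analysis_mask``
    marks the locations that enter the statistics; ``n`` is the total number
    of masked space-time bins.
    """

    counts: np.ndarray           # (rows, cols, T) int
    bin_size: float              # metres per bin edge
    T: int
    transform: GridTransform     # of the *bin* grid
    analysis_mask: np.ndarray = field(default=None)  # (rows, cols) bool
    pixel_area: float = 0.0      # m² per source pixel
    pixels_per_bin: np.ndarray = field(default=None)  # valid pixels per bin
    crs_tag: str = LOCAL_METRIC_CRS

    def __post_init__(self) -> None:
        if self.counts.ndim != 3 or self.counts.shape[2] != self.T:
            raise ValueError("counts must have shape (rows, cols, T)")
        if (self.counts < 0).any():
            raise ValueError("cube counts must be non-negative")
        if self.analysis_mask is None:
            self.analysis_mask = self.counts.sum(axis=2) > 0

    @property
    def n(self) -> int:
        """Number of space-time bins over masked locations."""
        return int(self.analysis_mask.sum()) * self.T

    @property
    def shape(self):
        return self.counts.shape

    def centroid(self, row, col):
        return self.transform.centroid(row, col)

    def write(self, path) -> None:
        """Write counts as a compressed array container + JSON sidecar."""
        path = Path(path)
        np.savez_compressed(path.with_suffix(".npz"), counts=self.counts,
                            analysis_mask=self.analysis_mask,
                            pixels_per_bin=self.pixels_per_bin)
        sidecar = {"bin_size": self.bin_size, "T": self.T,
                   "origin_x": self.transform.origin_x,
                   "origin_y": self.transform.origin_y,
                   "cell_size": self.transform.cell_size,
                   "pixel_area": self.pixel_area, "crs_tag": self.crs_tag}
        path.with_suffix(".json").write_text(json.dumps(sidecar))

    @classmethod
    def read(cls, path) -> "SpaceTimeCube":
        path = Path(path)
        arrays = np.load(path.with_suffix(".npz"))
        meta = json.loads(path.with_suffix(".json").read_text())
        transform = GridTransform(meta["origin_x"], meta["origin_y"],
                                  meta["cell_size"])
        return cls(counts=arrays["counts"], bin_size=meta["bin_size"],
                   T=meta["T"], transform=transform,
                   analysis_mask=arrays["analysis_mask"],
                   pixel_area=meta["pixel_area"],
                   pixels_per_bin=arrays["pixels_per_bin"],
                   crs_tag=meta["crs_tag"])


def build_cube(raster: LossYearRaster, bin_size: float,
               T: int | None = None, mask_mode: str = "any-loss") -> SpaceTimeCube:
    """Aggregate a loss-year raster into a space-time cube.

    ``bin_size`` must be a positive integer multiple of the pixel size.
    Partial bins at the right/bottom edges are retained with their true
    pixel counts. ``mask_mode`` controls which locations enter the
    statistics: ``"any-loss"`` (default) keeps locations with at least one
    loss event across all years; ``"all"`` keeps every location with valid
    pixels.
    """
    cell = raster.transform.cell_size
    if bin_size < cell:
        raise ValueError(f"bin_size {bin_size} smaller than cell size {cell}")
    factor = bin_size / cell
    if abs(factor - round(factor)) > 1e-9:
        raise ValueError(
            f"bin_size {bin_size} is not an integer multiple of cell size {cell}")
    factor = int(round(factor))
    if mask_mode not in ("any-loss", "all"):
        raise ValueError(f"unknown mask_mode {mask_mode!r}")
    T = T if T is not None else raster.n_years

    vals = raster.values
    data = raster.data_mask
    rows, cols = vals.shape
    brows = -(-rows // factor)
    bcols = -(-cols // factor)

    # one-hot per year then block-sum; loop over T keeps memory flat
    counts = np.zeros((brows, bcols, T), dtype=np.int64)
    for t in range(1, T + 1):
        hits = ((vals == t) & data).astype(np.int64)
        counts[:, :, t - 1] = _block_sum(hits, factor, brows, bcols)
    pixels_per_bin = _block_sum(data.astype(np.int64), factor, brows, bcols)

    mask = counts.sum(axis=2) > 0 if mask_mode == "any-loss" \
        else pixels_per_bin > 0
    return SpaceTimeCube(counts=counts, bin_size=float(bin_size), T=T,
                         transform=raster.transform.coarsen(factor),
                         analysis_mask=mask, pixel_area=raster.pixel_area_m2,
                         pixels_per_bin=pixels_per_bin,
                         crs_tag=raster.crs_tag)


def _block_sum(grid: np.ndarray, factor: int, brows: int, bcols: int) -> np.ndarray:
    """Sum a 2-D grid over factor×factor blocks, padding partial edges with 0."""
    rows, cols = grid.shape
    padded = np.zeros((brows * factor, bcols * factor), dtype=grid.dtype)
    padded[:rows, :cols] = grid
    return padded.reshape(brows, factor, bcols, factor).sum(axis=(1, 3))


def annual_loss_series(source: "LossYearRaster | SpaceTimeCube") -> pd.DataFrame:
    """Per-year loss area in km².

    Accepts the raster or any cube built from it (the totals are identical
    by conservation of counts). Returns a DataFrame with columns
    ``year_index`` (1..T), ``year`` (2000 + index) and ``area_km2``.
    """
    if isinstance(source, SpaceTimeCube):
        per_year = source.counts.sum(axis=(0, 1)).astype(float)
        pixel_area, T = source.pixel_area, source.T
    else:
        T = source.n_years
        vals = source.values[source.data_mask]
        per_year = np.bincount(vals[vals > 0], minlength=T + 1)[1:T + 1].astype(float)
        pixel_area = source.pixel_area_m2
    area_km2 = per_year * pixel_area / 1e6
    idx = np.arange(1, T + 1)
    return pd.DataFrame({"year_index": idx, "year": 2000 + idx,
                         "area_km2": area_km2})


def mean_annual_loss(total_km2: float, T: int, truncate: bool = True) -> float:
    """Mean annual loss in km²/yr from a study-period total.

    With ``truncate`` the mean is truncated toward zero to whole km²,
    the rounding used for headline island-scale rates (67,104/18 = 3,728
    exactly; 88,504/18 = 4,916.9 → 4,916).
    """
    mean = total_km2 / T
    return float(np.trunc(mean)) if truncate else float(mean)
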