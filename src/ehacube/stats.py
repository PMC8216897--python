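"""Getis-Ord Gi* on the space-time cube and Mann-Kendall trend tests.

Gi* compares the sum of loss counts in a bin-plus-neighborhood against the
expectation under the cube-wide mean, standardised to a z-score; bins with
z above the two-sided critical value (1.96 at alpha = 0.05) are hot spots,
below the negative critical value cold spots. Neighborhoods are binary:
all masked bins whose centroid lies within ``neighborhood_distance`` and
whose time step is within the temporal window (the focal bin included).

The Mann-Kendall test then scores each location's time series of Gi*
z-scores (the intensity of clustering) for a monotone trend; the pair of
hot/cold label sequence and trend direction drives the eight-category
classification in :mod:`ehacube.classify`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage
from scipy.stats import norm

from ehacube.cube import SpaceTimeCube
from ehacube.io import GridTransform, write_geotiff

LABEL_HOT, LABEL_NEITHER, LABEL_COLD = 1, 0, -1


@dataclass(frozen=True)
class EhaParams:
    """Parameters of the emerging hotspot analysis.

    neighborhood_distance : float
        Spatial neighborhood radius in metres between bin centroids
        (default 10 km).
    neighborhood_time_steps : int
        Temporal window half-width tau in time steps (default 1 year).
    alpha : float
        Two-sided significance level for both Gi* labels and the trend
        test (default 0.05, critical z = 1.96).
    hot_fraction : float
        Persistence threshold: fraction of the T steps a location must be
        hot to count as a long-run hotspot (default 0.90; 16 of 18 years).
    time_window : str
        ``"backward"`` includes the tau previous steps (the convention of
        emerging hotspot tooling — an analysis at step t never sees the
        future); ``"symmetric"`` includes tau steps on both sides.
    trend_on : str
        ``"zscores"`` runs Mann-Kendall on each location's Gi* z series
        (clustering intensity); ``"counts"`` on the raw bin counts.
    """

    neighborhood_distance: float = 10_000.0
    neighborhood_time_steps: int = 1
    alpha: float = 0.05
    hot_fraction: float = 0.90
    time_window: str = "backward"
    trend_on: str = "zscores"

    def __post_init__(self) -> None:
        if self.neighborhood_distance <= 0:
            raise ValueError("neighborhood_distance must be > 0")
        if self.neighborhood_time_steps < 0:
            raise ValueError("neighborhood_time_steps must be >= 0")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if not 0 < self.hot_fraction <= 1:
            raise ValueError("hot_fraction must be in (0, 1]")
        if self.time_window not in ("backward", "symmetric"):
            raise ValueError("time_window must be 'backward' or 'symmetric'")
        if self.trend_on not in ("zscores", "counts"):
            raise ValueError("trend_on must be 'zscores' or 'counts'")

    @property
    def z_crit(self) -> float:
        """Two-sided critical z at this alpha (1.959964 at 0.05)."""
        return float(norm.ppf(1 - self.alpha / 2))


@dataclass
class GiStarField:
    """Per-bin Gi* z-scores, p-values and hot/cold/neither labels.

    ``z`` and ``p`` are NaN and ``label`` 0 outside the analysis mask.
    """

    z: np.ndarray        # (rows, cols, T) float
    p: np.ndarray        # (rows, cols, T) float
    label: np.ndarray    # (rows, cols, T) int8: 1 hot, -1 cold, 0 neither
    params: EhaParams
    mask: np.ndarray     # (rows, cols) bool
    transform: GridTransform = None

    def write_z(self, path, crs_tag: str = "LOCAL_METRIC") -> None:
        """Write z-scores as a T-band GeoTIFF (band t = time step t)."""
        bands = np.moveaxis(self.z, 2, 0).astype(np.float32)
        write_geotiff(path, bands, self.transform, crs_tag=crs_tag)


@dataclass(frozen=True)
class MKResult:
    """Mann-Kendall trend test result."""

    S: int
    varS: float
    z: float
    p: float
    direction: str  # increasing | decreasing | none


def _time_window(t: int, T: int, params: EhaParams) -> range:
    tau = params.neighborhood_time_steps
    lo = max(1, t - tau)
    hi = t if params.time_window == "backward" else min(T, t + tau)
    return range(lo, hi + 1)


def _spatial_offsets(bin_size: float, distance: float) -> np.ndarray:
    r = int(np.floor(distance / bin_size + 1e-9))
    dr, dc = np.mgrid[-r:r + 1, -r:r + 1]
    keep = np.hypot(dr, dc) * bin_size <= distance + 1e-9
    return np.stack([dr[keep], dc[keep]], axis=1)


def spacetime_neighbors(cube: SpaceTimeCube, loc: tuple[int, int], t: int,
                        params: EhaParams) -> set[tuple[int, int, int]]:
    """Neighbor bins of (loc, t): masked bins within the spatial radius and
    the temporal window, the focal bin included (binary weight 1).

    ``t`` is the 1-based time step. Rejects locations outside the analysis
    mask — unmasked locations carry no statistics.
    """
    r0, c0 = loc
    if not cube.analysis_mask[r0, c0]:
        raise ValueError(f"location {loc} is outside the analysis mask")
    rows, cols, T = cube.shape
    if not 1 <= t <= T:
        raise ValueError(f"time step {t} outside 1..{T}")
    out = set()
    for dr, dc in _spatial_offsets(cube.bin_size, params.neighborhood_distance):
        r, c = r0 + int(dr), c0 + int(dc)
        if 0 <= r < rows and 0 <= c < cols and cube.analysis_mask[r, c]:
            for tt in _time_window(t, T, params):
                out.add((r, c, tt))
    return out


def gi_star(cube: SpaceTimeCube, params: EhaParams | None = None) -> GiStarField:
    """Getis-Ord Gi* z-score for every masked space-time bin.

    For bin i with binary neighbor weights w_ij over the space-time
    neighborhood::

        z_i = (sum_j w_ij x_j - xbar W_i)
              / (S * sqrt((n W_i - W_i^2) / (n - 1)))

    where W_i = sum_j w_ij, and xbar and S are the mean and (population)
    standard deviation of the counts over all n masked space-time bins of
    the cube (global standardisation). A constant cube (S = 0) yields
    z = 0 everywhere, labelled neither.
    """
    params = params or EhaParams()
    mask = cube.analysis_mask
    n_loc = int(mask.sum())
    if n_loc < 2:
        raise ValueError(f"Gi* requires >= 2 masked locations, got {n_loc}")
    rows, cols, T = cube.shape
    x = cube.counts.astype(float) * mask[:, :, None]
    n = n_loc * T
    total = x.sum()
    xbar = total / n
    s = np.sqrt((x * x).sum() / n - xbar ** 2)

    # binary spatial kernel: offsets with centroid distance <= radius
    offs = _spatial_offsets(cube.bin_size, params.neighborhood_distance)
    r = int(np.abs(offs).max()) if len(offs) else 0
    kernel = np.zeros((2 * r + 1, 2 * r + 1))
    kernel[offs[:, 0] + r, offs[:, 1] + r] = 1.0

    sp_sum = np.empty((rows, cols, T))
    for t in range(T):
        sp_sum[:, :, t] = ndimage.convolve(x[:, :, t], kernel, mode="constant")
    sp_w = ndimage.convolve(mask.astype(float), kernel, mode="constant")

    num = np.zeros((rows, cols, T))
    W = np.zeros((rows, cols, T))
    for t in range(1, T + 1):
        win = _time_window(t, T, params)
        num[:, :, t - 1] = sp_sum[:, :, [tt - 1 for tt in win]].sum(axis=2)
        W[:, :, t - 1] = len(win) * sp_w

    z = np.zeros((rows, cols, T))
    if s > 0:
        denom = s * np.sqrt(np.maximum(n * W - W ** 2, 0.0) / (n - 1))
        valid = denom > 0
        z[valid] = (num[valid] - xbar * W[valid]) / denom[valid]
    p = 2 * norm.sf(np.abs(z))
    zc = params.z_crit
    label = np.zeros((rows, cols, T), dtype=np.int8)
    label[z > zc] = LABEL_HOT
    label[z < -zc] = LABEL_COLD
    outside = ~mask
    z[outside] = np.nan
    p[outside] = np.nan
    label[outside] = LABEL_NEITHER
    return GiStarField(z=z, p=p, label=label, params=params, mask=mask.copy(),
                       transform=cube.transform)


def mann_kendall(series, alpha: float = 0.05) -> MKResult:
    """Mann-Kendall trend test with tie-corrected variance.

    S is the sum of signs of all pairwise forward differences; its variance
    under the null is ``[n(n-1)(2n+5) - sum_g t_g(t_g-1)(2t_g+5)] / 18``
    over tie groups g. The z-score uses the continuity correction
    (S -/+ 1); the p-value is two-sided normal. ``direction`` is set only
    when p < alpha. Requires n >= 4 (normal approximation).
    """
    x = np.asarray(series, dtype=float)
    n = x.size
    if n < 4:
        raise ValueError(f"Mann-Kendall requires n >= 4, got {n}")
    diffs = np.sign(x[None, :] - x[:, None])
    S = int(np.triu(diffs, k=1).sum())
    varS = _mk_variance(x)
    if S > 0:
        z = (S - 1) / np.sqrt(varS)
    elif S < 0:
        z = (S + 1) / np.sqrt(varS)
    else:
        z = 0.0
    p = float(2 * norm.sf(abs(z)))
    if p < alpha and S != 0:
        direction = "increasing" if S > 0 else "decreasing"
    else:
        direction = "none"
    return MKResult(S=S, varS=float(varS), z=float(z), p=p, direction=direction)


def _mk_variance(x: np.ndarray) -> float:
    n = x.size
    var = n * (n - 1) * (2 * n + 5)
    _, counts = np.unique(x, return_counts=True)
    ties = counts[counts > 1]
    var -= (ties * (ties - 1) * (2 * ties + 5)).sum()
    return var / 18.0


def mann_kendall_z_batch(series_matrix: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Vectorised Mann-Kendall over rows of an (m, n) matrix.

    Returns (S, z) arrays of length m; used for per-location trend maps
    where calling :func:`mann_kendall` per row would dominate runtime.
    Matches the scalar routine exactly (shared tie-corrected variance and
    continuity correction).
    """
    X = np.asarray(series_matrix, dtype=float)
    m, n = X.shape
    if n < 4:
        raise ValueError(f"Mann-Kendall requires n >= 4, got {n}")
    diffs = np.sign(X[:, None, :] - X[:, :, None])  # (m, i, j) sign(x_j - x_i)
    iu = np.triu_indices(n, k=1)
    S = diffs[:, iu[0], iu[1]].sum(axis=1)
    varS = np.array([_mk_variance(row) for row in X])
    z = np.zeros(m)
    pos, neg = S > 0, S < 0
    z[pos] = (S[pos] - 1) / np.sqrt(varS[pos])
    z[neg] = (S[neg] + 1) / np.sqrt(varS[neg])
    return S.astype(int), z


def intensity_trend(gi_field: GiStarField, location: tuple[int, int],
                    params: EhaParams | None = None,
                    cube: SpaceTimeCube | None = None) -> MKResult:
    """Mann-Kendall trend of a location's clustering intensity.

    By default the series tested is the location's Gi* z-scores over time;
    with ``params.trend_on == "counts"`` the raw bin counts are used
    instead (requires ``cube``).
    """
    params = params or gi_field.params
    r, c = location
    if not gi_field.mask[r, c]:
        raise ValueError(f"location {location} is outside the analysis mask")
    if params.trend_on == "counts":
        if cube is None:
            raise ValueError("trend_on='counts' requires the cube")
        series = cube.counts[r, c, :]
    else:
        series = gi_field.z[r, c, :]
    return mann_kendall(series, alpha=params.alpha)


def mk_results_frame(gi_field: GiStarField, params: EhaParams | None = None,
                     cube: SpaceTimeCube | None = None) -> pd.DataFrame:
    """Per-location Mann-Kendall results as a DataFrame
    (row, col, S, z, p, direction) over masked locations."""
    params = params or gi_field.params
    rr, cc = np.nonzero(gi_field.mask)
    if params.trend_on == "counts":
        if cube is None:
            raise ValueError("trend_on='counts' requires the cube")
        series = cube.counts[rr, cc, :].astype(float)
    else:
        series = gi_field.z[rr, cc, :]
    S, z = mann_kendall_z_batch(series)
    p = 2 * norm.sf(np.abs(z))
    direction = np.where(p >= params.alpha, "none",
                         np.where(S > 0, "increasing", "decreasing"))
    direction[S == 0] = "none"
    return pd.DataFrame({"row": rr, "col": cc, "S": S, "z": z, "p": p,
                         "direction": direction})
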