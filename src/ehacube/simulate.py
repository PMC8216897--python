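"""Synthetic loss-year rasters with planted space-time hotspot structure.

The generator emulates the pipeline's real-world inputs — an annual
first-loss raster, elevation/human-footprint covariates, plantation
features and protected-area polygons — on a local metric grid with known
ground truth, so every downstream stage can be validated against planted
patterns rather than external data.

Each planted patch carries a category template: a deterministic per-year
intensity profile (plus, for oscillating/cold templates, a suppression
flag that forces the within-patch loss rate to zero so the neighborhood
tests significantly *cold*). A pixel can be lost at most once: in year t a
still-standing pixel is lost with probability ``background_rate`` plus the
sum of patch contributions, and afterwards carries code t forever
(first-loss semantics, codes 0..n_years).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import shapely
import yaml
from shapely.geometry import LineString, Point, box

from ehacube.cube import LossYearRaster
from ehacube.io import GridTransform, LOCAL_METRIC_CRS

TEMPLATES = ("new", "consecutive", "intensifying", "persistent",
             "diminishing", "sporadic", "oscillating", "historical", "cold")

#: IUCN protected-area management categories (plus the two reporting codes).
IUCN_CATEGORIES = ("Ia", "Ib", "II", "III", "IV", "V", "VI",
                   "Not reported", "Not applicable")


def template_profile(category_template: str, n_years: int) -> np.ndarray:
    """Deterministic per-year intensity vector (values in [0, 1]) of a
    category template.

    The profiles are engineered so that, after the one-step temporal
    smoothing of the space-time Gi* neighborhood, a well-separated patch
    reproduces the hot/cold step counts its category requires:

    - new: on only in the final year;
    - consecutive: on only for a terminal run of floor(0.3 n) years;
    - intensifying / diminishing: linear ramps 0.3→1 / 1→0.3 (every year
      elevated, so the location stays hot throughout while the clustering
      intensity trends);
    - persistent: on every year;
    - historical: on for the first n−2 years, off for the final two;
    - sporadic: on/off blocks (2 on / 4 off from the final year backwards),
      never suppressed;
    - oscillating: alternating blocks of 2 on / 3 suppressed ending on
      (suppressed years force the patch rate below background → cold bins);
    - cold: suppressed every year.
    """
    if n_years < 2:
        raise ValueError(f"n_years must be >= 2, got {n_years}")
    if category_template not in TEMPLATES:
        raise ValueError(f"unknown template {category_template!r}; "
                         f"valid names: {', '.join(TEMPLATES)}")
    n = n_years
    prof = np.zeros(n)
    if category_template == "new":
        prof[-1] = 1.0
    elif category_template == "persistent":
        prof[:] = 1.0
    elif category_template == "consecutive":
        run = max(2, int(np.floor(0.3 * n)))
        prof[-run:] = 1.0
    elif category_template == "historical":
        prof[:n - 2] = 1.0
    elif category_template == "intensifying":
        prof[:] = np.linspace(0.3, 1.0, n)
    elif category_template == "diminishing":
        prof[:] = np.linspace(1.0, 0.3, n)
    elif category_template == "sporadic":
        prof[_block_on_years(n, on_len=2, off_len=4)] = 1.0
    elif category_template == "oscillating":
        prof[_block_on_years(n, on_len=2, off_len=3)] = 1.0
    # cold: all zeros
    return prof


def template_suppressed(category_template: str, n_years: int) -> np.ndarray:
    """Boolean per-year flags marking suppressed years, in which the patch
    forces the loss rate to zero inside its footprint (below the
    surrounding background) to induce Gi* cold bins."""
    template_profile(category_template, n_years)  # validate inputs
    n = n_years
    sup = np.zeros(n, dtype=bool)
    if category_template == "oscillating":
        sup[:] = ~_block_on_mask(n, on_len=2, off_len=3)
    elif category_template == "cold":
        sup[:] = True
    return sup


def _block_on_mask(n: int, on_len: int, off_len: int) -> np.ndarray:
    """On/off block pattern built backwards from the final year (final
    block on), truncated at the series start."""
    on = np.zeros(n, dtype=bool)
    t = n  # exclusive upper bound, walking backwards
    while t > 0:
        on[max(0, t - on_len):t] = True
        t -= on_len + off_len
    return on


def _block_on_years(n: int, on_len: int, off_len: int) -> np.ndarray:
    return np.nonzero(_block_on_mask(n, on_len, off_len))[0]


@dataclass(frozen=True)
class PlantedPatch:
    """A spatial footprint with a temporal category template.

    ``footprint`` is either ``("rect", row0, col0, row1, col1)`` with
    half-open pixel bounds, or ``("disc", center_row, center_col,
    radius_px)``. ``amplitude`` is the added per-pixel per-year loss
    probability when the template is fully on (scaled by the profile).
    """

    footprint: tuple
    category_template: str
    amplitude: float

    def mask(self, shape: tuple[int, int]) -> np.ndarray:
        rows, cols = shape
        kind = self.footprint[0]
        m = np.zeros(shape, dtype=bool)
        if kind == "rect":
            _, r0, c0, r1, c1 = self.footprint
            if not (0 <= r0 < r1 <= rows and 0 <= c0 < c1 <= cols):
                raise ValueError(f"rect footprint {self.footprint} outside "
                                 f"{rows}x{cols} grid")
            m[r0:r1, c0:c1] = True
        elif kind == "disc":
            _, cr, cc, rad = self.footprint
            if not (0 <= cr < rows and 0 <= cc < cols):
                raise ValueError(f"disc center {(cr, cc)} outside grid")
            rr, ccg = np.mgrid[0:rows, 0:cols]
            m = np.hypot(rr - cr, ccg - cc) <= rad
        else:
            raise ValueError(f"unknown footprint kind {kind!r}")
        return m


@dataclass
class ScenarioSpec:
    """Full description of a synthetic scenario.

    ``hazard_mode`` fixes the meaning of patch amplitudes. In ``"rate"``
    mode the amplitude adds directly to the per-year Bernoulli hazard of
    still-standing pixels; because a pixel is lost at most once, constant
    elevated rates deplete the patch and its yearly counts decay. In
    ``"mass"`` mode the amplitude is the *expected loss mass* (expected
    fraction of the patch's pixels newly lost that year); the generator
    divides by the expected survival to build the conditional hazard, so
    planted count profiles follow the template shape despite first-loss
    depletion — the mode used by the planted-truth recovery scenario.
    """

    grid_rows: int
    grid_cols: int
    cell_size: float = 1000.0
    n_years: int = 18
    background_rate: float = 0.02
    patches: list = field(default_factory=list)
    seed: int = 0
    hazard_mode: str = "rate"

    def __post_init__(self) -> None:
        if self.grid_rows < 3 or self.grid_cols < 3:
            raise ValueError("grid must be at least 3x3 pixels")
        if self.n_years < 2:
            raise ValueError("n_years must be >= 2")
        if not 0 <= self.background_rate < 1:
            raise ValueError("background_rate must be in [0, 1)")
        if self.hazard_mode not in ("rate", "mass"):
            raise ValueError("hazard_mode must be 'rate' or 'mass'")
        max_amp = max((p.amplitude for p in self.patches), default=0.0)
        if self.hazard_mode == "rate" and self.background_rate + max_amp > 1:
            raise ValueError(
                f"background_rate + max patch amplitude = "
                f"{self.background_rate + max_amp} exceeds 1")

    @property
    def transform(self) -> GridTransform:
        # origin at the top-left corner; y increases northward
        return GridTransform(0.0, self.grid_rows * self.cell_size,
                             self.cell_size)

    def pixel_centroids(self):
        """(x, y) centroid grids of every pixel."""
        rr, cc = np.mgrid[0:self.grid_rows, 0:self.grid_cols]
        return self.transform.centroid(rr, cc)

    def to_yaml(self, path) -> None:
        data = {
            "grid_rows": self.grid_rows, "grid_cols": self.grid_cols,
            "cell_size": self.cell_size, "n_years": self.n_years,
            "background_rate": self.background_rate, "seed": self.seed,
            "hazard_mode": self.hazard_mode,
            "patches": [{"footprint": list(p.footprint),
                         "category_template": p.category_template,
                         "amplitude": p.amplitude} for p in self.patches],
        }
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioSpec":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        patches = [PlantedPatch(footprint=tuple(p["footprint"]),
                                category_template=p["category_template"],
                                amplitude=p["amplitude"])
                   for p in data.pop("patches", [])]
        return cls(patches=patches, **data)


def generate_loss_raster(spec: ScenarioSpec, seed: int | None = None):
    """Simulate the first-loss process.

    Returns ``(raster, truth, legend)``: the loss-year raster, an integer
    ground-truth grid (0 = background, i+1 = patch i) and a legend mapping
    truth codes to template names. Each still-standing pixel is lost in
    year t with probability ``background_rate + sum(patch contributions)``;
    suppressed patch-years force the rate to 0 inside the patch.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    shape = (spec.grid_rows, spec.grid_cols)
    masks = [p.mask(shape) for p in spec.patches]
    profiles = [template_profile(p.category_template, spec.n_years)
                for p in spec.patches]
    suppressed = [template_suppressed(p.category_template, spec.n_years)
                  for p in spec.patches]

    codes = np.zeros(shape, dtype=np.int64)
    alive = np.ones(shape, dtype=bool)
    # expected survival under the deterministic hazard schedule; in "mass"
    # mode patch contributions are divided by it so that the expected count
    # profile tracks the template despite first-loss depletion
    survival = np.ones(shape)
    for t in range(1, spec.n_years + 1):
        p = np.full(shape, spec.background_rate)
        for patch, m, prof in zip(spec.patches, masks, profiles):
            contrib = patch.amplitude * prof[t - 1]
            if spec.hazard_mode == "mass":
                p[m] += contrib / np.maximum(survival[m], 1e-12)
            else:
                p[m] += contrib
        for m, sup in zip(masks, suppressed):
            if sup[t - 1]:
                p[m] = 0.0
        if (p > 1).any():
            raise ValueError(f"loss probability exceeds 1 in year {t}")
        lost = alive & (rng.random(shape) < p)
        codes[lost] = t
        alive &= ~lost
        survival *= 1.0 - p

    raster = LossYearRaster(values=codes, transform=spec.transform,
                            n_years=spec.n_years, crs_tag=LOCAL_METRIC_CRS)
    truth = np.zeros(shape, dtype=np.int16)
    for i, m in enumerate(masks):
        truth[m] = i + 1
    legend = {0: "background"}
    legend.update({i + 1: p.category_template
                   for i, p in enumerate(spec.patches)})
    return raster, truth, legend


def generate_covariates(spec: ScenarioSpec, seed: int | None = None,
                        n_bumps: int = 4, footprint_max: float = 30.0,
                        footprint_decay: float = 20_000.0,
                        plantation_density: float = 1.5e-9) -> dict:
    """Synthetic covariate stack and driver feature layers.

    - elevation: sum of ``n_bumps`` smooth Gaussian bumps (metres);
    - human footprint: ``footprint_max * exp(-d_road / footprint_decay)``
      clipped to the 0-50 index range, decaying from random straight
      "roads" crossing the grid;
    - plantations: homogeneous Poisson point sets (features per m²) for
      oil palm and wood fiber;
    - roads: the generating polylines.

    All layers share the loss raster's georeferencing.
    """
    rng = np.random.default_rng(spec.seed + 1 if seed is None else seed)
    x, y = spec.pixel_centroids()
    width = spec.grid_cols * spec.cell_size
    height = spec.grid_rows * spec.cell_size

    elevation = np.zeros(x.shape)
    for _ in range(n_bumps):
        cx, cy = rng.uniform(0, width), rng.uniform(0, height)
        amp = rng.uniform(100.0, 800.0)
        sigma = rng.uniform(0.1, 0.3) * min(width, height)
        elevation += amp * np.exp(-((x - cx) ** 2 + (y - cy) ** 2)
                                  / (2 * sigma ** 2))

    # two straight roads spanning the grid
    roads = []
    for _ in range(2):
        if rng.random() < 0.5:
            y0, y1 = rng.uniform(0, height, 2)
            roads.append(LineString([(0, y0), (width, y1)]))
        else:
            x0, x1 = rng.uniform(0, width, 2)
            roads.append(LineString([(x0, 0), (x1, height)]))
    pt_arr = shapely.points(np.column_stack([x.ravel(), y.ravel()]))
    d_road = np.min([shapely.distance(pt_arr, r) for r in roads], axis=0)
    d_road = d_road.reshape(x.shape)
    footprint = np.clip(footprint_max * np.exp(-d_road / footprint_decay),
                        0.0, 50.0)

    plantations = {}
    area = width * height
    for name in ("oil_palm", "wood_fiber"):
        k = rng.poisson(plantation_density * area)
        px = rng.uniform(0, width, k)
        py = rng.uniform(0, height, k)
        plantations[name] = [Point(a, b) for a, b in zip(px, py)]

    return {"elevation": elevation, "human_footprint": footprint,
            "roads": roads, "plantations": plantations,
            "transform": spec.transform, "crs_tag": LOCAL_METRIC_CRS}


def generate_protected_areas(spec: ScenarioSpec, n_pas: int,
                             seed: int | None = None) -> list[dict]:
    """Random non-degenerate protected-area polygons inside the grid.

    Returns GeoJSON-style feature dicts with shapely geometry, ``name`` and
    an ``iucn_category`` drawn from the nine IUCN values.
    """
    if n_pas < 0:
        raise ValueError("n_pas must be >= 0")
    rng = np.random.default_rng(spec.seed + 2 if seed is None else seed)
    width = spec.grid_cols * spec.cell_size
    height = spec.grid_rows * spec.cell_size
    feats = []
    for i in range(n_pas):
        if rng.random() < 0.5:
            w = rng.uniform(0.1, 0.35) * width
            h = rng.uniform(0.1, 0.35) * height
            x0 = rng.uniform(0, width - w)
            y0 = rng.uniform(0, height - h)
            geom = box(x0, y0, x0 + w, y0 + h)
        else:
            rad = rng.uniform(0.05, 0.2) * min(width, height)
            cx = rng.uniform(rad, width - rad)
            cy = rng.uniform(rad, height - rad)
            geom = Point(cx, cy).buffer(rad, quad_segs=16)
        feats.append({"geometry": geom, "name": f"PA-{i + 1}",
                      "iucn_category": str(rng.choice(IUCN_CATEGORIES))})
    return feats


def default_recovery_scenario(seed: int = 0, bin_size: float = 5000.0
                              ) -> tuple[ScenarioSpec, dict]:
    """The standard planted-truth scenario: one 5x5-bin patch per hotspot
    template on a 3200x3200-pixel (160x160-bin, 250 m cells) grid.

    Sized so that (a) patch bin-years are ~0.5% of the cube, keeping the
    global Gi* background (mean/SD over all masked bins) close to the
    background process so plain background bins do not drift into
    significance; (b) each bin holds 400 pixels, so planted contrasts (an
    expected 20 extra lost pixels per bin in a fully-on year against a
    background of 1) dominate Bernoulli noise; and (c) the planted signal
    variance inflates the global SD enough that background bins almost
    never cross the hot/cold critical value by chance — without which the
    count-sensitive categories (new: exactly one hot step; sporadic: zero
    cold steps) cannot be recovered reliably. Patches use "mass" hazard
    semantics. Returns the spec and a mapping template -> patch pixel
    bounds (row0, col0, row1, col1).
    """
    cell = 250.0
    bins_per = int(bin_size / cell)  # 20 pixels per bin edge
    corners = [(20, 20), (20, 70), (20, 120), (70, 20),
               (70, 120), (120, 20), (120, 70), (120, 120)]  # bin coords
    order = ("new", "consecutive", "intensifying", "persistent",
             "diminishing", "sporadic", "oscillating", "historical")
    patches, bounds = [], {}
    for (br, bc), name in zip(corners, order):
        r0, c0 = br * bins_per, bc * bins_per
        r1, c1 = r0 + 5 * bins_per, c0 + 5 * bins_per
        patches.append(PlantedPatch(footprint=("rect", r0, c0, r1, c1),
                                    category_template=name, amplitude=0.05))
        bounds[name] = (r0, c0, r1, c1)
    spec = ScenarioSpec(grid_rows=3200, grid_cols=3200, cell_size=cell,
                        n_years=18, background_rate=0.0025, patches=patches,
                        seed=seed, hazard_mode="mass")
    return spec, bounds
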