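"""Eight-category emerging-hotspot classification.

Each masked location carries a length-T sequence of hot/cold/neither Gi*
labels and a Mann-Kendall trend of its clustering intensity. The rules
below assign exactly one of the eight hotspot pattern categories — new,
consecutive, intensifying, persistent, diminishing, sporadic, oscillating,
historical — or none. Only hotspot patterns are emitted; cold labels enter
only through the oscillating rule (a final-step hotspot with a cold-spot
history). Mirror cold-spot categories are out of scope.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ehacube.cube import SpaceTimeCube
from ehacube.io import GridTransform, write_geotiff
from ehacube.stats import (EhaParams, GiStarField, LABEL_COLD, LABEL_HOT,
                           MKResult, gi_star, mann_kendall_z_batch)
from scipy.stats import norm

#: The eight hotspot pattern categories, in classification precedence order
#: (a location matching several definitions takes the first).
CATEGORIES = ("new", "consecutive", "intensifying", "persistent",
              "diminishing", "sporadic", "oscillating", "historical")
NONE_CATEGORY = "none"

#: Integer codes for raster output; 0 reserved for none/unmasked.
CATEGORY_CODES = {name: i + 1 for i, name in enumerate(CATEGORIES)}
CATEGORY_CODES[NONE_CATEGORY] = 0

_VALID_LABELS = frozenset(("hot", "cold", "neither"))


def min_hot_steps(T: int, hot_fraction: float = 0.90) -> int:
    """Smallest number of hot steps that counts as a "90 percent" hotspot
    history: floor(hot_fraction * T). With T = 18 and 0.90 this is 16,
    the operationalisation used for 18 annual time steps.
    """
    if T < 2:
        raise ValueError(f"T must be >= 2, got {T}")
    return int(np.floor(hot_fraction * T))


def _terminal_hot_run(labels: list[str]) -> int:
    run = 0
    for lab in reversed(labels):
        if lab == "hot":
            run += 1
        else:
            break
    return run


def classify_location(labels, trend: MKResult,
                      params: EhaParams | None = None) -> str:
    """Assign the hotspot pattern category for one location.

    ``labels`` is the length-T sequence of per-step Gi* labels
    ('hot'/'cold'/'neither'); ``trend`` the location's clustering-intensity
    Mann-Kendall result. The first matching rule wins:

    1. new — final step hot and never hot before (hot count exactly 1);
    2. consecutive — an uninterrupted terminal run of >= 2 hot steps, no
       hot step before the run, fewer hot steps than the 90% threshold;
    3. intensifying — final hot, hot in >= 90% of steps, significantly
       increasing intensity;
    4. diminishing — final hot, hot in >= 90% of steps, significantly
       decreasing intensity;
    5. persistent — final hot, hot in >= 90% of steps, no significant
       trend;
    6. oscillating — final hot with a cold-spot history, hot in < 90% of
       steps;
    7. sporadic — final hot, on-and-off hot history, never cold, hot in
       < 90% of steps;
    8. historical — final step not hot but hot in >= 90% of steps;
    9. none.
    """
    params = params or EhaParams()
    labels = list(labels)
    bad = set(labels) - _VALID_LABELS
    if bad:
        raise ValueError(f"invalid labels {sorted(bad)}; "
                         f"expected {sorted(_VALID_LABELS)}")
    T = len(labels)
    mhs = min_hot_steps(T, params.hot_fraction)
    hot_count = labels.count("hot")
    cold_count = labels.count("cold")
    final_hot = labels[-1] == "hot"
    term_run = _terminal_hot_run(labels)
    increasing = trend.direction == "increasing"
    decreasing = trend.direction == "decreasing"

    if final_hot and hot_count == 1:
        return "new"
    if final_hot and term_run >= 2 and hot_count == term_run and hot_count < mhs:
        return "consecutive"
    if final_hot and hot_count >= mhs and increasing:
        return "intensifying"
    if final_hot and hot_count >= mhs and decreasing:
        return "diminishing"
    if final_hot and hot_count >= mhs:
        return "persistent"
    if final_hot and cold_count >= 1 and hot_count < mhs:
        return "oscillating"
    if final_hot and cold_count == 0 and hot_count < mhs:
        return "sporadic"
    if not final_hot and hot_count >= mhs:
        return "historical"
    return NONE_CATEGORY


@dataclass
class CategoryMap:
    """Per-location emerging-hotspot category with diagnostics.

    ``category`` holds integer codes (see CATEGORY_CODES; 0 = none or
    unmasked); the diagnostics frame carries per-masked-location hot/cold
    counts, final-step hotness, terminal run length and trend direction.
    """

    category: np.ndarray     # (rows, cols) int8 codes
    mask: np.ndarray         # (rows, cols) bool
    diagnostics: pd.DataFrame
    params: EhaParams
    transform: GridTransform = None

    def category_name(self, row: int, col: int) -> str:
        code = int(self.category[row, col])
        for name, c in CATEGORY_CODES.items():
            if c == code:
                return name
        raise KeyError(code)

    def counts(self) -> dict[str, int]:
        """Number of masked locations per category (none included)."""
        out = {}
        masked = self.category[self.mask]
        for name, code in CATEGORY_CODES.items():
            out[name] = int((masked == code).sum())
        return out

    def write(self, path, legend_path=None, crs_tag: str = "LOCAL_METRIC") -> None:
        write_geotiff(path, self.category.astype(np.uint8), self.transform,
                      crs_tag=crs_tag, nodata=None)
        if legend_path is not None:
            with open(legend_path, "w") as fh:
                json.dump({str(v): k for k, v in CATEGORY_CODES.items()}, fh)


_LABEL_NAMES = {LABEL_HOT: "hot", LABEL_COLD: "cold", 0: "neither"}


def run_eha(cube: SpaceTimeCube, params: EhaParams | None = None,
            gi_field: GiStarField | None = None) -> CategoryMap:
    """Full emerging hotspot analysis of a space-time cube.

    Composes Gi* scoring, per-location label sequences, intensity-trend
    Mann-Kendall tests and the eight-category rules. Deterministic given
    the cube and parameters. An empty analysis mask yields an empty map.
    """
    params = params or EhaParams()
    rows, cols, T = cube.shape
    category = np.zeros((rows, cols), dtype=np.int8)
    mask = cube.analysis_mask
    if not mask.any():
        diag = pd.DataFrame(columns=["row", "col", "hot_count", "cold_count",
                                     "final_hot", "terminal_run",
                                     "trend_direction", "category"])
        return CategoryMap(category=category, mask=mask, diagnostics=diag,
                           params=params, transform=cube.transform)
    if gi_field is None:
        gi_field = gi_star(cube, params)

    rr, cc = np.nonzero(mask)
    label_codes = gi_field.label[rr, cc, :]           # (m, T)
    if params.trend_on == "counts":
        series = cube.counts[rr, cc, :].astype(float)
    else:
        series = gi_field.z[rr, cc, :]
    S, zmk = mann_kendall_z_batch(series)
    pmk = 2 * norm.sf(np.abs(zmk))

    mhs = min_hot_steps(T, params.hot_fraction)
    hot = label_codes == LABEL_HOT
    cold = label_codes == LABEL_COLD
    hot_count = hot.sum(axis=1)
    cold_count = cold.sum(axis=1)
    final_hot = hot[:, -1]
    # terminal uninterrupted hot run, vectorised: steps from the end until
    # the first non-hot label
    rev_not_hot = ~hot[:, ::-1]
    term_run = np.where(rev_not_hot.any(axis=1),
                        rev_not_hot.argmax(axis=1), T)
    sig = pmk < params.alpha
    increasing = sig & (S > 0)
    decreasing = sig & (S < 0)

    names = np.full(len(rr), NONE_CATEGORY, dtype=object)
    unset = np.ones(len(rr), dtype=bool)

    def assign(cond, name):
        nonlocal unset
        pick = cond & unset
        names[pick] = name
        unset &= ~pick

    assign(final_hot & (hot_count == 1), "new")
    assign(final_hot & (term_run >= 2) & (hot_count == term_run)
           & (hot_count < mhs), "consecutive")
    assign(final_hot & (hot_count >= mhs) & increasing, "intensifying")
    assign(final_hot & (hot_count >= mhs) & decreasing, "diminishing")
    assign(final_hot & (hot_count >= mhs), "persistent")
    assign(final_hot & (cold_count >= 1) & (hot_count < mhs), "oscillating")
    assign(final_hot & (cold_count == 0) & (hot_count < mhs), "sporadic")
    assign(~final_hot & (hot_count >= mhs), "historical")

    for i in range(len(rr)):
        category[rr[i], cc[i]] = CATEGORY_CODES[names[i]]
    direction = np.where(~sig | (S == 0), "none",
                         np.where(S > 0, "increasing", "decreasing"))
    diag = pd.DataFrame({
        "row": rr, "col": cc,
        "hot_count": hot_count, "cold_count": cold_count,
        "final_hot": final_hot, "terminal_run": term_run,
        "trend_direction": direction, "trend_z": zmk, "trend_p": pmk,
        "category": names.astype(str),
    })
    return CategoryMap(category=category, mask=mask, diagnostics=diag,
                       params=params, transform=cube.transform)
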