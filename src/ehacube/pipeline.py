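"""End-to-end orchestration: simulate → cube → Gi*/Mann-Kendall →
classification → protected-area overlay → driver attribution.

All randomness flows from the config seed; rerunning an identical config
reproduces the report byte-for-byte (timestamps excluded by design — the
report carries none).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

import ehacube
from ehacube.classify import CATEGORIES, CategoryMap, run_eha
from ehacube.cube import annual_loss_series, build_cube, read_loss_raster
from ehacube.drivers import (aggregate_to_bins, category_summaries,
                             euclidean_distance_map, fit_cart,
                             kruskal_wallis_by_category, slope_from_elevation)
from ehacube.io import read_geojson, write_geojson
from ehacube.overlay import pa_category_shares, rasterize_pa
from ehacube.simulate import (ScenarioSpec, default_recovery_scenario,
                              generate_covariates, generate_loss_raster,
                              generate_protected_areas)
from ehacube.stats import EhaParams, gi_star

log = logging.getLogger("ehacube")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunConfig:
    """Configuration of a full pipeline run.

    Either ``scenario`` (a ScenarioSpec or path to its YAML) drives the
    synthetic generator, or ``loss_raster``/``pa_file`` point at existing
    inputs. Every analysis parameter of the method (neighborhood distance,
    temporal window, alpha, persistence threshold, bin size, mask mode,
    trend series) is surfaced here — no hidden constants.
    """

    out_dir: str = "eha_out"
    seed: int = 0
    scenario: "ScenarioSpec | str | None" = None
    loss_raster: str | None = None
    pa_file: str | None = None
    n_years: int = 18
    bin_size: float = 5000.0
    mask_mode: str = "any-loss"
    n_pas: int = 3
    params: EhaParams = field(default_factory=EhaParams)
    cart_max_depth: int = 4
    cart_min_leaf: float = 0.05
    cart_criterion: str = "gini"
    ring_width: float = 5000.0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        params = EhaParams(**data.pop("params", {}))
        scenario = data.pop("scenario", None)
        if isinstance(scenario, dict):
            from ehacube.simulate import PlantedPatch
            patches = [PlantedPatch(footprint=tuple(p["footprint"]),
                                    category_template=p["category_template"],
                                    amplitude=p["amplitude"])
                       for p in scenario.pop("patches", [])]
            scenario = ScenarioSpec(patches=patches, **scenario)
        return cls(params=params, scenario=scenario, **data)

    def echo(self) -> dict:
        d = {"out_dir": self.out_dir, "seed": self.seed,
             "loss_raster": self.loss_raster, "pa_file": self.pa_file,
             "n_years": self.n_years, "bin_size": self.bin_size,
             "mask_mode": self.mask_mode, "n_pas": self.n_pas,
             "cart_max_depth": self.cart_max_depth,
             "cart_min_leaf": self.cart_min_leaf,
             "cart_criterion": self.cart_criterion,
             "ring_width": self.ring_width,
             "params": {
                 "neighborhood_distance": self.params.neighborhood_distance,
                 "neighborhood_time_steps": self.params.neighborhood_time_steps,
                 "alpha": self.params.alpha,
                 "hot_fraction": self.params.hot_fraction,
                 "time_window": self.params.time_window,
                 "trend_on": self.params.trend_on}}
        if isinstance(self.scenario, ScenarioSpec):
            d["scenario"] = {"grid_rows": self.scenario.grid_rows,
                             "grid_cols": self.scenario.grid_cols,
                             "n_patches": len(self.scenario.patches),
                             "seed": self.scenario.seed}
        elif self.scenario is not None:
            d["scenario"] = str(self.scenario)
        return d


def category_composition(category_map: CategoryMap) -> dict[str, float]:
    """Percentage of category-bearing locations per category.

    The none class is excluded from the denominator; the percentages sum
    to 100 over the categories present. Zero hotspot locations yield an
    empty composition (no division error).
    """
    counts = category_map.counts()
    total = sum(counts[c] for c in CATEGORIES)
    if total == 0:
        return {}
    return {c: 100.0 * counts[c] / total for c in CATEGORIES if counts[c] > 0}


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages and return the machine-readable run report.

    Artifacts written under ``config.out_dir``: the category GeoTIFF +
    legend, annual-loss CSV, diagnostics CSV, PA shares CSV, island
    inside/outside CSV, covariate summaries CSV, Kruskal-Wallis CSV, tree
    JSON/text, and the report JSON itself.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"software": {"package": "ehacube",
                                 "version": ehacube.__version__},
                    "config": config.echo(), "stages": {}}

    # --- inputs: simulate or load -----------------------------------------
    stage = "inputs"
    try:
        covs_raw = None
        pas = None
        truth_legend = None
        if config.scenario is not None:
            spec = config.scenario
            if not isinstance(spec, ScenarioSpec):
                spec = ScenarioSpec.from_yaml(spec)
            raster, truth, truth_legend = generate_loss_raster(
                spec, seed=config.seed)
            covs_raw = generate_covariates(spec, seed=config.seed + 1)
            pas = generate_protected_areas(spec, config.n_pas,
                                           seed=config.seed + 2)
            raster.write(out / "loss_year.tif")
            write_geojson(out / "protected_areas.geojson", pas)
            n_years = spec.n_years
        else:
            if config.loss_raster is None:
                raise ValueError("config needs a scenario or a loss_raster")
            raster = read_loss_raster(config.loss_raster,
                                      n_years=config.n_years)
            n_years = config.n_years
        report["stages"][stage] = {
            "grid_shape": list(raster.values.shape),
            "n_years": n_years,
            "loss_pixels": int((raster.values > 0).sum())}
        log.info("inputs: %s pixels, %d loss pixels", raster.values.shape,
                 (raster.values > 0).sum())
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001 - stage boundary
        raise PipelineError(stage, str(exc)) from exc

    # --- cube --------------------------------------------------------------
    stage = "cube"
    try:
        cube = build_cube(raster, bin_size=config.bin_size, T=n_years,
                          mask_mode=config.mask_mode)
        series = annual_loss_series(cube)
        series.to_csv(out / "annual_loss_km2.csv", index=False)
        report["stages"][stage] = {
            "bin_grid": list(cube.counts.shape[:2]),
            "bin_size_m": cube.bin_size,
            "masked_locations": int(cube.analysis_mask.sum()),
            "n_spacetime_bins": cube.n,
            "total_loss_km2": float(series["area_km2"].sum()),
            "mean_annual_loss_km2": float(series["area_km2"].mean())}
        log.info("cube: %s bins, %d masked locations",
                 cube.counts.shape[:2], cube.analysis_mask.sum())
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # --- statistics + classification ---------------------------------------
    stage = "classify"
    try:
        gi = gi_star(cube, config.params)
        cmap = run_eha(cube, config.params, gi_field=gi)
        gi.write_z(out / "gi_star_z.tif")
        cmap.write(out / "categories.tif", legend_path=out / "legend.json")
        cmap.diagnostics.to_csv(out / "diagnostics.csv", index=False)
        composition = category_composition(cmap)
        counts = cmap.counts()
        report["stages"][stage] = {
            "category_counts": counts,
            "composition_pct": composition,
            "hotspot_locations": int(sum(counts[c] for c in CATEGORIES))}
        log.info("classify: %s", composition)
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # --- protected-area overlay ---------------------------------------------
    stage = "overlay"
    try:
        if pas is None and config.pa_file:
            if not Path(config.pa_file).exists():
                raise FileNotFoundError(f"PA file not found: {config.pa_file}")
            pas = read_geojson(config.pa_file)
        if pas:
            pa_grid = rasterize_pa(pas, cmap)
            shares, island = pa_category_shares(cmap, pa_grid, pas)
            shares.to_csv(out / "pa_category_shares.csv", index=False)
            island.to_csv(out / "island_inside_outside.csv", index=False)
            report["stages"][stage] = {
                "n_pas": len(pas),
                "inside_pa_hotspots": int(
                    island.loc[island.category != "none", "inside_pa"].sum()),
                "outside_pa_hotspots": int(
                    island.loc[island.category != "none", "outside_pa"].sum())}
        else:
            report["stages"][stage] = {"n_pas": 0, "skipped": True}
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    # --- driver attribution --------------------------------------------------
    stage = "drivers"
    try:
        if covs_raw is not None:
            factor = int(round(config.bin_size / raster.transform.cell_size))
            elev_bin = aggregate_to_bins(covs_raw["elevation"], factor)
            slope_px = slope_from_elevation(covs_raw["elevation"],
                                            raster.transform.cell_size)
            covariates = {
                "human_footprint": aggregate_to_bins(
                    covs_raw["human_footprint"], factor),
                "elevation": elev_bin,
                "slope": aggregate_to_bins(slope_px, factor),
            }
            bshape = cmap.category.shape
            for pname, feats in covs_raw["plantations"].items():
                if feats:
                    covariates[f"dist_{pname}"] = euclidean_distance_map(
                        cmap.transform, bshape, feats)
            summaries = category_summaries(cmap, covariates)
            summaries.to_csv(out / "category_summaries.csv", index=False)
            kw = kruskal_wallis_by_category(cmap, covariates)
            kw.to_csv(out / "kruskal_wallis.csv", index=False)

            hot = cmap.category > 0
            labels = np.array([cmap.category_name(r, c)
                               for r, c in zip(*np.nonzero(hot))])
            feats = np.column_stack([np.asarray(covariates[k])[hot]
                                     for k in sorted(covariates)])
            tree_summary = None
            if hot.sum() >= 2 and len(np.unique(labels)) >= 2:
                tree = fit_cart(feats, labels,
                                feature_names=sorted(covariates),
                                max_depth=config.cart_max_depth,
                                min_leaf=config.cart_min_leaf,
                                criterion=config.cart_criterion)
                tree.to_json(out / "decision_tree.json")
                (out / "decision_tree.txt").write_text(tree.render() + "\n")
                tree_summary = {
                    "root_feature": tree.feature_names[tree.root.feature]
                    if not tree.root.is_leaf else None,
                    "root_threshold": tree.root.threshold,
                    "n_leaves": len(tree.leaves())}
            report["stages"][stage] = {
                "covariates": sorted(covariates),
                "kruskal_wallis": kw.to_dict(orient="records"),
                "tree": tree_summary}
        else:
            report["stages"][stage] = {"skipped": True}
    except PipelineError:
        raise
    except Exception as exc:  # noqa: BLE001
        raise PipelineError(stage, str(exc)) from exc

    if truth_legend is not None:
        report["scenario_truth"] = {str(k): v for k, v in truth_legend.items()}
    with open(out / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def demo_config(seed: int = 0, out_dir: str = "eha_out") -> RunConfig:
    """The bundled demo: the 8-patch planted-truth scenario."""
    spec, _ = default_recovery_scenario(seed=seed)
    return RunConfig(out_dir=out_dir, seed=seed, scenario=spec)
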