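"""End-to-end orchestration of the MET-source comparison experiment.

Stages (mirroring the experiment flowchart):

1. ``simulate_world``  — synthesize terrain, mines, truth wind, MET sources,
   ancillary layers and drainage zones.
2. ``build_layers``    — compute the eight criteria layers; the MET-sensitive
   wind layers once per MET combination and once from the truth wind field.
3. ``build_model``     — fuzzify, generate validation samples from the truth
   surface, fit RF weights, and combine one exposure surface per combination.
4. ``run_validation``  — repeated-subset GWR validation, ANOVA, k-fold CV,
   and the scale-variability test.

``run_pipeline`` composes the four; each stage also persists its artifacts so
the CLI subcommands compose to the same outputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from shapely.geometry import LineString, shape

from . import criteria as cl
from . import met as mt
from . import synthetic_world as sw
from . import validation as vl
from .config import COMBINATIONS, RunConfig
from .fuzzy import (
    ExposureSurface,
    ForestSettings,
    WeightVector,
    fuzzy_standardize,
    rf_weights,
    weighted_linear_combination,
)
from .raster import Grid, Raster, read_raster, write_raster

__all__ = [
    "World",
    "LayerStack",
    "ModelOutputs",
    "simulate_world",
    "build_layers",
    "build_model",
    "run_validation",
    "run_pipeline",
    "load_world",
    "load_layers",
    "load_model",
]

_SEED_NAMES = (
    "terrain", "mines", "wind", "met", "ancillary", "zones",
    "samples", "rf", "subset", "kfold", "anova", "scale",
)


def derive_seeds(master: int) -> dict[str, int]:
    """Independent named sub-seeds from the master seed (all below 2^31)."""
    state = np.random.SeedSequence(master).generate_state(len(_SEED_NAMES))
    return {n: int(v % (2**31 - 1)) for n, v in zip(_SEED_NAMES, state)}


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and offending input."""

    def __init__(self, stage: str, detail: str):
        super().__init__(f"stage {stage!r} failed: {detail}")
        self.stage = stage


# ---------------------------------------------------------------------------
# stage 1: synthetic world
# ---------------------------------------------------------------------------


@dataclass
class World:
    grid: Grid
    dem: Raster
    mines: list
    wind_direction: Raster
    wind_speed: Raster
    met_sources: dict[str, mt.MetSource]  # metars | met_stations | narr
    wells: pd.DataFrame
    roads: list[LineString]
    ndvi: Raster
    zones: cl.Zones
    truth: sw.WorldTruth
    seeds: dict[str, int] = field(default_factory=dict)


def simulate_world(cfg: RunConfig) -> World:
    seeds = derive_seeds(cfg.seed)
    g = cfg.grid
    grid = Grid(g.n_rows, g.n_cols, g.cell_size, g.origin_x, g.origin_y)
    w = cfg.world
    dem = sw.generate_terrain(grid, w.roughness, w.relief, seeds["terrain"])
    mines = sw.generate_mines(
        grid, w.n_clusters, w.mines_per_cluster, w.cluster_sd,
        (w.area_min, w.area_max), seeds["mines"],
    )
    wind_dir, wind_spd = sw.generate_wind_truth(
        grid, w.prevailing_deg, w.direction_sd, w.speed_mean, w.speed_sd,
        w.correlation_length, seeds["wind"],
    )
    # station-arm points are anchored at the mine-cluster centers, emulating
    # remediation-program weather stations deployed at the contaminated sites
    mine_xy = np.array([[m.x, m.y] for m in mines])
    cluster = np.repeat(np.arange(w.n_clusters), w.mines_per_cluster)
    anchors = np.array(
        [mine_xy[cluster == k].mean(axis=0) for k in range(w.n_clusters)]
    )[: w.n_met_stations]
    direct, gridded = sw.emulate_met_sources(
        (wind_dir, wind_spd), w.n_direct, w.grid_spacing,
        w.smoothing_radius, w.direction_bias, seeds["met"],
        anchor_xy=anchors,
    )
    # split the direct stations into the two direct arms of the experiment
    stations = mt.MetSource(
        "met_stations", direct.points[: w.n_met_stations], kind="direct"
    )
    metars = mt.MetSource("metars", direct.points[w.n_met_stations :], kind="direct")
    narr = mt.MetSource("narr", gridded.points, kind="gridded")
    wells, roads, ndvi = sw.generate_ancillary(
        grid, w.n_wells, w.n_roads, seeds["ancillary"]
    )
    zones = cl.voronoi_zones(grid, w.n_zones, seeds["zones"])
    truth = sw.WorldTruth(
        true_weights=np.array(w.true_weights),
        wind_direction=wind_dir,
        wind_speed=wind_spd,
        noise_sd=w.noise_sd,
    )
    return World(
        grid=grid, dem=dem, mines=mines,
        wind_direction=wind_dir, wind_speed=wind_spd,
        met_sources={"metars": metars, "met_stations": stations, "narr": narr},
        wells=wells, roads=roads, ndvi=ndvi, zones=zones, truth=truth, seeds=seeds,
    )


# ---------------------------------------------------------------------------
# stage 2: criteria layers
# ---------------------------------------------------------------------------


@dataclass
class LayerStack:
    static: dict[int, Raster]  # layers 1, 2, 5, 6, 7, 8
    met_layers: dict[str, dict[int, Raster]]  # combination -> {3, 4}
    truth_met: dict[int, Raster]  # {3, 4} from the truth wind field

    def stack_for(self, key: str | None) -> list[Raster]:
        """Ordered 8-layer stack; key None = truth wind layers."""
        met = self.truth_met if key is None else self.met_layers[key]
        return [
            self.static[1], self.static[2], met[3], met[4],
            self.static[5], self.static[6], self.static[7], self.static[8],
        ]


def _wind_layers(
    cfg: RunConfig, world: World, wind: mt.WindField
) -> dict[int, Raster]:
    sv = mt.scale_speed(wind.speed)
    terrain = cl.slope_aspect(world.dem)
    return {
        3: cl.wind_index(
            world.grid, world.mines, wind, sv, downwind_peak=cfg.layers.downwind_peak
        ),
        4: cl.topographic_exposure(terrain, wind, sv, beta_w=cfg.layers.beta_w),
    }


def build_layers(cfg: RunConfig, world: World) -> LayerStack:
    lc = cfg.layers
    try:
        terrain = cl.slope_aspect(world.dem)
        tpi_r = cl.tpi(world.dem, lc.tpi_radius)
        static = {
            1: cl.aum_proximity(world.grid, world.mines, lc.aum_radius),
            2: cl.drainage_layer(world.dem, world.mines, world.zones, lc.snap_threshold),
            5: cl.landform_classify(tpi_r, terrain.slope),
            6: cl.road_proximity(world.grid, world.roads),
            7: cl.idw_hazard(
                world.grid,
                world.wells[["x", "y"]].to_numpy(),
                world.wells["hazard_index"].to_numpy(),
                power=lc.idw_power,
            ),
            8: world.ndvi,
        }
    except Exception as exc:  # pragma: no cover - defensive
        raise StageError("layers", str(exc)) from exc
    met_layers: dict[str, dict[int, Raster]] = {}
    for name in cfg.combinations:
        sources = [world.met_sources[k] for k in COMBINATIONS[name]]
        fused = mt.combine_sources(sources, k_replace=lc.k_replace)
        wind = mt.rasterize_wind(fused, world.grid)
        wind.source_label = name
        met_layers[name] = _wind_layers(cfg, world, wind)
    truth_wind = mt.WindField(
        direction=world.wind_direction, speed=world.wind_speed, source_label="truth"
    )
    truth_met = _wind_layers(cfg, world, truth_wind)
    return LayerStack(static=static, met_layers=met_layers, truth_met=truth_met)


# ---------------------------------------------------------------------------
# stage 3: fuzzification, samples, weights, surfaces
# ---------------------------------------------------------------------------


@dataclass
class ModelOutputs:
    coords: np.ndarray
    concentrations: np.ndarray
    fuzzy_stacks: dict[str, list[Raster]]  # combination -> fuzzified stack
    fuzzy_truth: list[Raster]
    weights: dict[str, WeightVector]
    surfaces: dict[str, ExposureSurface]
    truth_surface: ExposureSurface


def _fuzzify_stack(cfg: RunConfig, stack: list[Raster]) -> list[Raster]:
    params = cfg.fuzzy_params()
    return [fuzzy_standardize(layer, params[i + 1]) for i, layer in enumerate(stack)]


def build_model(cfg: RunConfig, world: World, layers: LayerStack) -> ModelOutputs:
    seeds = world.seeds or derive_seeds(cfg.seed)
    w = cfg.world
    fuzzy_truth = _fuzzify_stack(cfg, layers.stack_for(None))
    samples = sw.generate_validation_samples(
        fuzzy_truth, world.truth.true_weights, w.n_samples, w.noise_sd,
        seeds["samples"], intercept=w.sample_intercept, slope=w.sample_slope,
    )
    coords = np.array([[s.x, s.y] for s in samples])
    conc = np.array([s.concentration for s in samples])
    truth_surface = weighted_linear_combination(
        fuzzy_truth, WeightVector(world.truth.true_weights), combination="truth"
    )
    forest = ForestSettings(n_trees=cfg.rf.n_trees, max_depth=cfg.rf.max_depth)
    fuzzy_stacks, weights, surfaces = {}, {}, {}
    for name in cfg.combinations:
        stack = _fuzzify_stack(cfg, layers.stack_for(name))
        features = np.column_stack(
            [layer.sample(coords[:, 0], coords[:, 1]) for layer in stack]
        )
        # the same training subset (same seed) is used for every combination,
        # so arms differ only through their MET layers
        wv = rf_weights(conc, features, n_train=cfg.rf.n_train,
                        settings=forest, seed=seeds["rf"])
        fuzzy_stacks[name] = stack
        weights[name] = wv
        surfaces[name] = weighted_linear_combination(stack, wv, combination=name)
    return ModelOutputs(
        coords=coords, concentrations=conc, fuzzy_stacks=fuzzy_stacks,
        fuzzy_truth=fuzzy_truth, weights=weights, surfaces=surfaces,
        truth_surface=truth_surface,
    )


# ---------------------------------------------------------------------------
# stage 4: validation battery
# ---------------------------------------------------------------------------


def run_validation(
    cfg: RunConfig, world: World, layers: LayerStack, model: ModelOutputs
) -> dict:
    seeds = world.seeds or derive_seeds(cfg.seed)
    v = cfg.validation
    coords, conc = model.coords, model.concentrations

    summaries = {}
    for name in cfg.combinations:
        summaries[name] = vl.repeated_subset_validation(
            coords, conc, model.surfaces[name],
            n_subset=v.n_subset, reps=v.reps, seed=seeds["subset"],
        )
    table4 = pd.DataFrame({name: s.as_series() for name, s in summaries.items()})

    f_stat, p_value = vl.anova_surfaces(
        [model.surfaces[n] for n in cfg.combinations],
        n_sample=v.anova_n, seed=seeds["anova"],
    )

    kfold = vl.kfold_cv(
        coords, conc, model.fuzzy_stacks[v.kfold_combination],
        k=v.kfold_k, n_train=v.kfold_train, n_test=v.kfold_test,
        seed=seeds["kfold"],
        forest=ForestSettings(n_trees=cfg.rf.n_trees, max_depth=cfg.rf.max_depth),
        combination=v.kfold_combination,
    )
    kfold_df = pd.DataFrame(
        {
            "fold": [r.fold for r in kfold],
            "r2": [r.r2 for r in kfold],
            **{
                f"w{i+1}": [r.weights.weights[i] for r in kfold]
                for i in range(8)
            },
        }
    )

    rng = np.random.default_rng(seeds["scale"])
    n_scale = min(v.scale_max_samples, len(conc))
    sub = rng.choice(len(conc), size=n_scale, replace=False)
    scale_tables = {}
    for name in cfg.combinations:
        scale_tables[name] = vl.scale_test(
            coords[sub], conc[sub], model.surfaces[name],
            n_sites=v.scale_sites, radii_km=tuple(v.scale_radii_km),
            min_samples=v.min_samples, seed=seeds["scale"],
        )

    mean_r2 = {name: s.mean for name, s in summaries.items()}
    summary = {
        "mean_r2": mean_r2,
        "best_combination": max(mean_r2, key=mean_r2.get),
        "anova_f": f_stat,
        "anova_p": p_value,
        "kfold_r2_min": float(kfold_df["r2"].min()),
        "kfold_r2_max": float(kfold_df["r2"].max()),
        "kfold_r2_spread": float(kfold_df["r2"].max() - kfold_df["r2"].min()),
    }
    return {
        "summaries": summaries,
        "table4": table4,
        "anova": (f_stat, p_value),
        "kfold": kfold_df,
        "scale": scale_tables,
        "summary": summary,
    }


# ---------------------------------------------------------------------------
# persistence
# ---------------------------------------------------------------------------


def _points_geojson(df: pd.DataFrame, props: list[str]) -> dict:
    return {
        "type": "FeatureCollection",
        "features": [
            {
                "type": "Feature",
                "geometry": {"type": "Point", "coordinates": [row["x"], row["y"]]},
                "properties": {p: row[p] for p in props},
            }
            for _, row in df.iterrows()
        ],
    }


def save_world(world: World, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    write_raster(world.dem, outdir / "dem.asc")
    write_raster(world.wind_direction, outdir / "wind_truth_direction.asc")
    write_raster(world.wind_speed, outdir / "wind_truth_speed.asc")
    write_raster(world.ndvi, outdir / "ndvi.asc")
    write_raster(world.zones.labels, outdir / "zones_labels.asc")
    mines = pd.DataFrame(
        {
            "id": [m.id for m in world.mines],
            "x": [m.x for m in world.mines],
            "y": [m.y for m in world.mines],
            "area": [m.area for m in world.mines],
        }
    )
    mines.to_csv(outdir / "mines.csv", index=False, float_format="%.17g")
    (outdir / "mines.geojson").write_text(
        json.dumps(_points_geojson(mines, ["id", "area"]))
    )
    world.wells.to_csv(outdir / "wells.csv", index=False, float_format="%.17g")
    (outdir / "wells.geojson").write_text(
        json.dumps(_points_geojson(world.wells, ["hazard_index"]))
    )
    (outdir / "roads.geojson").write_text(
        json.dumps(
            {
                "type": "FeatureCollection",
                "features": [
                    {
                        "type": "Feature",
                        "geometry": {
                            "type": "LineString",
                            "coordinates": [list(c) for c in r.coords],
                        },
                        "properties": {},
                    }
                    for r in world.roads
                ],
            }
        )
    )
    for key, src in world.met_sources.items():
        mt.write_met_csv(src, outdir / f"met_{key}.csv")
    (outdir / "zones.json").write_text(
        json.dumps(
            {
                "centroids": world.zones.centroids.tolist(),
                "mean_boundary_length": world.zones.mean_boundary_length,
            }
        )
    )
    (outdir / "truth.json").write_text(
        json.dumps(
            {
                "true_weights": world.truth.true_weights.tolist(),
                "noise_sd": world.truth.noise_sd,
                "seeds": world.seeds,
            }
        )
    )


def load_world(cfg: RunConfig, outdir: Path) -> World:
    dem = read_raster(outdir / "dem.asc")
    wind_dir = read_raster(outdir / "wind_truth_direction.asc")
    wind_spd = read_raster(outdir / "wind_truth_speed.asc")
    ndvi = read_raster(outdir / "ndvi.asc")
    labels = read_raster(outdir / "zones_labels.asc")
    zmeta = json.loads((outdir / "zones.json").read_text())
    zones = cl.Zones(
        labels=labels,
        centroids=np.array(zmeta["centroids"]),
        mean_boundary_length=zmeta["mean_boundary_length"],
    )
    mines_df = pd.read_csv(outdir / "mines.csv", float_precision="round_trip")
    mines = [
        cl.SourcePoint(id=str(r.id), x=r.x, y=r.y, area=r.area)
        for r in mines_df.itertuples()
    ]
    wells = pd.read_csv(outdir / "wells.csv", float_precision="round_trip")
    gj = json.loads((outdir / "roads.geojson").read_text())
    roads = [shape(f["geometry"]) for f in gj["features"]]
    met_sources = {
        key: mt.read_met_csv(outdir / f"met_{key}.csv", name=key)
        for key in ("metars", "met_stations", "narr")
    }
    tmeta = json.loads((outdir / "truth.json").read_text())
    truth = sw.WorldTruth(
        true_weights=np.array(tmeta["true_weights"]),
        wind_direction=wind_dir,
        wind_speed=wind_spd,
        noise_sd=tmeta["noise_sd"],
    )
    return World(
        grid=dem.grid, dem=dem, mines=mines,
        wind_direction=wind_dir, wind_speed=wind_spd,
        met_sources=met_sources, wells=wells, roads=roads, ndvi=ndvi,
        zones=zones, truth=truth, seeds=tmeta.get("seeds", {}),
    )


def save_layers(layers: LayerStack, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    for i, r in layers.static.items():
        write_raster(r, outdir / f"criteria_{i}.asc")
    for name, met in layers.met_layers.items():
        for i, r in met.items():
            write_raster(r, outdir / f"criteria_{i}_{name.replace('+', '_')}.asc")
    for i, r in layers.truth_met.items():
        write_raster(r, outdir / f"criteria_{i}_truth.asc")


def load_layers(cfg: RunConfig, outdir: Path) -> LayerStack:
    static = {i: read_raster(outdir / f"criteria_{i}.asc") for i in (1, 2, 5, 6, 7, 8)}
    met_layers = {
        name: {
            i: read_raster(outdir / f"criteria_{i}_{name.replace('+', '_')}.asc")
            for i in (3, 4)
        }
        for name in cfg.combinations
    }
    truth_met = {i: read_raster(outdir / f"criteria_{i}_truth.asc") for i in (3, 4)}
    return LayerStack(static=static, met_layers=met_layers, truth_met=truth_met)


def save_model(model: ModelOutputs, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        {
            "x": model.coords[:, 0],
            "y": model.coords[:, 1],
            "concentration": model.concentrations,
        }
    ).to_csv(outdir / "samples.csv", index=False, float_format="%.17g")
    for name, surf in model.surfaces.items():
        safe = name.replace("+", "_")
        write_raster(surf.raster, outdir / f"exposure_{safe}.asc")
        (outdir / f"weights_{safe}.json").write_text(
            json.dumps(
                {"combination": name, "weights": model.weights[name].weights.tolist()}
            )
        )
    write_raster(model.truth_surface.raster, outdir / "exposure_truth.asc")


def load_model(cfg: RunConfig, outdir: Path, layers: LayerStack) -> ModelOutputs:
    samples = pd.read_csv(outdir / "samples.csv", float_precision="round_trip")
    coords = samples[["x", "y"]].to_numpy()
    conc = samples["concentration"].to_numpy()
    fuzzy_truth = _fuzzify_stack(cfg, layers.stack_for(None))
    fuzzy_stacks, weights, surfaces = {}, {}, {}
    for name in cfg.combinations:
        safe = name.replace("+", "_")
        wv = WeightVector(
            np.array(json.loads((outdir / f"weights_{safe}.json").read_text())["weights"])
        )
        weights[name] = wv
        fuzzy_stacks[name] = _fuzzify_stack(cfg, layers.stack_for(name))
        surfaces[name] = ExposureSurface(
            raster=read_raster(outdir / f"exposure_{safe}.asc"),
            combination=name, weights=wv,
        )
    truth_surface = ExposureSurface(
        raster=read_raster(outdir / "exposure_truth.asc"), combination="truth"
    )
    return ModelOutputs(
        coords=coords, concentrations=conc, fuzzy_stacks=fuzzy_stacks,
        fuzzy_truth=fuzzy_truth, weights=weights, surfaces=surfaces,
        truth_surface=truth_surface,
    )


def save_validation(results: dict, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    results["table4"].to_csv(outdir / "table4.csv")
    f_stat, p_value = results["anova"]
    (outdir / "anova.json").write_text(
        json.dumps({"F": f_stat, "p": p_value})
    )
    results["kfold"].to_csv(outdir / "kfold.csv", index=False)
    fold_dir = outdir / "kfold"
    fold_dir.mkdir(exist_ok=True)
    for _, row in results["kfold"].iterrows():
        (fold_dir / f"fold_{int(row['fold'])}.json").write_text(
            json.dumps(
                {
                    "fold": int(row["fold"]),
                    "r2": float(row["r2"]),
                    "weights": [float(row[f"w{i+1}"]) for i in range(8)],
                }
            )
        )
    tidy = []
    for name, df in results["scale"].items():
        d = df.copy()
        d["combination"] = name
        tidy.append(d)
    tidy_df = pd.concat(tidy, ignore_index=True)
    tidy_df.to_csv(outdir / "table5_tidy.csv", index=False)
    wide = tidy_df.pivot(index="radius_km", columns="combination", values="mean_r2")
    sd = tidy_df.pivot(index="radius_km", columns="combination", values="sd_r2")
    cells = wide.round(3).astype(str) + " ± " + sd.round(3).astype(str)
    cells.to_csv(outdir / "table5.csv")
    (outdir / "summary.json").write_text(json.dumps(results["summary"], indent=2))


def run_pipeline(cfg: RunConfig, outdir: str | Path) -> dict:
    """Execute all stages and write every artifact plus a machine-readable
    summary and a log echoing the configuration and derived seeds."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    try:
        world = simulate_world(cfg)
        save_world(world, outdir)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("simulate", str(exc)) from exc
    layers = build_layers(cfg, world)
    save_layers(layers, outdir)
    try:
        model = build_model(cfg, world, layers)
        save_model(model, outdir)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("model", str(exc)) from exc
    try:
        results = run_validation(cfg, world, layers, model)
        save_validation(results, outdir)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("validate", str(exc)) from exc
    log = {"config": cfg.model_dump(), "seeds": derive_seeds(cfg.seed)}
    (outdir / "run_log.json").write_text(json.dumps(log, indent=2))
    return results
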