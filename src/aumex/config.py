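"""Run configuration: a versioned YAML schema for the whole experiment.

Every constant the analysis needs but the underlying study design leaves
open (fuzzy midpoints and spreads, RF hyperparameters, synthetic-world noise
levels, subset sizes) appears here explicitly with its default, so a run is
fully reproducible from (config, seed) alone.
"""

from __future__ import annotations

from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

from .fuzzy import FUZZY_FUNCTIONS, FuzzyParams

__all__ = ["RunConfig", "COMBINATIONS", "load_config"]

# The seven MET data combinations of the comparison experiment: each maps a
# label to the synthetic source arms it fuses (two direct arms emulating
# airport reports and local weather stations, one gridded reanalysis arm).
COMBINATIONS: dict[str, tuple[str, ...]] = {
    "met_stations": ("met_stations",),
    "metars": ("metars",),
    "narr": ("narr",),
    "metars+met_stations": ("metars", "met_stations"),
    "narr+met_stations": ("narr", "met_stations"),
    "narr+metars": ("narr", "metars"),
    "narr+metars+met_stations": ("narr", "metars", "met_stations"),
}


class GridConfig(BaseModel):
    n_rows: int = 128
    n_cols: int = 128
    cell_size: float = 500.0  # m; ~64 km extent, desk-scaled study domain
    origin_x: float = 0.0
    origin_y: float = 64_000.0


class WorldConfig(BaseModel):
    """Synthetic-world generation parameters (the study conditions)."""

    roughness: float = 1.3
    relief: float = 600.0  # m
    n_clusters: int = 5
    mines_per_cluster: int = 12
    cluster_sd: float = 3_000.0  # m
    area_min: float = 2_000.0  # m^2
    area_max: float = 200_000.0  # m^2
    prevailing_deg: float = 225.0  # southwest, blowing-from
    direction_sd: float = 25.0  # deg
    speed_mean: float = 4.0  # m/s
    speed_sd: float = 1.2  # m/s
    correlation_length: float = 20_000.0  # m
    n_metars: int = 13  # airport-like direct stations
    n_met_stations: int = 5  # local weather stations
    grid_spacing: float = 8_000.0  # gridded lattice spacing, scaled from 32 km
    smoothing_radius: float = 10_000.0  # m; reanalysis interpolation smoothing
    direction_bias: float = 15.0  # deg; systematic reanalysis bias
    n_wells: int = 150
    n_roads: int = 6
    n_zones: int = 300
    n_samples: int = 4_000
    noise_sd: float = 0.1
    sample_intercept: float = 1.0
    sample_slope: float = 3.0
    true_weights: list[float] = Field(
        default=[0.22, 0.02, 0.28, 0.06, 0.04, 0.09, 0.16, 0.13]
    )

    @field_validator("true_weights")
    @classmethod
    def _weights_simplex(cls, v: list[float]) -> list[float]:
        if len(v) != 8 or any(w < 0 for w in v) or abs(sum(v) - 1.0) > 1e-9:
            raise ValueError("true_weights must be 8 nonnegative values summing to 1")
        return v

    @property
    def n_direct(self) -> int:
        return self.n_metars + self.n_met_stations


class LayerConfig(BaseModel):
    aum_radius: float = 50_000.0  # m
    tpi_radius: float = 2_000.0  # m
    idw_power: float = 2.0
    snap_threshold: float | None = None  # None = mean zone boundary length
    k_replace: int = 4  # gridded points displaced per direct station
    n_sectors: int = 16
    beta_w: float = 0.0  # wind inclination above horizontal, deg
    downwind_peak: bool = True  # wind-index phase convention


class FuzzyLayerConfig(BaseModel):
    function: str
    midpoint: float | None = None
    spread: float = 5.0
    a: float = 1.0
    b: float = 1.0

    @field_validator("function")
    @classmethod
    def _known(cls, v: str) -> str:
        if v not in FUZZY_FUNCTIONS:
            raise ValueError(f"unknown fuzzy function {v!r}")
        return v

    def to_params(self) -> FuzzyParams:
        return FuzzyParams(self.function, self.midpoint, self.spread, self.a, self.b)


def _default_fuzzy() -> dict[int, FuzzyLayerConfig]:
    return {
        1: FuzzyLayerConfig(function="MSLarge"),
        2: FuzzyLayerConfig(function="Small"),
        3: FuzzyLayerConfig(function="Large"),
        4: FuzzyLayerConfig(function="MSLarge"),
        5: FuzzyLayerConfig(function="Small"),
        6: FuzzyLayerConfig(function="MSSmall"),
        7: FuzzyLayerConfig(function="Large"),
        8: FuzzyLayerConfig(function="Small"),
    }


class RFConfig(BaseModel):
    n_trees: int = 500
    n_train: int = 750
    max_depth: int | None = None


class ValidationConfig(BaseModel):
    n_subset: int = 1_000
    reps: int = 99
    kfold_k: int = 10
    kfold_train: int = 750
    kfold_test: int = 350
    kfold_combination: str = "metars+met_stations"
    anova_n: int = 500
    scale_sites: int = 33
    scale_max_samples: int = 1_200
    scale_radii_km: list[float] = Field(
        default=[25.0, 50.0, 75.0, 100.0, 125.0, 150.0, 175.0]
    )
    min_samples: int = 30


class RunConfig(BaseModel):
    schema_version: int = 1
    seed: int = 42
    grid: GridConfig = Field(default_factory=GridConfig)
    world: WorldConfig = Field(default_factory=WorldConfig)
    layers: LayerConfig = Field(default_factory=LayerConfig)
    fuzzy: dict[int, FuzzyLayerConfig] = Field(default_factory=_default_fuzzy)
    combinations: list[str] = Field(default_factory=lambda: list(COMBINATIONS))
    rf: RFConfig = Field(default_factory=RFConfig)
    validation: ValidationConfig = Field(default_factory=ValidationConfig)

    @model_validator(mode="after")
    def _check(self) -> "RunConfig":
        missing = set(range(1, 9)) - set(self.fuzzy)
        if missing:
            raise ValueError(f"fuzzy assignment missing for layers {sorted(missing)}")
        unknown = [c for c in self.combinations if c not in COMBINATIONS]
        if unknown:
            raise ValueError(f"unknown MET combinations {unknown}")
        if self.validation.kfold_combination not in COMBINATIONS:
            raise ValueError("kfold_combination must be a known MET combination")
        return self

    def fuzzy_params(self) -> dict[int, FuzzyParams]:
        return {k: v.to_params() for k, v in self.fuzzy.items()}

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.model_dump(), sort_keys=False))


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML run configuration, or the defaults when no path is given."""
    data = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
    data.update(overrides)
    return RunConfig(**data)
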