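"""Seeded synthetic county x year yield panels.

The generator emulates the statistical structure of a multi-state corn-yield
panel so the whole forecasting stack can be exercised without external data:

* a per-location linear technology trend in yield (slope drawn uniformly from
  a configurable kg/ha/yr range, mirroring the 32-189 kg/ha/yr spread seen in
  US Corn Belt counties),
* weekly weather blocks (seasonal sinusoid per variable + location offset +
  iid weekly noise), tagged with week-of-year,
* static soil columns and management columns (weekly cumulative planting
  progress, a static plant population),
* optional redundant feature pairs (affine copies with small jitter,
  |r| > 0.95 by construction) to exercise the correlation filter,
* a configurable additive linear effect of named features on the response.

Randomness is hierarchical: one global seed spawns one substream per location
(plus one for cross-location draws), so enlarging ``n_locations`` never
perturbs the rows of existing locations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .panel import INDEX_COLUMNS, FeatureInfo, PanelDataset

#: the seven weekly weather variables of a Daymet-style feed
WEATHER_VARIABLES = ("tmin", "tmax", "prcp", "srad", "vp", "swe", "dayl")


@dataclass
class SyntheticConfig:
    """Parameters of one synthetic panel draw.

    Defaults describe a desk-scale Corn Belt-like panel: 19 years of data,
    weekly weather for weeks 14-44, nine soil properties, planting progress
    over weeks 14-25 and a per-location yield trend between 32 and
    189 kg/ha/yr.
    """

    n_locations: int = 50
    year_start: int = 2000
    year_end: int = 2018
    trend_slope_range: tuple[float, float] = (32.0, 189.0)
    base_yield: float = 8000.0
    weather_weeks: tuple[int, int] = (14, 44)
    n_weather_vars: int = 7
    n_soil_features: int = 9
    planting_weeks: tuple[int, int] = (14, 25)
    noise_sd: float = 600.0
    n_redundant_pairs: int = 0
    effect_spec: Mapping[str, float] = field(default_factory=dict)
    n_states: int = 3
    districts_per_state: int = 3
    harvested_area_range: tuple[float, float] = (2_000.0, 120_000.0)
    include_plant_population: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.year_end <= self.year_start:
            raise ValueError("year_end must exceed year_start")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")
        lo, hi = self.trend_slope_range
        if lo > hi:
            raise ValueError("trend_slope_range low must not exceed high")
        if self.n_locations < 1:
            raise ValueError("need at least one location")
        if not 1 <= self.n_weather_vars <= len(WEATHER_VARIABLES):
            raise ValueError(
                f"n_weather_vars must be in [1, {len(WEATHER_VARIABLES)}]"
            )
        if self.weather_weeks[0] > self.weather_weeks[1]:
            raise ValueError("weather_weeks range is empty")


def _feature_layout(config: SyntheticConfig) -> dict[str, FeatureInfo]:
    """Canonical feature order: weather blocks, soil, management."""
    meta: dict[str, FeatureInfo] = {}
    lo, hi = config.weather_weeks
    for var in WEATHER_VARIABLES[: config.n_weather_vars]:
        for week in range(lo, hi + 1):
            meta[f"{var}_w{week:02d}"] = FeatureInfo("weather", week)
    for i in range(config.n_soil_features):
        meta[f"soil_{i:02d}"] = FeatureInfo("soil")
    for week in range(config.planting_weeks[0], config.planting_weeks[1] + 1):
        meta[f"planting_progress_w{week:02d}"] = FeatureInfo("management", week)
    if config.include_plant_population:
        meta["plant_population"] = FeatureInfo("management")
    return meta


def generate_panel(config: SyntheticConfig) -> PanelDataset:
    """Draw one panel; byte-identical for identical config (incl. seed)."""
    meta = _feature_layout(config)
    base_features = list(meta)

    root = np.random.SeedSequence(config.seed)
    global_ss, *loc_ss = root.spawn(config.n_locations + 1)
    grng = np.random.default_rng(global_ss)

    weeks = np.arange(config.weather_weeks[0], config.weather_weeks[1] + 1)
    n_weeks = len(weeks)
    wvars = WEATHER_VARIABLES[: config.n_weather_vars]
    # cross-location weather climatology: one (mean, amplitude, phase) per var
    clim_mean = grng.uniform(5.0, 25.0, size=len(wvars))
    clim_amp = grng.uniform(3.0, 12.0, size=len(wvars))
    clim_phase = grng.uniform(0.0, 52.0, size=len(wvars))

    # redundant pairs: affine copies of globally chosen base features
    if config.n_redundant_pairs > len(base_features):
        raise ValueError("more redundant pairs than features")
    dup_sources = list(
        grng.choice(base_features, size=config.n_redundant_pairs, replace=False)
    )
    dup_scale = grng.uniform(0.5, 2.0, size=config.n_redundant_pairs)
    dup_shift = grng.uniform(-5.0, 5.0, size=config.n_redundant_pairs)
    for src in dup_sources:
        meta[f"{src}__dup"] = meta[src]

    unknown = [f for f in config.effect_spec if f not in meta]
    if unknown:
        raise ValueError(
            f"effect_spec names features that are not generated: {unknown}"
        )

    years = np.arange(config.year_start, config.year_end + 1)
    n_years = len(years)
    blocks: list[pd.DataFrame] = []
    for i in range(config.n_locations):
        rng = np.random.default_rng(loc_ss[i])
        slope = rng.uniform(*config.trend_slope_range)
        area = np.exp(
            rng.uniform(
                np.log(config.harvested_area_range[0]),
                np.log(config.harvested_area_range[1]),
            )
        )
        weather_offset = rng.normal(0.0, 2.0, size=len(wvars))
        soil = rng.normal(0.0, 1.0, size=config.n_soil_features)

        cols: dict[str, np.ndarray] = {}
        for v, var in enumerate(wvars):
            seasonal = clim_mean[v] + clim_amp[v] * np.sin(
                2 * np.pi * (weeks - clim_phase[v]) / 52.0
            )
            vals = (
                seasonal[None, :]
                + weather_offset[v]
                + rng.normal(0.0, 1.5, size=(n_years, n_weeks))
            )
            for w, week in enumerate(weeks):
                cols[f"{var}_w{week:02d}"] = vals[:, w]
        for s in range(config.n_soil_features):
            cols[f"soil_{s:02d}"] = np.full(n_years, soil[s])
        # logistic cumulative planting progress, midpoint varies by year
        mid = rng.normal(19.0, 1.5, size=n_years)
        for week in range(config.planting_weeks[0], config.planting_weeks[1] + 1):
            cols[f"planting_progress_w{week:02d}"] = 100.0 / (
                1.0 + np.exp(-(week - mid) / 1.2)
            )
        if config.include_plant_population:
            cols["plant_population"] = rng.normal(79_000.0, 4_000.0, size=n_years)

        response = (
            config.base_yield
            + slope * (years - config.year_start)
            + rng.normal(0.0, config.noise_sd, size=n_years)
        )
        for feat, coef in config.effect_spec.items():
            if feat.endswith("__dup"):
                continue  # duplicates are copies; effects act through sources
            response = response + coef * cols[feat]

        # duplicates drawn from the location stream so adding a location
        # never perturbs another location's jitter
        for p, src in enumerate(dup_sources):
            jitter_sd = 0.01 * max(np.std(cols[src]), 1e-6)
            cols[f"{src}__dup"] = (
                dup_scale[p] * cols[src]
                + dup_shift[p]
                + rng.normal(0.0, jitter_sd, size=n_years)
            )

        # modulo assignment keeps labels stable when locations are added;
        # district index d satisfies d = i mod S*D, hence state(d) = d mod S
        state = f"S{i % config.n_states}"
        district = f"D{i % (config.n_states * config.districts_per_state)}"
        block = pd.DataFrame(
            {
                "location_id": f"L{i:04d}",
                "year": years,
                "state": state,
                "district": district,
                "response": response,
                "harvested_area": area,
                **cols,
            }
        )
        blocks.append(block)

    frame = pd.concat(blocks, ignore_index=True)[list(INDEX_COLUMNS) + list(meta)]
    # effects through duplicated source columns apply once, on the source;
    # effects named on a dup column are applied here (dup values now exist)
    for feat, coef in config.effect_spec.items():
        if feat.endswith("__dup"):
            frame["response"] = frame["response"] + coef * frame[feat]
    return PanelDataset(frame, meta)
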