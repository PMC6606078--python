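"""End-to-end pipeline: inputs -> score -> cost -> catchments -> referral
-> scenario reports.

The stage order mirrors how these analyses are run in practice: score
and classify the roster, build the single cost raster, delineate the
prioritised catchments (journey segment 1), route referrals (segment
2), then repeat the overlay for each improvement scenario and
summarise population-weighted access.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io
from .catchments import CatchmentRule, DEFAULT_RULES, delineate, facility_travel_times
from .cost import SpeedConfig, build_cost_surface
from .facilities import FacilityRecord, score_roster
from .referral import build_referral_table, build_road_graph
from .scenarios import AccessReport, ScenarioSpec, apply_scenario, summarise
from .synthetic import (
    LandscapeBundle,
    SyntheticConfig,
    generate_facilities,
    generate_landscape,
)

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Everything one run needs; synthetic inputs by default."""

    synthetic: SyntheticConfig = field(default_factory=SyntheticConfig)
    speeds: SpeedConfig = field(default_factory=SpeedConfig)
    rules: CatchmentRule = field(default_factory=lambda: DEFAULT_RULES)
    models: tuple[int, ...] = (0, 1, 2, 3)
    upgrades: int = 2
    band_minutes: float = 60.0
    out_dir: Path | None = None


def run_pipeline(config: PipelineConfig,
                 landscape: LandscapeBundle | None = None,
                 facilities: list[FacilityRecord] | None = None
                 ) -> dict[int, AccessReport]:
    """Run every configured model and return one report per model.

    Deterministic for a fixed config (the only randomness is the
    synthetic generator's seeded stream). When ``out_dir`` is set, the
    inputs and per-model reports are written there.
    """
    if landscape is None:
        landscape = generate_landscape(config.synthetic)
    if facilities is None:
        facilities = generate_facilities(config.synthetic, landscape)
    facilities = score_roster(facilities)

    cost = build_cost_surface(landscape, config.speeds)
    graph = build_road_graph(landscape.roads, config.speeds) \
        if landscape.roads else None
    if graph is None:
        raise ValueError("cannot run the referral stage without roads")
    population = landscape.population
    travel_maps = facility_travel_times(facilities, cost)

    reports: dict[int, AccessReport] = {}
    for model in config.models:
        spec = ScenarioSpec(model=model,
                            upgrades=config.upgrades if model in (1, 3) else 0)
        roster = apply_scenario(facilities, spec, cost, population,
                                travel_maps=travel_maps)
        assignment = delineate(roster, cost, config.rules,
                               travel_maps=travel_maps)
        referrals = build_referral_table(roster, graph)
        reports[model] = summarise(model, roster, assignment, referrals,
                                   population, config.band_minutes)
        logger.info("model %d: %.1f%% of population outside the models",
                    model,
                    100 * reports[model].population_outside
                    / max(reports[model].population_total, 1e-9))

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        io.write_ascii_grid(out / "landcover.asc",
                            landscape.landcover.astype(float), landscape.grid)
        io.write_ascii_grid(out / "dem.asc", landscape.dem, landscape.grid)
        io.write_ascii_grid(out / "population.asc", landscape.population,
                            landscape.grid)
        io.write_ascii_grid(out / "cost_minutes.asc", cost.cost, landscape.grid)
        io.write_roads_geojson(landscape.roads, out / "roads.geojson")
        io.write_facilities_csv(facilities, out / "facilities.csv")
        io.write_facilities_geojson(facilities, out / "facilities.geojson")
        for model, report in reports.items():
            io.write_report(report, out / f"report_model{model}.csv")
    return reports
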