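"""Improvement scenarios (Models 0-3) and population-weighted access.

* **Model 0** — status quo.
* **Model 1** — upgrade *k* geographically strategic level-4 facilities
  to level 5 (greedy population-coverage selection among high-scoring
  candidates).
* **Model 2** — place a vehicle and a communication mode at every
  facility lacking one. This zeroes the referral adjustments and, via
  the transport criterion, promotes score-0-9 facilities to level 3;
  the readiness score itself is frozen at its baseline value (the
  intervention delivers referral infrastructure, not clinical
  readiness).
* **Model 3** — both combined.

Access statistics are weighted by cell population: transfer-time
(segment 2) summaries cover only the subpopulation whose first
preferred facility needs onward referral, while total-journey
summaries cover the whole modelled (non-OUTSIDE) population.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .catchments import (
    OUTSIDE,
    CatchmentAssignment,
    CatchmentRule,
    DEFAULT_RULES,
    band_population,
    delineate,
    facility_travel_times,
)
from .cost import CostSurface
from .facilities import FacilityRecord, classify_level
from .referral import build_referral_table

LEVEL5_PRIMARY_BOUND_MIN = 120.0  # 2 h, the clinically critical mark


@dataclass(frozen=True)
class ScenarioSpec:
    """Which improvements to apply."""

    model: int  # 0..3
    upgrades: int = 0  # k, used by models 1 and 3

    def __post_init__(self) -> None:
        if self.model not in (0, 1, 2, 3):
            raise ValueError(f"model must be 0..3, got {self.model}")
        if self.model in (1, 3) and self.upgrades < 1:
            raise ValueError("models 1 and 3 need upgrades >= 1")


def select_upgrades(candidates: list[FacilityRecord], k: int,
                    cost: CostSurface, population: np.ndarray,
                    existing_level5s: list[FacilityRecord],
                    bound_min: float = LEVEL5_PRIMARY_BOUND_MIN,
                    candidate_maps: np.ndarray | None = None,
                    existing_maps: np.ndarray | None = None) -> list[str]:
    """Greedy choice of k level-4 facilities to upgrade.

    Each round picks the candidate bringing the most population newly
    within the level-5 primary bound; ties break by higher readiness
    score, then lower facility id. Deterministic.
    """
    if not candidates:
        raise ValueError("no upgrade candidates")
    if k > len(candidates):
        raise ValueError(f"requested {k} upgrades but only "
                         f"{len(candidates)} candidates")
    if candidate_maps is None:
        candidate_maps = facility_travel_times(candidates, cost)
    if existing_maps is None and existing_level5s:
        existing_maps = facility_travel_times(existing_level5s, cost)

    covered = np.zeros(cost.grid.shape, dtype=bool)
    if existing_maps is not None and len(existing_maps):
        covered = (existing_maps < bound_min).any(axis=0)
    masks = candidate_maps < bound_min

    chosen: list[str] = []
    remaining = list(range(len(candidates)))
    for _ in range(k):
        best = None
        for i in remaining:
            gain = float(population[masks[i] & ~covered].sum())
            key = (-gain, -(candidates[i].readiness_score or 0), candidates[i].id)
            if best is None or key < best[0]:
                best = (key, i)
        _, pick = best
        chosen.append(candidates[pick].id)
        covered |= masks[pick]
        remaining.remove(pick)
    return chosen


def apply_scenario(facilities: list[FacilityRecord], spec: ScenarioSpec,
                   cost: CostSurface | None = None,
                   population: np.ndarray | None = None,
                   travel_maps: np.ndarray | None = None
                   ) -> list[FacilityRecord]:
    """Return the modified roster for one scenario (input untouched)."""
    roster = [replace(f) for f in facilities]
    if spec.model in (1, 3):
        if cost is None or population is None:
            raise ValueError("models 1 and 3 need the cost surface and "
                             "population raster to select upgrades")
        candidates = [f for f in roster if f.level == 4]
        level5s = [f for f in roster if f.level == 5]
        by_id = {f.id: i for i, f in enumerate(facilities)}
        cand_maps = (travel_maps[[by_id[f.id] for f in candidates]]
                     if travel_maps is not None else None)
        l5_maps = (travel_maps[[by_id[f.id] for f in level5s]]
                   if travel_maps is not None else None)
        upgraded = set(select_upgrades(candidates, spec.upgrades, cost,
                                       population, level5s,
                                       candidate_maps=cand_maps,
                                       existing_maps=l5_maps))
        for f in roster:
            if f.id in upgraded:
                f.level = 5
                f.caesarean_last_3_months = True
    if spec.model in (2, 3):
        for f in roster:
            f.has_transport = True
            f.has_communication = True
            # Reclassify from the frozen baseline score: new transport
            # can promote a facility to level 3, but scenario upgrades
            # to level 5 (model 3) are kept.
            if f.level != 5:
                f.level = classify_level(f.readiness_score,
                                         f.caesarean_last_3_months, True)
    return roster


def total_journey(assignment: CatchmentAssignment,
                  referrals: pd.DataFrame) -> np.ndarray:
    """Per-cell total minutes (segment 1 + adjusted segment 2).

    Cells outside every catchment are NaN; cells whose facility is cut
    off from the road network are +inf.
    """
    total = np.full(assignment.facility_index.shape, np.nan)
    for i, fid in enumerate(assignment.facility_ids):
        sel = assignment.facility_index == i
        if not sel.any():
            continue
        if fid not in referrals.index:
            raise KeyError(f"facility {fid!r} missing from the referral table")
        row = referrals.loc[fid]
        seg2 = 0.0 if assignment.facility_levels[i] == 5 else row["adjusted_min"]
        if bool(row["unreachable"]):
            seg2 = np.inf
        total[sel] = assignment.minutes[sel] + seg2
    return total


@dataclass(frozen=True)
class WeightedStats:
    mean: float
    sd: float
    p95: float
    max: float


def weighted_quantile(values: np.ndarray, weights: np.ndarray,
                      q: float) -> float:
    """Quantile of the weight-expanded sample, linearly interpolated.

    For integer weights this equals ``np.percentile`` (linear method)
    of the sample with each value repeated ``weight`` times; fractional
    weights extend the same cumulative-weight interpolation.
    """
    order = np.argsort(values, kind="stable")
    v = values[order]
    w = weights[order]
    cum = np.cumsum(w)
    total = cum[-1]
    h = q * (total - 1)  # position in the expanded, 0-based sample
    # index of the expanded element at positions floor(h) and floor(h)+1
    lo = v[np.searchsorted(cum, np.floor(h), side="right")]
    hi = v[np.searchsorted(cum, np.floor(h) + 1, side="right")] \
        if np.floor(h) + 1 <= total - 1 else v[-1]
    frac = h - np.floor(h)
    return float(lo + (hi - lo) * frac)


def weighted_stats(values: np.ndarray, weights: np.ndarray) -> WeightedStats:
    """Population-weighted mean, SD, 95th percentile and max.

    The SD is the population (weight-expansion) definition, with no
    small-sample correction; the maximum is over cells with positive
    weight.
    """
    values = np.asarray(values, dtype=float).ravel()
    weights = np.asarray(weights, dtype=float).ravel()
    if values.shape != weights.shape:
        raise ValueError("values and weights must have the same shape")
    if np.any(weights < 0):
        raise ValueError("weights must be >= 0")
    pos = weights > 0
    if not pos.any():
        raise ValueError("at least one weight must be positive")
    v, w = values[pos], weights[pos]
    total = w.sum()
    mean = float((v * w).sum() / total)
    sd = float(np.sqrt((w * (v - mean) ** 2).sum() / total))
    p95 = weighted_quantile(v, w, 0.95)
    return WeightedStats(mean=mean, sd=sd, p95=p95, max=float(v.max()))


@dataclass
class AccessReport:
    """All per-scenario outputs: band table and weighted summaries."""

    model: int
    band_table: pd.DataFrame
    segment2: WeightedStats | None
    total: WeightedStats | None
    population_total: float
    population_outside: float
    population_needing_transfer: float
    population_unreachable: float

    def two_hour_summary(self) -> pd.Series:
        """Population able to reach each level within 2 h (segment 1)."""
        bands = [c for c in self.band_table.columns
                 if float(c.split("-")[0]) < 2.0]
        reach = self.band_table.loc[[5, 4, 3, 2, 1], bands].sum(axis=1)
        covered = self.band_table.loc[[5, 4, 3, 2, 1]].sum().sum()
        reach["beyond_2h"] = covered - reach.sum()
        reach["OUTSIDE"] = self.band_table.loc["OUTSIDE"].sum()
        return reach


def run_scenario(facilities: list[FacilityRecord], spec: ScenarioSpec,
                 cost: CostSurface, population: np.ndarray,
                 road_graph, rules: CatchmentRule = DEFAULT_RULES,
                 band_minutes: float = 60.0) -> AccessReport:
    """Apply one scenario end to end and summarise access."""
    base_maps = facility_travel_times(facilities, cost)
    roster = apply_scenario(facilities, spec, cost, population,
                            travel_maps=base_maps)
    assignment = delineate(roster, cost, rules, travel_maps=base_maps)
    referrals = build_referral_table(roster, road_graph)
    return summarise(spec.model, roster, assignment, referrals, population,
                     band_minutes)


def summarise(model: int, roster: list[FacilityRecord],
              assignment: CatchmentAssignment, referrals: pd.DataFrame,
              population: np.ndarray,
              band_minutes: float = 60.0) -> AccessReport:
    table = band_population(assignment, population, band_minutes)
    total_min = total_journey(assignment, referrals)

    covered = assignment.covered
    levels = assignment.assigned_level()
    needs_transfer = covered & (levels < 5) & (levels > 0)
    reachable = np.isfinite(total_min)
    unreachable_pop = float(population[needs_transfer & ~reachable].sum())

    seg2_vals, seg2_w = [], []
    for i, fid in enumerate(assignment.facility_ids):
        if assignment.facility_levels[i] == 5:
            continue
        sel = (assignment.facility_index == i) & reachable
        p = float(population[sel].sum())
        if p > 0:
            seg2_vals.append(float(referrals.loc[fid, "adjusted_min"]))
            seg2_w.append(p)
    seg2 = weighted_stats(np.array(seg2_vals), np.array(seg2_w)) \
        if seg2_w and sum(seg2_w) > 0 else None

    tot_sel = covered & reachable & (population > 0)
    tot = weighted_stats(total_min[tot_sel], population[tot_sel]) \
        if tot_sel.any() else None

    return AccessReport(
        model=model,
        band_table=table,
        segment2=seg2,
        total=tot,
        population_total=float(population.sum()),
        population_outside=float(population[~covered].sum()),
        population_needing_transfer=float(population[needs_transfer].sum()),
        population_unreachable=unreachable_pop,
    )


def expected_pregnancies(population: float, crude_birth_rate: float = 0.039,
                         severe_complication_rate: float = 0.15
                         ) -> tuple[float, float]:
    """(expected pregnancies, expected severe complications) for a
    population, via a crude-birth-rate multiplier and the assumption
    that 15% of pregnancies develop severe complications."""
    pregnancies = population * crude_birth_rate
    return pregnancies, pregnancies * severe_complication_rate
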