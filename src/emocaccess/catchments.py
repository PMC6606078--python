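"""Prioritised time-bound catchments modelling patient bypassing.

Each facility level carries a primary and (except level 1, which has
only a secondary) a secondary time-bound catchment, and each of the
nine (level, zone) classes has a priority rank. Where catchments
overlap, a cell keeps only the highest-priority (lowest-rank) one —
encoding the observation that a woman within reach of both a mid-level
facility and a surgical facility will often bypass the nearer one.

Default bounds and ranks:

====== ================= ==================
Level  Primary           Secondary
====== ================= ==================
5      0-2 h (rank 1)    2-5 h (rank 5)
4      0-2 h (rank 2)    2-5 h (rank 6)
3      0-1 h (rank 3)    1-3 h (rank 7)
2      0-1 h (rank 4)    1-3 h (rank 8)
1      —                 0-1 h (rank 9)
====== ================= ==================

Interval bounds are half-open [lower, upper) in hours: a cell at
exactly 2.0 h of a level 5 falls in its secondary zone.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cost import CostSurface, travel_time_map
from .facilities import FacilityRecord

OUTSIDE = -1  #: sentinel facility index for cells in no catchment


@dataclass(frozen=True)
class CatchmentClass:
    """One (level, zone) class: hour bounds and priority rank."""

    level: int
    zone: str  # "primary" | "secondary"
    lower_h: float
    upper_h: float
    rank: int


def _default_classes() -> tuple[CatchmentClass, ...]:
    return (
        CatchmentClass(5, "primary", 0.0, 2.0, 1),
        CatchmentClass(4, "primary", 0.0, 2.0, 2),
        CatchmentClass(3, "primary", 0.0, 1.0, 3),
        CatchmentClass(2, "primary", 0.0, 1.0, 4),
        CatchmentClass(5, "secondary", 2.0, 5.0, 5),
        CatchmentClass(4, "secondary", 2.0, 5.0, 6),
        CatchmentClass(3, "secondary", 1.0, 3.0, 7),
        CatchmentClass(2, "secondary", 1.0, 3.0, 8),
        CatchmentClass(1, "secondary", 0.0, 1.0, 9),
    )


@dataclass
class CatchmentRule:
    """The full nine-class bound/priority table."""

    classes: tuple[CatchmentClass, ...] = field(default_factory=_default_classes)

    def __post_init__(self) -> None:
        ranks = sorted(c.rank for c in self.classes)
        if ranks != list(range(1, len(self.classes) + 1)):
            raise ValueError("ranks must be a permutation of 1..n")
        if any(c.lower_h >= c.upper_h for c in self.classes):
            raise ValueError("each class needs lower bound < upper bound")
        for level in {c.level for c in self.classes}:
            prim = [c for c in self.classes if c.level == level
                    and c.zone == "primary"]
            sec = [c for c in self.classes if c.level == level
                   and c.zone == "secondary"]
            if prim and sec and prim[0].upper_h > sec[0].upper_h:
                raise ValueError(f"level {level}: primary bound exceeds secondary")

    def for_level(self, level: int) -> list[CatchmentClass]:
        return [c for c in self.classes if c.level == level]

    @property
    def max_bound_h(self) -> float:
        return max(c.upper_h for c in self.classes)


DEFAULT_RULES = CatchmentRule()


@dataclass
class CatchmentAssignment:
    """Per-cell first-preferred facility after priority overlay."""

    facility_ids: list[str]
    facility_levels: list[int]
    facility_index: np.ndarray  # int, OUTSIDE where uncovered
    rank: np.ndarray  # int, 0 where uncovered
    minutes: np.ndarray  # segment-1 travel time; inf where uncovered
    grid: object

    @property
    def covered(self) -> np.ndarray:
        return self.facility_index != OUTSIDE

    def assigned_level(self) -> np.ndarray:
        """Per-cell level of the first preferred facility (0 outside)."""
        levels = np.zeros(self.facility_index.shape, dtype=np.int8)
        for i, lvl in enumerate(self.facility_levels):
            levels[self.facility_index == i] = lvl
        return levels


def facility_travel_times(facilities: list[FacilityRecord],
                          cost: CostSurface) -> np.ndarray:
    """Stack of per-facility travel-time maps, shape (n_fac, rows, cols)."""
    bad = [f.id for f in facilities if not cost.grid.contains(f.x, f.y)]
    if bad:
        raise ValueError(f"facilities outside the grid: {bad}")
    maps = np.empty((len(facilities),) + cost.grid.shape)
    for i, f in enumerate(facilities):
        maps[i] = travel_time_map(cost, [cost.grid.cell_of(f.x, f.y)])
    return maps


def delineate(facilities: list[FacilityRecord], cost: CostSurface,
              rules: CatchmentRule = DEFAULT_RULES,
              travel_maps: np.ndarray | None = None) -> CatchmentAssignment:
    """Overlay all (facility, class) catchments, keeping the best rank.

    Ties on rank break by smaller segment-1 time, then smaller facility
    index (roster order). ``travel_maps`` may carry precomputed
    per-facility travel times to avoid recomputation across scenarios.
    """
    if any(f.level is None for f in facilities):
        raise ValueError("facilities must be classified before delineation")
    if travel_maps is None:
        travel_maps = facility_travel_times(facilities, cost)

    shape = cost.grid.shape
    best_rank = np.full(shape, np.iinfo(np.int32).max, dtype=np.int32)
    best_idx = np.full(shape, OUTSIDE, dtype=np.int32)
    best_time = np.full(shape, np.inf)

    for i, fac in enumerate(facilities):
        tt = travel_maps[i]
        for cls in rules.for_level(fac.level):
            lo, hi = cls.lower_h * 60.0, cls.upper_h * 60.0
            mask = (tt >= lo) & (tt < hi)
            better = mask & (
                (cls.rank < best_rank)
                | ((cls.rank == best_rank) & (tt < best_time))
            )
            best_rank[better] = cls.rank
            best_idx[better] = i
            best_time[better] = tt[better]

    uncovered = best_idx == OUTSIDE
    best_rank[uncovered] = 0
    best_time[uncovered] = np.inf
    return CatchmentAssignment(
        facility_ids=[f.id for f in facilities],
        facility_levels=[int(f.level) for f in facilities],
        facility_index=best_idx,
        rank=best_rank,
        minutes=best_time,
        grid=cost.grid,
    )


def band_population(assignment: CatchmentAssignment, population: np.ndarray,
                    band_minutes: float = 60.0) -> pd.DataFrame:
    """Population by (first-preferred level, hourly band) plus OUTSIDE.

    Rows are levels 5..1 and 'OUTSIDE'; columns are half-open time
    bands of ``band_minutes``. Sums conserve the raster total exactly.
    """
    if population.shape != assignment.facility_index.shape:
        raise ValueError("population grid does not match the assignment grid")
    levels = assignment.assigned_level()
    minutes = assignment.minutes
    covered = assignment.covered
    max_min = minutes[covered].max() if covered.any() else 0.0
    n_bands = max(1, int(np.ceil(max_min / band_minutes)) if max_min > 0 else 1)
    if covered.any() and max_min > 0 and max_min % band_minutes == 0:
        n_bands += 1  # a cell exactly on the last edge opens a new band

    cols = [f"{i * band_minutes / 60:g}-{(i + 1) * band_minutes / 60:g}h"
            for i in range(n_bands)]
    table = pd.DataFrame(0.0, index=[5, 4, 3, 2, 1, "OUTSIDE"], columns=cols)
    band_of = np.floor_divide(minutes, band_minutes, where=covered,
                              out=np.zeros_like(minutes)).astype(int)
    for lvl in (5, 4, 3, 2, 1):
        sel = covered & (levels == lvl)
        if not sel.any():
            continue
        sums = np.bincount(band_of[sel], weights=population[sel],
                           minlength=n_bands)
        table.loc[lvl, :] = sums[:n_bands]
    table.loc["OUTSIDE", cols[0]] = population[~covered].sum()
    return table
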