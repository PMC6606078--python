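"""Seeded synthetic landscapes for exercising the access pipeline.

Real inputs to this kind of analysis — a national facility census, a
land-cover raster, a digital elevation model, an OpenStreetMap road
network and a gridded population surface — are large and not generally
redistributable. This module fabricates small stand-ins with the
statistical structure the analysis assumes:

* a categorical land-cover surface (including a river of water cells),
* a smooth DEM,
* a sparse road network (spanning tree over settlements plus a few
  extra edges), with bridge flags where roads cross water,
* a clustered population raster (Gaussian kernels around settlements
  with log-normally distributed settlement sizes), and
* a facility roster whose attribute marginals echo a national
  emergency-obstetric-care assessment: a handful of fully capable
  hospitals, a large middle tier of health centres, and a tail of
  minimally equipped posts.

Every draw comes from a single numpy Generator seeded from the config,
so regeneration with the same config is bit-identical.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.sparse.csgraph import minimum_spanning_tree
from skimage.draw import line as _raster_line

from .facilities import (
    N_SIGNAL_FUNCTIONS,
    FacilityRecord,
    classify_level,
    score_roster,
)
from .grid import GridSpec

# Land-cover class codes.
WATER = 0
GRASSLAND = 1
FOREST = 2
CROPLAND = 3
BARE = 4
WETLAND = 5

LANDCOVER_CLASSES: dict[int, str] = {
    WATER: "water",
    GRASSLAND: "grassland",
    FOREST: "forest",
    CROPLAND: "cropland",
    BARE: "bare",
    WETLAND: "wetland",
}

ROAD_CLASSES: tuple[str, ...] = ("primary", "secondary", "tertiary")


@dataclass(frozen=True)
class RoadSegment:
    """A straight polyline segment with a class label and bridge flag."""

    start: tuple[float, float]
    end: tuple[float, float]
    road_class: str
    bridge: bool = False


@dataclass
class LandscapeBundle:
    """Co-registered synthetic input layers on one grid."""

    grid: GridSpec
    landcover: np.ndarray  # int codes, see LANDCOVER_CLASSES
    dem: np.ndarray  # metres
    population: np.ndarray  # persons per cell, >= 0
    roads: list[RoadSegment]
    settlements: list[tuple[float, float]] = field(default_factory=list)

    def __post_init__(self) -> None:
        for name in ("landcover", "dem", "population"):
            arr = getattr(self, name)
            if arr.shape != self.grid.shape:
                raise ValueError(f"{name} shape {arr.shape} != grid {self.grid.shape}")
        if not np.all(np.isfinite(self.population)) or np.any(self.population < 0):
            raise ValueError("population must be finite and non-negative")


@dataclass
class SyntheticConfig:
    """Knobs for the generator; defaults define the study conditions.

    The default roster (28 facilities) keeps the per-level mix of the
    kind of national census this emulates — few surgical hospitals,
    many mid-level health centres — at desk scale. Vehicle presence at
    levels 4-5 and communication everywhere are Bernoulli with the
    census-like marginals; levels 1-3 have transport pinned by the
    classification rules themselves.
    """

    seed: int = 0
    rows: int = 150
    cols: int = 150
    cell_size: float = 500.0  # metres (a 75 km x 75 km study window)
    n_settlements: int = 20
    n_isolated_settlements: int = 0  # settlements left off the road network
    extra_road_edges: int = 2
    facilities_per_level: dict[int, int] = field(
        default_factory=lambda: {5: 2, 4: 6, 3: 3, 2: 13, 1: 4}
    )
    vehicle_fraction: float = 0.62  # applied where the level leaves it free
    communication_fraction: float = 0.85
    population_total: float = 50_000.0
    rural_fraction: float = 0.4  # share of population spread off-settlement
    landcover_mixture: dict[int, float] = field(
        default_factory=lambda: {GRASSLAND: 0.35, FOREST: 0.25, CROPLAND: 0.25,
                                 BARE: 0.10, WETLAND: 0.05}
    )
    settlement_sigma_cells: float = 3.0
    relief_m: float = 400.0  # peak-to-trough elevation range
    caesarean_possible: bool = True

    def validate(self) -> None:
        if self.rows < 4 or self.cols < 4:
            raise ValueError("degenerate grid: rows and cols must be >= 4")
        if self.cell_size <= 0:
            raise ValueError("cell_size must be > 0")
        if self.n_settlements < 0 or self.extra_road_edges < 0:
            raise ValueError("counts must be >= 0")
        if not 0 <= self.n_isolated_settlements <= self.n_settlements:
            raise ValueError("n_isolated_settlements must be within [0, n_settlements]")
        for frac in (self.vehicle_fraction, self.communication_fraction):
            if not 0.0 <= frac <= 1.0:
                raise ValueError("fractions must lie in [0, 1]")
        if any(v < 0 for v in self.facilities_per_level.values()):
            raise ValueError("facility counts must be >= 0")
        if set(self.facilities_per_level) - {1, 2, 3, 4, 5}:
            raise ValueError("facility levels must be in 1..5")
        if self.population_total < 0:
            raise ValueError("population_total must be >= 0")


def _smooth_field(rng: np.random.Generator, shape: tuple[int, int],
                  sigma: float) -> np.ndarray:
    """Unit-range smoothed Gaussian noise field."""
    f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
    lo, hi = f.min(), f.max()
    if hi - lo < 1e-12:
        return np.zeros(shape)
    return (f - lo) / (hi - lo)


def _carve_river(rng: np.random.Generator, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of a west-to-east river through random waypoints."""
    rows, cols = shape
    mask = np.zeros(shape, dtype=bool)
    n_way = 4
    way_cols = np.linspace(0, cols - 1, n_way).astype(int)
    way_rows = rng.integers(rows // 4, 3 * rows // 4, size=n_way)
    for i in range(n_way - 1):
        rr, cc = _raster_line(way_rows[i], way_cols[i], way_rows[i + 1], way_cols[i + 1])
        mask[rr, cc] = True
    return mask


def generate_landscape(config: SyntheticConfig) -> LandscapeBundle:
    """Build the full co-registered input bundle for one seed."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    shape = (config.rows, config.cols)
    grid = GridSpec(config.cell_size, 0.0, 0.0, config.rows, config.cols)

    dem = _smooth_field(rng, shape, sigma=max(config.rows, config.cols) / 8) \
        * config.relief_m

    # Land cover: quantile-threshold a second smooth field by the mixture,
    # then overwrite river cells with water.
    cover_field = _smooth_field(rng, shape, sigma=max(config.rows, config.cols) / 12)
    classes = sorted(config.landcover_mixture)
    weights = np.array([config.landcover_mixture[c] for c in classes], dtype=float)
    weights = weights / weights.sum()
    edges = np.quantile(cover_field, np.cumsum(weights)[:-1])
    landcover = np.asarray(classes, dtype=np.int16)[
        np.searchsorted(edges, cover_field)
    ]
    river = _carve_river(rng, shape)
    landcover[river] = WATER

    # Settlements on land cells.
    land_rows, land_cols = np.nonzero(landcover != WATER)
    settlements: list[tuple[float, float]] = []
    if config.n_settlements > 0 and land_rows.size > 0:
        pick = rng.choice(land_rows.size, size=min(config.n_settlements,
                                                   land_rows.size), replace=False)
        settlements = [grid.cell_center(land_rows[i], land_cols[i]) for i in pick]

    population = _population_surface(config, grid, landcover, settlements, rng)
    roads = _road_network(config, grid, landcover, settlements, rng)
    return LandscapeBundle(grid=grid, landcover=landcover, dem=dem,
                           population=population, roads=roads,
                           settlements=settlements)


def _population_surface(config, grid, landcover, settlements, rng) -> np.ndarray:
    """Clustered-plus-rural population surface.

    Settlements contribute Gaussian kernels with log-normal sizes; a
    configurable share of the mass is spread as a patchy rural
    background over land cells. Total mass is set exactly to the
    configured total (zero on water).
    """
    pop = np.zeros(grid.shape)
    if not settlements or config.population_total <= 0:
        return pop
    sizes = rng.lognormal(mean=0.0, sigma=1.0, size=len(settlements))
    rr = np.arange(grid.rows)[:, None]
    cc = np.arange(grid.cols)[None, :]
    sig = config.settlement_sigma_cells
    for (x, y), size in zip(settlements, sizes):
        r0, c0 = grid.cell_of(x, y)
        d2 = (rr - r0) ** 2 + (cc - c0) ** 2
        pop += size * np.exp(-d2 / (2 * sig**2))
    land = landcover != WATER
    pop[~land] = 0.0
    if pop.sum() > 0:
        pop *= (1.0 - config.rural_fraction) * config.population_total / pop.sum()

    if config.rural_fraction > 0 and land.any():
        rural = _smooth_field(rng, grid.shape,
                              sigma=max(grid.rows, grid.cols) / 15) ** 2
        rural[~land] = 0.0
        if rural.sum() > 0:
            rural *= config.rural_fraction * config.population_total / rural.sum()
        pop += rural

    total = pop.sum()
    if total > 0:
        pop *= config.population_total / total
    return pop


def _road_network(config, grid, landcover, settlements, rng) -> list[RoadSegment]:
    """Spanning tree over connected settlements plus extra shortcut edges."""
    n_connected = len(settlements) - config.n_isolated_settlements
    pts = np.asarray(settlements[:n_connected], dtype=float)
    if len(pts) < 2:
        return []
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=-1)
    mst = minimum_spanning_tree(d).tocoo()
    edges = {(min(i, j), max(i, j)) for i, j in zip(mst.row, mst.col)}

    # Extra edges: shortest settlement pairs not already in the tree.
    candidates = sorted(
        ((d[i, j], i, j) for i in range(len(pts)) for j in range(i + 1, len(pts))
         if (i, j) not in edges),
        key=lambda t: t[0],
    )
    for _, i, j in candidates[: config.extra_road_edges]:
        edges.add((i, j))

    segments: list[RoadSegment] = []
    for i, j in sorted(edges):
        cls = str(rng.choice(ROAD_CLASSES, p=[0.2, 0.3, 0.5]))
        bridge = _crosses_water(grid, landcover, pts[i], pts[j])
        segments.append(RoadSegment(start=(float(pts[i][0]), float(pts[i][1])),
                                    end=(float(pts[j][0]), float(pts[j][1])),
                                    road_class=cls, bridge=bridge))
    return segments


def _crosses_water(grid: GridSpec, landcover: np.ndarray,
                   a: np.ndarray, b: np.ndarray) -> bool:
    r0, c0 = grid.cell_of(a[0], a[1])
    r1, c1 = grid.cell_of(b[0], b[1])
    rr, cc = _raster_line(r0, c0, r1, c1)
    return bool(np.any(landcover[rr, cc] == WATER))


def rasterize_roads(grid: GridSpec, roads: list[RoadSegment]) -> list[
        tuple[np.ndarray, np.ndarray, RoadSegment]]:
    """Cells covered by each segment (Bresenham, 1-cell width)."""
    out = []
    for seg in roads:
        r0, c0 = grid.cell_of(*seg.start)
        r1, c1 = grid.cell_of(*seg.end)
        rr, cc = _raster_line(r0, c0, r1, c1)
        out.append((rr, cc, seg))
    return out


# ---------------------------------------------------------------------------
# Facility roster generation
# ---------------------------------------------------------------------------

# Census-like mean readiness score per level, used to centre sampled scores.
_LEVEL_SCORE_MEAN = {5: 12.5, 4: 10.9, 3: 8.1, 2: 7.6, 1: 3.6}
_LEVEL_SCORE_BAND = {5: (10, 14), 4: (10, 14), 3: (1, 9), 2: (6, 9), 1: (0, 5)}

_CAESAREAN_IDX = N_SIGNAL_FUNCTIONS - 1  # caesarean is the last signal function


def generate_facilities(config: SyntheticConfig,
                        landscape: LandscapeBundle) -> list[FacilityRecord]:
    """Sample a roster whose classifier-assigned levels match the request.

    Attributes are constructed backwards from the target level: the
    transport flag is pinned where the level rules pin it (true for
    level 3, false for levels 1-2), a target score is drawn inside the
    level's band, and general/signal points are allocated to meet it
    exactly, so classification is the identity on the requested levels.
    """
    config.validate()
    if config.facilities_per_level.get(5, 0) > 0 and not config.caesarean_possible:
        raise ValueError(
            "level 5 facilities requested but caesarean readiness is disabled"
        )
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    sites = _facility_sites(config, landscape, rng)
    records: list[FacilityRecord] = []
    idx = 0
    for level in (5, 4, 3, 2, 1):
        for _ in range(config.facilities_per_level.get(level, 0)):
            x, y = sites[idx % len(sites)] if sites else landscape.grid.cell_center(
                landscape.grid.rows // 2, landscape.grid.cols // 2)
            records.append(_sample_facility(f"F{idx:03d}", x, y, level, config, rng))
            idx += 1
    return score_roster(records)


def _facility_sites(config, landscape, rng) -> list[tuple[float, float]]:
    """Facility locations: settlement centres first, then random land cells."""
    n_needed = sum(config.facilities_per_level.values())
    sites = list(landscape.settlements)
    land = np.argwhere(landscape.landcover != WATER)
    while len(sites) < n_needed and land.size:
        r, c = land[rng.integers(len(land))]
        sites.append(landscape.grid.cell_center(int(r), int(c)))
    rng.shuffle(sites)
    return sites[:n_needed] if sites else []


def _sample_facility(fid: str, x: float, y: float, level: int,
                     config: SyntheticConfig,
                     rng: np.random.Generator) -> FacilityRecord:
    lo, hi = _LEVEL_SCORE_BAND[level]
    score = int(np.clip(round(rng.normal(_LEVEL_SCORE_MEAN[level], 1.0)), lo, hi))

    if level == 3:
        transport = True
    elif level in (1, 2):
        transport = False
    else:  # levels 4-5: free, census-like marginal
        transport = bool(rng.random() < config.vehicle_fraction)
    # Without the transport point the attainable maximum is 4 + 9 = 13.
    score = min(score, 13 + int(transport))

    caesarean_recent = level == 5

    # Allocate score points: transport is worth one general point already.
    base = int(transport)
    sig_lo = max(0, score - base - 4)
    sig_hi = min(N_SIGNAL_FUNCTIONS, score - base)
    if level == 5:
        sig_lo = max(sig_lo, 1)  # must include caesarean readiness
    n_signal = int(rng.integers(sig_lo, sig_hi + 1)) if sig_hi >= sig_lo else 0
    n_general_extra = score - base - n_signal

    # Choose which of the four remaining general items are present;
    # communication is biased to its configured marginal when feasible.
    others = ["open_24_7", "has_electricity", "has_water"]
    comm = False
    if n_general_extra >= 4:
        comm = True
    elif n_general_extra > 0 and rng.random() < config.communication_fraction:
        comm = True
    n_others = n_general_extra - int(comm)
    chosen = set(rng.choice(others, size=min(n_others, 3), replace=False)) \
        if n_others > 0 else set()

    # Signal functions staffed-and-equipped; caesarean forced in for level 5.
    pool = list(range(N_SIGNAL_FUNCTIONS))
    ready: set[int] = set()
    if level == 5:
        ready.add(_CAESAREAN_IDX)
        pool.remove(_CAESAREAN_IDX)
    if n_signal - len(ready) > 0:
        ready |= set(rng.choice(pool, size=n_signal - len(ready), replace=False)
                     .tolist())
    staffed = [i in ready for i in range(N_SIGNAL_FUNCTIONS)]
    equipped = list(staffed)
    # Sprinkle staffed-only noise (no score contribution).
    for i in range(N_SIGNAL_FUNCTIONS):
        if i not in ready and rng.random() < 0.2:
            staffed[i] = True

    rec = FacilityRecord(
        id=fid, x=x, y=y,
        open_24_7="open_24_7" in chosen,
        has_electricity="has_electricity" in chosen,
        has_water="has_water" in chosen,
        has_transport=transport,
        has_communication=comm,
        signal_staffed=tuple(staffed),
        signal_equipped=tuple(equipped),
        caesarean_last_3_months=caesarean_recent,
        facility_type="hospital" if level == 5 else "health_centre",
    )
    # Paranoia: constructed attributes must classify back to the request.
    got_score = sum(rec.general_items) + n_signal
    assert got_score == score, (got_score, score)
    assert classify_level(score, caesarean_recent, transport) == level
    return rec
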