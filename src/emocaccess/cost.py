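"""Cost-distance modelling: per-cell crossing cost and travel-time maps.

A single raster holds the minutes needed to cross each cell. Cell speed
is the walking speed of its land-cover class, replaced by the motorised
class speed wherever a road overlaps the cell; walking speeds are
attenuated by terrain slope with a normalised exponential decay (an
isotropic Tobler-style hiking function, factor 1 on flat ground). Water
cells are impassable unless a bridge-flagged road crosses them.

Travel time outward from source points uses standard cost-distance
semantics: 8-connected moves, step cost equal to the mean of the two
cells' crossing costs, scaled by sqrt(2) for diagonal moves.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import dijkstra

from .grid import GridSpec
from .synthetic import LANDCOVER_CLASSES, WATER, LandscapeBundle, rasterize_roads

#: Literature-style walking speeds per land-cover class, km/h. The
#: per-class values are configurable substitutes, not survey constants.
DEFAULT_WALKING_KMH: dict[int, float] = {
    1: 5.0,   # grassland
    2: 3.0,   # forest
    3: 4.0,   # cropland
    4: 5.0,   # bare
    5: 2.0,   # wetland
}

DEFAULT_ROAD_KMH: dict[str, float] = {
    "primary": 80.0,
    "secondary": 50.0,
    "tertiary": 30.0,
}

SQRT2 = math.sqrt(2.0)


@dataclass
class SpeedConfig:
    """Travel-speed assumptions feeding the cost surface."""

    walking_kmh: dict[int, float] = field(
        default_factory=lambda: dict(DEFAULT_WALKING_KMH))
    road_kmh: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_ROAD_KMH))
    slope_decay: float = 3.5  # e-folding of walking speed per unit |dz/dx|
    attenuate_roads: bool = False
    impassable_classes: frozenset[int] = frozenset({WATER})

    def __post_init__(self) -> None:
        if any(v <= 0 for v in self.walking_kmh.values()):
            raise ValueError("walking speeds must be > 0")
        if any(v <= 0 for v in self.road_kmh.values()):
            raise ValueError("road speeds must be > 0")
        if self.slope_decay < 0:
            raise ValueError("slope_decay must be >= 0")


@dataclass
class CostSurface:
    """Minutes to cross each cell; +inf marks impassable cells."""

    cost: np.ndarray
    grid: GridSpec

    def __post_init__(self) -> None:
        if self.cost.shape != self.grid.shape:
            raise ValueError("cost shape does not match grid")
        finite = self.cost[np.isfinite(self.cost)]
        if finite.size and np.any(finite <= 0):
            raise ValueError("passable cells must have cost > 0")


def slope_attenuation(dem: np.ndarray, cell_size: float,
                      decay: float) -> np.ndarray:
    """Isotropic walking-speed factor exp(-decay * |slope|), 1 on flat."""
    gy, gx = np.gradient(dem, cell_size)
    slope = np.hypot(gx, gy)
    return np.exp(-decay * slope)


def build_cost_surface(landscape: LandscapeBundle,
                       speeds: SpeedConfig | None = None) -> CostSurface:
    """Combine land cover, roads and slope into minutes-per-cell."""
    speeds = speeds or SpeedConfig()
    lc = landscape.landcover
    unknown = set(np.unique(lc).tolist()) - set(speeds.walking_kmh) \
        - speeds.impassable_classes
    if unknown:
        names = {c: LANDCOVER_CLASSES.get(c, "?") for c in sorted(unknown)}
        raise ValueError(f"no walking speed for land-cover class(es) {names}")

    speed = np.zeros(lc.shape)
    for code, kmh in speeds.walking_kmh.items():
        speed[lc == code] = kmh
    atten = slope_attenuation(landscape.dem, landscape.grid.cell_size,
                              speeds.slope_decay)
    speed *= atten  # walking cells are slope-attenuated
    passable = ~np.isin(lc, list(speeds.impassable_classes))

    # Roads override walking; fastest class wins where segments overlap.
    road_speed = np.zeros(lc.shape)
    bridge = np.zeros(lc.shape, dtype=bool)
    for rr, cc, seg in rasterize_roads(landscape.grid, landscape.roads):
        if seg.road_class not in speeds.road_kmh:
            raise ValueError(f"no motorised speed for road class "
                             f"{seg.road_class!r}")
        kmh = speeds.road_kmh[seg.road_class]
        road_speed[rr, cc] = np.maximum(road_speed[rr, cc], kmh)
        if seg.bridge:
            bridge[rr, cc] = True

    on_road = road_speed > 0
    eff_road = road_speed * atten if speeds.attenuate_roads else road_speed
    speed[on_road] = eff_road[on_road]
    # Bridge-flagged road cells over water are passable at road speed.
    passable |= on_road & bridge

    cost = np.full(lc.shape, np.inf)
    ok = passable & (speed > 0)
    cost[ok] = (landscape.grid.cell_size / 1000.0) / speed[ok] * 60.0
    return CostSurface(cost=cost, grid=landscape.grid)


def _grid_graph(cost: np.ndarray) -> coo_matrix:
    """Sparse 8-connected graph; edge = mean crossing cost (x sqrt2 diag)."""
    rows, cols = cost.shape
    n = rows * cols
    idx = np.arange(n).reshape(rows, cols)
    data, src, dst = [], [], []
    # Right, down, down-right, down-left cover all undirected neighbours.
    for dr, dc, diag in ((0, 1, False), (1, 0, False), (1, 1, True), (1, -1, True)):
        if dr == 0 and dc == 1:
            a, b = idx[:, :-1], idx[:, 1:]
        elif dr == 1 and dc == 0:
            a, b = idx[:-1, :], idx[1:, :]
        elif dr == 1 and dc == 1:
            a, b = idx[:-1, :-1], idx[1:, 1:]
        else:  # dr == 1, dc == -1
            a, b = idx[:-1, 1:], idx[1:, :-1]
        w = 0.5 * (cost.ravel()[a.ravel()] + cost.ravel()[b.ravel()])
        if diag:
            w = w * SQRT2
        finite = np.isfinite(w)
        src.append(a.ravel()[finite])
        dst.append(b.ravel()[finite])
        data.append(w[finite])
    return coo_matrix(
        (np.concatenate(data), (np.concatenate(src), np.concatenate(dst))),
        shape=(n, n),
    )


def travel_time_map(cost_surface: CostSurface,
                    sources: list[tuple[int, int]]) -> np.ndarray:
    """Minutes from the nearest source to every cell (inf if unreachable).

    Sources are (row, col) cells; source cells get time 0. Raises if no
    source is inside the grid on a passable cell.
    """
    cost = cost_surface.cost
    rows, cols = cost.shape
    if not sources:
        raise ValueError("at least one source is required")
    flat = []
    for r, c in sources:
        if not (0 <= r < rows and 0 <= c < cols):
            raise ValueError(f"source ({r}, {c}) outside the grid")
        if np.isfinite(cost[r, c]):
            flat.append(r * cols + c)
    if not flat:
        raise ValueError("all sources lie on impassable cells")
    graph = _grid_graph(cost)
    dist = dijkstra(graph, directed=False, indices=flat, min_only=True)
    return dist.reshape(rows, cols)
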