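"""Interfacility referral (journey segment 2) along the road network.

Women whose first preferred facility cannot provide surgical care are
referred onward to the closest level-5 facility. Transfer time is the
shortest-path time along the road network at per-class motorised
speeds, then adjusted for the sending facility's infrastructure:

* no functioning vehicle — the receiving facility must send one to
  retrieve the patient, so the transfer time is **doubled**;
* no functioning communication — **+30 minutes** to locate a phone.

When both apply the doubling acts on the direct time and the phone
search is added once (2·T + 30): the call happens before any vehicle
moves, and the two delays are independent add-ons.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from .cost import SpeedConfig
from .facilities import FacilityRecord
from .synthetic import RoadSegment

logger = logging.getLogger(__name__)

NO_COMMUNICATION_PENALTY_MIN = 30.0
NO_VEHICLE_FACTOR = 2.0


def build_road_graph(roads: list[RoadSegment],
                     speeds: SpeedConfig | None = None,
                     snap_tolerance_m: float = 1.0) -> nx.Graph:
    """Undirected graph of road segments with traversal minutes.

    Endpoints within ``snap_tolerance_m`` merge into one node (keyed by
    the rounded coordinate). Zero-length segments are dropped with a
    warning; parallel segments keep the faster traversal.
    """
    if not roads:
        raise ValueError("road set is empty")
    speeds = speeds or SpeedConfig()
    g = nx.Graph()

    def key(pt: tuple[float, float]) -> tuple[float, float]:
        return (round(pt[0] / snap_tolerance_m) * snap_tolerance_m,
                round(pt[1] / snap_tolerance_m) * snap_tolerance_m)

    for seg in roads:
        if seg.road_class not in speeds.road_kmh:
            raise ValueError(f"no motorised speed for road class "
                             f"{seg.road_class!r}")
        a, b = key(seg.start), key(seg.end)
        length_km = math.dist(seg.start, seg.end) / 1000.0
        if a == b or length_km == 0.0:
            logger.warning("dropping zero-length road segment at %s", seg.start)
            continue
        minutes = length_km / speeds.road_kmh[seg.road_class] * 60.0
        if g.has_edge(a, b) and g[a][b]["minutes"] <= minutes:
            continue
        g.add_edge(a, b, minutes=minutes, length_km=length_km,
                   road_class=seg.road_class)
    for node in g.nodes:
        g.nodes[node]["x"], g.nodes[node]["y"] = node
    return g


def snap_to_graph(graph: nx.Graph, x: float, y: float) -> tuple[float, float]:
    """Nearest graph node to a point; the snap distance is logged."""
    nodes = list(graph.nodes)
    arr = np.asarray(nodes, dtype=float)
    i = int(np.argmin((arr[:, 0] - x) ** 2 + (arr[:, 1] - y) ** 2))
    d = math.hypot(arr[i, 0] - x, arr[i, 1] - y)
    if d > 0:
        logger.debug("snapped facility at (%.0f, %.0f) to road node %.0f m away",
                     x, y, d)
    return nodes[i]


def direct_transfer_time(graph: nx.Graph, sender: FacilityRecord,
                         level5s: list[FacilityRecord]
                         ) -> tuple[str | None, float]:
    """(closest level-5 id, shortest-path minutes); (None, inf) if cut off."""
    if not level5s:
        raise ValueError("no level-5 facility in the roster")
    src = snap_to_graph(graph, sender.x, sender.y)
    dist = nx.single_source_dijkstra_path_length(graph, src, weight="minutes")
    best_id, best_min = None, math.inf
    for f in level5s:
        node = snap_to_graph(graph, f.x, f.y)
        t = dist.get(node, math.inf)
        if t < best_min:
            best_id, best_min = f.id, t
    if not math.isfinite(best_min):
        return None, math.inf
    return best_id, best_min


def adjust_transfer_time(direct_min: float, has_vehicle: bool,
                         has_communication: bool) -> float:
    """Apply the no-vehicle doubling and the +30 min no-phone penalty."""
    if not (isinstance(direct_min, (int, float)) and math.isfinite(direct_min)) \
            or direct_min < 0:
        raise ValueError(f"direct transfer time must be finite and >= 0, "
                         f"got {direct_min}")
    adjusted = float(direct_min)
    if not has_vehicle:
        adjusted *= NO_VEHICLE_FACTOR
    if not has_communication:
        adjusted += NO_COMMUNICATION_PENALTY_MIN
    return adjusted


def build_referral_table(facilities: list[FacilityRecord],
                         graph: nx.Graph) -> pd.DataFrame:
    """Direct and adjusted transfer minutes per facility.

    Level-5 facilities need no transfer (0 min, and one lacking
    transport is treated as if a vehicle were stationed there). Rows
    for unreachable senders carry no times and ``unreachable=True``.
    """
    level5s = [f for f in facilities if f.level == 5]
    if not level5s:
        raise ValueError("no level-5 facility in the roster")
    rows = []
    for f in facilities:
        if f.level == 5:
            rows.append(dict(facility_id=f.id, level=5, nearest_level5=f.id,
                             direct_min=0.0, adjusted_min=0.0,
                             doubled=False, phone_penalty=False,
                             unreachable=False))
            continue
        dest, direct = direct_transfer_time(graph, f, level5s)
        if dest is None:
            rows.append(dict(facility_id=f.id, level=f.level,
                             nearest_level5=None, direct_min=np.nan,
                             adjusted_min=np.nan, doubled=False,
                             phone_penalty=False, unreachable=True))
            continue
        adjusted = adjust_transfer_time(direct, f.has_transport,
                                        f.has_communication)
        rows.append(dict(facility_id=f.id, level=f.level, nearest_level5=dest,
                         direct_min=direct, adjusted_min=adjusted,
                         doubled=not f.has_transport,
                         phone_penalty=not f.has_communication,
                         unreachable=False))
    return pd.DataFrame(rows).set_index("facility_id")
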