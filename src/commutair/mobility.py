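"""Concentration maps and health-optimal routing.

Georeferenced sensor records are aggregated into equal-area metric grid
cells (the air-quality map); a geographic route graph carrying per-edge
travel times and concentrations supports two routing objectives:

* ``fastest`` — minimise total travel time;
* ``avoid_pollution`` — minimise the inhaled dose, applied edge-wise as
  concentration × I/O(mode) × time(h) × IR(mode), so the chosen path is the
  one a commuter would breathe least on.

Cells use a local equirectangular projection centred on the data bounding
box — at city scale (cells of order 100 m) the metric distortion is
negligible.  The search is Dijkstra over non-negative edge costs with
deterministic lexicographic tie-breaking on the node-id sequence.
"""

from __future__ import annotations

import heapq
import logging
import math
from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .errors import NoPathError, ParameterError
from .exposure import inhaled_dose
from .sensor_io import FLAG_OK, InhalationTable, IORatioTable, SensorRecord

logger = logging.getLogger(__name__)

EARTH_RADIUS_M = 6_371_000.0
#: floor keeping avoid-pollution costs strictly positive on clean edges
COST_FLOOR = 1e-9

OBJECTIVES = ("fastest", "avoid_pollution")


# ---------------------------------------------------------------------------
# concentration grid


@dataclass(frozen=True)
class GridCell:
    ix: int
    iy: int
    mean_pm25: float
    mean_pm10: float
    count: int


@dataclass(frozen=True)
class ConcentrationGrid:
    """Equal-area aggregation of geolocated readings.

    ``origin`` is the (lat, lon) of the local projection centre; cell
    (ix, iy) covers [ix*s, (ix+1)*s) × [iy*s, (iy+1)*s) metres around it.
    """

    cell_size_m: float
    time_window: str
    origin: tuple[float, float]
    cells: Mapping[tuple[int, int], GridCell]

    @property
    def total_count(self) -> int:
        return sum(cell.count for cell in self.cells.values())

    def _unproject(self, x: float, y: float) -> tuple[float, float]:
        lat0, lon0 = self.origin
        lat = lat0 + math.degrees(y / EARTH_RADIUS_M)
        lon = lon0 + math.degrees(x / (EARTH_RADIUS_M * math.cos(math.radians(lat0))))
        return lat, lon

    def to_features(self) -> list[dict[str, Any]]:
        """GeoJSON polygon features (lon,lat ring per cell) with cell means."""
        features = []
        s = self.cell_size_m
        for (ix, iy), cell in sorted(self.cells.items()):
            corners_xy = [(ix * s, iy * s), ((ix + 1) * s, iy * s),
                          ((ix + 1) * s, (iy + 1) * s), (ix * s, (iy + 1) * s)]
            ring = []
            for x, y in corners_xy:
                lat, lon = self._unproject(x, y)
                ring.append([lon, lat])
            ring.append(ring[0])
            features.append(
                {
                    "geometry": {"type": "Polygon", "coordinates": [ring]},
                    "properties": {
                        "pm25": cell.mean_pm25,
                        "pm10": cell.mean_pm10,
                        "count": cell.count,
                    },
                }
            )
        return features


def _project(lat: np.ndarray, lon: np.ndarray, origin: tuple[float, float]) -> tuple[np.ndarray, np.ndarray]:
    lat0, lon0 = origin
    x = EARTH_RADIUS_M * math.cos(math.radians(lat0)) * np.radians(lon - lon0)
    y = EARTH_RADIUS_M * np.radians(lat - lat0)
    return x, y


def aggregate_grid(
    records: Sequence[SensorRecord],
    cell_size_m: float = 100.0,
    time_window: tuple | None = None,
    label: str = "all",
) -> ConcentrationGrid:
    """Aggregate ok-flagged, geolocated records into per-cell arithmetic means.

    Cell counts are conserved: their sum equals the number of usable records
    in the window.  With no geolocated records the grid comes back empty with
    a logged warning.
    """
    if cell_size_m <= 0:
        raise ParameterError("cell_size_m must be positive")
    usable = [r for r in records if r.flag == FLAG_OK and r.has_fix]
    if time_window is not None:
        start, end = time_window
        usable = [r for r in usable if start <= r.timestamp < end]
    if not usable:
        logger.warning("no geolocated ok-flagged records in window; returning empty grid")
        return ConcentrationGrid(cell_size_m, label, (0.0, 0.0), {})

    lats = np.array([r.lat for r in usable])
    lons = np.array([r.lon for r in usable])
    origin = (float((lats.min() + lats.max()) / 2), float((lons.min() + lons.max()) / 2))
    x, y = _project(lats, lons, origin)
    ix = np.floor(x / cell_size_m).astype(int)
    iy = np.floor(y / cell_size_m).astype(int)

    frame = pd.DataFrame(
        {
            "ix": ix,
            "iy": iy,
            "pm25": [r.pm25 for r in usable],
            "pm10": [r.pm10 for r in usable],
        }
    )
    grouped = frame.groupby(["ix", "iy"]).agg(
        mean_pm25=("pm25", "mean"), mean_pm10=("pm10", "mean"), n=("pm25", "size")
    )
    cells = {
        (int(i), int(j)): GridCell(int(i), int(j), float(row.mean_pm25),
                                   float(row.mean_pm10), int(row.n))
        for (i, j), row in grouped.iterrows()
    }
    return ConcentrationGrid(cell_size_m, label, origin, cells)


# ---------------------------------------------------------------------------
# route graph


def build_route_graph(
    nodes: Mapping[str, tuple[float, float]],
    edges: Iterable[tuple[str, str, Mapping[str, Any]]],
) -> nx.Graph:
    """Assemble the geographic route graph.

    ``nodes`` map id -> (lat, lon).  Each edge carries ``length_m`` (> 0),
    ``times`` (mode -> seconds, > 0) and non-negative ``pm25``/``pm10``
    concentrations (µg m^-3) bound from the most recent map cell it crosses.
    """
    graph = nx.Graph()
    for node_id, (lat, lon) in nodes.items():
        graph.add_node(str(node_id), lat=float(lat), lon=float(lon))
    for u, v, data in edges:
        length = float(data["length_m"])
        if length <= 0:
            raise ParameterError(f"edge ({u}, {v}) has non-positive length")
        times = {str(m): float(t) for m, t in dict(data["times"]).items()}
        if any(t <= 0 for t in times.values()):
            raise ParameterError(f"edge ({u}, {v}) has non-positive travel time")
        pm25 = float(data.get("pm25", 0.0))
        pm10 = float(data.get("pm10", 0.0))
        if pm25 < 0 or pm10 < 0:
            raise ParameterError(f"edge ({u}, {v}) has negative concentration")
        graph.add_edge(str(u), str(v), length_m=length, times=times, pm25=pm25, pm10=pm10)
    return graph


def bind_concentrations(graph: nx.Graph, grid: ConcentrationGrid,
                        background: tuple[float, float] = (0.0, 0.0)) -> None:
    """Attach grid-cell means to edges via their midpoint; cells absent from
    the grid fall back to the configured background concentrations."""
    for u, v, data in graph.edges(data=True):
        mid_lat = (graph.nodes[u]["lat"] + graph.nodes[v]["lat"]) / 2
        mid_lon = (graph.nodes[u]["lon"] + graph.nodes[v]["lon"]) / 2
        x, y = _project(np.array([mid_lat]), np.array([mid_lon]), grid.origin)
        key = (int(math.floor(x[0] / grid.cell_size_m)), int(math.floor(y[0] / grid.cell_size_m)))
        cell = grid.cells.get(key)
        if cell is None:
            data["pm25"], data["pm10"] = background
        else:
            data["pm25"], data["pm10"] = cell.mean_pm25, cell.mean_pm10


def edge_travel_time(data: Mapping[str, Any], mode: str) -> float:
    times = data.get("times", {})
    if mode not in times:
        raise ParameterError(f"edge has no travel time for mode {mode!r}")
    return float(times[mode])


def edge_cost(
    data: Mapping[str, Any],
    mode: str,
    objective: str,
    ir_table: InhalationTable,
    io_table: IORatioTable,
    fraction: str = "pm25",
) -> float:
    """Cost of traversing one edge under the chosen objective.

    ``fastest`` is the travel time in seconds; ``avoid_pollution`` is the
    inhaled dose (µg) on the edge, floored at a tiny epsilon so that path
    ordering stays well-defined on perfectly clean edges.
    """
    if objective not in OBJECTIVES:
        raise ParameterError(f"objective must be one of {OBJECTIVES}")
    seconds = edge_travel_time(data, mode)
    if objective == "fastest":
        return seconds
    dose = inhaled_dose(
        float(data[fraction]), io_table[(mode, fraction)], seconds / 3600.0, ir_table[mode]
    )
    return max(dose, COST_FLOOR)


def best_route(
    graph: nx.Graph,
    origin: str,
    destination: str,
    mode: str,
    objective: str,
    ir_table: InhalationTable,
    io_table: IORatioTable,
    fraction: str = "pm25",
) -> tuple[list[str], float, float]:
    """Least-cost path between two nodes under the chosen objective.

    Returns (node path, total travel time s, total inhaled dose µg) — both
    totals regardless of objective.  Ties in cost break deterministically on
    the lexicographically smallest node-id sequence.  Identical origin and
    destination give an empty path with zero totals; an unreachable
    destination raises :class:`NoPathError`.
    """
    for node in (origin, destination):
        if node not in graph:
            raise NoPathError(f"node {node!r} is not in the graph")
    if origin == destination:
        return [], 0.0, 0.0

    # Dijkstra over (cost, path) entries: heap order on equal cost falls
    # through to tuple comparison of the paths, giving the lexicographic rule.
    heap: list[tuple[float, tuple[str, ...]]] = [(0.0, (origin,))]
    settled: set[str] = set()
    while heap:
        cost, path = heapq.heappop(heap)
        node = path[-1]
        if node in settled:
            continue
        settled.add(node)
        if node == destination:
            total_time = 0.0
            total_dose = 0.0
            for u, v in zip(path[:-1], path[1:]):
                data = graph.edges[u, v]
                total_time += edge_travel_time(data, mode)
                total_dose += inhaled_dose(
                    float(data[fraction]),
                    io_table[(mode, fraction)],
                    edge_travel_time(data, mode) / 3600.0,
                    ir_table[mode],
                )
            return list(path), total_time, total_dose
        for neighbor in graph.neighbors(node):
            if neighbor not in settled:
                step = edge_cost(graph.edges[node, neighbor], mode, objective,
                                 ir_table, io_table, fraction)
                heapq.heappush(heap, (cost + step, path + (neighbor,)))
    raise NoPathError(f"destination {destination!r} unreachable from {origin!r}")


def path_metrics(graph: nx.Graph, path: Sequence[str], mode: str,
                 fraction: str = "pm25") -> dict[str, float]:
    """Length, time and mean exposure-weighted concentration along a path."""
    length = time_s = conc_time = 0.0
    for u, v in zip(path[:-1], path[1:]):
        data = graph.edges[u, v]
        length += data["length_m"]
        seconds = edge_travel_time(data, mode)
        time_s += seconds
        conc_time += float(data[fraction]) * seconds
    return {
        "length_m": length,
        "time_s": time_s,
        "mean_concentration": conc_time / time_s if time_s > 0 else 0.0,
    }


def compare_modes(
    graph: nx.Graph,
    path: Sequence[str],
    ir_table: InhalationTable,
    io_table: IORatioTable,
    factors: "EmissionFactorSet | None" = None,
    occupancy: Mapping[str, int] | None = None,
    emission_keys: Mapping[str, tuple[str, str, str] | None] | None = None,
    modes: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Per-mode dose and per-passenger emission over one path.

    Each row combines the dose model (per edge, per size fraction) with the
    per-passenger emission model over the path length.  Active (walking,
    bicycle) and unmapped modes emit 0.  ``emission_keys`` maps a mode to the
    (vehicle, fuel, euro) factor used for it.
    """
    from .emissions import emission_per_passenger  # local import avoids a cycle

    modes = tuple(modes) if modes is not None else ir_table.modes
    emission_keys = emission_keys or {}
    rows = []
    for mode in modes:
        time_s = dose25 = dose10 = length_m = 0.0
        for u, v in zip(path[:-1], path[1:]):
            data = graph.edges[u, v]
            seconds = edge_travel_time(data, mode)
            hours = seconds / 3600.0
            time_s += seconds
            length_m += data["length_m"]
            dose25 += inhaled_dose(float(data["pm25"]), io_table[(mode, "pm25")],
                                   hours, ir_table[mode])
            dose10 += inhaled_dose(float(data["pm10"]), io_table[(mode, "pm10")],
                                   hours, ir_table[mode])
        key = emission_keys.get(mode)
        if key is None or factors is None:
            emission = 0.0
        else:
            factor = factors[key]
            passengers = int((occupancy or {}).get(factor.vehicle, 1))
            emission = emission_per_passenger(factor.ef, length_m / 1000.0, passengers)
        rows.append(
            {
                "mode": mode,
                "time_s": time_s,
                "dose_pm25": dose25,
                "dose_pm10": dose10,
                "emission_g": emission,
            }
        )
    return pd.DataFrame(rows)
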