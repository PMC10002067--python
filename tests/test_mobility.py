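"""Concentration-grid aggregation and exposure-aware routing."""

from datetime import datetime, timezone

import networkx as nx
import numpy as np
import pytest

import commutair as ca
from commutair.errors import NoPathError, ParameterError
from commutair.mobility import edge_cost, edge_travel_time, path_metrics

T0 = datetime(2022, 6, 1, tzinfo=timezone.utc)


def record(pm25, lat=38.70, lon=-9.15, flag="ok", pm10=None):
    return ca.SensorRecord(T0, pm25, pm10 if pm10 is not None else 2 * pm25,
                           20.0, 50.0, lat=lat, lon=lon, flag=flag)


class TestAggregateGrid:
    def test_single_cell_mean_and_count(self):
        records = [record(v) for v in (1.0, 2.0, 3.0, 4.0, 5.0)]
        grid = ca.aggregate_grid(records, cell_size_m=100.0)
        assert len(grid.cells) == 1
        cell = next(iter(grid.cells.values()))
        assert cell.mean_pm25 == 3.0
        assert cell.count == 5

    def test_count_conservation_across_cells(self):
        near = [record(5.0, lat=38.700, lon=-9.150) for _ in range(3)]
        far = [record(9.0, lat=38.705, lon=-9.150) for _ in range(4)]  # ~550 m away
        grid = ca.aggregate_grid(near + far, cell_size_m=100.0)
        assert len(grid.cells) == 2
        assert grid.total_count == 7

    def test_excluded_and_unfixed_records_skipped(self):
        usable = [record(5.0) for _ in range(3)]
        excluded = [record(99.0, flag="excluded")]
        no_fix = [ca.SensorRecord(T0, 7.0, 14.0, 20.0, 50.0)]
        grid = ca.aggregate_grid(usable + excluded + no_fix)
        assert grid.total_count == 3
        assert next(iter(grid.cells.values())).mean_pm25 == 5.0

    def test_empty_input_warns_and_returns_empty_grid(self, caplog):
        grid = ca.aggregate_grid([], cell_size_m=100.0)
        assert grid.cells == {}
        assert grid.total_count == 0

    def test_constant_field_trip_gives_constant_cell_means(self):
        ambient = ca.simulate_ambient(
            ca.AmbientScenario(duration_h=1.0, step_s=60, log_sd=0.0, seed=1)
        )
        trip = ca.TripScenario(polyline=[(38.70, -9.15), (38.72, -9.13)],
                               resuspension_spike_rate=0.0)
        outdoor, _, _ = ca.simulate_trip(trip, ambient)
        grid = ca.aggregate_grid(outdoor, cell_size_m=100.0)
        assert len(grid.cells) > 1
        assert grid.total_count == len(outdoor)
        for cell in grid.cells.values():
            assert cell.mean_pm25 == pytest.approx(8.0)

    def test_cell_geometry_round_trips_through_geojson(self, tmp_path):
        records = [record(5.0)]
        grid = ca.aggregate_grid(records, cell_size_m=100.0)
        path = tmp_path / "grid.geojson"
        ca.write_geojson(grid.to_features(), path)
        from commutair.sensor_io import read_geojson

        features = read_geojson(path)["features"]
        assert features[0]["properties"]["count"] == 1


def make_diamond(config):
    """Origin A, destination D; B-branch fast but polluted, C-branch slow but clean."""
    nodes = {n: (38.70 + 0.01 * i, -9.15) for i, n in enumerate("ABCD")}
    edges = [
        ("A", "B", {"length_m": 500, "times": {"walking": 100.0}, "pm25": 80.0, "pm10": 120.0}),
        ("B", "D", {"length_m": 500, "times": {"walking": 100.0}, "pm25": 80.0, "pm10": 120.0}),
        ("A", "C", {"length_m": 900, "times": {"walking": 300.0}, "pm25": 2.0, "pm10": 4.0}),
        ("C", "D", {"length_m": 900, "times": {"walking": 300.0}, "pm25": 2.0, "pm10": 4.0}),
    ]
    return ca.build_route_graph(nodes, edges)


class TestEdgeCost:
    def test_dose_arithmetic(self, config):
        data = {"times": {"bus": 360.0}, "pm25": 10.0, "pm10": 20.0, "length_m": 100.0}
        cost = edge_cost(data, "bus", "avoid_pollution", config.inhalation, config.io_ratios)
        assert cost == pytest.approx(10.0 * 2.10 * 0.1 * 0.76)  # = 1.596 ug

    def test_fastest_ignores_concentration(self, config):
        clean = {"times": {"walking": 60.0}, "pm25": 0.0, "pm10": 0.0, "length_m": 10.0}
        dirty = {"times": {"walking": 60.0}, "pm25": 500.0, "pm10": 600.0, "length_m": 10.0}
        assert edge_cost(clean, "walking", "fastest", config.inhalation, config.io_ratios) == \
            edge_cost(dirty, "walking", "fastest", config.inhalation, config.io_ratios)

    def test_zero_concentration_floored_to_epsilon(self, config):
        clean = {"times": {"walking": 60.0}, "pm25": 0.0, "pm10": 0.0, "length_m": 10.0}
        cost = edge_cost(clean, "walking", "avoid_pollution", config.inhalation,
                         config.io_ratios)
        assert 0 < cost <= 1e-9

    def test_missing_mode_time_rejected(self, config):
        with pytest.raises(ParameterError):
            edge_cost({"times": {"bus": 60.0}, "pm25": 1.0}, "car", "fastest",
                      config.inhalation, config.io_ratios)


class TestBestRoute:
    def test_diamond_flips_between_objectives(self, config):
        graph = make_diamond(config)
        fast_path, fast_time, fast_dose = ca.best_route(
            graph, "A", "D", "walking", "fastest", config.inhalation, config.io_ratios
        )
        clean_path, clean_time, clean_dose = ca.best_route(
            graph, "A", "D", "walking", "avoid_pollution", config.inhalation, config.io_ratios
        )
        assert fast_path == ["A", "B", "D"]
        assert clean_path == ["A", "C", "D"]
        assert clean_time > fast_time
        assert clean_dose < fast_dose

    def test_identical_origin_destination(self, config):
        graph = make_diamond(config)
        assert ca.best_route(graph, "A", "A", "walking", "fastest",
                             config.inhalation, config.io_ratios) == ([], 0.0, 0.0)

    def test_unreachable_destination(self, config):
        graph = make_diamond(config)
        graph.add_node("Z", lat=38.0, lon=-9.0)
        with pytest.raises(NoPathError):
            ca.best_route(graph, "A", "Z", "walking", "fastest",
                          config.inhalation, config.io_ratios)

    def test_concentration_scaling_does_not_change_chosen_path(self, config):
        graph = make_diamond(config)
        base_path, _, _ = ca.best_route(graph, "A", "D", "walking", "avoid_pollution",
                                        config.inhalation, config.io_ratios)
        for u, v in graph.edges:
            graph.edges[u, v]["pm25"] *= 37.5
            graph.edges[u, v]["pm10"] *= 37.5
        scaled_path, _, _ = ca.best_route(graph, "A", "D", "walking", "avoid_pollution",
                                          config.inhalation, config.io_ratios)
        assert scaled_path == base_path


def random_graph(seed, config):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, 9))
    nodes = {str(i): (38.70 + 0.001 * i, -9.15) for i in range(n)}
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if rng.random() < 0.5:
                edges.append(
                    (str(i), str(j), {
                        "length_m": float(rng.uniform(50, 2000)),
                        "times": {"walking": float(rng.uniform(10, 600))},
                        "pm25": float(rng.uniform(0.5, 80.0)),
                        "pm10": float(rng.uniform(1.0, 120.0)),
                    })
                )
    return ca.build_route_graph(nodes, edges), rng


def brute_force(graph, origin, destination, mode, objective, config):
    """Independent oracle: exhaustive enumeration over all simple paths."""
    best = None
    for path in nx.all_simple_paths(graph, origin, destination):
        time_s = dose = 0.0
        for u, v in zip(path[:-1], path[1:]):
            data = graph.edges[u, v]
            seconds = data["times"][mode]
            time_s += seconds
            dose += data["pm25"] * 1.0 * (seconds / 3600.0) * config.inhalation[mode]
        cost = time_s if objective == "fastest" else dose
        if best is None or cost < best:
            best = cost
    return best


@pytest.mark.parametrize("objective", ["fastest", "avoid_pollution"])
def test_dijkstra_agrees_with_exhaustive_enumeration(objective, config):
    checked = 0
    for seed in range(200):
        graph, rng = random_graph(seed, config)
        nodes = sorted(graph.nodes)
        if len(nodes) < 2:
            continue
        origin, destination = nodes[0], nodes[-1]
        oracle = brute_force(graph, origin, destination, "walking", objective, config)
        if oracle is None:
            with pytest.raises(NoPathError):
                ca.best_route(graph, origin, destination, "walking", objective,
                              config.inhalation, config.io_ratios)
            continue
        _, time_s, dose = ca.best_route(graph, origin, destination, "walking", objective,
                                        config.inhalation, config.io_ratios)
        achieved = time_s if objective == "fastest" else dose
        assert achieved == pytest.approx(oracle, rel=1e-9)
        checked += 1
    assert checked > 100  # the sweep must actually exercise connected cases


class TestCompareModes:
    def test_contains_exactly_the_configured_modes(self, config, factor_set):
        graph = make_diamond(config)
        for u, v in graph.edges:
            graph.edges[u, v]["times"].update(
                {m: graph.edges[u, v]["times"]["walking"] for m in config.inhalation.modes}
            )
        table = ca.compare_modes(graph, ["A", "B", "D"], config.inhalation, config.io_ratios,
                                 factors=factor_set, occupancy=config.occupancy)
        assert sorted(table["mode"]) == sorted(config.inhalation.modes)
        assert (table.loc[table["mode"].isin(["walking", "bicycle"]), "emission_g"] == 0).all()

    def test_equal_time_dose_ordering_follows_ir_times_io(self, config):
        graph = make_diamond(config)
        for u, v in graph.edges:
            graph.edges[u, v]["times"] = {m: 300.0 for m in config.inhalation.modes}
        table = ca.compare_modes(graph, ["A", "B", "D"], config.inhalation, config.io_ratios)
        factor = {m: config.inhalation[m] * config.io_ratios[(m, "pm25")]
                  for m in config.inhalation.modes}
        by_factor = sorted(factor, key=factor.get)
        by_dose = list(table.sort_values("dose_pm25")["mode"])
        assert by_dose == by_factor

    def test_bicycle_to_car_dose_ratio(self, config):
        graph = make_diamond(config)
        for u, v in graph.edges:
            graph.edges[u, v]["times"] = {m: 300.0 for m in config.inhalation.modes}
        table = ca.compare_modes(graph, ["A", "B", "D"], config.inhalation,
                                 config.io_ratios).set_index("mode")
        ratio = table.loc["bicycle", "dose_pm25"] / table.loc["car", "dose_pm25"]
        assert ratio == pytest.approx((1.41 * 1.0) / (0.71 * 0.96))


def test_path_metrics_totals(config):
    graph = make_diamond(config)
    metrics = path_metrics(graph, ["A", "B", "D"], "walking")
    assert metrics["length_m"] == 1000.0
    assert metrics["time_s"] == 200.0
    assert metrics["mean_concentration"] == pytest.approx(80.0)
    assert edge_travel_time(graph.edges["A", "B"], "walking") == 100.0
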