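"""Per-map metrics: trail traffic and weight, resource-flow betweenness,
foraging effort, worker:forager ratio."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from helpers import brute_force_betweenness, chain_map, make_map, random_small_map
from polynest.colony import (
    CalibrationError,
    InvalidMeasurementError,
    Timepoint,
    UndefinedRatioError,
    UndefinedWeightError,
    categorize_flow,
    colony_foraging_effort,
    compute_trail_traffic,
    compute_trail_weight,
    nearest_tree_distance,
    population_from_volume,
    resource_flow_betweenness,
    worker_forager_ratio,
)


@pytest.mark.parametrize(
    "gap, length, apc, total",
    [
        (10, 500, 1.0, 500.0),
        (50, 50, 0.2, 10.0),  # the sample gap spans the whole trail: the 10 counted ants
        (25, 1000, 0.4, 400.0),
    ],
)
def test_trail_traffic_conversion(gap, length, apc, total):
    got_apc, got_total = compute_trail_traffic(gap, length)
    assert got_apc == pytest.approx(apc)
    assert got_total == pytest.approx(total)


@pytest.mark.parametrize("gap, length", [(0, 100), (-5, 100), (10, 0), (10, -1)])
def test_trail_traffic_rejects_nonpositive_measurements(gap, length):
    with pytest.raises(InvalidMeasurementError):
        compute_trail_traffic(gap, length)


@settings(deadline=None, derandomize=True)
@given(
    gap=st.floats(0.5, 500), length=st.floats(1, 10_000), scale=st.floats(0.01, 100)
)
def test_total_ants_invariant_to_length_units(gap, length, scale):
    """Re-expressing both lengths in another unit leaves the ant count."""
    _, total = compute_trail_traffic(gap, length)
    _, total_scaled = compute_trail_traffic(gap * scale, length * scale)
    assert total_scaled == pytest.approx(total, rel=1e-9)


def test_trail_weight_examples():
    assert compute_trail_weight(300, 10_000, 20_000, "internest") == pytest.approx(0.02)
    assert compute_trail_weight(500, 25_000, kind="foraging") == pytest.approx(0.02)
    assert compute_trail_weight(0, 100, 100, "internest") == 0.0


def test_trail_weight_requires_positive_populations():
    with pytest.raises(UndefinedWeightError):
        compute_trail_weight(10, 0, 100, "internest")
    with pytest.raises(UndefinedWeightError):
        compute_trail_weight(10, None, kind="foraging")


def test_star_map_betweenness():
    """One nest feeding on three trees: the nest is the only possible
    intermediary (3 tree-tree pairs); trees are zero."""
    cmap = make_map(
        nests=[("A", 0, 0, 1000)],
        trees=[("T1", 1, 0), ("T2", 0, 1), ("T3", -1, 0)],
        trails=[
            ("f1", "A", "T1", "foraging", 100, 10),
            ("f2", "A", "T2", "foraging", 100, 10),
            ("f3", "A", "T3", "foraging", 100, 10),
        ],
    )
    flow = resource_flow_betweenness(cmap)
    assert flow.raw["A"] == pytest.approx(3.0)
    assert flow.normalized["A"] == pytest.approx(1.0)
    assert all(flow.raw[t] == 0 for t in ("T1", "T2", "T3"))


def test_chain_map_betweenness():
    """T1-A-B-C-T2 with equal weights: raw 3, 4, 3; normalized 0.75, 1, 0.75."""
    flow = resource_flow_betweenness(chain_map())
    assert flow.raw["A"] == pytest.approx(3.0)
    assert flow.raw["B"] == pytest.approx(4.0)
    assert flow.raw["C"] == pytest.approx(3.0)
    assert flow.normalized["A"] == pytest.approx(0.75)
    assert flow.normalized["B"] == pytest.approx(1.0)
    assert flow.raw["T1"] == flow.raw["T2"] == 0.0


def test_single_nest_single_tree_max_zero_rule():
    cmap = make_map(
        nests=[("A", 0, 0, 1000)],
        trees=[("T1", 1, 0)],
        trails=[("f1", "A", "T1", "foraging", 100, 10)],
    )
    flow = resource_flow_betweenness(cmap)
    assert flow.raw["A"] == 0.0
    assert flow.normalized["A"] == 0.0  # all-zero maps normalize to zero
    assert flow.category["A"] == "zero"


def test_betweenness_matches_bruteforce_on_random_small_maps(rng):
    """Exhaustive path enumeration referees the weighted implementation on
    maps of up to 7 nodes; trees are always zero."""
    for _ in range(30):
        cmap = random_small_map(rng)
        flow = resource_flow_betweenness(cmap)
        oracle = brute_force_betweenness(cmap)
        for nid in cmap.nodes:
            assert flow.raw[nid] == pytest.approx(oracle[nid], abs=1e-8), (
                f"betweenness mismatch at {nid}"
            )
        assert all(flow.raw[t] == pytest.approx(0.0) for t in cmap.trees)
        nz = [v for n, v in flow.normalized.items() if n in cmap.nests]
        if max(flow.raw[n] for n in cmap.nests) > 0:
            assert max(nz) == pytest.approx(1.0)
        assert all(-1e-12 <= v <= 1 + 1e-12 for v in flow.normalized.values())


def test_normalized_betweenness_invariant_to_uniform_weight_scaling():
    """Halving every sample gap doubles every weight; shortest-path
    structure, hence normalized betweenness, is unchanged."""
    base = chain_map()
    scaled = make_map(
        nests=[("A", 1, 0, 10_000), ("B", 2, 0, 10_000), ("C", 3, 0, 10_000)],
        trees=[("T1", 0, 0), ("T2", 4, 0)],
        trails=[
            ("f1", "A", "T1", "foraging", 100, 5),
            ("e1", "A", "B", "internest", 100, 5),
            ("e2", "B", "C", "internest", 100, 5),
            ("f2", "C", "T2", "foraging", 100, 5),
        ],
    )
    f1 = resource_flow_betweenness(base)
    f2 = resource_flow_betweenness(scaled)
    for nid in f1.normalized:
        assert f1.normalized[nid] == pytest.approx(f2.normalized[nid])


@pytest.mark.parametrize(
    "value, category",
    [
        (0.0, "zero"), (1.0, "one"), (0.1, "low"), (0.5, "medium"), (0.9, "high"),
        (0.25, "medium"), (0.75, "medium"),  # boundary values fall in medium
        (0.2499, "low"), (0.7501, "high"),
    ],
)
def test_flow_categories(value, category):
    assert categorize_flow(value) == category


@pytest.mark.parametrize("value", [-0.1, 1.1, 2.0])
def test_flow_category_domain_error(value):
    with pytest.raises(ValueError):
        categorize_flow(value)


def test_colony_foraging_effort_sums_foraging_trails_only():
    cmap = make_map(
        nests=[("A", 0, 0, 10_000), ("B", 5, 0, 30_000)],
        trees=[("T1", 1, 1), ("T2", 4, 1)],
        trails=[
            ("e1", "A", "B", "internest", 500, 10),  # excluded from effort
            ("f1", "A", "T1", "foraging", 400, 20),  # 0.5 ants/cm * 400
            ("f2", "B", "T2", "foraging", 300, 10),  # 1.0 ants/cm * 300
        ],
    )
    assert colony_foraging_effort(cmap) == pytest.approx(500.0)
    assert worker_forager_ratio(cmap) == pytest.approx(40_000 / 500)


def test_no_foraging_trails_gives_zero_effort_and_undefined_ratio():
    cmap = make_map(
        nests=[("A", 0, 0, 1000), ("B", 1, 0, 1000)],
        trails=[("e1", "A", "B", "internest", 100, 10)],
    )
    assert colony_foraging_effort(cmap) == 0.0
    with pytest.raises(UndefinedRatioError):
        worker_forager_ratio(cmap)


def test_worker_forager_ratio_extreme_populations():
    """Populations spanning the observed extremes (68 to 288,380 workers)."""
    cmap = make_map(
        nests=[("A", 0, 0, 68), ("B", 5, 0, 288_380)],
        trees=[("T1", 1, 1)],
        trails=[
            ("e1", "A", "B", "internest", 100, 10),
            ("f1", "A", "T1", "foraging", 1000, 10),  # effort 1000
        ],
    )
    assert worker_forager_ratio(cmap) == pytest.approx(288.448)


def test_population_from_volume():
    assert population_from_volume(500, lambda v: v) == 500
    assert population_from_volume(12, lambda v: 100 * v) == 1200
    with pytest.raises(InvalidMeasurementError):
        population_from_volume(0, lambda v: v)
    with pytest.raises(CalibrationError):
        population_from_volume(10, None)


def test_nearest_tree_distance_is_straight_line():
    cmap = make_map(
        nests=[("A", 0, 0, 1000)],
        trees=[("T1", 3, 4), ("T2", 10, 0)],
        trails=[("f1", "A", "T2", "foraging", 1000, 10)],
    )
    # T1 is nearer in a straight line even though the trail goes to T2
    assert nearest_tree_distance(cmap)["A"] == pytest.approx(5.0)


def test_timepoint_ordering_and_parsing():
    tps = [Timepoint.parse(s) for s in ("2013-spring", "2012-summer", "2013-summer")]
    assert [str(t) for t in sorted(tps)] == ["2012-summer", "2013-spring", "2013-summer"]
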