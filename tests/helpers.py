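"""Shared test utilities: map builders and independent brute-force oracles.

The oracles here deliberately avoid the package's own code paths: shortest
paths are enumerated exhaustively, and the Cox partial likelihood is written
as plain nested loops, so they can referee the optimized implementations.
"""

from __future__ import annotations

import itertools
import math

import numpy as np

from polynest.colony import (
    ColonyMap,
    NodeRecord,
    TrailRecord,
    compute_trail_metrics,
)


def make_map(
    nests,
    trees=(),
    trails=(),
    colony_id="C1",
    timepoint="2012-summer",
    metrics=True,
):
    """Build a ColonyMap from terse tuples.

    nests: (id, x, y, population[, canopy]); trees: (id, x, y);
    trails: (id, a, b, kind, length_cm, sample_gap_cm).
    """
    nodes = []
    for t in nests:
        nid, x, y, pop = t[:4]
        canopy = t[4] if len(t) > 4 else None
        nodes.append(NodeRecord(nid, "nest", x, y, population=pop, canopy_cover=canopy))
    for tid, x, y in trees:
        nodes.append(NodeRecord(tid, "tree", x, y))
    trail_records = [
        TrailRecord(tid, a, b, kind, length, gap)
        for tid, a, b, kind, length, gap in trails
    ]
    cmap = ColonyMap.from_records(colony_id, timepoint, nodes, trail_records)
    return compute_trail_metrics(cmap) if metrics else cmap


def brute_force_betweenness(cmap: ColonyMap) -> dict[str, float]:
    """Raw betweenness by exhaustive enumeration of all simple paths.

    Edge cost is 1/weight; endpoints are excluded; each unordered node pair
    counts once; equally short paths (within 1e-9 relative) split their
    contribution fractionally.  Usable only on tiny maps.
    """
    adj: dict[str, dict[str, float]] = {nid: {} for nid in cmap.nodes}
    for t in cmap.trails.values():
        if t.weight is None or t.weight <= 0:
            continue
        cost = 1.0 / t.weight
        adj[t.endpoint_a][t.endpoint_b] = cost
        adj[t.endpoint_b][t.endpoint_a] = cost

    def all_paths(s, goal):
        stack = [(s, [s], 0.0)]
        while stack:
            v, path, cost = stack.pop()
            if v == goal:
                yield path, cost
                continue
            for w, c in adj[v].items():
                if w not in path:
                    stack.append((w, path + [w], cost + c))

    raw = {nid: 0.0 for nid in cmap.nodes}
    for s, t in itertools.combinations(sorted(cmap.nodes), 2):
        paths = list(all_paths(s, t))
        if not paths:
            continue
        best_cost = min(c for _, c in paths)
        shortest = [p for p, c in paths if c <= best_cost * (1 + 1e-9) + 1e-12]
        for p in shortest:
            for interior in p[1:-1]:
                raw[interior] += 1.0 / len(shortest)
    return raw


def random_small_map(rng: np.random.Generator, max_nodes: int = 7) -> ColonyMap:
    """A random connected map with <= max_nodes nodes, trees terminal."""
    n_nests = int(rng.integers(1, max_nodes))
    n_trees = int(rng.integers(0, max_nodes - n_nests + 1))
    nests = [
        (f"N{i}", float(rng.uniform(0, 20)), float(rng.uniform(0, 20)),
         int(rng.integers(500, 50_000)))
        for i in range(n_nests)
    ]
    trees = [
        (f"T{i}", float(rng.uniform(0, 20)), float(rng.uniform(0, 20)))
        for i in range(n_trees)
    ]
    trails = []
    k = 0
    # random spanning tree over nests, plus occasional extra edges
    for i in range(1, n_nests):
        j = int(rng.integers(0, i))
        trails.append((f"E{k}", f"N{i}", f"N{j}", "internest",
                       float(rng.uniform(200, 2000)), float(rng.uniform(5, 120))))
        k += 1
    for i in range(n_nests):
        for j in range(i + 1, n_nests):
            if rng.uniform() < 0.2 and not any(
                set(t[1:3]) == {f"N{i}", f"N{j}"} for t in trails
            ):
                trails.append((f"E{k}", f"N{i}", f"N{j}", "internest",
                               float(rng.uniform(200, 2000)), float(rng.uniform(5, 120))))
                k += 1
    for i in range(n_trees):
        owner = int(rng.integers(0, n_nests))
        trails.append((f"F{k}", f"N{owner}", f"T{i}", "foraging",
                       float(rng.uniform(200, 2000)), float(rng.uniform(5, 120))))
        k += 1
    return make_map(nests, trees, trails)


def chain_map():
    """T1 -- A -- B -- C -- T2 with all trail weights equal."""
    nests = [("A", 1, 0, 10_000), ("B", 2, 0, 10_000), ("C", 3, 0, 10_000)]
    trees = [("T1", 0, 0), ("T2", 4, 0)]
    trails = [
        ("f1", "A", "T1", "foraging", 100, 10),
        ("e1", "A", "B", "internest", 100, 10),
        ("e2", "B", "C", "internest", 100, 10),
        ("f2", "C", "T2", "foraging", 100, 10),
    ]
    return make_map(nests, trees, trails)


def naive_cox_partial_loglik(
    beta: float,
    x: np.ndarray,
    start: np.ndarray,
    stop: np.ndarray,
    event: np.ndarray,
    ties: str = "efron",
) -> float:
    """Single-covariate partial log-likelihood written as plain loops
    (independent of the package's vectorized fitter)."""
    ll = 0.0
    for t in sorted({float(s) for s, e in zip(stop, event) if e}):
        deaths = [i for i in range(len(x)) if event[i] and stop[i] == t]
        risk = [i for i in range(len(x)) if start[i] < t <= stop[i]]
        d = len(deaths)
        s_r = sum(math.exp(beta * x[i]) for i in risk)
        s_d = sum(math.exp(beta * x[i]) for i in deaths)
        ll += sum(beta * x[i] for i in deaths)
        for l in range(d):
            frac = l / d if (ties == "efron" and d > 1) else 0.0
            ll -= math.log(s_r - frac * s_d)
    return ll


def grid_search_cox(x, start, stop, event, ties="efron", lo=-5.0, hi=5.0, step=0.001):
    """Brute-force grid maximization of the naive partial likelihood."""
    grid = np.arange(lo, hi + step / 2, step)
    lls = [naive_cox_partial_loglik(b, x, start, stop, event, ties) for b in grid]
    return float(grid[int(np.argmax(lls))])
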