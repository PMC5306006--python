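"""Static colony maps and per-map network metrics.

A polydomous wood ant colony at one mapping timepoint is represented as a
spatially embedded, weighted graph.  Nests and the trees they forage on are
nodes; internest trails (nest--nest) and foraging trails (nest--tree) are
edges.  Trail traffic is measured in the field as the length of trail needed
to find 10 workers, which converts into ants per cm and a total ant count for
the trail; trail *weight* expresses that count relative to the population of
the connected nest(s).

The central network-position metric is resource-flow betweenness: weighted
betweenness centrality computed with edge cost ``1/weight`` (shortest-path
algorithms treat edge values as costs, so strong trails must be cheap),
normalized per map to the largest nest value.  Trees sit at the end of their
own branch and always carry betweenness zero.
"""

from __future__ import annotations

import functools
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Callable, Iterable

import networkx as nx
import pandas as pd

logger = logging.getLogger(__name__)

NEST = "nest"
TREE = "tree"
INTERNEST = "internest"
FORAGING = "foraging"

SEASONS = ("spring", "summer")

FLOW_CATEGORIES = ("zero", "low", "medium", "high", "one")


class InvalidMeasurementError(ValueError):
    """A field measurement (trail length, sample gap, volume) is not positive."""


class UndefinedWeightError(ValueError):
    """A trail weight cannot be formed because a nest population is zero/absent."""


class UndefinedRatioError(ValueError):
    """The worker:forager ratio is undefined (zero colony foraging effort)."""


class CalibrationError(ValueError):
    """No mound-volume -> population calibration supplied."""


@functools.total_ordering
@dataclass(frozen=True)
class Timepoint:
    """A mapping occasion: year plus season (spring = start, summer = height
    of the foraging season).  Ordered chronologically; serialized as
    ``YYYY-season``."""

    year: int
    season: str

    def __post_init__(self) -> None:
        if self.season not in SEASONS:
            raise ValueError(f"season must be one of {SEASONS}, got {self.season!r}")

    @classmethod
    def parse(cls, label: str) -> "Timepoint":
        year, _, season = str(label).partition("-")
        return cls(int(year), season.strip().lower())

    @property
    def _key(self) -> tuple[int, int]:
        return (self.year, SEASONS.index(self.season))

    def __lt__(self, other: "Timepoint") -> bool:
        return self._key < other._key

    def __str__(self) -> str:
        return f"{self.year}-{self.season}"


@dataclass(frozen=True)
class NodeRecord:
    """One node of a colony map: a nest (with population, mound volume and
    canopy cover) or a tree (optionally with species)."""

    node_id: str
    kind: str
    x: float
    y: float
    population: int | None = None
    mound_volume: float | None = None
    canopy_cover: float | None = None
    species: str | None = None

    def __post_init__(self) -> None:
        if self.kind not in (NEST, TREE):
            raise ValueError(f"node kind must be 'nest' or 'tree', got {self.kind!r}")
        if self.kind == TREE:
            if self.population is not None or self.canopy_cover is not None:
                raise ValueError(
                    f"tree {self.node_id!r} must not carry population/canopy attributes"
                )
        else:
            if self.population is not None and self.population < 0:
                raise ValueError(f"nest {self.node_id!r}: population must be >= 0")
            if self.canopy_cover is not None and not 0.0 <= self.canopy_cover <= 1.0:
                raise ValueError(f"nest {self.node_id!r}: canopy_cover must be in [0,1]")

    @property
    def is_nest(self) -> bool:
        return self.kind == NEST


@dataclass(frozen=True)
class TrailRecord:
    """One trail.  ``sample_gap_cm`` is the trail length needed to find 10
    workers; the derived fields (``ants_per_cm``, ``total_ants``, ``weight``)
    are filled by :func:`compute_trail_metrics`."""

    trail_id: str
    endpoint_a: str
    endpoint_b: str
    kind: str
    length_cm: float
    sample_gap_cm: float
    ants_per_cm: float | None = None
    total_ants: float | None = None
    weight: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in (INTERNEST, FORAGING):
            raise ValueError(
                f"trail kind must be 'internest' or 'foraging', got {self.kind!r}"
            )
        if self.length_cm <= 0 or self.sample_gap_cm <= 0:
            raise InvalidMeasurementError(
                f"trail {self.trail_id!r}: length_cm and sample_gap_cm must be > 0"
            )

    @property
    def endpoints(self) -> tuple[str, str]:
        return (self.endpoint_a, self.endpoint_b)


@dataclass
class ColonyMap:
    """One colony at one timepoint: node records plus trail records.

    A polydomous colony proper has two or more nests connected by internest
    trails; maps failing that definition are kept but flagged degenerate.
    """

    colony_id: str
    timepoint: Timepoint
    nodes: dict[str, NodeRecord] = field(default_factory=dict)
    trails: dict[str, TrailRecord] = field(default_factory=dict)

    @classmethod
    def from_records(
        cls,
        colony_id: str,
        timepoint: Timepoint | str,
        nodes: Iterable[NodeRecord],
        trails: Iterable[TrailRecord],
        validate: bool = True,
    ) -> "ColonyMap":
        if isinstance(timepoint, str):
            timepoint = Timepoint.parse(timepoint)
        node_map: dict[str, NodeRecord] = {}
        for n in nodes:
            if n.node_id in node_map:
                raise ValueError(f"duplicate node_id {n.node_id!r} in map")
            node_map[n.node_id] = n
        trail_map: dict[str, TrailRecord] = {}
        for t in trails:
            if t.trail_id in trail_map:
                raise ValueError(f"duplicate trail_id {t.trail_id!r} in map")
            trail_map[t.trail_id] = t
        cmap = cls(colony_id, timepoint, node_map, trail_map)
        if validate:
            cmap.validate()
        return cmap

    def validate(self) -> None:
        for t in self.trails.values():
            for e in t.endpoints:
                if e not in self.nodes:
                    raise ValueError(
                        f"trail {t.trail_id!r} references unknown node {e!r}"
                    )
            kinds = {self.nodes[t.endpoint_a].kind, self.nodes[t.endpoint_b].kind}
            if t.kind == FORAGING and kinds != {NEST, TREE}:
                raise ValueError(
                    f"foraging trail {t.trail_id!r} must join exactly one nest and one tree"
                )
            if t.kind == INTERNEST and kinds != {NEST}:
                raise ValueError(
                    f"internest trail {t.trail_id!r} must join two nests"
                )
        if self.is_degenerate:
            logger.debug(
                "map %s@%s is degenerate (fewer than two internest-connected nests)",
                self.colony_id,
                self.timepoint,
            )

    @property
    def nests(self) -> dict[str, NodeRecord]:
        return {i: n for i, n in self.nodes.items() if n.kind == NEST}

    @property
    def trees(self) -> dict[str, NodeRecord]:
        return {i: n for i, n in self.nodes.items() if n.kind == TREE}

    @property
    def internest_trails(self) -> dict[str, TrailRecord]:
        return {i: t for i, t in self.trails.items() if t.kind == INTERNEST}

    @property
    def foraging_trails(self) -> dict[str, TrailRecord]:
        return {i: t for i, t in self.trails.items() if t.kind == FORAGING}

    @property
    def is_degenerate(self) -> bool:
        """True when the map does not satisfy the polydomous-colony
        definition (>= 2 nests joined by internest trails)."""
        return len(self.nests) < 2 or not self.internest_trails

    def distance(self, a: str, b: str) -> float:
        na, nb = self.nodes[a], self.nodes[b]
        return math.hypot(na.x - nb.x, na.y - nb.y)


@dataclass
class FlowTable:
    """Per-node resource-flow betweenness for one map: raw, normalized to
    the largest nest value, and the categorical band used for display."""

    colony_id: str
    timepoint: Timepoint
    raw: dict[str, float]
    normalized: dict[str, float]
    category: dict[str, str]

    def to_frame(self) -> pd.DataFrame:
        ids = sorted(self.raw)
        return pd.DataFrame(
            {
                "node_id": ids,
                "raw_betweenness": [self.raw[i] for i in ids],
                "normalized_betweenness": [self.normalized[i] for i in ids],
                "flow_category": [self.category[i] for i in ids],
            }
        )


def compute_trail_traffic(sample_gap_cm: float, length_cm: float) -> tuple[float, float]:
    """Convert a 10-worker sample gap into (ants per cm, total ants on trail)."""
    if sample_gap_cm <= 0 or length_cm <= 0:
        raise InvalidMeasurementError(
            f"sample_gap_cm and length_cm must be > 0 "
            f"(got {sample_gap_cm!r}, {length_cm!r})"
        )
    ants_per_cm = 10.0 / sample_gap_cm
    return ants_per_cm, ants_per_cm * length_cm


def compute_trail_weight(
    total_ants: float,
    pop_a: float | None,
    pop_b: float | None = None,
    kind: str = INTERNEST,
) -> float:
    """Trail strength relative to nest population.

    Internest trails: total ants divided by the mean population of the two
    connected nests.  Foraging trails: total ants divided by the population
    of the single foraging nest (pass it as ``pop_a``).
    """
    if kind == INTERNEST:
        if not pop_a or not pop_b or pop_a <= 0 or pop_b <= 0:
            raise UndefinedWeightError(
                f"internest weight needs two positive nest populations, got {pop_a!r}, {pop_b!r}"
            )
        return total_ants / ((pop_a + pop_b) / 2.0)
    if kind == FORAGING:
        if not pop_a or pop_a <= 0:
            raise UndefinedWeightError(
                f"foraging weight needs a positive foraging-nest population, got {pop_a!r}"
            )
        return total_ants / pop_a
    raise ValueError(f"unknown trail kind {kind!r}")


def compute_trail_metrics(cmap: ColonyMap) -> ColonyMap:
    """Return a copy of the map with ants_per_cm, total_ants and weight
    filled in for every trail."""
    new_trails: dict[str, TrailRecord] = {}
    for tid, t in cmap.trails.items():
        apc, total = compute_trail_traffic(t.sample_gap_cm, t.length_cm)
        na, nb = cmap.nodes[t.endpoint_a], cmap.nodes[t.endpoint_b]
        if t.kind == INTERNEST:
            if na.population is None or nb.population is None:
                raise UndefinedWeightError(
                    f"trail {tid!r}: nest population missing on "
                    f"{na.node_id if na.population is None else nb.node_id!r}"
                )
            w = compute_trail_weight(total, na.population, nb.population, INTERNEST)
        else:
            nest = na if na.kind == NEST else nb
            if nest.population is None:
                raise UndefinedWeightError(
                    f"trail {tid!r}: population missing on foraging nest {nest.node_id!r}"
                )
            w = compute_trail_weight(total, nest.population, kind=FORAGING)
        new_trails[tid] = replace(t, ants_per_cm=apc, total_ants=total, weight=w)
    return ColonyMap(cmap.colony_id, cmap.timepoint, dict(cmap.nodes), new_trails)


def to_networkx(cmap: ColonyMap, flow: "FlowTable | None" = None) -> nx.Graph:
    """Undirected networkx view of a map, with node/trail attributes and the
    shortest-path edge cost ``1/weight``.  Zero-weight trails carry no cost
    (they are unusable for flow and are skipped by the betweenness graph)."""
    G = nx.Graph(colony_id=cmap.colony_id, timepoint=str(cmap.timepoint))
    for nid, n in cmap.nodes.items():
        attrs = {"kind": n.kind, "x": n.x, "y": n.y}
        for f in ("population", "mound_volume", "canopy_cover", "species"):
            v = getattr(n, f)
            if v is not None:
                attrs[f] = v
        if flow is not None and nid in flow.raw:
            attrs["raw_betweenness"] = flow.raw[nid]
            attrs["normalized_betweenness"] = flow.normalized[nid]
            attrs["flow_category"] = flow.category[nid]
        G.add_node(nid, **attrs)
    for tid, t in cmap.trails.items():
        attrs = {
            "trail_id": tid,
            "kind": t.kind,
            "length_cm": t.length_cm,
            "sample_gap_cm": t.sample_gap_cm,
        }
        for f in ("ants_per_cm", "total_ants", "weight"):
            v = getattr(t, f)
            if v is not None:
                attrs[f] = v
        if t.weight is not None and t.weight > 0:
            attrs["cost"] = 1.0 / t.weight
        G.add_edge(t.endpoint_a, t.endpoint_b, **attrs)
    return G


def _betweenness_graph(cmap: ColonyMap) -> nx.Graph:
    G = nx.Graph()
    G.add_nodes_from(cmap.nodes)
    for tid, t in cmap.trails.items():
        if t.weight is None:
            raise ValueError(
                f"trail {tid!r} has no weight; run compute_trail_metrics first"
            )
        if t.weight <= 0:
            logger.info(
                "map %s@%s: zero-weight trail %s unusable for flow, excluded "
                "from shortest paths",
                cmap.colony_id, cmap.timepoint, tid,
            )
            continue
        G.add_edge(t.endpoint_a, t.endpoint_b, cost=1.0 / t.weight)
    return G


def resource_flow_betweenness(cmap: ColonyMap) -> FlowTable:
    """Weighted betweenness centrality as a proxy for resource flow.

    Shortest paths are computed on the undirected graph with edge cost
    ``1/weight``; every node pair (trees included) contributes; path
    endpoints are excluded; equally short paths split their contribution
    fractionally.  Raw values are normalized to the largest value among
    nests; if that maximum is zero all normalized values are zero.
    """
    if not cmap.nodes:
        raise ValueError("map has no nodes")
    G = _betweenness_graph(cmap)
    if G.number_of_nodes() > 1 and not nx.is_connected(G):
        logger.warning(
            "map %s@%s is disconnected; betweenness computed within components",
            cmap.colony_id, cmap.timepoint,
        )
    raw = nx.betweenness_centrality(G, normalized=False, weight="cost", endpoints=False)
    for tid, node in cmap.trees.items():
        if raw.get(tid, 0.0) > 1e-12:
            logger.warning(
                "map %s@%s: tree %s lies on shortest paths (betweenness %.3g); "
                "the terminal-tree assumption is violated",
                cmap.colony_id, cmap.timepoint, tid, raw[tid],
            )
    nest_max = max((raw[i] for i in cmap.nests), default=0.0)
    if nest_max > 0:
        normalized = {i: raw[i] / nest_max for i in raw}
    else:
        normalized = {i: 0.0 for i in raw}
    category = {i: categorize_flow(min(v, 1.0)) for i, v in normalized.items()}
    return FlowTable(cmap.colony_id, cmap.timepoint, dict(raw), normalized, category)


def trail_betweenness(cmap: ColonyMap) -> dict[str, dict[str, float]]:
    """Edge betweenness of every trail (a colony-level attribute: importance
    of the trail to colony-wide resource flow), raw and normalized to the
    largest internest-trail value within the map."""
    G = _betweenness_graph(cmap)
    edge_raw = nx.edge_betweenness_centrality(G, normalized=False, weight="cost")
    out: dict[str, dict[str, float]] = {}
    raw_by_trail = {}
    for tid, t in cmap.trails.items():
        key = (t.endpoint_a, t.endpoint_b)
        raw_by_trail[tid] = edge_raw.get(key, edge_raw.get(key[::-1], 0.0))
    max_internest = max(
        (raw_by_trail[tid] for tid in cmap.internest_trails), default=0.0
    )
    for tid, v in raw_by_trail.items():
        norm = v / max_internest if max_internest > 0 else 0.0
        out[tid] = {"raw": v, "normalized": norm}
    return out


def categorize_flow(value: float) -> str:
    """Band a normalized betweenness value: exact 0 -> ``zero``; exact 1 ->
    ``one``; (0, 0.25) -> ``low``; [0.25, 0.75] -> ``medium``;
    (0.75, 1) -> ``high``.  Boundary values 0.25/0.75 fall in ``medium``."""
    if not 0.0 <= value <= 1.0:
        raise ValueError(f"normalized betweenness must be in [0,1], got {value!r}")
    if value == 0.0:
        return "zero"
    if value == 1.0:
        return "one"
    if value < 0.25:
        return "low"
    if value <= 0.75:
        return "medium"
    return "high"


def colony_foraging_effort(cmap: ColonyMap) -> float:
    """Instantaneous number of workers on foraging trails: sum over foraging
    trails of ants_per_cm x length_cm (a resource-acquisition effort measure,
    not a forager count)."""
    total = 0.0
    saw_foraging = False
    for t in cmap.foraging_trails.values():
        if t.ants_per_cm is None:
            raise ValueError(
                f"trail {t.trail_id!r} has no traffic; run compute_trail_metrics first"
            )
        saw_foraging = True
        total += t.ants_per_cm * t.length_cm
    if not saw_foraging:
        logger.warning(
            "map %s@%s has no foraging trails; foraging effort is 0",
            cmap.colony_id, cmap.timepoint,
        )
    return total


def worker_forager_ratio(cmap: ColonyMap) -> float:
    """Total colony population / colony foraging effort.  High values mean
    low foraging effort per worker."""
    pops = [n.population for n in cmap.nests.values()]
    if any(p is None for p in pops):
        missing = [i for i, n in cmap.nests.items() if n.population is None]
        raise UndefinedWeightError(f"nest populations missing: {missing}")
    effort = colony_foraging_effort(cmap)
    if effort <= 0:
        raise UndefinedRatioError(
            f"map {cmap.colony_id}@{cmap.timepoint}: zero foraging effort, "
            "worker:forager ratio undefined"
        )
    return float(sum(pops)) / effort


def population_from_volume(
    volume: float, calibration: Callable[[float], float] | None
) -> int:
    """Estimate a nest's worker population from its mound volume (litres)
    through a site-specific monotone calibration (e.g. fitted to
    mark--release--recapture data).  No default calibration exists; the
    caller must supply one."""
    if calibration is None:
        raise CalibrationError(
            "no mound-volume calibration supplied; provide a monotone "
            "callable volume (L) -> workers fitted for your site"
        )
    if volume <= 0:
        raise InvalidMeasurementError(f"mound volume must be > 0, got {volume!r}")
    pop = round(calibration(volume))
    if pop < 0:
        raise InvalidMeasurementError(
            f"calibration returned a negative population ({pop}) for volume {volume!r}"
        )
    return int(pop)


def nearest_tree_distance(cmap: ColonyMap) -> dict[str, float]:
    """Straight-line (not along-trail) distance from each nest to the
    nearest tree anywhere in the map; NaN when the map has no trees."""
    trees = list(cmap.trees.values())
    out: dict[str, float] = {}
    for nid, n in cmap.nests.items():
        if not trees:
            out[nid] = float("nan")
        else:
            out[nid] = min(math.hypot(n.x - t.x, n.y - t.y) for t in trees)
    return out


def colony_summary(cmap: ColonyMap) -> dict[str, float | int | str]:
    """One-line per-map summary (nest/tree/trail counts, total population,
    foraging effort, worker:forager ratio where defined)."""
    pops = [n.population or 0 for n in cmap.nests.values()]
    try:
        ratio: float | None = worker_forager_ratio(cmap)
    except (UndefinedRatioError, UndefinedWeightError, ValueError):
        ratio = None
    return {
        "colony_id": cmap.colony_id,
        "timepoint": str(cmap.timepoint),
        "n_nests": len(cmap.nests),
        "n_trees": len(cmap.trees),
        "n_internest_trails": len(cmap.internest_trails),
        "n_foraging_trails": len(cmap.foraging_trails),
        "total_population": int(sum(pops)),
        "worker_forager_ratio": float("nan") if ratio is None else ratio,
        "degenerate": cmap.is_degenerate,
    }
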