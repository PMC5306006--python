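"""Synthetic dynamic polydomous-colony generator with known ground truth.

Emulates the structure of multi-year wood ant colony field maps: around a
dozen colonies of 2-21 nests each, mapped five times (summer of year one,
then spring and summer of the following two years), nests with lognormal
worker populations spanning tens to over a million workers, trees as
terminal nodes attached by a single foraging trail, and internest trails
carrying measured traffic.

Dynamics are planted on the logit scale.  Per interval each nest is
abandoned with probability

    logistic(logit(p_abandon) + b_sb * betweenness + b_ss * z(log pop))

and each survivor buds a new nest with probability

    logistic(logit(p_bud) + b_bb * betweenness + b_bd * d_betweenness).

New nests appear next to their natal nest and are trail-connected to it
(satisfying the founder-inference assumption), and all metrics are
recomputed each timepoint so betweenness feeds back dynamically as nests
appear and disappear.  Every planted event is logged to a :class:`SimTruth`
ledger, which downstream modules are tested against.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import yaml

from .colony import (
    ColonyMap,
    FORAGING,
    INTERNEST,
    NEST,
    NodeRecord,
    TREE,
    Timepoint,
    TrailRecord,
    compute_trail_metrics,
    resource_flow_betweenness,
)
from .events import ColonyTimeSeries

logger = logging.getLogger(__name__)


def _roman(i: int) -> str:
    numerals = [
        (10, "X"), (9, "IX"), (5, "V"), (4, "IV"), (1, "I"),
    ]
    out = ""
    n = i
    while n > 0:
        for v, s in numerals:
            if n >= v:
                out += s
                n -= v
                break
    return out


@dataclass
class SimConfig:
    """Generator parameters.  Defaults emulate the field study conditions:
    13 colonies, five seasonal timepoints, 2-21 initial nests, lognormal
    nest populations reaching from tens of workers into the millions."""

    n_colonies: int = 13
    n_timepoints: int = 5
    initial_nests_range: tuple[int, int] = (2, 21)
    trees_per_colony_range: tuple[int, int] = (4, 14)
    arena_size_m: float = 40.0
    min_nest_separation_m: float = 3.0
    population_lognormal: tuple[float, float] = (9.8, 1.6)  # (mu, sigma) of log workers
    new_nest_population_offset: float = -1.5  # log-scale shift for freshly budded nests
    sample_gap_lognormal: tuple[float, float] = (math.log(30.0), 0.8)  # cm to 10 workers
    traffic_season_sigma: float = 0.3  # per-timepoint lognormal jitter on sample gaps
    population_drift_sigma: float = 0.15  # per-interval lognormal drift of populations
    extra_trail_prob: float = 0.35  # chance of a cycle-forming extra internest trail
    connect_radius_m: float = 15.0
    # planted effects (log-hazard / log-odds scale)
    beta_survival_betweenness: float = -2.0
    beta_survival_size: float = 0.0
    beta_bud_betweenness: float = 3.0
    beta_bud_delta: float = 0.0
    baseline_abandonment_prob: float = 0.20
    baseline_budding_prob: float = 0.025
    trail_dropout_prob: float = 0.08
    start_year: int = 2012
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (
            self.baseline_abandonment_prob,
            self.baseline_budding_prob,
            self.trail_dropout_prob,
        ):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must lie in [0, 1]")
        if self.initial_nests_range[0] > self.initial_nests_range[1]:
            raise ValueError("initial_nests_range is empty")
        if self.n_timepoints < 1 or self.n_colonies < 1:
            raise ValueError("need at least one colony and one timepoint")

    def timepoints(self) -> list[Timepoint]:
        tps = [Timepoint(self.start_year, "summer")]
        year, season = self.start_year, "summer"
        while len(tps) < self.n_timepoints:
            if season == "summer":
                year, season = year + 1, "spring"
            else:
                season = "summer"
            tps.append(Timepoint(year, season))
        return tps

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SimTruth:
    """Ledger of everything the generator planted."""

    config: SimConfig
    seed: int
    # per colony: list over intervals of event dicts
    abandoned: dict[str, list[dict[str, float]]] = field(default_factory=dict)
    founded: dict[str, list[dict[str, str]]] = field(default_factory=dict)
    forced_survivals: dict[str, list[list[str]]] = field(default_factory=dict)

    def effect_sizes(self) -> dict[str, float]:
        c = self.config
        return {
            "beta_survival_betweenness": c.beta_survival_betweenness,
            "beta_survival_size": c.beta_survival_size,
            "beta_bud_betweenness": c.beta_bud_betweenness,
            "beta_bud_delta": c.beta_bud_delta,
        }

    def to_json_dict(self) -> dict:
        return {
            "seed": self.seed,
            "effect_sizes": self.effect_sizes(),
            "abandoned": self.abandoned,
            "founded": self.founded,
            "forced_survivals": self.forced_survivals,
        }


def _logistic_prob(baseline: float, shift: float) -> float:
    if baseline <= 0.0:
        return 0.0
    if baseline >= 1.0:
        return 1.0
    logit = math.log(baseline / (1.0 - baseline)) + shift
    return 1.0 / (1.0 + math.exp(-logit))


@dataclass
class _Nest:
    nest_id: str
    x: float
    y: float
    population: float
    canopy: float


class _ColonySim:
    """State of one simulated colony while stepping through timepoints."""

    def __init__(self, colony_id: str, config: SimConfig, rng: np.random.Generator):
        self.colony_id = colony_id
        self.cfg = config
        self.rng = rng
        self.next_nest = 1
        self.nests: dict[str, _Nest] = {}
        n0 = int(rng.integers(config.initial_nests_range[0], config.initial_nests_range[1] + 1))
        for _ in range(n0):
            self._add_nest(self._place_anywhere())
        # trees are static across timepoints (honeydew sources are stable)
        n_trees = int(rng.integers(config.trees_per_colony_range[0], config.trees_per_colony_range[1] + 1))
        self.trees = {
            f"T{k + 1:02d}": (
                float(rng.uniform(0, config.arena_size_m)),
                float(rng.uniform(0, config.arena_size_m)),
            )
            for k in range(n_trees)
        }
        # base sample gaps per trail key; per-timepoint jitter applied on top
        self.base_gap: dict[tuple[str, str], float] = {}
        self.internest: set[tuple[str, str]] = set()
        self._rebuild_trails(initial=True)

    # --- placement -------------------------------------------------------
    def _place_anywhere(self) -> tuple[float, float]:
        a = self.cfg.arena_size_m
        for _ in range(200):
            x, y = self.rng.uniform(0, a), self.rng.uniform(0, a)
            if all(
                math.hypot(x - n.x, y - n.y) >= self.cfg.min_nest_separation_m
                for n in self.nests.values()
            ):
                return float(x), float(y)
        return float(self.rng.uniform(0, a)), float(self.rng.uniform(0, a))

    def _add_nest(self, xy: tuple[float, float], log_offset: float = 0.0) -> str:
        mu, sigma = self.cfg.population_lognormal
        pop = max(50.0, float(np.exp(self.rng.normal(mu + log_offset, sigma))))
        nid = f"N{self.next_nest:03d}"
        self.next_nest += 1
        self.nests[nid] = _Nest(nid, xy[0], xy[1], pop, float(self.rng.uniform(0.2, 0.95)))
        return nid

    # --- trail structure -------------------------------------------------
    def _key(self, a: str, b: str) -> tuple[str, str]:
        return (a, b) if a < b else (b, a)

    def _mst_edges(self) -> set[tuple[str, str]]:
        ids = sorted(self.nests)
        if len(ids) < 2:
            return set()
        # Prim's algorithm on Euclidean distances
        in_tree = {ids[0]}
        edges: set[tuple[str, str]] = set()
        while len(in_tree) < len(ids):
            best = None
            for a in sorted(in_tree):
                na = self.nests[a]
                for b in ids:
                    if b in in_tree:
                        continue
                    d = math.hypot(na.x - self.nests[b].x, na.y - self.nests[b].y)
                    if best is None or d < best[0]:
                        best = (d, a, b)
            edges.add(self._key(best[1], best[2]))
            in_tree.add(best[2])
        return edges

    def _rebuild_trails(self, initial: bool = False) -> None:
        """Internest structure: Euclidean MST backbone plus occasional
        near-neighbour extras forming cycles."""
        ids = sorted(self.nests)
        edges = self._mst_edges()
        for a in ids:
            na = self.nests[a]
            others = sorted(
                (math.hypot(na.x - self.nests[b].x, na.y - self.nests[b].y), b)
                for b in ids if b != a
            )
            for d, b in others[:2]:
                key = self._key(a, b)
                if key not in edges and d <= self.cfg.connect_radius_m:
                    if self.rng.uniform() < self.cfg.extra_trail_prob:
                        edges.add(key)
        self.internest = edges
        for key in edges:
            if key not in self.base_gap:
                self.base_gap[key] = self._draw_gap()
        # each tree forages to its nearest nest only -> trees stay terminal
        self.tree_owner: dict[str, str] = {}
        for tid, (tx, ty) in self.trees.items():
            owner = min(ids, key=lambda n: (math.hypot(tx - self.nests[n].x, ty - self.nests[n].y), n))
            self.tree_owner[tid] = owner
            key = self._key(tid, owner)
            if key not in self.base_gap:
                self.base_gap[key] = self._draw_gap()

    def _draw_gap(self) -> float:
        mu, sigma = self.cfg.sample_gap_lognormal
        return float(np.exp(self.rng.normal(mu, sigma)))

    # --- map emission ----------------------------------------------------
    def emit_map(self, timepoint: Timepoint) -> ColonyMap:
        nodes = []
        for nid in sorted(self.nests):
            n = self.nests[nid]
            pop = int(round(n.population))
            nodes.append(NodeRecord(
                node_id=nid, kind=NEST, x=n.x, y=n.y, population=pop,
                mound_volume=round(pop / 2000.0, 3), canopy_cover=round(n.canopy, 3),
            ))
        for tid in sorted(self.trees):
            tx, ty = self.trees[tid]
            nodes.append(NodeRecord(node_id=tid, kind=TREE, x=tx, y=ty, species="Pinus sylvestris"))
        trails = []
        jitter_sigma = self.cfg.traffic_season_sigma
        k = 1
        for a, b in sorted(self.internest):
            gap = self.base_gap[(a, b)]
            if jitter_sigma > 0:
                gap *= float(np.exp(self.rng.normal(0.0, jitter_sigma)))
            na, nb = self.nests[a], self.nests[b]
            length = max(100.0, math.hypot(na.x - nb.x, na.y - nb.y) * 100.0)
            trails.append(TrailRecord(
                trail_id=f"E{k:03d}", endpoint_a=a, endpoint_b=b, kind=INTERNEST,
                length_cm=round(length, 1), sample_gap_cm=round(gap, 2),
            ))
            k += 1
        for tid in sorted(self.trees):
            owner = self.tree_owner[tid]
            gap = self.base_gap[self._key(tid, owner)]
            if jitter_sigma > 0:
                gap *= float(np.exp(self.rng.normal(0.0, jitter_sigma)))
            tx, ty = self.trees[tid]
            n = self.nests[owner]
            length = max(100.0, math.hypot(n.x - tx, n.y - ty) * 100.0)
            trails.append(TrailRecord(
                trail_id=f"F{tid}", endpoint_a=owner, endpoint_b=tid, kind=FORAGING,
                length_cm=round(length, 1), sample_gap_cm=round(gap, 2),
            ))
        cmap = ColonyMap.from_records(self.colony_id, timepoint, nodes, trails)
        return compute_trail_metrics(cmap)

    # --- one interval of dynamics ---------------------------------------
    def step(
        self, cmap: ColonyMap, prev_betw: dict[str, float] | None, truth: SimTruth
    ) -> dict[str, float]:
        cfg = self.cfg
        flow = resource_flow_betweenness(cmap)
        betw = {nid: flow.normalized[nid] for nid in self.nests}
        logpops = np.array([math.log(self.nests[n].population) for n in sorted(self.nests)])
        z = (logpops - logpops.mean()) / logpops.std() if logpops.std() > 0 else logpops * 0.0
        zmap = dict(zip(sorted(self.nests), z))

        occupied_at_t = [(n.x, n.y) for n in self.nests.values()]
        abandoned: dict[str, float] = {}
        for nid in sorted(self.nests):
            shift = cfg.beta_survival_betweenness * betw[nid] + cfg.beta_survival_size * zmap[nid]
            p = _logistic_prob(cfg.baseline_abandonment_prob, shift)
            if self.rng.uniform() < p:
                abandoned[nid] = shift
        forced: list[str] = []
        if abandoned and len(abandoned) == len(self.nests):
            keep = sorted(abandoned)[int(self.rng.integers(len(abandoned)))]
            del abandoned[keep]
            forced.append(keep)
            logger.warning(
                "colony %s: every nest drew abandonment; %s kept (uniformly at random)",
                self.colony_id, keep,
            )
        for nid in abandoned:
            del self.nests[nid]

        founded: dict[str, str] = {}
        bud_lp: dict[str, float] = {}
        for nid in sorted(self.nests):
            d_b = betw[nid] - prev_betw.get(nid, betw[nid]) if prev_betw else 0.0
            shift = cfg.beta_bud_betweenness * betw[nid] + cfg.beta_bud_delta * d_b
            p = _logistic_prob(cfg.baseline_budding_prob, shift)
            if self.rng.uniform() < p:
                natal = self.nests[nid]
                placed = None
                for _ in range(20):
                    ang = self.rng.uniform(0, 2 * math.pi)
                    r = self.rng.uniform(2.6, 5.0)
                    x = min(max(natal.x + r * math.cos(ang), 0.0), cfg.arena_size_m)
                    y = min(max(natal.y + r * math.sin(ang), 0.0), cfg.arena_size_m)
                    # stay clear of every site occupied at the interval start
                    # (just-abandoned mounds included) by more than the
                    # identity-link radius, so spatial linkage stays exact
                    if all(
                        math.hypot(x - ox, y - oy) >= 2.5 for ox, oy in occupied_at_t
                    ) and all(
                        math.hypot(x - o.x, y - o.y) >= 2.5
                        for o in self.nests.values()
                    ):
                        placed = (x, y)
                        break
                if placed is None:
                    continue
                new_id = self._add_nest(placed, cfg.new_nest_population_offset)
                founded[new_id] = nid
                bud_lp[new_id] = shift
                # founder-inference assumption: budded nests stay connected to
                # their natal nest (and, here, only to it)
                self.internest.add(self._key(new_id, nid))
                self.base_gap[self._key(new_id, nid)] = self._draw_gap()

        # drop trails whose endpoints died; occasional dropout of cycle trails
        surviving = set(self.nests)
        self.internest = {
            (a, b) for a, b in self.internest if a in surviving and b in surviving
        }
        self._apply_dropout()
        self._ensure_connected()
        # trees whose nest died forage to the nearest surviving nest
        for tid, (tx, ty) in self.trees.items():
            if self.tree_owner.get(tid) not in surviving:
                owner = min(
                    sorted(surviving),
                    key=lambda n: (math.hypot(tx - self.nests[n].x, ty - self.nests[n].y), n),
                )
                self.tree_owner[tid] = owner
                key = self._key(tid, owner)
                if key not in self.base_gap:
                    self.base_gap[key] = self._draw_gap()
        # slow population drift
        if cfg.population_drift_sigma > 0:
            for n in self.nests.values():
                n.population = max(
                    50.0, n.population * float(np.exp(self.rng.normal(0.0, cfg.population_drift_sigma)))
                )

        truth.abandoned[self.colony_id].append(
            {nid: lp for nid, lp in sorted(abandoned.items())}
        )
        truth.founded[self.colony_id].append(dict(sorted(founded.items())))
        truth.forced_survivals[self.colony_id].append(forced)
        return betw

    def _components(self) -> list[set[str]]:
        ids = sorted(self.nests)
        adj: dict[str, set[str]] = {n: set() for n in ids}
        for a, b in self.internest:
            adj[a].add(b)
            adj[b].add(a)
        seen: set[str] = set()
        comps = []
        for n in ids:
            if n in seen:
                continue
            stack, comp = [n], set()
            while stack:
                v = stack.pop()
                if v in comp:
                    continue
                comp.add(v)
                stack.extend(adj[v] - comp)
            seen |= comp
            comps.append(comp)
        return comps

    def _ensure_connected(self) -> None:
        comps = self._components()
        while len(comps) > 1:
            best = None
            base = comps[0]
            for comp in comps[1:]:
                for a in sorted(base):
                    for b in sorted(comp):
                        d = math.hypot(
                            self.nests[a].x - self.nests[b].x,
                            self.nests[a].y - self.nests[b].y,
                        )
                        if best is None or d < best[0]:
                            best = (d, a, b)
            key = self._key(best[1], best[2])
            self.internest.add(key)
            if key not in self.base_gap:
                self.base_gap[key] = self._draw_gap()
            comps = self._components()

    def _apply_dropout(self) -> None:
        if self.cfg.trail_dropout_prob <= 0:
            return
        for key in sorted(self.internest):
            if self.rng.uniform() < self.cfg.trail_dropout_prob:
                trial = set(self.internest)
                trial.discard(key)
                saved = self.internest
                self.internest = trial
                if len(self._components()) > 1:
                    self.internest = saved  # keep bridges: colony stays connected


def simulate_timeseries(
    config: SimConfig | None = None,
) -> tuple[list[ColonyTimeSeries], SimTruth]:
    """Simulate every colony through all timepoints.

    Returns one :class:`ColonyTimeSeries` per colony (identity links are
    exact because nests do not move) and the :class:`SimTruth` ledger of
    planted events.  Colonies that shrink to a single nest continue as
    degenerate maps with a logged warning.
    """
    if config is None:
        config = SimConfig()
    rng = np.random.default_rng(config.seed)
    truth = SimTruth(config=config, seed=config.seed)
    series: list[ColonyTimeSeries] = []
    timepoints = config.timepoints()
    for c in range(1, config.n_colonies + 1):
        colony_id = _roman(c)
        truth.abandoned[colony_id] = []
        truth.founded[colony_id] = []
        truth.forced_survivals[colony_id] = []
        sim = _ColonySim(colony_id, config, rng)
        maps = [sim.emit_map(timepoints[0])]
        prev_betw: dict[str, float] | None = None
        for t in range(1, config.n_timepoints):
            prev_betw = sim.step(maps[-1], prev_betw, truth)
            maps.append(sim.emit_map(timepoints[t]))
        if len(maps[-1].nests) < 2:
            logger.warning(
                "colony %s ends with %d nest(s): extinction-adjacent trajectory",
                colony_id, len(maps[-1].nests),
            )
        series.append(ColonyTimeSeries.from_maps(maps))
    return series, truth


def export_fixture(
    series: Sequence[ColonyTimeSeries],
    truth: SimTruth,
    directory: str | Path,
    overwrite: bool = False,
) -> list[Path]:
    """Write the fixture directory layout:
    ``colony_<id>/t<k>_nodes.csv``, ``colony_<id>/t<k>_edges.csv``,
    ``truth.json`` and ``config.yaml``.  Refuses to write into a non-empty
    directory unless ``overwrite`` is set."""
    from .io import write_colony_map_csvs

    directory = Path(directory)
    if directory.exists() and any(directory.iterdir()) and not overwrite:
        raise FileExistsError(
            f"{directory} is not empty; pass overwrite=True to replace it"
        )
    directory.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for ts in series:
        cdir = directory / f"colony_{ts.colony_id}"
        cdir.mkdir(exist_ok=True)
        for k, cmap in enumerate(ts.maps):
            node_path = cdir / f"t{k}_nodes.csv"
            edge_path = cdir / f"t{k}_edges.csv"
            write_colony_map_csvs(cmap, node_path, edge_path)
            written += [node_path, edge_path]
    truth_path = directory / "truth.json"
    truth_path.write_text(json.dumps(truth.to_json_dict(), indent=1, sort_keys=True))
    config_path = directory / "config.yaml"
    config_path.write_text(yaml.safe_dump(truth.config.to_dict(), sort_keys=True))
    written += [truth_path, config_path]
    return written
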