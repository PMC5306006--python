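"""Temporal linkage of colony maps: nest identity across blind remappings,
abandonment/founding events, founder classification, and counting-process
survival records for nests and trails.

Each colony was remapped blind, so nest identity across adjacent timepoints
is resolved spatially: mound positions are effectively static between
seasons, and a greedy mutual-nearest-neighbour match within a small radius
recovers identity.  A nest present at time t but unmatched at t+1 was
abandoned during the interval (t, t+1]; an unmatched nest at t+1 was newly
founded.  Nests present at the final map are right-censored.

Newly founded nests arise by budding: workers and queens walk from an
existing (natal) nest to the new site.  The natal nest is inferred from two
assumptions: a newly budded nest stays trail-connected to its natal nest,
and the natal nest is the nearest nest to which the new nest is attached.
When that nearest attached nest is itself newly founded, foundation order is
unknowable and the nearest established nest is labelled a possible founder.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .colony import (
    ColonyMap,
    FlowTable,
    Timepoint,
    nearest_tree_distance,
    resource_flow_betweenness,
    trail_betweenness,
    worker_forager_ratio,
)

logger = logging.getLogger(__name__)

FOUNDER_STATUSES = ("newly_founded", "founder", "possible_founder", "nonfounder")

#: Column order of the counting-process survival table.
SURVIVAL_COLUMNS = [
    "subject_id", "subject_kind", "colony_id", "start", "stop", "event",
    "population", "log_population", "canopy_cover", "tree_distance",
    "betweenness", "worker_forager_ratio",
    "traffic", "weight", "trail_betweenness",
    "min_endpoint_betweenness", "endpoint_survival",
]


@dataclass
class ColonyTimeSeries:
    """Ordered maps of one colony plus identity links between adjacent maps.

    ``identity_links[i]`` maps nest ids of ``maps[i]`` to nest ids of
    ``maps[i+1]`` (partial, one-to-one, nests only).
    """

    colony_id: str
    maps: list[ColonyMap]
    identity_links: list[dict[str, str]]

    def __post_init__(self) -> None:
        tps = [m.timepoint for m in self.maps]
        if tps != sorted(tps):
            raise ValueError("maps must be strictly ordered in time")
        if len(set(map(str, tps))) != len(tps):
            raise ValueError("duplicate timepoints in series")
        if len(self.identity_links) != max(len(self.maps) - 1, 0):
            raise ValueError("need exactly one identity link per adjacent map pair")

    @classmethod
    def from_maps(
        cls,
        maps: Sequence[ColonyMap],
        max_distance_m: float = 2.0,
    ) -> "ColonyTimeSeries":
        maps = sorted(maps, key=lambda m: m.timepoint)
        links = [
            link_identities(maps[i], maps[i + 1], max_distance_m)
            for i in range(len(maps) - 1)
        ]
        return cls(maps[0].colony_id, list(maps), links)

    @property
    def n_intervals(self) -> int:
        return len(self.maps) - 1

    def subject_ids(self) -> list[dict[str, str]]:
        """Per map: node_id -> persistent subject id (the nest's id at first
        appearance), chained through the identity links."""
        out: list[dict[str, str]] = []
        current = {nid: nid for nid in self.maps[0].nests}
        out.append(dict(current))
        for i, link in enumerate(self.identity_links):
            nxt: dict[str, str] = {}
            for old, new in link.items():
                nxt[new] = current[old]
            for nid in self.maps[i + 1].nests:
                if nid not in nxt:
                    nxt[nid] = nid  # newly founded: its own id becomes the subject id
            out.append(nxt)
            current = nxt
        return out


@dataclass
class FounderLabel:
    """Founder status of one nest at one timepoint."""

    nest_id: str
    timepoint: Timepoint
    status: str
    natal_of: list[str] = field(default_factory=list)
    natal: str | None = None  # for newly founded nests: inferred natal nest

    def __post_init__(self) -> None:
        if self.status not in FOUNDER_STATUSES:
            raise ValueError(f"unknown founder status {self.status!r}")


@dataclass
class IntervalEvents:
    """Events of one interval (maps[i] -> maps[i+1])."""

    interval: int
    abandoned: set[str]
    new: set[str]
    links: dict[str, str]


@dataclass
class EventTable:
    colony_id: str
    intervals: list[IntervalEvents]

    def check_bookkeeping(self, ts: ColonyTimeSeries) -> None:
        """|nests(t+1)| = |nests(t)| - abandoned + new, for every interval."""
        for ev in self.intervals:
            n_t = len(ts.maps[ev.interval].nests)
            n_t1 = len(ts.maps[ev.interval + 1].nests)
            if ev.abandoned & ev.new:
                raise AssertionError("a nest cannot be both abandoned and new")
            if n_t1 != n_t - len(ev.abandoned) + len(ev.new):
                raise AssertionError(
                    f"interval {ev.interval}: {n_t} - {len(ev.abandoned)} + "
                    f"{len(ev.new)} != {n_t1}"
                )


def link_identities(
    map_t: ColonyMap, map_t1: ColonyMap, max_distance_m: float = 2.0
) -> dict[str, str]:
    """Greedy mutual-nearest-neighbour matching of nests between adjacent
    maps, accepting pairs within ``max_distance_m``.  Ties on distance break
    on the smaller (old_id, new_id) pair and are logged."""
    if map_t.colony_id != map_t1.colony_id:
        raise ValueError("maps belong to different colonies")
    old = sorted(map_t.nests)
    new = sorted(map_t1.nests)
    if not old or not new:
        return {}
    candidates = []
    for i, a in enumerate(old):
        for j, b in enumerate(new):
            na, nb = map_t.nodes[a], map_t1.nodes[b]
            d = math.hypot(na.x - nb.x, na.y - nb.y)
            if d <= max_distance_m:
                candidates.append((d, a, b))
    candidates.sort()
    for k in range(len(candidates) - 1):
        if candidates[k][0] == candidates[k + 1][0]:
            logger.debug(
                "identity link tie at distance %.3f m between %s and %s; "
                "breaking on node id",
                candidates[k][0], candidates[k][1:], candidates[k + 1][1:],
            )
    links: dict[str, str] = {}
    used_new: set[str] = set()
    for d, a, b in candidates:
        if a in links or b in used_new:
            continue
        links[a] = b
        used_new.add(b)
    return links


def extract_events(ts: ColonyTimeSeries) -> EventTable:
    """Abandonments (unlinked old nests) and foundings (unlinked new nests)
    per interval.  Nests present in the final map are right-censored, never
    marked abandoned."""
    intervals = []
    for i, link in enumerate(ts.identity_links):
        old = set(ts.maps[i].nests)
        new = set(ts.maps[i + 1].nests)
        abandoned = old - set(link)
        founded = new - set(link.values())
        intervals.append(IntervalEvents(i, abandoned, founded, dict(link)))
    table = EventTable(ts.colony_id, intervals)
    table.check_bookkeeping(ts)
    return table


def classify_founders(
    map_t1: ColonyMap,
    new_nests: set[str],
    established_nests: set[str],
    possible_founder_connected_only: bool = False,
) -> list[FounderLabel]:
    """Label every nest of ``map_t1`` as newly_founded, founder,
    possible_founder or nonfounder.

    For each new nest: its candidate natal nests are the nests it shares a
    trail with; the natal nest is the trail-connected nest at smallest
    Euclidean distance.  If that nest is itself newly founded, the nearest
    established nest (over all established nests by default, or restricted
    to trail-connected ones) becomes a possible founder.  A nest acting as
    both founder and possible founder keeps the founder status.
    """
    neighbours: dict[str, set[str]] = {nid: set() for nid in map_t1.nests}
    for t in map_t1.internest_trails.values():
        a, b = t.endpoints
        neighbours[a].add(b)
        neighbours[b].add(a)

    founders: dict[str, list[str]] = {}
    possibles: dict[str, list[str]] = {}
    new_labels: list[FounderLabel] = []
    for nid in sorted(new_nests):
        cands = sorted(neighbours.get(nid, set()))
        natal: str | None = None
        if not cands:
            logger.info(
                "new nest %s@%s has no trail to any nest (isolated foundation)",
                nid, map_t1.timepoint,
            )
        else:
            natal = min(cands, key=lambda c: (map_t1.distance(nid, c), c))
            if natal in established_nests:
                founders.setdefault(natal, []).append(nid)
            else:
                pool = (
                    sorted(set(cands) & established_nests)
                    if possible_founder_connected_only
                    else sorted(established_nests)
                )
                if pool:
                    poss = min(pool, key=lambda c: (map_t1.distance(nid, c), c))
                    possibles.setdefault(poss, []).append(nid)
                else:
                    logger.info(
                        "new nest %s@%s has no established nest to assign as "
                        "possible founder", nid, map_t1.timepoint,
                    )
        new_labels.append(
            FounderLabel(nid, map_t1.timepoint, "newly_founded", natal=natal)
        )

    labels = new_labels
    for nid in sorted(established_nests):
        if nid in founders:
            labels.append(
                FounderLabel(nid, map_t1.timepoint, "founder", natal_of=founders[nid])
            )
        elif nid in possibles:
            labels.append(
                FounderLabel(
                    nid, map_t1.timepoint, "possible_founder", natal_of=possibles[nid]
                )
            )
        else:
            labels.append(FounderLabel(nid, map_t1.timepoint, "nonfounder"))
    return labels


@dataclass
class MapMetrics:
    """All per-map quantities the survival/budding tables draw on."""

    flow: FlowTable
    trail_flow: dict[str, dict[str, float]]
    tree_distance: dict[str, float]
    wf_ratio: float | None


def compute_map_metrics(cmap: ColonyMap) -> MapMetrics:
    flow = resource_flow_betweenness(cmap)
    tflow = trail_betweenness(cmap)
    tdist = nearest_tree_distance(cmap)
    try:
        ratio: float | None = worker_forager_ratio(cmap)
    except Exception:
        ratio = None
        logger.warning(
            "map %s@%s: worker:forager ratio undefined", cmap.colony_id, cmap.timepoint
        )
    return MapMetrics(flow, tflow, tdist, ratio)


def _trail_key(link_subjects: Mapping[str, str], trail) -> tuple[str, str] | None:
    a = link_subjects.get(trail.endpoint_a)
    b = link_subjects.get(trail.endpoint_b)
    if a is None or b is None:
        return None
    return tuple(sorted((a, b)))  # type: ignore[return-value]


def build_survival_records(
    ts: ColonyTimeSeries,
    metrics: Sequence[MapMetrics] | None = None,
    include_trails: bool = True,
) -> pd.DataFrame:
    """Counting-process survival table: one row per subject (nest or
    internest trail) per observed interval, covariates measured at the
    interval start.  Subjects founded after the first map enter late
    (delayed entry); subjects present at the last map are censored.

    Trail subjects inherit identity from their (linked) endpoint pair.  Each
    trail row carries traffic, weight, trail betweenness, the lower of the
    two endpoint normalized-betweenness values, and an indicator that both
    endpoint nests survive the interval.
    """
    if metrics is None:
        metrics = [compute_map_metrics(m) for m in ts.maps]
    subjects = ts.subject_ids()
    rows: list[dict] = []
    for i in range(ts.n_intervals):
        cmap = ts.maps[i]
        met = metrics[i]
        link = ts.identity_links[i]
        for nid, node in cmap.nests.items():
            pop = node.population
            rows.append({
                "subject_id": f"{ts.colony_id}:{subjects[i][nid]}",
                "subject_kind": "nest",
                "colony_id": ts.colony_id,
                "start": i,
                "stop": i + 1,
                "event": int(nid not in link),
                "population": np.nan if pop is None else float(pop),
                "log_population": np.nan if not pop else math.log(pop),
                "canopy_cover": np.nan if node.canopy_cover is None else node.canopy_cover,
                "tree_distance": met.tree_distance.get(nid, np.nan),
                "betweenness": met.flow.normalized.get(nid, np.nan),
                "worker_forager_ratio": np.nan if met.wf_ratio is None else met.wf_ratio,
            })
        if include_trails:
            next_keys = {
                _trail_key(subjects[i + 1], t)
                for t in ts.maps[i + 1].internest_trails.values()
            }
            for tid, t in cmap.internest_trails.items():
                key = _trail_key(subjects[i], t)
                if key is None:
                    continue
                survives = key in next_keys
                both_alive = t.endpoint_a in link and t.endpoint_b in link
                bet_a = met.flow.normalized.get(t.endpoint_a, np.nan)
                bet_b = met.flow.normalized.get(t.endpoint_b, np.nan)
                rows.append({
                    "subject_id": f"{ts.colony_id}:trail:{key[0]}|{key[1]}",
                    "subject_kind": "trail",
                    "colony_id": ts.colony_id,
                    "start": i,
                    "stop": i + 1,
                    "event": int(not survives),
                    "traffic": t.total_ants,
                    "weight": t.weight,
                    "trail_betweenness": met.trail_flow[tid]["normalized"],
                    "min_endpoint_betweenness": min(bet_a, bet_b),
                    "endpoint_survival": int(both_alive),
                    "worker_forager_ratio": np.nan if met.wf_ratio is None else met.wf_ratio,
                })
    df = pd.DataFrame(rows)
    for col in SURVIVAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[SURVIVAL_COLUMNS]
    n_missing = int(df[df.subject_kind == "nest"]["betweenness"].isna().sum())
    if n_missing:
        logger.info("%d nest records carry a missing covariate marker", n_missing)
    return df


def delta_covariate(
    ts: ColonyTimeSeries, values: Sequence[Mapping[str, float]]
) -> pd.DataFrame:
    """Per-nest change of a covariate over each interval, for linked nests.

    ``values[i]`` maps node ids of ``maps[i]`` to the covariate value.
    Returns columns interval, nest_id (the id at the interval end), delta,
    and ``direction`` (``increase`` for delta > 0, else
    ``static_or_decrease``).  Newly founded nests have no previous value and
    produce no row.
    """
    if len(values) != len(ts.maps):
        raise ValueError("need one value mapping per map")
    rows = []
    for i, link in enumerate(ts.identity_links):
        for old, new in link.items():
            if old not in values[i] or new not in values[i + 1]:
                continue
            delta = values[i + 1][new] - values[i][old]
            rows.append({
                "interval": i,
                "nest_id": new,
                "previous_id": old,
                "delta": delta,
                "direction": "increase" if delta > 0 else "static_or_decrease",
            })
    return pd.DataFrame(rows, columns=["interval", "nest_id", "previous_id", "delta", "direction"])
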