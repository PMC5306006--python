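"""Readers and writers for colony maps and analysis tables.

CSV dialect is pinned: comma-separated, ``.`` decimal point, UTF-8, header
row mandatory; timepoints serialize as ``YYYY-season``.  Loading validates
every type invariant with line-numbered messages and never silently coerces.
GraphML export carries all node/trail attributes (metrics included) and
round-trips losslessly.
"""

from __future__ import annotations

import csv
import logging
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

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
    to_networkx,
)
from .events import ColonyTimeSeries

logger = logging.getLogger(__name__)

NODE_COLUMNS = [
    "colony_id", "timepoint", "node_id", "kind", "x", "y",
    "population", "mound_volume", "canopy_cover", "species",
]
EDGE_COLUMNS = [
    "colony_id", "timepoint", "trail_id", "endpoint_a", "endpoint_b",
    "kind", "length_cm", "sample_gap_cm",
]


class MapLoadError(ValueError):
    """A CSV row violates a colony-map invariant."""


def _fmt(value) -> str:
    if value is None:
        return ""
    return repr(value) if isinstance(value, float) else str(value)


def write_colony_map_csvs(
    cmap: ColonyMap, node_path: str | Path, edge_path: str | Path
) -> None:
    """Write one map as a node table and an edge table (raw measurements;
    derived trail metrics are recomputed on load)."""
    with open(node_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(NODE_COLUMNS)
        for nid in sorted(cmap.nodes):
            n = cmap.nodes[nid]
            w.writerow([
                cmap.colony_id, str(cmap.timepoint), n.node_id, n.kind,
                _fmt(n.x), _fmt(n.y), _fmt(n.population), _fmt(n.mound_volume),
                _fmt(n.canopy_cover), _fmt(n.species),
            ])
    with open(edge_path, "w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh)
        w.writerow(EDGE_COLUMNS)
        for tid in sorted(cmap.trails):
            t = cmap.trails[tid]
            w.writerow([
                cmap.colony_id, str(cmap.timepoint), t.trail_id, t.endpoint_a,
                t.endpoint_b, t.kind, _fmt(t.length_cm), _fmt(t.sample_gap_cm),
            ])


def _parse_float(value: str, field: str, where: str) -> float:
    try:
        return float(value)
    except ValueError as exc:
        raise MapLoadError(f"{where}: field {field!r} is not numeric: {value!r}") from exc


def _read_rows(path: str | Path, required: Sequence[str]) -> list[dict[str, str]]:
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None:
            raise MapLoadError(f"{path}: missing header row")
        missing = [c for c in required if c not in reader.fieldnames]
        if missing:
            raise MapLoadError(f"{path}: missing required columns {missing}")
        return list(reader)


def read_colony_maps(
    node_csv: str | Path, edge_csv: str | Path, compute_metrics: bool = True
) -> list[ColonyMap]:
    """Load validated colony maps (possibly several colonies/timepoints per
    file pair), sorted by (colony, timepoint).  Every invariant violation is
    reported with its file and row number."""
    node_rows = _read_rows(node_csv, NODE_COLUMNS)
    edge_rows = _read_rows(edge_csv, EDGE_COLUMNS)

    nodes: dict[tuple[str, str], list[NodeRecord]] = {}
    for i, row in enumerate(node_rows, start=2):
        where = f"{node_csv}:{i}"
        key = (row["colony_id"], row["timepoint"])
        kind = row["kind"].strip()
        if kind not in (NEST, TREE):
            raise MapLoadError(f"{where}: unknown node kind {kind!r}")
        if kind == TREE and row.get("population", "").strip():
            raise MapLoadError(
                f"{where}: tree {row['node_id']!r} must not carry a population"
            )
        try:
            rec = NodeRecord(
                node_id=row["node_id"],
                kind=kind,
                x=_parse_float(row["x"], "x", where),
                y=_parse_float(row["y"], "y", where),
                population=(
                    int(_parse_float(row["population"], "population", where))
                    if row.get("population", "").strip() else None
                ),
                mound_volume=(
                    _parse_float(row["mound_volume"], "mound_volume", where)
                    if row.get("mound_volume", "").strip() else None
                ),
                canopy_cover=(
                    _parse_float(row["canopy_cover"], "canopy_cover", where)
                    if row.get("canopy_cover", "").strip() else None
                ),
                species=row.get("species") or None,
            )
        except ValueError as exc:
            raise MapLoadError(f"{where}: {exc}") from exc
        nodes.setdefault(key, []).append(rec)

    trails: dict[tuple[str, str], list[TrailRecord]] = {}
    for i, row in enumerate(edge_rows, start=2):
        where = f"{edge_csv}:{i}"
        key = (row["colony_id"], row["timepoint"])
        kind = row["kind"].strip()
        if kind not in (INTERNEST, FORAGING):
            raise MapLoadError(f"{where}: unknown trail kind {kind!r}")
        known = {n.node_id for n in nodes.get(key, [])}
        for ep in ("endpoint_a", "endpoint_b"):
            if row[ep] not in known:
                raise MapLoadError(
                    f"{where}: trail {row['trail_id']!r} references unknown "
                    f"node {row[ep]!r}"
                )
        try:
            rec = TrailRecord(
                trail_id=row["trail_id"],
                endpoint_a=row["endpoint_a"],
                endpoint_b=row["endpoint_b"],
                kind=kind,
                length_cm=_parse_float(row["length_cm"], "length_cm", where),
                sample_gap_cm=_parse_float(row["sample_gap_cm"], "sample_gap_cm", where),
            )
        except ValueError as exc:
            raise MapLoadError(f"{where}: {exc}") from exc
        trails.setdefault(key, []).append(rec)

    maps = []
    for key in sorted(nodes, key=lambda k: (k[0], Timepoint.parse(k[1])._key)):
        colony_id, tp = key
        try:
            cmap = ColonyMap.from_records(
                colony_id, tp, nodes[key], trails.get(key, [])
            )
        except ValueError as exc:
            raise MapLoadError(f"map {colony_id}@{tp}: {exc}") from exc
        maps.append(compute_trail_metrics(cmap) if compute_metrics else cmap)
    return maps


def read_fixture_dir(directory: str | Path, max_link_distance_m: float = 2.0):
    """Load a fixture directory written by :func:`polynest.simulate.export_fixture`.

    Returns (list of ColonyTimeSeries, truth dict or None, config dict or None).
    """
    import json

    import yaml

    directory = Path(directory)
    series = []
    for cdir in sorted(directory.glob("colony_*")):
        maps = []
        for node_path in sorted(
            cdir.glob("t*_nodes.csv"), key=lambda p: int(p.name.split("_")[0][1:])
        ):
            edge_path = cdir / node_path.name.replace("_nodes", "_edges")
            loaded = read_colony_maps(node_path, edge_path)
            if len(loaded) != 1:
                raise MapLoadError(f"{node_path}: expected exactly one map per file")
            maps.append(loaded[0])
        series.append(ColonyTimeSeries.from_maps(maps, max_link_distance_m))
    truth_path = directory / "truth.json"
    truth = json.loads(truth_path.read_text()) if truth_path.exists() else None
    config_path = directory / "config.yaml"
    config = yaml.safe_load(config_path.read_text()) if config_path.exists() else None
    return series, truth, config


def export_graphml(cmap: ColonyMap, path: str | Path, flow=None) -> None:
    """Write one map as GraphML with metrics as node/edge attributes."""
    nx.write_graphml(to_networkx(cmap, flow), str(path))


def import_graphml(path: str | Path) -> ColonyMap:
    """Reconstruct a ColonyMap from a GraphML export (lossless round trip of
    the raw fields; derived trail metrics are restored from the attributes
    when present)."""
    G = nx.read_graphml(str(path))
    nodes = []
    for nid, data in G.nodes(data=True):
        nodes.append(NodeRecord(
            node_id=str(nid),
            kind=data["kind"],
            x=float(data["x"]),
            y=float(data["y"]),
            population=int(data["population"]) if "population" in data else None,
            mound_volume=float(data["mound_volume"]) if "mound_volume" in data else None,
            canopy_cover=float(data["canopy_cover"]) if "canopy_cover" in data else None,
            species=data.get("species"),
        ))
    trails = []
    for a, b, data in G.edges(data=True):
        trails.append(TrailRecord(
            trail_id=data["trail_id"],
            endpoint_a=str(a),
            endpoint_b=str(b),
            kind=data["kind"],
            length_cm=float(data["length_cm"]),
            sample_gap_cm=float(data["sample_gap_cm"]),
            ants_per_cm=float(data["ants_per_cm"]) if "ants_per_cm" in data else None,
            total_ants=float(data["total_ants"]) if "total_ants" in data else None,
            weight=float(data["weight"]) if "weight" in data else None,
        ))
    return ColonyMap.from_records(
        G.graph["colony_id"], G.graph["timepoint"], nodes, trails
    )


def write_survival_records(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, index=False)


def write_founder_labels(labels: Iterable, colony_id: str, path: str | Path) -> None:
    rows = [
        {
            "colony_id": colony_id,
            "timepoint": str(lab.timepoint),
            "nest_id": lab.nest_id,
            "status": lab.status,
            "natal_of": ";".join(lab.natal_of),
        }
        for lab in labels
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
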