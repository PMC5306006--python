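"""Identity linkage, event extraction, founder classification and
counting-process record assembly."""

import itertools

import numpy as np
import pytest

from helpers import make_map
from polynest.events import (
    ColonyTimeSeries,
    build_survival_records,
    classify_founders,
    delta_covariate,
    extract_events,
    link_identities,
)


def _simple_map(positions, timepoint, pop=1000):
    """Map with nests at given positions, chained by internest trails."""
    ids = sorted(positions)
    nests = [(nid, positions[nid][0], positions[nid][1], pop) for nid in ids]
    trails = [
        (f"e{i}", ids[i], ids[i + 1], "internest", 500, 10)
        for i in range(len(ids) - 1)
    ]
    return make_map(nests, trails=trails, timepoint=timepoint)


def test_identical_maps_link_all_nests():
    pos = {"A": (0, 0), "B": (5, 0), "C": (10, 0)}
    m0 = _simple_map(pos, "2012-summer")
    m1 = _simple_map(pos, "2013-spring")
    links = link_identities(m0, m1)
    assert links == {"A": "A", "B": "B", "C": "C"}


def test_missing_nest_becomes_abandonment_candidate():
    m0 = _simple_map({"A": (0, 0), "B": (5, 0), "C": (10, 0)}, "2012-summer")
    m1 = _simple_map({"A": (0, 0), "B": (5, 0)}, "2013-spring")
    links = link_identities(m0, m1)
    assert "C" not in links and len(links) == 2


def test_near_swap_recovers_spatially_consistent_pairing():
    """Two nests renamed and offset by 0.1 m: the mutual-nearest matching
    must agree with the minimum-total-distance bipartite assignment."""
    m0 = _simple_map({"A": (0, 0), "B": (5, 0)}, "2012-summer")
    m1 = _simple_map({"X": (5.05, 0), "Y": (0.05, 0)}, "2013-spring")
    links = link_identities(m0, m1)
    # brute force over all bipartite matchings
    old, new = ["A", "B"], ["X", "Y"]
    coords0 = {"A": (0, 0), "B": (5, 0)}
    coords1 = {"X": (5.05, 0), "Y": (0.05, 0)}
    best = min(
        itertools.permutations(new),
        key=lambda perm: sum(
            np.hypot(
                coords0[o][0] - coords1[n][0], coords0[o][1] - coords1[n][1]
            )
            for o, n in zip(old, perm)
        ),
    )
    assert links == dict(zip(old, best)) == {"A": "Y", "B": "X"}


def test_link_respects_max_distance():
    m0 = _simple_map({"A": (0, 0)}, "2012-summer")
    m1 = _simple_map({"A": (10, 0)}, "2013-spring")
    assert link_identities(m0, m1, max_distance_m=2.0) == {}


def test_extract_events_censoring_and_definition():
    pos = {"A": (0, 0), "B": (5, 0), "C": (10, 0)}
    tps = ["2012-summer", "2013-spring", "2013-summer", "2014-spring", "2014-summer"]
    # C present t0-t2, absent from t3 on; final-map nests never marked abandoned
    maps = [
        _simple_map(pos if k < 3 else {"A": pos["A"], "B": pos["B"]}, tps[k])
        for k in range(5)
    ]
    ts = ColonyTimeSeries.from_maps(maps)
    table = extract_events(ts)
    assert [ev.abandoned for ev in table.intervals] == [set(), set(), {"C"}, set()]
    assert all(not ev.new for ev in table.intervals)


def test_constant_series_has_no_events():
    pos = {"A": (0, 0), "B": (5, 0)}
    maps = [
        _simple_map(pos, tp)
        for tp in ("2012-summer", "2013-spring", "2013-summer", "2014-spring", "2014-summer")
    ]
    table = extract_events(ColonyTimeSeries.from_maps(maps))
    assert all(not ev.abandoned and not ev.new for ev in table.intervals)


def _founder_map(new_positions, established_positions, trails):
    nests = [(nid, x, y, 1000) for nid, (x, y) in {**established_positions, **new_positions}.items()]
    return make_map(nests, trails=trails, timepoint="2013-spring")


def test_unique_candidate_founder():
    cmap = _founder_map(
        {"N3": (1, 0)}, {"N1": (0, 0), "N2": (10, 10)},
        [("e1", "N1", "N3", "internest", 100, 10),
         ("e2", "N1", "N2", "internest", 1400, 10)],
    )
    labels = {l.nest_id: l for l in classify_founders(cmap, {"N3"}, {"N1", "N2"})}
    assert labels["N1"].status == "founder" and labels["N1"].natal_of == ["N3"]
    assert labels["N2"].status == "nonfounder"
    assert labels["N3"].status == "newly_founded" and labels["N3"].natal == "N1"


def test_nearest_connected_nest_is_the_natal_nest():
    cmap = _founder_map(
        {"N3": (0, 0)}, {"N1": (5, 0), "N2": (9, 0)},
        [("e1", "N1", "N3", "internest", 500, 10),
         ("e2", "N2", "N3", "internest", 900, 10),
         ("e3", "N1", "N2", "internest", 400, 10)],
    )
    labels = {l.nest_id: l for l in classify_founders(cmap, {"N3"}, {"N1", "N2"})}
    assert labels["N1"].status == "founder"
    assert labels["N2"].status == "nonfounder"


@pytest.mark.parametrize("far_established", [(3.5, 0), (1.9, 1)])
def test_chained_new_nests_yield_possible_founder(far_established):
    """N1(est)-N3(new)-N4(new): N3's natal is N1; N4's nearest connected
    nest is new, so the nearest established nest becomes a possible
    founder.  Checked for both distance orderings of the established
    nests relative to N4."""
    cmap = _founder_map(
        {"N3": (1, 0), "N4": (2, 0)},
        {"N1": (0, 0), "N5": far_established},
        [("e1", "N1", "N3", "internest", 100, 10),
         ("e2", "N3", "N4", "internest", 100, 10),
         ("e3", "N1", "N5", "internest", 100, 10)],
    )
    labels = {l.nest_id: l for l in classify_founders(cmap, {"N3", "N4"}, {"N1", "N5"})}
    assert labels["N1"].status == "founder"  # natal of N3
    # nearest established nest to N4 by Euclidean distance
    d1 = np.hypot(2 - 0, 0 - 0)
    d5 = np.hypot(2 - far_established[0], 0 - far_established[1])
    expected_possible = "N1" if d1 < d5 else "N5"
    if expected_possible == "N1":
        # founder status takes priority over possible_founder
        assert labels["N1"].status == "founder"
        assert labels["N5"].status == "nonfounder"
    else:
        assert labels["N5"].status == "possible_founder"
        assert labels["N5"].natal_of == ["N4"]


def test_isolated_new_nest_has_no_natal():
    nests = [("N1", 0, 0, 1000), ("N2", 1, 0, 1000), ("N3", 10, 10, 1000)]
    cmap = make_map(nests, trails=[("e1", "N1", "N2", "internest", 100, 10)],
                    timepoint="2013-spring")
    labels = {l.nest_id: l for l in classify_founders(cmap, {"N3"}, {"N1", "N2"})}
    assert labels["N3"].status == "newly_founded" and labels["N3"].natal is None


def test_every_new_nest_gets_exactly_one_assignment(small_sim):
    """Founder, possible founder, or no natal: exactly one per new nest."""
    series, _ = small_sim
    for ts in series:
        table = extract_events(ts)
        for ev in table.intervals:
            cmap = ts.maps[ev.interval + 1]
            established = set(cmap.nests) - ev.new
            labels = classify_founders(cmap, ev.new, established)
            natal_map = {}
            for lab in labels:
                for new_id in lab.natal_of:
                    assert new_id not in natal_map
                    natal_map[new_id] = lab.nest_id
            for lab in labels:
                if lab.status == "newly_founded":
                    # a founder/possible founder was assigned iff a natal
                    # nest could be inferred
                    assert (lab.nest_id in natal_map) == (lab.natal is not None)


def test_survival_record_counts_and_censoring():
    pos = {"A": (0, 0), "B": (5, 0)}
    tps = ["2012-summer", "2013-spring", "2013-summer", "2014-spring", "2014-summer"]
    maps = [_simple_map(pos, tp) for tp in tps]
    ts = ColonyTimeSeries.from_maps(maps)
    records = build_survival_records(ts, include_trails=False)
    for sid in ("C1:A", "C1:B"):
        rows = records[records.subject_id == sid]
        assert len(rows) == 4  # alive through all five maps
        assert rows.event.sum() == 0  # censored, never marked abandoned
        assert list(rows.start) == [0, 1, 2, 3]


def test_delayed_entry_and_event_on_final_record():
    tps = ["2012-summer", "2013-spring", "2013-summer", "2014-spring", "2014-summer"]
    base = {"A": (0, 0), "B": (5, 0)}
    with_c = {**base, "C": (2.5, 3)}
    # C founded at t2, abandoned in (t3, t4]
    maps = [
        _simple_map(base, tps[0]),
        _simple_map(base, tps[1]),
        _simple_map(with_c, tps[2]),
        _simple_map(with_c, tps[3]),
        _simple_map(base, tps[4]),
    ]
    ts = ColonyTimeSeries.from_maps(maps)
    records = build_survival_records(ts, include_trails=False)
    rows = records[records.subject_id == "C1:C"]
    assert list(rows.start) == [2, 3]
    assert list(rows.event) == [0, 1]


def test_record_total_matches_independent_tally(default_sim, default_records):
    """Total nest records = sum over non-final maps of nests alive there."""
    series, _ = default_sim
    expected = sum(
        len(m.nests) for ts in series for m in ts.maps[:-1]
    )
    nest_records = default_records[default_records.subject_kind == "nest"]
    assert len(nest_records) == expected
    # no overlapping intervals, at most one event per subject
    for _, grp in nest_records.groupby("subject_id"):
        assert grp.event.sum() <= 1
        starts = sorted(grp.start)
        assert starts == sorted(set(starts))


def test_delta_covariate_direction_classification():
    pos = {"A": (0, 0), "B": (5, 0)}
    tps = ["2012-summer", "2013-spring", "2013-summer"]
    maps = [_simple_map(pos, tp) for tp in tps]
    ts = ColonyTimeSeries.from_maps(maps)
    values = [{"A": 0.4, "B": 0.7}, {"A": 0.9, "B": 0.7}, {"A": 0.9, "B": 0.5}]
    out = delta_covariate(ts, values)
    a = out[(out.nest_id == "A")].set_index("interval")
    b = out[(out.nest_id == "B")].set_index("interval")
    assert a.loc[0, "delta"] == pytest.approx(0.5)
    assert a.loc[0, "direction"] == "increase"
    assert b.loc[0, "delta"] == 0.0
    assert b.loc[0, "direction"] == "static_or_decrease"  # no change counts as static
    assert b.loc[1, "direction"] == "static_or_decrease"
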