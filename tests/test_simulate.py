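"""The synthetic colony generator: determinism, conservation, planted
effects and the fixture round trip."""

import pandas as pd
import pytest

from polynest.events import build_survival_records, classify_founders, extract_events
from polynest.io import read_fixture_dir
from polynest.simulate import SimConfig, export_fixture, simulate_timeseries


def _no_dynamics_config():
    return SimConfig(
        n_colonies=3, seed=9,
        beta_survival_betweenness=0.0, beta_survival_size=0.0,
        beta_bud_betweenness=0.0, beta_bud_delta=0.0,
        baseline_abandonment_prob=0.0, baseline_budding_prob=0.0,
        trail_dropout_prob=0.0, traffic_season_sigma=0.0,
        population_drift_sigma=0.0,
    )


def test_no_dynamics_maps_are_identical_across_timepoints():
    series, truth = simulate_timeseries(_no_dynamics_config())
    for ts in series:
        first = ts.maps[0]
        for cmap in ts.maps[1:]:
            assert set(cmap.nodes) == set(first.nodes)
            for nid in first.nodes:
                assert cmap.nodes[nid] == first.nodes[nid].__class__(
                    **{**first.nodes[nid].__dict__}
                )
            assert {
                (t.endpoint_a, t.endpoint_b, t.kind, t.length_cm, t.sample_gap_cm)
                for t in cmap.trails.values()
            } == {
                (t.endpoint_a, t.endpoint_b, t.kind, t.length_cm, t.sample_gap_cm)
                for t in first.trails.values()
            }
    assert all(not d for c in truth.abandoned.values() for d in c)
    assert all(not d for c in truth.founded.values() for d in c)


def test_same_seed_is_byte_identical(tmp_path):
    a, b = tmp_path / "a", tmp_path / "b"
    for d in (a, b):
        series, truth = simulate_timeseries(SimConfig(n_colonies=3, seed=17))
        export_fixture(series, truth, d)
    files_a = sorted(p.relative_to(a) for p in a.rglob("*") if p.is_file())
    files_b = sorted(p.relative_to(b) for p in b.rglob("*") if p.is_file())
    assert files_a == files_b
    for rel in files_a:
        assert (a / rel).read_bytes() == (b / rel).read_bytes(), rel


def test_conservation_and_ledger_agreement(default_sim):
    """|nests(t+1)| = |nests(t)| - abandoned + new on every interval, and
    the extracted event table equals the generator's ledger exactly."""
    series, truth = default_sim
    for ts in series:
        table = extract_events(ts)  # raises internally if bookkeeping breaks
        for ev in table.intervals:
            planted_gone = set(truth.abandoned[ts.colony_id][ev.interval])
            planted_new = set(truth.founded[ts.colony_id][ev.interval])
            assert ev.abandoned == planted_gone
            assert ev.new == planted_new


def test_founder_classification_recovers_planted_natal_nests(default_sim):
    """Every planted budding is recovered with its natal nest (new nests
    are trail-connected to exactly their natal nest)."""
    series, truth = default_sim
    total = recovered = 0
    for ts in series:
        table = extract_events(ts)
        for ev in table.intervals:
            planted = truth.founded[ts.colony_id][ev.interval]
            if not planted:
                continue
            cmap = ts.maps[ev.interval + 1]
            established = set(cmap.nests) - ev.new
            labels = {l.nest_id: l for l in classify_founders(cmap, ev.new, established)}
            for new_id, natal_id in planted.items():
                total += 1
                recovered += labels[new_id].natal == natal_id
    assert total > 0
    assert recovered == total


def test_protective_flow_effect_separates_abandoned_from_survivors():
    """With a strongly protective flow effect (slope -3), abandoned nests
    have lower mean betweenness than survivors in nearly all replicates."""
    hits = trials = 0
    for r in range(100):
        cfg = SimConfig(
            n_colonies=5, seed=5000 + r, beta_survival_betweenness=-3.0,
        )
        series, _ = simulate_timeseries(cfg)
        recs = pd.concat(
            [build_survival_records(ts, include_trails=False) for ts in series],
            ignore_index=True,
        )
        gone = recs[recs.event == 1].betweenness
        kept = recs[recs.event == 0].betweenness
        if len(gone) >= 3:
            trials += 1
            hits += gone.mean() < kept.mean()
    assert trials >= 90
    assert hits / trials >= 0.95


def test_initial_nest_counts_within_configured_range(default_sim):
    series, truth = default_sim
    lo, hi = truth.config.initial_nests_range
    for ts in series:
        assert lo <= len(ts.maps[0].nests) <= hi


def test_fixture_round_trip_is_idempotent(tmp_path, small_sim):
    series, truth = small_sim
    first = tmp_path / "first"
    export_fixture(series, truth, first)
    loaded, truth_dict, config = read_fixture_dir(first)
    assert truth_dict["effect_sizes"] == truth.effect_sizes()
    assert config["n_colonies"] == truth.config.n_colonies
    second = tmp_path / "second"
    export_fixture(loaded, truth, second)
    for rel in sorted(p.relative_to(first) for p in first.rglob("*.csv")):
        assert (first / rel).read_bytes() == (second / rel).read_bytes(), rel


def test_export_refuses_nonempty_directory(tmp_path, small_sim):
    series, truth = small_sim
    target = tmp_path / "out"
    target.mkdir()
    (target / "junk.txt").write_text("already here")
    with pytest.raises(FileExistsError):
        export_fixture(series, truth, target)
    export_fixture(series, truth, target, overwrite=True)  # explicit opt-in
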