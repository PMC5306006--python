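"""The extended Cox fitter against independent oracles: brute-force grid
search, lifelines, simulation coverage, and hand-computed Kaplan-Meier."""

import numpy as np
import pandas as pd
import pytest

from helpers import grid_search_cox
from polynest.cox import (
    CoxSpec,
    NoEventsError,
    SingularInformationError,
    fit_extended_cox,
    kaplan_meier,
    model_survival_curve,
    survival_curve,
)


def _toy_records():
    """20 subjects, single binary covariate, tied integer event times."""
    rng = np.random.default_rng(2024)
    x = np.repeat([0.0, 1.0], 10)
    stop = rng.integers(1, 5, size=20).astype(float)
    event = rng.uniform(size=20) < 0.7
    return pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(20)],
        "subject_kind": "nest",
        "colony_id": "C1",
        "start": 0.0,
        "stop": stop,
        "event": event.astype(int),
        "x": x,
    })


@pytest.mark.parametrize("ties", ["efron", "breslow"])
def test_beta_matches_bruteforce_grid_search(ties):
    df = _toy_records()
    fit = fit_extended_cox(df, CoxSpec(covariates=("x",), colony_term="none", tie_method=ties))
    beta_grid = grid_search_cox(
        df.x.to_numpy(), df.start.to_numpy(), df.stop.to_numpy(),
        df.event.to_numpy(bool), ties=ties,
    )
    assert fit.coef("x") == pytest.approx(beta_grid, abs=1e-3)
    assert fit.z_for("x") == pytest.approx(fit.coef("x") / fit.se[0])
    assert fit.loglik >= fit.loglik_null


def test_matches_lifelines_time_varying_fitter(default_records):
    """Counting-process fit with colony factor agrees with lifelines."""
    lifelines = pytest.importorskip("lifelines")
    nest = default_records[default_records.subject_kind == "nest"]
    spec = CoxSpec(covariates=("betweenness", "log_population"))
    fit = fit_extended_cox(nest, spec)
    df = nest[["subject_id", "start", "stop", "event",
               "betweenness", "log_population", "colony_id"]].dropna()
    df = pd.get_dummies(df, columns=["colony_id"], drop_first=True, dtype=float)
    ctv = lifelines.CoxTimeVaryingFitter()
    ctv.fit(df, id_col="subject_id", start_col="start", stop_col="stop", event_col="event")
    for name in ("betweenness", "log_population"):
        assert fit.coef(name) == pytest.approx(ctv.summary.loc[name, "coef"], abs=1e-5)
        assert fit.z_for(name) == pytest.approx(ctv.summary.loc[name, "z"], abs=1e-4)


def test_no_events_error():
    df = _toy_records()
    df["event"] = 0
    with pytest.raises(NoEventsError):
        fit_extended_cox(df, CoxSpec(covariates=("x",), colony_term="none"))


def test_constant_covariate_error():
    df = _toy_records()
    df["x"] = 1.0
    with pytest.raises(SingularInformationError):
        fit_extended_cox(df, CoxSpec(covariates=("x",), colony_term="none"))


def test_wald_ci_coverage_under_known_hazard_ratio():
    """Exponential hazards with true hazard ratio 2: the 95% CI on beta
    should cover ln 2 in at least 93% of replicates."""
    rng = np.random.default_rng(7)
    true_beta = np.log(2.0)
    covered = 0
    n_rep = 200
    for _ in range(n_rep):
        n = 500
        x = (rng.uniform(size=n) < 0.5).astype(float)
        t = rng.exponential(1.0 / (0.1 * np.exp(true_beta * x)))
        cens = 8.0
        stop = np.minimum(t, cens)
        event = (t <= cens).astype(int)
        df = pd.DataFrame({
            "subject_id": np.arange(n).astype(str),
            "subject_kind": "nest", "colony_id": "C",
            "start": 0.0, "stop": stop, "event": event, "x": x,
        })
        fit = fit_extended_cox(df, CoxSpec(covariates=("x",), colony_term="none"))
        lo = fit.coef("x") - 1.96 * fit.se[0]
        hi = fit.coef("x") + 1.96 * fit.se[0]
        covered += lo <= true_beta <= hi
    assert covered / n_rep >= 0.93


def test_kaplan_meier_hand_example():
    """4 subjects, events at t=1 and t=2, two censored at t=3:
    S = 1, 0.75, 0.50, 0.50."""
    start = np.zeros(4)
    stop = np.array([1.0, 2.0, 3.0, 3.0])
    event = np.array([1, 1, 0, 0])
    curve = kaplan_meier(start, stop, event)
    assert list(curve.times) == [0.0, 1.0, 2.0, 3.0]
    assert list(curve.survival) == pytest.approx([1.0, 0.75, 0.50, 0.50])


def test_kaplan_meier_no_events_stays_at_one():
    curve = kaplan_meier(np.zeros(5), np.full(5, 3.0), np.zeros(5, int))
    assert np.all(curve.survival == 1.0)


def test_kaplan_meier_matches_lifelines_with_delayed_entry(default_records):
    lifelines = pytest.importorskip("lifelines")
    nest = default_records[default_records.subject_kind == "nest"]
    per_subject = nest.groupby("subject_id").agg(
        entry=("start", "min"), stop=("stop", "max"), event=("event", "max")
    )
    curve = kaplan_meier(
        per_subject.entry.to_numpy(), per_subject.stop.to_numpy(),
        per_subject.event.to_numpy(),
    )
    kmf = lifelines.KaplanMeierFitter()
    kmf.fit(per_subject.stop, per_subject.event, entry=per_subject.entry)
    for t, s in zip(curve.times, curve.survival):
        assert s == pytest.approx(
            float(kmf.survival_function_at_times(t).iloc[0]), abs=1e-10
        )


def test_model_curves_order_by_resource_flow(default_records):
    """Predicted survival for the three flow profiles (0.1 / 0.5 / 0.9)
    orders correctly under the protective planted effect, is nonincreasing
    and starts at 1."""
    nest = default_records[default_records.subject_kind == "nest"]
    fit = fit_extended_cox(nest, CoxSpec(covariates=("betweenness",)))
    curves = {v: model_survival_curve(fit, {"betweenness": v}) for v in (0.1, 0.5, 0.9)}
    for curve in curves.values():
        assert curve.survival[0] == 1.0
        assert np.all(np.diff(curve.survival) <= 1e-12)
    final = {v: c.survival[-1] for v, c in curves.items()}
    assert final[0.9] > final[0.5] > final[0.1]


def test_raw_km_subgroups_are_nonincreasing(default_records):
    nest = default_records[default_records.subject_kind == "nest"]
    curve = survival_curve(nest, subset={"colony_id": "I"})
    assert np.all(np.diff(curve.survival) <= 1e-12)
    assert curve.profile == {"colony_id": "I"}


def test_single_interval_records_equal_standard_cox(default_records):
    """With only first-interval rows (no time-varying covariates, common
    entry), the counting-process path must agree with a standard
    right-censored fit on the same data re-expressed as durations."""
    lifelines = pytest.importorskip("lifelines")
    nest = default_records[
        (default_records.subject_kind == "nest") & (default_records.start == 0)
    ].copy()
    fit = fit_extended_cox(nest, CoxSpec(covariates=("betweenness",), colony_term="none"))
    cph = lifelines.CoxPHFitter()
    cph.fit(
        nest[["stop", "event", "betweenness"]].dropna(),
        duration_col="stop", event_col="event",
    )
    assert fit.coef("betweenness") == pytest.approx(
        float(cph.summary.loc["betweenness", "coef"]), abs=1e-3
    )
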