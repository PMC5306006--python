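"""Nest survival: extended Cox model with QAP permutation significance.

Fits the hazard of nest abandonment on normalized betweenness (resource
flow) with colony as a covariate, then derives significance from a null
distribution built by shuffling betweenness among the nests of each colony
map (quadratic assignment procedure).  The generator plants a protective
flow effect (log-hazard slope -2), which the test should detect."""

import pandas as pd

from polynest import (
    CoxSpec,
    SimConfig,
    build_survival_records,
    model_survival_curve,
    fit_extended_cox,
    qap_significance,
    simulate_timeseries,
)

series, _ = simulate_timeseries(SimConfig(seed=1))
records = pd.concat(
    [build_survival_records(ts, include_trails=False) for ts in series],
    ignore_index=True,
)
print(f"{len(records)} nest survival records, {int(records.event.sum())} abandonments")

spec = CoxSpec(covariates=("betweenness",))
result = qap_significance(records, spec, "betweenness", B=999, seed=1)
print(
    f"betweenness: z = {result.observed_stat:+.2f}, n = {result.n}, "
    f"B = {result.B}, p = {result.p_value:.4f} ({result.tail})"
)
# A negative z means higher resource flow lowers the abandonment hazard;
# p is the share of permutation refits at least as extreme (add-one rule).

fit = fit_extended_cox(records, spec)
for profile in (0.1, 0.5, 0.9):
    curve = model_survival_curve(fit, {"betweenness": profile})
    print(
        f"predicted S(t) for flow {profile}: "
        + ", ".join(f"{s:.2f}" for s in curve.survival)
    )
# Survival curves for low / medium / high resource-flow nests: higher flow,
# flatter curve.
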