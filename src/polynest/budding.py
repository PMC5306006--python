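"""Which nests found new nests?  Binomial GLMM tests of founder status.

Each established nest at each timepoint is a row: its founder status in the
interval ending at that timepoint (founder / nonfounder / possible founder)
is the response, modelled with a binomial-logit mixed model with the
attribute of interest as the fixed effect and random intercepts for colony,
nest identity and season.  Significance is a chi-squared analysis of
deviance (AoD): twice the log-likelihood difference between the full model
and the null model without the fixed effect.

Possible founders are nests whose contribution cannot be ordered (the
nearest trail-connected nest of the new nest was itself newly founded); a
binary response cannot carry three classes, so a policy decides their
coding: ``exclude`` (default), ``as_founder`` or ``as_nonfounder``.  The
policy-sensitivity harness runs all three and reports whether the
qualitative conclusion is policy-stable.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .colony import categorize_flow
from .events import (
    ColonyTimeSeries,
    MapMetrics,
    classify_founders,
    compute_map_metrics,
    extract_events,
)
from .glmm import GLMMFit, fit_binomial_glmm

logger = logging.getLogger(__name__)

POLICIES = ("exclude", "as_founder", "as_nonfounder")

#: covariate columns of the budding dataset
BUDDING_COVARIATES = [
    "betweenness", "d_betweenness", "log_population", "d_log_population",
    "tree_distance", "canopy_cover", "worker_forager_ratio",
    "d_worker_forager_ratio", "flow_band", "season",
]


class IncomparableModelsError(ValueError):
    """Full and null model were fitted on different rows."""


@dataclass
class AoDResult:
    """Chi-squared analysis of deviance for one fixed effect."""

    fixed_effects: tuple[str, ...]
    policy: str
    chisq: float
    df: int
    p: float
    n: int
    full: GLMMFit
    null: GLMMFit

    def summary(self) -> dict:
        return {
            "fixed_effects": list(self.fixed_effects),
            "policy": self.policy,
            "chisq": self.chisq,
            "df": self.df,
            "p": self.p,
            "n": self.n,
            "sigma": self.full.sigma,
        }


def build_budding_dataset(
    series: Sequence[ColonyTimeSeries],
    metrics: Mapping[str, Sequence[MapMetrics]] | None = None,
) -> pd.DataFrame:
    """One row per established nest per interval, with founder status, the
    nest/network/colony covariates evaluated at the interval start, and
    their change (``d_*``) over the founding interval.

    Level covariates are pre-event by construction: a newly budded nest is
    attached to its founder, so measuring the founder's betweenness after
    the event would mechanically inflate it.  The ``d_*`` covariates span
    the founding interval and therefore deliberately include that feedback
    (the change in flow over the period in which the new nest appeared).
    Newly founded nests are excluded: they cannot be founders of themselves
    within the same interval.
    """
    rows = []
    for ts in series:
        met = (
            list(metrics[ts.colony_id])
            if metrics is not None
            else [compute_map_metrics(m) for m in ts.maps]
        )
        events = extract_events(ts)
        subjects = ts.subject_ids()
        for ev in events.intervals:
            i = ev.interval
            cmap = ts.maps[i + 1]
            established = set(cmap.nests) - ev.new
            labels = {
                lab.nest_id: lab
                for lab in classify_founders(cmap, ev.new, established)
            }
            back = {new: old for old, new in ev.links.items()}
            for nid in sorted(established):
                old = back[nid]
                node0 = ts.maps[i].nodes[old]
                betw1 = met[i + 1].flow.normalized.get(nid, np.nan)
                betw0 = met[i].flow.normalized.get(old, np.nan)
                pop1 = cmap.nodes[nid].population
                pop0 = node0.population
                lp1 = math.log(pop1) if pop1 else np.nan
                lp0 = math.log(pop0) if pop0 else np.nan
                wf1 = np.nan if met[i + 1].wf_ratio is None else met[i + 1].wf_ratio
                wf0 = np.nan if met[i].wf_ratio is None else met[i].wf_ratio
                rows.append({
                    "colony_id": ts.colony_id,
                    "interval": i,
                    "timepoint": str(cmap.timepoint),
                    "season": cmap.timepoint.season,
                    "nest_id": f"{ts.colony_id}:{subjects[i + 1][nid]}",
                    "status": labels[nid].status,
                    "betweenness": betw0,
                    "d_betweenness": betw1 - betw0,
                    "population": np.nan if pop0 is None else float(pop0),
                    "log_population": lp0,
                    "d_log_population": lp1 - lp0,
                    "tree_distance": met[i].tree_distance.get(old, np.nan),
                    "canopy_cover": np.nan if node0.canopy_cover is None else node0.canopy_cover,
                    "worker_forager_ratio": wf0,
                    "d_worker_forager_ratio": wf1 - wf0,
                    "flow_band": _flow_band(betw0),
                })
    return pd.DataFrame(rows)


def _flow_band(value: float) -> str:
    """Collapse the five display categories to three analysis bands
    (zero joins low; one joins high)."""
    if np.isnan(value):
        return "low"
    cat = categorize_flow(min(max(value, 0.0), 1.0))
    return {"zero": "low", "one": "high"}.get(cat, cat)


def _apply_policy(df: pd.DataFrame, policy: str) -> tuple[pd.DataFrame, np.ndarray]:
    if policy not in POLICIES:
        raise ValueError(f"policy must be one of {POLICIES}")
    if policy == "exclude":
        df = df[df["status"] != "possible_founder"]
        y = (df["status"] == "founder").to_numpy(float)
    elif policy == "as_founder":
        y = df["status"].isin(["founder", "possible_founder"]).to_numpy(float)
    else:
        y = (df["status"] == "founder").to_numpy(float)
    return df, y


def _design(df: pd.DataFrame, fixed_effects: Sequence[str]) -> tuple[np.ndarray, list[str]]:
    cols = [np.ones(len(df))]
    names = ["intercept"]
    for eff in fixed_effects:
        col = df[eff]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(col.astype(str).unique())
            for lev in levels[1:]:
                cols.append((col.astype(str) == lev).to_numpy(float))
                names.append(f"{eff}[{lev}]")
        else:
            cols.append(col.to_numpy(float))
            names.append(eff)
    return np.column_stack(cols), names


def fit_founder_glmm(
    dataset: pd.DataFrame,
    fixed_effects: str | Sequence[str],
    policy: str = "exclude",
) -> tuple[GLMMFit, pd.DataFrame]:
    """Binomial-logit mixed model of founder status with random intercepts
    for colony, nest identity and season.  Returns the fit and the rows used
    (complete cases under the given possible-founder policy)."""
    effs = [fixed_effects] if isinstance(fixed_effects, str) else list(fixed_effects)
    df = dataset[dataset["status"] != "newly_founded"]
    df = df.dropna(subset=[e for e in effs])
    df, y = _apply_policy(df, policy)
    if len(df) < 4:
        raise ValueError("too few rows to fit a mixed model")
    X, names = _design(df, effs)
    groups = {
        "colony": df["colony_id"].to_numpy(),
        "nest": df["nest_id"].to_numpy(),
        "season": df["season"].to_numpy(),
    }
    fit = fit_binomial_glmm(y, X, groups, fixed_names=names)
    return fit, df.reset_index(drop=True)


def analysis_of_deviance(full: GLMMFit, null: GLMMFit) -> tuple[float, int, float]:
    """chisq = 2*(l_full - l_null); df = fixed-parameter difference;
    p from the upper chi-squared tail."""
    if full.n != null.n:
        raise IncomparableModelsError(
            f"full and null models use different rows ({full.n} vs {null.n})"
        )
    df = len(full.fixed_names) - len(null.fixed_names)
    if df < 1:
        raise IncomparableModelsError("null model must drop the fixed effect")
    chisq = 2.0 * (full.loglik - null.loglik)
    if chisq < -1e-6:
        logger.warning("negative deviance difference (%.3g); numerical noise", chisq)
    p = float(stats.chi2.sf(max(chisq, 0.0), df))
    return float(chisq), df, p


def founder_aod(
    dataset: pd.DataFrame,
    fixed_effects: str | Sequence[str],
    policy: str = "exclude",
) -> AoDResult:
    """Fit full and intercept-only null models on the same rows and compare
    by chi-squared analysis of deviance."""
    effs = [fixed_effects] if isinstance(fixed_effects, str) else list(fixed_effects)
    full, rows = fit_founder_glmm(dataset, effs, policy)
    y = (
        rows["status"].isin(["founder", "possible_founder"]) if policy == "as_founder"
        else rows["status"] == "founder"
    ).to_numpy(float)
    X0 = np.ones((len(rows), 1))
    groups = {
        "colony": rows["colony_id"].to_numpy(),
        "nest": rows["nest_id"].to_numpy(),
        "season": rows["season"].to_numpy(),
    }
    null = fit_binomial_glmm(y, X0, groups, fixed_names=["intercept"])
    chisq, df, p = analysis_of_deviance(full, null)
    return AoDResult(tuple(effs), policy, chisq, df, p, full.n, full, null)


def policy_sensitivity(
    dataset: pd.DataFrame, fixed_effects: str | Sequence[str], alpha: float = 0.05
) -> pd.DataFrame:
    """Run the AoD under all three possible-founder policies and report
    whether the qualitative conclusion (p < alpha) is policy-stable."""
    rows = []
    for policy in POLICIES:
        res = founder_aod(dataset, fixed_effects, policy)
        rows.append({
            "policy": policy, "chisq": res.chisq, "df": res.df,
            "p": res.p, "n": res.n, "significant": res.p < alpha,
        })
    out = pd.DataFrame(rows)
    out.attrs["policy_stable"] = bool(out["significant"].nunique() == 1)
    return out
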