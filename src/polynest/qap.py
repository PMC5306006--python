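"""Quadratic-assignment-procedure significance for network survival models.

Survival models assume independent subjects; nests and trails embedded in
one colony network violate that.  Significance is therefore taken from a
permutation null: the covariate of interest is shuffled among the subjects
of each colony map (one colony at one timepoint) independently, the Cox
model is refitted, and the observed Wald z is compared against the null
distribution of z.  Only the tested covariate is permuted, so the null
preserves the observed association structure of any co-adjusted covariates
(joint permutation is available as an option).  The permutation p-value uses
the add-one rule p = (1 + #extreme) / (1 + B), valid under exchangeability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cox import (
    ConvergenceError,
    CoxEngine,
    CoxSpec,
    SingularInformationError,
    build_design,
    fit_extended_cox,
    _ridge_vector,
)

logger = logging.getLogger(__name__)

TAILS = ("lower", "upper", "two_sided")


@dataclass
class QAPResult:
    """Observed statistic, permutation null and permutation p-value."""

    covariate: str
    observed_stat: float
    observed_beta: float
    null_stats: np.ndarray
    B: int
    n_failed: int
    p_value: float
    tail: str
    seed: int | None
    n: int
    n_events: int
    unreliable: bool = False

    def summary(self) -> dict:
        return {
            "covariate": self.covariate,
            "z": self.observed_stat,
            "beta": self.observed_beta,
            "n": self.n,
            "n_events": self.n_events,
            "B": self.B,
            "n_failed_fits": self.n_failed,
            "p_value": self.p_value,
            "tail": self.tail,
            "seed": self.seed,
            "null_mean": float(np.mean(self.null_stats)) if self.null_stats.size else float("nan"),
            "null_sd": float(np.std(self.null_stats)) if self.null_stats.size else float("nan"),
            "unreliable": self.unreliable,
        }


def permutation_pvalue(observed: float, null: np.ndarray, tail: str) -> float:
    """Add-one permutation p-value: (1 + #{null as or more extreme}) /
    (1 + B).  Valid under exchangeability; its floor is 1/(B+1)."""
    if tail not in TAILS:
        raise ValueError(f"tail must be one of {TAILS}")
    null = np.asarray(null, float)
    if null.size == 0:
        return float("nan")
    eps = 1e-12
    if tail == "lower":
        count = int((null <= observed + eps).sum())
    elif tail == "upper":
        count = int((null >= observed - eps).sum())
    else:
        count = int((np.abs(null) >= abs(observed) - eps).sum())
    return (1 + count) / (1 + null.size)


def _map_groups(rows: pd.DataFrame) -> list[np.ndarray]:
    """Row-index groups for one colony map: (colony_id, interval start).
    Values are exchanged only within a group, never across colonies or
    timepoints; a subject observed in several maps is permuted independently
    in each."""
    grouped = rows.groupby(["colony_id", "start"], sort=True).indices
    return [np.asarray(idx) for _, idx in sorted(grouped.items())]


def permute_within_maps(
    records: pd.DataFrame,
    covariate: str | Sequence[str],
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Return a copy of ``records`` with the covariate value(s) shuffled
    uniformly among the subjects of each colony map.  With a list of
    covariates the rows' value tuples are permuted jointly."""
    covs = [covariate] if isinstance(covariate, str) else list(covariate)
    out = records.copy()
    for idx in _map_groups(out):
        if idx.size < 2:
            logger.info("map with a single subject: value fixed, nothing to permute")
            continue
        perm = rng.permutation(idx.size)
        for c in covs:
            vals = out[c].to_numpy()
            vals[idx] = vals[idx][perm]
            out[c] = vals
    return out


def qap_significance(
    records: pd.DataFrame,
    spec: CoxSpec,
    covariate_of_interest: str,
    B: int = 10_000,
    tail: str = "two_sided",
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    joint: Iterable[str] | None = None,
) -> QAPResult:
    """Extended Cox fit plus within-map QAP permutation test.

    ``joint`` optionally names further covariates to permute together with
    the covariate of interest (joint permutation preserves their mutual
    association while breaking the link to survival).
    """
    if tail not in TAILS:
        raise ValueError(f"tail must be one of {TAILS}")
    if B < 100:
        logger.warning("B=%d is small; permutation p-values will be coarse", B)
    if rng is None:
        rng = np.random.default_rng(seed)

    observed = fit_extended_cox(records, spec)
    j = observed.names.index(covariate_of_interest)
    z_obs = float(observed.z[j])

    rows, X, names, means, strata = build_design(records, spec)
    engine = CoxEngine(
        X,
        rows["start"].to_numpy(float),
        rows["stop"].to_numpy(float),
        rows["event"].to_numpy(int),
        strata,
        spec.tie_method,
        _ridge_vector(names, spec.ridge),
    )
    permute_cols = [covariate_of_interest] + (list(joint) if joint else [])
    col_idx = [names.index(c) for c in permute_cols]
    base_vals = [rows[c].to_numpy(float) for c in permute_cols]
    groups = _map_groups(rows)
    warm = observed.beta.copy()

    null_stats: list[float] = []
    n_failed = 0
    for _ in range(B):
        perm_vals = [v.copy() for v in base_vals]
        for idx in groups:
            if idx.size < 2:
                continue
            perm = rng.permutation(idx.size)
            for v in perm_vals:
                v[idx] = v[idx][perm]
        for k, jcol in enumerate(col_idx):
            engine.set_column(jcol, perm_vals[k] - means[jcol])
        try:
            beta_b, se_b, _, conv = engine.fit(beta0=warm)
            if not conv:
                raise ConvergenceError("permutation refit did not converge")
            null_stats.append(float(beta_b[j] / se_b[j]))
        except (ConvergenceError, SingularInformationError, FloatingPointError):
            n_failed += 1
    null = np.asarray(null_stats)
    p = permutation_pvalue(z_obs, null, tail)
    unreliable = n_failed > 0.05 * B
    if unreliable:
        logger.warning(
            "%d of %d permutation refits failed (>5%%); QAP result flagged unreliable",
            n_failed, B,
        )
    return QAPResult(
        covariate=covariate_of_interest,
        observed_stat=z_obs,
        observed_beta=float(observed.beta[j]),
        null_stats=null,
        B=B,
        n_failed=n_failed,
        p_value=p,
        tail=tail,
        seed=seed,
        n=observed.n,
        n_events=observed.n_events,
        unreliable=unreliable,
    )


def min_endpoint_betweenness(trail, flow_table) -> float:
    """The lower of the two endpoint nests' normalized betweenness values
    (internest trails only)."""
    from .colony import INTERNEST

    if trail.kind != INTERNEST:
        raise ValueError(
            f"trail {trail.trail_id!r} is a foraging trail; endpoint "
            "betweenness applies to internest trails only"
        )
    return min(
        flow_table.normalized[trail.endpoint_a],
        flow_table.normalized[trail.endpoint_b],
    )
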