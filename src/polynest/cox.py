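"""Extended Cox proportional-hazards model on counting-process records.

The hazard for subject i is ``h(t, X) = h0(t) * exp(sum_j beta_j X_ij)``
with time-dependent covariates carried by the counting-process layout: one
(start, stop] row per subject per observation interval, covariates measured
at the interval start.  The partial likelihood is maximized by Newton's
method with Efron (default) or Breslow tie handling; event times here are
mapping intervals, so ties are heavy and Efron's correction matters.

The fitter is written directly on numpy (risk-set index structures are
precomputed once and reused), because the quadratic-assignment-procedure
null distribution requires thousands of refits of the same design with one
permuted column.  An optional per-covariate ridge penalty is available for
separation-prone indicator covariates (e.g. the endpoint-survival indicator
in trail models); significance is assessed by permutation, which applies the
same penalty under the null.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)


class NoEventsError(ValueError):
    """The record set contains no abandonment events."""


class SingularInformationError(ValueError):
    """A covariate carries no variation, so its coefficient is inestimable."""


class ConvergenceError(RuntimeError):
    """Newton iteration failed (typically a monotone partial likelihood
    caused by perfect separation)."""


@dataclass(frozen=True)
class CoxSpec:
    """Model specification: covariate columns (in order), how the colony
    term enters (categorical fixed covariate or baseline stratum), tie
    handling, and optional per-covariate ridge penalties."""

    covariates: tuple[str, ...]
    colony_term: str = "factor"  # "factor" | "stratum" | "none"
    tie_method: str = "efron"  # "efron" | "breslow"
    ridge: Mapping[str, float] | None = None

    def __post_init__(self) -> None:
        if not self.covariates:
            raise ValueError("at least one covariate is required")
        if self.colony_term not in ("factor", "stratum", "none"):
            raise ValueError(f"unknown colony_term {self.colony_term!r}")
        if self.tie_method not in ("efron", "breslow"):
            raise ValueError(f"unknown tie_method {self.tie_method!r}")


@dataclass
class CoxFit:
    """Fitted extended Cox model."""

    spec: CoxSpec
    names: list[str]
    beta: np.ndarray
    se: np.ndarray
    z: np.ndarray
    loglik: float
    loglik_null: float
    baseline: pd.DataFrame  # columns: stratum, time, cumulative_hazard
    n: int
    n_events: int
    n_subjects: int
    converged: bool
    column_means: np.ndarray

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.beta, "se": self.se, "z": self.z}, index=self.names
        )

    def coef(self, name: str) -> float:
        return float(self.beta[self.names.index(name)])

    def z_for(self, name: str) -> float:
        return float(self.z[self.names.index(name)])


@dataclass
class SurvivalCurve:
    """A survival function S(t): nonincreasing, S(0) = 1."""

    times: np.ndarray
    survival: np.ndarray
    profile: dict[str, float] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"time": self.times, "survival": self.survival})
        for k, v in self.profile.items():
            df[k] = v
        return df


class CoxEngine:
    """Partial-likelihood machinery with precomputed risk/death index sets.

    The index structures depend only on (start, stop, event, strata), so a
    permutation that replaces one covariate column reuses all of them via
    :meth:`set_column`.
    """

    def __init__(
        self,
        X: np.ndarray,
        start: np.ndarray,
        stop: np.ndarray,
        event: np.ndarray,
        strata: np.ndarray | None = None,
        tie_method: str = "efron",
        ridge: np.ndarray | None = None,
    ) -> None:
        self.X = np.ascontiguousarray(X, dtype=float)
        self.n, self.p = self.X.shape
        self.tie_method = tie_method
        self.ridge = np.zeros(self.p) if ridge is None else np.asarray(ridge, float)
        start = np.asarray(start, float)
        stop = np.asarray(stop, float)
        event = np.asarray(event, bool)
        if strata is None:
            strata = np.zeros(self.n, dtype=int)
        self.n_events = int(event.sum())
        if self.n_events == 0:
            raise NoEventsError("no events in the record set")
        # one block per (stratum, event time)
        self.blocks: list[tuple[int, float, np.ndarray, np.ndarray]] = []
        for s in np.unique(strata):
            in_s = strata == s
            times = np.unique(stop[in_s & event])
            for t in times:
                risk = np.flatnonzero(in_s & (start < t) & (stop >= t))
                death = np.flatnonzero(in_s & event & (stop == t))
                self.blocks.append((int(s), float(t), risk, death))

    def set_column(self, j: int, values: np.ndarray) -> None:
        self.X[:, j] = values

    def loglik_grad_hess(
        self, beta: np.ndarray, want_derivs: bool = True
    ) -> tuple[float, np.ndarray | None, np.ndarray | None]:
        X = self.X
        eta = X @ beta
        eta_c = eta - eta.max()
        w = np.exp(eta_c)
        ll = 0.0
        grad = np.zeros(self.p) if want_derivs else None
        hess = np.zeros((self.p, self.p)) if want_derivs else None
        for _, _, risk, death in self.blocks:
            d = death.size
            Xr = X[risk]
            wr = w[risk]
            S_R = wr.sum()
            ll += eta_c[death].sum()
            if self.tie_method == "efron" and d > 1:
                frac = np.arange(d) / d
            else:
                frac = np.zeros(d)
            wd = w[death]
            S_D = wd.sum()
            phi = S_R - frac * S_D
            ll -= np.log(phi).sum()
            if not want_derivs:
                continue
            Xd = X[death]
            Sx_R = Xr.T @ wr
            Sx_D = Xd.T @ wd
            num = Sx_R[None, :] - frac[:, None] * Sx_D[None, :]
            r = num / phi[:, None]
            grad += Xd.sum(axis=0) - r.sum(axis=0)
            Sxx_R = (Xr * wr[:, None]).T @ Xr
            Sxx_D = (Xd * wd[:, None]).T @ Xd
            c1 = (1.0 / phi).sum()
            c2 = (frac / phi).sum()
            hess += -(c1 * Sxx_R - c2 * Sxx_D) + r.T @ r
        if self.ridge.any():
            ll -= 0.5 * float(self.ridge @ (beta * beta))
            if want_derivs:
                grad -= self.ridge * beta
                hess -= np.diag(self.ridge)
        return float(ll), grad, hess

    def fit(
        self,
        beta0: np.ndarray | None = None,
        max_iter: int = 50,
        tol: float = 1e-9,
    ) -> tuple[np.ndarray, np.ndarray, float, bool]:
        """Newton with step halving.  Returns (beta, se, loglik, converged)."""
        beta = np.zeros(self.p) if beta0 is None else np.array(beta0, float)
        ll, grad, hess = self.loglik_grad_hess(beta)
        converged = False
        for _ in range(max_iter):
            try:
                step = np.linalg.solve(-hess, grad)
            except np.linalg.LinAlgError as exc:
                raise SingularInformationError(
                    "information matrix is singular (a covariate may carry "
                    "no variation within risk sets)"
                ) from exc
            # step halving
            factor = 1.0
            for _ in range(30):
                cand = beta + factor * step
                ll_new, g_new, h_new = self.loglik_grad_hess(cand)
                if np.isfinite(ll_new) and ll_new >= ll - 1e-12:
                    break
                factor *= 0.5
            else:
                break
            improved = ll_new - ll
            beta, ll, grad, hess = cand, ll_new, g_new, h_new
            if np.abs(beta).max() > 50:
                raise ConvergenceError(
                    "coefficients diverging (|beta| > 50): monotone partial "
                    "likelihood / perfect separation; consider a ridge "
                    "penalty on the offending covariate"
                )
            if improved < tol and np.abs(grad).max() < 1e-4:
                converged = True
                break
        try:
            cov = np.linalg.inv(-hess)
        except np.linalg.LinAlgError as exc:
            raise SingularInformationError("singular information at optimum") from exc
        diag = np.diag(cov).copy()
        if (diag <= 0).any():
            raise SingularInformationError("non-positive variance estimate")
        return beta, np.sqrt(diag), ll, converged

    def baseline_hazard(self, beta: np.ndarray) -> pd.DataFrame:
        """Breslow estimator of the cumulative baseline hazard per stratum,
        at the centered-covariate origin."""
        eta = self.X @ beta
        w = np.exp(eta)
        rows = []
        cum: dict[int, float] = {}
        for s, t, risk, death in self.blocks:
            cum.setdefault(s, 0.0)
            cum[s] += death.size / w[risk].sum()
            rows.append({"stratum": s, "time": t, "cumulative_hazard": cum[s]})
        return pd.DataFrame(rows)


def build_design(
    records: pd.DataFrame, spec: CoxSpec
) -> tuple[pd.DataFrame, np.ndarray, list[str], np.ndarray, np.ndarray]:
    """Complete-case design matrix.  Returns (rows used, X centered, names,
    column means, strata codes)."""
    needed = list(spec.covariates)
    for col in needed + ["start", "stop", "event", "colony_id", "subject_id"]:
        if col not in records.columns:
            raise KeyError(f"records are missing column {col!r}")
    mask = records[needed].notna().all(axis=1)
    rows = records.loc[mask].reset_index(drop=True)
    dropped = int((~mask).sum())
    if dropped:
        logger.info("complete-case analysis: dropped %d rows with missing covariates", dropped)
    cols = [rows[c].to_numpy(float) for c in needed]
    names = list(spec.covariates)
    colonies = np.asarray(rows["colony_id"].astype(str))
    levels = sorted(set(colonies))
    if spec.colony_term == "factor" and len(levels) > 1:
        for lev in levels[1:]:
            cols.append((colonies == lev).astype(float))
            names.append(f"colony[{lev}]")
        strata = np.zeros(len(rows), dtype=int)
    elif spec.colony_term == "stratum":
        strata = np.searchsorted(levels, colonies)
    else:
        strata = np.zeros(len(rows), dtype=int)
    X = np.column_stack(cols) if cols else np.empty((len(rows), 0))
    for j, name in enumerate(names):
        if np.std(X[:, j]) == 0:
            raise SingularInformationError(
                f"covariate {name!r} is constant across records"
            )
    means = X.mean(axis=0)
    return rows, X - means, names, means, strata


def _ridge_vector(names: Sequence[str], ridge: Mapping[str, float] | None) -> np.ndarray:
    out = np.zeros(len(names))
    if ridge:
        for k, v in ridge.items():
            if k in names:
                out[list(names).index(k)] = float(v)
    return out


def fit_extended_cox(records: pd.DataFrame, spec: CoxSpec) -> CoxFit:
    """Maximize the partial likelihood of the extended Cox model over the
    counting-process ``records`` (see ``events.SURVIVAL_COLUMNS``)."""
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
    beta, se, ll, converged = engine.fit()
    if not converged:
        logger.warning("Cox fit stopped before full convergence")
    ll0, _, _ = engine.loglik_grad_hess(np.zeros(len(names)), want_derivs=False)
    return CoxFit(
        spec=spec,
        names=names,
        beta=beta,
        se=se,
        z=beta / se,
        loglik=ll,
        loglik_null=ll0,
        baseline=engine.baseline_hazard(beta),
        n=len(rows),
        n_events=engine.n_events,
        n_subjects=rows["subject_id"].nunique(),
        converged=converged,
        column_means=means,
    )


def kaplan_meier(
    start: np.ndarray, stop: np.ndarray, event: np.ndarray
) -> SurvivalCurve:
    """Product-limit estimator on counting-process intervals (handles
    delayed entry: a row is at risk at t when start < t <= stop)."""
    start = np.asarray(start, float)
    stop = np.asarray(stop, float)
    event = np.asarray(event, bool)
    times = np.unique(stop)
    out_t = [0.0]
    out_s = [1.0]
    s = 1.0
    for t in times:
        at_risk = int(((start < t) & (stop >= t)).sum())
        deaths = int((event & (stop == t)).sum())
        if at_risk == 0:
            logger.warning("empty risk set at t=%s; curve truncated", t)
            break
        s *= 1.0 - deaths / at_risk
        out_t.append(float(t))
        out_s.append(s)
    return SurvivalCurve(np.array(out_t), np.array(out_s))


def survival_curve(
    records: pd.DataFrame, subset: Mapping[str, object] | None = None
) -> SurvivalCurve:
    """Raw Kaplan-Meier curve from survival records, optionally restricted
    to a subgroup (``subset`` maps column name -> required value)."""
    df = records
    profile: dict[str, float] = {}
    if subset:
        for k, v in subset.items():
            df = df[df[k] == v]
            profile[k] = v  # type: ignore[assignment]
    if df.empty:
        raise ValueError("no records selected")
    curve = kaplan_meier(
        df["start"].to_numpy(), df["stop"].to_numpy(), df["event"].to_numpy()
    )
    curve.profile = profile
    return curve


def model_survival_curve(fit: CoxFit, profile: Mapping[str, float]) -> SurvivalCurve:
    """Survival curve the fitted model predicts for a subject holding the
    ``profile`` covariate values fixed over time (unnamed covariates sit at
    their sample mean; with a colony factor this is the average-colony
    baseline).  S(t) = exp(-H0(t))**exp(lp)."""
    lp = 0.0
    for name, value in profile.items():
        if name not in fit.names:
            raise KeyError(f"{name!r} is not a fitted covariate")
        j = fit.names.index(name)
        lp += fit.beta[j] * (float(value) - fit.column_means[j])
    base = fit.baseline
    if base["stratum"].nunique() > 1:
        logger.warning("stratified fit: using the first stratum's baseline")
        base = base[base["stratum"] == base["stratum"].iloc[0]]
    times = np.concatenate([[0.0], base["time"].to_numpy(float)])
    H0 = np.concatenate([[0.0], base["cumulative_hazard"].to_numpy(float)])
    surv = np.exp(-H0 * np.exp(lp))
    return SurvivalCurve(times, surv, dict(profile))
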