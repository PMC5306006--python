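"""Binomial (logit) mixed models with crossed random intercepts.

The budding analysis models founder status with random intercepts for
colony, nest identity and season.  The marginal likelihood is approximated
by the Laplace method at the joint mode of the fixed effects and spherical
random effects (the PIRLS scheme used by lme4 with ``nAGQ = 0``): writing
u = sigma_g * v with v ~ N(0, I), the inner step maximizes the penalized
Bernoulli log-likelihood over (beta, v) by Newton iteration, and the outer
step maximizes the Laplace-approximate log-likelihood

    l(sigma) = l_bern(beta_hat, v_hat) - |v_hat|^2 / 2
               - log det(Z_s' W Z_s + I) / 2

over log(sigma) by Nelder-Mead.  All numerical settings (tolerances,
iteration caps, optimizer options) are pinned module constants so repeated
fits are deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg, optimize, special

logger = logging.getLogger(__name__)

# pinned numerical settings
INNER_TOL = 1e-10
INNER_MAX_ITER = 100
NM_OPTIONS = {"xatol": 1e-4, "fatol": 1e-7, "maxiter": 400}
LOG_SIGMA_START = np.log(0.5)
LOG_SIGMA_BOUNDS = (-8.0, 4.0)
BOUNDARY_SIGMA = 1e-3


class DegenerateResponseError(ValueError):
    """The response has a single class; the model is not identifiable."""


class SingularDesignError(ValueError):
    """A fixed-effect column (other than the intercept) is constant."""


@dataclass
class GLMMFit:
    """Fitted binomial-logit mixed model."""

    fixed_names: list[str]
    beta: np.ndarray
    se: np.ndarray
    sigma: dict[str, float]
    loglik: float
    n: int
    converged: bool
    boundary: dict[str, bool]
    n_levels: dict[str, int]

    def coef(self, name: str) -> float:
        return float(self.beta[self.fixed_names.index(name)])

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"coef": self.beta, "se": self.se}, index=self.fixed_names
        )


def _expand_groups(
    groups: Mapping[str, Sequence], n: int
) -> tuple[list[str], list[np.ndarray], list[int]]:
    names, codes_list, sizes = [], [], []
    for name, labels in groups.items():
        labels = np.asarray(labels)
        if labels.shape[0] != n:
            raise ValueError(f"group {name!r} has wrong length")
        _, codes = np.unique(labels, return_inverse=True)
        names.append(name)
        codes_list.append(codes)
        sizes.append(int(codes.max()) + 1)
    return names, codes_list, sizes


class _LaplaceObjective:
    def __init__(self, y, X, codes_list, sizes):
        self.y = y
        self.X = X
        self.n, self.p = X.shape
        self.codes_list = codes_list
        self.sizes = sizes
        self.q = int(sum(sizes))
        # sparse-free indicator matrix (n is small in this problem)
        Z = np.zeros((self.n, self.q))
        offset = 0
        self.offsets = []
        for codes, size in zip(codes_list, sizes):
            Z[np.arange(self.n), offset + codes] = 1.0
            self.offsets.append(offset)
            offset += size
        self.Z = Z
        self.warm = np.zeros(self.p + self.q)

    def _scaled(self, sigmas: np.ndarray) -> np.ndarray:
        scale = np.concatenate(
            [np.full(size, s) for s, size in zip(sigmas, self.sizes)]
        )
        return self.Z * scale

    def neg_loglik(self, log_sigma: np.ndarray) -> float:
        ll, *_ = self.laplace(np.exp(np.clip(log_sigma, *LOG_SIGMA_BOUNDS)))
        return -ll

    def laplace(self, sigmas: np.ndarray):
        """Inner PIRLS + Laplace correction.  Returns (loglik, coef, H)."""
        Zs = self._scaled(sigmas)
        A = np.concatenate([self.X, Zs], axis=1)
        pen = np.concatenate([np.zeros(self.p), np.ones(self.q)])
        c = self.warm.copy()

        def penalized_ll(c):
            eta = np.clip(A @ c, -30, 30)
            ll = float(self.y @ eta - np.logaddexp(0.0, eta).sum())
            return ll - 0.5 * float(pen @ (c * c))

        pll = penalized_ll(c)
        H = None
        for _ in range(INNER_MAX_ITER):
            eta = np.clip(A @ c, -30, 30)
            mu = special.expit(eta)
            w = np.maximum(mu * (1 - mu), 1e-10)
            grad = A.T @ (self.y - mu) - pen * c
            H = (A * w[:, None]).T @ A + np.diag(pen)
            try:
                cho = linalg.cho_factor(H, lower=True)
            except linalg.LinAlgError:
                H += np.eye(H.shape[0]) * 1e-8
                cho = linalg.cho_factor(H, lower=True)
            step = linalg.cho_solve(cho, grad)
            factor = 1.0
            for _ in range(30):
                cand = c + factor * step
                pll_new = penalized_ll(cand)
                if np.isfinite(pll_new) and pll_new >= pll - 1e-13:
                    break
                factor *= 0.5
            c = cand
            if pll_new - pll < INNER_TOL:
                pll = pll_new
                break
            pll = pll_new
        self.warm = c.copy()
        v = c[self.p:]
        eta = np.clip(A @ c, -30, 30)
        mu = special.expit(eta)
        w = np.maximum(mu * (1 - mu), 1e-10)
        bern = float(self.y @ eta - np.logaddexp(0.0, eta).sum())
        Hvv = (Zs * w[:, None]).T @ Zs + np.eye(self.q)
        sign, logdet = np.linalg.slogdet(Hvv)
        ll = bern - 0.5 * float(v @ v) - 0.5 * logdet
        H = (A * w[:, None]).T @ A + np.diag(pen)
        return ll, c, H


def fit_binomial_glmm(
    y: np.ndarray,
    X: np.ndarray,
    groups: Mapping[str, Sequence],
    fixed_names: Sequence[str] | None = None,
) -> GLMMFit:
    """Fit a binomial-logit mixed model with random intercepts for each
    grouping factor in ``groups``.

    ``X`` must include an explicit intercept column (conventionally first,
    named ``intercept``).  Returns the Laplace-approximate maximum-likelihood
    fit, flagging variance components estimated at the zero boundary.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    n, p = X.shape
    if fixed_names is None:
        fixed_names = [f"x{j}" for j in range(p)]
    fixed_names = list(fixed_names)
    if y.min() == y.max():
        raise DegenerateResponseError(
            "response has a single class; nothing to model"
        )
    for j, name in enumerate(fixed_names):
        if name != "intercept" and np.std(X[:, j]) == 0:
            raise SingularDesignError(f"fixed effect {name!r} is constant")
    gnames, codes_list, sizes = _expand_groups(groups, n)
    obj = _LaplaceObjective(y, X, codes_list, sizes)
    x0 = np.full(len(gnames), LOG_SIGMA_START)
    res = optimize.minimize(obj.neg_loglik, x0, method="Nelder-Mead", options=NM_OPTIONS)
    log_sigma = np.clip(res.x, *LOG_SIGMA_BOUNDS)
    sigmas = np.exp(log_sigma)
    ll, c, H = obj.laplace(sigmas)
    cov = np.linalg.inv(H)[:p, :p]
    se = np.sqrt(np.maximum(np.diag(cov), 0.0))
    boundary = {g: bool(s < BOUNDARY_SIGMA) for g, s in zip(gnames, sigmas)}
    if any(boundary.values()):
        logger.info(
            "variance component(s) at the zero boundary: %s",
            [g for g, b in boundary.items() if b],
        )
    return GLMMFit(
        fixed_names=fixed_names,
        beta=c[:p].copy(),
        se=se,
        sigma={g: float(s) for g, s in zip(gnames, sigmas)},
        loglik=float(ll),
        n=n,
        converged=bool(res.success),
        boundary=boundary,
        n_levels={g: s for g, s in zip(gnames, sizes)},
    )
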