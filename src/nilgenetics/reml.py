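"""REML estimation for Gaussian mixed models with independent random factors.

Model: ``y = X b + sum_k Z_k u_k + e`` with ``u_k ~ N(0, sigma2_k I)`` and
``e ~ N(0, sigma2_e I)``; every ``Z_k`` is the indicator matrix of a factor.
Fixed effects are estimated by generalised least squares at the REML variance
estimates; in a field-trial context with genotype indicators as ``X`` these
are the genotype BLUEs.

The restricted log-likelihood is profiled over the residual variance and
evaluated through Henderson's mixed-model equations, so one evaluation costs
a single Cholesky factorisation of the (p + q) coefficient matrix.  The
variance ratios gamma_k = sigma2_k / sigma2_e are optimised on the log scale
with Nelder-Mead, which keeps every component non-negative by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import scipy.linalg
import scipy.optimize
import scipy.sparse

__all__ = ["REMLResult", "REMLConvergenceError", "reml_fit"]

# Variance ratios gamma = sigma2_k / sigma2_e are confined to [e^-14, e^14].
# The upper cap bounds the condition number of the mixed-model equations
# (relative error ~ machine epsilon times gamma), so GLS estimates stay
# accurate to ~1e-9 even for noiseless degenerate data; real designs sit
# many orders of magnitude below the cap.
_LOG_GAMMA_BOUND = 14.0


class REMLConvergenceError(RuntimeError):
    """REML optimisation failed; carries the last iterate in ``last_params``."""

    def __init__(self, message: str, last_params: Mapping[str, float]):
        super().__init__(message)
        self.last_params = dict(last_params)


@dataclass
class REMLResult:
    """Fitted mixed model: GLS fixed effects plus REML variance components."""

    beta: np.ndarray
    beta_names: list[str]
    varcomp: dict[str, float]       # sigma2 per random factor
    sigma2_resid: float
    neg2_restricted_ll: float       # up to an additive constant
    n_obs: int
    n_fixed: int
    n_evaluations: int
    blups: dict[str, np.ndarray] = field(default_factory=dict)

    def beta_series(self):
        import pandas as pd

        return pd.Series(self.beta, index=self.beta_names, dtype=float)


def _factor_indicator(codes: np.ndarray) -> tuple[scipy.sparse.csr_matrix, int]:
    codes = np.asarray(codes)
    levels, idx = np.unique(codes, return_inverse=True)
    n, q = codes.shape[0], levels.shape[0]
    Z = scipy.sparse.csr_matrix(
        (np.ones(n), (np.arange(n), idx)), shape=(n, q)
    )
    return Z, q


def reml_fit(
    y: np.ndarray,
    X: np.ndarray,
    random_factors: Mapping[str, np.ndarray],
    beta_names: Sequence[str] | None = None,
    xtol: float = 1e-10,
    max_evaluations: int = 4000,
) -> REMLResult:
    """Fit the mixed model by REML.

    Parameters
    ----------
    y : (n,) response.
    X : (n, p) fixed-effect design, full column rank.
    random_factors : mapping factor-name -> (n,) level codes; each factor
        contributes an i.i.d. random effect per level.
    """
    y = np.asarray(y, dtype=float)
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if y.shape[0] != n:
        raise ValueError("y and X have incompatible shapes")
    names = list(random_factors)
    Zs, qs = [], []
    for name in names:
        Z, q = _factor_indicator(random_factors[name])
        Zs.append(Z)
        qs.append(q)
    K = len(names)
    if n - p <= 0:
        raise ValueError("no residual degrees of freedom")

    if K == 0:
        # plain OLS
        beta, ssr_, *_ = np.linalg.lstsq(X, y, rcond=None)
        resid = y - X @ beta
        ssr = float(resid @ resid)
        return REMLResult(
            beta=beta,
            beta_names=list(beta_names) if beta_names else [f"b{i}" for i in range(p)],
            varcomp={},
            sigma2_resid=ssr / (n - p),
            neg2_restricted_ll=(n - p) * np.log(max(ssr, 1e-300)),
            n_obs=n,
            n_fixed=p,
            n_evaluations=1,
        )

    Z = scipy.sparse.hstack(Zs, format="csr")
    q_tot = int(Z.shape[1])
    offsets = np.concatenate([[0], np.cumsum(qs)])

    # cross products, computed once
    XtX = X.T @ X
    Xty = X.T @ y
    ZtX = (Z.T @ X)
    Zty = Z.T @ y
    ZtZ = (Z.T @ Z).toarray()
    yty = float(y @ y)
    rhs = np.concatenate([Xty, Zty])

    C0 = np.zeros((p + q_tot, p + q_tot))
    C0[:p, :p] = XtX
    C0[:p, p:] = ZtX.T
    C0[p:, :p] = ZtX
    C0[p:, p:] = ZtZ

    state = {"evals": 0}

    def _assemble(log_gamma: np.ndarray) -> np.ndarray:
        C = C0.copy()
        inv_gamma = np.exp(-np.clip(log_gamma, -_LOG_GAMMA_BOUND, _LOG_GAMMA_BOUND))
        diag_add = np.repeat(inv_gamma, qs)
        idx = np.arange(p, p + q_tot)
        C[idx, idx] += diag_add
        return C

    def _solve(log_gamma: np.ndarray):
        C = _assemble(log_gamma)
        cho = scipy.linalg.cho_factor(C, lower=True, check_finite=False)
        sol = scipy.linalg.cho_solve(cho, rhs, check_finite=False)
        logdet_C = 2.0 * np.sum(np.log(np.diag(cho[0])))
        ssr = yty - float(rhs @ sol)
        return sol, logdet_C, ssr

    def neg2ll(log_gamma: np.ndarray) -> float:
        state["evals"] += 1
        lg = np.clip(log_gamma, -_LOG_GAMMA_BOUND, _LOG_GAMMA_BOUND)
        try:
            _, logdet_C, ssr = _solve(lg)
        except np.linalg.LinAlgError:
            return np.inf
        ssr = max(ssr, 1e-30 * (yty + 1.0))
        # profiled -2 restricted log-likelihood (constant dropped):
        #   (n - p) log(ssr) + log|C| + sum_k q_k log(gamma_k)
        return float((n - p) * np.log(ssr) + logdet_C + np.dot(qs, lg))

    x0 = np.zeros(K)
    res = scipy.optimize.minimize(
        neg2ll,
        x0,
        method="Nelder-Mead",
        options={
            "xatol": xtol,
            "fatol": 1e-12,
            "maxfev": max_evaluations,
            "maxiter": max_evaluations,
        },
    )
    log_gamma = np.clip(res.x, -_LOG_GAMMA_BOUND, _LOG_GAMMA_BOUND)
    if not np.all(np.isfinite(res.x)) or not np.isfinite(res.fun):
        raise REMLConvergenceError(
            "REML optimisation diverged",
            {name: float(g) for name, g in zip(names, np.exp(log_gamma))},
        )

    sol, _, ssr = _solve(log_gamma)
    ssr = max(ssr, 0.0)
    sigma2_e = ssr / (n - p)
    gammas = np.exp(log_gamma)
    varcomp = {name: float(g * sigma2_e) for name, g in zip(names, gammas)}
    beta = sol[:p]
    blups = {
        name: sol[p + offsets[k]: p + offsets[k + 1]] for k, name in enumerate(names)
    }
    return REMLResult(
        beta=beta,
        beta_names=list(beta_names) if beta_names else [f"b{i}" for i in range(p)],
        varcomp=varcomp,
        sigma2_resid=float(sigma2_e),
        neg2_restricted_ll=float(res.fun),
        n_obs=n,
        n_fixed=p,
        n_evaluations=state["evals"],
        blups=blups,
    )
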