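"""REML fitting of the repeated-measures mixed model.

Model for a trait observed on seedlings over DATs (days after
transplantation) in a randomized complete block design:

    y = X beta + Z u + e

* ``X beta`` — sum-to-zero-coded fixed factorial of ecotype, treatment,
  DAT and their interactions;
* ``u`` — block x DAT random intercepts, iid N(0, sigma_bd^2);
* ``e`` — per-seedling residual vectors across DATs with heterogeneous
  first-order autoregressive covariance R = D C D, where
  C[i, j] = rho^|i-j| and D = diag(sigma_1 .. sigma_T).

Variance parameters are estimated by REML with a log parameterisation
of the standard deviations and an atanh parameterisation of rho, the
fixed effects profiled out analytically (GLS at each candidate).

For the usual balanced case (every seedling observed at every DAT) the
restricted likelihood is evaluated in O(T^3) per block via an
orthogonal rotation in the seedling dimension: within a block of m
seedlings the block-mean component has covariance R + m sigma_bd^2 I
and the m - 1 orthogonal components have covariance R.  Unbalanced data
fall back to a dense marginal covariance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, solve_triangular
from scipy.optimize import minimize

from .design import FULL_FACTORIAL_TERMS, DesignInfo, build_design

__all__ = ["MixedModelFit", "fit_lmm_ar1", "marginal_covariance", "ConvergenceError"]

_RESTART_SEEDS = (11, 23, 47)


class ConvergenceError(RuntimeError):
    """REML optimisation failed from every start; carries the trace."""

    def __init__(self, message: str, trace: list):
        super().__init__(message)
        self.trace = trace


@dataclass
class MixedModelFit:
    """Converged REML fit of the heterogeneous-AR1 mixed model."""

    beta: pd.Series
    cov_beta: np.ndarray
    sigma_bd: float
    rho: float
    sigma_d: np.ndarray
    dat_levels: list
    loglik: float
    converged: bool
    n_obs: int
    design: DesignInfo
    observed_cells: set = field(default_factory=set)
    n_iter: int = 0

    @property
    def se(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_beta)), index=self.beta.index)

    def summary(self) -> pd.DataFrame:
        return pd.DataFrame({"estimate": self.beta, "se": self.se})


def _ar1_corr(rho: float, T: int) -> np.ndarray:
    idx = np.arange(T)
    return rho ** np.abs(idx[:, None] - idx[None, :])


def _residual_cov(rho: float, sigma_d: np.ndarray) -> np.ndarray:
    D = np.diag(sigma_d)
    return D @ _ar1_corr(rho, len(sigma_d)) @ D


def marginal_covariance(
    data: pd.DataFrame,
    sigma_bd: float,
    rho: float,
    sigma_d: Sequence[float],
    dat_levels: Optional[Sequence] = None,
) -> np.ndarray:
    """Dense marginal covariance V = Z sigma_bd^2 Z' + blockdiag(R) in data row order.

    The residual block of each seedling is the sub-matrix of the full
    T x T heterogeneous-AR1 matrix at that seedling's observed DATs.
    """
    sigma_d = np.asarray(sigma_d, dtype=float)
    if dat_levels is None:
        dat_levels = sorted(pd.unique(data["dat"]).tolist())
    dat_idx = {d: i for i, d in enumerate(dat_levels)}
    n = len(data)
    R = _residual_cov(rho, sigma_d)
    V = np.zeros((n, n))
    pos = np.arange(n)
    d_of = data["dat"].map(dat_idx).to_numpy()
    for _, rows in pd.Series(pos).groupby(data["seedling_id"].to_numpy()):
        idx = rows.to_numpy()
        sub = d_of[idx]
        V[np.ix_(idx, idx)] += R[np.ix_(sub, sub)]
    # block x DAT random intercept is shared across seedlings of a block
    cell = list(zip(data["block"].to_numpy(), data["dat"].to_numpy()))
    for _, rows in pd.Series(pos).groupby(pd.Series(cell).to_numpy()):
        idx = rows.to_numpy()
        V[np.ix_(idx, idx)] += sigma_bd ** 2
    return V


def _helmert_q(m: int) -> np.ndarray:
    """Orthonormal m x m basis whose first column is 1/sqrt(m)."""
    q, _ = np.linalg.qr(np.hstack([np.ones((m, 1)) / np.sqrt(m), np.eye(m, m - 1)]))
    # QR sign convention can flip the first column; fix it
    if q[0, 0] < 0:
        q = -q
    return q


class _BalancedREML:
    """Rotated-profile REML objective for balanced designs."""

    def __init__(self, y: np.ndarray, X: np.ndarray, seedling: np.ndarray,
                 block: np.ndarray, dat_code: np.ndarray, T: int):
        p = X.shape[1]
        aug = np.column_stack([y, X])
        mean_groups: dict[int, list[np.ndarray]] = {}
        resid_groups: list[np.ndarray] = []
        for b in pd.unique(block):
            sids = pd.unique(seedling[block == b])
            m = len(sids)
            # (m, T, p+1), rows of each seedling ordered by dat code
            cube = np.empty((m, T, p + 1))
            for i, s in enumerate(sids):
                sel = seedling == s
                order = np.argsort(dat_code[sel])
                cube[i] = aug[sel][order]
            q = _helmert_q(m)
            rotated = np.einsum("im,mtp->itp", q.T, cube)
            mean_groups.setdefault(m, []).append(rotated[0])
            if m > 1:
                resid_groups.append(rotated[1:])
        self.mean_groups = {
            m: np.stack(gs) for m, gs in mean_groups.items()
        }  # m -> (n_blocks_m, T, p+1)
        self.resid = (np.concatenate(resid_groups)
                      if resid_groups else np.empty((0, T, p + 1)))
        self.T = T
        self.p = p
        self.n = len(y)

    def minus2_reml(self, rho, sigma_bd, sigma_d):
        T, p = self.T, self.p
        R = _residual_cov(rho, sigma_d)
        logdet = 0.0
        C = np.zeros((p + 1, p + 1))

        def accumulate(cov, stack):
            nonlocal logdet, C
            if stack.shape[0] == 0:
                return
            L = np.linalg.cholesky(cov)
            logdet += 2.0 * stack.shape[0] * np.log(np.diag(L)).sum()
            flat = stack.transpose(1, 0, 2).reshape(T, -1)
            w = solve_triangular(L, flat, lower=True)
            w = w.reshape(T, stack.shape[0], p + 1).transpose(1, 0, 2)
            w2 = w.reshape(-1, p + 1)
            C += w2.T @ w2

        accumulate(R, self.resid)
        for m, stack in self.mean_groups.items():
            accumulate(R + m * sigma_bd ** 2 * np.eye(T), stack)

        XtViX = C[1:, 1:]
        XtViy = C[1:, 0]
        ytViy = C[0, 0]
        cf = cho_factor(XtViX + 1e-12 * np.eye(p))
        beta = cho_solve(cf, XtViy)
        quad = ytViy - XtViy @ beta
        sign, logdet_x = np.linalg.slogdet(XtViX)
        if sign <= 0:
            raise np.linalg.LinAlgError("X'V^-1X not positive definite")
        return logdet + logdet_x + quad, beta, XtViX


class _DenseREML:
    """Dense-covariance REML objective (unbalanced fallback)."""

    def __init__(self, y, X, data, dat_levels):
        self.y, self.X = y, X
        self.data = data
        self.dat_levels = dat_levels
        self.p = X.shape[1]

    def minus2_reml(self, rho, sigma_bd, sigma_d):
        V = marginal_covariance(self.data, sigma_bd, rho, sigma_d, self.dat_levels)
        L = np.linalg.cholesky(V)
        logdet = 2.0 * np.log(np.diag(L)).sum()
        wy = solve_triangular(L, self.y, lower=True)
        wX = solve_triangular(L, self.X, lower=True)
        XtViX = wX.T @ wX
        XtViy = wX.T @ wy
        cf = cho_factor(XtViX + 1e-12 * np.eye(self.p))
        beta = cho_solve(cf, XtViy)
        quad = wy @ wy - XtViy @ beta
        sign, logdet_x = np.linalg.slogdet(XtViX)
        if sign <= 0:
            raise np.linalg.LinAlgError("X'V^-1X not positive definite")
        return logdet + logdet_x + quad, beta, XtViX


def _start_values(y, X, dat_code, T):
    beta0, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta0
    sigma_d0 = np.array([
        max(np.std(resid[dat_code == t]), 1e-3) for t in range(T)
    ])
    # crude lag-1 residual correlation across adjacent DATs
    r01 = []
    for t in range(T - 1):
        a, b = resid[dat_code == t], resid[dat_code == t + 1]
        if a.size == b.size and a.size > 2:
            r01.append(np.corrcoef(a, b)[0, 1])
    rho0 = float(np.clip(np.nanmean(r01) if r01 else 0.0, -0.9, 0.9))
    return rho0, 0.3 * sigma_d0.mean(), sigma_d0


def fit_lmm_ar1(
    data: pd.DataFrame,
    terms: tuple[str, ...] = FULL_FACTORIAL_TERMS,
    value_col: str = "value",
    maxiter: int = 400,
) -> MixedModelFit:
    """Fit the block x DAT / heterogeneous-AR1 mixed model by REML.

    ``data`` is a long-format trait table with columns seedling_id,
    ecotype, treatment, block, dat and ``value_col`` (one trait).
    """
    data = data.reset_index(drop=True)
    dat_levels = sorted(pd.unique(data["dat"]).tolist())
    T = len(dat_levels)
    if T < 2:
        raise ValueError("heterogeneous AR1 needs at least 2 DAT levels")
    if data.duplicated(["seedling_id", "dat"]).any():
        raise ValueError("each seedling may have at most one value per DAT")
    design = build_design(data, terms)
    X = design.X
    y = data[value_col].to_numpy(dtype=float)
    dat_code = data["dat"].map({d: i for i, d in enumerate(dat_levels)}).to_numpy()
    seedling = data["seedling_id"].to_numpy()
    block = data["block"].to_numpy()

    counts = data.groupby("seedling_id")["dat"].apply(
        lambda s: tuple(sorted(s))
    )
    balanced = counts.nunique() == 1 and len(counts.iloc[0]) == T
    if balanced:
        objective = _BalancedREML(y, X, seedling, block, dat_code, T)
    else:
        objective = _DenseREML(y, X, data, dat_levels)

    def unpack(theta):
        rho = np.tanh(theta[0])
        sigma_bd = np.exp(theta[1])
        sigma_d = np.exp(theta[2:])
        return rho, sigma_bd, sigma_d

    def fun(theta):
        try:
            val, _, _ = objective.minus2_reml(*unpack(theta))
        except np.linalg.LinAlgError:
            return 1e12
        return val if np.isfinite(val) else 1e12

    rho0, sbd0, sd0 = _start_values(y, X, dat_code, T)
    theta0 = np.concatenate([[np.arctanh(rho0), np.log(max(sbd0, 1e-3))],
                             np.log(sd0)])
    starts = [theta0]
    for s in _RESTART_SEEDS:
        rng = np.random.default_rng(s)
        starts.append(theta0 + rng.normal(0.0, 0.3, theta0.size))

    trace = []
    best = None
    for i, th0 in enumerate(starts):
        res = minimize(fun, th0, method="L-BFGS-B",
                       options={"maxiter": maxiter, "ftol": 1e-11})
        trace.append({"start": i, "fun": res.fun, "success": bool(res.success),
                      "nit": res.nit, "message": str(res.message)})
        if np.isfinite(res.fun) and res.fun < 1e11:
            best = res
            break
    if best is None:
        raise ConvergenceError("REML optimisation failed from every start", trace)

    rho, sigma_bd, sigma_d = unpack(best.x)
    m2, beta, XtViX = objective.minus2_reml(rho, sigma_bd, sigma_d)
    cov_beta = np.linalg.inv(XtViX)
    observed = set(map(tuple, data[design.factor_names()].drop_duplicates()
                       .itertuples(index=False, name=None)))
    return MixedModelFit(
        beta=pd.Series(beta, index=design.column_names),
        cov_beta=cov_beta,
        sigma_bd=float(sigma_bd),
        rho=float(rho),
        sigma_d=np.asarray(sigma_d, dtype=float),
        dat_levels=dat_levels,
        loglik=-0.5 * float(m2),
        converged=bool(best.success) or best.fun < 1e11,
        n_obs=len(y),
        design=design,
        observed_cells=observed,
        n_iter=int(best.nit),
    )
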