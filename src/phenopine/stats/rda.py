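"""Redundancy analysis (RDA) with permutation tests.

Constrained ordination of a z-scored trait matrix on categorical
predictors (ecotype, treatment): the traits are regressed on the
predictor dummies by least squares, the fitted values are decomposed by
SVD into constrained axes, and R^2 (the fraction of total trait
variance explained by the predictors) together with per-predictor
marginal effects is tested by freely permuting the rows of the
response matrix.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["RdaResult", "rda", "zscore"]


def zscore(matrix) -> np.ndarray:
    """Column-wise standardisation to mean 0, SD 1 (sample SD, ddof=1)."""
    if isinstance(matrix, pd.DataFrame):
        names = list(matrix.columns)
        arr = matrix.to_numpy(dtype=float)
    else:
        arr = np.asarray(matrix, dtype=float)
        names = [str(i) for i in range(arr.shape[1])]
    sd = arr.std(axis=0, ddof=1)
    for j, s in enumerate(sd):
        if s == 0:
            raise ValueError(f"constant response column {names[j]!r}")
    return (arr - arr.mean(axis=0)) / sd


@dataclass
class RdaResult:
    """Constrained-ordination summary."""

    r_squared: float
    eigenvalues: np.ndarray
    axis_fractions: np.ndarray
    overall_p: float
    predictor_p: dict[str, float]
    site_scores: np.ndarray
    trait_scores: np.ndarray
    n_perm: int


def _dummy_matrix(predictors: pd.DataFrame) -> tuple[np.ndarray, dict[str, slice]]:
    """Centred full-rank dummy coding (first level dropped per factor)."""
    cols = []
    slices = {}
    start = 0
    for name in predictors.columns:
        col = predictors[name]
        if col.dtype.kind in "OUSb" or isinstance(col.dtype, pd.CategoricalDtype):
            levels = sorted(pd.unique(col).tolist())
            block = np.column_stack([
                (col == lev).to_numpy(dtype=float) for lev in levels[1:]
            ])
        else:
            block = col.to_numpy(dtype=float)[:, None]
        cols.append(block)
        slices[name] = slice(start, start + block.shape[1])
        start += block.shape[1]
    X = np.hstack(cols)
    return X - X.mean(axis=0), slices


def _fitted_ss(q: np.ndarray, yc: np.ndarray) -> float:
    proj = q.T @ yc
    return float(np.sum(proj * proj))


def rda(
    responses,
    predictors: pd.DataFrame,
    n_perm: int = 999,
    seed: int = 0,
    standardize: bool = True,
) -> RdaResult:
    """Redundancy analysis of ``responses`` on categorical ``predictors``.

    Responses are z-scored (unless ``standardize=False``, in which case
    they are only centred); significance of the overall model and of
    each predictor's marginal (extra sum of squares) effect is assessed
    by ``n_perm`` free row permutations of the response matrix.
    """
    Y = zscore(responses) if standardize else None
    if Y is None:
        arr = (responses.to_numpy(dtype=float)
               if isinstance(responses, pd.DataFrame)
               else np.asarray(responses, dtype=float))
        Y = arr - arr.mean(axis=0)
    n, q_resp = Y.shape
    if q_resp < 2:
        raise ValueError("RDA needs at least 2 response variables")
    Xc, slices = _dummy_matrix(predictors.reset_index(drop=True))
    if np.linalg.matrix_rank(Xc) >= n - 1:
        raise ValueError("more predictor df than rows leave nothing to test")

    Q, _ = np.linalg.qr(Xc)
    total_ss = float(np.sum(Y * Y))
    fitted = Q @ (Q.T @ Y)
    fitted_ss = float(np.sum(fitted * fitted))
    r2 = min(fitted_ss / total_ss, 1.0)  # guard float overshoot at exact fit

    U, s, Vt = np.linalg.svd(fitted, full_matrices=False)
    eig = s ** 2
    keep = eig > max(1e-10 * eig.max(), 1e-30) if eig.size else eig > 0
    eig = eig[keep]
    axis_fractions = eig / eig.sum() if eig.size else eig
    site_scores = U[:, keep] * s[keep]
    trait_scores = Vt[keep].T

    # marginal (type-III-like) predictor statistics: extra SS given the others
    marg_obs = {}
    reduced_q = {}
    for name in predictors.columns:
        others = [c for c in range(Xc.shape[1])
                  if not (slices[name].start <= c < slices[name].stop)]
        if others:
            Qr, _ = np.linalg.qr(Xc[:, others])
        else:
            Qr = np.zeros((n, 0))
        reduced_q[name] = Qr
        marg_obs[name] = fitted_ss - _fitted_ss(Qr, Y)

    rng = np.random.default_rng(seed)
    exceed_overall = 0
    exceed_marg = {name: 0 for name in predictors.columns}
    for _ in range(n_perm):
        Yp = Y[rng.permutation(n)]
        full = _fitted_ss(Q, Yp)
        if full >= fitted_ss - 1e-12:
            exceed_overall += 1
        for name in predictors.columns:
            if full - _fitted_ss(reduced_q[name], Yp) >= marg_obs[name] - 1e-12:
                exceed_marg[name] += 1
    overall_p = (1 + exceed_overall) / (n_perm + 1)
    predictor_p = {
        name: (1 + cnt) / (n_perm + 1) for name, cnt in exceed_marg.items()
    }
    return RdaResult(r2, eig, axis_fractions, overall_p, predictor_p,
                     site_scores, trait_scores, n_perm)
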