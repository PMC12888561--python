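"""Wald tests, predicted means and FDR-adjusted pairwise comparisons.

Fixed-effect terms are tested marginally with chi-square Wald
statistics (each term's coefficient block given all others).  Predicted
means are estimable linear combinations of the fixed effects averaged
over the omitted factors, with normal 95 % intervals (multiplier 1.96).
Pairwise contrasts carry Benjamini-Hochberg adjusted p-values and
Cohen's d standardised by the model's residual SD at the relevant DAT.
"""

from __future__ import annotations

from itertools import combinations, product
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .lmm import MixedModelFit

__all__ = [
    "wald_tests",
    "predicted_means",
    "pairwise_comparisons",
    "benjamini_hochberg",
    "NonEstimableError",
]

Z95 = 1.96


class NonEstimableError(ValueError):
    """Requested mean involves factor cells absent from the data."""


def wald_tests(fit: MixedModelFit) -> pd.DataFrame:
    """Marginal Wald chi-square test per fixed-effect term.

    W = beta_term' C_term^-1 beta_term, referred to chi-square with the
    term's degrees of freedom; p-values are unadjusted.
    """
    rows = []
    for term in fit.design.terms:
        if term == "1":
            continue
        sl = fit.design.slices[term]
        b = fit.beta.to_numpy()[sl]
        if b.size == 0:
            raise ValueError(f"term {term!r} has an empty coefficient block")
        C = fit.cov_beta[sl, sl]
        try:
            W = float(b @ np.linalg.solve(C, b))
        except np.linalg.LinAlgError as err:
            raise np.linalg.LinAlgError(
                f"singular covariance block for term {term!r}"
            ) from err
        df = b.size
        rows.append({"term": term, "wald": W, "df": df,
                     "p_value": float(sps.chi2.sf(W, df))})
    return pd.DataFrame(rows)


def _prediction_row(fit: MixedModelFit, fixed: dict) -> np.ndarray:
    """Design row for a cell mean averaged over factors absent from ``fixed``."""
    design = fit.design
    all_factors = design.factor_names()
    for f in fixed:
        if f not in all_factors:
            raise NonEstimableError(f"factor {f!r} is not in the model")
    free = [f for f in all_factors if f not in fixed]
    cells = []
    for combo in product(*(design.levels[f] for f in free)):
        cell = dict(fixed)
        cell.update(dict(zip(free, combo)))
        key = tuple(cell[f] for f in all_factors)
        if fit.observed_cells and key not in fit.observed_cells:
            raise NonEstimableError(
                f"cell {dict(zip(all_factors, key))} has no data; "
                "the requested mean is not estimable"
            )
        cells.append(design.row_for_cell(cell))
    return np.mean(cells, axis=0)


def predicted_means(
    fit: MixedModelFit, factors: Sequence[str]
) -> pd.DataFrame:
    """Model-based means with 95 % CI for each combination of ``factors``.

    Omitted model factors are averaged over with equal weight per level.
    """
    factors = list(factors)
    design = fit.design
    for f in factors:
        if f not in design.levels:
            raise NonEstimableError(f"factor {f!r} is not in the model")
    beta = fit.beta.to_numpy()
    rows = []
    for combo in product(*(design.levels[f] for f in factors)):
        fixed = dict(zip(factors, combo))
        r = _prediction_row(fit, fixed)
        est = float(r @ beta)
        se = float(np.sqrt(r @ fit.cov_beta @ r))
        rows.append({**fixed, "estimate": est, "se": se,
                     "lower": est - Z95 * se, "upper": est + Z95 * se})
    return pd.DataFrame(rows)


def benjamini_hochberg(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value family")
    return multipletests(p, method="fdr_bh")[1]


def _pooled_sd(fit: MixedModelFit, dat) -> float:
    if dat is not None:
        return float(fit.sigma_d[fit.dat_levels.index(dat)])
    return float(np.sqrt(np.mean(fit.sigma_d ** 2)))


def pairwise_comparisons(
    fit: MixedModelFit,
    factor: str,
    by: Optional[Sequence[str]] = None,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """All pairwise level contrasts of ``factor`` within each ``by`` cell.

    One BH family per call (the declared family is all returned
    contrasts).  Cohen's d divides each contrast by the model residual
    SD at that cell's DAT, or the root-mean-square residual SD when DAT
    is averaged over.
    """
    by = list(by or [])
    design = fit.design
    if factor not in design.levels:
        raise NonEstimableError(f"factor {factor!r} is not in the model")
    beta = fit.beta.to_numpy()
    rows = []
    for combo in product(*(design.levels[f] for f in by)):
        ctx = dict(zip(by, combo))
        for a, b in combinations(design.levels[factor], 2):
            ra = _prediction_row(fit, {**ctx, factor: a})
            rb = _prediction_row(fit, {**ctx, factor: b})
            d = ra - rb
            est = float(d @ beta)
            se = float(np.sqrt(d @ fit.cov_beta @ d))
            z = est / se if se > 0 else np.inf
            p = float(2.0 * sps.norm.sf(abs(z)))
            sd = _pooled_sd(fit, ctx.get("dat"))
            rows.append({**ctx, "level_a": a, "level_b": b,
                         "estimate": est, "se": se,
                         "lower": est - Z95 * se, "upper": est + Z95 * se,
                         "p_raw": p, "cohen_d": est / sd if sd > 0 else np.nan})
    if not rows:
        raise ValueError("empty contrast family")
    table = pd.DataFrame(rows)
    table["p_adj"] = benjamini_hochberg(table["p_raw"].to_numpy())
    table["significant"] = table["p_adj"] < alpha
    return table
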