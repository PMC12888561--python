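"""Sum-to-zero factorial design matrices for the trait mixed model.

Factors are coded with sum-to-zero contrasts (each factor's effects sum
to zero, the last level carries minus the sum of the others), which
matches the generating model of the synthetic trait data and keeps the
intercept equal to the grand mean in balanced designs.  Interaction
columns are element-wise products of the parent contrast columns.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["DesignInfo", "build_design", "FULL_FACTORIAL_TERMS"]

FULL_FACTORIAL_TERMS = (
    "ecotype", "treatment", "dat",
    "ecotype:treatment", "treatment:dat", "ecotype:dat",
    "ecotype:treatment:dat",
)


def sum_to_zero_contrast(n_levels: int) -> np.ndarray:
    """(L, L-1) contrast matrix: identity rows, last row all -1."""
    c = np.vstack([np.eye(n_levels - 1), -np.ones(n_levels - 1)])
    return c


@dataclass
class DesignInfo:
    """A fixed-effects design with named term blocks."""

    X: np.ndarray
    terms: tuple[str, ...]
    slices: dict[str, slice]
    levels: dict[str, list]
    column_names: list[str]

    @property
    def n_params(self) -> int:
        return self.X.shape[1]

    def factor_names(self) -> list[str]:
        names: list[str] = []
        for t in self.terms:
            for f in t.split(":"):
                if f != "1" and f not in names:
                    names.append(f)
        return names

    def row_for_cell(self, cell: dict) -> np.ndarray:
        """Design row of a single factor-level combination."""
        row = [np.ones(1)]
        for term in self.terms:
            if term == "1":
                continue
            block = np.ones(1)
            for f in term.split(":"):
                levels = self.levels[f]
                contrast = sum_to_zero_contrast(len(levels))
                i = levels.index(cell[f])
                block = (block[:, None] * contrast[i][None, :]).ravel()
            row.append(block)
        return np.concatenate(row)


def _factor_columns(df: pd.DataFrame, factor: str) -> tuple[np.ndarray, list]:
    levels = sorted(pd.unique(df[factor]).tolist())
    if len(levels) < 2:
        raise ValueError(f"factor {factor!r} needs at least 2 levels")
    contrast = sum_to_zero_contrast(len(levels))
    idx = pd.Categorical(df[factor], categories=levels).codes
    return contrast[idx], levels


def build_design(
    df: pd.DataFrame, terms: tuple[str, ...] = FULL_FACTORIAL_TERMS
) -> DesignInfo:
    """Build the fixed-effects matrix with an intercept plus ``terms``.

    ``terms`` are factor names or colon-joined interactions; every
    factor named must be a column of ``df``.
    """
    terms = tuple(t for t in terms if t != "1")
    n = len(df)
    cols = [np.ones((n, 1))]
    names = ["(Intercept)"]
    slices = {"1": slice(0, 1)}
    levels: dict[str, list] = {}
    main_cols: dict[str, np.ndarray] = {}
    start = 1
    for term in terms:
        factors = term.split(":")
        block = np.ones((n, 1))
        label_parts: list[list[str]] = [[]]
        for f in factors:
            if f not in main_cols:
                main_cols[f], levels[f] = _factor_columns(df, f)
            fc = main_cols[f]
            block = (block[:, :, None] * fc[:, None, :]).reshape(n, -1)
            label_parts = [
                lp + [f"{f}[{lev}]"] for lp in label_parts
                for lev in levels[f][:-1]
            ]
        cols.append(block)
        names.extend(":".join(lp) for lp in label_parts)
        slices[term] = slice(start, start + block.shape[1])
        start += block.shape[1]
    X = np.hstack(cols)
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("design matrix is rank deficient for these terms")
    return DesignInfo(X, ("1",) + terms, slices, levels, names)
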