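"""Monte-Carlo evaluation studies for the mixed-model layer.

Repeats the generate-fit cycle under known truth to measure confidence
interval coverage, AR1-correlation recovery and the Wald test's type-I
error.  Study conditions: the 2 ecotype x 3 treatment factorial with 20
seedlings per cell in 5 blocks (120 seedlings, 720 observations),
T = 6 DATs, rho = 0.6, unit residual SDs and a 0.5 SD block x DAT
effect — a scale at which a full replicate study runs in minutes.
"""

from __future__ import annotations

from itertools import product

import numpy as np

from .stats import fit_lmm_ar1, wald_tests
from .synthetic import TraitEffectSpec, generate_trait_dataset

__all__ = ["study_spec", "true_beta_for", "lmm_recovery_study", "wald_null_study"]

_ECO = {"lowland": 0, "upland": 1}
_TRT = {"C": 0, "MD": 1, "D": 2}


def study_spec(seed: int, null: bool = False, n_dats: int = 6,
               n_per_cell: int = 20, rho: float = 0.6) -> TraitEffectSpec:
    """The recovery-study generating model (all effects zero when ``null``)."""
    if null:
        return TraitEffectSpec(dat_effects=(0.0,) * n_dats, ar1_rho=rho,
                               n_per_cell=n_per_cell, n_blocks=5, seed=seed)
    dat_eff = np.linspace(-1.0, 1.0, n_dats)
    return TraitEffectSpec(
        ecotype_effects=(0.5, -0.5),
        treatment_effects=(0.6, 0.0, -0.6),
        dat_effects=tuple(dat_eff - dat_eff.mean()),
        ar1_rho=rho, n_per_cell=n_per_cell, n_blocks=5, seed=seed,
    )


def true_beta_for(spec: TraitEffectSpec, design) -> np.ndarray:
    """True coefficients in the fitted design's coding, solved from cell means."""
    rows, means = [], []
    for eco, trt, dat in product(design.levels["ecotype"],
                                 design.levels["treatment"],
                                 design.levels["dat"]):
        rows.append(design.row_for_cell(
            {"ecotype": eco, "treatment": trt, "dat": dat}))
        means.append(spec.cell_mean(_ECO[eco], _TRT[trt], dat - 1))
    beta, *_ = np.linalg.lstsq(np.asarray(rows), np.asarray(means), rcond=None)
    return beta


def lmm_recovery_study(n_datasets: int = 200, seed: int = 0) -> dict:
    """CI coverage per fixed effect and rho recovery over replicate fits."""
    rng = np.random.default_rng(seed)
    cover = None
    rhos = []
    true_beta = None
    for _ in range(n_datasets):
        spec = study_spec(int(rng.integers(2 ** 31)))
        fit = fit_lmm_ar1(generate_trait_dataset(spec))
        if true_beta is None:
            true_beta = true_beta_for(spec, fit.design)
            cover = np.zeros(true_beta.size)
        b, se = fit.beta.to_numpy(), fit.se.to_numpy()
        cover += np.abs(b - true_beta) <= 1.96 * se
        rhos.append(fit.rho)
    coverage = cover / n_datasets
    return {
        "coverage": coverage,
        "coverage_min": float(coverage.min()),
        "coverage_max": float(coverage.max()),
        "coverage_mean": float(coverage.mean()),
        "rho_mean": float(np.mean(rhos)),
        "rho_truth": 0.6,
        "n_datasets": n_datasets,
    }


def wald_null_study(n_datasets: int = 200, seed: int = 0,
                    term: str = "ecotype:treatment",
                    alpha: float = 0.05) -> dict:
    """Empirical type-I error of the marginal Wald test under the null."""
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(n_datasets):
        spec = study_spec(int(rng.integers(2 ** 31)), null=True)
        table = wald_tests(fit_lmm_ar1(generate_trait_dataset(spec)))
        p = table.loc[table["term"] == term, "p_value"].iloc[0]
        rejections += p < alpha
    return {"type_i_error": rejections / n_datasets, "alpha": alpha,
            "term": term, "n_datasets": n_datasets}
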