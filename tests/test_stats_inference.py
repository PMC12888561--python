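"""Wald tests, predicted means, BH adjustment and Cohen's d."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from phenopine.stats import (
    NonEstimableError,
    benjamini_hochberg,
    build_design,
    fit_lmm_ar1,
    pairwise_comparisons,
    predicted_means,
    wald_tests,
)
from phenopine.stats.lmm import MixedModelFit
from phenopine.synthetic import TraitEffectSpec, generate_trait_dataset


def brute_force_bh(p):
    """Literal step-up rule: padj_(i) = min over j>=i of min(1, m p_(j) / j)."""
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    adj = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        adj[i] = running
    return np.minimum(adj, 1.0)


def toy_fit(beta, cov, terms=("ecotype",), sigma_d=(1.0, 1.0)):
    """Hand-built fit over a balanced 2-level ecotype design."""
    df = pd.DataFrame({
        "ecotype": ["lowland", "upland"] * 4,
        "treatment": ["C"] * 8,
        "dat": [1, 1, 2, 2] * 2,
    })
    design = build_design(df, terms)
    observed = set(map(tuple, df[design.factor_names()].drop_duplicates()
                       .itertuples(index=False, name=None)))
    return MixedModelFit(
        beta=pd.Series(beta, index=design.column_names),
        cov_beta=np.asarray(cov, dtype=float),
        sigma_bd=0.0, rho=0.0, sigma_d=np.asarray(sigma_d, dtype=float),
        dat_levels=[1, 2], loglik=0.0, converged=True, n_obs=len(df),
        design=design, observed_cells=observed,
    )


class TestWald:
    def test_matches_direct_quadratic_form(self):
        fit = toy_fit([10.0, 0.8], np.diag([0.04, 0.01]))
        table = wald_tests(fit)
        row = table[table["term"] == "ecotype"].iloc[0]
        assert row["wald"] == pytest.approx(0.8 ** 2 / 0.01)
        assert row["p_value"] == pytest.approx(sps.chi2.sf(64.0, 1))

    def test_multi_df_term_quadratic_form(self):
        spec = TraitEffectSpec(dat_effects=(0.0, 0.0, 0.0), n_per_cell=4,
                               n_blocks=2, seed=2)
        fit = fit_lmm_ar1(generate_trait_dataset(spec))
        table = wald_tests(fit)
        sl = fit.design.slices["treatment:dat"]
        b = fit.beta.to_numpy()[sl]
        W = b @ np.linalg.inv(fit.cov_beta[sl, sl]) @ b
        row = table[table["term"] == "treatment:dat"].iloc[0]
        assert row["wald"] == pytest.approx(W, rel=1e-9)
        assert row["df"] == b.size

    def test_empty_term_block_rejected(self):
        fit = toy_fit([10.0, 0.8], np.diag([0.04, 0.01]))
        fit.design.slices["ecotype"] = slice(1, 1)
        with pytest.raises(ValueError, match="empty"):
            wald_tests(fit)

    def test_null_pvalues_roughly_uniform(self):
        ps = []
        for seed in range(40):
            spec = TraitEffectSpec(dat_effects=(0.0, 0.0), n_per_cell=6,
                                   n_blocks=3, ar1_rho=0.3, seed=900 + seed)
            fit = fit_lmm_ar1(generate_trait_dataset(spec),
                              terms=("ecotype", "treatment", "dat"))
            t = wald_tests(fit)
            ps.append(t.loc[t["term"] == "treatment", "p_value"].iloc[0])
        assert 0.30 <= np.mean(ps) <= 0.70
        assert np.mean(np.array(ps) < 0.05) <= 0.20


class TestPredictedMeans:
    def test_intercept_only_returns_grand_mean(self):
        spec = TraitEffectSpec(dat_effects=(0.0, 0.0), n_per_cell=6, n_blocks=3,
                               ar1_rho=0.0, seed=4)
        df = generate_trait_dataset(spec)
        fit = fit_lmm_ar1(df, terms=())
        out = predicted_means(fit, [])
        assert len(out) == 1
        # GLS grand mean: equals the intercept exactly, near the sample mean
        assert out["estimate"].iloc[0] == fit.beta.iloc[0]
        assert out["se"].iloc[0] == pytest.approx(np.sqrt(fit.cov_beta[0, 0]))
        assert out["estimate"].iloc[0] == pytest.approx(df["value"].mean(), abs=0.05)
        assert out["upper"].iloc[0] - out["estimate"].iloc[0] == pytest.approx(
            1.96 * out["se"].iloc[0])

    def test_balanced_two_group_means_recovered(self):
        spec = TraitEffectSpec(ecotype_effects=(1.0, -1.0),
                               dat_effects=(0.0, 0.0), ar1_rho=0.0,
                               block_dat_sd=0.0, per_dat_sd=(1.0, 1.0),
                               n_per_cell=30, n_blocks=2, seed=8)
        df = generate_trait_dataset(spec)
        fit = fit_lmm_ar1(df, terms=("ecotype",))
        out = predicted_means(fit, ["ecotype"]).set_index("ecotype")
        sample = df.groupby("ecotype")["value"].mean()
        for eco in ("lowland", "upland"):
            assert out.loc[eco, "estimate"] == pytest.approx(sample[eco], abs=0.02)

    def test_missing_cell_is_non_estimable(self):
        spec = TraitEffectSpec(dat_effects=(0.0, 0.0, 0.0), n_per_cell=4,
                               n_blocks=2, seed=2)
        fit = fit_lmm_ar1(generate_trait_dataset(spec))
        fit.observed_cells.discard(("lowland", "C", 1))
        with pytest.raises(NonEstimableError, match="no data"):
            predicted_means(fit, ["ecotype"])

    def test_unknown_factor_rejected(self):
        fit = toy_fit([1.0, 0.0], np.eye(2))
        with pytest.raises(NonEstimableError, match="not in the model"):
            predicted_means(fit, ["needle_age"])


class TestBenjaminiHochberg:
    def test_worked_example(self):
        np.testing.assert_allclose(
            benjamini_hochberg([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    @settings(derandomize=True, max_examples=100, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    def test_matches_brute_force_step_up(self, p):
        np.testing.assert_allclose(benjamini_hochberg(p), brute_force_bh(p),
                                   atol=1e-12)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(st.lists(st.floats(0.0, 1.0), min_size=2, max_size=30))
    def test_monotone_in_rank_and_at_least_raw(self, p):
        p = np.asarray(p)
        adj = benjamini_hochberg(p)
        assert np.all(adj >= p - 1e-12)
        order = np.argsort(p, kind="mergesort")
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_empty_family_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            benjamini_hochberg([])


class TestPairwise:
    def test_identical_groups_give_zero_d(self):
        fit = toy_fit([10.0, 0.0], np.diag([0.04, 0.01]))
        table = pairwise_comparisons(fit, "ecotype")
        assert table["cohen_d"].iloc[0] == 0.0
        assert table["estimate"].iloc[0] == 0.0

    def test_one_pooled_sd_gap_gives_unit_d(self):
        # sum-to-zero effect +-0.5 -> group difference 1.0; sigma_d = 1
        fit = toy_fit([10.0, 0.5], np.diag([0.04, 0.01]))
        table = pairwise_comparisons(fit, "ecotype")
        assert table["cohen_d"].iloc[0] == pytest.approx(1.0)

    def test_adjusted_never_below_raw(self):
        spec = TraitEffectSpec(dat_effects=(0.0, 0.0, 0.0), n_per_cell=4,
                               n_blocks=2, seed=6)
        fit = fit_lmm_ar1(generate_trait_dataset(spec))
        table = pairwise_comparisons(fit, "treatment", by=["dat"])
        assert len(table) == 9  # 3 pairs x 3 DATs
        assert np.all(table["p_adj"] >= table["p_raw"] - 1e-12)

    def test_per_dat_sd_used_for_d(self):
        fit = toy_fit([10.0, 0.5, 0.0], np.diag([0.04, 0.01, 0.01]),
                      terms=("ecotype", "dat"), sigma_d=(2.0, 4.0))
        table = pairwise_comparisons(fit, "ecotype", by=["dat"]).set_index("dat")
        assert table.loc[1, "cohen_d"] == pytest.approx(1.0 / 2.0)
        assert table.loc[2, "cohen_d"] == pytest.approx(1.0 / 4.0)
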