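"""Regression, Wagstaff decomposition, mediation, Holm and Spearman."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import lifecap as lc
from lifecap.decompose import RankDeficientError

from conftest import random_design_cohort
from _oracles import brute_force_holm, numpy_early_life_shares


class TestFitOLS:
    def test_outcome_equal_to_dummy_is_exact(self):
        df = pd.DataFrame(
            {"g": pd.Categorical(["a", "b"] * 40, categories=["a", "b"])}
        )
        df["y"] = (df["g"] == "b").astype(float)
        fit = lc.fit_ols(df, "y", ["g"])
        assert fit.params["g[b]"] == pytest.approx(1.0, abs=1e-12)
        assert fit.rsquared == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_regressors_match_univariate_slopes(self):
        rng = np.random.default_rng(1)
        n = 400
        x1 = np.repeat([0.0, 1.0], n // 2)
        x2 = np.tile([0.0, 1.0], n // 2)  # balanced => orthogonal to x1
        df = pd.DataFrame({"x1": x1, "x2": x2})
        df["y"] = 2.0 + 0.7 * x1 - 0.3 * x2 + rng.standard_normal(n)
        multi = lc.fit_ols(df, "y", ["x1", "x2"])
        uni1 = lc.fit_ols(df, "y", ["x1"])
        uni2 = lc.fit_ols(df, "y", ["x2"])
        assert multi.params["x1"] == pytest.approx(uni1.params["x1"], abs=1e-10)
        assert multi.params["x2"] == pytest.approx(uni2.params["x2"], abs=1e-10)

    def test_rank_deficiency_names_columns(self):
        df = pd.DataFrame(
            {
                "g": pd.Categorical(["a", "b"] * 30),
                "h": pd.Categorical(["p", "q"] * 30),  # aliased with g
            }
        )
        df["y"] = np.random.default_rng(0).standard_normal(60)
        with pytest.raises(RankDeficientError, match=r"h\[q\]"):
            lc.fit_ols(df, "y", ["g", "h"])

    def test_intercept_only_allowed(self):
        df = pd.DataFrame({"y": [1.0, 2.0, 3.0]})
        fit = lc.fit_ols(df, "y", [])
        assert fit.params["const"] == pytest.approx(2.0)

    def test_planted_effect_recovery_default_cohort(
        self, default_cfg, covariate_names, references
    ):
        coh = lc.generate_cohort(default_cfg.replace(n=21783, seed=2))
        fit = lc.fit_ols(coh, "latent_overall", covariate_names, references)
        term = "father_literate[literate]"
        lo, hi = fit.conf_int.loc[term]
        assert lo <= 0.040 <= hi

    def test_weights_honoured(self):
        df = pd.DataFrame({"x": [0.0, 0.0, 1.0, 1.0], "y": [0.0, 4.0, 1.0, 1.0]})
        w = np.array([1.0, 0.0, 1.0, 1.0])  # zero weight kills the outlier
        fit = lc.fit_ols(df, "y", ["x"], weights=w)
        assert fit.params["x"] == pytest.approx(1.0, abs=1e-10)


class TestDecompose:
    def test_intercept_only_residual_is_total(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame({"y": rng.uniform(1, 2, 200)})
        fit = lc.fit_ols(df, "y", [])
        r = lc.fractional_rank(rng.normal(size=200))
        dec = lc.decompose(fit, r)
        assert len(dec.table) == 0
        assert dec.residual_contribution == pytest.approx(dec.total, abs=1e-14)

    def test_noiseless_single_regressor_explains_everything(self):
        rng = np.random.default_rng(5)
        x = rng.uniform(0, 1, 300)
        df = pd.DataFrame({"x": x, "y": 2.0 + 1.5 * x})
        fit = lc.fit_ols(df, "y", ["x"])
        r = lc.fractional_rank(x)
        dec = lc.decompose(fit, r)
        assert dec.table.loc["x", "contribution"] == pytest.approx(
            dec.total, abs=1e-12
        )
        assert dec.residual_contribution == pytest.approx(0.0, abs=1e-12)
        assert dec.table.loc["x", "share"] == pytest.approx(100.0, abs=1e-8)

    @settings(deadline=None, max_examples=100)
    @given(seed=st.integers(0, 2**16))
    def test_additivity_identity_random_cohorts(self, seed):
        rng = np.random.default_rng(seed)
        df = random_design_cohort(rng)
        df["y"] = df["y"] - df["y"].min() + 0.5  # positive-mean contract
        fit = lc.fit_ols(df, "y", ["f0", "f1", "f2"])
        r = lc.fractional_rank(df["rankvar"].to_numpy())
        dec = lc.decompose(fit, r)
        gap = dec.table["contribution"].sum() + dec.residual_contribution - dec.total
        assert abs(gap) < 1e-10

    def test_share_invariance_under_positive_scaling(self):
        rng = np.random.default_rng(7)
        df = random_design_cohort(rng, n=300)
        r = lc.fractional_rank(df["rankvar"].to_numpy())
        fit1 = lc.fit_ols(df, "y", ["f0", "f1"])
        df2 = df.assign(y=df["y"] * 7.7)
        fit2 = lc.fit_ols(df2, "y", ["f0", "f1"])
        d1 = lc.decompose(fit1, r)
        d2 = lc.decompose(fit2, r)
        np.testing.assert_allclose(
            d1.table["share"].to_numpy(), d2.table["share"].to_numpy(), atol=1e-8
        )

    def test_row_mismatch_rejected(self):
        rng = np.random.default_rng(8)
        df = random_design_cohort(rng, n=50)
        fit = lc.fit_ols(df, "y", ["f0"])
        with pytest.raises(ValueError):
            lc.decompose(fit, np.linspace(0, 1, 49))


class TestRollup:
    def _decomposition(self, seed=11):
        rng = np.random.default_rng(seed)
        df = random_design_cohort(rng)
        df["y"] = df["y"] - df["y"].min() + 0.5  # positive-mean contract
        fit = lc.fit_ols(df, "y", ["f0", "f1", "f2"])
        r = lc.fractional_rank(df["rankvar"].to_numpy())
        return lc.decompose(fit, r)

    def test_single_category_gets_everything_but_residual(self):
        dec = self._decomposition()
        shares = lc.rollup_categories(
            dec, {"f0": "all", "f1": "all", "f2": "all"}
        )
        assert shares["all"] == pytest.approx(100.0 - dec.residual_share, abs=1e-8)

    def test_partition_additivity(self):
        dec = self._decomposition()
        merged = lc.rollup_categories(
            dec, {"f0": "one", "f1": "one", "f2": "two"}
        )
        split = lc.rollup_categories(
            dec, {"f0": "a", "f1": "b", "f2": "two"}
        )
        assert merged["one"] == pytest.approx(split["a"] + split["b"], abs=1e-10)

    def test_unmapped_determinant_rejected(self):
        dec = self._decomposition()
        with pytest.raises(KeyError):
            lc.rollup_categories(dec, {"f0": "x", "f1": "x"})

    def test_planted_single_category_dominates(self):
        """Only one determinant has both a nonzero effect and a nonzero
        determinant index: its category absorbs ~100% of C."""
        rng = np.random.default_rng(13)
        n = 4000
        g = rng.random(n) < 0.5
        df = pd.DataFrame(
            {
                "early": pd.Categorical(
                    np.where(g, "hi", "lo"), categories=["lo", "hi"]
                ),
                "noise_f": pd.Categorical(
                    rng.choice(["a", "b"], n), categories=["a", "b"]
                ),
            }
        )
        df["rankvar"] = g + 0.2 * rng.standard_normal(n)  # rich iff early=hi
        df["y"] = 1.0 + 0.8 * g + 0.01 * rng.standard_normal(n)
        fit = lc.fit_ols(df, "y", ["early", "noise_f"])
        dec = lc.decompose(fit, lc.fractional_rank(df["rankvar"].to_numpy()))
        shares = lc.rollup_categories(
            dec, {"early": "early_life", "noise_f": "other"}
        )
        assert shares["early_life"] == pytest.approx(100.0, abs=2.0)
        assert abs(shares["other"]) < 2.0


class TestMediation:
    def test_empty_mediator_list_direct_equals_total(self, small_cohort,
                                                     covariate_names,
                                                     references,
                                                     early_life_names):
        med = lc.mediation_contrast(
            small_cohort, "latent_overall", covariate_names, [],
            early_life_names, references=references,
        )
        assert med.direct_share == med.total_share
        assert med.indirect_share == 0.0

    def test_unknown_mediator_rejected(self, small_cohort, covariate_names,
                                       early_life_names):
        with pytest.raises(ValueError):
            lc.mediation_contrast(
                small_cohort, "latent_overall", covariate_names,
                ["not_a_column"], early_life_names,
            )

    def test_null_mediators_give_no_indirect_share(self):
        """Mediators that are pure noise (no path from the early-life
        factors, no effect on the outcome) leave the early-life share
        unchanged within the bootstrap interval."""
        rng = np.random.default_rng(17)
        n = 4000
        adv = rng.random(n) < 0.5
        df = pd.DataFrame(
            {
                "early": pd.Categorical(
                    np.where(adv, "hi", "lo"), categories=["lo", "hi"]
                ),
                "mediator": pd.Categorical(
                    rng.choice(["m0", "m1"], n), categories=["m0", "m1"]
                ),
            }
        )
        df["wealth"] = np.exp(0.5 * adv + 0.5 * rng.standard_normal(n))
        df["y"] = 0.5 * adv + rng.standard_normal(n)
        med = lc.mediation_contrast(
            df, "y", ["early", "mediator"], ["mediator"], ["early"],
            B=200, seed=3,
        )
        lo, hi = med.indirect_ci
        assert lo <= 0.0 <= hi
        assert abs(med.indirect_share) < 5.0

    def test_planted_path_total_exceeds_direct(self, default_cfg,
                                               covariate_names, references,
                                               early_life_names, ses_names):
        coh = lc.generate_cohort(default_cfg.replace(n=8000, seed=23))
        med = lc.mediation_contrast(
            coh, "latent_overall", covariate_names, ses_names,
            early_life_names, references=references,
        )
        assert med.total_share > med.direct_share > 0

    def test_matches_numpy_oracle_on_same_rows(self, default_cfg,
                                               covariate_names, references,
                                               early_life_names, ses_names):
        """Package shares equal an all-numpy reimplementation on the same
        cohort to numerical precision."""
        coh = lc.generate_cohort(default_cfg.replace(n=6000, seed=29))
        med = lc.mediation_contrast(
            coh, "latent_overall", covariate_names, ses_names,
            early_life_names, references=references,
        )
        specs = [
            (c.name, list(c.levels), c.reference)
            for c in default_cfg.covariates
        ]
        direct, total = numpy_early_life_shares(
            coh, "latent_overall", specs, set(ses_names), set(early_life_names)
        )
        assert med.direct_share == pytest.approx(direct, abs=1e-8)
        assert med.total_share == pytest.approx(total, abs=1e-8)


class TestHolm:
    def test_hand_example(self):
        adj = lc.holm_adjust([0.01, 0.04, 0.03], alpha=0.05)
        np.testing.assert_allclose(adj.adjusted, [0.03, 0.06, 0.06])
        assert adj.reject.tolist() == [True, False, False]

    def test_single_p_unchanged(self):
        adj = lc.holm_adjust([0.2])
        assert adj.adjusted[0] == pytest.approx(0.2)

    def test_all_zero_all_rejected(self):
        adj = lc.holm_adjust([0.0, 0.0, 0.0])
        assert adj.reject.all()

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            lc.holm_adjust([0.5, 1.2])

    @settings(deadline=None, max_examples=300)
    @given(
        p=st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=12)
    )
    def test_matches_brute_force_by_definition(self, p):
        adj = lc.holm_adjust(p)
        bf_adj, bf_rej = brute_force_holm(np.array(p))
        np.testing.assert_allclose(adj.adjusted, bf_adj, atol=1e-12)
        assert (adj.reject == bf_rej).all()
        # monotone, >= raw, capped
        assert np.all(adj.adjusted >= adj.raw - 1e-15)
        assert np.all(adj.adjusted <= 1.0)


class TestSpearman:
    def test_self_correlation_is_one(self, small_cohort):
        m = lc.spearman_matrix(small_cohort, ["education", "education"])
        assert m.iloc[0, 1] == pytest.approx(1.0)

    def test_hand_example(self):
        df = pd.DataFrame({"a": [1, 2, 3], "b": [3, 1, 2]})
        m = lc.spearman_matrix(df, ["a", "b"])
        assert m.loc["a", "b"] == pytest.approx(-0.5)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(31)
        df = pd.DataFrame({"x": rng.normal(size=100)})
        df["t"] = np.exp(df["x"])
        m = lc.spearman_matrix(df, ["x", "t"])
        assert m.loc["x", "t"] == pytest.approx(1.0)

    def test_constant_column_flagged_not_zero(self):
        df = pd.DataFrame({"c": np.ones(50), "x": np.arange(50.0)})
        with pytest.warns(UserWarning, match="constant"):
            m = lc.spearman_matrix(df, ["c", "x"])
        assert np.isnan(m.loc["c", "x"])
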