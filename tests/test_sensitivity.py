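"""Selection correction, chained imputation, Rubin pooling and subgroups."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import lifecap as lc

from _oracles import brute_force_rubin


class TestInverseMills:
    def test_closed_form_values(self):
        assert lc.inverse_mills(0.0) == pytest.approx(0.7978845608, abs=1e-9)
        assert lc.inverse_mills(-1.96) == pytest.approx(
            stats.norm.pdf(1.96) / stats.norm.cdf(-1.96), rel=1e-12
        )
        assert lc.inverse_mills(-1.96) == pytest.approx(2.338, abs=5e-4)

    def test_positive_decreasing_vanishing(self):
        z = np.linspace(-8, 8, 200)
        lam = lc.inverse_mills(z)
        assert np.all(lam > 0)
        assert np.all(np.diff(lam) < 0)
        assert lam[-1] < 1e-5


def _selection_cohort(rng, n, rho=0.0, beta_x=0.3):
    """Outcome model y = beta_x * x + e; probit selection on an excluded
    continuous instrument; corr(selection error, e) = rho."""
    x = (rng.random(n) < 0.5).astype(float)
    instrument = rng.standard_normal(n)
    e = rng.standard_normal(n)
    u = rho * e + np.sqrt(1 - rho**2) * rng.standard_normal(n)
    y = beta_x * x + e
    z = 0.3 + 0.8 * instrument
    included = (z + u) > 0
    df = pd.DataFrame(
        {
            "x": pd.Categorical(np.where(x > 0, "b", "a"), categories=["a", "b"]),
            "instrument": instrument,
            "y": y,
        }
    )
    return df, included


class TestHeckman:
    def test_null_selection_mills_coefficient_near_zero(self):
        rng = np.random.default_rng(101)
        df, incl = _selection_cohort(rng, 20000, rho=0.0)
        res = lc.heckman_adjust(df, incl, ["instrument"], "y", ["x"])
        assert abs(res.mills_t) < 3

    def test_informative_selection_detected(self):
        rng = np.random.default_rng(103)
        df, incl = _selection_cohort(rng, 20000, rho=0.7)
        res = lc.heckman_adjust(df, incl, ["instrument"], "y", ["x"])
        assert res.mills_coef > 0.3
        assert abs(res.mills_t) > 5
        # and the correction keeps the slope near truth
        assert res.outcome_fit.params["x[b]"] == pytest.approx(0.3, abs=0.06)

    def test_exclusion_restriction_warning(self):
        rng = np.random.default_rng(107)
        df, incl = _selection_cohort(rng, 3000)
        with pytest.warns(UserWarning, match="exclusion restriction"):
            lc.heckman_adjust(
                df, incl, ["instrument"], "y", ["x", "instrument"]
            )

    def test_probit_recovers_selection_rate(self, small_cohort):
        kept, incl = lc.apply_selection(
            small_cohort, {"intercept": 0.4, "wealth_z": 0.3}, seed=5
        )
        sub = small_cohort.copy()
        sub["log_wealth"] = np.log(sub["wealth"])
        sel = lc.sensitivity.fit_selection_probit(sub, incl, ["log_wealth"])
        assert sel.converged and not sel.separation_flag
        # wealth enters selection positively
        assert sel.gamma["log_wealth"] > 0


class TestChainedImputation:
    def test_no_missing_returns_input_copies(self, small_cohort):
        outs = lc.chained_imputation(small_cohort.head(300), m=3, seed=1)
        assert len(outs) == 3
        for o in outs:
            pd.testing.assert_frame_equal(o, small_cohort.head(300))

    def test_seed_determinism(self, small_cohort):
        masked = lc.inject_missingness(
            small_cohort.head(600), {"education": 0.2, "wealth": 0.1}, seed=2
        )
        a = lc.chained_imputation(masked, m=2, seed=9, iterations=2)
        b = lc.chained_imputation(masked, m=2, seed=9, iterations=2)
        for x, y in zip(a, b):
            pd.testing.assert_frame_equal(x, y)

    def test_m_below_two_rejected(self, small_cohort):
        with pytest.raises(ValueError):
            lc.chained_imputation(small_cohort, m=1, seed=1)

    def test_fully_missing_column_rejected(self, small_cohort):
        masked = lc.inject_missingness(small_cohort.head(100), {"wealth": 1.0}, seed=1)
        with pytest.raises(ValueError, match="no observed values"):
            lc.chained_imputation(masked, m=2, seed=1)

    def test_imputed_categories_stay_in_level_set(self, small_cohort):
        masked = lc.inject_missingness(
            small_cohort.head(800), {"education": 0.3}, seed=4
        )
        outs = lc.chained_imputation(masked, m=2, seed=5, iterations=2)
        for o in outs:
            assert not o["education"].isna().any()
            assert set(o["education"].unique()) <= set(
                small_cohort["education"].cat.categories
            )

    def test_mcar_recovery_of_planted_effect(self, default_cfg,
                                             covariate_names, references):
        """20% MCAR on one covariate: the Rubin-pooled coefficient stays
        consistent with the complete-data planted value."""
        cfg = default_cfg.replace(n=6000, seed=41)
        coh = lc.generate_cohort(cfg)
        masked = lc.inject_missingness(coh, {"father_literate": 0.2}, seed=42)
        completed = lc.chained_imputation(masked, m=5, seed=43, iterations=3)
        fits = [
            lc.fit_ols(df, "latent_overall", covariate_names, references)
            for df in completed
        ]
        pooled = lc.sensitivity.pool_fits(fits, "father_literate[literate]")
        lo, hi = pooled.conf_int()
        assert lo <= 0.040 <= hi


class TestRubinPool:
    def test_hand_example(self):
        p = lc.rubin_pool([1.0, 2.0], [0.5, 0.5])
        assert p.qbar == pytest.approx(1.5)
        assert p.between == pytest.approx(0.5)
        assert p.total == pytest.approx(0.5 + 1.5 * 0.5)

    def test_identical_estimates_reproduce_single_dataset(self):
        p = lc.rubin_pool([0.7, 0.7, 0.7], [0.04, 0.04, 0.04])
        assert p.between == 0.0
        assert p.total == pytest.approx(0.04)
        assert np.isinf(p.df)
        lo, hi = p.conf_int()
        z = stats.norm.ppf(0.975)
        assert lo == pytest.approx(0.7 - z * 0.2, abs=1e-9)

    def test_single_imputation_rejected(self):
        with pytest.raises(ValueError):
            lc.rubin_pool([1.0], [0.5])

    def test_matches_brute_force_random_inputs(self):
        rng = np.random.default_rng(55)
        for _ in range(300):
            m = int(rng.integers(2, 12))
            q = rng.normal(size=m)
            v = rng.uniform(0.01, 1.0, size=m)
            p = lc.rubin_pool(q, v)
            qbar, wbar, b, t = brute_force_rubin(q, v)
            assert p.qbar == pytest.approx(qbar, abs=1e-12)
            assert p.within == pytest.approx(wbar, abs=1e-12)
            assert p.between == pytest.approx(b, abs=1e-12)
            assert p.total == pytest.approx(t, abs=1e-12)
            assert p.total >= p.within - 1e-15


class TestSubgroups:
    def test_split_on_independent_column_agrees(self, default_cfg,
                                                covariate_names, references,
                                                category_map):
        coh = lc.generate_cohort(default_cfg.replace(n=6000, seed=61))
        rng = np.random.default_rng(62)
        coh["coin"] = rng.random(len(coh))
        con = lc.subgroup_contrast(
            coh, lc.SubgroupSpec("coin", "coin", threshold=0.5),
            "latent_overall", ["gender", "education", "father_literate"],
            references=references, category_map=category_map,
        )
        # exchangeable halves: no coefficient difference beyond joint CI
        z = con.coefficient_table["z"].abs()
        assert (z < 3.5).all()

    def test_age_split_produces_complete_tables(self, small_cohort,
                                                references, category_map,
                                                covariate_names):
        con = lc.subgroup_contrast(
            small_cohort,
            lc.SubgroupSpec("age", "age_group", levels=["lt45", "45_60"]),
            "latent_overall", covariate_names,
            references=references, category_map=category_map,
        )
        assert not con.coefficient_table["effect_a"].isna().all()
        assert con.group_a.ols.n + con.group_b.ols.n == len(small_cohort)

    def test_empty_subgroup_rejected(self, small_cohort):
        with pytest.raises(ValueError, match="empty"):
            lc.SubgroupSpec("none", "wealth", threshold=-1.0).split(small_cohort)

    def test_missing_split_column_rejected(self, small_cohort):
        with pytest.raises(KeyError):
            lc.SubgroupSpec("x", "nope", threshold=0.0).split(small_cohort)

    def test_planted_interaction_recovered(self):
        """A planted group-by-covariate interaction shows up as the
        subgroup coefficient difference; the oracle is a pooled fit with an
        explicit interaction term."""
        rng = np.random.default_rng(71)
        n = 100000
        old = (rng.random(n) < 0.5)
        x = (rng.random(n) < 0.5).astype(float)
        y = 0.2 * x + 0.15 * x * old + rng.standard_normal(n)
        df = pd.DataFrame(
            {
                "grp": pd.Categorical(np.where(old, "old", "young")),
                "x": pd.Categorical(np.where(x > 0, "b", "a")),
                "y": y,
                "wealth": np.exp(rng.standard_normal(n)),
            }
        )
        # oracle: explicit interaction regression
        X = np.column_stack([np.ones(n), x, old, x * old])
        beta = np.linalg.lstsq(X, y, rcond=None)[0]
        con = lc.subgroup_contrast(
            df, lc.SubgroupSpec("age", "grp", levels=["old"]), "y", ["x"],
        )
        diff = (
            con.coefficient_table.loc["x[b]", "effect_a"]
            - con.coefficient_table.loc["x[b]", "effect_b"]
        )
        se = np.sqrt(
            con.coefficient_table.loc["x[b]", "se_a"] ** 2
            + con.coefficient_table.loc["x[b]", "se_b"] ** 2
        )
        assert diff == pytest.approx(beta[3], abs=3 * se)
        assert diff == pytest.approx(0.15, abs=3 * se)
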