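"""Permutation ANCOVA, contrasts, correlation families, demographics."""

import numpy as np
import pandas as pd
import pytest

from brainstemnm.stats import (
    GlmSpec,
    PermutationAncova,
    bh_adjust,
    bonferroni_family_alpha,
    correlation_family,
    demographics_tests,
    levene,
)


def make_cohort(rng, n_per_group=20, effect=(0.0, 0.0, 0.0), age_beta=0.0, sigma=1.0):
    rows = []
    for g, mu in zip(("HC", "iRBD", "PD"), effect):
        for _ in range(n_per_group):
            age = rng.uniform(45, 80)
            sex = rng.choice(["M", "F"])
            y = mu + age_beta * age + sigma * rng.standard_normal()
            rows.append({"group": g, "age": age, "sex": sex, "y": y})
    return pd.DataFrame(rows)


class TestOmnibus:
    def test_constant_outcome_gives_zero_f_p_one(self, rng):
        d = make_cohort(rng, 10)
        d["y"] = 5.0
        res = PermutationAncova(d, GlmSpec("y", n_perm=200, seed=1)).fit()
        assert res.omnibus.F == 0.0
        assert res.omnibus.p_perm == 1.0

    def test_perm_p_close_to_parametric_under_null(self, rng):
        d = make_cohort(rng, 50)
        res = PermutationAncova(d, GlmSpec("y", n_perm=4000, seed=2)).fit()
        assert abs(res.omnibus.p_perm - res.omnibus.p_param) < 0.04

    def test_strong_effect_detected(self, rng):
        d = make_cohort(rng, 18, effect=(0.0, -1.5, -1.5))
        res = PermutationAncova(d, GlmSpec("y", n_perm=1000, seed=3)).fit()
        assert res.omnibus.p_perm < 0.01

    def test_reproducible_given_seed(self, rng):
        d = make_cohort(rng, 15, effect=(0, 0.5, 1.0))
        a = PermutationAncova(d, GlmSpec("y", n_perm=500, seed=42)).fit()
        b = PermutationAncova(d, GlmSpec("y", n_perm=500, seed=42)).fit()
        assert a.omnibus.p_perm == b.omnibus.p_perm
        assert [c.p_perm for c in a.contrasts] == [c.p_perm for c in b.contrasts]

    def test_p_perm_respects_plus_one_bound(self, rng):
        d = make_cohort(rng, 18, effect=(0.0, -3.0, -3.0))
        res = PermutationAncova(d, GlmSpec("y", n_perm=99, seed=4)).fit()
        assert res.omnibus.p_perm >= 1.0 / 100.0

    def test_missing_rows_dropped_and_counted(self, rng):
        d = make_cohort(rng, 10)
        d.loc[3, "y"] = np.nan
        model = PermutationAncova(d, GlmSpec("y", n_perm=100, seed=0))
        assert model.n_dropped == 1 and model.n == 29

    def test_df_matches_standard_ancova_parameterization(self, rng):
        # 50 subjects, intercept + age + sex + 2 dummies -> (2, 45)
        d = make_cohort(rng, 17).iloc[:50]
        model = PermutationAncova(d, GlmSpec("y", n_perm=10, seed=0))
        assert model.df == (2, 45)

    def test_manly_scheme_also_valid(self, rng):
        d = make_cohort(rng, 30)
        res = PermutationAncova(d, GlmSpec("y", n_perm=2000, seed=5, scheme="manly")).fit()
        assert abs(res.omnibus.p_perm - res.omnibus.p_param) < 0.06


class TestContrasts:
    def test_family_structure_and_alpha(self, rng):
        d = make_cohort(rng, 10)
        res = PermutationAncova(d, GlmSpec("y", n_perm=100, seed=0)).fit()
        labels = {c.label for c in res.contrasts}
        assert len(labels) == 6
        assert "HC > iRBD" in labels and "iRBD > HC" in labels
        assert bonferroni_family_alpha() == pytest.approx(0.05 / 6)

    def test_bonferroni_cap_and_arithmetic(self, rng):
        d = make_cohort(rng, 10)
        res = PermutationAncova(d, GlmSpec("y", n_perm=100, seed=0)).fit()
        for c in res.contrasts:
            assert c.p_fwer == pytest.approx(min(1.0, 6 * c.p_perm))
            assert c.p_fwer >= c.p_perm

    def test_directional_pair_tails_nearly_complementary(self, rng):
        d = make_cohort(rng, 15, effect=(0.0, -0.8, 0.3))
        res = PermutationAncova(d, GlmSpec("y", n_perm=999, seed=7)).fit()
        n_perm = 999
        for a, b in (("HC", "iRBD"), ("HC", "PD"), ("iRBD", "PD")):
            p_ab = res.contrast(f"{a} > {b}").p_perm
            p_ba = res.contrast(f"{b} > {a}").p_perm
            # one-tailed pair sums to ~1 up to the +1 smoothing and tie mass
            assert p_ab + p_ba <= 1.0 + 3.0 / (n_perm + 1)
            assert p_ab + p_ba >= 1.0 - 1e-9

    def test_true_group_deficit_flagged_directionally(self, rng):
        d = make_cohort(rng, 18, effect=(1.5, 0.0, 0.0))
        res = PermutationAncova(d, GlmSpec("y", n_perm=1000, seed=8)).fit()
        assert res.contrast("HC > iRBD").p_fwer < 0.05
        assert res.contrast("iRBD > HC").p_fwer == 1.0

    def test_summary_mentions_all_contrasts(self, rng):
        d = make_cohort(rng, 10)
        res = PermutationAncova(d, GlmSpec("y", n_perm=50, seed=0)).fit()
        s = res.summary()
        assert "omnibus F" in s and s.count(">") >= 6


class TestLevene:
    def test_identical_spreads_give_zero(self):
        d = pd.DataFrame({"group": ["a"] * 3 + ["b"] * 3 + ["c"] * 3, "y": [1, 2, 3] * 3})
        W, _ = levene(d, "y")
        assert W == pytest.approx(0.0)

    def test_inflated_variance_detected(self, rng):
        y = np.concatenate([rng.normal(0, 1, 50), rng.normal(0, 5, 50), rng.normal(0, 1, 50)])
        d = pd.DataFrame({"group": np.repeat(["a", "b", "c"], 50), "y": y})
        _, p = levene(d, "y")
        assert p < 0.01

    def test_degenerate_groups_rejected(self):
        d = pd.DataFrame({"group": ["a", "a", "b"], "y": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            levene(d, "y")


class TestCorrelationFamily:
    def test_perfect_correlation(self, rng):
        x = rng.normal(size=30)
        d = pd.DataFrame({"x": x, "y": x})
        fam = correlation_family(d, [("x", "y")])
        assert fam.loc[0, "r"] == pytest.approx(1.0)
        assert fam.loc[0, "df"] == 28
        assert fam.loc[0, "p"] < 1e-20

    def test_bh_hand_worked_family(self):
        adj = bh_adjust([0.001, 0.01, 0.04, 0.2])
        np.testing.assert_allclose(adj, [0.004, 0.02, 0.04 * 4 / 3, 0.2])

    def test_bh_monotone_and_order_invariant(self, rng):
        p = rng.uniform(size=12)
        adj = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        shuffled = rng.permutation(len(p))
        np.testing.assert_allclose(bh_adjust(p[shuffled]), adj[shuffled])

    def test_pairwise_deletion_df(self, rng):
        d = pd.DataFrame({"x": rng.normal(size=20), "y": rng.normal(size=20)})
        d.loc[:4, "y"] = np.nan
        fam = correlation_family(d, [("x", "y")])
        assert fam.loc[0, "df"] == 13

    def test_constant_column_rejected(self):
        d = pd.DataFrame({"x": [1.0] * 10, "y": np.arange(10.0)})
        with pytest.raises(ValueError, match="constant"):
            correlation_family(d, [("x", "y")])


class TestDemographics:
    def test_perfectly_separated_sex_table(self):
        d = pd.DataFrame(
            {
                "group": ["a"] * 10 + ["b"] * 10,
                "sex": ["M"] * 10 + ["F"] * 10,
                "age": np.tile(np.arange(10.0), 2),
            }
        )
        out = demographics_tests(d)
        chi = out[out["test"] == "sex chi-square"].iloc[0]
        assert chi["statistic"] == pytest.approx(20.0)
        assert chi["p"] < 0.001

    def test_mann_whitney_fully_ordered(self):
        d = pd.DataFrame(
            {
                "group": ["iRBD"] * 3 + ["PD"] * 3,
                "sex": ["M"] * 6,
                "age": [58.0, 60.0, 62.0, 59.0, 61.0, 63.0],
                "moca": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            }
        )
        out = demographics_tests(d)
        u = out[out["test"] == "moca Mann-Whitney"].iloc[0]
        assert u["statistic"] == 0.0

    def test_identical_groups_high_kw_p(self, rng):
        ages = rng.normal(60, 8, 40)
        d = pd.DataFrame(
            {
                "group": np.repeat(["a", "b"], 40),
                "sex": ["M", "F"] * 40,
                "age": np.concatenate([ages, ages]),
            }
        )
        out = demographics_tests(d)
        kw = out[out["test"] == "age Kruskal-Wallis"].iloc[0]
        assert kw["p"] > 0.9
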