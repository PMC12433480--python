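import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from oncolysis.doseresp import (
    SusceptibilityScorer,
    dunnett_adjusted_p,
    dunnett_max_abs_t_cdf,
    lowest_significant_rank,
    one_way_anova,
    pairwise_adjust,
    rank_cell_lines,
    susceptibility_score,
    two_way_anova_type3,
)

MOI_GRID = (0.001, 0.01, 0.1, 1.0, 10.0)


class TestOneWayAnova:
    def test_identical_groups_convention(self):
        r = one_way_anova([[1, 2, 3], [1, 2, 3]])
        assert r.F == pytest.approx(0.0)
        assert r.p == pytest.approx(1.0)

    def test_hand_computed_sums_of_squares(self):
        # SSB = 54, SSW = 6 -> F = (54/2)/(6/6) = 27 on (2, 6) df
        r = one_way_anova([[1, 2, 3], [4, 5, 6], [7, 8, 9]])
        assert r.F == pytest.approx(27.0)
        assert (r.df1, r.df2) == (2, 6)
        assert r.p == pytest.approx(stats.f.sf(27.0, 2, 6), abs=1e-6)

    def test_matches_scipy_f_oneway(self, rng):
        groups = [rng.normal(m, 1, 5) for m in (0, 0.5, 2)]
        r = one_way_anova(groups)
        ref = stats.f_oneway(*groups)
        assert r.F == pytest.approx(ref.statistic, rel=1e-10)
        assert r.p == pytest.approx(ref.pvalue, rel=1e-8)

    def test_small_group_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova([[1.0], [1, 2]])


class TestDunnett:
    def test_single_comparison_equals_pooled_t_test(self, rng):
        control = rng.normal(0, 1, 4)
        treated = rng.normal(1, 1, 5)
        p = dunnett_adjusted_p(control, [treated])[0]
        ref = stats.ttest_ind(treated, control, equal_var=True).pvalue
        assert p == pytest.approx(ref, abs=1e-6)

    def test_zero_difference_gives_p_one(self):
        control = [1.0, 2.0, 3.0]
        p = dunnett_adjusted_p(control, [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]])
        assert p[0] == pytest.approx(1.0, abs=1e-9)

    def test_matches_scipy_dunnett(self, rng):
        control = rng.normal(0, 1, 3)
        treatments = [rng.normal(m, 1, 3) for m in (0.0, 0.5, 1.5, 2.5, 4.0)]
        ours = dunnett_adjusted_p(control, treatments)
        ref = stats.dunnett(*treatments, control=control).pvalue
        np.testing.assert_allclose(ours, ref, atol=2e-3)

    def test_adjusted_p_non_decreasing_in_k(self):
        # for a fixed statistic and df, adding comparisons can only raise p
        prev = 0.0
        for k in range(1, 6):
            lam = np.sqrt(np.full(k, 0.5))
            p = 1.0 - dunnett_max_abs_t_cdf(2.5, lam, df=12)
            assert p >= prev - 1e-10
            prev = p

    def test_adjusted_at_least_unadjusted(self, rng):
        control = rng.normal(0, 1, 3)
        treatments = [rng.normal(m, 1, 3) for m in (0.5, 1.0, 2.0)]
        adj = dunnett_adjusted_p(control, treatments)
        groups = [control] + treatments
        df = sum(len(g) for g in groups) - len(groups)
        s2 = sum(((g - g.mean()) ** 2).sum() for g in treatments)
        s2 = (s2 + ((control - control.mean()) ** 2).sum()) / df
        for g, p_adj in zip(treatments, adj):
            t = (g.mean() - control.mean()) / math.sqrt(s2 * (1 / 3 + 1 / 3))
            raw = 2 * stats.t.sf(abs(t), df)
            assert p_adj >= raw - 1e-9

    def test_all_constant_equal_gives_one(self):
        p = dunnett_adjusted_p([2.0, 2.0], [[2.0, 2.0], [2.0, 2.0]])
        np.testing.assert_allclose(p, 1.0)

    def test_no_treatment_rejected(self):
        with pytest.raises(ValueError):
            dunnett_adjusted_p([1.0, 2.0], [])


class TestRankMultiplier:
    def test_fourth_moi_first_significant(self):
        p = dict(zip(MOI_GRID, (0.2, 0.2, 0.2, 0.01, 0.001)))
        assert lowest_significant_rank(p) == 4

    def test_nothing_significant_gives_six(self):
        p = dict(zip(MOI_GRID, (0.2, 0.9, 0.5, 0.06, 0.051)))
        assert lowest_significant_rank(p) == 6

    def test_everything_significant_gives_one(self):
        p = dict(zip(MOI_GRID, (0.001,) * 5))
        assert lowest_significant_rank(p) == 1

    def test_threshold_is_inclusive(self):
        p = dict(zip(MOI_GRID, (0.2, 0.2, 0.05, 0.2, 0.2)))
        assert lowest_significant_rank(p) == 3

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            lowest_significant_rank({})


class TestScore:
    @pytest.mark.parametrize(
        "aucs, mult, expected",
        [
            ((0.9, 0.8, 0.5, 0.3, 0.2), 3, 8.1),
            ((1.0,) * 5, 6, 30.0),
            ((0.1,) * 5, 1, 0.5),
        ],
    )
    def test_worked_examples(self, aucs, mult, expected):
        assert susceptibility_score(aucs, mult) == pytest.approx(expected)

    def test_negative_auc_rejected(self):
        with pytest.raises(ValueError):
            susceptibility_score([-0.1, 0.5], 2)

    def test_monotone_in_auc_and_rank(self, rng):
        aucs = rng.uniform(0.1, 1.0, 5)
        base = susceptibility_score(aucs, 3)
        assert susceptibility_score(aucs * 0.9, 3) < base
        assert susceptibility_score(aucs, 4) > base


class TestRanking:
    def test_lowest_score_is_rank_one(self):
        assert rank_cell_lines({"A": 8.1, "B": 30.0}) == {"A": 1, "B": 2}

    def test_tie_breaks_alphabetical(self):
        ranks = rank_cell_lines({"B": 5.0, "A": 5.0}, {"A": 1.0, "B": 1.0})
        assert ranks == {"A": 1, "B": 2}

    def test_order_invariance(self):
        scores = {"C": 3.0, "A": 1.0, "B": 2.0}
        assert rank_cell_lines(scores) == rank_cell_lines(dict(reversed(scores.items())))

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            rank_cell_lines({})


class TestTwoWayType3:
    def test_additive_table_has_zero_interaction(self):
        rows = [
            {"time": a, "moi": b, "value": ai + bj, "rep": r}
            for a, ai in [("t1", 1.0), ("t2", 3.0)]
            for b, bj in [("m1", 0.0), ("m2", 5.0), ("m3", 7.0)]
            for r in range(2)
        ]
        out = two_way_anova_type3(pd.DataFrame(rows))
        inter = out.loc[out["effect"] == "time:moi", "ss"].iloc[0]
        assert inter == pytest.approx(0.0, abs=1e-18)

    def test_matches_statsmodels_type3(self, rng):
        sm = pytest.importorskip("statsmodels.api")
        smf = pytest.importorskip("statsmodels.formula.api")
        rows = [
            {"time": a, "moi": b, "value": rng.normal()}
            for a in ("t1", "t2", "t3")
            for b in ("m1", "m2", "m3", "m4")
            for _ in range(3)
        ]
        df = pd.DataFrame(rows)
        ours = two_way_anova_type3(df).set_index("effect")
        fit = smf.ols("value ~ C(time, Sum)*C(moi, Sum)", data=df).fit()
        ref = sm.stats.anova_lm(fit, typ=3)
        for eff, key in [
            ("time", "C(time, Sum)"),
            ("moi", "C(moi, Sum)"),
            ("time:moi", "C(time, Sum):C(moi, Sum)"),
        ]:
            assert ours.loc[eff, "F"] == pytest.approx(ref.loc[key, "F"], rel=1e-6)
            assert ours.loc[eff, "p"] == pytest.approx(ref.loc[key, "PR(>F)"], abs=1e-6)

    def test_balanced_ss_additivity(self, rng):
        rows = [
            {"time": a, "moi": b, "value": rng.normal()}
            for a in ("t1", "t2")
            for b in ("m1", "m2", "m3")
            for _ in range(3)
        ]
        df = pd.DataFrame(rows)
        out = two_way_anova_type3(df)
        total = ((df["value"] - df["value"].mean()) ** 2).sum()
        assert out["ss"].sum() == pytest.approx(total, rel=1e-9)

    def test_constant_table_convention(self):
        rows = [
            {"time": a, "moi": b, "value": 5.0}
            for a in ("t1", "t2")
            for b in ("m1", "m2")
            for _ in range(2)
        ]
        out = two_way_anova_type3(pd.DataFrame(rows))
        tested = out[out["effect"] != "residual"]
        np.testing.assert_allclose(tested["F"], 0.0)
        np.testing.assert_allclose(tested["p"], 1.0)

    def test_empty_cell_rejected(self):
        rows = [
            {"time": "t1", "moi": "m1", "value": 1.0},
            {"time": "t1", "moi": "m2", "value": 2.0},
            {"time": "t2", "moi": "m1", "value": 3.0},
        ]
        with pytest.raises(ValueError, match="empty design cells"):
            two_way_anova_type3(pd.DataFrame(rows))


class TestPairwiseAdjust:
    def test_sidak_identity_single_pair(self, rng):
        groups = [rng.normal(0, 1, 4), rng.normal(1, 1, 4)]
        out = pairwise_adjust(groups, "sidak")
        assert out["p_adj"].iloc[0] == pytest.approx(out["p_raw"].iloc[0], rel=1e-12)

    def test_sidak_closed_form(self):
        # 1 - 0.99^6 for p = 0.01 over m = 6 pairs
        assert 1 - (1 - 0.01) ** 6 == pytest.approx(0.0585198506, abs=1e-9)
        groups = [[0.0, 0.1], [0.05, 0.15], [0.2, 0.3], [0.25, 0.35]]
        out = pairwise_adjust(groups, "sidak")
        m = len(out)
        assert m == 6
        np.testing.assert_allclose(
            out["p_adj"], 1 - (1 - out["p_raw"]) ** m, rtol=1e-12
        )

    def test_tukey_matches_scipy_and_dominates_raw(self, rng):
        groups = [rng.normal(m, 1, 5) for m in (0, 0.5, 1.0)]
        out = pairwise_adjust(groups, "tukey")
        ref = stats.tukey_hsd(*groups)
        expected = [ref.pvalue[0, 1], ref.pvalue[0, 2], ref.pvalue[1, 2]]
        np.testing.assert_allclose(out["p_adj"], expected, atol=1e-8)
        assert (out["p_adj"] >= out["p_raw"] - 1e-12).all()

    def test_tukey_matches_monte_carlo_studentized_range(self, rng):
        # equal-mean groups: adjusted p for one pair vs a 2e5-draw MC oracle
        k, n = 3, 5
        groups = [rng.normal(0, 1, n) for _ in range(k)]
        out = pairwise_adjust(groups, "tukey")
        t_obs = abs(out["t"].iloc[0])
        q_obs = t_obs * math.sqrt(2)
        df = k * n - k
        draws = 200_000
        means = rng.normal(0, 1 / math.sqrt(n), size=(draws, k))
        s = np.sqrt(rng.chisquare(df, size=draws) / df)
        q_null = (means.max(axis=1) - means.min(axis=1)) * math.sqrt(n) / s
        mc = float(np.mean(q_null >= q_obs))
        assert out["p_adj"].iloc[0] == pytest.approx(mc, abs=5e-3)

    def test_fisher_lsd_is_unadjusted(self, rng):
        groups = [rng.normal(m, 1, 4) for m in (0, 1, 2)]
        out = pairwise_adjust(groups, "fisher_lsd")
        np.testing.assert_allclose(out["p_adj"], out["p_raw"])

    def test_unknown_method_rejected(self):
        with pytest.raises(ValueError):
            pairwise_adjust([[1, 2], [3, 4]], "bonferroni")


class TestSusceptibilityScorer:
    def _auc_df(self, lines):
        rng = np.random.default_rng(5)
        rows = []
        for line, effect in lines.items():
            for rep in ("r1", "r2", "r3"):
                rows.append({"cell_line": line, "repeat": rep, "moi": 0.0,
                             "auc_norm": 1.0})
                for i, moi in enumerate(MOI_GRID):
                    depress = effect * (i + 1) / 5
                    rows.append({
                        "cell_line": line, "repeat": rep, "moi": moi,
                        "auc_norm": max(1.0 - depress + rng.normal(0, 0.01), 0.01),
                    })
        return pd.DataFrame(rows)

    def test_more_susceptible_line_ranks_first(self):
        df = self._auc_df({"STRONG": 0.9, "WEAK": 0.05})
        scorer = SusceptibilityScorer().fit(df)
        assert scorer.ranks_["STRONG"] == 1
        assert scorer.ranks_["WEAK"] == 2
        assert scorer.scores_["STRONG"] < scorer.scores_["WEAK"]

    def test_score_identity_and_rank_bounds(self):
        df = self._auc_df({"A": 0.5, "B": 0.2, "C": 0.0})
        scorer = SusceptibilityScorer().fit(df)
        for r in scorer.results_:
            assert r.score == pytest.approx(r.auc_sum * r.rank_multiplier)
            assert 1 <= r.rank_multiplier <= 6
        assert sorted(scorer.ranks_.index) == ["A", "B", "C"]
        assert sorted(scorer.ranks_.values) == [1, 2, 3]

    def test_sklearn_param_interface(self):
        scorer = SusceptibilityScorer(alpha=0.01)
        assert scorer.get_params()["alpha"] == 0.01
        scorer.set_params(alpha=0.1)
        assert scorer.alpha == 0.1

    def test_invalid_alpha_rejected(self):
        with pytest.raises(ValueError):
            SusceptibilityScorer(alpha=1.5).fit(self._auc_df({"A": 0.5}))
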