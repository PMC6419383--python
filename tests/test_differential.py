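"""Moderated t, diffVar, iEVORA, worst-rank combination, BH adjustment."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

import methworks.differential as diff
from methworks.errors import DataError


def _comparison(n0=10, n1=10):
    return diff.GroupComparison(
        labels=("g0", "g1"), idx0=np.arange(n0), idx1=np.arange(n0, n0 + n1)
    )


class TestModeratedT:
    def test_prior_off_equals_student_t(self):
        rng = np.random.default_rng(0)
        V = rng.normal(0, 1, (300, 20))
        comp = _comparison()
        out = diff.moderated_t_table(V, comp, prior=False)
        ref = stats.ttest_ind(V[:, comp.idx1], V[:, comp.idx0], axis=1, equal_var=True)
        np.testing.assert_allclose(out["statistic"], ref.statistic, atol=1e-10)
        np.testing.assert_allclose(out["p"], ref.pvalue, atol=1e-10)

    def test_full_shrinkage_limit_equalises_variances(self):
        # units with identical variance except chi-square noise: the fit
        # detects no excess dispersion, d0 = inf, all posteriors equal s0^2
        rng = np.random.default_rng(1)
        V = rng.normal(0, 2.0, (4000, 20))
        out = diff.moderated_t_table(V, _comparison(), prior=True)
        # no real between-unit dispersion: d0 is huge (possibly inf) and the
        # posterior variances collapse onto the common prior variance ~4
        assert out.attrs["d0"] > 500
        s2 = out["s2_post"].to_numpy()
        assert np.ptp(s2) / s2.mean() < 0.05
        assert s2.mean() == pytest.approx(4.0, rel=0.1)

    def test_shrinkage_interpolates_between_unit_and_prior_variance(self):
        rng = np.random.default_rng(2)
        scales = rng.choice([0.5, 1.0, 2.0], size=2000)
        V = rng.normal(0, 1, (2000, 20)) * scales[:, None]
        comp = _comparison()
        out = diff.moderated_t_table(V, comp, prior=True)
        d0, s0 = out.attrs["d0"], out.attrs["s0_sq"]
        assert 0 < d0 < np.inf
        raw = diff.moderated_t_table(V, comp, prior=False)["s2_post"].to_numpy()
        expected = (d0 * s0 + 18 * raw) / (d0 + 18)
        np.testing.assert_allclose(out["s2_post"], expected, rtol=1e-10)

    def test_null_type_one_error_calibrated(self):
        rng = np.random.default_rng(7)
        scales = np.exp(rng.normal(0, 0.5, 5000))
        V = rng.normal(0, 1, (5000, 40)) * scales[:, None]
        out = diff.moderated_t_table(V, _comparison(20, 20), prior=True)
        frac = float((out["p"] < 0.05).mean())
        assert 0.04 <= frac <= 0.06

    def test_group_too_small_errors(self):
        with pytest.raises(DataError, match="at least 2"):
            diff.GroupComparison(labels=("a", "b"), idx0=[0], idx1=[1, 2])

    def test_missing_units_dropped_and_counted(self):
        V = np.random.default_rng(3).normal(0, 1, (10, 8))
        V[2, 1] = np.nan
        out = diff.moderated_t_table(V, _comparison(4, 4))
        assert out.attrs["n_dropped"] == 1
        assert np.isnan(out.loc[2, "statistic"])

    def test_zero_variance_with_prior_off_warns_tiny_p(self):
        V = np.tile([1.0] * 4 + [2.0] * 4, (3, 1))
        with pytest.warns(UserWarning, match="zero pooled variance"):
            out = diff.moderated_t_table(V, _comparison(4, 4), prior=False)
        assert (out["p"] == np.finfo(float).tiny).all()


class TestDiffVar:
    def test_identical_group_multisets_give_null_statistic(self):
        row = np.array([0.1, 0.4, 0.3, 0.8, 0.1, 0.4, 0.3, 0.8])
        V = np.tile(row, (5, 1))
        out = diff.diffvar_table(V, _comparison(4, 4), prior=False)
        np.testing.assert_allclose(out["statistic"], 0.0, atol=1e-12)
        np.testing.assert_allclose(out["p"], 1.0, atol=1e-12)

    def test_sign_convention_spread_in_group1_is_positive(self):
        rng = np.random.default_rng(4)
        V = np.hstack(
            [np.full((20, 10), 0.5), 0.5 + rng.normal(0, 0.2, (20, 10))]
        )
        out = diff.diffvar_table(V, _comparison(10, 10), prior=False)
        assert (out["statistic"] > 0).all()
        assert out["statistic"].median() > 3
        assert (out["var_diff"] > 0).all()

    def test_equals_moderated_t_on_deviations_with_prior_off(self):
        rng = np.random.default_rng(5)
        V = rng.uniform(0, 1, (100, 16))
        comp = _comparison(8, 8)
        out = diff.diffvar_table(V, comp, prior=False)
        Z = np.empty_like(V)
        Z[:, comp.idx0] = np.abs(V[:, comp.idx0] - np.median(V[:, comp.idx0], axis=1)[:, None])
        Z[:, comp.idx1] = np.abs(V[:, comp.idx1] - np.median(V[:, comp.idx1], axis=1)[:, None])
        ref = diff.moderated_t_table(Z, comp, prior=False)
        np.testing.assert_array_equal(out["statistic"].to_numpy(), ref["statistic"].to_numpy())
        np.testing.assert_array_equal(out["p"].to_numpy(), ref["p"].to_numpy())

    def test_null_p_values_approximately_uniform(self):
        rng = np.random.default_rng(6)
        V = rng.normal(0, 1, (5000, 40))
        out = diff.diffvar_table(V, _comparison(20, 20), prior=True)
        ks = stats.kstest(out["p"], "uniform").statistic
        assert ks < 0.03


class TestIevora:
    def test_equal_variances_give_zero_statistic(self):
        v0 = np.array([1.0, 2.0])
        T, p = diff.bartlett_two_group(v0, v0, 20, 20)
        np.testing.assert_allclose(T, 0.0, atol=1e-12)
        np.testing.assert_allclose(p, 1.0)

    def test_closed_form_hand_evaluation(self):
        # var0=1, var1=4, n0=n1=20: independent evaluation of the formula
        n0 = n1 = 20
        sp2 = (19 * 1.0 + 19 * 4.0) / 38
        num = 38 * np.log(sp2) - 19 * np.log(1.0) - 19 * np.log(4.0)
        C = 1 + (1 / 19 + 1 / 19 - 1 / 38) / 3
        expected = num / C
        T, p = diff.bartlett_two_group(np.array([1.0]), np.array([4.0]), n0, n1)
        assert T[0] == pytest.approx(expected, rel=1e-12)
        assert p[0] == pytest.approx(stats.chi2.sf(expected, 1), rel=1e-12)

    def test_matches_scipy_bartlett_oracle(self):
        rng = np.random.default_rng(8)
        for _ in range(20):
            x0 = rng.normal(0, 1, 15)
            x1 = rng.normal(0, rng.uniform(0.5, 3), 12)
            T, p = diff.bartlett_two_group(
                np.array([x0.var(ddof=1)]), np.array([x1.var(ddof=1)]), 15, 12
            )
            ref = stats.bartlett(x0, x1)
            assert T[0] == pytest.approx(ref.statistic, rel=1e-10)
            assert p[0] == pytest.approx(ref.pvalue, rel=1e-8)

    def test_selection_rule_and_ordering(self):
        rng = np.random.default_rng(9)
        V = rng.normal(0.5, 0.02, (200, 40))
        # strong DV in group1 with an accompanying mean shift: the t filter
        # keeps only variance differences that move the bulk of the samples
        V[:5, 20:] = rng.normal(0.65, 0.3, (5, 20))
        out = diff.ievora_table(V, _comparison(20, 20))
        sel = out["selected"]
        assert set(out.index[sel]) <= set(range(200))
        assert sel[:5].all()
        order = out.attrs["selected_order"]
        tps = out.loc[order, "t_p"].to_numpy()
        assert (np.diff(tps) >= 0).all()

    def test_null_selection_is_conservative(self):
        rng = np.random.default_rng(10)
        V = rng.normal(0, 1, (10000, 40))
        out = diff.ievora_table(V, _comparison(20, 20))
        assert out["selected"].mean() <= 0.002


def combine_ranks_oracle(p_adj, effect, quotient):
    """Naive worst-rank: rank each criterion by explicit counting."""
    n = len(p_adj)

    def rank(vals, better_small):
        out = []
        for i in range(n):
            if better_small:
                better = sum(1 for j in range(n) if vals[j] < vals[i])
            else:
                better = sum(1 for j in range(n) if vals[j] > vals[i])
            out.append(better + 1)
        return out

    rp = rank(list(p_adj), True)
    re = rank([abs(v) for v in effect], False)
    rq = rank([abs(v) for v in quotient], False)
    return [max(a, b, c) for a, b, c in zip(rp, re, rq)]


class TestCombineRanks:
    def test_worked_example_with_tiebreak(self):
        table = pd.DataFrame(
            {
                # criterion ranks: A=(1,3,2), B=(2,1,1), C=(3,2,3)
                "p_adj": [0.01, 0.02, 0.03],
                "diff": [0.1, 0.5, 0.3],
                "log_quotient": [0.4, 0.9, 0.2],
            },
            index=["A", "B", "C"],
        )
        out = diff.combine_ranks(table)
        assert out["combined_rank"].to_dict() == {"B": 2, "A": 3, "C": 3}
        assert list(out.index) == ["B", "A", "C"]  # A before C by p tiebreak

    def test_single_unit_rank_one(self):
        table = pd.DataFrame({"p_adj": [0.5], "diff": [0.0], "log_quotient": [0.0]})
        out = diff.combine_ranks(table)
        assert out["combined_rank"].iloc[0] == 1

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_naive_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = 50
        table = pd.DataFrame(
            {
                "p_adj": rng.uniform(0.001, 1, n),
                "diff": rng.normal(0, 1, n),
                "log_quotient": rng.normal(0, 1, n),
            }
        )
        out = diff.combine_ranks(table)
        expected = combine_ranks_oracle(
            table["p_adj"], table["diff"], table["log_quotient"]
        )
        got = out["combined_rank"].reindex(table.index)
        assert list(got) == expected

    def test_invariant_under_monotone_transform_and_permutation(self):
        rng = np.random.default_rng(11)
        n = 40
        table = pd.DataFrame(
            {
                "p_adj": rng.uniform(0.001, 1, n),
                "diff": rng.normal(0, 1, n),
                "log_quotient": rng.normal(0, 1, n),
            }
        )
        base = diff.combine_ranks(table)["combined_rank"].sort_index()
        # strictly monotone transform of a criterion preserves its ranks
        t2 = table.copy()
        t2["p_adj"] = table["p_adj"] ** 2
        assert (diff.combine_ranks(t2)["combined_rank"].sort_index() == base).all()
        perm = table.sample(frac=1, random_state=0)
        assert (diff.combine_ranks(perm)["combined_rank"].sort_index() == base).all()

    def test_missing_criterion_ranks_last(self):
        table = pd.DataFrame(
            {
                "p_adj": [0.01, np.nan, 0.5],
                "diff": [1.0, 1.0, 0.2],
                "log_quotient": [1.0, 1.0, 0.1],
            }
        )
        out = diff.combine_ranks(table)
        assert out["combined_rank"].loc[1] == 3
        assert out.attrs["n_unranked"] == 1


class TestAutoRankCutoff:
    def test_no_significant_units_means_zero(self):
        table = pd.DataFrame({"p_adj": [1.0, 1.0], "combined_rank": [1, 2]})
        assert diff.auto_rank_cutoff(table) == 0

    def test_counting_rule(self):
        table = pd.DataFrame({"p_adj": [0.01, 0.02, 0.2]})
        assert diff.auto_rank_cutoff(table, fdr=0.05) == 2

    def test_selected_set_is_best_by_combined_rank(self):
        rng = np.random.default_rng(12)
        table = pd.DataFrame(
            {
                "p_adj": rng.uniform(0, 1, 30),
                "diff": rng.normal(0, 1, 30),
                "log_quotient": rng.normal(0, 1, 30),
            }
        )
        ranked = diff.combine_ranks(table)
        sel = diff.select_units(ranked, fdr=0.5)
        cutoff = diff.auto_rank_cutoff(ranked, fdr=0.5)
        assert len(sel) == cutoff
        worst_selected = ranked.loc[sel, "combined_rank"].max()
        unselected = ranked.drop(index=sel)
        assert (unselected["combined_rank"] >= worst_selected).all() or cutoff == 0


def bh_oracle(p):
    """Definitional BH: adj_i = min over j with p_j-rank >= rank_i of m*p_(j)/j."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adj = [None] * m
    best = np.inf
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        best = min(best, m * p[i] / (pos + 1))
        adj[i] = min(best, 1.0)
    return adj


class TestAdjustBH:
    def test_hand_step_up_example(self):
        np.testing.assert_allclose(
            diff.adjust_bh(np.array([0.01, 0.02, 0.03])), [0.03, 0.03, 0.03]
        )

    def test_single_p_unchanged(self):
        np.testing.assert_allclose(diff.adjust_bh(np.array([0.42])), [0.42])

    @given(st.lists(st.floats(1e-8, 1.0), min_size=1, max_size=60))
    @settings(max_examples=100, deadline=None)
    def test_matches_definition_oracle(self, ps):
        p = np.asarray(ps)
        np.testing.assert_allclose(diff.adjust_bh(p), bh_oracle(list(p)), atol=1e-12)

    def test_matches_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(13)
        p = rng.uniform(1e-6, 1, 200)
        ref = multipletests(p, method="fdr_bh")[1]
        np.testing.assert_allclose(diff.adjust_bh(p), ref, atol=1e-12)

    def test_monotone_and_dominates_p(self):
        rng = np.random.default_rng(14)
        p = rng.uniform(1e-6, 1, 100)
        adj = diff.adjust_bh(p)
        assert (adj >= p).all()
        assert (adj <= 1).all()
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-15).all()

    def test_out_of_range_rejected(self):
        with pytest.raises(DataError):
            diff.adjust_bh(np.array([0.0, 0.5]))
        with pytest.raises(DataError):
            diff.adjust_bh(np.array([1.5]))


class TestSharedRankingPath:
    def test_dm_table_uses_same_combine_ranks_machinery(self):
        rng = np.random.default_rng(15)
        V = rng.uniform(0, 1, (80, 20))
        comp = _comparison(10, 10)
        dm = diff.differential_methylation(V, comp, prior=True)
        rebuilt = diff.combine_ranks(
            dm.drop(columns=["rank_p", "rank_effect", "rank_quotient", "combined_rank"]),
            p_col="p_adj", effect_col="diff", quotient_col="log_quotient",
        )
        assert (dm["combined_rank"] == rebuilt["combined_rank"]).all()
        assert list(dm.index) == list(rebuilt.index)

    def test_dv_table_criteria_are_variance_based(self):
        rng = np.random.default_rng(16)
        V = rng.uniform(0, 1, (50, 20))
        comp = _comparison(10, 10)
        dv = diff.differential_variability(V, comp, method="diffvar")
        for col in ("var_diff", "var_log_ratio", "p_adj", "combined_rank"):
            assert col in dv.columns
        dv2 = diff.differential_variability(V, comp, method="ievora")
        assert "combined_rank" in dv2.columns
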