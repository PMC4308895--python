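import dataclasses

import numpy as np
import pandas as pd
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

from exprvar.differential import (bh_adjust, combine_ranked_lists,
                                  common_top_k, differential_expression,
                                  differential_variability, f_test_two_sided,
                                  select_dv_genes, RankedGeneList)
from exprvar.errors import ValidationError
from exprvar.simulate import SyntheticSpec, generate_cohorts

from oracles import bh_step_up, common_top_k_scan, f_cdf_via_beta, welch_t


def ranked(genes):
    return RankedGeneList(genes=list(genes), key_name="key",
                          key_values=np.arange(len(genes), 0, -1))


class TestFTest:
    def test_identical_samples_give_f_one_p_one(self, rng):
        x = rng.normal(size=12)
        f, p = f_test_two_sided(x, x)
        assert f == pytest.approx(1.0)
        assert p == pytest.approx(1.0)

    def test_known_variance_ratio_against_beta_cdf_oracle(self):
        # 11 values per group engineered to exact variances 4 and 1
        base = np.array([-2, -1.5, -1, -0.5, 0, 0.5, 1, 1.5, 2, -0.25, 0.25])
        x = base * np.sqrt(4 / base.var(ddof=1))
        y = base * np.sqrt(1 / base.var(ddof=1))
        f, p = f_test_two_sided(x, y)
        assert f == pytest.approx(4.0)
        cdf = f_cdf_via_beta(4.0, 10, 10)
        assert p == pytest.approx(2 * min(cdf, 1 - cdf), rel=1e-9)

    def test_swapping_groups_inverts_f_keeps_p(self, rng):
        x = rng.normal(0, 2, 15)
        y = rng.normal(0, 1, 9)
        f, p = f_test_two_sided(x, y)
        f2, p2 = f_test_two_sided(y, x)
        assert f2 == pytest.approx(1 / f)
        assert p2 == pytest.approx(p)

    def test_degenerate_inputs_rejected(self, rng):
        with pytest.raises(ValidationError):
            f_test_two_sided([1.0, 2.0], rng.normal(size=5))
        with pytest.raises(ValidationError):
            f_test_two_sided([1.0, 1.0, 1.0], rng.normal(size=5))

    def test_null_p_values_uniform(self, rng):
        pvals = [f_test_two_sided(rng.normal(size=10), rng.normal(size=14))[1]
                 for _ in range(2000)]
        assert scipy.stats.kstest(pvals, "uniform").statistic < 0.03


class TestBHAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.2])[0] == pytest.approx(0.2)

    def test_hand_step_up_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_matches_literal_step_up_oracle(self, rng):
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 40))
            assert np.abs(bh_adjust(p) - bh_step_up(list(p))).max() < 1e-12

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.2])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(min_value=0, max_value=1, allow_nan=False),
                    min_size=2, max_size=30))
    def test_monotone_in_p(self, pvals):
        q = bh_adjust(pvals)
        order = np.argsort(pvals)
        assert (np.diff(q[order]) >= -1e-12).all()


@pytest.fixture(scope="module")
def dv_table(small_cohorts):
    return differential_variability(small_cohorts["m1"], small_cohorts["g1"])


class TestDifferentialVariability:
    def test_true_dv_genes_show_concordant_sign_pattern(self, dv_table,
                                                        small_cohorts):
        truth = small_cohorts["truth"]
        rows = dv_table.loc[sorted(truth.dv_genes)]
        frac = ((rows["cv_diff"] < 0) & (rows["ev_diff"] < 0)
                & (rows["f_stat"] < 1)).mean()
        assert frac >= 0.95

    def test_concordance_flags_mutually_exclusive(self, dv_table):
        assert not (dv_table["concordant_up_in_A"]
                    & dv_table["concordant_up_in_B"]).any()

    def test_relabeling_groups_negates_diffs_inverts_f(self, small_cohorts):
        m, g = small_cohorts["m1"], small_cohorts["g1"]
        swapped = g.map({"M": "U", "U": "M"})
        t1 = differential_variability(m, g)
        t2 = differential_variability(m, swapped)
        assert np.allclose(t1["cv_diff"], -t2["cv_diff"], equal_nan=True)
        assert np.allclose(t1["f_stat"], 1 / t2["f_stat"], equal_nan=True)
        assert np.allclose(t1["q"], t2["q"], equal_nan=True)

    def test_zero_variance_genes_flagged_untestable(self, small_cohorts):
        m = small_cohorts["m1"].copy()
        m.iloc[0] = 5.0
        table = differential_variability(m, small_cohorts["g1"])
        assert not table["testable"].iloc[0]
        assert np.isnan(table["q"].iloc[0])
        assert table["testable"].iloc[1:].all()

    def test_deterministic(self, small_cohorts, dv_table):
        again = differential_variability(small_cohorts["m1"], small_cohorts["g1"])
        pd.testing.assert_frame_equal(dv_table, again)


class TestDifferentialExpression:
    def test_identical_groups_m_zero_not_significant(self):
        vals = np.tile(np.array([[5.0, 6.0, 7.0, 5.0, 6.0, 7.0]]), (60, 1))
        vals += np.linspace(0, 1, 60)[:, None]
        m = pd.DataFrame(vals, index=[f"g{i}" for i in range(60)],
                         columns=[f"s{j}" for j in range(6)])
        groups = pd.Series(["M"] * 3 + ["U"] * 3, index=m.columns)
        table = differential_expression(m, groups)
        assert np.allclose(table["m_value"], 0.0)
        assert not table["significant"].any()

    def test_welch_hand_example(self):
        a = np.array([0.0, 0.1, -0.1])
        b = np.array([2.0, 2.1, 1.9])
        m = pd.DataFrame([np.concatenate([a, b])], index=["g1"],
                         columns=[f"s{j}" for j in range(6)])
        m.loc["g2"] = np.concatenate([a, b * 0.5])  # second gene for FDR universe
        groups = pd.Series(["M"] * 3 + ["U"] * 3, index=m.columns)
        table = differential_expression(m, groups)
        assert table.loc["g1", "m_value"] == pytest.approx(2.0)
        t_expect, df_expect = welch_t(b, a)
        assert table.loc["g1", "t_stat"] == pytest.approx(t_expect)
        p_expect = 2 * scipy.stats.t.sf(abs(t_expect), df_expect)
        assert table.loc["g1", "p"] == pytest.approx(p_expect, rel=1e-9)

    def test_strict_m_cutoff_excludes_m_below_one(self):
        rngl = np.random.default_rng(0)
        base = rngl.normal(8, 0.05, (50, 20))
        m = pd.DataFrame(base, index=[f"g{i}" for i in range(50)],
                         columns=[f"s{j}" for j in range(20)])
        m.iloc[0, 10:] = m.iloc[0, 10:] - m.iloc[0, 10:].mean() + m.iloc[0, :10].mean() + 0.99
        groups = pd.Series(["M"] * 10 + ["U"] * 10, index=m.columns)
        table = differential_expression(m, groups)
        assert table["q"].iloc[0] < 0.05
        assert abs(table["m_value"].iloc[0]) == pytest.approx(0.99, abs=1e-9)
        assert not table["significant"].iloc[0]


class TestSelectDVGenes:
    def test_discordant_gene_excluded(self, dv_table):
        list_cv, _ = select_dv_genes(dv_table, apply_fdr=True)
        rows = dv_table.loc[list_cv.genes]
        assert ((rows["cv_diff"] < 0) & (rows["ev_diff"] < 0)
                & (rows["f_stat"] < 1)).all()
        assert (rows["q"] < 0.05).all()

    def test_no_fdr_returns_all_concordant(self, dv_table):
        list_cv, list_ev = select_dv_genes(dv_table, apply_fdr=False)
        n_concordant = int(dv_table["concordant_up_in_B"].sum())
        assert len(list_cv) == len(list_ev) == n_concordant

    def test_lists_ordered_by_abs_diff_with_id_ties(self, dv_table):
        list_cv, list_ev = select_dv_genes(dv_table, apply_fdr=False)
        keys = dv_table.loc[list_cv.genes, "cv_diff"].abs().to_numpy()
        assert (np.diff(keys) <= 1e-15).all()
        keys_ev = dv_table.loc[list_ev.genes, "ev_diff"].abs().to_numpy()
        assert (np.diff(keys_ev) <= 1e-15).all()

    def test_recovers_true_dv_genes(self, dv_table, small_cohorts):
        list_cv, _ = select_dv_genes(dv_table)
        top = set(list_cv.top(20))
        assert len(top & small_cohorts["truth"].dv_genes) >= 16


class TestCommonTopK:
    def test_identical_lists(self):
        lst = ranked(["g1", "g2", "g3", "g4", "g5", "g6"])
        common, depth = common_top_k(lst, ranked(lst.genes), k=5)
        assert depth == 5
        assert common == {"g1", "g2", "g3", "g4", "g5"}

    def test_hand_traced_lockstep_expansion(self):
        a = ranked(["g1", "g2", "g3", "g4"])
        b = ranked(["g3", "g1", "g7", "g2"])
        common, depth = common_top_k(a, b, k=2)
        assert depth == 3
        assert common == {"g1", "g3"}

    def test_matches_exhaustive_depth_scan(self, rng):
        genes = [f"g{i}" for i in range(1000)]
        a = ranked(rng.permutation(genes))
        b = ranked(rng.permutation(genes))
        assert common_top_k(a, b, 50) == common_top_k_scan(a.genes, b.genes, 50)
        for _ in range(100):
            size = int(rng.integers(3, 30))
            universe = [f"g{i}" for i in range(size)]
            a = ranked(rng.permutation(universe))
            b = ranked(rng.permutation(universe)[:rng.integers(2, size + 1)])
            k = int(rng.integers(1, len(b.genes) + 1))
            assert common_top_k(a, b, k) == common_top_k_scan(a.genes, b.genes, k)

    def test_unreachable_k_reports_maximum(self):
        a = ranked(["g1", "g2"])
        b = ranked(["g1", "g3"])
        with pytest.raises(ValidationError, match="only 1"):
            common_top_k(a, b, k=2)


def test_combined_rank_merges_cv_and_ev_orders():
    a = ranked(["g1", "g2", "g3"])
    b = ranked(["g3", "g2", "g1"])
    combined = combine_ranked_lists(a, b)
    # g2 has mean rank 2; g1 and g3 mean rank 2 as well -> tie on id
    assert set(combined.genes) == {"g1", "g2", "g3"}
    assert combined.genes == sorted(combined.genes,
                                    key=lambda g: (-dict(zip(combined.genes,
                                                             combined.key_values))[g], g))


def test_null_cohort_yields_no_fdr_calls(null_cohort):
    table = differential_variability(null_cohort["m"], null_cohort["groups"])
    assert (table["q"] < 0.05).sum() <= 2
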