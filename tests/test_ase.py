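import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from haploquartet import (
    CountsMatrix,
    ProportionVector,
    Quartet,
    QuartetSimConfig,
    allelic_bias,
    bh_adjust,
    condition_proportions,
    contrast_chi_square,
    rank_and_delta,
    run_ase,
    select_quartets,
    simulate_quartets,
)

from _oracles import bh_step_up


def _pv(values):
    v = np.asarray(values, dtype=float)
    return ProportionVector(v / v.sum(), int(v.sum()))


class TestProportions:
    def test_pooling_over_replicates(self, contrast_sheet):
        q = Quartet("OG1", ("ga", "gb", "gc", "gd"))
        cols = contrast_sheet.sample_ids
        df = pd.DataFrame(
            [[15, 15, 15, 15, 0, 0, 0, 0],
             [5, 5, 5, 5, 0, 0, 0, 0],
             [2, 3, 2, 3, 0, 0, 0, 0],
             [2, 3, 2, 3, 0, 0, 0, 0]],
            index=["ga", "gb", "gc", "gd"], columns=cols,
        )
        pv = condition_proportions(
            q, CountsMatrix(df), contrast_sheet, "control"
        )
        assert pv.pooled_total == 100
        np.testing.assert_allclose(pv.p, [0.6, 0.2, 0.1, 0.1])

    def test_zero_pooled_total_is_error(self, contrast_sheet):
        q = Quartet("OG1", ("ga", "gb", "gc", "gd"))
        df = pd.DataFrame(
            np.zeros((4, 8), dtype=int),
            index=["ga", "gb", "gc", "gd"], columns=contrast_sheet.sample_ids,
        )
        with pytest.raises(ValueError, match="zero pooled"):
            condition_proportions(q, CountsMatrix(df), contrast_sheet, "control")

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.integers(0, 10_000), min_size=4, max_size=4).filter(
        lambda v: sum(v) > 0))
    def test_proportions_equal_counts_over_total(self, pooled):
        pv = _pv(pooled)
        np.testing.assert_allclose(pv.p, np.array(pooled) / sum(pooled), atol=1e-12)
        assert abs(pv.p.sum() - 1.0) < 1e-12


class TestAllelicBias:
    @pytest.mark.parametrize(
        "p,bias,cls",
        [
            ((0.25, 0.25, 0.25, 0.25), 0.0, "balanced"),
            ((0.6, 0.2, 0.1, 0.1), 0.5, "mild"),  # boundary inclusive to mild
            ((0.8, 0.1, 0.05, 0.05), 0.75, "strong"),
            ((0.35, 0.25, 0.25, 0.15), 0.2, "balanced"),
            ((0.4, 0.25, 0.2, 0.15), 0.25, "mild"),  # 0.25 boundary is mild
        ],
    )
    def test_bias_and_dominance_class(self, p, bias, cls):
        r = allelic_bias(np.array(p))
        assert r.bias == pytest.approx(bias)
        assert r.dominance_class == cls


class TestChiSquare:
    def test_identical_rows_give_zero(self):
        stat, dof, p = contrast_chi_square([10, 10, 10, 10], [10, 10, 10, 10])
        assert stat == pytest.approx(0.0)
        assert dof == 3
        assert p == pytest.approx(1.0)

    def test_disjoint_support_reduces_table(self):
        stat, dof, p = contrast_chi_square([100, 0, 0, 0], [0, 100, 0, 0])
        assert stat == pytest.approx(200.0)
        assert dof == 1
        assert p < 1e-40

    def test_matches_scipy_oracle(self):
        a, b = [30, 20, 10, 40], [10, 20, 30, 40]
        stat, dof, p = contrast_chi_square(a, b)
        o_stat, o_p, o_dof, _ = stats.chi2_contingency([a, b], correction=False)
        assert stat == pytest.approx(o_stat, abs=1e-10)
        assert dof == o_dof
        assert p == pytest.approx(o_p, abs=1e-10)

    def test_degenerate_table_flagged_undefined(self):
        stat, dof, p = contrast_chi_square([50, 0, 0, 0], [70, 0, 0, 0])
        assert np.isnan(stat) and np.isnan(p) and dof == 0

    @settings(derandomize=True, max_examples=100)
    @given(
        st.lists(st.integers(0, 500), min_size=4, max_size=4),
        st.lists(st.integers(0, 500), min_size=4, max_size=4),
    )
    def test_condition_swap_symmetry(self, a, b):
        r1 = contrast_chi_square(a, b)
        r2 = contrast_chi_square(b, a)
        for x, y in zip(r1, r2):
            assert (np.isnan(x) and np.isnan(y)) or x == pytest.approx(y)


class TestBH:
    def test_textbook_example(self):
        q = bh_adjust([0.01, 0.02, 0.03, 0.04])
        np.testing.assert_allclose(q, [0.04, 0.04, 0.04, 0.04])

    def test_degenerate_cases(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])
        np.testing.assert_allclose(bh_adjust([0.37]), [0.37])

    def test_nan_reinserted(self):
        q = bh_adjust([0.01, np.nan, 0.5])
        assert np.isnan(q[1]) and not np.isnan(q[0])

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])

    @settings(derandomize=True, max_examples=300)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=8))
    def test_equals_brute_force_step_up_exactly(self, ps):
        got = bh_adjust(ps)
        expected = bh_step_up(ps)
        assert list(got) == expected

    @settings(derandomize=True, max_examples=100)
    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=20))
    def test_cross_check_against_statsmodels(self, ps):
        from statsmodels.stats.multitest import multipletests

        got = bh_adjust(ps)
        ref = multipletests(ps, method="fdr_bh")[1]
        np.testing.assert_allclose(got, ref, atol=1e-12)


class TestRankAndDelta:
    def test_no_switch_no_effect(self):
        rd = rank_and_delta(_pv([4, 3, 2, 1]), _pv([4, 3, 2, 1]))
        assert not rd["rank_switch"]
        assert rd["delta"] == pytest.approx(0.0)
        assert rd["effect_class"] == "none"

    def test_switch_with_moderate_delta(self):
        rd = rank_and_delta(
            _pv([40, 30, 20, 10]), _pv([20, 55, 15, 10])
        )
        assert rd["rank_switch"]
        assert rd["top_control"] == "A" and rd["top_stress"] == "B"
        assert rd["delta"] == pytest.approx(0.15)
        assert rd["effect_class"] == "moderate"

    def test_tie_broken_alphabetically_and_flagged(self):
        rd = rank_and_delta(_pv([3, 3, 2, 2]), _pv([5, 3, 1, 1]))
        assert rd["top_control"] == "A"
        assert rd["tie_control"] and not rd["tie_stress"]

    def test_pronounced_threshold(self):
        rd = rank_and_delta(_pv([30, 28, 22, 20]), _pv([10, 50, 20, 20]))
        assert rd["delta"] == pytest.approx(0.20)
        assert rd["effect_class"] == "pronounced"


@pytest.fixture(scope="module")
def small_run():
    cfg = QuartetSimConfig(n_quartets=60, frac_switch=0.2, seed=5)
    counts, sheet, og, _, truth = simulate_quartets(cfg)
    qs = select_quartets(og)
    table, summary = run_ase(qs, counts, sheet, ("control", "stress"))
    return counts, sheet, og, qs, table, summary


class TestRunAse:
    def test_q_at_least_p_and_delta_in_range(self, small_run):
        *_, table, _ = small_run
        ok = ~table["p_value"].isna()
        assert (table.loc[ok, "q_value"] >= table.loc[ok, "p_value"] - 1e-12).all()
        assert table["delta"].between(0, 1).all()
        assert table["bias_control"].between(0, 1).all()

    def test_haplotype_relabeling_invariance(self, small_run):
        counts, sheet, og, qs, table, _ = small_run
        # reverse the haplotype assignment D<->A, C<->B for every quartet
        flipped = [
            type(q)(q.orthogroup_id, q.genes[::-1]) for q in qs
        ]
        t2, _ = run_ase(flipped, counts, sheet, ("control", "stress"))
        np.testing.assert_allclose(t2["bias_control"], table["bias_control"])
        np.testing.assert_allclose(t2["chi2_stat"], table["chi2_stat"])
        np.testing.assert_allclose(t2["delta"], table["delta"])
        assert (t2["rank_switch"] == table["rank_switch"]).all()

    def test_condition_swap_invariance(self, small_run):
        counts, sheet, og, qs, table, _ = small_run
        t2, _ = run_ase(qs, counts, sheet, ("stress", "control"))
        np.testing.assert_allclose(t2["chi2_stat"], table["chi2_stat"])
        np.testing.assert_allclose(t2["p_value"], table["p_value"])
        np.testing.assert_allclose(t2["delta"], table["delta"])
        assert (t2["rank_switch"] == table["rank_switch"]).all()

    def test_rerun_is_identical(self, small_run):
        counts, sheet, og, qs, table, _ = small_run
        t2, _ = run_ase(qs, counts, sheet, ("control", "stress"))
        pd.testing.assert_frame_equal(table, t2)

    def test_empty_quartet_set_warns(self, small_run):
        counts, sheet, *_ = small_run
        with pytest.warns(UserWarning, match="empty"):
            table, summary = run_ase([], counts, sheet, ("control", "stress"))
        assert summary["n_quartets"] == 0 and table.empty

    def test_planted_switches_recovered_in_summary(self, small_run):
        counts, sheet, og, qs, table, summary = small_run
        cfg = QuartetSimConfig(n_quartets=60, frac_switch=0.2, seed=5)
        truth = simulate_quartets(cfg)[4]
        n_true = int((truth["class"] == "switch").sum())
        # planted delta 0.25 -> every true switch should sit above 0.1
        m = table.merge(truth, on="orthogroup_id")
        sw = m[m["class"] == "switch"]
        assert (sw["delta"] >= 0.1).mean() >= 0.9
        assert summary["n_rank_switch"] >= 0.8 * n_true
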