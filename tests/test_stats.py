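"""Statistical battery: chi-square closed form, ANOVA sums of squares and
df conventions, Spearman screen."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency

import cagecontagion as cc
from cagecontagion.events import ValidationError
from cagecontagion.stats import UndefinedStatisticError

from oracles import pearson_chi2_cellwise


class TestChiSquare:
    def test_proportional_rows_give_zero(self):
        r = cc.chi_square_2x2([[5, 5], [5, 5]])
        assert r.statistic == 0.0 and r.p_value == 1.0

    def test_published_style_cohort_tables(self):
        # activated observers 7/16 vs 13/15 and followers 2/16 vs 8/15
        assert cc.chi_square_2x2([[7, 9], [13, 2]]).statistic == pytest.approx(6.229, abs=5e-4)
        assert cc.chi_square_2x2([[2, 14], [8, 7]]).statistic == pytest.approx(5.907, abs=5e-4)

    def test_pooled_edge_table_closed_form(self):
        # 2/38 vs 10/36 actualized edges: value fixed by the closed formula
        r = cc.chi_square_2x2([[2, 36], [10, 26]])
        assert r.statistic == pytest.approx(pearson_chi2_cellwise([[2, 36], [10, 26]]))

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.tuples(*[st.integers(0, 40)] * 4))
    def test_agrees_with_cellwise_form_and_scipy(self, cells):
        a, b, c, d = cells
        if a + b == 0 or c + d == 0 or a + c == 0 or b + d == 0:
            return
        table = [[a, b], [c, d]]
        r = cc.chi_square_2x2(table)
        assert r.statistic == pytest.approx(pearson_chi2_cellwise(table), abs=1e-9)
        stat, p, _, _ = chi2_contingency(table, correction=False)
        assert r.statistic == pytest.approx(stat) and r.p_value == pytest.approx(p)
        ry = cc.chi_square_2x2(table, continuity_correction=True)
        stat_y, _, _, _ = chi2_contingency(table, correction=True)
        assert ry.statistic == pytest.approx(stat_y)

    def test_symmetric_under_simultaneous_row_and_column_swap(self):
        r1 = cc.chi_square_2x2([[7, 9], [13, 2]])
        r2 = cc.chi_square_2x2([[2, 13], [9, 7]])
        assert r1.statistic == pytest.approx(r2.statistic)

    def test_zero_column_marginal_is_undefined(self):
        with pytest.raises(UndefinedStatisticError):
            cc.chi_square_2x2([[0, 5], [0, 7]])


def _nested_toy():
    rows = []
    for strain, cage, values in [
        ("s1", "A", [1, 2, 3]), ("s1", "B", [2, 4, 6]),
        ("s2", "C", [5, 5, 8]), ("s2", "D", [7, 9, 11]),
    ]:
        rows += [(f"{cage}{i}", strain, cage, float(v)) for i, v in enumerate(values)]
    return pd.DataFrame(rows, columns=["animal", "strain", "cage", "value"])


class TestNestedAnova:
    def test_toy_dataset_matches_hand_sums_of_squares(self):
        # frozen from an independent hand computation on the 2x2x3 toy:
        # SS_strain=60.75, SS_cage(strain)=19.5, SS_res=24 -> F=20.25, 3.25
        res = {r.effect: r for r in cc.nested_anova(_nested_toy(), df_convention="residual")}
        assert res["strain"].statistic == pytest.approx(20.25)
        assert res["cage(strain)"].statistic == pytest.approx(3.25)
        assert (res["strain"].df1, res["strain"].df2) == (1, 8)
        assert res["strain"].p_value == pytest.approx(0.002002, abs=1e-5)

    def test_cage_error_term_option(self):
        res = {r.effect: r for r in cc.nested_anova(_nested_toy(), error_term="cage")}
        assert res["strain"].statistic == pytest.approx(6.230769, abs=1e-5)

    def test_reported_df_convention_uses_subjects_minus_one(self):
        res = {r.effect: r for r in cc.nested_anova(_nested_toy())}
        assert res["strain"].df2 == 11 and res["cage(strain)"].df2 == 11

    def test_identical_strain_values_give_zero_f(self):
        df = _nested_toy()
        df["value"] = np.tile([1.0, 2.0, 3.0], 4)  # same cage pattern everywhere
        res = {r.effect: r for r in cc.nested_anova(df)}
        assert res["strain"].statistic == pytest.approx(0.0)

    def test_singleton_cage_rejected(self):
        df = _nested_toy().drop(index=[1, 2]).reset_index(drop=True)
        with pytest.raises(ValidationError, match="single animal"):
            cc.nested_anova(df)


def _rm_toy():
    y = {
        ("s1", "A"): (3, 5), ("s2", "A"): (2, 4), ("s3", "A"): (6, 7),
        ("s4", "B"): (4, 9), ("s5", "B"): (5, 8), ("s6", "B"): (3, 9),
    }
    rows = []
    for (s, g), (v1, v2) in y.items():
        rows.append((s, g, "baseline", float(v1)))
        rows.append((s, g, "contagion", float(v2)))
    return pd.DataFrame(rows, columns=["animal", "cage", "condition", "value"])


class TestRmAnova:
    def test_toy_dataset_matches_hand_sums_of_squares(self):
        # frozen from an independent mixed-design SS computation:
        # F_between=3.025, F_within=45.125, F_interaction=10.125
        res = {r.effect: r for r in cc.rm_anova(_rm_toy(), df_convention="residual")}
        assert res["between"].statistic == pytest.approx(3.025)
        assert res["within"].statistic == pytest.approx(45.125)
        assert res["interaction"].statistic == pytest.approx(10.125)
        assert res["within"].df2 == 4

    def test_reported_df_convention(self):
        res = {r.effect: r for r in cc.rm_anova(_rm_toy())}
        assert all(r.df2 == 5 for r in res.values())

    def test_identical_conditions_give_zero_within_f(self):
        df = _rm_toy()
        piv = df.pivot(index=["animal", "cage"], columns="condition", values="value")
        piv["contagion"] = piv["baseline"]
        long = piv.reset_index().melt(
            id_vars=["animal", "cage"], var_name="condition", value_name="value"
        )
        res = {r.effect: r for r in cc.rm_anova(long)}
        assert res["within"].statistic == pytest.approx(0.0, abs=1e-12)

    def test_missing_condition_is_an_error(self):
        df = _rm_toy().drop(index=0)
        with pytest.raises(ValidationError, match="missing a within condition"):
            cc.rm_anova(df)

    def test_df_structure_matches_cohort_layout(self):
        """15 subjects in 4 cages: reported df (1, 14) within, (3, 14) between."""
        rng = np.random.default_rng(0)
        rows = []
        for i, size in enumerate([4, 4, 4, 3]):
            for j in range(size):
                a = f"S{i}{j}"
                rows.append((a, f"C{i}", "baseline", rng.normal()))
                rows.append((a, f"C{i}", "contagion", rng.normal()))
        df = pd.DataFrame(rows, columns=["animal", "cage", "condition", "value"])
        res = {r.effect: r for r in cc.rm_anova(df)}
        assert (res["within"].df1, res["within"].df2) == (1, 14)
        assert (res["between"].df1, res["between"].df2) == (3, 14)
        assert (res["interaction"].df1, res["interaction"].df2) == (3, 14)


class TestSpearman:
    def _summaries(self, x, y):
        animals = [f"A{i}" for i in range(len(x))]
        base = pd.DataFrame({"animal": animals, "window_label": "baseline",
                             "total_visits": x, "drinking_visits": x,
                             "inspection_visits": 0.0, "licking_time": x})
        cont = base.copy()
        cont["window_label"] = "contagion"
        for col in ("total_visits", "drinking_visits", "licking_time"):
            cont[col] = y
        return base, cont

    def test_monotone_transform_gives_rho_one(self):
        x = np.arange(10.0)
        base, cont = self._summaries(x, np.exp(x))
        out = cc.spearman_screen(base, cont, ["total_visits"])
        assert out.loc[0, "rho"] == pytest.approx(1.0)

    def test_reversed_order_gives_rho_minus_one(self):
        x = np.arange(10.0)
        base, cont = self._summaries(x, -x)
        out = cc.spearman_screen(base, cont, ["total_visits"])
        assert out.loc[0, "rho"] == pytest.approx(-1.0)

    def test_constant_vector_reported_as_undefined(self):
        base, cont = self._summaries(np.zeros(8), np.arange(8.0))
        out = cc.spearman_screen(base, cont, ["total_visits"])
        assert np.isnan(out.loc[0, "rho"]) and "undefined" in out.loc[0, "note"]

    def test_independent_data_rarely_significant(self):
        """Under independence P(p > 0.10) = 0.90; check the Monte-Carlo rate."""
        rng = np.random.default_rng(42)
        n_over = 0
        n_seeds = 400
        for _ in range(n_seeds):
            base, cont = self._summaries(rng.normal(size=16), rng.normal(size=16))
            out = cc.spearman_screen(base, cont, ["total_visits"])
            n_over += out.loc[0, "p_value"] > 0.10
        assert n_over / n_seeds == pytest.approx(0.90, abs=0.05)
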