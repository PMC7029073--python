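"""Two-way ANOVA, MANOVA (Wilks), Tukey-Kramer, and paired t tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from camoquant import manova_wilks, paired_t, tukey_hsd, two_way_anova
from camoquant.stats import DesignError, MulticollinearityError, _compact_letters

from _oracles import balanced_anova_oracle, tukey_oracle, type3_anova_oracle, wilks_oracle


def _frame(cells: dict, response="y", rng=None) -> pd.DataFrame:
    rows = []
    for (sp, sx), values in cells.items():
        for v in values:
            rows.append({"species": sp, "sex": sx, response: float(v)})
    return pd.DataFrame(rows)


@pytest.fixture
def balanced():
    return _frame(
        {
            ("A", "f"): [3, 5],
            ("A", "m"): [7, 9],
            ("B", "f"): [2, 4],
            ("B", "m"): [12, 14],
        }
    )


@pytest.fixture
def unbalanced(rng):
    cells = {
        ("A", "f"): rng.normal(0.0, 1.0, 5),
        ("A", "m"): rng.normal(1.0, 1.0, 8),
        ("B", "f"): rng.normal(0.5, 1.0, 6),
        ("B", "m"): rng.normal(2.0, 1.0, 9),
    }
    return _frame(cells)


class TestTwoWayAnova:
    def test_constant_response_gives_f_zero_p_one(self):
        frame = _frame({k: [4.0, 4.0, 4.0] for k in [("A", "f"), ("A", "m"), ("B", "f"), ("B", "m")]})
        res = two_way_anova(frame, "y")
        for term in ("species", "sex", "species:sex"):
            assert res.term(term)["F"] == 0.0
            assert res.term(term)["p"] == 1.0

    def test_balanced_design_matches_classical_decomposition(self, balanced):
        res = two_way_anova(balanced, "y")
        oracle = balanced_anova_oracle(balanced, "y")
        for term in ("species", "sex", "species:sex", "error"):
            assert res.term(term)["sum_sq"] == pytest.approx(oracle[term], abs=1e-10)
        # df bookkeeping: term dfs + error df = n - 1
        assert res.table["df"].sum() == len(balanced) - 1

    def test_unbalanced_design_matches_projection_oracle(self, unbalanced):
        res = two_way_anova(unbalanced, "y")
        oracle = type3_anova_oracle(unbalanced, "y")
        for term in ("species", "sex", "species:sex"):
            assert res.term(term)["sum_sq"] == pytest.approx(oracle[term]["sum_sq"], abs=1e-8)
            assert res.term(term)["F"] == pytest.approx(oracle[term]["F"], abs=1e-8)
            assert res.term(term)["p"] == pytest.approx(oracle[term]["p"], abs=1e-10)
        assert res.term("error")["sum_sq"] == pytest.approx(oracle["error"]["sum_sq"], abs=1e-8)

    def test_empty_cell_rejected(self):
        frame = _frame(
            {("A", "f"): [1.0, 2.0], ("A", "m"): [1.0, 2.0], ("B", "f"): [1.0, 2.0]}
        )
        with pytest.raises(DesignError):
            two_way_anova(frame, "y")

    def test_null_type_one_error_nominal(self):
        rng = np.random.default_rng(77)
        reps, rejections = 400, 0
        for _ in range(reps):
            frame = _frame(
                {
                    ("A", "f"): rng.normal(size=6),
                    ("A", "m"): rng.normal(size=8),
                    ("B", "f"): rng.normal(size=7),
                    ("B", "m"): rng.normal(size=9),
                }
            )
            if two_way_anova(frame, "y").term("species")["p"] < 0.05:
                rejections += 1
        assert rejections / reps == pytest.approx(0.05, abs=0.03)


class TestManovaWilks:
    @staticmethod
    def _multi_frame(rng, n=(6, 8, 7, 9), effect=0.0):
        rows = []
        for (sp, sx), m in zip(
            [("A", "f"), ("A", "m"), ("B", "f"), ("B", "m")], n
        ):
            shift = effect if sp == "A" else 0.0
            for _ in range(m):
                y = rng.normal(size=3)
                rows.append(
                    {
                        "species": sp,
                        "sex": sx,
                        "y1": y[0] + shift,
                        "y2": y[1],
                        "y3": y[2],
                    }
                )
        return pd.DataFrame(rows)

    def test_single_response_reduces_to_univariate_f(self, unbalanced):
        res = manova_wilks(unbalanced, ["y"])
        uni = two_way_anova(unbalanced, "y")
        for term in ("species", "sex", "species:sex"):
            sse = uni.term("error")["sum_sq"]
            ssh = uni.term(term)["sum_sq"]
            assert res[term].wilks_lambda == pytest.approx(sse / (sse + ssh), abs=1e-10)
            assert res[term].F == pytest.approx(uni.term(term)["F"], abs=1e-8)

    def test_matches_reference_library(self, rng):
        frame = self._multi_frame(rng, effect=1.0)
        res = manova_wilks(frame, ["y1", "y2", "y3"])
        oracle = wilks_oracle(frame, ["y1", "y2", "y3"])
        for term in ("species", "sex", "species:sex"):
            lam, F = oracle[term]
            assert res[term].wilks_lambda == pytest.approx(lam, abs=1e-8)
            assert res[term].F == pytest.approx(F, abs=1e-6)

    def test_duplicated_response_rejected(self, rng):
        frame = self._multi_frame(rng)
        frame["y2"] = frame["y1"]
        with pytest.raises(MulticollinearityError):
            manova_wilks(frame, ["y1", "y2", "y3"])

    def test_lambda_bounded_and_decreasing_in_effect_size(self):
        rng = np.random.default_rng(5)
        lams = []
        for effect in (0.0, 0.8, 1.6, 3.2):
            vals = []
            for _ in range(20):
                frame = self._multi_frame(rng, effect=effect)
                res = manova_wilks(frame, ["y1", "y2", "y3"])
                assert 0.0 < res["species"].wilks_lambda <= 1.0
                vals.append(res["species"].wilks_lambda)
            lams.append(np.mean(vals))
        assert all(a > b for a, b in zip(lams, lams[1:]))

    def test_null_p_values_uniform(self):
        rng = np.random.default_rng(9)
        ps = []
        for _ in range(200):
            frame = self._multi_frame(rng)
            ps.append(manova_wilks(frame, ["y1", "y2", "y3"])["sex"].p)
        assert sps.kstest(ps, "uniform").pvalue > 0.01


class TestTukeyHsd:
    def test_identical_groups_not_different(self):
        values = np.array([1.0, 2.0, 3.0, 1.0, 2.0, 3.0])
        groups = np.array(["a"] * 3 + ["b"] * 3)
        res = tukey_hsd(values, groups)
        row = res.table.iloc[0]
        assert row["diff"] == 0.0
        assert row["p_adj"] > 0.99
        assert res.letters["a"] == res.letters["b"]

    def test_two_groups_reduce_to_t_test(self, rng):
        a = rng.normal(0.0, 1.0, 8)
        b = rng.normal(1.0, 1.0, 11)
        res = tukey_hsd(np.concatenate([a, b]), np.array(["a"] * 8 + ["b"] * 11))
        t_p = sps.ttest_ind(a, b).pvalue  # q = sqrt(2) * |t| identity
        assert res.table.iloc[0]["p_adj"] == pytest.approx(t_p, abs=1e-6)

    def test_matches_reference_library(self, rng):
        values = np.concatenate(
            [rng.normal(m, 1.0, n) for m, n in ((0, 6), (0.5, 9), (2.5, 7), (1.0, 8))]
        )
        groups = np.array(
            ["a"] * 6 + ["b"] * 9 + ["c"] * 7 + ["d"] * 8
        )
        res = tukey_hsd(values, groups)
        oracle = tukey_oracle(values, groups)
        for _, row in res.table.iterrows():
            orow = oracle[
                (oracle.group1 == row.group1) & (oracle.group2 == row.group2)
            ].iloc[0]
            # statsmodels reports group2 - group1
            assert -row["diff"] == pytest.approx(float(orow["meandiff"]), abs=1e-8)
            assert row["p_adj"] == pytest.approx(float(orow["p-adj"]), abs=2e-4)
            assert bool(row["reject"]) == bool(orow["reject"])

    def test_shifted_group_gets_distinct_letter(self, rng):
        values = np.concatenate(
            [rng.normal(0, 0.5, 8), rng.normal(0.2, 0.5, 8), rng.normal(30.0, 0.5, 8)]
        )
        groups = np.array(["a"] * 8 + ["b"] * 8 + ["c"] * 8)
        res = tukey_hsd(values, groups)
        assert set(res.letters["c"]).isdisjoint(set(res.letters["a"]))
        assert set(res.letters["c"]).isdisjoint(set(res.letters["b"]))
        assert set(res.letters["a"]) & set(res.letters["b"])

    def test_single_group_rejected(self):
        with pytest.raises(DesignError):
            tukey_hsd(np.array([1.0, 2.0]), np.array(["a", "a"]))

    def test_letter_display_consistency(self):
        # chain a~b, b~c, a!~c: b must share a letter with both
        letters = _compact_letters(
            ["a", "b", "c"], {frozenset(("a", "b")), frozenset(("b", "c"))}
        )
        assert set(letters["a"]) & set(letters["b"])
        assert set(letters["b"]) & set(letters["c"])
        assert not set(letters["a"]) & set(letters["c"])


class TestPairedT:
    def test_alternating_differences_give_t_zero(self):
        res = paired_t(np.array([2.0, 1.0, 2.0, 1.0]), np.array([1.0, 2.0, 1.0, 2.0]))
        assert res.t == 0.0
        assert res.p == 1.0

    def test_hand_formula_oracle(self):
        bg = np.array([10.0, 20.0, 30.0, 40.0])
        res = paired_t(bg + np.array([1.0, 2.0, 3.0, 4.0]), bg)
        assert res.t == pytest.approx(2.5 / (np.std([1, 2, 3, 4], ddof=1) / 2.0), abs=1e-9)
        assert res.t == pytest.approx(3.873, abs=1e-3)
        assert res.df == 3
        assert res.p == pytest.approx(float(sps.ttest_rel(bg + [1, 2, 3, 4], bg).pvalue), abs=1e-12)

    def test_unequal_lengths_rejected(self):
        with pytest.raises(ValueError):
            paired_t(np.array([1.0, 2.0]), np.array([1.0]))

    def test_constant_nonzero_differences_rejected(self):
        with pytest.raises(DesignError):
            paired_t(np.array([2.0, 3.0, 4.0]), np.array([1.0, 2.0, 3.0]))

    def test_null_type_one_error_nominal(self):
        rng = np.random.default_rng(11)
        reps, rejections = 1000, 0
        for _ in range(reps):
            t = rng.normal(size=20)
            b = rng.normal(size=20)
            if paired_t(t, b).p < 0.05:
                rejections += 1
        assert rejections / reps == pytest.approx(0.05, abs=0.02)
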