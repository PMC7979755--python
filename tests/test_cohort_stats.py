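"""Group summaries, t-test, interaction ANOVA, correlations, TMB-H.

The t statistic is checked against the hand-evaluated pooled-variance
closed form, and the interaction F against an independent nested
least-squares oracle built directly on dummy-coded design matrices.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tmburden.cohort_stats import (
    classify_tmb_high,
    correlation_matrix,
    interaction_anova,
    student_t_test,
    summarize_groups,
)
from tmburden.tmb_calculator import TMBRecord
from tmburden.variant_core import DataError


def rec(pid, group, criterion, tmb, region="exome"):
    return TMBRecord(pid, group, region, criterion,
                     int(round(tmb * 75)), tmb)


def long_df(groups, crits, values):
    rows = []
    for (g, c), vs in zip([(g, c) for g in groups for c in crits], values):
        for v in vs:
            rows.append({"group": g, "criterion": c, "tmb": v})
    return pd.DataFrame(rows)


def oracle_interaction_f(df):
    """Nested least-squares oracle: dummy design matrices and RSS comparison."""
    g = pd.get_dummies(df["group"], drop_first=True).to_numpy(float)
    c = pd.get_dummies(df["criterion"], drop_first=True).to_numpy(float)
    inter = np.einsum("ij,ik->ijk", g, c).reshape(len(df), -1)
    y = df["tmb"].to_numpy(float)
    ones = np.ones((len(df), 1))
    X_add = np.hstack([ones, g, c])
    X_full = np.hstack([X_add, inter])

    def rss(X):
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        r = y - X @ beta
        return float(r @ r)

    df_num = inter.shape[1]
    df_den = len(df) - X_full.shape[1]
    f = ((rss(X_add) - rss(X_full)) / df_num) / (rss(X_full) / df_den)
    return f, df_num, df_den, float(stats.f.sf(f, df_num, df_den))


class TestSummarizeGroups:
    def test_mean_and_se_small_cells(self):
        records = [rec("P1", "A", "c", 4.0), rec("P2", "A", "c", 6.0),
                   rec("P3", "B", "c", 7.0)]
        s = summarize_groups(records).set_index("group")
        assert s.loc["A", "mean"] == 5.0 and s.loc["A", "se"] == 1.0
        assert s.loc["B", "mean"] == 7.0 and np.isnan(s.loc["B", "se"])

    def test_constant_cell_has_zero_se(self):
        records = [rec(f"P{i}", "A", "c", 3.0) for i in range(3)]
        s = summarize_groups(records)
        assert s["mean"].iloc[0] == 3.0 and s["se"].iloc[0] == 0.0

    def test_mean_bounded_by_extremes(self):
        rng = np.random.default_rng(0)
        vals = rng.gamma(2, 3, 40)
        records = [rec(f"P{i}", "A", "c", v) for i, v in enumerate(vals)]
        s = summarize_groups(records)
        assert vals.min() <= s["mean"].iloc[0] <= vals.max()


class TestStudentT:
    def test_hand_computed_pooled_formula(self):
        # pooled s^2 = 1, se = sqrt(2/3), t = -1 / se
        r = student_t_test([1, 2, 3], [2, 3, 4])
        assert r.df == 4
        assert r.t == pytest.approx(-1 / np.sqrt(2 / 3), abs=1e-9)
        assert r.t == pytest.approx(-1.2247, abs=1e-4)

    def test_identical_samples_give_t0_p1(self):
        r = student_t_test([1.0, 2.0, 5.0], [5.0, 1.0, 2.0])
        assert r.t == pytest.approx(0.0, abs=1e-12) and r.p == pytest.approx(1.0)

    def test_antisymmetry(self):
        a, b = [1.0, 2.5, 3.0, 8.0], [2.0, 4.0, 4.5]
        r1, r2 = student_t_test(a, b), student_t_test(b, a)
        assert r1.t == pytest.approx(-r2.t) and r1.p == pytest.approx(r2.p)

    def test_degenerate_inputs(self):
        r = student_t_test([2.0, 2.0], [2.0, 2.0])
        assert (r.t, r.p) == (0.0, 1.0)
        with pytest.raises(DataError):
            student_t_test([2.0, 2.0], [3.0, 3.0])
        with pytest.raises(DataError):
            student_t_test([1.0], [1.0, 2.0])

    def test_welch_option_differs_under_unequal_variance(self):
        rng = np.random.default_rng(1)
        a = rng.normal(0, 1, 10)
        b = rng.normal(0, 10, 50)
        pooled = student_t_test(a, b)
        welch = student_t_test(a, b, welch=True)
        assert welch.df != pooled.df


class TestInteractionAnova:
    def test_perfectly_additive_cells_give_zero_f(self):
        df = long_df(["A", "B"], ["1", "2"],
                     [[1, 2], [3, 4], [2, 3], [4, 5]])
        r = interaction_anova(df)
        assert r.f == pytest.approx(0.0, abs=1e-12)
        assert r.p == pytest.approx(1.0)
        assert r.ss_table.loc["interaction", "ss"] == pytest.approx(0.0,
                                                                    abs=1e-12)

    def test_matches_nested_lstsq_oracle_on_random_tables(self):
        rng = np.random.default_rng(7)
        for trial in range(20):
            n_g = rng.integers(2, 4)
            n_c = rng.integers(2, 5)
            values = [rng.normal(rng.normal(0, 2), 1,
                                 rng.integers(2, 7)).tolist()
                      for _ in range(n_g * n_c)]
            df = long_df([f"g{i}" for i in range(n_g)],
                         [f"c{j}" for j in range(n_c)], values)
            r = interaction_anova(df)
            f, df_num, df_den, p = oracle_interaction_f(df)
            assert r.f == pytest.approx(f, abs=1e-9, rel=1e-9)
            assert (r.df_num, r.df_den) == (df_num, df_den)
            assert r.p == pytest.approx(p, abs=1e-12, rel=1e-9)

    def test_interaction_df_and_nonnegative_ss(self):
        rng = np.random.default_rng(3)
        df = long_df(["A", "B"], ["c1", "c2", "c3", "c4"],
                     [rng.normal(0, 1, 5).tolist() for _ in range(8)])
        r = interaction_anova(df)
        assert r.df_num == (2 - 1) * (4 - 1)
        assert (r.ss_table["ss"] >= 0).all()

    def test_type_one_error_calibrated_on_independent_noise(self):
        """Additive truth + iid noise: rejection rate ~ alpha."""
        rng = np.random.default_rng(2024)
        n_rep, rejections = 300, 0
        for _ in range(n_rep):
            values = [rng.normal(g_eff + c_eff, 1.0, 6).tolist()
                      for g_eff in (0.0, 1.0) for c_eff in (0.0, 0.5, 2.0)]
            df = long_df(["A", "B"], ["c1", "c2", "c3"], values)
            if interaction_anova(df).p < 0.05 :
                rejections += 1
        rate = rejections / n_rep
        # binomial 95% band around 0.05 for n=300 is about +-0.025
        assert 0.02 <= rate <= 0.08

    def test_empty_cell_raises_with_cell_named(self):
        df = long_df(["A", "B"], ["1", "2"], [[1, 2], [3, 4], [2, 3], []])
        with pytest.raises(DataError, match="empty"):
            interaction_anova(df)


class TestCorrelationMatrix:
    def test_affine_and_sign_relations(self):
        x = np.arange(10, dtype=float)
        wide = pd.DataFrame({"a": x, "b": 2 * x + 1, "c": -x,
                             "d": np.full(10, 3.0)})
        corr = correlation_matrix(wide)
        assert corr.loc["a", "a"] == 1.0
        assert corr.loc["a", "b"] == pytest.approx(1.0)
        assert corr.loc["a", "c"] == pytest.approx(-1.0)
        assert np.isnan(corr.loc["a", "d"]) and np.isnan(corr.loc["d", "d"])
        assert np.allclose(corr.drop("d", axis=0).drop("d", axis=1),
                           corr.drop("d", axis=0).drop("d", axis=1).T)

    def test_too_few_patients_rejected(self):
        with pytest.raises(DataError):
            correlation_matrix(pd.DataFrame({"a": [1.0, 2.0]}))


class TestClassifyTmbHigh:
    def records(self):
        return [
            rec("P1", "Black", "TMB_Germline", 6.0),
            rec("P1", "Black", "TMB_DB0.01", 12.0),
            rec("P2", "White", "TMB_Germline", 10.0),   # boundary: inclusive
            rec("P2", "White", "TMB_DB0.01", 11.0),
            rec("P3", "White", "TMB_Germline", 9.99),
            rec("P3", "White", "TMB_DB0.01", 9.99),
        ]

    def test_threshold_inclusive_and_discordance(self):
        r = classify_tmb_high(self.records(), threshold=10.0)
        counts = r.counts.set_index(["group", "criterion"])["n_tmb_high"]
        assert counts[("Black", "TMB_DB0.01")] == 1
        assert counts[("White", "TMB_Germline")] == 1    # exactly 10.0 is high
        assert counts[("White", "TMB_DB0.01")] == 1
        disc = r.discordant.set_index(["group", "criterion"])["n_discordant"]
        assert disc[("Black", "TMB_DB0.01")] == 1        # 6 -> 12 flips status
        assert disc[("White", "TMB_DB0.01")] == 0        # already high at 10.0

    def test_no_discordance_when_criteria_agree(self):
        records = [rec("P1", "A", "TMB_Germline", 12.0),
                   rec("P1", "A", "TMB_DB0", 12.0)]
        r = classify_tmb_high(records)
        assert (r.discordant["n_discordant"] == 0).all()

    def test_invalid_threshold(self):
        with pytest.raises(DataError):
            classify_tmb_high(self.records(), threshold=0.0)
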