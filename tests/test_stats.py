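"""Reliability and comparison statistics against explicit formula oracles."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ivdmorph.stats import (
    DegenerateVarianceWarning,
    GroupTable,
    RaterTable,
    StatsError,
    anova_posthoc,
    cross_resolution_report,
    icc,
    paired_t,
    pearson,
)


def icc2_oracle(vals: np.ndarray) -> float:
    """ICC(2,1) from explicitly formed ANOVA sums of squares (loops, no numpy tricks)."""
    n, k = vals.shape
    grand = sum(vals[i][j] for i in range(n) for j in range(k)) / (n * k)
    row = [sum(vals[i][j] for j in range(k)) / k for i in range(n)]
    col = [sum(vals[i][j] for i in range(n)) / n for j in range(k)]
    ssr = k * sum((r - grand) ** 2 for r in row)
    ssc = n * sum((c - grand) ** 2 for c in col)
    sst = sum((vals[i][j] - grand) ** 2 for i in range(n) for j in range(k))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


def anova_f_oracle(groups):
    """One-way ANOVA F from explicit sums of squares."""
    all_vals = [v for g in groups for v in g]
    grand = sum(all_vals) / len(all_vals)
    ssb = sum(len(g) * (sum(g) / len(g) - grand) ** 2 for g in groups)
    ssw = sum((v - sum(g) / len(g)) ** 2 for g in groups for v in g)
    dfb, dfw = len(groups) - 1, len(all_vals) - len(groups)
    return (ssb / dfb) / (ssw / dfw)


class TestICC:
    def test_perfect_agreement_gives_one_with_unit_upper_bound(self):
        table = np.tile(np.array([[1.0], [2.0], [3.0], [5.0]]), (1, 3))
        res = icc(table)
        assert res.estimate == 1.0
        assert res.ci_upper == 1.0

    def test_no_subject_effect_null_is_near_zero_with_ci_covering_zero(self):
        rng = np.random.default_rng(17)
        res = icc(rng.normal(0.0, 1.0, (10, 3)))
        assert abs(res.estimate) < 0.4
        assert res.ci_lower < 0.0 < res.ci_upper

    def test_matches_brute_force_sums_of_squares_oracle(self):
        rng = np.random.default_rng(99)
        vals = rng.normal(10, 3, (6, 1)) + rng.normal(0, 1, (6, 3))
        res = icc(vals)
        assert res.estimate == pytest.approx(icc2_oracle(vals), rel=1e-12)

    def test_matches_independent_reference_implementation(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(4)
        n, k = 8, 3
        vals = rng.normal(5, 2, (n, 1)) + rng.normal(0, 1, (n, k)) + rng.normal(0, 0.5, (1, k))
        df = pd.DataFrame(
            {
                "s": np.repeat(np.arange(n), k),
                "r": np.tile(np.arange(k), n),
                "y": vals.ravel(),
            }
        )
        ref = pg.intraclass_corr(df, "s", "r", "y").set_index("Type")
        for form, label in (("icc2", "ICC(A,1)"), ("icc3", "ICC(C,1)")):
            mine = icc(vals, form=form)
            assert mine.estimate == pytest.approx(ref.loc[label, "ICC"], abs=1e-10)
            # pingouin rounds its CI to 2 decimals
            assert mine.ci_lower == pytest.approx(ref.loc[label, "CI95"][0], abs=6e-3)
            assert mine.ci_upper == pytest.approx(ref.loc[label, "CI95"][1], abs=6e-3)

    def test_zero_between_subject_variance_degenerates_to_zero(self):
        with pytest.warns(DegenerateVarianceWarning):
            res = icc(np.tile(np.array([[4.0, 4.0, 4.0]]), (5, 1)))
        assert res.estimate == 0.0
        assert res.degenerate

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(
        st.integers(0, 2**31 - 1),
        st.floats(-50, 50),
        st.floats(0.1, 20),
    )
    def test_invariant_to_shift_and_positive_rescale(self, seed, shift, scale):
        rng = np.random.default_rng(seed)
        vals = rng.normal(0, 1, (6, 3)) + rng.normal(0, 2, (6, 1))
        a = icc(vals)
        b = icc(vals * scale + shift)
        assert a.estimate == pytest.approx(b.estimate, abs=1e-9)

    def test_incomplete_table_rejected(self):
        vals = np.ones((4, 3))
        vals[1, 2] = np.nan
        with pytest.raises(StatsError, match="complete"):
            RaterTable(vals)


class TestPairedT:
    def test_identical_pairs_give_t0_p1(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        assert paired_t(x, x.copy()) == (0.0, 1.0, 0.0)

    def test_constant_shift_with_jitter_is_highly_significant(self):
        rng = np.random.default_rng(2)
        x = rng.normal(10, 1, 12)
        y = x - 5 + rng.normal(0, 1e-3, 12)
        assert paired_t(x, y).p < 0.001

    def test_matches_hand_formula(self):
        rng = np.random.default_rng(8)
        x, y = rng.normal(0, 1, 15), rng.normal(0, 1, 15)
        d = x - y
        expected_t = d.mean() / (d.std(ddof=1) / np.sqrt(len(d)))
        res = paired_t(x, y)
        assert res.t == pytest.approx(expected_t, rel=1e-12)
        assert res.mean_difference == pytest.approx(d.mean())

    def test_short_input_rejected(self):
        with pytest.raises(StatsError):
            paired_t([1.0], [2.0])


class TestPearson:
    def test_perfect_linear_relations(self):
        x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
        res = pearson(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)
        assert res.r_squared == pytest.approx(1.0)
        neg = pearson(x, -x)
        assert neg.r == pytest.approx(-1.0)
        assert neg.r_squared == pytest.approx(1.0)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(3)
        x, y = rng.normal(0, 2, 30), rng.normal(1, 3, 30)
        expected = np.sum((x - x.mean()) * (y - y.mean())) / np.sqrt(
            np.sum((x - x.mean()) ** 2) * np.sum((y - y.mean()) ** 2)
        )
        assert pearson(x, y).r == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(StatsError):
            pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestAnovaPosthoc:
    TOY = {"g1": [1.0, 2.0, 3.0], "g2": [2.0, 3.0, 4.0], "g3": [7.0, 8.0, 9.0]}

    def test_toy_groups_match_sums_of_squares_oracle(self):
        res = anova_posthoc(self.TOY)
        assert res.f == pytest.approx(anova_f_oracle(list(self.TOY.values())), rel=1e-12)

    def test_extreme_group_significant_under_both_methods(self):
        rng = np.random.default_rng(6)
        pooled_sd = 1.0
        groups = {
            "a": rng.normal(0, pooled_sd, 8),
            "b": rng.normal(0, pooled_sd, 8),
            "c": rng.normal(5 * pooled_sd, pooled_sd, 8),
        }
        for method in ("tukey_hsd", "fisher_lsd"):
            pairwise = anova_posthoc(groups, method=method).pairwise
            involving_c = pairwise[(pairwise.group_a == "c") | (pairwise.group_b == "c")]
            assert involving_c.significant.all()

    def test_tukey_p_values_dominate_lsd(self):
        rng = np.random.default_rng(12)
        groups = {c: rng.normal(i * 0.4, 1, 7) for i, c in enumerate("abcd")}
        tukey = anova_posthoc(groups, "tukey_hsd").pairwise
        lsd = anova_posthoc(groups, "fisher_lsd").pairwise
        assert np.all(tukey.p.to_numpy() >= lsd.p.to_numpy() - 1e-12)

    def test_null_simulation_rarely_finds_pairwise_significance(self):
        rng = np.random.default_rng(123)
        clean = 0
        n_rep = 1000
        for _ in range(n_rep):
            groups = {c: rng.normal(0, 1, 6) for c in "abc"}
            if not anova_posthoc(groups, "tukey_hsd").pairwise.significant.any():
                clean += 1
        assert clean / n_rep >= 0.94

    def test_single_observation_group_rejected(self):
        with pytest.raises(StatsError):
            GroupTable((("a", np.array([1.0])), ("b", np.array([1.0, 2.0]))))

    def test_group_table_from_frame(self):
        df = pd.DataFrame({"v": [1.0, 2, 3, 4, 5, 6], "age": ["d1"] * 3 + ["d10"] * 3})
        table = GroupTable.from_frame(df, "v", "age")
        assert [name for name, _ in table.groups] == ["d1", "d10"]


class TestCrossResolutionReport:
    @staticmethod
    def _metrics_frame(rng, n=8):
        return pd.DataFrame(
            {
                "sample_id": [f"s{i}" for i in range(n)],
                "total_volume_um3": rng.uniform(1e6, 4e6, n),
                "nc_pct": rng.uniform(1, 8, n),
            }
        )

    def test_identical_tables_give_unit_r2_and_p1(self):
        df = self._metrics_frame(np.random.default_rng(0))
        rep = cross_resolution_report(df, df.copy()).set_index("metric")
        assert np.allclose(rep.r_squared.to_numpy(), 1.0)
        assert np.allclose(rep.paired_t_p.to_numpy(), 1.0)

    def test_one_percent_noise_keeps_r2_above_099(self):
        rng = np.random.default_rng(5)
        a = self._metrics_frame(rng)
        b = a.copy()
        b["total_volume_um3"] *= 1 + rng.normal(0, 0.01, len(b))
        rep = cross_resolution_report(a, b).set_index("metric")
        assert rep.loc["total_volume_um3", "r_squared"] > 0.99

    def test_unmatched_ids_listed_in_error(self):
        rng = np.random.default_rng(1)
        a = self._metrics_frame(rng)
        b = self._metrics_frame(rng).iloc[:-1]
        with pytest.raises(StatsError, match="s7"):
            cross_resolution_report(a, b)
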