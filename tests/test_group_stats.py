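import itertools
import math

import numpy as np
import pytest
from scipy import stats

from parkoct import (DegenerateDataError, anova_oneway,
                     dunnett_critical_value, dunnett_vs_control, spearman,
                     summary_table, tukey_all_pairs)


class TestAnova:
    def test_two_groups_f_is_squared_pooled_t(self, rng):
        a, b = rng.normal(0, 1, 12), rng.normal(0.5, 1, 9)
        f, p = anova_oneway({"A": a, "B": b})
        t, pt = stats.ttest_ind(a, b, equal_var=True)
        assert f == pytest.approx(t ** 2)
        assert p == pytest.approx(pt)

    def test_all_identical_raises_degenerate(self):
        with pytest.raises(DegenerateDataError):
            anova_oneway({"A": [5.0, 5.0, 5.0], "B": [5.0, 5.0]})

    def test_null_pvalues_uniform(self, rng):
        """Under 5 equal-mean normal groups the ANOVA p-value is U(0,1)."""
        ps = []
        for _ in range(1000):
            groups = {k: rng.normal(size=15) for k in "ABCDE"}
            ps.append(anova_oneway(groups)[1])
        assert stats.kstest(ps, "uniform").pvalue > 0.01

    def test_nans_are_dropped(self, rng):
        a = np.r_[rng.normal(size=10), np.nan]
        b = rng.normal(size=10)
        f, _ = anova_oneway({"A": a, "B": b})
        f2, _ = anova_oneway({"A": a[:10], "B": b})
        assert f == pytest.approx(f2)


class TestDunnett:
    def test_single_comparison_reduces_to_pooled_t(self, rng):
        ctrl, trt = rng.normal(0, 1, 15), rng.normal(0.7, 1, 12)
        res = dunnett_vs_control({"Control": ctrl, "T": trt})
        _, pt = stats.ttest_ind(trt, ctrl, equal_var=True)
        assert res[0].p_adjusted == pytest.approx(pt, abs=1e-4)

    def test_critical_value_matches_published_table(self):
        """Two-sided Dunnett point, 4 comparisons, large df: table gives 2.44."""
        c = dunnett_critical_value(0.05, k=4, df=2000, n_draws=1_000_000,
                                   seed=1)
        assert c == pytest.approx(2.44, abs=0.01)

    def test_adjustment_never_anticonservative(self, rng):
        groups = {"Control": rng.normal(size=20),
                  **{k: rng.normal(size=20) for k in "BCDE"}}
        for r in dunnett_vs_control(groups):
            name = r.comparison.split(" vs ")[0]
            _, pt = stats.ttest_ind(groups[name], groups["Control"],
                                    equal_var=True)
            assert r.p_adjusted >= pt - 1e-10

    def test_group_order_invariance(self, rng):
        groups = {"Control": rng.normal(size=10), "B": rng.normal(size=8),
                  "C": rng.normal(size=12)}
        res1 = {r.comparison: r.p_adjusted
                for r in dunnett_vs_control(groups)}
        rev = dict(reversed(list(groups.items())))
        res2 = {r.comparison: r.p_adjusted for r in dunnett_vs_control(rev)}
        # the multivariate-t integrator is quasi-random: ~1e-5 jitter
        for k in res1:
            assert res1[k] == pytest.approx(res2[k], abs=1e-3)

    def test_shift_invariance(self, rng):
        groups = {"Control": rng.normal(size=10), "B": rng.normal(size=10)}
        shifted = {k: v + 100.0 for k, v in groups.items()}
        p1 = dunnett_vs_control(groups)[0].p_adjusted
        p2 = dunnett_vs_control(shifted)[0].p_adjusted
        assert p1 == pytest.approx(p2, abs=1e-3)

    def test_missing_control_raises(self, rng):
        with pytest.raises(ValueError, match="control"):
            dunnett_vs_control({"A": rng.normal(size=5),
                                "B": rng.normal(size=5)})

    def test_tiny_group_marked_non_estimable(self, rng):
        groups = {"Control": rng.normal(size=10), "B": rng.normal(size=10),
                  "C": [1.0]}
        res = {r.comparison: r for r in dunnett_vs_control(groups)}
        assert math.isnan(res["C vs Control"].p_adjusted)
        assert "non-estimable" in res["C vs Control"].note
        assert not math.isnan(res["B vs Control"].p_adjusted)


class TestTukey:
    def test_two_groups_reduce_to_pooled_t(self, rng):
        a, b = rng.normal(0, 1, 10), rng.normal(1, 1, 14)
        res = tukey_all_pairs({"A": a, "B": b})
        _, pt = stats.ttest_ind(a, b, equal_var=True)
        assert res[0].p_adjusted == pytest.approx(pt, abs=1e-6)

    def test_separated_group_all_pairs_significant(self, rng):
        groups = {k: rng.normal(size=15) for k in "ABCD"}
        groups["E"] = rng.normal(size=15) + 10.0
        res = tukey_all_pairs(groups)
        for r in res:
            if "E" in r.comparison:
                assert r.significant

    def test_adjustment_never_anticonservative(self, rng):
        groups = {k: rng.normal(size=12) for k in "ABC"}
        for r in tukey_all_pairs(groups):
            a, b = r.comparison.split(" vs ")
            _, pt = stats.ttest_ind(groups[a], groups[b], equal_var=True)
            assert r.p_adjusted >= pt - 1e-10


class TestSpearman:
    def test_monotone_increasing_is_one(self):
        x = [1.0, 2.0, 3.0, 4.0, 5.0]
        rho, _ = spearman(x, np.exp(x))
        assert rho == pytest.approx(1.0)

    def test_reversal_is_minus_one(self):
        x = np.arange(6.0)
        rho, _ = spearman(x, -x)
        assert rho == pytest.approx(-1.0)

    def test_tied_data_matches_brute_force_ranks(self, rng):
        """Average-rank rho against an independent rank computation, n<=8."""
        def brute_rho(x, y):
            def avg_ranks(v):
                order = sorted(range(len(v)), key=lambda i: v[i])
                ranks = [0.0] * len(v)
                i = 0
                while i < len(v):
                    j = i
                    while j + 1 < len(v) and v[order[j + 1]] == v[order[i]]:
                        j += 1
                    for k in range(i, j + 1):
                        ranks[order[k]] = (i + j) / 2 + 1
                    i = j + 1
                return ranks
            rx, ry = avg_ranks(list(x)), avg_ranks(list(y))
            mx, my = sum(rx) / len(rx), sum(ry) / len(ry)
            num = sum((a - mx) * (b - my) for a, b in zip(rx, ry))
            den = math.sqrt(sum((a - mx) ** 2 for a in rx)
                            * sum((b - my) ** 2 for b in ry))
            return num / den

        for _ in range(25):
            n = int(rng.integers(4, 9))
            x = rng.integers(0, 4, size=n).astype(float)
            y = rng.integers(0, 4, size=n).astype(float)
            if len(set(x)) < 2 or len(set(y)) < 2:
                continue
            rho, _ = spearman(x, y)
            assert rho == pytest.approx(brute_rho(x, y), abs=1e-12)

    def test_exact_permutation_p_small_n(self):
        """n=4 exact two-sided p for perfect concordance is 2/4! = 1/12."""
        rho, p = spearman([1, 2, 3, 4], [10, 20, 30, 40])
        assert rho == 1.0
        assert p == pytest.approx(2 / 24)

    def test_large_n_uses_t_approximation(self, rng):
        x = rng.normal(size=30)
        y = x + rng.normal(size=30)
        rho, p = spearman(x, y)
        t = rho * math.sqrt(28 / (1 - rho ** 2))
        assert p == pytest.approx(2 * stats.t.sf(abs(t), 28))

    def test_missing_pairs_removed_and_min_n_enforced(self):
        rho, _ = spearman([1, 2, 3, np.nan], [1, 2, 3, 4])
        assert rho == pytest.approx(1.0)
        with pytest.raises(ValueError):
            spearman([1, np.nan], [1, 2])


class TestSummaryTable:
    def test_degenerate_cohort_means_exact_no_flags(self, degenerate_features):
        s = summary_table(degenerate_features,
                          parameters=("onl_central", "mt_total"))
        row = s.set_index("parameter").loc["onl_central"]
        assert row["PSP_mean"] == pytest.approx(93.92)
        assert row["PD_mean"] == pytest.approx(105.8)
        assert row["Control_mean"] == pytest.approx(105.1)
        for g in ("PD", "MSA", "CBS", "PSP"):
            assert row[f"{g}_sig"] == False  # noqa: E712
        assert "zero variance" in row["note"]

    def test_control_only_cohort_reports_means_without_comparisons(
            self, study_features):
        ctrl = study_features.query("group == 'Control'")
        s = summary_table(ctrl, parameters=("onl_central",))
        row = s.iloc[0]
        assert not math.isnan(row["Control_mean"])
        assert "no comparisons" in row["note"]

    def test_flags_equal_p_below_alpha(self, study_features):
        s = summary_table(study_features, parameters=("mt_total", "mean_inl",
                                                      "onl_central"))
        for _, row in s.iterrows():
            for g in ("PD", "MSA", "CBS", "PSP"):
                p = row.get(f"{g}_p")
                if isinstance(p, float) and not math.isnan(p):
                    assert row[f"{g}_sig"] == (p < 0.05)

    def test_eye_handling_recorded(self, study_features):
        s = summary_table(study_features, parameters=("mt_total",),
                          eye_handling="subject_means")
        assert s.attrs["eye_handling"] == "subject_means"
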