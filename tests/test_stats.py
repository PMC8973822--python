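import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from celloc import stats
from celloc.stats import WelchOneWay, significance_stars


def make_groups(seed=0, ns=(31, 33, 30), means=(0.0, 0.3, -0.2),
                sds=(1.0, 2.0, 0.5)):
    rng = np.random.default_rng(seed)
    return [rng.normal(m, s, n) for n, m, s in zip(ns, means, sds)]


def records_frame(groups, names, comarker="PM"):
    rows = []
    for name, g in zip(names, groups):
        for i, v in enumerate(g):
            rows.append({"image_id": f"{name}_{i // 5}", "cell_label": i,
                         "genotype_label": name, "comarker": comarker,
                         "pearson_r": v, "n_pixels": 900,
                         "provenance": "auto"})
    return pd.DataFrame(rows)


class TestSummaries:
    def test_odd_n_order_statistics(self):
        df = records_frame([np.array([1.0, 2, 3, 4, 5])], ["g"])
        (s,) = stats.summarize_groups(df)
        assert (s.median, s.q1, s.q3) == (3.0, 2.0, 4.0)
        assert (s.min, s.max, s.n) == (1.0, 5.0, 5)

    def test_single_value_collapses(self):
        df = records_frame([np.array([0.5])], ["g"])
        (s,) = stats.summarize_groups(df)
        assert s.min == s.q1 == s.median == s.q3 == s.max == 0.5

    def test_matches_sorted_array_oracle(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 30)
        df = records_frame([x], ["g"])
        (s,) = stats.summarize_groups(df)
        # linear-interpolation quartiles computed long-hand on sorted values
        xs = np.sort(x)

        def quantile(q):
            pos = q * (len(xs) - 1)
            lo = int(np.floor(pos))
            frac = pos - lo
            return xs[lo] * (1 - frac) + xs[min(lo + 1, len(xs) - 1)] * frac

        assert s.q1 == pytest.approx(quantile(0.25), rel=1e-12)
        assert s.median == pytest.approx(quantile(0.5), rel=1e-12)
        assert s.q3 == pytest.approx(quantile(0.75), rel=1e-12)

    def test_invariants_hold(self):
        for s in stats.summarize_groups(records_frame(make_groups(),
                                                      ["a", "b", "c"])):
            assert s.min <= s.q1 <= s.median <= s.q3 <= s.max

    def test_empty_input_empty_output(self):
        assert stats.summarize_groups(records_frame([], [])) == []


class TestWelchAnova:
    def test_equal_means_give_zero_F(self):
        groups = [np.array([-1.0, 0, 1]), np.array([-2.0, 0, 2]),
                  np.array([-3.0, 0, 3])]
        res = stats.welch_anova(groups)
        assert res.F == pytest.approx(0.0, abs=1e-15)
        assert res.p == pytest.approx(1.0)
        assert res.df1 == 2

    def test_k2_reduces_to_welch_t(self):
        g = make_groups()[:2]
        res = stats.welch_anova(g)
        t = sps.ttest_ind(*g, equal_var=False)
        assert res.F == pytest.approx(t.statistic ** 2, rel=1e-12)
        assert res.p == pytest.approx(t.pvalue, rel=1e-10)
        assert res.df2 == pytest.approx(t.df, rel=1e-12)

    def test_matches_independent_implementation(self):
        """Seeded three-group fixture against pingouin's Welch ANOVA."""
        pg = pytest.importorskip("pingouin")
        groups = make_groups(seed=3)
        df = pd.DataFrame({
            "y": np.concatenate(groups),
            "g": np.repeat(["a", "b", "c"], [len(g) for g in groups])})
        ref = pg.welch_anova(df, dv="y", between="g").iloc[0]
        res = stats.welch_anova(groups)
        assert res.F == pytest.approx(ref["F"], rel=1e-10)
        assert res.p == pytest.approx(ref["p_unc"], rel=1e-10)
        assert res.df2 == pytest.approx(ref["ddof2"], rel=1e-10)

    def test_scale_location_invariance(self):
        groups = make_groups(seed=4)
        r0 = stats.welch_anova(groups)
        r1 = stats.welch_anova([3.2 * g + 17.0 for g in groups])
        assert r1.F == pytest.approx(r0.F, rel=1e-11)
        assert r1.p == pytest.approx(r0.p, rel=1e-10)
        assert r1.df2 == pytest.approx(r0.df2, rel=1e-11)

    def test_zero_variance_group_identified(self):
        groups = [np.array([1.0, 1.0, 1.0]), np.array([0.0, 1.0, 2.0])]
        with pytest.raises(ValueError, match="group 0"):
            stats.welch_anova(groups)

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            stats.welch_anova([np.array([1.0, 2.0])])


class TestGamesHowell:
    def test_identical_samples_not_significant(self):
        x = np.array([0.1, 0.5, 0.9, 0.3, 0.7])
        (c,) = stats.games_howell([x, x.copy()], ["a", "b"])
        assert c.t == 0.0
        assert c.p_adj == pytest.approx(1.0)
        assert c.significance_stars == "ns"

    def test_k2_reduces_to_welch_t(self):
        g = make_groups()[:2]
        (c,) = stats.games_howell(g, ["a", "b"])
        t = sps.ttest_ind(*g, equal_var=False)
        assert c.p_adj == pytest.approx(t.pvalue, rel=1e-6)
        assert c.df == pytest.approx(t.df, rel=1e-12)
        assert c.q == pytest.approx(np.sqrt(2) * abs(t.statistic), rel=1e-12)

    def test_matches_independent_implementation(self):
        pg = pytest.importorskip("pingouin")
        groups = make_groups(seed=5)
        df = pd.DataFrame({
            "y": np.concatenate(groups),
            "g": np.repeat(["a", "b", "c"], [len(g) for g in groups])})
        ref = pg.pairwise_gameshowell(df, dv="y", between="g")
        ours = stats.games_howell(groups, ["a", "b", "c"])
        for c, (_, row) in zip(ours, ref.iterrows()):
            assert (c.group_i, c.group_j) == (row["A"], row["B"])
            assert c.p_adj == pytest.approx(row["pval"], rel=1e-6)
            assert c.df == pytest.approx(row["df"], rel=1e-9)

    def test_adjustment_conservative_beyond_two_groups(self):
        groups = make_groups(seed=6)
        ours = stats.games_howell(groups, ["a", "b", "c"])
        for c in ours:
            i = ["a", "b", "c"].index(c.group_i)
            j = ["a", "b", "c"].index(c.group_j)
            t = sps.ttest_ind(groups[i], groups[j], equal_var=False)
            assert c.p_adj >= t.pvalue - 1e-12

    def test_reference_mode_filters_pairs(self):
        groups = make_groups(seed=7)
        vs_ref = stats.games_howell(groups, ["a", "b", "c"], reference="b")
        assert {(c.group_i, c.group_j) for c in vs_ref} == {("b", "a"),
                                                            ("b", "c")}

    def test_absent_reference_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            stats.games_howell(make_groups(), ["a", "b", "c"], reference="z")

    def test_stars_thresholds(self):
        assert significance_stars(0.2) == "ns"
        assert significance_stars(0.04) == "*"
        assert significance_stars(0.009) == "**"
        assert significance_stars(0.0009) == "***"


class TestCompareToWt:
    def test_single_genotype_rejected(self):
        df = records_frame([np.random.default_rng(0).normal(0, 1, 35)], ["WT"])
        with pytest.raises(ValueError):
            stats.compare_to_wt(df, "WT")

    def test_min_cells_gate_lists_offenders(self):
        groups = make_groups(ns=(35, 10, 40))
        df = records_frame(groups, ["WT", "tiny", "m1"])
        with pytest.raises(ValueError, match="tiny"):
            stats.compare_to_wt(df, "WT")
        out = stats.compare_to_wt(df, "WT", enforce_min_cells=False)
        assert "PM" in out

    def test_absent_wt_rejected(self):
        df = records_frame(make_groups(), ["a", "b", "c"])
        with pytest.raises(ValueError, match="absent"):
            stats.compare_to_wt(df, "WT", enforce_min_cells=False)

    def test_comparisons_are_vs_wt_only(self):
        df = records_frame(make_groups(ns=(35, 34, 33)), ["WT", "m1", "m2"])
        out = stats.compare_to_wt(df, "WT")
        anova, comparisons = out["PM"]
        assert anova.k == 3
        assert {c.group_i for c in comparisons} == {"WT"}
        assert len(comparisons) == 2


class TestModelObjects:
    def test_fit_returns_results_with_summary(self):
        df = records_frame(make_groups(), ["WT", "m1", "m2"])
        model = WelchOneWay.from_dataframe(df, value="pearson_r",
                                           group="genotype_label")
        res = model.fit(reference="WT")
        assert res.anova.k == 3
        text = res.summary()
        assert "Welch one-way ANOVA" in text and "Games-Howell" in text
        assert set(res.posthoc_frame["group_i"]) == {"WT"}
        assert set(res.group_means().index) == {"WT", "m1", "m2"}
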