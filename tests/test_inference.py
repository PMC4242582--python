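"""Statistical battery: site-effect LRT, ANOVA/Tukey, correlations, OLS."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from limosa.benthos import cores_to_wide
from limosa.fieldobs import sex_ratio_table
from limosa.inference import (
    hypothesis_panel,
    linear_fit,
    one_way_anova,
    pearson_test,
    site_effect_test,
    tukey_hsd,
)


def sessions_frame(site_probs, n_sessions=10, n_birds=100, seed=0):
    rng = np.random.default_rng(seed)
    rows = []
    for site, p in site_probs.items():
        nf = rng.binomial(n_birds, p, size=n_sessions)
        for j, f in enumerate(nf):
            rows.append(
                {"site": site, "session_id": f"{site}-{j}", "n_male": n_birds - f,
                 "n_female": int(f)}
            )
    return pd.DataFrame(rows)


class TestSiteEffect:
    def test_identical_sessions_give_null_result(self):
        df = pd.DataFrame(
            {"site": list("AABB"), "session_id": list("abcd"),
             "n_male": [50] * 4, "n_female": [50] * 4}
        )
        res = site_effect_test(df)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_strong_site_effect_detected(self):
        probs = {s: p for s, p in zip("ABCDEF", [0.2, 0.3, 0.4, 0.6, 0.7, 0.8])}
        res = site_effect_test(sessions_frame(probs, seed=5))
        assert res.df == 5
        assert res.p_value < 0.001

    def test_chi2_nonnegative_and_relabel_invariant(self):
        probs = {s: 0.5 for s in "ABCDEF"}
        df = sessions_frame(probs, seed=9)
        res = site_effect_test(df)
        relabeled = df.assign(site=df["site"].map(lambda s: s * 2))
        res2 = site_effect_test(relabeled)
        assert res.statistic >= 0.0
        assert res.statistic == pytest.approx(res2.statistic, rel=1e-12)

    def test_single_site_refused(self):
        df = sessions_frame({"A": 0.5})
        with pytest.raises(ValueError):
            site_effect_test(df)


class TestAnova:
    def test_identical_groups_f_zero(self):
        res = one_way_anova([1, 2, 3, 1, 2, 3], list("AAABBB"))
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_two_groups_equal_squared_t(self, rng):
        x = rng.normal(0.0, 1.0, 12)
        y = rng.normal(0.5, 1.0, 9)
        res = one_way_anova(np.concatenate([x, y]), ["a"] * 12 + ["b"] * 9)
        t, _ = stats.ttest_ind(x, y)
        assert res.statistic == pytest.approx(t**2, abs=1e-10)

    def test_matches_hand_computed_sums_of_squares(self, rng):
        vals = rng.normal(0.0, 1.0, 60)
        vals[:10] += 1.5
        groups = np.repeat(list("ABCDEF"), 10)
        res = one_way_anova(vals, groups)
        # independent oracle: explicit between/within decomposition
        grand = vals.mean()
        ssb = sum(10 * (vals[groups == g].mean() - grand) ** 2 for g in "ABCDEF")
        ssw = sum(((vals[groups == g] - vals[groups == g].mean()) ** 2).sum() for g in "ABCDEF")
        f_oracle = (ssb / 5) / (ssw / 54)
        assert res.statistic == pytest.approx(f_oracle, abs=1e-10)
        assert res.df == (5, 54)

    def test_all_identical_values_degenerate_path(self):
        res = one_way_anova([2.0] * 8, list("AABBCCDD"))
        assert res.statistic == 0.0 and res.p_value == 1.0


class TestTukey:
    def test_identical_groups_all_null(self, rng):
        base = rng.normal(0.0, 1.0, 10)
        vals = np.tile(base, 3)
        out = tukey_hsd(vals, np.repeat(list("ABC"), 10))
        assert (out["p_adj"] > 0.95).all()
        assert not out["significant"].any()

    def test_single_shifted_group_flagged(self, rng):
        vals = rng.normal(0.0, 1.0, 60)
        groups = np.repeat(list("ABCDEF"), 10)
        vals[groups == "D"] += 4.0
        out = tukey_hsd(vals, groups)
        hits = out[out["significant"]]
        assert len(hits) == 5
        assert ((hits["group1"] == "D") | (hits["group2"] == "D")).all()

    def test_adjusted_p_not_below_pairwise_t(self, rng):
        vals = rng.normal(0.0, 1.0, 40)
        vals[10:20] += 1.0
        groups = np.repeat(list("ABCD"), 10)
        out = tukey_hsd(vals, groups)
        for _, row in out.iterrows():
            a = vals[groups == row["group1"]]
            b = vals[groups == row["group2"]]
            _, p_raw = stats.ttest_ind(a, b)
            assert row["p_adj"] >= p_raw - 1e-10

    def test_matches_scipy_reference_unbalanced(self, rng):
        groups = ["A"] * 8 + ["B"] * 12 + ["C"] * 10
        vals = rng.normal(0.0, 1.0, 30)
        vals[8:20] += 1.2
        ours = tukey_hsd(vals, groups).set_index(["group1", "group2"])
        ref = stats.tukey_hsd(vals[:8], vals[8:20], vals[20:])
        for (i, gi), (j, gj) in [((0, "A"), (1, "B")), ((0, "A"), (2, "C")), ((1, "B"), (2, "C"))]:
            assert ours.loc[(gi, gj), "p_adj"] == pytest.approx(
                ref.pvalue[i, j], abs=1e-6
            )


class TestPearson:
    def test_perfect_lines(self):
        x = np.arange(5.0)
        assert pearson_test(x, 2 * x + 1).statistic == pytest.approx(1.0)
        assert pearson_test(x, -x).statistic == pytest.approx(-1.0)

    def test_six_point_worked_example(self):
        res = pearson_test([1, 2, 3, 4, 5, 6], [2, 1, 4, 3, 6, 5])
        assert res.statistic == pytest.approx(0.8285714285714285, abs=1e-12)
        assert res.df == 4

    def test_symmetric_and_affine_invariant(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        r1 = pearson_test(x, y).statistic
        assert pearson_test(y, x).statistic == pytest.approx(r1, rel=1e-12)
        assert pearson_test(3 * x - 7, y).statistic == pytest.approx(r1, rel=1e-12)
        assert pearson_test(-2 * x, y).statistic == pytest.approx(-r1, rel=1e-12)

    def test_zero_variance_is_an_error(self):
        with pytest.raises(ValueError):
            pearson_test([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestLinearFit:
    def test_exact_line(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0, 4.0], "y": [2.0, 4.0, 6.0, 8.0]})
        fit = linear_fit(df, "y ~ x")
        assert fit.r_squared == pytest.approx(1.0)
        assert fit.f_test.p_value < 1e-10 or fit.f_test.p_value == 0.0

    def test_orthogonal_response(self):
        df = pd.DataFrame({"x": [-1.0, 1.0, -1.0, 1.0], "y": [0.0, 0.0, 1.0, 1.0]})
        fit = linear_fit(df, "y ~ x")
        assert fit.params["x"] == pytest.approx(0.0, abs=1e-12)
        assert fit.r_squared == pytest.approx(0.0, abs=1e-12)

    def test_singular_design_rejected(self):
        df = pd.DataFrame({"x": [1.0, 2.0, 3.0], "z": [2.0, 4.0, 6.0], "y": [1.0, 2.0, 1.0]})
        with pytest.raises(ValueError, match="singular"):
            linear_fit(df, "y ~ x + z")


class TestHypothesisPanel:
    @staticmethod
    def panel_for(dataset, sample_level=True):
        wide = cores_to_wide(dataset["cores"])
        ratios = sex_ratio_table(dataset["counts"])
        site_cost = (
            dataset["costs"].groupby("site", as_index=False)["seasonal_total_kj"].mean()
            .rename(columns={"seasonal_total_kj": "cost_kj"})
        )
        tab = (
            dataset["benthos_summary"]
            .merge(ratios[["site", "pct_female"]], on="site")
            .merge(site_cost, on="site")
        )
        return hypothesis_panel(tab, wide, sample_level=sample_level)

    def test_four_results_with_expected_dfs(self, rp_dataset):
        panel = self.panel_for(rp_dataset)
        assert set(panel) == {"cost", "bottom", "top", "bottom_pct"}
        assert panel["cost"].df == 4 and panel["bottom_pct"].df == 4
        assert panel["bottom"].df == 58  # 60 cores, sample-level pairing

    def test_site_level_variant(self, rp_dataset):
        panel = self.panel_for(rp_dataset, sample_level=False)
        assert panel["bottom"].df == 4 and panel["top"].df == 4

    def test_constant_female_share_flagged_not_crashed(self, rp_dataset):
        wide = cores_to_wide(rp_dataset["cores"])
        tab = pd.DataFrame(
            {
                "site": rp_dataset["sites"]["site"],
                "pct_female": 50.0,
                "cost_kj": np.linspace(1.0, 2.0, 6),
                "bottom_pct_mean": np.linspace(60, 90, 6),
            }
        )
        panel = hypothesis_panel(tab, wide)
        for res in panel.values():
            assert "[undefined]" in res.method
            assert np.isnan(res.statistic)

    def test_missing_columns_rejected(self, rp_dataset):
        wide = cores_to_wide(rp_dataset["cores"])
        with pytest.raises(ValueError, match="missing"):
            hypothesis_panel(pd.DataFrame({"site": ["A"]}), wide)
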