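"""Expression statistics: baselines, fold changes, trends, ANOVA, r^2 windows."""

import numpy as np
import pandas as pd
import pytest

from yeastnuc.expression import (
    ExpressionTable,
    baseline_expression,
    binned_group_analysis,
    count_significant_movers,
    log2_fold_change,
    position_trend,
    resampled_correlation_comparison,
    sequential_anova_cen,
    windowed_r2_comparison,
)


def table_from_dict(data: dict[str, dict[str, float]]) -> ExpressionTable:
    """Build a table from {strain: {gene: value}} with n replicates per strain."""
    cols, meta = {}, []
    for strain, genes in data.items():
        for rep, scale in enumerate((1.0, 1.0, 1.0, 1.0), start=1):
            name = f"{strain}_{rep}"
            cols[name] = {g: v * scale for g, v in genes.items()}
            meta.append({"sample": name, "strain": strain, "replicate": rep})
    values = pd.DataFrame(cols)
    return ExpressionTable(values=values, samples=pd.DataFrame(meta).set_index("sample"))


class TestBaseline:
    def test_single_eligible_strain_uses_its_median(self):
        t = table_from_dict({"WT": {"g": 10.0}, "A": {"g": 30.0}, "B": {"g": 50.0}})
        delta = pd.DataFrame({"A": {"g": 0.5}, "B": {"g": 10.0}})  # only A (and WT) eligible
        base = baseline_expression(t, delta)
        assert base["g"] == pytest.approx(np.median([10.0, 30.0]))

    def test_median_across_eligible_strains(self):
        t = table_from_dict({"WT": {"g": 10.0}, "A": {"g": 20.0}, "B": {"g": 30.0}})
        delta = pd.DataFrame({"A": {"g": 0.0}, "B": {"g": 0.0}})
        assert baseline_expression(t, delta)["g"] == 20.0

    def test_fallback_to_wild_type_when_none_eligible(self):
        t = table_from_dict({"WT": {"g": 12.0}, "A": {"g": 99.0}})
        delta = pd.DataFrame({"A": {"g": 30.0}})
        base = baseline_expression(t, delta)
        # WT itself always counts as delta = 0, so WT median is the floor
        assert base["g"] == 12.0

    def test_nested_median_matches_brute_force(self):
        rng = np.random.default_rng(0)
        strains = ["WT", "A", "B", "C"]
        genes = [f"g{i}" for i in range(30)]
        cols, meta = {}, []
        for s in strains:
            for rep in range(1, 5):
                cols[f"{s}_{rep}"] = rng.lognormal(2, 1, size=30)
                meta.append({"sample": f"{s}_{rep}", "strain": s, "replicate": rep})
        t = ExpressionTable(
            values=pd.DataFrame(cols, index=genes),
            samples=pd.DataFrame(meta).set_index("sample"),
        )
        delta = pd.DataFrame(
            rng.uniform(-3, 3, size=(30, 3)), index=genes, columns=["A", "B", "C"]
        )
        base = baseline_expression(t, delta)
        for g in genes:
            meds = []
            for s in strains:
                d = 0.0 if s == "WT" else delta.loc[g, s]
                if abs(d) < 1.0:
                    meds.append(np.median([cols[f"{s}_{r}"][genes.index(g)] for r in range(1, 5)]))
            expect = np.median(meds) if meds else np.median(
                [cols[f"WT_{r}"][genes.index(g)] for r in range(1, 5)]
            )
            assert base[g] == pytest.approx(expect)


class TestFoldChange:
    def test_equal_to_baseline_gives_zero(self):
        t = table_from_dict({"WT": {"g": 10.0}, "A": {"g": 10.0}})
        lfc = log2_fold_change(t, pd.Series({"g": 10.0}))
        assert lfc.loc["g", "A"] == 0.0

    def test_doubling_gives_one(self):
        t = table_from_dict({"WT": {"g": 10.0}, "A": {"g": 20.0}})
        lfc = log2_fold_change(t, pd.Series({"g": 10.0}), pseudocount=0.0)
        assert lfc.loc["g", "A"] == pytest.approx(1.0)

    def test_pseudocount_policy_for_zero_expression(self):
        t = table_from_dict({"WT": {"g": 10.0}, "A": {"g": 0.0}})
        lfc = log2_fold_change(t, pd.Series({"g": 10.0}), pseudocount=0.1)
        assert lfc.loc["g", "A"] == pytest.approx(np.log2(0.1 / 10.1))


class TestPositionTrend:
    def test_flat_null_stays_near_zero(self):
        rng = np.random.default_rng(1)
        delta = rng.uniform(-30, 0, size=2000)
        lfc = rng.normal(0.0, 0.2, size=2000)
        tr = position_trend(delta, lfc)
        se = 0.2 / np.sqrt(100)  # window of 100 points
        assert np.abs(tr["lfc_trend"]).max() < 4 * se

    def test_recovers_injected_linear_relation(self):
        rng = np.random.default_rng(2)
        delta = rng.uniform(-30, 0, size=3000)
        lfc = np.log2(1 - 0.01 * delta) + rng.normal(0, 0.1, size=3000)
        tr = position_trend(delta, lfc)
        near = tr[(tr.delta_pp > -26) & (tr.delta_pp < -24)]
        assert near["lfc_trend"].mean() == pytest.approx(np.log2(1.25), abs=0.05)

    def test_small_sample_warns_and_shrinks(self):
        with pytest.warns(UserWarning, match="window shrunk"):
            position_trend(np.arange(10.0), np.zeros(10))


class TestBinnedGroups:
    def test_identical_reference_group_not_significant(self):
        rng = np.random.default_rng(3)
        delta = np.concatenate([rng.uniform(-4, -1.5, 200), rng.uniform(-0.9, 0.9, 200)])
        lfc = rng.normal(0, 0.1, 400)  # no real effect anywhere
        summary, contrasts = binned_group_analysis(delta, lfc)
        rej = contrasts["reject"].astype(str)
        assert (rej == "False").all()

    def test_displaced_group_detected(self):
        rng = np.random.default_rng(4)
        delta = np.concatenate([rng.uniform(-30, -16, 300), rng.uniform(-0.9, 0.9, 300)])
        lfc = np.where(delta < -15, 0.3, 0.0) + rng.normal(0, 0.1, 600)
        summary, contrasts = binned_group_analysis(delta, lfc)
        assert summary.loc["< -15 pp", "mean"] == pytest.approx(0.3, abs=0.05)
        row = contrasts[
            (contrasts["group1"] == "< -15 pp") | (contrasts["group2"] == "< -15 pp")
        ].iloc[0]
        assert str(row["reject"]) == "True"
        assert summary.attrs["anova_p"] < 1e-6


class TestMoverCounts:
    def test_empty_input_counts_zero(self):
        t = table_from_dict({"WT": {"g": 1.0}, "A": {"g": 1.0}})
        res = count_significant_movers(t, pd.DataFrame({"A": {"g": 0.0}}))
        assert res["n_movers"] == 0 and res["n_significant"] == 0

    def test_null_calibration_near_alpha(self):
        # movers with no true expression change: ~5% false positives
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(1000)]
        cols, meta = {}, []
        for s in ("WT", "A"):
            for rep in range(1, 5):
                cols[f"{s}_{rep}"] = pd.Series(rng.lognormal(3, 0.2, 1000), index=genes)
                meta.append({"sample": f"{s}_{rep}", "strain": s, "replicate": rep})
        t = ExpressionTable(
            values=pd.DataFrame(cols), samples=pd.DataFrame(meta).set_index("sample")
        )
        delta = pd.DataFrame({"A": pd.Series(-10.0, index=genes)})
        res = count_significant_movers(t, delta)
        assert res["n_tested"] == 1000
        rate = res["n_significant"] / res["n_tested"]
        # 3 binomial SEs around 0.05 (Welch-t on 4v4 log-normals is near-exact)
        se = np.sqrt(0.05 * 0.95 / 1000)
        assert abs(rate - 0.05) < 4 * se

    def test_power_for_two_sd_effects(self):
        # a 2-SD true effect, 4 replicates against a multi-strain baseline
        # pool (as in the real analysis, where many strains are eligible)
        rng = np.random.default_rng(6)
        genes = [f"g{i}" for i in range(300)]
        sd = 0.25
        cols, meta = {}, []
        mu = rng.normal(3, 1, 300)
        for s in ("WT", "B", "C", "A"):
            shift = 2.5 * sd if s == "A" else 0.0
            for rep in range(1, 5):
                cols[f"{s}_{rep}"] = pd.Series(
                    2 ** (mu + shift + rng.normal(0, sd, 300)), index=genes
                )
                meta.append({"sample": f"{s}_{rep}", "strain": s, "replicate": rep})
        t = ExpressionTable(
            values=pd.DataFrame(cols), samples=pd.DataFrame(meta).set_index("sample")
        )
        delta = pd.DataFrame(
            {
                "A": pd.Series(-10.0, index=genes),
                "B": pd.Series(0.0, index=genes),
                "C": pd.Series(0.0, index=genes),
            }
        )
        res = count_significant_movers(t, delta)
        assert res["n_tested"] == 300
        assert res["n_significant"] / res["n_tested"] > 0.8

    def test_single_replicate_skipped(self):
        cols = {"WT_1": {"g": 5.0}, "WT_2": {"g": 6.0}, "A_1": {"g": 50.0}}
        meta = pd.DataFrame(
            [
                {"sample": "WT_1", "strain": "WT", "replicate": 1},
                {"sample": "WT_2", "strain": "WT", "replicate": 2},
                {"sample": "A_1", "strain": "A", "replicate": 1},
            ]
        ).set_index("sample")
        t = ExpressionTable(values=pd.DataFrame(cols), samples=meta)
        res = count_significant_movers(t, pd.DataFrame({"A": {"g": -10.0}}))
        assert res["n_skipped"] == 1 and res["n_significant"] == 0


class TestSequentialAnova:
    @staticmethod
    def _frame(n=600, seed=7, response="delta_only"):
        rng = np.random.default_rng(seed)
        delta = rng.uniform(-30, 0, n)
        wt_expr = rng.normal(5, 2, n)
        cen_dist = rng.uniform(0, 400, n)
        cen_lost = rng.random(n) < 0.4
        if response == "delta_only":
            lfc = -0.01 * delta * np.log2(np.e) + rng.normal(0, 0.1, n)
        elif response == "zero":
            lfc = np.zeros(n)
        else:
            raise ValueError(response)
        return pd.DataFrame(
            {
                "lfc": lfc,
                "delta_pp": delta,
                "wt_expr": wt_expr,
                "cen_dist_kb": cen_dist,
                "cen_lost": cen_lost,
            }
        )

    def test_cen_terms_not_significant_when_response_is_delta_only(self):
        out = sequential_anova_cen(self._frame())
        tbl = out["all"]
        assert tbl.loc["delta_pp", "PR(>F)"] < 1e-10
        for term in ("cen_dist_kb", "cen_lost", "cen_dist_kb:cen_lost"):
            assert tbl.loc[term, "PR(>F)"] > 0.01

    def test_subsets_by_cen_distance(self):
        out = sequential_anova_cen(self._frame(n=2000))
        assert set(out) == {"all", "<=200kb", "<=100kb", "<=75kb", "<=15kb"}
        assert out["<=200kb"].loc["delta_pp", "PR(>F)"] < 1e-6

    def test_orthogonal_covariates_sequential_equals_marginal(self):
        # orthogonal design: sequential SS equals the single-predictor SS
        rng = np.random.default_rng(8)
        n = 512
        a = np.repeat([-1.0, 1.0], n // 2)
        b = np.tile([-1.0, 1.0], n // 2)
        y = 0.5 * a + 0.25 * b + rng.normal(0, 0.3, n)
        df = pd.DataFrame(
            {
                "lfc": y,
                "delta_pp": a,
                "wt_expr": b,
                "cen_dist_kb": np.zeros(n),
                "cen_lost": np.zeros(n, dtype=bool),
            }
        )
        import statsmodels.api as sm
        import statsmodels.formula.api as smf

        seq = sm.stats.anova_lm(smf.ols("lfc ~ delta_pp + wt_expr", data=df).fit(), typ=1)
        marg_a = sm.stats.anova_lm(smf.ols("lfc ~ delta_pp", data=df).fit(), typ=1)
        assert seq.loc["delta_pp", "sum_sq"] == pytest.approx(
            marg_a.loc["delta_pp", "sum_sq"]
        )

    def test_zero_variance_response(self):
        out = sequential_anova_cen(self._frame(response="zero"))
        tbl = out["all"]
        assert (tbl["F"].fillna(0.0) == 0.0).all()


class TestWindowedR2:
    @staticmethod
    def _frame(n=800, seed=9, driver="delta"):
        rng = np.random.default_rng(seed)
        dist = rng.uniform(0, 120, n)
        delta = -25 * np.exp(-dist / 40) + rng.normal(0, 2, n)
        if driver == "delta":
            lfc = -0.02 * delta + rng.normal(0, 0.08, n)
        else:  # identical predictors
            lfc = rng.normal(0, 0.1, n)
        return pd.DataFrame(
            {"lfc": lfc, "delta_pp": delta, "dist_deleted_tel_kb": dist}
        )

    def test_identical_predictors_give_zero_ratio(self):
        rng = np.random.default_rng(10)
        dist = rng.uniform(1, 100, 400)
        delta = np.log(dist + 1.0)  # delta IS log-distance
        lfc = 0.1 * delta + rng.normal(0, 0.05, 400)
        df = pd.DataFrame({"lfc": lfc, "delta_pp": delta, "dist_deleted_tel_kb": dist})
        out = windowed_r2_comparison(df)
        assert np.allclose(out["log2_r2_ratio"].dropna(), 0.0, atol=1e-9)

    def test_delta_driver_wins_majority_of_windows(self):
        out = windowed_r2_comparison(self._frame(), window_kb=50.0)
        ratios = out["log2_r2_ratio"].dropna()
        assert (ratios > 0).mean() > 0.5

    def test_r2_matches_brute_force_least_squares(self):
        df = self._frame(n=200, seed=11)
        out = windowed_r2_comparison(df, window_kb=50.0)
        row = out.iloc[0]
        c, half = row["centre_kb"], 25.0
        sel = (df.dist_deleted_tel_kb >= c - half) & (df.dist_deleted_tel_kb <= c + half)
        x = df.delta_pp[sel].to_numpy()
        y = df.lfc[sel].to_numpy()
        X = np.column_stack([np.ones(sel.sum()), x])
        beta, res, *_ = np.linalg.lstsq(X, y, rcond=None)
        ss_tot = ((y - y.mean()) ** 2).sum()
        brute = 1.0 - res[0] / ss_tot
        assert row["r2_delta_pp"] == pytest.approx(brute)

    def test_sparse_windows_skipped(self):
        df = self._frame(n=12, seed=12)
        out = windowed_r2_comparison(df, window_kb=10.0, min_genes=5)
        assert (out["n_genes"] >= 5).all()


class TestResampledCorrelation:
    def test_perfect_correlation_is_one_in_every_resample(self):
        genes = [f"g{i}" for i in range(100)]
        pp = pd.Series(np.linspace(0, 100, 100), index=genes)
        expr = pd.Series(2 ** (10 - 0.05 * pp.to_numpy()), index=genes)
        dist = pd.Series(np.linspace(1, 300, 100), index=genes)
        out = resampled_correlation_comparison(expr, pp, dist, n_resamples=50, seed=1)
        res = out["resamples"]
        allstr = res[res.stratum == "all"]
        assert np.allclose(allstr["abs_corr_pct_peripheral"], 1.0)

    def test_resample_spread_shrinks_with_gene_count(self):
        rng = np.random.default_rng(13)

        def spread(n):
            genes = [f"g{i}" for i in range(n)]
            pp = pd.Series(rng.uniform(0, 100, n), index=genes)
            expr = pd.Series(2 ** (8 - 0.02 * pp + rng.normal(0, 1, n)), index=genes)
            dist = pd.Series(rng.uniform(1, 300, n), index=genes)
            out = resampled_correlation_comparison(expr, pp, dist, n_resamples=200, seed=2)
            res = out["resamples"]
            return res[res.stratum == "all"]["abs_corr_pct_peripheral"].std()

        assert spread(1600) < spread(100)

    def test_position_driven_expression_dominates_distance(self):
        rng = np.random.default_rng(14)
        n = 500
        genes = [f"g{i}" for i in range(n)]
        dist = pd.Series(rng.uniform(0, 200, n), index=genes)
        # % peripheral loosely related to distance, expression driven by %P only
        pp = pd.Series(
            np.clip(30 + 60 * np.exp(-dist / 30) + rng.normal(0, 15, n), 0, 100),
            index=genes,
        )
        expr = pd.Series(2 ** (8 - 0.03 * pp + rng.normal(0, 0.3, n)), index=genes)
        out = resampled_correlation_comparison(expr, pp, dist, n_resamples=200, seed=3)
        res = out["resamples"]
        allstr = res[res.stratum == "all"]
        dom = (allstr["abs_corr_pct_peripheral"] > allstr["abs_corr_log_dist"]).mean()
        assert dom > 0.95
        biv = out["bivariate_model"]
        assert abs(biv.loc["pct_peripheral_std", "t"]) > abs(
            biv.loc["log_dist_tel_std", "t"]
        )
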