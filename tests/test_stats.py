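"""Agreement-statistics battery vs closed forms and independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sp_stats

from qmapsr.io import load_lesion_roi_table
from qmapsr.stats import (TOSTConfig, bland_altman_percent, build_agreement_report,
                          cv_intergroup, cv_intragroup, extract_mean,
                          lesion_table_compare, linear_regression, paired_ttest,
                          tost_equivalence)


class TestExtractMean:
    def test_trivial_cases(self):
        img = np.full((6, 6), 10.0)
        mask = np.zeros((6, 6), dtype=bool)
        mask[2:4, 2:4] = True
        assert extract_mean(img, mask) == 10.0
        single = np.zeros((6, 6), dtype=bool)
        single[1, 1] = True
        img[1, 1] = 77.0
        assert extract_mean(img, single) == 77.0
        checker = np.indices((6, 6)).sum(axis=0) % 2 == 0
        board = np.where(checker, 0.0, 2.0)
        assert extract_mean(board, np.ones((6, 6), dtype=bool)) == 1.0

    def test_empty_mask_rejected(self):
        with pytest.raises(ValueError):
            extract_mean(np.zeros((4, 4)), np.zeros((4, 4), dtype=bool))


class TestPairedT:
    def test_closed_form_small_sample(self):
        # differences (1,2,3): mean 2, sd 1 -> t = 2 sqrt(3), df = 2
        res = paired_ttest([2.0, 4.0, 6.0], [1.0, 2.0, 3.0])
        assert res.t == pytest.approx(2 * np.sqrt(3))
        assert res.df == 2
        expect_p = 2 * sp_stats.t.sf(2 * np.sqrt(3), 2)
        assert res.p == pytest.approx(expect_p, abs=1e-10)
        assert res.p == pytest.approx(0.0742, abs=5e-4)

    def test_zero_variance_flagged_degenerate(self):
        res = paired_ttest([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.degenerate and np.isnan(res.p)

    def test_matches_closed_form_oracle_on_seeded_vectors(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            n = rng.integers(5, 40)
            x = rng.normal(10, 2, n)
            y = x + rng.normal(0.2, 1, n)
            res = paired_ttest(x, y)
            d = x - y
            t = d.mean() / (d.std(ddof=1) / np.sqrt(n))
            p = 2 * sp_stats.t.sf(abs(t), n - 1)
            assert res.t == pytest.approx(t, rel=1e-10)
            assert res.p == pytest.approx(p, abs=1e-8)


class TestTOST:
    def test_published_margins_from_routine_means(self):
        cfg = TOSTConfig()
        means = {"T1_GM": 1232.65, "T2_GM": 93.33, "PD_GM": 80.11,
                 "T1_WM": 837.86, "T2_WM": 79.92, "PD_WM": 68.21}
        expect = {"T1_GM": 61.63, "T2_GM": 4.67, "PD_GM": 4.01,
                  "T1_WM": 41.89, "T2_WM": 4.00, "PD_WM": 3.41}
        for key, mean in means.items():
            assert round(cfg.margin(mean), 2) == expect[key], key

    def test_infinite_margin_always_equivalent(self):
        rng = np.random.default_rng(1)
        x = rng.normal(100, 5, 10)
        y = rng.normal(110, 5, 10)
        res = tost_equivalence(x, y, TOSTConfig(margin_fraction=0.999), 1e9)
        assert res.equivalent

    def test_large_shift_not_equivalent_and_matches_statsmodels(self):
        from statsmodels.stats.weightstats import ttost_paired
        rng = np.random.default_rng(2)
        cfg = TOSTConfig()
        for shift in (0.0, 0.5, 5.0, 50.0):
            x = rng.normal(100, 3, 15)
            y = x + shift + rng.normal(0, 1, 15)
            ref_mean = float(y.mean())
            res = tost_equivalence(x, y, cfg, ref_mean)
            p, *_ = ttost_paired(x, y, -res.epsilon, res.epsilon)
            # CI-inclusion at 90% <=> both one-sided tests reject at 5%
            assert res.equivalent == bool(p < 0.05)
        assert not tost_equivalence(
            x, x + 50.0, cfg, float(x.mean())).equivalent

    def test_ci_is_t_based(self):
        x = np.array([10.0, 12.0, 11.0, 9.0, 13.0])
        y = np.array([9.5, 11.0, 11.5, 8.0, 12.0])
        res = tost_equivalence(x, y, TOSTConfig(), 10.0)
        d = x - y
        se = d.std(ddof=1) / np.sqrt(5)
        tcrit = sp_stats.t.ppf(0.95, 4)
        assert res.ci_low == pytest.approx(d.mean() - tcrit * se)
        assert res.ci_high == pytest.approx(d.mean() + tcrit * se)


class TestRegression:
    def test_exact_lines(self):
        x = np.arange(10.0)
        slope, intercept, r2 = linear_regression(x, x)
        assert (slope, intercept, r2) == pytest.approx((1.0, 0.0, 1.0))
        slope, intercept, r2 = linear_regression(x, 2 * x + 1)
        assert (slope, intercept, r2) == pytest.approx((2.0, 1.0, 1.0))

    def test_matches_normal_equations(self):
        rng = np.random.default_rng(3)
        x = rng.uniform(0, 100, 50)
        y = 3.2 * x - 7.0 + rng.normal(0, 5, 50)
        slope, intercept, r2 = linear_regression(x, y)
        X = np.column_stack([x, np.ones_like(x)])
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        resid = y - X @ beta
        r2_o = 1 - (resid ** 2).sum() / ((y - y.mean()) ** 2).sum()
        assert slope == pytest.approx(beta[0], abs=1e-10)
        assert intercept == pytest.approx(beta[1], abs=1e-10)
        assert r2 == pytest.approx(r2_o, abs=1e-10)

    def test_degenerate_input_rejected(self):
        with pytest.raises(ValueError):
            linear_regression([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestBlandAltman:
    def test_identity_gives_zero_bias_and_limits(self):
        x = np.array([10.0, 20.0, 30.0])
        bias, lo, hi = bland_altman_percent(x, x)
        assert (bias, lo, hi) == (0.0, 0.0, 0.0)

    def test_pair_mean_denominator_arithmetic(self):
        bias, lo, hi = bland_altman_percent([100.0, 110.0], [100.0, 100.0])
        # percent diffs: 0 and 100*10/105 = 9.5238 -> bias 4.7619
        assert bias == pytest.approx(100 * 10 / 105 / 2, rel=1e-9)
        assert lo < bias < hi

    def test_limits_match_definition_oracle(self):
        rng = np.random.default_rng(4)
        x = rng.normal(50, 5, 40)
        y = x + rng.normal(0, 2, 40)
        bias, lo, hi = bland_altman_percent(x, y)
        pct = 100 * (x - y) / ((x + y) / 2)
        assert bias == pytest.approx(pct.mean())
        assert lo == pytest.approx(pct.mean() - 1.96 * pct.std(ddof=1))
        assert hi == pytest.approx(pct.mean() + 1.96 * pct.std(ddof=1))
        assert lo <= bias <= hi

    def test_limits_cover_about_95_percent(self):
        rng = np.random.default_rng(5)
        x = rng.normal(100, 3, 4000)
        y = x + rng.normal(1, 2, 4000)
        bias, lo, hi = bland_altman_percent(x, y)
        pct = 100 * (x - y) / ((x + y) / 2)
        coverage = np.mean((pct >= lo) & (pct <= hi))
        assert abs(coverage - 0.95) < 0.015


class TestCVs:
    def test_intragroup_arithmetic(self):
        assert cv_intragroup([5.0, 5.0, 5.0]) == 0.0
        assert cv_intragroup([8.0, 12.0]) == pytest.approx(100 * 2 * np.sqrt(2) / 10)
        rng = np.random.default_rng(6)
        v = rng.uniform(50, 150, 30)
        assert cv_intragroup(v) == pytest.approx(100 * v.std(ddof=1) / v.mean())

    def test_intergroup_arithmetic(self):
        assert cv_intergroup([7.0, 7.0]) == 0.0
        assert cv_intergroup([100.0, 102.0]) == pytest.approx(100 * np.sqrt(2) / 101)
        rng = np.random.default_rng(7)
        m = rng.uniform(90, 110, 3)
        assert cv_intergroup(m) == pytest.approx(100 * m.std(ddof=1) / m.mean())


class TestLesionTable:
    def test_packaged_table_healthy_parameters(self):
        res = lesion_table_compare(load_lesion_roi_table()).set_index("parameter")
        assert round(res.loc["T1", "p"], 2) == 0.67
        assert round(res.loc["T2", "p"], 2) == 0.73
        assert (res.n_rois == 12).all()

    def test_pd_column_agrees_with_independent_paired_test(self):
        """The PD columns of the packaged table give a small paired-t
        p-value (the two methods differ systematically in PD here);
        cross-check against scipy."""
        table = load_lesion_roi_table()
        res = lesion_table_compare(table).set_index("parameter")
        want = sp_stats.ttest_rel(table.pd_dl, table.pd_routine).pvalue
        assert res.loc["PD", "p"] == pytest.approx(want, abs=1e-10)

    def test_duplicated_columns_flagged_degenerate(self):
        table = load_lesion_roi_table().copy()
        for p in ("t1", "t2", "pd"):
            table[f"{p}_dl"] = table[f"{p}_routine"]
        res = lesion_table_compare(table)
        assert res.degenerate.all()


class TestAgreementReport:
    def test_identity_methods_report_perfect_agreement(self):
        rng = np.random.default_rng(8)
        gm = rng.normal(1230, 30, 12)
        wm = rng.normal(840, 30, 12)
        tissue = {"GM": {"DL": gm, "routine": gm.copy()},
                  "WM": {"DL": wm, "routine": wm.copy()}}
        report = build_agreement_report("T1", tissue)
        assert report.bland_altman["bias_percent"] == 0.0
        assert report.tissue.equivalent.all()
        assert report.tissue.degenerate.all()
        assert report.pooled_regression["slope"] == pytest.approx(1.0)
        assert report.pooled_regression["r2"] == pytest.approx(1.0)

    def test_region_cvs_and_serialization(self):
        rng = np.random.default_rng(9)
        base = rng.normal(1000, 50, 10)
        tissue = {"GM": {"DL": base * 1.01, "routine": base}}
        regions = {"GM_region_1": {"DL": base * 1.02, "routine": base}}
        report = build_agreement_report("T1", tissue, regions)
        row = report.regions.iloc[0]
        assert row.cv_intragroup_test == pytest.approx(
            cv_intragroup(base * 1.02))
        assert row.cv_intergroup == pytest.approx(
            cv_intergroup([np.mean(base * 1.02), np.mean(base)]))
        d = report.to_dict()
        assert {"tissue", "regions", "pooled_regression"} <= set(d)
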