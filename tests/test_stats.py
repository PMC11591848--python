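"""Statistical procedures against hand computations and library oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from corsistudy import cohort
from corsistudy.scoring import round_half_up
from corsistudy.stats import (
    AnalysisOptions,
    ancova,
    chi_square,
    covariate_independence,
    describe,
    eta_p_squared,
    exclude_unassessable,
    experience_split_anova,
    levene,
    mann_whitney,
    metacompetence_table,
    one_way_anova,
    pearson,
    pooled_mean,
    render_report,
    run_full_analysis,
    slopes_homogeneity,
    t_interval,
    welch_or_student_t,
)


class TestDescriptives:
    @pytest.mark.parametrize(
        "mean, sd, n, lo, hi, nd_hi",
        [
            # observed subgroup rows: mean, SD, n and their printed t-intervals
            (6.35, 0.95, 11, 5.71, 6.99, 2),
            (6.87, 0.76, 8, 6.23, 7.5, 1),
            (6.27, 1.20, 18, 5.67, 6.87, 2),
        ],
    )
    def test_t_interval_reproduces_printed_rows(self, mean, sd, n, lo, hi, nd_hi):
        a, b = t_interval(mean, sd, n)
        assert round_half_up(a, 2) == lo
        assert round_half_up(b, nd_hi) == hi

    def test_describe_from_raw_scores(self, rng):
        x = rng.normal(7, 1, size=30)
        row = describe({"g": x})[0]
        assert row.mean == pytest.approx(x.mean())
        assert row.sd == pytest.approx(x.std(ddof=1))
        assert row.ci_low <= row.mean <= row.ci_high
        lo, hi = sps.t.interval(0.95, 29, loc=x.mean(), scale=sps.sem(x))
        assert (row.ci_low, row.ci_high) == pytest.approx((lo, hi))

    def test_zero_sd_collapses_interval(self):
        row = describe({"g": np.full(5, 6.5)})[0]
        assert (row.ci_low, row.ci_high) == (6.5, 6.5)

    def test_single_observation_errors(self):
        with pytest.raises(ValueError):
            describe({"g": np.array([1.0])})

    @pytest.mark.parametrize(
        "rows, expected",
        [
            ([(6.87, 8), (7.10, 23)], 7.04),  # musician subgroups pool to 7.04
            ([(6.35, 11), (6.27, 18)], 6.30),  # non-musician subgroups to 6.30
            ([(4.2, 17)], 4.2),
        ],
    )
    def test_pooled_mean(self, rows, expected):
        assert round_half_up(pooled_mean(rows)) == expected

    def test_pooled_mean_rejects_bad_input(self):
        with pytest.raises(ValueError):
            pooled_mean([])
        with pytest.raises(ValueError):
            pooled_mean([(5.0, 0)])


class TestEtaPartial:
    @pytest.mark.parametrize(
        "F, df1, df2, expected",
        [
            (7.52, 1, 56, 0.118),  # group term
            (8.25, 1, 56, 0.128),  # sex covariate
            (2.17, 1, 56, 0.037),  # age covariate
        ],
    )
    def test_identity_from_reported_triplets(self, F, df1, df2, expected):
        assert round_half_up(eta_p_squared(F, df1, df2), 3) == expected


def _brute_ancova_f(y, X, cols):
    """Independent oracle: explicit normal equations + model-comparison F."""
    def rss(M):
        beta = np.linalg.solve(M.T @ M, M.T @ y)
        return float(y @ y - beta @ (M.T @ y))

    full = rss(X)
    keep = [j for j in range(X.shape[1]) if j not in cols]
    red = rss(X[:, keep])
    df1 = len(cols)
    df2 = X.shape[0] - X.shape[1]
    F = (red - full) / df1 / (full / df2)
    return F, (red - full) / (red - full + full)


class TestAncova:
    @staticmethod
    def _orthogonal_dataset():
        # sex and age balanced within each group; dv symmetric over both
        rows = []
        for grp, base in (("a", 6.0), ("b", 9.0)):
            for sex, age, bump in [
                ("female", 20, -1.0), ("female", 30, 1.0),
                ("male", 20, 1.0), ("male", 30, -1.0),
                ("female", 25, 0.5), ("male", 25, -0.5),
            ]:
                rows.append(
                    {"grp": grp, "sex": sex, "age": age, "dv": base + bump}
                )
        return pd.DataFrame(rows)

    def test_factor_ss_equals_one_way_between_ss_when_orthogonal(self):
        df = self._orthogonal_dataset()
        res = ancova(df, "dv", "grp", ("sex", "age"))
        groups = [g["dv"].to_numpy() for _, g in df.groupby("grp")]
        grand = df["dv"].mean()
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        assert res.term("grp").ss == pytest.approx(ss_between, abs=1e-10)

    def test_identical_dv_across_groups_gives_zero_f(self):
        df = self._orthogonal_dataset()
        df["dv"] = 5.0
        res = ancova(df, "dv", "grp", ("sex", "age"))
        assert res.term("grp").F == pytest.approx(0.0, abs=1e-10)

    def test_matches_brute_force_oracle_on_constructed_data(self):
        rng = np.random.default_rng(8)
        df = pd.DataFrame(
            {
                "dv": rng.normal(7, 1, 18),
                "grp": ["a"] * 9 + ["b"] * 9,
                "sex": list(rng.choice(["male", "female"], 18)),
                "age": rng.uniform(18, 40, 18),
            }
        )
        res = ancova(df, "dv", "grp", ("sex", "age"))
        y = df["dv"].to_numpy()
        X = np.column_stack(
            [
                np.ones(18),
                (df["grp"] == "b").to_numpy(float),
                (df["sex"] == "male").to_numpy(float),
                df["age"].to_numpy(),
            ]
        )
        for name, col in [("grp", 1), ("sex", 2), ("age", 3)]:
            F, eta = _brute_ancova_f(y, X, [col])
            assert res.term(name).F == pytest.approx(F, abs=1e-10)
            assert res.term(name).eta_p_sq == pytest.approx(eta, abs=1e-10)

    def test_matches_pingouin_on_random_data(self):
        pg = pytest.importorskip("pingouin")
        rng = np.random.default_rng(3)
        df = pd.DataFrame(
            {
                "dv": rng.normal(size=50),
                "grp": list(rng.choice(["a", "b"], 50)),
                "sex": rng.integers(0, 2, 50).astype(float),
                "age": rng.normal(25, 5, 50),
            }
        )
        ours = ancova(df, "dv", "grp", ("sex", "age"))
        theirs = pg.ancova(data=df, dv="dv", between="grp", covar=["sex", "age"])
        for name in ("grp", "sex", "age"):
            row = theirs[theirs.Source == name].iloc[0]
            assert ours.term(name).F == pytest.approx(row.F, rel=1e-9)
            assert ours.term(name).p == pytest.approx(row.p_unc, rel=1e-9)
            assert ours.term(name).eta_p_sq == pytest.approx(row.np2, rel=1e-9)

    def test_reduces_to_one_way_anova_without_covariates(self):
        rng = np.random.default_rng(21)
        df = pd.DataFrame(
            {"dv": rng.normal(size=24), "grp": ["a", "b", "c"] * 8}
        )
        res = ancova(df, "dv", "grp", ())
        ref = one_way_anova([g["dv"].to_numpy() for _, g in df.groupby("grp")])
        assert res.term("grp").F == pytest.approx(ref.value, abs=1e-10)
        assert res.term("grp").df1 == ref.df[0]
        assert res.term("grp").df2 == ref.df[1]

    def test_rank_deficiency_names_columns(self):
        df = self._orthogonal_dataset()
        df["age2"] = df["age"]  # collinear copy
        with pytest.raises(ValueError, match="rank deficient"):
            ancova(df, "dv", "grp", ("age", "age2"))

    def test_adjusted_means_at_covariate_means(self):
        df = self._orthogonal_dataset()
        res = ancova(df, "dv", "grp", ("sex", "age"))
        # orthogonal design: adjusted means equal raw group means
        assert res.adjusted_means["a"] == pytest.approx(6.0)
        assert res.adjusted_means["b"] == pytest.approx(9.0)


class TestLevene:
    def test_identical_multisets_give_zero(self):
        g = np.array([1.0, 2.0, 3.0, 4.0])
        assert levene([g, g.copy()]).value == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_three_plus_three(self):
        # |dev| groups (1,0,1) and (2,0,2): F = (2/3)/(10/12) = 0.8 on (1,4)
        res = levene([np.array([1.0, 2, 3]), np.array([2.0, 4, 6])])
        assert res.value == pytest.approx(0.8, abs=1e-12)
        assert res.df == (1, 4)

    def test_variance_separation_increases_f(self, rng):
        a = rng.normal(0, 1, 40)
        b = rng.normal(0, 1, 40)
        f1 = levene([a, b]).value
        f2 = levene([a, b * 3.0]).value
        assert f2 > f1

    def test_matches_scipy(self, rng):
        a, b = rng.normal(0, 1, 25), rng.normal(0, 2, 30)
        ours = levene([a, b], center="mean")
        w, p = sps.levene(a, b, center="mean")
        assert ours.value == pytest.approx(w, rel=1e-12)
        assert ours.p == pytest.approx(p, rel=1e-12)
        ours_med = levene([a, b], center="median")
        w, p = sps.levene(a, b, center="median")
        assert ours_med.value == pytest.approx(w, rel=1e-12)


class TestSlopesHomogeneity:
    def test_null_p_values_are_uniform(self):
        """Equal slopes: interaction p ~ U(0,1) over 500 simulated studies."""
        rng = np.random.default_rng(17)
        ps = []
        for _ in range(500):
            n = 200
            grp = np.repeat(["a", "b"], n // 2)
            age = rng.uniform(18, 40, n)
            y = 0.05 * age + (grp == "b") * 0.4 + rng.normal(0, 1, n)
            df = pd.DataFrame({"final_score": y, "group": grp, "age": age})
            ps.append(slopes_homogeneity(df).p)
        stat, p = sps.kstest(ps, "uniform")
        assert p > 0.001

    def test_identical_dv_gives_zero_f(self):
        df = pd.DataFrame(
            {
                "final_score": 5.0,
                "group": ["a"] * 10 + ["b"] * 10,
                "age": np.arange(20.0, 40.0),
            }
        )
        assert slopes_homogeneity(df).value == pytest.approx(0.0, abs=1e-10)

    def test_detects_strongly_different_slopes(self):
        rng = np.random.default_rng(19)
        n = 200
        grp = np.repeat(["a", "b"], n // 2)
        age = rng.uniform(18, 40, n)
        slope = np.where(grp == "a", 1.0, -1.0)
        y = slope * age + rng.normal(0, 1, n)
        df = pd.DataFrame({"final_score": y, "group": grp, "age": age})
        assert slopes_homogeneity(df).p < 0.001


class TestCovariateIndependence:
    def test_identical_ages_give_zero(self):
        df = pd.DataFrame(
            {"group": ["a"] * 3 + ["b"] * 3, "age": [20.0, 25, 30] * 2}
        )
        assert covariate_independence(df).value == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_sums_of_squares(self):
        # ages (20,22,24) vs (30,34,38): SSB=216, SSW=40 -> F = 216/10 = 21.6
        df = pd.DataFrame(
            {"group": ["a"] * 3 + ["b"] * 3, "age": [20.0, 22, 24, 30, 34, 38]}
        )
        res = covariate_independence(df)
        assert res.value == pytest.approx(21.6, abs=1e-12)
        assert res.df == (1, 4)

    def test_group_shift_increases_f(self):
        df = pd.DataFrame(
            {"group": ["a"] * 5 + ["b"] * 5, "age": list(range(20, 30))}
        )
        f1 = covariate_independence(df).value
        df2 = df.copy()
        df2.loc[df2.group == "b", "age"] += 10
        assert covariate_independence(df2).value > f1


class TestPearson:
    def test_perfect_correlations(self):
        x = np.arange(10.0)
        assert pearson(x, x).value == pytest.approx(1.0)
        assert pearson(x, -x).value == pytest.approx(-1.0)

    def test_brute_force_five_points(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = np.array([2.0, 1, 4, 3, 7])
        # oracle: direct covariance / variance arithmetic
        r_expected = (((x - x.mean()) * (y - y.mean())).sum()
                      / np.sqrt(((x - x.mean()) ** 2).sum()
                                * ((y - y.mean()) ** 2).sum()))
        res = pearson(x, y)
        assert res.value == pytest.approx(r_expected, rel=1e-12)
        r_sp, p_sp = sps.pearsonr(x, y)
        assert res.value == pytest.approx(r_sp, rel=1e-12)
        assert res.p == pytest.approx(p_sp, rel=1e-9)

    def test_zero_variance_errors(self):
        with pytest.raises(ValueError):
            pearson(np.ones(5), np.arange(5.0))


class TestChiSquare:
    def test_proportional_rows_give_zero(self):
        assert chi_square([[10, 20, 30], [20, 40, 60]]).value == pytest.approx(
            0.0, abs=1e-12
        )

    def test_hand_computed_two_by_two(self):
        # margins 30/30: all expecteds 15; chi2 = 4 * 25/15 = 6.667
        res = chi_square([[10, 20], [20, 10]])
        assert res.value == pytest.approx(20 / 3, abs=1e-12)
        assert res.df == 1

    def test_printed_p_value_for_reported_statistic(self):
        # chi2 = 14.43 on df 4 prints as p = 0.006
        assert round_half_up(float(sps.chi2.sf(14.43, 4)), 3) == 0.006

    def test_zero_margin_errors(self):
        with pytest.raises(ValueError):
            chi_square([[0, 0], [5, 5]])

    def test_matches_scipy_contingency(self, rng):
        table = rng.integers(5, 40, size=(2, 4))
        ours = chi_square(table)
        stat, p, df, _ = sps.chi2_contingency(table, correction=False)
        assert ours.value == pytest.approx(stat, rel=1e-12)
        assert ours.p == pytest.approx(p, rel=1e-12)
        assert ours.df == df


class TestMannWhitney:
    def test_identical_tiny_samples_exact_p_is_one(self):
        x = np.array([1.0, 2, 3])
        res = mann_whitney(x, x.copy())
        assert res.effect["method"] == "exact"
        assert res.p == pytest.approx(1.0)

    def test_complete_separation_u_extremes(self):
        x = np.array([1.0, 2, 3, 4, 5])
        y = x + 10
        assert mann_whitney(x, y).value == 0.0
        assert mann_whitney(y, x).value == 25.0

    def test_exact_and_normal_agree_on_moderate_samples(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            x = rng.normal(size=8)
            y = rng.normal(0.3, 1, size=8)
            pe = mann_whitney(x, y, method="exact").p
            pn = mann_whitney(x, y, method="normal").p
            assert abs(pe - pn) < 0.02

    def test_matches_scipy_normal_approximation(self, rng):
        x = rng.normal(size=30)
        y = rng.normal(0.5, 1, size=25)
        ours = mann_whitney(x, y)
        ref = sps.mannwhitneyu(
            x, y, alternative="two-sided", method="asymptotic", use_continuity=True
        )
        assert ours.value == pytest.approx(ref.statistic, abs=1e-9)
        assert ours.p == pytest.approx(ref.pvalue, rel=1e-9)


class TestTwoSampleT:
    def test_identical_samples(self):
        x = np.array([1.0, 2, 3, 4])
        res = welch_or_student_t(x, x.copy())
        assert res.value == 0.0
        assert res.effect["d"] == 0.0

    def test_hand_computed_pooled_t(self):
        x = np.array([1.0, 2, 3, 4])
        y = np.array([3.0, 4, 5, 6])
        res = welch_or_student_t(x, y, "student")
        assert res.value == pytest.approx(-2.0 / np.sqrt(5 / 6), rel=1e-12)
        assert res.df == 6
        assert res.effect["d"] == pytest.approx(-2.0 / np.sqrt(5 / 3), rel=1e-12)

    def test_antisymmetry(self, rng):
        x, y = rng.normal(size=12), rng.normal(1, 2, size=9)
        a = welch_or_student_t(x, y)
        b = welch_or_student_t(y, x)
        assert a.value == pytest.approx(-b.value)
        assert a.effect["d"] == pytest.approx(-b.effect["d"])

    @pytest.mark.parametrize("variant", ["student", "welch"])
    def test_matches_scipy(self, rng, variant):
        x, y = rng.normal(size=15), rng.normal(0.5, 2, size=20)
        res = welch_or_student_t(x, y, variant)
        ref = sps.ttest_ind(x, y, equal_var=(variant == "student"))
        assert res.value == pytest.approx(ref.statistic, rel=1e-12)
        assert res.p == pytest.approx(ref.pvalue, rel=1e-12)

    def test_t_squared_equals_one_way_f(self, rng):
        x, y = rng.normal(size=10), rng.normal(0.4, 1, size=12)
        t = welch_or_student_t(x, y, "student").value
        f = one_way_anova([x, y]).value
        assert t**2 == pytest.approx(f, rel=1e-10)


def _constructed_meta_dataset():
    """Counts consistent with the study's accuracy figure: (19,4; 6,12)."""
    rows = []
    cells = [
        ("musician", "good", 7.5, 19), ("musician", "good", 6.0, 4),
        ("non_musician", "good", 7.5, 6), ("non_musician", "good", 6.0, 12),
        ("musician", "bad", 6.5, 8), ("non_musician", "bad", 6.2, 11),
    ]
    i = 0
    for group, claim, score, n in cells:
        for _ in range(n):
            rows.append(
                {
                    "id": f"P{i:03d}", "group": group,
                    "self_assessment": claim, "final_score": score,
                }
            )
            i += 1
    return pd.DataFrame(rows)


class TestMetacompetenceTable:
    def test_figure_percentages_from_constructed_counts(self):
        d = _constructed_meta_dataset()
        table = metacompetence_table(d, threshold=7.0)
        assert table.n_denominator == 41
        pct = table.percentages
        assert round_half_up(pct.loc["musician", ("good", "good")], 2) == 46.34
        assert round_half_up(pct.loc["musician", ("good", "poor")], 2) == 9.76
        assert round_half_up(pct.loc["non_musician", ("good", "good")], 2) == 14.63
        assert round_half_up(pct.loc["non_musician", ("good", "poor")], 2) == 29.27
        assert pct.to_numpy().sum() == pytest.approx(100.0)

    def test_row_sums_preserve_claim_counts(self):
        d = _constructed_meta_dataset()
        counts = metacompetence_table(d).counts
        good = counts[("good", "good")] + counts[("good", "poor")]
        assert good["musician"] == 23
        assert good["non_musician"] == 18

    def test_unanimous_good_good_cell(self):
        d = pd.DataFrame(
            {
                "group": ["musician"] * 4 + ["non_musician"] * 2,
                "self_assessment": ["good"] * 6,
                "final_score": [8.0] * 4 + [5.0] * 2,
            }
        )
        pct = metacompetence_table(d).percentages
        assert pct.loc["musician", ("good", "good")] == pytest.approx(400 / 6)
        assert pct.loc["musician", ("good", "poor")] == 0.0

    def test_requires_prefiltered_labels(self):
        d = _constructed_meta_dataset()
        d.loc[0, "self_assessment"] = "normal"
        with pytest.raises(ValueError, match="exclude_unassessable"):
            metacompetence_table(d)


class TestExperienceSplit:
    @staticmethod
    def _musicians(scores_lo, scores_hi):
        rows = [
            {"years_reading": 3.0, "final_score": s} for s in scores_lo
        ] + [{"years_reading": 12.0, "final_score": s} for s in scores_hi]
        return pd.DataFrame(rows)

    def test_identical_scores_give_zero_f(self):
        res, _ = experience_split_anova(self._musicians([7.0] * 4, [7.0] * 4))
        assert res.value == pytest.approx(0.0, abs=1e-12)

    def test_equals_squared_pooled_t(self, rng):
        lo = rng.normal(7.2, 0.7, 16)
        hi = rng.normal(6.8, 0.8, 15)
        res, rows = experience_split_anova(self._musicians(lo, hi))
        t = welch_or_student_t(lo, hi, "student").value
        assert res.value == pytest.approx(t**2, rel=1e-10)
        assert {r.n for r in rows} == {16, 15}

    def test_empty_stratum_errors(self):
        with pytest.raises(ValueError, match="stratum"):
            experience_split_anova(self._musicians([7.0] * 4, []))


class TestFullAnalysis:
    def test_report_contains_all_stages(self):
        ds = cohort.simulate_study(cohort.default_spec(101))
        report = run_full_analysis(ds.data, provenance=ds.provenance)
        for key in (
            "sample", "matching", "assumptions", "ancova",
            "descriptives", "correlations", "metacompetence", "experience_split",
        ):
            assert key in report
        assert {t["name"] for t in report["ancova"]["terms"]} == {
            "group", "sex", "age",
        }
        n = report["sample"]
        assert n["n_excluded"] == 60 - sum(n["n_analyzed"].values())
        text = render_report(report)
        assert "ANCOVA" in text and "chi-square" in text

    def test_seeded_run_is_reproducible(self):
        a = run_full_analysis(cohort.simulate_study(cohort.default_spec(7)).data)
        b = run_full_analysis(cohort.simulate_study(cohort.default_spec(7)).data)
        assert a == b

    def test_exclusion_filter_removes_normal_and_unable(self):
        d = cohort.simulate_study(cohort.default_spec(5)).data
        kept = exclude_unassessable(d)
        assert set(kept.self_assessment) <= {"good", "bad"}
        assert len(kept) + (~d.self_assessment.isin(["good", "bad"])).sum() == len(d)

    def test_single_group_input_rejected(self):
        d = cohort.simulate_study(cohort.default_spec(5)).data
        with pytest.raises(ValueError, match="both groups"):
            run_full_analysis(d[d.group == "musician"])

    def test_options_round_trip_into_report(self):
        ds = cohort.simulate_study(cohort.default_spec(3))
        report = run_full_analysis(
            ds.data, AnalysisOptions(performance_threshold=6.5, experience_cut=5.0)
        )
        assert report["options"]["performance_threshold"] == 6.5
        assert report["options"]["experience_cut"] == 5.0
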