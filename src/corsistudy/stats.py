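"""Statistical procedures for the musician / non-musician CBT comparison.

Everything here is computed from first principles on top of numpy linear
algebra, with p-values taken from scipy's exact distribution functions
(Student t, F, chi-square, normal): descriptive statistics with Student-t
confidence intervals, a one-factor ANCOVA with partial (Type-III
equivalent) F-tests and partial eta squared, Levene's test, covariate
independence and homogeneity-of-slopes checks, Pearson correlation,
Mann-Whitney U (exact enumeration for small samples), two-sample t with
Cohen's d, the self-assessment-accuracy contingency table, and the
experience-split one-way ANOVA.  :func:`run_full_analysis` chains all
stages in the study's order, applying the normal/unable exclusion filter
first.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb, sqrt

import numpy as np
import pandas as pd
from scipy import stats as sps

from .scoring import classify_performance, round_half_up

__all__ = [
    "DescriptiveRow",
    "TermResult",
    "AncovaResult",
    "TestResult",
    "ContingencyTable",
    "AnalysisOptions",
    "t_interval",
    "describe",
    "pooled_mean",
    "eta_p_squared",
    "one_way_anova",
    "ancova",
    "levene",
    "slopes_homogeneity",
    "covariate_independence",
    "pearson",
    "chi_square",
    "mann_whitney",
    "welch_or_student_t",
    "metacompetence_table",
    "experience_split_anova",
    "exclude_unassessable",
    "run_full_analysis",
    "render_report",
]


# ---------------------------------------------------------------------------
# result containers


@dataclass(frozen=True)
class DescriptiveRow:
    label: str
    mean: float
    sd: float
    ci_low: float
    ci_high: float
    n: int

    def to_dict(self) -> dict:
        return {
            "label": self.label, "mean": self.mean, "sd": self.sd,
            "ci_low": self.ci_low, "ci_high": self.ci_high, "n": self.n,
        }


@dataclass(frozen=True)
class TermResult:
    name: str
    F: float
    df1: int
    df2: int
    p: float
    eta_p_sq: float
    ss: float

    def to_dict(self) -> dict:
        return {
            "name": self.name, "F": self.F, "df1": self.df1, "df2": self.df2,
            "p": self.p, "eta_p_sq": self.eta_p_sq, "ss": self.ss,
        }


@dataclass(frozen=True)
class AncovaResult:
    terms: tuple[TermResult, ...]
    adjusted_means: dict
    residual_df: int
    n: int

    def term(self, name: str) -> TermResult:
        for t in self.terms:
            if t.name == name:
                return t
        raise KeyError(name)

    def to_dict(self) -> dict:
        return {
            "terms": [t.to_dict() for t in self.terms],
            "adjusted_means": self.adjusted_means,
            "residual_df": self.residual_df,
            "n": self.n,
        }


@dataclass(frozen=True)
class TestResult:
    statistic: str  # "t" | "F" | "chi2" | "U" | "r"
    value: float
    df: tuple | float | None
    p: float
    effect: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "statistic": self.statistic, "value": self.value,
            "df": list(self.df) if isinstance(self.df, tuple) else self.df,
            "p": self.p, "effect": self.effect,
        }


@dataclass(frozen=True)
class ContingencyTable:
    """Group x (claim, performance) counts with derived percentages."""

    counts: pd.DataFrame
    percentages: pd.DataFrame
    denominator: str
    n_denominator: int

    def to_dict(self) -> dict:
        def flat(df: pd.DataFrame) -> dict:
            return {
                f"{idx}|{c[0]}-{c[1]}": float(df.loc[idx, c])
                for idx in df.index
                for c in df.columns
            }

        return {
            "counts": flat(self.counts),
            "percentages": flat(self.percentages),
            "denominator": self.denominator,
            "n_denominator": self.n_denominator,
        }


@dataclass(frozen=True)
class AnalysisOptions:
    """Knobs of the reporting pipeline."""

    performance_threshold: float = 7.0
    levene_center: str = "mean"
    meta_denominator: str = "claim_good"  # or "all"
    experience_cut: float = 8.0  # lower stratum: years < cut
    alpha: float = 0.05


# ---------------------------------------------------------------------------
# descriptives


def t_interval(mean: float, sd: float, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Two-sided Student-t confidence interval for a mean from summary stats."""
    if n < 2:
        raise ValueError("a t-interval needs n >= 2")
    half = sps.t.ppf(0.5 + conf / 2.0, n - 1) * sd / sqrt(n)
    return (mean - half, mean + half)


def describe(groups: dict[str, np.ndarray], conf: float = 0.95) -> list[DescriptiveRow]:
    """Mean, n-1 SD and 95% t-interval for each labelled group of scores."""
    rows = []
    for label, values in groups.items():
        x = np.asarray(values, dtype=float)
        n = x.size
        if n < 2:
            raise ValueError(f"group {label!r} has n={n} < 2: interval undefined")
        mean = float(x.mean())
        sd = float(x.std(ddof=1))
        lo, hi = t_interval(mean, sd, n, conf)
        rows.append(DescriptiveRow(label, mean, sd, lo, hi, n))
    return rows


def pooled_mean(subgroups: list[tuple[float, int]]) -> float:
    """Size-weighted mean of subgroup means: sum(n_i m_i) / sum(n_i)."""
    if not subgroups:
        raise ValueError("no subgroups given")
    if any(n <= 0 for _, n in subgroups):
        raise ValueError("all subgroup sizes must be > 0")
    total = sum(n for _, n in subgroups)
    return sum(m * n for m, n in subgroups) / total


def eta_p_squared(F: float, df1: int, df2: int) -> float:
    """Partial eta squared recovered from an F statistic and its dfs."""
    return F * df1 / (F * df1 + df2)


# ---------------------------------------------------------------------------
# linear-model machinery


def _ols_rss(y: np.ndarray, X: np.ndarray) -> tuple[float, np.ndarray]:
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    return float(resid @ resid), beta


def _check_full_rank(X: np.ndarray, names: list[str]) -> None:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(f"design matrix is rank deficient; columns: {names}")


def _encode_column(col: pd.Series) -> tuple[np.ndarray, list[str]]:
    """Numeric columns pass through; categoricals get drop-first dummies."""
    if pd.api.types.is_numeric_dtype(col):
        return col.to_numpy(dtype=float)[:, None], [col.name]
    levels = sorted(col.dropna().unique())
    if len(levels) < 2:
        raise ValueError(f"column {col.name!r} has a single level")
    cols = [(col == lv).to_numpy(dtype=float) for lv in levels[1:]]
    names = [f"{col.name}[{lv}]" for lv in levels[1:]]
    return np.column_stack(cols), names


def _partial_f(
    y: np.ndarray, X: np.ndarray, term_cols: list[int], names: list[str]
) -> TermResult:
    """Partial (drop-term) F-test of the columns `term_cols` of X."""
    _check_full_rank(X, names)
    n, p = X.shape
    rss_full, _ = _ols_rss(y, X)
    keep = [j for j in range(p) if j not in term_cols]
    rss_red, _ = _ols_rss(y, X[:, keep])
    df1 = len(term_cols)
    df2 = n - p
    ss_term = rss_red - rss_full
    if df2 <= 0:
        raise ValueError("no residual degrees of freedom")
    ms_res = rss_full / df2
    # guard against a perfectly fit (constant) outcome, where both sums of
    # squares are numerical noise
    tol = 1e-12 * max(1.0, float(y @ y))
    if rss_full <= tol and ss_term <= tol:
        F = 0.0
    elif ms_res > 0:
        F = max(ss_term, 0.0) / df1 / ms_res
    else:
        F = float("inf")
    pval = float(sps.f.sf(F, df1, df2))
    eta = max(ss_term, 0.0) / (max(ss_term, 0.0) + rss_full) if (ss_term + rss_full) > 0 else 0.0
    return TermResult(
        name=",".join(names[j] for j in term_cols),
        F=float(F), df1=df1, df2=df2, p=pval, eta_p_sq=float(eta),
        ss=float(max(ss_term, 0.0)),
    )


def ancova(
    data: pd.DataFrame,
    dv: str = "final_score",
    factor: str = "group",
    covariates: tuple[str, ...] = ("sex", "age"),
) -> AncovaResult:
    """One-factor ANCOVA via OLS with partial (Type-III equivalent) F-tests.

    The factor and any categorical covariates are dummy-coded (drop
    first).  Each term's F compares the full model against the model with
    that term removed; partial eta squared is SS_term / (SS_term +
    SS_residual).  Adjusted group means are model predictions at the
    sample means of the covariate columns.
    """
    y = data[dv].to_numpy(dtype=float)
    n = y.size
    blocks: list[np.ndarray] = [np.ones((n, 1))]
    names: list[str] = ["intercept"]
    term_cols: dict[str, list[int]] = {}
    col = 1
    for name in (factor, *covariates):
        enc, enc_names = _encode_column(data[name])
        blocks.append(enc)
        term_cols[name] = list(range(col, col + enc.shape[1]))
        names.extend(enc_names)
        col += enc.shape[1]
    X = np.column_stack(blocks)
    _check_full_rank(X, names)

    terms = []
    for name in (factor, *covariates):
        tr = _partial_f(y, X, term_cols[name], names)
        terms.append(
            TermResult(name, tr.F, tr.df1, tr.df2, tr.p, tr.eta_p_sq, tr.ss)
        )

    # adjusted means: prediction per factor level at covariate means
    _, beta = _ols_rss(y, X)
    cov_cols = [j for t in covariates for j in term_cols[t]]
    x_base = np.zeros(X.shape[1])
    x_base[0] = 1.0
    for j in cov_cols:
        x_base[j] = X[:, j].mean()
    levels = sorted(data[factor].dropna().unique())
    adjusted = {}
    for i, lv in enumerate(levels):
        x = x_base.copy()
        for k, j in enumerate(term_cols[factor]):
            x[j] = 1.0 if k == i - 1 else 0.0  # first level is the reference
        adjusted[str(lv)] = float(x @ beta)
    return AncovaResult(
        terms=tuple(terms),
        adjusted_means=adjusted,
        residual_df=n - X.shape[1],
        n=n,
    )


def one_way_anova(groups: list[np.ndarray]) -> TestResult:
    """Classical one-way ANOVA from explicit sums of squares."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 1 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    all_x = np.concatenate(groups)
    grand = all_x.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
    df1 = len(groups) - 1
    df2 = all_x.size - len(groups)
    if df2 <= 0:
        raise ValueError("no residual degrees of freedom")
    if ss_within == 0:
        F = 0.0 if ss_between == 0 else float("inf")
    else:
        F = (ss_between / df1) / (ss_within / df2)
    p = float(sps.f.sf(F, df1, df2))
    eta = ss_between / (ss_between + ss_within) if (ss_between + ss_within) > 0 else 0.0
    return TestResult("F", float(F), (df1, df2), p, {"eta_p_sq": float(eta)})


def levene(groups: list[np.ndarray], center: str = "mean") -> TestResult:
    """Levene's homogeneity-of-variance test.

    One-way ANOVA on absolute deviations from the group center; the
    classic test centers on the mean (default), the Brown-Forsythe
    variant on the median.
    """
    if center not in ("mean", "median"):
        raise ValueError("center must be 'mean' or 'median'")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(g.size < 2 for g in groups):
        raise ValueError("Levene's test needs >= 2 groups with n >= 2")
    devs = []
    for g in groups:
        c = g.mean() if center == "mean" else float(np.median(g))
        devs.append(np.abs(g - c))
    res = one_way_anova(devs)
    return TestResult("F", res.value, res.df, res.p, {"center": center})


def slopes_homogeneity(
    data: pd.DataFrame,
    dv: str = "final_score",
    factor: str = "group",
    covariate: str = "age",
) -> TestResult:
    """Homogeneity-of-regression-slopes check for one covariate.

    Partial F of the factor x covariate interaction added to the model
    ``dv ~ factor + covariate``.
    """
    y = data[dv].to_numpy(dtype=float)
    n = y.size
    g_enc, g_names = _encode_column(data[factor])
    c = data[covariate].to_numpy(dtype=float)[:, None]
    inter = g_enc * c
    X = np.column_stack([np.ones((n, 1)), g_enc, c, inter])
    names = (
        ["intercept"] + g_names + [covariate]
        + [f"{gn}:{covariate}" for gn in g_names]
    )
    cols = list(range(X.shape[1] - inter.shape[1], X.shape[1]))
    tr = _partial_f(y, X, cols, names)
    return TestResult(
        "F", tr.F, (tr.df1, tr.df2), tr.p, {"eta_p_sq": tr.eta_p_sq}
    )


def covariate_independence(
    data: pd.DataFrame, covariate: str = "age", factor: str = "group"
) -> TestResult:
    """One-way ANOVA of the covariate across factor levels."""
    groups = [
        sub[covariate].to_numpy(dtype=float)
        for _, sub in data.groupby(factor, observed=True)
    ]
    return one_way_anova(groups)


# ---------------------------------------------------------------------------
# simple tests


def pearson(x: np.ndarray, y: np.ndarray) -> TestResult:
    """Pearson correlation with a two-sided t-test on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n != y.size or n < 3:
        raise ValueError("pearson needs two equal-length samples with n >= 3")
    xd = x - x.mean()
    yd = y - y.mean()
    denom = sqrt(float(xd @ xd) * float(yd @ yd))
    if denom == 0:
        raise ValueError("zero variance in one of the inputs")
    r = float(xd @ yd) / denom
    r = max(-1.0, min(1.0, r))
    df = n - 2
    if abs(r) == 1.0:
        p = 0.0
    else:
        t = r * sqrt(df / (1.0 - r * r))
        p = float(2.0 * sps.t.sf(abs(t), df))
    return TestResult("r", r, df, p, {"n": n})


def chi_square(table: np.ndarray | pd.DataFrame) -> TestResult:
    """Pearson chi-square test of independence on an r x c count table."""
    obs = np.asarray(table, dtype=float)
    if obs.ndim != 2 or obs.min() < 0:
        raise ValueError("need a 2-D table of non-negative counts")
    row = obs.sum(axis=1, keepdims=True)
    colsum = obs.sum(axis=0, keepdims=True)
    total = obs.sum()
    if (row == 0).any() or (colsum == 0).any() or total == 0:
        raise ValueError("table has a zero margin")
    expected = row @ colsum / total
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(sps.chi2.sf(stat, df))
    return TestResult("chi2", stat, df, p, {"n": float(total)})


def _u_statistic(x: np.ndarray, y: np.ndarray) -> float:
    """U for sample x: #(x_i > y_j) + 0.5 #(x_i == y_j)."""
    gt = (x[:, None] > y[None, :]).sum()
    eq = (x[:, None] == y[None, :]).sum()
    return float(gt) + 0.5 * float(eq)


def mann_whitney(x: np.ndarray, y: np.ndarray, method: str = "auto") -> TestResult:
    """Mann-Whitney U test, two-sided.

    Small samples (combined n <= 10, or ``method="exact"``) use exhaustive
    enumeration of the permutation distribution of U; otherwise a
    tie-corrected normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    u = _u_statistic(x, y)
    mu = n1 * n2 / 2.0

    if method == "exact" or (method == "auto" and n1 + n2 <= 10):
        pooled = np.concatenate([x, y])
        idx = range(n1 + n2)
        devs = []
        for combo in itertools.combinations(idx, n1):
            mask = np.zeros(n1 + n2, dtype=bool)
            mask[list(combo)] = True
            devs.append(abs(_u_statistic(pooled[mask], pooled[~mask]) - mu))
        devs = np.array(devs)
        p = float((devs >= abs(u - mu) - 1e-12).mean())
        return TestResult("U", u, None, min(p, 1.0), {"method": "exact"})

    # tie-corrected normal approximation
    pooled = np.concatenate([x, y])
    nt = n1 + n2
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = ((counts**3 - counts).sum()) / (nt * (nt - 1))
    var = n1 * n2 / 12.0 * (nt + 1 - tie_term)
    if var == 0:
        return TestResult("U", u, None, 1.0, {"method": "normal"})
    z = (abs(u - mu) - 0.5) / sqrt(var)
    p = float(2.0 * sps.norm.sf(max(z, 0.0)))
    return TestResult("U", u, None, min(p, 1.0), {"method": "normal"})


def welch_or_student_t(
    x: np.ndarray, y: np.ndarray, variant: str = "student"
) -> TestResult:
    """Two-sample t-test (pooled Student or Welch) with Cohen's d.

    Cohen's d uses the pooled SD in both variants; the confidence interval
    is for the mean difference x - y at the variant's df.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise ValueError("each sample needs n >= 2")
    m1, m2 = x.mean(), y.mean()
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    diff = m1 - m2
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    d = diff / sqrt(sp2) if sp2 > 0 else 0.0
    if variant == "student":
        df: float = n1 + n2 - 2
        se = sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    elif variant == "welch":
        se2 = v1 / n1 + v2 / n2
        se = sqrt(se2)
        df = (
            se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
            if se2 > 0
            else n1 + n2 - 2
        )
    else:
        raise ValueError("variant must be 'student' or 'welch'")
    if se == 0:
        t, p = 0.0, 1.0
        ci = (diff, diff)
    else:
        t = diff / se
        p = float(2.0 * sps.t.sf(abs(t), df))
        half = sps.t.ppf(0.975, df) * se
        ci = (diff - half, diff + half)
    return TestResult(
        "t", float(t), float(df), p,
        {"d": float(d), "mean_diff": float(diff), "ci": [float(ci[0]), float(ci[1])]},
    )


# ---------------------------------------------------------------------------
# study-specific stages


def exclude_unassessable(data: pd.DataFrame) -> pd.DataFrame:
    """Drop participants whose self-assessment is 'normal' or 'unable'."""
    return data[data["self_assessment"].isin(["good", "bad"])].copy()


def metacompetence_table(
    data: pd.DataFrame,
    threshold: float = 7.0,
    denominator: str = "claim_good",
) -> ContingencyTable:
    """Cross group x (self-assessment claim, measured performance).

    Expects data already filtered to good/bad claims.  Percentages use
    either the claim-good subsample (default, the four cells summing to
    100 as in the study's figure) or the whole filtered sample.
    """
    if data.empty:
        raise ValueError("empty dataset")
    if denominator not in ("claim_good", "all"):
        raise ValueError("denominator must be 'claim_good' or 'all'")
    d = data.copy()
    bad = set(d["self_assessment"]) - {"good", "bad"}
    if bad:
        raise ValueError(
            f"unexpected self-assessment labels {sorted(bad)}; "
            "apply exclude_unassessable first"
        )
    d["performance"] = [
        classify_performance(s, threshold) for s in d["final_score"]
    ]
    counts = (
        d.groupby(["group", "self_assessment", "performance"], observed=False)
        .size()
        .unstack(["self_assessment", "performance"], fill_value=0)
    )
    # stable cell order
    cols = pd.MultiIndex.from_product([["good", "bad"], ["good", "poor"]])
    counts = counts.reindex(columns=cols, fill_value=0)
    counts = counts.reindex(sorted(counts.index), fill_value=0)

    if denominator == "claim_good":
        denom = int(counts[("good", "good")].sum() + counts[("good", "poor")].sum())
        pct_counts = counts[[("good", "good"), ("good", "poor")]]
    else:
        denom = int(counts.to_numpy().sum())
        pct_counts = counts
    if denom == 0:
        raise ValueError("denominator subsample is empty")
    percentages = pct_counts / denom * 100.0
    return ContingencyTable(
        counts=counts,
        percentages=percentages,
        denominator=denominator,
        n_denominator=denom,
    )


def experience_split_anova(
    musicians: pd.DataFrame, cut: float = 8.0
) -> tuple[TestResult, list[DescriptiveRow]]:
    """One-way ANOVA of CBT score across music-reading experience strata.

    Strata: years_reading < cut versus >= cut (default 8, i.e. 1-7 vs 8+
    years).
    """
    lo = musicians[musicians["years_reading"] < cut]["final_score"].to_numpy()
    hi = musicians[musicians["years_reading"] >= cut]["final_score"].to_numpy()
    if lo.size == 0 or hi.size == 0:
        raise ValueError("one experience stratum is empty; adjust the cut")
    res = one_way_anova([lo, hi])
    rows = describe({f"<{cut:g} years": lo, f">={cut:g} years": hi})
    return res, rows


def run_full_analysis(
    data: pd.DataFrame,
    options: AnalysisOptions | None = None,
    provenance: dict | None = None,
) -> dict:
    """Execute the full analysis pipeline on a joined study table.

    Stages, in study order: exclusion of unassessable participants,
    group-matching checks (age t-test, sex Mann-Whitney), ANCOVA
    assumption checks (Levene, covariate independence, homogeneity of
    slopes), the group ANCOVA controlling sex and age, descriptives,
    age/experience correlations, the self-assessment accuracy contingency
    analysis, and the experience-split ANOVA.  Returns a JSON-serializable
    report.
    """
    options = options or AnalysisOptions()
    full_n = {g: int(n) for g, n in data.groupby("group").size().items()}
    d = exclude_unassessable(data)
    if d["group"].nunique() < 2:
        raise ValueError("analysis needs both groups present after exclusions")
    mus = d[d["group"] == "musician"]
    non = d[d["group"] == "non_musician"]

    sex_code = d["sex"].map({"female": 0, "male": 1})
    matching = {
        "age_t": welch_or_student_t(
            mus["age"].to_numpy(), non["age"].to_numpy(), "student"
        ).to_dict(),
        "sex_mann_whitney": mann_whitney(
            sex_code[d["group"] == "musician"].to_numpy(dtype=float),
            sex_code[d["group"] == "non_musician"].to_numpy(dtype=float),
        ).to_dict(),
    }

    score_groups = [mus["final_score"].to_numpy(), non["final_score"].to_numpy()]
    assumptions = {
        "levene": levene(score_groups, options.levene_center).to_dict(),
        "covariate_independence_age": covariate_independence(d, "age", "group").to_dict(),
        "slopes_homogeneity_age": slopes_homogeneity(d, "final_score", "group", "age").to_dict(),
    }

    anc = ancova(d, "final_score", "group", ("sex", "age"))

    by_group = describe(
        {"musician": score_groups[0], "non_musician": score_groups[1]}
    )
    table1 = describe(
        {
            f"{g}|claim_{c}": sub["final_score"].to_numpy()
            for (g, c), sub in d.groupby(["group", "self_assessment"], observed=True)
            if len(sub) >= 2
        }
    )

    correlations = {
        "age_overall": pearson(d["age"], d["final_score"]).to_dict(),
        "age_musicians": pearson(mus["age"], mus["final_score"]).to_dict(),
        "age_non_musicians": pearson(non["age"], non["final_score"]).to_dict(),
        "years_reading_musicians": pearson(
            mus["years_reading"], mus["final_score"]
        ).to_dict(),
    }

    table = metacompetence_table(
        d, options.performance_threshold, options.meta_denominator
    )
    meta = {
        "table": table.to_dict(),
        "chi_square": chi_square(table.counts.to_numpy()).to_dict(),
        "claim_good_vs_bad_anova": one_way_anova(
            [
                d[d["self_assessment"] == "good"]["final_score"].to_numpy(),
                d[d["self_assessment"] == "bad"]["final_score"].to_numpy(),
            ]
        ).to_dict()
        if (d["self_assessment"] == "bad").any()
        else None,
    }

    try:
        exp_res, exp_rows = experience_split_anova(mus, options.experience_cut)
        experience = {
            "anova": exp_res.to_dict(),
            "descriptives": [r.to_dict() for r in exp_rows],
        }
    except ValueError as err:
        experience = {"error": str(err)}

    return {
        "provenance": provenance or {},
        "options": {
            "performance_threshold": options.performance_threshold,
            "levene_center": options.levene_center,
            "meta_denominator": options.meta_denominator,
            "experience_cut": options.experience_cut,
        },
        "sample": {
            "n_simulated": full_n,
            "n_analyzed": {g: int(n) for g, n in d.groupby("group").size().items()},
            "n_excluded": int(len(data) - len(d)),
        },
        "matching": matching,
        "assumptions": assumptions,
        "ancova": anc.to_dict(),
        "descriptives": {
            "by_group": [r.to_dict() for r in by_group],
            "table1": [r.to_dict() for r in table1],
        },
        "correlations": correlations,
        "metacompetence": meta,
        "experience_split": experience,
    }


def render_report(report: dict) -> str:
    """Plain-text rendering of a full-analysis report."""

    def fmt_test(t: dict) -> str:
        df = t.get("df")
        dfs = (
            f"({df[0]},{df[1]})" if isinstance(df, list)
            else f"({df:g})" if isinstance(df, (int, float)) and df is not None
            else ""
        )
        eff = t.get("effect") or {}
        extra = "".join(
            f", {k} = {round_half_up(v, 3):g}"
            for k, v in eff.items()
            if isinstance(v, (int, float))
        )
        return (
            f"{t['statistic']}{dfs} = {round_half_up(t['value'], 2):g}, "
            f"p = {round_half_up(t['p'], 3):g}{extra}"
        )

    lines = ["CBT study report", "================", ""]
    n = report["sample"]
    lines.append(
        f"Sample: {n['n_analyzed']} analyzed "
        f"({n['n_excluded']} excluded as normal/unable)."
    )
    lines.append("")
    lines.append("Matching checks")
    lines.append(f"  age: {fmt_test(report['matching']['age_t'])}")
    lines.append(f"  sex: {fmt_test(report['matching']['sex_mann_whitney'])}")
    lines.append("Assumption checks")
    for key, label in [
        ("levene", "Levene"),
        ("covariate_independence_age", "age independence"),
        ("slopes_homogeneity_age", "slope homogeneity"),
    ]:
        lines.append(f"  {label}: {fmt_test(report['assumptions'][key])}")
    lines.append("ANCOVA (final score ~ group + sex + age)")
    for t in report["ancova"]["terms"]:
        lines.append(
            f"  {t['name']}: F({t['df1']},{t['df2']}) = "
            f"{round_half_up(t['F'], 2):g}, p = {round_half_up(t['p'], 3):g}, "
            f"eta_p^2 = {round_half_up(t['eta_p_sq'], 3):g}"
        )
    lines.append("Group descriptives")
    for r in report["descriptives"]["by_group"]:
        lines.append(
            f"  {r['label']}: M = {round_half_up(r['mean'], 2):g}, "
            f"SD = {round_half_up(r['sd'], 2):g}, 95% CI "
            f"[{round_half_up(r['ci_low'], 2):g}, {round_half_up(r['ci_high'], 2):g}], "
            f"n = {r['n']}"
        )
    lines.append("Correlations")
    for key, t in report["correlations"].items():
        lines.append(f"  {key}: {fmt_test(t)}")
    meta = report["metacompetence"]
    lines.append(
        "Metacompetence (percent of claim-good sample, "
        f"n = {meta['table']['n_denominator']})"
    )
    for cell, v in meta["table"]["percentages"].items():
        lines.append(f"  {cell}: {round_half_up(v, 2):g}%")
    lines.append(f"  chi-square: {fmt_test(meta['chi_square'])}")
    exp = report["experience_split"]
    if "anova" in exp:
        lines.append(f"Experience split: {fmt_test(exp['anova'])}")
        for r in exp["descriptives"]:
            lines.append(
                f"  {r['label']}: M = {round_half_up(r['mean'], 2):g}, "
                f"SD = {round_half_up(r['sd'], 2):g}, n = {r['n']}"
            )
    return "\n".join(lines) + "\n"
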