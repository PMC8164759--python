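"""Cohort statistics: group comparisons, contingency tests, survival and concordance.

The analysis plan mirrors a standard IHC cohort study: Kruskal–Wallis
tests (with Dunn's pairwise post-hoc, Bonferroni-adjusted) compare
hotspot marker levels across histological groups; uncorrected Pearson
χ² tests associate dichotomized markers with clinicopathological
variables; Mann–Whitney U compares infiltrates between IDO-positive
and IDO-negative tumors; Kaplan–Meier/log-rank and Cox regression
(Efron tie handling, via lifelines) cover uni- and multivariate
survival; Pearson correlation links markers and raters.  Missing data
are handled complete-case per test, with n reported for every test.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .datatypes import CoxConvergenceError, TestResult
from . import scoring

ALPHA = 0.050  # significance threshold, inclusive


# --- contingency --------------------------------------------------------------

def pearson_chi2(table) -> TestResult:
    """Uncorrected Pearson χ² for a 2×2 table.

    statistic = N(ad − bc)² / (r₁ r₂ c₁ c₂), df = 1, upper-tail
    chi-square p.  No continuity correction.  A zero row or column
    margin leaves the test undefined and raises ValueError.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("pearson_chi2 expects a 2x2 table of non-negative counts")
    rows, cols = t.sum(axis=1), t.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("chi-square undefined: a table margin is zero")
    n = t.sum()
    a, b, c, d = t.ravel()
    statistic = n * (a * d - b * c) ** 2 / (rows.prod() * cols.prod())
    return TestResult(
        method="pearson_chi2",
        statistic=float(statistic),
        p_value=float(sps.chi2.sf(statistic, 1)),
        n=int(n),
        df=1,
    )


# --- rank tests ---------------------------------------------------------------

def kruskal_wallis(groups: Sequence[Sequence[float]]) -> TestResult:
    """Tie-corrected Kruskal–Wallis H with the chi-square approximation."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    groups = [g[np.isfinite(g)] for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("kruskal_wallis needs >= 2 non-empty groups")
    n = int(sum(len(g) for g in groups))
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:  # all observations tied: H := 0, p := 1
        return TestResult("kruskal_wallis", 0.0, 1.0, n, df=len(groups) - 1)
    h, p = sps.kruskal(*groups)
    return TestResult("kruskal_wallis", float(h), float(p), n, df=len(groups) - 1)


def pairwise_posthoc(
    groups: Sequence[Sequence[float]],
    labels: Optional[Sequence[str]] = None,
) -> list[TestResult]:
    """Dunn's z-tests on pooled ranks for all group pairs, Bonferroni-adjusted.

    z_ij = |R̄_i − R̄_j| / sqrt((N(N+1)/12 − T)(1/n_i + 1/n_j)) with the
    tie term T = Σ(t³ − t) / (12(N − 1)); adjusted p = min(1, m·p_raw)
    with m = k(k−1)/2 comparisons.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    groups = [g[np.isfinite(g)] for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValueError("post-hoc needs >= 2 non-empty groups")
    if labels is None:
        labels = [f"group{i}" for i in range(len(groups))]
    pooled = np.concatenate(groups)
    ranks = sps.rankdata(pooled)
    n_total = len(pooled)
    sizes = [len(g) for g in groups]
    offsets = np.cumsum([0] + sizes)
    mean_ranks = [ranks[offsets[i]:offsets[i + 1]].mean() for i in range(len(groups))]

    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1)) if n_total > 1 else 0.0
    var_factor = n_total * (n_total + 1) / 12.0 - tie_term

    k = len(groups)
    m = k * (k - 1) // 2
    out = []
    for i in range(k):
        for j in range(i + 1, k):
            if var_factor <= 0:
                z, p_raw = 0.0, 1.0
            else:
                se = np.sqrt(var_factor * (1.0 / sizes[i] + 1.0 / sizes[j]))
                z = abs(mean_ranks[i] - mean_ranks[j]) / se
                p_raw = 2.0 * sps.norm.sf(z)
            out.append(
                TestResult(
                    method="dunn_z",
                    statistic=float(z),
                    p_value=float(min(1.0, m * p_raw)),
                    n=sizes[i] + sizes[j],
                    adjustment="bonferroni",
                    detail={"pair": f"{labels[i]} vs {labels[j]}", "p_raw": float(p_raw)},
                )
            )
    return out


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided Mann–Whitney U.

    Exact p for small samples (both n ≤ 8, no ties), otherwise the
    normal approximation with tie correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[np.isfinite(x)], y[np.isfinite(y)]
    if len(x) == 0 or len(y) == 0:
        raise ValueError("mann_whitney_u needs non-empty samples")
    pooled = np.concatenate([x, y])
    has_ties = len(np.unique(pooled)) < len(pooled)
    if np.ptp(pooled) == 0:  # identical constants: no evidence either way
        u = len(x) * len(y) / 2.0
        return TestResult("mann_whitney_u", float(u), 1.0, len(x) + len(y))
    method = "exact" if (max(len(x), len(y)) <= 8 and not has_ties) else "asymptotic"
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method=method)
    return TestResult(
        method="mann_whitney_u",
        statistic=float(res.statistic),
        p_value=float(min(1.0, res.pvalue)),
        n=len(x) + len(y),
        detail={"p_method": method},
    )


def pearson_correlation(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Pearson r with the t-transform p-value; complete-case on pairs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) != len(y):
        raise ValueError("x and y must have equal length")
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if len(x) < 3:
        raise ValueError("pearson correlation needs >= 3 paired values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("pearson correlation undefined for constant input")
    r, p = sps.pearsonr(x, y)
    return TestResult("pearson_r", float(r), float(p), len(x))


# --- survival -----------------------------------------------------------------

def km_logrank(
    time: Sequence[float],
    event: Sequence[float],
    group_label: Sequence,
) -> tuple[dict, TestResult]:
    """Kaplan–Meier curves per group plus the two-group log-rank test."""
    from lifelines import KaplanMeierFitter
    from lifelines.statistics import logrank_test

    df = pd.DataFrame({"time": time, "event": event, "group": group_label}).dropna()
    levels = sorted(df["group"].unique())
    if len(levels) != 2:
        raise ValueError(f"km_logrank expects exactly 2 groups, got {levels}")
    if (df["time"] < 0).any():
        raise ValueError("survival times must be >= 0")
    sub = {lvl: df[df["group"] == lvl] for lvl in levels}
    if any(len(s) == 0 for s in sub.values()):
        raise ValueError("a group has zero subjects")
    if df["event"].sum() == 0:
        raise ValueError("log-rank undefined: no events in either group")

    curves = {}
    for lvl, s in sub.items():
        kmf = KaplanMeierFitter()
        kmf.fit(s["time"], s["event"], label=str(lvl))
        curves[lvl] = kmf.survival_function_

    a, b = levels
    res = logrank_test(
        sub[a]["time"], sub[b]["time"], sub[a]["event"], sub[b]["event"]
    )
    tr = TestResult(
        method="logrank",
        statistic=float(res.test_statistic),
        p_value=float(res.p_value),
        n=len(df),
        df=1,
        detail={"groups": f"{a} vs {b}", "n_events": float(df["event"].sum())},
    )
    return curves, tr


def cox_regression(
    time: Sequence[float],
    event: Sequence[float],
    covariates: pd.DataFrame,
) -> tuple[pd.DataFrame, list[TestResult]]:
    """Cox proportional hazards (Efron ties) via lifelines.

    Returns the summary table (hazard ratios with 95 % CI) and one Wald
    test result per covariate.  Non-convergence or separation raises
    :class:`CoxConvergenceError`.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    df = pd.concat(
        [pd.DataFrame({"time": np.asarray(time, float), "event": np.asarray(event, float)}),
         covariates.reset_index(drop=True)],
        axis=1,
    ).dropna()
    if df["event"].sum() < 1:
        raise CoxConvergenceError("no events: partial likelihood is flat")
    cph = CoxPHFitter()
    try:
        cph.fit(df, duration_col="time", event_col="event")
    except (ConvergenceError, ValueError) as exc:
        raise CoxConvergenceError(f"Cox fit failed: {exc}") from exc
    if not np.all(np.isfinite(cph.params_)):
        raise CoxConvergenceError("Cox fit produced non-finite coefficients")

    summary = cph.summary
    results = [
        TestResult(
            method="cox_wald",
            statistic=float(row["z"]),
            p_value=float(row["p"]),
            n=len(df),
            detail={
                "covariate": str(name),
                "hazard_ratio": float(row["exp(coef)"]),
                "hr_ci_low": float(row["exp(coef) lower 95%"]),
                "hr_ci_high": float(row["exp(coef) upper 95%"]),
            },
        )
        for name, row in summary.iterrows()
    ]
    return summary, results


# --- concordance --------------------------------------------------------------

def interrater_concordance(
    auto_counts: Sequence[float],
    manual_counts: Sequence[float],
    qc_flags: Optional[Sequence[bool]] = None,
) -> tuple[TestResult, np.ndarray]:
    """Method-vs-rater agreement plus the override-resolved final counts.

    Returns the Pearson correlation between the automated and manual
    count vectors, and the final counts in which images flagged for
    manual review take the manual value.
    """
    auto = np.asarray(auto_counts, dtype=float)
    manual = np.asarray(manual_counts, dtype=float)
    if len(auto) != len(manual):
        raise ValueError("count vectors must align")
    if qc_flags is None:
        flags = np.zeros(len(auto), dtype=bool)
    else:
        flags = np.asarray(qc_flags, dtype=bool)
        if len(flags) != len(auto):
            raise ValueError("qc_flags must align with counts")
    if np.array_equal(auto, manual):
        tr = TestResult("pearson_r", 1.0, 0.0, len(auto))
    else:
        tr = pearson_correlation(auto, manual)
    final = np.where(flags, manual, auto)
    return tr, final


# --- full pipeline ------------------------------------------------------------

_REQUIRED_COLUMNS = [
    "sample_id", "group", "treg_count", "ido_stromal_count",
    "ido_coverage_category", "ido_status", "ido_intensity_group",
    "nodular_growth", "mitoses_present", "capsule_rupture",
    "recurrence", "locoregional_recurrence", "distal_recurrence",
    "rfs_years", "event_recurrence_free",
]


def _chi2_from_columns(df: pd.DataFrame, row_col: str, col_col: str) -> TestResult:
    sub = df[[row_col, col_col]].dropna()
    tab = pd.crosstab(sub[row_col], sub[col_col])
    if tab.shape != (2, 2):
        raise ValueError(f"{row_col} x {col_col}: not a 2x2 table (shape {tab.shape})")
    return pearson_chi2(tab.to_numpy())


def run_full_analysis(
    cohort: pd.DataFrame,
    groups: Optional[Sequence[str]] = None,
    tests: Optional[Sequence[str]] = None,
) -> dict:
    """Run the whole cohort analysis plan and return a JSON-ready report.

    Tests: Kruskal–Wallis (+ Dunn/Bonferroni post-hoc) across the
    histological groups for both hotspot markers and the IDO coverage
    category; χ² associations of IDO tumor-cell status with growth
    pattern, mitoses and recurrence (and intensity group with capsule
    rupture in nodal metastases); Mann–Whitney comparisons of
    infiltrates by IDO status; Kaplan–Meier/log-rank for recurrence-
    free survival by IDO status; Cox regression with histological group
    as covariate; Pearson correlation between the two markers; median
    dichotomization thresholds.  Tests whose inputs degenerate (e.g. a
    zero margin in a random cohort) are reported as errors, not raised.
    ``tests`` restricts the run to the named subset (useful for
    replication studies of a single test).
    """
    missing = [c for c in _REQUIRED_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort table is missing required columns: {missing}")
    group_order = list(groups) if groups is not None else [
        g for g in ("benign", "dysplastic", "in_situ", "pT1", "pT4", "pN1")
        if g in set(cohort["group"])
    ]

    wanted = set(tests) if tests is not None else None
    report: dict = {"n_samples": int(len(cohort)), "groups": group_order, "tests": {}}
    out_tests = report["tests"]

    def record(name, fn):
        if wanted is not None and name not in wanted:
            return None
        try:
            res = fn()
        except (ValueError, CoxConvergenceError) as exc:
            out_tests[name] = {"error": str(exc)}
            return None
        out_tests[name] = res.to_dict() if isinstance(res, TestResult) else res
        return res

    # group comparisons of marker levels
    for marker in ("treg_count", "ido_stromal_count", "ido_coverage_category"):
        by_group = [cohort.loc[cohort["group"] == g, marker].to_numpy(float) for g in group_order]
        record(f"kw_{marker}", lambda bg=by_group: kruskal_wallis(bg))
        record(
            f"posthoc_{marker}",
            lambda bg=by_group: [t.to_dict() for t in pairwise_posthoc(bg, group_order)],
        )

    # contingency: IDO tumor-cell status vs clinicopathological parameters
    malignant = cohort[cohort["group"].isin(("pT1", "pT4", "pN1"))]
    for var in ("nodular_growth", "mitoses_present", "recurrence",
                "locoregional_recurrence", "distal_recurrence"):
        record(f"chi2_ido_status_x_{var}",
               lambda v=var: _chi2_from_columns(malignant, "ido_status", v))
    nodal = cohort[cohort["group"] == "pN1"]
    record("chi2_intensity_x_capsule_rupture",
           lambda: _chi2_from_columns(nodal, "ido_intensity_group", "capsule_rupture"))

    # infiltrates by IDO status (malignant tumors)
    for marker in ("treg_count", "ido_stromal_count"):
        pos = malignant.loc[malignant["ido_status"] == scoring.IDO_POSITIVE, marker]
        neg = malignant.loc[malignant["ido_status"] == scoring.IDO_NEGATIVE, marker]
        record(f"mwu_{marker}_by_ido_status", lambda p=pos, n=neg: mann_whitney_u(p, n))

    # recurrence-free survival by IDO status
    surv = malignant[["rfs_years", "event_recurrence_free", "ido_status"]].dropna()
    record("logrank_rfs_by_ido_status",
           lambda: km_logrank(surv["rfs_years"], surv["event_recurrence_free"], surv["ido_status"])[1])

    # multivariate: Cox with histological group as covariate
    def _cox():
        d = malignant[["rfs_years", "event_recurrence_free", "ido_status", "group"]].dropna()
        cov = pd.DataFrame({
            "ido_positive": (d["ido_status"] == scoring.IDO_POSITIVE).astype(float).to_numpy(),
        })
        for g in ("pT4", "pN1"):  # pT1 is the reference level
            cov[f"group_{g}"] = (d["group"] == g).astype(float).to_numpy()
        _, results = cox_regression(d["rfs_years"].to_numpy(), d["event_recurrence_free"].to_numpy(), cov)
        return {r.detail["covariate"]: r.to_dict() for r in results}

    record("cox_rfs_ido_status_adj_group", _cox)

    # marker correlation
    record("pearson_treg_vs_ido_stromal",
           lambda: pearson_correlation(cohort["treg_count"], cohort["ido_stromal_count"]))

    # median dichotomization thresholds used for the contingency/survival stages
    try:
        report["median_thresholds"] = {
            "treg_count": scoring.dichotomize_by_median(cohort["treg_count"]).threshold,
            "ido_stromal_count": scoring.dichotomize_by_median(cohort["ido_stromal_count"]).threshold,
        }
    except ValueError as exc:
        report["median_thresholds"] = {"error": str(exc)}
    return report


def render_report_markdown(report: dict) -> str:
    """Human-readable Markdown rendering of a full-analysis report."""
    lines = [
        "# Cohort analysis report",
        "",
        f"Samples: {report['n_samples']}; groups: {', '.join(report['groups'])}",
        "",
        "| test | statistic | df | p | n |",
        "|---|---|---|---|---|",
    ]
    for name, res in report["tests"].items():
        if isinstance(res, dict) and "error" in res:
            lines.append(f"| {name} | — | — | error: {res['error']} | — |")
        elif isinstance(res, dict) and "p_value" in res:
            df = res.get("df", "—")
            lines.append(
                f"| {name} | {res['statistic']:.4g} | {df} | {res['p_value']:.4g} | {res['n']} |"
            )
        else:
            lines.append(f"| {name} | (multiple) | | | |")
    thr = report.get("median_thresholds", {})
    if thr and "error" not in thr:
        lines += ["", f"Median split thresholds: Treg {thr['treg_count']:.2f}, "
                      f"IDO stromal {thr['ido_stromal_count']:.2f}"]
    return "\n".join(lines) + "\n"
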