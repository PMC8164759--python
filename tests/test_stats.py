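"""Statistical operations against independent brute-force oracles."""

import itertools
from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps
from scipy.optimize import minimize_scalar

from ihctme.cohort_stats import (
    cox_regression,
    interrater_concordance,
    km_logrank,
    kruskal_wallis,
    mann_whitney_u,
    pairwise_posthoc,
    pearson_chi2,
    pearson_correlation,
    run_full_analysis,
)
from ihctme.datatypes import CoxConvergenceError
from ihctme.synthetic import CohortSimParams, generate_cohort, simulate_survival


# --- Pearson chi-square -------------------------------------------------------

class TestPearsonChi2:
    def test_proportional_rows_give_zero_statistic(self):
        res = pearson_chi2([[2, 4], [3, 6]])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_margin_is_an_error(self):
        with pytest.raises(ValueError):
            pearson_chi2([[0, 0], [3, 6]])
        with pytest.raises(ValueError):
            pearson_chi2([[0, 4], [0, 6]])

    def test_capsule_rupture_table(self):
        """[[0,4],[6,2]]: statistic 6.000, p ≈ 0.0143."""
        res = pearson_chi2([[0, 4], [6, 2]])
        assert res.statistic == pytest.approx(6.0, abs=1e-12)
        assert res.p_value == pytest.approx(0.0143, abs=5e-4)

    def test_nodular_growth_table_rounds_to_alpha(self):
        res = pearson_chi2([[11, 10], [17, 4]])
        assert round(res.p_value, 3) == 0.050

    def test_matches_scipy_oracle_on_random_tables(self, rng):
        for _ in range(300):
            t = rng.integers(1, 40, size=(2, 2))
            mine = pearson_chi2(t)
            stat, p, df, _ = sps.chi2_contingency(t, correction=False)
            assert mine.statistic == pytest.approx(stat, abs=1e-10)
            assert mine.p_value == pytest.approx(p, abs=1e-10)
            assert mine.df == df == 1


# --- Kruskal-Wallis and Dunn post-hoc ----------------------------------------

def _kw_oracle(groups):
    """Tie-corrected H from first principles with exact rank arithmetic."""
    pooled = sorted((v, gi) for gi, g in enumerate(groups) for v in g)
    n = len(pooled)
    ranks = {}
    i = 0
    while i < n:
        j = i
        while j < n and pooled[j][0] == pooled[i][0]:
            j += 1
        avg = Fraction(i + 1 + j, 2)
        for k in range(i, j):
            ranks.setdefault(pooled[i][0], avg)
        i = j
    rank_sums = [Fraction(0)] * len(groups)
    for gi, g in enumerate(groups):
        for v in g:
            rank_sums[gi] += ranks[v]
    h = Fraction(12, n * (n + 1)) * sum(
        rs * rs / len(g) for rs, g in zip(rank_sums, groups)
    ) - 3 * (n + 1)
    tie_counts = {}
    for v, _ in pooled:
        tie_counts[v] = tie_counts.get(v, 0) + 1
    correction = 1 - Fraction(sum(t**3 - t for t in tie_counts.values()), n**3 - n)
    return float(h / correction) if correction else 0.0


class TestKruskalWallis:
    def test_hand_ranked_example(self):
        """[1,2,3] vs [4,5,6]: rank sums 6 and 15 give H = 27/7 ≈ 3.857."""
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert res.statistic == pytest.approx(27 / 7, abs=1e-12)
        assert res.df == 1

    def test_constant_data_gives_p_one(self):
        res = kruskal_wallis([[5, 5, 5], [5, 5], [5]])
        assert res.statistic == 0.0 and res.p_value == 1.0

    def test_fewer_than_two_groups_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1, 2, 3]])

    def test_matches_exact_rank_oracle(self, rng):
        for _ in range(200):
            k = int(rng.integers(2, 5))
            groups = [rng.integers(0, 8, size=int(rng.integers(2, 6))).tolist() for _ in range(k)]
            if len({v for g in groups for v in g}) == 1:
                continue
            res = kruskal_wallis(groups)
            assert res.statistic == pytest.approx(_kw_oracle(groups), abs=1e-10)


class TestDunnPosthoc:
    def test_identical_groups_have_unit_adjusted_p(self):
        groups = [[1, 2, 3], [1, 2, 3], [10, 11, 12]]
        results = pairwise_posthoc(groups, labels=["a", "b", "c"])
        pair_ab = next(r for r in results if r.detail["pair"] == "a vs b")
        assert pair_ab.statistic == pytest.approx(0.0, abs=1e-12)
        assert pair_ab.p_value == 1.0

    def test_bonferroni_adjustment_identity(self, rng):
        groups = [rng.normal(size=8).tolist() for _ in range(4)]
        results = pairwise_posthoc(groups)
        m = 4 * 3 // 2
        assert len(results) == m
        for r in results:
            assert r.p_value == pytest.approx(min(1.0, m * r.detail["p_raw"]), abs=1e-12)

    def test_shifted_group_dominates_significant_pairs(self):
        """Only pairs involving the shifted group reject, in >= 90 % of replicates."""
        hits = 0
        n_rep = 200
        for s in range(n_rep):
            r = np.random.default_rng(1_000 + s)
            groups = [r.normal(0, 1, 25), r.normal(0, 1, 25), r.normal(2.0, 1, 25)]
            results = pairwise_posthoc(groups, labels=["g0", "g1", "g2"])
            sig = {res.detail["pair"] for res in results if res.p_value <= 0.05}
            if sig == {"g0 vs g2", "g1 vs g2"}:
                hits += 1
        assert hits / n_rep >= 0.90


# --- Mann-Whitney U -----------------------------------------------------------

def _u_oracle(x, y):
    return sum(
        1.0 if xi > yi else (0.5 if xi == yi else 0.0) for xi in x for yi in y
    )


def _exact_p_oracle(x, y):
    """Two-sided exact p by enumerating all label assignments."""
    pooled = list(x) + list(y)
    n1 = len(x)
    u_obs = _u_oracle(x, y)
    n_all = 0
    n_extreme = 0
    u_mid = n1 * len(y) / 2.0
    for idx in itertools.combinations(range(len(pooled)), n1):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in idx]
        u = _u_oracle(xs, ys)
        n_all += 1
        if abs(u - u_mid) >= abs(u_obs - u_mid) - 1e-12:
            n_extreme += 1
    return n_extreme / n_all


class TestMannWhitney:
    def test_separated_pairs_exact_p(self):
        """x=[1,2], y=[3,4]: U = 0 and exact two-sided p = 1/3."""
        res = mann_whitney_u([1, 2], [3, 4])
        assert res.statistic == 0.0
        assert res.p_value == pytest.approx(1 / 3, abs=1e-12)

    def test_identical_multisets_give_p_one(self):
        res = mann_whitney_u([3, 1, 2], [1, 2, 3])
        assert res.p_value == pytest.approx(1.0)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])

    def test_u_statistic_matches_pair_counting_oracle(self, rng):
        for _ in range(200):
            x = rng.integers(0, 12, size=int(rng.integers(1, 10)))
            y = rng.integers(0, 12, size=int(rng.integers(1, 10)))
            res = mann_whitney_u(x, y)
            assert res.statistic == pytest.approx(_u_oracle(x, y), abs=1e-10)

    def test_small_sample_p_matches_enumeration(self, rng):
        for _ in range(20):
            x = rng.normal(size=int(rng.integers(2, 6)))
            y = rng.normal(size=int(rng.integers(2, 6)))
            res = mann_whitney_u(x, y)
            assert res.p_value == pytest.approx(_exact_p_oracle(x, y), abs=1e-10)


# --- Pearson correlation ------------------------------------------------------

class TestPearsonCorrelation:
    def test_perfect_correlations(self):
        x = [1.0, 2.0, 3.0, 4.5]
        assert pearson_correlation(x, x).statistic == pytest.approx(1.0)
        assert pearson_correlation(x, [-v for v in x]).statistic == pytest.approx(-1.0)

    def test_constant_input_rejected(self):
        with pytest.raises(ValueError):
            pearson_correlation([1, 1, 1], [1, 2, 3])

    def test_matches_covariance_formula_oracle(self, rng):
        for _ in range(200):
            n = int(rng.integers(3, 12))
            x = rng.integers(-5, 6, size=n)
            y = rng.integers(-5, 6, size=n)
            if len(set(x.tolist())) == 1 or len(set(y.tolist())) == 1:
                continue
            xf = [Fraction(int(v)) for v in x]
            yf = [Fraction(int(v)) for v in y]
            mx, my = sum(xf) / n, sum(yf) / n
            num = sum((a - mx) * (b - my) for a, b in zip(xf, yf))
            den2 = sum((a - mx) ** 2 for a in xf) * sum((b - my) ** 2 for b in yf)
            oracle = float(num) / float(den2) ** 0.5
            assert pearson_correlation(x, y).statistic == pytest.approx(oracle, abs=1e-10)


# --- survival -----------------------------------------------------------------

class TestKaplanMeierLogrank:
    def test_identical_groups_do_not_differ(self):
        t = [1, 2, 3, 4, 5, 6]
        e = [1, 0, 1, 1, 0, 1]
        curves, res = km_logrank(t + t, e + e, ["a"] * 6 + ["b"] * 6)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)

    def test_no_events_is_degenerate(self):
        with pytest.raises(ValueError):
            km_logrank([1, 2, 3, 4], [0, 0, 0, 0], ["a", "a", "b", "b"])

    def test_km_estimate_matches_hand_risk_table(self):
        """Product-limit estimate against a step-by-step hand computation."""
        time = [1, 2, 2, 3, 5, 7]
        event = [1, 1, 0, 1, 1, 0]
        curves, _ = km_logrank(
            time * 2, event * 2, ["a"] * 6 + ["b"] * 6
        )
        sf = curves["a"].iloc[:, 0]
        # risk table: t=1 d=1 n=6 -> 5/6; t=2 d=1 n=5 -> 5/6*4/5; t=3 d=1 n=3;
        # t=5 d=1 n=2
        expected = {
            1.0: 5 / 6,
            2.0: 5 / 6 * 4 / 5,
            3.0: 5 / 6 * 4 / 5 * 2 / 3,
            5.0: 5 / 6 * 4 / 5 * 2 / 3 * 1 / 2,
        }
        for t_val, s_val in expected.items():
            assert sf.loc[t_val] == pytest.approx(s_val, abs=1e-12)

    def test_logrank_matches_hand_observed_minus_expected(self):
        """Two-group log-rank against a hand-computed risk-table oracle."""
        t = [1, 2, 3, 4, 5, 6, 7, 8]
        e = [1, 1, 1, 0, 1, 1, 0, 1]
        g = ["a", "b", "a", "b", "a", "b", "a", "b"]
        _, res = km_logrank(t, e, g)
        # hand computation of sum(O-E) and hypergeometric variance per event time
        o_minus_e = 0.0
        var = 0.0
        for ti, ei, gi in sorted(zip(t, e, g)):
            if not ei:
                continue
            at_risk = [(tj, gj) for tj, ej, gj in zip(t, e, g) if tj >= ti]
            n = len(at_risk)
            n_a = sum(1 for _, gj in at_risk if gj == "a")
            d = 1
            o_minus_e += (1 if gi == "a" else 0) - d * n_a / n
            if n > 1:
                var += d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
        oracle = o_minus_e**2 / var
        assert res.statistic == pytest.approx(oracle, abs=1e-10)


def _cox_neg_loglik(beta, time, event, x):
    """Breslow/Efron-free partial likelihood (valid: no tied event times)."""
    order = np.argsort(time)
    time, event, x = time[order], event[order], x[order]
    ll = 0.0
    for i in range(len(time)):
        if event[i]:
            risk = x[time >= time[i]]
            ll += beta * x[i] - np.log(np.sum(np.exp(beta * risk)))
    return -ll


class TestCoxRegression:
    def test_matches_partial_likelihood_oracle_without_ties(self, rng):
        for seed in range(5):
            r = np.random.default_rng(seed)
            n = 30
            x = r.normal(size=n)
            t = r.exponential(1.0 / np.exp(0.5 * x))
            e = (r.random(n) < 0.8).astype(float)
            if e.sum() < 2:
                continue
            summary, _ = cox_regression(t, e, pd.DataFrame({"x": x}))
            opt = minimize_scalar(
                _cox_neg_loglik, bounds=(-4, 4), args=(t, e, x), method="bounded",
                options={"xatol": 1e-10},
            )
            assert summary["coef"].iloc[0] == pytest.approx(opt.x, abs=1e-4)

    def test_null_covariate_recovers_unit_hazard_ratio(self):
        df = simulate_survival(2000, hazard_ratio=1.0, seed=7)
        summary, results = cox_regression(df["time"], df["event"], df[["recurrence"]])
        lo, hi = summary["exp(coef) lower 95%"].iloc[0], summary["exp(coef) upper 95%"].iloc[0]
        assert lo <= 1.0 <= hi

    def test_no_events_raises_explicit_failure(self):
        with pytest.raises(CoxConvergenceError):
            cox_regression([1, 2, 3], [0, 0, 0], pd.DataFrame({"x": [0.0, 1.0, 0.5]}))


# --- concordance --------------------------------------------------------------

class TestInterrater:
    def test_perfect_agreement(self):
        res, final = interrater_concordance([3, 5, 8], [3, 5, 8])
        assert res.statistic == 1.0
        assert np.array_equal(final, [3, 5, 8])

    def test_flagged_images_take_manual_value(self):
        _, final = interrater_concordance([10, 20, 30], [11, 25, 29], [False, True, False])
        assert final.tolist() == [10, 25, 30]

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            interrater_concordance([1, 2], [1, 2, 3])

    def test_correlation_decreases_with_rater_noise(self):
        """Mean concordance over seeds falls monotonically as rater noise grows."""
        sds = [1.0, 5.0, 15.0, 40.0]
        mean_r = []
        for sd in sds:
            rs = []
            for s in range(100):
                r = np.random.default_rng(s)
                auto = r.uniform(20, 120, size=60)
                manual = auto + r.normal(0, sd, size=60)
                rs.append(interrater_concordance(auto, manual)[0].statistic)
            mean_r.append(np.mean(rs))
        assert all(a > b for a, b in zip(mean_r, mean_r[1:]))


# --- full pipeline ------------------------------------------------------------

class TestRunFullAnalysis:
    def test_missing_columns_are_listed(self):
        df = generate_cohort(CohortSimParams(seed=1)).drop(columns=["treg_count", "recurrence"])
        with pytest.raises(ValueError, match="treg_count"):
            run_full_analysis(df)

    def test_report_is_deterministic(self):
        import json

        r1 = run_full_analysis(generate_cohort(CohortSimParams(seed=5)))
        r2 = run_full_analysis(generate_cohort(CohortSimParams(seed=5)))
        assert json.dumps(r1, sort_keys=True) == json.dumps(r2, sort_keys=True)

    def test_all_p_values_in_unit_interval_and_n_reconciles(self):
        cohort = generate_cohort(CohortSimParams(seed=3))
        report = run_full_analysis(cohort)
        for name, res in report["tests"].items():
            if isinstance(res, dict) and "p_value" in res:
                assert 0.0 <= res["p_value"] <= 1.0, name
                assert 0 < res["n"] <= len(cohort), name
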