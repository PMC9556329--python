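"""Clinical endpoint statistics: response calls, rates, exact tests, Welch,
TMB, survival, power, correlation."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats
from scipy.optimize import brentq
from scipy.special import gammaln

from immunopred.endpoints import (TmbRecord, classify_response, compute_tmb,
                                  correlate, design_power, fisher_exact,
                                  km_estimate, log_rank, response_rate_ci,
                                  round_percent, welch_p_from_stats, welch_t)


class TestClassifyResponse:
    @pytest.mark.parametrize("viable,resection,expected", [
        (10.0, "R0", "MPR(non-pCR)"),   # threshold is inclusive
        (0.0, "R0", "pCR"),
        (5.0, "R1/R2", "non-MPR"),      # incomplete resection precludes MPR
        (10.1, "R0", "non-MPR"),
        (0.0, "R1/R2", "non-MPR"),
    ])
    def test_categories(self, viable, resection, expected):
        call = classify_response(viable, resection, surgery=True)
        assert call.category == expected

    def test_no_surgery_not_evaluable(self):
        call = classify_response(None, "none", surgery=False)
        assert call.category == "not-evaluable"
        assert call.pathological_regression is None

    def test_regression_scale(self):
        call = classify_response(35.0, "R0", surgery=True)
        assert call.pathological_regression == -65.0

    def test_viable_without_surgery_inconsistent(self):
        with pytest.raises(ValueError, match="without surgery"):
            classify_response(20.0, "none", surgery=False)


class TestRates:
    def test_mpr_rate_from_printed_counts(self):
        r = response_rate_ci(29, 143)
        assert r.rate_percent == 20
        assert r.ci_percent == (14, 28)

    def test_zero_successes(self):
        r = response_rate_ci(0, 50)
        assert r.rate == 0.0 and r.ci_low == 0.0

    def test_wilson_matches_root_finding_oracle(self):
        # invert the Wilson score equation numerically, independently
        x, n, z = 8, 143, stats.norm.ppf(0.975)

        def score(p, side):
            return (x / n - p) + side * z * math.sqrt(p * (1 - p) / n)

        lo = brentq(lambda p: score(p, -1), 1e-9, x / n)
        hi = brentq(lambda p: score(p, 1), x / n, 1 - 1e-9)
        r = response_rate_ci(8, 143, method="wilson")
        assert r.ci_low == pytest.approx(lo, abs=1e-9)
        assert r.ci_high == pytest.approx(hi, abs=1e-9)

    def test_round_half_away_from_zero(self):
        assert round_percent(14.5) == 15
        assert round_percent(-14.5) == -15
        assert round_percent(14.4) == 14

    def test_clopper_pearson_coverage(self):
        # simulation: the exact interval should cover p=0.2 at >= ~95%
        rng = np.random.default_rng(0)
        n, p, reps = 143, 0.2, 2_000
        hits = 0
        for x in rng.binomial(n, p, reps):
            r = response_rate_ci(int(x), n)
            hits += r.ci_low <= p <= r.ci_high
        se = math.sqrt(0.95 * 0.05 / reps)
        assert hits / reps >= 0.95 - 3 * se


class TestFisherExact:
    def test_proportional_rows_give_one(self):
        assert fisher_exact([[2, 4], [1, 2]]) == pytest.approx(1.0)

    def test_2x2_agrees_with_scipy(self):
        rng = np.random.default_rng(1)
        for _ in range(25):
            t = rng.integers(0, 15, (2, 2))
            if t.sum(0).min() == 0 or t.sum(1).min() == 0:
                continue
            ours = fisher_exact(t)
            ref = stats.fisher_exact(t)[1]
            assert ours == pytest.approx(ref, abs=1e-10)

    def test_collapsed_2x3_equals_2x2(self):
        # a zero column contributes nothing to the enumeration
        p2 = fisher_exact([[3, 7], [8, 2]])
        p3 = fisher_exact([[3, 7, 0], [8, 2, 0]])
        assert p3 == pytest.approx(p2, abs=1e-12)

    def test_rxc_matches_log_gamma_oracle(self):
        # independent Freeman-Halton oracle via explicit triple loop
        table = np.array([[6, 47], [1, 19], [15, 30]])
        rows, cols, n = table.sum(1), table.sum(0), table.sum()
        lognorm = (gammaln(rows + 1).sum() + gammaln(cols + 1).sum()
                   - gammaln(n + 1))

        def logp(t):
            return lognorm - gammaln(np.asarray(t) + 1).sum()

        p0 = logp(table)
        total = 0.0
        for a in range(min(rows[0], cols[0]) + 1):
            for b in range(min(rows[1], cols[0] - a) + 1):
                c = cols[0] - a - b
                if 0 <= c <= rows[2]:
                    t = [[a, rows[0] - a], [b, rows[1] - b], [c, rows[2] - c]]
                    lp = logp(t)
                    if lp <= p0 + 1e-12:
                        total += math.exp(lp)
        assert fisher_exact(table) == pytest.approx(total, abs=1e-12)

    def test_negative_entries_rejected(self):
        with pytest.raises(ValueError):
            fisher_exact([[1, -1], [2, 3]])

    def test_empty_margin_rejected(self):
        with pytest.raises(ValueError, match="margin"):
            fisher_exact([[0, 0], [2, 3]])


class TestWelch:
    def test_identical_samples(self):
        x = [1.0, 2.0, 3.0, 4.0]
        w = welch_t(x, x)
        assert w.t == 0.0 and w.p == 1.0

    def test_matches_formula_oracle(self, rng):
        x = rng.normal(0, 1, 20)
        y = rng.normal(0.5, 2, 35)
        w = welch_t(x, y)
        vx, vy = x.var(ddof=1), y.var(ddof=1)
        nx, ny = len(x), len(y)
        t_o = (x.mean() - y.mean()) / math.sqrt(vx / nx + vy / ny)
        df_o = (vx / nx + vy / ny) ** 2 / (
            (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
        )
        assert w.t == pytest.approx(t_o, abs=1e-12)
        assert w.df == pytest.approx(df_o, abs=1e-12)
        ref = stats.ttest_ind(x, y, equal_var=False)
        assert w.p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_zero_variance_names_group(self):
        with pytest.raises(ValueError, match="second"):
            welch_t([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])

    def test_p_from_stats_edge_cases(self):
        assert welch_p_from_stats(0.0, 10.0) == 1.0
        with pytest.raises(ValueError):
            welch_p_from_stats(1.0, 0.0)


class TestTmb:
    def test_simple_arithmetic(self):
        rec = compute_tmb(5, 2_500_000)
        assert rec.tmb == pytest.approx(2.0)
        assert rec.tmb_group == "<10"

    def test_zero_mutations(self):
        rec = compute_tmb(0, 30_000_000)
        assert rec.tmb == 0.0 and rec.tmb_group == "<10"

    def test_bin_edges_exhaustive(self):
        # the strata must partition [0, inf): [0,10), [10,16), [16,inf)
        for tmb, expected in [(0.0, "<10"), (9.999, "<10"), (10.0, "10-15"),
                              (15.4, "10-15"), (15.999, "10-15"),
                              (16.0, ">=16"), (40.0, ">=16")]:
            assert TmbRecord.group_of(tmb) == expected
        grid = np.arange(0, 30, 0.125)
        groups = [TmbRecord.group_of(t) for t in grid]
        assert all(g in ("<10", "10-15", ">=16") for g in groups)

    def test_zero_footprint_rejected(self):
        with pytest.raises(ValueError):
            compute_tmb(3, 0)


class TestKaplanMeier:
    def test_no_events_survival_stays_one(self):
        curve = km_estimate([3, 5, 7], [0, 0, 0])
        assert curve.times.size == 0
        assert curve.landmark(10.0) == 1.0

    def test_no_censoring_equals_empirical_survival(self):
        times = [2.0, 4.0, 6.0, 8.0, 10.0]
        curve = km_estimate(times, [1] * 5)
        for t, s in zip(curve.times, curve.survival):
            assert s == pytest.approx(np.mean(np.array(times) > t), abs=1e-12)

    def test_hand_computed_product_limit_table(self):
        # times 1, 2+, 3, 4, 5+ with events at 1, 3, 4:
        #   t=1: 5 at risk, 1 event -> S = 4/5
        #   t=3: 3 at risk, 1 event -> S = 4/5 * 2/3 = 8/15
        #   t=4: 2 at risk, 1 event -> S = 8/15 * 1/2 = 4/15
        curve = km_estimate([1, 2, 3, 4, 5], [1, 0, 1, 1, 0])
        assert np.allclose(curve.times, [1, 3, 4])
        assert np.allclose(curve.survival, [4 / 5, 8 / 15, 4 / 15],
                           atol=1e-10)
        assert curve.landmark(3.5) == pytest.approx(8 / 15)
        assert curve.landmark(0.5) == 1.0

    def test_agrees_with_lifelines(self, rng):
        from lifelines import KaplanMeierFitter
        times = rng.exponential(10, 60).round(2) + 0.01
        events = rng.integers(0, 2, 60)
        curve = km_estimate(times, events)
        kmf = KaplanMeierFitter().fit(times, events)
        for t, s in zip(curve.times, curve.survival):
            assert s == pytest.approx(
                float(kmf.survival_function_at_times(t).iloc[0]), abs=1e-10
            )

    def test_log_rank_separates_groups(self, rng):
        t1 = rng.exponential(5, 50) + 0.01
        t2 = rng.exponential(50, 50) + 0.01
        chi2, p = log_rank(np.r_[t1, t2], np.ones(100, dtype=int),
                           ["a"] * 50 + ["b"] * 50)
        assert p < 1e-6

    def test_empty_dataset_rejected(self):
        with pytest.raises(ValueError):
            km_estimate([], [])


class TestDesignPower:
    def test_trial_design_reaches_95_percent(self):
        power, critical = design_power(0.05, 0.15, 0.05, 180)
        assert power >= 0.95
        # the critical value is the smallest k with P(X >= k | p0) <= alpha
        assert stats.binom.sf(critical - 1, 180, 0.05) <= 0.05
        assert stats.binom.sf(critical - 2, 180, 0.05) > 0.05

    def test_two_outcome_enumeration(self):
        # n=1: P(X>=1 | p0=0.05) = 0.05 <= alpha, so c=1 and power = p1
        power, critical = design_power(0.05, 0.4, 0.05, 1)
        assert critical == 1
        assert power == pytest.approx(0.4)

    def test_infeasible_returns_zero(self):
        power, critical = design_power(0.5, 0.6, 1e-12, 3)
        assert (power, critical) == (0.0, None)

    def test_invalid_rates_rejected(self):
        with pytest.raises(ValueError):
            design_power(0.3, 0.2, 0.05, 10)


class TestCorrelate:
    def test_perfect_positive_and_negative(self, rng):
        x = rng.random(12)
        assert correlate(x, x)[0] == pytest.approx(1.0)
        assert correlate(x, -x)[0] == pytest.approx(-1.0)

    def test_exact_permutation_p_matches_enumeration(self, rng):
        # full 720-permutation oracle at n=6, computed independently
        x = rng.random(6)
        y = rng.random(6)
        r_obs, p = correlate(x, y, method="pearson")
        count = 0
        for perm in itertools.permutations(range(6)):
            r_perm = np.corrcoef(x, y[list(perm)])[0, 1]
            if abs(r_perm) >= abs(r_obs) - 1e-12:
                count += 1
        assert p == pytest.approx(count / math.factorial(6), abs=1e-12)

    def test_spearman_uses_ranks(self):
        x = [1, 2, 3, 4, 5, 6, 7, 8, 9, 10]
        y = [v ** 3 for v in x]   # monotone -> rho = 1
        assert correlate(x, y, method="spearman")[0] == pytest.approx(1.0)

    def test_large_sample_approximations(self, rng):
        x = rng.normal(0, 1, 50)
        y = 0.5 * x + rng.normal(0, 1, 50)
        r_p, p_p = correlate(x, y, method="pearson")
        ref = stats.pearsonr(x, y)
        assert r_p == pytest.approx(ref.statistic, abs=1e-12)
        assert p_p == pytest.approx(ref.pvalue, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            correlate([1, 1, 1, 1], [1, 2, 3, 4])
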