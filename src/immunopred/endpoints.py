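"""Trial endpoint formulas and statistical tests.

Covers the endpoint layer of a neoadjuvant immunotherapy trial analysis:
pathological response classification (MPR / pCR), response rates with
binomial confidence intervals, exact contingency-table tests (2x2 Fisher
and the Freeman-Halton r x c generalization), Welch's unequal-variance
t-test with Satterthwaite degrees of freedom, tumor mutational burden,
correlation with exact small-sample permutation p-values, Kaplan-Meier
survival with log-rank comparison, and the exact-binomial design power of
a single-arm response-rate test.

Conventions used throughout (documented because the source reports leave
them open):

* MPR is viable tumor <= 10% with complete (R0) resection; incomplete
  resection precludes MPR regardless of viable percent; no surgery means
  not evaluable; pCR is viable = 0 with R0.
* TMB strata <10 / 10-15 / >=16 mut/Mb are implemented as the exhaustive
  half-open partition [0, 10), [10, 16), [16, inf).
* Two-sided 2x2 Fisher p sums all tables with point probability at most
  the observed one (1e-12 comparison tolerance for float ties).
* Percent rates are rounded half away from zero to whole percents.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "ResponseCall",
    "classify_response",
    "is_mpr",
    "RateCI",
    "response_rate_ci",
    "fisher_exact",
    "WelchResult",
    "welch_t",
    "welch_p_from_stats",
    "TmbRecord",
    "compute_tmb",
    "KmCurve",
    "km_estimate",
    "log_rank",
    "design_power",
    "correlate",
    "round_percent",
]

_PROB_TOL = 1e-12


# ---------------------------------------------------------------- response

@dataclass(frozen=True)
class ResponseCall:
    category: str                      # pCR | MPR(non-pCR) | non-MPR | not-evaluable
    pathological_regression: float | None   # viable percent - 100, in [-100, 0]

    @property
    def mpr(self) -> bool:
        return self.category in ("pCR", "MPR(non-pCR)")


def classify_response(
    viable_percent: float | None,
    resection_status: str,
    surgery: bool,
    mpr_threshold: float = 10.0,
) -> ResponseCall:
    """Classify one patient's pathological response.

    Rules: no surgery -> not evaluable (viable must then be absent);
    incomplete resection (R1/R2) -> non-MPR regardless of viable percent;
    otherwise MPR iff viable <= threshold (inclusive), pCR iff viable = 0.
    """
    if not surgery:
        if viable_percent is not None and not (
            isinstance(viable_percent, float) and math.isnan(viable_percent)
        ):
            raise ValueError(
                "viable_percent present for a patient without surgery"
            )
        return ResponseCall(category="not-evaluable", pathological_regression=None)
    if viable_percent is None or (
        isinstance(viable_percent, float) and math.isnan(viable_percent)
    ):
        raise ValueError("viable_percent missing for a resected patient")
    if not 0 <= viable_percent <= 100:
        raise ValueError(f"viable_percent {viable_percent} outside [0, 100]")
    regression = viable_percent - 100.0
    if resection_status in ("R1/R2", "R1", "R2"):
        return ResponseCall(category="non-MPR", pathological_regression=regression)
    if resection_status != "R0":
        raise ValueError(f"unknown resection status {resection_status!r}")
    if viable_percent == 0:
        return ResponseCall(category="pCR", pathological_regression=regression)
    if viable_percent <= mpr_threshold:
        return ResponseCall(category="MPR(non-pCR)",
                            pathological_regression=regression)
    return ResponseCall(category="non-MPR", pathological_regression=regression)


def is_mpr(call: ResponseCall) -> bool:
    return call.mpr


# ------------------------------------------------------------------- rates

def round_percent(x: float) -> int:
    """Round a percent half away from zero to a whole number."""
    return int(math.floor(abs(x) + 0.5) * (1 if x >= 0 else -1))


@dataclass(frozen=True)
class RateCI:
    successes: int
    n: int
    rate: float
    ci_low: float
    ci_high: float
    method: str
    level: float

    @property
    def rate_percent(self) -> int:
        return round_percent(100 * self.rate)

    @property
    def ci_percent(self) -> tuple[int, int]:
        return round_percent(100 * self.ci_low), round_percent(100 * self.ci_high)


def response_rate_ci(
    successes: int, n: int, method: str = "clopper_pearson", level: float = 0.95
) -> RateCI:
    """Binomial rate with Clopper-Pearson (exact) or Wilson interval."""
    if not 0 <= successes <= n or n <= 0:
        raise ValueError(f"need 0 <= successes <= n with n > 0, got {successes}/{n}")
    scipy_method = {"clopper_pearson": "exact", "wilson": "wilson"}.get(method)
    if scipy_method is None:
        raise ValueError(f"unknown CI method {method!r}")
    ci = stats.binomtest(successes, n).proportion_ci(
        confidence_level=level, method=scipy_method
    )
    return RateCI(
        successes=successes, n=n, rate=successes / n,
        ci_low=float(ci.low), ci_high=float(ci.high),
        method=method, level=level,
    )


# ------------------------------------------------------------- exact tests

def _log_table_prob(table: np.ndarray, row_sums, col_sums, lognorm) -> float:
    return float(
        lognorm - gammaln(table + 1).sum()
    )


def fisher_exact(table) -> float:
    """Two-sided exact test of independence on an r x c count table.

    For 2x2 tables this is Fisher's exact test with the point-probability
    two-sided rule: the p-value sums the hypergeometric probabilities of
    all tables (with the observed margins) whose probability does not
    exceed the observed table's, within a 1e-12 tolerance.  For larger
    tables it is the Freeman-Halton generalization, computed by full
    enumeration of all nonnegative integer tables with the observed
    margins.  Suitable for the modest totals of clinical contingency
    tables (enumeration cost grows quickly with dimensions and totals).
    """
    t = np.asarray(table, dtype=np.int64)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("table must be at least 2x2")
    if np.any(t < 0):
        raise ValueError("negative entries in contingency table")
    # all-zero rows/columns carry no information; dropping them leaves the
    # enumeration (and hence p) unchanged
    t = t[t.sum(axis=1) > 0][:, t.sum(axis=0) > 0]
    if t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("empty margin in contingency table")
    row_sums = t.sum(axis=1)
    col_sums = t.sum(axis=0)
    n = int(t.sum())
    lognorm = gammaln(row_sums + 1).sum() + gammaln(col_sums + 1).sum() - gammaln(n + 1)

    obs_logp = _log_table_prob(t, row_sums, col_sums, lognorm)
    cutoff = obs_logp + _PROB_TOL

    r, c = t.shape
    total = 0.0

    def _enumerate(row: int, remaining_cols: np.ndarray, logacc: float):
        nonlocal total
        if row == r - 1:
            # last row is forced by the column margins
            last = remaining_cols
            lp = logacc - gammaln(last + 1).sum()
            if lp <= cutoff:
                total += math.exp(lp)
            return
        # enumerate row `row` cell by cell under its row margin
        def _fill(col: int, left_in_row: int, cols_left: np.ndarray, acc: float):
            if col == c - 1:
                if left_in_row <= cols_left[col]:
                    new_cols = cols_left.copy()
                    new_cols[col] -= left_in_row
                    _enumerate(row + 1, new_cols,
                               acc - gammaln(left_in_row + 1))
                return
            hi = min(left_in_row, cols_left[col])
            for v in range(hi + 1):
                new_cols = cols_left.copy()
                new_cols[col] -= v
                _fill(col + 1, left_in_row - v, new_cols,
                      acc - gammaln(v + 1))

        _fill(0, int(row_sums[row]), remaining_cols, logacc)

    _enumerate(0, col_sums.copy(), float(lognorm))
    return min(total, 1.0)


# ----------------------------------------------------------------- Welch t

@dataclass(frozen=True)
class WelchResult:
    t: float
    df: float
    p: float
    ci_low: float
    ci_high: float
    mean_diff: float


def welch_t(x, y, level: float = 0.95) -> WelchResult:
    """Welch's two-sample t-test with Satterthwaite fractional df and CI."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    for name, s in (("first", x), ("second", y)):
        if s.size < 2:
            raise ValueError(f"{name} sample needs >= 2 values")
        if np.var(s, ddof=1) == 0:
            raise ValueError(f"{name} sample has zero variance")
    vx, vy = np.var(x, ddof=1), np.var(y, ddof=1)
    nx, ny = x.size, y.size
    se2 = vx / nx + vy / ny
    diff = float(np.mean(x) - np.mean(y))
    t = diff / math.sqrt(se2)
    df = se2 ** 2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = welch_p_from_stats(t, df)
    tcrit = stats.t.ppf(0.5 + level / 2, df)
    half = tcrit * math.sqrt(se2)
    return WelchResult(t=t, df=df, p=p, ci_low=diff - half, ci_high=diff + half,
                       mean_diff=diff)


def welch_p_from_stats(t: float, df: float) -> float:
    """Two-sided p from a t statistic with (possibly fractional) df."""
    if not (np.isfinite(t) and np.isfinite(df)) or df <= 0:
        raise ValueError(f"need finite t and df > 0, got t={t}, df={df}")
    return float(2 * stats.t.sf(abs(t), df))


# --------------------------------------------------------------------- TMB

TMB_GROUPS = ("<10", "10-15", ">=16")


@dataclass(frozen=True)
class TmbRecord:
    protein_affecting_mutations: int
    covered_coding_bases: int
    tmb: float                       # mutations per megabase
    tmb_group: str

    @staticmethod
    def group_of(tmb: float) -> str:
        # exhaustive half-open partition [0, 10), [10, 16), [16, inf)
        if tmb < 10:
            return "<10"
        if tmb < 16:
            return "10-15"
        return ">=16"


def compute_tmb(protein_affecting_mutations: int, covered_coding_bases: int) -> TmbRecord:
    """Mutations per megabase: protein-affecting count over the >=7x footprint."""
    if covered_coding_bases <= 0:
        raise ValueError("covered_coding_bases must be positive")
    if protein_affecting_mutations < 0:
        raise ValueError("mutation count must be nonnegative")
    tmb = protein_affecting_mutations / (covered_coding_bases / 1e6)
    return TmbRecord(
        protein_affecting_mutations=protein_affecting_mutations,
        covered_coding_bases=covered_coding_bases,
        tmb=tmb, tmb_group=TmbRecord.group_of(tmb),
    )


# ---------------------------------------------------------------- survival

@dataclass
class KmCurve:
    """Kaplan-Meier product-limit estimate with Greenwood variance."""

    times: np.ndarray            # distinct event times, ascending
    survival: np.ndarray         # S(t) just after each event time
    variance: np.ndarray         # Greenwood variance of S at each time
    n_at_risk: np.ndarray
    n_events: np.ndarray

    def landmark(self, t: float) -> float:
        """S at the largest step time <= t (1.0 before the first event)."""
        i = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if i < 0 else float(self.survival[i])


def km_estimate(times, events) -> KmCurve:
    """Product-limit survival estimate from (time, event-flag) data."""
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("empty survival dataset")
    if np.any(times <= 0):
        raise ValueError("survival times must be positive")

    order = np.argsort(times, kind="stable")
    t_sorted, e_sorted = times[order], events[order]
    n = times.size
    distinct = np.unique(t_sorted[e_sorted == 1])

    surv, var_terms, at_risk_out, d_out = [], [], [], []
    s = 1.0
    gw = 0.0
    for ti in distinct:
        at_risk = int(np.sum(t_sorted >= ti))
        d = int(np.sum((t_sorted == ti) & (e_sorted == 1)))
        s *= (at_risk - d) / at_risk
        if at_risk - d > 0:
            gw += d / (at_risk * (at_risk - d))
            var = s * s * gw
        else:
            var = 0.0
        surv.append(s)
        var_terms.append(var)
        at_risk_out.append(at_risk)
        d_out.append(d)
    return KmCurve(
        times=distinct,
        survival=np.asarray(surv),
        variance=np.asarray(var_terms),
        n_at_risk=np.asarray(at_risk_out),
        n_events=np.asarray(d_out),
    )


def log_rank(times, events, groups) -> tuple[float, float]:
    """Log-rank test across groups; returns (chi-square, p)."""
    from lifelines.statistics import multivariate_logrank_test

    df = pd.DataFrame({"t": times, "e": events, "g": groups})
    if df["g"].nunique() < 2:
        raise ValueError("log-rank needs >= 2 groups")
    res = multivariate_logrank_test(df["t"], df["g"], df["e"])
    return float(res.test_statistic), float(res.p_value)


# ------------------------------------------------------------ design power

def design_power(p0: float, p1: float, alpha_one_sided: float, n: int
                 ) -> tuple[float, int | None]:
    """Exact binomial power of the one-sided single-arm response-rate test.

    The critical value is the smallest k with P(X >= k | n, p0) <= alpha;
    power is P(X >= c | n, p1).  Returns (power, critical value), with
    (0.0, None) when no feasible critical value exists.
    """
    if not (0 < p0 < p1 < 1):
        raise ValueError("need 0 < p0 < p1 < 1")
    if n < 1:
        raise ValueError("n must be >= 1")
    for k in range(n + 1):
        if stats.binom.sf(k - 1, n, p0) <= alpha_one_sided:
            return float(stats.binom.sf(k - 1, n, p1)), k
    return 0.0, None


# ------------------------------------------------------------- correlation

def correlate(x, y, method: str = "spearman") -> tuple[float, float]:
    """Pearson or Spearman correlation with an exact permutation p for n <= 9.

    For small n the two-sided p-value is the exact fraction of the n!
    permutations of y whose |r| is at least the observed |r|; beyond that,
    the usual t (Pearson) or large-sample (Spearman) approximation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need paired samples with n >= 3")
    if not (np.all(np.isfinite(x)) and np.all(np.isfinite(y))):
        raise ValueError("non-finite values in correlation input")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in correlation input")
    if method == "spearman":
        xs = stats.rankdata(x)
        ys = stats.rankdata(y)
    elif method == "pearson":
        xs, ys = x, y
    else:
        raise ValueError(f"unknown correlation method {method!r}")

    r = float(np.corrcoef(xs, ys)[0, 1])
    n = x.size
    if n <= 9:
        xz = (xs - xs.mean()) / xs.std()
        yz = (ys - ys.mean()) / ys.std()
        perms = np.array(list(itertools.permutations(range(n))))
        r_perm = (yz[perms] @ xz) / n
        p = float(np.mean(np.abs(r_perm) >= abs(r) - 1e-12))
    else:
        if method == "pearson":
            p = float(stats.pearsonr(x, y).pvalue)
        else:
            p = float(stats.spearmanr(x, y).pvalue)
    return r, p
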