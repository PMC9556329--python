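"""Penalized additive logistic classification of pathological response.

The predictive model is a GAM-LASSO: a logistic generalized additive model
with one smooth term per immunophenotype feature and a group-lasso penalty
over each smooth's basis coefficients, so the penalty zeroes whole smooths
and performs feature selection.  The fitting pipeline is:

1. candidate filtering — non-prevalent features are ranked by a chi-squared
   test on the 2x2 detected-vs-outcome table, prevalent features by a
   Welch t-test (falling back to the Wilcoxon rank-sum when a per-class
   normality screen fails); the top ``candidate_caps`` per stratum enter
   the model;
2. smooths are cubic B-spline bases (about 4 effective df per feature by
   default) on each feature's observed training range, columns
   standardized; the intercept is unpenalized;
3. the group-lasso logistic objective is minimized by FISTA (proximal
   gradient with Nesterov acceleration); the penalty is chosen on a grid
   by cross-validated AUC;
4. to avoid overfitting, at most ``max_prevalent_in_model`` prevalent
   features may enter the additive part; the constraint is enforced
   exactly, by refitting over prevalent-feature singletons (plus the
   no-prevalent option) and keeping the best cross-validated combination.

Also here: the ROC/AUC contract (AUC = Mann-Whitney U over n1*n2 with ties
counted one half), predicted-probability group comparisons (one-way ANOVA
plus pairwise Welch tests, deliberately unadjusted for multiplicity), and
paired pre/post expansion-contraction testing with Benjamini-Hochberg
control across features.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.interpolate import BSpline

from .features import AbundanceMatrix, PrevalenceSplit
from .simulate import module_rng
from . import endpoints

__all__ = [
    "ModelConfig",
    "CandidateSet",
    "FittedModel",
    "RocResult",
    "filter_candidates",
    "fit_gam_lasso",
    "predict_probability",
    "roc_auc",
    "compare_probability_groups",
    "paired_pre_post_test",
]

logger = logging.getLogger(__name__)


@dataclass
class ModelConfig:
    non_prevalent_cap: int = 17
    prevalent_cap: int = 10
    max_prevalent_in_model: int = 1
    n_internal_knots: int = 1        # cubic basis -> internal + 4 columns
    penalty_grid: tuple = tuple(float(x) for x in np.logspace(-3.5, 0.0, 8))
    cv_folds: int = 5
    cv_tolerance: float = 0.01       # parsimony: largest penalty within this
                                     # CV-AUC margin of the best wins
    prevalent_test: str = "auto"     # auto | welch | ranksum
    normality_alpha: float = 0.05
    max_iter: int = 400
    tol: float = 1e-7
    seed: int = 0

    def validate(self) -> None:
        if self.non_prevalent_cap < 0 or self.prevalent_cap < 0:
            raise ValueError("candidate caps must be nonnegative")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        grid = list(self.penalty_grid)
        if not grid or any(g <= 0 for g in grid) or grid != sorted(grid):
            raise ValueError("penalty_grid must be positive and ascending")


@dataclass
class CandidateSet:
    non_prevalent: list[str]
    prevalent: list[str]
    pvalues: pd.Series = field(repr=False, default=None)

    @property
    def all(self) -> list[str]:
        return self.non_prevalent + self.prevalent


def _chi2_detection_p(detected: np.ndarray, y: np.ndarray) -> float:
    """Chi-squared p on the 2x2 detected x outcome table, no continuity correction."""
    table = np.array(
        [
            [np.sum(detected & (y == 1)), np.sum(detected & (y == 0))],
            [np.sum(~detected & (y == 1)), np.sum(~detected & (y == 0))],
        ]
    )
    if table.sum(axis=1).min() == 0 or table.sum(axis=0).min() == 0:
        return 1.0  # degenerate: all-detected, all-undetected, or one-class
    return float(stats.chi2_contingency(table, correction=False)[1])


def _abundance_p(x: np.ndarray, y: np.ndarray, config: ModelConfig) -> float:
    """Two-class location test on abundance: Welch t or rank-sum fallback."""
    a, b = x[y == 1], x[y == 0]
    if np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0:
        return 1.0
    use = config.prevalent_test
    if use == "auto":
        use = "welch"
        for grp in (a, b):
            if np.var(grp) == 0:
                use = "ranksum"
                break
            if grp.size >= 3 and stats.shapiro(grp).pvalue < config.normality_alpha:
                use = "ranksum"
                break
    if use == "welch":
        try:
            return endpoints.welch_t(a, b).p
        except ValueError:
            return 1.0
    return float(stats.ranksums(a, b).pvalue)


def filter_candidates(
    split: PrevalenceSplit,
    matrix: AbundanceMatrix,
    labels: pd.Series,
    config: ModelConfig,
) -> CandidateSet:
    """Rank and cap candidates per stratum before model fitting.

    Non-prevalent features are ranked by the chi-squared p-value of their
    detected/undetected split against the outcome; prevalent features by a
    location test on abundance.  Degenerate tables get p = 1.  Ties break
    by feature id so the selection is deterministic.
    """
    config.validate()
    y = labels.loc[matrix.sample_ids].to_numpy().astype(int)
    if len(np.unique(y)) != 2:
        raise ValueError("labels must contain both classes")
    det = matrix.detected()
    pvals = {}
    for fid in split.non_prevalent:
        pvals[fid] = _chi2_detection_p(det[fid].to_numpy(), y)
    for fid in split.prevalent:
        pvals[fid] = _abundance_p(matrix.data[fid].to_numpy(dtype=float), y, config)
    pseries = pd.Series(pvals, name="p")

    def _top(ids, cap):
        ranked = sorted(ids, key=lambda f: (pvals[f], f))
        return ranked[:cap]

    chosen = CandidateSet(
        non_prevalent=_top(split.non_prevalent, config.non_prevalent_cap),
        prevalent=_top(split.prevalent, config.prevalent_cap),
        pvalues=pseries,
    )
    logger.info(
        "candidate filter: %d non-prevalent, %d prevalent retained",
        len(chosen.non_prevalent), len(chosen.prevalent),
    )
    return chosen


# ------------------------------------------------------------ spline basis

@dataclass
class _FeatureBasis:
    feature_id: str
    prevalent: bool
    knots: list[float]               # full knot vector, degree-3
    col_mean: list[float]
    col_scale: list[float]
    degenerate: bool = False

    @property
    def n_cols(self) -> int:
        return 0 if self.degenerate else len(self.knots) - 4

    def design(self, x: np.ndarray) -> np.ndarray:
        if self.degenerate:
            return np.zeros((x.size, 0))
        t = np.asarray(self.knots)
        xc = np.clip(x, t[0], t[-1])   # constant extrapolation at the boundary
        B = BSpline.design_matrix(xc, t, 3).toarray()
        return (B - np.asarray(self.col_mean)) / np.asarray(self.col_scale)


def _build_basis(fid: str, x: np.ndarray, prevalent: bool,
                 n_internal: int) -> _FeatureBasis:
    lo, hi = float(np.min(x)), float(np.max(x))
    if hi - lo < 1e-12:
        return _FeatureBasis(feature_id=fid, prevalent=prevalent, knots=[],
                             col_mean=[], col_scale=[], degenerate=True)
    qs = np.linspace(0, 1, n_internal + 2)[1:-1]
    internal = np.unique(np.quantile(x, qs))
    internal = internal[(internal > lo) & (internal < hi)]
    t = np.r_[[lo] * 4, internal, [hi] * 4]
    B = BSpline.design_matrix(np.clip(x, lo, hi), t, 3).toarray()
    mean = B.mean(axis=0)
    scale = B.std(axis=0)
    scale[scale < 1e-12] = 1.0
    return _FeatureBasis(
        feature_id=fid, prevalent=prevalent, knots=[float(v) for v in t],
        col_mean=[float(v) for v in mean], col_scale=[float(v) for v in scale],
    )


# ------------------------------------------------------------ group lasso

def _lipschitz(X: np.ndarray) -> float:
    """Lipschitz constant of the logistic gradient (intercept included)."""
    n = X.shape[0]
    Xa = np.hstack([np.ones((n, 1)), X])
    return (np.linalg.norm(Xa, 2) ** 2) / (4 * n) + 1e-12


def _fit_group_lasso(X: np.ndarray, y: np.ndarray, groups: list[slice],
                     lam: float, max_iter: int, tol: float,
                     L: float | None = None,
                     beta0=None, icpt0: float | None = None):
    """FISTA for group-lasso penalized logistic regression.

    Minimizes mean log-loss + lam * sum_g sqrt(p_g) ||beta_g||_2 with an
    unpenalized intercept.  Returns (beta, intercept).
    """
    n, p = X.shape
    beta = np.zeros(p) if beta0 is None else beta0.copy()
    icpt = float(np.log(y.mean() / (1 - y.mean()))) if icpt0 is None else icpt0
    if not np.isfinite(icpt):
        icpt = 0.0
    weights = np.array([math.sqrt(g.stop - g.start) for g in groups])

    if L is None:
        L = _lipschitz(X)
    step = 1.0 / L

    zb, zi = beta.copy(), icpt
    t_acc = 1.0
    prev_obj = np.inf
    for it in range(max_iter):
        eta = zi + X @ zb
        mu = 1.0 / (1.0 + np.exp(-eta))
        grad_b = X.T @ (mu - y) / n
        grad_i = float(np.mean(mu - y))
        b_new = zb - step * grad_b
        i_new = zi - step * grad_i
        # group soft-threshold
        for g, w in zip(groups, weights):
            seg = b_new[g]
            norm = np.linalg.norm(seg)
            thr = lam * w * step
            b_new[g] = 0.0 if norm <= thr else seg * (1 - thr / norm)
        t_next = (1 + math.sqrt(1 + 4 * t_acc * t_acc)) / 2
        zb = b_new + (t_acc - 1) / t_next * (b_new - beta)
        zi = i_new + (t_acc - 1) / t_next * (i_new - icpt)
        db = np.max(np.abs(b_new - beta), initial=0.0) + abs(i_new - icpt)
        beta, icpt, t_acc = b_new, i_new, t_next
        if db < tol * (1 + np.max(np.abs(beta), initial=0.0)):
            break
    return beta, icpt


# ------------------------------------------------------------ fitted model

@dataclass
class FittedModel:
    bases: list[_FeatureBasis]
    coefs: list[np.ndarray]          # one coefficient block per basis
    intercept: float
    penalty: float
    base_rate: float
    apparent_auc: float | None
    cv_auc: float | None
    config: ModelConfig

    @property
    def selected_features(self) -> list[str]:
        return [
            b.feature_id
            for b, c in zip(self.bases, self.coefs)
            if c.size and np.any(c != 0)
        ]

    @property
    def n_prevalent_selected(self) -> int:
        sel = set(self.selected_features)
        return sum(1 for b in self.bases if b.prevalent and b.feature_id in sel)

    def to_json(self) -> str:
        payload = {
            "format": "immunopred-gam-lasso/1",
            "intercept": self.intercept,
            "penalty": self.penalty,
            "base_rate": self.base_rate,
            "apparent_auc": self.apparent_auc,
            "cv_auc": self.cv_auc,
            "features": [
                {
                    "feature_id": b.feature_id,
                    "prevalent": b.prevalent,
                    "knots": b.knots,
                    "col_mean": b.col_mean,
                    "col_scale": b.col_scale,
                    "degenerate": b.degenerate,
                    "coefs": [float(v) for v in c],
                }
                for b, c in zip(self.bases, self.coefs)
            ],
        }
        return json.dumps(payload, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, text: str, config: ModelConfig | None = None) -> "FittedModel":
        d = json.loads(text)
        bases, coefs = [], []
        for f in d["features"]:
            bases.append(
                _FeatureBasis(
                    feature_id=f["feature_id"], prevalent=f["prevalent"],
                    knots=f["knots"], col_mean=f["col_mean"],
                    col_scale=f["col_scale"], degenerate=f["degenerate"],
                )
            )
            coefs.append(np.asarray(f["coefs"], dtype=float))
        return cls(
            bases=bases, coefs=coefs, intercept=d["intercept"],
            penalty=d["penalty"], base_rate=d["base_rate"],
            apparent_auc=d["apparent_auc"], cv_auc=d["cv_auc"],
            config=config or ModelConfig(),
        )


def _assemble(bases: list[_FeatureBasis], data: pd.DataFrame):
    blocks, groups = [], []
    start = 0
    for b in bases:
        B = b.design(data[b.feature_id].to_numpy(dtype=float))
        blocks.append(B)
        groups.append(slice(start, start + B.shape[1]))
        start += B.shape[1]
    X = np.hstack(blocks) if blocks else np.zeros((len(data), 0))
    return X, groups


def _cv_auc_grid(X, y, groups, grid, folds, max_iter, tol, rng) -> dict:
    """Stratified K-fold cross-validated AUC for every penalty in the grid.

    Folds are fixed across the grid; within each fold the solver is
    warm-started from the previous (larger) penalty's solution, walking the
    grid from most to least shrunk.
    """
    n = y.size
    idx_pos = np.flatnonzero(y == 1)
    idx_neg = np.flatnonzero(y == 0)
    rng.shuffle(idx_pos)
    rng.shuffle(idx_neg)
    fold_of = np.empty(n, dtype=int)
    fold_of[idx_pos] = np.arange(idx_pos.size) % folds
    fold_of[idx_neg] = np.arange(idx_neg.size) % folds

    lams = sorted(grid, reverse=True)
    scores = {lam: np.empty(n) for lam in lams}
    for k in range(folds):
        test = fold_of == k
        ytr = y[~test]
        if ytr.min() == ytr.max():
            for lam in lams:
                scores[lam][test] = ytr.mean()
            continue
        Xtr = X[~test]
        L = _lipschitz(Xtr)
        beta, icpt = None, None
        for lam in lams:
            beta, icpt = _fit_group_lasso(Xtr, ytr, groups, lam, max_iter,
                                          tol, L=L, beta0=beta, icpt0=icpt)
            scores[lam][test] = icpt + X[test] @ beta
    return {lam: roc_auc(scores[lam], y).auc for lam in lams}


@dataclass
class RocResult:
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float


def roc_auc(scores, labels) -> RocResult:
    """ROC curve and AUC with the Mann-Whitney tie convention.

    AUC equals the number of (positive, negative) score pairs won by the
    positive, ties counting one half, divided by n1 * n2 — identical to the
    normalized Mann-Whitney U statistic.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels).astype(int)
    n1 = int(np.sum(y == 1))
    n0 = int(np.sum(y == 0))
    if n1 == 0 or n0 == 0:
        raise ValueError("both classes must be present for ROC")
    ranks = stats.rankdata(s)
    u = float(np.sum(ranks[y == 1]) - n1 * (n1 + 1) / 2)
    auc = u / (n1 * n0)

    order = np.argsort(-s, kind="stable")
    ys = y[order]
    ss = s[order]
    tp = np.cumsum(ys)
    fp = np.cumsum(1 - ys)
    # collapse tied thresholds to their last index
    last_of_tie = np.r_[ss[1:] != ss[:-1], True]
    tpr = np.r_[0.0, tp[last_of_tie] / n1]
    fpr = np.r_[0.0, fp[last_of_tie] / n0]
    return RocResult(fpr=fpr, tpr=tpr, auc=auc)


def fit_gam_lasso(
    candidates: CandidateSet,
    matrix: AbundanceMatrix,
    labels: pd.Series,
    config: ModelConfig,
) -> FittedModel:
    """Fit the constrained group-lasso additive logistic model.

    The penalty is chosen on ``config.penalty_grid`` by stratified
    cross-validated AUC with a parsimony rule (the largest penalty whose
    CV AUC is within ``cv_tolerance`` of the best).  The prevalent-feature
    cap is enforced exactly:
    every admissible prevalent subset of size at most
    ``max_prevalent_in_model`` (singletons plus the empty option, under the
    default cap of one) is tried with the full non-prevalent candidate
    list, and the best cross-validated combination wins.  Deterministic
    given ``config.seed``.
    """
    config.validate()
    if not candidates.all:
        raise ValueError("empty candidate set")
    y = labels.loc[matrix.sample_ids].to_numpy().astype(int)
    if len(np.unique(y)) != 2:
        raise ValueError("labels must contain both classes")

    prevalent_options: list[list[str]] = [[]]
    if config.max_prevalent_in_model >= 1:
        prevalent_options += [[f] for f in candidates.prevalent]
    if config.max_prevalent_in_model > 1:
        logger.warning(
            "max_prevalent_in_model > 1 is enforced by singleton search; "
            "using singletons only"
        )

    entries = []   # (cv_auc, lam, -option_index, bases, X, groups)
    for opt_i, prev_opt in enumerate(prevalent_options):
        fids = candidates.non_prevalent + prev_opt
        bases = [
            _build_basis(
                fid, matrix.data[fid].to_numpy(dtype=float),
                prevalent=fid in set(candidates.prevalent),
                n_internal=config.n_internal_knots,
            )
            for fid in fids
        ]
        X, groups = _assemble(bases, matrix.data)
        rng = module_rng(config.seed, f"cv-{opt_i}")
        cv_by_lam = _cv_auc_grid(X, y, groups, config.penalty_grid,
                                 config.cv_folds, config.max_iter,
                                 config.tol, rng)
        for lam, cv in cv_by_lam.items():
            entries.append((cv, lam, -opt_i, bases, X, groups))

    # parsimony rule: among (option, penalty) pairs within cv_tolerance of
    # the best cross-validated AUC, take the most shrunk (largest penalty);
    # remaining ties break by option order, so the fit is deterministic
    best_cv = max(e[0] for e in entries)
    admissible = [e for e in entries if e[0] >= best_cv - config.cv_tolerance]
    admissible.sort(key=lambda e: (e[1], e[2], e[0]), reverse=True)
    cv, lam, _negi, bases, X, groups = admissible[0]
    beta, icpt = _fit_group_lasso(X, y, groups, lam, config.max_iter, config.tol)
    coefs = [beta[g].copy() for g in groups]
    # zero out groups below numerical noise so selection is crisp
    for c in coefs:
        if c.size and np.linalg.norm(c) < 1e-10:
            c[:] = 0.0
    scores = icpt + X @ beta
    apparent = roc_auc(scores, y).auc if len(np.unique(y)) == 2 else None
    model = FittedModel(
        bases=bases, coefs=coefs, intercept=float(icpt), penalty=float(lam),
        base_rate=float(y.mean()), apparent_auc=apparent, cv_auc=float(cv),
        config=config,
    )
    assert model.n_prevalent_selected <= config.max_prevalent_in_model
    logger.info(
        "GAM-LASSO: penalty %.4g, cv AUC %.3f, %d features selected "
        "(%d prevalent)",
        lam, cv, len(model.selected_features), model.n_prevalent_selected,
    )
    return model


def predict_probability(model: FittedModel, matrix: AbundanceMatrix) -> pd.Series:
    """Predicted MPR probability per sample; fails loudly on missing features."""
    needed = [b.feature_id for b, c in zip(model.bases, model.coefs)
              if c.size and np.any(c != 0)]
    missing = [f for f in needed if f not in matrix.data.columns]
    if missing:
        raise ValueError(f"matrix lacks selected features: {missing}")
    eta = np.full(matrix.n_samples, model.intercept, dtype=float)
    for b, c in zip(model.bases, model.coefs):
        if c.size == 0 or not np.any(c != 0):
            continue
        B = b.design(matrix.data[b.feature_id].to_numpy(dtype=float))
        eta += B @ c
    p = 1.0 / (1.0 + np.exp(-eta))
    return pd.Series(p, index=matrix.data.index, name="p_mpr")


# ------------------------------------------------- group comparison / paired

def compare_probability_groups(probabilities, group_labels) -> dict:
    """One-way ANOVA plus pairwise Welch tests on predicted probabilities.

    Groups with fewer than two members are excluded (with a warning).  No
    multiplicity adjustment is applied to the pairwise tests; the output
    flags this explicitly.
    """
    s = pd.Series(np.asarray(probabilities, dtype=float))
    g = pd.Series(np.asarray(group_labels, dtype=object))
    sizes = g.value_counts()
    small = sizes[sizes < 2].index.tolist()
    if small:
        logger.warning("excluding groups with < 2 members: %s", small)
        keep = ~g.isin(small)
        s, g = s[keep], g[keep]
    names = sorted(g.unique())
    if len(names) < 2:
        raise ValueError("need >= 2 groups with >= 2 members each")
    arrays = [s[g == name].to_numpy() for name in names]

    grand = s.mean()
    ss_between = sum(a.size * (a.mean() - grand) ** 2 for a in arrays)
    ss_within = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    df_between = len(names) - 1
    df_within = s.size - len(names)
    ms_between = ss_between / df_between
    ms_within = ss_within / df_within
    # guard float dust: constant data must give F = 0, not a 0/0 artifact
    tiny = 1e-12 * max(1.0, grand * grand)
    if ss_within <= tiny * s.size:
        degenerate_between = ss_between <= tiny * s.size
        f_stat = 0.0 if degenerate_between else math.inf
        p = 1.0 if degenerate_between else 0.0
    else:
        f_stat = ms_between / ms_within
        p = float(stats.f.sf(f_stat, df_between, df_within))

    pairwise = []
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            a, b = arrays[i], arrays[j]
            dust = (1e-12 * (np.abs(a).max() + np.abs(b).max() + 1.0)) ** 2
            identical = (np.var(a, ddof=1) <= dust and np.var(b, ddof=1) <= dust
                         and (a.mean() - b.mean()) ** 2 <= dust)
            if identical or (np.var(a, ddof=1) == 0 and np.var(b, ddof=1) == 0):
                w = endpoints.WelchResult(t=0.0, df=float(a.size + b.size - 2),
                                          p=1.0, ci_low=0.0, ci_high=0.0,
                                          mean_diff=float(a.mean() - b.mean()))
            else:
                w = endpoints.welch_t(a, b)
            pairwise.append({"groups": (names[i], names[j]), "result": w})

    return {
        "anova": {
            "df_between": df_between, "df_within": df_within,
            "ss_between": float(ss_between), "ss_within": float(ss_within),
            "ms_between": float(ms_between), "ms_within": float(ms_within),
            "F": float(f_stat), "p": p,
        },
        "pairwise": pairwise,
        "multiplicity_adjusted": False,
    }


def paired_pre_post_test(
    matrix_pre: AbundanceMatrix,
    matrix_post: AbundanceMatrix,
    sample_ids,
    method: str = "wilcoxon",
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-feature paired expansion/contraction test across matched samples.

    Restricts both matrices to ``sample_ids`` (typically the MPR patients),
    drops unpaired samples with a warning, applies a Wilcoxon signed-rank
    (default) or paired t-test per shared feature, and controls the FDR
    across features by Benjamini-Hochberg.  The reported direction is the
    sign of the median change (expansion / contraction / none).
    """
    from statsmodels.stats.multitest import multipletests

    wanted = list(sample_ids)
    paired = [s for s in wanted
              if s in matrix_pre.data.index and s in matrix_post.data.index]
    dropped = sorted(set(wanted) - set(paired))
    if dropped:
        logger.warning("dropping %d unpaired samples: %s", len(dropped),
                       dropped[:5])
    if not paired:
        raise ValueError("no paired samples")
    shared = [c for c in matrix_pre.feature_ids
              if c in set(matrix_post.feature_ids)]
    pre = matrix_pre.data.loc[paired, shared]
    post = matrix_post.data.loc[paired, shared]
    diffs = post.to_numpy(dtype=float) - pre.to_numpy(dtype=float)

    rows = []
    for j, fid in enumerate(shared):
        d = diffs[:, j]
        med = float(np.median(d))
        if np.allclose(d, 0):
            stat_val, p = 0.0, 1.0
        elif method == "wilcoxon":
            nz = d[d != 0]
            if nz.size == 0:
                stat_val, p = 0.0, 1.0
            else:
                res = stats.wilcoxon(nz)
                stat_val, p = float(res.statistic), float(res.pvalue)
        elif method == "paired_t":
            res = stats.ttest_rel(post[fid], pre[fid])
            stat_val, p = float(res.statistic), float(res.pvalue)
        else:
            raise ValueError(f"unknown method {method!r}")
        direction = "expansion" if med > 0 else ("contraction" if med < 0 else "none")
        rows.append((fid, stat_val, p, med, direction))

    out = pd.DataFrame(rows, columns=["feature_id", "statistic", "p",
                                      "median_change", "direction"])
    out["q"] = multipletests(out["p"], method="fdr_bh")[1]
    out["significant"] = out["q"] < alpha
    return out
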