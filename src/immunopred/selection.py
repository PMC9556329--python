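"""Extreme-cohort construction and divergence-based feature ranking.

The selection stage asks which marker combinations differ most between
clear responders and clear non-responders.  It works on two *extreme
cohorts* drawn from the training set — k patients with the most
pathological regression (lowest viable-tumor percent) and k with the most
progression (highest) — and ranks features by an information-divergence
importance score estimated through massive random subsampling:

* draw ``m`` features at random (without replacement), ``B`` times;
* within each subset, score every feature's class separation by the
  divergence between its per-arm value distributions;
* a feature's raw importance is its mean score over the iterations that
  contained it;
* the same draws are re-scored under label permutation, and the permuted
  mean is subtracted, so importance is null-centered: features are
  retained iff the centered importance is strictly positive.

The divergence kernel here is the Jensen-Shannon divergence between
histograms on shared bins with additive smoothing — symmetric, bounded by
log 2, and zero for identical samples.  It stands behind a small named
interface so another divergence can be substituted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata

from .features import AbundanceMatrix
from .simulate import module_rng

__all__ = [
    "SelectionConfig",
    "FeatureSelectionResult",
    "select_extreme_cohorts",
    "normalize_immunome",
    "i_index",
    "subsample_rank",
]


@dataclass
class SelectionConfig:
    subset_size: int = 30            # m: features per random subset
    n_subsamples: int = 10_000       # B: number of subsets drawn
    regression_viable_max: float = 88.0
    progression_viable_min: float = 20.0
    per_arm_k: int = 13
    bins: int = 6      # ~sqrt(n) resolution for the 13-per-arm extreme design
    smoothing: float = 1.0
    normalization: str = "rank"
    seed: int = 0

    def validate(self) -> None:
        if self.subset_size < 2:
            raise ValueError("subset_size must be >= 2")
        if self.n_subsamples < 1:
            raise ValueError("n_subsamples must be >= 1")
        if self.per_arm_k < 2:
            raise ValueError("per_arm_k must be >= 2")
        if self.bins < 2:
            raise ValueError("bins must be >= 2")


@dataclass
class FeatureSelectionResult:
    """Per-feature importances plus bookkeeping of the selection run."""

    table: pd.DataFrame              # feature_id, importance, times_sampled, retained
    stage_counts: dict
    config: SelectionConfig

    @property
    def retained(self) -> list[str]:
        return self.table.loc[self.table["retained"], "feature_id"].tolist()


def select_extreme_cohorts(
    cohort: pd.DataFrame,
    matrix: AbundanceMatrix,
    config: SelectionConfig,
) -> tuple[list[str], list[str]]:
    """Pick the regression and progression extreme arms from the training set.

    Regression arm: the ``per_arm_k`` patients with the lowest viable
    percent among those at or below ``regression_viable_max``.  Progression
    arm: the ``per_arm_k`` highest among those at or above
    ``progression_viable_min``.  The two literal eligibility windows
    overlap; a doubly eligible patient is assigned to the arm whose extreme
    (0 or 100) it is closer to, and never to both.  Ties break by viable
    percent then patient id, so the result is deterministic.
    """
    config.validate()
    ids = [s for s in matrix.sample_ids if s in cohort.index]
    viable = cohort.loc[ids, "viable_percent"]
    viable = viable.dropna()

    reg_elig = viable[viable <= config.regression_viable_max]
    prog_elig = viable[viable >= config.progression_viable_min]
    both = set(reg_elig.index) & set(prog_elig.index)
    # distance-to-extreme assignment for the overlap region
    reg_pool = {pid for pid in reg_elig.index if pid not in both or viable[pid] <= 100 - viable[pid]}
    prog_pool = {pid for pid in prog_elig.index if pid not in both or viable[pid] > 100 - viable[pid]}

    def _take(pool: set, ascending: bool, arm: str) -> list[str]:
        if len(pool) < config.per_arm_k:
            raise ValueError(
                f"insufficient candidates for the {arm} arm: "
                f"{len(pool)} available, {config.per_arm_k} required"
            )
        order = sorted(pool, key=lambda p: (viable[p] if ascending else -viable[p], p))
        return order[: config.per_arm_k]

    regression = _take(reg_pool, ascending=True, arm="regression")
    progression = _take(prog_pool, ascending=False, arm="progression")
    assert not set(regression) & set(progression)
    return regression, progression


def normalize_immunome(matrix: AbundanceMatrix, method: str = "rank",
                       cofactor: float = 5.0) -> AbundanceMatrix:
    """Normalize per feature: 'rank' (mid-ranks in (0, 1]), 'arcsinh', or 'none'.

    Rank normalization makes downstream divergence estimation invariant to
    any strictly monotone per-feature transform; arcsinh(x / cofactor) is
    the conventional cytometry variance stabilizer.
    """
    if method == "none":
        return AbundanceMatrix(data=matrix.data.copy(), timepoint=matrix.timepoint)
    if method == "arcsinh":
        return AbundanceMatrix(
            data=np.arcsinh(matrix.data / cofactor), timepoint=matrix.timepoint
        )
    if method == "rank":
        n = matrix.n_samples
        ranked = matrix.data.apply(lambda c: rankdata(c, method="average") / n, axis=0)
        return AbundanceMatrix(data=ranked, timepoint=matrix.timepoint)
    raise ValueError(f"unknown normalization method {method!r}")


def _bin_indices(values: np.ndarray, bins: int) -> np.ndarray:
    """Shared equal-width bin index per entry, column-wise, in [0, bins)."""
    lo = values.min(axis=0, keepdims=True)
    hi = values.max(axis=0, keepdims=True)
    span = np.where(hi > lo, hi - lo, 1.0)
    idx = np.floor((values - lo) / span * bins).astype(np.int64)
    return np.clip(idx, 0, bins - 1)


def _js_from_counts(ca: np.ndarray, cb: np.ndarray, smoothing: float) -> np.ndarray:
    """Jensen-Shannon divergence (nats) per column of two count matrices.

    ``ca``/``cb`` have shape (n_features, bins).  Additive smoothing is
    applied to every bin before normalization; with smoothing 0, empty bins
    contribute nothing (0 log 0 := 0).
    """
    pa = ca + smoothing
    pb = cb + smoothing
    pa = pa / pa.sum(axis=1, keepdims=True)
    pb = pb / pb.sum(axis=1, keepdims=True)
    m = 0.5 * (pa + pb)
    with np.errstate(divide="ignore", invalid="ignore"):
        ta = np.where(pa > 0, pa * np.log(pa / m), 0.0)
        tb = np.where(pb > 0, pb * np.log(pb / m), 0.0)
    return 0.5 * ta.sum(axis=1) + 0.5 * tb.sum(axis=1)


def i_index(values_a, values_b, bins: int = 10, smoothing: float = 1.0) -> float:
    """Divergence importance of one feature between two sample groups.

    Histograms of the two samples are taken on ``bins`` equal-width bins
    spanning their *shared* range, smoothed additively, and compared by
    Jensen-Shannon divergence (natural log).  The value is symmetric in its
    arguments and lies in [0, log 2]; identical samples score 0.
    """
    if bins < 2:
        raise ValueError("bins must be >= 2")
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be nonempty")
    combined = np.concatenate([a, b])[:, None]
    idx = _bin_indices(combined, bins)[:, 0]
    ia, ib = idx[: a.size], idx[a.size:]
    ca = np.bincount(ia, minlength=bins)[None, :].astype(float)
    cb = np.bincount(ib, minlength=bins)[None, :].astype(float)
    return float(_js_from_counts(ca, cb, smoothing)[0])


def _divergence_columns(idx: np.ndarray, mask_a: np.ndarray, bins: int,
                        smoothing: float, cols=None) -> np.ndarray:
    """JS divergence of every (selected) column between groups a and not-a."""
    sub = idx if cols is None else idx[:, cols]
    m = sub.shape[1]
    offsets = np.arange(m) * bins
    ca = np.bincount((sub[mask_a] + offsets).ravel(), minlength=m * bins)
    cb = np.bincount((sub[~mask_a] + offsets).ravel(), minlength=m * bins)
    return _js_from_counts(
        ca.reshape(m, bins).astype(float), cb.reshape(m, bins).astype(float),
        smoothing,
    )


def subsample_rank(
    matrix: AbundanceMatrix,
    labels: pd.Series,
    config: SelectionConfig,
) -> FeatureSelectionResult:
    """Random-subsampling divergence ranking with permutation null-centering.

    ``matrix`` should already be restricted to the extreme-cohort samples
    and normalized; ``labels`` maps each of its sample ids to one of two
    classes.  For each of ``B = n_subsamples`` iterations, ``m =
    subset_size`` features are drawn uniformly without replacement and each
    is scored by :func:`i_index` between the two classes — and, under a
    fresh label permutation, for the null.  A feature's importance is its
    mean observed score minus its mean permuted score over the iterations
    that sampled it; features with importance > 0 are retained.
    """
    config.validate()
    labels = labels.loc[matrix.sample_ids]
    classes = pd.unique(labels)
    if len(classes) != 2:
        raise ValueError(f"labels must have exactly 2 classes, got {len(classes)}")
    fids = matrix.feature_ids
    n_feat = len(fids)
    if config.subset_size > n_feat:
        raise ValueError(
            f"subset_size {config.subset_size} exceeds feature count {n_feat}"
        )

    rng = module_rng(config.seed, "subsample-rank")
    X = matrix.data.to_numpy(dtype=float)
    idx = _bin_indices(X, config.bins)
    mask_a = (labels == classes[0]).to_numpy()
    n = mask_a.size

    # observed divergence is subset-independent (marginal scoring), so the
    # mean over containing iterations equals the single full computation
    observed = _divergence_columns(idx, mask_a, config.bins, config.smoothing)

    times_sampled = np.zeros(n_feat, dtype=np.int64)
    null_sum = np.zeros(n_feat)
    m = config.subset_size
    B = config.n_subsamples
    for _ in range(B):
        cols = rng.choice(n_feat, size=m, replace=False)
        perm_mask = np.zeros(n, dtype=bool)
        perm_mask[rng.choice(n, size=int(mask_a.sum()), replace=False)] = True
        null_div = _divergence_columns(idx, perm_mask, config.bins,
                                       config.smoothing, cols)
        times_sampled[cols] += 1
        null_sum[cols] += null_div

    with np.errstate(invalid="ignore", divide="ignore"):
        null_mean = np.where(times_sampled > 0, null_sum / times_sampled, np.nan)
    importance = observed - null_mean
    retained = np.where(np.isnan(importance), False, importance > 0)

    table = pd.DataFrame(
        {
            "feature_id": fids,
            "importance": importance,
            "times_sampled": times_sampled,
            "retained": retained,
        }
    )
    stage_counts = {
        "features_scored": n_feat,
        "features_retained": int(retained.sum()),
    }
    return FeatureSelectionResult(table=table, stage_counts=stage_counts,
                                  config=config)
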