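"""Candidate filtering, the penalized additive classifier, ROC, group
comparisons, and paired pre/post testing."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from immunopred.features import split_by_prevalence
from immunopred.model import (FittedModel, ModelConfig, CandidateSet,
                              compare_probability_groups, filter_candidates,
                              fit_gam_lasso, paired_pre_post_test,
                              predict_probability, roc_auc)
from immunopred.model import _assemble, _build_basis, _fit_group_lasso

from conftest import make_matrix


def _labels(matrix, y):
    return pd.Series(np.asarray(y, dtype=int), index=matrix.sample_ids)


class TestFilterCandidates:
    def test_perfect_detection_split_ranks_first(self, rng):
        # 10/10 responders detected vs 0/10 non-responders: X^2 = 20
        # before correction, p ~ 7.7e-6
        vals = rng.random((20, 5)) + 0.5
        vals[10:, 0] = 0.0           # feature 0 undetected in non-responders
        vals[::2, 1] = 0.0           # noise detection pattern
        m = make_matrix(vals)
        y = _labels(m, [1] * 10 + [0] * 10)
        split = split_by_prevalence(m, 0.95)
        cands = filter_candidates(split, m, y, ModelConfig())
        assert cands.non_prevalent[0] == m.feature_ids[0]
        assert cands.pvalues[m.feature_ids[0]] < 1e-3

    def test_identical_feature_gets_p_one(self, rng):
        vals = np.ones((16, 2))
        vals[:, 1] = rng.random(16) + 0.5
        m = make_matrix(vals)
        y = _labels(m, [1] * 8 + [0] * 8)
        split = split_by_prevalence(m, 0.5)
        cands = filter_candidates(split, m, y, ModelConfig())
        assert cands.pvalues[m.feature_ids[0]] == 1.0

    def test_planted_prevalent_features_reach_candidates(self):
        # simulation oracle: 3 continuous features shifted by d=1.2 among
        # 20 prevalent ones, n=60 -> Welch noncentrality ~4.6, so all 3
        # should make the top-10 cut in nearly every replicate
        hits = 0
        for seed in range(20):
            r = np.random.default_rng(800 + seed)
            X = r.normal(5, 1, (60, 20))
            X[:30, :3] += 1.2
            m = make_matrix(X)
            y = _labels(m, [1] * 30 + [0] * 30)
            split = split_by_prevalence(m, 0.85)
            cands = filter_candidates(split, m, y, ModelConfig(seed=seed))
            if all(f in cands.prevalent for f in m.feature_ids[:3]):
                hits += 1
        assert hits >= 18

    def test_single_class_labels_rejected(self, rng):
        m = make_matrix(rng.random((8, 3)))
        with pytest.raises(ValueError, match="class"):
            filter_candidates(split_by_prevalence(m, 0.5), m,
                              _labels(m, [1] * 8), ModelConfig())


class TestFitGamLasso:
    def test_infinite_penalty_returns_base_rate(self, rng):
        vals = rng.random((40, 6)) * 10
        m = make_matrix(vals)
        y = _labels(m, rng.integers(0, 2, 40))
        cands = CandidateSet(non_prevalent=m.feature_ids[:4],
                             prevalent=m.feature_ids[4:])
        cfg = ModelConfig(penalty_grid=(1e6,), seed=0)
        model = fit_gam_lasso(cands, m, y, cfg)
        assert model.selected_features == []
        probs = predict_probability(model, m)
        assert np.allclose(probs, y.mean(), atol=1e-6)

    def test_perfectly_aligned_feature_gives_auc_one(self):
        n = 40
        y_vals = np.array([1] * 20 + [0] * 20)
        vals = np.column_stack([y_vals * 10.0 + 1.0,
                                np.linspace(1, 2, n)])
        m = make_matrix(vals)
        y = _labels(m, y_vals)
        cands = CandidateSet(non_prevalent=[m.feature_ids[0]],
                             prevalent=[])
        cfg = ModelConfig(penalty_grid=(1e-3, 1e-2), seed=1)
        model = fit_gam_lasso(cands, m, y, cfg)
        assert model.cv_auc == 1.0

    def test_prevalent_cap_enforced(self, rng):
        # several informative prevalent features: only one may enter
        y_vals = np.array([1] * 25 + [0] * 25)
        X = rng.normal(5, 1, (50, 8))
        X[:, :4] += y_vals[:, None] * 1.5
        m = make_matrix(X)
        y = _labels(m, y_vals)
        split = split_by_prevalence(m, 0.0)   # everything prevalent
        cands = filter_candidates(split, m, y, ModelConfig())
        model = fit_gam_lasso(cands, m, y, ModelConfig(seed=3))
        assert model.n_prevalent_selected <= 1

    def test_penalty_monotonicity_of_selection(self, rng):
        vals = rng.random((60, 5)) * 10
        y_vals = rng.integers(0, 2, 60)
        m = make_matrix(vals)
        bases = [_build_basis(f, m.data[f].to_numpy(), False, 1)
                 for f in m.feature_ids]
        X, groups = _assemble(bases, m.data)
        counts = []
        for lam in (1e-4, 1e-3, 1e-2, 1e-1, 1.0):
            beta, _ = _fit_group_lasso(X, y_vals.astype(float), groups, lam,
                                       max_iter=500, tol=1e-8)
            counts.append(sum(np.linalg.norm(beta[g]) > 1e-8 for g in groups))
        assert all(a >= b for a, b in zip(counts, counts[1:]))

    def test_empty_candidates_rejected(self, rng):
        m = make_matrix(rng.random((10, 2)))
        with pytest.raises(ValueError, match="empty candidate"):
            fit_gam_lasso(CandidateSet([], []), m,
                          _labels(m, [0, 1] * 5), ModelConfig())

    def test_deterministic(self, rng):
        vals = rng.random((30, 6)) * 10
        y = rng.integers(0, 2, 30)
        m = make_matrix(vals)
        labels = _labels(m, y)
        cands = CandidateSet(non_prevalent=m.feature_ids[:3],
                             prevalent=m.feature_ids[3:])
        m1 = fit_gam_lasso(cands, m, labels, ModelConfig(seed=5))
        m2 = fit_gam_lasso(cands, m, labels, ModelConfig(seed=5))
        assert m1.to_json() == m2.to_json()


class TestPredict:
    def _toy_model(self, rng, n=50):
        y_vals = np.array([1] * (n // 2) + [0] * (n // 2))
        vals = np.column_stack([
            y_vals + rng.normal(0, 0.3, n) + 2.0,
            rng.random(n) + 1.0,
        ])
        m = make_matrix(vals)
        y = _labels(m, y_vals)
        cands = CandidateSet(non_prevalent=list(m.feature_ids), prevalent=[])
        model = fit_gam_lasso(cands, m, y, ModelConfig(seed=2))
        return model, m, y

    def test_probabilities_in_unit_interval(self, rng):
        model, m, _ = self._toy_model(rng)
        p = predict_probability(model, m)
        assert ((p >= 0) & (p <= 1)).all()

    def test_round_trip_reproduces_apparent_auc(self, rng):
        model, m, y = self._toy_model(rng)
        p = predict_probability(model, m)
        assert roc_auc(p.to_numpy(), y.to_numpy()).auc == pytest.approx(
            model.apparent_auc, abs=1e-12
        )

    def test_missing_feature_error_lists_ids(self, rng):
        model, m, _ = self._toy_model(rng)
        assert model.selected_features   # otherwise nothing can be missing
        reduced = m.data.drop(columns=model.selected_features[:1])
        from immunopred.features import AbundanceMatrix
        m2 = AbundanceMatrix(data=reduced)
        with pytest.raises(ValueError, match=model.selected_features[0].replace("+", "\\+")):
            predict_probability(model, m2)

    def test_serialization_round_trip(self, rng):
        model, m, _ = self._toy_model(rng)
        restored = FittedModel.from_json(model.to_json())
        p1 = predict_probability(model, m)
        p2 = predict_probability(restored, m)
        assert np.allclose(p1, p2, atol=0)


class TestRocAuc:
    def test_perfect_ranking(self):
        r = roc_auc([0.9, 0.8, 0.2, 0.1], [1, 1, 0, 0])
        assert r.auc == 1.0

    def test_all_ties_give_half(self):
        r = roc_auc([0.5] * 10, [1] * 4 + [0] * 6)
        assert r.auc == 0.5

    def test_matches_exhaustive_pair_count(self, rng):
        # brute-force oracle over all n1*n2 score pairs, ties count 1/2
        scores = rng.choice([0.1, 0.3, 0.3, 0.7, 0.9], size=30)
        y = rng.integers(0, 2, 30)
        if y.min() == y.max():
            y[0] = 1 - y[0]
        pos = scores[y == 1]
        neg = scores[y == 0]
        wins = sum((p > q) + 0.5 * (p == q) for p in pos for q in neg)
        expected = wins / (len(pos) * len(neg))
        assert roc_auc(scores, y).auc == pytest.approx(expected, abs=1e-12)

    def test_agrees_with_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score
        scores = rng.normal(0, 1, 80)
        y = rng.integers(0, 2, 80)
        y[:2] = [0, 1]
        assert roc_auc(scores, y).auc == pytest.approx(
            roc_auc_score(y, scores), abs=1e-12
        )

    def test_curve_invariants(self, rng):
        scores = rng.normal(0, 1, 40)
        y = rng.integers(0, 2, 40)
        y[:2] = [0, 1]
        r = roc_auc(scores, y)
        assert (r.fpr[0], r.tpr[0]) == (0.0, 0.0)
        assert (r.fpr[-1], r.tpr[-1]) == (1.0, 1.0)
        assert np.all(np.diff(r.fpr) >= 0) and np.all(np.diff(r.tpr) >= 0)
        assert r.auc == pytest.approx(np.trapezoid(r.tpr, r.fpr), abs=1e-12)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.2], [1, 1])


class TestCompareProbabilityGroups:
    def test_identical_groups(self):
        p = [0.2, 0.2, 0.2] * 3
        g = ["MPR"] * 3 + ["non-MPR"] * 3 + ["PD"] * 3
        out = compare_probability_groups(p, g)
        assert out["anova"]["F"] == 0.0
        assert all(pc["result"].p == 1.0 for pc in out["pairwise"])
        assert out["multiplicity_adjusted"] is False

    def test_maximal_separation(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 1e-9, 4)
        b = 1 + rng.normal(0, 1e-9, 4)
        out = compare_probability_groups(np.r_[a, b], ["A"] * 4 + ["B"] * 4)
        w = out["pairwise"][0]["result"]
        assert w.p < 1e-10
        assert not (w.ci_low <= 0 <= w.ci_high)

    def test_matches_two_pass_anova_oracle(self, rng):
        vals = rng.random(30)
        groups = rng.choice(["a", "b", "c"], 30)
        for g in "abc":    # ensure every group has >= 2 members
            idx = np.flatnonzero(groups == g)
            if idx.size < 2:
                groups[:2] = g
        out = compare_probability_groups(vals, groups)["anova"]
        # textbook decomposition, computed independently
        grand = vals.mean()
        sst = ((vals - grand) ** 2).sum()
        ssw = sum(((vals[groups == g] - vals[groups == g].mean()) ** 2).sum()
                  for g in np.unique(groups))
        ssb = sst - ssw
        k = len(np.unique(groups))
        f_oracle = (ssb / (k - 1)) / (ssw / (30 - k))
        assert out["ss_between"] == pytest.approx(ssb, abs=1e-10)
        assert out["ss_within"] == pytest.approx(ssw, abs=1e-10)
        assert out["F"] == pytest.approx(f_oracle, abs=1e-10)
        assert out["p"] == pytest.approx(
            stats.f_oneway(*[vals[groups == g] for g in np.unique(groups)]).pvalue,
            rel=1e-9,
        )

    def test_small_group_excluded(self):
        p = [0.1, 0.2, 0.3, 0.4, 0.9]
        g = ["A", "A", "B", "B", "C"]
        out = compare_probability_groups(p, g)
        names = {n for pc in out["pairwise"] for n in pc["groups"]}
        assert "C" not in names


class TestPairedPrePost:
    def test_no_change_flags_nothing(self, rng):
        pre = make_matrix(rng.random((12, 8)) * 10)
        post = make_matrix(pre.data.to_numpy(), timepoint="post")
        post.data.index = pre.data.index
        out = paired_pre_post_test(pre, post, pre.sample_ids)
        assert (out["p"] == 1.0).all()
        assert not out["significant"].any()

    def test_constant_shift_flagged_as_expansion(self, rng):
        # signed-rank oracle: 30 strictly positive paired differences give
        # the minimal attainable p ~ 1.9e-9 << 0.05 even after BH over 10
        vals = rng.random((30, 10)) * 10 + 1
        pre = make_matrix(vals)
        shifted = vals.copy()
        shifted[:, 4] += 3.0
        post = make_matrix(shifted, timepoint="post")
        post.data.index = pre.data.index
        out = paired_pre_post_test(pre, post, pre.sample_ids).set_index("feature_id")
        target = pre.feature_ids[4]
        assert out.loc[target, "significant"]
        assert out.loc[target, "direction"] == "expansion"

    def test_bh_adjustment_monotone(self, rng):
        vals = rng.random((20, 15)) * 5 + 1
        pre = make_matrix(vals)
        post_vals = vals + rng.normal(0, 0.5, vals.shape)
        post = make_matrix(np.maximum(post_vals, 0), timepoint="post")
        post.data.index = pre.data.index
        out = paired_pre_post_test(pre, post, pre.sample_ids)
        s = out.sort_values("p")
        assert (s["q"].diff().dropna() >= -1e-12).all()

    def test_unpaired_samples_dropped(self, rng):
        pre = make_matrix(rng.random((10, 4)) + 1)
        post = make_matrix(rng.random((8, 4)) + 1, timepoint="post")
        post.data.index = pre.data.index[:8]
        out = paired_pre_post_test(pre, post, pre.sample_ids)
        assert len(out) == 4   # one row per feature, unpaired ids ignored
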