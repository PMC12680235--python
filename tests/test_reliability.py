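"""Reliability metric oracles: hand-computed MI / Spearman / AUPRC values,
cross-checks against scipy/sklearn, invariances, and slide-set aggregation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import spearmanr
from sklearn.metrics import average_precision_score, mutual_info_score

from milrel.bagcore import PatchScoreSet, ScoreChannel
from milrel.reliability import (
    auprc,
    evaluate_model,
    evaluate_scores,
    mutual_information,
    spearman,
)


class TestMutualInformation:
    def test_constant_scores_give_zero(self):
        assert mutual_information(np.ones(6), np.array([0, 1, 0, 1, 0, 1])) == 0.0

    def test_constant_labels_warn_and_zero(self):
        with pytest.warns(UserWarning, match="constant labels"):
            assert mutual_information(np.arange(4), np.zeros(4, int)) == 0.0

    def test_perfect_dependence_is_label_entropy(self):
        scores = np.array([0, 0, 0, 1, 1, 1], float)
        labels = np.array([0, 0, 0, 1, 1, 1])
        assert mutual_information(scores, labels) == pytest.approx(np.log(2), abs=1e-12)

    def test_two_by_two_joint_hand_value(self):
        """Joint counts [[2,1],[1,2]]: plug-in MI computed from the 2x2
        formula directly."""
        scores = np.array([0, 0, 0, 1, 1, 1], float)
        labels = np.array([0, 0, 1, 0, 1, 1])
        p = np.array([[2, 1], [1, 2]]) / 6
        expected = sum(
            p[i, j] * np.log(p[i, j] / (p[i].sum() * p[:, j].sum()))
            for i in range(2) for j in range(2)
        )
        assert mutual_information(scores, labels) == pytest.approx(expected, abs=1e-12)

    def test_matches_sklearn_on_binned_scores(self, rng):
        scores = rng.normal(size=200)
        labels = (rng.random(200) < 0.3).astype(int)
        binned = (scores >= np.median(scores)).astype(int)
        assert mutual_information(scores, labels) == pytest.approx(
            mutual_info_score(binned, labels), abs=1e-12)

    def test_probability_channel_threshold(self):
        # all probabilities below 0.5 -> constant binned scores -> MI 0
        scores = np.array([0.1, 0.2, 0.3, 0.4])
        labels = np.array([0, 0, 1, 1])
        assert mutual_information(scores, labels, threshold=0.5) == 0.0
        assert mutual_information(scores, labels) > 0.0  # median split differs


class TestSpearman:
    def test_identity_and_reversal(self):
        labels = np.array([0, 1, 0, 1, 1])
        assert spearman(labels.astype(float), labels) == pytest.approx(1.0)
        assert spearman(1.0 - labels, labels) == pytest.approx(-1.0)

    def test_midrank_hand_value(self):
        got = spearman(np.array([1.0, 2, 3, 4]), np.array([0, 0, 1, 1]))
        assert got == pytest.approx(2 / np.sqrt(5), abs=1e-12)

    def test_matches_scipy(self, rng):
        scores = rng.normal(size=150)
        labels = (rng.random(150) < 0.4).astype(int)
        assert spearman(scores, labels) == pytest.approx(
            spearmanr(scores, labels).statistic, abs=1e-12)

    def test_zero_variance_flagged(self):
        with pytest.warns(UserWarning, match="zero rank variance"):
            assert spearman(np.ones(4), np.array([0, 1, 0, 1])) == 0.0


class TestAUPRC:
    def test_perfect_ranking(self):
        assert auprc(np.array([0.9, 0.8, 0.2, 0.1]),
                     np.array([1, 1, 0, 0])) == pytest.approx(1.0)

    def test_three_threshold_hand_value(self):
        got = auprc(np.array([0.9, 0.8, 0.7]), np.array([1, 0, 1]))
        assert got == pytest.approx(1 / 2 + 1 / 3, abs=1e-12)

    def test_single_class_raises(self):
        with pytest.raises(ValueError):
            auprc(np.arange(4, dtype=float), np.ones(4, int))

    def test_matches_sklearn(self, rng):
        scores = rng.random(300)
        labels = (rng.random(300) < 0.25).astype(int)
        assert auprc(scores, labels) == pytest.approx(
            average_precision_score(labels, scores), abs=1e-12)

    def test_random_scores_approach_prevalence(self, rng):
        """Monte-Carlo: the expected AP of uniform random scores sits at
        the positive prevalence (up to the known finite-sample upward
        bias, which shrinks with n)."""
        n, prev, reps = 200, 0.2, 2000
        labels = (np.arange(n) < prev * n).astype(int)
        vals = [auprc(rng.random(n), labels) for _ in range(reps)]
        assert np.mean(vals) == pytest.approx(prev, abs=0.03)


@settings(max_examples=30, deadline=None, derandomize=True)
@given(st.integers(0, 2 ** 31 - 1))
def test_metrics_invariant_to_monotone_transform(seed):
    rng = np.random.default_rng(seed)
    scores = rng.normal(size=50)
    labels = (rng.random(50) < 0.4).astype(int)
    if labels.min() == labels.max():
        return
    warped = np.exp(2.0 * scores) + 1.0   # strictly increasing
    assert mutual_information(warped, labels) == pytest.approx(
        mutual_information(scores, labels), abs=1e-9)
    assert spearman(warped, labels) == pytest.approx(spearman(scores, labels), abs=1e-9)
    assert auprc(warped, labels) == pytest.approx(auprc(scores, labels), abs=1e-9)


def _ss(slide, scores):
    return PatchScoreSet(slide, np.asarray(scores, float), ScoreChannel.patch_prob)


class TestAggregation:
    def test_all_slides_roi_free_is_error(self):
        sets = [_ss("a", [0.1, 0.2]), _ss("b", [0.3, 0.4])]
        labels = [np.zeros(2, int), np.zeros(2, int)]
        with pytest.raises(ValueError, match="no ROI"):
            evaluate_scores(sets, labels)

    def test_single_slide_identity_both_aggregations(self, rng):
        scores = rng.random(40)
        labels = (rng.random(40) < 0.3).astype(int)
        labels[0] = 1
        for agg in ("per_slide_mean", "pooled"):
            mi, rho, ap, n, _ = evaluate_scores([_ss("a", scores)], [labels], agg)
            assert n == 1
            assert mi == pytest.approx(
                mutual_information(scores, labels, threshold=0.5))
            assert rho == pytest.approx(spearman(scores, labels))
            assert ap == pytest.approx(auprc(scores, labels))

    def test_per_slide_mean_averages_hand_values(self):
        s1, l1 = np.array([0.9, 0.8, 0.7]), np.array([1, 0, 1])
        s2, l2 = np.array([0.9, 0.1]), np.array([1, 0])
        _, _, ap, n, _ = evaluate_scores([_ss("a", s1), _ss("b", s2)], [l1, l2])
        assert n == 2
        assert ap == pytest.approx((auprc(s1, l1) + auprc(s2, l2)) / 2)

    def test_pooled_equals_concatenated_metric(self, rng):
        sets, labels = [], []
        for sid in "abc":
            sc = rng.random(30)
            lb = (rng.random(30) < 0.4).astype(int)
            lb[0] = 1
            sets.append(_ss(sid, sc))
            labels.append(lb)
        mi, rho, ap, n, _ = evaluate_scores(sets, labels, "pooled")
        s = np.concatenate([x.scores for x in sets])
        y = np.concatenate(labels)
        assert mi == pytest.approx(mutual_information(s, y, threshold=0.5))
        assert rho == pytest.approx(spearman(s, y))
        assert ap == pytest.approx(auprc(s, y))

    def test_roi_free_slides_excluded(self, rng):
        sc = rng.random(20)
        lb = (rng.random(20) < 0.5).astype(int)
        lb[0] = 1
        ref = evaluate_scores([_ss("a", sc)], [lb])
        with_empty = evaluate_scores(
            [_ss("a", sc), _ss("b", rng.random(15))], [lb, np.zeros(15, int)])
        assert with_empty == ref

    def test_oracle_scorer_and_random_scorer(self, rng):
        """A scorer emitting the true labels is maximally reliable; an
        independent random scorer approaches the no-information level."""
        labels = [np.r_[np.ones(8, int), np.zeros(32, int)] for _ in range(30)]
        oracle = [_ss(f"s{i}", lb.astype(float)) for i, lb in enumerate(labels)]
        mi, rho, ap, _, _ = evaluate_scores(oracle, labels)
        split_entropy = -(0.2 * np.log(0.2) + 0.8 * np.log(0.8))
        assert ap == pytest.approx(1.0) and rho == pytest.approx(1.0)
        assert mi == pytest.approx(split_entropy, abs=1e-9)
        rand = [_ss(f"s{i}", rng.random(40)) for i in range(30)]
        mi, rho, ap, _, _ = evaluate_scores(rand, labels)
        assert mi < 0.05 and abs(rho) < 0.1 and abs(ap - 0.2) < 0.1

    def test_result_wrapper_carries_ids(self, rng):
        sc = rng.random(20)
        lb = (rng.random(20) < 0.5).astype(int)
        lb[0] = 1
        res = evaluate_model("abmil", 3, [_ss("a", sc)], [lb])
        assert res.model_id == "abmil" and res.seed == 3 and res.n_slides_used == 1
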