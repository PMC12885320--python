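"""Evaluation metrics against independent brute-force oracles, plus the
Naive baseline and the frequency/depth strata."""

import numpy as np
import pytest

from magin.metrics import (THRESHOLDS, aupr_micro, error_strata, fmax,
                           naive_baseline, per_term_f1, smin, term_auc)
from magin.ontology import AnnotationTable

# ---------------------------------------------------------------------------
# Brute-force oracles: naive double loops over proteins, terms, thresholds.
# ---------------------------------------------------------------------------


def oracle_fmax(scores, truth):
    best, best_t = 0.0, 0.0
    m, L = scores.shape
    for t in THRESHOLDS:
        precs, recs = [], []
        for i in range(m):
            pred = {j for j in range(L) if scores[i, j] >= t}
            true = {j for j in range(L) if truth[i, j]}
            tp = len(pred & true)
            if pred:
                precs.append(tp / len(pred))
            if true:
                recs.append(tp / len(true))
        p = sum(precs) / len(precs) if precs else 0.0
        r = sum(recs) / len(recs) if recs else 0.0
        f = 2 * p * r / (p + r) if p + r else 0.0
        if f > best + 1e-12:
            best, best_t = f, float(t)
    return best, best_t


def oracle_smin(scores, truth, w):
    m, L = scores.shape
    best = np.inf
    for t in THRESHOLDS[THRESHOLDS > 0]:
        ru = mi = 0.0
        for i in range(m):
            for j in range(L):
                pred = scores[i, j] >= t
                if truth[i, j] and not pred:
                    ru += w[j]
                elif pred and not truth[i, j]:
                    mi += w[j]
        best = min(best, np.sqrt((ru / m) ** 2 + (mi / m) ** 2))
    return best


def oracle_aupr(scores, truth):
    """All-cutoffs PR curve with trapezoidal area."""
    s = scores.ravel()
    y = truth.ravel()
    cuts = np.unique(s)[::-1]
    pts = [(0.0, 1.0)]
    for c in cuts:
        pred = s >= c
        tp = int((pred & (y == 1)).sum())
        prec = tp / pred.sum()
        rec = tp / y.sum()
        pts.append((rec, prec))
    area = 0.0
    for (r0, p0), (r1, p1) in zip(pts, pts[1:]):
        area += (r1 - r0) * (p0 + p1) / 2
    return area


def oracle_term_auc(scores, truth):
    """Mann-Whitney pair counting, ties 0.5."""
    aucs = []
    for j in range(truth.shape[1]):
        pos = scores[truth[:, j] == 1, j]
        neg = scores[truth[:, j] == 0, j]
        if len(pos) == 0 or len(neg) == 0:
            continue
        wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
        aucs.append(wins / (len(pos) * len(neg)))
    return (float(np.mean(aucs)), len(aucs)) if aucs else (None, 0)


def rand_instance(seed, m=None, L=None):
    rng = np.random.default_rng(seed)
    m = m or int(rng.integers(2, 7))
    L = L or int(rng.integers(2, 6))
    scores = np.round(rng.random((m, L)), 2)
    truth = (rng.random((m, L)) < 0.4).astype(int)
    if truth.sum() == 0:
        truth[rng.integers(m), rng.integers(L)] = 1
    return scores, truth


class TestFmax:
    def test_perfect_scores_give_one(self):
        truth = np.array([[1, 0, 1], [0, 1, 0]])
        v, t = fmax(truth.astype(float), truth)
        assert v == pytest.approx(1.0)
        assert t <= 1.0

    def test_all_zero_scores_vs_oracle(self):
        rng = np.random.default_rng(0)
        truth = (rng.random((3, 3)) < 0.5).astype(int)
        truth[0, 0] = 1
        scores = np.zeros((3, 3))
        assert fmax(scores, truth) == pytest.approx(oracle_fmax(scores, truth))

    def test_tie_returns_smallest_threshold(self):
        truth = np.array([[1, 1]])
        scores = np.array([[1.0, 1.0]])
        v, t = fmax(scores, truth)
        assert v == pytest.approx(1.0)
        assert t == pytest.approx(0.0)

    @pytest.mark.parametrize("seed", range(40))
    def test_random_instances_vs_set_arithmetic_oracle(self, seed):
        scores, truth = rand_instance(seed)
        v, t = fmax(scores, truth)
        ov, ot = oracle_fmax(scores, truth)
        assert v == pytest.approx(ov)
        assert t == pytest.approx(ot)

    def test_adding_correct_prediction_never_decreases(self):
        scores, truth = rand_instance(11)
        v0, _ = fmax(scores, truth)
        scores2 = scores.copy()
        pos = np.argwhere(truth == 1)[0]
        scores2[pos[0], pos[1]] = 1.0
        v1, _ = fmax(scores2, truth)
        assert v1 >= v0 - 1e-12


class TestSmin:
    def test_perfect_predictions_zero(self):
        truth = np.array([[1, 0], [0, 1]])
        w = {"a": 1.0, "b": 2.0}
        assert smin(truth.astype(float), truth, w, ["a", "b"]) == 0.0

    def test_single_missed_term_equals_its_ic(self):
        truth = np.array([[1]])
        assert smin(np.zeros((1, 1)), truth, {"t": 2.0}, ["t"]) \
            == pytest.approx(2.0)

    @pytest.mark.parametrize("seed", range(40))
    def test_random_instances_vs_brute_force(self, seed):
        scores, truth = rand_instance(seed, m=2, L=3)
        w = np.round(np.random.default_rng(seed + 1).random(3) * 3, 2)
        terms = ["a", "b", "c"]
        ic = dict(zip(terms, w))
        assert smin(scores, truth, ic, terms) == pytest.approx(
            oracle_smin(scores, truth, w))

    def test_missing_ic_entry_raises(self):
        with pytest.raises(KeyError):
            smin(np.zeros((1, 2)), np.ones((1, 2), dtype=int),
                 {"a": 1.0}, ["a", "b"])

    def test_ic_weighted_false_positives_never_decrease_smin(self):
        scores, truth = rand_instance(21, m=3, L=3)
        terms = ["a", "b", "c"]
        ic = {"a": 1.0, "b": 1.5, "c": 0.5}
        s0 = smin(scores, truth, ic, terms)
        neg = np.argwhere(truth == 0)
        if len(neg):
            scores2 = scores.copy()
            scores2[neg[0][0], neg[0][1]] = 1.0
            assert smin(scores2, truth, ic, terms) >= s0 - 1e-12


class TestAupr:
    def test_perfect_ranking_is_one(self):
        scores = np.array([[0.9, 0.8, 0.1, 0.2]])
        truth = np.array([[1, 1, 0, 0]])
        assert aupr_micro(scores, truth) == pytest.approx(1.0)

    def test_inverted_ranking_hand_curve(self):
        """1 positive ranked last among 4: precision at full recall is
        1/4; curve from the 4 cutoffs."""
        scores = np.array([[0.1, 0.9, 0.8, 0.7]])
        truth = np.array([[1, 0, 0, 0]])
        assert aupr_micro(scores, truth) == pytest.approx(
            oracle_aupr(scores, truth))

    @pytest.mark.parametrize("seed", range(40))
    def test_random_instances_vs_all_cutoffs_oracle(self, seed):
        scores, truth = rand_instance(seed, m=5, L=4)
        assert aupr_micro(scores, truth) == pytest.approx(
            oracle_aupr(scores, truth), abs=1e-9)

    def test_zero_positives_raise(self):
        with pytest.raises(ValueError):
            aupr_micro(np.zeros((2, 2)), np.zeros((2, 2), dtype=int))


class TestTermAuc:
    def test_constant_scores_give_exactly_half(self):
        truth = np.array([[1, 0], [0, 1], [1, 1], [0, 0]])
        scores = np.full((4, 2), 0.37)
        mean, n = term_auc(scores, truth)
        assert mean == 0.5
        assert n == 2

    def test_perfect_separation_is_one(self):
        truth = np.array([[1], [0], [1], [0]])
        scores = np.array([[0.9], [0.1], [0.8], [0.2]])
        assert term_auc(scores, truth) == (1.0, 1)

    def test_pure_terms_skipped_and_counted(self):
        truth = np.array([[1, 1], [1, 0]])   # first term all-positive
        mean, n = term_auc(np.random.default_rng(0).random((2, 2)), truth)
        assert n == 1

    def test_no_mixed_terms_reports_absent(self):
        assert term_auc(np.zeros((2, 1)), np.ones((2, 1), dtype=int)) \
            == (None, 0)

    @pytest.mark.parametrize("seed", range(40))
    def test_random_instances_vs_mann_whitney(self, seed):
        scores, truth = rand_instance(seed, m=6, L=3)
        mean, n = term_auc(scores, truth)
        omean, on = oracle_term_auc(scores, truth)
        assert n == on
        if n:
            assert mean == pytest.approx(omean)


class TestNaiveBaseline:
    def make_train(self, n=100, k=50):
        t = AnnotationTable([(f"p{i}", "GO:1") for i in range(k)]
                            + [(f"p{i}", "GO:2") for i in range(n)],
                            propagated=True)
        return t

    def test_frequency_scores(self):
        nv = naive_baseline(self.make_train(), ["GO:1", "GO:2"],
                            ["x", "y", "z"])
        assert np.allclose(nv[:, 0], 0.5)
        assert np.allclose(nv[:, 1], 1.0)

    def test_unseen_term_scores_zero(self):
        nv = naive_baseline(self.make_train(), ["GO:9"], ["x"])
        assert np.allclose(nv, 0.0)

    def test_all_rows_identical(self):
        nv = naive_baseline(self.make_train(), ["GO:1", "GO:2"],
                            [f"q{i}" for i in range(7)])
        assert np.allclose(nv, nv[0])

    def test_empty_training_raises(self):
        with pytest.raises(ValueError):
            naive_baseline(AnnotationTable([], propagated=True), ["GO:1"],
                           ["x"])

    def test_unpropagated_rejected(self):
        with pytest.raises(ValueError):
            naive_baseline(AnnotationTable([("p", "GO:1")]), ["GO:1"], ["x"])


class TestErrorStrata:
    def test_per_term_f1_matches_column_fmax_oracle(self):
        scores, truth = rand_instance(5, m=6, L=2)
        f1 = per_term_f1(scores, truth)
        for j in range(2):
            best = 0.0
            for t in THRESHOLDS:
                pred = scores[:, j] >= t
                tp = int((pred & (truth[:, j] == 1)).sum())
                fp = int((pred & (truth[:, j] == 0)).sum())
                fn = int(((~pred) & (truth[:, j] == 1)).sum())
                if 2 * tp + fp + fn:
                    best = max(best, 2 * tp / (2 * tp + fp + fn))
            assert f1[j] == pytest.approx(best)

    def test_bucket_boundaries(self):
        terms = ["hi", "mid", "lo"]
        pairs = ([(f"p{i}", "hi") for i in range(150)]
                 + [(f"p{i}", "mid") for i in range(10)]
                 + [(f"p{i}", "lo") for i in range(9)])
        train = AnnotationTable(pairs, propagated=True)
        scores = np.random.default_rng(0).random((4, 3))
        truth = np.array([[1, 0, 1], [0, 1, 0], [1, 1, 0], [0, 0, 1]])
        depths = {"hi": 0, "mid": 5, "lo": 9}
        out = error_strata(scores, truth, terms, train, depths)
        assert out["frequency"]["high"]["n_terms"] == 1
        assert out["frequency"]["medium"]["n_terms"] == 1
        assert out["frequency"]["low"]["n_terms"] == 1
        assert out["depth"]["shallow"]["n_terms"] == 1
        assert out["depth"]["medium"]["n_terms"] == 1
        assert out["depth"]["deep"]["n_terms"] == 1

    def test_empty_buckets_absent(self):
        train = AnnotationTable([("p0", "a")], propagated=True)
        out = error_strata(np.array([[0.5]]), np.array([[1]]), ["a"], train,
                           {"a": 2})
        assert "high" not in out["frequency"]
        assert "deep" not in out["depth"]
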