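"""Early-recognition metric values, oracles and ranking-only invariances."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hybridscreen.metrics import (RANDOM_LOGAUC, RankedResult, bedroc, dcg,
                                  enrichment_factor, ranged_log_auc, roc_curve)


def ranked(scores, labels):
    scores = np.asarray(scores, dtype=float)
    return RankedResult(np.arange(len(scores)), scores, np.asarray(labels))


def front_loaded(n, N, jitter=None):
    """All n actives above all N-n inactives."""
    scores = np.concatenate([np.linspace(2, 3, n), np.linspace(0, 1, N - n)])
    labels = np.concatenate([np.ones(n, int), np.zeros(N - n, int)])
    return ranked(scores, labels)


class TestRocCurve:
    def test_perfect_separation(self):
        c = roc_curve(ranked([4, 3, 2, 1], [1, 1, 0, 0]))
        pts = list(zip(c.fpr.tolist(), c.tpr.tolist()))
        assert pts[0] == (0.0, 0.0) and pts[-1] == (1.0, 1.0)
        assert (0.0, 1.0) in pts

    def test_all_tied_is_single_diagonal_block(self):
        c = roc_curve(ranked([1, 1, 1, 1], [1, 0, 1, 0]))
        assert np.array_equal(c.fpr, [0, 1]) and np.array_equal(c.tpr, [0, 1])

    def test_hand_sweep(self):
        c = roc_curve(ranked([0.9, 0.8, 0.7, 0.6], [1, 0, 1, 0]))
        expected = [(0, 0), (0, 0.5), (0.5, 0.5), (0.5, 1), (1, 1)]
        assert list(zip(c.fpr.tolist(), c.tpr.tolist())) == expected

    def test_single_class_fatal(self):
        with pytest.raises(ValueError, match="roc_curve"):
            roc_curve(ranked([1, 2], [1, 1]))


class TestRangedLogAuc:
    def test_perfect_classifier_is_one(self):
        # >= 1000 inactives so TPR = 1 throughout [0.001, 0.1]
        assert ranged_log_auc(front_loaded(10, 1510)) == pytest.approx(1.0, abs=1e-9)

    def test_all_tied_matches_printed_integral(self):
        r = ranked(np.ones(2000), np.r_[np.ones(20), np.zeros(1980)])
        assert ranged_log_auc(r) == pytest.approx(0.0215, abs=5e-4)
        assert ranged_log_auc(r) == pytest.approx(RANDOM_LOGAUC, abs=1e-6)

    def test_back_loaded_is_zero(self):
        scores = np.r_[np.zeros(10), np.ones(1990)]
        labels = np.r_[np.ones(10, int), np.zeros(1990, int)]
        assert ranged_log_auc(ranked(scores, labels)) == pytest.approx(0.0, abs=1e-12)

    def riemann_oracle(self, r, lo=0.001, hi=0.1, steps=200_000):
        """Independent very-fine midpoint Riemann sum in the log domain.

        TPR at a query FPR comes from the sweep-ordered ROC vertices: for
        x between two distinct FPRs the bracketing segment runs from the
        last vertex at the lower FPR to the first at the higher.
        """
        import sklearn.metrics
        fpr, tpr, _ = sklearn.metrics.roc_curve(r.labels, r.scores,
                                                drop_intermediate=False)
        fpr, tpr = np.r_[0.0, fpr], np.r_[0.0, tpr]
        u = np.linspace(np.log10(lo), np.log10(hi), steps)
        x = 10 ** ((u[1:] + u[:-1]) / 2)
        idx = np.searchsorted(fpr, x, side="left")
        x0, x1 = fpr[idx - 1], fpr[idx]
        y0, y1 = tpr[idx - 1], tpr[idx]
        y = np.where(x1 == x0, y1, y0 + (y1 - y0) * (x - x0)
                     / np.where(x1 == x0, 1.0, x1 - x0))
        return (y * np.diff(u)).sum() / (np.log10(hi) - np.log10(lo))

    def test_agrees_with_riemann_oracle(self, rng):
        for _ in range(30):
            n = int(rng.integers(50, 3000))
            scores = rng.random(n)
            labels = (rng.random(n) < 0.05).astype(int)
            if labels.sum() in (0, n):
                continue
            r = ranked(scores, labels)
            assert ranged_log_auc(r) == pytest.approx(
                self.riemann_oracle(r), abs=1e-4)


class TestBedroc:
    def test_front_loaded_approaches_one(self):
        val = bedroc(front_loaded(10, 1000))
        assert 0.95 < val <= 1.0

    def test_back_loaded_near_zero(self):
        scores = np.r_[np.zeros(10), np.ones(990)]
        labels = np.r_[np.ones(10, int), np.zeros(990, int)]
        assert bedroc(ranked(scores, labels)) < 0.01

    def brute_force(self, r, alpha):
        order = np.argsort(-r.scores, kind="stable")
        lab = r.labels[order]
        N, n = len(lab), lab.sum()
        ranks = np.nonzero(lab)[0] + 1
        denom = (n / N) * (1 - np.exp(-alpha)) / (np.exp(alpha / N) - 1)
        rie = sum(np.exp(-alpha * ri / N) for ri in ranks) / denom
        rie_max = sum(np.exp(-alpha * i / N) for i in range(1, n + 1)) / denom
        rie_min = sum(np.exp(-alpha * i / N)
                      for i in range(N - n + 1, N + 1)) / denom
        return (rie - rie_min) / (rie_max - rie_min)

    @pytest.mark.parametrize("alpha", [0.5, 5.0, 20.0, 100.0])
    def test_matches_brute_force_sum(self, alpha, rng):
        scores = rng.random(400)
        labels = (rng.random(400) < 0.1).astype(int)
        labels[0] = 1
        r = ranked(scores, labels)
        assert bedroc(r, alpha) == pytest.approx(
            self.brute_force(r, alpha), abs=1e-12)

    def test_alternating_near_half_for_small_alpha(self):
        # n = N/2 actives alternating with inactives: early-recognition
        # weighting vanishes as alpha -> 0 and the score approaches 1/2
        N = 1000
        labels = np.tile([1, 0], N // 2)
        r = ranked(np.arange(N)[::-1], labels)
        assert bedroc(r, alpha=0.01) == pytest.approx(0.5, abs=0.01)

    def test_matches_rdkit_reference(self, rng):
        from rdkit.ML.Scoring.Scoring import CalcBEDROC
        scores = rng.random(500)
        labels = (rng.random(500) < 0.08).astype(int)
        labels[:2] = 1
        r = ranked(scores, labels)
        order = np.argsort(-scores, kind="stable")
        pairs = [[scores[i], labels[i]] for i in order]
        assert bedroc(r, 20.0) == pytest.approx(
            CalcBEDROC(pairs, 1, 20.0), abs=1e-10)


class TestEnrichmentFactor:
    def test_random_like_top_block_gives_one(self):
        # top-100 active fraction equals the global fraction (5%) -> EF = 1
        labels = np.zeros(1000, int)
        labels[:5] = 1          # 5 actives in top 100
        labels[900:945] = 1     # 45 more below -> n = 50
        r = ranked(np.arange(1000)[::-1], labels)
        assert enrichment_factor(r, 100) == 1.0

    def test_no_actives_in_top_gives_zero(self):
        labels = np.zeros(1000, int)
        labels[500:550] = 1
        r = ranked(np.arange(1000)[::-1], labels)
        assert enrichment_factor(r, 100) == 0.0

    def test_all_actives_in_top(self):
        labels = np.zeros(1000, int)
        labels[:50] = 1
        r = ranked(np.arange(1000)[::-1], labels)
        assert enrichment_factor(r, 100) == 10.0  # (50/100)/(50/1000)

    def test_cutoff_exceeds_dataset_fatal(self):
        with pytest.raises(ValueError, match="cutoff"):
            enrichment_factor(ranked([1, 2, 3], [1, 0, 1]), 100)


class TestDcg:
    def test_single_active_at_rank_one(self):
        labels = np.zeros(100, int)
        labels[0] = 1
        d, cg = dcg(ranked(np.arange(100)[::-1], labels), 100)
        assert d == pytest.approx(1.0)
        assert cg == 1

    def test_actives_at_ranks_one_and_three(self):
        labels = np.zeros(100, int)
        labels[[0, 2]] = 1
        d, cg = dcg(ranked(np.arange(100)[::-1], labels), 100)
        assert d == pytest.approx(1.5)  # 1/log2(2) + 1/log2(4)
        assert cg == 2

    def test_no_actives_in_top(self):
        labels = np.zeros(200, int)
        labels[150:] = 1
        d, cg = dcg(ranked(np.arange(200)[::-1], labels), 100)
        assert (d, cg) == (0.0, 0)

    def test_cg_order_invariant_dcg_not(self):
        # same actives inside the top 100, different order
        labels_a = np.zeros(200, int)
        labels_a[[0, 1]] = 1
        labels_b = np.zeros(200, int)
        labels_b[[0, 50]] = 1
        scores = np.arange(200)[::-1]
        da, cga = dcg(ranked(scores, labels_a), 100)
        db, cgb = dcg(ranked(scores, labels_b), 100)
        assert cga == cgb == 2
        assert da != db


class TestTiePolicy:
    def test_shuffle_average_on_all_tied_scores_is_near_random(self):
        # stable order puts all actives first (input order); averaging over
        # shuffled tie blocks instead approaches the random expectation
        labels = np.r_[np.ones(30, int), np.zeros(270, int)]
        r = ranked(np.ones(300), labels)
        assert enrichment_factor(r, 100) == pytest.approx(3.0)
        ef_avg = enrichment_factor(r, 100, tie_policy="shuffle-average")
        assert 0.5 < ef_avg < 1.5
        assert bedroc(r, tie_policy="shuffle-average") < bedroc(r)

    def test_shuffle_average_is_seeded_deterministic(self, rng):
        scores = np.round(rng.random(200), 1)  # plenty of ties
        labels = (rng.random(200) < 0.2).astype(int)
        labels[:1] = 1
        labels[1:2] = 0
        r = ranked(scores, labels)
        a = bedroc(r, tie_policy="shuffle-average")
        b = bedroc(r, tie_policy="shuffle-average")
        assert a == b

    def test_unknown_policy_fatal(self):
        r = ranked([1, 2, 3], [1, 0, 1])
        with pytest.raises(ValueError, match="tie policy"):
            bedroc(r, tie_policy="bogus")


class TestRankingInvariances:
    METRICS = [
        lambda r: ranged_log_auc(r),
        lambda r: bedroc(r),
        lambda r: enrichment_factor(r, 100),
        lambda r: dcg(r, 100)[0],
    ]

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=10, deadline=None)
    def test_monotone_transform_leaves_metrics_unchanged(self, seed):
        rng = np.random.default_rng(seed)
        scores = rng.random(300)
        labels = (rng.random(300) < 0.1).astype(int)
        labels[0] = 1
        labels[1] = 0
        r1 = ranked(scores, labels)
        r2 = ranked(np.exp(3 * scores) - 0.5, labels)  # strictly increasing
        for metric in self.METRICS:
            assert metric(r1) == pytest.approx(metric(r2), abs=1e-12)

    def test_promoting_an_active_never_hurts(self, rng):
        scores = np.sort(rng.random(300))[::-1].copy()
        labels = (rng.random(300) < 0.15).astype(int)
        labels[0], labels[1] = 1, 0
        # find an adjacent (inactive above active) pair and swap it
        for i in range(299):
            if labels[i] == 0 and labels[i + 1] == 1:
                swapped = labels.copy()
                swapped[i], swapped[i + 1] = 1, 0
                r_before = ranked(scores, labels)
                r_after = ranked(scores, swapped)
                for metric in self.METRICS:
                    assert metric(r_after) >= metric(r_before) - 1e-12
                break
        else:
            pytest.fail("no adjacent inactive/active pair found")
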