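import numpy as np
import pandas as pd
import pytest

import trisomod as tm
from trisomod.errors import DegenerateDataError, UndefinedMetricError

from conftest import random_labels_scores


def _pairwise_auc(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    cases = scores[labels == 1]
    controls = scores[labels == 0]
    wins = 0.0
    for c in cases:
        for k in controls:
            wins += 1.0 if c > k else (0.5 if c == k else 0.0)
    return wins / (len(cases) * len(controls))


def _sweep_average_precision(scores, labels):
    scores = np.asarray(scores, float)
    labels = np.asarray(labels, int)
    total_pos = labels.sum()
    thresholds = np.unique(scores)[::-1]
    ap, prev_recall = 0.0, 0.0
    for t in thresholds:
        sel = scores >= t
        tp = labels[sel].sum()
        precision = tp / sel.sum()
        recall = tp / total_pos
        ap += (recall - prev_recall) * precision
        prev_recall = recall
    return ap


class TestRocAuc:
    def test_perfect_separation(self):
        assert tm.roc_auc([0.9, 0.8, 0.4, 0.3], [1, 1, 0, 0]) == 1.0

    def test_hand_counted_half(self):
        assert tm.roc_auc([0.9, 0.3, 0.8, 0.4], [1, 1, 0, 0]) == 0.5

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(200):
            scores, labels = random_labels_scores(rng, n=int(rng.integers(6, 40)))
            if rng.random() < 0.3:  # induce ties
                scores = np.round(scores)
            assert tm.roc_auc(scores, labels) == pytest.approx(
                _pairwise_auc(scores, labels), abs=1e-12)

    def test_negated_scores_flip_auc(self, rng):
        scores, labels = random_labels_scores(rng)
        a = tm.roc_auc(scores, labels)
        assert tm.roc_auc(-scores, labels) == pytest.approx(1 - a, abs=1e-12)

    def test_monotone_transform_invariance(self, rng):
        scores, labels = random_labels_scores(rng)
        a = tm.roc_auc(scores, labels)
        assert tm.roc_auc(np.exp(3 * scores) - 2, labels) == pytest.approx(a)

    def test_single_class_rejected(self):
        with pytest.raises(UndefinedMetricError):
            tm.roc_auc([1.0, 2.0], [1, 1])


class TestAveragePrecision:
    def test_perfect_ranking(self):
        assert tm.average_precision([3, 2, 1, 0], [1, 1, 0, 0]) == 1.0

    def test_worked_example(self):
        assert tm.average_precision([0.9, 0.8, 0.7], [1, 0, 1]) == \
            pytest.approx(5 / 6)

    def test_matches_sweep_oracle(self, rng):
        for _ in range(200):
            scores, labels = random_labels_scores(rng, n=int(rng.integers(5, 40)))
            if rng.random() < 0.3:
                scores = np.round(scores)
            assert tm.average_precision(scores, labels) == pytest.approx(
                _sweep_average_precision(scores, labels), abs=1e-12)

    def test_no_cases_rejected(self):
        with pytest.raises(UndefinedMetricError):
            tm.average_precision([1.0, 2.0], [0, 0])


class TestBalancedMaps:
    def test_balanced_classes_reduce_to_plain_ap(self, rng):
        scores = rng.normal(size=20)
        labels = np.r_[np.ones(10), np.zeros(10)].astype(int)
        maps, sd = tm.balanced_maps(scores, labels, iterations=50, seed=0)
        assert maps == pytest.approx(tm.average_precision(scores, labels))
        assert sd == 0.0

    def test_deterministic_given_seed(self, rng):
        scores, labels = random_labels_scores(rng, n=60, p_case=0.25)
        a = tm.balanced_maps(scores, labels, iterations=50, seed=7)
        b = tm.balanced_maps(scores, labels, iterations=50, seed=7)
        assert a == b

    def test_monte_carlo_stability(self):
        rng = np.random.default_rng(12)
        scores = rng.normal(size=800)
        labels = np.r_[np.ones(200), np.zeros(600)].astype(int)
        vals = [tm.balanced_maps(scores, labels, iterations=50, seed=s)[0]
                for s in range(10)]
        assert max(vals) - min(vals) < 2 * 0.02

    def test_fewer_controls_than_cases_logged(self, caplog):
        rng = np.random.default_rng(1)
        scores = rng.normal(size=12)
        labels = np.r_[np.ones(9), np.zeros(3)].astype(int)
        with caplog.at_level("INFO"):
            maps, _ = tm.balanced_maps(scores, labels, iterations=5, seed=0)
        assert "fewer controls" in caplog.text
        assert 0 <= maps <= 1


class TestEvaluateModules:
    def test_planted_comorbidity_module_passes(self, small_dataset):
        ds = small_dataset
        metrics = tm.evaluate_modules(ds.truth.B_true, ds.metadata, seed=0)
        row = metrics[(metrics["lv"] == "LV2") & (metrics["comorbidity"] == "com_a")]
        assert len(row) == 1 and bool(row["passes"].iloc[0])

    def test_permuted_labels_pass_nothing(self, small_dataset):
        ds = small_dataset
        rng = np.random.default_rng(0)
        meta = ds.metadata.copy()
        t21 = meta["karyotype"] == "T21"
        meta.loc[t21, "com_a"] = rng.permutation(meta.loc[t21, "com_a"].to_numpy())
        metrics = tm.evaluate_modules(ds.truth.B_true, meta, seed=0)
        assert not metrics["passes"].any()

    def test_underpowered_pair_skipped(self, small_dataset, caplog):
        ds = small_dataset
        meta = ds.metadata.copy()
        t21_idx = meta.index[meta["karyotype"] == "T21"]
        meta["rare"] = np.nan
        meta.loc[t21_idx, "rare"] = 0.0
        meta.loc[t21_idx[:2], "rare"] = 1.0  # only 2 cases
        with caplog.at_level("INFO"):
            metrics = tm.evaluate_modules(ds.truth.B_true, meta,
                                          comorbidities=["rare"], seed=0)
        assert len(metrics) == 0


class TestQuartileEnrichment:
    def test_cases_exactly_top_quartile(self):
        scores = np.arange(16, dtype=float)
        labels = np.r_[np.zeros(12), np.ones(4)].astype(int)
        res = tm.quartile_enrichment(scores, labels)
        assert res.table.tolist() == [[4, 0], [0, 12]]
        assert res.pvalue == pytest.approx(1 / 1820)

    def test_null_pvalues_roughly_uniform(self):
        """Independent labels: one-sided p behaves like a (discrete) null
        p-value — its sub-uniformity never undershoots uniform."""
        from scipy.stats import kstest
        rng = np.random.default_rng(3)
        pvals = []
        for _ in range(200):
            scores = rng.normal(size=40)
            labels = (rng.random(40) < 0.3).astype(int)
            if labels.sum() in (0, 40):
                continue
            pvals.append(tm.quartile_enrichment(scores, labels).pvalue)
        # discrete exact tests are conservative; test stochastic dominance of
        # the uniform (empirical CDF never significantly above the diagonal)
        assert kstest(pvals, "uniform", alternative="greater").pvalue > 0.01

    def test_constant_scores_rejected(self):
        with pytest.raises(DegenerateDataError):
            tm.quartile_enrichment(np.ones(10), np.r_[np.ones(3), np.zeros(7)])

    def test_matches_hypergeometric_tail(self, rng):
        import math

        def tail(a, b, c, d):
            r1, c1, n = a + b, a + c, a + b + c + d
            return sum(math.comb(c1, x) * math.comb(n - c1, r1 - x)
                       for x in range(a, min(r1, c1) + 1)) / math.comb(n, r1)

        for _ in range(100):
            n = int(rng.integers(10, 60))
            scores = rng.normal(size=n)
            labels = (rng.random(n) < 0.4).astype(int)
            if labels.sum() in (0, n) or np.unique(scores).size == 1:
                continue
            res = tm.quartile_enrichment(scores, labels)
            a, b = res.table[0]
            c, d = res.table[1]
            assert res.pvalue == pytest.approx(tail(a, b, c, d), abs=1e-12)
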