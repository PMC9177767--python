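"""Linear classifiers: patient-grouped splits, separability, AUC against a
brute-force concordance oracle, tumor scoring and clustering metrics."""

import numpy as np
import pytest

import monekit as mk
from monekit.classify import (
    _rank_auc,
    class_labels,
    clustermap_metrics,
    cross_classification,
    embed_mlda_tsne,
    evaluate,
    fit_lr_lasso,
    fit_mlda,
    make_splits,
    nonzero_features,
    universal_tumor_score,
)
from monekit.data import SlideMeta


def _meta_two_classes(n_patients_per_class=4, slides_per_patient=1):
    meta = []
    for cls, lesion in (("A", "tumor"), ("A", "normal")):
        for p in range(n_patients_per_class):
            pid = f"{lesion}-P{p}"
            for s in range(slides_per_patient):
                meta.append(
                    SlideMeta(f"{pid}-S{s}", pid, "A", lesion, "frozen", f"{pid}-V{s}")
                )
    return meta


class TestSplits:
    def test_two_patients_per_class_half_split(self):
        meta = _meta_two_classes(n_patients_per_class=2)
        plan = make_splits(meta, n_reps=5, test_fraction=0.5, seed=0)
        for train, test in plan:
            train_labels = [meta[i].lesion for i in train]
            test_labels = [meta[i].lesion for i in test]
            assert sorted(set(train_labels)) == ["normal", "tumor"]
            assert sorted(set(test_labels)) == ["normal", "tumor"]

    def test_partition_and_no_patient_leakage(self, small_cohort):
        *_, meta, _, mones, _ = small_cohort
        plan = make_splits(mones.meta, n_reps=6, test_fraction=0.25, seed=3)
        n = len(mones.meta)
        for train, test in plan:
            assert sorted(np.r_[train, test].tolist()) == list(range(n))
            train_patients = {mones.meta[i].patient_id for i in train}
            test_patients = {mones.meta[i].patient_id for i in test}
            assert not (train_patients & test_patients)

    def test_deterministic_given_seed(self, small_cohort):
        *_, mones, _ = small_cohort
        p1 = make_splits(mones.meta, n_reps=3, seed=7)
        p2 = make_splits(mones.meta, n_reps=3, seed=7)
        for (a, b), (c, d) in zip(p1, p2):
            assert np.array_equal(a, c) and np.array_equal(b, d)

    def test_class_ratio_preserved(self, small_cohort):
        *_, mones, _ = small_cohort
        labels = class_labels(mones.meta)
        plan = make_splits(mones.meta, n_reps=4, test_fraction=0.25, seed=1)
        for _, test in plan:
            test_labels = labels[test]
            for cls in np.unique(labels):
                total = (labels == cls).sum()
                got = (test_labels == cls).sum()
                # patient granularity: allow one patient's worth of slack
                assert abs(got - 0.25 * total) <= 2

    def test_single_patient_class_rejected(self):
        meta = [
            SlideMeta("S0", "P0", "A", "tumor", "frozen", "V0"),
            SlideMeta("S1", "P1", "A", "normal", "frozen", "V1"),
            SlideMeta("S2", "P2", "A", "normal", "frozen", "V2"),
        ]
        with pytest.raises(ValueError, match="tumor"):
            make_splits(meta, n_reps=1)


class TestClassifiers:
    def _separable(self, rng, sep=10.0, n=30, m=10):
        # class means at -sep/2 and +sep/2 on feature 0
        X = rng.standard_normal((2 * n, m))
        X[:n, 0] -= sep / 2
        X[n:, 0] += sep / 2
        y = np.array(["a"] * n + ["b"] * n)
        return X, y

    def test_mlda_separable_auc_one(self, rng):
        X, y = self._separable(rng)
        clf = fit_mlda(X[::2], y[::2])
        rep = evaluate(clf, X[1::2], y[1::2])
        assert rep.macro_auc == 1.0

    def test_mlda_permuted_labels_chance(self, rng):
        X, y = self._separable(rng, sep=0.0, n=100, m=10)
        clf = fit_mlda(X[::2], y[::2])
        rep = evaluate(clf, X[1::2], y[1::2])
        assert abs(rep.macro_auc - 0.5) < 0.2

    def test_lasso_probabilities_sum_to_one(self, rng):
        X, y = self._separable(rng)
        clf = fit_lr_lasso(X, y)
        assert np.allclose(clf.predict_proba(X).sum(axis=1), 1.0)

    def test_lasso_sparse_recovery(self, rng):
        # single informative feature among many nulls; at C=0.3 the L1
        # penalty prunes nearly all null coefficients to exact zeros
        hits, nonzeros = 0, []
        for seed in range(5):
            r = np.random.default_rng(seed)
            X = r.standard_normal((120, 200))
            y = (X[:, 7] + 0.3 * r.standard_normal(120) > 0).astype(int)
            clf = fit_lr_lasso(X, y, C=0.3, seed=seed)
            nz = set(nonzero_features(clf).tolist())
            hits += 7 in nz
            nonzeros.append(len(nz))
        assert hits >= 4
        assert np.median(nonzeros) <= 25

    def test_lasso_insensitive_to_C_when_separable(self, rng):
        X, y = self._separable(rng, sep=4.0, n=60)
        aucs = []
        for C in (1.0, 100.0, 1000.0):
            clf = fit_lr_lasso(X[::2], y[::2], C=C)
            aucs.append(evaluate(clf, X[1::2], y[1::2]).macro_auc)
        assert max(aucs) - min(aucs) < 0.01


class TestEvaluate:
    def test_auc_equals_concordance_oracle(self, rng):
        for _ in range(20):
            n = int(rng.integers(8, 50))
            scores = rng.random(n)
            pos = rng.random(n) < 0.5
            if pos.sum() in (0, n):
                continue
            auc = _rank_auc(scores, pos)
            # O(n^2) pairwise concordance with ties counted half
            num = 0.0
            for i in np.flatnonzero(pos):
                for j in np.flatnonzero(~pos):
                    num += (scores[i] > scores[j]) + 0.5 * (scores[i] == scores[j])
            assert auc == pytest.approx(num / (pos.sum() * (~pos).sum()), abs=1e-12)

    def test_constant_scores_auc_half(self):
        assert _rank_auc(np.ones(10), np.r_[np.ones(5, bool), np.zeros(5, bool)]) == 0.5

    def test_absent_class_reported_missing(self, rng):
        X = rng.standard_normal((30, 4))
        y = np.array(["a", "b", "c"] * 10)
        clf = fit_mlda(X, y)
        rep = evaluate(clf, X[y != "c"], y[y != "c"])
        assert rep.ovr_auc["c"] is None

    def test_confusion_rows_sum_to_one(self, rng):
        X = rng.standard_normal((40, 3))
        y = np.array(["a", "b"] * 20)
        clf = fit_mlda(X, y)
        rep = evaluate(clf, X, y)
        assert np.allclose(rep.confusion.sum(axis=1), 1.0, atol=1e-9)


class TestTumorScoring:
    def test_universal_score_in_unit_interval(self, rng):
        X = rng.standard_normal((60, 5))
        y = np.array(
            ["A:tumor", "A:normal", "B:tumor", "B:normal"] * 15
        )
        clf = fit_lr_lasso(X, y)
        s = universal_tumor_score(clf, X)
        assert np.all((s >= 0) & (s <= 1))

    def test_wrong_scheme_rejected(self, rng):
        X = rng.standard_normal((20, 3))
        y = np.array(["a", "b"] * 10)
        clf = fit_lr_lasso(X, y)
        with pytest.raises(ValueError, match="scheme"):
            universal_tumor_score(clf, X)

    def test_cross_classification_shared_markers(self):
        r = np.random.default_rng(0)
        cohorts = {}
        for c in ("A", "B"):
            X = r.standard_normal((80, 10))
            y = np.r_[np.zeros(40, int), np.ones(40, int)]
            X[y == 1, 0] += 4.0  # shared marker feature
            cohorts[c] = (X, y)
        auc = cross_classification(cohorts, seed=0)
        assert np.all(auc > 0.95)  # off-diagonals track the diagonal


class TestClustermap:
    def test_perfect_separation_all_ones(self, rng):
        X = rng.standard_normal((30, 5))
        labels = np.r_[np.zeros(15, bool), np.ones(15, bool)]
        X[labels] += 10.0
        auc, rand, ari = clustermap_metrics(X, labels)
        assert (auc, rand, ari) == (1.0, 1.0, 1.0)

    def test_random_labels_ari_near_zero(self, rng):
        aris = []
        for _ in range(10):
            X = rng.standard_normal((40, 5))
            labels = rng.random(40) < 0.5
            if labels.sum() < 2 or (~labels).sum() < 2:
                continue
            aris.append(clustermap_metrics(X, labels)[2])
        assert abs(np.mean(aris)) < 0.1

    def test_metrics_in_valid_ranges(self, rng):
        X = rng.standard_normal((20, 4))
        labels = np.r_[np.zeros(10, bool), np.ones(10, bool)]
        auc, rand, ari = clustermap_metrics(X, labels)
        assert 0.0 <= auc <= 1.0 and 0.0 <= rand <= 1.0 and ari <= 1.0


class TestTsne:
    def test_reproducible_given_seed(self, rng):
        X = rng.standard_normal((60, 3))
        with pytest.warns(UserWarning, match="perplexity"):
            a = embed_mlda_tsne(X, perplexity=50, seed=1)
            b = embed_mlda_tsne(X, perplexity=50, seed=1)
        assert np.array_equal(a, b)

    def test_one_dimensional_input_handled(self, rng):
        X = rng.standard_normal(45)
        out = embed_mlda_tsne(X, perplexity=10, seed=0)
        assert out.shape == (45, 2)

    def test_cluster_neighbors_preserved(self, rng):
        # two tight, well-separated clouds stay co-located in the embedding
        X = np.r_[rng.standard_normal((30, 4)) * 0.1,
                  rng.standard_normal((30, 4)) * 0.1 + 8.0]
        emb = embed_mlda_tsne(X, perplexity=10, seed=0)
        labels = np.r_[np.zeros(30, bool), np.ones(30, bool)]
        overlap = 0
        for i in range(60):
            d = np.linalg.norm(emb - emb[i], axis=1)
            d[i] = np.inf
            overlap += labels[np.argmin(d)] == labels[i]
        assert overlap / 60 >= 0.5
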