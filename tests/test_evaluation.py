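import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import phavip as p
from phavip import evaluation as ev
from phavip import naive_bayes as nb


def make_matrix(values, labels):
    values = np.asarray(values, dtype=float)
    return p.FeatureMatrix(
        values=values,
        ids=tuple(f"s{i}" for i in range(values.shape[0])),
        feature_names=tuple(p.CANONICAL_FEATURE_NAMES[: values.shape[1]]),
        labels=np.asarray(labels, dtype=int),
    )


class TestMetrics:
    def test_benchmark_confusion_matrix(self):
        # 75/99 virion and 168/208 nonvirion correct
        sn, sp, acc = p.metrics(p.ConfusionMatrix(tp=75, fn=24, tn=168, fp=40))
        assert (p.round2(sn), p.round2(sp), p.round2(acc)) == (75.76, 80.77, 79.15)

    def test_coin_flip_symmetry(self):
        sn, sp, acc = p.metrics(p.ConfusionMatrix(tp=7, fn=7, tn=13, fp=13))
        assert sn == sp == acc == 50.0

    def test_perfect_classifier(self):
        sn, sp, acc = p.metrics(p.ConfusionMatrix(tp=5, fn=0, tn=9, fp=0))
        assert sn == sp == acc == 100.0

    def test_empty_class_undefined(self):
        with pytest.raises(ev.EvaluationError):
            p.metrics(p.ConfusionMatrix(tp=0, fn=0, tn=3, fp=1))

    @given(st.integers(0, 50), st.integers(0, 50), st.integers(0, 50), st.integers(0, 50))
    def test_accuracy_is_prevalence_weighted_mean(self, tp, fn, tn, fp):
        if tp + fn == 0 or tn + fp == 0:
            return
        sn, sp, acc = p.metrics(p.ConfusionMatrix(tp=tp, fn=fn, tn=tn, fp=fp))
        n_pos, n_neg = tp + fn, tn + fp
        assert acc == pytest.approx((sn * n_pos + sp * n_neg) / (n_pos + n_neg))

    def test_round_half_up(self):
        assert p.round2(79.145) == 79.15
        assert p.round2(75.755) == 75.76


class TestRocCurve:
    def test_endpoints_and_monotonicity(self):
        rng = np.random.default_rng(0)
        curve = p.roc_curve(rng.random(50), rng.integers(0, 2, 50))
        assert (curve.fpr[0], curve.tpr[0]) == (0.0, 0.0)
        assert (curve.fpr[-1], curve.tpr[-1]) == (1.0, 1.0)
        assert (np.diff(curve.fpr) >= 0).all() and (np.diff(curve.tpr) >= 0).all()

    def test_perfect_scores_pass_through_corner(self):
        labels = np.array([1, 0, 1, 0, 1])
        curve = p.roc_curve(labels.astype(float), labels)
        assert any(f == 0.0 and t == 1.0 for f, t in zip(curve.fpr, curve.tpr))

    def test_all_tied_scores_collapse_to_diagonal(self):
        curve = p.roc_curve(np.full(6, 0.5), np.array([0, 1] * 3))
        np.testing.assert_array_equal(curve.fpr, [0.0, 1.0])
        np.testing.assert_array_equal(curve.tpr, [0.0, 1.0])

    def test_hand_enumerated_six_pairs(self):
        # scores 6..1 descending; labels: 1,1,0,1,0,0
        scores = np.array([6.0, 5.0, 4.0, 3.0, 2.0, 1.0])
        labels = np.array([1, 1, 0, 1, 0, 0])
        curve = p.roc_curve(scores, labels)
        np.testing.assert_allclose(curve.tpr, [0, 1 / 3, 2 / 3, 2 / 3, 1, 1, 1])
        np.testing.assert_allclose(curve.fpr, [0, 0, 0, 1 / 3, 1 / 3, 2 / 3, 1])

    def test_single_class_rejected(self):
        with pytest.raises(ev.EvaluationError):
            p.roc_curve(np.array([0.1, 0.2]), np.array([1, 1]))

    def test_tsv_export(self, tmp_path):
        curve = p.roc_curve(np.array([0.9, 0.1]), np.array([1, 0]))
        curve.to_tsv(tmp_path / "roc.tsv")
        lines = (tmp_path / "roc.tsv").read_text().splitlines()
        assert lines[0] == "fpr\ttpr"


class TestAuroc:
    def test_perfect_separation_is_one(self):
        labels = np.array([0, 0, 1, 1])
        assert p.auroc(p.roc_curve(labels.astype(float), labels)) == 1.0

    def test_mann_whitney_pairwise_example(self):
        # 4 positive-negative pairs, 3 concordant -> 0.75
        scores = np.array([0.9, 0.8, 0.7, 0.6])
        labels = np.array([1, 0, 1, 0])
        assert p.auroc(p.roc_curve(scores, labels)) == pytest.approx(0.75)

    def test_label_independent_scores_near_half(self):
        rng = np.random.default_rng(42)
        labels = np.concatenate([np.ones(2000, int), np.zeros(2000, int)])
        scores = rng.random(4000)
        assert p.auroc(p.roc_curve(scores, labels)) == pytest.approx(0.5, abs=0.02)

    @pytest.mark.parametrize("seed", range(4))
    def test_trapezoid_equals_mann_whitney_with_ties(self, seed):
        rng = np.random.default_rng(seed)
        # coarse grid forces ties
        scores = rng.integers(0, 5, 60).astype(float)
        labels = rng.integers(0, 2, 60)
        if labels.sum() in (0, len(labels)):
            labels[0] = 1 - labels[0]
        trap = p.auroc(p.roc_curve(scores, labels))
        assert trap == pytest.approx(p.mann_whitney_auc(scores, labels), abs=1e-12)

    def test_agrees_with_reference_implementation(self):
        roc_auc_score = pytest.importorskip("sklearn.metrics").roc_auc_score
        rng = np.random.default_rng(5)
        scores = rng.normal(size=200)
        labels = rng.integers(0, 2, 200)
        ours = p.auroc(p.roc_curve(scores, labels))
        assert ours == pytest.approx(roc_auc_score(labels, scores), abs=1e-12)

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(6)
        scores = rng.normal(size=80)
        labels = rng.integers(0, 2, 80)
        before = p.auroc(p.roc_curve(scores, labels))
        after = p.auroc(p.roc_curve(np.exp(3 * scores) + 1, labels))
        assert before == pytest.approx(after, abs=1e-12)


class TestJackknife:
    def test_exactly_n_fits(self, monkeypatch):
        rng = np.random.default_rng(1)
        matrix = make_matrix(rng.random((10, 2)), [0, 1] * 5)
        calls = []
        real_fit = nb.fit
        monkeypatch.setattr(
            nb, "fit", lambda *a, **kw: calls.append(1) or real_fit(*a, **kw)
        )
        report = p.jackknife_evaluate(matrix)
        assert len(calls) == 10
        n_pred = (report.confusion.tp + report.confusion.tn
                  + report.confusion.fp + report.confusion.fn)
        assert n_pred == 10

    def test_strong_signal_recovered(self):
        config = p.GeneratorConfig(
            n_pos=60, n_neg=60, length_range=(80, 200), effect_size=0.35, seed=3
        )
        matrix = p.encode_matrix(p.sample_dataset(config))
        report = p.jackknife_evaluate(matrix)
        assert report.acc > 90.0
        assert report.auroc > 0.95

    def test_shuffled_labels_score_at_chance(self):
        config = p.GeneratorConfig(
            n_pos=50, n_neg=50, length_range=(60, 120), effect_size=0.35, seed=4
        )
        matrix = p.encode_matrix(p.sample_dataset(config))
        rng = np.random.default_rng(11)
        shuffled = make_matrix(matrix.values, rng.permutation(matrix.labels))
        report = p.jackknife_evaluate(shuffled)
        assert report.auroc == pytest.approx(0.5, abs=0.1)

    def test_deterministic(self):
        rng = np.random.default_rng(2)
        matrix = make_matrix(rng.random((12, 3)), [0, 1] * 6)
        r1 = p.jackknife_evaluate(matrix)
        r2 = p.jackknife_evaluate(matrix)
        np.testing.assert_array_equal(r1.scores, r2.scores)
        assert r1.confusion == r2.confusion

    def test_requires_two_per_class(self):
        rng = np.random.default_rng(3)
        matrix = make_matrix(rng.random((4, 2)), [1, 0, 0, 0])
        with pytest.raises(ev.EvaluationError):
            p.jackknife_evaluate(matrix)

    def test_tuned_theta_policy_runs(self):
        rng = np.random.default_rng(4)
        values = rng.random((14, 2))
        values[7:] += 0.6
        matrix = make_matrix(values, [0] * 7 + [1] * 7)
        report = p.jackknife_evaluate(matrix, theta_policy="tuned")
        assert report.protocol == "jackknife"
        assert 0.0 <= report.acc <= 100.0

    def test_theta_sweep_point_lies_on_roc(self):
        rng = np.random.default_rng(5)
        matrix = make_matrix(rng.random((20, 3)), [0, 1] * 10)
        report = p.jackknife_evaluate(matrix)
        curve = p.roc_curve(report.scores, report.labels)
        points = set(zip(curve.fpr.round(12), curve.tpr.round(12)))
        for theta in np.quantile(report.scores, [0.1, 0.5, 0.9]):
            pred = report.scores >= theta
            tpr = (pred & (report.labels == 1)).sum() / (report.labels == 1).sum()
            fpr = (pred & (report.labels == 0)).sum() / (report.labels == 0).sum()
            assert (round(fpr, 12), round(tpr, 12)) in points

    def test_report_json_round_trip_fields(self, tmp_path):
        rng = np.random.default_rng(6)
        matrix = make_matrix(rng.random((8, 2)), [0, 1] * 4)
        report = p.jackknife_evaluate(matrix)
        import json

        doc = json.loads(report.to_json(tmp_path / "report.json"))
        assert doc["protocol"] == "jackknife"
        assert doc["confusion"]["tp"] == report.confusion.tp
        assert "Sn" in report.to_text()


class TestStratifiedFolds:
    def test_k_equals_n_gives_singleton_folds(self):
        labels = np.array([0, 1] * 5)
        folds = p.stratified_folds(labels, k=10, seed=0)
        assert len(folds) == 10
        assert all(len(f) == 1 for f in folds)
        assert sorted(int(f[0]) for f in folds) == list(range(10))

    def test_partition_and_determinism(self):
        labels = np.array([0] * 12 + [1] * 8)
        folds1 = p.stratified_folds(labels, k=5, seed=9)
        folds2 = p.stratified_folds(labels, k=5, seed=9)
        assert all(np.array_equal(a, b) for a, b in zip(folds1, folds2))
        combined = np.sort(np.concatenate(folds1))
        np.testing.assert_array_equal(combined, np.arange(20))

    def test_stratification_balances_classes(self):
        labels = np.array([0] * 15 + [1] * 10)
        for fold in p.stratified_folds(labels, k=5, seed=1):
            assert (labels[fold] == 1).sum() == 2
            assert (labels[fold] == 0).sum() == 3

    def test_k_larger_than_n_rejected(self):
        with pytest.raises(ev.EvaluationError):
            p.stratified_folds(np.array([0, 1, 0, 1]), k=5, seed=0)


class TestKFoldFeatureSelection:
    def _signal_matrix(self, n=40, seed=0):
        rng = np.random.default_rng(seed)
        labels = np.array([0, 1] * (n // 2))
        values = rng.random((n, 5))
        values[:, 2] = labels + 0.01 * rng.random(n)  # perfectly predictive
        return make_matrix(values, labels)

    def test_predictive_feature_in_every_fold_and_consensus(self):
        matrix = self._signal_matrix()
        result = p.kfold_feature_selection(matrix, k=5, seed=1)
        name = matrix.feature_names[2]
        assert all(name in s.names for s in result.fold_subsets)
        assert name in result.consensus.names
        assert len(result.fold_accuracy) == 5
        assert min(result.fold_accuracy) > 0.9

    def test_same_seed_identical_results(self):
        matrix = self._signal_matrix(seed=2)
        r1 = p.kfold_feature_selection(matrix, k=4, seed=7)
        r2 = p.kfold_feature_selection(matrix, k=4, seed=7)
        assert [s.names for s in r1.fold_subsets] == [s.names for s in r2.fold_subsets]
        assert r1.fold_accuracy == r2.fold_accuracy
        assert r1.consensus == r2.consensus

    def test_k_equal_n_matches_jackknife_structure(self):
        matrix = self._signal_matrix(n=12, seed=3)
        result = p.kfold_feature_selection(matrix, k=12, seed=0)
        assert len(result.folds) == 12
        assert all(len(f) == 1 for f in result.folds)

    def test_k_exceeding_n_rejected(self):
        matrix = self._signal_matrix(n=8, seed=4)
        with pytest.raises(ev.EvaluationError):
            p.kfold_feature_selection(matrix, k=9, seed=0)
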