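"""Classifier zoo: metrics correctness, filters, transfer matrix, baselines."""

import numpy as np
import pandas as pd
import pytest

from tivae.classification import (
    ArchitectureSpec,
    FilterList,
    TrainConfig,
    apply_gene_filter,
    auc_mann_whitney,
    compare_filters,
    cross_tissue_eval,
    evaluate_metrics,
    filter_from_gene_lists,
    majority_baseline,
    predict_scores,
    shallow_baselines,
    train_classifier,
)


def separable_data(n=120, g=60, seed=0):
    rng = np.random.default_rng(seed)
    x = rng.random((n, g))
    y = (rng.random(n) < 0.5).astype(int)
    x[y == 1, :8] += 0.9
    return np.clip(x, 0, 1), y


class TestMetrics:
    def test_auc_matches_sklearn_on_random_scores(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(0)
        for _ in range(30):
            y = rng.integers(0, 2, size=50)
            if y.min() == y.max():
                continue
            s = np.round(rng.random(50), 2)  # ties included
            assert auc_mann_whitney(y, s) == pytest.approx(roc_auc_score(y, s))

    def test_metrics_match_brute_force_confusion_matrix(self):
        """Accuracy/precision/recall/F1 agree with explicit confusion-matrix
        arithmetic over 1,000 random prediction vectors."""
        from tivae.classification import _metrics_from_scores

        rng = np.random.default_rng(1)
        for _ in range(1000):
            n = int(rng.integers(4, 30))
            y = rng.integers(0, 2, size=n)
            s = rng.random(n)
            m = _metrics_from_scores(y, s, "test")
            pred = (s >= 0.5).astype(int)
            tp = int(((y == 1) & (pred == 1)).sum())
            fp = int(((y == 0) & (pred == 1)).sum())
            fn = int(((y == 1) & (pred == 0)).sum())
            tn = int(((y == 0) & (pred == 0)).sum())
            assert m.accuracy == pytest.approx((tp + tn) / n)
            prec = tp / (tp + fp) if tp + fp else 0.0
            rec = tp / (tp + fn) if tp + fn else 0.0
            assert m.precision == pytest.approx(prec)
            assert m.recall == pytest.approx(rec)
            f1 = 2 * prec * rec / (prec + rec) if prec + rec else 0.0
            assert m.f1 == pytest.approx(f1)

    def test_random_scores_give_half_auc(self):
        rng = np.random.default_rng(2)
        y = np.repeat([0, 1], 1000)
        s = rng.random(2000)
        assert auc_mann_whitney(y, s) == pytest.approx(0.5, abs=0.05)

    def test_single_class_auc_missing(self):
        assert np.isnan(auc_mann_whitney(np.ones(5), np.random.random(5)))


class TestMajorityCollapse:
    def test_constant_predictor_signature(self):
        y_train = np.array([1] * 13 + [0] * 7)
        y_test = np.array([1] * 13 + [0] * 7)
        m = majority_baseline(y_train, y_test)
        assert m.accuracy == pytest.approx(0.65)
        assert m.auc == pytest.approx(0.5)
        assert m.recall == pytest.approx(1.0)

    def test_minority_majority_flip(self):
        m = majority_baseline(np.array([0, 0, 0, 1]), np.array([0, 0, 1, 1]))
        assert m.accuracy == pytest.approx(0.5)
        assert m.auc == pytest.approx(0.5)


class TestGeneFilter:
    def test_intersection_preserves_order(self):
        m = pd.DataFrame(np.zeros((2, 3)), columns=["A", "B", "C"])
        f = FilterList(name="f", provenance="external", global_genes=["C", "A"])
        assert list(apply_gene_filter(m, f).columns) == ["A", "C"]

    def test_absent_genes_silently_dropped(self, caplog):
        m = pd.DataFrame(np.zeros((2, 2)), columns=["A", "B"])
        f = FilterList(name="f", provenance="external", global_genes=["A", "ZZZ"])
        assert list(apply_gene_filter(m, f).columns) == ["A"]

    def test_empty_intersection_rejected(self):
        m = pd.DataFrame(np.zeros((2, 2)), columns=["A", "B"])
        f = FilterList(name="f", provenance="external", global_genes=["X"])
        with pytest.raises(ValueError):
            apply_gene_filter(m, f)

    def test_per_tissue_filter_requires_tissue(self):
        f = FilterList(name="f", provenance="unsupervised", per_tissue={"t1": ["A"]})
        with pytest.raises(ValueError):
            f.genes_for("t2")

    def test_filter_from_gene_lists(self):
        from collections import Counter

        from tivae.prioritization import aggregate_across_vaes

        lists = aggregate_across_vaes({"t1": [], "t2": []}, min_count=0)
        lists.retained_up["t1"] = ["A", "B"]
        lists.retained_down["t1"] = ["B", "C"]
        lists.up_counts["t1"] = Counter({"A": 4, "B": 4})
        lists.down_counts["t1"] = Counter({"B": 4, "C": 4})
        f = filter_from_gene_lists(lists)
        assert f.genes_for("t1") == ["A", "B", "C"]


class TestTraining:
    def test_recurrent_learns_separable_data(self):
        x, y = separable_data()
        arch = ArchitectureSpec(kind="recurrent", input_width=x.shape[1],
                                reduced=True, chunk=16)
        run = train_classifier(x, y, arch, TrainConfig(epochs=30, batch_size=32,
                                                       n_folds=3, seed=0))
        assert evaluate_metrics(run.model, x, y).accuracy > 0.9

    def test_single_timestep_mode_runs(self):
        x, y = separable_data(n=60, g=20)
        arch = ArchitectureSpec(kind="recurrent", input_width=20, reduced=True,
                                single_timestep=True)
        run = train_classifier(x, y, arch, TrainConfig(epochs=10, batch_size=32,
                                                       n_folds=2, seed=0))
        assert np.isfinite(run.train_auc)

    def test_seed_determinism_of_fold_metrics(self):
        x, y = separable_data(n=80, g=30)
        arch = ArchitectureSpec(kind="dense-2", input_width=30, reduced=True)
        cfg = TrainConfig(epochs=8, batch_size=32, n_folds=3, seed=4)
        a = train_classifier(x, y, arch, cfg)
        b = train_classifier(x, y, arch, cfg)
        assert [m.as_dict() for m in a.fold_metrics] == [m.as_dict() for m in b.fold_metrics]

    def test_permuted_labels_give_chance_auc(self):
        """Mean cross-validated AUC under label permutation stays within
        [0.40, 0.60] over 5 seeds."""
        x, _ = separable_data(n=100, g=30)
        aucs = []
        for seed in range(5):
            y = np.random.default_rng(50 + seed).permutation(
                np.repeat([0, 1], 50))
            arch = ArchitectureSpec(kind="dense-2", input_width=30, reduced=True)
            run = train_classifier(x, y, arch, TrainConfig(epochs=10, batch_size=32,
                                                           n_folds=3, seed=seed))
            aucs.append(run.train_auc)
        assert 0.40 <= float(np.mean(aucs)) <= 0.60

    def test_single_class_rejected(self):
        x, _ = separable_data(n=40, g=10)
        arch = ArchitectureSpec(kind="dense-2", input_width=10, reduced=True)
        with pytest.raises(ValueError):
            train_classifier(x, np.zeros(40, dtype=int), arch, TrainConfig(n_folds=2))

    @pytest.mark.parametrize("kind", ["dense-1", "conv-1", "conv-2"])
    def test_other_architectures_train(self, kind):
        x, y = separable_data(n=60, g=64)
        arch = ArchitectureSpec(kind=kind, input_width=64, reduced=True)
        run = train_classifier(x, y, arch, TrainConfig(epochs=6, batch_size=32,
                                                       n_folds=2, seed=0))
        assert np.isfinite(run.train_auc)
        assert len(run.fold_metrics) == 2


class TestCrossTissue:
    def test_identical_tissues_match_diagonal_scores(self):
        x, y = separable_data(n=80, g=40)
        arch = ArchitectureSpec(kind="dense-2", input_width=40, reduced=True)
        cfg = TrainConfig(epochs=10, batch_size=32, n_folds=2, seed=0)
        run = train_classifier(x, y, arch, cfg)
        runs = {"t1": run, "t2": run}
        tests = {"t1": (x, y), "t2": (x, y)}
        matrix = cross_tissue_eval(runs, tests).auc
        assert matrix.shape == (2, 2)
        assert matrix.loc["t1", "t2"] == pytest.approx(matrix.loc["t2", "t1"], abs=1e-9)
        assert matrix.loc["t1", "t1"] == pytest.approx(run.train_auc)

    def test_label_permutation_gives_chance_transfer(self):
        x, y = separable_data(n=80, g=40, seed=3)
        arch = ArchitectureSpec(kind="dense-2", input_width=40, reduced=True)
        run = train_classifier(x, y, arch, TrainConfig(epochs=10, batch_size=32,
                                                       n_folds=2, seed=0))
        rng = np.random.default_rng(0)
        aucs = [
            auc_mann_whitney(rng.permutation(y), predict_scores(run.model, x))
            for _ in range(20)
        ]
        assert abs(float(np.mean(aucs)) - 0.5) < 0.1

    def test_width_mismatch_rejected(self):
        x, y = separable_data(n=40, g=20)
        arch = ArchitectureSpec(kind="dense-2", input_width=20, reduced=True)
        run = train_classifier(x, y, arch, TrainConfig(epochs=3, batch_size=32,
                                                       n_folds=2, seed=0))
        with pytest.raises(ValueError, match="mismatch"):
            cross_tissue_eval({"t1": run, "t2": run},
                              {"t1": (x, y), "t2": (x[:, :10], y)})


class TestCompareFilters:
    def test_uniform_improvement_is_significant(self):
        rng = np.random.default_rng(0)
        base = 0.5 + 0.05 * rng.random(10)
        result = compare_filters(base, base + 0.05 + 0.001 * rng.random(10))
        assert result.pvalue < 0.01
        assert result.mean_difference > 0.04

    def test_identical_vectors_undefined(self):
        base = np.full(5, 0.6)
        result = compare_filters(base, base)
        assert np.isnan(result.pvalue)
        assert "zero-variance" in result.note

    def test_independent_values_usually_not_significant(self):
        rng = np.random.default_rng(1)
        hits = sum(
            compare_filters(0.5 + 0.1 * rng.random(8), 0.5 + 0.1 * rng.random(8)).pvalue < 0.05
            for _ in range(20)
        )
        assert hits <= 4

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            compare_filters(np.array([0.5, 0.6]), np.array([0.5, 0.6]))


def test_shallow_baselines_report_all_metrics():
    x, y = separable_data(n=80, g=20)
    reports = shallow_baselines(x[:60], y[:60], x[60:], y[60:], seed=0)
    assert sorted(reports) == ["logistic-regression", "random-forest", "svm"]
    for m in reports.values():
        assert 0.0 <= m.accuracy <= 1.0
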