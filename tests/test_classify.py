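"""SVM cross-validation protocol and metric arithmetic."""

import numpy as np
import pytest
from sklearn.preprocessing import StandardScaler

from ulameeg.classify import SVMConfig, compute_metrics, run_cv


def blobs(n=100, sep=10.0, seed=0):
    rng = np.random.default_rng(seed)
    half = n // 2
    X = np.vstack([
        rng.normal(loc=0.0, size=(half, 5)),
        rng.normal(loc=sep, size=(half, 5)),
    ])
    y = np.array(["normal"] * half + ["ADHD"] * half)
    return X, y


class TestMetrics:
    def test_perfect(self):
        m = compute_metrics(10, 0, 10, 0)
        assert all(v == 1.0 for v in m.values())

    def test_degenerate_no_predicted_positives(self):
        m = compute_metrics(0, 0, 10, 10)
        assert m["sensitivity"] == 0 and m["precision"] == 0 and m["f1"] == 0
        assert m["accuracy"] == 0.5

    def test_hand_worked_confusion(self):
        m = compute_metrics(tp=9, fp=2, tn=8, fn=1)
        assert m["accuracy"] == pytest.approx(0.850, abs=5e-4)
        assert m["sensitivity"] == pytest.approx(0.900, abs=5e-4)
        assert m["precision"] == pytest.approx(0.818, abs=5e-4)
        assert m["f1"] == pytest.approx(0.857, abs=5e-4)

    def test_all_zero_counts_rejected(self):
        with pytest.raises(ValueError):
            compute_metrics(0, 0, 0, 0)


class TestRunCV:
    def test_separable_blobs_score_perfectly(self):
        X, y = blobs(n=100, sep=10.0)
        rep = run_cv(X, y, folds=10, seed=0)
        assert rep.per_fold["accuracy"] == [1.0] * 10
        assert rep.positive_class == "ADHD"

    def test_fold_partition_and_stratification(self):
        X, y = blobs(n=60, sep=0.5, seed=1)
        from sklearn.model_selection import StratifiedKFold

        seen = []
        for _, test_idx in StratifiedKFold(10, shuffle=True, random_state=3).split(X, y):
            seen.extend(test_idx.tolist())
            labels, counts = np.unique(y[test_idx], return_counts=True)
            assert abs(counts[0] - counts[1]) <= 1
        assert sorted(seen) == list(range(60))

    def test_seed_determinism(self):
        X, y = blobs(n=60, sep=2.0, seed=2)
        a = run_cv(X, y, folds=5, seed=7)
        b = run_cv(X, y, folds=5, seed=7)
        assert a.per_fold == b.per_fold and a.confusion_total == b.confusion_total

    def test_null_data_near_chance(self):
        """Permutation null: signal-free data scores ~50% over seeds."""
        rng = np.random.default_rng(10)
        accs = []
        for seed in range(12):
            X = rng.standard_normal((60, 8))
            y = np.array(["ADHD"] * 30 + ["normal"] * 30)
            rng.shuffle(y)
            rep = run_cv(X, y, cfg=SVMConfig(inner_folds=3), folds=5, seed=seed)
            accs.append(rep.mean_sd["accuracy"][0])
        accs = np.array(accs)
        se = accs.std(ddof=1) / np.sqrt(len(accs))
        assert abs(accs.mean() - 0.5) < 3 * se + 1e-9

    def test_class_smaller_than_folds_rejected(self):
        X, y = blobs(n=10, sep=1.0)
        with pytest.raises(ValueError, match="folds"):
            run_cv(X, y, folds=10)

    def test_training_fold_standardizer_differs_from_global(self):
        """Per-fold scaling uses training data only, not the whole matrix."""
        X, y = blobs(n=40, sep=3.0, seed=5)
        global_mean = StandardScaler().fit(X).mean_
        from sklearn.model_selection import StratifiedKFold

        train_idx, _ = next(
            StratifiedKFold(5, shuffle=True, random_state=0).split(X, y)
        )
        fold_mean = StandardScaler().fit(X[train_idx]).mean_
        assert not np.allclose(global_mean, fold_mean)

    def test_feature_selector_sees_training_fold_only(self):
        X, y = blobs(n=40, sep=5.0, seed=6)
        seen_sizes = []

        def selector(X_tr, y_tr):
            seen_sizes.append(len(X_tr))
            return np.arange(X_tr.shape[1])

        run_cv(X, y, folds=5, seed=0, feature_selector=selector)
        assert all(s == 32 for s in seen_sizes)  # 4/5 of 40, never 40

    def test_subject_grouping_keeps_groups_in_one_fold(self):
        X, y = blobs(n=40, sep=5.0, seed=7)
        groups = np.repeat(np.arange(10), 4)
        rep = run_cv(X, y, folds=2, seed=0, groups=groups)
        assert rep.folds == 2

    def test_markdown_report_shape(self):
        X, y = blobs(n=40, sep=8.0, seed=8)
        rep = run_cv(X, y, folds=4, seed=1)
        md = rep.to_markdown()
        assert md.splitlines()[0].startswith("| Accuracy")
        assert "±" in md
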