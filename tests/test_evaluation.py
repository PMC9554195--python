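"""Fold planning, confusion metrics, AUC and t-interval aggregation."""

from types import SimpleNamespace

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from sonodeclutter import evaluation as ev

STUDY_CLASS_SIZES = {"normal": 214, "cystadenoma": 272, "teratoma": 364,
                     "endometrioma": 224, "malignant": 539}


def _manifest_from_counts(counts: dict[str, int]):
    rows = [SimpleNamespace(id=f"{label}-{i}", label=label)
            for label, n in counts.items() for i in range(n)]
    return SimpleNamespace(rows=rows)


class TestFoldPlan:
    def test_study_cohort_fold_sizes(self):
        """The five class totals split into validation folds of
        324/324/323/323/319 images (1613 total)."""
        plan = ev.make_fold_plan(_manifest_from_counts(STUDY_CLASS_SIZES), 5, seed=0)
        assert plan.fold_sizes() == [324, 324, 323, 323, 319]
        assert sum(plan.fold_sizes()) == 1613

    def test_five_items_five_folds_one_each(self):
        plan = ev.make_fold_plan(_manifest_from_counts({"x": 5}), 5, seed=1)
        assert plan.fold_sizes() == [1, 1, 1, 1, 1]

    @given(sizes=st.lists(st.integers(1, 40), min_size=1, max_size=4),
           seed=st.integers(0, 1000))
    @settings(max_examples=25, deadline=None)
    def test_per_class_fold_counts_differ_by_at_most_one(self, sizes, seed):
        counts = {f"c{i}": n for i, n in enumerate(sizes)}
        manifest = _manifest_from_counts(counts)
        if sum(sizes) < 3:
            return
        import warnings
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            plan = ev.make_fold_plan(manifest, 3, seed=seed)
        for label, n in counts.items():
            per_fold = [sum(1 for rid, f in plan.assignment.items()
                            if f == k and rid.startswith(label + "-"))
                        for k in range(1, 4)]
            assert sum(per_fold) == n
            assert max(per_fold) - min(per_fold) <= 1
            # remainders dealt to the lowest-numbered folds
            assert sorted(per_fold, reverse=True) == per_fold

    def test_small_class_warns(self):
        with pytest.warns(UserWarning, match="fewer members"):
            ev.make_fold_plan(_manifest_from_counts({"x": 2, "y": 10}), 5, seed=0)

    def test_more_folds_than_images_rejected(self):
        with pytest.raises(ValueError):
            ev.make_fold_plan(_manifest_from_counts({"x": 3}), 5, seed=0)


class TestConfusion:
    def test_perfect_prediction_is_diagonal(self):
        truth = [0, 0, 1, 2, 2, 2]
        cm = ev.confusion(truth, truth, 3)
        assert np.array_equal(cm.counts, np.diag([2, 1, 3]))

    def test_empty_input_gives_zero_matrix(self):
        cm = ev.confusion([], [], 4)
        assert cm.counts.sum() == 0 and cm.counts.shape == (4, 4)

    def test_matches_loop_oracle_on_random_case(self):
        rng = np.random.default_rng(0)
        truth = rng.integers(0, 5, 100)
        pred = rng.integers(0, 5, 100)
        cm = ev.confusion(truth, pred, 5)
        expected = np.zeros((5, 5), dtype=int)
        for t, p in zip(truth, pred):
            expected[t, p] += 1
        assert np.array_equal(cm.counts, expected)
        assert cm.accuracy() == pytest.approx(np.trace(expected) / 100)

    def test_out_of_range_label_rejected(self):
        with pytest.raises(ValueError):
            ev.confusion([0, 5], [0, 1], 5)


class TestBinaryMetrics:
    def _cm_from_binary(self, tp, fn, fp, tn):
        return ev.ConfusionMatrix(np.array([[tp, fn], [fp, tn]]))

    def test_malignant_sensitivity_467_of_539(self):
        m = ev.binary_metrics(self._cm_from_binary(467, 72, 50, 1024), 0)
        assert m["sensitivity"] == pytest.approx(86.6, abs=0.05)

    def test_malignant_sensitivity_451_of_539(self):
        m = ev.binary_metrics(self._cm_from_binary(451, 88, 50, 1024), 0)
        assert m["sensitivity"] == pytest.approx(83.7, abs=0.05)

    def test_zero_denominator_flagged_not_zero(self):
        m = ev.binary_metrics(self._cm_from_binary(0, 0, 3, 7), 0)
        assert m["sensitivity"] is None
        assert m["specificity"] == pytest.approx(70.0)

    def test_one_vs_rest_collapse_of_multiclass_matrix(self):
        counts = np.array([[5, 1, 0], [2, 6, 1], [0, 1, 4]])
        m = ev.binary_metrics(ev.ConfusionMatrix(counts), 1)
        tp, fn, fp = 6, 3, 2
        tn = counts.sum() - tp - fn - fp
        assert m["sensitivity"] == pytest.approx(100 * tp / (tp + fn))
        assert m["ppv"] == pytest.approx(100 * tp / (tp + fp))
        assert m["npv"] == pytest.approx(100 * tn / (tn + fn))
        assert m["accuracy"] == pytest.approx(100 * (tp + tn) / counts.sum())

    def test_sensitivity_equals_diagonal_over_rowsum(self):
        rng = np.random.default_rng(3)
        counts = rng.integers(0, 30, (5, 5))
        counts[2] += 1  # ensure nonzero row
        cm = ev.ConfusionMatrix(counts)
        for c in range(5):
            m = ev.binary_metrics(cm, c)
            row = counts[c].sum()
            if row:
                assert m["sensitivity"] == pytest.approx(100 * counts[c, c] / row)

    def test_empty_matrix_rejected(self):
        with pytest.raises(ValueError):
            ev.binary_metrics(ev.ConfusionMatrix(np.zeros((2, 2), dtype=int)), 0)


class TestRocAuc:
    def test_perfect_separation_gives_one(self):
        auc, points = ev.roc_auc([0.9, 0.8, 0.2, 0.1], [True, True, False, False])
        assert auc == 1.0
        assert points[0] == (0.0, 0.0) and points[-1] == (1.0, 1.0)

    def test_all_ties_give_half(self):
        auc, _ = ev.roc_auc([0.5] * 10, [True] * 5 + [False] * 5)
        assert auc == 0.5

    def test_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(7)
        scores = np.round(rng.random(12), 1)  # coarse grid forces some ties
        labels = np.array([True] * 6 + [False] * 6)
        wins = 0.0
        for sp in scores[labels]:
            for sn in scores[~labels]:
                wins += 1.0 if sp > sn else (0.5 if sp == sn else 0.0)
        auc, _ = ev.roc_auc(scores, labels)
        assert auc == pytest.approx(wins / 36)

    def test_agrees_with_sklearn(self):
        from sklearn.metrics import roc_auc_score

        rng = np.random.default_rng(8)
        scores = rng.random(50)
        labels = rng.random(50) < 0.4
        labels[0], labels[1] = True, False
        auc, _ = ev.roc_auc(scores, labels)
        assert auc == pytest.approx(roc_auc_score(labels, scores))

    def test_invariant_under_monotone_transform(self):
        rng = np.random.default_rng(9)
        scores = rng.random(30)
        labels = np.arange(30) % 3 == 0
        a1, _ = ev.roc_auc(scores, labels)
        a2, _ = ev.roc_auc(np.exp(5 * scores), labels)
        assert a1 == pytest.approx(a2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError, match="both classes"):
            ev.roc_auc([0.1, 0.2], [True, True])


class TestAggregateCi:
    def test_identical_values_give_zero_width(self):
        agg = ev.aggregate_ci([84.0] * 5)
        assert agg == {"mean": 84.0, "lower": 84.0, "upper": 84.0}

    def test_closed_form_with_t_2_776(self):
        agg = ev.aggregate_ci([80.0, 82.0, 84.0, 86.0, 88.0])
        half = 2.776 * np.sqrt(10.0) / np.sqrt(5.0)
        assert agg["mean"] == pytest.approx(84.0)
        assert agg["upper"] - agg["mean"] == pytest.approx(half, abs=1e-3)

    def test_interval_symmetric_about_mean(self):
        rng = np.random.default_rng(1)
        vals = rng.normal(70, 5, 7)
        agg = ev.aggregate_ci(vals)
        assert agg["lower"] <= agg["mean"] <= agg["upper"]
        assert (agg["mean"] - agg["lower"]) == pytest.approx(agg["upper"] - agg["mean"])

    def test_large_n_approaches_normal_interval(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(0, 1, 1000)
        agg = ev.aggregate_ci(vals)
        half = agg["upper"] - agg["mean"]
        normal_half = 1.96 * vals.std(ddof=1) / np.sqrt(1000)
        assert half == pytest.approx(normal_half, rel=5e-3)

    def test_fewer_than_two_values_rejected(self):
        with pytest.raises(ValueError):
            ev.aggregate_ci([1.0])


class _OracleClassifier:
    """Predicts the truth by looking labels up from image fingerprints."""

    def __init__(self, lookup):
        self.lookup = lookup
        self.classes_ = np.arange(5)

    def fit(self, X, y):
        return self

    def get_params(self):
        return {}

    def predict_proba(self, X):
        p = np.full((len(X), 5), 1e-6)
        for i, img in enumerate(X):
            p[i, self.lookup[img.tobytes()]] = 1.0
        return p / p.sum(axis=1, keepdims=True)


class _ConstantClassifier:
    def __init__(self):
        self.classes_ = np.arange(5)

    def fit(self, X, y):
        return self

    def get_params(self):
        return {}

    def predict_proba(self, X):
        p = np.zeros((len(X), 5))
        p[:, 0] = 1.0
        return p


def _toy_cv_inputs(n_per_class=6):
    rng = np.random.default_rng(0)
    images, labels = {}, {}
    classes = [f"c{k}" for k in range(5)]
    lookup = {}
    for k, cls in enumerate(classes):
        for i in range(n_per_class):
            img = rng.random((8, 8)).astype(np.float32)
            rid = f"{cls}-{i}"
            images[rid], labels[rid] = img, cls
            lookup[img.tobytes()] = k
    manifest = SimpleNamespace(rows=[SimpleNamespace(id=r, label=labels[r])
                                     for r in images])
    plan = ev.make_fold_plan(manifest, 3, seed=0)
    return images, labels, plan, classes, lookup


class TestEvaluateCv:
    def test_oracle_classifier_scores_perfectly(self):
        images, labels, plan, classes, lookup = _toy_cv_inputs()
        report = ev.evaluate_cv(images, labels, plan,
                                lambda fold: _OracleClassifier(lookup),
                                classes, augment=False)
        for cls in classes:
            agg = report.aggregated[cls]
            assert agg["accuracy"]["mean"] == pytest.approx(100.0)
            assert agg["auc"]["mean"] == pytest.approx(1.0)
            assert agg["accuracy"]["upper"] - agg["accuracy"]["lower"] == pytest.approx(0.0)
        for cm in report.confusions:
            assert np.array_equal(cm.counts, np.diag(np.diag(cm.counts)))

    def test_constant_classifier_forced_outcome(self):
        images, labels, plan, classes, _ = _toy_cv_inputs()
        report = ev.evaluate_cv(images, labels, plan,
                                lambda fold: _ConstantClassifier(),
                                classes, augment=False)
        c0 = report.aggregated[classes[0]]
        assert c0["sensitivity"]["mean"] == pytest.approx(100.0)
        assert c0["specificity"]["mean"] == pytest.approx(0.0)

    def test_report_tsv_is_deterministic(self):
        images, labels, plan, classes, lookup = _toy_cv_inputs()
        r1 = ev.evaluate_cv(images, labels, plan,
                            lambda fold: _OracleClassifier(lookup), classes,
                            augment=False)
        r2 = ev.evaluate_cv(images, labels, plan,
                            lambda fold: _OracleClassifier(lookup), classes,
                            augment=False)
        assert r1.to_tsv() == r2.to_tsv()

    def test_fold_sizes_partition_dataset(self):
        images, labels, plan, classes, _ = _toy_cv_inputs()
        assert sum(plan.fold_sizes()) == len(images)
        all_ids = [i for k in range(1, 4) for i in plan.fold_ids(k)]
        assert sorted(all_ids) == sorted(images)
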