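"""Stratified five-fold evaluation machinery.

Fold planning deals each class's shuffled images across folds as evenly as
possible, assigning remainders to the lowest-numbered folds; with the study
cohort's class totals {214, 272, 364, 224, 539} this yields validation folds
of 324, 324, 323, 323 and 319 images.

Per-class performance uses the one-vs-rest collapse of the 5x5 confusion
matrix: sensitivity TP/(TP+FN), specificity TN/(TN+FP), PPV TP/(TP+FP),
NPV TN/(TN+FN), accuracy (TP+TN)/total, all in percent, plus AUC from the
class's softmax score computed by the rank statistic (ties credited 0.5).
Ratios with a zero denominator are reported as missing (None), never as 0.

Fold-level metrics are aggregated as mean +/- t_{0.975, n-1} * s / sqrt(n)
(Student's t interval across folds; multiplier 2.776 for five folds).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats


@dataclass
class FoldPlan:
    n_folds: int
    assignment: dict[str, int]  # image id -> fold index, 1-based

    def fold_ids(self, fold: int) -> list[str]:
        return [i for i, f in self.assignment.items() if f == fold]

    def fold_sizes(self) -> list[int]:
        return [sum(1 for f in self.assignment.values() if f == k)
                for k in range(1, self.n_folds + 1)]


def make_fold_plan(manifest, n_folds: int = 5, seed: int = 0) -> FoldPlan:
    """Stratified fold assignment over a manifest (or any object with
    ``rows`` carrying ``.id`` and ``.label``).

    Within each class, ids are shuffled by ``seed`` and dealt so fold sizes
    differ by at most one, remainders going to the lowest-numbered folds.
    """
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    rows = manifest.rows
    if n_folds > len(rows):
        raise ValueError("more folds than images")
    by_class: dict[str, list[str]] = {}
    for r in rows:
        by_class.setdefault(r.label, []).append(r.id)
    rng = np.random.default_rng(seed)
    assignment: dict[str, int] = {}
    for label in sorted(by_class):
        ids = sorted(by_class[label])
        if len(ids) < n_folds:
            warnings.warn(f"class {label!r} has fewer members ({len(ids)}) than folds",
                          stacklevel=2)
        ids = [ids[i] for i in rng.permutation(len(ids))]
        base, rem = divmod(len(ids), n_folds)
        pos = 0
        for fold in range(1, n_folds + 1):
            take = base + (1 if fold <= rem else 0)
            for i in ids[pos : pos + take]:
                assignment[i] = fold
            pos += take
    return FoldPlan(n_folds, assignment)


@dataclass
class ConfusionMatrix:
    counts: np.ndarray  # K x K, rows = truth, columns = prediction

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def accuracy(self) -> float:
        return float(np.trace(self.counts)) / self.total


def confusion(truth, pred, n_classes: int) -> ConfusionMatrix:
    truth = np.asarray(truth, dtype=np.int64)
    pred = np.asarray(pred, dtype=np.int64)
    if truth.shape != pred.shape:
        raise ValueError("truth and pred must have equal length")
    if truth.size and (truth.min() < 0 or truth.max() >= n_classes
                       or pred.min() < 0 or pred.max() >= n_classes):
        raise ValueError(f"labels out of range 0..{n_classes - 1}")
    counts = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(counts, (truth, pred), 1)
    return ConfusionMatrix(counts)


def binary_metrics(cm: ConfusionMatrix, positive_class: int) -> dict[str, float | None]:
    """One-vs-rest collapse of a multiclass confusion matrix, in percent."""
    c = cm.counts
    if c.sum() == 0:
        raise ValueError("empty confusion matrix")
    tp = int(c[positive_class, positive_class])
    fn = int(c[positive_class].sum() - tp)
    fp = int(c[:, positive_class].sum() - tp)
    tn = int(c.sum() - tp - fn - fp)

    def ratio(num, den):
        return 100.0 * num / den if den > 0 else None

    return {
        "accuracy": ratio(tp + tn, tp + tn + fp + fn),
        "sensitivity": ratio(tp, tp + fn),
        "specificity": ratio(tn, tn + fp),
        "ppv": ratio(tp, tp + fp),
        "npv": ratio(tn, tn + fn),
    }


def roc_auc(scores, is_positive) -> tuple[float, list[tuple[float, float]]]:
    """AUC by the rank statistic (ties 0.5) plus the ROC point list."""
    s = np.asarray(scores, dtype=np.float64)
    pos = np.asarray(is_positive, dtype=bool)
    if s.shape != pos.shape:
        raise ValueError("scores and labels must have equal length")
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be represented to compute AUC")
    ranks = stats.rankdata(s)
    auc = (ranks[pos].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)

    order = np.argsort(-s, kind="stable")
    points = [(0.0, 0.0)]
    tp = fp = 0
    prev = None
    for i in order:
        if prev is not None and s[i] != prev:
            points.append((fp / n_neg, tp / n_pos))
        if pos[i]:
            tp += 1
        else:
            fp += 1
        prev = s[i]
    points.append((1.0, 1.0))
    return float(auc), points


def aggregate_ci(fold_values) -> dict[str, float]:
    """Mean and 95% Student's-t interval across fold-level values."""
    v = np.asarray(fold_values, dtype=np.float64)
    if v.size < 2:
        raise ValueError("need at least 2 fold values")
    n = v.size
    mean = float(v.mean())
    s = float(v.std(ddof=1))
    half = float(stats.t.ppf(0.975, n - 1)) * s / np.sqrt(n)
    return {"mean": mean, "lower": mean - half, "upper": mean + half}


# ---------------------------------------------------------------------------
# cross-validated pipeline evaluation


@dataclass
class MetricReport:
    classes: list[str]
    per_fold: list[dict]                  # fold -> class -> metric -> value
    aggregated: dict                      # class -> metric -> {mean, lower, upper}
    confusions: list[ConfusionMatrix] = field(default_factory=list)

    def to_tsv(self) -> str:
        lines = ["class\tmetric\t" + "\t".join(
            f"fold{k + 1}" for k in range(len(self.per_fold))) + "\tmean\tci_low\tci_high"]
        metrics = ["accuracy", "sensitivity", "specificity", "ppv", "npv", "auc"]
        for cls in self.classes:
            for m in metrics:
                vals = [self.per_fold[k][cls].get(m) for k in range(len(self.per_fold))]
                agg = self.aggregated.get(cls, {}).get(m)
                cells = ["NA" if v is None else f"{v:.4f}" for v in vals]
                if agg is None:
                    cells += ["NA", "NA", "NA"]
                else:
                    cells += [f"{agg['mean']:.4f}", f"{agg['lower']:.4f}", f"{agg['upper']:.4f}"]
                lines.append(f"{cls}\t{m}\t" + "\t".join(cells))
        return "\n".join(lines) + "\n"


def evaluate_cv(images: dict[str, np.ndarray], labels: dict[str, str],
                plan: FoldPlan, estimator_factory, classes: list[str],
                cae_model=None, augment: bool = True) -> MetricReport:
    """Train and validate once per fold; returns Table-1-style metrics.

    ``estimator_factory(fold)`` must return an unfitted classifier exposing
    fit / predict_proba over (n, S, S) image stacks.  When a denoiser is
    supplied every image (training and validation) is decluttered first;
    augmentation is handled by the estimator on training images only.
    """
    cls_index = {c: i for i, c in enumerate(classes)}
    ids = sorted(plan.assignment)
    per_fold, confusions = [], []
    for fold in range(1, plan.n_folds + 1):
        val_ids = [i for i in ids if plan.assignment[i] == fold]
        train_ids = [i for i in ids if plan.assignment[i] != fold]
        Xtr = np.stack([images[i] for i in train_ids])
        Xva = np.stack([images[i] for i in val_ids])
        if cae_model is not None:
            Xtr = cae_model.transform(Xtr)
            Xva = cae_model.transform(Xva)
        ytr = np.array([cls_index[labels[i]] for i in train_ids])
        yva = np.array([cls_index[labels[i]] for i in val_ids])
        est = estimator_factory(fold)
        if hasattr(est, "set_params") and "augment" in est.get_params():
            est.set_params(augment=augment)
        est.fit(Xtr, ytr)
        proba = np.atleast_2d(est.predict_proba(Xva))
        pred = np.asarray(est.classes_)[np.argmax(proba, axis=1)]
        cm = confusion(yva, pred, len(classes))
        confusions.append(cm)
        fold_metrics = {}
        for cls in classes:
            k = cls_index[cls]
            m = binary_metrics(cm, k)
            if (yva == k).any() and (yva != k).any():
                col = np.asarray(est.classes_).tolist().index(k) if k in est.classes_ else None
                if col is not None:
                    m["auc"], _ = roc_auc(proba[:, col], yva == k)
                else:
                    m["auc"] = None
            else:
                m["auc"] = None  # class missing from this fold: flagged, run continues
            fold_metrics[cls] = m
        per_fold.append(fold_metrics)

    aggregated = {}
    for cls in classes:
        aggregated[cls] = {}
        for metric in ["accuracy", "sensitivity", "specificity", "ppv", "npv", "auc"]:
            vals = [pf[cls][metric] for pf in per_fold]
            if any(v is None for v in vals):
                aggregated[cls][metric] = None
            else:
                aggregated[cls][metric] = aggregate_ci(vals)
    return MetricReport(classes, per_fold, aggregated, confusions)
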