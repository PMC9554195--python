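"""Shared fixtures.

The expensive desk-scale experiments (denoiser training on 200 pairs,
classifier training on the 160-phantom dataset) are session-scoped so the
property suites and the acceptance tests share one run each.
"""

from __future__ import annotations

import numpy as np
import pytest

from sonodeclutter import cae, classifier as clf, evaluation as ev
from sonodeclutter import phantom as ph

DESK_SIZE = 64


def make_records(master_seed: int, counts: dict[str, int], size: int = DESK_SIZE):
    params = ph.PhantomParams(image_size=size, class_counts=dict(counts),
                              master_seed=master_seed)
    return [ph.generate_record(label, i, params)
            for label in ph.CLASSES
            for i in range(params.class_counts.get(label, 0))]


class _RecordManifest:
    """Duck-typed manifest over in-memory records (no disk round trip)."""

    def __init__(self, records):
        self.rows = records  # PhantomRecord has .id and .label


@pytest.fixture(scope="session")
def desk_cae_run():
    """Desk denoiser profile: 200 training pairs, 64x64, 30 epochs, seed 0,
    plus 40 held-out pairs for transfer checks."""
    train = make_records(0, {c: 40 for c in ph.CLASSES})
    heldout = make_records(123456, {c: 8 for c in ph.CLASSES})
    model, trace = cae.train_cae(train, cae.DESK_ARCH,
                                 cae.CaeConfig(epochs=30, lr0=1e-3, seed=0))
    return {"model": model, "trace": trace, "train": train, "heldout": heldout}


@pytest.fixture(scope="session")
def desk_dataset():
    """The 160-phantom desk dataset with its stratified five-fold plan."""
    records = make_records(0, ph.DESK_CLASS_COUNTS)
    plan = ev.make_fold_plan(_RecordManifest(records), 5, seed=0)
    by_id = {r.id: r for r in records}
    cls_index = {c: k for k, c in enumerate(ph.CLASSES)}
    train_ids = sorted(i for i, f in plan.assignment.items() if f != 1)
    val_ids = sorted(i for i, f in plan.assignment.items() if f == 1)
    return {
        "records": records, "plan": plan, "by_id": by_id,
        "cls_index": cls_index, "train_ids": train_ids, "val_ids": val_ids,
    }


def _fold1_training(desk_dataset, field):
    by_id = desk_dataset["by_id"]
    cls_index = desk_dataset["cls_index"]
    X = np.stack([getattr(by_id[i], field) for i in desk_dataset["train_ids"]])
    y = np.array([cls_index[by_id[i].label] for i in desk_dataset["train_ids"]])
    return X, y


@pytest.fixture(scope="session")
def desk_clf_clean(desk_dataset):
    """Desk classifier trained on clean fold-1 training images (30 epochs,
    8x augmentation) — the decluttered arm of the ablation design."""
    X, y = _fold1_training(desk_dataset, "clean")
    return clf.DenseNetClassifier(epochs=30, seed=0, augment=True).fit(X, y)


@pytest.fixture(scope="session")
def desk_clf_marked(desk_dataset):
    """Same schedule and seed trained on the marked images (the no-CAE arm);
    identical initialization isolates the effect of the marks."""
    X, y = _fold1_training(desk_dataset, "marked")
    return clf.DenseNetClassifier(epochs=30, seed=0, augment=True).fit(X, y)


@pytest.fixture(scope="session")
def probe_records():
    """50 marked phantoms disjoint from every training set, for the
    Grad-CAM mark-reliance probe."""
    return make_records(987654, {c: 10 for c in ph.CLASSES})
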