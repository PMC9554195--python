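"""End-to-end study pipeline: simulate -> denoiser -> classifier -> report.

One master seed fans out to per-stage seeds by stable hashing, so enabling
or disabling a stage never reseeds the others.  Every run writes a
self-contained directory: the dumped configuration, trained model files,
the metric report, Grad-CAM renderings for a few validation cases, and a
manifest of SHA-256 artifact hashes that makes bit-level rerun comparison a
one-line check.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import cae as cae_mod
from . import classifier as clf_mod
from . import evaluation, gradcam
from . import phantom as ph
from .preprocess import PreprocessConfig, standardize

PROFILES = ("desk", "full")


def stage_seed(master_seed: int, stage: str) -> int:
    digest = hashlib.sha256(f"{master_seed}:{stage}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class RunConfig:
    profile: str = "desk"
    master_seed: int = 0
    out_root: str = "runs"
    image_size: int = 64
    class_counts: dict = field(default_factory=lambda: dict(ph.DESK_CLASS_COUNTS))
    n_cae_pairs: int = 200
    cae_arch: cae_mod.CaeArchitecture = field(default_factory=lambda: cae_mod.DESK_ARCH)
    cae_cfg: cae_mod.CaeConfig = field(default_factory=lambda: cae_mod.DESK_CONFIG)
    clf_cfg: clf_mod.ClfConfig = field(default_factory=lambda: clf_mod.DESK_CLF_CONFIG)
    backbone: str = "desk"
    n_folds: int = 5
    use_cae: bool = True
    n_gradcam_examples: int = 5
    strict: bool = False

    @classmethod
    def for_profile(cls, profile: str, master_seed: int = 0, **overrides) -> "RunConfig":
        if profile not in PROFILES:
            raise ValueError(f"unknown profile {profile!r}; expected one of {PROFILES}")
        if profile == "full":
            base = dict(
                profile="full", image_size=ph.FULL_CLASS_COUNTS and 360,
                class_counts=dict(ph.FULL_CLASS_COUNTS), n_cae_pairs=171,
                cae_arch=cae_mod.FULL_ARCH, cae_cfg=cae_mod.FULL_CONFIG,
                clf_cfg=clf_mod.FULL_CLF_CONFIG, backbone="d161",
            )
        else:
            base = dict(profile="desk")
        base.update(overrides)
        return cls(master_seed=master_seed, **base)

    def to_dict(self) -> dict:
        return asdict(self)


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig, run_name: str | None = None) -> Path:
    """Execute the full study flow; returns the run directory."""
    run_dir = Path(config.out_root) / (run_name or f"run-seed{config.master_seed}")
    if run_dir.exists() and config.strict and any(run_dir.iterdir()):
        raise FileExistsError(f"run directory {run_dir} already has artifacts (strict mode)")
    run_dir.mkdir(parents=True, exist_ok=True)
    (run_dir / "config.yaml").write_text(yaml.safe_dump(config.to_dict(), sort_keys=True))

    # -- simulate ----------------------------------------------------------
    params = ph.PhantomParams(image_size=config.image_size,
                              class_counts=dict(config.class_counts),
                              master_seed=stage_seed(config.master_seed, "simulate"))
    data_dir = run_dir / "data"
    manifest = ph.generate_dataset(params, data_dir)

    pre = PreprocessConfig(target_size=config.image_size)
    images, clean_images, labels, lesion_masks = {}, {}, {}, {}
    for row in manifest.rows:
        images[row.id] = standardize(
            (manifest.load_image(row.marked_path) * 255).astype(np.uint8), pre)
        clean_images[row.id] = standardize(
            (manifest.load_image(row.clean_path) * 255).astype(np.uint8), pre)
        labels[row.id] = row.label
        lesion_masks[row.id] = manifest.load_image(row.lesionmask_path) > 0.5

    # -- denoiser ----------------------------------------------------------
    cae_model = None
    if config.use_cae:
        pair_seed = stage_seed(config.master_seed, "cae-pairs")
        pair_params = ph.PhantomParams(image_size=config.image_size,
                                       class_counts=_pair_counts(config.n_cae_pairs),
                                       master_seed=pair_seed)
        pairs = [ph.generate_record(lab, i, pair_params)
                 for lab in ph.CLASSES
                 for i in range(pair_params.class_counts.get(lab, 0))]
        cae_cfg = cae_mod.CaeConfig(config.cae_cfg.epochs, config.cae_cfg.batch_size,
                                    lr0=config.cae_cfg.lr0, lr_decay=config.cae_cfg.lr_decay,
                                    seed=stage_seed(config.master_seed, "cae-train"))
        cae_model, _ = cae_mod.train_cae(pairs, config.cae_arch, cae_cfg)
        cae_mod.save_cae(cae_model, run_dir / "cae_model.npz")

    # -- cross-validated classifier + report -------------------------------
    plan = evaluation.make_fold_plan(manifest, config.n_folds,
                                     seed=stage_seed(config.master_seed, "folds"))
    clf_seed = stage_seed(config.master_seed, "clf-train")

    def factory(fold: int):
        return clf_mod.DenseNetClassifier(
            backbone=config.backbone, epochs=config.clf_cfg.epochs,
            batch_size=config.clf_cfg.batch_size, lr0=config.clf_cfg.lr0,
            lr_decay=config.clf_cfg.lr_decay, seed=(clf_seed + fold) % 2**31)

    report = evaluation.evaluate_cv(images, labels, plan, factory,
                                    classes=list(ph.CLASSES), cae_model=cae_model)
    (run_dir / "metrics.tsv").write_text(report.to_tsv())

    # -- Grad-CAM renderings on a few fold-1 validation cases --------------
    cam_dir = run_dir / "gradcam"
    cam_dir.mkdir(exist_ok=True)
    est = factory(0)
    fold1 = plan.fold_ids(1)
    train_ids = [i for i in plan.assignment if plan.assignment[i] != 1]
    cls_index = {c: k for k, c in enumerate(ph.CLASSES)}
    Xtr = np.stack([images[i] for i in train_ids])
    if cae_model is not None:
        Xtr = cae_model.transform(Xtr)
    est.set_params(augment=False)
    est.fit(Xtr, np.array([cls_index[labels[i]] for i in train_ids]))
    cam_scores = ["id\tlabel\tlesion_score\tmark_score"]
    for rid in fold1[: config.n_gradcam_examples]:
        img = images[rid]
        if cae_model is not None:
            img = cae_model.transform(img)
        hm = gradcam.compute_gradcam(est, img, cls_index[labels[rid]])
        gradcam.overlay(hm, img, path=cam_dir / f"{rid}_cam.png")
        lscore = gradcam.localization_score(hm, lesion_masks[rid])
        row = manifest.rows[[r.id for r in manifest.rows].index(rid)]
        mmask = manifest.load_image(row.markmask_path) > 0.5
        mscore = gradcam.localization_score(hm, mmask)
        cam_scores.append(f"{rid}\t{labels[rid]}\t"
                          f"{'NA' if lscore is None else f'{lscore:.4f}'}\t"
                          f"{'NA' if mscore is None else f'{mscore:.4f}'}")
    (cam_dir / "localization.tsv").write_text("\n".join(cam_scores) + "\n")

    # -- artifact hash manifest -------------------------------------------
    hashes = {str(p.relative_to(run_dir)): _sha256(p)
              for p in sorted(run_dir.rglob("*")) if p.is_file() and p.name != "hashes.json"}
    (run_dir / "hashes.json").write_text(json.dumps(hashes, indent=1, sort_keys=True))
    return run_dir


def _pair_counts(n_pairs: int) -> dict[str, int]:
    """Spread the denoiser's training pairs across the five classes."""
    base, rem = divmod(n_pairs, len(ph.CLASSES))
    return {lab: base + (1 if i < rem else 0) for i, lab in enumerate(ph.CLASSES)}
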