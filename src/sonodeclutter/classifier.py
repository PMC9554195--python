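"""Dense-block convolutional classifier with a five-class head.

The backbone follows the DenseNet pattern: a stem convolution, then repeated
[dense block -> transition] stages.  Inside a dense block every layer sees the
concatenation of the block input and all previous layer outputs and adds
``growth_rate`` new channels; transitions compress channels with a 1x1
convolution and halve the spatial size by average pooling.  A global average
pool and linear layer produce the five class scores.

Named presets: ``d121`` [6,12,24,16] g=32, ``d161`` [6,12,36,24] g=48,
``d201`` [6,12,48,32] g=32 mirror the standard layer layouts; ``desk``
[2,2] g=8 is the scaled profile that trains in minutes on one CPU.  Batch
normalization and the 1x1 bottleneck of DenseNet-BC are omitted; the channel
bookkeeping (growth-rate concatenation, compression, spatial halving) is kept
exact.

Training: cross-entropy over the five labels, Adam, per-epoch exponential
learning-rate decay; the study schedule is 50 epochs at batch size 8 with
lr 5e-5 decaying by 0.95.  Random seeded initialization is the default;
externally supplied pretrained weights can be loaded through
``DenseNetClassifier.net_.load_state_dict``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import nn
from .nn import tensor as T
from .preprocess import augment8

N_CLASSES = 5


@dataclass
class DenseBackboneConfig:
    block_layout: tuple[int, ...]
    growth_rate: int
    compression: float = 0.5
    input_channels: int = 1
    num_classes: int = N_CLASSES
    stem_channels: int = 16
    stem_stride: int = 1

    def __post_init__(self):
        if not self.block_layout:
            raise ValueError("block_layout must be nonempty")
        if self.growth_rate < 1:
            raise ValueError("growth_rate must be >= 1")
        if not (0 < self.compression <= 1):
            raise ValueError("compression must be in (0, 1]")


BACKBONES: dict[str, DenseBackboneConfig] = {
    "desk": DenseBackboneConfig((2, 2), 12, stem_channels=24, stem_stride=1),
    "d121": DenseBackboneConfig((6, 12, 24, 16), 32, stem_channels=64, stem_stride=2),
    "d161": DenseBackboneConfig((6, 12, 36, 24), 48, stem_channels=96, stem_stride=2),
    "d201": DenseBackboneConfig((6, 12, 48, 32), 32, stem_channels=64, stem_stride=2),
}


class _DenseBlock(nn.Module):
    def __init__(self, cin: int, n_layers: int, growth: int, rng):
        self.convs = [nn.Conv2d(cin + i * growth, growth, 3, rng, padding=1)
                      for i in range(n_layers)]
        self.out_channels = cin + n_layers * growth

    def forward(self, x):
        feats = x
        for conv in self.convs:
            new = conv(T.relu(feats))
            feats = T.concat([feats, new], axis=1)
        return feats


class _Transition(nn.Module):
    def __init__(self, cin: int, compression: float, rng):
        self.out_channels = max(int(cin * compression), 1)
        self.conv = nn.Conv2d(cin, self.out_channels, 1, rng)

    def forward(self, x):
        return T.avg_pool2d(self.conv(T.relu(x)), 2)


class DenseNet(nn.Module):
    """Backbone + head; records named feature taps for Grad-CAM."""

    def __init__(self, cfg: DenseBackboneConfig, rng: np.random.Generator):
        self.cfg = cfg
        self.stem = nn.Conv2d(cfg.input_channels, cfg.stem_channels, 3, rng,
                              stride=cfg.stem_stride, padding=1)
        c = cfg.stem_channels
        self.blocks = []
        self.transitions = []
        for i, n_layers in enumerate(cfg.block_layout):
            block = _DenseBlock(c, n_layers, cfg.growth_rate, rng)
            self.blocks.append(block)
            c = block.out_channels
            if i < len(cfg.block_layout) - 1:
                tr = _Transition(c, cfg.compression, rng)
                self.transitions.append(tr)
                c = tr.out_channels
        self.head = nn.Linear(c, cfg.num_classes, rng)
        self.feature_taps: dict[str, T.Tensor] = {}

    # downsampling: stem stride, stem pool, one pool per transition
    def _min_input(self) -> int:
        return self.cfg.stem_stride * 2 * 2 ** len(self.transitions)

    def forward(self, x):
        size = x.data.shape[-1]
        if size % self._min_input() or size < 4 * self._min_input():
            raise ValueError(
                f"input size {size} incompatible with the downsampling chain "
                f"(needs a multiple of {self._min_input()}, at least {4 * self._min_input()})"
            )
        taps = {}
        h = T.avg_pool2d(T.relu(self.stem(x)), 2)
        taps["stem"] = h
        for i, block in enumerate(self.blocks):
            h = block(h)
            taps[f"block{i + 1}"] = h
            if i < len(self.transitions):
                h = self.transitions[i](h)
        taps["final"] = h
        self.feature_taps = taps
        return self.head(T.global_avg_pool(h))

    def n_params(self) -> int:
        return sum(p.data.size for p in self.parameters())


def build_dense_classifier(cfg: DenseBackboneConfig | str, seed: int = 0) -> DenseNet:
    """Instantiate a seeded dense-block network from a config or preset name."""
    if isinstance(cfg, str):
        if cfg not in BACKBONES:
            raise ValueError(f"unknown backbone {cfg!r}; presets: {sorted(BACKBONES)}")
        cfg = BACKBONES[cfg]
    return DenseNet(cfg, np.random.default_rng(seed))


@dataclass
class ClfConfig:
    epochs: int = 50
    batch_size: int = 8
    loss: str = "cross_entropy"
    optimizer: str = "adam"
    lr0: float = 5e-5
    lr_decay: float = 0.95
    seed: int = 0
    use_cae: bool = True

    def __post_init__(self):
        if not (0 < self.lr_decay <= 1):
            raise ValueError("lr_decay must be in (0, 1]")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


#: Study schedule and the scaled desk schedule (lr raised for the short run).
FULL_CLF_CONFIG = ClfConfig()
DESK_CLF_CONFIG = ClfConfig(epochs=30, lr0=3e-3)


class DenseNetClassifier(ClassifierMixin, BaseEstimator):
    """Five-class image classifier with a scikit-learn surface.

    ``fit(X, y)`` takes (n, S, S) standardized images and labels; with
    ``augment=True`` the training set is expanded 8x by the dihedral orbit
    (training images only — callers never augment validation data).
    Fitted attributes: ``net_``, ``classes_``, ``loss_trace_``.
    """

    def __init__(self, backbone: str = "desk", epochs: int = 30,
                 batch_size: int = 8, lr0: float = 3e-3, lr_decay: float = 0.95,
                 seed: int = 0, augment: bool = False):
        self.backbone = backbone
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr0 = lr0
        self.lr_decay = lr_decay
        self.seed = seed
        self.augment = augment

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float32)
        y = np.asarray(y)
        if X.ndim != 3 or len(y) != X.shape[0]:
            raise ValueError("expected (n, S, S) images with n labels")
        self.classes_ = np.unique(y)
        if len(self.classes_) > N_CLASSES:
            raise ValueError(f"more than {N_CLASSES} distinct labels")
        index = {c: i for i, c in enumerate(self.classes_)}
        yi = np.array([index[v] for v in y], dtype=np.int64)
        if self.augment:
            X = np.concatenate([np.stack(augment8(img)) for img in X])
            yi = np.repeat(yi, 8)
        rng = np.random.default_rng(self.seed)
        net = build_dense_classifier(self.backbone, seed=self.seed)
        opt = nn.Adam(net.parameters(), lr=self.lr0)
        n = X.shape[0]
        trace = []
        for epoch in range(1, self.epochs + 1):
            opt.lr = nn.lr_at_epoch(self.lr0, self.lr_decay, epoch)
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, self.batch_size):
                idx = order[start : start + self.batch_size]
                logits = net(T.Tensor(X[idx][:, None]))
                loss = T.softmax_cross_entropy(logits, yi[idx])
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            trace.append(float(np.mean(losses)))
        self.net_ = net
        self.loss_trace_ = trace
        self.input_size_ = int(X.shape[1])
        return self

    def decision_function(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        single = X.ndim == 2
        if single:
            X = X[None]
        if X.shape[1] != self.input_size_:
            raise ValueError(
                f"expected {self.input_size_}x{self.input_size_} images, got {X.shape[1:]}"
            )
        outs = []
        with T.no_grad():
            for start in range(0, X.shape[0], 32):
                outs.append(self.net_(T.Tensor(X[start : start + 32][:, None])).data)
        logits = np.concatenate(outs)
        return logits[0] if single else logits

    def predict_proba(self, X) -> np.ndarray:
        return nn.softmax(self.decision_function(X))

    def predict(self, X):
        p = np.atleast_2d(self.predict_proba(X))
        return self.classes_[np.argmax(p, axis=1)]


def predict_proba(model: DenseNetClassifier, image: np.ndarray) -> np.ndarray:
    """Softmax class scores for one standardized image."""
    return model.predict_proba(np.asarray(image, dtype=np.float32))


def train_classifier(images: np.ndarray, labels, cfg: ClfConfig,
                     backbone: str = "desk", cae_model=None) -> DenseNetClassifier:
    """Train on standardized images; with ``cfg.use_cae`` each image is first
    decluttered by the supplied denoiser (the no-CAE path is the ablation arm).
    """
    X = np.asarray(images, dtype=np.float32)
    if cfg.use_cae:
        if cae_model is None:
            raise ValueError("use_cae is set but no trained denoiser was supplied")
        X = cae_model.transform(X)
    est = DenseNetClassifier(backbone=backbone, epochs=cfg.epochs,
                             batch_size=cfg.batch_size, lr0=cfg.lr0,
                             lr_decay=cfg.lr_decay, seed=cfg.seed, augment=True)
    return est.fit(X, labels)
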