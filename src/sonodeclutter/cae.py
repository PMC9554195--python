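"""Mark-removal convolutional autoencoder.

An encoder–decoder network in the U-net family, specialized with two blocks:
squeeze-and-excitation channel gating after each encoder level, and a
multi-dilation bottleneck that aggregates context at several receptive-field
sizes before decoding.  Downsampling uses average pooling; upsampling uses
learnable transposed convolutions; encoder features are concatenated into the
decoder at matching resolutions; a sigmoid head keeps outputs in (0, 1).

Training minimizes the mean squared error between the network's output on a
marked image and its paired clean image (Adam, per-epoch exponential
learning-rate decay).  The full profile uses the study settings — 200 epochs,
batch size 2, lr 5e-5 decaying by 0.95 per epoch, 171 training pairs; the
desk profile scales this to a single-CPU run.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from . import nn
from .nn import tensor as T
from .phantom import PhantomRecord


@dataclass
class CaeArchitecture:
    levels: int = 2
    base_channels: int = 8
    se_reduction: int = 16
    dilations: tuple[int, ...] = (1, 2, 4, 8)
    skip_merge: str = "concat"
    output_activation: str = "sigmoid"

    def __post_init__(self):
        if self.levels < 2:
            raise ValueError("levels must be >= 2")
        if self.base_channels < 4:
            raise ValueError("base_channels must be >= 4")
        if not self.dilations or any(d < 1 for d in self.dilations):
            raise ValueError("dilations must be nonempty, all >= 1")


@dataclass
class CaeConfig:
    epochs: int = 200
    batch_size: int = 2
    loss: str = "mse"
    optimizer: str = "adam"
    lr0: float = 5e-5
    lr_decay: float = 0.95
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.lr_decay <= 1):
            raise ValueError("lr_decay must be in (0, 1]")
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")


#: Full-scale architecture (4 levels, 32 base channels) and study schedule.
FULL_ARCH = CaeArchitecture(levels=4, base_channels=32)
FULL_CONFIG = CaeConfig()
#: Desk-scale: shallower net, fewer epochs, lr raised to compensate.
DESK_ARCH = CaeArchitecture(levels=2, base_channels=8)
DESK_CONFIG = CaeConfig(epochs=30, lr0=1e-3)


class DilatedBottleneck(nn.Module):
    """Parallel same-padded 3x3 convolutions at several dilation rates,
    concatenated and fused by a 1x1 convolution (output = 2x input channels)."""

    def __init__(self, channels: int, dilations: tuple[int, ...], rng: np.random.Generator):
        if not dilations:
            raise ValueError("dilation list must be nonempty")
        self.dilations = tuple(dilations)
        self.branches = [
            nn.Conv2d(channels, channels, 3, rng, padding=d, dilation=d)
            for d in self.dilations
        ]
        self.fuse = nn.Conv2d(channels * len(self.dilations), 2 * channels, 1, rng)

    def forward(self, x):
        outs = [T.relu(b(x)) for b in self.branches]
        return T.relu(self.fuse(T.concat(outs, axis=1)))


class _EncoderLevel(nn.Module):
    def __init__(self, cin: int, cout: int, se_reduction: int, rng):
        self.conv1 = nn.Conv2d(cin, cout, 3, rng, padding=1)
        self.conv2 = nn.Conv2d(cout, cout, 3, rng, padding=1)
        self.se = nn.SEBlock(cout, se_reduction, rng)

    def forward(self, x):
        h = T.relu(self.conv2(T.relu(self.conv1(x))))
        return self.se(h)


class _DecoderLevel(nn.Module):
    def __init__(self, cin: int, skip: int, cout: int, rng):
        self.up = nn.ConvTranspose2d(cin, cout, rng, stride=2)
        self.conv1 = nn.Conv2d(cout + skip, cout, 3, rng, padding=1)
        self.conv2 = nn.Conv2d(cout, cout, 3, rng, padding=1)

    def forward(self, x, skip):
        h = T.concat([self.up(x), skip], axis=1)
        return T.relu(self.conv2(T.relu(self.conv1(h))))


class CaeNet(nn.Module):
    """The assembled encoder / dilated bottleneck / decoder network."""

    def __init__(self, arch: CaeArchitecture, rng: np.random.Generator):
        self.arch = arch
        chans = [arch.base_channels * 2**i for i in range(arch.levels)]
        self.encoders = []
        cin = 1
        for c in chans:
            self.encoders.append(_EncoderLevel(cin, c, arch.se_reduction, rng))
            cin = c
        self.bottleneck = DilatedBottleneck(chans[-1], arch.dilations, rng)
        self.decoders = []
        cin = 2 * chans[-1]
        for c in reversed(chans):
            self.decoders.append(_DecoderLevel(cin, c, c, rng))
            cin = c
        self.head = nn.Conv2d(chans[0], 1, 1, rng)

    def forward(self, x):
        size = x.data.shape[-1]
        div = 2**self.arch.levels
        if size % div:
            raise ValueError(
                f"input size {size} not divisible by 2**levels = {div}; "
                f"resize the input or reduce the encoder depth"
            )
        skips = []
        h = x
        for enc in self.encoders:
            h = enc(h)
            skips.append(h)
            h = T.avg_pool2d(h, 2)
        h = self.bottleneck(h)
        for dec, skip in zip(self.decoders, reversed(skips)):
            h = dec(h, skip)
        return T.sigmoid(self.head(h))

    def n_params(self) -> int:
        return sum(p.data.size for p in self.parameters())


def build_cae(arch: CaeArchitecture, seed: int = 0) -> CaeNet:
    """Instantiate a seeded, randomly initialized network for the given plan."""
    return CaeNet(arch, np.random.default_rng(seed))


# -- functional surfaces for the two specialized blocks ---------------------

def se_gate(features: np.ndarray, reduction: int = 16,
            block: nn.SEBlock | None = None, seed: int = 0) -> np.ndarray:
    """Apply squeeze-and-excitation gating to (C, H, W) or (N, C, H, W)."""
    arr = np.asarray(features, dtype=np.float32)
    squeeze = arr.ndim == 3
    if squeeze:
        arr = arr[None]
    if block is None:
        block = nn.SEBlock(arr.shape[1], reduction, np.random.default_rng(seed))
    with T.no_grad():
        out = block(T.Tensor(arr)).data
    return out[0] if squeeze else out


def dilated_bottleneck(features: np.ndarray, dilations: tuple[int, ...],
                       module: DilatedBottleneck | None = None, seed: int = 0) -> np.ndarray:
    """Apply the multi-dilation context block to (C, H, W) or (N, C, H, W)."""
    arr = np.asarray(features, dtype=np.float32)
    squeeze = arr.ndim == 3
    if squeeze:
        arr = arr[None]
    if module is None:
        module = DilatedBottleneck(arr.shape[1], tuple(dilations), np.random.default_rng(seed))
    with T.no_grad():
        out = module(T.Tensor(arr)).data
    return out[0] if squeeze else out


# -- estimator ---------------------------------------------------------------

class CaeDenoiser(TransformerMixin, BaseEstimator):
    """Paired image-to-image denoiser with a scikit-learn surface.

    ``fit(X, y)`` takes marked images ``X`` and their clean counterparts
    ``y`` as (n, S, S) arrays in [0, 1]; ``transform(X)`` returns decluttered
    images.  Fitted attributes: ``net_``, ``loss_trace_`` (one mean-MSE entry
    per epoch), ``input_size_``.
    """

    def __init__(self, levels: int = 2, base_channels: int = 8,
                 se_reduction: int = 16, dilations: tuple[int, ...] = (1, 2, 4, 8),
                 epochs: int = 30, batch_size: int = 2,
                 lr0: float = 1e-3, lr_decay: float = 0.95, seed: int = 0):
        self.levels = levels
        self.base_channels = base_channels
        self.se_reduction = se_reduction
        self.dilations = dilations
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr0 = lr0
        self.lr_decay = lr_decay
        self.seed = seed

    def _arch(self) -> CaeArchitecture:
        return CaeArchitecture(self.levels, self.base_channels,
                               self.se_reduction, tuple(self.dilations))

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float32)
        Y = np.asarray(y, dtype=np.float32)
        if X.ndim != 3 or X.shape != Y.shape:
            raise ValueError("expected matching (n, S, S) marked and clean stacks")
        if X.shape[0] < 2:
            raise ValueError("need at least 2 training pairs")
        cfg = CaeConfig(self.epochs, self.batch_size, lr0=self.lr0,
                        lr_decay=self.lr_decay, seed=self.seed)
        rng = np.random.default_rng(self.seed)
        net = CaeNet(self._arch(), rng)
        opt = nn.Adam(net.parameters(), lr=cfg.lr0)
        n = X.shape[0]
        trace = []
        for epoch in range(1, cfg.epochs + 1):
            opt.lr = nn.lr_at_epoch(cfg.lr0, cfg.lr_decay, epoch)
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, cfg.batch_size):
                idx = order[start : start + cfg.batch_size]
                out = net(T.Tensor(X[idx][:, None]))
                loss = T.mse_loss(out, Y[idx][:, None])
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            trace.append(float(np.mean(losses)))
        self.net_ = net
        self.loss_trace_ = trace
        self.input_size_ = int(X.shape[1])
        return self

    def transform(self, X) -> np.ndarray:
        X = np.asarray(X, dtype=np.float32)
        single = X.ndim == 2
        if single:
            X = X[None]
        if X.shape[1] != self.input_size_ or X.shape[2] != self.input_size_:
            raise ValueError(
                f"expected {self.input_size_}x{self.input_size_} images, got {X.shape[1:]}"
            )
        with T.no_grad():
            out = self.net_(T.Tensor(X[:, None])).data[:, 0]
        return out[0] if single else out


# -- procedural wrappers -----------------------------------------------------

def train_cae(pairs: list[PhantomRecord], arch: CaeArchitecture,
              cfg: CaeConfig) -> tuple[CaeDenoiser, list[float]]:
    """Train the denoiser on (marked, clean) pairs from phantom records."""
    if not pairs:
        raise ValueError("empty pair list")
    X = np.stack([p.marked for p in pairs])
    Y = np.stack([p.clean for p in pairs])
    est = CaeDenoiser(arch.levels, arch.base_channels, arch.se_reduction,
                      arch.dilations, cfg.epochs, cfg.batch_size,
                      cfg.lr0, cfg.lr_decay, cfg.seed)
    est.fit(X, Y)
    return est, est.loss_trace_


def declutter(model: CaeDenoiser, image: np.ndarray) -> np.ndarray:
    """Single forward pass removing marks from one standardized image."""
    return model.transform(np.asarray(image, dtype=np.float32))


def psnr(a: np.ndarray, b: np.ndarray, peak: float = 1.0) -> float:
    """Peak signal-to-noise ratio in dB; +inf when the images are identical."""
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"shape mismatch: {a.shape} vs {b.shape}")
    if peak <= 0:
        raise ValueError("peak must be > 0")
    mse = float(np.mean((a - b) ** 2))
    if mse == 0.0:
        return math.inf
    return 10.0 * math.log10(peak**2 / mse)


# -- serialization -----------------------------------------------------------

_FORMAT_VERSION = 1


def save_cae(model: CaeDenoiser, path: str | Path) -> None:
    """Self-describing single-file checkpoint (hyperparameters + weights)."""
    meta = {
        "format_version": _FORMAT_VERSION,
        "kind": "cae",
        "params": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in model.get_params().items()},
        "input_size": model.input_size_,
        "loss_trace": model.loss_trace_,
    }
    arrays = {f"w/{k}": v for k, v in model.net_.state_dict().items()}
    np.savez(path, meta=json.dumps(meta), **arrays)


def load_cae(path: str | Path) -> CaeDenoiser:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        if meta.get("kind") != "cae" or meta.get("format_version") != _FORMAT_VERSION:
            raise ValueError("not a recognized denoiser checkpoint")
        params = meta["params"]
        params["dilations"] = tuple(params["dilations"])
        est = CaeDenoiser(**params)
        est.net_ = build_cae(est._arch(), seed=params.get("seed", 0))
        est.net_.load_state_dict({k[2:]: z[k] for k in z.files if k.startswith("w/")})
        est.input_size_ = int(meta["input_size"])
        est.loss_trace_ = list(meta["loss_trace"])
    return est
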