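"""Gradient-weighted class activation mapping (Grad-CAM).

For a chosen convolutional feature layer, each channel is weighted by the
spatial mean of the gradient of the target class logit with respect to that
channel's feature map; the rectified weighted sum, upsampled to the input
size and normalized by its maximum, localizes the evidence the classifier
used.  A mask-based localization score quantifies how much heatmap mass
falls inside a ground-truth region (lesion or burned-in marks), turning the
qualitative "does the model look at the lesion, not the calipers?" check
into a number.
"""

from __future__ import annotations

from dataclasses import dataclass

import matplotlib
import numpy as np
from PIL import Image
from skimage.transform import resize

from .nn import tensor as T


@dataclass
class Heatmap:
    map: np.ndarray          # S x S in [0, 1]
    target_class: int
    source_layer: str


def available_layers(net) -> list[str]:
    """Names of the feature taps a classifier network exposes."""
    if not getattr(net, "feature_taps", None):
        # populate by a probe forward if the net has never run
        raise ValueError("network has no recorded feature taps; run a forward pass first")
    return list(net.feature_taps)


def compute_gradcam(model, image: np.ndarray, target_class: int,
                    layer: str = "auto") -> Heatmap:
    """Grad-CAM heatmap for one standardized image.

    ``model`` is a fitted classifier estimator (or a bare network exposing
    ``feature_taps``); ``layer`` names a feature tap, with ``"auto"``
    selecting the last convolutional features before global pooling.
    """
    net = getattr(model, "net_", model)
    image = np.asarray(image, dtype=np.float32)
    size = image.shape[-1]
    x = T.Tensor(image[None, None])
    logits = net(x)
    taps = net.feature_taps
    name = "final" if layer == "auto" else layer
    if name not in taps:
        raise ValueError(f"unknown layer {name!r}; available: {sorted(taps)}")
    feat = taps[name]
    logits.pick(0, target_class).backward()
    if feat.grad is None:
        weights = np.zeros(feat.data.shape[1], dtype=np.float32)
    else:
        weights = feat.grad[0].mean(axis=(1, 2))
    raw = np.maximum((weights[:, None, None] * feat.data[0]).sum(axis=0), 0.0)
    up = resize(raw.astype(np.float64), (size, size), order=1,
                anti_aliasing=False, preserve_range=True)
    up = np.maximum(up, 0.0)
    peak = up.max()
    if peak > 0:
        up = up / peak
    return Heatmap(up.astype(np.float32), target_class, name)


def localization_score(heatmap: Heatmap | np.ndarray, region: np.ndarray) -> float | None:
    """Fraction of total heatmap mass inside a binary region; None when the
    heatmap is identically zero (flagged, not zero-filled)."""
    hm = heatmap.map if isinstance(heatmap, Heatmap) else np.asarray(heatmap)
    region = np.asarray(region).astype(bool)
    if hm.shape != region.shape:
        raise ValueError(f"shape mismatch: {hm.shape} vs {region.shape}")
    total = float(hm.sum())
    if total == 0.0:
        return None
    return float(hm[region].sum()) / total


def overlay(heatmap: Heatmap | np.ndarray, image: np.ndarray,
            alpha: float = 0.45, path=None) -> np.ndarray:
    """Blend a blue-to-red rendering of the heatmap over the grayscale image.

    Returns an (S, S, 3) uint8 RGB array; writes a PNG when ``path`` is given.
    """
    hm = heatmap.map if isinstance(heatmap, Heatmap) else np.asarray(heatmap)
    image = np.asarray(image, dtype=np.float64)
    if hm.shape != image.shape:
        raise ValueError(f"shape mismatch: {hm.shape} vs {image.shape}")
    cmap = matplotlib.colormaps["jet"]
    colored = cmap(np.clip(hm, 0.0, 1.0))[..., :3]
    gray = np.repeat(np.clip(image, 0.0, 1.0)[..., None], 3, axis=2)
    blended = (1.0 - alpha) * gray + alpha * colored
    out = np.clip(np.round(blended * 255.0), 0, 255).astype(np.uint8)
    if path is not None:
        Image.fromarray(out, mode="RGB").save(path)
    return out


def occlusion_drop(model, image: np.ndarray, heatmap: Heatmap,
                   target_class: int, quantile: float = 0.9) -> float:
    """Softmax-score drop for the target class after blanking the top-decile
    heatmap region (positive = the highlighted region mattered)."""
    p0 = model.predict_proba(image)
    hm = heatmap.map
    thresh = np.quantile(hm, quantile)
    occluded = np.array(image, dtype=np.float32)
    occluded[hm >= thresh] = 0.0
    p1 = model.predict_proba(occluded)
    return float(p0[target_class] - p1[target_class])
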