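"""Image standardization and 8-fold dihedral augmentation.

The standardization chain matches the study protocol: center-crop to a 1:1
aspect ratio (so nothing is anisotropically rescaled), map 8-bit pixel values
to [0, 1] by dividing by a fixed maximum, and resize to a square working
resolution (360 px for the full profile, 96 px for the desk profile).

Offline augmentation multiplies each training image by 8: rotations by 0°,
90°, 180°, 270°, plus a horizontal flip of each — the full dihedral group D4.
Augmentation is applied to training folds only, never to validation images.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.transform import resize

FULL_TARGET_SIZE = 360
DESK_TARGET_SIZE = 96


@dataclass
class PreprocessConfig:
    target_size: int = DESK_TARGET_SIZE
    crop_anchor: str = "center"
    normalize_max: float = 255.0

    def __post_init__(self):
        if self.target_size < 32:
            raise ValueError("target_size must be >= 32")
        if self.crop_anchor != "center":
            raise ValueError("only center crop is supported")


def center_crop_square(image: np.ndarray) -> np.ndarray:
    """Crop to min(H, W) x min(H, W) about the image center."""
    h, w = image.shape
    m = min(h, w)
    y0 = (h - m) // 2
    x0 = (w - m) // 2
    return image[y0 : y0 + m, x0 : x0 + m]


def standardize(image: np.ndarray, cfg: PreprocessConfig | None = None) -> np.ndarray:
    """Crop square -> scale to [0, 1] -> bilinear resize to target_size.

    When the cropped image is already at the target size the resize is
    skipped, so the output equals ``image / normalize_max`` exactly.
    """
    cfg = cfg or PreprocessConfig()
    image = np.asarray(image)
    if image.size == 0:
        raise ValueError("empty image")
    if image.ndim != 2:
        raise ValueError("expected a single-channel 2-D image")
    sq = center_crop_square(image).astype(np.float64) / cfg.normalize_max
    if sq.shape[0] != cfg.target_size:
        sq = resize(sq, (cfg.target_size, cfg.target_size), order=1,
                    anti_aliasing=False, preserve_range=True)
    return np.clip(sq, 0.0, 1.0).astype(np.float32)


#: Fixed output order of :func:`augment8`.
AUGMENT_ORDER = (
    "rot0", "rot90", "rot180", "rot270",
    "rot0_hflip", "rot90_hflip", "rot180_hflip", "rot270_hflip",
)


def augment8(image: np.ndarray) -> list[np.ndarray]:
    """The dihedral-group (D4) orbit of a square image.

    Order: rotations by 0°, 90°, 180°, 270°, then the horizontal flip of
    each rotation; element 0 is the untouched input.
    """
    image = np.asarray(image)
    if image.ndim != 2 or image.shape[0] != image.shape[1]:
        raise ValueError("augment8 requires a square single-channel image")
    rots = [np.rot90(image, k) for k in range(4)]
    return [r.copy() for r in rots] + [np.fliplr(r).copy() for r in rots]
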