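"""Synthetic ovarian-ultrasound phantoms with ground-truth masks.

Real transvaginal ultrasound of the ovary is private clinical data, so this
module generates seeded stand-ins that reproduce the image statistics the
downstream models depend on: a fan-shaped field of view, multiplicative
Rayleigh speckle over a smooth tissue template, one of five sonographic
lesion appearances, and procedurally burned-in sonographer marks (caliper
glyphs, dashed measurement lines, annotation text) with exact pixel masks.

Class taxonomy (sonographic rendering):

- ``normal``        no dominant lesion; a few small dark follicles
- ``cystadenoma``   large smooth-walled anechoic (dark) cyst, optional thin septum
- ``teratoma``      heterogeneous hyperechoic (bright) mass with distal shadowing
- ``endometrioma``  cyst with homogeneous low-level mid-gray interior echoes
- ``malignant``     irregular-margin mixed solid/cystic mass with papillary nodules
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage

CLASSES = ("normal", "cystadenoma", "teratoma", "endometrioma", "malignant")

#: Study-cohort image counts per class (full scale).
FULL_CLASS_COUNTS = {
    "normal": 214,
    "cystadenoma": 272,
    "teratoma": 364,
    "endometrioma": 224,
    "malignant": 539,
}

#: Desk-scale counts: full counts / 10, rounded to nearest (total 160).
DESK_CLASS_COUNTS = {
    "normal": 21,
    "cystadenoma": 27,
    "teratoma": 36,
    "endometrioma": 22,
    "malignant": 54,
}


@dataclass
class PhantomRecord:
    """One synthetic case; images are float arrays in [0, 1], masks binary."""

    id: str
    clean: np.ndarray
    label: str
    seed: int
    lesion_mask: np.ndarray
    marked: np.ndarray | None = None
    mark_mask: np.ndarray | None = None


@dataclass
class PhantomParams:
    """Generator settings for a whole dataset."""

    image_size: int = 64
    class_counts: dict = field(default_factory=lambda: dict(DESK_CLASS_COUNTS))
    mark_density: float = 1.0
    speckle_scale: float = 0.35
    lesion_size_range: tuple[float, float] = (0.22, 0.40)
    master_seed: int = 0

    def __post_init__(self):
        if self.image_size < 32:
            raise ValueError("image_size must be >= 32")
        if any(v < 0 for v in self.class_counts.values()):
            raise ValueError("class_counts must be nonnegative")


def record_seed(master_seed: int, label: str, index: int) -> int:
    """Stable per-record seed: adding a class never reshuffles the others."""
    digest = hashlib.sha256(f"{label}:{index}".encode()).digest()
    return (master_seed + int.from_bytes(digest[:4], "big")) % (2**31)


# ---------------------------------------------------------------------------
# clean-image synthesis


def _fan_mask(size: int, half_angle_deg: float = 35.0) -> np.ndarray:
    """Circular sector (apex at top-center) mimicking a convex-probe field."""
    yy, xx = np.mgrid[0:size, 0:size]
    cy, cx = -0.08 * size, size / 2.0
    dy, dx = yy - cy, xx - cx
    r = np.hypot(dy, dx)
    ang = np.degrees(np.arctan2(dx, dy))  # 0 = straight down
    return (np.abs(ang) <= half_angle_deg) & (r <= 1.02 * size) & (r >= 0.06 * size)


def _speckle(rng: np.random.Generator, size: int, scale: float) -> np.ndarray:
    """First-order ultrasound speckle: smoothed Rayleigh multiplicative field
    with unit mean (``scale`` sets the texture contrast)."""
    ray = rng.rayleigh(scale=1.0, size=(size, size))
    ray = ndimage.gaussian_filter(ray, sigma=0.7)
    ray /= ray.mean()
    return 1.0 + scale * (ray - 1.0)


def _ellipse_mask(size: int, cy: float, cx: float, ry: float, rx: float,
                  theta: float = 0.0, wobble: np.ndarray | None = None) -> np.ndarray:
    yy, xx = np.mgrid[0:size, 0:size]
    dy, dx = yy - cy, xx - cx
    ct, st = np.cos(theta), np.sin(theta)
    u = (ct * dx + st * dy) / rx
    v = (-st * dx + ct * dy) / ry
    rad = np.hypot(u, v)
    if wobble is not None:
        ang = np.arctan2(v, u)
        k = np.arange(2, 2 + len(wobble))
        mod = 1.0 + sum(a * np.cos(kk * ang + p) for (a, p), kk in zip(wobble, k))
        return rad <= mod
    return rad <= 1.0


def _lesion_geometry(rng: np.random.Generator, size: int,
                     size_range: tuple[float, float]) -> tuple:
    frac = rng.uniform(*size_range)
    ry = 0.5 * frac * size * rng.uniform(0.75, 1.0)
    rx = 0.5 * frac * size * rng.uniform(0.9, 1.25)
    cy = rng.uniform(0.42, 0.62) * size
    cx = size / 2.0 + rng.uniform(-0.08, 0.08) * size
    theta = rng.uniform(-0.5, 0.5)
    return cy, cx, ry, rx, theta


def generate_phantom(label: str, size: int, seed: int,
                     speckle_scale: float = 0.35,
                     lesion_size_range: tuple[float, float] = (0.22, 0.40)) -> PhantomRecord:
    """Render the clean image and lesion mask for one case.

    Deterministic in (label, size, seed): the same arguments reproduce the
    record bit-identically.
    """
    if label not in CLASSES:
        raise ValueError(f"unknown class {label!r}; expected one of {CLASSES}")
    if size < 32:
        raise ValueError("size must be >= 32")
    rng = np.random.default_rng(seed)

    fan = _fan_mask(size)
    # smooth tissue template around mid-gray
    template = 0.45 + 0.12 * ndimage.gaussian_filter(
        rng.standard_normal((size, size)), sigma=size / 8.0) * 8.0
    template = np.clip(template, 0.25, 0.7)
    lesion_mask = np.zeros((size, size), dtype=np.uint8)
    speckle_damp = np.ones((size, size))

    if label == "normal":
        # a few small anechoic follicles, deliberately not recorded as lesions
        for _ in range(rng.integers(2, 5)):
            fy = rng.uniform(0.35, 0.75) * size
            fx = rng.uniform(0.3, 0.7) * size
            fr = rng.uniform(0.02, 0.045) * size
            m = _ellipse_mask(size, fy, fx, fr, fr)
            template[m] = 0.12
    else:
        cy, cx, ry, rx, theta = _lesion_geometry(rng, size, lesion_size_range)
        if label == "malignant":
            wobble = [(rng.uniform(0.08, 0.18), rng.uniform(0, 2 * np.pi))
                      for _ in range(3)]
            core = _ellipse_mask(size, cy, cx, ry, rx, theta, wobble=wobble)
        else:
            core = _ellipse_mask(size, cy, cx, ry, rx, theta)
        core &= fan
        lesion_mask[core] = 1

        if label == "cystadenoma":
            template[core] = 0.05
            speckle_damp[core] = 0.25
            if rng.random() < 0.6:  # thin septum across the cyst
                t = np.linspace(-1.2, 1.2, 4 * size)
                sy = (cy + t * ry * np.cos(theta + rng.uniform(-0.4, 0.4))).astype(int)
                sx = (cx + t * rx * np.sin(theta + rng.uniform(0.8, 2.2))).astype(int)
                ok = (sy >= 0) & (sy < size) & (sx >= 0) & (sx < size)
                sept = np.zeros_like(core)
                sept[sy[ok], sx[ok]] = True
                sept = ndimage.binary_dilation(sept) & core
                template[sept] = 0.55
        elif label == "teratoma":
            blobs = ndimage.gaussian_filter(rng.standard_normal((size, size)),
                                            sigma=size / 24.0)
            interior = 0.72 + 0.35 * blobs
            template[core] = np.clip(interior[core], 0.45, 1.0)
            # distal acoustic shadow below the mass (not part of the lesion)
            cols = np.where(core.any(axis=0))[0]
            for x in cols:
                ys = np.where(core[:, x])[0]
                template[ys.max() + 1 :, x] *= 0.35
        elif label == "endometrioma":
            template[core] = 0.34
            speckle_damp[core] = 0.35  # homogeneous low-level echoes
        elif label == "malignant":
            template[core] = 0.10
            speckle_damp[core] = 0.4
            # bright papillary solid nodules protruding into the cystic part
            for _ in range(rng.integers(2, 5)):
                ang = rng.uniform(0, 2 * np.pi)
                rad = rng.uniform(0.3, 0.85)
                py = cy + rad * ry * np.sin(ang)
                px = cx + rad * rx * np.cos(ang)
                pr = rng.uniform(0.12, 0.3) * min(ry, rx)
                nod = _ellipse_mask(size, py, px, pr, pr) & core
                template[nod] = rng.uniform(0.65, 0.85)
                speckle_damp[nod] = 1.0

    spk = _speckle(rng, size, speckle_scale)
    img = template * (1.0 + (spk - 1.0) * speckle_damp)
    img = np.clip(img, 0.0, 1.0)
    img[~fan] = 0.0
    lesion_mask[~fan] = 0

    return PhantomRecord(
        id=f"{label}-{seed}",
        clean=img.astype(np.float32),
        label=label,
        seed=seed,
        lesion_mask=lesion_mask,
    )


# ---------------------------------------------------------------------------
# sonographer marks


def _draw_cross(canvas: np.ndarray, y: int, x: int, arm: int, diag: bool) -> None:
    size = canvas.shape[0]
    for d in range(-arm, arm + 1):
        if diag:
            pts = [(y + d, x + d), (y + d, x - d)]
        else:
            pts = [(y + d, x), (y, x + d)]
        for py, px in pts:
            if 0 <= py < size and 0 <= px < size:
                canvas[py, px] = True


def _dashed_line(canvas: np.ndarray, p0: tuple, p1: tuple) -> None:
    size = canvas.shape[0]
    n = int(max(abs(p1[0] - p0[0]), abs(p1[1] - p0[1]))) + 1
    ys = np.linspace(p0[0], p1[0], n).round().astype(int)
    xs = np.linspace(p0[1], p1[1], n).round().astype(int)
    for k, (py, px) in enumerate(zip(ys, xs)):
        if (k // 3) % 2 == 0 and 0 <= py < size and 0 <= px < size:
            canvas[py, px] = True


def _annotation_glyphs(canvas: np.ndarray, rng: np.random.Generator) -> None:
    """Clusters of 3x5 pseudo-characters near the image border."""
    size = canvas.shape[0]
    for _ in range(rng.integers(1, 4)):
        n_chars = rng.integers(2, 6)
        if rng.random() < 0.5:
            y0 = int(rng.uniform(0.02, 0.10) * size)
        else:
            y0 = int(rng.uniform(0.85, 0.93) * size)
        x0 = int(rng.uniform(0.05, max(0.05, 0.9 - 0.06 * n_chars)) * size)
        for ci in range(n_chars):
            gx = x0 + ci * 4
            glyph = rng.random((5, 3)) < 0.55
            glyph[0, :] = True  # every pseudo-char has a solid top bar
            ys = slice(y0, min(y0 + 5, size))
            xs = slice(gx, min(gx + 3, size))
            canvas[ys, xs] |= glyph[: ys.stop - ys.start, : xs.stop - xs.start]


def _boundary_points(mask: np.ndarray) -> np.ndarray:
    """(y, x) pixels on the outer boundary of a binary mask."""
    if not mask.any():
        return np.empty((0, 2), dtype=int)
    er = ndimage.binary_erosion(mask.astype(bool))
    edge = mask.astype(bool) & ~er
    return np.argwhere(edge)


def overlay_marks(record: PhantomRecord, density: float, seed: int,
                  force_min_marks: bool = True) -> PhantomRecord:
    """Burn caliper pairs, dashed measurement lines and annotation text onto
    a copy of the clean image; fills ``marked`` and ``mark_mask``.

    ``density`` is the expected number of caliper pairs.  Marks are drawn at
    near-saturated gray (>= 0.9); the mask records exactly the overwritten
    pixels, so ``marked == clean`` everywhere outside the mask.
    """
    if density < 0:
        raise ValueError("mark density must be >= 0")
    rng = np.random.default_rng(seed)
    size = record.clean.shape[0]
    canvas = np.zeros((size, size), dtype=bool)

    n_pairs = int(rng.poisson(density))
    if force_min_marks:
        n_pairs = max(n_pairs, 1)

    if n_pairs > 0:
        boundary = _boundary_points(record.lesion_mask)
        for _ in range(n_pairs):
            if len(boundary) >= 2:
                # opposite-ish points on the lesion boundary
                i = rng.integers(len(boundary))
                p0 = boundary[i]
                d = np.hypot(*(boundary - p0).T)
                far = np.argwhere(d >= 0.7 * d.max()).ravel()
                p1 = boundary[rng.choice(far)]
            else:
                cy = rng.uniform(0.35, 0.7, 2) * size
                cx = rng.uniform(0.3, 0.7, 2) * size
                p0 = np.array([cy[0], cx[0]], dtype=int)
                p1 = np.array([cy[1], cx[1]], dtype=int)
            arm = int(rng.integers(2, 5))  # stroke length 5..9 px
            diag = bool(rng.random() < 0.5)
            _draw_cross(canvas, int(p0[0]), int(p0[1]), arm, diag)
            _draw_cross(canvas, int(p1[0]), int(p1[1]), arm, diag)
            _dashed_line(canvas, tuple(p0), tuple(p1))
        _annotation_glyphs(canvas, rng)

    marked = record.clean.copy()
    level = np.float32(rng.uniform(0.9, 0.99))
    marked[canvas] = level
    # mask means "differs from clean": nudge any accidental coincidences
    coincide = canvas & (marked == record.clean)
    marked[coincide] = np.float32(min(1.0, level + 0.01))
    record.marked = marked
    record.mark_mask = canvas.astype(np.uint8)
    return record


# ---------------------------------------------------------------------------
# dataset export / manifest


@dataclass
class ManifestRow:
    id: str
    label: str
    clean_path: str
    marked_path: str
    markmask_path: str
    lesionmask_path: str
    seed: int


class DatasetManifest:
    """Ordered (id, paths, label) table; the unit fold planning partitions."""

    def __init__(self, rows: list[ManifestRow], root: Path | None = None):
        self.rows = list(rows)
        self.root = Path(root) if root is not None else None
        ids = [r.id for r in self.rows]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate ids in manifest")

    def __len__(self):
        return len(self.rows)

    def labels(self) -> list[str]:
        return [r.label for r in self.rows]

    def class_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for r in self.rows:
            counts[r.label] = counts.get(r.label, 0) + 1
        return counts

    def save(self, path: str | Path) -> None:
        path = Path(path)
        lines = ["id\tlabel\tclean\tmarked\tmark_mask\tlesion_mask\tseed"]
        for r in self.rows:
            lines.append("\t".join([r.id, r.label, r.clean_path, r.marked_path,
                                    r.markmask_path, r.lesionmask_path, str(r.seed)]))
        path.write_text("\n".join(lines) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "DatasetManifest":
        path = Path(path)
        lines = path.read_text().strip().splitlines()
        rows = []
        for line in lines[1:]:
            f = line.split("\t")
            rows.append(ManifestRow(f[0], f[1], f[2], f[3], f[4], f[5], int(f[6])))
        return cls(rows, root=path.parent)

    def load_image(self, rel_path: str) -> np.ndarray:
        """Read one 8-bit grayscale PNG as float in [0, 1]."""
        if self.root is None:
            raise ValueError("manifest has no root directory")
        arr = np.asarray(Image.open(self.root / rel_path), dtype=np.float32)
        return arr / 255.0


def _save_png(path: Path, img: np.ndarray, binary: bool = False) -> None:
    if binary:
        data = (img.astype(np.uint8) * 255)
    else:
        data = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
    Image.fromarray(data, mode="L").save(path)


#: Relative mark burden per class: sonographers measure lesions, so mark
#: density correlates with the diagnosis (few marks on normal ovaries, many
#: caliper pairs on complex malignant masses).
MARK_DENSITY_BY_CLASS = {
    "normal": 0.3,
    "cystadenoma": 1.0,
    "teratoma": 1.0,
    "endometrioma": 1.0,
    "malignant": 2.0,
}


def generate_record(label: str, index: int, params: PhantomParams) -> PhantomRecord:
    """Generate one fully marked record under the dataset's seeding scheme."""
    seed = record_seed(params.master_seed, label, index)
    rec = generate_phantom(label, params.image_size, seed,
                           speckle_scale=params.speckle_scale,
                           lesion_size_range=params.lesion_size_range)
    rec.id = f"{label}-{index:04d}"
    density = params.mark_density * MARK_DENSITY_BY_CLASS[label]
    overlay_marks(rec, density, seed + 1, force_min_marks=(label != "normal"))
    return rec


def generate_dataset(params: PhantomParams, out_dir: str | Path) -> DatasetManifest:
    """Write the full phantom dataset (PNGs + tab-separated manifest)."""
    if not params.class_counts:
        raise ValueError("class_counts must be nonempty")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    img_dir = out / "images"
    img_dir.mkdir(exist_ok=True)
    rows = []
    for label in CLASSES:
        for index in range(params.class_counts.get(label, 0)):
            rec = generate_record(label, index, params)
            paths = {}
            for kind, img, binary in [
                ("clean", rec.clean, False),
                ("marked", rec.marked, False),
                ("markmask", rec.mark_mask, True),
                ("lesionmask", rec.lesion_mask, True),
            ]:
                rel = f"images/{rec.id}_{kind}.png"
                _save_png(out / rel, img, binary=binary)
                paths[kind] = rel
            rows.append(ManifestRow(rec.id, label, paths["clean"], paths["marked"],
                                    paths["markmask"], paths["lesionmask"], rec.seed))
    manifest = DatasetManifest(rows, root=out)
    manifest.save(out / "manifest.tsv")
    return manifest


def shape_features(record: PhantomRecord) -> np.ndarray:
    """4-feature summary used to audit class separability.

    [interior mean, interior variance, lesion area fraction,
    boundary irregularity perimeter^2 / area]; all zero for empty masks.
    """
    mask = record.lesion_mask.astype(bool)
    if not mask.any():
        return np.zeros(4, dtype=np.float64)
    interior = record.clean[mask]
    area = float(mask.sum())
    perimeter = float(len(_boundary_points(record.lesion_mask)))
    return np.array([
        interior.mean(),
        interior.var(),
        area / mask.size,
        perimeter**2 / area,
    ])
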