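"""Reading, splitting, patching and stitching of fundus image/mask pairs.

Coordinate convention: 0-based (row, col) origins with half-open extents.
Images live in memory as H×W×3 float arrays scaled to [0, 1]; masks are H×W
uint8 arrays with values in {0, 1}.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import imageio.v3 as iio
import numpy as np

AUGMENT_OPS = ("hflip", "vflip", "rot90", "rot180", "rot270", "translate")

TRANSLATE_MAX = 8  # uniform integer shifts in [-8, +8] px per axis


class DataError(ValueError):
    pass


@dataclass
class ImagePair:
    """Co-registered RGB image, binary vessel mask, optional FOV mask."""

    image: np.ndarray
    mask: np.ndarray
    fov: np.ndarray | None = None
    source_id: str = ""

    def __post_init__(self):
        self.image = np.asarray(self.image, dtype=np.float64)
        self.mask = np.asarray(self.mask)
        if self.image.ndim != 3 or self.image.shape[2] != 3:
            raise DataError(f"image must be H×W×3, got {self.image.shape}")
        if self.mask.shape != self.image.shape[:2]:
            raise DataError(
                f"mask shape {self.mask.shape} does not match image "
                f"{self.image.shape[:2]}")
        if not np.isin(self.mask, (0, 1)).all():
            raise DataError("mask values must be in {0, 1}")
        self.mask = self.mask.astype(np.uint8)
        if self.fov is not None:
            self.fov = np.asarray(self.fov)
            if self.fov.shape != self.mask.shape:
                raise DataError(
                    f"fov shape {self.fov.shape} does not match image")
            if not np.isin(self.fov, (0, 1)).all():
                raise DataError("fov values must be in {0, 1}")
            self.fov = self.fov.astype(np.uint8)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape


@dataclass
class Patch:
    image: np.ndarray  # size×size×3
    mask: np.ndarray   # size×size
    row: int
    col: int
    source_id: str = ""


@dataclass
class PatchSet:
    patches: list[Patch] = field(default_factory=list)

    def __len__(self):
        return len(self.patches)

    def __iter__(self):
        return iter(self.patches)

    def arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Stack into (N, 3, s, s) float32 images and (N, s, s) float32 masks."""
        x = np.stack([p.image.transpose(2, 0, 1) for p in self.patches])
        y = np.stack([p.mask for p in self.patches])
        return x.astype(np.float32), y.astype(np.float32)


# ---------------------------------------------------------------------------
# raster I/O
# ---------------------------------------------------------------------------

def _read_scaled(path) -> np.ndarray:
    """Read a raster and scale to float64 in [0, 1]."""
    arr = iio.imread(path)
    if arr.ndim == 4:  # animated container (e.g. GIF): first frame
        arr = arr[0]
    if arr.dtype == np.uint8:
        arr = arr.astype(np.float64) / 255.0
    elif arr.dtype == np.uint16:
        arr = arr.astype(np.float64) / 65535.0
    elif arr.dtype == bool:
        arr = arr.astype(np.float64)
    else:
        arr = arr.astype(np.float64)
        if arr.max() > 1.0:
            arr = arr / 255.0
    return arr


def _to_rgb(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 2:
        return np.repeat(arr[:, :, None], 3, axis=2)
    if arr.shape[2] == 4:  # drop alpha
        return arr[:, :, :3]
    return arr[:, :, :3]


def _to_binary(arr: np.ndarray) -> np.ndarray:
    if arr.ndim == 3:
        arr = arr.mean(axis=2)
    return (arr > 0.5).astype(np.uint8)


def load_image_pair(image_path, mask_path, fov_path=None,
                    source_id: str | None = None) -> ImagePair:
    """Load an image/mask(/FOV) triple; masks are binarized at midpoint."""
    image = _to_rgb(_read_scaled(image_path))
    mask = _to_binary(_read_scaled(mask_path))
    if mask.shape != image.shape[:2]:
        raise DataError(
            f"mask {mask.shape} does not match image {image.shape[:2]} "
            f"({mask_path} vs {image_path})")
    fov = None
    if fov_path is not None:
        fov = _to_binary(_read_scaled(fov_path))
    if source_id is None:
        source_id = Path(image_path).stem
    return ImagePair(image=image, mask=mask, fov=fov, source_id=source_id)


def write_image_pair(directory, pair: ImagePair) -> dict:
    """Write image/mask(/fov) as PNGs; returns a manifest record."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    stem = pair.source_id or "image"
    record = {"id": stem}
    img_path = directory / f"{stem}_image.png"
    iio.imwrite(img_path, np.round(pair.image * 255).astype(np.uint8))
    record["image"] = img_path.name
    mask_path = directory / f"{stem}_mask.png"
    iio.imwrite(mask_path, (pair.mask * 255).astype(np.uint8))
    record["mask"] = mask_path.name
    if pair.fov is not None:
        fov_path = directory / f"{stem}_fov.png"
        iio.imwrite(fov_path, (pair.fov * 255).astype(np.uint8))
        record["fov"] = fov_path.name
    return record


# ---------------------------------------------------------------------------
# manifests
# ---------------------------------------------------------------------------

def write_manifest(path, records: list[dict], name: str = "dataset"):
    """JSON manifest: {"name", "images": [{"id","image","mask","fov","split"}]}."""
    path = Path(path)
    payload = {"name": name, "images": records}
    path.write_text(json.dumps(payload, indent=2))


def load_manifest(path) -> list[dict]:
    path = Path(path)
    payload = json.loads(path.read_text())
    if "images" not in payload:
        raise DataError(f"manifest {path} has no 'images' key")
    return payload["images"]


def load_pairs_from_manifest(path, split: str | None = None) -> list[ImagePair]:
    path = Path(path)
    base = path.parent
    pairs = []
    for rec in load_manifest(path):
        if split is not None and rec.get("split") != split:
            continue
        pairs.append(load_image_pair(
            base / rec["image"], base / rec["mask"],
            base / rec["fov"] if rec.get("fov") else None,
            source_id=rec["id"]))
    return pairs


# ---------------------------------------------------------------------------
# dataset splits
# ---------------------------------------------------------------------------

def split_dataset(name: str, ordered_ids) -> tuple[list[str], list[str]]:
    """Train/test division for the public fundus benchmarks.

    STARE (20 images, no official split): first 10 by filename order train,
    last 10 test.  DRIVE (40 images): the official division — the first 20
    ids in filename order are the test images (01–20), the last 20 the
    training images (21–40).
    """
    ids = sorted(str(i) for i in ordered_ids)
    name = name.upper()
    if name == "STARE":
        if len(ids) != 20:
            raise DataError(f"STARE expects 20 ids, got {len(ids)}")
        return ids[:10], ids[10:]
    if name == "DRIVE":
        if len(ids) != 40:
            raise DataError(f"DRIVE expects 40 ids, got {len(ids)}")
        return ids[20:], ids[:20]
    raise DataError(f"unknown dataset {name!r} (expected STARE or DRIVE)")


# ---------------------------------------------------------------------------
# patch extraction
# ---------------------------------------------------------------------------

def _grid_origins(extent: int, size: int, stride: int) -> list[int]:
    origins = list(range(0, extent - size + 1, stride))
    if origins[-1] != extent - size:
        origins.append(extent - size)
    return origins


def extract_patches(pair: ImagePair, size: int = 64, strategy: str = "random",
                    n_or_stride: int = 500, seed: int = 0,
                    fov_min_coverage: float = 0.5) -> PatchSet:
    """Cut size×size patches from an image pair.

    strategy "random": ``n_or_stride`` patches at seeded uniform origins;
    when a FOV mask exists, candidates covering < ``fov_min_coverage`` of
    their area in FOV are rejected (resampled).  strategy "grid": origins on
    a stride lattice, last row/col snapped inside the bounds.
    """
    h, w = pair.shape
    if h < size or w < size:
        raise DataError(f"image {h}x{w} smaller than patch size {size}")

    def cut(r, c):
        return Patch(image=pair.image[r:r + size, c:c + size].copy(),
                     mask=pair.mask[r:r + size, c:c + size].copy(),
                     row=int(r), col=int(c), source_id=pair.source_id)

    patches: list[Patch] = []
    if strategy == "random":
        rng = np.random.default_rng(seed)
        n = int(n_or_stride)
        attempts = 0
        max_attempts = max(50 * n, 1000)
        while len(patches) < n and attempts < max_attempts:
            attempts += 1
            r = int(rng.integers(0, h - size + 1))
            c = int(rng.integers(0, w - size + 1))
            if pair.fov is not None:
                cov = pair.fov[r:r + size, c:c + size].mean()
                if cov < fov_min_coverage:
                    continue
            patches.append(cut(r, c))
        if len(patches) < n:
            raise DataError(
                f"could not sample {n} patches with FOV coverage >= "
                f"{fov_min_coverage} (got {len(patches)})")
    elif strategy == "grid":
        stride = int(n_or_stride)
        for r in _grid_origins(h, size, stride):
            for c in _grid_origins(w, size, stride):
                patches.append(cut(r, c))
    else:
        raise DataError(f"unknown strategy {strategy!r}")
    return PatchSet(patches)


# ---------------------------------------------------------------------------
# augmentation
# ---------------------------------------------------------------------------

def augment(image: np.ndarray, mask: np.ndarray, ops, seed: int | None = None
            ) -> tuple[np.ndarray, np.ndarray]:
    """Apply the named geometric ops, in order, to image and mask alike.

    Flips and right-angle rotations are pure pixel permutations.  "translate"
    shifts by a seeded uniform integer offset in [-8, 8] px per axis with
    zero fill (pixels shifted out are lost); pass a (dy, dx) tuple as
    ``("translate", dy, dx)`` for a deterministic shift.
    """
    image = np.asarray(image).copy()
    mask = np.asarray(mask).copy()
    rng = np.random.default_rng(seed)
    for op in ops:
        shift = None
        if isinstance(op, (tuple, list)):
            op, shift = op[0], (int(op[1]), int(op[2]))
        if op == "hflip":
            image, mask = image[:, ::-1], mask[:, ::-1]
        elif op == "vflip":
            image, mask = image[::-1], mask[::-1]
        elif op in ("rot90", "rot180", "rot270"):
            k = {"rot90": 1, "rot180": 2, "rot270": 3}[op]
            image, mask = np.rot90(image, k), np.rot90(mask, k)
        elif op == "translate":
            if shift is None:
                shift = tuple(rng.integers(-TRANSLATE_MAX, TRANSLATE_MAX + 1,
                                           size=2))
            image = _shift2d(image, shift)
            mask = _shift2d(mask, shift)
        else:
            raise DataError(f"unknown augmentation op {op!r}")
    return np.ascontiguousarray(image), np.ascontiguousarray(mask)


def _shift2d(arr: np.ndarray, shift: tuple[int, int]) -> np.ndarray:
    """Integer shift with zero fill (nearest-neighbour; masks stay binary)."""
    dy, dx = shift
    out = np.zeros_like(arr)
    h, w = arr.shape[:2]
    ys = slice(max(dy, 0), min(h + dy, h))
    xs = slice(max(dx, 0), min(w + dx, w))
    ys_src = slice(max(-dy, 0), min(h - dy, h))
    xs_src = slice(max(-dx, 0), min(w - dx, w))
    out[ys, xs] = arr[ys_src, xs_src]
    return out


def random_augment(image: np.ndarray, mask: np.ndarray,
                   rng: np.random.Generator,
                   ops=AUGMENT_OPS) -> tuple[np.ndarray, np.ndarray]:
    """Randomly compose one flip/rotation and (maybe) a translation."""
    chosen = []
    geo = [o for o in ops if o != "translate"]
    if geo and rng.random() < 0.75:
        chosen.append(geo[rng.integers(len(geo))])
    if "translate" in ops and rng.random() < 0.5:
        dy, dx = rng.integers(-TRANSLATE_MAX, TRANSLATE_MAX + 1, size=2)
        chosen.append(("translate", int(dy), int(dx)))
    return augment(image, mask, chosen)


# ---------------------------------------------------------------------------
# stitching and thresholding
# ---------------------------------------------------------------------------

def stitch_predictions(tiles, full_shape) -> tuple[np.ndarray, np.ndarray]:
    """Average overlapping tile predictions into a full-size map.

    ``tiles`` is an iterable of (prob_patch, (row, col)).  Returns
    (probability map, coverage mask); pixels covered by no tile are 0 in the
    coverage mask and hold probability 0.
    """
    h, w = full_shape
    acc = np.zeros((h, w), dtype=np.float64)
    count = np.zeros((h, w), dtype=np.int64)
    for prob, (r, c) in tiles:
        prob = np.asarray(prob)
        ph, pw = prob.shape
        if r < 0 or c < 0 or r + ph > h or c + pw > w:
            raise DataError(
                f"tile at ({r},{c}) size {ph}x{pw} exceeds bounds {h}x{w}")
        acc[r:r + ph, c:c + pw] += prob
        count[r:r + ph, c:c + pw] += 1
    covered = count > 0
    out = np.zeros((h, w), dtype=np.float64)
    out[covered] = acc[covered] / count[covered]
    return out, covered.astype(np.uint8)


def binarize(prob: np.ndarray, threshold: float = 0.5) -> np.ndarray:
    """Strictly-greater-than threshold; ties go to background."""
    prob = np.asarray(prob)
    return (prob > threshold).astype(np.uint8)


def write_probability_png(path, prob: np.ndarray):
    """8-bit PNG with value = round(255·p)."""
    prob = np.asarray(prob, dtype=np.float64)
    if prob.min() < 0 or prob.max() > 1:
        raise DataError("probabilities must lie in [0, 1]")
    iio.imwrite(Path(path), np.round(prob * 255).astype(np.uint8))


def read_probability_png(path) -> np.ndarray:
    arr = iio.imread(Path(path))
    if arr.ndim == 3:
        arr = arr[..., 0]
    return arr.astype(np.float64) / 255.0
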