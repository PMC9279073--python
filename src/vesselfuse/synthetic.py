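"""Seeded vessel-phantom generator.

Phantoms emulate the statistics a patch-based vessel segmenter sees in fundus
photographs: curvilinear branching trees of tubular structures, darker than a
bright, unevenly illuminated background, inside a circular field of view, with
additive Gaussian pixel noise.  Ground truth comes from the noiseless vessel
response (full-width-half-maximum rule), never from the noisy image, so the
labels are exact.

Geometry: each tree is a random walk of line segments (length U(10, 30) px,
heading jitter up to ±10° per step).  At each step a side branch spawns with
probability ``branch_prob`` at a heading offset of ±U(10°, 40°); a child's
width is 0.8× its parent's and recursion stops below ``width_min``.  Segments
render with a Gaussian cross-section whose FWHM equals the local width.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_io import ImagePair, write_image_pair, write_manifest

_FWHM = 2.0 * math.sqrt(2.0 * math.log(2.0))  # sigma -> full width half max


@dataclass
class PhantomConfig:
    size: tuple[int, int] = (256, 256)
    n_trees: int = 5
    branch_prob: float = 0.35
    width_root: float = 5.0
    width_min: float = 1.0
    vessel_contrast: float = 0.35
    background_level: float = 0.65
    noise_sigma: float = 0.03
    illumination_gradient: float = 0.15
    fov_radius_frac: float = 0.95
    seed: int = 0
    dark_vessels: bool = True  # fundus convention; False inverts polarity
    width_taper: float = 0.97  # per-segment width decay along a walk
    max_steps: int = 30
    # total centerline length rendered per image (px), shared across trees;
    # fixes the expected vessel density so the foreground fraction is stable
    # across seeds.  Scales with the image area relative to 256x256.
    total_length: float = 1400.0

    def validate(self):
        if self.width_min < 1:
            raise ValueError("width_min must be >= 1 px")
        for name in ("branch_prob", "vessel_contrast", "background_level",
                     "illumination_gradient"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if not 0.0 < self.fov_radius_frac <= 1.0:
            raise ValueError("fov_radius_frac must be in (0, 1]")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if self.n_trees < 0:
            raise ValueError("n_trees must be >= 0")


def _fov_disc(h: int, w: int, radius_frac: float) -> np.ndarray:
    cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    radius = radius_frac * min(h, w) / 2.0
    yy, xx = np.mgrid[0:h, 0:w]
    return (((yy - cy) ** 2 + (xx - cx) ** 2) <= radius ** 2).astype(np.uint8)


def _render_segment(response: np.ndarray, p0, p1, width: float):
    """Max-combine a Gaussian-profile segment into the response field."""
    h, w = response.shape
    sigma = max(width, 1.0) / _FWHM
    reach = 3.0 * sigma + 1.0
    r0 = max(int(math.floor(min(p0[0], p1[0]) - reach)), 0)
    r1 = min(int(math.ceil(max(p0[0], p1[0]) + reach)) + 1, h)
    c0 = max(int(math.floor(min(p0[1], p1[1]) - reach)), 0)
    c1 = min(int(math.ceil(max(p0[1], p1[1]) + reach)) + 1, w)
    if r0 >= r1 or c0 >= c1:
        return
    yy, xx = np.mgrid[r0:r1, c0:c1]
    dy, dx = p1[0] - p0[0], p1[1] - p0[1]
    seg_len2 = dy * dy + dx * dx
    if seg_len2 == 0:
        d2 = (yy - p0[0]) ** 2 + (xx - p0[1]) ** 2
    else:
        t = ((yy - p0[0]) * dy + (xx - p0[1]) * dx) / seg_len2
        t = np.clip(t, 0.0, 1.0)
        d2 = (yy - (p0[0] + t * dy)) ** 2 + (xx - (p0[1] + t * dx)) ** 2
    local = np.exp(-d2 / (2.0 * sigma * sigma))
    np.maximum(response[r0:r1, c0:c1], local, out=response[r0:r1, c0:c1])


def _grow_tree(response: np.ndarray, rng: np.random.Generator,
               start, heading: float, width: float, cfg: PhantomConfig,
               fov_radius: float, center, budget: list[float]):
    """Depth-first growth of one vessel tree into the response field.

    ``budget`` is the remaining total centerline length (shared across all
    trees of the image); growth stops when it is exhausted.
    """
    stack = [(start, heading, width)]
    while stack and budget[0] > 0:
        pos, ang, wid = stack.pop()
        steps = 0
        while wid >= cfg.width_min and steps < cfg.max_steps and budget[0] > 0:
            steps += 1
            length = min(rng.uniform(10.0, 30.0), budget[0])
            budget[0] -= length
            ang += rng.uniform(-math.radians(10), math.radians(10))
            nxt = (pos[0] + length * math.sin(ang),
                   pos[1] + length * math.cos(ang))
            _render_segment(response, pos, nxt, wid)
            pos = nxt
            r = math.hypot(pos[0] - center[0], pos[1] - center[1])
            if r > fov_radius:
                break
            if rng.random() < cfg.branch_prob:
                side = rng.choice((-1.0, 1.0))
                child_ang = ang + side * rng.uniform(math.radians(10),
                                                     math.radians(40))
                child_w = 0.8 * wid
                if child_w >= cfg.width_min:
                    stack.append((pos, child_ang, child_w))
            wid *= cfg.width_taper


def generate_phantom(cfg: PhantomConfig | None = None) -> ImagePair:
    """Render one phantom; bitwise deterministic for a fixed config."""
    cfg = cfg or PhantomConfig()
    cfg.validate()
    h, w = cfg.size
    rng = np.random.default_rng(cfg.seed)
    center = ((h - 1) / 2.0, (w - 1) / 2.0)
    fov = _fov_disc(h, w, cfg.fov_radius_frac)
    fov_radius = cfg.fov_radius_frac * min(h, w) / 2.0

    response = np.zeros((h, w), dtype=np.float64)
    # the length budget scales with the image area so density is resolution-free
    budget = [cfg.total_length * (h * w) / (256.0 * 256.0)] \
        if cfg.n_trees else [0.0]
    tree = 0
    while budget[0] > 0:
        # roots start inside 60% of the FOV radius, heading uniform
        rr = fov_radius * 0.6 * math.sqrt(rng.random())
        theta = rng.uniform(0, 2 * math.pi)
        start = (center[0] + rr * math.sin(theta),
                 center[1] + rr * math.cos(theta))
        heading = rng.uniform(0, 2 * math.pi)
        per_tree = [min(budget[0], cfg.total_length * (h * w)
                        / (256.0 * 256.0) / cfg.n_trees)] \
            if tree < cfg.n_trees - 1 else [budget[0]]
        budget[0] -= per_tree[0]
        _grow_tree(response, rng, start, heading, cfg.width_root, cfg,
                   fov_radius, center, per_tree)
        budget[0] += per_tree[0]  # return unused remainder to the pool
        tree += 1
        if tree > 4 * cfg.n_trees:  # safety: walks that exit the FOV early
            break

    # exact labels: noiseless response above half its (unit) peak, inside FOV
    mask = ((response > 0.5) & (fov > 0)).astype(np.uint8)

    # illumination: smooth linear ramp in a random direction, amplitude
    # illumination_gradient about the background level
    phi = rng.uniform(0, 2 * math.pi)
    yy, xx = np.mgrid[0:h, 0:w]
    ramp = ((yy - center[0]) * math.sin(phi) + (xx - center[1]) * math.cos(phi))
    ramp /= max(np.abs(ramp).max(), 1.0)
    clean = cfg.background_level + 0.5 * cfg.illumination_gradient * ramp
    sign = -1.0 if cfg.dark_vessels else 1.0
    clean = clean + sign * cfg.vessel_contrast * response
    clean[fov == 0] = 0.02  # near-black border outside the field of view

    noisy = clean + rng.normal(0.0, cfg.noise_sigma, size=(h, w))
    image = np.clip(noisy, 0.0, 1.0)[:, :, None].repeat(3, axis=2)
    return ImagePair(image=image, mask=mask, fov=fov,
                     source_id=f"phantom_{cfg.seed:05d}")


def generate_dataset(cfg: PhantomConfig, n_images: int, base_seed: int,
                     out_dir=None, split: str | None = None,
                     manifest_name: str = "manifest.json") -> list[ImagePair]:
    """Generate ``n_images`` phantoms with seeds base_seed + index.

    When ``out_dir`` is given, PNGs plus a JSON manifest in the data_io
    format are written there.
    """
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    pairs = []
    records = []
    for i in range(n_images):
        pcfg = PhantomConfig(**{**cfg.__dict__, "seed": base_seed + i})
        pair = generate_phantom(pcfg)
        pairs.append(pair)
        if out_dir is not None:
            rec = write_image_pair(out_dir, pair)
            if split is not None:
                rec["split"] = split
            records.append(rec)
    if out_dir is not None:
        write_manifest(Path(out_dir) / manifest_name, records,
                       name="vessel-phantoms")
    return pairs
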