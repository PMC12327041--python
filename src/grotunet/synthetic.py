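"""Synthetic rosette-plant images with instance labels.

Emulates the geometry of top-view rosette phenotyping imagery (e.g.
Arabidopsis trays): 1-20 elliptical leaf blades radiating from a common
center, each joined to it by a thin petiole (1-3 px), with leaf-leaf
occlusion, per-leaf shading variation, global illumination jitter and
Gaussian blur.  Labels record the *visible* partition — pixels of occluded
leaf parts belong to the occluder, as in 2-D annotation of real datasets.

What this does not emulate: real leaf venation/texture, specular soil
artifacts, growth sequences, or amodal (hidden-part) masks.

Everything is deterministic per seed.  Datasets are written as paired PNGs
(`plantNNN_rgb.png` 8-bit RGB / `plantNNN_label.png` 16-bit grayscale,
0 = background).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage
from skimage.draw import ellipse as draw_ellipse
from skimage.draw import polygon as draw_polygon

__all__ = ["RosetteSpec", "SamplePair", "generate_rosette", "generate_dataset",
           "augment", "write_dataset", "read_dataset", "make_splits"]


@dataclass
class RosetteSpec:
    image_size: tuple[int, int] = (256, 256)
    n_leaves: tuple[int, int] = (1, 20)          # inclusive range
    leaf_axis_range: tuple[int, int] = (20, 60)  # semi-major axis, px
    petiole_width: tuple[int, int] = (1, 3)
    overlap_factor: float = 0.5
    blur_sigma: float = 0.8
    illumination_jitter: float = 0.15
    background_texture: str = "noise"            # 'noise' or 'plain'
    seed: int = 0

    def __post_init__(self):
        h, w = self.image_size
        if h < 32 or w < 32:
            raise ValueError("image size must be at least 32x32")
        if self.n_leaves[0] < 1:
            raise ValueError("need at least one leaf")
        if self.petiole_width[0] < 1:
            raise ValueError("petiole width must be >= 1 px")
        if not 0.0 <= self.overlap_factor <= 1.0:
            raise ValueError("overlap_factor must be in [0, 1]")


@dataclass
class SamplePair:
    image: np.ndarray   # uint8 [H, W, 3]
    labels: np.ndarray  # int32 [H, W], 0 = background


def _leaf_mask(h: int, w: int, cy: float, cx: float, angle: float,
               a: float, b: float, start_r: float, pw: int) -> np.ndarray:
    """Rasterize one leaf: rotated ellipse + petiole rectangle joining it
    to the rosette center region."""
    mask = np.zeros((h, w), dtype=bool)
    ey = cy + (start_r + a) * np.sin(angle)
    ex = cx + (start_r + a) * np.cos(angle)
    rr, cc = draw_ellipse(ey, ex, a, b, shape=(h, w), rotation=angle - np.pi / 2)
    mask[rr, cc] = True
    # petiole: rectangle from the start radius to the ellipse center
    ny, nx = np.cos(angle), -np.sin(angle)   # unit normal to the petiole axis
    half = pw / 2.0
    p0 = (cy + start_r * np.sin(angle), cx + start_r * np.cos(angle))
    p1 = (ey, ex)
    ys = [p0[0] - ny * half, p0[0] + ny * half, p1[0] + ny * half, p1[0] - ny * half]
    xs = [p0[1] - nx * half, p0[1] + nx * half, p1[1] + nx * half, p1[1] - nx * half]
    rr, cc = draw_polygon(ys, xs, shape=(h, w))
    mask[rr, cc] = True
    if pw == 1:  # a 1-px petiole: ensure an unbroken pixel line
        n_steps = int(max(abs(p1[0] - p0[0]), abs(p1[1] - p0[1]))) + 1
        t = np.linspace(0.0, 1.0, n_steps)
        lr = np.clip(np.round(p0[0] + (p1[0] - p0[0]) * t).astype(int), 0, h - 1)
        lc = np.clip(np.round(p0[1] + (p1[1] - p0[1]) * t).astype(int), 0, w - 1)
        mask[lr, lc] = True
    return mask


def _connected(mask: np.ndarray) -> bool:
    _, n = ndimage.label(mask, structure=np.ones((3, 3)))
    return n == 1


def _try_layout(spec: RosetteSpec, rng: np.random.Generator) -> np.ndarray | None:
    """One layout attempt; returns the label map or None if invariants fail."""
    h, w = spec.image_size
    cy, cx = h / 2.0, w / 2.0
    n = int(rng.integers(spec.n_leaves[0], spec.n_leaves[1] + 1))
    f = spec.overlap_factor
    amin, amax = spec.leaf_axis_range
    max_fit = 0.42 * min(h, w)
    labels = np.zeros((h, w), dtype=np.int32)
    masks = []
    base = rng.uniform(0, 2 * np.pi)
    order = rng.permutation(n)
    for idx in range(n):
        angle = base + 2 * np.pi * order[idx] / n + rng.uniform(-0.5, 0.5) * f * (np.pi / max(n, 2))
        a_hi = min(amax, max_fit * 0.55)
        a = rng.uniform(amin, a_hi) if a_hi > amin else float(a_hi)
        aspect = rng.uniform(0.30, 0.45) * (0.6 + 0.8 * f)
        b = max(2.0, a * aspect)
        start_r = rng.uniform(3.0, 6.0)
        if start_r + 2 * a > max_fit:
            a = (max_fit - start_r) / 2.0
        if a < 4.0:
            return None  # frame cannot fit the drawn leaves
        pw = int(rng.integers(spec.petiole_width[0], spec.petiole_width[1] + 1))
        mask = _leaf_mask(h, w, cy, cx, angle, a, b, start_r, pw)
        if f == 0.0:
            union = np.zeros((h, w), dtype=bool)
            for m in masks:
                union |= m
            shrink = 0
            while (mask & union).any() and shrink < 8:
                b = max(1.5, b * 0.7)
                start_r += 1.5
                mask = _leaf_mask(h, w, cy, cx, angle, a, b, start_r, pw)
                shrink += 1
            if (mask & union).any():
                return None
        if not mask.any():
            return None
        masks.append(mask)
    for i, mask in enumerate(masks):  # later leaves occlude earlier ones
        labels[mask] = i + 1
    present = set(np.unique(labels)) - {0}
    if len(present) != n:
        return None
    for c in range(1, n + 1):
        if not _connected(labels == c):
            return None
    return labels


def _render(labels: np.ndarray, spec: RosetteSpec,
            rng: np.random.Generator) -> np.ndarray:
    h, w = labels.shape
    img = np.empty((h, w, 3), dtype=np.float64)
    base_bg = np.array([0.18, 0.13, 0.09])
    img[:] = base_bg
    if spec.background_texture == "noise":
        img += rng.normal(0.0, 0.03, (h, w, 1)) + rng.normal(0.0, 0.012, (h, w, 3))
    yy, xx = np.mgrid[0:h, 0:w]
    for c in range(1, labels.max() + 1):
        m = labels == c
        if not m.any():
            continue
        # per-leaf green shade: hue/value variation as real leaves show
        g = rng.uniform(0.45, 0.85)
        r = g * rng.uniform(0.25, 0.75)
        b = g * rng.uniform(0.15, 0.45)
        shade = 1.0 - 0.25 * rng.random() * (
            np.hypot(yy[m] - yy[m].mean(), xx[m] - xx[m].mean())
            / max(1.0, np.hypot(yy[m] - yy[m].mean(), xx[m] - xx[m].mean()).max()))
        img[m] = np.stack([r * shade, g * shade, b * shade], axis=-1)
    if spec.illumination_jitter > 0:
        j = spec.illumination_jitter
        plane = (1.0 + rng.uniform(-j, j)
                 + rng.uniform(-j, j) * (xx - w / 2) / w
                 + rng.uniform(-j, j) * (yy - h / 2) / h)
        img *= plane[..., None]
    if spec.blur_sigma > 0:
        img = ndimage.gaussian_filter(img, sigma=(spec.blur_sigma, spec.blur_sigma, 0))
    return (np.clip(img, 0.0, 1.0) * 255).round().astype(np.uint8)


def generate_rosette(spec: RosetteSpec) -> SamplePair:
    """Draw one rosette plant; deterministic for a given spec (incl. seed)."""
    rng = np.random.default_rng(spec.seed)
    labels = None
    for _ in range(64):
        labels = _try_layout(spec, rng)
        if labels is not None:
            break
    if labels is None:
        raise ValueError(
            f"could not fit {spec.n_leaves} leaves of axis {spec.leaf_axis_range} "
            f"into a {spec.image_size} frame")
    return SamplePair(image=_render(labels, spec, rng), labels=labels)


def generate_dataset(spec: RosetteSpec, n: int, seed: int | None = None) -> list[SamplePair]:
    """`n` independent samples; sample i uses seed `seed + i`."""
    base = spec.seed if seed is None else seed
    out = []
    for i in range(n):
        d = {**spec.__dict__, "seed": base + i}
        out.append(generate_rosette(RosetteSpec(**d)))
    return out


def augment(sample: SamplePair, seed: int,
            crop_size: tuple[int, int] | None = None) -> SamplePair:
    """Random crop + random vertical/horizontal flips, applied jointly to
    image and labels (label values preserved)."""
    rng = np.random.default_rng(seed)
    img, lab = sample.image, sample.labels
    if crop_size is not None:
        ch, cw = crop_size
        h, w = lab.shape
        if ch > h or cw > w:
            raise ValueError(f"crop {crop_size} larger than image {lab.shape}")
        top = int(rng.integers(0, h - ch + 1))
        left = int(rng.integers(0, w - cw + 1))
        img = img[top:top + ch, left:left + cw]
        lab = lab[top:top + ch, left:left + cw]
    if rng.random() < 0.5:
        img, lab = img[::-1], lab[::-1]
    if rng.random() < 0.5:
        img, lab = img[:, ::-1], lab[:, ::-1]
    return SamplePair(image=np.ascontiguousarray(img), labels=np.ascontiguousarray(lab))


# -- dataset I/O --------------------------------------------------------------

_STEM = re.compile(r"^(plant\d+)_(rgb|label)\.png$")


def write_dataset(directory, samples: list[SamplePair]) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for i, s in enumerate(samples):
        Image.fromarray(s.image, mode="RGB").save(directory / f"plant{i:03d}_rgb.png")
        lab = Image.fromarray(s.labels.astype(np.uint16))
        lab.save(directory / f"plant{i:03d}_label.png")


def read_dataset(directory) -> list[SamplePair]:
    """Read paired image/label PNGs; unpaired stems raise with their names."""
    directory = Path(directory)
    stems: dict[str, set[str]] = {}
    for p in sorted(directory.iterdir()):
        m = _STEM.match(p.name)
        if m:
            stems.setdefault(m.group(1), set()).add(m.group(2))
    orphans = sorted(s for s, kinds in stems.items() if kinds != {"rgb", "label"})
    if orphans:
        raise ValueError(f"unpaired dataset stems in {directory}: {orphans}")
    if not stems:
        raise ValueError(f"no dataset samples found in {directory}")
    out = []
    for stem in sorted(stems):
        img = np.asarray(Image.open(directory / f"{stem}_rgb.png").convert("RGB"))
        lab = np.asarray(Image.open(directory / f"{stem}_label.png"), dtype=np.int32)
        out.append(SamplePair(image=img, labels=lab))
    return out


def make_splits(n: int, fractions: tuple[float, ...] = (0.85, 0.15),
                seed: int = 0) -> list[list[int]]:
    """Seeded shuffled index split; earlier parts get floor(n*f), the last
    part takes the remainder, so e.g. 128 at 85/15 gives 108/20."""
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ValueError("fractions must sum to 1")
    idx = list(np.random.default_rng(seed).permutation(n))
    sizes = [int(np.floor(n * f)) for f in fractions[:-1]]
    sizes.append(n - sum(sizes))
    parts, at = [], 0
    for s in sizes:
        parts.append([int(i) for i in idx[at:at + s]])
        at += s
    return parts
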