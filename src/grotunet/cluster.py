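"""Instance recovery: mean-shift clustering of the embedding space.

The discriminative loss pulls pixels of one instance within ``delta_v`` of
their mean and pushes distinct means at least ``2*delta_d`` apart, so a
flat-kernel mean shift with bandwidth ``delta_v`` finds one mode per
instance.  Pixels are assigned to the nearest mode within
``assign_radius``; tiny clusters are dissolved; the background cluster is
identified (by default as the mode owning most image-border pixels, since
rosette images are plant-centered) and mapped to label 0; the remaining
clusters are renumbered 1..K by decreasing size.
"""

from __future__ import annotations

import numpy as np
from sklearn.cluster import MeanShift

from .config import ClusterConfig

__all__ = ["mean_shift_centers", "merge_centers", "assign_instances",
           "predict_instances"]


def _flatten(emb: np.ndarray) -> np.ndarray:
    emb = np.asarray(emb, dtype=np.float64)
    if emb.ndim != 3 or emb.size == 0:
        raise ValueError(f"embedding map must be a nonempty [H,W,E] array, got {emb.shape}")
    return emb.reshape(-1, emb.shape[-1])


def mean_shift_centers(emb: np.ndarray, cfg: ClusterConfig | None = None,
                       seed: int = 0) -> np.ndarray:
    """Converged mean-shift modes, deduplicated within one bandwidth.

    Seeds are placed on a regular pixel subgrid (every ``seed_stride``-th
    pixel) for speed; set ``seed_stride=1`` for full-pixel seeding.  The
    procedure is deterministic for a given seed.
    """
    cfg = cfg or ClusterConfig()
    h, w, _ = np.asarray(emb).shape
    x = _flatten(emb)
    stride = max(1, cfg.seed_stride)
    rng = np.random.default_rng(seed)
    off = int(rng.integers(0, stride))
    rows = np.arange(off, h, stride)
    cols = np.arange(off, w, stride)
    seed_idx = (rows[:, None] * w + cols[None, :]).ravel()
    seeds = np.unique(x[seed_idx], axis=0)
    # density is estimated from a regular pixel subgrid: the embedding field
    # is spatially smooth, so a subsample preserves the modes while cutting
    # the neighbor-search cost quadratically
    fs = max(1, cfg.fit_stride)
    fit_idx = (np.arange(0, h, fs)[:, None] * w + np.arange(0, w, fs)[None, :]).ravel()
    ms = MeanShift(bandwidth=cfg.bandwidth, seeds=seeds, cluster_all=True)
    ms.fit(x[fit_idx])
    return np.asarray(ms.cluster_centers_, dtype=np.float64)


def _border_mask(h: int, w: int) -> np.ndarray:
    m = np.zeros((h, w), dtype=bool)
    m[0, :] = m[-1, :] = True
    m[:, 0] = m[:, -1] = True
    return m


def assign_instances(emb: np.ndarray, centers: np.ndarray,
                     cfg: ClusterConfig | None = None) -> np.ndarray:
    """Label map from embedding modes (see module docstring for the rules)."""
    cfg = cfg or ClusterConfig()
    emb = np.asarray(emb)
    h, w, _ = emb.shape
    centers = np.asarray(centers, dtype=np.float64)
    if centers.size == 0:
        return np.zeros((h, w), dtype=np.int32)
    x = _flatten(emb)
    d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=-1)
    nearest = d2.argmin(axis=1)
    within = d2[np.arange(len(x)), nearest] <= cfg.assign_radius ** 2
    raw = np.where(within, nearest + 1, 0).reshape(h, w)

    # dissolve clusters below the minimum size
    ids, counts = np.unique(raw[raw > 0], return_counts=True)
    for c, n in zip(ids, counts):
        if n < cfg.min_instance_pixels:
            raw[raw == c] = 0

    # background cluster -> 0
    ids, counts = np.unique(raw[raw > 0], return_counts=True)
    if len(ids):
        if cfg.background_rule == "border_majority":
            border = raw[_border_mask(h, w)]
            border = border[border > 0]
            bg = np.bincount(border).argmax() if border.size else None
        else:  # largest_cluster
            bg = ids[counts.argmax()]
        if bg is not None:
            raw[raw == bg] = 0

    # renumber 1..K by decreasing size
    ids, counts = np.unique(raw[raw > 0], return_counts=True)
    out = np.zeros((h, w), dtype=np.int32)
    for new, old in enumerate(ids[np.argsort(-counts, kind="stable")], start=1):
        out[raw == old] = new
    return out


def merge_centers(centers: np.ndarray, radius: float) -> np.ndarray:
    """Attach low-support modes to a dominant mode closer than `radius`.

    A trained embedding keeps distinct instance means at least 2*delta_d
    apart while mean shift at bandwidth delta_v can fragment one instance
    into several nearby modes, so a mode within delta_d of a stronger mode
    is treated as a fragment of it.  `centers` must be ordered by decreasing
    support (as mean_shift_centers returns them); attachment is greedy and
    non-transitive, so diffuse clusters cannot chain distinct instances
    together.  Kept modes are returned unchanged.
    """
    centers = np.asarray(centers, dtype=np.float64)
    if len(centers) <= 1 or radius <= 0:
        return centers
    kept: list[np.ndarray] = []
    for c in centers:
        if not kept or min(np.linalg.norm(c - k) for k in kept) >= radius:
            kept.append(c)
    return np.stack(kept)


def predict_instances(emb: np.ndarray, cfg: ClusterConfig | None = None,
                      seed: int = 0) -> np.ndarray:
    """Embedding map -> instance label map (mean shift, fragment merging,
    assignment)."""
    cfg = cfg or ClusterConfig()
    centers = mean_shift_centers(emb, cfg, seed=seed)
    centers = merge_centers(centers, cfg.merge_radius)
    return assign_instances(emb, centers, cfg)
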