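"""Discriminative embedding loss.

Three terms over per-pixel embedding vectors x_i and per-instance mean
embeddings mu_c:

* variance term — pulls each pixel within the margin delta_v of its
  instance mean: mean over instances of mean over pixels of
  ``[||mu_c - x_i|| - delta_v]_+^2``;
* distance term — pushes instance means at least 2*delta_d apart: mean over
  ordered pairs of distinct instances of ``[2 delta_d - ||mu_a - mu_b||]_+^2``
  (zero when only one instance exists);
* regularizer — mean of ``||mu_c||``, keeping the embedding bounded.

Total: ``alpha * L_var + beta * L_dist + gamma * L_reg``.  With
``background_as_instance`` (the default) the background participates as one
extra cluster, so minimizing the loss separates foreground instances *and*
background in the same embedding space.

All terms are differentiable with respect to the embedding map; pass a
:class:`~grotunet.nn.Tensor` to keep the graph, or a plain array to get
floats back.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .config import LossConfig
from .nn import Tensor

_EPS = 1e-12


def _cluster_ids(labels: np.ndarray, background_as_instance: bool) -> list[int]:
    ids = [int(c) for c in np.unique(labels) if c > 0]
    if background_as_instance and (labels == 0).any():
        ids = [0] + ids
    if not ids:
        raise ValueError("label map contains no instances")
    return ids


def _flat(emb) -> tuple[Tensor, int, int]:
    t = emb if isinstance(emb, Tensor) else Tensor(emb)
    if t.ndim != 3:
        raise ValueError(f"embedding map must be [H,W,E], got shape {t.shape}")
    h, w, e = t.shape
    return t.reshape(h * w, e), h * w, e


def _norm(t: Tensor, cfg: LossConfig, axis: int = -1) -> Tensor:
    if cfg.norm == "l1":
        return t.abs().sum(axis=axis)
    return ((t ** 2.0).sum(axis=axis) + _EPS).sqrt()


def _means(x: Tensor, labels: np.ndarray, ids: list[int]) -> tuple[Tensor, np.ndarray]:
    """Instance means [C,E] plus the one-hot assignment matrix [C,P]."""
    flat = labels.ravel()
    onehot = np.stack([(flat == c) for c in ids]).astype(x.data.dtype)
    counts = onehot.sum(axis=1)
    return Tensor(onehot / counts[:, None]) @ x, onehot


def instance_means(emb, labels: np.ndarray, background_as_instance: bool = False
                   ) -> dict[int, np.ndarray]:
    """Arithmetic mean embedding of every labeled instance, keyed by label."""
    labels = np.asarray(labels)
    ids = _cluster_ids(labels, background_as_instance)
    x, p, _ = _flat(emb)
    if labels.size != p:
        raise ValueError("label map and embedding map disagree in size")
    mu, _ = _means(x, labels, ids)
    return {c: mu.data[i].copy() for i, c in enumerate(ids)}


def variance_term(emb, labels: np.ndarray, cfg: LossConfig | None = None):
    cfg = cfg or LossConfig()
    labels = np.asarray(labels)
    ids = _cluster_ids(labels, cfg.background_as_instance)
    x, p, _ = _flat(emb)
    mu, onehot = _means(x, labels, ids)
    # distance of each assigned pixel to its own instance mean
    mu_pix = Tensor(onehot.T) @ mu                      # [P,E]; zero rows unassigned
    d = _norm(mu_pix - x, cfg)                          # [P]
    hinge = nn.relu(d - cfg.delta_v) ** 2.0
    counts = onehot.sum(axis=1)
    weights = (onehot / counts[:, None]).sum(axis=0) / len(ids)   # [P]
    out = (hinge * Tensor(weights)).sum()
    return out if isinstance(emb, Tensor) else out.item()


def distance_term(emb, labels: np.ndarray, cfg: LossConfig | None = None):
    cfg = cfg or LossConfig()
    labels = np.asarray(labels)
    ids = _cluster_ids(labels, cfg.background_as_instance)
    x, _, e = _flat(emb)
    c = len(ids)
    if c == 1:
        out = Tensor(0.0)
        return out if isinstance(emb, Tensor) else 0.0
    mu, _ = _means(x, labels, ids)
    diff = mu.reshape(c, 1, e) - mu.reshape(1, c, e)
    d = _norm(diff, cfg)                                # [C,C]
    hinge = nn.relu(2.0 * cfg.delta_d - d) ** 2.0
    mask = Tensor(1.0 - np.eye(c, dtype=mu.data.dtype))
    out = (hinge * mask).sum() * (1.0 / (c * (c - 1)))
    return out if isinstance(emb, Tensor) else out.item()


def reg_term(emb, labels: np.ndarray, cfg: LossConfig | None = None):
    cfg = cfg or LossConfig()
    labels = np.asarray(labels)
    ids = _cluster_ids(labels, cfg.background_as_instance)
    x, _, _ = _flat(emb)
    mu, _ = _means(x, labels, ids)
    out = _norm(mu, cfg).mean()
    return out if isinstance(emb, Tensor) else out.item()


def discriminative_loss(emb, labels: np.ndarray, cfg: LossConfig | None = None):
    """Weighted total plus the three parts, as Tensors (Tensor input) or
    floats (array input)."""
    cfg = cfg or LossConfig()
    lv = variance_term(emb, labels, cfg)
    ld = distance_term(emb, labels, cfg)
    lr = reg_term(emb, labels, cfg)
    total = cfg.alpha * lv + cfg.beta * ld + cfg.gamma * lr
    return total, (lv, ld, lr)
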