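"""Training, evaluation and prediction pipelines.

Training minimizes the discriminative embedding loss over network outputs
with AdamW (decoupled weight decay) and a reduce-on-plateau learning-rate
schedule.  All randomness — initialization, data order, augmentation — is
derived from the single seed in :class:`~grotunet.config.TrainConfig`, so
two runs with the same seed produce identical loss traces.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from PIL import Image

from . import nn
from .cluster import predict_instances
from .config import ClusterConfig, TrainConfig
from .loss import discriminative_loss
from .metrics import MetricsReport
from .model import GrotUNet
from .nn import AdamW, ReduceLROnPlateau, Tensor
from .synthetic import SamplePair, augment, make_splits, read_dataset

__all__ = ["RunLog", "train", "evaluate", "predict", "write_label_png"]


@dataclass
class RunLog:
    """Per-step loss parts and per-epoch validation summaries."""

    seed: int = 0
    config: dict = field(default_factory=dict)
    steps: list[dict] = field(default_factory=list)
    epochs: list[dict] = field(default_factory=list)

    def log_step(self, **kw) -> None:
        self.steps.append(kw)

    def log_epoch(self, **kw) -> None:
        self.epochs.append(kw)

    def to_jsonl(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(json.dumps({"kind": "config", "seed": self.seed,
                                 "config": self.config}) + "\n")
            for row in self.steps:
                fh.write(json.dumps({"kind": "step", **row}) + "\n")
            for row in self.epochs:
                fh.write(json.dumps({"kind": "epoch", **row}) + "\n")


def _to_input(image: np.ndarray) -> np.ndarray:
    return np.asarray(image, dtype=np.float32).transpose(2, 0, 1) / 255.0


def _batch_loss(model: GrotUNet, images: np.ndarray, labels: list[np.ndarray],
                cfg: TrainConfig):
    emb = model(Tensor(images))                       # [B,E,H,W]
    b = emb.shape[0]
    per = [discriminative_loss(_one_hwe(emb, i), labels[i], cfg.loss)
           for i in range(b)]
    total = per[0][0]
    parts = [p.item() for p in per[0][1]]
    for t, ps in per[1:]:
        total = total + t
        for i, p in enumerate(ps):
            parts[i] += p.item()
    scale = 1.0 / b
    return total * scale, [p * scale for p in parts]


def _one_hwe(emb: Tensor, i: int) -> Tensor:
    # [B,E,H,W] -> [H,W,E] for image i, staying in the graph
    from .nn.tensor import select
    return select(emb, i).transpose(1, 2, 0)


def train(cfg: TrainConfig, dataset_dir, max_steps: int | None = None,
          sbd_every: int = 0, log_path=None) -> tuple[GrotUNet, RunLog]:
    """Fit a model on a directory of paired image/label PNGs.

    `max_steps` caps the total number of optimizer steps (useful for smoke
    runs); `sbd_every` > 0 computes validation instance metrics every that
    many epochs and uses them for lr scheduling and model selection,
    otherwise the validation loss is used.
    """
    samples = read_dataset(dataset_dir)
    if not samples:
        raise ValueError("empty dataset")
    train_idx, val_idx = make_splits(
        len(samples), (1.0 - cfg.val_fraction, cfg.val_fraction), seed=cfg.seed)
    if not train_idx:
        raise ValueError("no training samples after split")
    model = GrotUNet(cfg.model, rng=np.random.default_rng(cfg.seed))
    opt = AdamW(model.parameters(), lr=cfg.lr, weight_decay=cfg.weight_decay)
    sched = ReduceLROnPlateau(opt, factor=cfg.lr_decay_factor,
                              patience=cfg.lr_patience, mode="max")
    log = RunLog(seed=cfg.seed, config=dataclasses.asdict(cfg))
    cluster_cfg = cfg.cluster
    best_score, best_state = -np.inf, None
    step = 0
    for epoch in range(cfg.epochs):
        order = np.random.default_rng([cfg.seed, 7, epoch]).permutation(train_idx)
        model.train()
        for start in range(0, len(order), cfg.batch_size):
            idx = order[start:start + cfg.batch_size]
            ims, labs = [], []
            for i in idx:
                s = samples[i]
                if cfg.augment:
                    aug_seed = (cfg.seed * 1000003 + epoch * 9176 + int(i)) % (2**31)
                    s = augment(s, seed=aug_seed, crop_size=cfg.crop_size)
                ims.append(_to_input(s.image))
                labs.append(s.labels)
            total, parts = _batch_loss(model, np.stack(ims), labs, cfg)
            if not np.isfinite(total.item()):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} step {step}: "
                    f"total={total.item()}, parts={parts}")
            opt.zero_grad()
            total.backward()
            opt.step()
            log.log_step(epoch=epoch, step=step, total=float(total.item()),
                         var=float(parts[0]), dist=float(parts[1]),
                         reg=float(parts[2]), lr=float(opt.lr))
            step += 1
            if max_steps is not None and step >= max_steps:
                break
        # validation
        val_loss = float("nan")
        if val_idx:
            model.eval()
            with nn.no_grad():
                losses = []
                for i in val_idx:
                    s = samples[i]
                    emb = model(Tensor(_to_input(s.image)[None]))
                    t, _ = discriminative_loss(
                        emb.reshape(*emb.shape[1:]).transpose(1, 2, 0),
                        s.labels, cfg.loss)
                    losses.append(t.item())
                val_loss = float(np.mean(losses))
        row = {"epoch": epoch, "val_loss": val_loss}
        score = -val_loss if np.isfinite(val_loss) else 0.0
        if sbd_every and val_idx and (epoch + 1) % sbd_every == 0:
            report = MetricsReport()
            for i in val_idx:
                s = samples[i]
                emb = model.embed_image(s.image.astype(np.float32) / 255.0)
                pred = predict_instances(emb, cluster_cfg, seed=cfg.seed)
                report.add(f"val{i:03d}", s.labels, pred)
            row["val_sbd"] = report.means["sbd"]
            row["val_abs_dic"] = report.means["abs_dic"]
            score = report.means["sbd"]
        if score > best_score:
            best_score, best_state = score, model.state_dict()
        sched.step(score)
        log.log_epoch(**row)
        if max_steps is not None and step >= max_steps:
            break
    if best_state is not None:
        model.load_state_dict(best_state)
    if log_path is not None:
        log.to_jsonl(log_path)
    return model, log


def evaluate(model: GrotUNet, dataset_dir, cluster_cfg: ClusterConfig | None = None,
             seed: int = 0) -> MetricsReport:
    """Run instance prediction on every sample and score it against the
    ground-truth labels."""
    cluster_cfg = cluster_cfg or ClusterConfig()
    report = MetricsReport()
    for i, s in enumerate(read_dataset(dataset_dir)):
        pred = _predict_sample(model, s, cluster_cfg, seed)
        report.add(f"plant{i:03d}", s.labels, pred)
    return report


def _predict_sample(model: GrotUNet, s: SamplePair,
                    cluster_cfg: ClusterConfig, seed: int) -> np.ndarray:
    emb = model.embed_image(s.image.astype(np.float32) / 255.0)
    return predict_instances(emb, cluster_cfg, seed=seed)


def write_label_png(labels: np.ndarray, path) -> None:
    """Single-channel 16-bit PNG, 0 = background."""
    Image.fromarray(np.asarray(labels).astype(np.uint16)).save(path)


def predict(model: GrotUNet, source, out_dir,
            cluster_cfg: ClusterConfig | None = None, seed: int = 0) -> list[Path]:
    """Predict instance label maps for an image file or a directory of
    `*_rgb.png` images; writes one 16-bit label PNG per input."""
    cluster_cfg = cluster_cfg or ClusterConfig()
    source, out_dir = Path(source), Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = sorted(source.glob("*_rgb.png")) if source.is_dir() else [source]
    if not paths:
        raise ValueError(f"no *_rgb.png images under {source}")
    written = []
    for p in paths:
        image = np.asarray(Image.open(p).convert("RGB"))
        emb = model.embed_image(image.astype(np.float32) / 255.0)
        labels = predict_instances(emb, cluster_cfg, seed=seed)
        out = out_dir / (p.stem.replace("_rgb", "") + "_label.png")
        write_label_png(labels, out)
        written.append(out)
    return written
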