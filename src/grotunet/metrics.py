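"""Instance-segmentation evaluation: FBD, Best Dice, SBD, DiC.

Conventions for degenerate maps (the definitions are undefined there):
an exact all-background prediction of an all-background truth scores 100;
if exactly one side is empty of instances, FBD/SBD score 0.  These keep
"perfect prediction" at 100 everywhere.
"""

from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field

import numpy as np

__all__ = ["fbd", "best_dice", "sbd", "dic", "abs_dic", "MetricsReport",
           "score_pair", "score_maps"]


def _check_shapes(a: np.ndarray, b: np.ndarray) -> None:
    if a.shape != b.shape:
        raise ValueError(f"label maps differ in shape: {a.shape} vs {b.shape}")


def fbd(gt: np.ndarray, pred: np.ndarray) -> float:
    """Foreground-background Dice, percent."""
    gt, pred = np.asarray(gt), np.asarray(pred)
    _check_shapes(gt, pred)
    pg, pp = gt > 0, pred > 0
    denom = pg.sum() + pp.sum()
    if denom == 0:
        return 100.0
    return 100.0 * 2.0 * np.logical_and(pg, pp).sum() / denom


def _instances(labels: np.ndarray) -> list[np.ndarray]:
    return [labels == c for c in np.unique(labels) if c > 0]


def best_dice(a: np.ndarray, b: np.ndarray) -> float:
    """Directed Best Dice BD(a, b): for each instance of `a`, the best Dice
    against any instance of `b`, averaged over `a`'s instances. Percent."""
    a, b = np.asarray(a), np.asarray(b)
    _check_shapes(a, b)
    inst_a = _instances(a)
    if not inst_a:
        raise ValueError("first argument has no instances; directed Best Dice is undefined")
    inst_b = _instances(b)
    if not inst_b:
        return 0.0
    sizes_b = [int(m.sum()) for m in inst_b]
    # python-scalar arithmetic: integer set sizes in, one float op per pair
    bests = []
    for ma in inst_a:
        sa = int(ma.sum())
        bests.append(max(
            100.0 * 2 * int(np.logical_and(ma, mb).sum()) / (sa + sb)
            for mb, sb in zip(inst_b, sizes_b)))
    return sum(bests) / len(bests)


def sbd(gt: np.ndarray, pred: np.ndarray) -> float:
    """Symmetric Best Dice: min of the two directed Best Dice values."""
    gt, pred = np.asarray(gt), np.asarray(pred)
    _check_shapes(gt, pred)
    n_gt, n_pred = len(_instances(gt)), len(_instances(pred))
    if n_gt == 0 and n_pred == 0:
        return 100.0
    if n_gt == 0 or n_pred == 0:
        return 0.0
    return min(best_dice(gt, pred), best_dice(pred, gt))


def dic(gt: np.ndarray, pred: np.ndarray) -> int:
    """Difference in count: predicted minus true number of instances."""
    return len(_instances(np.asarray(pred))) - len(_instances(np.asarray(gt)))


def abs_dic(gt: np.ndarray, pred: np.ndarray) -> int:
    return abs(dic(gt, pred))


@dataclass
class MetricsReport:
    """Per-image and mean FBD/SBD/DiC/|DiC| over a dataset."""

    per_image: list[dict] = field(default_factory=list)

    def add(self, name: str, gt: np.ndarray, pred: np.ndarray) -> dict:
        row = score_pair(gt, pred)
        row["name"] = name
        self.per_image.append(row)
        return row

    @property
    def means(self) -> dict:
        if not self.per_image:
            return {k: float("nan") for k in ("fbd", "sbd", "dic", "abs_dic")}
        return {k: float(np.mean([r[k] for r in self.per_image]))
                for k in ("fbd", "sbd", "dic", "abs_dic")}

    def to_json(self, path=None) -> str:
        payload = json.dumps({"per_image": self.per_image, "means": self.means}, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(payload)
        return payload

    def to_csv(self, path) -> None:
        cols = ["name", "fbd", "sbd", "dic", "abs_dic"]
        with open(path, "w", newline="") as fh:
            writer = csv.DictWriter(fh, fieldnames=cols)
            writer.writeheader()
            for row in self.per_image:
                writer.writerow({c: row[c] for c in cols})
            writer.writerow({"name": "mean", **{k: v for k, v in self.means.items()}})


def score_pair(gt: np.ndarray, pred: np.ndarray) -> dict:
    d = dic(gt, pred)
    return {"fbd": float(fbd(gt, pred)), "sbd": float(sbd(gt, pred)),
            "dic": int(d), "abs_dic": abs(int(d))}


def score_maps(gts, preds, names=None) -> MetricsReport:
    report = MetricsReport()
    names = names or [f"image{i:03d}" for i in range(len(gts))]
    for name, g, p in zip(names, gts, preds):
        report.add(name, g, p)
    return report
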