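"""Pixel-level segmentation metrics and ablation-table arithmetic.

Vessel pixels are the positive class.  With TP/TN/FP/FN pooled over the
evaluated region,

    Acc = (TP + TN) / (TP + TN + FP + FN)
    Se  = TP / (TP + FN)
    Sp  = TN / (TN + FP)

and AUC is the area under the ROC curve of the probability map against the
binary truth (rank statistic with tie correction, via scikit-learn).  A
metric whose denominator is zero is reported as ``None``, never silently 0.

The module also computes fine-grained ablation improvements over a results
table keyed by (dataset, configuration): the mean, across datasets, of the
metric difference between two configurations.  A transcription of the
published TiM-Net coarse-grained ablation results on DRIVE / CHASEDB1 /
STARE ships with the package as the default table.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .exceptions import ValidationError

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "confusion_counts",
    "compute_metrics",
    "roc_auc",
    "dice",
    "evaluate",
    "load_ablation_table",
    "default_ablation_table",
    "ablation_improvement",
]

METRIC_COLUMNS = ("Acc", "Se", "Sp", "AUC")


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.tn + other.tn, self.fp + other.fp, self.fn + other.fn)


@dataclass
class MetricsReport:
    acc: float | None
    se: float | None
    sp: float | None
    auc: float | None = None

    def as_dict(self) -> dict:
        return {"Acc": self.acc, "Se": self.se, "Sp": self.sp, "AUC": self.auc}


def _binary(arr: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(arr)
    if not np.isin(arr, (0, 1)).all():
        raise ValidationError(f"{name} must be binary {{0,1}}")
    return arr.astype(bool)


def confusion_counts(pred: np.ndarray, gt: np.ndarray, fov: np.ndarray | None = None) -> ConfusionCounts:
    """Pixel confusion counts inside the field of view (all pixels if none)."""
    pred = _binary(pred, "prediction")
    gt = _binary(gt, "ground truth")
    if pred.shape != gt.shape:
        raise ValidationError(f"shape mismatch: prediction {pred.shape} vs ground truth {gt.shape}")
    if fov is not None:
        fov = _binary(fov, "fov")
        if fov.shape != gt.shape:
            raise ValidationError(f"shape mismatch: fov {fov.shape} vs ground truth {gt.shape}")
        pred, gt = pred[fov], gt[fov]
    return ConfusionCounts(
        tp=int((pred & gt).sum()),
        tn=int((~pred & ~gt).sum()),
        fp=int((pred & ~gt).sum()),
        fn=int((~pred & gt).sum()),
    )


def compute_metrics(c: ConfusionCounts) -> MetricsReport:
    """Acc/Se/Sp from pooled counts; undefined ratios come back as None."""
    acc = (c.tp + c.tn) / c.total if c.total else None
    se = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else None
    sp = c.tn / (c.tn + c.fp) if (c.tn + c.fp) else None
    return MetricsReport(acc=acc, se=se, sp=sp)


def roc_auc(prob: np.ndarray, gt: np.ndarray, fov: np.ndarray | None = None) -> float | None:
    """Area under the ROC curve of the probability map; None if the
    evaluated region contains a single class."""
    prob = np.asarray(prob, dtype=np.float64)
    gt = _binary(gt, "ground truth")
    if prob.shape != gt.shape:
        raise ValidationError(f"shape mismatch: probabilities {prob.shape} vs ground truth {gt.shape}")
    if fov is not None:
        fov = _binary(fov, "fov")
        prob, gt = prob[fov], gt[fov]
    if gt.all() or not gt.any():
        return None
    return float(roc_auc_score(gt.ravel(), prob.ravel()))


def dice(pred: np.ndarray, gt: np.ndarray) -> float:
    """Dice overlap 2|A∩B|/(|A|+|B|); 1.0 when both masks are empty."""
    pred = _binary(pred, "prediction")
    gt = _binary(gt, "ground truth")
    denom = pred.sum() + gt.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * (pred & gt).sum() / denom)


def evaluate(
    prob: np.ndarray,
    gt: np.ndarray,
    fov: np.ndarray | None = None,
    threshold: float = 0.5,
) -> MetricsReport:
    """Threshold a probability map and report Acc/Se/Sp/AUC."""
    pred = (np.asarray(prob, dtype=np.float64) >= threshold).astype(np.uint8)
    report = compute_metrics(confusion_counts(pred, gt, fov))
    report.auc = roc_auc(prob, gt, fov)
    return report


def load_ablation_table(path) -> pd.DataFrame:
    """Read a results CSV with columns dataset, config, Acc, Se, Sp, AUC,
    indexed by (dataset, config)."""
    df = pd.read_csv(path)
    required = {"dataset", "config", *METRIC_COLUMNS}
    missing = required - set(df.columns)
    if missing:
        raise ValidationError(f"ablation table missing columns: {sorted(missing)}")
    return df.set_index(["dataset", "config"])


def default_ablation_table() -> pd.DataFrame:
    """The packaged coarse-grained ablation results of the TiM-Net study."""
    with resources.files("timnet.resources").joinpath("coarse_ablation.csv").open() as fh:
        return load_ablation_table(fh)


def ablation_improvement(
    table: pd.DataFrame,
    metric: str,
    cfg_a: str,
    cfg_b: str,
    datasets: Sequence[str],
) -> float:
    """Mean over datasets of metric[cfg_b] − metric[cfg_a]."""
    if metric not in METRIC_COLUMNS:
        raise ValidationError(f"metric must be one of {METRIC_COLUMNS}, got {metric!r}")
    if not datasets:
        raise ValidationError("at least one dataset required")
    diffs = []
    for ds in datasets:
        for cfg in (cfg_a, cfg_b):
            if (ds, cfg) not in table.index:
                raise KeyError(f"no ablation row for dataset={ds!r}, config={cfg!r}")
        diffs.append(float(table.loc[(ds, cfg_b), metric]) - float(table.loc[(ds, cfg_a), metric]))
    return float(np.mean(diffs))
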