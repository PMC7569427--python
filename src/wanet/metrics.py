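"""Pixel-level segmentation metrics: confusion counts, the standard
ratio metrics, and ROC/AUC.

All metrics treat the vessel class as positive. Evaluation can be
restricted to a field-of-view (FOV) mask, since pixels outside the
camera aperture are trivially background and inflate accuracy and
specificity when included.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve


@dataclass
class ConfusionCounts:
    tp: int
    tn: int
    fp: int
    fn: int

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass
class MetricsReport:
    """Acc, Sens, Spec, Prec, F1 (at a threshold) and AUC.

    Acc  = (TP+TN)/(TP+FP+TN+FN)   Sens = TP/(TP+FN)
    Spec = TN/(TN+FP)              Prec = TP/(TP+FP)
    F1   = 2*Prec*Sens/(Prec+Sens)

    ``undefined`` lists metrics whose denominator was zero (reported
    as 0.0).
    """

    acc: float
    sens: float
    spec: float
    prec: float
    f1: float
    threshold: float = 0.5
    auc: float | None = None
    roc_points: np.ndarray | None = None
    undefined: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = asdict(self)
        if self.roc_points is not None:
            d["roc_points"] = np.asarray(self.roc_points).tolist()
        return d

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)


def _flatten(prob_map, truth, fov=None):
    p = np.asarray(prob_map, dtype=float)
    t = np.asarray(truth)
    if p.shape != t.shape:
        raise ValueError(f"shape mismatch: probs {p.shape} vs truth {t.shape}")
    if fov is not None:
        f = np.asarray(fov).astype(bool)
        if f.shape != p.shape:
            raise ValueError(f"shape mismatch: fov {f.shape} vs probs {p.shape}")
        return p[f], t[f]
    return p.ravel(), t.ravel()


def confusion(prob_map, truth, threshold: float = 0.5, fov=None) -> ConfusionCounts:
    """Binarize at ``threshold`` (prob >= threshold is vessel) and count."""
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    p, t = _flatten(prob_map, truth, fov)
    pred = p >= threshold
    pos = t.astype(bool)
    return ConfusionCounts(
        tp=int(np.sum(pred & pos)),
        tn=int(np.sum(~pred & ~pos)),
        fp=int(np.sum(pred & ~pos)),
        fn=int(np.sum(~pred & pos)),
    )


def _ratio(num: int, den: int, name: str, undefined: list[str]) -> float:
    if den == 0:
        undefined.append(name)
        return 0.0
    return num / den


def summarize(counts: ConfusionCounts, threshold: float = 0.5) -> MetricsReport:
    """Ratio metrics from confusion counts; 0/0 cases flagged, not raised."""
    if counts.total == 0:
        raise ValueError("no evaluated pixels")
    undefined: list[str] = []
    acc = (counts.tp + counts.tn) / counts.total
    sens = _ratio(counts.tp, counts.tp + counts.fn, "sens", undefined)
    spec = _ratio(counts.tn, counts.tn + counts.fp, "spec", undefined)
    prec = _ratio(counts.tp, counts.tp + counts.fp, "prec", undefined)
    if "sens" in undefined or "prec" in undefined or prec + sens == 0:
        undefined.append("f1")
        f1 = 0.0
    else:
        f1 = 2 * prec * sens / (prec + sens)
    return MetricsReport(acc=acc, sens=sens, spec=spec, prec=prec, f1=f1,
                         threshold=threshold, undefined=undefined)


def roc_auc(prob_map, truth, fov=None) -> tuple[np.ndarray, float]:
    """ROC by threshold sweep and AUC by the trapezoidal rule.

    The trapezoidal integral with all distinct scores as thresholds
    equals the Mann-Whitney all-pairs statistic, with the half-credit
    convention for tied scores.
    """
    p, t = _flatten(prob_map, truth, fov)
    classes = np.unique(t)
    if 1 not in classes:
        raise ValueError("truth contains no positive (vessel) pixels")
    if 0 not in classes:
        raise ValueError("truth contains no negative (background) pixels")
    fpr, tpr, _ = _sk_roc_curve(t.astype(int), p, drop_intermediate=False)
    auc = float(np.trapezoid(tpr, fpr))
    return np.column_stack([fpr, tpr]), auc


def evaluate(prob_map, truth, threshold: float = 0.5, fov=None,
             with_roc: bool = True) -> MetricsReport:
    """Full report: thresholded ratio metrics plus ROC/AUC."""
    report = summarize(confusion(prob_map, truth, threshold, fov), threshold)
    if with_roc:
        report.roc_points, report.auc = roc_auc(prob_map, truth, fov)
    return report
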