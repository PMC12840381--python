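"""Diagnostic-accuracy evaluation: confusion counts, ROC/AUC, reports.

Metrics follow the standard 2x2 definitions: accuracy = (TP+TN)/n,
sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), PPV = TP/(TP+FP),
NPV = TN/(TN+FN), Youden J = sensitivity + specificity - 1. A metric whose
denominator is zero is reported as None (undefined), never as 0. Display
rounding is half-up to one decimal in percent, with raw values retained.
"""

from __future__ import annotations

import decimal
import json
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_curve

from .errors import LVScreenError


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise LVScreenError("confusion counts must be non-negative")
        if self.total == 0:
            raise LVScreenError("confusion counts must not all be zero")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    @staticmethod
    def from_calls(labels: np.ndarray, calls: np.ndarray) -> "ConfusionCounts":
        y = np.asarray(labels).astype(int)
        c = np.asarray(calls).astype(int)
        if len(y) != len(c):
            raise LVScreenError("labels and calls have different lengths")
        return ConfusionCounts(
            tp=int(np.sum((c == 1) & (y == 1))),
            fp=int(np.sum((c == 1) & (y == 0))),
            fn=int(np.sum((c == 0) & (y == 1))),
            tn=int(np.sum((c == 0) & (y == 0))))


def _ratio(num: int, den: int) -> float | None:
    return num / den if den > 0 else None


def round_percent(x: float | None, decimals: int = 1) -> float | None:
    """Half-up rounding of a rate to percent, as printed in reports."""
    if x is None:
        return None
    q = decimal.Decimal(10) ** -decimals
    return float(decimal.Decimal(str(100.0 * x)).quantize(
        q, rounding=decimal.ROUND_HALF_UP))


@dataclass(frozen=True)
class DiagnosticMetrics:
    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    youden_j: float | None
    flagged: int
    flagged_fraction: float

    DEFINITIONS = {
        "accuracy": "(TP+TN)/total",
        "sensitivity": "TP/(TP+FN)",
        "specificity": "TN/(TN+FP)",
        "ppv": "TP/(TP+FP)",
        "npv": "TN/(TN+FN)",
        "youden_j": "sensitivity + specificity - 1",
        "flagged": "TP+FP (positive calls)",
    }

    def as_percent(self) -> dict:
        """Display form: percentages rounded half-up to one decimal."""
        return {
            "accuracy_pct": round_percent(self.accuracy),
            "sensitivity_pct": round_percent(self.sensitivity),
            "specificity_pct": round_percent(self.specificity),
            "ppv_pct": round_percent(self.ppv),
            "npv_pct": round_percent(self.npv),
            "flagged_pct": round_percent(self.flagged_fraction),
        }


def metrics_from_confusion(counts: ConfusionCounts) -> DiagnosticMetrics:
    """Derive the diagnostic-accuracy measures from 2x2 counts."""
    sens = _ratio(counts.tp, counts.tp + counts.fn)
    spec = _ratio(counts.tn, counts.tn + counts.fp)
    return DiagnosticMetrics(
        accuracy=_ratio(counts.tp + counts.tn, counts.total),
        sensitivity=sens,
        specificity=spec,
        ppv=_ratio(counts.tp, counts.tp + counts.fp),
        npv=_ratio(counts.tn, counts.tn + counts.fn),
        youden_j=(sens + spec - 1.0) if None not in (sens, spec) else None,
        flagged=counts.tp + counts.fp,
        flagged_fraction=(counts.tp + counts.fp) / counts.total)


@dataclass
class ROCCurve:
    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float
    ci_low: float | None = None
    ci_high: float | None = None
    ci_level: float = 0.95
    n_boot: int = 0
    seed: int | None = None


def roc_auc(labels: np.ndarray, scores: np.ndarray, n_boot: int = 2000,
            seed: int = 0, ci_level: float = 0.95) -> ROCCurve:
    """ROC curve with trapezoidal AUC and a stratified bootstrap CI."""
    y = np.asarray(labels).astype(int)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise LVScreenError("ROC needs both classes")
    fpr, tpr, thr = roc_curve(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    lo = hi = None
    if n_boot > 0:
        rng = np.random.default_rng(seed)
        pos = np.flatnonzero(y == 1)
        neg = np.flatnonzero(y == 0)
        aucs = np.empty(n_boot)
        for b in range(n_boot):
            ip = rng.choice(pos, size=len(pos), replace=True)
            ineg = rng.choice(neg, size=len(neg), replace=True)
            yb = np.concatenate([y[ip], y[ineg]])
            sb = np.concatenate([s[ip], s[ineg]])
            f, t, _ = roc_curve(yb, sb)
            aucs[b] = np.trapezoid(t, f)
        alpha = (1.0 - ci_level) / 2.0
        lo = float(np.percentile(aucs, 100 * alpha))
        hi = float(np.percentile(aucs, 100 * (1 - alpha)))
    return ROCCurve(thresholds=thr, fpr=fpr, tpr=tpr, auc=auc,
                    ci_low=lo, ci_high=hi, ci_level=ci_level,
                    n_boot=n_boot, seed=seed)


def external_style_report(labels: np.ndarray, calls: np.ndarray,
                          endpoint_id: str = "below_normal",
                          extra: dict | None = None) -> dict:
    """JSON-serialisable screening report from binary calls and labels.

    Contains the confusion counts, raw and percent-rounded diagnostic
    metrics, the flagged fraction, the endpoint rule, and any provenance
    passed via ``extra``. Deterministic for identical inputs.
    """
    counts = ConfusionCounts.from_calls(labels, calls)
    m = metrics_from_confusion(counts)
    report = {
        "endpoint": endpoint_id,
        "n": counts.total,
        "confusion": {"TP": counts.tp, "FP": counts.fp,
                      "FN": counts.fn, "TN": counts.tn},
        "metrics_raw": {
            "accuracy": m.accuracy, "sensitivity": m.sensitivity,
            "specificity": m.specificity, "ppv": m.ppv, "npv": m.npv,
            "youden_j": m.youden_j,
            "flagged": m.flagged, "flagged_fraction": m.flagged_fraction,
        },
        "metrics_percent": m.as_percent(),
        "definitions": DiagnosticMetrics.DEFINITIONS,
    }
    if extra:
        report["provenance"] = extra
    return report


def report_to_json(report: dict) -> str:
    return json.dumps(report, indent=2, sort_keys=True)
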