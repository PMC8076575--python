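"""Confusion-matrix construction and the binary cry-detection metric suite.

Metrics: accuracy, Matthews correlation coefficient (MCC), sensitivity,
specificity, positive and negative predictive value. Any metric with a
zero denominator is defined as 0 and flagged rather than returned as NaN,
so per-subject evaluation of single-class stretches never crashes a
pipeline. Counts may be real-valued so that pooled metrics can be
reconstructed from published rates and class totals.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: float
    fp: float
    tn: float
    fn: float

    def __post_init__(self) -> None:
        for name in ("tp", "fp", "tn", "fn"):
            v = getattr(self, name)
            if not math.isfinite(v) or v < 0:
                raise ValueError(f"confusion count {name}={v} must be finite and >= 0")

    @property
    def total(self) -> float:
        return self.tp + self.fp + self.tn + self.fn

    def swapped(self) -> "ConfusionMatrix":
        """The confusion matrix with positive and negative classes exchanged."""
        return ConfusionMatrix(tp=self.tn, fp=self.fn, tn=self.tp, fn=self.fp)


@dataclass(frozen=True)
class MetricSet:
    accuracy: float
    mcc: float
    sensitivity: float
    specificity: float
    ppv: float
    npv: float
    #: names of metrics whose denominator was zero (value reported as 0)
    flags: tuple[str, ...] = field(default_factory=tuple)

    def as_dict(self) -> dict[str, float]:
        return {
            "accuracy": self.accuracy,
            "mcc": self.mcc,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "ppv": self.ppv,
            "npv": self.npv,
        }


def confusion(truth, predicted) -> ConfusionMatrix:
    """Count agreement between two aligned binary label series."""
    t = np.asarray(getattr(truth, "labels", truth), dtype=np.int64)
    p = np.asarray(getattr(predicted, "labels", predicted), dtype=np.int64)
    if t.shape != p.shape:
        raise ValueError(f"label series lengths differ: {t.size} vs {p.size}")
    for arr, name in ((t, "truth"), (p, "predicted")):
        if arr.size and not np.isin(arr, (0, 1)).all():
            raise ValueError(f"{name} labels must be binary (0/1)")
    tp = int(np.sum((t == 1) & (p == 1)))
    fp = int(np.sum((t == 0) & (p == 1)))
    tn = int(np.sum((t == 0) & (p == 0)))
    fn = int(np.sum((t == 1) & (p == 0)))
    return ConfusionMatrix(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num: float, den: float, name: str, flags: list[str]) -> float:
    if den == 0:
        flags.append(name)
        return 0.0
    return num / den


def compute_metrics(cm: ConfusionMatrix) -> MetricSet:
    """Full metric suite from a confusion matrix.

    MCC = (tp*tn - fp*fn) / sqrt((tp+fp)(tp+fn)(tn+fp)(tn+fn)); when any
    marginal is zero the coefficient is reported as 0 and flagged.
    """
    if cm.total <= 0:
        raise ValueError("cannot compute metrics on an empty confusion matrix")
    flags: list[str] = []
    accuracy = (cm.tp + cm.tn) / cm.total
    sensitivity = _ratio(cm.tp, cm.tp + cm.fn, "sensitivity", flags)
    specificity = _ratio(cm.tn, cm.tn + cm.fp, "specificity", flags)
    ppv = _ratio(cm.tp, cm.tp + cm.fp, "ppv", flags)
    npv = _ratio(cm.tn, cm.tn + cm.fn, "npv", flags)
    denom = math.sqrt(
        (cm.tp + cm.fp) * (cm.tp + cm.fn) * (cm.tn + cm.fp) * (cm.tn + cm.fn)
    )
    if denom == 0:
        flags.append("mcc")
        mcc = 0.0
    else:
        mcc = (cm.tp * cm.tn - cm.fp * cm.fn) / denom
    return MetricSet(
        accuracy=accuracy,
        mcc=mcc,
        sensitivity=sensitivity,
        specificity=specificity,
        ppv=ppv,
        npv=npv,
        flags=tuple(flags),
    )


def metrics_from_rates(
    sensitivity: float, specificity: float, n_pos: float, n_neg: float
) -> MetricSet:
    """Reconstruct pooled metrics from published rates and class totals.

    Builds the real-valued confusion matrix tp = sensitivity * n_pos,
    tn = specificity * n_neg (fn/fp the complements) and delegates to
    :func:`compute_metrics`; useful for checking published tables.
    """
    for name, r in (("sensitivity", sensitivity), ("specificity", specificity)):
        if not 0.0 <= r <= 1.0:
            raise ValueError(f"{name}={r} outside [0, 1]")
    if n_pos <= 0 or n_neg <= 0:
        raise ValueError("class totals must be positive")
    tp = sensitivity * n_pos
    tn = specificity * n_neg
    return compute_metrics(
        ConfusionMatrix(tp=tp, fn=n_pos - tp, tn=tn, fp=n_neg - tn)
    )


def format_percent(x: float, decimals: int = 1) -> float:
    """Express a rate as a percentage, rounding half away from zero."""
    scale = 10**decimals
    v = x * 100.0 * scale
    return math.copysign(math.floor(abs(v) + 0.5), v) / scale
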