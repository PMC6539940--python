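"""Binary-classification evaluation: ACC, PRE, REC, MCC and Cohen's κ.

The convention throughout is +1 = active compound, −1 = inactive. Ratios
with a zero denominator are reported as NaN together with a flag, rather
than silently coerced to 0.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np


@dataclass(frozen=True)
class ConfusionCounts:
    """TP/TN/FP/FN counts with +1 = active taken as the positive class."""

    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self):
        for name in ("TP", "TN", "FP", "FN"):
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"{name} must be a non-negative integer")
        if self.total == 0:
            raise ValueError("confusion counts sum to zero")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricsReport:
    """The five evaluation measures plus the κ agreement components.

    ACC, PRE, REC ∈ [0, 1]; MCC, kappa ∈ [−1, 1]; PA is the observed and PE
    the chance level of agreement entering κ = (PA − PE)/(1 − PE).
    ``undefined`` flags any measure whose denominator was zero (its value
    is NaN).
    """

    ACC: float
    PRE: float
    REC: float
    MCC: float
    kappa: float
    PA: float
    PE: float
    undefined: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["undefined"] = list(self.undefined)
        return d


def confusion_counts(y_true, y_pred) -> ConfusionCounts:
    """Exact integer confusion counts for ±1 label vectors."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape or y_true.size == 0:
        raise ValueError("label vectors must be non-empty and equal-length")
    for arr, name in ((y_true, "y_true"), (y_pred, "y_pred")):
        if not np.isin(arr, (-1, 1)).all():
            raise ValueError(f"{name} must contain only -1/+1 labels")
    return ConfusionCounts(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        TN=int(np.sum((y_true == -1) & (y_pred == -1))),
        FP=int(np.sum((y_true == -1) & (y_pred == 1))),
        FN=int(np.sum((y_true == 1) & (y_pred == -1))),
    )


def _ratio(num: float, den: float, name: str, undefined: list) -> float:
    if den == 0:
        undefined.append(name)
        return float("nan")
    return num / den


def evaluate(c: ConfusionCounts) -> MetricsReport:
    """Compute ACC, PRE, REC, MCC and Cohen's κ from confusion counts.

        ACC = (TP+TN)/n          PRE = TP/(TP+FP)       REC = TP/(TP+FN)
        MCC = (TP·TN − FP·FN)/√((TP+FP)(TP+FN)(TN+FP)(TN+FN))
        κ   = (PA − PE)/(1 − PE),  PA = (TP+TN)/n,
        PE  = [(TP+FP)(TP+FN) + (FN+TN)(FP+TN)] / n²
    """
    TP, TN, FP, FN = c.TP, c.TN, c.FP, c.FN
    n = c.total
    undefined: list[str] = []
    acc = (TP + TN) / n
    pre = _ratio(TP, TP + FP, "PRE", undefined)
    rec = _ratio(TP, TP + FN, "REC", undefined)
    mcc_den = np.sqrt(float(TP + FP) * (TP + FN) * (TN + FP) * (TN + FN))
    mcc = _ratio(TP * TN - FP * FN, mcc_den, "MCC", undefined)
    pa = acc
    pe = ((TP + FP) * (TP + FN) + (FN + TN) * (FP + TN)) / n**2
    kappa = _ratio(pa - pe, 1 - pe, "kappa", undefined)
    return MetricsReport(ACC=acc, PRE=pre, REC=rec, MCC=float(mcc),
                         kappa=kappa, PA=pa, PE=pe,
                         undefined=tuple(undefined))


def evaluate_predictions(y_true, y_pred) -> MetricsReport:
    """Convenience wrapper: counts + metrics in one call."""
    return evaluate(confusion_counts(y_true, y_pred))
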