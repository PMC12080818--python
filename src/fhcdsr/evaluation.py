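"""Threshold-free evaluation of change-score maps: ROC curves and AUC.

A pixel is predicted changed when its score is at least the current
threshold; sweeping all distinct score values (ties grouped at one
threshold) traces the ROC curve from (0, 0) to (1, 1).  The trapezoidal
area under that curve equals the Mann-Whitney statistic
``P(score_pos > score_neg) + 0.5 * P(tie)``, so a constant map scores
exactly 0.5 and any strictly increasing transform of the scores leaves
the curve unchanged.
"""

from __future__ import annotations

import io
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from sklearn.metrics import roc_curve as _sk_roc_curve

from .cube import ChangeMask
from .detector import ChangeScoreMap

__all__ = ["AucReport", "RocCurve", "auc_report", "roc"]


@dataclass(frozen=True)
class RocCurve:
    """ROC operating points (thresholds descending) and trapezoidal AUC."""

    thresholds: np.ndarray
    fpr: np.ndarray
    tpr: np.ndarray
    auc: float

    @property
    def auc_percent(self) -> float:
        return 100.0 * self.auc

    def to_csv(self) -> str:
        buf = io.StringIO()
        buf.write("threshold,fpr,tpr\n")
        for t, f, p in zip(self.thresholds, self.fpr, self.tpr):
            buf.write(f"{t!r},{f!r},{p!r}\n")
        buf.write(f"AUC,{self.auc!r},\n")
        return buf.getvalue()


def roc(scores: ChangeScoreMap | np.ndarray, truth: ChangeMask | np.ndarray) -> RocCurve:
    """ROC curve and AUC of a score map against a binary truth mask.

    Raises if truth holds a single class (AUC undefined).
    """
    score_arr = scores.scores if isinstance(scores, ChangeScoreMap) else np.asarray(scores)
    truth_arr = truth.labels if isinstance(truth, ChangeMask) else np.asarray(truth)
    if score_arr.shape != truth_arr.shape:
        raise ValueError(
            f"score map shape {score_arr.shape} does not match truth shape {truth_arr.shape}"
        )
    y = (truth_arr != 0).ravel().astype(np.int8)
    s = score_arr.ravel().astype(np.float64)
    if y.min() == y.max():
        raise ValueError(
            "undefined AUC: ground truth contains a single class "
            "(need at least one changed and one unchanged pixel)"
        )
    fpr, tpr, thresholds = _sk_roc_curve(y, s)
    auc = float(np.trapezoid(tpr, fpr))
    return RocCurve(thresholds=thresholds, fpr=fpr, tpr=tpr, auc=auc)


@dataclass(frozen=True)
class AucReport:
    """Per-method AUC table; all methods tied at the best value are flagged."""

    methods: tuple[str, ...]
    auc_values: tuple[float, ...]

    @property
    def best(self) -> tuple[str, ...]:
        top = max(self.auc_values)
        return tuple(m for m, a in zip(self.methods, self.auc_values) if a == top)

    def to_text(self) -> str:
        best = set(self.best)
        width = max(len(m) for m in self.methods)
        lines = [f"{'method':<{width}}  AUC (%)"]
        for m, a in zip(self.methods, self.auc_values):
            flag = " *best*" if m in best else ""
            lines.append(f"{m:<{width}}  {100 * a:.3f}{flag}")
        return "\n".join(lines) + "\n"

    def to_csv(self) -> str:
        best = set(self.best)
        rows = ["method,auc_percent,best"]
        for m, a in zip(self.methods, self.auc_values):
            rows.append(f"{m},{100 * a:.3f},{int(m in best)}")
        return "\n".join(rows) + "\n"


def auc_report(curves: Sequence[tuple[str, RocCurve]]) -> AucReport:
    """Tabulate AUC (as percentages) for a set of named ROC curves."""
    if not curves:
        raise ValueError("auc_report needs at least one curve")
    methods = tuple(name for name, _ in curves)
    aucs = tuple(float(curve.auc) for _, curve in curves)
    return AucReport(methods=methods, auc_values=aucs)
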