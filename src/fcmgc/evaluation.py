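"""Three-class confusion matrices and performance metrics.

Conventions: matrix rows are the predicted class, columns the actual class,
both in the fixed order (high, medium, low). Overall accuracy is
100 * trace / total; per-class recall divides the diagonal cell by its
column sum, per-class precision by its row sum (one-vs-rest). MAE and RMSE
compare real and predicted output-concept value matrices:

    MAE  = (1/N) * sum_L sum_J |OC_real - OC_pred|
    RMSE = sqrt( (1/(N*C)) * sum_L sum_J (OC_real - OC_pred)^2 )

Reported percentages are *truncated* (floored) at the configured number of
decimals rather than rounded; internal values keep full precision. A zero
row or column sum yields NaN (undefined metric) instead of an error.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .fcm_core import InputError

RISK_ORDER = ("high", "medium", "low")

__all__ = [
    "RISK_ORDER",
    "ConfusionMatrix3",
    "MetricsReport",
    "truncate",
    "confusion",
    "accuracy",
    "recall",
    "precision",
    "mae",
    "rmse",
    "metrics_report",
]


def truncate(value: float, dp: int = 2) -> float:
    """Floor ``value`` at ``dp`` decimals (93.877 -> 93.87, never 93.88).

    A 1e-9 guard absorbs binary floating-point noise just below an exact
    decimal (e.g. 29.999999999999996 for 30).
    """
    scale = 10**dp
    return math.floor(value * scale + 1e-9) / scale


@dataclass(frozen=True)
class ConfusionMatrix3:
    """3x3 counts; rows = predicted, columns = actual (high, medium, low)."""

    counts: np.ndarray

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        object.__setattr__(self, "counts", c)
        if c.shape != (3, 3):
            raise InputError("confusion matrix must be 3x3")
        if np.any(c < 0):
            raise InputError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def _class_index(self, cls: str) -> int:
        try:
            return RISK_ORDER.index(cls)
        except ValueError:
            raise InputError(f"unknown risk class {cls!r}") from None


def confusion(
    predicted: Sequence[str], actual: Sequence[str]
) -> ConfusionMatrix3:
    """Cross-tabulate predicted vs actual risk classes."""
    if len(predicted) != len(actual):
        raise InputError("predicted and actual must have the same length")
    if len(predicted) == 0:
        raise InputError("cannot build a confusion matrix from no records")
    idx = {cls: k for k, cls in enumerate(RISK_ORDER)}
    counts = np.zeros((3, 3), dtype=int)
    for p, a in zip(predicted, actual):
        if p not in idx or a not in idx:
            raise InputError(f"unknown risk class in ({p!r}, {a!r})")
        counts[idx[p], idx[a]] += 1
    return ConfusionMatrix3(counts)


def accuracy(m: ConfusionMatrix3, dp: int | None = 2) -> float:
    """Overall accuracy in percent, truncated to ``dp`` decimals (None = full)."""
    if m.total == 0:
        raise InputError("empty confusion matrix")
    value = 100.0 * np.trace(m.counts) / m.total
    return value if dp is None else truncate(value, dp)


def recall(m: ConfusionMatrix3, cls: str, dp: int | None = 2) -> float:
    """Per-class recall in percent: diagonal / actual (column) count."""
    k = m._class_index(cls)
    denom = m.counts[:, k].sum()
    if denom == 0:
        return math.nan
    value = 100.0 * m.counts[k, k] / denom
    return value if dp is None else truncate(value, dp)


def precision(m: ConfusionMatrix3, cls: str, dp: int | None = 2) -> float:
    """Per-class precision in percent: diagonal / predicted (row) count."""
    k = m._class_index(cls)
    denom = m.counts[k, :].sum()
    if denom == 0:
        return math.nan
    value = 100.0 * m.counts[k, k] / denom
    return value if dp is None else truncate(value, dp)


def _check_shapes(real: np.ndarray, pred: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    real = np.atleast_2d(np.asarray(real, dtype=float))
    pred = np.atleast_2d(np.asarray(pred, dtype=float))
    if real.shape != pred.shape:
        raise InputError(
            f"shape mismatch: real {real.shape} vs predicted {pred.shape}"
        )
    return real, pred


def mae(real_ocs: np.ndarray, predicted_ocs: np.ndarray) -> float:
    """Mean absolute error of output-concept values, averaged over records."""
    real, pred = _check_shapes(real_ocs, predicted_ocs)
    return float(np.sum(np.abs(real - pred)) / real.shape[0])


def rmse(real_ocs: np.ndarray, predicted_ocs: np.ndarray) -> float:
    """Root-mean-square error over all record/output cells."""
    real, pred = _check_shapes(real_ocs, predicted_ocs)
    return float(np.sqrt(np.sum((real - pred) ** 2) / real.size))


@dataclass(frozen=True)
class MetricsReport:
    """Full metric suite for one classifier on one test split."""

    matrix: ConfusionMatrix3
    accuracy: float
    recall: dict[str, float]
    precision: dict[str, float]
    mae: float | None = None
    rmse: float | None = None

    def to_dict(self) -> dict:
        return {
            "confusion": self.matrix.counts.tolist(),
            "class_order": list(RISK_ORDER),
            "accuracy": self.accuracy,
            "recall": self.recall,
            "precision": self.precision,
            "mae": self.mae,
            "rmse": self.rmse,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), indent=2, **kwargs)

    def format_table(self) -> str:
        """Human-readable table: one row per class plus overall lines."""
        lines = [
            f"{'':>8} {'high':>6} {'medium':>6} {'low':>6} "
            f"{'recall':>8} {'precision':>10}"
        ]
        for k, cls in enumerate(RISK_ORDER):
            c = self.matrix.counts[k]
            lines.append(
                f"{cls:>8} {c[0]:>6} {c[1]:>6} {c[2]:>6} "
                f"{self.recall[cls]:>8.2f} {self.precision[cls]:>10.2f}"
            )
        lines.append(f"overall accuracy: {self.accuracy:.2f}%")
        if self.mae is not None:
            lines.append(f"MAE: {self.mae:.4f}  RMSE: {self.rmse:.4f}")
        return "\n".join(lines)


def metrics_report(
    m: ConfusionMatrix3,
    real_ocs: np.ndarray | None = None,
    predicted_ocs: np.ndarray | None = None,
    dp: int = 2,
) -> MetricsReport:
    """Assemble the metric suite from a confusion matrix (and OC values)."""
    return MetricsReport(
        matrix=m,
        accuracy=accuracy(m, dp),
        recall={cls: recall(m, cls, dp) for cls in RISK_ORDER},
        precision={cls: precision(m, cls, dp) for cls in RISK_ORDER},
        mae=None if real_ocs is None else mae(real_ocs, predicted_ocs),
        rmse=None if real_ocs is None else rmse(real_ocs, predicted_ocs),
    )
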