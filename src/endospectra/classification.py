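"""Classification-report arithmetic and the two-factor ANOVA.

Everything here operates on confusion matrices or on already-computed
per-class metric columns: per-class precision/recall/F1, overall
accuracy, macro and support-weighted aggregation, the exact identity
``accuracy = sum_c n_c * recall_c / N`` used to audit printed report
tables, and a classical two-factor analysis of variance without
replication for comparing imaging modalities across models/metrics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix",
    "MetricsTable",
    "AnovaResult",
    "metrics_from_confusion",
    "weighted_accuracy_from_recalls",
    "aggregate",
    "anova_two_factor_no_rep",
    "round_half_away",
]


def round_half_away(x: float, decimals: int = 0) -> float:
    """Round half away from zero (the convention of printed report
    tables), unlike banker's rounding."""
    factor = 10.0**decimals
    return float(np.sign(x) * np.floor(abs(x) * factor + 0.5) / factor)


@dataclass
class ConfusionMatrix:
    """Square count table; rows = true class, columns = predicted."""

    classes: list[str]
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        n = len(self.classes)
        if n == 0:
            raise ValueError("confusion matrix needs at least one class")
        if self.counts.shape != (n, n):
            raise ValueError(f"counts must be {n}x{n}")
        if np.any(self.counts < 0):
            raise ValueError("confusion counts must be nonnegative")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.allclose(self.counts, np.round(self.counts)):
                raise ValueError("confusion counts must be integers")
            self.counts = np.round(self.counts).astype(np.int64)

    @property
    def supports(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=self.classes, columns=self.classes)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "ConfusionMatrix":
        return cls(classes=[str(c) for c in frame.index], counts=frame.to_numpy())


@dataclass
class MetricsTable:
    classes: list[str]
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    supports: np.ndarray
    accuracy: float

    def to_frame(self) -> pd.DataFrame:
        """Report layout: Class, Precision, Recall, F1, Accuracy."""
        frame = pd.DataFrame(
            {
                "Class": self.classes,
                "Precision": self.precision,
                "Recall": self.recall,
                "F1": self.f1,
                "Support": self.supports,
            }
        )
        frame["Accuracy"] = self.accuracy
        return frame


@dataclass
class AnovaResult:
    ss_rows: float
    ss_cols: float
    ss_residual: float
    ss_total: float
    df_rows: int
    df_cols: int
    df_residual: int
    f_rows: float
    f_cols: float
    p_rows: float
    p_cols: float
    col_means: np.ndarray = field(default_factory=lambda: np.array([]))
    col_sds: np.ndarray = field(default_factory=lambda: np.array([]))
    row_labels: list = field(default_factory=list)
    col_labels: list = field(default_factory=list)


def metrics_from_confusion(cm: ConfusionMatrix) -> MetricsTable:
    """Per-class precision/recall/F1 and overall accuracy.

    A class never predicted has precision 0 (logged); F1 is the harmonic
    mean of its row's precision and recall, 0 when both vanish.
    """
    counts = cm.counts.astype(float)
    if counts.sum() == 0:
        raise ValueError("confusion matrix is empty")
    tp = np.diag(counts)
    col = counts.sum(axis=0)
    row = counts.sum(axis=1)
    zero_cols = col == 0
    if np.any(zero_cols):
        logger.warning(
            "classes never predicted, precision set to 0: %s",
            [c for c, z in zip(cm.classes, zero_cols) if z],
        )
    precision = np.divide(tp, col, out=np.zeros_like(tp), where=col > 0)
    recall = np.divide(tp, row, out=np.zeros_like(tp), where=row > 0)
    denom = precision + recall
    f1 = np.divide(2 * precision * recall, denom, out=np.zeros_like(tp), where=denom > 0)
    return MetricsTable(
        classes=list(cm.classes),
        precision=precision,
        recall=recall,
        f1=f1,
        supports=cm.supports,
        accuracy=float(tp.sum() / counts.sum()),
    )


def weighted_accuracy_from_recalls(recalls, supports) -> float:
    """Exact identity accuracy = sum_c n_c * recall_c / N.

    Because TP_c = n_c * recall_c, the support-weighted mean of the
    per-class recalls equals the overall accuracy of any confusion
    matrix consistent with those columns — handy for auditing printed
    report tables that show recalls and class sizes but no matrix.
    """
    recalls = np.asarray(recalls, dtype=float)
    supports = np.asarray(supports, dtype=float)
    if recalls.shape != supports.shape:
        raise ValueError("recalls and supports must have equal length")
    if np.any(supports <= 0):
        raise ValueError("supports must be positive")
    return float(np.sum(supports * recalls) / supports.sum())


def aggregate(table: MetricsTable, mode: str = "macro") -> tuple[float, float, float]:
    """Summarize per-class metrics: ``macro`` (unweighted class mean) or
    ``weighted`` (support-weighted mean).  Returns (precision, recall, F1)."""
    if mode == "macro":
        w = np.ones_like(table.supports, dtype=float)
    elif mode == "weighted":
        w = table.supports.astype(float)
    else:
        raise ValueError(f"unknown aggregation mode {mode!r}")
    w = w / w.sum()
    return (
        float(w @ table.precision),
        float(w @ table.recall),
        float(w @ table.f1),
    )


def anova_two_factor_no_rep(values: np.ndarray, row_labels=None, col_labels=None) -> AnovaResult:
    """Two-factor ANOVA without replication on a complete r x c table.

    Classical decomposition: SS_total = SS_rows + SS_cols + SS_residual
    with df (r-1), (c-1) and (r-1)(c-1); each factor's F uses the
    residual mean square, with upper-tail p-values from the F
    distribution.  Per-column mean and sample standard deviation are
    reported alongside (the "modality mean ± sd" summary).
    """
    values = np.asarray(values, dtype=float)
    if values.ndim != 2:
        raise ValueError("values must be a 2-D table")
    r, c = values.shape
    if r < 2 or c < 2:
        raise ValueError("need at least a 2x2 table")
    if not np.all(np.isfinite(values)):
        raise ValueError("table has missing or non-finite cells; "
                         "no-replication ANOVA needs a complete table")

    grand = values.mean()
    row_means = values.mean(axis=1)
    col_means = values.mean(axis=0)
    ss_rows = c * float(np.sum((row_means - grand) ** 2))
    ss_cols = r * float(np.sum((col_means - grand) ** 2))
    ss_total = float(np.sum((values - grand) ** 2))
    ss_res = ss_total - ss_rows - ss_cols

    df_rows, df_cols = r - 1, c - 1
    df_res = df_rows * df_cols
    ms_res = ss_res / df_res
    if ms_res <= 0:
        f_rows = np.inf if ss_rows > 0 else 0.0
        f_cols = np.inf if ss_cols > 0 else 0.0
    else:
        f_rows = (ss_rows / df_rows) / ms_res
        f_cols = (ss_cols / df_cols) / ms_res
    p_rows = float(stats.f.sf(f_rows, df_rows, df_res))
    p_cols = float(stats.f.sf(f_cols, df_cols, df_res))

    return AnovaResult(
        ss_rows=ss_rows, ss_cols=ss_cols, ss_residual=ss_res, ss_total=ss_total,
        df_rows=df_rows, df_cols=df_cols, df_residual=df_res,
        f_rows=float(f_rows), f_cols=float(f_cols), p_rows=p_rows, p_cols=p_cols,
        col_means=col_means, col_sds=values.std(axis=0, ddof=1),
        row_labels=list(row_labels) if row_labels is not None else [],
        col_labels=list(col_labels) if col_labels is not None else [],
    )
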