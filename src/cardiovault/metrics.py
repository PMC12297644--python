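"""Classification and security evaluation metrics.

Standard confusion-matrix rates plus two fidelity dialects kept from the
source framework's printed formulas: a "paper" recall TP/(TN+TP) alongside
the standard TP/(TP+FN), and a security ratio hacked/original reported
together with its complement (protection = 1 - ratio), which is the
quantity the "98% security" framing actually refers to.

All rate functions are total: a zero denominator returns 0.0 with a logged
warning rather than raising.
"""

from __future__ import annotations

import logging
import time
from contextlib import contextmanager
from dataclasses import dataclass
from typing import Callable, Iterator, List, NamedTuple, Tuple

import numpy as np

__all__ = [
    "ConfusionCounts",
    "confusion_from_labels",
    "precision",
    "accuracy",
    "recall",
    "f1",
    "SecurityReport",
    "security_ratio",
    "TimingRecord",
    "time_phase",
    "threshold_sweep",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def as_table(self) -> str:
        """Printable 2x2 confusion table (rows: truth, cols: prediction)."""
        return (
            "              pred 0   pred 1\n"
            f"  true 0    {self.tn:7d}  {self.fp:7d}\n"
            f"  true 1    {self.fn:7d}  {self.tp:7d}"
        )


def confusion_from_labels(y_true, y_pred) -> ConfusionCounts:
    yt = np.asarray(y_true, dtype=int)
    yp = np.asarray(y_pred, dtype=int)
    return ConfusionCounts(
        tp=int(((yt == 1) & (yp == 1)).sum()),
        fp=int(((yt == 0) & (yp == 1)).sum()),
        tn=int(((yt == 0) & (yp == 0)).sum()),
        fn=int(((yt == 1) & (yp == 0)).sum()),
    )


def _ratio(num: float, den: float, name: str) -> float:
    if den == 0:
        logger.warning("%s: zero denominator, returning 0.0", name)
        return 0.0
    return num / den


def precision(c: ConfusionCounts) -> float:
    """TP / (FP + TP)."""
    return _ratio(c.tp, c.fp + c.tp, "precision")


def accuracy(c: ConfusionCounts) -> float:
    """(TP + TN) / total."""
    return _ratio(c.tp + c.tn, c.total, "accuracy")


def recall(c: ConfusionCounts, dialect: str = "standard") -> float:
    """Standard dialect TP/(TP+FN); "paper" dialect keeps the printed
    TP/(TN+TP) for fidelity testing."""
    if dialect == "standard":
        return _ratio(c.tp, c.tp + c.fn, "recall")
    if dialect == "paper":
        return _ratio(c.tp, c.tn + c.tp, "recall(paper)")
    raise ValueError(f"unknown recall dialect {dialect!r}")


def f1(c: ConfusionCounts, dialect: str = "standard") -> float:
    """Harmonic mean 2PR/(P+R), with R in the chosen recall dialect."""
    p = precision(c)
    r = recall(c, dialect)
    return _ratio(2.0 * p * r, p + r, "f1")


class SecurityReport(NamedTuple):
    ratio: float        # hacked / original
    protection: float   # 1 - ratio


def security_ratio(hacked: float, original: float) -> SecurityReport:
    """Fraction of records compromised, and its complement.

    The printed formula SA = hacked/original would call a 98%-secure system
    one with 98% of its data hacked; the protection complement is therefore
    reported alongside."""
    if hacked < 0 or original < 0:
        raise ValueError("counts must be non-negative")
    ratio = _ratio(hacked, original, "security_ratio")
    return SecurityReport(ratio=ratio, protection=1.0 - ratio)


@dataclass
class TimingRecord:
    kind: str  # encryption | key_generation | decryption
    start: float
    end: float

    @property
    def duration(self) -> float:
        return self.end - self.start


def time_phase(kind: str, thunk: Callable[[], object]) -> Tuple[object, TimingRecord]:
    """Run ``thunk`` under a monotonic clock.  Exceptions propagate and the
    record is discarded."""
    start = time.monotonic()
    result = thunk()
    end = time.monotonic()
    return result, TimingRecord(kind=kind, start=start, end=end)


def threshold_sweep(
    y_true, scores, thresholds=None
) -> List[Tuple[float, float, float]]:
    """Qualitative ROC-style sweep: (threshold, TPR, FPR) triples."""
    yt = np.asarray(y_true, dtype=int)
    s = np.asarray(scores, dtype=float)
    if thresholds is None:
        thresholds = np.linspace(0.0, 1.0, 21)
    out = []
    for t in thresholds:
        pred = (s >= t).astype(int)
        c = confusion_from_labels(yt, pred)
        tpr = _ratio(c.tp, c.tp + c.fn, "tpr")
        fpr = _ratio(c.fp, c.fp + c.tn, "fpr")
        out.append((float(t), tpr, fpr))
    return out
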