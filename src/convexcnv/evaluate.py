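"""Exon-level scoring of copy-number calls against a known truth.

An exon is a positive when its true copy number differs from neutral (2).
By default a true positive requires only the *direction* of the change to
match (a loss called as any loss, a gain as any gain); ``strict_copy``
additionally requires the exact copy number.  A call in the wrong
direction is counted both as a false positive (a wrong CNV call was made)
and as a false negative (the true CNV was missed), so with direction
mismatches present tp+fp+tn+fn can exceed the exon count.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .targets_io import InputError

__all__ = ["ConfusionMetrics", "score_exons"]

NEUTRAL_COPY = 2


def _safe_div(num: int, den: int) -> float:
    return num / den if den > 0 else math.nan


@dataclass
class ConfusionMetrics:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def sensitivity(self) -> float:
        return _safe_div(self.tp, self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return _safe_div(self.tn, self.tn + self.fp)

    @property
    def precision(self) -> float:
        return _safe_div(self.tp, self.tp + self.fp)

    @property
    def accuracy(self) -> float:
        return _safe_div(self.tp + self.tn, self.tp + self.tn + self.fp + self.fn)

    def as_dict(self) -> dict[str, float]:
        return {
            "tp": self.tp, "fp": self.fp, "tn": self.tn, "fn": self.fn,
            "sensitivity": self.sensitivity, "specificity": self.specificity,
            "precision": self.precision, "accuracy": self.accuracy,
        }


def score_exons(
    truth: np.ndarray,
    called: np.ndarray,
    strict_copy: bool = False,
) -> ConfusionMetrics:
    """Score per-exon integer copy calls against per-exon integer truth."""
    truth = np.asarray(truth, dtype=int)
    called = np.asarray(called, dtype=int)
    if truth.shape != called.shape:
        raise InputError(
            f"truth ({truth.size}) and calls ({called.size}) have different lengths"
        )
    t_pos = truth != NEUTRAL_COPY
    c_pos = called != NEUTRAL_COPY
    if strict_copy:
        match = truth == called
    else:
        match = np.sign(truth - NEUTRAL_COPY) == np.sign(called - NEUTRAL_COPY)

    tp = int(np.sum(t_pos & c_pos & match))
    tn = int(np.sum(~t_pos & ~c_pos))
    fn = int(np.sum(t_pos & ~c_pos))
    fp = int(np.sum(~t_pos & c_pos))
    # wrong-direction (or, in strict mode, wrong-copy) calls on true CNV
    # exons: a spurious call was made AND the real event was missed
    mismatch = int(np.sum(t_pos & c_pos & ~match))
    return ConfusionMetrics(tp=tp, fp=fp + mismatch, tn=tn, fn=fn + mismatch)
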