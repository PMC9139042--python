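"""Confusion matrices and the six classification performance indices.

Models are scored on their held-out test set with Cohen's kappa, accuracy,
sensitivity, specificity, PPV and NPV. A reconstruction helper inverts
printed (sensitivity, specificity, class sizes) back to integer confusion
counts, which lets published index tables be checked for mutual consistency.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .pose_io import round_half_up


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fn: int
    tn: int
    fp: int
    positive_label: str = "positive"

    def __post_init__(self) -> None:
        if min(self.tp, self.fn, self.tn, self.fp) < 0:
            raise ValueError("confusion counts must be nonnegative")
        if self.total == 0:
            raise ValueError("confusion matrix must contain at least one sample")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.tn + self.fp


@dataclass(frozen=True)
class PerformanceIndices:
    """kappa, accuracy, sensitivity, specificity, PPV, NPV.

    An index whose denominator is zero is reported as None and listed in
    ``undefined`` rather than propagated as NaN.
    """

    kappa: float
    accuracy: float
    sensitivity: float | None
    specificity: float | None
    ppv: float | None
    npv: float | None
    undefined: tuple[str, ...] = ()

    def rounded(self, ndigits: int = 2) -> dict:
        out = {}
        for k in ("kappa", "accuracy", "sensitivity", "specificity", "ppv", "npv"):
            v = getattr(self, k)
            out[k] = None if v is None else round(v, ndigits)
        return out


def confusion(true_labels: Sequence, predicted_labels: Sequence, positive_label) -> ConfusionMatrix:
    """Tally a 2-class confusion matrix."""
    t = np.asarray(true_labels)
    p = np.asarray(predicted_labels)
    if t.shape != p.shape:
        raise ValueError("true and predicted label sequences differ in length")
    classes = set(np.unique(t)) | set(np.unique(p))
    if len(classes) > 2:
        raise ValueError(f"expected a 2-class problem, got classes {sorted(map(str, classes))}")
    if positive_label not in classes:
        raise ValueError(f"positive label {positive_label!r} absent from labels")
    tpos = t == positive_label
    ppos = p == positive_label
    return ConfusionMatrix(
        tp=int((tpos & ppos).sum()),
        fn=int((tpos & ~ppos).sum()),
        tn=int((~tpos & ~ppos).sum()),
        fp=int((~tpos & ppos).sum()),
        positive_label=str(positive_label),
    )


def performance_indices(cm: ConfusionMatrix) -> PerformanceIndices:
    """The six indices of a confusion matrix.

    kappa = (p_o - p_e) / (1 - p_e) with observed agreement p_o = accuracy and
    chance agreement p_e = [(tp+fn)(tp+fp) + (tn+fp)(tn+fn)] / total^2.
    """
    total = cm.total
    acc = (cm.tp + cm.tn) / total
    undefined = []

    def ratio(num: int, den: int, name: str) -> float | None:
        if den == 0:
            undefined.append(name)
            return None
        return num / den

    sen = ratio(cm.tp, cm.tp + cm.fn, "sensitivity")
    spe = ratio(cm.tn, cm.tn + cm.fp, "specificity")
    ppv = ratio(cm.tp, cm.tp + cm.fp, "ppv")
    npv = ratio(cm.tn, cm.tn + cm.fn, "npv")
    p_e = ((cm.tp + cm.fn) * (cm.tp + cm.fp) + (cm.tn + cm.fp) * (cm.tn + cm.fn)) / total**2
    kappa = 0.0 if math.isclose(p_e, 1.0) else (acc - p_e) / (1 - p_e)
    return PerformanceIndices(kappa, acc, sen, spe, ppv, npv, tuple(undefined))


def reconstruct_confusion(sen: float, spe: float, n_pos: int, n_neg: int,
                          positive_label: str = "positive") -> ConfusionMatrix:
    """Invert printed sensitivity/specificity to integer confusion counts.

    tp = round(sen * n_pos), tn = round(spe * n_neg) (half up), with fn and fp
    as the complements. Used as a consistency oracle for published index
    tables: feeding the reconstructed matrix back through
    ``performance_indices`` must reproduce all six printed values.
    """
    if not (0 <= sen <= 1 and 0 <= spe <= 1):
        raise ValueError("sen and spe must lie in [0, 1]")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("class sizes must be at least 1")
    tp = round_half_up(sen * n_pos)
    tn = round_half_up(spe * n_neg)
    return ConfusionMatrix(tp=tp, fn=n_pos - tp, tn=tn, fp=n_neg - tn,
                           positive_label=positive_label)
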