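"""Class-specific accuracy, confusion matrices, and session reports.

Accuracy is computed in a class-specific manner: the per-class segment
accuracy is averaged with equal weight over the M movement types,

    Acc = (1/M) * sum_j  (#correct segments / #total segments)_j,

which removes the bias of global accuracy toward over-represented classes.
With perfectly balanced classes the two coincide exactly.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError

__all__ = ["AccuracyReport", "class_specific_accuracy", "confusion_matrix",
           "session_report"]


@dataclass
class AccuracyReport:
    """Per-class accuracies and their unweighted mean."""

    per_class: dict[int, float]
    accuracy: float
    n_classes: int
    n_segments: int


def _check_streams(predicted, truth, n_classes: int):
    predicted = np.asarray(predicted, dtype=np.int64).ravel()
    truth = np.asarray(truth, dtype=np.int64).ravel()
    if len(predicted) != len(truth):
        raise ParameterError(
            f"length mismatch: {len(predicted)} predictions vs {len(truth)} truths")
    if truth.size and (truth.min() < 0 or truth.max() >= n_classes):
        raise ParameterError(f"truth labels outside [0, {n_classes})")
    return predicted, truth


def class_specific_accuracy(predicted, truth, n_classes: int) -> AccuracyReport:
    """Unweighted mean of per-class segment accuracies over the M classes.

    Classes absent from the truth stream are excluded from the mean, with a
    warning (a balanced protocol never hits this case).
    """
    predicted, truth = _check_streams(predicted, truth, n_classes)
    per_class: dict[int, float] = {}
    missing = []
    for j in range(n_classes):
        mask = truth == j
        if not mask.any():
            missing.append(j)
            continue
        per_class[j] = float((predicted[mask] == j).mean())
    if missing:
        warnings.warn(
            f"classes {missing} absent from truth; excluded from the class-specific mean",
            stacklevel=2)
    if not per_class:
        raise ParameterError("no truth labels present")
    return AccuracyReport(
        per_class=per_class,
        accuracy=float(np.mean(list(per_class.values()))),
        n_classes=n_classes,
        n_segments=len(truth),
    )


def confusion_matrix(predicted, truth, n_classes: int) -> np.ndarray:
    """M x M count matrix; entry (j, k) counts truth-j segments predicted k."""
    predicted, truth = _check_streams(predicted, truth, n_classes)
    if predicted.size and (predicted.min() < 0 or predicted.max() >= n_classes):
        raise ParameterError(f"predicted labels outside [0, {n_classes})")
    flat = np.bincount(truth * n_classes + predicted, minlength=n_classes ** 2)
    return flat.reshape(n_classes, n_classes)


def session_report(log, baseline_log) -> pd.DataFrame:
    """Per-session accuracy table of a scenario against a baseline.

    Rows are sessions (plus an ``average`` row); columns hold the scenario
    accuracy, the baseline accuracy, and their difference. Session I is the
    first testing session; recalibration can only act from session II on.
    """
    if len(log.results) != len(baseline_log.results):
        raise ParameterError(
            f"session count mismatch: {len(log.results)} vs {len(baseline_log.results)}")
    acc = log.accuracies
    base = baseline_log.accuracies
    roman = ["I", "II", "III", "IV", "V", "VI", "VII", "VIII", "IX", "X"]
    names = [roman[i] if i < len(roman) else str(i + 1) for i in range(len(acc))]
    frame = pd.DataFrame({
        log.scenario.value: acc,
        baseline_log.scenario.value: base,
        "difference": acc - base,
    }, index=pd.Index(names, name="session"))
    frame.loc["average"] = frame.mean()
    return frame
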