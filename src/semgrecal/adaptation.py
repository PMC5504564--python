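"""Offline pseudo-label correction and the self-recalibration session protocol.

After the initial supervised training, no new ground-truth labels ever reach
the classifier. Instead, the predictions from each finished testing session
are corrected offline — exploiting that neighboring segments almost always
belong to the same movement — and fed back as pseudo-labels to fine-tune the
network before the next session. Two correction rules are provided:

* **mode** — each label is replaced by the most frequent label in the
  adjacent ±x segments (multi-vote), usable with any classifier;
* **median_prob** — per class, the median predicted probability over the
  ±x window is taken, and the corrected label is its argmax. The median
  (rather than the mean) suppresses outlier segments; this variant is the
  default for the probabilistic CNN.

Three recalibration scenarios are supported: ``none`` (train once, never
update), ``last_only`` (fine-tune on the corrected predictions of the most
recent session only — the practical deployment mode), and ``all_session``
(fine-tune on the initial training set plus the corrected predictions of all
previous sessions — an estimate of the attainable maximum).
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .classifier import (ModelConfig, ModelState, TrainConfig, build_model,
                         fine_tune, predict_proba, train)
from .errors import ConfigurationError, ParameterError
from .evaluation import AccuracyReport, class_specific_accuracy
from .feature_grid import GridLayout, center_out_order, rearrange_batch
from .preprocessing import FeatureSet

__all__ = ["CorrectionConfig", "Prediction", "RecalScenario", "Buffer",
           "SessionResult", "SessionLog", "correct_labels_mode",
           "correct_labels_median_prob", "correct_labels",
           "run_session_protocol"]


@dataclass
class CorrectionConfig:
    """Label-correction settings: half-window ``x`` in segments and method."""

    x: int = 10
    method: str = "median_prob"

    def __post_init__(self) -> None:
        if self.x < 0:
            raise ConfigurationError("x must be >= 0")
        if self.method not in ("mode", "median_prob"):
            raise ConfigurationError(f"unknown correction method {self.method!r}")


@dataclass
class Prediction:
    """One segment's prediction: index i, label L^i, probability row P(i, .)."""

    index: int
    label: int
    probabilities: np.ndarray


class RecalScenario(enum.Enum):
    NONE = "none"
    ALL_SESSION = "all_session"
    LAST_ONLY = "last_only"


def _as_label_array(predictions) -> np.ndarray:
    if len(predictions) and isinstance(predictions[0], Prediction):
        return np.array([p.label for p in predictions], dtype=np.int64)
    return np.asarray(predictions, dtype=np.int64)


def _as_prob_matrix(predictions) -> np.ndarray:
    if len(predictions) and isinstance(predictions[0], Prediction):
        return np.stack([p.probabilities for p in predictions])
    return np.asarray(predictions, dtype=np.float64)


def correct_labels_mode(predictions, x: int) -> np.ndarray:
    """Multi-vote correction: L^i <- mode(L^{i-x}, ..., L^{i+x}).

    Windows are truncated at the sequence boundaries. If several labels tie
    for the mode, the original L^i is kept when it is among them, otherwise
    the smallest class id wins.
    """
    labels = _as_label_array(predictions)
    n = len(labels)
    out = labels.copy()
    for i in range(n):
        window = labels[max(0, i - x):min(n, i + x + 1)]
        vals, counts = np.unique(window, return_counts=True)
        winners = vals[counts == counts.max()]
        out[i] = labels[i] if labels[i] in winners else winners.min()
    return out


def correct_labels_median_prob(predictions, x: int) -> np.ndarray:
    """Median-probability correction: L^i <- argmax_j median_w P(w, j).

    Per class j the median probability over the truncated ±x window is
    computed; the corrected label is its argmax (ties to the smallest class
    id, the numpy argmax convention).
    """
    probs = _as_prob_matrix(predictions)
    n = probs.shape[0]
    out = np.empty(n, dtype=np.int64)
    for i in range(n):
        med = np.median(probs[max(0, i - x):min(n, i + x + 1)], axis=0)
        out[i] = int(np.argmax(med))
    return out


def correct_labels(labels: np.ndarray, probs: np.ndarray,
                   config: CorrectionConfig) -> np.ndarray:
    if config.method == "mode":
        return correct_labels_mode(labels, config.x)
    return correct_labels_median_prob(probs, config.x)


@dataclass
class Buffer:
    """FIFO store of (feature grid, corrected label) pairs for retraining.

    Retraining is triggered whenever the buffer has been filled to capacity;
    capacity defaults to one full session when driven by the protocol.
    """

    capacity: int
    grids: list = field(default_factory=list)
    labels: list = field(default_factory=list)

    def add(self, grid: np.ndarray, label: int) -> bool:
        """Add one pair; returns True when the buffer just became full."""
        self.grids.append(grid)
        self.labels.append(int(label))
        return self.full

    @property
    def full(self) -> bool:
        return len(self.labels) >= self.capacity

    def drain(self) -> tuple[np.ndarray, np.ndarray]:
        grids = np.stack(self.grids)
        labels = np.asarray(self.labels, dtype=np.int64)
        self.grids.clear()
        self.labels.clear()
        return grids, labels


@dataclass
class SessionResult:
    """Everything logged for one testing session."""

    session: int
    predicted: np.ndarray
    probabilities: np.ndarray
    corrected: np.ndarray
    report: AccuracyReport


@dataclass
class SessionLog:
    """Per-session outcomes of one recalibration scenario run."""

    scenario: RecalScenario
    results: list[SessionResult]
    model_snapshots: list[ModelState] = field(default_factory=list)

    @property
    def accuracies(self) -> np.ndarray:
        return np.array([r.report.accuracy for r in self.results])


def run_session_protocol(
    initial_train: FeatureSet,
    sessions: Sequence[FeatureSet],
    scenario: RecalScenario | str,
    correction: CorrectionConfig | None = None,
    model_config: ModelConfig | None = None,
    train_config: TrainConfig | None = None,
    fine_tune_config: TrainConfig | None = None,
    layout: GridLayout | None = None,
    keep_snapshots: bool = False,
    train_audit: Callable[[np.ndarray, np.ndarray], None] | None = None,
) -> SessionLog:
    """Run the session-by-session self-recalibration protocol.

    The model is trained once on ``initial_train`` (the only data with true
    labels it ever sees), then each testing session is predicted in order.
    Between sessions, depending on the scenario, the model is fine-tuned on
    corrected pseudo-labels: the last session's (``last_only``) or the
    initial set plus all previous sessions' (``all_session``). The true
    labels of testing sessions are used exclusively for scoring.

    ``train_audit``, when given, is invoked with every (grids, labels) pair
    that is actually passed to a training call — an audit hook to verify
    that session ground truth never leaks into training.
    """
    if not sessions:
        raise ParameterError("at least one testing session is required")
    scenario = RecalScenario(scenario)
    correction = correction or CorrectionConfig()
    if model_config is None:
        n_classes = int(initial_train.labels.max()) + 1
        model_config = ModelConfig(n_classes=n_classes)
    train_config = train_config or TrainConfig()
    if fine_tune_config is None:
        fine_tune_config = TrainConfig(epochs=15, seed=train_config.seed,
                                       learning_rate=train_config.learning_rate,
                                       batch_size=train_config.batch_size,
                                       mode="fine_tune")
    if layout is None:
        layout = center_out_order(model_config.grid_size)

    def to_grids(fs: FeatureSet) -> np.ndarray:
        return rearrange_batch(fs.scores, layout)

    x0, y0 = to_grids(initial_train), initial_train.labels
    if train_audit is not None:
        train_audit(x0, y0)
    model = build_model(model_config, seed=train_config.seed)
    model = train(model, x0, y0, train_config)

    m = model_config.n_classes
    session_size = max(len(s) for s in sessions)
    log = SessionLog(scenario=scenario, results=[])
    accumulated: list[tuple[np.ndarray, np.ndarray]] = []

    for s, fs in enumerate(sessions):
        grids = to_grids(fs)
        probs, predicted = predict_proba(model, grids)
        report = class_specific_accuracy(predicted, fs.labels, m)
        corrected = correct_labels(predicted, probs, correction)
        log.results.append(SessionResult(
            session=s, predicted=predicted, probabilities=probs,
            corrected=corrected, report=report))
        if keep_snapshots:
            log.model_snapshots.append(model.copy())
        if s == len(sessions) - 1 or scenario is RecalScenario.NONE:
            continue
        # fill the retraining buffer with this session's corrected pairs
        buffer = Buffer(capacity=min(session_size, len(fs)))
        for grid, lab in zip(grids, corrected):
            buffer.add(grid, lab)
        if not buffer.full:
            continue
        new_grids, new_labels = buffer.drain()
        if scenario is RecalScenario.LAST_ONLY:
            xt, yt = new_grids, new_labels
        else:  # ALL_SESSION
            accumulated.append((new_grids, new_labels))
            xt = np.concatenate([x0] + [g for g, _ in accumulated])
            yt = np.concatenate([y0] + [l for _, l in accumulated])
        if train_audit is not None:
            train_audit(xt, yt)
        model = fine_tune(model, xt, yt, fine_tune_config)
    return log
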