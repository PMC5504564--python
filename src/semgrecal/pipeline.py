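"""End-to-end composition: featurization and the multi-session drift study.

:func:`fit_feature_pipeline` fits the normalization percentiles and the
per-channel PCA basis on the initial training recording and freezes them;
:func:`featurize_recording` applies the frozen pipeline to any session.
:func:`run_drift_study` wires the whole system together on a synthetic
multi-session study — generate, featurize, train once, then run the
session protocol under one or more recalibration scenarios — and is the
harness behind both the test suite's stochastic checks and the
reproduction script.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .adaptation import CorrectionConfig, RecalScenario, SessionLog, run_session_protocol
from .classifier import ModelConfig, TrainConfig
from .io_formats import Recording
from .preprocessing import (FeatureSet, NormalizationStats, PCATransform,
                            compute_spectrogram, fit_normalization, fit_pca,
                            normalize, project_pca_batch, segment_stream)
from .synthetic_data import DriftSpec, SynthConfig, generate_study

__all__ = ["FeaturePipeline", "fit_feature_pipeline", "featurize_recording",
           "StudyConfig", "run_drift_study"]


@dataclass
class FeaturePipeline:
    """Frozen feature-extraction state fitted on the initial training data."""

    stats: NormalizationStats
    pca: PCATransform
    window_ms: float = 200.0
    step_ms: float = 100.0
    nfft: int = 256
    noverlap: int = 184
    keep_bins: int = 95


def _segment_spectrograms(recording: Recording, window_ms, step_ms, nfft,
                          noverlap, keep_bins):
    segments = segment_stream(recording, window_ms=window_ms, step_ms=step_ms)
    specs = [compute_spectrogram(s, nfft=nfft, noverlap=noverlap,
                                 keep_bins=keep_bins) for s in segments]
    return segments, specs


def fit_feature_pipeline(recording: Recording, n_components: int = 25,
                         window_ms: float = 200.0, step_ms: float = 100.0,
                         nfft: int = 256, noverlap: int = 184,
                         keep_bins: int = 95) -> FeaturePipeline:
    """Fit normalization and per-channel PCA on one training recording."""
    _, specs = _segment_spectrograms(recording, window_ms, step_ms, nfft,
                                     noverlap, keep_bins)
    stats = fit_normalization(specs)
    normalized = [normalize(s, stats) for s in specs]
    pca = fit_pca(normalized, n_components=n_components)
    return FeaturePipeline(stats=stats, pca=pca, window_ms=window_ms,
                           step_ms=step_ms, nfft=nfft, noverlap=noverlap,
                           keep_bins=keep_bins)


def featurize_recording(recording: Recording,
                        pipeline: FeaturePipeline) -> FeatureSet:
    """Apply a frozen feature pipeline to a recording -> per-segment PC scores."""
    segments, specs = _segment_spectrograms(
        recording, pipeline.window_ms, pipeline.step_ms, pipeline.nfft,
        pipeline.noverlap, pipeline.keep_bins)
    normalized = [normalize(s, pipeline.stats) for s in specs]
    scores = project_pca_batch(normalized, pipeline.pca)
    return FeatureSet(
        scores=scores,
        labels=np.array([s.label for s in segments]),
        repetitions=np.array([s.repetition for s in segments]),
        indices=np.array([s.index for s in segments]),
    )


@dataclass
class StudyConfig:
    """Desk-scale study conditions for the synthetic drifting experiment.

    Defaults define the scaled-down analogue of a multi-session protocol:
    5 movement classes plus rest on 12 channels, 6 repetition-sessions with
    moderate cumulative spatial drift (0.15 rad channel mixing and 8% gain
    drift per session), a small network (8 filters, 128 FC neurons), and the
    ±10-segment median-probability label correction. Spatial drift moves all
    classes coherently, so accumulated past sessions act as augmentation
    rather than contradiction — the regime in which the relative ordering of
    the recalibration scenarios matches multi-session sEMG studies.
    """

    synth: SynthConfig = field(default_factory=lambda: SynthConfig(
        n_classes=5, noise_sd=0.4))
    drift: DriftSpec = field(default_factory=lambda: DriftSpec(
        mixing_angle_per_session=0.15,
        gain_drift_per_session=1.08,
        spectral_shift_per_session=0.0))
    n_filters: int = 8
    fc_neurons: int = 128
    dropout_rate: float = 0.5
    epochs: int = 60
    fine_tune_epochs: int = 15
    batch_size: int = 64
    learning_rate: float = 0.05
    correction: CorrectionConfig = field(default_factory=CorrectionConfig)
    n_components: int = 25
    include_rest: bool = True


def run_drift_study(config: StudyConfig, scenarios: Sequence[RecalScenario | str],
                    seed: int = 0) -> dict[str, SessionLog]:
    """Generate one synthetic study and run the protocol under each scenario.

    Session 0 (repetition 1, undrifted) is the initial training set; sessions
    1..5 (cumulatively drifted) are tested one by one. The rest state is
    included as class 0, so a study with C movement classes trains an
    (C+1)-way classifier. Returns one SessionLog per scenario, keyed by the
    scenario value; all scenarios share the same data, features and seeds,
    so their accuracies are directly comparable.
    """
    synth = SynthConfig(**{**config.synth.__dict__,
                           "class_spectra": config.synth.class_spectra,
                           "seed": seed})
    sessions = generate_study(synth, config.drift)
    pipeline = fit_feature_pipeline(sessions[0], n_components=config.n_components)
    feature_sets = [featurize_recording(rec, pipeline) for rec in sessions]
    if not config.include_rest:
        # drop rest segments and renumber movement classes to 0..C-1
        def strip_rest(fs: FeatureSet) -> FeatureSet:
            keep = fs.labels > 0
            return FeatureSet(scores=fs.scores[keep], labels=fs.labels[keep] - 1,
                              repetitions=fs.repetitions[keep],
                              indices=fs.indices[keep])
        feature_sets = [strip_rest(fs) for fs in feature_sets]
    initial, testing = feature_sets[0], feature_sets[1:]

    n_classes = synth.n_classes + (1 if config.include_rest else 0)
    model_config = ModelConfig(
        n_classes=n_classes,
        grid_size=int(np.sqrt(config.n_components)),
        n_channels=synth.n_channels,
        n_filters=config.n_filters,
        fc_neurons=config.fc_neurons,
        dropout_rate=config.dropout_rate,
    )
    train_config = TrainConfig(epochs=config.epochs, batch_size=config.batch_size,
                               learning_rate=config.learning_rate, seed=seed)
    ft_config = TrainConfig(epochs=config.fine_tune_epochs,
                            batch_size=config.batch_size,
                            learning_rate=config.learning_rate, seed=seed,
                            mode="fine_tune")
    logs: dict[str, SessionLog] = {}
    for scenario in scenarios:
        scenario = RecalScenario(scenario)
        logs[scenario.value] = run_session_protocol(
            initial, testing, scenario,
            correction=config.correction,
            model_config=model_config,
            train_config=train_config,
            fine_tune_config=ft_config,
        )
    return logs
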