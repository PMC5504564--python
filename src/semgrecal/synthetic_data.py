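"""Seeded synthetic multi-session sEMG studies with controllable drift.

The generator emulates the structure of a NinaPro-style acquisition: each
movement class is performed in blocks separated by rest, repeated a fixed
number of times, on a 12-channel 2 kHz recording. Movement activity is
modelled as band-pass-filtered Gaussian noise with a class-specific center
frequency and bandwidth (classes are separable by their spectral content,
the property the spectrogram features exploit), scaled by per-class
per-channel amplitude weights and shaped by a trapezoidal onset/offset
envelope. Session-to-session non-stationarity — the concept drift that
motivates self-recalibration — is modelled by :class:`DriftSpec` as a
cumulative composition of three canonical effects: channel mixing (electrode
shift), per-channel gain drift, and a global spectral shift.
"""

from __future__ import annotations

from dataclasses import dataclass, replace as dc_replace
from typing import Sequence

import numpy as np
import scipy.signal

from .errors import ConfigurationError
from .io_formats import Recording

__all__ = [
    "SynthConfig",
    "DriftSpec",
    "generate_recording",
    "apply_session_drift",
    "generate_study",
]


def _default_class_spectra(n_classes: int, fs: float) -> list[tuple[float, float]]:
    """Evenly spaced center frequencies in the sEMG-energetic band (~60-450 Hz)."""
    lo, hi = 80.0, min(450.0, 0.45 * fs)
    centers = np.linspace(lo, hi, n_classes)
    return [(float(c), 120.0) for c in centers]


def _default_channel_weights(n_classes: int, n_channels: int) -> np.ndarray:
    """Each class emphasizes a different ring of channels (smooth Gaussian bump)."""
    ch = np.arange(n_channels)
    weights = np.empty((n_classes, n_channels))
    for c in range(n_classes):
        center = (c + 0.5) * n_channels / n_classes
        d = np.minimum(np.abs(ch - center), n_channels - np.abs(ch - center))
        weights[c] = 0.3 + np.exp(-(d ** 2) / 8.0)
    return weights


@dataclass
class SynthConfig:
    """Study-design parameters for the synthetic generator.

    ``class_spectra`` holds one ``(center_hz, bandwidth_hz)`` pair per class;
    ``channel_weights`` is an ``(n_classes, n_channels)`` non-negative
    amplitude matrix. Defaults mirror a DB2-like protocol: 12 channels at
    2000 Hz, 6 repetitions per movement with 3 s rest in between.
    """

    n_classes: int
    n_channels: int = 12
    fs: float = 2000.0
    movement_duration: float = 5.0
    rest_duration: float = 3.0
    n_repetitions: int = 6
    class_spectra: Sequence[tuple[float, float]] | None = None
    channel_weights: np.ndarray | None = None
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_classes < 1:
            raise ConfigurationError("n_classes must be >= 1")
        if self.n_channels < 1:
            raise ConfigurationError("n_channels must be >= 1")
        if self.fs <= 0:
            raise ConfigurationError("fs must be positive")
        if self.movement_duration <= 0:
            raise ConfigurationError("movement_duration must be positive")
        if self.rest_duration <= 0:
            raise ConfigurationError("rest_duration must be positive")
        if self.n_repetitions < 1:
            raise ConfigurationError("n_repetitions must be >= 1")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be non-negative")
        if self.class_spectra is None:
            self.class_spectra = _default_class_spectra(self.n_classes, self.fs)
        self.class_spectra = [(float(c), float(b)) for c, b in self.class_spectra]
        if len(self.class_spectra) != self.n_classes:
            raise ConfigurationError("class_spectra must have one entry per class")
        for center, bw in self.class_spectra:
            if bw <= 0:
                raise ConfigurationError("class_spectra bandwidth must be positive")
            if self.fs <= 2 * center or center + bw / 2 >= self.fs / 2:
                raise ConfigurationError(
                    f"class_spectra band {center}±{bw / 2} Hz violates Nyquist at fs={self.fs}"
                )
        if self.channel_weights is None:
            self.channel_weights = _default_channel_weights(self.n_classes, self.n_channels)
        self.channel_weights = np.asarray(self.channel_weights, dtype=np.float64)
        if self.channel_weights.shape != (self.n_classes, self.n_channels):
            raise ConfigurationError(
                "channel_weights must have shape (n_classes, n_channels)"
            )
        if (self.channel_weights < 0).any():
            raise ConfigurationError("channel_weights must be non-negative")
        if not (self.channel_weights.max(axis=1) > 0).all():
            raise ConfigurationError(
                "channel_weights needs at least one positive entry per class"
            )


@dataclass
class DriftSpec:
    """Cumulative session-to-session drift.

    The drift applied at session ``s`` is the ``s``-fold composition of the
    per-session transform: a rotation of ``mixing_angle_per_session`` radians
    applied pairwise to adjacent channels (electrode shift / crosstalk), a
    multiplicative per-channel gain of ``gain_drift_per_session`` (scalar or
    per-channel vector), and a single-sideband spectral shift of
    ``spectral_shift_per_session`` Hz. All three are monotone in the session
    index. The transforms are deterministic; ``seed`` is reserved for future
    stochastic drift components.
    """

    mixing_angle_per_session: float = 0.0
    gain_drift_per_session: float | np.ndarray = 1.0
    spectral_shift_per_session: float = 0.0
    seed: int = 0


def _movement_envelope(n: int, fs: float, ramp_s: float = 0.1) -> np.ndarray:
    ramp = min(int(round(ramp_s * fs)), n // 2)
    env = np.ones(n)
    if ramp > 0:
        r = np.linspace(0.0, 1.0, ramp, endpoint=False)
        env[:ramp] = r
        env[n - ramp:] = r[::-1]
    return env


def _bandpass_noise(rng, n: int, n_channels: int, center: float, bw: float,
                    fs: float) -> np.ndarray:
    lo = max(center - bw / 2, 1.0)
    hi = min(center + bw / 2, 0.499 * fs)
    sos = scipy.signal.butter(4, [lo, hi], btype="bandpass", fs=fs, output="sos")
    white = rng.standard_normal((n, n_channels))
    return scipy.signal.sosfilt(sos, white, axis=0)


def generate_recording(config: SynthConfig, session_index: int = 0) -> Recording:
    """Generate one synthetic recording (undrifted).

    The label stream alternates rest and movement blocks: for each repetition
    pass, every class appears once, preceded by a rest block. Movement samples
    carry their class id and repetition number; rest samples carry 0 in both
    streams. ``session_index`` only selects an independent random realization;
    drift is applied separately by :func:`apply_session_drift`.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, session_index]))
    n_mov = int(round(config.movement_duration * config.fs))
    n_rest = int(round(config.rest_duration * config.fs))

    sig_blocks, lab_blocks, rep_blocks = [], [], []
    for rep in range(1, config.n_repetitions + 1):
        for cls in range(1, config.n_classes + 1):
            sig_blocks.append(config.noise_sd
                              * rng.standard_normal((n_rest, config.n_channels)))
            lab_blocks.append(np.zeros(n_rest, dtype=np.int64))
            rep_blocks.append(np.zeros(n_rest, dtype=np.int64))

            center, bw = config.class_spectra[cls - 1]
            burst = _bandpass_noise(rng, n_mov, config.n_channels, center, bw, config.fs)
            burst *= config.channel_weights[cls - 1][None, :]
            burst *= _movement_envelope(n_mov, config.fs)[:, None]
            burst += config.noise_sd * rng.standard_normal((n_mov, config.n_channels))
            sig_blocks.append(burst)
            lab_blocks.append(np.full(n_mov, cls, dtype=np.int64))
            rep_blocks.append(np.full(n_mov, rep, dtype=np.int64))

    return Recording(
        emg=np.concatenate(sig_blocks),
        fs=config.fs,
        labels=np.concatenate(lab_blocks),
        repetition=np.concatenate(rep_blocks),
        subject_id="synthetic",
        session_id=f"session{session_index}",
    )


def _pairwise_rotation(n_channels: int, angle: float) -> np.ndarray:
    """Block-diagonal rotation by ``angle`` on channel pairs (0,1), (2,3), ..."""
    rot = np.eye(n_channels)
    c, s = np.cos(angle), np.sin(angle)
    for i in range(0, n_channels - 1, 2):
        rot[i, i] = c
        rot[i, i + 1] = -s
        rot[i + 1, i] = s
        rot[i + 1, i + 1] = c
    return rot


def _spectral_shift(emg: np.ndarray, shift_hz: float, fs: float) -> np.ndarray:
    """Shift all spectral content up by ``shift_hz`` (single-sideband modulation)."""
    if shift_hz == 0.0:
        return emg
    analytic = scipy.signal.hilbert(emg, axis=0)
    t = np.arange(emg.shape[0]) / fs
    return np.real(analytic * np.exp(2j * np.pi * shift_hz * t)[:, None])


def apply_session_drift(recording: Recording, drift: DriftSpec,
                        session_index: int) -> Recording:
    """Apply the ``session_index``-fold composed drift to a recording.

    ``session_index = 0`` returns an identical copy. Label and repetition
    streams are never altered. The composed operator is evaluated in closed
    form: rotation angle, gain exponent and spectral shift all scale linearly
    with the session index.
    """
    if session_index < 0:
        raise ConfigurationError("session_index must be >= 0")
    emg = recording.emg.copy()
    if session_index > 0:
        emg = _spectral_shift(
            emg, session_index * drift.spectral_shift_per_session, recording.fs)
        gain = np.broadcast_to(
            np.asarray(drift.gain_drift_per_session, dtype=np.float64),
            (recording.n_channels,),
        )
        emg = emg * (gain ** session_index)[None, :]
        if drift.mixing_angle_per_session != 0.0:
            rot = _pairwise_rotation(
                recording.n_channels,
                session_index * drift.mixing_angle_per_session)
            emg = emg @ rot.T
    return dc_replace(recording, emg=emg,
                      labels=recording.labels.copy(),
                      repetition=recording.repetition.copy())


def generate_study(config: SynthConfig, drift: DriftSpec) -> list[Recording]:
    """Generate one recording per repetition-session with cumulative drift.

    Session ``k`` (0-based) contains every class exactly once, carries
    repetition index ``k + 1`` on its movement samples, and is transformed by
    the ``k``-fold composed drift. Session 0 (repetition 1) is undrifted and
    serves as the initial training session in the recalibration protocol.
    """
    sessions = []
    single = dc_replace(config, n_repetitions=1)
    for k in range(config.n_repetitions):
        rec = generate_recording(single, session_index=k)
        rec.repetition[rec.repetition > 0] = k + 1
        sessions.append(apply_session_drift(rec, drift, k))
    return sessions
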