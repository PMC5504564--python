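"""Segmentation, spectrogram features, percentile normalization, per-channel PCA.

The feature pipeline converts a continuous recording into one
dimension-reduced feature vector per 200 ms analysis window:

1. :func:`segment_stream` — overlapping 200 ms windows at 100 ms steps
   (400 / 200 samples at 2 kHz); each window is labelled by the per-sample
   label mode.
2. :func:`compute_spectrogram` — per channel, the magnitude of a short-time
   DFT: 256-point FFT, Hamming taper, 184-point overlap, giving 129
   frequencies x 3 time bins per window; only the first 95 frequency bins
   (0 to ~734 Hz) are kept, since sEMG energy concentrates below ~700 Hz.
3. :func:`fit_normalization` / :func:`normalize` — intensities mapped to
   [0, 1] per channel using the training set's 1st/99th percentiles as
   min/max; out-of-range values are clipped.
4. :func:`fit_pca` / :func:`project_pca` — the 95x3 spectrogram of each
   channel is vectorized and reduced to its first 25 principal-component
   scores, so a window becomes a 25 x 12 score matrix (300 scores).

Normalization statistics and the PCA basis are fitted once on the initial
training data and frozen thereafter, keeping the feature space stable for
the warm-started classifier.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import scipy.signal
from sklearn.decomposition import PCA

from .errors import ParameterError
from .io_formats import Recording

__all__ = [
    "Segment",
    "SpectrogramTensor",
    "NormalizationStats",
    "PCATransform",
    "FeatureSet",
    "segment_stream",
    "compute_spectrogram",
    "fit_normalization",
    "normalize",
    "fit_pca",
    "project_pca",
]


@dataclass
class Segment:
    """One analysis window: ``samples`` is window_length x channels."""

    samples: np.ndarray
    label: int
    repetition: int
    index: int
    fs: float


@dataclass
class SpectrogramTensor:
    """Per-segment intensity array, n_freq x n_time x n_channels, non-negative."""

    intensities: np.ndarray
    freq_axis: np.ndarray
    truncated: bool

    @property
    def n_channels(self) -> int:
        return self.intensities.shape[2]


@dataclass
class NormalizationStats:
    """Per-channel 1st (p1) and 99th (p99) intensity percentiles of the training set."""

    p1: np.ndarray
    p99: np.ndarray


@dataclass
class PCATransform:
    """Per-channel PCA basis: ``mean`` (C x D) and ``components`` (C x K x D).

    Component rows are orthonormal, ordered by descending explained variance,
    with sign fixed so the largest-magnitude loading entry is positive.
    """

    mean: np.ndarray
    components: np.ndarray

    @property
    def n_components(self) -> int:
        return self.components.shape[1]

    @property
    def n_channels(self) -> int:
        return self.components.shape[0]


@dataclass
class FeatureSet:
    """PC scores for a stream of segments: ``scores`` is n_segments x K x C."""

    scores: np.ndarray
    labels: np.ndarray
    repetitions: np.ndarray
    indices: np.ndarray

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=np.float64)
        self.labels = np.asarray(self.labels, dtype=np.int64)
        self.repetitions = np.asarray(self.repetitions, dtype=np.int64)
        self.indices = np.asarray(self.indices, dtype=np.int64)

    def __len__(self) -> int:
        return self.scores.shape[0]


def _window_mode(values: np.ndarray) -> int:
    """Mode of an int window; ties broken by earliest occurrence in the window."""
    uniq, counts = np.unique(values, return_counts=True)
    candidates = uniq[counts == counts.max()]
    if len(candidates) == 1:
        return int(candidates[0])
    first_pos = [int(np.argmax(values == v)) for v in candidates]
    return int(candidates[int(np.argmin(first_pos))])


def segment_stream(recording: Recording, window_ms: float = 200.0,
                   step_ms: float = 100.0) -> list[Segment]:
    """Section a recording into overlapping windows.

    Returns ``floor((N - window) / step) + 1`` segments in temporal order.
    Each segment's label is the per-sample label mode within the window
    (ties go to the earlier-occurring label); its repetition is the mode of
    the repetition stream among samples carrying that label.
    """
    window = int(round(window_ms * recording.fs / 1000.0))
    step = int(round(step_ms * recording.fs / 1000.0))
    if step < 1 or window < 1:
        raise ParameterError("window_ms and step_ms must map to >= 1 sample")
    n = recording.n_samples
    if n < window:
        warnings.warn(
            f"recording of {n} samples is shorter than one {window}-sample window",
            stacklevel=2,
        )
        return []
    segments = []
    for i, start in enumerate(range(0, n - window + 1, step)):
        sl = slice(start, start + window)
        lab_win = recording.labels[sl]
        label = _window_mode(lab_win)
        rep_win = recording.repetition[sl][lab_win == label]
        repetition = _window_mode(rep_win) if rep_win.size else 0
        segments.append(Segment(
            samples=recording.emg[sl],
            label=label,
            repetition=repetition,
            index=i,
            fs=recording.fs,
        ))
    return segments


def stft_magnitude(samples: np.ndarray, nfft: int, noverlap: int,
                   window: str | np.ndarray = "hamming") -> np.ndarray:
    """|short-time DFT| of a window_length x channels array -> n_freq x n_time x C.

    Frames are consecutive length-``nfft`` slices advanced by
    ``nfft - noverlap`` samples; each frame is tapered and transformed, and
    the magnitude is returned without further scaling.
    """
    samples = np.asarray(samples, dtype=np.float64)
    length = samples.shape[0]
    if nfft > length:
        raise ParameterError(
            f"nfft={nfft} exceeds segment length {length}")
    if not 0 <= noverlap < nfft:
        raise ParameterError("noverlap must satisfy 0 <= noverlap < nfft")
    taper = (scipy.signal.get_window(window, nfft)
             if isinstance(window, str) else np.asarray(window))
    step = nfft - noverlap
    n_time = (length - nfft) // step + 1
    frames = np.stack([samples[t * step:t * step + nfft] for t in range(n_time)],
                      axis=1)                      # nfft x n_time x C
    spec = np.fft.rfft(frames * taper[:, None, None], n=nfft, axis=0)
    return np.abs(spec)


def compute_spectrogram(segment: Segment, nfft: int = 256, noverlap: int = 184,
                        window: str = "hamming",
                        keep_bins: int | None = 95) -> SpectrogramTensor:
    """Per-channel magnitude spectrogram of one segment, truncated in frequency.

    At the defaults a 400-sample segment yields a 129 x 3 grid per channel
    (``nfft/2 + 1`` frequencies, 3 time bins), truncated to the first
    ``keep_bins`` frequency rows. Channels are processed independently.
    """
    mag = stft_magnitude(segment.samples, nfft, noverlap, window)
    freq_axis = np.arange(mag.shape[0]) * segment.fs / nfft
    truncated = keep_bins is not None and keep_bins < mag.shape[0]
    if truncated:
        mag = mag[:keep_bins]
        freq_axis = freq_axis[:keep_bins]
    return SpectrogramTensor(intensities=mag, freq_axis=freq_axis,
                             truncated=truncated)


def fit_normalization(spectrograms: Sequence[SpectrogramTensor]) -> NormalizationStats:
    """Per-channel 1st/99th percentiles pooled over all training segments,
    frequencies and time bins."""
    if len(spectrograms) == 0:
        raise ParameterError("fit_normalization needs at least one spectrogram")
    stacked = np.concatenate(
        [s.intensities.reshape(-1, s.n_channels) for s in spectrograms], axis=0)
    p1, p99 = np.percentile(stacked, [1, 99], axis=0)
    return NormalizationStats(p1=p1, p99=p99)


def normalize(spectrogram: SpectrogramTensor,
              stats: NormalizationStats) -> SpectrogramTensor:
    """Map intensities into [0, 1]: ``clip((v - p1) / (p99 - p1), 0, 1)``.

    Values outside the percentile range are forced to 0 or 1. Degenerate
    channels (p99 == p1) map to 0.
    """
    if len(stats.p1) != spectrogram.n_channels:
        raise ParameterError(
            f"stats cover {len(stats.p1)} channels, spectrogram has "
            f"{spectrogram.n_channels}")
    span = stats.p99 - stats.p1
    safe = np.where(span > 0, span, 1.0)
    scaled = (spectrogram.intensities - stats.p1[None, None, :]) / safe[None, None, :]
    scaled = np.where(span[None, None, :] > 0, scaled, 0.0)
    return SpectrogramTensor(
        intensities=np.clip(scaled, 0.0, 1.0),
        freq_axis=spectrogram.freq_axis,
        truncated=spectrogram.truncated,
    )


def _vectorize(spectrograms: Sequence[SpectrogramTensor]) -> np.ndarray:
    """Stack to n_segments x D x C with D = n_freq * n_time (channel-wise vectors)."""
    return np.stack(
        [s.intensities.reshape(-1, s.n_channels) for s in spectrograms], axis=0)


def fit_pca(spectrograms: Sequence[SpectrogramTensor],
            n_components: int = 25) -> PCATransform:
    """Fit an independent PCA per channel on vectorized normalized spectrograms.

    Requires at least ``n_components`` training segments. Component sign is
    fixed so each component's largest-magnitude loading is positive, making
    the basis reproducible across numerically equivalent fits.
    """
    if len(spectrograms) < n_components:
        raise ParameterError(
            f"need >= {n_components} training segments, got {len(spectrograms)}")
    x = _vectorize(spectrograms)                      # N x D x C
    n_channels = x.shape[2]
    means, comps = [], []
    for c in range(n_channels):
        pca = PCA(n_components=n_components, svd_solver="full")
        pca.fit(x[:, :, c])
        components = pca.components_.copy()
        for k in range(n_components):
            j = np.argmax(np.abs(components[k]))
            if components[k, j] < 0:
                components[k] = -components[k]
        means.append(pca.mean_)
        comps.append(components)
    return PCATransform(mean=np.stack(means), components=np.stack(comps))


def project_pca(spectrogram: SpectrogramTensor,
                transform: PCATransform) -> np.ndarray:
    """Project one normalized spectrogram to its K x C PC-score matrix."""
    v = spectrogram.intensities.reshape(-1, spectrogram.n_channels)  # D x C
    if v.shape[0] != transform.mean.shape[1] or v.shape[1] != transform.n_channels:
        raise ParameterError(
            f"spectrogram shape {v.shape} does not match fitted transform "
            f"({transform.n_channels} channels x {transform.mean.shape[1]} features)")
    centered = v.T - transform.mean                  # C x D
    return np.einsum("ckd,cd->kc", transform.components, centered)


def project_pca_batch(spectrograms: Sequence[SpectrogramTensor],
                      transform: PCATransform) -> np.ndarray:
    """Vectorized :func:`project_pca` over a list of segments -> N x K x C."""
    x = _vectorize(spectrograms)                     # N x D x C
    centered = np.transpose(x, (0, 2, 1)) - transform.mean[None]   # N x C x D
    return np.einsum("ckd,ncd->nkc", transform.components, centered)
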