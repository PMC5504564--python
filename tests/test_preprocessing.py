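"""Segmentation, spectrogram, normalization and per-channel PCA checks.

Spectrogram values are verified against a direct windowed-DFT oracle and
cross-checked against scipy's ShortTimeFFT; PCA is verified against a
brute-force covariance eigendecomposition.
"""

import numpy as np
import pytest
import scipy.signal

from semgrecal import (Recording, Segment, compute_spectrogram,
                       fit_normalization, fit_pca, normalize, project_pca,
                       segment_stream)
from semgrecal.errors import ParameterError
from semgrecal.preprocessing import project_pca_batch


def _make_recording(emg, fs=2000.0, labels=None, repetition=None):
    n = emg.shape[0]
    return Recording(
        emg=emg, fs=fs,
        labels=np.zeros(n, dtype=np.int64) if labels is None else labels,
        repetition=np.zeros(n, dtype=np.int64) if repetition is None else repetition,
    )


def _segment(samples, fs=2000.0, label=0):
    return Segment(samples=samples, label=label, repetition=0, index=0, fs=fs)


class TestSegmentStream:
    def test_default_window_count_and_length(self, rng):
        rec = _make_recording(rng.standard_normal((2000, 3)))
        segs = segment_stream(rec)
        assert len(segs) == 9                       # floor((2000-400)/200)+1
        assert all(s.samples.shape == (400, 3) for s in segs)
        assert [s.index for s in segs] == list(range(9))

    def test_non_overlapping_tiling(self, rng):
        rec = _make_recording(rng.standard_normal((1000, 2)))
        segs = segment_stream(rec, window_ms=100, step_ms=100)
        assert len(segs) == 5                       # floor(1000/200)

    def test_constant_label_inherited(self, rng):
        n = 1200
        rec = _make_recording(rng.standard_normal((n, 2)),
                              labels=np.full(n, 3, dtype=np.int64),
                              repetition=np.full(n, 2, dtype=np.int64))
        segs = segment_stream(rec)
        assert all(s.label == 3 and s.repetition == 2 for s in segs)

    def test_mixed_window_takes_mode_with_earlier_tiebreak(self):
        labels = np.concatenate([np.full(190, 5), np.full(210, 1)])
        rec = _make_recording(np.zeros((400, 1)), labels=labels)
        assert segment_stream(rec)[0].label == 1    # 210 > 190
        labels = np.concatenate([np.full(200, 5), np.full(200, 1)])
        rec = _make_recording(np.zeros((400, 1)), labels=labels)
        assert segment_stream(rec)[0].label == 5    # tie -> earlier occurring

    def test_too_short_recording_warns_and_returns_empty(self):
        rec = _make_recording(np.zeros((100, 2)))
        with pytest.warns(UserWarning):
            assert segment_stream(rec) == []


class TestSpectrogram:
    def test_default_dimensions(self, rng):
        seg = _segment(rng.standard_normal((400, 12)))
        full = compute_spectrogram(seg, keep_bins=None)
        assert full.intensities.shape == (129, 3, 12)
        spec = compute_spectrogram(seg)
        assert spec.intensities.shape == (95, 3, 12)
        assert spec.truncated
        assert spec.freq_axis[1] - spec.freq_axis[0] == pytest.approx(7.8125)

    def test_zero_segment_gives_zero_intensities(self):
        spec = compute_spectrogram(_segment(np.zeros((400, 2))))
        assert (spec.intensities == 0).all()

    def test_sinusoid_peaks_at_expected_bin_and_matches_dft_oracle(self):
        """250 Hz at fs 2000, nfft 256 -> bin 32; values equal the direct DFT."""
        t = np.arange(400) / 2000.0
        x = np.sin(2 * np.pi * 250.0 * t)[:, None]
        spec = compute_spectrogram(_segment(x), keep_bins=None)
        assert (spec.intensities[:, :, 0].argmax(axis=0) == 32).all()

        win = scipy.signal.get_window("hamming", 256)
        for tbin, start in enumerate([0, 72, 144]):
            frame = x[start:start + 256, 0]
            oracle = np.abs(np.fft.rfft(frame * win))
            np.testing.assert_allclose(spec.intensities[:, tbin, 0], oracle,
                                       atol=1e-12)

    def test_matches_scipy_shorttimefft_up_to_scaling(self, rng):
        """scipy's STFT agrees once its window-sum scaling is undone."""
        x = rng.standard_normal((400, 1))
        spec = compute_spectrogram(_segment(x), keep_bins=None)
        win = scipy.signal.get_window("hamming", 256)
        stft = scipy.signal.ShortTimeFFT(win, hop=72, fs=2000.0,
                                         scale_to="magnitude", phase_shift=None)
        ours = spec.intensities[:, :, 0]
        theirs = np.abs(stft.stft(x[:, 0], p0=0, p1=3, k_offset=128)) * win.sum()
        np.testing.assert_allclose(ours, theirs, atol=1e-9)

    def test_nfft_longer_than_segment_raises(self, rng):
        with pytest.raises(ParameterError):
            compute_spectrogram(_segment(rng.standard_normal((100, 1))), nfft=256)


class TestNormalization:
    def test_percentiles_match_uniform_quantiles(self, rng):
        """Empirical-quantile oracle: uniform [0, 10] -> p1 ~ 0.1, p99 ~ 9.9."""
        specs = [compute_spectrogram(_segment(rng.standard_normal((400, 1))))
                 for _ in range(3)]
        flat_n = specs[0].intensities.size * 3
        from semgrecal.preprocessing import SpectrogramTensor
        values = rng.uniform(0, 10, (95, 3 * len(specs), 1))
        fake = SpectrogramTensor(intensities=values,
                                 freq_axis=specs[0].freq_axis, truncated=True)
        stats = fit_normalization([fake])
        assert stats.p1[0] == pytest.approx(0.1, abs=0.15)
        assert stats.p99[0] == pytest.approx(9.9, abs=0.15)

    def test_constant_channel_degenerates_to_zero(self):
        from semgrecal.preprocessing import SpectrogramTensor
        const = SpectrogramTensor(intensities=np.full((4, 3, 2), 5.0),
                                  freq_axis=np.arange(4.0), truncated=True)
        stats = fit_normalization([const])
        assert (stats.p1 == stats.p99).all()
        out = normalize(const, stats)
        assert (out.intensities == 0).all()

    def test_endpoints_midpoint_and_clipping(self):
        from semgrecal.preprocessing import NormalizationStats, SpectrogramTensor
        stats = NormalizationStats(p1=np.array([2.0]), p99=np.array([6.0]))
        vals = np.array([2.0, 6.0, 4.0, 8.0, 0.0]).reshape(5, 1, 1)
        spec = SpectrogramTensor(intensities=vals, freq_axis=np.arange(5.0),
                                 truncated=True)
        out = normalize(spec, stats).intensities.ravel()
        np.testing.assert_allclose(out, [0.0, 1.0, 0.5, 1.0, 0.0])

    def test_idempotent_on_normalized_range(self, rng):
        from semgrecal.preprocessing import NormalizationStats, SpectrogramTensor
        spec = SpectrogramTensor(intensities=rng.uniform(0, 1, (10, 3, 2)),
                                 freq_axis=np.arange(10.0), truncated=True)
        unit = NormalizationStats(p1=np.zeros(2), p99=np.ones(2))
        once = normalize(spec, unit)
        twice = normalize(once, unit)
        np.testing.assert_allclose(once.intensities, twice.intensities)


def _random_specs(rng, n=50, n_freq=95, n_time=3, channels=2):
    from semgrecal.preprocessing import SpectrogramTensor
    return [SpectrogramTensor(
        intensities=rng.uniform(0, 1, (n_freq, n_time, channels)),
        freq_axis=np.arange(n_freq, dtype=float), truncated=True)
        for _ in range(n)]


class TestPCA:
    def test_matches_eigendecomposition_oracle(self, rng):
        """Scores equal a brute-force covariance eigendecomposition, tol 1e-8."""
        specs = _random_specs(rng)
        transform = fit_pca(specs, n_components=25)
        x = np.stack([s.intensities.reshape(-1, 2) for s in specs])  # N x D x C
        for c in range(2):
            xc = x[:, :, c]
            centered = xc - xc.mean(axis=0)
            cov = centered.T @ centered / (len(xc) - 1)
            evals, evecs = np.linalg.eigh(cov)
            order = np.argsort(evals)[::-1][:25]
            oracle = centered @ evecs[:, order]        # N x 25, sign-ambiguous
            ours = np.stack([project_pca(s, transform)[:, c] for s in specs])
            for k in range(25):
                sign = np.sign(oracle[:, k] @ ours[:, k])
                np.testing.assert_allclose(ours[:, k], sign * oracle[:, k],
                                           atol=1e-8)

    def test_component_orthonormality_and_score_decorrelation(self, rng):
        specs = _random_specs(rng)
        transform = fit_pca(specs, n_components=10)
        for c in range(transform.n_channels):
            gram = transform.components[c] @ transform.components[c].T
            np.testing.assert_allclose(gram, np.eye(10), atol=1e-10)
        scores = project_pca_batch(specs, transform)
        for c in range(2):
            corr = np.cov(scores[:, :, c].T)
            off = corr - np.diag(np.diag(corr))
            assert np.abs(off).max() < 1e-6

    def test_total_score_count_at_defaults(self, rng):
        specs = _random_specs(rng, n=30, channels=12)
        transform = fit_pca(specs, n_components=25)
        scores = project_pca(specs[0], transform)
        assert scores.shape == (25, 12)
        assert scores.size == 300

    def test_projecting_channel_mean_gives_zero_scores(self, rng):
        from semgrecal.preprocessing import SpectrogramTensor
        specs = _random_specs(rng)
        transform = fit_pca(specs, n_components=5)
        mean_spec = SpectrogramTensor(
            intensities=transform.mean.T.reshape(95, 3, 2),
            freq_axis=specs[0].freq_axis, truncated=True)
        np.testing.assert_allclose(project_pca(mean_spec, transform),
                                   0.0, atol=1e-12)

    def test_rank_one_data_explained_by_first_component(self, rng):
        from semgrecal.preprocessing import SpectrogramTensor
        direction = rng.standard_normal(95 * 3)
        specs = []
        for _ in range(30):
            t = rng.standard_normal()
            v = (t * direction).reshape(95, 3, 1)
            specs.append(SpectrogramTensor(intensities=v,
                                           freq_axis=np.arange(95.0),
                                           truncated=True))
        transform = fit_pca(specs, n_components=3)
        scores = project_pca_batch(specs, transform)
        var = scores[:, :, 0].var(axis=0)
        assert var[0] > 0
        assert var[1] / var[0] < 1e-10 and var[2] / var[0] < 1e-10

    def test_reconstruction_error_monotone_in_components(self, rng):
        specs = _random_specs(rng, n=40, channels=1)
        x = np.stack([s.intensities.reshape(-1) for s in specs])
        errors = []
        for k in (24, 25):
            tr = fit_pca(specs, n_components=k)
            centered = x - tr.mean[0]
            recon = centered @ tr.components[0].T @ tr.components[0]
            errors.append(((centered - recon) ** 2).sum())
        assert errors[1] <= errors[0]

    def test_too_few_segments_raises(self, rng):
        with pytest.raises(ParameterError):
            fit_pca(_random_specs(rng, n=10), n_components=25)
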