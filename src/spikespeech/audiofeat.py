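"""Mel-spectrogram targets and audio reconstruction.

The decoding target is the mel-scaled power spectrogram of the session
audio: a short-time Fourier transform (Hann window, centered frames,
reflect padding, FFT window 2048 by default) compressed onto triangular,
mel-spaced filters covering 0 Hz to the Nyquist frequency. Targets are
per-band zero-mean standardized with means fitted on training frames
only. Reconstruction inverts the filterbank (pseudo-inverse, clipped at
zero) and recovers phase with the Griffin-Lim algorithm.

Targets are linear mel power by default; a dB scale is available via
``log_power=True`` on :func:`mel_compress` for experimentation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import fft as sp_fft
from scipy.signal.windows import hann
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "MelSpec",
    "TargetStandardizer",
    "stft_magnitude",
    "istft",
    "mel_filterbank",
    "mel_compress",
    "mel_invert",
    "griffin_lim",
    "fit_standardizer",
    "n_frames_for",
]

MEL_BAND_GRID = (32, 64, 128, 256)
HOP_MS_GRID = (10, 20, 30, 40, 50)


@dataclass
class MelSpec:
    """A band x frame mel-scaled power spectrogram."""

    values: np.ndarray
    n_mels: int
    hop: float
    n_fft: int
    fs: float

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2 or self.values.shape[0] != self.n_mels:
            raise ValueError("values must be a (n_mels, n_frames) matrix")
        if np.any(self.values < 0):
            raise ValueError("mel power must be nonnegative")

    @property
    def n_frames(self) -> int:
        return self.values.shape[1]


def _hop_samples(hop: float, fs: float) -> int:
    hop_n = hop * fs
    if hop_n <= 0 or abs(hop_n - round(hop_n)) > 1e-9:
        raise ValueError(f"hop ({hop} s) must be a positive integer number of samples at fs={fs}")
    return int(round(hop_n))


def n_frames_for(n_samples: int, hop: float, fs: float) -> int:
    """Frame count of a centered STFT: ``floor(n_samples/hop) + 1``."""
    return n_samples // _hop_samples(hop, fs) + 1


def _frame(audio: np.ndarray, n_fft: int, hop_n: int) -> np.ndarray:
    pad = n_fft // 2
    if audio.size < 1:
        raise ValueError("audio is empty")
    # reflect padding needs at least pad+1 samples; fall back to zeros at the ends
    if audio.size > pad:
        x = np.pad(audio, pad, mode="reflect")
    else:
        x = np.pad(audio, pad, mode="constant")
    n_frames = audio.size // hop_n + 1
    idx = np.arange(n_fft)[None, :] + hop_n * np.arange(n_frames)[:, None]
    return x[idx]


def stft_magnitude(
    audio: np.ndarray, fs: float, n_fft: int = 2048, hop: float = 0.040
) -> np.ndarray:
    """Magnitude spectrogram, shape ``(n_fft // 2 + 1, n_frames)``.

    Frames are Hann-windowed, centered (frame ``t`` is centered on sample
    ``t * hop * fs``), with reflect padding at the edges.
    """
    audio = np.asarray(audio, dtype=np.float64)
    hop_n = _hop_samples(hop, fs)
    frames = _frame(audio, n_fft, hop_n)
    win = hann(n_fft, sym=False)
    spec = sp_fft.rfft(frames * win, axis=1)
    return np.abs(spec).T


def _stft_complex(audio: np.ndarray, n_fft: int, hop_n: int) -> np.ndarray:
    frames = _frame(np.asarray(audio, dtype=np.float64), n_fft, hop_n)
    win = hann(n_fft, sym=False)
    return sp_fft.rfft(frames * win, axis=1).T


def istft(spec: np.ndarray, n_fft: int, hop_n: int, n_samples: int) -> np.ndarray:
    """Inverse STFT by windowed overlap-add with squared-window normalization."""
    win = hann(n_fft, sym=False)
    frames = sp_fft.irfft(spec.T, n=n_fft, axis=1) * win
    n_frames = frames.shape[0]
    total = hop_n * (n_frames - 1) + n_fft
    out = np.zeros(total)
    norm = np.zeros(total)
    w2 = win**2
    for t in range(n_frames):
        start = t * hop_n
        out[start : start + n_fft] += frames[t]
        norm[start : start + n_fft] += w2
    out = out / np.maximum(norm, 1e-12)
    pad = n_fft // 2
    return out[pad : pad + n_samples]


def _hz_to_mel(f: np.ndarray | float) -> np.ndarray:
    return 2595.0 * np.log10(1.0 + np.asarray(f, dtype=np.float64) / 700.0)


def _mel_to_hz(m: np.ndarray | float) -> np.ndarray:
    return 700.0 * (10.0 ** (np.asarray(m, dtype=np.float64) / 2595.0) - 1.0)


def mel_filterbank(n_mels: int, n_fft: int, fs: float) -> np.ndarray:
    """Triangular mel-spaced filters, 0 Hz to fs/2, area-normalized.

    Returns a ``(n_mels, n_fft // 2 + 1)`` weight matrix. Rows are
    normalized to unit area (2 / bandwidth in Hz), so summed band energy
    never exceeds summed spectral energy.
    """
    if n_mels < 1:
        raise ValueError("n_mels must be >= 1")
    n_bins = n_fft // 2 + 1
    freqs = np.linspace(0.0, fs / 2.0, n_bins)
    mel_pts = np.linspace(_hz_to_mel(0.0), _hz_to_mel(fs / 2.0), n_mels + 2)
    hz_pts = _mel_to_hz(mel_pts)
    fb = np.zeros((n_mels, n_bins))
    for m in range(n_mels):
        lo, ctr, hi = hz_pts[m], hz_pts[m + 1], hz_pts[m + 2]
        up = (freqs - lo) / max(ctr - lo, 1e-12)
        down = (hi - freqs) / max(hi - ctr, 1e-12)
        fb[m] = np.maximum(0.0, np.minimum(up, down))
        fb[m] *= 2.0 / max(hi - lo, 1e-12)
    return fb


def mel_compress(
    spec: np.ndarray,
    n_mels: int,
    fs: float,
    n_fft: int,
    hop: float,
    log_power: bool = False,
) -> MelSpec:
    """Compress a magnitude spectrogram onto *n_mels* mel bands (power scale)."""
    spec = np.asarray(spec, dtype=np.float64)
    fb = mel_filterbank(n_mels, n_fft, fs)
    values = fb @ (spec**2)
    if log_power:
        # dB re 1e-12 power floor; +120 dB offset keeps the scale nonnegative
        values = np.maximum(10.0 * np.log10(np.maximum(values, 1e-12)) + 120.0, 0.0)
    return MelSpec(values=values, n_mels=n_mels, hop=hop, n_fft=n_fft, fs=fs)


def melspectrogram(
    audio: np.ndarray, fs: float, n_mels: int = 128, n_fft: int = 2048, hop: float = 0.040
) -> MelSpec:
    """Audio straight to mel power: :func:`stft_magnitude` + :func:`mel_compress`."""
    return mel_compress(stft_magnitude(audio, fs, n_fft, hop), n_mels, fs, n_fft, hop)


def mel_invert(mel: MelSpec) -> np.ndarray:
    """Approximate the linear magnitude spectrogram from mel power.

    Solves the filterbank inversion per frame with the Moore-Penrose
    pseudo-inverse, clips negative power to zero, and returns magnitudes.
    Negative mel inputs (possible in decoder output) are clipped first.
    """
    fb = mel_filterbank(mel.n_mels, mel.n_fft, mel.fs)
    power = np.linalg.pinv(fb) @ np.maximum(mel.values, 0.0)
    return np.sqrt(np.maximum(power, 0.0))


def griffin_lim(
    spec: np.ndarray,
    fs: float,
    n_fft: int = 2048,
    hop: float = 0.040,
    n_iter: int = 64,
    seed: int = 0,
    return_errors: bool = False,
):
    """Recover a waveform from a magnitude spectrogram by Griffin-Lim.

    Alternates between enforcing the target magnitudes and projecting
    onto the set of consistent STFTs, starting from seeded random phase.

    Parameters
    ----------
    spec : ndarray (n_bins, n_frames)
        Target magnitude spectrogram (nonnegative).
    n_iter : int
        Number of projection iterations (>= 1).
    seed : int
        Seed for the random phase initialization.
    return_errors : bool
        If True, also return the per-iteration spectral-convergence error
        ``|| |STFT(x)| - spec ||_F / ||spec||_F``.
    """
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    spec = np.asarray(spec, dtype=np.float64)
    if np.any(spec < 0):
        raise ValueError("magnitude spectrogram must be nonnegative")
    hop_n = _hop_samples(hop, fs)
    n_samples = (spec.shape[1] - 1) * hop_n
    if n_samples <= 0:
        n_samples = hop_n
    rng = np.random.default_rng(seed)
    phase = np.exp(2j * np.pi * rng.random(spec.shape))
    denom = np.linalg.norm(spec)
    errors = []
    x = istft(spec * phase, n_fft, hop_n, n_samples)
    for _ in range(n_iter):
        stft_x = _stft_complex(x, n_fft, hop_n)[:, : spec.shape[1]]
        mag = np.abs(stft_x)
        errors.append(float(np.linalg.norm(mag - spec) / max(denom, 1e-12)))
        phase = stft_x / np.maximum(mag, 1e-12)
        x = istft(spec * phase, n_fft, hop_n, n_samples)
    if return_errors:
        return x, np.asarray(errors)
    return x


class TargetStandardizer(TransformerMixin, BaseEstimator):
    """Per-band zero-mean standardization of mel targets.

    Fitted on training frames only; validation and test frames are
    transformed with the training means. ``inverse_transform`` restores
    the original scale. Frames are rows (frame x band layout).
    """

    def fit(self, X: np.ndarray, y=None) -> "TargetStandardizer":
        X = np.asarray(X, dtype=np.float64)
        if X.ndim != 2 or X.shape[0] < 1:
            raise ValueError("need a non-empty (n_frames, n_bands) matrix")
        self.mean_ = X.mean(axis=0)
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=np.float64) - self.mean_

    def inverse_transform(self, X: np.ndarray) -> np.ndarray:
        return np.asarray(X, dtype=np.float64) + self.mean_


def fit_standardizer(train_frames: np.ndarray) -> TargetStandardizer:
    """Fit a :class:`TargetStandardizer` on training frames (frame x band)."""
    train_frames = np.asarray(train_frames)
    if train_frames.shape[0] < 2:
        raise ValueError("need at least 2 training frames")
    return TargetStandardizer().fit(train_frames)
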