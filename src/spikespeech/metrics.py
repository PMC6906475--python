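"""Reconstruction-quality metrics for decoded audio.

Six metrics compare a reconstruction against its target:

1. Fisher-mean mel correlation — per-band Pearson r between target and
   predicted mel-spectrograms, averaged through Fisher's z-transform.
2. Envelope correlation — Pearson r between the 50 Hz low-passed
   Hilbert envelopes of the two waveforms.
3. Gross pitch error (GPE) — percentage of target-voiced frames whose
   relative fundamental-frequency error exceeds 20% (strict), with F0
   tracked by the normalized correlation function (NCF) method.
4. Mean loudness factor — time mean of ``2^(|l - l_hat| / 10)`` over
   momentary loudness (ITU-R BS.1770-4 / EBU R 128 K-weighted LUFS,
   400 ms windows, 75% overlap); 1 is perfect, a constant 10 dB error
   scores 2 (a perceived doubling/halving of loudness).
5. ESTOI — extended short-time objective intelligibility: third-octave
   subband envelopes, row/column-normalized over 384 ms segments,
   orthogonal projection of the degraded onto the clean representation.
6. STMI — spectro-temporal modulation index
   ``1 - ||T - N||^2 / ||T||^2`` over time-averaged modulation content
   of an auditory (log-frequency) spectrogram filtered by a bank of
   spectro-temporal modulation filters.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "MetricReport",
    "PitchTrack",
    "fisher_mean_correlation",
    "envelope",
    "envelope_correlation",
    "ncf_pitch",
    "gross_pitch_error",
    "momentary_loudness",
    "mean_loudness_factor",
    "estoi",
    "stmi",
    "stmi_index",
    "evaluate_all",
]

SILENCE_FLOOR_LUFS = -120.0


@dataclass
class MetricReport:
    """Per-split metric values for one decoding model."""

    fisher_mean_r: float
    envelope_r: float
    gpe_percent: float
    mean_loudness_factor: float
    estoi: float
    stmi: float

    def as_dict(self) -> dict:
        return {
            "fisher_mean_r": self.fisher_mean_r,
            "envelope_r": self.envelope_r,
            "gpe_percent": self.gpe_percent,
            "mean_loudness_factor": self.mean_loudness_factor,
            "estoi": self.estoi,
            "stmi": self.stmi,
        }


@dataclass
class PitchTrack:
    """Frame-wise F0 estimates (Hz) with voicing decisions."""

    f0: np.ndarray
    voiced: np.ndarray
    hop: float


# ---------------------------------------------------------------- correlation

def fisher_mean_correlation(Y: np.ndarray, Y_hat: np.ndarray) -> float:
    """Mean per-band Pearson correlation through Fisher's z-transform.

    Correlations are z-transformed (``atanh``), averaged across bands,
    and mapped back with ``tanh``. Bands with zero variance in either
    input are excluded; r values are clipped away from +/-1 before the
    transform. Inputs are (band, frame) matrices.
    """
    Y = np.asarray(Y, dtype=np.float64)
    Y_hat = np.asarray(Y_hat, dtype=np.float64)
    if Y.shape != Y_hat.shape or Y.shape[1] < 3:
        raise ValueError("need equal (band, frame) matrices with >= 3 frames")
    yc = Y - Y.mean(axis=1, keepdims=True)
    pc = Y_hat - Y_hat.mean(axis=1, keepdims=True)
    sy = np.sqrt((yc**2).sum(axis=1))
    sp = np.sqrt((pc**2).sum(axis=1))
    valid = (sy > 0) & (sp > 0)
    if not np.any(valid):
        raise ValueError("all bands have zero variance")
    r = (yc[valid] * pc[valid]).sum(axis=1) / (sy[valid] * sp[valid])
    z = np.arctanh(np.clip(r, -1 + 1e-7, 1 - 1e-7))
    return float(np.tanh(z.mean()))


# ------------------------------------------------------------------- envelope

def envelope(audio: np.ndarray, fs: float, cutoff_hz: float = 50.0) -> np.ndarray:
    """Temporal envelope: |Hilbert transform| low-passed (zero-phase, 4th order)."""
    audio = np.asarray(audio, dtype=np.float64)
    mag = np.abs(signal.hilbert(audio))
    sos = signal.butter(4, cutoff_hz, btype="low", fs=fs, output="sos")
    return signal.sosfiltfilt(sos, mag)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = x - x.mean()
    y = y - y.mean()
    denom = np.sqrt((x**2).sum() * (y**2).sum())
    if denom == 0:
        return 0.0
    return float((x * y).sum() / denom)


def envelope_correlation(x: np.ndarray, y: np.ndarray, fs: float) -> float:
    """Pearson correlation between the temporal envelopes of two signals."""
    x, y = np.asarray(x), np.asarray(y)
    if x.shape != y.shape:
        raise ValueError("signals must have equal length")
    return _pearson(envelope(x, fs), envelope(y, fs))


# ---------------------------------------------------------------------- pitch

def ncf_pitch(
    audio: np.ndarray,
    fs: float,
    f0_range: tuple[float, float] = (50.0, 400.0),
    frame: float = 0.040,
    hop: float = 0.040,
    voicing_threshold: float = 0.6,
) -> PitchTrack:
    """Frame-wise F0 by the normalized correlation function (NCF).

    For each frame the NCF is evaluated over lags spanning the F0 search
    range; the maximizing lag gives the F0 estimate, and the frame is
    voiced when the NCF peak reaches *voicing_threshold* and the frame
    is not silent.
    """
    lo, hi = f0_range
    if hi >= fs / 2:
        raise ValueError("f0 range must lie well below the Nyquist frequency")
    audio = np.asarray(audio, dtype=np.float64)
    frame_n = int(round(frame * fs))
    hop_n = int(round(hop * fs))
    lag_min = max(2, int(np.floor(fs / hi)))
    lag_max = int(np.ceil(fs / lo))
    if frame_n < 2 * lag_max:
        frame_n = 2 * lag_max  # guarantee >= 2 periods of the lowest f0
    n_frames = max(0, 1 + (audio.size - frame_n) // hop_n)
    f0 = np.zeros(n_frames)
    voiced = np.zeros(n_frames, dtype=bool)
    silence_rms = 1e-6 + 1e-4 * np.sqrt(np.mean(audio**2))
    for i in range(n_frames):
        x = audio[i * hop_n : i * hop_n + frame_n]
        if np.sqrt(np.mean(x**2)) < silence_rms:
            continue
        # full autocorrelation via FFT, normalized per lag
        nfft = int(2 ** np.ceil(np.log2(2 * frame_n)))
        spec = np.fft.rfft(x, nfft)
        ac = np.fft.irfft(spec * np.conj(spec), nfft)[: lag_max + 1]
        e = np.concatenate(([0.0], np.cumsum(x**2)))
        lags = np.arange(lag_min, lag_max + 1)
        e_head = e[frame_n - lags] - e[0]
        e_tail = e[frame_n] - e[lags]
        denom = np.sqrt(e_head * e_tail)
        ncf = np.where(denom > 0, ac[lag_min:] / np.maximum(denom, 1e-20), 0.0)
        k = int(np.argmax(ncf))
        if ncf[k] >= voicing_threshold:
            voiced[i] = True
            f0[i] = fs / lags[k]
    return PitchTrack(f0=f0, voiced=voiced, hop=hop)


def gross_pitch_error(
    f0: np.ndarray,
    f0_hat: np.ndarray,
    p: float = 0.2,
    voiced: np.ndarray | None = None,
) -> float:
    """GPE: percent of target-voiced frames with relative F0 error > p.

    A frame is an error iff ``|F0 - F0_hat| > F0 * p`` (strict), so an
    error of exactly 20% does not count. Frames unvoiced in the target
    are excluded via *voiced*; reconstruction frames with no pitch
    (``f0_hat == 0`` or NaN) count as errors.
    """
    f0 = np.asarray(f0, dtype=np.float64)
    f0_hat = np.asarray(f0_hat, dtype=np.float64)
    if f0.shape != f0_hat.shape:
        raise ValueError("pitch tracks must have equal length")
    mask = np.ones(f0.shape, dtype=bool) if voiced is None else np.asarray(voiced, dtype=bool)
    n = int(mask.sum())
    if n == 0:
        raise ValueError("no voiced target frames")
    t = f0[mask]
    h = f0_hat[mask]
    err = np.abs(t - h) > t * p
    err |= ~np.isfinite(h) | (h <= 0)
    return float(err.sum() / n * 100.0)


# ------------------------------------------------------------------- loudness

def _k_weighting_sos(fs: float) -> np.ndarray:
    """K-weighting per ITU-R BS.1770-4: high shelf + high pass, any fs."""
    # stage 1: high shelf
    f0, G, Q = 1681.9744509555319, 3.99984385397, 0.7071752369554193
    K = np.tan(np.pi * f0 / fs)
    Vh = 10.0 ** (G / 20.0)
    Vb = Vh**0.499666774155
    a0 = 1.0 + K / Q + K * K
    shelf_b = np.array([Vh + Vb * K / Q + K * K, 2.0 * (K * K - Vh), Vh - Vb * K / Q + K * K]) / a0
    shelf_a = np.array([1.0, 2.0 * (K * K - 1.0) / a0, (1.0 - K / Q + K * K) / a0])
    # stage 2: high pass
    f0, Q = 38.13547087602444, 0.5003270373238773
    K = np.tan(np.pi * f0 / fs)
    a0 = 1.0 + K / Q + K * K
    hp_b = np.array([1.0, -2.0, 1.0])
    hp_a = np.array([1.0, 2.0 * (K * K - 1.0) / a0, (1.0 - K / Q + K * K) / a0])
    return np.vstack([np.concatenate([shelf_b, shelf_a]), np.concatenate([hp_b, hp_a])])


def momentary_loudness(audio: np.ndarray, fs: float) -> np.ndarray:
    """Momentary loudness series in LUFS (400 ms windows, 75% overlap).

    The signal is K-weighted (shelving then high-pass biquads designed
    for the given sample rate) and the loudness of each window is
    ``-0.691 + 10 log10(mean square)``. Windows of digital silence are
    floored at :data:`SILENCE_FLOOR_LUFS`.
    """
    audio = np.asarray(audio, dtype=np.float64)
    win_n = int(round(0.400 * fs))
    step_n = int(round(0.100 * fs))
    if audio.size < win_n:
        raise ValueError("audio shorter than one 400 ms loudness window")
    y = signal.sosfilt(_k_weighting_sos(fs), audio)
    n_win = 1 + (y.size - win_n) // step_n
    e = np.concatenate(([0.0], np.cumsum(y**2)))
    starts = np.arange(n_win) * step_n
    ms = (e[starts + win_n] - e[starts]) / win_n
    with np.errstate(divide="ignore"):
        lufs = -0.691 + 10.0 * np.log10(ms)
    return np.maximum(lufs, SILENCE_FLOOR_LUFS)


def mean_loudness_factor(l: np.ndarray, l_hat: np.ndarray) -> float:
    """Time mean of the loudness factor ``2^(|l - l_hat| / 10)`` (>= 1)."""
    l = np.asarray(l, dtype=np.float64)
    l_hat = np.asarray(l_hat, dtype=np.float64)
    if l.shape != l_hat.shape:
        raise ValueError("loudness series must have equal length")
    return float(np.mean(2.0 ** (np.abs(l - l_hat) / 10.0)))


# ---------------------------------------------------------------------- ESTOI

_ESTOI_FS = 10000
_ESTOI_FRAME = 256
_ESTOI_HOP = 128
_ESTOI_NFFT = 512
_ESTOI_NBANDS = 15
_ESTOI_MINFREQ = 150.0
_ESTOI_SEG = 30  # frames per 384 ms segment
_ESTOI_DYN_RANGE = 40.0


def _resample_to(audio: np.ndarray, fs: float, target: int) -> np.ndarray:
    if fs == target:
        return audio
    from fractions import Fraction

    frac = Fraction(int(round(target)), int(round(fs))).limit_denominator(1000)
    return signal.resample_poly(audio, frac.numerator, frac.denominator)


def _stoi_frames(x: np.ndarray) -> np.ndarray:
    n = 1 + (x.size - _ESTOI_FRAME) // _ESTOI_HOP
    if n < 1:
        raise ValueError("signal too short for ESTOI framing")
    idx = np.arange(_ESTOI_FRAME)[None, :] + _ESTOI_HOP * np.arange(n)[:, None]
    return x[idx] * np.hanning(_ESTOI_FRAME)


def _third_octave_matrix() -> np.ndarray:
    f = np.arange(_ESTOI_NFFT // 2 + 1) * _ESTOI_FS / _ESTOI_NFFT
    cfs = _ESTOI_MINFREQ * 2.0 ** (np.arange(_ESTOI_NBANDS) / 3.0)
    mat = np.zeros((_ESTOI_NBANDS, f.size))
    for i, cf in enumerate(cfs):
        f1, f2 = cf / 2 ** (1 / 6), cf * 2 ** (1 / 6)
        mat[i, (f >= f1) & (f < f2)] = 1.0
    return mat


def estoi(clean: np.ndarray, noisy: np.ndarray, fs: float) -> float:
    """Extended short-time objective intelligibility of *noisy* given *clean*.

    Both signals are resampled to 10 kHz; frames more than 40 dB below
    the loudest clean frame are removed from both; 15 third-octave
    subband envelopes are formed from 512-point spectra; each sliding
    384 ms (30-frame) segment is row- then column-normalized and the
    intermediate score is the mean projection of degraded onto clean
    columns; the final score averages segments.
    """
    clean = np.asarray(clean, dtype=np.float64)
    noisy = np.asarray(noisy, dtype=np.float64)
    if clean.shape != noisy.shape:
        raise ValueError("signals must have equal length")
    x = _resample_to(clean, fs, _ESTOI_FS)
    y = _resample_to(noisy, fs, _ESTOI_FS)
    xf = _stoi_frames(x)
    yf = _stoi_frames(y)
    energy = 20.0 * np.log10(np.linalg.norm(xf, axis=1) + 1e-20)
    keep = energy > energy.max() - _ESTOI_DYN_RANGE
    if not np.any(keep):
        raise ValueError("clean signal is entirely silent")
    xf, yf = xf[keep], yf[keep]
    if xf.shape[0] < _ESTOI_SEG:
        raise ValueError("need at least 384 ms of non-silent clean signal")
    band = _third_octave_matrix()
    X = np.sqrt(band @ (np.abs(np.fft.rfft(xf, _ESTOI_NFFT, axis=1)).T ** 2))
    Y = np.sqrt(band @ (np.abs(np.fft.rfft(yf, _ESTOI_NFFT, axis=1)).T ** 2))
    scores = []
    for m in range(X.shape[1] - _ESTOI_SEG + 1):
        Xs = X[:, m : m + _ESTOI_SEG]
        Ys = Y[:, m : m + _ESTOI_SEG]
        Xs = Xs - Xs.mean(axis=1, keepdims=True)
        Ys = Ys - Ys.mean(axis=1, keepdims=True)
        Xs = Xs / (np.linalg.norm(Xs, axis=1, keepdims=True) + 1e-20)
        Ys = Ys / (np.linalg.norm(Ys, axis=1, keepdims=True) + 1e-20)
        Xs = Xs - Xs.mean(axis=0, keepdims=True)
        Ys = Ys - Ys.mean(axis=0, keepdims=True)
        Xs = Xs / (np.linalg.norm(Xs, axis=0, keepdims=True) + 1e-20)
        Ys = Ys / (np.linalg.norm(Ys, axis=0, keepdims=True) + 1e-20)
        scores.append(np.sum(Xs * Ys) / _ESTOI_SEG)
    return float(np.mean(scores))


# ----------------------------------------------------------------------- STMI

STMI_RATES_HZ = (2.0, 4.0, 8.0, 16.0, 32.0)
STMI_SCALES_CPO = (0.25, 0.5, 1.0, 2.0, 4.0, 8.0)
_STMI_NCHAN = 128
_STMI_FMIN = 100.0
_STMI_HOP = 0.005


def _auditory_spectrogram(audio: np.ndarray, fs: float) -> np.ndarray:
    """Constant-Q-style log-frequency magnitude spectrogram (128 channels).

    Gaussian filters with constant log2-frequency bandwidth applied to a
    linear STFT magnitude; everything stays linear in amplitude so the
    modulation content scales with the waveform.
    """
    n_fft = 2048 if fs >= 16000 else 1024
    hop_n = int(round(_STMI_HOP * fs))
    n = audio.size
    if n < n_fft:
        audio = np.pad(audio, (0, n_fft - n))
        n = audio.size
    n_frames = 1 + (n - n_fft) // hop_n
    idx = np.arange(n_fft)[None, :] + hop_n * np.arange(n_frames)[:, None]
    frames = audio[idx] * np.hanning(n_fft)
    mag = np.abs(np.fft.rfft(frames, axis=1)).T  # (bins, frames)
    freqs = np.arange(mag.shape[0]) * fs / n_fft
    fmax = fs / 2.0
    centers = _STMI_FMIN * 2.0 ** (
        np.linspace(0.0, np.log2(fmax / _STMI_FMIN), _STMI_NCHAN)
    )
    oct_axis = np.full(freqs.size, -np.inf)
    oct_axis[1:] = np.log2(freqs[1:] / _STMI_FMIN)
    bw_oct = np.log2(fmax / _STMI_FMIN) / _STMI_NCHAN * 1.5
    fb = np.exp(
        -0.5 * ((oct_axis[None, :] - np.log2(centers / _STMI_FMIN)[:, None]) / bw_oct) ** 2
    )
    fb[:, 0] = 0.0
    return fb @ mag  # (channels, frames)


def _modulation_content(aud: np.ndarray) -> np.ndarray:
    """Time-averaged spectro-temporal modulation energy (rate x scale x channel)."""
    n_ch, n_fr = aud.shape
    frame_rate = 1.0 / _STMI_HOP
    ch_per_oct = _STMI_NCHAN / np.log2(15000.0 / _STMI_FMIN)
    A = np.fft.fft2(aud)
    ft = np.fft.fftfreq(n_fr, d=1.0 / frame_rate)[None, :]
    fc = np.fft.fftfreq(n_ch, d=1.0 / ch_per_oct)[:, None]
    out = np.zeros((len(STMI_RATES_HZ), len(STMI_SCALES_CPO), n_ch))
    analytic = (ft > 0).astype(float) * 2.0  # temporal analytic signal
    for ri, rate in enumerate(STMI_RATES_HZ):
        Hr = np.exp(-0.5 * ((np.abs(ft) - rate) / (0.5 * rate)) ** 2)
        for si, scale in enumerate(STMI_SCALES_CPO):
            Hs = np.exp(-0.5 * ((np.abs(fc) - scale) / (0.5 * scale)) ** 2)
            resp = np.fft.ifft2(A * Hr * Hs * analytic)
            out[ri, si] = np.abs(resp).mean(axis=1)
    return out


def stmi_index(T: np.ndarray, N: np.ndarray) -> float:
    """The index ``1 - ||T - N||^2 / ||T||^2`` on modulation-content arrays."""
    T = np.asarray(T, dtype=np.float64)
    N = np.asarray(N, dtype=np.float64)
    denom = float(np.sum(T**2))
    if denom == 0:
        raise ValueError("silent target: ||T|| is zero")
    return float(1.0 - np.sum((T - N) ** 2) / denom)


def stmi(target_audio: np.ndarray, noisy_audio: np.ndarray, fs: float) -> float:
    """Spectro-temporal modulation index of a reconstruction.

    Both signals pass through the auditory spectrogram and the
    modulation filterbank (rates 2-32 Hz, scales 0.25-8 cyc/oct); the
    index compares their time-averaged modulation content.
    """
    target_audio = np.asarray(target_audio, dtype=np.float64)
    noisy_audio = np.asarray(noisy_audio, dtype=np.float64)
    if target_audio.shape != noisy_audio.shape:
        raise ValueError("signals must have equal length")
    T = _modulation_content(_auditory_spectrogram(target_audio, fs))
    N = _modulation_content(_auditory_spectrogram(noisy_audio, fs))
    return stmi_index(T, N)


# -------------------------------------------------------------------- summary

def evaluate_all(
    target_audio: np.ndarray,
    recon_audio: np.ndarray,
    fs: float,
    target_mel: np.ndarray | None = None,
    recon_mel: np.ndarray | None = None,
    hop: float = 0.040,
) -> MetricReport:
    """All six metrics for one (target, reconstruction) pair.

    If mel matrices are omitted they are computed from the waveforms at
    128 bands / the given hop.
    """
    from .audiofeat import melspectrogram

    if target_mel is None:
        target_mel = melspectrogram(target_audio, fs, n_mels=128, hop=hop).values
    if recon_mel is None:
        recon_mel = melspectrogram(recon_audio, fs, n_mels=128, hop=hop).values
    pt = ncf_pitch(target_audio, fs, hop=hop)
    pr = ncf_pitch(recon_audio, fs, hop=hop)
    n = min(pt.f0.size, pr.f0.size)
    gpe = gross_pitch_error(pt.f0[:n], pr.f0[:n], voiced=pt.voiced[:n])
    lt = momentary_loudness(target_audio, fs)
    lr = momentary_loudness(recon_audio, fs)
    m = min(lt.size, lr.size)
    return MetricReport(
        fisher_mean_r=fisher_mean_correlation(target_mel, recon_mel),
        envelope_r=envelope_correlation(target_audio, recon_audio, fs),
        gpe_percent=gpe,
        mean_loudness_factor=mean_loudness_factor(lt[:m], lr[:m]),
        estoi=estoi(target_audio, recon_audio, fs),
        stmi=stmi(target_audio, recon_audio, fs),
    )
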