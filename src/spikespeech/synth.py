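"""Synthetic listening sessions with a known audio-to-spiking link.

Real sessions pair a microphone track with broadband multielectrode
recordings from auditory cortex while word-like sounds play in
pseudorandom order at roughly one-second intervals, each sound repeated
40-60 times. This module emulates that setup end to end with a known
generative model so every downstream stage can be validated:

* word-like audio tokens — a harmonic source with swept formant
  resonances and an attack/decay envelope, spectrally distinct per token;
* an encoding model — each informative channel carries a smooth,
  localized spectrotemporal receptive field (STRF) mapping recent
  mel-band power to a firing rate through a half-wave rectification
  (the rectification makes the code nonlinear, the regime where gated
  recurrent decoders are expected to beat linear ones);
* broadband traces — inhomogeneous Poisson spikes rendered as biphasic
  extracellular waveforms on top of mixed white/pink noise.

Everything is deterministic given the relevant seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .audiofeat import melspectrogram
from .io_formats import RecordingBundle, TrialTable

__all__ = [
    "TokenSpec",
    "EncodingModel",
    "SessionSpec",
    "default_vocabulary",
    "synth_token_audio",
    "build_session",
    "sample_encoding_model",
    "default_spike_waveform",
    "encode_neural",
    "make_session",
]

TOKEN_RMS = 0.1  # normalization level of every synthesized token


@dataclass
class TokenSpec:
    """A word-like synthetic sound.

    ``formant_tracks`` is a list of ``(start_hz, end_hz)`` resonance
    sweeps; ``attack``/``decay`` give the envelope ramps in seconds.
    """

    name: str
    duration: float
    f0: float
    formant_tracks: list[tuple[float, float]]
    attack: float = 0.04
    decay: float = 0.08
    formant_bandwidth: float = 120.0

    def validate(self, fs: float) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        for lo, hi in self.formant_tracks:
            if max(lo, hi) >= fs / 2:
                raise ValueError("formant centers must lie below the Nyquist frequency")


@dataclass
class EncodingModel:
    """Generative audio-to-spiking model for one session.

    ``strf`` has shape (channel, mel band, lag); rates are
    ``rectify(baseline + gain * (strf (*) mel power))`` evaluated on the
    hop grid. ``waveform`` is the biphasic spike template inserted at
    each spike time (negative peak, extracellular convention).
    """

    strf: np.ndarray
    baseline: np.ndarray
    gain: float
    waveform: np.ndarray
    noise_sd: float = 5.0
    pink_fraction: float = 0.5
    seed: int = 0
    n_fft: int = 1024
    hop: float = 0.010

    def __post_init__(self) -> None:
        self.strf = np.asarray(self.strf, dtype=np.float64)
        self.baseline = np.asarray(self.baseline, dtype=np.float64)
        self.waveform = np.asarray(self.waveform, dtype=np.float64)
        if self.strf.ndim != 3:
            raise ValueError("strf must be (channel, band, lag)")
        if self.strf.shape[2] < 1:
            raise ValueError("need at least one lag")
        if np.any(self.baseline < 0):
            raise ValueError("baseline rates must be nonnegative")
        if self.waveform.min() >= 0:
            raise ValueError("spike waveform peak must be negative")

    @property
    def n_channels(self) -> int:
        return self.strf.shape[0]

    @property
    def n_mels(self) -> int:
        return self.strf.shape[1]

    @property
    def n_lags(self) -> int:
        return self.strf.shape[2]


@dataclass
class SessionSpec:
    """One synthetic listening session.

    Defaults follow the emulated task structure: each token repeated
    40-60 times in seeded pseudorandom order at ~1 s intervals.
    """

    vocabulary: list[TokenSpec] = field(default_factory=lambda: default_vocabulary())
    reps_per_token: int = 40
    iti: float = 1.0
    fs: float = 30000.0
    seed: int = 0

    def validate(self) -> None:
        if not self.vocabulary:
            raise ValueError("vocabulary is empty")
        if self.reps_per_token < 1:
            raise ValueError("reps_per_token must be >= 1")
        if self.iti <= 0:
            raise ValueError("iti must be positive")
        for tok in self.vocabulary:
            tok.validate(self.fs)


def default_vocabulary() -> list[TokenSpec]:
    """Three spectrally distinct word-like tokens (different lengths, f0s, formants)."""
    return [
        TokenSpec("bah", duration=0.35, f0=120.0,
                  formant_tracks=[(750.0, 550.0), (1300.0, 1000.0)]),
        TokenSpec("dee", duration=0.50, f0=170.0,
                  formant_tracks=[(320.0, 380.0), (2400.0, 2700.0)]),
        TokenSpec("koo", duration=0.42, f0=95.0,
                  formant_tracks=[(420.0, 330.0), (3600.0, 3100.0)]),
    ]


def synth_token_audio(spec: TokenSpec, fs: float, seed: int = 0) -> np.ndarray:
    """Render one token: harmonic source shaped by swept formant resonances.

    Harmonic amplitudes follow Gaussian formant envelopes whose centers
    sweep linearly over the token; a small seeded aspiration-noise floor
    is added, then an attack/decay envelope and RMS normalization to
    :data:`TOKEN_RMS`. Deterministic given (spec, fs, seed).
    """
    spec.validate(fs)
    n = int(round(spec.duration * fs))
    t = np.arange(n) / fs
    frac = t / spec.duration  # 0 -> 1 over the token
    rng = np.random.default_rng(seed)
    f_max = min(fs / 2.0, 8000.0)
    n_harm = max(1, int(f_max / spec.f0))
    x = np.zeros(n)
    two_pi_t = 2.0 * np.pi * t
    for k in range(1, n_harm + 1):
        fk = k * spec.f0
        amp = np.zeros(n)
        for lo, hi in spec.formant_tracks:
            center = lo + (hi - lo) * frac
            amp += np.exp(-0.5 * ((fk - center) / spec.formant_bandwidth) ** 2)
        if amp.max() < 1e-8:
            continue
        phase = rng.uniform(0, 2 * np.pi)
        x += amp * np.sin(two_pi_t * fk + phase)
    x += 0.01 * x.std() * rng.standard_normal(n)  # aspiration floor
    env = np.ones(n)
    na = min(n, int(round(spec.attack * fs)))
    nd = min(n, int(round(spec.decay * fs)))
    if na > 0:
        env[:na] = np.linspace(0.0, 1.0, na)
    if nd > 0:
        env[n - nd :] = np.minimum(env[n - nd :], np.linspace(1.0, 0.0, nd))
    x *= env
    rms = np.sqrt(np.mean(x**2))
    if rms > 0:
        x *= TOKEN_RMS / rms
    return x.astype(np.float64)


def build_session(spec: SessionSpec) -> tuple[np.ndarray, TrialTable]:
    """Concatenate tokens in seeded pseudorandom order with silence between.

    Returns the session audio and a :class:`TrialTable` whose half-open
    spans exactly cover each token (all ``keep=True``).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    labels = [tok.name for tok in spec.vocabulary for _ in range(spec.reps_per_token)]
    order = rng.permutation(len(labels))
    labels = [labels[i] for i in order]
    tokens = {
        tok.name: synth_token_audio(tok, spec.fs, seed=spec.seed + i)
        for i, tok in enumerate(spec.vocabulary)
    }
    iti_n = int(round(spec.iti * spec.fs))
    gap = np.zeros(iti_n)
    pieces = [gap]
    begins, ends = [], []
    cursor = iti_n
    for lab in labels:
        tok = tokens[lab]
        begins.append(cursor)
        ends.append(cursor + tok.size)
        pieces.append(tok)
        pieces.append(gap)
        cursor += tok.size + iti_n
    audio = np.concatenate(pieces)
    trials = TrialTable(
        begin=np.asarray(begins), end=np.asarray(ends),
        label=labels, keep=np.ones(len(labels), dtype=bool),
    )
    return audio, trials


def default_spike_waveform(fs: float, amplitude_uv: float = 60.0) -> np.ndarray:
    """Biphasic extracellular template: sharp negative peak, slow overshoot (~1.4 ms)."""
    n = max(8, int(round(1.4e-3 * fs)))
    t = np.arange(n) / fs * 1e3  # ms
    w = -np.exp(-0.5 * ((t - 0.25) / 0.1) ** 2) + 0.35 * np.exp(-0.5 * ((t - 0.7) / 0.25) ** 2)
    return amplitude_uv * w


def sample_encoding_model(
    n_channels: int,
    n_mels: int = 32,
    n_lags: int = 5,
    informative_fraction: float = 0.75,
    seed: int = 0,
    baseline_hz: float = 2.0,
    gain: float = 30.0,
    noise_sd: float = 5.0,
    pink_fraction: float = 0.5,
    fs: float = 30000.0,
) -> EncodingModel:
    """Draw a random encoding model with smooth, localized STRFs.

    The first ``round(informative_fraction * n_channels)`` channels get a
    Gaussian excitatory bump (random center band/lag, random width) with
    a weaker inhibitory flank, normalized to unit L2 norm; the remaining
    channels have zero STRF and fire only at baseline (pure noise
    channels). ``gain`` is in spikes/s per unit normalized drive given
    the token normalization level of the synthesizer.
    """
    if n_channels < 1 or n_mels < 1 or n_lags < 1:
        raise ValueError("counts must be >= 1")
    rng = np.random.default_rng(seed)
    n_info = int(round(informative_fraction * n_channels))
    strf = np.zeros((n_channels, n_mels, n_lags))
    bands = np.arange(n_mels)[:, None]
    lags = np.arange(n_lags)[None, :]
    for c in range(n_info):
        # receptive fields tuned within the stimulus band (roughly the
        # speech range: lower ~55% of the mel axis at a 15 kHz Nyquist)
        cb = rng.uniform(0.05, 0.55) * (n_mels - 1)
        cl = rng.uniform(0, n_lags - 1)
        wb = rng.uniform(0.05, 0.2) * n_mels
        wl = rng.uniform(0.6, 1.5)
        bump = np.exp(-0.5 * (((bands - cb) / wb) ** 2 + ((lags - cl) / wl) ** 2))
        flank_cb = cb + rng.choice([-1.0, 1.0]) * 2.2 * wb
        flank = np.exp(-0.5 * (((bands - flank_cb) / wb) ** 2 + ((lags - cl) / wl) ** 2))
        w = bump - 0.4 * flank
        strf[c] = w / np.linalg.norm(w)
    baseline = np.full(n_channels, baseline_hz)
    return EncodingModel(
        strf=strf,
        baseline=baseline,
        gain=gain,
        waveform=default_spike_waveform(fs),
        noise_sd=noise_sd,
        pink_fraction=pink_fraction,
        seed=seed,
    )


def _pink_noise(rng: np.random.Generator, n: int) -> np.ndarray:
    """Unit-variance pink noise: white noise shaped by a 1/sqrt(f) spectrum."""
    from scipy import fft as sp_fft

    nfast = sp_fft.next_fast_len(n)
    white = rng.standard_normal(nfast)
    spec = sp_fft.rfft(white)
    freqs = sp_fft.rfftfreq(nfast)
    shaping = np.zeros_like(freqs)
    shaping[1:] = 1.0 / np.sqrt(freqs[1:])
    spec *= shaping
    x = sp_fft.irfft(spec, n=nfast)[:n]
    sd = x.std()
    return x / sd if sd > 0 else x


def encode_neural(audio: np.ndarray, fs: float, model: EncodingModel) -> RecordingBundle:
    """Render broadband traces whose spiking is driven by the audio.

    Per channel the firing rate on the hop grid is
    ``rectify(baseline + gain * sum_{band,lag} strf * melpower(t - lag))``
    held piecewise-constant within each hop; spikes are drawn from an
    inhomogeneous Poisson process at full sample resolution, each
    inserting the waveform template (overlaps sum); mixed white/pink
    Gaussian noise of total SD ``noise_sd`` microvolts is added. The
    audio is stored unmodified. Deterministic given ``model.seed``.
    """
    audio = np.asarray(audio, dtype=np.float64)
    if audio.size == 0:
        raise ValueError("audio is empty")
    hop_n = model.hop * fs
    if abs(hop_n - round(hop_n)) > 1e-9:
        raise ValueError("hop must be an integer number of samples at this fs")
    hop_n = int(round(hop_n))
    n_samples = audio.size
    n_frames = int(np.ceil(n_samples / hop_n))
    mel = melspectrogram(audio, fs, n_mels=model.n_mels, n_fft=model.n_fft, hop=model.hop)
    M = mel.values[:, :n_frames]
    if M.shape[1] < n_frames:  # pad tail frames if ceil exceeded the stft count
        M = np.pad(M, ((0, 0), (0, n_frames - M.shape[1])))
    # normalize drive scale: mel power in units of the mean active-frame power
    scale = np.mean(M[M > 0]) if np.any(M > 0) else 1.0
    Mn = M / max(scale, 1e-20)
    # lagged tensor (lag, band, frame): lag l sees melpower shifted l frames back
    L = model.n_lags
    Mlag = np.zeros((L, M.shape[0], n_frames))
    for l in range(L):
        Mlag[l, :, l:] = Mn[:, : n_frames - l]
    drive = np.einsum("cbl,lbf->cf", model.strf, Mlag)
    rate = np.maximum(0.0, model.baseline[:, None] + model.gain * drive)

    rng = np.random.default_rng(model.seed)
    wf = model.waveform
    traces = np.zeros((model.n_channels, n_samples), dtype=np.float64)
    for c in range(model.n_channels):
        counts = rng.poisson(rate[c] * model.hop)
        total = int(counts.sum())
        if total:
            frames = np.repeat(np.arange(n_frames), counts)
            offs = rng.uniform(0.0, hop_n, size=total)
            starts = np.minimum((frames * hop_n + offs).astype(np.int64), n_samples - 1)
            for s in starts:
                end = min(s + wf.size, n_samples)
                traces[c, s:end] += wf[: end - s]
        if model.noise_sd > 0:
            white = rng.standard_normal(n_samples)
            pink = _pink_noise(rng, n_samples)
            noise = (np.sqrt(1.0 - model.pink_fraction) * white
                     + np.sqrt(model.pink_fraction) * pink)
            traces[c] += model.noise_sd * noise
    return RecordingBundle(
        neural=traces.astype(np.float32),
        audio=audio.astype(np.float32),
        fs=fs,
        array_label="SYN",
    )


def make_session(
    session: SessionSpec | None = None, model: EncodingModel | None = None
) -> tuple[RecordingBundle, TrialTable, EncodingModel]:
    """Convenience: build audio + trials and render the neural traces."""
    session = session or SessionSpec()
    audio, trials = build_session(session)
    if model is None:
        model = sample_encoding_model(
            n_channels=16, seed=session.seed, fs=session.fs
        )
    bundle = encode_neural(audio, session.fs, model)
    return bundle, trials, model
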