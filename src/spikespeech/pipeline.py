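"""End-to-end decoding experiments: dataset assembly, training, grids.

An experiment goes recording + trial table -> aligned (features,
targets) -> sequential 80/10/10 split -> decoder training -> bin-by-bin
prediction -> un-standardization -> mel inversion + Griffin-Lim ->
metrics. Everything fitted from data (noise levels, channel ranking,
target means) uses training frames only.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from itertools import product

import numpy as np
import pandas as pd

from . import audiofeat, neurofeat
from .audiofeat import TargetStandardizer, melspectrogram
from .decoders import ALGORITHMS, DecoderSpec, make_decoder
from .io_formats import RecordingBundle, TrialTable
from .metrics import fisher_mean_correlation

__all__ = [
    "SplitSpec",
    "AudioConfig",
    "NeuroConfig",
    "ExperimentConfig",
    "GridSpec",
    "Dataset",
    "sequential_split",
    "assemble_dataset",
    "run_experiment",
    "grid_search",
    "reconstruct_audio",
]


@dataclass(frozen=True)
class SplitSpec:
    """Sequential train/validation/test fractions (default 80/10/10)."""

    train: float = 0.8
    val: float = 0.1
    test: float = 0.1

    def validate(self) -> None:
        if min(self.train, self.val, self.test) <= 0:
            raise ValueError("fractions must be positive")
        if abs(self.train + self.val + self.test - 1.0) > 1e-9:
            raise ValueError("fractions must sum to 1")


def sequential_split(
    n_frames: int, spec: SplitSpec = SplitSpec()
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Contiguous, ordered, disjoint index ranges covering all frames.

    Sizes are ``floor(train * n)``, ``floor(val * n)``, remainder; the
    assignment is sequential (earliest frames train), not shuffled.
    """
    spec.validate()
    if n_frames < 10:
        raise ValueError("need at least 10 frames to split")
    n_train = int(np.floor(spec.train * n_frames))
    n_val = int(np.floor(spec.val * n_frames))
    idx = np.arange(n_frames)
    return idx[:n_train], idx[n_train : n_train + n_val], idx[n_train + n_val :]


@dataclass(frozen=True)
class AudioConfig:
    """Mel-target construction parameters."""

    n_mels: int = 128
    hop_ms: float = 40.0
    n_fft: int = 2048
    log_power: bool = False

    @property
    def hop(self) -> float:
        return self.hop_ms / 1000.0


@dataclass(frozen=True)
class NeuroConfig:
    """Spike-count feature extraction parameters."""

    filter_low_hz: float = 500.0
    filter_high_hz: float = 3000.0
    threshold_factor: float = 4.0
    dead_time_ms: float = 1.0
    span: int = 4
    n_channels: int | None = None  # None = all channels


@dataclass
class Dataset:
    """Aligned features and targets for one configuration."""

    X: np.ndarray           # frame x (channel * (span+1)) windowed counts
    Y: np.ndarray           # frame x band standardized mel targets
    targets_raw: np.ndarray  # frame x band mel power (unstandardized)
    counts: np.ndarray       # frame x channel (selected, ranked) raw counts
    standardizer: TargetStandardizer
    train_idx: np.ndarray
    val_idx: np.ndarray
    test_idx: np.ndarray
    channel_order: np.ndarray
    noise_sigma: np.ndarray
    audio_cfg: AudioConfig
    neuro_cfg: NeuroConfig
    fs: float
    frame_trial: np.ndarray   # trial index per frame
    frame_start: np.ndarray   # session sample index of each frame's bin start

    def split(self, which: str) -> tuple[np.ndarray, np.ndarray]:
        idx = {"train": self.train_idx, "val": self.val_idx, "test": self.test_idx}[which]
        return self.X[idx], self.Y[idx]


def assemble_dataset(
    bundle: RecordingBundle,
    trials: TrialTable,
    sound_subset: list[str] | None = None,
    audio_cfg: AudioConfig = AudioConfig(),
    neuro_cfg: NeuroConfig = NeuroConfig(),
    split_spec: SplitSpec = SplitSpec(),
) -> Dataset:
    """Build aligned features/targets from a recording and its trials.

    Kept trials (``keep`` and label in *sound_subset*) are concatenated
    in session order; mel targets and binned crossing counts share the
    hop grid (each trial contributes ``floor(len / hop)`` frames).
    Noise levels, channel ranking, and the target standardizer are
    fitted on training frames only.
    """
    vocab = trials.vocabulary
    subset = vocab if sound_subset is None else list(sound_subset)
    unknown = set(subset) - set(vocab)
    if unknown:
        raise ValueError(f"sounds not in vocabulary: {sorted(unknown)}")
    if not subset:
        raise ValueError("empty sound subset")
    hop = audio_cfg.hop
    hop_n = hop * bundle.fs
    if abs(hop_n - round(hop_n)) > 1e-9:
        raise ValueError("hop incompatible with the recording sample rate")
    hop_n = int(round(hop_n))

    keep = [
        i for i in range(len(trials))
        if trials.keep[i] and trials.label[i] in subset
    ]
    if not keep:
        raise ValueError("no kept trials for the requested subset")

    fspec = neurofeat.design_bandpass(
        neuro_cfg.filter_low_hz, neuro_cfg.filter_high_hz, bundle.fs
    )
    filtered = neurofeat.apply_bandpass(fspec, bundle.neural)

    mel_parts, frame_trial, frame_start = [], [], []
    for i in keep:
        b, e = int(trials.begin[i]), int(trials.end[i])
        n_frames_i = (e - b) // hop_n
        if n_frames_i < 1:
            continue
        mel = melspectrogram(
            np.asarray(bundle.audio[b:e], dtype=np.float64), bundle.fs,
            n_mels=audio_cfg.n_mels, n_fft=audio_cfg.n_fft, hop=hop,
        )
        vals = mel.values
        if audio_cfg.log_power:
            vals = np.maximum(10.0 * np.log10(np.maximum(vals, 1e-12)) + 120.0, 0.0)
        mel_parts.append(vals[:, :n_frames_i].T)
        frame_trial.extend([i] * n_frames_i)
        frame_start.extend(b + hop_n * np.arange(n_frames_i))
    targets_raw = np.vstack(mel_parts)
    frame_trial = np.asarray(frame_trial)
    frame_start = np.asarray(frame_start)
    n_frames = targets_raw.shape[0]

    train_idx, val_idx, test_idx = sequential_split(n_frames, split_spec)

    # per-channel noise from training-frame samples only
    train_spans = frame_start[train_idx]
    sample_idx = (train_spans[:, None] + np.arange(hop_n)[None, :]).ravel()
    sigma = np.array([
        neurofeat.estimate_noise(filtered[c, sample_idx])
        for c in range(bundle.n_channels)
    ])

    # crossings per channel per trial, binned on the shared hop grid
    counts_parts = []
    dead = neuro_cfg.dead_time_ms / 1000.0
    for i in keep:
        b, e = int(trials.begin[i]), int(trials.end[i])
        n_frames_i = (e - b) // hop_n
        if n_frames_i < 1:
            continue
        crossings = [
            neurofeat.detect_crossings(
                filtered[c, b:e], sigma[c], neuro_cfg.threshold_factor, dead, bundle.fs
            )
            for c in range(bundle.n_channels)
        ]
        counts_parts.append(
            neurofeat.bin_counts(crossings, bundle.fs, hop, n_frames_i)
        )
    counts = np.vstack(counts_parts)

    order = neurofeat.rank_channels(counts[train_idx])
    n_ch = neuro_cfg.n_channels or bundle.n_channels
    selected = order[:n_ch]
    counts_sel = counts[:, selected]

    X = neurofeat.window_features(counts_sel, neuro_cfg.span)
    standardizer = TargetStandardizer().fit(targets_raw[train_idx])
    Y = standardizer.transform(targets_raw)

    return Dataset(
        X=X.astype(np.float64), Y=Y, targets_raw=targets_raw, counts=counts_sel,
        standardizer=standardizer, train_idx=train_idx, val_idx=val_idx,
        test_idx=test_idx, channel_order=order, noise_sigma=sigma,
        audio_cfg=audio_cfg, neuro_cfg=neuro_cfg, fs=bundle.fs,
        frame_trial=frame_trial, frame_start=frame_start,
    )


@dataclass
class ExperimentConfig:
    """One grid point: feature, target, and decoder configuration."""

    decoder: DecoderSpec
    audio: AudioConfig = AudioConfig()
    neuro: NeuroConfig = NeuroConfig()
    sound_subset: list[str] | None = None
    shuffle_targets: bool = False  # permutation-null control
    seed: int = 0


def _decoder_for(config: ExperimentConfig, dataset: Dataset):
    spec = config.decoder
    hp = dict(spec.hyperparameters)
    if spec.algorithm in ("simple_rnn", "gru_rnn", "lstm_rnn"):
        hp.setdefault("n_steps", dataset.neuro_cfg.span + 1)
    return make_decoder(replace(spec, hyperparameters=hp))


def run_experiment(
    config: ExperimentConfig,
    bundle: RecordingBundle,
    trials: TrialTable,
    dataset: Dataset | None = None,
) -> dict:
    """Train one decoder and score all three splits bin-by-bin.

    The Kalman filter consumes single-bin features (span 0); all other
    algorithms consume the windowed rows. Returns a result dict with the
    fitted model, per-split Fisher-mean mel correlations, and per-split
    predicted mel power (un-standardized, clipped at zero) for
    reconstruction. Training failures are reported in the result, not
    raised, so a grid survives individual failures.
    """
    if dataset is None:
        neuro_cfg = config.neuro
        if config.decoder.algorithm == "kalman":
            neuro_cfg = replace(neuro_cfg, span=0)
        dataset = assemble_dataset(
            bundle, trials, config.sound_subset, config.audio, neuro_cfg
        )
    Y = dataset.Y
    if config.shuffle_targets:
        rng = np.random.default_rng(config.seed)
        Y = Y[rng.permutation(Y.shape[0])]
    X = dataset.X
    tr, va, te = dataset.train_idx, dataset.val_idx, dataset.test_idx
    model = _decoder_for(config, dataset)
    result: dict = {"config": config, "dataset": dataset}
    try:
        model.fit(X[tr], Y[tr], X_val=X[va], Y_val=Y[va])
    except Exception as exc:  # noqa: BLE001 - grid robustness
        result["error"] = repr(exc)
        return result
    result["model"] = model
    result["predictions"] = {}
    for name, idx in (("train", tr), ("val", va), ("test", te)):
        pred_std = model.predict(X[idx])
        pred_mel = np.maximum(dataset.standardizer.inverse_transform(pred_std), 0.0)
        r = fisher_mean_correlation(Y[idx].T, pred_std.T)
        result[f"{name}_r"] = r
        result["predictions"][name] = pred_mel
    return result


def reconstruct_audio(
    pred_mel: np.ndarray,
    audio_cfg: AudioConfig,
    fs: float,
    n_iter: int = 64,
    seed: int = 0,
) -> np.ndarray:
    """Predicted mel power (frame x band) to a waveform via inversion + Griffin-Lim."""
    mel = audiofeat.MelSpec(
        values=np.maximum(pred_mel, 0.0).T, n_mels=audio_cfg.n_mels,
        hop=audio_cfg.hop, n_fft=audio_cfg.n_fft, fs=fs,
    )
    spec = audiofeat.mel_invert(mel)
    return audiofeat.griffin_lim(
        spec, fs, n_fft=audio_cfg.n_fft, hop=audio_cfg.hop, n_iter=n_iter, seed=seed
    )


@dataclass
class GridSpec:
    """Hyperparameter lists for a grid search (cartesian product)."""

    algorithms: list[DecoderSpec] = field(
        default_factory=lambda: [DecoderSpec("wiener")]
    )
    filter_cutoffs: list[tuple[float, float]] = field(
        default_factory=lambda: [(500.0, 3000.0)]
    )
    threshold_factors: list[float] = field(default_factory=lambda: [4.0])
    spans: list[int] = field(default_factory=lambda: [4])
    channel_counts: list[int | None] = field(default_factory=lambda: [None])
    n_mels: list[int] = field(default_factory=lambda: [128])
    hop_ms: list[float] = field(default_factory=lambda: [40.0])
    sound_subsets: list[list[str] | None] = field(default_factory=lambda: [None])


def grid_search(
    grid: GridSpec,
    bundle: RecordingBundle,
    trials: TrialTable,
    seed: int = 0,
) -> pd.DataFrame:
    """Evaluate every grid combination; rank by validation correlation.

    Returns one row per evaluated model with its full configuration and
    per-split Fisher-mean correlations, sorted by ``val_r`` descending.
    Failed runs are kept with NaN scores and the error message.
    """
    rows = []
    for (low, high), tf, span, n_ch, nm, hm, subset, dec in product(
        grid.filter_cutoffs, grid.threshold_factors, grid.spans,
        grid.channel_counts, grid.n_mels, grid.hop_ms, grid.sound_subsets,
        grid.algorithms,
    ):
        cfg = ExperimentConfig(
            decoder=dec,
            audio=AudioConfig(n_mels=nm, hop_ms=hm),
            neuro=NeuroConfig(
                filter_low_hz=low, filter_high_hz=high, threshold_factor=tf,
                span=span, n_channels=n_ch,
            ),
            sound_subset=subset,
            seed=seed,
        )
        res = run_experiment(cfg, bundle, trials)
        rows.append(
            {
                "algorithm": dec.algorithm,
                "hyperparameters": str(dec.hyperparameters),
                "filter_low_hz": low,
                "filter_high_hz": high,
                "threshold_factor": tf,
                "span": span,
                "n_channels": n_ch,
                "n_mels": nm,
                "hop_ms": hm,
                "sounds": "all" if subset is None else "+".join(subset),
                "train_r": res.get("train_r", np.nan),
                "val_r": res.get("val_r", np.nan),
                "test_r": res.get("test_r", np.nan),
                "error": res.get("error", ""),
            }
        )
    return (
        pd.DataFrame(rows)
        .sort_values("val_r", ascending=False, na_position="last")
        .reset_index(drop=True)
    )
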