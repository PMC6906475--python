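"""File formats for recordings, trial tables, and result tables.

A recording session is stored as a directory holding

* ``neural.f32`` — the multichannel broadband trace, channel-major
  (channel 0's samples first), 32-bit little-endian IEEE float,
  in microvolts;
* ``audio.wav`` — the synchronized microphone track as 32-bit float WAV
  at the shared sample rate;
* ``recording.json`` — a sidecar with ``n_channels``, ``n_samples``,
  ``fs``, ``channel_ids`` and ``array_label``.

Trial tables are TSV files with columns ``begin_sample``, ``end_sample``,
``label``, ``keep``; sample indices are 0-based and spans are half-open
``[begin, end)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.io import wavfile

__all__ = [
    "RecordingBundle",
    "TrialTable",
    "write_recording",
    "read_recording",
    "read_trials",
    "write_trials",
]

_NEURAL_FILE = "neural.f32"
_AUDIO_FILE = "audio.wav"
_SIDECAR_FILE = "recording.json"


@dataclass
class RecordingBundle:
    """Synchronized multichannel neural trace and mono audio.

    Parameters
    ----------
    neural : ndarray of shape (n_channels, n_samples)
        Broadband voltage traces in microvolts.
    audio : ndarray of shape (n_samples,)
        Mono audio in the range [-1, 1].
    fs : float
        Shared sample rate in samples/second (nominally 30000).
    channel_ids : list of str, optional
        Ordered channel labels; defaults to ``ch000`` style names.
    array_label : str
        Free-text array identifier (e.g. ``RPB`` or ``CPB``).
    """

    neural: np.ndarray
    audio: np.ndarray
    fs: float
    channel_ids: list[str] = field(default_factory=list)
    array_label: str = ""

    def __post_init__(self) -> None:
        self.neural = np.asarray(self.neural, dtype=np.float32)
        self.audio = np.asarray(self.audio, dtype=np.float32)
        if not self.channel_ids:
            self.channel_ids = [f"ch{i:03d}" for i in range(self.neural.shape[0])]
        self.validate()

    @property
    def n_channels(self) -> int:
        return self.neural.shape[0]

    @property
    def n_samples(self) -> int:
        return self.neural.shape[1]

    def validate(self) -> None:
        if self.neural.ndim != 2 or self.neural.shape[0] < 1:
            raise ValueError("neural must be a (n_channels, n_samples) matrix with >= 1 channel")
        if self.audio.ndim != 1:
            raise ValueError("audio must be a 1-D vector")
        if self.neural.shape[1] != self.audio.shape[0]:
            raise ValueError(
                f"neural sample count ({self.neural.shape[1]}) must equal "
                f"audio sample count ({self.audio.shape[0]})"
            )
        if not self.fs > 0:
            raise ValueError("fs must be positive")
        if len(self.channel_ids) != self.neural.shape[0]:
            raise ValueError("channel_ids length must equal channel count")
        if not (np.isfinite(self.neural).all() and np.isfinite(self.audio).all()):
            raise ValueError("recording contains non-finite values")


@dataclass
class TrialTable:
    """Labeled sound presentations over a recording timeline.

    Spans are half-open ``[begin, end)`` in samples, sorted and
    non-overlapping. ``keep`` flags trials accepted for analysis
    (artifact-contaminated trials carry ``keep=False``).
    """

    begin: np.ndarray
    end: np.ndarray
    label: list[str]
    keep: np.ndarray

    def __post_init__(self) -> None:
        self.begin = np.asarray(self.begin, dtype=np.int64)
        self.end = np.asarray(self.end, dtype=np.int64)
        self.label = list(self.label)
        self.keep = np.asarray(self.keep, dtype=bool)
        self.validate()

    def __len__(self) -> int:
        return len(self.begin)

    def validate(self) -> None:
        n = len(self.begin)
        if not (len(self.end) == n and len(self.label) == n and len(self.keep) == n):
            raise ValueError("trial table columns have unequal lengths")
        if np.any(self.begin >= self.end):
            raise ValueError("every trial must satisfy begin < end")
        if n > 1:
            if np.any(np.diff(self.begin) < 0):
                raise ValueError("trials must be sorted by begin sample")
            if np.any(self.begin[1:] < self.end[:-1]):
                raise ValueError("trial spans must not overlap")

    @property
    def vocabulary(self) -> list[str]:
        return sorted(set(self.label))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "begin_sample": self.begin,
                "end_sample": self.end,
                "label": self.label,
                "keep": self.keep.astype(int),
            }
        )


def write_recording(bundle: RecordingBundle, path: str | Path) -> Path:
    """Write a recording bundle to directory *path* and return it."""
    bundle.validate()
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    payload = np.ascontiguousarray(bundle.neural, dtype="<f4")
    (path / _NEURAL_FILE).write_bytes(payload.tobytes())
    wavfile.write(path / _AUDIO_FILE, int(bundle.fs), bundle.audio.astype(np.float32))
    sidecar = {
        "n_channels": int(bundle.n_channels),
        "n_samples": int(bundle.n_samples),
        "fs": float(bundle.fs),
        "channel_ids": list(bundle.channel_ids),
        "array_label": bundle.array_label,
    }
    (path / _SIDECAR_FILE).write_text(json.dumps(sidecar, indent=1))
    return path


def read_recording(path: str | Path) -> RecordingBundle:
    """Read a recording bundle written by :func:`write_recording`.

    Raises
    ------
    ValueError
        If the binary payload size disagrees with the sidecar, or the WAV
        sample rate disagrees with the sidecar ``fs``.
    """
    path = Path(path)
    sidecar = json.loads((path / _SIDECAR_FILE).read_text())
    n_channels = int(sidecar["n_channels"])
    n_samples = int(sidecar["n_samples"])
    raw = (path / _NEURAL_FILE).read_bytes()
    expected = n_channels * n_samples * 4
    if len(raw) != expected:
        raise ValueError(
            f"neural payload is {len(raw)} bytes; sidecar implies {expected}"
        )
    neural = np.frombuffer(raw, dtype="<f4").reshape(n_channels, n_samples)
    wav_fs, audio = wavfile.read(path / _AUDIO_FILE)
    if float(wav_fs) != float(sidecar["fs"]):
        raise ValueError(
            f"WAV sample rate {wav_fs} disagrees with sidecar fs {sidecar['fs']}"
        )
    return RecordingBundle(
        neural=neural.copy(),
        audio=np.asarray(audio, dtype=np.float32),
        fs=float(sidecar["fs"]),
        channel_ids=list(sidecar["channel_ids"]),
        array_label=sidecar.get("array_label", ""),
    )


def write_trials(table: TrialTable, path: str | Path) -> Path:
    table.validate()
    path = Path(path)
    table.to_frame().to_csv(path, sep="\t", index=False)
    return path


def read_trials(path: str | Path) -> TrialTable:
    df = pd.read_csv(path, sep="\t")
    required = {"begin_sample", "end_sample", "label", "keep"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trial table missing columns: {sorted(missing)}")
    return TrialTable(
        begin=df["begin_sample"].to_numpy(),
        end=df["end_sample"].to_numpy(),
        label=[str(x) for x in df["label"]],
        keep=df["keep"].astype(int).to_numpy().astype(bool),
    )
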