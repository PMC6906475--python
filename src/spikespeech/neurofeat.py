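"""Multiunit spike-count features from broadband traces.

The feature path mirrors standard unsorted-multiunit practice: bandpass
the raw 30 kS/s voltage trace with a 2nd-order elliptic filter
(zero-phase), estimate each channel's noise level on training-set
samples with the median absolute deviation (robust to the spikes
themselves), detect negative threshold crossings at
``-threshold_factor * sigma``, bin the crossings into non-overlapping
windows aligned to the audio target hop, rank channels by training-set
activity, and concatenate a centered window of neighboring bins per
channel ("feature window span").
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np
from scipy import signal
from sklearn.base import BaseEstimator, TransformerMixin

__all__ = [
    "FilterSpec",
    "design_bandpass",
    "apply_bandpass",
    "enumerate_filter_grid",
    "estimate_noise",
    "detect_crossings",
    "bin_counts",
    "rank_channels",
    "window_features",
    "FeatureWindower",
    "DEFAULT_LOW_GRID",
    "DEFAULT_HIGH_GRID",
    "THRESHOLD_FACTOR_GRID",
    "SPAN_GRID",
    "CHANNEL_COUNT_GRID",
]

# hyperparameter grids of the standard search space
DEFAULT_LOW_GRID = tuple(range(100, 1001, 100))
DEFAULT_HIGH_GRID = tuple(range(1000, 10001, 1000))
THRESHOLD_FACTOR_GRID = (2, 3, 4, 5)
SPAN_GRID = (4, 8, 16)
CHANNEL_COUNT_GRID = (2, 4, 8, 16, 32, 64, 96)

MAD_GAUSSIAN_CONSTANT = 0.6745


@dataclass(frozen=True)
class FilterSpec:
    """A realizable 2nd-order elliptic bandpass design (SOS form)."""

    low_hz: float
    high_hz: float
    fs: float
    order: int = 2
    passband_ripple_db: float = 0.1
    stopband_atten_db: float = 40.0

    @property
    def sos(self) -> np.ndarray:
        return signal.ellip(
            self.order,
            self.passband_ripple_db,
            self.stopband_atten_db,
            [self.low_hz, self.high_hz],
            btype="bandpass",
            fs=self.fs,
            output="sos",
        )


def design_bandpass(low_hz: float, high_hz: float, fs: float) -> FilterSpec:
    """Design the 2nd-order elliptic bandpass used before spike extraction."""
    if not 0 < low_hz < high_hz:
        raise ValueError("need 0 < low_hz < high_hz")
    if high_hz >= fs / 2:
        raise ValueError("high_hz must be below the Nyquist frequency")
    return FilterSpec(low_hz=float(low_hz), high_hz=float(high_hz), fs=float(fs))


def apply_bandpass(spec: FilterSpec, trace: np.ndarray) -> np.ndarray:
    """Zero-phase (forward-backward) application along the last axis."""
    return signal.sosfiltfilt(spec.sos, np.asarray(trace, dtype=np.float64), axis=-1)


def enumerate_filter_grid(
    lows=DEFAULT_LOW_GRID, highs=DEFAULT_HIGH_GRID
) -> list[tuple[float, float]]:
    """All (low, high) cutoff pairs with low < high, lexicographically sorted."""
    return sorted((lo, hi) for lo, hi in product(lows, highs) if lo < hi)


def estimate_noise(trace: np.ndarray) -> float:
    """MAD noise level: ``median(|x - median(x)|) / 0.6745`` (microvolts).

    The median absolute deviation tracks the background noise even when
    a few percent of samples are large spikes, unlike the plain standard
    deviation.
    """
    trace = np.asarray(trace, dtype=np.float64)
    if trace.size == 0:
        raise ValueError("cannot estimate noise on an empty trace")
    med = np.median(trace)
    return float(np.median(np.abs(trace - med)) / MAD_GAUSSIAN_CONSTANT)


def detect_crossings(
    trace: np.ndarray,
    sigma: float,
    threshold_factor: float,
    dead_time: float,
    fs: float,
) -> np.ndarray:
    """Negative threshold crossing indices on one channel.

    A crossing is the first sample at which the trace passes from above
    the threshold ``-threshold_factor * sigma`` to at or below it.
    Crossings within *dead_time* seconds of an accepted crossing are
    suppressed.
    """
    if threshold_factor <= 0:
        raise ValueError("threshold_factor must be positive")
    if dead_time <= 0:
        raise ValueError("dead_time must be positive")
    trace = np.asarray(trace, dtype=np.float64)
    thr = -threshold_factor * sigma
    below = trace <= thr
    # onset: above threshold at i-1, at/below at i; sample 0 counts if below
    onsets = np.flatnonzero(below & ~np.concatenate(([False], below[:-1])))
    if onsets.size == 0:
        return onsets
    dead_n = int(round(dead_time * fs))
    kept = [int(onsets[0])]
    for idx in onsets[1:]:
        if idx - kept[-1] >= dead_n:
            kept.append(int(idx))
    return np.asarray(kept, dtype=np.int64)


def bin_counts(
    crossings: list[np.ndarray] | dict[int, np.ndarray],
    fs: float,
    hop: float,
    n_frames: int,
) -> np.ndarray:
    """Bin per-channel crossing indices into a (frame, channel) count matrix.

    Bin ``b`` counts crossings with sample index in
    ``[b * hop * fs, (b + 1) * hop * fs)`` — half-open bins aligned to the
    audio target hop. Crossings outside the covered range are dropped.
    """
    hop_n = hop * fs
    if abs(hop_n - round(hop_n)) > 1e-9 or hop_n <= 0:
        raise ValueError("hop must be a positive integer number of samples")
    hop_n = int(round(hop_n))
    if isinstance(crossings, dict):
        crossings = [crossings[k] for k in sorted(crossings)]
    counts = np.zeros((n_frames, len(crossings)), dtype=np.int64)
    for ch, idx in enumerate(crossings):
        idx = np.asarray(idx, dtype=np.int64)
        bins = idx // hop_n
        valid = (bins >= 0) & (bins < n_frames)
        np.add.at(counts[:, ch], bins[valid], 1)
    return counts


def rank_channels(train_counts: np.ndarray) -> np.ndarray:
    """Channels ordered by descending total training-set crossing count.

    Ties break toward the lower channel index, so repeated calls are
    stable and top-k selection is a prefix of the full order.
    """
    train_counts = np.asarray(train_counts)
    if train_counts.ndim != 2 or train_counts.shape[0] < 1:
        raise ValueError("need a non-empty (frame, channel) count matrix")
    totals = train_counts.sum(axis=0)
    return np.lexsort((np.arange(totals.size), -totals))


def window_features(counts: np.ndarray, span: int) -> np.ndarray:
    """Centered window of bins per channel, concatenated channel-major.

    Row ``t`` holds, for each channel in turn, the counts at frames
    ``t - span/2 ... t + span/2`` (``span + 1`` values per channel; the
    span excludes the current bin). Out-of-range frames contribute zeros.
    """
    if span < 0 or span % 2 != 0:
        raise ValueError("span must be even and >= 0")
    counts = np.asarray(counts)
    n_frames, n_channels = counts.shape
    half = span // 2
    cols = []
    for ch in range(n_channels):
        for off in range(-half, half + 1):
            col = np.zeros(n_frames, dtype=counts.dtype)
            lo = max(0, -off)
            hi = min(n_frames, n_frames - off)
            col[lo:hi] = counts[lo + off : hi + off, ch]
            cols.append(col)
    return np.column_stack(cols)


class FeatureWindower(TransformerMixin, BaseEstimator):
    """sklearn transformer wrapping :func:`window_features`.

    Parameters
    ----------
    span : int
        Feature window span (even); ``span + 1`` bins enter each row.
    """

    def __init__(self, span: int = 4):
        self.span = span

    def fit(self, X: np.ndarray, y=None) -> "FeatureWindower":
        X = np.asarray(X)
        if X.ndim != 2:
            raise ValueError("expected a (frame, channel) count matrix")
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X: np.ndarray) -> np.ndarray:
        return window_features(np.asarray(X), self.span)
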