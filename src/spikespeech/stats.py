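"""Statistical comparison of decoding models.

Two families of tests are used, matching how each metric is sampled:

* Mel-correlation values (one r per model, with the validation frame
  count as sample size) are compared with the multisample chi-square
  test of Paul (1988) on Fisher-z-transformed correlations, followed by
  a Tukey-type studentized-range post-hoc on the z values.
* Every other metric is computed on non-overlapping 2 s blocks of
  validation audio, giving a block x model matrix analyzed with a
  Friedman test and Conover post-hoc pairwise comparisons
  (Holm-adjusted).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sp_stats

__all__ = [
    "CorrelationSamples",
    "paul_chi_square",
    "tukey_correlation_posthoc",
    "blockify",
    "friedman_test",
    "conover_posthoc",
]


@dataclass
class CorrelationSamples:
    """Per-model correlation coefficients with their sample sizes."""

    r: np.ndarray
    n: np.ndarray
    labels: list[str] | None = None

    def __post_init__(self) -> None:
        self.r = np.asarray(self.r, dtype=np.float64)
        self.n = np.asarray(self.n, dtype=np.float64)
        if self.r.shape != self.n.shape or self.r.ndim != 1:
            raise ValueError("r and n must be equal-length vectors")
        if np.any(np.abs(self.r) >= 1):
            raise ValueError("correlations must satisfy |r| < 1")
        if np.any(self.n < 4):
            raise ValueError("each sample size must be >= 4")
        if self.labels is None:
            self.labels = [f"model{i}" for i in range(self.r.size)]


def paul_chi_square(samples: CorrelationSamples) -> tuple[float, int, float]:
    """Multisample equality test for correlation coefficients.

    The common correlation ``r_w`` is the sample-size-weighted mean of
    the Fisher-z values, back-transformed; the statistic is
    ``chi2 = sum n_i (r_i - r_w)^2 / (1 - r_i r_w)^2`` with k - 1
    degrees of freedom, upper-tail p-value.
    """
    r, n = samples.r, samples.n
    if r.size < 2:
        raise ValueError("need at least 2 samples")
    z = np.arctanh(r)
    r_w = float(np.tanh(np.sum(n * z) / np.sum(n)))
    chi2 = float(np.sum(n * (r - r_w) ** 2 / (1.0 - r * r_w) ** 2))
    df = r.size - 1
    p = float(sp_stats.chi2.sf(chi2, df))
    return chi2, df, p


def tukey_correlation_posthoc(samples: CorrelationSamples) -> pd.DataFrame:
    """Tukey-type pairwise comparisons on Fisher-z-transformed correlations.

    The studentized-range statistic for pair (i, j) is
    ``q = |z_i - z_j| / sqrt((1/(n_i - 3) + 1/(n_j - 3)) / 2)`` referred
    to the studentized range distribution with k groups and infinite
    degrees of freedom. The returned table is symmetric. With k = 2 the
    comparison reduces to the two-sample z test (flagged in the
    ``method`` attribute).
    """
    r, n = samples.r, samples.n
    k = r.size
    z = np.arctanh(r)
    se2 = 1.0 / (n - 3.0)
    p = np.ones((k, k))
    for i in range(k):
        for j in range(i + 1, k):
            se = np.sqrt(0.5 * (se2[i] + se2[j]))
            q = abs(z[i] - z[j]) / se
            if k >= 3:
                pij = float(sp_stats.studentized_range.sf(q, k, np.inf))
            else:
                pij = float(2.0 * sp_stats.norm.sf(q / np.sqrt(2.0)))
            p[i, j] = p[j, i] = pij
    table = pd.DataFrame(p, index=samples.labels, columns=samples.labels)
    table.attrs["method"] = "tukey_z" if k >= 3 else "two_sample_z"
    return table


def blockify(
    target_audio: np.ndarray,
    reconstructions: dict[str, np.ndarray],
    fs: float,
    metric,
    block: float = 2.0,
) -> pd.DataFrame:
    """Evaluate *metric* per model on non-overlapping blocks of audio.

    ``metric(target_block, recon_block, fs)`` is called independently on
    each full *block*-second block (trailing partial blocks dropped).
    Returns a block x model DataFrame. Requires >= 3 full blocks.
    """
    target_audio = np.asarray(target_audio, dtype=np.float64)
    block_n = int(round(block * fs))
    n_blocks = target_audio.size // block_n
    if n_blocks < 3:
        raise ValueError("need at least 3 full blocks of audio")
    out = {}
    for name, recon in reconstructions.items():
        recon = np.asarray(recon, dtype=np.float64)
        if recon.size < n_blocks * block_n:
            raise ValueError(f"reconstruction {name!r} shorter than the target blocks")
        vals = [
            metric(
                target_audio[b * block_n : (b + 1) * block_n],
                recon[b * block_n : (b + 1) * block_n],
                fs,
            )
            for b in range(n_blocks)
        ]
        out[name] = vals
    return pd.DataFrame(out)


def _block_ranks(m: np.ndarray) -> np.ndarray:
    return np.apply_along_axis(sp_stats.rankdata, 1, m)


def friedman_test(blocks: pd.DataFrame | np.ndarray) -> tuple[float, int, float]:
    """Friedman rank test over a block x model matrix (midrank ties).

    Returns (statistic, df, p) with the chi-square approximation,
    df = models - 1. The tie-corrected statistic matches
    ``scipy.stats.friedmanchisquare``.
    """
    m = np.asarray(blocks, dtype=np.float64)
    if m.ndim != 2 or m.shape[1] < 2:
        raise ValueError("need a (blocks, models) matrix with >= 2 models")
    if np.any(~np.isfinite(m)):
        raise ValueError("block matrix contains missing values")
    n, k = m.shape
    ranks = _block_ranks(m)
    col_sums = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * np.sum(col_sums**2) - 3.0 * n * (k + 1)
    # tie correction
    ties = 0.0
    for row in m:
        _, counts = np.unique(row, return_counts=True)
        ties += np.sum(counts**3 - counts)
    correction = 1.0 - ties / (n * k * (k**2 - 1)) if k > 1 else 1.0
    if correction > 0:
        stat = stat / correction
    df = k - 1
    return float(stat), df, float(sp_stats.chi2.sf(stat, df))


def conover_posthoc(blocks: pd.DataFrame, alpha: float = 0.05) -> pd.DataFrame:
    """Conover pairwise comparisons after a Friedman test.

    Pairwise t statistics on rank sums,
    ``t = |R_i - R_j| / sqrt(2 n (1 - chi2/(n (k-1))) (A - B) / ((n-1)(k-1)))``
    with ``A = sum of squared ranks`` and ``B = sum R_j^2 / n``, referred
    to a t distribution with (n-1)(k-1) degrees of freedom; p-values are
    Holm-adjusted. Returns a symmetric model x model p-value table.
    """
    m = np.asarray(blocks, dtype=np.float64)
    if m.shape[1] < 3:
        raise ValueError("Conover post-hoc needs at least 3 models")
    labels = list(blocks.columns) if isinstance(blocks, pd.DataFrame) else [
        f"model{i}" for i in range(m.shape[1])
    ]
    n, k = m.shape
    ranks = _block_ranks(m)
    R = ranks.sum(axis=0)
    stat, _, _ = friedman_test(m)
    A = float(np.sum(ranks**2))
    B = float(np.sum(R**2)) / n
    df = (n - 1) * (k - 1)
    denom2 = 2.0 * n * (1.0 - stat / (n * (k - 1.0))) * (A - B) / df
    denom2 = max(denom2, 1e-300)
    raw, pairs = [], []
    for i in range(k):
        for j in range(i + 1, k):
            t = abs(R[i] - R[j]) / np.sqrt(denom2)
            raw.append(float(2.0 * sp_stats.t.sf(t, df)))
            pairs.append((i, j))
    # Holm step-down adjustment
    order = np.argsort(raw)
    adj = np.empty(len(raw))
    running = 0.0
    for rank_pos, idx in enumerate(order):
        val = min(1.0, (len(raw) - rank_pos) * raw[idx])
        running = max(running, val)
        adj[idx] = running
    p = np.ones((k, k))
    for (i, j), pij in zip(pairs, adj):
        p[i, j] = p[j, i] = pij
    return pd.DataFrame(p, index=labels, columns=labels)
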