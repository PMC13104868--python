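"""Beta burst detection from the smoothed Hilbert envelope.

Bursts are maximal runs of samples whose smoothed analytic amplitude
exceeds the 75th percentile of the envelope (computed per contact over the
whole trimmed signal); non-burst epochs are runs below the 50th percentile.
Samples between the two thresholds are transitional and belong to neither
class.  Runs shorter than 100 ms are discarded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .recording import BetaSignal, check_intervals


@dataclass
class Envelope:
    """Smoothed analytic amplitude of a beta-band signal."""

    a: np.ndarray
    fs: float
    smooth_ms: float = 50.0
    source_label: str = ""

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        if self.a.ndim != 1 or self.a.size == 0:
            raise ValueError("envelope must be a non-empty 1-D array")
        if np.any(self.a < 0):
            raise ValueError("envelope amplitudes must be non-negative")


@dataclass
class EpochSet:
    """Burst and non-burst sample intervals for one STN contact.

    Intervals are half-open ``[start, end)`` in trimmed-signal sample
    coordinates; ``thresholds`` records the (burst, non-burst) amplitude
    cutoffs that produced them.
    """

    bursts: np.ndarray
    nonbursts: np.ndarray
    thresholds: tuple[float, float]
    source_label: str = ""
    excluded_adjacent: bool = False  # set by exclude_sparse_pairs

    def __post_init__(self) -> None:
        self.bursts = check_intervals(self.bursts)
        self.nonbursts = check_intervals(self.nonbursts)
        burst_thr, nonburst_thr = self.thresholds
        if burst_thr < nonburst_thr:
            raise ValueError("burst threshold below non-burst threshold")

    @property
    def n_bursts(self) -> int:
        return len(self.bursts)

    @property
    def n_nonbursts(self) -> int:
        return len(self.nonbursts)


def moving_average(x: np.ndarray, window: int) -> np.ndarray:
    """Centered moving mean with shrinking windows at the edges.

    For window length ``w`` the mean at sample ``i`` runs over
    ``[i - (w-1)//2, i + w//2]``, truncated at the signal boundaries (so
    edge samples average over fewer points rather than padded zeros).
    """
    x = np.asarray(x, dtype=float)
    if window <= 1:
        return x.copy()
    left = (window - 1) // 2
    right = window // 2
    csum = np.concatenate(([0.0], np.cumsum(x)))
    n = x.size
    idx = np.arange(n)
    lo = np.maximum(idx - left, 0)
    hi = np.minimum(idx + right + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def compute_envelope(beta: BetaSignal, smooth_ms: float = 50.0) -> Envelope:
    """Magnitude of the analytic signal, smoothed with a moving mean.

    The smoothing window is ``round(smooth_ms * fs / 1000)`` samples,
    centered, shrinking at the edges.
    """
    if len(beta) == 0:
        raise ValueError("empty beta signal")
    amp = np.abs(sps.hilbert(beta.x))
    window = max(1, int(round(smooth_ms * beta.fs / 1000.0)))
    return Envelope(
        a=moving_average(amp, window),
        fs=beta.fs,
        smooth_ms=smooth_ms,
        source_label=beta.source_label,
    )


def _runs_above(mask: np.ndarray) -> np.ndarray:
    """Maximal runs of True in a boolean mask as half-open intervals."""
    if mask.size == 0:
        return np.empty((0, 2), dtype=np.int64)
    padded = np.concatenate(([False], mask, [False]))
    d = np.diff(padded.astype(np.int8))
    starts = np.flatnonzero(d == 1)
    ends = np.flatnonzero(d == -1)
    return np.column_stack([starts, ends]).astype(np.int64)


def detect_epochs(
    env: Envelope,
    burst_pct: float = 75.0,
    nonburst_pct: float = 50.0,
    min_dur_ms: float = 100.0,
) -> EpochSet:
    """Threshold the envelope into burst and non-burst epochs.

    Bursts are maximal runs with amplitude strictly above the
    ``burst_pct`` percentile; non-bursts strictly below the
    ``nonburst_pct`` percentile (linear-interpolation percentiles over the
    full signal).  Runs shorter than ``min_dur_ms`` are dropped from both
    lists.  A constant envelope yields equal thresholds and hence no
    bursts — documented behaviour, not an error.
    """
    if burst_pct <= nonburst_pct:
        raise ValueError("burst_pct must exceed nonburst_pct")
    a = env.a
    burst_thr = float(np.percentile(a, burst_pct))
    nonburst_thr = float(np.percentile(a, nonburst_pct))
    min_len = max(1, int(round(min_dur_ms * env.fs / 1000.0)))

    bursts = _runs_above(a > burst_thr)
    nonbursts = _runs_above(a < nonburst_thr)
    bursts = bursts[(bursts[:, 1] - bursts[:, 0]) >= min_len]
    nonbursts = nonbursts[(nonbursts[:, 1] - nonbursts[:, 0]) >= min_len]
    return EpochSet(
        bursts=bursts,
        nonbursts=nonbursts,
        thresholds=(burst_thr, nonburst_thr),
        source_label=env.source_label,
    )


def exclude_sparse_pairs(epoch_sets: dict[str, EpochSet]) -> dict[str, EpochSet]:
    """Flag contacts with too few bursts.

    Contacts with fewer than two bursts are flagged as excluded from
    burst-adjacent analyses; contacts with zero bursts cannot enter any
    burst analysis (callers must check ``n_bursts``).  The mapping is
    returned with flags set in place.
    """
    for es in epoch_sets.values():
        es.excluded_adjacent = es.n_bursts < 2
    return epoch_sets
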