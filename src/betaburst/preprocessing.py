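"""Filtering and trimming chain producing analysis-ready beta-band signals.

Raw channels are (1) high-pass filtered at 1 Hz, (2) band-pass filtered to
13-30 Hz, both with zero-phase (forward-backward) fourth-order Butterworth
filters, then (3) trimmed: the first 60 s of the recording are discarded
and 2 s are removed from each end of the filtered signal to suppress filter
edge artifacts.  All downstream sample indices are relative to the trimmed
origin.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import signal as sps

from .recording import Recording, BetaSignal

DEFAULT_BAND = (13.0, 30.0)
DEFAULT_ORDER = 4
DEFAULT_HEAD_DISCARD_S = 60.0
DEFAULT_EDGE_TRIM_S = 2.0


class RecordingTooShortError(ValueError):
    """Raised when a recording cannot absorb the requested trims."""


def _check_length(x: np.ndarray, order: int) -> None:
    if x.size <= 6 * order:
        raise ValueError(
            f"signal of {x.size} samples is too short for stable order-{order} "
            "zero-phase filtering"
        )


def bandpass_beta(
    channel: np.ndarray,
    fs: float,
    band: tuple[float, float] = DEFAULT_BAND,
    order: int = DEFAULT_ORDER,
    source_label: str = "",
) -> BetaSignal:
    """Zero-phase Butterworth band-pass of nominal order ``order``.

    Applied forward and backward (``sosfiltfilt``), so the effective
    attenuation is doubled and the net group delay is zero.
    """
    x = np.asarray(channel, dtype=float)
    lo, hi = band
    if not 0.0 < lo < hi:
        raise ValueError(f"invalid band {band!r}")
    if hi >= fs / 2.0:
        raise ValueError(f"band edge {hi} Hz is at or above Nyquist ({fs / 2.0} Hz)")
    _check_length(x, order)
    sos = sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")
    y = sps.sosfiltfilt(sos, x)
    return BetaSignal(x=y, fs=fs, band=(lo, hi), source_label=source_label)


def highpass_1hz(
    channel: np.ndarray, fs: float, cutoff: float = 1.0, order: int = DEFAULT_ORDER
) -> np.ndarray:
    """Zero-phase order-4 Butterworth high-pass (1 Hz by default)."""
    x = np.asarray(channel, dtype=float)
    if not 0.0 < cutoff < fs / 2.0:
        raise ValueError(f"cutoff {cutoff} Hz outside (0, Nyquist)")
    _check_length(x, order)
    sos = sps.butter(order, cutoff, btype="highpass", fs=fs, output="sos")
    return sps.sosfiltfilt(sos, x)


def trim_edges(
    x: np.ndarray,
    fs: float,
    head_discard_s: float = DEFAULT_HEAD_DISCARD_S,
    edge_trim_s: float = DEFAULT_EDGE_TRIM_S,
) -> np.ndarray:
    """Drop the first ``head_discard_s`` seconds plus ``edge_trim_s`` from
    both ends of a filtered signal.

    Sample counts are ``floor(seconds * fs)`` so the arithmetic is
    deterministic for non-integer products.
    """
    x = np.asarray(x)
    head = int(math.floor(head_discard_s * fs))
    edge = int(math.floor(edge_trim_s * fs))
    minimum = head + 2 * edge + 1
    if x.size < minimum:
        raise RecordingTooShortError(
            f"recording of {x.size} samples ({x.size / fs:.1f} s) is shorter than the "
            f"minimum {minimum} samples ({minimum / fs:.1f} s) required by a "
            f"{head_discard_s} s head discard plus {edge_trim_s} s edge trims"
        )
    stop = x.size - edge
    return x[head + edge:stop]


def preprocess_channel(
    channel: np.ndarray,
    fs: float,
    band: tuple[float, float] = DEFAULT_BAND,
    order: int = DEFAULT_ORDER,
    head_discard_s: float = DEFAULT_HEAD_DISCARD_S,
    edge_trim_s: float = DEFAULT_EDGE_TRIM_S,
    source_label: str = "",
) -> BetaSignal:
    """Full chain for one channel: high-pass, beta band-pass, trim."""
    hp = highpass_1hz(channel, fs, order=order)
    beta = bandpass_beta(hp, fs, band=band, order=order, source_label=source_label)
    trimmed = trim_edges(beta.x, fs, head_discard_s=head_discard_s, edge_trim_s=edge_trim_s)
    return BetaSignal(x=trimmed, fs=fs, band=band, source_label=source_label)


def preprocess_recording(
    rec: Recording,
    band: tuple[float, float] = DEFAULT_BAND,
    order: int = DEFAULT_ORDER,
    head_discard_s: float = DEFAULT_HEAD_DISCARD_S,
    edge_trim_s: float = DEFAULT_EDGE_TRIM_S,
) -> dict[str, BetaSignal]:
    """Apply :func:`preprocess_channel` to every channel, keyed by label."""
    return {
        lab: preprocess_channel(
            rec.channel(lab),
            rec.fs,
            band=band,
            order=order,
            head_discard_s=head_discard_s,
            edge_trim_s=edge_trim_s,
            source_label=lab,
        )
        for lab in rec.labels
    }
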