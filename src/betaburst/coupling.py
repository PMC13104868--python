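"""Coherence and dwPLI over collections of epoch-restricted segment pairs.

Both metrics are estimated from a single pool of tapered Welch sub-windows:
within each segment (burst, non-burst, or sliding window), sub-windows of
``window_len`` samples with 50% overlap are extracted, mean-removed,
Hamming-tapered and Fourier transformed; the per-sub-window cross- and
auto-spectra are pooled across segments before forming

* magnitude-squared coherence  C(f) = |sum Sxy|^2 / (sum Sxx * sum Syy),
* the debiased squared weighted phase-lag index computed from the
  imaginary cross-spectrum,

      dwPLI(f) = [ (sum I_j)^2 - sum I_j^2 ] / [ (sum |I_j|)^2 - sum I_j^2 ]

  with I_j = Im(Sxy) of sub-window j.  dwPLI is insensitive to zero-lag
  coupling (all I_j = 0 gives 0 by convention) and may be slightly
  negative under the null; negative values are reported as computed.

Band-averaged scalars use a fixed set of frequency-grid indices covering
13-30 Hz, chosen once per contact pair and reused verbatim for burst,
non-burst and surrogate estimates so conditions stay comparable.

Because short bursts rarely hold more than a couple of sub-windows,
pooling across segments is what makes the estimators well defined; each
epoch is treated as an independent realization of the underlying coupling.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .bursts import EpochSet
from .recording import BetaSignal

logger = logging.getLogger(__name__)

DEFAULT_BAND = (13.0, 30.0)


@dataclass
class CouplingConfig:
    """Estimator settings shared by all conditions of a contact pair."""

    band: tuple[float, float] = DEFAULT_BAND
    max_window: int = 256      # Welch sub-window cap, samples
    min_window: int = 64       # segments shorter than this are unusable
    overlap_frac: float = 0.5
    nonburst_cap: int = 100    # max non-burst segments sampled per pair

    def __post_init__(self) -> None:
        if not 0.0 <= self.overlap_frac < 1.0:
            raise ValueError("overlap_frac must lie in [0, 1)")
        if self.min_window < 4 or self.max_window < self.min_window:
            raise ValueError("invalid window bounds")


@dataclass
class SegmentPairSet:
    """Equal-length (STN, cortex) sample windows for one condition."""

    segments: list[tuple[np.ndarray, np.ndarray]]
    fs: float
    condition: str = "burst"  # burst | nonburst | surrogate | window

    def __post_init__(self) -> None:
        for i, (x, y) in enumerate(self.segments):
            x = np.asarray(x, dtype=float)
            y = np.asarray(y, dtype=float)
            if x.shape != y.shape or x.ndim != 1:
                raise ValueError(f"segment {i}: STN/cortex windows must be equal-length 1-D")
            if x.size < 2:
                raise ValueError(f"segment {i}: segments need >= 2 samples")
            self.segments[i] = (x, y)


@dataclass
class PooledSpectra:
    """Per-sub-window spectra pooled across segments on one grid."""

    freqs: np.ndarray    # (F,)
    Sxy: np.ndarray      # (k, F) complex cross-spectra
    Sxx: np.ndarray      # (k, F) real auto-spectra
    Syy: np.ndarray      # (k, F)
    n_skipped: int = 0   # segments shorter than the window

    @property
    def n_subwindows(self) -> int:
        return self.Sxy.shape[0]


@dataclass
class CouplingSpectrum:
    """Per-frequency coherence and dwPLI plus band-averaged scalars."""

    freqs: np.ndarray
    coh: np.ndarray
    dwpli: np.ndarray
    band_idx: np.ndarray
    coh_band: float
    dwpli_band: float
    n_subwindows: int = 0
    n_segments: int = 0
    degenerate: bool = False        # single sub-window: coherence identically 1
    dwpli_zero_flag: bool = False   # all imaginary parts vanished in-band


@dataclass
class PairCoupling:
    """Burst and non-burst coupling for one STN-cortical contact pair."""

    stn_label: str
    ctx_label: str
    burst: CouplingSpectrum
    nonburst: CouplingSpectrum
    diff_coh: float = field(init=False)
    diff_dwpli: float = field(init=False)

    def __post_init__(self) -> None:
        self.diff_coh = self.burst.coh_band - self.nonburst.coh_band
        self.diff_dwpli = self.burst.dwpli_band - self.nonburst.dwpli_band


def hamming_taper(window_len: int) -> np.ndarray:
    return sps.get_window("hamming", window_len)


def subwindow_offsets(seg_len: int, window_len: int, overlap_frac: float) -> np.ndarray:
    """Start offsets of Welch sub-windows inside a segment of seg_len."""
    step = max(1, int(round(window_len * (1.0 - overlap_frac))))
    if seg_len < window_len:
        return np.empty(0, dtype=np.int64)
    return np.arange(0, seg_len - window_len + 1, step, dtype=np.int64)


def pooled_subwindow_starts(
    intervals: np.ndarray, window_len: int, overlap_frac: float
) -> np.ndarray:
    """Absolute sub-window start indices pooled over a list of intervals."""
    starts: list[np.ndarray] = []
    for s, e in np.asarray(intervals, dtype=np.int64).reshape(-1, 2):
        offs = subwindow_offsets(e - s, window_len, overlap_frac)
        if offs.size:
            starts.append(s + offs)
    if not starts:
        return np.empty(0, dtype=np.int64)
    return np.concatenate(starts)


def tapered_fft(windows: np.ndarray, taper: np.ndarray, nfft: int | None = None) -> np.ndarray:
    """Mean-removed, tapered rFFT of a (k, window_len) block of sub-windows."""
    w = windows - windows.mean(axis=-1, keepdims=True)
    return np.fft.rfft(w * taper, n=nfft, axis=-1)


def spectra_from_ffts(X: np.ndarray, Y: np.ndarray, freqs: np.ndarray) -> PooledSpectra:
    return PooledSpectra(
        freqs=freqs,
        Sxy=X * np.conj(Y),
        Sxx=np.abs(X) ** 2,
        Syy=np.abs(Y) ** 2,
    )


def cross_spectra(
    segment_pairs: SegmentPairSet,
    window_len: int,
    overlap_frac: float = 0.5,
    nfft: int | None = None,
) -> PooledSpectra:
    """Pool tapered sub-window cross/auto spectra across segments.

    Segments shorter than ``window_len`` are skipped (counted in
    ``n_skipped``); zero usable segments is an error.
    """
    if window_len < 2:
        raise ValueError("window_len must be >= 2")
    nfft = nfft or window_len
    taper = hamming_taper(window_len)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / segment_pairs.fs)
    X_blocks, Y_blocks = [], []
    n_skipped = 0
    for x, y in segment_pairs.segments:
        offs = subwindow_offsets(x.size, window_len, overlap_frac)
        if offs.size == 0:
            n_skipped += 1
            continue
        idx = offs[:, None] + np.arange(window_len)[None, :]
        X_blocks.append(tapered_fft(x[idx], taper, nfft))
        Y_blocks.append(tapered_fft(y[idx], taper, nfft))
    if not X_blocks:
        raise ValueError(
            f"no segment reaches the {window_len}-sample Welch window "
            f"({n_skipped} skipped)"
        )
    if n_skipped:
        logger.info("cross_spectra: skipped %d segments shorter than %d samples",
                    n_skipped, window_len)
    X = np.concatenate(X_blocks, axis=0)
    Y = np.concatenate(Y_blocks, axis=0)
    ps = spectra_from_ffts(X, Y, freqs)
    ps.n_skipped = n_skipped
    return ps


def msc(pooled: PooledSpectra) -> np.ndarray:
    """Magnitude-squared coherence over the pooled sub-windows.

    With a single sub-window the estimator is identically 1; a warning is
    raised and callers should treat the value as degenerate.
    """
    if pooled.n_subwindows < 2:
        warnings.warn(
            "coherence from a single Welch sub-window is identically 1 (degenerate)",
            UserWarning,
            stacklevel=2,
        )
    num = np.abs(pooled.Sxy.sum(axis=0)) ** 2
    den = pooled.Sxx.sum(axis=0) * pooled.Syy.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(den > 0, num / np.maximum(den, np.finfo(float).tiny), 0.0)
    return np.clip(c, 0.0, 1.0)


def dwpli(pooled: PooledSpectra) -> tuple[np.ndarray, np.ndarray]:
    """Debiased squared weighted phase-lag index per frequency.

    Returns ``(values, zero_flags)`` where ``zero_flags`` marks bins whose
    denominator vanished (all imaginary parts zero, e.g. pure zero-lag
    coupling); those bins are defined as 0.
    """
    if pooled.n_subwindows < 2:
        raise ValueError("dwPLI is undefined for fewer than 2 sub-windows")
    imag = np.imag(pooled.Sxy)
    sum_i = imag.sum(axis=0)
    sum_i2 = (imag ** 2).sum(axis=0)
    sum_abs = np.abs(imag).sum(axis=0)
    num = sum_i ** 2 - sum_i2
    den = sum_abs ** 2 - sum_i2
    # a vanished denominator means the imaginary parts carry no signal;
    # judged relative to the cross-spectral magnitude so that float
    # round-off from exactly zero-lag (real-proportional) pairs is caught
    mag_sum = np.abs(pooled.Sxy).sum(axis=0)
    zero = (den <= 0) | (sum_abs <= 1e-9 * mag_sum)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(zero, 0.0, num / np.where(zero, 1.0, den))
    return out, zero


def select_band_indices(
    window_len: int,
    fs: float,
    band: tuple[float, float] = DEFAULT_BAND,
    nfft: int | None = None,
) -> np.ndarray:
    """Frequency-grid indices with ``band[0] <= f <= band[1]``.

    The grid is the rFFT grid implied by ``nfft`` (default: the Welch
    window length itself); the same indices are reused verbatim for burst,
    non-burst and surrogate estimates of a pair.
    """
    nfft = nfft or window_len
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    idx = np.flatnonzero((freqs >= band[0]) & (freqs <= band[1]))
    if idx.size == 0:
        min_len = int(np.ceil(fs / (band[1] - band[0]))) + 1
        raise ValueError(
            f"no frequency bin in [{band[0]}, {band[1]}] Hz on a {nfft}-point grid at "
            f"fs={fs}; use a window of at least ~{min_len} samples"
        )
    return idx


def sample_nonburst_segments(
    nonbursts: np.ndarray, cap: int = 100, rng: np.random.Generator | None = None
) -> np.ndarray:
    """Uniform subsample (without replacement) of at most ``cap`` intervals.

    Returned in original temporal order; deterministic under a seeded rng.
    """
    nb = np.asarray(nonbursts, dtype=np.int64).reshape(-1, 2)
    if len(nb) <= cap:
        return nb
    rng = rng or np.random.default_rng()
    keep = np.sort(rng.choice(len(nb), size=cap, replace=False))
    return nb[keep]


def spectrum_from_pooled(
    pooled: PooledSpectra, band_idx: np.ndarray, n_segments: int = 0
) -> CouplingSpectrum:
    """Assemble a CouplingSpectrum (both metrics + band averages)."""
    degenerate = pooled.n_subwindows < 2
    coh = msc(pooled)
    if degenerate:
        dw = np.zeros_like(coh)
        zero = np.ones_like(coh, dtype=bool)
    else:
        dw, zero = dwpli(pooled)
    return CouplingSpectrum(
        freqs=pooled.freqs,
        coh=coh,
        dwpli=dw,
        band_idx=band_idx,
        coh_band=float(coh[band_idx].mean()),
        dwpli_band=float(dw[band_idx].mean()),
        n_subwindows=pooled.n_subwindows,
        n_segments=n_segments,
        degenerate=degenerate,
        dwpli_zero_flag=bool(zero[band_idx].all()),
    )


def choose_window_len(
    intervals_per_condition: list[np.ndarray], cfg: CouplingConfig
) -> int:
    """Shared Welch window: min(max_window, shortest usable segment).

    A segment is usable when it is at least ``cfg.min_window`` samples
    long; the choice is shared across conditions so the frequency grid and
    band indices match.
    """
    lengths = []
    for intervals in intervals_per_condition:
        arr = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
        lens = arr[:, 1] - arr[:, 0]
        lengths.extend(lens[lens >= cfg.min_window].tolist())
    if not lengths:
        raise ValueError(
            f"no usable segment of >= {cfg.min_window} samples in any condition"
        )
    return int(min(cfg.max_window, min(lengths)))


def segments_from_intervals(
    stn: np.ndarray, ctx: np.ndarray, intervals: np.ndarray, fs: float, condition: str
) -> SegmentPairSet:
    """Cut equal-index (STN, cortex) windows out of the full signals."""
    segs = [
        (stn[s:e].copy(), ctx[s:e].copy())
        for s, e in np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
    ]
    return SegmentPairSet(segments=segs, fs=fs, condition=condition)


def pair_coupling(
    stn: BetaSignal,
    ctx: BetaSignal,
    epochs: EpochSet,
    cfg: CouplingConfig | None = None,
    rng: np.random.Generator | None = None,
) -> PairCoupling:
    """Burst vs non-burst coupling for one STN-cortical contact pair.

    Cortical samples are taken at identical sample indices as the STN
    epochs.  Non-burst segments are capped at ``cfg.nonburst_cap`` by
    uniform sampling; the Welch window and band indices are shared between
    conditions.
    """
    cfg = cfg or CouplingConfig()
    if epochs.n_bursts == 0:
        raise ValueError(f"contact {epochs.source_label!r} has no bursts")
    if epochs.n_nonbursts == 0:
        raise ValueError(f"contact {epochs.source_label!r} has no non-burst epochs")
    nb = sample_nonburst_segments(epochs.nonbursts, cap=cfg.nonburst_cap, rng=rng)
    window_len = choose_window_len([epochs.bursts, nb], cfg)
    band_idx = select_band_indices(window_len, stn.fs, cfg.band)

    spectra = {}
    for condition, intervals in (("burst", epochs.bursts), ("nonburst", nb)):
        pairs = segments_from_intervals(stn.x, ctx.x, intervals, stn.fs, condition)
        pooled = cross_spectra(pairs, window_len, cfg.overlap_frac)
        spectra[condition] = spectrum_from_pooled(pooled, band_idx, n_segments=len(intervals))
        logger.info(
            "pair %s-%s %s: %d segments, %d sub-windows (%d skipped)",
            stn.source_label, ctx.source_label, condition,
            len(intervals), pooled.n_subwindows, pooled.n_skipped,
        )
    return PairCoupling(
        stn_label=stn.source_label,
        ctx_label=ctx.source_label,
        burst=spectra["burst"],
        nonburst=spectra["nonburst"],
    )
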