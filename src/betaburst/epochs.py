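"""Burst-adjacent and peri-burst time-resolved coupling analyses.

Two complementary views of whether coupling persists outside bursts:

* **Burst-adjacent triplets** — for every burst of length L, the last L
  samples of the nearest earlier non-burst interval at least L samples
  long (pre) and the first L samples of the nearest later such interval
  (post).  Non-burst runs too short to hold the burst's length are passed
  over rather than shortened, keeping durations exactly matched; a burst
  with no qualifying neighbour on either side yields an invalid (skipped,
  counted) triplet.  Coupling is pooled per role across bursts, so burst
  vs pre vs post are directly comparable at matched durations.

* **Peri-burst traces** — coupling in short sliding windows (15 ms window,
  5 ms step) centered from 50 ms before to 50 ms after burst onset.  A
  15 ms window cannot hold multiple Welch sub-windows, so each window
  contributes a single tapered DFT and the across-burst collection forms
  the trial dimension of the estimators; spectra are zero-padded to a
  common grid so beta-band bins exist.  A matched non-burst baseline uses
  windows of identical length sampled at least 50 ms from any burst.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .bursts import EpochSet
from .coupling import (
    CouplingConfig,
    cross_spectra,
    hamming_taper,
    msc,
    dwpli,
    select_band_indices,
    choose_window_len,
    segments_from_intervals,
    spectrum_from_pooled,
    spectra_from_ffts,
    tapered_fft,
    CouplingSpectrum,
)
from .recording import BetaSignal


@dataclass
class AdjacentTriplet:
    """One burst with its length-matched pre and post non-burst windows."""

    burst: tuple[int, int]
    pre: tuple[int, int] | None
    post: tuple[int, int] | None
    valid: bool

    def check(self) -> None:
        if not self.valid:
            return
        bs, be = self.burst
        ps, pe = self.pre
        qs, qe = self.post
        L = be - bs
        assert pe - ps == L and qe - qs == L, "length mismatch in valid triplet"
        assert pe <= bs, "pre window must end at or before burst start"
        assert qs >= be, "post window must start at or after burst end"


@dataclass
class PeriBurstTrace:
    """Mean coupling per sliding window relative to burst onset."""

    offsets_ms: np.ndarray
    coh_trace: np.ndarray
    dwpli_trace: np.ndarray
    baseline_coh: float
    baseline_dwpli: float
    baseline_coh_sd: float
    baseline_dwpli_sd: float
    window_ms: float = 15.0
    step_ms: float = 5.0
    n_bursts_used: int = 0
    n_bursts_dropped: int = 0


def build_adjacent_triplets(epochs: EpochSet) -> list[AdjacentTriplet]:
    """Length-matched pre/post windows for every burst.

    ``pre`` is the last L samples of the nearest non-burst interval that
    ends at or before the burst start *and* is at least L samples long;
    ``post`` the first L samples of the nearest such interval starting at
    or after the burst end.  A triplet is valid only when both sides have
    a qualifying interval; invalid triplets are kept (flagged) so
    exclusion counts are auditable.
    """
    if epochs.n_bursts < 2:
        raise ValueError(
            f"contact {epochs.source_label!r} has {epochs.n_bursts} burst(s); "
            "burst-adjacent analysis needs >= 2"
        )
    nb = epochs.nonbursts
    lens = nb[:, 1] - nb[:, 0] if len(nb) else np.empty(0, dtype=np.int64)
    triplets: list[AdjacentTriplet] = []
    for bs, be in epochs.bursts:
        L = be - bs
        pre = post = None
        earlier = nb[(nb[:, 1] <= bs) & (lens >= L)]
        if len(earlier):
            ps, pe = earlier[-1]
            pre = (int(pe - L), int(pe))
        later = nb[(nb[:, 0] >= be) & (lens >= L)]
        if len(later):
            qs, qe = later[0]
            post = (int(qs), int(qs + L))
        valid = pre is not None and post is not None
        t = AdjacentTriplet(burst=(int(bs), int(be)), pre=pre, post=post, valid=valid)
        t.check()
        triplets.append(t)
    return triplets


def adjacent_coupling(
    stn: BetaSignal,
    ctx: BetaSignal,
    triplets: list[AdjacentTriplet],
    cfg: CouplingConfig | None = None,
) -> dict[str, CouplingSpectrum]:
    """Pooled coupling per triplet role (burst / pre / post).

    Only valid triplets contribute; the Welch window and band indices are
    shared across roles (segment lengths are matched by construction).
    """
    cfg = cfg or CouplingConfig()
    valid = [t for t in triplets if t.valid]
    if len(valid) < 2:
        raise ValueError(f"only {len(valid)} valid triplets; need >= 2")
    roles = {
        "burst": np.array([t.burst for t in valid], dtype=np.int64),
        "pre": np.array([t.pre for t in valid], dtype=np.int64),
        "post": np.array([t.post for t in valid], dtype=np.int64),
    }
    window_len = choose_window_len([roles["burst"]], cfg)
    band_idx = select_band_indices(window_len, stn.fs, cfg.band)
    out: dict[str, CouplingSpectrum] = {}
    for role, intervals in roles.items():
        order = np.argsort(intervals[:, 0])
        pairs = segments_from_intervals(stn.x, ctx.x, intervals[order], stn.fs, role)
        pooled = cross_spectra(pairs, window_len, cfg.overlap_frac)
        out[role] = spectrum_from_pooled(pooled, band_idx, n_segments=len(valid))
    return out


def _windows_band_coupling(
    stn_x: np.ndarray,
    ctx_x: np.ndarray,
    starts: np.ndarray,
    window_len: int,
    nfft: int,
    band_idx: np.ndarray,
    fs: float,
) -> tuple[float, float]:
    """One (coherence, dwPLI) band value from a set of whole windows.

    Each window is a single tapered, zero-padded DFT; the window set is
    the trial dimension.
    """
    taper = hamming_taper(window_len)
    idx = starts[:, None] + np.arange(window_len)[None, :]
    X = tapered_fft(stn_x[idx], taper, nfft)
    Y = tapered_fft(ctx_x[idx], taper, nfft)
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    pooled = spectra_from_ffts(X, Y, freqs)
    coh = msc(pooled)
    dw, _ = dwpli(pooled)
    return float(coh[band_idx].mean()), float(dw[band_idx].mean())


def matched_nonburst_windows(
    epochs: EpochSet,
    n_windows: int,
    window_ms: float,
    fs: float,
    n_samples: int,
    exclusion_ms: float = 50.0,
    rng: np.random.Generator | None = None,
) -> np.ndarray:
    """Random window starts lying >= ``exclusion_ms`` from every burst.

    Returns ``n_windows`` start indices (without replacement when the
    eligible region allows); an empty eligible region is an error.
    """
    rng = rng or np.random.default_rng()
    w = max(2, int(round(window_ms * fs / 1000.0)))
    excl = int(round(exclusion_ms * fs / 1000.0))
    eligible = np.ones(max(0, n_samples - w + 1), dtype=bool)
    for bs, be in epochs.bursts:
        lo = max(0, bs - excl - w + 1)
        hi = min(eligible.size, be + excl)
        eligible[lo:hi] = False
    starts = np.flatnonzero(eligible)
    if starts.size == 0:
        raise ValueError(
            f"no eligible non-burst window of {window_ms} ms at >= {exclusion_ms} ms "
            "from every burst"
        )
    replace = starts.size < n_windows
    return np.sort(rng.choice(starts, size=n_windows, replace=replace))


def peri_burst_trace(
    stn: BetaSignal,
    ctx: BetaSignal,
    epochs: EpochSet,
    window_ms: float = 15.0,
    step_ms: float = 5.0,
    span_ms: float = 50.0,
    nfft: int = 256,
    exclusion_ms: float = 50.0,
    n_baseline_draws: int = 20,
    band: tuple[float, float] = (13.0, 30.0),
    rng: np.random.Generator | None = None,
) -> PeriBurstTrace:
    """Sliding-window coupling aligned to burst onsets.

    Offsets run from ``-span_ms`` to ``+span_ms`` in ``step_ms`` steps;
    the window at each offset is centered on (onset + offset).  Bursts
    whose full peri-onset context leaves the recording are dropped and
    counted.  The baseline is the mean +/- SD over ``n_baseline_draws``
    independent matched non-burst window sets of the same size.
    """
    rng = rng or np.random.default_rng()
    fs = stn.fs
    n = len(stn)
    w = max(2, int(round(window_ms * fs / 1000.0)))
    half_lo = (w - 1) // 2
    half_hi = w - half_lo
    span = int(round(span_ms * fs / 1000.0))
    step = int(round(step_ms * fs / 1000.0))
    offsets = np.arange(-span, span + 1, step, dtype=np.int64)

    onsets = epochs.bursts[:, 0] if epochs.n_bursts else np.empty(0, dtype=np.int64)
    ok = (onsets - span - half_lo >= 0) & (onsets + span + half_hi <= n)
    used = onsets[ok]
    if used.size < 2:
        raise ValueError(
            f"only {used.size} burst(s) with full peri-onset context; need >= 2"
        )
    band_idx = select_band_indices(w, fs, band, nfft=nfft)

    coh_trace = np.empty(offsets.size)
    dw_trace = np.empty(offsets.size)
    for i, off in enumerate(offsets):
        starts = used + off - half_lo
        coh_trace[i], dw_trace[i] = _windows_band_coupling(
            stn.x, ctx.x, starts, w, nfft, band_idx, fs
        )

    base_coh = np.empty(n_baseline_draws)
    base_dw = np.empty(n_baseline_draws)
    for d in range(n_baseline_draws):
        starts = matched_nonburst_windows(
            epochs, used.size, window_ms, fs, n, exclusion_ms=exclusion_ms, rng=rng
        )
        base_coh[d], base_dw[d] = _windows_band_coupling(
            stn.x, ctx.x, starts, w, nfft, band_idx, fs
        )

    return PeriBurstTrace(
        offsets_ms=offsets * 1000.0 / fs,
        coh_trace=coh_trace,
        dwpli_trace=dw_trace,
        baseline_coh=float(base_coh.mean()),
        baseline_dwpli=float(base_dw.mean()),
        baseline_coh_sd=float(base_coh.std(ddof=1)) if n_baseline_draws > 1 else 0.0,
        baseline_dwpli_sd=float(base_dw.std(ddof=1)) if n_baseline_draws > 1 else 0.0,
        window_ms=window_ms,
        step_ms=step_ms,
        n_bursts_used=int(used.size),
        n_bursts_dropped=int(onsets.size - used.size),
    )
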