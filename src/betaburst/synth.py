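"""Synthetic STN/cortex signal pairs with known burst and coupling structure.

The generator produces a two-channel recording — one subthalamic-like and
one cortical-like channel — in which every quantity the downstream pipeline
estimates is known by construction:

* the STN channel carries a narrowband beta (13-30 Hz) component whose
  amplitude envelope is elevated by ``burst_gain`` inside discrete burst
  intervals drawn from a homogeneous Poisson process;
* the cortical channel carries a beta component whose instantaneous phase
  is a mixture of the STN beta phase (shifted by ``phase_lag_rad``) and an
  independent phase, with mixing weight ``coupling_strength`` applied
  inside the coupling region selected by ``coupling_mode`` (inside bursts
  only, everywhere, or nowhere);
* both channels sit on independent 1/f-shaped Gaussian backgrounds.

Coupling acts on the beta component's phase rather than by adding the raw
STN trace, so phase-based (dwPLI) and magnitude-based (coherence) targets
are controllable independently of amplitude.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, asdict

import numpy as np

from .recording import Recording, ROLE_STN, ROLE_CORTICAL, check_intervals, intervals_to_mask

COUPLING_MODES = ("burst_locked", "tonic", "none")


@dataclass
class SynthConfig:
    """Parameters of one synthetic STN/cortex pair.

    Defaults describe a resting intraoperative recording regime: 120 s at
    1000 Hz, a 20 Hz beta rhythm bursting about every other second with
    ~300 ms bursts at four-fold envelope gain, and strong burst-locked
    cortico-STN phase coupling at a quarter-cycle lag.
    """

    duration_s: float = 120.0
    fs: float = 1000.0
    beta_freq: float = 20.0           # Hz, carrier within [13, 30]
    burst_rate: float = 0.5           # bursts / second (Poisson onset rate)
    burst_dur_mean_ms: float = 300.0
    burst_dur_sd_ms: float = 100.0
    burst_gain: float = 4.0           # envelope multiplier inside bursts, >= 1
    coupling_mode: str = "burst_locked"
    coupling_strength: float = 0.9    # in [0, 1]
    phase_lag_rad: float = math.pi / 4
    noise_exponent: float = 1.0       # power ~ f^(-noise_exponent)
    beta_amp: float = 1.0             # baseline beta envelope amplitude
    noise_amp: float = 1.0            # background standard deviation
    # Per-sample SD of white instantaneous-frequency noise.  The resulting
    # beta peak is Lorentzian with FWHM = (2*pi*freq_jitter_hz/fs)^2 * fs / (2*pi)
    # (~4 Hz at the default) — a linewidth consistent with 100-500 ms
    # bursts, so independent oscillators decorrelate within ~100 ms as
    # real beta rhythms do.
    freq_jitter_hz: float = 25.0
    seed: int = 0

    #: durations below this are resampled (bursts shorter than the
    #: detector's 100 ms minimum would be filtered downstream)
    min_burst_dur_ms: float = 120.0

    def validate(self) -> None:
        numeric = {k: v for k, v in asdict(self).items() if k != "coupling_mode"}
        for name, value in numeric.items():
            if not np.isfinite(value):
                raise ValueError(f"non-finite parameter {name}={value!r}")
        if self.duration_s <= 0:
            raise ValueError("duration_s must be positive")
        if self.fs <= 60.0:
            raise ValueError("fs must exceed twice the 30 Hz beta upper edge")
        if not 13.0 <= self.beta_freq <= 30.0:
            raise ValueError("beta_freq must lie in [13, 30] Hz")
        if not 0.0 <= self.coupling_strength <= 1.0:
            raise ValueError("coupling_strength must lie in [0, 1]")
        if self.burst_gain < 1.0:
            raise ValueError("burst_gain must be >= 1")
        if self.coupling_mode not in COUPLING_MODES:
            raise ValueError(f"coupling_mode must be one of {COUPLING_MODES}")
        if self.burst_rate < 0:
            raise ValueError("burst_rate must be non-negative")
        if self.burst_dur_mean_ms < 100.0:
            warnings.warn(
                "burst_dur_mean_ms < 100 ms: most bursts would be removed by the "
                "downstream 100 ms minimum-duration rule",
                UserWarning,
                stacklevel=3,
            )


@dataclass
class GroundTruth:
    """What the generator actually injected, for recovery checks."""

    true_burst_intervals: np.ndarray  # (n, 2) half-open raw-sample intervals
    coupling_mode: str
    phase_lag_rad: float
    n_samples: int = 0

    def __post_init__(self) -> None:
        self.true_burst_intervals = check_intervals(
            self.true_burst_intervals, self.n_samples or None
        )

    def intervals_in_trimmed(
        self, fs: float, head_discard_s: float, edge_trim_s: float, n_trimmed: int
    ) -> np.ndarray:
        """True burst intervals re-expressed in trimmed-signal coordinates.

        The preprocessing chain drops ``head_discard_s + edge_trim_s``
        seconds from the front of the raw timeline; intervals are shifted
        accordingly and clipped to ``[0, n_trimmed)``.
        """
        offset = int(math.floor((head_discard_s + edge_trim_s) * fs))
        out = []
        for s, e in self.true_burst_intervals:
            s2, e2 = max(0, s - offset), min(n_trimmed, e - offset)
            if e2 > s2:
                out.append((s2, e2))
        return np.asarray(out, dtype=np.int64).reshape(-1, 2)


def _powerlaw_noise(n: int, exponent: float, rng: np.random.Generator) -> np.ndarray:
    """Unit-variance Gaussian noise with power spectrum ~ f^(-exponent)."""
    white = rng.standard_normal(n)
    if exponent == 0:
        return white
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    scale = np.ones_like(f)
    nz = f > 0
    scale[nz] = f[nz] ** (-exponent / 2.0)
    scale[0] = 0.0  # no DC
    x = np.fft.irfft(spec * scale, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _sample_burst_intervals(cfg: SynthConfig, n: int, rng: np.random.Generator) -> np.ndarray:
    """Poisson onsets with truncated-normal durations, overlaps merged."""
    expected = cfg.burst_rate * cfg.duration_s
    n_onsets = rng.poisson(expected)
    if n_onsets == 0:
        return np.empty((0, 2), dtype=np.int64)
    onsets_s = np.sort(rng.uniform(0.0, cfg.duration_s, size=n_onsets))
    durs_ms = rng.normal(cfg.burst_dur_mean_ms, cfg.burst_dur_sd_ms, size=n_onsets)
    # truncate at the minimum duration by redrawing
    bad = durs_ms < cfg.min_burst_dur_ms
    guard = 0
    while np.any(bad) and guard < 1000:
        durs_ms[bad] = rng.normal(cfg.burst_dur_mean_ms, cfg.burst_dur_sd_ms, size=bad.sum())
        bad = durs_ms < cfg.min_burst_dur_ms
        guard += 1
    durs_ms = np.maximum(durs_ms, cfg.min_burst_dur_ms)

    starts = np.floor(onsets_s * cfg.fs).astype(np.int64)
    ends = starts + np.maximum(1, np.round(durs_ms * cfg.fs / 1000.0).astype(np.int64))
    # merge intervals that overlap or touch (gap of >= 1 sample enforced)
    merged: list[list[int]] = []
    for s, e in zip(starts, ends):
        e = min(e, n)
        s = min(s, n - 1)
        if e <= s:
            continue
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=np.int64).reshape(-1, 2)


def _phase_track(n: int, f0: float, fs: float, jitter_hz: float,
                 rng: np.random.Generator) -> np.ndarray:
    """Instantaneous phase of a narrowband oscillator with frequency jitter."""
    inst_freq = f0 + jitter_hz * rng.standard_normal(n)
    phase = 2.0 * np.pi * np.cumsum(inst_freq) / fs
    return phase + rng.uniform(0.0, 2.0 * np.pi)


def _burst_envelope(cfg: SynthConfig, intervals: np.ndarray, n: int) -> np.ndarray:
    """Beta envelope: baseline, raised to burst_gain inside bursts.

    Edges are smoothed with a short Hann ramp so the injected envelope has
    no single-sample steps (a step would ring through the band-pass).
    """
    env = intervals_to_mask(intervals, n).astype(float)
    ramp_len = max(1, int(round(0.02 * cfg.fs)))  # 20 ms
    if ramp_len > 1:
        kernel = np.hanning(2 * ramp_len + 1)
        kernel /= kernel.sum()
        env = np.convolve(env, kernel, mode="same")
    return cfg.beta_amp * (1.0 + (cfg.burst_gain - 1.0) * env)


def generate_pair(config: SynthConfig) -> tuple[Recording, GroundTruth]:
    """Generate one STN/cortex channel pair with known ground truth.

    Returns a two-channel :class:`Recording` (labels ``STN_1``, ``ECOG_1``)
    and the :class:`GroundTruth` holding the sampled burst intervals in raw
    sample coordinates.  Fully reproducible: the same config (including
    ``seed``) yields bit-identical output.
    """
    config.validate()
    n = int(round(config.duration_s * config.fs))
    ss = np.random.SeedSequence(config.seed)
    r_bursts, r_stn_phase, r_ctx_phase, r_stn_noise, r_ctx_noise = (
        np.random.default_rng(child) for child in ss.spawn(5)
    )

    intervals = _sample_burst_intervals(config, n, r_bursts)
    envelope = _burst_envelope(config, intervals, n)

    phi_stn = _phase_track(n, config.beta_freq, config.fs, config.freq_jitter_hz, r_stn_phase)
    phi_ind = _phase_track(n, config.beta_freq, config.fs, config.freq_jitter_hz, r_ctx_phase)

    stn_beta = envelope * np.cos(phi_stn)

    if config.coupling_mode == "none":
        region = np.zeros(n, dtype=bool)
    elif config.coupling_mode == "tonic":
        region = np.ones(n, dtype=bool)
    else:  # burst_locked
        region = intervals_to_mask(intervals, n)

    c = config.coupling_strength * region.astype(float)
    # complex mixture of locked and independent unit phasors
    z = c * np.exp(1j * (phi_stn + config.phase_lag_rad)) + (1.0 - c) * np.exp(1j * phi_ind)
    ctx_beta = config.beta_amp * np.real(z)

    stn = stn_beta + config.noise_amp * _powerlaw_noise(n, config.noise_exponent, r_stn_noise)
    ctx = ctx_beta + config.noise_amp * _powerlaw_noise(n, config.noise_exponent, r_ctx_noise)

    rec = Recording(
        samples=np.column_stack([stn, ctx]),
        fs=config.fs,
        labels=["STN_1", "ECOG_1"],
        roles={"STN_1": ROLE_STN, "ECOG_1": ROLE_CORTICAL},
    )
    truth = GroundTruth(
        true_burst_intervals=intervals,
        coupling_mode=config.coupling_mode,
        phase_lag_rad=config.phase_lag_rad,
        n_samples=n,
    )
    return rec, truth


def write_fixture(recording: Recording, path, format: str = "tsv") -> None:
    """Write a recording to disk as an analysis fixture.

    ``tsv`` writes a lossless text matrix plus a YAML sidecar; ``edf``
    writes a 16-bit EDF file (round trips to within one quantization step
    of the stored physical range).
    """
    if recording.n_samples == 0:
        raise ValueError("cannot write an empty recording")
    if format == "tsv":
        from .io import write_recording_tsv

        write_recording_tsv(recording, path)
    elif format == "edf":
        from .edf import write_edf

        write_edf(recording, path)
    else:
        raise ValueError(f"unsupported fixture format {format!r} (use 'tsv' or 'edf')")
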