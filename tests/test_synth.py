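"""Generator properties: reproducibility, burst statistics, coupling construction."""

import numpy as np
import pytest
from scipy import stats as spstats
from scipy import signal as sps

import betaburst as bb
from betaburst.recording import intervals_to_mask


def test_same_seed_is_bit_identical():
    cfg = bb.SynthConfig(duration_s=10, seed=42)
    rec1, truth1 = bb.generate_pair(cfg)
    rec2, truth2 = bb.generate_pair(bb.SynthConfig(duration_s=10, seed=42))
    np.testing.assert_array_equal(rec1.samples, rec2.samples)
    np.testing.assert_array_equal(truth1.true_burst_intervals, truth2.true_burst_intervals)


def test_different_seeds_differ():
    r1, _ = bb.generate_pair(bb.SynthConfig(duration_s=5, seed=1))
    r2, _ = bb.generate_pair(bb.SynthConfig(duration_s=5, seed=2))
    assert not np.array_equal(r1.samples, r2.samples)


@pytest.mark.parametrize("seed", [0, 7, 99])
def test_true_bursts_sorted_disjoint_in_bounds(seed):
    rec, truth = bb.generate_pair(bb.SynthConfig(duration_s=60, seed=seed))
    iv = truth.true_burst_intervals
    assert np.all(iv[:, 1] > iv[:, 0])
    assert np.all(iv[1:, 0] > iv[:-1, 1] - 1)  # inter-burst gap >= 1 sample
    assert iv.min(initial=0) >= 0 and iv.max(initial=0) <= rec.n_samples


def test_burst_count_within_poisson_99_interval():
    # 120 s at 0.5 bursts/s: expected 60 onsets; merging can only reduce the
    # count, so compare against the Poisson 99% interval around 60
    cfg = bb.SynthConfig(duration_s=120, fs=1000, burst_rate=0.5, seed=7)
    _, truth = bb.generate_pair(cfg)
    n = len(truth.true_burst_intervals)
    lo = spstats.poisson.ppf(0.005, 60)
    hi = spstats.poisson.ppf(0.995, 60)
    assert lo <= n <= hi


def test_short_burst_duration_warns():
    with pytest.warns(UserWarning, match="100 ms"):
        bb.generate_pair(bb.SynthConfig(duration_s=5, burst_dur_mean_ms=80, seed=0))


@pytest.mark.parametrize(
    "bad",
    [
        dict(duration_s=np.nan),
        dict(burst_gain=0.5),
        dict(coupling_strength=1.5),
        dict(coupling_mode="sometimes"),
        dict(fs=40.0),
        dict(beta_freq=50.0),
    ],
)
def test_invalid_config_rejected(bad):
    params = {"duration_s": 5, "seed": 0, **bad}
    with pytest.raises(ValueError):
        bb.generate_pair(bb.SynthConfig(**params))


def test_tonic_full_coupling_is_quarter_cycle_shifted_copy():
    # with full tonic coupling, zero noise and flat envelope, the cortical
    # beta phase is the STN phase + pi/2 everywhere
    cfg = bb.SynthConfig(
        duration_s=10, seed=3, coupling_mode="tonic", coupling_strength=1.0,
        phase_lag_rad=np.pi / 2, noise_amp=0.0, burst_gain=1.0,
    )
    rec, _ = bb.generate_pair(cfg)
    sos = sps.butter(4, [13, 30], btype="bandpass", fs=cfg.fs, output="sos")
    stn = sps.hilbert(sps.sosfiltfilt(sos, rec.channel("STN_1")))
    ctx = sps.hilbert(sps.sosfiltfilt(sos, rec.channel("ECOG_1")))
    dphi = np.angle(ctx * np.conj(stn))[500:-500]  # discard filter/analytic edges
    err = np.angle(np.exp(1j * (dphi - np.pi / 2)))
    # residual spread is the finite-linewidth analytic-signal error (a
    # jittered-phase cosine has slight negative-frequency content, so its
    # quadrature is not exactly its Hilbert transform)
    resultant = np.mean(np.exp(1j * err))
    assert abs(np.angle(resultant)) < 0.05   # centered on the quarter-cycle lag
    assert abs(resultant) > 0.98             # tightly concentrated
    assert np.percentile(np.abs(err), 95) < 0.3


def test_none_mode_channels_are_independent():
    # empirical check: band coherence of a none pair over many sub-windows is tiny
    cfg = bb.SynthConfig(duration_s=30, seed=11, coupling_mode="none")
    rec, _ = bb.generate_pair(cfg)
    f, c = sps.coherence(rec.channel("STN_1"), rec.channel("ECOG_1"),
                         fs=rec.fs, nperseg=256)
    band = (f >= 13) & (f <= 30)
    assert c[band].mean() < 0.1


def test_stn_envelope_elevated_inside_bursts():
    cfg = bb.SynthConfig(duration_s=60, seed=5, noise_amp=0.0)
    rec, truth = bb.generate_pair(cfg)
    env = np.abs(sps.hilbert(rec.channel("STN_1")))
    mask = intervals_to_mask(truth.true_burst_intervals, rec.n_samples)
    assert env[mask].mean() > 2.5 * env[~mask].mean()


def test_intervals_in_trimmed_coordinates():
    truth = bb.GroundTruth(
        true_burst_intervals=np.array([[100, 300], [2500, 2700], [5100, 5300]]),
        coupling_mode="none", phase_lag_rad=0.0, n_samples=6000,
    )
    out = truth.intervals_in_trimmed(fs=1000, head_discard_s=2, edge_trim_s=0, n_trimmed=3500)
    # first burst is entirely inside the discarded head; last is clipped
    np.testing.assert_array_equal(out, [[500, 700], [3100, 3300]])


def test_write_fixture_rejects_unknown_format(tmp_path):
    rec, _ = bb.generate_pair(bb.SynthConfig(duration_s=2, seed=0))
    with pytest.raises(ValueError, match="format"):
        bb.write_fixture(rec, tmp_path / "x.dat", format="mat")


def test_empty_recording_is_rejected():
    with pytest.raises(ValueError):
        bb.Recording(samples=np.empty((0, 2)), fs=1000,
                     labels=["STN_1", "ECOG_1"],
                     roles={"STN_1": "stn", "ECOG_1": "cortical"})
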