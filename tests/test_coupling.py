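"""Coherence and dwPLI estimators against independent brute-force oracles."""

import numpy as np
import pytest

import betaburst as bb
from betaburst.coupling import (
    CouplingConfig,
    PooledSpectra,
    SegmentPairSet,
    cross_spectra,
    msc,
    dwpli,
    select_band_indices,
    sample_nonburst_segments,
    choose_window_len,
)

FS = 1000.0


# ---------------------------------------------------------------- oracles
def naive_pooled_spectra(segments, fs, window_len, overlap_frac):
    """Direct-DFT re-implementation: explicit loops, explicit taper formula."""
    step = max(1, int(round(window_len * (1.0 - overlap_frac))))
    n = np.arange(window_len)
    taper = 0.54 - 0.46 * np.cos(2.0 * np.pi * n / window_len)  # periodic Hamming
    freqs = np.arange(window_len // 2 + 1) * fs / window_len
    Sxy, Sxx, Syy = [], [], []
    for x, y in segments:
        for s in range(0, len(x) - window_len + 1, step):
            xw = x[s:s + window_len] - x[s:s + window_len].mean()
            yw = y[s:s + window_len] - y[s:s + window_len].mean()
            X = np.array([np.sum(taper * xw * np.exp(-2j * np.pi * k * n / window_len))
                          for k in range(window_len // 2 + 1)])
            Y = np.array([np.sum(taper * yw * np.exp(-2j * np.pi * k * n / window_len))
                          for k in range(window_len // 2 + 1)])
            Sxy.append(X * np.conj(Y))
            Sxx.append(np.abs(X) ** 2)
            Syy.append(np.abs(Y) ** 2)
    return freqs, np.array(Sxy), np.array(Sxx), np.array(Syy)


def naive_msc(Sxy, Sxx, Syy):
    return np.abs(Sxy.sum(0)) ** 2 / (Sxx.sum(0) * Syy.sum(0))


def naive_dwpli(Sxy):
    im = np.imag(Sxy)
    num = im.sum(0) ** 2 - (im ** 2).sum(0)
    den = np.abs(im).sum(0) ** 2 - (im ** 2).sum(0)
    out = np.zeros(im.shape[1])
    ok = den > 0
    out[ok] = num[ok] / den[ok]
    return out


def random_segments(rng, n_segments, min_len=40, max_len=120):
    segs = []
    for _ in range(n_segments):
        L = int(rng.integers(min_len, max_len))
        segs.append((rng.standard_normal(L), rng.standard_normal(L)))
    return segs


# ---------------------------------------------------------------- tests
def test_estimators_match_brute_force_oracle(rng):
    for trial in range(10):
        segs = random_segments(rng, n_segments=int(rng.integers(2, 6)))
        window_len = 32
        pooled = cross_spectra(SegmentPairSet(segments=list(segs), fs=FS, condition="burst"),
                               window_len, overlap_frac=0.5)
        _, Sxy, Sxx, Syy = naive_pooled_spectra(segs, FS, window_len, 0.5)
        np.testing.assert_allclose(msc(pooled), naive_msc(Sxy, Sxx, Syy), atol=1e-10)
        ours, _ = dwpli(pooled)
        # DC and Nyquist bins of a real signal carry no phase information:
        # there the oracle's direct DFT divides numerical noise by numerical
        # noise, so only interior bins are compared
        np.testing.assert_allclose(ours[1:-1], naive_dwpli(Sxy)[1:-1], atol=1e-10)


def test_self_cross_spectrum_is_real_autospectrum(rng):
    x = rng.standard_normal(300)
    pooled = cross_spectra(SegmentPairSet(segments=[(x, x.copy())], fs=FS, condition="burst"),
                           64, 0.5)
    np.testing.assert_allclose(pooled.Sxy.imag, 0.0, atol=1e-12)
    np.testing.assert_allclose(pooled.Sxy.real, pooled.Sxx, atol=1e-9)


def test_quarter_cycle_delay_gives_quarter_cycle_phase():
    t = np.arange(1024) / FS
    x = np.sin(2 * np.pi * 20 * t)
    delay = int(round(FS / 20 / 4))  # quarter cycle of 20 Hz
    y = np.roll(x, delay)
    pooled = cross_spectra(SegmentPairSet(segments=[(x[100:900], y[100:900])],
                                          fs=FS, condition="burst"), 200, 0.5)
    k20 = int(np.argmin(np.abs(pooled.freqs - 20.0)))
    phase = np.angle(pooled.Sxy[:, k20])
    assert np.allclose(np.abs(phase), np.pi / 2, atol=0.1)


def test_coherence_of_scaled_copy_is_one(rng):
    x = rng.standard_normal(2000)
    pooled = cross_spectra(SegmentPairSet(segments=[(x, -3.2 * x)], fs=FS, condition="burst"),
                           128, 0.5)
    c = msc(pooled)
    assert c.min() > 1.0 - 1e-10


def test_coherence_bias_of_independent_noise_scales_as_one_over_k(rng):
    segs = [(rng.standard_normal(6464), rng.standard_normal(6464))]
    pooled = cross_spectra(SegmentPairSet(segments=segs, fs=FS, condition="burst"), 64, 0.0)
    k = pooled.n_subwindows
    assert k >= 100
    mean_c = msc(pooled).mean()
    assert mean_c < 0.1
    assert mean_c == pytest.approx(1.0 / k, rel=0.6)  # E[C] ~ 1/K for independent noise


def test_equal_power_common_signal_gives_half_coherence(rng):
    # y = x + independent noise of equal in-band power -> C = SNR/(1+SNR) = 0.5
    from scipy import signal as sps
    sos = sps.butter(4, [13, 30], btype="bandpass", fs=FS, output="sos")
    common = sps.sosfiltfilt(sos, rng.standard_normal(60_000))
    noise = sps.sosfiltfilt(sos, rng.standard_normal(60_000))
    noise *= common.std() / noise.std()
    pooled = cross_spectra(
        SegmentPairSet(segments=[(common, common + noise)], fs=FS, condition="burst"),
        256, 0.5,
    )
    band = select_band_indices(256, FS)
    c = msc(pooled)[band].mean()
    assert c == pytest.approx(0.5, abs=0.06)


def test_single_subwindow_is_degenerate(rng):
    x = rng.standard_normal(64)
    pooled = cross_spectra(SegmentPairSet(segments=[(x, x)], fs=FS, condition="burst"), 64, 0.5)
    with pytest.warns(UserWarning, match="degenerate"):
        c = msc(pooled)
    assert np.allclose(c[1:-1], 1.0)


def make_pooled(imags):
    """PooledSpectra with a single frequency bin and crafted Im(Sxy)."""
    im = np.asarray(imags, float)[:, None]
    return PooledSpectra(freqs=np.array([20.0]), Sxy=1j * im,
                         Sxx=np.ones_like(im), Syy=np.ones_like(im))


def test_dwpli_formula_consistent_positive_lags():
    val, zero = dwpli(make_pooled([2.0, 2.0, 2.0]))
    assert val[0] == pytest.approx(1.0) and not zero[0]


def test_dwpli_formula_opposed_lags_is_minus_one():
    val, _ = dwpli(make_pooled([1.0, -1.0]))
    assert val[0] == pytest.approx(-1.0)  # reported unclipped


def test_dwpli_zero_lag_flagged_zero(rng):
    x = rng.standard_normal(2000)
    pooled = cross_spectra(SegmentPairSet(segments=[(x, 2.0 * x)], fs=FS, condition="burst"),
                           128, 0.5)
    val, zero = dwpli(pooled)
    assert np.all(val == 0.0) and np.all(zero)


def test_dwpli_invariant_to_amplitude_and_lag_sign(rng):
    X = rng.standard_normal((20, 9)) + 1j * rng.standard_normal((20, 9))
    Y = rng.standard_normal((20, 9)) + 1j * rng.standard_normal((20, 9))
    freqs = np.arange(9, dtype=float)
    p_fwd = PooledSpectra(freqs=freqs, Sxy=X * np.conj(Y),
                          Sxx=np.abs(X) ** 2, Syy=np.abs(Y) ** 2)
    # amplitude scaling
    p_scaled = PooledSpectra(freqs=freqs, Sxy=(5 * X) * np.conj(0.3 * Y),
                             Sxx=np.abs(5 * X) ** 2, Syy=np.abs(0.3 * Y) ** 2)
    # lag sign flip: conjugate cross-spectra
    p_rev = PooledSpectra(freqs=freqs, Sxy=np.conj(X * np.conj(Y)),
                          Sxx=np.abs(X) ** 2, Syy=np.abs(Y) ** 2)
    v, _ = dwpli(p_fwd)
    vs, _ = dwpli(p_scaled)
    vr, _ = dwpli(p_rev)
    np.testing.assert_allclose(v, vs, atol=1e-12)
    np.testing.assert_allclose(v, vr, atol=1e-12)


def test_msc_invariant_to_channel_scaling(rng):
    x, y = rng.standard_normal(1000), rng.standard_normal(1000)
    p1 = cross_spectra(SegmentPairSet(segments=[(x, y)], fs=FS, condition="burst"), 128, 0.5)
    p2 = cross_spectra(SegmentPairSet(segments=[(7.0 * x, -0.01 * y)], fs=FS,
                                      condition="burst"), 128, 0.5)
    np.testing.assert_allclose(msc(p1), msc(p2), atol=1e-12)


def test_dwpli_is_debiased_under_independence(rng):
    # mean over 1000 independent pairs of 20-trial spectra stays within +/- 0.02
    vals = []
    for _ in range(1000):
        X = rng.standard_normal((20, 5)) + 1j * rng.standard_normal((20, 5))
        Y = rng.standard_normal((20, 5)) + 1j * rng.standard_normal((20, 5))
        p = PooledSpectra(freqs=np.arange(5, dtype=float), Sxy=X * np.conj(Y),
                          Sxx=np.abs(X) ** 2, Syy=np.abs(Y) ** 2)
        v, _ = dwpli(p)
        vals.append(v.mean())
    assert abs(np.mean(vals)) <= 0.02


def test_select_band_indices_grid_arithmetic():
    idx = select_band_indices(256, FS)
    np.testing.assert_allclose(np.fft.rfftfreq(256, 1 / FS)[idx],
                               [15.625, 19.53125, 23.4375, 27.34375])
    # 64-point grid at 1000 Hz steps by 15.625 Hz: only the 15.625 Hz bin
    # falls inside [13, 30] (31.25 is already above the band edge)
    np.testing.assert_allclose(np.fft.rfftfreq(64, 1 / FS)[select_band_indices(64, FS)],
                               [15.625])
    with pytest.raises(ValueError, match="window"):
        select_band_indices(16, FS)


def test_sample_nonburst_segments_cap_and_determinism():
    nb = np.array([[i * 10, i * 10 + 5] for i in range(250)])
    few = sample_nonburst_segments(nb[:40], cap=100, rng=np.random.default_rng(0))
    np.testing.assert_array_equal(few, nb[:40])  # cap not binding: original order
    s1 = sample_nonburst_segments(nb, cap=100, rng=np.random.default_rng(5))
    s2 = sample_nonburst_segments(nb, cap=100, rng=np.random.default_rng(5))
    assert len(s1) == 100 and len(np.unique(s1[:, 0])) == 100
    np.testing.assert_array_equal(s1, s2)
    assert np.all(np.diff(s1[:, 0]) > 0)  # temporal order preserved


def test_pair_coupling_burst_locked_direction(burst_locked_pair):
    stn, ctx, epochs, _ = burst_locked_pair
    pc = bb.pair_coupling(stn, ctx, epochs, rng=np.random.default_rng(0))
    assert pc.diff_coh > 0 and pc.diff_dwpli > 0
    assert 0 <= pc.burst.coh_band <= 1
    assert pc.burst.dwpli_band <= 1


def test_pair_coupling_none_mode_centered_near_zero(pair_factory):
    diffs_c, diffs_d = [], []
    for seed in range(8):
        stn, ctx, epochs, _ = pair_factory("none", 100 + seed)
        pc = bb.pair_coupling(stn, ctx, epochs, rng=np.random.default_rng(seed))
        diffs_c.append(pc.diff_coh)
        diffs_d.append(pc.diff_dwpli)
    assert abs(np.mean(diffs_c)) < 0.05
    assert abs(np.mean(diffs_d)) < 0.08


def test_pair_coupling_requires_bursts(none_pair):
    stn, ctx, epochs, _ = none_pair
    empty = bb.EpochSet(bursts=np.empty((0, 2), dtype=int), nonbursts=epochs.nonbursts,
                        thresholds=epochs.thresholds, source_label="STN_1")
    with pytest.raises(ValueError, match="no bursts"):
        bb.pair_coupling(stn, ctx, empty)


def test_choose_window_len_uses_shortest_usable():
    cfg = CouplingConfig()
    bursts = np.array([[0, 500], [600, 700]])
    nb = np.array([[800, 1200], [1300, 1330]])  # 30-sample run is unusable
    assert choose_window_len([bursts, nb], cfg) == 100
    with pytest.raises(ValueError, match="usable"):
        choose_window_len([np.array([[0, 10]])], cfg)


def test_cross_spectra_skips_short_segments(rng):
    segs = [(rng.standard_normal(200), rng.standard_normal(200)),
            (rng.standard_normal(30), rng.standard_normal(30))]
    pooled = cross_spectra(SegmentPairSet(segments=segs, fs=FS, condition="burst"), 64, 0.5)
    assert pooled.n_skipped == 1
    with pytest.raises(ValueError, match="no segment"):
        cross_spectra(SegmentPairSet(segments=segs[1:], fs=FS, condition="burst"), 64, 0.5)
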