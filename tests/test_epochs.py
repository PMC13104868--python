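"""Burst-adjacent triplets and peri-burst sliding-window traces."""

import numpy as np
import pytest

import betaburst as bb
from betaburst.epochs import (
    build_adjacent_triplets,
    adjacent_coupling,
    matched_nonburst_windows,
    peri_burst_trace,
)


def epoch_set(bursts, nonbursts, label="STN_1"):
    return bb.EpochSet(bursts=np.asarray(bursts), nonbursts=np.asarray(nonbursts),
                       thresholds=(1.0, 0.5), source_label=label)


def test_triplet_interval_arithmetic():
    es = epoch_set([[100, 150], [400, 450]],
                   [[0, 90], [160, 300], [460, 600]])
    t0, t1 = build_adjacent_triplets(es)
    assert t0.valid and t0.pre == (40, 90) and t0.post == (160, 210)
    assert t1.valid and t1.pre == (250, 300) and t1.post == (460, 510)


def test_triplet_skips_short_runs_and_searches_farther():
    # the run immediately before the second burst (40 samples) cannot hold
    # its 50-sample length, so the matcher reaches back to [160, 300)
    es = epoch_set([[100, 150], [400, 450]],
                   [[0, 90], [160, 300], [330, 370], [460, 600]])
    t0, t1 = build_adjacent_triplets(es)
    assert t1.valid and t1.pre == (250, 300) and t1.post == (460, 510)
    # no earlier run at all holds the first burst's length -> invalid side
    es2 = epoch_set([[100, 180], [400, 450]], [[50, 90], [460, 600]])
    u0, u1 = build_adjacent_triplets(es2)
    assert not u0.valid and u0.pre is None and u0.post == (460, 540)


def test_triplets_require_two_bursts():
    es = epoch_set([[100, 150]], [[0, 90]])
    with pytest.raises(ValueError, match=">= 2"):
        build_adjacent_triplets(es)


def test_triplet_invariants_on_synthetic_runs(pair_factory):
    for seed in (7, 8, 9):
        _, _, epochs, _ = pair_factory("burst_locked", seed)
        for t in build_adjacent_triplets(epochs):
            t.check()  # asserts matched lengths and ordering when valid


def test_adjacent_coupling_burst_exceeds_flanks(burst_locked_pair):
    stn, ctx, epochs, _ = burst_locked_pair
    roles = adjacent_coupling(stn, ctx, build_adjacent_triplets(epochs))
    for metric in ("coh_band", "dwpli_band"):
        b = getattr(roles["burst"], metric)
        assert b > getattr(roles["pre"], metric)
        assert b > getattr(roles["post"], metric)


def test_pre_post_symmetric_under_no_coupling(pair_factory):
    diffs = []
    for seed in range(10):
        stn, ctx, epochs, _ = pair_factory("none", 400 + seed)
        roles = adjacent_coupling(stn, ctx, build_adjacent_triplets(epochs))
        diffs.append(roles["pre"].coh_band - roles["post"].coh_band)
    diffs = np.array(diffs)
    se = diffs.std(ddof=1) / np.sqrt(diffs.size)
    assert abs(diffs.mean()) <= 2.5 * se + 1e-3


def test_matched_windows_respect_exclusion_zone():
    es = epoch_set([[1000, 1200]], [[0, 900]])
    rng = np.random.default_rng(0)
    starts = matched_nonburst_windows(es, n_windows=200, window_ms=15, fs=1000,
                                      n_samples=3000, exclusion_ms=50, rng=rng)
    # a 15-sample window must end by 950 (burst start - 50 ms) or start at
    # or after 1250 (burst end + 50 ms): eligible starts < 936 or >= 1250
    assert np.all((starts < 936) | (starts >= 1250))


def test_matched_windows_deterministic_and_error_when_full():
    es = epoch_set([[0, 2990]], [[2995, 3000]])
    with pytest.raises(ValueError, match="eligible"):
        matched_nonburst_windows(es, 5, 15, 1000, 3000, rng=np.random.default_rng(0))
    es2 = epoch_set([[1000, 1200]], [[0, 900]])
    s1 = matched_nonburst_windows(es2, 20, 15, 1000, 3000, rng=np.random.default_rng(3))
    s2 = matched_nonburst_windows(es2, 20, 15, 1000, 3000, rng=np.random.default_rng(3))
    np.testing.assert_array_equal(s1, s2)


def test_trace_has_twenty_one_offsets(burst_locked_pair):
    stn, ctx, epochs, _ = burst_locked_pair
    trace = peri_burst_trace(stn, ctx, epochs, rng=np.random.default_rng(0))
    assert trace.offsets_ms.size == 21
    np.testing.assert_allclose(np.diff(trace.offsets_ms), 5.0)
    assert trace.offsets_ms[0] == -50.0 and trace.offsets_ms[-1] == 50.0


def test_trace_rises_after_onset_for_burst_locked(burst_locked_pair):
    stn, ctx, epochs, _ = burst_locked_pair
    trace = peri_burst_trace(stn, ctx, epochs, rng=np.random.default_rng(1))
    inside = trace.offsets_ms >= 15.0   # window fully inside the burst
    assert trace.coh_trace[inside].mean() > trace.baseline_coh + 2 * trace.baseline_coh_sd
    assert trace.dwpli_trace[inside].mean() > trace.baseline_dwpli + 2 * trace.baseline_dwpli_sd
    # 50 ms before onset the window is fully outside the burst
    assert trace.coh_trace[0] < trace.coh_trace[inside].mean()


def test_trace_flat_for_uncoupled_pair(none_pair):
    stn, ctx, epochs, _ = none_pair
    trace = peri_burst_trace(stn, ctx, epochs, rng=np.random.default_rng(2))
    # the whole trace stays within the matched-baseline null band
    assert trace.coh_trace.mean() <= trace.baseline_coh + 2 * trace.baseline_coh_sd
    assert trace.dwpli_trace.mean() <= trace.baseline_dwpli + 2 * trace.baseline_dwpli_sd


def test_trace_requires_bursts_with_context():
    x = np.zeros(5000)
    stn = bb.BetaSignal(x=x, fs=1000.0, source_label="STN_1")
    ctx = bb.BetaSignal(x=x, fs=1000.0, source_label="ECOG_1")
    es = epoch_set([[10, 130]], [[1000, 4000]])  # onset too close to the start
    with pytest.raises(ValueError, match="context"):
        peri_burst_trace(stn, ctx, es, rng=np.random.default_rng(0))
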