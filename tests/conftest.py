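"""Shared fixtures: small synthetic STN/cortex pairs run through the
preprocessing and burst-detection stages.

Pairs are 30 s at 1000 Hz with no head discard (the generator starts
stationary, unlike an operating-room recording) so tests stay fast while
keeping 2 s filter-edge trims."""

import numpy as np
import pytest

import betaburst as bb


def make_pair(mode: str, seed: int, duration_s: float = 30.0, **kw):
    """Generate, preprocess and burst-detect one synthetic pair."""
    cfg = bb.SynthConfig(duration_s=duration_s, seed=seed, coupling_mode=mode, **kw)
    rec, truth = bb.generate_pair(cfg)
    beta = bb.preprocess_recording(rec, head_discard_s=0.0, edge_trim_s=2.0)
    stn, ctx = beta["STN_1"], beta["ECOG_1"]
    epochs = bb.detect_epochs(bb.compute_envelope(stn))
    return stn, ctx, epochs, truth


@pytest.fixture(scope="session")
def pair_factory():
    return make_pair


@pytest.fixture(scope="session")
def burst_locked_pair():
    return make_pair("burst_locked", 7)


@pytest.fixture(scope="session")
def none_pair():
    return make_pair("none", 7)


@pytest.fixture(scope="session")
def tonic_pair():
    return make_pair("tonic", 7)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
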