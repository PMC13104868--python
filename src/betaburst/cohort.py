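"""Cohort-level simulation experiments over synthetic pairs.

Runs many independently-seeded synthetic STN/cortex pairs through the full
analysis chain (preprocess -> burst detection -> coupling -> surrogates ->
burst-adjacent) and collects one row per pair.  This is how the package's
statistical properties — dissociation recovery, null calibration, tonic
contrast — are measured.

Cohort recordings default to 30 s with no head discard: the generator is
stationary from the first sample, so the 60 s settling discard applied to
operating-room recordings would only throw away data here.  Filter edge
trims (2 s) are kept.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bursts import compute_envelope, detect_epochs
from .coupling import (
    CouplingConfig,
    choose_window_len,
    pair_coupling,
    sample_nonburst_segments,
    select_band_indices,
)
from .epochs import adjacent_coupling, build_adjacent_triplets
from .preprocessing import preprocess_recording
from .surrogates import SurrogateConfig, substream, surrogate_null
from .synth import SynthConfig, generate_pair

METRICS = ("coh", "dwpli")


def pair_seeds(base_seed: int, n: int) -> np.ndarray:
    """n reproducible generator seeds derived from one base seed."""
    return np.random.SeedSequence(base_seed).generate_state(n) % (2**31)


def analyze_synthetic_pair(
    mode: str,
    seed: int,
    *,
    duration_s: float = 30.0,
    head_discard_s: float = 0.0,
    edge_trim_s: float = 2.0,
    conditions: tuple[str, ...] = (),
    adjacent: bool = False,
    surrogate_cfg: SurrogateConfig | None = None,
    coupling_cfg: CouplingConfig | None = None,
    synth_overrides: dict | None = None,
    pair_id: str | None = None,
) -> dict:
    """One synthetic pair through the full chain; returns a flat result row.

    ``conditions`` lists the epoch conditions ("burst", "nonburst") for
    which surrogate p-values are wanted; both metrics are always computed.
    """
    surrogate_cfg = surrogate_cfg or SurrogateConfig()
    coupling_cfg = coupling_cfg or CouplingConfig()
    pair_id = pair_id or f"{mode}-{seed}"

    cfg = SynthConfig(duration_s=duration_s, seed=int(seed),
                      coupling_mode=mode, **(synth_overrides or {}))
    rec, truth = generate_pair(cfg)
    beta = preprocess_recording(rec, head_discard_s=head_discard_s,
                                edge_trim_s=edge_trim_s)
    stn, ctx = beta["STN_1"], beta["ECOG_1"]
    epochs = detect_epochs(compute_envelope(stn))
    row: dict = {"pair_id": pair_id, "mode": mode, "seed": int(seed),
                 "n_bursts": epochs.n_bursts, "n_nonbursts": epochs.n_nonbursts}
    if epochs.n_bursts == 0 or epochs.n_nonbursts == 0:
        row["analyzable"] = False
        return row
    row["analyzable"] = True

    rng = substream(surrogate_cfg.seed, pair_id, "nonburst", "sample")
    nb = sample_nonburst_segments(epochs.nonbursts, cap=coupling_cfg.nonburst_cap, rng=rng)
    sub = type(epochs)(bursts=epochs.bursts, nonbursts=nb,
                       thresholds=epochs.thresholds, source_label=epochs.source_label)
    pc = pair_coupling(stn, ctx, sub, coupling_cfg)
    row.update(
        coh_burst=pc.burst.coh_band, coh_nonburst=pc.nonburst.coh_band,
        coh_diff=pc.diff_coh,
        dwpli_burst=pc.burst.dwpli_band, dwpli_nonburst=pc.nonburst.dwpli_band,
        dwpli_diff=pc.diff_dwpli,
    )

    if conditions:
        window_len = choose_window_len([epochs.bursts, nb], coupling_cfg)
        band_idx = select_band_indices(window_len, stn.fs, coupling_cfg.band)
        for condition in conditions:
            for metric in METRICS:
                null = surrogate_null(
                    stn, ctx, epochs, condition, metric,
                    cfg=surrogate_cfg, coupling_cfg=coupling_cfg, pair_id=pair_id,
                    nonburst_intervals=nb, window_len=window_len, band_idx=band_idx,
                )
                row[f"p_{metric}_{condition}"] = null.p_emp
                row[f"null_mean_{metric}_{condition}"] = float(null.null_values.mean())

    if adjacent and epochs.n_bursts >= 2:
        triplets = build_adjacent_triplets(epochs)
        n_valid = sum(t.valid for t in triplets)
        row["n_valid_triplets"] = n_valid
        if n_valid >= 2:
            roles = adjacent_coupling(stn, ctx, triplets, coupling_cfg)
            for role in ("burst", "pre", "post"):
                row[f"adj_coh_{role}"] = roles[role].coh_band
                row[f"adj_dwpli_{role}"] = roles[role].dwpli_band
    return row


def run_cohort(mode: str, n_pairs: int, base_seed: int, **kwargs) -> pd.DataFrame:
    """Independently seeded pairs of one coupling mode, one row each."""
    seeds = pair_seeds(base_seed, n_pairs)
    rows = [
        analyze_synthetic_pair(mode, s, pair_id=f"{mode}-{i}", **kwargs)
        for i, s in enumerate(seeds)
    ]
    return pd.DataFrame(rows)
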