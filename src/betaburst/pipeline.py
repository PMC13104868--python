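"""End-to-end orchestration: config, run directory, stage sequencing.

``run_pipeline`` executes preprocessing -> burst detection -> burst vs
non-burst coupling -> surrogate testing -> burst-adjacent and peri-burst
analyses -> statistics, writing every stage product (TSV tables, config
snapshot, log) into a run directory.  Runs are deterministic under a fixed
seed: every random choice (non-burst subsampling, surrogate shifts,
baseline windows) draws from a substream keyed on the seed and the
identifiers of the consuming test.
"""

from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import stats as stats_mod
from .bursts import compute_envelope, detect_epochs, exclude_sparse_pairs
from .coupling import CouplingConfig, pair_coupling, sample_nonburst_segments, \
    choose_window_len, select_band_indices
from .epochs import build_adjacent_triplets, adjacent_coupling, peri_burst_trace
from .io import read_recording, write_epochs_tsv, write_table
from .preprocessing import preprocess_recording
from .recording import Recording, ROLE_STN, ROLE_CORTICAL
from .surrogates import SurrogateConfig, surrogate_null, substream
from .synth import SynthConfig, generate_pair

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

#: files every completed run directory must contain
MANIFEST = (
    "config.yaml",
    "log.txt",
    "epochs.tsv",
    "epoch_counts.tsv",
    "pair_coupling.tsv",
    "adjacent_coupling.tsv",
    "peri_burst_traces.tsv",
    "report.md",
)


@dataclass
class RunConfig:
    """Validated pipeline configuration (YAML-serializable)."""

    out_dir: str = "run"
    input_path: str | None = None
    input_format: str | None = None
    synth: dict | None = None            # SynthConfig fields, alternative to input_path
    band: tuple[float, float] = (13.0, 30.0)
    filter_order: int = 4
    head_discard_s: float = 60.0
    edge_trim_s: float = 2.0
    smooth_ms: float = 50.0
    burst_pct: float = 75.0
    nonburst_pct: float = 50.0
    min_dur_ms: float = 100.0
    welch: dict = field(default_factory=dict)       # CouplingConfig overrides
    surrogate: dict = field(default_factory=dict)   # SurrogateConfig overrides
    peri: dict = field(default_factory=dict)        # peri_burst_trace overrides
    run_peri: bool = True
    alpha: float = 0.05
    schema_version: int = SCHEMA_VERSION

    def __post_init__(self) -> None:
        if self.schema_version != SCHEMA_VERSION:
            raise ValueError(f"unsupported config schema version {self.schema_version}")
        if (self.input_path is None) == (self.synth is None):
            raise ValueError("config needs exactly one of input_path or synth")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        for block, allowed in (
            ("welch", {"band", "max_window", "min_window", "overlap_frac", "nonburst_cap"}),
            ("surrogate", {"n_surrogates", "shift_range_s", "seed", "alpha"}),
            ("peri", {"window_ms", "step_ms", "span_ms", "nfft", "exclusion_ms",
                      "n_baseline_draws"}),
        ):
            unknown = set(getattr(self, block)) - allowed
            if unknown:
                raise ValueError(f"unknown keys in {block!r} block: {sorted(unknown)}")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = set(cls.__dataclass_fields__)
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "band" in data:
            data["band"] = tuple(data["band"])
        return cls(**data)

    def to_yaml(self, path) -> None:
        data = asdict(self)
        data["band"] = list(self.band)
        Path(path).write_text(yaml.safe_dump(data, sort_keys=True))

    def coupling_config(self) -> CouplingConfig:
        kw = dict(self.welch)
        kw.setdefault("band", self.band)
        if isinstance(kw["band"], list):
            kw["band"] = tuple(kw["band"])
        return CouplingConfig(**kw)

    def surrogate_config(self) -> SurrogateConfig:
        kw = dict(self.surrogate)
        if "shift_range_s" in kw:
            kw["shift_range_s"] = tuple(kw["shift_range_s"])
        kw.setdefault("alpha", self.alpha)
        return SurrogateConfig(**kw)


def _load_recording(cfg: RunConfig) -> Recording:
    if cfg.input_path is not None:
        return read_recording(cfg.input_path, cfg.input_format)
    rec, _ = generate_pair(SynthConfig(**cfg.synth))
    return rec


def analyze_pair(
    stn_beta,
    ctx_beta,
    epochs,
    coupling_cfg: CouplingConfig,
    surrogate_cfg: SurrogateConfig,
) -> dict:
    """Coupling + surrogate row for one STN-cortical contact pair.

    The non-burst subsample is drawn once (substream keyed on the pair)
    and shared between the observed estimate and every surrogate, as are
    the Welch window and band indices.
    """
    pair_id = f"{stn_beta.source_label}|{ctx_beta.source_label}"
    rng = substream(surrogate_cfg.seed, pair_id, "nonburst", "sample")
    nb = sample_nonburst_segments(epochs.nonbursts, cap=coupling_cfg.nonburst_cap, rng=rng)
    sub_epochs = type(epochs)(
        bursts=epochs.bursts, nonbursts=nb, thresholds=epochs.thresholds,
        source_label=epochs.source_label,
    )
    pc = pair_coupling(stn_beta, ctx_beta, sub_epochs, coupling_cfg)
    window_len = choose_window_len([epochs.bursts, nb], coupling_cfg)
    band_idx = select_band_indices(window_len, stn_beta.fs, coupling_cfg.band)

    row = {
        "stn_label": stn_beta.source_label,
        "ctx_label": ctx_beta.source_label,
        "n_bursts": epochs.n_bursts,
        "n_nonburst_sampled": len(nb),
        "coh_burst": pc.burst.coh_band,
        "coh_nonburst": pc.nonburst.coh_band,
        "coh_diff": pc.diff_coh,
        "dwpli_burst": pc.burst.dwpli_band,
        "dwpli_nonburst": pc.nonburst.dwpli_band,
        "dwpli_diff": pc.diff_dwpli,
    }
    for metric in ("coh", "dwpli"):
        for condition in ("burst", "nonburst"):
            null = surrogate_null(
                stn_beta, ctx_beta, epochs, condition, metric,
                cfg=surrogate_cfg, coupling_cfg=coupling_cfg, pair_id=pair_id,
                nonburst_intervals=nb, window_len=window_len, band_idx=band_idx,
            )
            row[f"p_{metric}_{condition}"] = null.p_emp
            row[f"null_mean_{metric}_{condition}"] = float(null.null_values.mean())
            # consistency: the surrogate path's shift-0 value is the observed one
            observed_key = f"{metric}_{condition}"
            if not np.isclose(null.observed, row[observed_key], atol=1e-9):
                logger.warning("observed mismatch for %s %s: %.3g vs %.3g",
                               pair_id, observed_key, null.observed, row[observed_key])
    return row


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute the full analysis and return the run directory path."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "log.txt", mode="w")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    root = logging.getLogger("betaburst")
    root.addHandler(handler)
    root.setLevel(logging.INFO)
    cfg.to_yaml(out / "config.yaml")
    coupling_cfg = cfg.coupling_config()
    surrogate_cfg = cfg.surrogate_config()

    try:
        t0 = time.perf_counter()
        stage = "input"
        rec = _load_recording(cfg)
        logger.info("loaded recording: %d samples x %d channels at %g Hz",
                    rec.n_samples, rec.n_channels, rec.fs)

        stage = "preprocessing"
        beta = preprocess_recording(
            rec, band=cfg.band, order=cfg.filter_order,
            head_discard_s=cfg.head_discard_s, edge_trim_s=cfg.edge_trim_s,
        )
        logger.info("preprocessing done in %.2f s", time.perf_counter() - t0)

        stage = "burst detection"
        stn_labels = rec.channels_with_role(ROLE_STN)
        ctx_labels = rec.channels_with_role(ROLE_CORTICAL)
        epoch_sets = {}
        for lab in stn_labels:
            env = compute_envelope(beta[lab], smooth_ms=cfg.smooth_ms)
            epoch_sets[lab] = detect_epochs(
                env, burst_pct=cfg.burst_pct, nonburst_pct=cfg.nonburst_pct,
                min_dur_ms=cfg.min_dur_ms,
            )
        exclude_sparse_pairs(epoch_sets)
        write_epochs_tsv(epoch_sets, out / "epochs.tsv")
        counts = pd.DataFrame(
            [
                {
                    "stn_label": lab,
                    "n_bursts": es.n_bursts,
                    "n_nonbursts": es.n_nonbursts,
                    "burst_thr": es.thresholds[0],
                    "nonburst_thr": es.thresholds[1],
                    "excluded_adjacent": es.excluded_adjacent,
                }
                for lab, es in sorted(epoch_sets.items())
            ]
        )
        write_table(counts, out / "epoch_counts.tsv")
        for lab, es in epoch_sets.items():
            if es.n_bursts == 0:
                logger.warning("excluding %s from all burst analyses: no bursts", lab)
            elif es.excluded_adjacent:
                logger.warning("excluding %s from burst-adjacent analyses: "
                               "fewer than 2 bursts", lab)

        stage = "coupling + surrogates"
        rows = []
        for stn_lab in stn_labels:
            es = epoch_sets[stn_lab]
            if es.n_bursts == 0 or es.n_nonbursts == 0:
                continue
            for ctx_lab in ctx_labels:
                rows.append(
                    analyze_pair(beta[stn_lab], beta[ctx_lab], es,
                                 coupling_cfg, surrogate_cfg)
                )
        if not rows:
            raise ValueError("no analyzable STN-cortical pairs")
        pair_table = pd.DataFrame(rows)
        write_table(pair_table, out / "pair_coupling.tsv")
        logger.info("coupling stage done at %.2f s", time.perf_counter() - t0)

        stage = "burst-adjacent analysis"
        adj_rows = []
        for stn_lab in stn_labels:
            es = epoch_sets[stn_lab]
            if es.excluded_adjacent:
                continue
            triplets = build_adjacent_triplets(es)
            n_valid = sum(t.valid for t in triplets)
            logger.info("%s: %d/%d valid burst-adjacent triplets",
                        stn_lab, n_valid, len(triplets))
            if n_valid < 2:
                continue
            for ctx_lab in ctx_labels:
                roles = adjacent_coupling(beta[stn_lab], beta[ctx_lab],
                                          triplets, coupling_cfg)
                adj_rows.append(
                    {
                        "stn_label": stn_lab,
                        "ctx_label": ctx_lab,
                        "n_valid_triplets": n_valid,
                        "n_triplets": len(triplets),
                        **{f"coh_{r}": roles[r].coh_band for r in ("burst", "pre", "post")},
                        **{f"dwpli_{r}": roles[r].dwpli_band for r in ("burst", "pre", "post")},
                    }
                )
        write_table(pd.DataFrame(adj_rows), out / "adjacent_coupling.tsv")

        stage = "peri-burst analysis"
        trace_rows = []
        if cfg.run_peri:
            for stn_lab in stn_labels:
                es = epoch_sets[stn_lab]
                if es.n_bursts < 2:
                    continue
                for ctx_lab in ctx_labels:
                    rng = substream(surrogate_cfg.seed, f"{stn_lab}|{ctx_lab}",
                                    "peri", "baseline")
                    trace = peri_burst_trace(
                        beta[stn_lab], beta[ctx_lab], es,
                        band=cfg.band, rng=rng, **cfg.peri,
                    )
                    for i, off in enumerate(trace.offsets_ms):
                        trace_rows.append(
                            {
                                "stn_label": stn_lab,
                                "ctx_label": ctx_lab,
                                "offset_ms": off,
                                "coh": trace.coh_trace[i],
                                "dwpli": trace.dwpli_trace[i],
                                "baseline_coh": trace.baseline_coh,
                                "baseline_coh_sd": trace.baseline_coh_sd,
                                "baseline_dwpli": trace.baseline_dwpli,
                                "baseline_dwpli_sd": trace.baseline_dwpli_sd,
                                "n_bursts_used": trace.n_bursts_used,
                            }
                        )
        write_table(pd.DataFrame(trace_rows), out / "peri_burst_traces.tsv")

        stage = "report"
        stats_mod.report(out)
        logger.info("pipeline finished in %.2f s", time.perf_counter() - t0)
    except Exception as exc:
        logger.exception("pipeline aborted during stage: %s", stage)
        raise RuntimeError(f"pipeline failed during stage: {stage}: {exc}") from exc
    finally:
        root.removeHandler(handler)
        handler.close()
    return out


def validate_run(run_dir) -> list[str]:
    """Check a run directory against the expected manifest.

    Returns the list of missing files (empty when the run is complete).
    """
    run_dir = Path(run_dir)
    return [name for name in MANIFEST if not (run_dir / name).exists()]
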