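"""Readers and writers for recordings, epochs and pair tables.

Two on-disk recording formats are supported:

* **TSV matrix** — one column per channel with a header row of labels,
  plus a YAML sidecar (``<stem>.yaml``) carrying ``fs`` and channel roles.
  Lossless (full float precision).
* **EDF** — standard 16-bit European Data Format (see
  :mod:`betaburst.edf`), quantized to the stored physical range.

When the sampling rate is missing from metadata it defaults to 1000 Hz
with a logged warning.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .recording import Recording, ROLE_STN, ROLE_CORTICAL

logger = logging.getLogger(__name__)

DEFAULT_FS = 1000.0


def infer_roles(labels: list[str]) -> dict[str, str]:
    """Channel roles from conventional label prefixes (STN_* / ECOG_*)."""
    roles = {}
    for lab in labels:
        up = lab.upper()
        if up.startswith("STN"):
            roles[lab] = ROLE_STN
        elif up.startswith(("ECOG", "CTX", "CORT")):
            roles[lab] = ROLE_CORTICAL
        else:
            raise ValueError(
                f"cannot infer role of channel {lab!r}; provide a sidecar with roles"
            )
    return roles


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(".yaml")


def write_recording_tsv(recording: Recording, path) -> None:
    """Lossless TSV matrix + YAML sidecar ({fs, roles})."""
    path = Path(path)
    header = "\t".join(recording.labels)
    np.savetxt(path, recording.samples, fmt="%.17g", delimiter="\t",
               header=header, comments="")
    sidecar = {"fs": float(recording.fs), "roles": dict(recording.roles)}
    _sidecar_path(path).write_text(yaml.safe_dump(sidecar, sort_keys=True))


def read_recording_tsv(path) -> Recording:
    path = Path(path)
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    labels = list(df.columns)
    sidecar = _sidecar_path(path)
    fs = None
    roles = None
    if sidecar.exists():
        meta = yaml.safe_load(sidecar.read_text()) or {}
        fs = meta.get("fs")
        roles = meta.get("roles")
    if fs is None:
        logger.warning("no sampling rate in sidecar for %s; defaulting to %g Hz",
                       path, DEFAULT_FS)
        fs = DEFAULT_FS
    if roles is None:
        roles = infer_roles(labels)
    else:
        missing = set(labels) - set(roles)
        if missing:
            raise ValueError(f"sidecar roles missing channels: {sorted(missing)}")
    return Recording(samples=df.to_numpy(dtype=float), fs=float(fs),
                     labels=labels, roles=roles)


def read_recording(path, format: str | None = None) -> Recording:
    """Read a recording, auto-detecting the format from the extension."""
    path = Path(path)
    if format is None:
        format = "edf" if path.suffix.lower() == ".edf" else "tsv"
    if format == "tsv":
        return read_recording_tsv(path)
    if format == "edf":
        from .edf import read_edf

        return read_edf(path)
    raise ValueError(f"unsupported recording format {format!r}")


def write_epochs_tsv(epoch_sets: dict, path) -> None:
    """BED-like epoch table: source_label, start, end, label.

    Thresholds are recorded in ``#`` header comment lines.
    """
    path = Path(path)
    lines = []
    for lab in sorted(epoch_sets):
        es = epoch_sets[lab]
        lines.append(
            f"# {lab}\tburst_thr={es.thresholds[0]:.10g}"
            f"\tnonburst_thr={es.thresholds[1]:.10g}"
            f"\texcluded_adjacent={int(es.excluded_adjacent)}"
        )
    rows = ["source_label\tstart_sample\tend_sample\tlabel"]
    for lab in sorted(epoch_sets):
        es = epoch_sets[lab]
        for s, e in es.bursts:
            rows.append(f"{lab}\t{s}\t{e}\tburst")
        for s, e in es.nonbursts:
            rows.append(f"{lab}\t{s}\t{e}\tnonburst")
    path.write_text("\n".join(lines + rows) + "\n")


def read_epochs_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
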