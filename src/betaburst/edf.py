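"""Minimal EDF (European Data Format) writer and reader.

Implements the plain-EDF subset this package needs for fixtures and data
exchange: a fixed ASCII header, one or more equal-rate signals, 16-bit
little-endian samples, 1-second data records.  Samples round-trip to
within one quantization step of each channel's stored physical range.
The writer is cross-checked against an independent EDF reader in the test
suite.
"""

from __future__ import annotations

import math
import warnings
from pathlib import Path

import numpy as np

from .recording import Recording
from .io import infer_roles

DIGITAL_MIN = -32768
DIGITAL_MAX = 32767


def _ascii_field(value, width: int) -> bytes:
    s = str(value)
    if len(s) > width:
        raise ValueError(f"field {s!r} exceeds {width} ASCII characters")
    return s.ljust(width).encode("ascii")


def _format_physical(v: float, width: int = 8) -> str:
    """Shortest decimal representation of v that fits the 8-char field."""
    for prec in range(7, 0, -1):
        s = f"{v:.{prec}g}"
        if len(s) <= width:
            return s
    raise ValueError(f"cannot format {v!r} in {width} characters")


def write_edf(recording: Recording, path) -> None:
    """Write a recording as plain EDF with 1-second data records.

    The sampling rate must be a positive integer (samples per record).  If
    the signal length is not a whole number of records the final record is
    padded by repeating the last sample; a warning reports the padding.
    """
    if recording.n_samples == 0:
        raise ValueError("cannot write an empty recording")
    fs = recording.fs
    if fs != int(fs) or fs <= 0:
        raise ValueError(f"EDF writer requires an integer sampling rate, got {fs}")
    spr = int(fs)  # samples per 1 s record
    n = recording.n_samples
    n_records = math.ceil(n / spr)
    pad = n_records * spr - n
    if pad:
        warnings.warn(
            f"padding final EDF record with {pad} repeated samples", UserWarning
        )

    data = recording.samples
    n_ch = recording.n_channels
    pmins = data.min(axis=0)
    pmaxs = data.max(axis=0)
    # avoid a zero physical range on constant channels
    flat = pmaxs - pmins <= 0
    pmaxs = np.where(flat, pmins + 1.0, pmaxs)
    # re-parse the formatted values so the scaling used for encoding matches
    # what a reader will recover from the header text
    pmin_txt = [_format_physical(v) for v in pmins]
    pmax_txt = [_format_physical(v) for v in pmaxs]
    pmins = np.array([float(s) for s in pmin_txt])
    pmaxs = np.array([float(s) for s in pmax_txt])

    scale = (DIGITAL_MAX - DIGITAL_MIN) / (pmaxs - pmins)
    digital = np.round((data - pmins) * scale + DIGITAL_MIN)
    digital = np.clip(digital, DIGITAL_MIN, DIGITAL_MAX).astype("<i2")
    if pad:
        digital = np.vstack([digital, np.tile(digital[-1], (pad, 1))])

    header = b"".join(
        [
            _ascii_field("0", 8),                      # version
            _ascii_field("X X X X", 80),               # patient id
            _ascii_field("Startdate X X X X", 80),     # recording id
            _ascii_field("01.01.00", 8),               # fixed date: deterministic files
            _ascii_field("00.00.00", 8),
            _ascii_field(256 * (n_ch + 1), 8),         # header bytes
            _ascii_field("", 44),
            _ascii_field(n_records, 8),
            _ascii_field(1, 8),                        # record duration, s
            _ascii_field(n_ch, 4),
        ]
    )
    per_signal = [
        (16, recording.labels),
        (80, [""] * n_ch),                             # transducer
        (8, ["uV"] * n_ch),
        (8, pmin_txt),
        (8, pmax_txt),
        (8, [DIGITAL_MIN] * n_ch),
        (8, [DIGITAL_MAX] * n_ch),
        (80, [""] * n_ch),                             # prefiltering
        (8, [spr] * n_ch),
        (32, [""] * n_ch),
    ]
    for width, values in per_signal:
        header += b"".join(_ascii_field(v, width) for v in values)

    with open(path, "wb") as fh:
        fh.write(header)
        # records: all samples of signal 0, then signal 1, ... per record
        for r in range(n_records):
            block = digital[r * spr:(r + 1) * spr]
            fh.write(block.T.tobytes())


def read_edf(path) -> Recording:
    """Read a plain EDF file written by :func:`write_edf` (or compatible)."""
    raw = Path(path).read_bytes()
    if len(raw) < 256:
        raise ValueError("file too short to be EDF")

    def field(offset: int, width: int) -> str:
        return raw[offset:offset + width].decode("ascii", errors="replace").strip()

    n_records = int(field(236, 8))
    record_dur = float(field(244, 8))
    n_ch = int(field(252, 4))
    header_bytes = 256 * (n_ch + 1)
    if len(raw) < header_bytes:
        raise ValueError("truncated EDF header")

    def signal_fields(base: int, width: int, cast):
        off = 256 + base * n_ch
        return [cast(field(off + i * width, width)) for i in range(n_ch)]

    labels = signal_fields(0, 16, str)
    pmins = np.array(signal_fields(104, 8, float))
    pmaxs = np.array(signal_fields(112, 8, float))
    dmins = np.array(signal_fields(120, 8, float))
    dmaxs = np.array(signal_fields(128, 8, float))
    sprs = signal_fields(216, 8, int)
    if len(set(sprs)) != 1:
        raise ValueError("mixed per-signal sampling rates are not supported")
    spr = sprs[0]
    fs = spr / record_dur

    body = np.frombuffer(raw, dtype="<i2", offset=header_bytes)
    expected = n_records * spr * n_ch
    if body.size < expected:
        raise ValueError("truncated EDF data section")
    body = body[:expected].reshape(n_records, n_ch, spr)
    digital = body.transpose(0, 2, 1).reshape(n_records * spr, n_ch).astype(float)
    scale = (pmaxs - pmins) / (dmaxs - dmins)
    physical = (digital - dmins) * scale + pmins
    return Recording(
        samples=physical, fs=fs, labels=labels, roles=infer_roles(labels)
    )
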