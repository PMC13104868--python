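"""Core containers for multichannel intracranial recordings.

A :class:`Recording` holds a sample-by-channel matrix together with the
sampling rate, channel labels and channel roles (subthalamic depth contacts
vs cortical strip contacts).  A :class:`BetaSignal` is a single channel
after band-pass filtering to the beta range, carrying its provenance.

Sample intervals throughout the package are 0-based half-open
``[start, end)`` pairs in integer sample coordinates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Channel roles recognized by the pipeline.
ROLE_STN = "stn"
ROLE_CORTICAL = "cortical"
VALID_ROLES = (ROLE_STN, ROLE_CORTICAL)


@dataclass
class Recording:
    """Multichannel time series in physical units (microvolts).

    Parameters
    ----------
    samples : ndarray, shape (n_samples, n_channels)
        Signal matrix, one column per channel.
    fs : float
        Sampling rate in Hz.
    labels : list of str
        Unique channel names, e.g. ``"STN_1"``, ``"ECOG_9"``.
    roles : dict
        Mapping from label to ``"stn"`` or ``"cortical"``.
    """

    samples: np.ndarray
    fs: float
    labels: list[str]
    roles: dict[str, str]

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (n_samples, n_channels) matrix")
        if self.samples.shape[0] == 0:
            raise ValueError("recording has no samples")
        if self.fs <= 0 or not np.isfinite(self.fs):
            raise ValueError(f"invalid sampling rate {self.fs!r}")
        if len(self.labels) != self.samples.shape[1]:
            raise ValueError("number of labels does not match number of channels")
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("channel labels must be unique")
        for lab in self.labels:
            role = self.roles.get(lab)
            if role not in VALID_ROLES:
                raise ValueError(f"channel {lab!r} has invalid role {role!r}")

    @property
    def n_samples(self) -> int:
        return self.samples.shape[0]

    @property
    def n_channels(self) -> int:
        return self.samples.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def channel(self, label: str) -> np.ndarray:
        """Return one channel as a 1-D array."""
        try:
            idx = self.labels.index(label)
        except ValueError:
            raise KeyError(f"no channel named {label!r}") from None
        return self.samples[:, idx]

    def channels_with_role(self, role: str) -> list[str]:
        if role not in VALID_ROLES:
            raise ValueError(f"invalid role {role!r}")
        return [lab for lab in self.labels if self.roles[lab] == role]


@dataclass
class BetaSignal:
    """A single channel band-passed to the beta range.

    ``band`` records the pass band in Hz ((13, 30) by default across the
    pipeline); ``source_label`` names the originating channel.
    """

    x: np.ndarray
    fs: float
    band: tuple[float, float] = (13.0, 30.0)
    source_label: str = ""

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        if self.x.ndim != 1:
            raise ValueError("BetaSignal.x must be 1-D")
        if not np.all(np.isfinite(self.x)):
            raise ValueError("BetaSignal contains non-finite values")

    def __len__(self) -> int:
        return self.x.size


def check_intervals(intervals: np.ndarray, n_samples: int | None = None) -> np.ndarray:
    """Validate a list of half-open sample intervals.

    Intervals must be sorted, non-overlapping, non-empty and, when
    ``n_samples`` is given, contained in ``[0, n_samples)``.  Returns the
    intervals as an ``(n, 2)`` integer array (possibly empty).
    """
    arr = np.asarray(intervals, dtype=np.int64).reshape(-1, 2)
    if arr.size == 0:
        return arr
    if np.any(arr[:, 1] <= arr[:, 0]):
        raise ValueError("empty or inverted interval")
    if np.any(arr[:, 0] < 0):
        raise ValueError("negative interval start")
    if n_samples is not None and np.any(arr[:, 1] > n_samples):
        raise ValueError("interval extends past end of signal")
    if np.any(arr[1:, 0] < arr[:-1, 1]):
        raise ValueError("intervals overlap or are unsorted")
    return arr


def intervals_to_mask(intervals: np.ndarray, n_samples: int) -> np.ndarray:
    """Boolean membership mask of length ``n_samples`` for a set of intervals."""
    mask = np.zeros(n_samples, dtype=bool)
    for s, e in np.asarray(intervals, dtype=np.int64).reshape(-1, 2):
        mask[max(0, s):min(n_samples, e)] = True
    return mask
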