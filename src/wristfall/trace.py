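"""Labeled tri-axial accelerometer traces.

The :class:`AccelTrace` is the universal currency of the toolkit: a
timestamped stream of (ax, ay, az) samples in units of G with a per-sample
binary fall label and an optional activity-of-daily-living (ADL) tag.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

#: Closed two-value label vocabulary used in the CSV dialect.
FALL = "Fall"
NOTFALL = "NotFall"

_VALID_SOURCES = ("smartwatch", "notch", "farseeing", "synthetic")


def labels_to_bool(labels) -> np.ndarray:
    """Convert an array of ``Fall``/``NotFall`` strings (or bools) to bool.

    Raises
    ------
    ValueError
        If any label is outside the closed two-value vocabulary.
    """
    arr = np.asarray(labels)
    if arr.dtype == bool:
        return arr.copy()
    out = np.zeros(arr.shape, dtype=bool)
    for i, lab in enumerate(arr.ravel()):
        if lab == FALL:
            out.ravel()[i] = True
        elif lab == NOTFALL:
            out.ravel()[i] = False
        else:
            raise ValueError(
                f"unknown label {lab!r}: expected {FALL!r} or {NOTFALL!r}"
            )
    return out


def bool_to_labels(fall: np.ndarray) -> np.ndarray:
    """Inverse of :func:`labels_to_bool`."""
    return np.where(np.asarray(fall, dtype=bool), FALL, NOTFALL)


@dataclass
class AccelTrace:
    """A labeled tri-axial acceleration stream at a nominal sampling rate.

    Parameters
    ----------
    t : ndarray of shape (n,)
        Timestamps in seconds, strictly increasing.
    acc : ndarray of shape (n, 3)
        Acceleration components (ax, ay, az) in G.
    fall : ndarray of shape (n,), bool
        Per-sample fall label (True = ``Fall``).
    rate_hz : float
        Nominal sampling rate in Hz.
    activity : ndarray of shape (n,), optional
        Free-text ADL tag per sample; empty string means untagged.
    subject_id : str
        Opaque identifier of the recording.
    source : str
        One of ``smartwatch``, ``notch``, ``farseeing``, ``synthetic``.
    """

    t: np.ndarray
    acc: np.ndarray
    fall: np.ndarray
    rate_hz: float
    activity: np.ndarray | None = None
    subject_id: str = ""
    source: str = "synthetic"

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.acc = np.asarray(self.acc, dtype=float)
        self.fall = np.asarray(self.fall, dtype=bool)
        if self.acc.ndim != 2 or self.acc.shape[1] != 3:
            raise ValueError("acc must have shape (n, 3)")
        n = len(self.t)
        if self.acc.shape[0] != n or self.fall.shape[0] != n:
            raise ValueError("t, acc and fall must have equal length")
        if not np.all(np.isfinite(self.acc)) or not np.all(np.isfinite(self.t)):
            raise ValueError("timestamps and components must be finite")
        if n > 1 and not np.all(np.diff(self.t) > 0):
            raise ValueError("timestamps must be strictly increasing")
        if not self.rate_hz > 0:
            raise ValueError("rate_hz must be positive")
        if self.source not in _VALID_SOURCES:
            raise ValueError(f"unknown source {self.source!r}")
        if self.activity is not None:
            self.activity = np.asarray(self.activity, dtype=object)
            if self.activity.shape[0] != n:
                raise ValueError("activity must have one tag per sample")

    def __len__(self) -> int:
        return len(self.t)

    @property
    def n_samples(self) -> int:
        return len(self.t)

    @property
    def duration_s(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self.t) > 1 else 0.0

    @property
    def labels(self) -> np.ndarray:
        """Per-sample labels as ``Fall``/``NotFall`` strings."""
        return bool_to_labels(self.fall)

    def has_activity_tags(self) -> bool:
        return self.activity is not None and any(
            a != "" for a in self.activity
        )

    def copy(self) -> "AccelTrace":
        return replace(
            self,
            t=self.t.copy(),
            acc=self.acc.copy(),
            fall=self.fall.copy(),
            activity=None if self.activity is None else self.activity.copy(),
        )

    def __eq__(self, other) -> bool:
        if not isinstance(other, AccelTrace):
            return NotImplemented
        same_act = (
            (self.activity is None and other.activity is None)
            or (
                self.activity is not None
                and other.activity is not None
                and np.array_equal(self.activity, other.activity)
            )
        )
        return (
            np.array_equal(self.t, other.t)
            and np.array_equal(self.acc, other.acc)
            and np.array_equal(self.fall, other.fall)
            and self.rate_hz == other.rate_hz
            and same_act
        )


def concat_traces(segments, rate_hz: float, subject_id: str = "",
                  source: str = "synthetic") -> AccelTrace:
    """Concatenate trace segments onto one uniform time grid at ``rate_hz``.

    Segment timestamps are discarded; the output grid starts at 0 with
    spacing ``1/rate_hz``.
    """
    segments = list(segments)
    if not segments:
        raise ValueError("no segments to concatenate")
    acc = np.vstack([s.acc for s in segments])
    fall = np.concatenate([s.fall for s in segments])
    acts = []
    for s in segments:
        if s.activity is None:
            acts.append(np.full(len(s), "", dtype=object))
        else:
            acts.append(s.activity)
    activity = np.concatenate(acts)
    n = len(fall)
    t = np.arange(n) / rate_hz
    return AccelTrace(t=t, acc=acc, fall=fall, rate_hz=rate_hz,
                      activity=activity, subject_id=subject_id, source=source)
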