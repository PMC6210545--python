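"""Handcrafted sliding-window features for the traditional classifiers.

Four features describe each sample:

* ``a_res`` — resultant acceleration, the Euclidean norm of (ax, ay, az);
* ``s_min`` / ``s_max`` — minimum / maximum resultant acceleration within a
  750 ms sliding window;
* ``delta_s`` — the swing ``s_max - s_min`` within that window.

Windows tile the stream with 50% overlap by default (750 ms at 31.25 Hz is
23 samples with an 11-sample hop).  Window statistics are assigned
*causally*: sample ``i`` carries the statistics of the most recent window
that has fully completed at or before ``i``, so a one-sample-at-a-time
streaming evaluation reproduces the batch result exactly.  Samples before
the first complete window (the warm-up prefix) get no feature row.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, TransformerMixin

from .trace import AccelTrace

FEATURE_NAMES = ("a_res", "s_min", "s_max", "delta_s")


@dataclass(frozen=True)
class FeatureConfig:
    """Sliding-window geometry for feature extraction.

    window_ms
        Window length in milliseconds (750 gave the best accuracy in the
        500–1000 ms range explored for this feature set).
    overlap_frac
        Fractional window overlap in [0, 1); 0.5 means consecutive windows
        share half their samples.
    rate_hz
        Sampling rate the window is converted against.
    """

    window_ms: float = 750.0
    overlap_frac: float = 0.5
    rate_hz: float = 31.25

    def __post_init__(self):
        if not self.window_ms > 0:
            raise ValueError("window_ms must be positive")
        if not (0 <= self.overlap_frac < 1):
            raise ValueError("overlap_frac must lie in [0, 1)")
        if self.window_len < 2:
            raise ValueError("window shorter than 2 samples at this rate")

    @property
    def window_len(self) -> int:
        """Window length in samples: floor(window_ms/1000 * rate_hz)."""
        return int(np.floor(self.window_ms / 1000.0 * self.rate_hz))

    @property
    def hop(self) -> int:
        """Hop between window starts: floor(window_len * (1 - overlap))."""
        return max(1, int(np.floor(self.window_len * (1 - self.overlap_frac))))


def euclidean_norm(v) -> float:
    """Length of a 3-vector in G."""
    v = np.asarray(v, dtype=float)
    if v.shape != (3,):
        raise ValueError("expected a 3-vector")
    if not np.all(np.isfinite(v)):
        raise ValueError("components must be finite")
    # identical operation order to resultant_series so streaming and batch
    # paths agree bit-for-bit
    return float(np.sqrt((v ** 2).sum()))


def resultant_series(trace_or_acc) -> np.ndarray:
    """Per-sample resultant acceleration of a trace or an (n, 3) array."""
    acc = (
        trace_or_acc.acc
        if isinstance(trace_or_acc, AccelTrace)
        else np.asarray(trace_or_acc, dtype=float)
    )
    if acc.size == 0:
        return np.zeros(0)
    return np.sqrt((acc ** 2).sum(axis=1))


@dataclass
class WindowFeatureSet:
    """Per-window min/max/swing statistics (half-open index ranges)."""

    start: np.ndarray  # (m,) 0-based window start indices
    end: np.ndarray    # (m,) half-open window end indices
    s_min: np.ndarray
    s_max: np.ndarray

    @property
    def delta_s(self) -> np.ndarray:
        return self.s_max - self.s_min

    def __len__(self) -> int:
        return len(self.start)


def window_features(series, cfg: FeatureConfig) -> WindowFeatureSet:
    """Min/max/swing statistics over windows tiling the resultant series."""
    series = np.asarray(series, dtype=float)
    w, hop = cfg.window_len, cfg.hop
    if len(series) < w:
        raise ValueError(
            f"series of {len(series)} samples is shorter than one "
            f"{w}-sample window"
        )
    views = sliding_window_view(series, w)
    starts = np.arange(0, len(series) - w + 1, hop)
    wins = views[starts]
    return WindowFeatureSet(
        start=starts,
        end=starts + w,
        s_min=wins.min(axis=1),
        s_max=wins.max(axis=1),
    )


def per_sample_features(trace_or_acc, cfg: FeatureConfig | None = None):
    """Per-sample feature rows (a_res, s_min, s_max, delta_s), batch form.

    Returns
    -------
    feats : ndarray of shape (n - window_len + 1, 4)
        One row per sample from the first fully-covered sample onward.
    offset : int
        Sample index of the first row (= window_len - 1, the warm-up
        prefix that is never classified).
    """
    cfg = cfg or FeatureConfig()
    res = resultant_series(trace_or_acc)
    w, hop = cfg.window_len, cfg.hop
    if len(res) < w:
        raise ValueError("trace shorter than one window")
    ws = window_features(res, cfg)
    idx = np.arange(w - 1, len(res))
    widx = (idx - w + 1) // hop
    feats = np.column_stack(
        [res[idx], ws.s_min[widx], ws.s_max[widx], ws.delta_s[widx]]
    )
    return feats, w - 1


class StreamingFeatureExtractor:
    """One-sample-at-a-time feature extraction, equal to the batch form.

    ``push`` returns ``None`` during warm-up, then a 4-tuple per sample.
    """

    def __init__(self, cfg: FeatureConfig | None = None):
        self.cfg = cfg or FeatureConfig()
        self._buf = deque(maxlen=self.cfg.window_len)
        self._count = 0
        self._s_min = None
        self._s_max = None

    def push(self, sample) -> tuple | None:
        a_res = euclidean_norm(np.asarray(sample, dtype=float))
        self._buf.append(a_res)
        i = self._count
        self._count += 1
        w, hop = self.cfg.window_len, self.cfg.hop
        if i >= w - 1 and (i - (w - 1)) % hop == 0:
            # a window just completed at index i: refresh the statistics
            self._s_min = min(self._buf)
            self._s_max = max(self._buf)
        if self._s_min is None:
            return None
        return (a_res, self._s_min, self._s_max, self._s_max - self._s_min)

    def run(self, trace_or_acc):
        """Feed a whole trace through ``push``; mirrors the batch API."""
        acc = (
            trace_or_acc.acc
            if isinstance(trace_or_acc, AccelTrace)
            else np.asarray(trace_or_acc, dtype=float)
        )
        rows = [r for r in (self.push(s) for s in acc) if r is not None]
        return np.array(rows, dtype=float), self.cfg.window_len - 1


class WindowFeatureTransformer(BaseEstimator, TransformerMixin):
    """Scikit-learn transformer from raw (n, 3) acceleration to features.

    Stateless: ``fit`` only validates.  ``transform`` drops the warm-up
    prefix, so the output has ``window_len - 1`` fewer rows than the input;
    :meth:`trim_labels` applies the same trim to a label vector.
    """

    def __init__(self, window_ms: float = 750.0, overlap_frac: float = 0.5,
                 rate_hz: float = 31.25):
        self.window_ms = window_ms
        self.overlap_frac = overlap_frac
        self.rate_hz = rate_hz

    def _cfg(self) -> FeatureConfig:
        return FeatureConfig(self.window_ms, self.overlap_frac, self.rate_hz)

    def fit(self, X, y=None):
        self._cfg()
        self.n_features_in_ = 3
        return self

    def transform(self, X):
        feats, _ = per_sample_features(np.asarray(X, dtype=float), self._cfg())
        return feats

    def trim_labels(self, y):
        return np.asarray(y)[self._cfg().window_len - 1:]
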