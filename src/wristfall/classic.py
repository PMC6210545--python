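"""Traditional per-sample classifiers with the consecutive-count event rule.

A Gaussian Naive Bayes or RBF-kernel SVM classifier labels every sample
(via its four window features) as fall / not-fall; a fall *event* is then
declared whenever a run of consecutive fall-labeled samples has length
between ``min_count`` and ``max_count`` (3 and 50 by default).  Runs longer
than ``max_count`` emit nothing: a sustained high-acceleration activity
such as jogging produces long runs and is thereby rejected, which is the
point of the upper bound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.naive_bayes import GaussianNB
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .features import FeatureConfig, per_sample_features
from .trace import AccelTrace, labels_to_bool


@dataclass(frozen=True)
class ConsecutiveRule:
    """Run-length bounds for declaring a fall event."""

    min_count: int = 3
    max_count: int = 50

    def __post_init__(self):
        if not (1 <= self.min_count <= self.max_count):
            raise ValueError("need 1 <= min_count <= max_count")


@dataclass(frozen=True)
class DetectionEvent:
    """A fall alarm localized to a half-open sample index range."""

    start_idx: int
    end_idx: int
    model: str = ""           # one of {"nb", "svm", "gru"}
    score: float | None = None

    def __post_init__(self):
        if not self.start_idx < self.end_idx:
            raise ValueError("event must span at least one sample")


def consecutive_count_decision(labels, rule: ConsecutiveRule | None = None,
                               model: str = "", offset: int = 0):
    """Turn per-sample fall labels into events via the run-length rule.

    A counter increments on each fall label; when a run terminates (a
    not-fall label, or end of stream) an event spanning the run is emitted
    iff ``min_count <= run length <= max_count``, and the counter resets.
    ``offset`` shifts emitted indices into trace coordinates.
    """
    rule = rule or ConsecutiveRule()
    fall = labels_to_bool(labels)
    events: list[DetectionEvent] = []
    run = 0
    for i, lab in enumerate(fall):
        if lab:
            run += 1
        else:
            if rule.min_count <= run <= rule.max_count:
                events.append(
                    DetectionEvent(offset + i - run, offset + i, model=model)
                )
            run = 0
    # end-of-stream flushes an open run through the same test, so a fall at
    # the very end of a file is not silently dropped
    if rule.min_count <= run <= rule.max_count:
        n = len(fall)
        events.append(
            DetectionEvent(offset + n - run, offset + n, model=model)
        )
    return events


class ClassicFallDetector(BaseEstimator, ClassifierMixin):
    """Per-sample NB/SVM classifier + consecutive-count event decision.

    Parameters
    ----------
    model : {"nb", "svm"}
        Gaussian Naive Bayes or an RBF-kernel SVM on features standardized
        by training-set mean/variance.
    min_count, max_count : int
        Run-length bounds of the event rule.
    window_ms, overlap_frac, rate_hz
        Feature-window geometry (see :mod:`wristfall.features`).
    max_train_samples : int, optional
        Stratified cap on training rows (keeps SVM training tractable on
        long streams); None disables.
    random_state : int
        Seeds the subsample draw; the underlying fits are deterministic.
    """

    def __init__(self, model: str = "nb", min_count: int = 3,
                 max_count: int = 50, window_ms: float = 750.0,
                 overlap_frac: float = 0.5, rate_hz: float = 31.25,
                 max_train_samples: int | None = None, random_state: int = 0):
        self.model = model
        self.min_count = min_count
        self.max_count = max_count
        self.window_ms = window_ms
        self.overlap_frac = overlap_frac
        self.rate_hz = rate_hz
        self.max_train_samples = max_train_samples
        self.random_state = random_state

    # -- core estimator API -------------------------------------------------

    def _make_clf(self):
        if self.model == "nb":
            return GaussianNB()
        if self.model == "svm":
            return make_pipeline(StandardScaler(), SVC(kernel="rbf", C=1.0))
        raise ValueError(f"unknown model kind {self.model!r}")

    def _feature_cfg(self) -> FeatureConfig:
        return FeatureConfig(self.window_ms, self.overlap_frac, self.rate_hz)

    def _rule(self) -> ConsecutiveRule:
        return ConsecutiveRule(self.min_count, self.max_count)

    def fit(self, X, y):
        """Fit on per-sample feature rows X (n, 4) and fall labels y."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 4:
            raise ValueError("X must have shape (n_samples, 4)")
        y = labels_to_bool(y)
        if len(X) == 0:
            raise ValueError("empty training set")
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        if self.max_train_samples and len(X) > self.max_train_samples:
            X, y = _stratified_subsample(
                X, y, self.max_train_samples, self.random_state
            )
        self.clf_ = self._make_clf().fit(X, y)
        self.classes_ = np.array([False, True])
        self.n_features_in_ = 4
        return self

    def predict(self, X):
        """Per-sample fall labels (bool) for feature rows X."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 4:
            raise ValueError("X must have shape (n_samples, 4)")
        return self.clf_.predict(X).astype(bool)

    # -- trace-level API ----------------------------------------------------

    def fit_traces(self, traces):
        """Fit from labeled traces: extract features, trim warm-up labels."""
        cfg = self._feature_cfg()
        Xs, ys = [], []
        for tr in traces:
            feats, off = per_sample_features(tr, cfg)
            Xs.append(feats)
            ys.append(tr.fall[off:])
        return self.fit(np.vstack(Xs), np.concatenate(ys))

    def detect_trace(self, trace: AccelTrace):
        """Detect fall events in one trace (batch evaluation)."""
        feats, off = per_sample_features(trace, self._feature_cfg())
        preds = self.predict(feats)
        return consecutive_count_decision(
            preds, self._rule(), model=self.model, offset=off
        )

    def detect_stream(self, trace: AccelTrace):
        """Sample-by-sample replay; identical output to ``detect_trace``."""
        from .features import StreamingFeatureExtractor

        ext = StreamingFeatureExtractor(self._feature_cfg())
        events: list[DetectionEvent] = []
        run = 0
        rule = self._rule()
        n_seen = 0
        off = self._feature_cfg().window_len - 1
        for sample in trace.acc:
            row = ext.push(sample)
            if row is None:
                continue
            i = off + n_seen
            n_seen += 1
            lab = bool(self.predict(np.asarray(row)[None, :])[0])
            if lab:
                run += 1
            else:
                if rule.min_count <= run <= rule.max_count:
                    events.append(
                        DetectionEvent(i - run, i, model=self.model)
                    )
                run = 0
        if rule.min_count <= run <= rule.max_count:
            end = off + n_seen
            events.append(DetectionEvent(end - run, end, model=self.model))
        return events


def _stratified_subsample(X, y, cap: int, seed: int):
    rng = np.random.default_rng(seed)
    idx_parts = []
    for cls in (False, True):
        idx = np.nonzero(y == cls)[0]
        take = max(1, int(round(cap * len(idx) / len(y))))
        if take < len(idx):
            idx = rng.choice(idx, size=take, replace=False)
        idx_parts.append(idx)
    keep = np.sort(np.concatenate(idx_parts))
    return X[keep], y[keep]


def train_classic(features, labels, kind: str = "nb", **kwargs):
    """Functional wrapper: fit a :class:`ClassicFallDetector` on rows."""
    return ClassicFallDetector(model=kind, **kwargs).fit(features, labels)


def classify_samples(model: ClassicFallDetector, features):
    """Functional wrapper over :meth:`ClassicFallDetector.predict`."""
    return model.predict(features)
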