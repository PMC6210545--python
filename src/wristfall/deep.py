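"""Streaming GRU fall detector with probability-average alarm smoothing.

The network consumes raw (ax, ay, az) windows of ``steps_n`` samples
(default 40, i.e. 1.28 s at 31.25 Hz) and outputs a fall probability per
window.  At inference the window slides one sample at a time, producing one
probability per sample from index ``steps_n - 1`` onward.  An alarm is
raised when the mean of ``heuristic_k`` consecutive probabilities reaches
the decision threshold; averaging suppresses isolated positive predictions
that would otherwise trigger false alarms.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view
from sklearn.base import BaseEstimator, ClassifierMixin

from . import _gru
from .classic import DetectionEvent
from .trace import AccelTrace, labels_to_bool

#: Numerical tolerance for the "mean >= threshold" tie so the comparison is
#: robust to floating-point summation order.
_TIE_EPS = 1e-12


@dataclass(frozen=True)
class GruConfig:
    """Architecture and decision parameters of the deep detector."""

    steps_n: int = 40          # window length in samples (1.28 s at 31.25 Hz)
    gru_units: int = 20
    fc_units: int = 20
    heuristic_k: int = 10      # consecutive probabilities averaged
    threshold: float = 0.5
    rate_hz: float = 31.25
    seed: int = 0

    def __post_init__(self):
        if self.steps_n < 1 or self.heuristic_k < 1:
            raise ValueError("steps_n and heuristic_k must be >= 1")
        if not (0 < self.threshold < 1):
            raise ValueError("threshold must lie in (0, 1)")
        if self.gru_units < 1 or self.fc_units < 1:
            raise ValueError("layer sizes must be positive")

    @property
    def window_duration_s(self) -> float:
        """Time span one prediction looks back over: steps_n / rate_hz."""
        return self.steps_n / self.rate_hz


@dataclass
class ProbabilityStream:
    """Per-sample fall probabilities aligned to window-final sample indices."""

    probs: np.ndarray   # (n - steps_n + 1,)
    offset: int         # sample index of probs[0] (= steps_n - 1)

    def __len__(self) -> int:
        return len(self.probs)

    def sample_index(self, i: int) -> int:
        return self.offset + i


def heuristic_decision(probs, cfg: GruConfig | None = None,
                       refractory_steps: int = 31, model: str = "gru"):
    """Rolling mean-of-k alarm rule over a probability stream.

    The mean of each run of ``heuristic_k`` consecutive probabilities is
    compared with the threshold (ties trigger).  A triggering run emits an
    event covering the ``heuristic_k`` window-final sample indices behind
    it.  Triggers within ``refractory_steps`` samples of the previously
    emitted trigger are absorbed (one physical fall raises one alarm), and
    re-arming is immediate afterwards.

    Raises
    ------
    ValueError
        If fewer than ``heuristic_k`` probabilities are available.
    """
    cfg = cfg or GruConfig()
    if isinstance(probs, ProbabilityStream):
        p, offset = probs.probs, probs.offset
    else:
        p, offset = np.asarray(probs, dtype=float), 0
    k = cfg.heuristic_k
    if len(p) < k:
        raise ValueError(
            f"need at least heuristic_k={k} probabilities, got {len(p)}"
        )
    means = sliding_window_view(p, k).mean(axis=1)
    trig = np.nonzero(means >= cfg.threshold - _TIE_EPS)[0]
    events: list[DetectionEvent] = []
    last = None
    for m in trig:
        j = offset + m + k - 1          # sample index of the final window
        if last is not None and j - last < refractory_steps:
            continue
        events.append(
            DetectionEvent(j - k + 1, j + 1, model=model,
                           score=float(means[m]))
        )
        last = j
    return events


def windows_from_trace(trace: AccelTrace, steps_n: int, stride: int = 1):
    """Training windows (m, steps_n, 3) and final-sample fall labels (m,)."""
    n = len(trace)
    if n < steps_n:
        raise ValueError(f"trace of {n} samples shorter than steps_n={steps_n}")
    wins = sliding_window_view(trace.acc, steps_n, axis=0)  # (m, 3, T)
    wins = np.transpose(wins, (0, 2, 1))[::stride]
    labels = trace.fall[steps_n - 1:][::stride]
    return np.ascontiguousarray(wins, dtype=float), labels.copy()


class GRUFallDetector(BaseEstimator, ClassifierMixin):
    """GRU sequence classifier over raw accelerometer windows.

    Parameters mirror :class:`GruConfig` plus the training specification.
    Each training window of ``steps_n`` raw samples is labeled by its final
    sample's label.  ``class_weight="balanced"`` applies inverse-frequency
    weights in the cross-entropy loss.  ``n_ensemble`` trains that many
    independently initialized networks on the same windows and averages
    their output probabilities — a variance-reduction step that stabilizes
    recognition of weak (low-magnitude) falls.

    Fitted attributes: ``members_`` (list of weight dicts, one per ensemble
    member), ``params_`` (the first member, for inspection), ``history_``
    (per-epoch training loss averaged over members).
    """

    def __init__(self, steps_n: int = 40, gru_units: int = 20,
                 fc_units: int = 20, heuristic_k: int = 10,
                 threshold: float = 0.5, rate_hz: float = 31.25,
                 epochs: int = 30, learning_rate: float = 1e-3,
                 batch_size: int = 64, class_weight: str | None = None,
                 refractory_steps: int = 31,
                 max_windows_per_class: int | None = None,
                 n_ensemble: int = 1,
                 random_state: int = 0):
        self.steps_n = steps_n
        self.gru_units = gru_units
        self.fc_units = fc_units
        self.heuristic_k = heuristic_k
        self.threshold = threshold
        self.rate_hz = rate_hz
        self.epochs = epochs
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.class_weight = class_weight
        self.refractory_steps = refractory_steps
        self.max_windows_per_class = max_windows_per_class
        self.n_ensemble = n_ensemble
        self.random_state = random_state

    def config(self) -> GruConfig:
        return GruConfig(self.steps_n, self.gru_units, self.fc_units,
                         self.heuristic_k, self.threshold, self.rate_hz,
                         self.random_state)

    # -- training -----------------------------------------------------------

    def fit(self, X, y):
        """Fit on windows X of shape (m, steps_n, 3) with fall labels y."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[1] != self.steps_n or X.shape[2] != 3:
            raise ValueError(
                f"X must have shape (m, {self.steps_n}, 3), got {X.shape}"
            )
        y = labels_to_bool(y).astype(int)
        if len(np.unique(y)) < 2:
            raise ValueError("training data must contain both classes")
        if self.n_ensemble < 1:
            raise ValueError("n_ensemble must be >= 1")
        rng = np.random.default_rng(self.random_state)
        if self.max_windows_per_class is not None:
            keep = _cap_per_class(y, self.max_windows_per_class, rng)
            X, y = X[keep], y[keep]
        w = np.ones(len(y))
        if self.class_weight == "balanced":
            counts = np.bincount(y, minlength=2)
            w = (len(y) / (2.0 * counts))[y]
        m = len(y)
        self.members_ = []
        histories = []
        for member in range(self.n_ensemble):
            mrng = np.random.default_rng([self.random_state, member])
            params = _gru.init_params(3, self.gru_units, self.fc_units, mrng)
            opt = _gru.Adam(params, lr=self.learning_rate)
            hist = []
            for _ in range(self.epochs):
                order = mrng.permutation(m)
                losses = []
                for s in range(0, m, self.batch_size):
                    idx = order[s:s + self.batch_size]
                    loss, grads = _gru.loss_and_grads(
                        params, X[idx], y[idx], w[idx]
                    )
                    opt.step(params, grads)
                    losses.append(loss)
                hist.append(float(np.mean(losses)))
            self.members_.append(params)
            histories.append(hist)
        self.params_ = self.members_[0]
        self.history_ = [
            float(np.mean(col)) for col in zip(*histories)
        ]
        self.classes_ = np.array([False, True])
        return self

    def fit_traces(self, traces, stride: int = 1):
        """Fit from labeled traces; windows labeled by their final sample."""
        Xs, ys = [], []
        for tr in traces:
            w, lab = windows_from_trace(tr, self.steps_n, stride=stride)
            Xs.append(w)
            ys.append(lab)
        return self.fit(np.vstack(Xs), np.concatenate(ys))

    # -- inference ----------------------------------------------------------

    def predict_proba(self, X):
        """(m, 2) class probabilities for windows X of (m, steps_n, 3)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 3 or X.shape[1] != self.steps_n or X.shape[2] != 3:
            raise ValueError(
                f"X must have shape (m, {self.steps_n}, 3), got {X.shape}"
            )
        members = getattr(self, "members_", None) or [self.params_]
        return np.mean([_gru.forward(p, X) for p in members], axis=0)

    def predict(self, X):
        return self.predict_proba(X)[:, 1] >= self.threshold

    def predict_stream(self, trace: AccelTrace) -> ProbabilityStream:
        """Slide one sample at a time over a trace.

        Each probability is computed from the trailing ``steps_n`` raw
        samples; probability i is aligned to sample index
        ``steps_n - 1 + i``.
        """
        n = len(trace)
        if n < self.steps_n:
            raise ValueError(
                f"trace of {n} samples shorter than steps_n={self.steps_n}"
            )
        wins = sliding_window_view(trace.acc, self.steps_n, axis=0)
        wins = np.ascontiguousarray(np.transpose(wins, (0, 2, 1)))
        # chunked evaluation bounds peak memory on long streams
        probs = np.concatenate([
            self.predict_proba(wins[s:s + 4096])[:, 1]
            for s in range(0, len(wins), 4096)
        ])
        return ProbabilityStream(probs=probs, offset=self.steps_n - 1)

    def detect_trace(self, trace: AccelTrace):
        """Probability stream + mean-of-k heuristic -> fall events."""
        ps = self.predict_stream(trace)
        if len(ps) < self.heuristic_k:
            return []
        return heuristic_decision(ps, self.config(),
                                  refractory_steps=self.refractory_steps)


def _cap_per_class(y, cap: int, rng: np.random.Generator):
    keep = []
    for cls in (0, 1):
        idx = np.nonzero(y == cls)[0]
        if len(idx) > cap:
            idx = rng.choice(idx, size=cap, replace=False)
        keep.append(idx)
    return np.sort(np.concatenate(keep))


def build_gru_model(cfg: GruConfig) -> GRUFallDetector:
    """Functional wrapper: an unfitted detector with initialized weights."""
    det = GRUFallDetector(
        steps_n=cfg.steps_n, gru_units=cfg.gru_units, fc_units=cfg.fc_units,
        heuristic_k=cfg.heuristic_k, threshold=cfg.threshold,
        rate_hz=cfg.rate_hz, random_state=cfg.seed,
    )
    rng = np.random.default_rng(cfg.seed)
    det.params_ = _gru.init_params(3, cfg.gru_units, cfg.fc_units, rng)
    det.members_ = [det.params_]
    det.history_ = []
    det.classes_ = np.array([False, True])
    return det


def train_gru(model: GRUFallDetector, traces, stride: int = 1):
    """Functional wrapper over :meth:`GRUFallDetector.fit_traces`."""
    return model.fit_traces(traces, stride=stride)


def predict_probabilities(model: GRUFallDetector,
                          trace: AccelTrace) -> ProbabilityStream:
    """Functional wrapper over :meth:`GRUFallDetector.predict_stream`."""
    return model.predict_stream(trace)
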