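"""Event-based evaluation: instance segmentation, matching, and metrics.

Ground truth is counted in *instances*: a fall instance is a maximal run of
Fall-labeled samples; an ADL instance is either a tagged activity segment
(when the trace carries activity tags) or a 1-second tile of consecutive
NotFall samples.  A detector alarm (event) that overlaps any Fall-labeled
sample is a true positive; otherwise it is a false positive.  A fall
instance touched by no true-positive alarm is a false negative; an ADL
instance containing no alarm is a true negative.  Each fall instance is
credited at most one true positive — extra alarms on the same fall are
ignored rather than punished.

Recall = TP/(TP+FN), Precision = TP/(TP+FP),
Accuracy = (TP+TN)/(TP+TN+FP+FN).  Recall is the metric that matters most:
a missed fall is the costly error.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import clone

from .classic import DetectionEvent
from .trace import AccelTrace


@dataclass
class InstanceSet:
    """Ground-truth fall and ADL instances of one trace (half-open ranges)."""

    falls: list
    adls: list
    adl_names: list = field(default_factory=list)

    @property
    def n_falls(self) -> int:
        return len(self.falls)

    @property
    def n_adls(self) -> int:
        return len(self.adls)


@dataclass
class OutcomeCounts:
    tp: int = 0
    fp: int = 0
    fn: int = 0
    tn: int = 0

    def __add__(self, other: "OutcomeCounts") -> "OutcomeCounts":
        return OutcomeCounts(self.tp + other.tp, self.fp + other.fp,
                             self.fn + other.fn, self.tn + other.tn)


@dataclass
class EvalReport:
    """Counts plus the derived fractions; undefined ratios are None."""

    tp: int
    fp: int
    fn: int
    tn: int
    precision: float | None
    recall: float | None
    overall_accuracy: float | None
    adl_accuracy: float | None
    fall_accuracy: float | None
    per_activity: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "tp": self.tp, "fp": self.fp, "fn": self.fn, "tn": self.tn,
            "precision": self.precision, "recall": self.recall,
            "overall_accuracy": self.overall_accuracy,
            "adl_accuracy": self.adl_accuracy,
            "fall_accuracy": self.fall_accuracy,
        }

    def pretty(self) -> str:
        """Aligned text block in the conventional benchmark row layout."""
        def fmt(v):
            return "  n/a" if v is None else f"{v:5.2f}"

        lines = [
            f"Precision     {fmt(self.precision)}",
            f"Recall        {fmt(self.recall)}",
            f"ADL Acc.      {fmt(self.adl_accuracy)}",
            f"Overall Acc.  {fmt(self.overall_accuracy)}",
            f"(tp={self.tp} fp={self.fp} fn={self.fn} tn={self.tn})",
        ]
        return "\n".join(lines)


def _maximal_runs(mask: np.ndarray):
    """Half-open (start, end) spans of maximal True runs."""
    if len(mask) == 0:
        return []
    padded = np.concatenate([[False], mask, [False]])
    d = np.diff(padded.astype(int))
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    return list(zip(starts.tolist(), ends.tolist()))


def segment_instances(trace: AccelTrace, adl_tile_s: float = 1.0,
                      use_tags: bool | None = None) -> InstanceSet:
    """Segment a labeled trace into fall and ADL instances.

    Fall instances are maximal Fall runs.  For ADLs, tagged activity
    segments are used when present (``use_tags=None`` auto-detects);
    otherwise each maximal NotFall stretch is tiled into non-overlapping
    ``round(rate_hz * adl_tile_s)``-sample instances, the trailing partial
    tile being discarded.
    """
    falls = _maximal_runs(trace.fall)
    if use_tags is None:
        use_tags = trace.has_activity_tags()
    adls, names = [], []
    if use_tags:
        act = trace.activity
        notfall = ~trace.fall
        start = None
        for i in range(len(trace) + 1):
            here = (
                i < len(trace) and notfall[i] and act is not None
                and act[i] != ""
            )
            if here and start is None:
                start = i
            elif start is not None and (
                not here or act[i] != act[start]
            ):
                adls.append((start, i))
                names.append(str(act[start]))
                start = i if here else None
    else:
        tile = int(round(trace.rate_hz * adl_tile_s))
        for s, e in _maximal_runs(~trace.fall):
            for k in range((e - s) // tile):
                adls.append((s + k * tile, s + (k + 1) * tile))
                names.append("")
    return InstanceSet(falls=falls, adls=adls, adl_names=names)


def match_events(events, instances: InstanceSet, trace: AccelTrace,
                 mode: str = "classic") -> OutcomeCounts:
    """Match detector events against ground-truth instances.

    An event is a true positive iff any sample index it covers is labeled
    Fall (for the deep detector the event range is, by construction, the
    set of window-final indices behind its trigger, so the same check
    applies).  Each fall instance credits at most one TP; surplus events on
    an already-credited fall are ignored.  ADL instances overlapped by no
    event count as TN.
    """
    if mode not in ("classic", "deep"):
        raise ValueError(f"unknown matching mode {mode!r}")
    n = len(trace)
    counts = OutcomeCounts()
    credited = [False] * len(instances.falls)
    for ev in sorted(events, key=lambda e: e.start_idx):
        if ev.start_idx < 0 or ev.end_idx > n:
            raise ValueError(
                f"event [{ev.start_idx}, {ev.end_idx}) outside trace of {n}"
            )
        if trace.fall[ev.start_idx:ev.end_idx].any():
            hit = [
                i for i, (s, e) in enumerate(instances.falls)
                if ev.start_idx < e and s < ev.end_idx
            ]
            fresh = [i for i in hit if not credited[i]]
            if fresh:
                credited[fresh[0]] = True
                counts.tp += 1
            # else: extra event on an already-detected fall — ignored
        else:
            counts.fp += 1
    counts.fn = sum(1 for c in credited if not c)
    for s, e in instances.adls:
        touched = any(
            ev.start_idx < e and s < ev.end_idx for ev in events
        )
        if not touched:
            counts.tn += 1
    return counts


def compute_metrics(counts: OutcomeCounts,
                    per_activity: dict | None = None) -> EvalReport:
    """Apply the precision/recall/accuracy formulas to outcome counts."""
    tp, fp, fn, tn = counts.tp, counts.fp, counts.fn, counts.tn
    if min(tp, fp, fn, tn) < 0:
        raise ValueError("counts must be non-negative")

    def ratio(num, den):
        return num / den if den > 0 else None

    return EvalReport(
        tp=tp, fp=fp, fn=fn, tn=tn,
        precision=ratio(tp, tp + fp),
        recall=ratio(tp, tp + fn),
        overall_accuracy=ratio(tp + tn, tp + tn + fp + fn),
        adl_accuracy=ratio(tn, tn + fp),
        fall_accuracy=ratio(tp, tp + fn),
        per_activity=per_activity or {},
    )


def evaluate_split(traces, detector, split: str = "leave_one_file_out",
                   seed: int | None = None, fit_kwargs: dict | None = None,
                   return_folds: bool = False):
    """Train/detect/match/aggregate over a file-level split.

    ``split`` is ``"leave_one_file_out"`` (each file is held out once) or
    ``"two_thirds_holdout"`` (the first two-thirds of the files train, the
    rest test; files are kept contiguous to avoid within-recording
    leakage).  The detector template is cloned per fold, so folds are
    independent; pass ``seed`` to fix its ``random_state``.
    """
    traces = list(traces)
    fit_kwargs = fit_kwargs or {}
    if split == "leave_one_file_out":
        if len(traces) < 2:
            raise ValueError("leave-one-out needs at least 2 files")
        folds = [
            ([t for j, t in enumerate(traces) if j != i], [traces[i]])
            for i in range(len(traces))
        ]
    elif split == "two_thirds_holdout":
        n_train = int(round(len(traces) * 2 / 3))
        if n_train < 1 or n_train >= len(traces):
            raise ValueError("holdout split degenerate for this file count")
        folds = [(traces[:n_train], traces[n_train:])]
    else:
        raise ValueError(f"unknown split {split!r}")
    mode = "deep" if hasattr(detector, "predict_stream") else "classic"
    total = OutcomeCounts()
    fold_counts = []
    for train, test in folds:
        det = clone(detector)
        if seed is not None and "random_state" in det.get_params():
            det.set_params(random_state=seed)
        det.fit_traces(train, **fit_kwargs)
        fold = OutcomeCounts()
        for tr in test:
            inst = segment_instances(tr)
            events = det.detect_trace(tr)
            fold = fold + match_events(events, inst, tr, mode=mode)
        fold_counts.append(fold)
        total = total + fold
    report = compute_metrics(total)
    if return_folds:
        return report, fold_counts
    return report
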