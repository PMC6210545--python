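"""Trace CSV I/O, stream resampling, and fall-peak label post-processing.

The CSV dialect is ``t,ax,ay,az,label[,activity]`` with a header row,
comma separators, 6-decimal fixed-point numbers and UTF-8 encoding.
Sample indexing is 0-based everywhere in the toolkit.

Resampling targets the smartwatch rate (31.25 Hz): higher-rate streams are
down-sampled by deleting random samples, lower-rate streams are up-sampled
by inserting random samples equal to the mean of their two neighbors.
After either operation timestamps are regenerated on an exact uniform grid
starting at the first input timestamp, because downstream windowing assumes
uniform spacing.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .trace import FALL, NOTFALL, AccelTrace, bool_to_labels, labels_to_bool

#: Decimal places used for time and acceleration columns on disk.
CSV_DECIMALS = 6

_COLUMNS = ["t", "ax", "ay", "az", "label"]


def read_trace_csv(path, rate_hz: float | None = None,
                   dialect: str = "standard",
                   subject_id: str = "", source: str = "synthetic") -> AccelTrace:
    """Read a labeled trace from CSV.

    Parameters
    ----------
    path : path-like
        CSV file with header ``t,ax,ay,az,label`` and an optional trailing
        ``activity`` column.
    rate_hz : float, optional
        Nominal sampling rate; inferred from the median timestamp delta
        when omitted.
    dialect : str
        Dataset-layout name; only ``"standard"`` is defined.

    Raises
    ------
    ValueError
        On a malformed row (the error names the offending line), an unknown
        label string, or non-monotone timestamps.
    """
    if dialect != "standard":
        raise ValueError(f"unknown CSV dialect {dialect!r}")
    df = pd.read_csv(path, dtype={"label": str, "activity": str})
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    for col in ("t", "ax", "ay", "az"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(~np.isfinite(vals.to_numpy()))[0]
        if len(bad):
            # +2: one for the header row, one for 1-based file lines
            raise ValueError(
                f"{path}: malformed value in column {col!r} at line {bad[0] + 2}"
            )
        df[col] = vals
    fall = labels_to_bool(df["label"].to_numpy())
    activity = None
    if "activity" in df.columns:
        activity = (
            df["activity"].fillna("").astype(str).to_numpy(dtype=object)
        )
    t = df["t"].to_numpy(dtype=float)
    if rate_hz is None:
        if len(t) > 1:
            rate_hz = 1.0 / float(np.median(np.diff(t)))
        else:
            rate_hz = 31.25
    return AccelTrace(
        t=t,
        acc=df[["ax", "ay", "az"]].to_numpy(dtype=float),
        fall=fall,
        rate_hz=rate_hz,
        activity=activity,
        subject_id=subject_id,
        source=source,
    )


def write_trace_csv(trace: AccelTrace, path) -> None:
    """Write a trace in the standard dialect (6-decimal fixed precision).

    A written file re-read with :func:`read_trace_csv` compares equal to a
    trace whose floats were already at 6-decimal precision; the synthetic
    generator and the resamplers only ever produce such traces indirectly,
    so round-trips in practice are tested on rounded traces.
    """
    df = pd.DataFrame(
        {
            "t": trace.t,
            "ax": trace.acc[:, 0],
            "ay": trace.acc[:, 1],
            "az": trace.acc[:, 2],
            "label": bool_to_labels(trace.fall),
        }
    )
    if trace.activity is not None:
        df["activity"] = trace.activity
    df.to_csv(path, index=False, float_format=f"%.{CSV_DECIMALS}f",
              encoding="utf-8")


def round_trace(trace: AccelTrace) -> AccelTrace:
    """Round time/acceleration to the on-disk precision (helper for tests)."""
    out = trace.copy()
    out.t = np.round(out.t, CSV_DECIMALS)
    out.acc = np.round(out.acc, CSV_DECIMALS)
    return out


def downsample_random(trace: AccelTrace, target_hz: float,
                      seed: int | np.random.Generator) -> AccelTrace:
    """Down-sample by deleting random samples until ``target_hz`` is reached.

    The number of survivors is ``floor(n * target_hz / rate_hz)``; deleted
    indices are drawn uniformly without replacement under ``seed``; the
    surviving samples keep their original component values and labels, in
    order, and receive new timestamps on a uniform grid at ``target_hz``
    starting at the first input timestamp.
    """
    if not target_hz < trace.rate_hz:
        raise ValueError(
            "target_hz must be below the trace rate; use upsample_random to "
            "raise the rate"
        )
    rng = np.random.default_rng(seed)
    n = len(trace)
    m = int(np.floor(n * target_hz / trace.rate_hz))
    drop = rng.choice(n, size=n - m, replace=False)
    keep = np.setdiff1d(np.arange(n), drop)
    t0 = trace.t[0] if n else 0.0
    return AccelTrace(
        t=t0 + np.arange(m) / target_hz,
        acc=trace.acc[keep],
        fall=trace.fall[keep],
        rate_hz=target_hz,
        activity=None if trace.activity is None else trace.activity[keep],
        subject_id=trace.subject_id,
        source=trace.source,
    )


def upsample_random(trace: AccelTrace, target_hz: float,
                    seed: int | np.random.Generator) -> AccelTrace:
    """Up-sample by inserting random samples equal to neighbor means.

    The output length is ``n * target_hz / rate_hz`` rounded half-to-even.
    Insertion gaps are drawn uniformly without replacement from the ``n-1``
    neighbor pairs, so each inserted sample's components are the arithmetic
    mean of two *original* neighbors.  An inserted sample inherits the label
    its neighbors share; when they disagree it is labeled ``Fall`` (the
    conservative choice: never dilute fall evidence).  A single call can at
    most double the rate.
    """
    if not target_hz > trace.rate_hz:
        raise ValueError(
            "target_hz must exceed the trace rate; use downsample_random to "
            "lower the rate"
        )
    n = len(trace)
    if n < 2:
        raise ValueError("need at least 2 samples to interpolate")
    rng = np.random.default_rng(seed)
    m = int(np.rint(n * target_hz / trace.rate_hz))
    k = m - n
    if k > n - 1:
        raise ValueError(
            "cannot more than double the rate in one call "
            f"(need {k} insertions but only {n - 1} neighbor gaps)"
        )
    gaps = np.sort(rng.choice(n - 1, size=k, replace=False))
    # gap g means "insert between samples g and g+1" -> np.insert position g+1
    new_acc = 0.5 * (trace.acc[gaps] + trace.acc[gaps + 1])
    new_fall = trace.fall[gaps] | trace.fall[gaps + 1]
    acc = np.insert(trace.acc, gaps + 1, new_acc, axis=0)
    fall = np.insert(trace.fall, gaps + 1, new_fall)
    activity = None
    if trace.activity is not None:
        new_act = np.array(
            [
                trace.activity[g] if trace.activity[g] == trace.activity[g + 1]
                else ""
                for g in gaps
            ],
            dtype=object,
        )
        activity = np.insert(trace.activity, gaps + 1, new_act)
    t0 = trace.t[0]
    return AccelTrace(
        t=t0 + np.arange(m) / target_hz,
        acc=acc,
        fall=fall,
        rate_hz=target_hz,
        activity=activity,
        subject_id=trace.subject_id,
        source=trace.source,
    )


def resample(trace: AccelTrace, target_hz: float,
             seed: int | np.random.Generator) -> AccelTrace:
    """Dispatch to the random down- or up-sampler; identity at equal rates."""
    if target_hz == trace.rate_hz:
        return trace.copy()
    if target_hz < trace.rate_hz:
        return downsample_random(trace, target_hz, seed)
    return upsample_random(trace, target_hz, seed)


def enforce_fall_peak_labels(trace: AccelTrace,
                             margin_s: float = 0.5) -> AccelTrace:
    """Force the acceleration peak of a fall-session file to be labeled Fall.

    Manual labeling (a button pressed during recording) can miss the impact
    itself; this post-processing relabels the sample of maximum resultant
    acceleration, and every sample within ``margin_s`` seconds of it, as
    ``Fall``.  All other labels are unchanged, so the operation is idempotent
    and never removes a fall label.

    Raises
    ------
    ValueError
        If the trace carries no fall label at all (it is then an ADL-only
        file and the rule does not apply).
    """
    if not trace.fall.any():
        raise ValueError(
            "enforce_fall_peak_labels applies only to fall-session files "
            "(no Fall label found)"
        )
    out = trace.copy()
    res = np.linalg.norm(out.acc, axis=1)
    peak = int(np.argmax(res))
    half = int(round(margin_s * out.rate_hz))
    lo = max(0, peak - half)
    hi = min(len(out), peak + half + 1)
    out.fall[lo:hi] = True
    return out
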