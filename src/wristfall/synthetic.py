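"""Synthetic wrist-accelerometer signal generator.

Falls follow the critical-phase morphology seen in wrist recordings: a
~1 G resting baseline, an optional weightlessness dip toward 0 G, a single
sharp impact peak, and exponentially damped oscillations back to rest.
Three variants are generated:

* ``full_critical_phase`` — the textbook shape, impact peak near 5.5 G;
* ``no_weightlessness`` — the free-fall dip is absent (common when the arm
  leads the body);
* ``low_magnitude`` — the whole pattern is compressed, the peak never
  exceeding 3 G (typical of sideways falls where the hands do not break
  the fall).

ADLs are scripted: sitting (one low transient), waving (1–3 Hz periodic),
jogging (~2.5 Hz sustained high amplitude for at least several seconds),
walking (~1.8 Hz low amplitude) and throwing (one short spike).  Gravity is
included — the resting resultant is ~1 G — and each segment receives a
random 3-D wrist-orientation rotation plus additive Gaussian noise.

All randomness flows from one seed through ``numpy.random.SeedSequence``
spawning, so sessions, files and benchmarks are bit-reproducible.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import yaml
from scipy.spatial.transform import Rotation

from .trace import AccelTrace, concat_traces

FALL_VARIANTS = ("full_critical_phase", "no_weightlessness", "low_magnitude")
ADL_KINDS = ("sitting", "waving", "jogging", "walking", "throwing")
FALL_DIRECTIONS = ("front", "back", "left", "right")

#: Minimum scripted durations (seconds) per ADL kind.
ADL_MIN_DURATION_S = {
    "sitting": 0.0, "waving": 3.0, "jogging": 10.0, "walking": 10.0,
    "throwing": 0.0,
}
_ADL_DEFAULT_DURATION_S = {
    "sitting": 4.0, "waving": 3.0, "jogging": 10.0, "walking": 10.0,
    "throwing": 3.0,
}


@dataclass(frozen=True)
class FallShapeParams:
    """Morphology of one simulated fall signature."""

    variant: str = "full_critical_phase"
    freefall_ms: float = 300.0   # duration of the near-0 G dip (0 = none)
    peak_g: float = 5.5          # impact peak magnitude in G
    osc_freq_hz: float = 4.0     # damped-oscillation frequency
    osc_decay_s: float = 0.4     # oscillation amplitude time constant

    def __post_init__(self):
        if self.variant not in FALL_VARIANTS:
            raise ValueError(f"unknown fall variant {self.variant!r}")
        if not self.peak_g > 1:
            raise ValueError("peak_g must exceed the 1 G baseline")
        if self.variant == "low_magnitude" and self.peak_g > 3.0:
            raise ValueError("low_magnitude falls never exceed 3 G")
        if self.variant == "no_weightlessness" and self.freefall_ms != 0:
            raise ValueError("no_weightlessness implies freefall_ms = 0")

    @classmethod
    def for_variant(cls, variant: str,
                    rng: np.random.Generator | None = None):
        """Canonical parameters per variant, with mild jitter under rng."""
        base = {
            "full_critical_phase": dict(freefall_ms=300.0, peak_g=5.5),
            "no_weightlessness": dict(freefall_ms=0.0, peak_g=5.0),
            "low_magnitude": dict(freefall_ms=150.0, peak_g=2.5),
        }[variant]
        if rng is not None:
            # person-to-person impact variability; low-magnitude impacts
            # range down to barely twice the resting level, where they
            # overlap vigorous ADLs
            base = dict(base)
            if variant == "low_magnitude":
                base["peak_g"] = float(rng.uniform(1.8, 2.9))
            else:
                base["peak_g"] *= float(rng.uniform(0.85, 1.15))
        return cls(variant=variant, **base)


@dataclass(frozen=True)
class SimSessionConfig:
    """Composition of one simulated recording session."""

    rate_hz: float = 31.25
    noise_sd: float = 0.03                     # additive Gaussian noise, G
    adl_mix: dict = field(default_factory=lambda: {
        "sitting": 1.0, "waving": 1.0, "jogging": 1.0, "walking": 1.0,
        "throwing": 1.0,
    })
    falls_per_type: int = 1                    # per direction (4 directions)
    n_adls: int = 8                            # scripted ADL segments
    fall_to_adl_ratio: float | None = None     # overrides n_adls when set
    quiet_pad_s: float = 2.0                   # extra trailing quiet time
    tag_activities: bool = True
    seed: int = 0

    def __post_init__(self):
        if any(w < 0 for w in self.adl_mix.values()):
            raise ValueError("adl_mix weights must be non-negative")
        if not self.rate_hz > 0:
            raise ValueError("rate_hz must be positive")


def _rotate(rng: np.random.Generator) -> np.ndarray:
    return Rotation.random(rng=rng).as_matrix()


def _embed(resultant: np.ndarray, fall: np.ndarray, rate_hz: float,
           noise_sd: float, rng: np.random.Generator,
           activity: str = "") -> AccelTrace:
    """Lay a resultant profile along a random wrist orientation.

    Adds slow 3-D arm-motion wander (the wrist moves independently of the
    trunk) plus white measurement noise, so window minima/maxima are not
    noiseless copies of the scripted profile.
    """
    R = _rotate(rng)
    direction = R @ np.array([0.0, 0.0, 1.0])
    acc = np.outer(resultant, direction)
    n = len(resultant)
    tt = np.arange(n) / rate_hz
    for axis in range(3):
        amp = rng.uniform(0.03, 0.15)
        f = rng.uniform(0.3, 1.0)
        acc[:, axis] += amp * np.sin(2 * np.pi * f * tt +
                                     rng.uniform(0, 2 * np.pi))
    acc = acc + rng.normal(0.0, noise_sd, size=acc.shape)
    n = len(resultant)
    act = np.full(n, activity, dtype=object)
    return AccelTrace(
        t=np.arange(n) / rate_hz, acc=acc, fall=fall, rate_hz=rate_hz,
        activity=act, source="synthetic",
    )


def _quiet(duration_s: float, rate_hz: float, noise_sd: float,
           rng: np.random.Generator) -> AccelTrace:
    n = max(1, int(round(duration_s * rate_hz)))
    r = np.ones(n)
    return _embed(r, np.zeros(n, dtype=bool), rate_hz, noise_sd, rng)


def simulate_fall(params: FallShapeParams, rate_hz: float = 31.25,
                  seed: int | np.random.Generator = 0,
                  noise_sd: float = 0.03) -> AccelTrace:
    """One fall segment: quiet lead-in, critical phase (labeled Fall), rest.

    The resultant profile rests near 1 G, optionally dips toward 0 G for
    ``freefall_ms``, rises to a single global maximum of ``peak_g``, and
    rings down as a damped oscillation.  Fall labels cover dip-through-
    oscillation, so the peak sample is always labeled Fall.
    """
    rng = np.random.default_rng(seed)
    dt = 1.0 / rate_hz

    def n_of(sec):
        return max(1, int(round(sec * rate_hz)))

    pre = np.ones(n_of(0.5))
    parts = [pre]
    fall_flags = [np.zeros(len(pre), dtype=bool)]

    if params.freefall_ms > 0:
        nf = n_of(params.freefall_ms / 1000.0)
        # weightlessness is rarely a clean 0 G on the wrist: the dip depth
        # varies with how much the arm swings during the descent
        if params.variant == "low_magnitude":
            dip_floor = float(rng.uniform(0.35, 0.75))
        else:
            dip_floor = float(rng.uniform(0.05, 0.35))
        ramp = np.linspace(1.0, dip_floor, nf)
        parts.append(ramp)
        fall_flags.append(np.ones(nf, dtype=bool))

    # impact: raised-cosine bump whose maximum is exactly peak_g; an odd
    # sample count puts one sample exactly on the crest
    ni = max(3, n_of(0.13))
    if ni % 2 == 0:
        ni += 1
    bump = 0.5 * (1 - np.cos(2 * np.pi * np.arange(ni) / (ni - 1)))
    start_level = parts[-1][-1]
    impact = start_level + (params.peak_g - start_level) * bump
    parts.append(impact)
    fall_flags.append(np.ones(ni, dtype=bool))

    nosc = n_of(1.5)
    tt = np.arange(nosc) * dt
    amp = max(0.2, 0.35 * (params.peak_g - 1.0))
    osc = 1.0 + amp * np.exp(-tt / params.osc_decay_s) * np.cos(
        2 * np.pi * params.osc_freq_hz * tt
    )
    parts.append(osc)
    fall_flags.append(np.ones(nosc, dtype=bool))

    post = np.ones(n_of(0.5))
    parts.append(post)
    fall_flags.append(np.zeros(len(post), dtype=bool))

    resultant = np.concatenate(parts)
    fall = np.concatenate(fall_flags)
    # the labels extend half a second either side of the impact crest, the
    # same envelope the fall-peak post-processing rule enforces
    crest = len(pre) + (len(parts[1]) if params.freefall_ms > 0 else 0) \
        + (ni - 1) // 2
    half = int(round(0.5 * rate_hz))
    fall[max(0, crest - half):crest + half + 1] = True
    return _embed(resultant, fall, rate_hz, noise_sd, rng)


def simulate_adl(kind: str, duration_s: float | None = None,
                 rate_hz: float = 31.25,
                 seed: int | np.random.Generator = 0,
                 noise_sd: float = 0.03) -> AccelTrace:
    """One scripted ADL segment, labeled NotFall with an activity tag."""
    if kind not in ADL_KINDS:
        raise ValueError(f"unknown ADL kind {kind!r}")
    rng = np.random.default_rng(seed)
    if duration_s is None:
        duration_s = _ADL_DEFAULT_DURATION_S[kind]
    if duration_s < ADL_MIN_DURATION_S[kind]:
        raise ValueError(
            f"{kind} requires at least {ADL_MIN_DURATION_S[kind]} s"
        )
    n = max(2, int(round(duration_s * rate_hz)))
    tt = np.arange(n) / rate_hz
    # per-segment intensity varies from person to person and bout to bout;
    # vigorous jogging overlaps low-magnitude falls in peak and swing
    if kind == "sitting":
        r = np.ones(n)
        c = rng.uniform(0.3, 0.7) * duration_s
        r += rng.uniform(0.4, 0.8) * np.exp(-0.5 * ((tt - c) / 0.25) ** 2)
    elif kind == "waving":
        f = rng.uniform(1.0, 3.0)
        amp = rng.uniform(0.4, 0.8)
        r = 1.0 + amp * np.sin(2 * np.pi * f * tt + rng.uniform(0, 2 * np.pi))
    elif kind == "jogging":
        # sustained foot-strike transients, 2.5 Hz cadence
        f = rng.uniform(2.3, 2.7)
        amp = rng.uniform(1.0, 2.0)
        strikes = np.maximum(0.0, np.sin(2 * np.pi * f * tt)) ** 2
        per_strike = 1.0 + 0.2 * np.sin(
            2 * np.pi * rng.uniform(0.2, 0.5) * tt + rng.uniform(0, 2 * np.pi)
        )
        r = 1.0 + amp * per_strike * strikes \
            + 0.1 * np.sin(2 * np.pi * 2 * f * tt)
    elif kind == "walking":
        f = rng.uniform(1.6, 2.0)
        r = 1.0 + rng.uniform(0.25, 0.5) * np.sin(2 * np.pi * f * tt)
    else:  # throwing
        r = np.ones(n)
        c = rng.uniform(0.3, 0.7) * duration_s
        r += rng.uniform(1.2, 2.0) * np.exp(-0.5 * ((tt - c) / 0.08) ** 2)
    return _embed(np.maximum(r, 0.0), np.zeros(n, dtype=bool), rate_hz,
                  noise_sd, rng, activity=kind)


def _fall_params_for_direction(direction: str,
                               rng: np.random.Generator) -> FallShapeParams:
    """Front/back falls mostly show the full critical phase; left/right
    falls frequently present the anomalous morphologies."""
    if direction in ("front", "back"):
        choices = ["full_critical_phase"] * 3 + ["no_weightlessness"]
    else:
        choices = ["full_critical_phase", "no_weightlessness",
                   "low_magnitude", "low_magnitude"]
    variant = choices[rng.integers(len(choices))]
    return FallShapeParams.for_variant(variant, rng)


def simulate_session(cfg: SimSessionConfig,
                     subject_id: str = "sim") -> AccelTrace:
    """Concatenate falls, ADLs and quiet gaps into one labeled session."""
    rng = np.random.default_rng(cfg.seed)
    n_falls = 4 * cfg.falls_per_type
    n_adls = cfg.n_adls
    if cfg.fall_to_adl_ratio is not None and cfg.fall_to_adl_ratio > 0:
        n_adls = max(1, int(round(n_falls / cfg.fall_to_adl_ratio)))
    if n_falls + n_adls == 0:
        raise ValueError("session must contain at least one activity")

    positive = [(k, w) for k, w in cfg.adl_mix.items() if w > 0]
    if n_adls > 0 and not positive:
        raise ValueError("n_adls > 0 but every adl_mix weight is zero")
    kinds, weights = zip(*positive) if positive else ((), ())
    plan = []
    for d in FALL_DIRECTIONS:
        plan += [("fall", d)] * cfg.falls_per_type
    p = np.array(weights, dtype=float)
    p = p / p.sum() if len(p) else p
    for _ in range(n_adls):
        plan.append(("adl", str(rng.choice(kinds, p=p))))
    rng.shuffle(plan)

    segments = []
    for what, detail in plan:
        segments.append(
            _quiet(rng.uniform(0.5, 1.5), cfg.rate_hz, cfg.noise_sd, rng)
        )
        if what == "fall":
            params = _fall_params_for_direction(detail, rng)
            segments.append(
                simulate_fall(params, cfg.rate_hz, rng, cfg.noise_sd)
            )
        else:
            segments.append(
                simulate_adl(detail, None, cfg.rate_hz, rng, cfg.noise_sd)
            )
    if cfg.quiet_pad_s > 0:
        segments.append(_quiet(cfg.quiet_pad_s, cfg.rate_hz, cfg.noise_sd,
                               rng))
    trace = concat_traces(segments, cfg.rate_hz, subject_id=subject_id)
    if not cfg.tag_activities:
        trace.activity = np.full(len(trace), "", dtype=object)
    return trace


# -- benchmark presets ------------------------------------------------------

def load_presets() -> dict:
    """Benchmark preset parameters shipped with the package (YAML)."""
    with resources.files("wristfall").joinpath("presets.yaml").open() as fh:
        return yaml.safe_load(fh)


def simulate_benchmark(preset: str, seed: int = 0) -> list[AccelTrace]:
    """A multi-file dataset whose fall:ADL instance imbalance mirrors the
    published wrist-sensor datasets (an ~1:1 tagged-ADL set, a ~1:23
    untagged set, and a heavily imbalanced real-world-like set scaled down
    tenfold for desk-scale generation).

    Returns one trace per simulated subject file.  For untagged presets the
    per-file 1-second ADL tile count is topped up with quiet (idle) time to
    the preset target, so the overall instance ratio is controlled.
    """
    presets = load_presets()
    if preset not in presets:
        raise ValueError(
            f"unknown preset {preset!r}; available: {sorted(presets)}"
        )
    spec = presets[preset]
    ss = np.random.SeedSequence([seed, zlib.crc32(preset.encode())])
    children = ss.spawn(len(spec["falls_per_file"]))
    traces = []
    from .evaluation import segment_instances

    for fi, (n_falls, child) in enumerate(
        zip(spec["falls_per_file"], children)
    ):
        rng = np.random.default_rng(child)
        segments = []
        directions = [FALL_DIRECTIONS[i % 4] for i in range(n_falls)]
        rng.shuffle(directions)
        plan = [("fall", d) for d in directions]
        n_adls = spec["adl_segments_per_file"][fi]
        kinds = list(spec["adl_mix"].keys())
        p = np.array(list(spec["adl_mix"].values()), dtype=float)
        p /= p.sum()
        plan += [("adl", str(rng.choice(kinds, p=p))) for _ in range(n_adls)]
        rng.shuffle(plan)
        for what, detail in plan:
            segments.append(_quiet(rng.uniform(0.5, 1.5), spec["rate_hz"],
                                   spec["noise_sd"], rng))
            if what == "fall":
                params = _fall_params_for_direction(detail, rng)
                segments.append(simulate_fall(params, spec["rate_hz"], rng,
                                              spec["noise_sd"]))
            else:
                segments.append(simulate_adl(detail, None, spec["rate_hz"],
                                             rng, spec["noise_sd"]))
        trace = concat_traces(segments, spec["rate_hz"],
                              subject_id=f"{preset}_{fi:02d}")
        if not spec["tag_activities"]:
            trace.activity = np.full(len(trace), "", dtype=object)
            target = spec["adl_tiles_per_file"][fi]
            tile = int(round(spec["rate_hz"]))
            have = segment_instances(trace).n_adls
            if have < target:
                pad_n = (target - have) * tile
                pad = _quiet(pad_n / spec["rate_hz"], spec["rate_hz"],
                             spec["noise_sd"], rng)
                pad.activity = np.full(len(pad), "", dtype=object)
                trace = concat_traces([trace, pad], spec["rate_hz"],
                                      subject_id=trace.subject_id)
        traces.append(trace)
    return traces
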