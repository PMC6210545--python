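# Methods

This note records the models implemented in `wristfall`, the choices made
where the design was genuinely open, and what the synthetic benchmark can
and cannot show.

## Signal model and units

All signals are tri-axial acceleration in units of G (standard gravity).
Gravity is part of the signal: a resting wrist shows a resultant
acceleration of ≈1 G. The nominal sampling rate is the smartwatch rate of
31.25 Hz; traces at other rates are brought to it by random-sample
deletion (down-sampling, survivor count = ⌊n·target/source⌋) or random
insertion of neighbor means (up-sampling, output count = n·target/source
rounded half-to-even). Insertion gaps are drawn without replacement so
every inserted sample is the mean of two *original* neighbors; one call
can therefore at most double the rate, which covers the 20 → 31.25 Hz
case. After resampling, timestamps are regenerated on an exact uniform
grid starting at the first input timestamp because the windowing below
assumes uniform spacing. An inserted sample inherits the label its
neighbors share; on disagreement it is labeled `Fall` — the conservative
direction, since diluting fall evidence is the costlier error.

The fall-peak relabeling rule addresses sloppy manual labeling: in a
fall-session file, the sample of maximum resultant acceleration and all
samples within ±`margin_s` of it are forced to `Fall`. `margin_s` defaults
to 0.5 s; the rule is idempotent and never removes a label. Applying it to
an ADL-only file is a contract error rather than a silent no-op.

## Window features

Per sample: A_res = √(ax² + ay² + az²); S_min and S_max are the minimum
and maximum of A_res within a 750 ms sliding window; ΔS = S_max − S_min.
ΔS is computed on scalar resultants (the source statistics S_min/S_max are
scalars; a vector-difference reading of ΔS coincides up to sign on this
convention). Window length in samples is ⌊0.750 × rate⌋ = 23 at 31.25 Hz,
hop = ⌊23 × 0.5⌋ = 11 for 50% overlap — floor keeps windows within the
stated duration. Window statistics are assigned *causally*: sample *i*
carries the statistics of the most recent window fully completed at or
before *i*, which makes a real-time streaming implementation possible;
streaming and batch paths are required (and tested) to agree exactly, down
to using the same floating-point operation order for the norm. Samples
before the first complete window (22 at defaults) form a warm-up prefix
that is never classified.

## Classic detectors and the run-length rule

Gaussian Naive Bayes (continuous features, hence Gaussian
class-conditionals) and an SVM with RBF kernel on features standardized by
training-set mean and variance; the kernel and scaling are this package's
choices, as is an optional stratified cap on training rows that keeps SVM
training tractable on long streams. Per-sample labels become events via
the consecutive-count rule: a counter increments on each fall label; when
a run ends, an event is emitted iff 3 ≤ run ≤ 50. Two boundary choices:
(1) end-of-stream flushes an open run through the same test, otherwise a
fall at the end of a file would be dropped silently; (2) a run longer than
50 emits nothing — that is the literal else-if semantics of the rule, and
it is what rejects sustained activities like jogging. The whole stream is
treated as one prediction interval.

## GRU detector

Architecture: 3 input nodes (raw ax, ay, az) → GRU layer of 20 units → 
dense layer of 20 ReLU units → 2-way softmax. "ReLU nodes" in the
recurrent layer is implemented as a standard GRU (sigmoid update and reset
gates) whose candidate state uses a rectified-linear activation — the
closest reading that remains a GRU. The network, backpropagation through
time, and Adam live in `wristfall._gru` as plain NumPy in float64; the
analytic gradients are verified against central finite differences in the
test suite, and training is bit-reproducible from a seed.

Training windows are `steps_n` = 40 consecutive raw samples (1.28 s),
labeled by the label of the window's **final** sample — the label the
stream would know in real time. Defaults: Adam at learning rate 1e-3, 30
epochs, batch 64, optional inverse-frequency class weights. At inference
the window slides one sample at a time, giving one P(fall) per sample from
index 39 onward. An alarm fires when the mean of `heuristic_k` = 10
consecutive probabilities reaches the threshold (default 0.5; ties
trigger, with a 1e-12 numerical tolerance so the tie convention is robust
to summation order). The averaging is a rolling mean advancing one step at
a time, consistent with the streaming scheme. Emitted events cover exactly
the 10 window-final sample indices behind the trigger. After a trigger,
re-triggering is suppressed for `refractory_steps` = 31 samples (1 s) so
one physical fall raises one alarm. This emit-and-re-arm scan was chosen
deliberately: it makes the emitted events a greedy minimum-separation
packing of the triggering positions, which guarantees that raising the
threshold can never increase the number of emitted events (a merge-gaps
rule does not have that property).

`n_ensemble` > 1 trains that many networks from independent
initializations on the same windows and averages their probabilities.
This is plain variance reduction: single small networks occasionally
recognize a weak (low-magnitude) fall only after its labeled extent has
passed, which the event-matching protocol counts as a miss plus a false
alarm; averaging two members removes most of these failures. The standard
benchmark uses a two-member ensemble.

## Evaluation protocol

Instances: fall = maximal run of `Fall` samples; ADL = tagged activity
segment when tags exist, else a 1-second tile (31 samples) of consecutive
`NotFall` samples, non-overlapping, trailing partial tile dropped. An
event is a true positive iff any sample it covers is labeled `Fall`; for
the deep detector the event range is by construction the 10 window-final
indices behind the trigger, so the same check implements the
final-row matching rule. Each fall instance credits at most one TP; extra
events on an already-credited fall are ignored (neither TP nor FP). ADL
instances touched by no event are TN. Undefined ratios (zero denominator)
are reported as absent, never as 0. Splits are by whole file —
leave-one-file-out, or first two-thirds of files for training — to avoid
within-recording leakage; counts are summed across folds before metrics
are computed, because per-fold recalls over ~15 falls are too grainy to
compare detectors on. Split evaluation runs the batch detection path;
sample-by-sample streaming replay is implemented alongside it and tested
to produce identical events, so the batch numbers are exactly the
simulated-online numbers.

## Synthetic generator

The generator emulates wrist recordings of scripted falls and ADLs:

* **Falls** follow the critical phase — optional weightlessness dip,
  single impact crest, exponentially damped ~4 Hz oscillation back to
  ≈1 G — in three variants: full pattern (peak ≈5.5 G), missing
  weightlessness, and low-magnitude (peak ≤3 G, dip only partial). Falls
  to the front/back are mostly full-pattern; falls to the left/right are
  predominantly the anomalous variants, mirroring how sideways falls
  present at the wrist. Fall labels cover the dip through the oscillation
  and always extend ±0.5 s around the crest, the same envelope the
  fall-peak rule enforces.
* **ADLs**: sitting (one low transient), waving (1–3 Hz periodic,
  ≥3 s), jogging (~2.5 Hz foot-strike transients sustained ≥10 s, peak
  intensity varying by bout up to ≈3 G), walking (~1.8 Hz low amplitude,
  ≥10 s), throwing (one short spike).
* **Wrist realism**: each segment gets a random 3-D orientation rotation,
  slow multi-axis arm-motion wander (0.3–1 Hz, up to 0.15 G per axis) and
  white noise (σ = 0.03 G, a free parameter — the true sensor noise floor
  is unknown). The wander and the bout-to-bout intensity spread are what
  make vigorous ADLs overlap low-magnitude falls in the window features,
  so the feature-based detectors face a genuinely hard minority class.

All randomness flows from one seed through `numpy.random.SeedSequence`
spawning, so individual files are independently reproducible and a whole
benchmark is byte-identical under a fixed seed. Benchmark presets mirror
published dataset imbalances: ≈1:1 (91 falls : 90 tagged ADLs over 7
files), ≈1:23 (107 falls : 2456 untagged 1-second ADL tiles over 7 files),
and a heavily imbalanced ≈1:119 preset (23 falls : 2741 tiles over 3
files) that is one tenth of its real-world counterpart's ADL volume so it
generates in seconds; untagged files are topped up with quiet idle time to
hit their tile targets exactly.

What passing on synthetic data does **not** show: the generator scripts
smooth, piecewise-deterministic morphologies with idealized spectra; real
wrist data has richer frequency content, unscripted compound movements,
and label noise beyond the ±0.5 s envelope. Results here demonstrate that
the pipeline's machinery behaves as specified and that the qualitative
recall ordering of the detectors (recurrent ≥ Naive Bayes ≥ SVM) emerges
under controlled imbalance — not that any absolute accuracy carries over
to human data. The precision ordering of the detectors on real data is
likewise out of scope: on this generator the GRU trades precision for
recall more aggressively than the feature-based models.

## Benchmark problem sizes

The standard recall benchmark (`wristfall.benchmarks.run_recall_benchmark`)
generates three ≈1:23-imbalance datasets (seven files of ~12 000 samples
each), and runs leave-one-file-out per detector. Per fold, the GRU ensemble
(2 members × 15 epochs, learning rate 3e-3, class-balanced loss) trains on
a class-capped subsample (≤6000 windows per class, every second window);
the SVM trains on ≤6000 stratified feature rows. These sizes keep a full
three-seed run within minutes on a single CPU core while leaving every
fall of every test file in play.

## Known limitations

* The GRU forward/backward is plain NumPy: adequate for these problem
  sizes, not for large-scale training.
* Up-sampling beyond 2× requires repeated calls.
* `euclidean_norm` and the feature extractors assume finite inputs and
  raise on NaN/Inf rather than propagating them.
* The generator does not model gyroscope channels, compound ADLs, or
  biomechanically accurate limb kinematics.
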