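"""Instance segmentation, event matching, metric formulas, split protocol."""

import numpy as np
import pytest

from wristfall import (
    AccelTrace,
    ClassicFallDetector,
    DetectionEvent,
    OutcomeCounts,
    compute_metrics,
    evaluate_split,
    match_events,
    segment_instances,
    simulate_session,
    SimSessionConfig,
)

from conftest import random_trace


def labeled_trace(fall_pattern, rate_hz=31.25):
    n = len(fall_pattern)
    return AccelTrace(
        t=np.arange(n) / rate_hz,
        acc=np.tile([0.0, 0.0, 1.0], (n, 1)),
        fall=np.asarray(fall_pattern, dtype=bool),
        rate_hz=rate_hz,
    )


class TestSegmentation:
    def test_fall_run_and_tiled_adls(self):
        tr = labeled_trace([False] * 40 + [True] * 20 + [False] * 40)
        inst = segment_instances(tr)
        assert inst.falls == [(40, 60)]
        # each 40-sample NotFall stretch holds one 31-sample tile
        assert inst.adls == [(0, 31), (60, 91)]

    def test_all_notfall_tiling_drops_partial(self):
        tr = labeled_trace([False] * 93)
        inst = segment_instances(tr)
        assert inst.n_falls == 0
        assert inst.adls == [(0, 31), (31, 62), (62, 93)]

    def test_empty_trace_empty_instances(self):
        tr = AccelTrace(t=np.zeros(0), acc=np.zeros((0, 3)),
                        fall=np.zeros(0, bool), rate_hz=31.25)
        inst = segment_instances(tr)
        assert inst.n_falls == 0 and inst.n_adls == 0

    def test_tagged_segments_used_when_present(self, session_trace):
        inst = segment_instances(session_trace)
        # one ADL instance per scripted activity segment
        assert inst.n_adls == 6
        assert all(name != "" for name in inst.adl_names)

    def test_tag_mode_can_be_forced_off(self, session_trace):
        tiled = segment_instances(session_trace, use_tags=False)
        assert tiled.n_adls > 6  # 1-second tiles outnumber segments


class TestMatching:
    def test_event_inside_fall_run_is_tp(self):
        tr = labeled_trace([False] * 40 + [True] * 20 + [False] * 40)
        inst = segment_instances(tr)
        c = match_events([DetectionEvent(45, 55)], inst, tr)
        assert (c.tp, c.fp, c.fn, c.tn) == (1, 0, 0, 2)

    def test_event_inside_adl_tile_is_fp_and_kills_tn(self):
        tr = labeled_trace([False] * 40 + [True] * 20 + [False] * 40)
        inst = segment_instances(tr)
        c = match_events([DetectionEvent(5, 12)], inst, tr)
        assert c.fp == 1
        assert c.fn == 1          # the fall was never detected
        assert c.tn == 1          # the touched tile is no longer a TN

    def test_no_events_counts_misses_and_tns(self):
        tr = labeled_trace([False] * 40 + [True] * 20 + [False] * 40)
        inst = segment_instances(tr)
        c = match_events([], inst, tr)
        assert (c.tp, c.fp, c.fn, c.tn) == (0, 0, 1, 2)

    def test_extra_events_on_same_fall_ignored(self):
        tr = labeled_trace([False] * 40 + [True] * 30 + [False] * 40)
        inst = segment_instances(tr)
        c = match_events(
            [DetectionEvent(42, 50), DetectionEvent(55, 65)], inst, tr
        )
        assert (c.tp, c.fp) == (1, 0)

    def test_out_of_bounds_event_rejected(self):
        tr = labeled_trace([True] * 10)
        with pytest.raises(ValueError, match="outside"):
            match_events([DetectionEvent(5, 20)], segment_instances(tr), tr)

    def test_count_conservation(self, rng):
        for _ in range(20):
            tr = labeled_trace(rng.random(300) < 0.2)
            inst = segment_instances(tr)
            events = []
            for _ in range(rng.integers(0, 6)):
                s = int(rng.integers(0, 290))
                events.append(DetectionEvent(s, s + int(rng.integers(1, 10))))
            c = match_events(events, inst, tr)
            assert c.tp + c.fn == inst.n_falls
            assert c.tn <= inst.n_adls


class TestMetrics:
    def test_perfect_single_detection(self):
        r = compute_metrics(OutcomeCounts(tp=1, fp=0, fn=0, tn=0))
        assert r.precision == 1 and r.recall == 1

    def test_all_misses_zero_recall(self):
        r = compute_metrics(OutcomeCounts(tp=0, fp=0, fn=5, tn=0))
        assert r.recall == 0

    def test_mixed_counts_formulas(self):
        r = compute_metrics(OutcomeCounts(tp=43, fp=25, fn=7, tn=100))
        assert r.recall == pytest.approx(0.86)
        assert r.precision == pytest.approx(43 / 68)
        assert r.overall_accuracy == pytest.approx(143 / 175)

    def test_undefined_ratios_are_absent_not_zero(self):
        r = compute_metrics(OutcomeCounts(tp=0, fp=0, fn=0, tn=3))
        assert r.precision is None
        assert r.recall is None
        assert r.overall_accuracy == 1.0

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError, match="non-negative"):
            compute_metrics(OutcomeCounts(tp=-1, fp=0, fn=0, tn=0))

    def test_hand_computed_random_confusion_matrices(self, rng):
        for _ in range(20):
            tp, fp, fn, tn = (int(x) for x in rng.integers(0, 50, size=4))
            r = compute_metrics(OutcomeCounts(tp, fp, fn, tn))
            if tp + fp:
                assert r.precision == tp / (tp + fp)
            else:
                assert r.precision is None
            if tp + fn:
                assert r.recall == tp / (tp + fn)
            else:
                assert r.recall is None
            if tp + fp + fn + tn:
                assert r.overall_accuracy == (tp + tn) / (tp + fp + fn + tn)


@pytest.fixture(scope="module")
def files():
    return [
        simulate_session(
            SimSessionConfig(falls_per_type=1, n_adls=4, seed=40 + s)
        )
        for s in range(3)
    ]


class TestSplits:

    def test_leave_one_out_runs_one_fold_per_file(self, files):
        det = ClassicFallDetector(model="nb")
        report, folds = evaluate_split(
            files, det, split="leave_one_file_out", seed=0, return_folds=True
        )
        assert len(folds) == 3
        total = folds[0] + folds[1] + folds[2]
        assert (report.tp, report.fp, report.fn, report.tn) == (
            total.tp, total.fp, total.fn, total.tn
        )

    def test_same_seed_identical_report(self, files):
        det = ClassicFallDetector(model="nb")
        r1 = evaluate_split(files, det, seed=5)
        r2 = evaluate_split(files, det, seed=5)
        assert r1.as_dict() == r2.as_dict()

    def test_holdout_trains_on_two_thirds(self, files):
        det = ClassicFallDetector(model="nb")
        report = evaluate_split(files, det, split="two_thirds_holdout",
                                seed=0)
        assert report.tp + report.fn == 4  # falls of the single held-out file

    def test_leave_one_out_needs_two_files(self, files):
        with pytest.raises(ValueError, match="2 files"):
            evaluate_split(files[:1], ClassicFallDetector(),
                           split="leave_one_file_out")

    def test_metrics_in_unit_interval(self, files):
        report = evaluate_split(files, ClassicFallDetector(model="nb"),
                                seed=1)
        for v in (report.precision, report.recall, report.overall_accuracy,
                  report.adl_accuracy, report.fall_accuracy):
            if v is not None:
                assert 0 <= v <= 1
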