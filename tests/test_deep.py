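"""GRU detector: network contracts, BPTT gradients, heuristic properties."""

import numpy as np
import pytest

from wristfall import (
    GruConfig,
    GRUFallDetector,
    ProbabilityStream,
    build_gru_model,
    heuristic_decision,
    windows_from_trace,
)
from wristfall import _gru
from wristfall.synthetic import SimSessionConfig, simulate_session

from conftest import random_trace


def make_window_data(n_per_class=80, steps=40, seed=0):
    """Separable raw windows: falls contain a large transient."""
    rng = np.random.default_rng(seed)
    quiet = rng.normal(0, 0.1, size=(n_per_class, steps, 3))
    quiet[:, :, 2] += 1.0
    falls = rng.normal(0, 0.1, size=(n_per_class, steps, 3))
    falls[:, :, 2] += 1.0
    for w in falls:
        c = rng.integers(10, steps - 5)
        w[c:c + 4, 2] += rng.uniform(3.5, 5.0)
    X = np.vstack([quiet, falls])
    y = np.array([False] * n_per_class + [True] * n_per_class)
    perm = rng.permutation(len(y))
    return X[perm], y[perm]


class TestNetworkContracts:
    def test_softmax_outputs_sum_to_one(self, rng):
        model = build_gru_model(GruConfig(seed=1))
        X = rng.normal(0, 1, size=(5, 40, 3))
        probs = model.predict_proba(X)
        assert np.allclose(probs.sum(axis=1), 1.0)
        assert (probs >= 0).all()

    def test_zero_weights_give_symmetric_output(self):
        model = build_gru_model(GruConfig(seed=0))
        for k in model.params_:
            model.params_[k][:] = 0.0
        probs = model.predict_proba(np.ones((3, 40, 3)))
        assert np.allclose(probs, 0.5)

    def test_same_seed_identical_initial_parameters(self):
        a = build_gru_model(GruConfig(seed=7))
        b = build_gru_model(GruConfig(seed=7))
        for k in a.params_:
            assert np.array_equal(a.params_[k], b.params_[k])

    def test_invalid_config_rejected(self):
        with pytest.raises(ValueError):
            GruConfig(steps_n=0)
        with pytest.raises(ValueError):
            GruConfig(threshold=1.5)
        with pytest.raises(ValueError):
            GruConfig(gru_units=0)

    def test_window_duration_at_defaults(self):
        assert GruConfig().window_duration_s == pytest.approx(1.28)


class TestGradients:
    def test_bptt_gradients_match_finite_differences(self):
        rng = np.random.default_rng(0)
        p = _gru.init_params(3, 4, 3, rng)
        X = rng.normal(0, 1, (3, 6, 3))
        y = np.array([0, 1, 1])
        w = np.array([1.0, 2.0, 0.5])
        _, grads = _gru.loss_and_grads(p, X, y, w)
        eps = 1e-6
        worst = 0.0
        for k in p:
            flat = p[k].ravel()
            gflat = grads[k].ravel()
            for i in range(flat.size):
                orig = flat[i]
                flat[i] = orig + eps
                lp, _ = _gru.loss_and_grads(p, X, y, w)
                flat[i] = orig - eps
                lm, _ = _gru.loss_and_grads(p, X, y, w)
                flat[i] = orig
                num = (lp - lm) / (2 * eps)
                denom = max(abs(num), abs(gflat[i]), 1e-8)
                worst = max(worst, abs(num - gflat[i]) / denom)
        assert worst < 1e-3


class TestTraining:
    def test_loss_decreases_over_first_epochs(self):
        X, y = make_window_data(seed=1)
        det = GRUFallDetector(epochs=5, random_state=1).fit(X, y)
        assert det.history_[-1] < det.history_[0]

    def test_separable_windows_learned(self):
        X, y = make_window_data(seed=2)
        det = GRUFallDetector(epochs=15, learning_rate=3e-3,
                              random_state=2).fit(X, y)
        recall = (det.predict(X) & y).sum() / y.sum()
        assert recall >= 0.9

    def test_identical_seed_reproduces_final_loss(self):
        X, y = make_window_data(n_per_class=40, seed=3)
        d1 = GRUFallDetector(epochs=3, random_state=9).fit(X, y)
        d2 = GRUFallDetector(epochs=3, random_state=9).fit(X, y)
        assert d1.history_ == d2.history_

    def test_single_class_rejected(self):
        X, _ = make_window_data(n_per_class=10)
        with pytest.raises(ValueError, match="both classes"):
            GRUFallDetector(epochs=1).fit(X, np.zeros(len(X), bool))


@pytest.fixture(scope="module")
def fitted():
    X, y = make_window_data(seed=4)
    return GRUFallDetector(epochs=8, random_state=4).fit(X, y)


class TestPrediction:

    def test_stream_length_and_range(self, fitted):
        tr = random_trace(200, seed=1)
        ps = fitted.predict_stream(tr)
        assert len(ps) == 200 - 40 + 1
        assert ps.offset == 39
        assert ((ps.probs >= 0) & (ps.probs <= 1)).all()

    def test_sliding_equals_per_window_recomputation(self, fitted):
        tr = random_trace(200, seed=2)
        ps = fitted.predict_stream(tr)
        for i in range(0, len(ps), 17):
            window = tr.acc[i:i + 40][None, :, :]
            solo = fitted.predict_proba(window)[0, 1]
            assert ps.probs[i] == pytest.approx(solo, abs=1e-12)

    def test_short_trace_rejected(self, fitted):
        with pytest.raises(ValueError, match="steps_n"):
            fitted.predict_stream(random_trace(30))

    def test_window_labels_come_from_final_sample(self):
        tr = random_trace(60, seed=5, fall_frac=0.3)
        X, y = windows_from_trace(tr, steps_n=40)
        assert np.array_equal(y, tr.fall[39:])
        assert np.array_equal(X[0], tr.acc[:40])


class TestHeuristic:
    def test_sustained_high_probability_triggers(self):
        events = heuristic_decision(np.ones(10))
        assert len(events) == 1
        assert (events[0].start_idx, events[0].end_idx) == (0, 10)

    def test_all_zero_probabilities_silent(self):
        assert heuristic_decision(np.zeros(30)) == []

    def test_exact_tie_triggers(self):
        p = np.array([0.9] * 5 + [0.1] * 5)
        assert len(heuristic_decision(p)) == 1

    def test_fewer_than_k_probabilities_rejected(self):
        with pytest.raises(ValueError, match="heuristic_k"):
            heuristic_decision(np.ones(5))

    def test_isolated_spike_suppressed(self):
        p = np.zeros(50)
        p[25] = 1.0
        assert heuristic_decision(p) == []

    def test_isolated_spikes_suppressed_over_random_streams(self, rng):
        cfg = GruConfig(threshold=0.2)
        for _ in range(200):
            p = np.zeros(60)
            p[rng.integers(0, 60)] = 1.0
            assert heuristic_decision(p, cfg) == []

    def test_raising_threshold_never_adds_events(self, rng):
        for trial in range(300):
            p = rng.random(rng.integers(10, 80))
            lo = heuristic_decision(p, GruConfig(threshold=0.4))
            hi = heuristic_decision(p, GruConfig(threshold=0.6))
            assert len(hi) <= len(lo)

    def test_raising_one_probability_keeps_detection(self, rng):
        for trial in range(200):
            p = rng.random(30)
            before = heuristic_decision(p)
            if not before:
                continue
            boosted = p.copy()
            boosted[rng.integers(0, 30)] = 1.0
            assert len(heuristic_decision(boosted)) >= 1

    def test_event_covers_k_final_indices_with_offset(self):
        ps = ProbabilityStream(probs=np.ones(12), offset=39)
        events = heuristic_decision(ps)
        assert events[0].start_idx == 39
        assert events[0].end_idx == 49

    def test_refractory_absorbs_back_to_back_triggers(self):
        p = np.ones(40)
        events = heuristic_decision(p, refractory_steps=31)
        assert len(events) == 1
        events = heuristic_decision(p, refractory_steps=5)
        assert len(events) > 1


class TestEndToEnd:
    def test_gru_detects_fall_in_synthetic_session(self):
        train = [
            simulate_session(SimSessionConfig(falls_per_type=2, n_adls=8,
                                              seed=s))
            for s in (31, 32)
        ]
        test = simulate_session(
            SimSessionConfig(falls_per_type=1, n_adls=4, seed=33)
        )
        det = GRUFallDetector(epochs=10, learning_rate=3e-3,
                              class_weight="balanced",
                              max_windows_per_class=3000, random_state=0)
        det.fit_traces(train, stride=2)
        events = det.detect_trace(test)
        hits = [
            e for e in events if test.fall[e.start_idx:e.end_idx].any()
        ]
        assert len(hits) >= 1
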