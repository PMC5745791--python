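"""Decision rule, artifact gates, AR modelling and the streaming decoder."""

import numpy as np
import pytest
from scipy.stats import norm

from smrbci.containers import Recording
from smrbci.online import (ARModel, ArtifactGateState, BlinkDetector,
                           DecisionConfig, OnlineDecoder, ar_fit, ar_gate,
                           blink_gate, calibrate, decide, estimate_bias)
from smrbci.synthetic import generate_resting, inject_artifacts
from smrbci.containers import LabelledSession

from conftest import small_config


def prob_stream(n, k=4, hot=None, p_hot=0.9):
    p = np.full((n, k), (1 - p_hot) / (k - 1) if hot is not None else 1.0 / k)
    if hot is not None:
        p[:, hot] = p_hot
    return p / p.sum(axis=1, keepdims=True)


CLASSES = ["HAND", "FEET", "SUB", "REST"]


class TestDecide:
    def test_unreachable_thresholds_emit_nothing(self):
        cfg = DecisionConfig({c: 1.01 for c in CLASSES})
        out = decide(prob_stream(512, hot=1), CLASSES, cfg, sfreq=128.0)
        assert all(c is None for c in out.commands())
        assert len(out.entries) > 0

    def test_constant_probability_emits_every_tick_after_burnin(self):
        cfg = DecisionConfig({c: 0.5 for c in CLASSES}, emit_rate=16.0)
        out = decide(prob_stream(4 * 128, hot=1), CLASSES, cfg, sfreq=128.0)
        assert all(c == "FEET" for c in out.commands())
        # ticks from 1 s to 4 s at 16 Hz
        assert len(out.entries) == (4 - 1) * 16 + 1
        assert out.entries[0][0] == pytest.approx(1.0, abs=0.01)

    def test_exact_tie_emits_none(self):
        p = np.zeros((256, 4))
        p[:, 0] = p[:, 1] = 0.45
        p[:, 2] = p[:, 3] = 0.05
        cfg = DecisionConfig({c: 0.3 for c in CLASSES})
        out = decide(p, CLASSES, cfg, sfreq=128.0)
        assert all(c is None for c in out.commands())

    def test_gate_forces_none(self):
        cfg = DecisionConfig({c: 0.5 for c in CLASSES})
        gate = np.zeros(512, dtype=bool)
        gate[200:300] = True
        out = decide(prob_stream(512, hot=0), CLASSES, cfg, sfreq=128.0,
                     gate_blocked=gate)
        for t, cmd, gated in out.entries:
            s = int(t * 128) - 1
            if gate[s]:
                assert cmd is None and gated
            else:
                assert cmd == "HAND"

    def test_rows_must_sum_to_one(self):
        cfg = DecisionConfig({c: 0.5 for c in CLASSES})
        with pytest.raises(ValueError, match="sum"):
            decide(np.full((100, 4), 0.3), CLASSES, cfg, sfreq=128.0)

    def test_causality_by_truncation(self):
        """Commands up to time T are unchanged if the future is removed."""
        rng = np.random.default_rng(0)
        p = rng.dirichlet(np.ones(4), size=1024)
        cfg = DecisionConfig({c: 0.3 for c in CLASSES})
        full = decide(p, CLASSES, cfg, sfreq=128.0)
        half = decide(p[:512], CLASSES, cfg, sfreq=128.0)
        assert full.entries[: len(half.entries)] == half.entries


class TestBlinkGate:
    def _resting(self, seed=0, duration=40.0):
        return generate_resting(small_config(seed=seed), duration)

    def test_false_block_rate_on_clean_resting(self):
        """Calibrated on the session's own opening rest (the protocol), the
        3-SD threshold blocks only the tail of the power distribution: the
        250 ms power of 1-10 Hz activity is roughly chi^2 with ~4.5 dof
        (2 x bandwidth x window), whose mean + 3 SD tail is ~1.5%."""
        stream = self._resting(seed=1, duration=100.0)
        sf = stream.sfreq
        head = Recording(stream.data[:, : int(40 * sf)], sf,
                         list(stream.channel_labels))
        det = BlinkDetector().fit(head)
        tail = Recording(stream.data[:, int(40 * sf):], sf,
                         list(stream.channel_labels))
        blocked, _ = blink_gate(tail, det)
        assert blocked.mean() <= 0.03

    def test_injected_blink_detected(self):
        det = BlinkDetector().fit(self._resting(seed=3))
        stream = self._resting(seed=4, duration=30.0)
        sess = LabelledSession(stream, [], [], (0, stream.n_samples))
        sess = inject_artifacts(sess, [12.0], [], blink_amplitude=200.0)
        blocked, intervals = blink_gate(sess.recording, det)
        a, b, _ = sess.artifact_intervals[0]
        assert any(lo < b and hi > a for lo, hi in intervals)

    def test_uncalibrated_or_degenerate_raises(self):
        stream = self._resting(seed=5, duration=5.0)
        with pytest.raises(ValueError):
            blink_gate(stream, BlinkDetector())
        flat = Recording(np.zeros((1, 1000)), 128.0, ["AFz"])
        with pytest.raises(ValueError):
            BlinkDetector().fit(flat)

    def test_missing_electrode(self):
        det = BlinkDetector(electrode="AFz")
        rec = Recording(np.random.default_rng(0).standard_normal((1, 4000)),
                        128.0, ["Cz"])
        with pytest.raises(ValueError, match="AFz"):
            det.fit(rec)


class TestARFit:
    def test_recovers_ar2_coefficients(self):
        """Textbook AR(2) with a = (0.75, -0.5): Yule-Walker recovery."""
        rng = np.random.default_rng(6)
        n = 60_000
        x = np.zeros(n)
        e = rng.standard_normal(n)
        for t in range(2, n):
            x[t] = 0.75 * x[t - 1] - 0.5 * x[t - 2] + e[t]
        rec = Recording(x[None, 2000:], 128.0, ["a"])
        m = ar_fit(rec, order=10)
        assert abs(m.coeffs[0, 0] - 0.75) < 0.05
        assert abs(m.coeffs[0, 1] - (-0.5)) < 0.05
        assert np.all(np.abs(m.coeffs[0, 2:]) < 0.05)

    def test_white_noise_coefficients_near_zero(self):
        rng = np.random.default_rng(7)
        rec = Recording(rng.standard_normal((1, 20_000)), 128.0, ["a"])
        m = ar_fit(rec, order=10)
        assert np.all(np.abs(m.coeffs) < 2.0 / np.sqrt(20_000) + 0.02)
        assert abs(m.error_sd[0] - 1.0) < 0.05

    def test_determinism_and_short_input(self):
        rng = np.random.default_rng(8)
        rec = Recording(rng.standard_normal((2, 5000)), 128.0, ["a", "b"])
        m1, m2 = ar_fit(rec), ar_fit(rec)
        np.testing.assert_array_equal(m1.coeffs, m2.coeffs)
        with pytest.raises(ValueError, match="short"):
            ar_fit(Recording(np.zeros((1, 500)), 128.0, ["a"]), order=10)


class TestARGate:
    def _model_and_stream(self, seed=0, duration=60.0):
        cfg = small_config(seed=seed)
        rest = generate_resting(cfg, 40.0)
        model = ar_fit(rest, order=10)
        stream = generate_resting(cfg, duration, seed=seed + 100)
        return model, stream

    def test_false_block_rate_union_bounded(self):
        model, stream = self._model_and_stream(seed=9)
        blocked, _, _ = ar_gate(stream, model, adapt_memory=None)
        per_sample_bound = 2 * norm.sf(3.0) * stream.n_channels
        assert blocked.mean() <= 2.0 * per_sample_bound + 0.01

    def test_step_artifact_blocks_within_50ms(self):
        model, stream = self._model_and_stream(seed=10, duration=30.0)
        sess = LabelledSession(stream, [], [], (0, stream.n_samples))
        sess = inject_artifacts(sess, [], [15.0], step_amplitude=80.0)
        blocked, intervals, _ = ar_gate(sess.recording, model, adapt_memory=None)
        onsets = [lo for lo, hi in intervals if 14.9 < lo < 15.1]
        assert onsets and min(abs(o - 15.0) for o in onsets) <= 0.05

    def test_adaptation_tracks_slow_drift(self):
        """x2 amplitude drift over the stream: with adaptation the block
        rate at the end stays within 2x of the rate at the start."""
        model, stream = self._model_and_stream(seed=11, duration=120.0)
        ramp = np.linspace(1.0, 2.0, stream.n_samples)
        drifted = Recording(stream.data * ramp[None, :], stream.sfreq,
                            list(stream.channel_labels))
        blocked, _, _ = ar_gate(drifted, model, adapt_memory=20.0)
        n = stream.n_samples
        start = blocked[: n // 4].mean()
        end = blocked[-n // 4:].mean()
        assert end <= max(2.0 * start, 0.02)


@pytest.fixture(scope="module")
def decoder_setup(calib_session, code_map):
    cfg, sess = calib_session
    decoder, bias, ts = calibrate(sess, cfg.class_set, code_map,
                                  scheme=(2, 4), seed=0)
    return cfg, sess, decoder, bias


class TestBiasAndDecoder:
    def test_bias_estimate_deterministic(self, calib_trials):
        b1 = estimate_bias(calib_trials, scheme=(1, 4), seed=5)
        b2 = estimate_bias(calib_trials, scheme=(1, 4), seed=5)
        np.testing.assert_array_equal(b1.mean, b2.mean)
        assert b1.suggested_thresholds == b2.suggested_thresholds
        assert np.all(b1.var >= 0)

    def test_suggested_thresholds_reasonable(self, decoder_setup):
        _, _, _, bias = decoder_setup
        for c, th in bias.suggested_thresholds.items():
            assert 0.0 < th <= 1.0

    def test_streaming_matches_batch(self, decoder_setup):
        """Feeding a stream in blocks equals feeding it at once."""
        cfg, sess, decoder, _ = decoder_setup
        stream = generate_resting(cfg, 6.0, seed=77)
        import copy

        d1 = copy.deepcopy(decoder)
        d2 = copy.deepcopy(decoder)
        full = d1.process(stream.data)
        parts = []
        k = 0
        for size in [100, 7, 301, 64, 200]:
            parts += d2.process(stream.data[:, k:k + size]).entries
            k += size
        parts += d2.process(stream.data[:, k:]).entries
        assert full.entries == parts

    def test_gate_soundness_in_stream(self, decoder_setup):
        """Commands are none whenever the gate is active (blink injected)."""
        cfg, sess, decoder, _ = decoder_setup
        import copy

        stream = generate_resting(cfg, 10.0, seed=78)
        s2 = LabelledSession(stream, [], [], (0, stream.n_samples))
        s2 = inject_artifacts(s2, [5.0], [], blink_amplitude=300.0)
        out = copy.deepcopy(decoder).process(s2.recording.data)
        gated = [e for e in out.entries if e[2]]
        assert gated, "blink should trigger the gate at some tick"
        assert all(cmd is None for _, cmd, g in out.entries if g)
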