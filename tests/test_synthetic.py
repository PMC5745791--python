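"""Generator properties: determinism, spectral shape, ERD ground truth,
paradigm timing, artifact injection."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal

from smrbci.containers import LabelledSession, Recording
from smrbci.synthetic import (LAPLACIAN_NEIGHBOURS, ParadigmSpec, SimConfig,
                              Source, generate_calibration_session,
                              generate_race_stream, generate_resting,
                              inject_artifacts)

from conftest import small_config


def welch_band_power(x: np.ndarray, sfreq: float, band: tuple) -> float:
    f, p = signal.welch(x, fs=sfreq, nperseg=min(len(x), int(2 * sfreq)))
    m = (f >= band[0]) & (f <= band[1])
    return float(np.trapezoid(p[m], f[m]))


class TestResting:
    def test_determinism(self):
        cfg = small_config(seed=7)
        a = generate_resting(cfg, 5.0)
        b = generate_resting(cfg, 5.0)
        np.testing.assert_array_equal(a.data, b.data)

    def test_zero_noise_no_sources_is_silent(self):
        cfg = small_config(seed=1, noise_sd=0.0, sources=[],
                           erd_depth={c: {} for c in ["HAND", "FEET", "SUB", "REST"]},
                           mixing_matrix=np.zeros((0, 16)))
        rec = generate_resting(cfg, 2.0)
        assert np.all(rec.data == 0)

    def test_length_and_invalid_duration(self):
        cfg = small_config(seed=2)
        rec = generate_resting(cfg, 3.5)
        assert rec.n_samples == int(3.5 * cfg.sampling_rate)
        with pytest.raises(ValueError):
            generate_resting(cfg, 0.0)

    def test_background_spectral_slope(self):
        """Welch log-log slope of the 1/f background within 20% of target.

        Fitted outside the oscillatory bands (8-30 Hz) where the idling
        rhythms sit on top of the background.
        """
        cfg = SimConfig(seed=3, background_slope=1.0)
        rec = generate_resting(cfg, 60.0)
        f, p = signal.welch(rec.data[rec.index("O1")], fs=cfg.sampling_rate,
                            nperseg=4096)
        m = ((f >= 1.0) & (f <= 6.0)) | ((f >= 35.0) & (f <= 60.0))
        slope = -np.polyfit(np.log(f[m]), np.log(p[m]), 1)[0]
        assert abs(slope - cfg.background_slope) < 0.2 * cfg.background_slope


class TestCalibration:
    def test_counts_and_balance(self, calib_session):
        cfg, sess = calib_session
        assert len(sess.events) == 40  # 10 TPC x 4 classes
        assert len(sess.labels) == 40
        for c in cfg.class_set:
            assert sess.labels.count(c) == 10

    def test_event_monotonic_and_timing(self, calib_session):
        cfg, sess = calib_session
        samples = [s for s, _ in sess.events]
        gaps = np.diff(samples) / cfg.sampling_rate
        # pre(3) + imagery(5) + break in [2, 3]
        assert np.all(gaps >= 10.0 - 1e-6)
        assert np.all(gaps <= 11.0 + 1e-6)
        assert sess.rest_segment == (0, int(30 * cfg.sampling_rate))

    def test_unknown_class_raises(self):
        cfg = small_config(seed=4)
        cfg.class_set = ["HAND", "NOSUCH"]
        with pytest.raises(ValueError, match="NOSUCH"):
            generate_calibration_session(cfg, 2)

    def test_erd_power_ratio_matches_depth(self):
        """-0.5 power modulation over the C4 area shows up at C4 as a
        Welch band-power ratio of ~0.5 imagery vs baseline."""
        channels = ["C4"] + LAPLACIAN_NEIGHBOURS["C4"] + ["AFz"]
        src = [Source("mu_C4", (8.0, 16.0), 10.0)]
        M = np.zeros((1, len(channels)))
        M[0, 0] = 1.0
        M[0, 1:5] = 0.5
        cfg = SimConfig(sampling_rate=128.0, channel_labels=channels,
                        class_set=["HAND", "REST"], sources=src,
                        erd_depth={"HAND": {"mu_C4": -0.5}, "REST": {}},
                        mixing_matrix=M, seed=5)
        sess = generate_calibration_session(cfg, 20)
        sf = cfg.sampling_rate
        c4 = sess.recording.data[0]
        imagery, baseline = [], []
        for (samp, code), lab in zip(sess.events, sess.labels):
            if lab != "HAND":
                continue
            # skip the 250 ms ramp at the window edges
            imagery.append(c4[samp + int(0.5 * sf): samp + int(4.5 * sf)])
            baseline.append(c4[samp - int(2.5 * sf): samp - int(0.5 * sf)])
        p_im = welch_band_power(np.concatenate(imagery), sf, (8, 16))
        p_bl = welch_band_power(np.concatenate(baseline), sf, (8, 16))
        assert abs(p_im / p_bl - 0.5) < 0.1

    def test_null_depth_no_class_difference(self):
        cfg = small_config(seed=6)
        cfg.erd_depth = {c: {} for c in cfg.class_set}
        sess = generate_calibration_session(cfg, 12)
        sf = cfg.sampling_rate
        c3 = sess.recording.data[0]
        powers = {c: [] for c in cfg.class_set}
        for (samp, _), lab in zip(sess.events, sess.labels):
            seg = c3[samp: samp + int(4 * sf)]
            powers[lab].append(np.mean(seg ** 2))
        means = {c: np.mean(v) for c, v in powers.items()}
        ses = {c: np.std(v) / np.sqrt(len(v)) for c, v in powers.items()}
        for a in cfg.class_set:
            for b in cfg.class_set:
                if a < b:
                    tol = 2 * np.hypot(ses[a], ses[b])
                    assert abs(means[a] - means[b]) < 2 * tol


class TestRaceStream:
    def test_pad_events_and_rest_pads(self):
        cfg = small_config(seed=8)
        sess = generate_race_stream(cfg, ["HAND", "REST", "FEET", "REST"])
        assert len(sess.events) == 4
        samples = [s for s, _ in sess.events]
        assert samples == sorted(samples)
        # pads are 10 s apart after a 30 s resting lead-in
        assert np.allclose(np.diff(samples), 10 * cfg.sampling_rate)
        assert samples[0] == int(30 * cfg.sampling_rate)

    def test_task_modulation_first_half_only(self):
        """HAND pad: C3 mu power suppressed in the first 5 s, back to
        baseline in the second 5 s; REST pad unmodulated throughout."""
        cfg = small_config(seed=9)
        sess = generate_race_stream(cfg, ["HAND", "REST"] * 3)
        sf = cfg.sampling_rate
        c3 = sess.recording.data[0]
        rest_ref = welch_band_power(sess.resting().data[0], sf, (8, 16))

        def pad_power(i, half):
            s0 = sess.events[i][0] + int((0.5 + 5.0 * half) * sf)
            return welch_band_power(c3[s0: s0 + int(4 * sf)], sf, (8, 16))

        hand_task = np.mean([pad_power(i, 0) for i in (0, 2, 4)])
        hand_break = np.mean([pad_power(i, 1) for i in (0, 2, 4)])
        rest_all = np.mean([pad_power(i, h) for i in (1, 3, 5) for h in (0, 1)])
        assert hand_task / rest_ref < 0.75
        assert abs(hand_break / rest_ref - 1.0) < 0.3
        assert abs(rest_all / rest_ref - 1.0) < 0.3

    def test_empty_track_raises(self):
        with pytest.raises(ValueError):
            generate_race_stream(small_config(), [])


class TestArtifacts:
    def test_empty_injection_is_identity(self):
        cfg = small_config(seed=10)
        rec = generate_resting(cfg, 4.0)
        sess = LabelledSession(rec, [], [], (0, rec.n_samples))
        out = inject_artifacts(sess, [], [])
        np.testing.assert_array_equal(out.recording.data, rec.data)

    def test_zero_amplitude_blink_unchanged(self):
        cfg = small_config(seed=11)
        rec = generate_resting(cfg, 4.0)
        sess = LabelledSession(rec, [], [], (0, rec.n_samples))
        out = inject_artifacts(sess, [2.0], [], blink_amplitude=0.0)
        np.testing.assert_allclose(out.recording.data, rec.data, atol=1e-12)

    def test_blink_bandpower_oracle(self):
        """A 200 uV blink at t=10 s lifts AFz 1-10 Hz power in a 0.5 s
        window more than 3 SD above the resting distribution."""
        cfg = small_config(seed=12)
        rec = generate_resting(cfg, 20.0)
        sess = LabelledSession(rec, [], [], (0, rec.n_samples))
        out = inject_artifacts(sess, [10.0], [], blink_amplitude=200.0)
        sf = cfg.sampling_rate
        sos = signal.butter(4, (1, 10), btype="bandpass", fs=sf, output="sos")
        afz = signal.sosfilt(sos, out.recording.data[out.recording.index("AFz")])
        win = int(0.5 * sf)
        powers = (afz[: rec.n_samples // win * win] ** 2).reshape(-1, win).mean(axis=1)
        blink_win = powers[int(10 * sf) // win]
        rest = np.delete(powers, int(10 * sf) // win)
        assert blink_win > rest.mean() + 3 * rest.std()
        assert out.artifact_intervals and out.artifact_intervals[0][2] == "blink"

    def test_out_of_range_time_raises(self):
        cfg = small_config(seed=13)
        rec = generate_resting(cfg, 4.0)
        sess = LabelledSession(rec, [], [], (0, rec.n_samples))
        with pytest.raises(ValueError):
            inject_artifacts(sess, [99.0], [])


class TestProperties:
    def test_mixing_linearity(self):
        """Doubling a source's mixing weights doubles its channel RMS."""
        from conftest import two_source_config

        cfg = two_source_config(seed=14)
        cfg.noise_sd = 0.0
        rec1 = generate_resting(cfg, 5.0)
        cfg2 = two_source_config(seed=14)
        cfg2.noise_sd = 0.0
        cfg2.mixing_matrix = cfg.mixing_matrix * 2.0
        rec2 = generate_resting(cfg2, 5.0)
        r1 = np.sqrt(np.mean(rec1.data ** 2))
        r2 = np.sqrt(np.mean(rec2.data ** 2))
        assert abs(r2 / r1 - 2.0) < 0.02

    @settings(max_examples=10, deadline=None, derandomize=True)
    @given(tpc=st.integers(1, 4), seed=st.integers(0, 10_000))
    def test_label_balance_property(self, tpc, seed):
        cfg = SimConfig(sampling_rate=64.0, channel_labels=["C3", "Cz"],
                        class_set=["A", "B"], sources=[],
                        erd_depth={"A": {}, "B": {}},
                        mixing_matrix=np.zeros((0, 2)), noise_sd=1.0, seed=seed)
        sess = generate_calibration_session(
            cfg, tpc, ParadigmSpec(rest_duration=2.0))
        assert sess.labels.count("A") == tpc
        assert sess.labels.count("B") == tpc
        assert len(sess.events) == 2 * tpc

    def test_erd_depth_validation(self):
        with pytest.raises(ValueError, match="-1"):
            SimConfig(erd_depth={"HAND": {"mu_C3": -1.2}})
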