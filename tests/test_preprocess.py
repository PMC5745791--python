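"""Filter responses, Laplacian derivations, segmentation and rejection."""

import warnings

import numpy as np
import pytest
from scipy import signal

from smrbci.containers import Recording, TrialSet
from smrbci.preprocess import (FilterSpec, butter_filter, laplacian,
                               reject_outlier_trials, segment,
                               variance_normalize)
from smrbci.synthetic import generate_calibration_session

from conftest import small_config


def sine_recording(freq, sfreq=512.0, duration=4.0, n_ch=1, labels=None):
    t = np.arange(int(duration * sfreq)) / sfreq
    data = np.tile(np.sin(2 * np.pi * freq * t), (n_ch, 1))
    labels = labels or [f"ch{i}" for i in range(n_ch)]
    return Recording(data, sfreq, labels)


class TestButterFilter:
    def test_notch_kills_50hz(self):
        rec = sine_recording(50.0)
        out = butter_filter(rec, FilterSpec("notch", 50.0))
        steady = out.data[0, 1024:]
        assert np.sqrt(np.mean(steady ** 2)) < 0.01 * np.sqrt(0.5)

    @pytest.mark.parametrize("band,expect_pass", [((8, 16), True), ((16, 30), False)])
    def test_passband_vs_stopband_gain(self, band, expect_pass):
        """10 Hz tone: near-unity gain in 8-16 Hz, > 20 dB down in 16-30 Hz.

        Cross-checked against the analytic Butterworth magnitude response.
        """
        rec = sine_recording(10.0, duration=8.0)
        out = butter_filter(rec, FilterSpec("bandpass", band, 4, "causal"))
        steady = out.data[0, 2048:]
        gain = np.sqrt(np.mean(steady ** 2)) / np.sqrt(0.5)
        sos = signal.butter(4, band, btype="bandpass", fs=512.0, output="sos")
        _, h = signal.sosfreqz(sos, worN=[10.0], fs=512.0)
        analytic = np.abs(h[0])
        assert abs(gain - analytic) < 0.02
        if expect_pass:
            assert 0.9 <= gain <= 1.001
        else:
            assert 20 * np.log10(max(gain, 1e-12)) < -20

    def test_zero_in_zero_out_and_linearity(self):
        rng = np.random.default_rng(0)
        x = rng.standard_normal((2, 2048))
        y = rng.standard_normal((2, 2048))
        spec = FilterSpec("bandpass", (8, 30), 4, "causal")
        mk = lambda d: Recording(d, 512.0, ["a", "b"])
        fx = butter_filter(mk(x), spec).data
        fy = butter_filter(mk(y), spec).data
        fz = butter_filter(mk(3 * x - 2 * y), spec).data
        np.testing.assert_allclose(fz, 3 * fx - 2 * fy, atol=1e-9)
        assert np.all(butter_filter(mk(np.zeros_like(x)), spec).data == 0)

    def test_zero_phase_has_no_group_delay(self):
        rec = sine_recording(12.0, duration=4.0)
        out = butter_filter(rec, FilterSpec("bandpass", (8, 16), 4, "zero_phase"))
        mid = slice(512, 1536)
        xc = np.correlate(out.data[0, mid], rec.data[0, mid], "full")
        lag = np.argmax(xc) - (len(xc) // 2)
        assert lag == 0

    def test_band_beyond_nyquist_rejected(self):
        rec = sine_recording(10.0, sfreq=128.0)
        with pytest.raises(ValueError, match="Nyquist"):
            butter_filter(rec, FilterSpec("bandpass", (8, 70), 4, "causal"))

    def test_events_preserved(self):
        rec = sine_recording(10.0)
        rec.events = [(10, 1), (500, 2)]
        out = butter_filter(rec, FilterSpec("bandpass", (8, 16)))
        assert out.events == [(10, 1), (500, 2)]


class TestLaplacian:
    def test_common_mode_rejected(self):
        data = np.tile(np.arange(100.0), (5, 1))
        rec = Recording(data, 128.0, ["c", "n1", "n2", "n3", "n4"])
        out = laplacian(rec, "c", ["n1", "n2", "n3", "n4"])
        np.testing.assert_allclose(out.data, 0.0, atol=1e-12)

    def test_constant_arithmetic(self):
        data = np.vstack([np.full(50, 4.0)] + [np.full(50, 2.0)] * 4)
        rec = Recording(data, 128.0, ["c", "n1", "n2", "n3", "n4"])
        out = laplacian(rec, "c", ["n1", "n2", "n3", "n4"])
        np.testing.assert_allclose(out.data, 2.0)

    def test_focal_source_passes_common_source_cancelled(self):
        """With a known mixing matrix, a source hitting all 5 electrodes
        equally is removed; a centre-only source passes at gain 1."""
        rng = np.random.default_rng(1)
        s_focal = rng.standard_normal(1000)
        s_common = rng.standard_normal(1000)
        labels = ["c", "n1", "n2", "n3", "n4"]
        data = np.outer([1, 0, 0, 0, 0], s_focal) + np.outer(np.ones(5), s_common)
        rec = Recording(data, 128.0, labels)
        out = laplacian(rec, "c", labels[1:])
        np.testing.assert_allclose(out.data[0], s_focal, atol=1e-12)

    def test_missing_channel(self):
        rec = Recording(np.zeros((2, 10)), 128.0, ["a", "b"])
        with pytest.raises(KeyError):
            laplacian(rec, "a", ["b", "b", "b", "nope"])


class TestSegment:
    def test_counts_and_window(self, calib_session, code_map):
        cfg, sess = calib_session
        ts = segment(sess.recording, code_map, (-3.0, 5.0))
        assert ts.data.shape == (40, len(cfg.channel_labels),
                                 int(8 * cfg.sampling_rate))
        assert ts.time_axis[0] == pytest.approx(-3.0)
        np.testing.assert_allclose(np.diff(ts.time_axis), 1 / cfg.sampling_rate)

    def test_zero_cues_empty(self):
        rec = Recording(np.zeros((1, 1000)), 128.0, ["a"])
        ts = segment(rec, {1: "X"}, (-1.0, 1.0))
        assert ts.n_trials == 0

    def test_truncated_window_dropped_with_warning(self):
        rec = Recording(np.zeros((1, 5120)), 512.0, ["a"],
                        events=[(100, 1), (2000, 1)])
        with pytest.warns(UserWarning, match="truncated"):
            ts = segment(rec, {1: "X"}, (-3.0, 5.0))
        assert ts.n_trials == 1

    def test_segment_concat_roundtrip_bitexact(self):
        rng = np.random.default_rng(2)
        data = rng.standard_normal((2, 1000))
        events = [(100, 1), (300, 1), (500, 1)]
        rec = Recording(data, 100.0, ["a", "b"], events)
        ts = segment(rec, {1: "X"}, (0.0, 2.0))
        recon = np.concatenate([ts.data[i] for i in range(3)], axis=1)
        np.testing.assert_array_equal(recon, data[:, 100:700])


class TestRejection:
    def _clean_trials(self, n=20, seed=0):
        rng = np.random.default_rng(seed)
        data = rng.standard_normal((n, 3, 256)) * 10.0
        return TrialSet(data, np.arange(256) / 128.0, np.array(["X"] * n),
                        128.0, ["a", "b", "c"])

    def test_identical_clean_trials_none_rejected(self):
        ts = self._clean_trials()
        out = reject_outlier_trials(ts)
        assert out.kept_mask.all()

    def test_spike_trial_rejected(self):
        ts = self._clean_trials()
        ts.data[7, 1, 100] = 150.0
        out = reject_outlier_trials(ts)
        assert not out.kept_mask[7]
        assert out.kept_mask.sum() == ts.n_trials - 1

    def test_contamination_fraction_recovered(self):
        """~10% of trials contaminated -> ~10% rejected."""
        ts = self._clean_trials(n=50, seed=3)
        bad = [4, 17, 23, 31, 42]
        for i in bad:
            ts.data[i, 0, ::7] += 130.0
        out = reject_outlier_trials(ts)
        rejected = (~out.kept_mask).sum()
        assert rejected == len(bad)

    def test_too_few_trials_warns_and_passes_through(self):
        ts = self._clean_trials(n=4)
        with pytest.warns(UserWarning):
            out = reject_outlier_trials(ts)
        assert out.kept_mask.all()

    def test_never_rejects_majority_on_clean_data(self, calib_trials):
        out = reject_outlier_trials(calib_trials)
        assert out.kept_mask.sum() >= 0.5 * out.n_trials


class TestVarianceNormalize:
    def test_unit_resting_identity(self):
        rng = np.random.default_rng(4)
        rest = Recording(rng.standard_normal((2, 20000)), 128.0, ["a", "b"])
        rest.data /= rest.data.std(axis=1, keepdims=True)
        task = Recording(rng.standard_normal((2, 500)), 128.0, ["a", "b"])
        out = variance_normalize(task, rest)
        np.testing.assert_allclose(out.data, task.data)

    def test_scale_equivariance(self):
        rng = np.random.default_rng(5)
        rest = Recording(rng.standard_normal((2, 1000)), 128.0, ["a", "b"])
        task = Recording(rng.standard_normal((2, 500)), 128.0, ["a", "b"])
        out1 = variance_normalize(task, rest)
        rest10 = Recording(rest.data * 10, 128.0, ["a", "b"])
        task10 = Recording(task.data * 10, 128.0, ["a", "b"])
        out2 = variance_normalize(task10, rest10)
        np.testing.assert_allclose(out1.data, out2.data, atol=1e-12)

    def test_resting_sd_becomes_one(self):
        rng = np.random.default_rng(6)
        rest = Recording(rng.standard_normal((3, 2000)) * [[3.0], [0.5], [7.0]],
                         128.0, ["a", "b", "c"])
        out = variance_normalize(rest, rest)
        np.testing.assert_allclose(out.data.std(axis=1), 1.0, atol=1e-9)

    def test_zero_variance_names_channel(self):
        rest = Recording(np.vstack([np.zeros(100), np.ones(100) * 2]),
                         128.0, ["dead", "alive"])
        rest.data[1] += np.random.default_rng(0).standard_normal(100)
        task = Recording(np.ones((2, 50)), 128.0, ["dead", "alive"])
        with pytest.raises(ValueError, match="dead"):
            variance_normalize(task, rest)
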