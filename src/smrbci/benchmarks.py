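"""End-to-end evaluation experiments.

These routines wire the whole pipeline together for calibration studies
that are run repeatedly (seeded) rather than once: permutation tests of the
chance-level machinery, artifact-gate detection rates, and the closed-loop
race study in which a decoder calibrated on synthetic EEG races against the
random-input baseline.
"""

from __future__ import annotations

import numpy as np

from .classify import PipelineSpec, crossvalidate
from .containers import LabelledSession
from .game import RaceConfig, closed_loop_race, generate_track, random_baseline
from .online import calibrate
from .preprocess import segment
from .synthetic import (RaceStreamSimulator, SimConfig,
                        generate_calibration_session, generate_resting,
                        inject_artifacts)

__all__ = [
    "permutation_chance_experiment",
    "gate_detection_experiment",
    "closed_loop_experiment",
]


def permutation_chance_experiment(
    n_seeds: int = 100,
    trials_per_class: int = 8,
    seed: int = 0,
    config: SimConfig | None = None,
) -> dict:
    """Permuted-label cross-validation against the adjusted-Wald bound.

    One calibration session is generated; per seed the labels are permuted
    and a stratified CV (1 x 5) is run with in-fold CSP + sLDA.  Under the
    null the trial-majority accuracy should exceed the chance upper bound
    in at most ~alpha of the runs.
    """
    cfg = config or _small_default(seed)
    sess = generate_calibration_session(cfg, trials_per_class, seed=seed)
    code_map = {i + 1: c for i, c in enumerate(cfg.class_set)}
    ts = segment(sess.recording, code_map, (-3.0, 5.0))
    accs, curve_means, exceed, peak_exceed = [], [], 0, 0
    bound = None
    for k in range(n_seeds):
        rng = np.random.default_rng(seed + 1000 + k)
        permuted = ts.select(np.arange(ts.n_trials))
        permuted.labels = rng.permutation(permuted.labels)
        res = crossvalidate(permuted, list(cfg.class_set), scheme=(1, 5),
                            seed=seed + k)
        bound = res.chance.upper_bound
        accs.append(res.trial_accuracy)
        post = res.time_axis > 0
        curve_means.append(float(res.accuracy_curve[post].mean()))
        exceed += res.trial_accuracy > bound
        peak_exceed += res.peak[1] > bound
    return {
        # strict-majority voting over 4 classes sits below 1/k under the
        # null (plurality without absolute majority counts as incorrect)
        "mean_majority_accuracy": float(np.mean(accs)),
        "mean_curve_accuracy": float(np.mean(curve_means)),
        "chance_upper_bound": float(bound),
        "exceedance_rate": exceed / n_seeds,
        "peak_exceedance_rate": peak_exceed / n_seeds,
        "n_seeds": n_seeds,
        "n_trials": ts.n_trials,
    }


def gate_detection_experiment(seed: int = 0, n_blinks: int = 5,
                              n_steps: int = 5,
                              config: SimConfig | None = None) -> dict:
    """False-block rates on clean resting EEG and detection of injected
    200 uV blinks / 80 uV step artifacts by the two gates."""
    from .online import BlinkDetector, ar_fit, ar_gate, blink_gate

    cfg = config or _small_default(seed)
    rest = generate_resting(cfg, 60.0, seed=seed)
    sf = cfg.sampling_rate
    from .containers import Recording

    head = Recording(rest.data[:, : int(30 * sf)], sf, list(rest.channel_labels))
    tail = Recording(rest.data[:, int(30 * sf):], sf, list(rest.channel_labels))
    blink_det = BlinkDetector().fit(head)
    ar_model = ar_fit(head, order=10)
    fb_blink, _ = blink_gate(tail, blink_det)
    fb_ar, _, _ = ar_gate(tail, ar_model, adapt_memory=None)

    stream = generate_resting(cfg, 20.0 + 10.0 * max(n_blinks, n_steps),
                              seed=seed + 1)
    sess = LabelledSession(stream, [], [], (0, stream.n_samples))
    blink_times = [10.0 + 10.0 * i for i in range(n_blinks)]
    step_times = [15.0 + 10.0 * i for i in range(n_steps)]
    sess = inject_artifacts(sess, blink_times, step_times,
                            blink_amplitude=200.0, step_amplitude=80.0)
    det_blink, blink_ivals = blink_gate(sess.recording, blink_det)
    det_ar, ar_ivals, _ = ar_gate(sess.recording, ar_model, adapt_memory=None)

    def hit(t0, t1, ivals):
        return any(lo < t1 and hi > t0 for lo, hi in ivals)

    blink_hits = sum(hit(a, b, blink_ivals)
                     for a, b, k in sess.artifact_intervals if k == "blink")
    step_hits = sum(hit(a, b, ar_ivals)
                    for a, b, k in sess.artifact_intervals if k == "step")
    return {
        "blink_false_block_rate": float(fb_blink.mean()),
        "ar_false_block_rate": float(fb_ar.mean()),
        "blink_detection_rate": blink_hits / n_blinks,
        "step_detection_rate": step_hits / n_steps,
        "n_channels": cfg and len(cfg.channel_labels),
    }


def erds_null_experiment(n_sessions: int = 4, n_trials: int = 40,
                         n_boot: int = 400, alpha: float = 0.05,
                         seed: int = 0) -> dict:
    """Bootstrap false-positive fraction of the ERD/ERS mask on null data.

    White-noise trials carry no modulation, so significant bins are pure
    false positives; their fraction should sit near the nominal level.
    """
    from .containers import TrialSet
    from .erds import bootstrap_significance, compute_erds, default_bands

    fracs = []
    sfreq = 128.0
    n_s = int(8 * sfreq)
    t = np.arange(n_s) / sfreq - 3.0
    for k in range(n_sessions):
        rng = np.random.default_rng(seed + k)
        ts = TrialSet(rng.standard_normal((n_trials, 1, n_s)), t,
                      np.array(["X"] * n_trials), sfreq, ["c"])
        m = compute_erds(ts, default_bands(8, 28, 2, 2), decimate=32)
        m = bootstrap_significance(m, alpha=alpha, n_boot=n_boot, seed=seed + k)
        sl = m.time_axis > -1.5
        fracs.append(float(m.sig_mask[:, :, sl].mean()))
    return {
        "sig_fraction": float(np.mean(fracs)),
        "alpha": alpha,
        "n_bins": int(m.sig_mask[:, :, sl].size),
        "n_sessions": n_sessions,
        "n_trials": n_trials,
    }


def closed_loop_experiment(
    n_races: int = 100,
    trials_per_class_calib: int = 20,
    trials_per_class_race: int = 4,
    seed: int = 0,
    config: SimConfig | None = None,
    race_cfg: RaceConfig | None = None,
    n_baseline_runs: int = 500,
) -> dict:
    """Calibrate once on a synthetic session, then race repeatedly.

    Per race a fresh pseudorandom track and a fresh EEG stream are drawn;
    the decoder state is reset.  The significance threshold is the median
    runtime under uniformly random commands.
    """
    cfg = config or SimConfig(seed=seed)
    race_cfg = race_cfg or RaceConfig()
    sess = generate_calibration_session(cfg, trials_per_class_calib, seed=seed)
    code_map = {i + 1: c for i, c in enumerate(cfg.class_set)}
    decoder, bias, _ = calibrate(sess, list(cfg.class_set), code_map,
                                 scheme=(2, 5), seed=seed)
    baseline = random_baseline(
        {"trials_per_class": trials_per_class_race}, race_cfg,
        n_runs=n_baseline_runs, seed=seed + 1)

    runtimes, corrects, wrongs = [], [], []
    rng = np.random.default_rng(seed + 2)
    for i in range(n_races):
        track = generate_track(trials_per_class_race,
                               seed=int(rng.integers(2 ** 31)))
        stream = RaceStreamSimulator(cfg, max_duration=330.0,
                                     seed=int(rng.integers(2 ** 31)))
        decoder.reset()
        res = closed_loop_race(decoder, stream, track, race_cfg,
                               max_duration=320.0)
        runtimes.append(res.runtime)
        corrects.append(res.correct)
        wrongs.append(res.wrong)
    runtimes = np.array(runtimes)
    n_cmd = np.array(corrects) + np.array(wrongs)
    return {
        "baseline_median_runtime": float(baseline),
        "median_runtime": float(np.median(runtimes)),
        "mean_runtime": float(runtimes.mean()),
        "fraction_beating_baseline": float(np.mean(runtimes < baseline)),
        "correct_command_rate": float(np.sum(corrects) / max(np.sum(n_cmd), 1)),
        "n_races": n_races,
        "runtimes": runtimes.tolist(),
    }


def _small_default(seed: int) -> SimConfig:
    """Reduced montage for repeated-run experiments."""
    from .synthetic import LAPLACIAN_NEIGHBOURS

    channels = (["C3"] + LAPLACIAN_NEIGHBOURS["C3"]
                + ["Cz"] + LAPLACIAN_NEIGHBOURS["Cz"]
                + ["Pz", "P3", "P4", "AFz", "Fz", "O1"])
    return SimConfig(sampling_rate=128.0, channel_labels=channels, seed=seed)
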