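"""Time-frequency ERD/ERS maps with bootstrap significance masking.

Event-related desynchronization/synchronization quantifies band-power
change relative to a pre-cue reference interval:

    ERDS(f, t) = 100 * (A(f, t) - R(f)) / R(f)        [percent]

with A the trial-averaged, time-smoothed band power and R its mean over the
reference interval.  Negative values (ERD) mark power decreases during the
task, positive (ERS) increases.  The estimator is the Graz-style
bandpass-square-average: a causal Butterworth bandpass per frequency bin,
squaring, trial averaging and a short moving-average smoother.  Trials are
reflect-padded before filtering so the narrow-band filters are settled by
the reference interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .containers import TrialSet

__all__ = ["ERDSMap", "default_bands", "compute_erds", "bootstrap_significance"]


@dataclass
class ERDSMap:
    """values: channels x frequencies x times, percent change vs reference."""

    values: np.ndarray
    freq_axis: np.ndarray  # bin centre frequencies, Hz
    time_axis: np.ndarray  # s relative to cue
    channel_labels: list[str]
    reference: tuple[float, float]
    alpha: float = 0.05
    sig_mask: np.ndarray | None = None
    bands: list[tuple[float, float]] = field(default_factory=list)
    # retained for bootstrapping: per-trial smoothed power (decimated) and
    # per-trial reference power
    trial_power: np.ndarray | None = None  # trials x ch x f x t
    trial_ref: np.ndarray | None = None  # trials x ch x f


def default_bands(lo: float = 2.0, hi: float = 40.0, width: float = 2.0,
                  step: float = 1.0) -> list[tuple[float, float]]:
    """2 Hz-wide bins stepped by 1 Hz over 2-40 Hz."""
    starts = np.arange(lo, hi - width + 1e-9, step)
    return [(float(s), float(s + width)) for s in starts]


def _bandpower_timecourse(ts: TrialSet, bands, order: int,
                          smooth: float, pad: float = 2.0) -> np.ndarray:
    """trials x channels x bands x times smoothed instantaneous band power.

    Each trial is reflect-padded by ``pad`` seconds at its start so causal
    narrow-band filters have settled within the analysis window.
    """
    n_t, n_c, n_s = ts.data.shape
    n_pad = min(int(round(pad * ts.sfreq)), n_s - 1)
    x = np.concatenate([ts.data[:, :, n_pad:0:-1], ts.data], axis=2)
    out = np.empty((n_t, n_c, len(bands), n_s))
    win = max(int(round(smooth * ts.sfreq)), 1)
    for bi, band in enumerate(bands):
        sos = signal.butter(order, band, btype="bandpass", fs=ts.sfreq, output="sos")
        p = signal.sosfilt(sos, x, axis=2) ** 2
        cs = np.cumsum(p, axis=2)
        sm = np.empty_like(cs)
        sm[..., :win] = cs[..., :win] / np.arange(1, win + 1)
        sm[..., win:] = (cs[..., win:] - cs[..., :-win]) / win
        out[:, :, bi, :] = sm[..., n_pad:]
        del p, cs, sm
    return out


def compute_erds(
    ts: TrialSet,
    bands: list[tuple[float, float]] | None = None,
    reference: tuple[float, float] = (-2.0, -1.0),
    filter_order: int = 6,
    smooth: float = 0.25,
    decimate: int = 1,
) -> ERDSMap:
    """ERD/ERS map for every channel and frequency bin.

    ``reference`` must lie inside the trial window and end at or before the
    cue.  ``decimate`` keeps every k-th time sample of the map (the power
    estimate is computed at full rate first).
    """
    bands = bands if bands is not None else default_bands()
    lo, hi = reference
    if lo < ts.time_axis[0] or hi > ts.time_axis[-1]:
        raise ValueError("reference interval outside the trial window")
    if hi > 0:
        raise ValueError("reference interval must end at or before the cue")

    power = _bandpower_timecourse(ts, bands, filter_order, smooth)
    ref_sl = ts.window_slice(reference)
    trial_ref = power[:, :, :, ref_sl].mean(axis=3)  # trials x ch x f
    A = power.mean(axis=0)  # ch x f x t
    R = np.maximum(trial_ref.mean(axis=0), 1e-30)  # ch x f
    values = 100.0 * (A - R[:, :, None]) / R[:, :, None]

    sl = slice(None, None, max(int(decimate), 1))
    freq_axis = np.array([(a + b) / 2.0 for a, b in bands])
    return ERDSMap(
        values=values[:, :, sl],
        freq_axis=freq_axis,
        time_axis=ts.time_axis[sl],
        channel_labels=list(ts.channel_labels),
        reference=reference,
        bands=list(bands),
        trial_power=power[:, :, :, sl],
        trial_ref=trial_ref,
    )


def bootstrap_significance(
    erds_map: ERDSMap,
    ts: TrialSet | None = None,
    alpha: float = 0.05,
    n_boot: int = 1000,
    seed: int = 0,
) -> ERDSMap:
    """Percentile-t bootstrap mask: significant where the CI excludes 0.

    Trials are resampled with replacement and the whole map — including
    the reference power — is recomputed per resample.  The studentized
    statistic t* = (v* - v) / se* is collected per bin (se* via the
    per-trial values normalized by the resample's reference), and its
    percentiles invert to a confidence interval for the map value.
    ``ts`` is accepted for interface symmetry; the per-trial powers stored
    on the map are what is resampled.
    """
    if n_boot < 200:
        raise ValueError("n_boot must be >= 200 for stable percentiles")
    if not (0 < alpha <= 1):
        raise ValueError("alpha must be in (0, 1]")
    if erds_map.trial_power is None:
        raise ValueError("map carries no per-trial values; recompute with compute_erds")
    power = erds_map.trial_power  # trials x ch x f x t
    ref = erds_map.trial_ref  # trials x ch x f
    n = power.shape[0]
    shape = power.shape[1:]
    flat_p = power.reshape(n, -1)
    n_bins = flat_p.shape[1]
    # bin index -> (ch, f) reference index
    ref_idx = np.repeat(np.arange(ref.shape[1] * ref.shape[2]), power.shape[3])
    flat_r = ref.reshape(n, -1)

    def stat(idx):
        Rb = np.maximum(flat_r[idx].mean(axis=0), 1e-30)[ref_idx]
        w = 100.0 * (flat_p[idx] / Rb[None, :] - 1.0)
        v = w.mean(axis=0)
        se = np.maximum(w.std(axis=0, ddof=1) / np.sqrt(n), 1e-30)
        return v, se

    v_hat, se_hat = stat(np.arange(n))
    rng = np.random.default_rng(seed)
    t_stats = np.empty((n_boot, n_bins))
    for b in range(n_boot):
        vb, seb = stat(rng.integers(0, n, size=n))
        t_stats[b] = (vb - v_hat) / seb
    t_lo, t_hi = np.quantile(t_stats, [alpha / 2.0, 1 - alpha / 2.0], axis=0)
    ci_lo = v_hat - t_hi * se_hat
    ci_hi = v_hat - t_lo * se_hat
    sig = (ci_lo > 0) | (ci_hi < 0)
    if alpha >= 1.0:
        sig = np.ones_like(sig, dtype=bool)

    erds_map.sig_mask = sig.reshape(shape)
    erds_map.alpha = alpha
    return erds_map
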