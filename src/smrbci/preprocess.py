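"""Filtering, spatial derivations, segmentation and trial rejection.

All filters are per-channel IIR Butterworth designs (SOS form).  Zero-phase
filtering runs forward-backward (doubling the effective order), causal
filtering forward only — the online system uses causal filters so that
training and feedback share the same characteristics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import signal, stats

from .containers import Recording, TrialSet

__all__ = [
    "FilterSpec",
    "butter_filter",
    "design_sos",
    "laplacian",
    "segment",
    "reject_outlier_trials",
    "variance_normalize",
]


@dataclass
class FilterSpec:
    """Butterworth bandpass or IIR notch.

    ``band`` is an (low, high) Hz pair for a bandpass, or a single notch
    frequency.  ``phase`` selects causal (forward) or zero-phase
    (forward-backward) application.
    """

    kind: str = "bandpass"  # bandpass | notch
    band: tuple[float, float] | float = (8.0, 30.0)
    order: int = 4
    phase: str = "causal"  # causal | zero_phase
    notch_q: float = 35.0

    def validate(self, sfreq: float) -> None:
        nyq = sfreq / 2.0
        if self.kind == "bandpass":
            lo, hi = self.band
            if not (0 < lo < hi < nyq):
                raise ValueError(
                    f"bandpass ({lo}, {hi}) Hz invalid for Nyquist {nyq} Hz"
                )
        elif self.kind == "notch":
            f0 = float(self.band) if np.isscalar(self.band) else self.band[0]
            if not (0 < f0 < nyq):
                raise ValueError(f"notch frequency {f0} Hz beyond Nyquist {nyq} Hz")
        else:
            raise ValueError(f"unknown filter kind {self.kind!r}")
        if self.phase not in ("causal", "zero_phase"):
            raise ValueError(f"unknown phase {self.phase!r}")


def design_sos(spec: FilterSpec, sfreq: float) -> np.ndarray:
    """Second-order-section coefficients for a spec at a given rate."""
    spec.validate(sfreq)
    if spec.kind == "bandpass":
        return signal.butter(spec.order, spec.band, btype="bandpass",
                             fs=sfreq, output="sos")
    f0 = float(spec.band) if np.isscalar(spec.band) else spec.band[0]
    b, a = signal.iirnotch(f0, spec.notch_q, fs=sfreq)
    return signal.tf2sos(b, a)


def butter_filter(rec: Recording, spec: FilterSpec) -> Recording:
    """Filter every channel; events are preserved untouched."""
    sos = design_sos(spec, rec.sfreq)
    if spec.phase == "zero_phase":
        data = signal.sosfiltfilt(sos, rec.data, axis=1)
    else:
        data = signal.sosfilt(sos, rec.data, axis=1)
    return Recording(np.ascontiguousarray(data), rec.sfreq,
                     list(rec.channel_labels), list(rec.events))


def filter_trials(ts: TrialSet, spec: FilterSpec) -> TrialSet:
    """Same filtering applied per trial along the sample axis."""
    sos = design_sos(spec, ts.sfreq)
    if spec.phase == "zero_phase":
        data = signal.sosfiltfilt(sos, ts.data, axis=2)
    else:
        data = signal.sosfilt(sos, ts.data, axis=2)
    return TrialSet(np.ascontiguousarray(data), ts.time_axis, ts.labels, ts.sfreq,
                    list(ts.channel_labels), ts.kept_mask.copy())


def laplacian(rec: Recording, center: str, neighbours: list[str]) -> Recording:
    """5-point Laplacian derivation: centre minus the mean of 4 neighbours.

    Enhances focal activity under the centre electrode by cancelling
    activity common to the local neighbourhood.
    """
    if len(neighbours) != 4:
        raise ValueError("a 5-point Laplacian needs exactly 4 neighbours")
    ci = rec.index(center)
    ni = [rec.index(nb) for nb in neighbours]
    out = rec.data[ci] - rec.data[ni].mean(axis=0)
    return Recording(out[None, :], rec.sfreq, [center], list(rec.events))


def segment(rec: Recording, cue_codes: dict[int, str] | set,
            window: tuple[float, float]) -> TrialSet:
    """Cut cue-locked trials from a continuous recording.

    ``cue_codes`` maps event code -> class label (a plain set of codes
    yields string codes as labels).  ``window`` is (start, stop) seconds
    relative to the cue; trials whose window would be truncated are dropped
    with a warning.
    """
    lo, hi = window
    if hi <= lo:
        raise ValueError("window stop must exceed start")
    sfreq = rec.sfreq
    i_lo = int(round(lo * sfreq))
    i_hi = int(round(hi * sfreq))
    n_win = i_hi - i_lo
    if isinstance(cue_codes, set):
        code_map = {c: str(c) for c in cue_codes}
    else:
        code_map = dict(cue_codes)
    trials, labels = [], []
    for samp, code in rec.events:
        if code not in code_map:
            continue
        a, b = samp + i_lo, samp + i_lo + n_win
        if a < 0 or b > rec.n_samples:
            warnings.warn(
                f"cue at sample {samp} has a truncated window; trial dropped",
                stacklevel=2,
            )
            continue
        trials.append(rec.data[:, a:b])
        labels.append(code_map[code])
    time_axis = (np.arange(n_win) + i_lo) / sfreq
    data = np.stack(trials) if trials else np.zeros((0, rec.n_channels, n_win))
    return TrialSet(data, time_axis, np.array(labels, dtype=object), sfreq,
                    list(rec.channel_labels))


def reject_outlier_trials(
    ts: TrialSet,
    amplitude_threshold: float = 100.0,
    sd_threshold: float = 4.0,
) -> TrialSet:
    """Statistical trial rejection on three criteria, single pass.

    A trial is marked rejected if (1) any channel sample exceeds the
    amplitude threshold (default +/-100 uV), (2) its joint log-probability
    under per-channel Gaussian fits across trials, or (3) its kurtosis,
    deviates from the across-trial mean by more than ``sd_threshold``
    standard deviations (two-sided).  All criteria are evaluated on the
    original set — no iterative re-fitting.  With fewer than 5 trials the
    input is returned unchanged with a warning.
    """
    if ts.n_trials < 5:
        warnings.warn("fewer than 5 trials: outlier rejection skipped", stacklevel=2)
        return ts

    x = ts.data  # trials x channels x samples
    amp_bad = np.abs(x).max(axis=(1, 2)) > amplitude_threshold

    # per-channel Gaussian fits across all trials and samples
    mu = x.mean(axis=(0, 2), keepdims=True)
    sd = np.maximum(x.std(axis=(0, 2), keepdims=True), 1e-30)
    # joint log-probability: Gaussian log-likelihood summed over channels/samples
    logp = -0.5 * (((x - mu) / sd) ** 2).sum(axis=(1, 2))
    jp_z = _zscore_across_trials(logp)

    kurt = stats.kurtosis(x, axis=2, fisher=True).mean(axis=1)
    k_z = _zscore_across_trials(kurt)

    bad = amp_bad | (np.abs(jp_z) > sd_threshold) | (np.abs(k_z) > sd_threshold)
    mask = ts.kept_mask & ~bad
    return TrialSet(ts.data, ts.time_axis, ts.labels, ts.sfreq,
                    list(ts.channel_labels), mask)


def _zscore_across_trials(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    if sd < 1e-30:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def variance_normalize(rec: Recording, resting: Recording) -> Recording:
    """Divide each channel by its standard deviation in the resting segment.

    Reduces the influence of high-variance channels and makes sessions
    recorded on different days comparable before pooling calibration trials.
    """
    if rec.channel_labels != resting.channel_labels:
        raise ValueError("recording and resting must share the same channel set")
    sd = resting.data.std(axis=1)
    zero = np.where(sd <= 0)[0]
    if zero.size:
        names = [rec.channel_labels[i] for i in zero]
        raise ValueError(f"zero resting variance on channel(s) {names}")
    return Recording(rec.data / sd[:, None], rec.sfreq,
                     list(rec.channel_labels), list(rec.events))
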