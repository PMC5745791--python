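"""Closed-loop decision making with artifact gating.

Class probabilities from the shrinkage-LDA are averaged over a trailing
one-second window; whenever the averaged probability of a class exceeds its
class-specific threshold, the corresponding command is emitted at the next
decision tick (the highest averaged probability wins among classes above
threshold; an exact tie emits nothing).  Two real-time artifact detectors
gate the output:

* blink gate — 1-10 Hz band power at a frontal electrode (AFz) compared to
  mean + 3 SD of the same statistic on resting EEG;
* AR gate — the EEG is modeled per channel as an autoregressive process of
  order 10 fitted on resting EEG; the output is blocked while the one-step
  linear prediction error exceeds 3 times its resting SD on any channel.
  Coefficients and error SD adapt by exponential forgetting (on unblocked
  samples only) to track slow drifts.

While either gate is active the decision output is forced to "none".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal
from statsmodels.regression.linear_model import yule_walker

from .containers import LabelledSession, Recording, TrialSet
from .classify import (PipelineSpec, SLDAModel, crossvalidate, fit_slda)
from .features import FeatureExtractor, build_extractor, extract
from .preprocess import reject_outlier_trials, segment

__all__ = [
    "DecisionConfig",
    "BiasEstimate",
    "BlinkDetector",
    "ARModel",
    "ArtifactGateState",
    "CommandStream",
    "estimate_bias",
    "decide",
    "blink_gate",
    "ar_fit",
    "ar_gate",
    "OnlineDecoder",
    "calibrate",
]


@dataclass
class DecisionConfig:
    """Thresholded decision rule parameters."""

    thresholds: dict[str, float]
    averaging_window: float = 1.0
    emit_rate: float = 16.0  # decisions per second

    def __post_init__(self) -> None:
        if self.averaging_window <= 0:
            raise ValueError("averaging_window must be positive")
        for c, th in self.thresholds.items():
            if not 0 <= th <= 1.01:
                raise ValueError(f"threshold for {c!r} outside [0, 1]: {th}")


@dataclass
class BiasEstimate:
    """Out-of-fold class-probability statistics from cross-validation."""

    class_order: list[str]
    mean: np.ndarray  # true-class x prob-class
    var: np.ndarray
    suggested_thresholds: dict[str, float]


@dataclass
class CommandStream:
    """(time s, command or None, gated flag) triples, time-ordered."""

    entries: list[tuple[float, str | None, bool]] = field(default_factory=list)

    def commands(self) -> list[str | None]:
        return [c for _, c, _ in self.entries]

    def times(self) -> np.ndarray:
        return np.array([t for t, _, _ in self.entries])

    def append(self, t: float, cmd: str | None, gated: bool) -> None:
        if self.entries and t < self.entries[-1][0]:
            raise ValueError("command times must be non-decreasing")
        self.entries.append((t, cmd, gated))


# ---------------------------------------------------------------------------
# bias estimation


def estimate_bias(
    ts: TrialSet,
    pipeline_spec: PipelineSpec | None = None,
    scheme: tuple[int, int] = (5, 5),
    seed: int = 0,
    threshold_sd: float = 2.0,
) -> BiasEstimate:
    """Classifier bias from out-of-fold probabilities, 5x5 CV by default.

    The suggested threshold per class is the mean probability the class
    receives on trials of *other* classes plus ``threshold_sd`` SDs — a
    reproducible starting point for the manual per-class tuning a technician
    would otherwise do.
    """
    res = crossvalidate(ts, None, pipeline_spec, scheme, seed=seed,
                        collect_probs=True)
    classes = res.class_order
    probs, true = res.oof_probs, res.oof_true
    k = len(classes)
    mean = np.zeros((k, k))
    var = np.zeros((k, k))
    for i, c in enumerate(classes):
        m = true == c
        mean[i] = probs[m].mean(axis=0)
        var[i] = probs[m].var(axis=0)
    thresholds = {}
    for j, c in enumerate(classes):
        off = probs[true != c][:, j]
        thresholds[c] = float(min(off.mean() + threshold_sd * off.std(), 1.0))
    return BiasEstimate(classes, mean, var, thresholds)


# ---------------------------------------------------------------------------
# decision rule


def _trailing_mean(x: np.ndarray, win: int) -> np.ndarray:
    """Trailing moving average with growing window during burn-in; axis 0."""
    cs = np.cumsum(x, axis=0)
    out = np.empty_like(cs, dtype=float)
    upto = min(win, len(x))
    out[:upto] = cs[:upto] / np.arange(1, upto + 1)[:, None]
    if len(x) > win:
        out[win:] = (cs[win:] - cs[:-win]) / win
    return out


def _threshold_decision(avg: np.ndarray, thresholds: np.ndarray,
                        class_order: list[str]) -> str | None:
    """Highest averaged probability among classes above threshold; tie -> none."""
    above = avg > thresholds
    if not above.any():
        return None
    cand = np.where(above)[0]
    best = avg[cand].max()
    winners = cand[avg[cand] >= best - 1e-12]
    if len(winners) > 1:
        return None
    return class_order[winners[0]]


def decide(
    prob_stream: np.ndarray,
    class_order: list[str],
    cfg: DecisionConfig,
    sfreq: float,
    gate_blocked: np.ndarray | None = None,
) -> CommandStream:
    """Offline decision pass over a per-sample probability stream.

    ``prob_stream`` is samples x classes with rows summing to 1.  Decisions
    are emitted at ``cfg.emit_rate`` ticks once a full averaging window is
    available; while ``gate_blocked`` is true at the tick sample, the output
    is forced to none with the gated flag set.
    """
    prob_stream = np.asarray(prob_stream, dtype=float)
    if prob_stream.ndim != 2 or prob_stream.shape[1] != len(class_order):
        raise ValueError("prob_stream must be samples x classes")
    if not np.allclose(prob_stream.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    win = int(round(cfg.averaging_window * sfreq))
    avg = _trailing_mean(prob_stream, win)
    th = np.array([cfg.thresholds.get(c, 1.01) for c in class_order])
    step = sfreq / cfg.emit_rate
    out = CommandStream()
    k = 1
    while True:
        s = int(round(k * step)) - 1
        if s >= len(prob_stream):
            break
        t = (s + 1) / sfreq
        if t + 1e-9 >= cfg.averaging_window:
            gated = bool(gate_blocked[s]) if gate_blocked is not None else False
            cmd = None if gated else _threshold_decision(avg[s], th, class_order)
            out.append(t, cmd, gated)
        k += 1
    return out


# ---------------------------------------------------------------------------
# blink gate


@dataclass
class BlinkDetector:
    """Resting-calibrated frontal band-power blink detector."""

    electrode: str = "AFz"
    band: tuple[float, float] = (1.0, 10.0)
    window: float = 0.25
    k: float = 3.0
    rest_mean: float = 0.0
    rest_sd: float = 0.0
    filter_order: int = 4

    def fit(self, resting: Recording) -> "BlinkDetector":
        power = self._power(resting)
        self.rest_mean = float(power.mean())
        self.rest_sd = float(power.std())
        if self.rest_sd <= 0:
            raise ValueError("zero-variance resting band power; cannot calibrate")
        return self

    @property
    def threshold(self) -> float:
        return self.rest_mean + self.k * self.rest_sd

    def _sos(self, sfreq: float) -> np.ndarray:
        return signal.butter(self.filter_order, self.band, btype="bandpass",
                             fs=sfreq, output="sos")

    def _power(self, rec: Recording) -> np.ndarray:
        if self.electrode not in rec.channel_labels:
            raise ValueError(f"electrode {self.electrode!r} absent from recording")
        x = rec.data[rec.index(self.electrode)]
        f = signal.sosfilt(self._sos(rec.sfreq), x)
        win = max(int(round(self.window * rec.sfreq)), 1)
        return _trailing_mean((f ** 2)[:, None], win)[:, 0]


def blink_gate(rec_stream: Recording, detector: BlinkDetector
               ) -> tuple[np.ndarray, list[tuple[float, float]]]:
    """Per-sample blocked mask and merged block intervals (seconds)."""
    if detector.rest_sd <= 0:
        raise ValueError("detector not calibrated: fit on resting EEG first")
    power = detector._power(rec_stream)
    blocked = power > detector.threshold
    return blocked, _mask_to_intervals(blocked, rec_stream.sfreq)


def _mask_to_intervals(mask: np.ndarray, sfreq: float) -> list[tuple[float, float]]:
    edges = np.flatnonzero(np.diff(np.r_[0, mask.astype(int), 0]))
    return [(a / sfreq, b / sfreq) for a, b in zip(edges[::2], edges[1::2])]


# ---------------------------------------------------------------------------
# AR gate


@dataclass
class ARModel:
    """Per-channel AR(order) model with residual SDs."""

    order: int
    coeffs: np.ndarray  # channels x order
    error_sd: np.ndarray  # per channel
    channel_labels: list[str]
    k: float = 3.0


def ar_fit(resting: Recording, order: int = 10) -> ARModel:
    """Autocorrelation-method (Yule-Walker) AR fit per channel."""
    if resting.n_samples < 100 * order:
        raise ValueError(
            f"resting segment too short: need >= {100 * order} samples, "
            f"got {resting.n_samples}"
        )
    coeffs = np.empty((resting.n_channels, order))
    sds = np.empty(resting.n_channels)
    for c in range(resting.n_channels):
        x = resting.data[c] - resting.data[c].mean()
        rho, sigma = yule_walker(x, order=order, method="mle")
        coeffs[c] = rho
        sds[c] = sigma
    return ARModel(order, coeffs, sds, list(resting.channel_labels))


def _prediction_errors(x: np.ndarray, coeffs: np.ndarray,
                       history: np.ndarray | None = None) -> np.ndarray:
    """One-step-ahead prediction errors, channels x samples.

    ``history`` supplies the ``order`` samples preceding ``x`` (zeros when
    absent, i.e. at stream start).
    """
    n_ch, order = coeffs.shape
    if history is None:
        history = np.zeros((n_ch, order))
    ext = np.concatenate([history, x], axis=1)
    pred = np.zeros_like(x)
    for lag in range(1, order + 1):
        pred += coeffs[:, lag - 1][:, None] * ext[:, order - lag:-lag]
    return x - pred


def ar_gate(
    rec_stream: Recording,
    model: ARModel,
    adapt_memory: float = 30.0,
    block_size: float = 0.25,
    refit: bool = True,
) -> tuple[np.ndarray, list[tuple[float, float]], ARModel]:
    """AR prediction-error gate with exponential-forgetting adaptation.

    The stream is processed in ``block_size``-second blocks.  Within a
    block, samples where |error| > k * SD on any channel are blocked.
    After each block the per-channel autocorrelations and error variance
    are updated from the unblocked samples with forgetting constant
    ``adapt_memory`` (seconds) and the coefficients re-solved, so slow
    amplitude drifts do not inflate the block rate.  Pass
    ``adapt_memory=None`` to disable adaptation.
    """
    sfreq = rec_stream.sfreq
    n = rec_stream.n_samples
    step = max(int(round(block_size * sfreq)), 1)
    order = model.order
    coeffs = model.coeffs.copy()
    var = model.error_sd.copy() ** 2
    blocked = np.zeros(n, dtype=bool)
    x = rec_stream.data
    lam = np.exp(-block_size / adapt_memory) if adapt_memory else 1.0
    # exponentially forgotten autocorrelation state, seeded from the model
    acov = None
    for start in range(0, n, step):
        stop = min(start + step, n)
        hist = x[:, max(start - order, 0):start]
        if hist.shape[1] < order:
            hist = np.pad(hist, ((0, 0), (order - hist.shape[1], 0)))
        err = _prediction_errors(x[:, start:stop], coeffs, hist)
        bad = np.abs(err) > model.k * np.sqrt(var)[:, None]
        blk = bad.any(axis=0)
        blocked[start:stop] = blk
        if adapt_memory is None:
            continue
        ok = ~blk
        if ok.sum() < order + 2:
            continue
        seg = x[:, start:stop][:, ok]
        seg = seg - seg.mean(axis=1, keepdims=True)
        lags = np.arange(order + 1)
        new_acov = np.stack([
            np.array([np.dot(seg[c, :seg.shape[1] - l], seg[c, l:]) / seg.shape[1]
                      for l in lags])
            for c in range(seg.shape[0])
        ])
        acov = new_acov if acov is None else lam * acov + (1 - lam) * new_acov
        new_var = (err[:, ok] ** 2).mean(axis=1)
        var = lam * var + (1 - lam) * new_var
        if refit:
            for c in range(coeffs.shape[0]):
                r = acov[c]
                if r[0] <= 0:
                    continue
                R = np.array([[r[abs(i - j)] for j in range(order)]
                              for i in range(order)])
                try:
                    coeffs[c] = np.linalg.solve(
                        R + 1e-9 * r[0] * np.eye(order), r[1:order + 1]
                    )
                except np.linalg.LinAlgError:
                    pass
    updated = ARModel(order, coeffs, np.sqrt(var), list(model.channel_labels), model.k)
    return blocked, _mask_to_intervals(blocked, sfreq), updated


@dataclass
class ArtifactGateState:
    """Combined gate: blink detector + AR prediction-error detector."""

    blink: BlinkDetector | None = None
    ar: ARModel | None = None
    adapt_memory: float = 30.0
    blocked: bool = False

    def offline_mask(self, rec: Recording) -> np.ndarray:
        mask = np.zeros(rec.n_samples, dtype=bool)
        if self.blink is not None:
            m, _ = blink_gate(rec, self.blink)
            mask |= m
        if self.ar is not None:
            m, _, _ = ar_gate(rec, self.ar, self.adapt_memory)
            mask |= m
        return mask


# ---------------------------------------------------------------------------
# streaming decoder


class OnlineDecoder:
    """Causal streaming pipeline: filter -> normalize -> CSP log band power
    -> sLDA probabilities -> 1 s averaging -> thresholded commands, with
    artifact gating.  Consumes raw EEG blocks of arbitrary size; all filter
    and window states persist across blocks, so feeding a stream in blocks
    is sample-exact equivalent to feeding it at once.
    """

    def __init__(
        self,
        extractor: FeatureExtractor,
        model: SLDAModel,
        cfg: DecisionConfig,
        gate: ArtifactGateState | None = None,
    ):
        self.extractor = extractor
        self.model = model
        self.cfg = cfg
        self.gate = gate or ArtifactGateState()
        self.sfreq = extractor.sfreq
        self._win = int(round(extractor.window * self.sfreq))
        self._avg_win = int(round(cfg.averaging_window * self.sfreq))
        self._tick = self.sfreq / cfg.emit_rate
        self._sos = [
            signal.butter(extractor.filter_order, band, btype="bandpass",
                          fs=self.sfreq, output="sos")
            for band in extractor.bands
        ]
        self._W = [extractor.stacked_filters(b) for b in extractor.bands]
        self._th = np.array([cfg.thresholds.get(c, 1.01) for c in model.class_list])
        self.reset()

    def reset(self) -> None:
        """Zero all filter/window/gate states (fresh stream)."""
        n_ch = len(self.extractor.channel_labels)
        self._zi = [np.zeros((sos.shape[0], n_ch, 2)) for sos in self._sos]
        self._sq_buf = [np.zeros((W.shape[0], 0)) for W in self._W]
        self._prob_buf = np.zeros((0, len(self.model.class_list)))
        self._n_seen = 0
        self._next_tick = 1
        # gate state
        blink = self.gate.blink
        if blink is not None:
            self._blink_sos = blink._sos(self.sfreq)
            self._blink_zi = np.zeros((self._blink_sos.shape[0], 2))
            self._blink_buf = np.zeros(0)
            self._blink_ch = self.extractor.channel_labels.index(blink.electrode)
            self._blink_win = max(int(round(blink.window * self.sfreq)), 1)
        if self.gate.ar is not None:
            self._ar_hist = np.zeros((n_ch, self.gate.ar.order))
            self._ar_coeffs = self.gate.ar.coeffs.copy()
            self._ar_var = self.gate.ar.error_sd.copy() ** 2

    # -- internals ---------------------------------------------------------

    def _trailing(self, buf: np.ndarray, new: np.ndarray, win: int,
                  offset: int) -> tuple[np.ndarray, np.ndarray]:
        """Trailing mean of ``new`` columns given past buffer; returns
        (means for the new samples, updated buffer).  ``offset`` is the
        number of samples seen before this block (growing window during
        the first ``win`` samples of the stream)."""
        full = np.concatenate([buf, new], axis=-1)
        cs = np.cumsum(full, axis=-1)
        nb = buf.shape[-1]
        n = new.shape[-1]
        j = np.arange(n)
        total_seen = offset + j + 1
        hi = cs[..., nb + j]
        lo_idx = nb + j - win
        lo = np.where(lo_idx >= 0, cs[..., np.maximum(lo_idx, 0)], 0.0)
        denom = np.minimum(total_seen, win)
        out = np.where(total_seen >= win, (hi - lo) / win, hi / denom)
        keep = min(win - 1, full.shape[-1])
        return out, full[..., full.shape[-1] - keep:]

    def _gate_mask(self, block: np.ndarray) -> np.ndarray:
        n = block.shape[1]
        mask = np.zeros(n, dtype=bool)
        blink = self.gate.blink
        if blink is not None:
            x = block[self._blink_ch]
            f, self._blink_zi = signal.sosfilt(self._blink_sos, x, zi=self._blink_zi)
            power, self._blink_buf = self._trailing(
                self._blink_buf[None, :], (f ** 2)[None, :],
                self._blink_win, self._n_seen)
            self._blink_buf = self._blink_buf[0]
            mask |= power[0] > blink.threshold
        ar = self.gate.ar
        if ar is not None:
            err = _prediction_errors(block, self._ar_coeffs, self._ar_hist)
            bad = np.abs(err) > ar.k * np.sqrt(self._ar_var)[:, None]
            mask |= bad.any(axis=0)
            keep = min(ar.order, block.shape[1])
            self._ar_hist = np.concatenate(
                [self._ar_hist[:, keep:], block[:, -keep:]], axis=1)
        return mask

    # -- public ------------------------------------------------------------

    def process(self, block: np.ndarray) -> CommandStream:
        """Consume a channels x n raw EEG block; emit this block's commands."""
        block = np.asarray(block, dtype=float)
        n = block.shape[1]
        feats = []
        for i, band in enumerate(self.extractor.bands):
            f, self._zi[i] = signal.sosfilt(self._sos[i], block, zi=self._zi[i])
            if self.extractor.band_scales is not None:
                f = f / self.extractor.band_scales[i][:, None]
            proj = self._W[i] @ f
            power, self._sq_buf[i] = self._trailing(
                self._sq_buf[i], proj ** 2, self._win, self._n_seen)
            feats.append(np.log(np.maximum(power, self.extractor.log_floor)))
        X = np.concatenate(feats, axis=0).T  # n x features
        probs = self.model.predict_proba(X)
        avg, buf = self._trailing(self._prob_buf.T, probs.T,
                                  self._avg_win, self._n_seen)
        self._prob_buf = buf.T
        avg = avg.T
        gmask = self._gate_mask(block)

        out = CommandStream()
        while True:
            s = int(round(self._next_tick * self._tick)) - 1
            if s >= self._n_seen + n:
                break
            j = s - self._n_seen
            if j >= 0:
                t = (s + 1) / self.sfreq
                if t + 1e-9 >= self.cfg.averaging_window:
                    gated = bool(gmask[j])
                    cmd = None if gated else _threshold_decision(
                        avg[j], self._th, self.model.class_list)
                    out.append(t, cmd, gated)
            self._next_tick += 1
        self._n_seen += n
        return out


# ---------------------------------------------------------------------------
# calibration convenience


def calibrate(
    session: LabelledSession,
    classes: list[str],
    code_map: dict[int, str],
    bands=((8.0, 16.0), (16.0, 30.0)),
    fit_window: tuple[float, float] = (1.0, 3.0),
    train_times: tuple = (2.5, 3.5, 4.5),
    scheme: tuple[int, int] = (5, 5),
    seed: int = 0,
    reject: bool = True,
    with_gates: bool = True,
    emit_rate: float = 16.0,
) -> tuple[OnlineDecoder, BiasEstimate, TrialSet]:
    """Train a full online decoder from a labelled calibration session.

    Segments cue-locked trials, applies statistical outlier rejection,
    fits the two-band CSP feature extractor (resting-variance normalized),
    trains the sLDA on multi-timepoint features, estimates class bias by
    5x5 CV to suggest decision thresholds, and calibrates both artifact
    gates on the resting segment.
    """
    resting = session.resting()
    ts = segment(session.recording, code_map, (-3.0, 5.0))
    if reject:
        ts = reject_outlier_trials(ts).kept()
    extractor = build_extractor(ts, classes, bands, fit_window, "auto",
                                resting=resting)
    feats = extract(extractor, ts)
    fm = feats.at_times(list(train_times))
    model = fit_slda(fm.values, fm.labels, "auto")
    order = [model.class_list.index(c) for c in classes]
    model = SLDAModel(list(classes), model.means[order], model.pooled_cov,
                      model.weights[order], model.bias[order],
                      model.shrinkage_intensity)
    spec = PipelineSpec(bands=tuple(tuple(b) for b in bands),
                        fit_window=fit_window, train_times=tuple(train_times))
    bias = estimate_bias(ts, spec, scheme, seed)
    cfg = DecisionConfig(dict(bias.suggested_thresholds), emit_rate=emit_rate)
    gate = ArtifactGateState()
    if with_gates:
        gate.blink = BlinkDetector().fit(resting)
        gate.ar = ar_fit(resting, order=10)
    decoder = OnlineDecoder(extractor, model, cfg, gate)
    return decoder, bias, ts
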