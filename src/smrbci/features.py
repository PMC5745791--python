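"""Shrinkage-regularized CSP and logarithmic band-power features.

Common spatial patterns (CSP) finds spatial filters w maximizing the
variance ratio between two classes.  With class covariance matrices S_A,
S_B it solves the generalized eigenproblem

    S_A w = lambda (S_A + S_B) w,          lambda in [0, 1],

so eigenvalues are class-A variance ratios: filters with extreme
eigenvalues (largest and smallest) are the most discriminative.  Each class
covariance is shrunk toward scaled identity,

    S_hat = (1 - gamma) S + gamma (tr S / C) I,

which keeps the problem well-posed for many channels and few trials
("auto" uses a Ledoit-Wolf estimate of gamma).  One CSP model is fitted per
unordered class pair and per frequency band; each model contributes the
filters of its two largest and two smallest eigenvalues, so the feature
dimension is n_pairs x 4 x n_bands (48 for 4 classes and 2 bands).

Features are logarithmic band powers: project, square, average causally
over the trailing 1 s window (step 1 sample), take the natural log.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
from scipy import linalg
from sklearn.covariance import ledoit_wolf_shrinkage

from .containers import Recording, TrialSet
from .preprocess import FilterSpec, filter_trials, butter_filter

__all__ = [
    "CSPModel",
    "FeatureExtractor",
    "FeatureMatrix",
    "TrialFeatures",
    "fit_csp",
    "build_extractor",
    "extract",
]

N_FILTERS = 4  # two largest + two smallest eigenvalues per model
LOG_FLOOR = 1e-12


@dataclass
class CSPModel:
    pair: tuple[str, str]
    band: tuple[float, float]
    filters: np.ndarray  # channels x channels, rows = filters, eigenvalue-desc
    eigenvalues: np.ndarray  # class-A variance ratios, descending in [0, 1]
    selected: list[int]
    shrinkage: float

    @property
    def selected_filters(self) -> np.ndarray:
        return self.filters[self.selected]


@dataclass
class FeatureMatrix:
    """observations x features log band power, with timestamps."""

    values: np.ndarray
    times: np.ndarray
    labels: np.ndarray | None = None
    burn_in: np.ndarray | None = None  # True where the 1 s window is partial

    @property
    def n_features(self) -> int:
        return self.values.shape[1]


@dataclass
class TrialFeatures:
    """Per-trial feature time courses: trials x samples x features."""

    values: np.ndarray
    time_axis: np.ndarray
    labels: np.ndarray
    sfreq: float

    def at_times(self, times: list[float]) -> FeatureMatrix:
        """Stack the feature vectors at the given cue-relative times.

        One observation per trial per time point (training convention for
        the multi-timepoint classifier).
        """
        idx = [int(np.argmin(np.abs(self.time_axis - t))) for t in times]
        vals = np.concatenate([self.values[:, i, :] for i in idx], axis=0)
        labs = np.tile(self.labels, len(idx))
        ts = np.concatenate([np.full(self.values.shape[0], self.time_axis[i])
                             for i in idx])
        return FeatureMatrix(vals, ts, labs)


@dataclass
class FeatureExtractor:
    bands: list[tuple[float, float]]
    csp_models: list[CSPModel]
    sfreq: float
    channel_labels: list[str]
    window: float = 1.0
    log_floor: float = LOG_FLOOR
    filter_order: int = 4
    # per-band channel scales (resting SD of the band-filtered signal);
    # None disables normalization
    band_scales: list[np.ndarray] | None = None

    @property
    def n_features(self) -> int:
        return len(self.csp_models) * N_FILTERS

    def models_for_band(self, band: tuple[float, float]) -> list[CSPModel]:
        return [m for m in self.csp_models if m.band == tuple(band)]

    def stacked_filters(self, band: tuple[float, float]) -> np.ndarray:
        """All selected filters of one band stacked: (n_pairs*4) x channels."""
        return np.vstack([m.selected_filters for m in self.models_for_band(band)])


# ---------------------------------------------------------------------------
# CSP fitting


def _trial_covariances(x: np.ndarray, trace_norm: bool = True) -> np.ndarray:
    """Per-trial covariance, trace-normalized by default (trials x ch x ch).

    Trace normalization equalizes trial weights against broadband amplitude
    fluctuations; disabling it makes CSP eigenvalues exactly invariant
    under invertible channel mixing.
    """
    c = np.einsum("tcs,tds->tcd", x, x)
    if trace_norm:
        tr = np.maximum(np.trace(c, axis1=1, axis2=2), 1e-30)
        c = c / tr[:, None, None]
    else:
        c = c / x.shape[2]
    return c


def _shrink(cov: np.ndarray, gamma: float) -> np.ndarray:
    c = cov.shape[0]
    return (1 - gamma) * cov + gamma * (np.trace(cov) / c) * np.eye(c)


def _auto_gamma(x: np.ndarray) -> float:
    """Ledoit-Wolf shrinkage intensity from trial samples (zero-mean data)."""
    flat = np.transpose(x, (0, 2, 1)).reshape(-1, x.shape[1])
    # subsample for speed on long windows; deterministic stride
    if flat.shape[0] > 20000:
        flat = flat[:: flat.shape[0] // 20000 + 1]
    return float(ledoit_wolf_shrinkage(flat, assume_centered=True))


def fit_csp(
    ts: TrialSet,
    pair: tuple[str, str],
    fit_window: tuple[float, float] = (1.0, 3.0),
    shrinkage: float | str = "auto",
    band: tuple[float, float] = (8.0, 30.0),
    trace_norm: bool = True,
) -> CSPModel:
    """Fit a one-vs-one CSP model on (already band-filtered) trial data.

    Covariances are averaged over trace-normalized per-trial covariances in
    ``fit_window``.  Filters follow a deterministic sign convention: the
    largest-magnitude coefficient of each filter is positive.
    """
    a, b = pair
    sl = ts.window_slice(fit_window)
    xa = ts.data[ts.labels == a][:, :, sl]
    xb = ts.data[ts.labels == b][:, :, sl]
    if len(xa) < 4 or len(xb) < 4:
        raise ValueError(f"need >= 4 trials per class, got {len(xa)}/{len(xb)}")

    if shrinkage == "auto":
        gamma = max(_auto_gamma(xa), _auto_gamma(xb))
    else:
        gamma = float(shrinkage)
        if not 0 <= gamma <= 1:
            raise ValueError("shrinkage must be in [0, 1]")

    Sa = _shrink(_trial_covariances(xa, trace_norm).mean(axis=0), gamma)
    Sb = _shrink(_trial_covariances(xb, trace_norm).mean(axis=0), gamma)
    try:
        evals, evecs = linalg.eigh(Sa, Sa + Sb)
    except linalg.LinAlgError as err:
        raise ValueError(
            "singular combined covariance; refit with shrinkage > 0"
        ) from err
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, 1.0)
    filters = evecs[:, order].T
    # sign convention
    flip = filters[np.arange(len(filters)),
                   np.argmax(np.abs(filters), axis=1)] < 0
    filters[flip] *= -1
    n = filters.shape[0]
    selected = [0, 1, n - 2, n - 1]
    return CSPModel(pair=(a, b), band=tuple(band), filters=filters,
                    eigenvalues=evals, selected=selected, shrinkage=gamma)


def band_filter_trials(ts: TrialSet, bands, order: int = 4,
                       scales: list[np.ndarray] | None = None) -> list[TrialSet]:
    """Causal band filtering (optionally resting-variance normalized) per band.

    Label-independent, so it may be computed once outside cross-validation
    folds without leakage.
    """
    out = []
    for i, band in enumerate(bands):
        f = filter_trials(ts, FilterSpec("bandpass", tuple(band), order, "causal"))
        if scales is not None:
            f.data = f.data / scales[i][None, :, None]
        out.append(f)
    return out


def resting_band_scales(resting: Recording, bands, order: int = 4) -> list[np.ndarray]:
    """Per-band channel SDs of the band-filtered resting EEG."""
    scales = []
    for band in bands:
        f = butter_filter(resting, FilterSpec("bandpass", tuple(band), order, "causal"))
        sd = f.data.std(axis=1)
        if np.any(sd <= 0):
            bad = [resting.channel_labels[i] for i in np.where(sd <= 0)[0]]
            raise ValueError(f"zero resting variance on channel(s) {bad}")
        scales.append(sd)
    return scales


def build_extractor(
    ts: TrialSet,
    classes: list[str] | None = None,
    bands: list[tuple[float, float]] = ((8.0, 16.0), (16.0, 30.0)),
    fit_window: tuple[float, float] = (1.0, 3.0),
    shrinkage: float | str = "auto",
    resting: Recording | None = None,
    filter_order: int = 4,
    window: float = 1.0,
) -> FeatureExtractor:
    """One CSP model per unordered class pair per band.

    If ``resting`` is given, band-filtered channels are normalized by their
    resting SD before CSP fitting (and the scales are stored for later
    extraction), mirroring the online processing order
    filter -> normalize -> CSP.
    """
    classes = list(classes) if classes is not None else list(ts.classes)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    bands = [tuple(b) for b in bands]
    scales = resting_band_scales(resting, bands, filter_order) if resting is not None else None
    filtered = band_filter_trials(ts, bands, filter_order, scales)
    models = []
    for band, fts in zip(bands, filtered):
        for pair in combinations(classes, 2):
            models.append(fit_csp(fts, pair, fit_window, shrinkage, band))
    return FeatureExtractor(bands=bands, csp_models=models, sfreq=ts.sfreq,
                            channel_labels=list(ts.channel_labels),
                            window=window, filter_order=filter_order,
                            band_scales=scales)


# ---------------------------------------------------------------------------
# extraction


def _log_bandpower(proj_sq: np.ndarray, win: int, floor: float) -> np.ndarray:
    """Causal trailing moving average of squared projections, then log.

    ``proj_sq``: (..., samples).  The first ``win - 1`` samples use a
    growing (partial) window.
    """
    cs = np.cumsum(proj_sq, axis=-1)
    out = np.empty_like(cs)
    out[..., :win] = cs[..., :win] / np.arange(1, min(win, cs.shape[-1]) + 1)
    if cs.shape[-1] > win:
        out[..., win:] = (cs[..., win:] - cs[..., :-win]) / win
    return np.log(np.maximum(out, floor))


def extract(extractor: FeatureExtractor, rec_or_ts: Recording | TrialSet):
    """Log band-power feature time courses, sample by sample.

    Returns a :class:`FeatureMatrix` for a continuous recording and a
    :class:`TrialFeatures` (trials x samples x features) for a trial set.
    The first second of output uses a growing window and is flagged as
    burn-in on the FeatureMatrix.
    """
    if isinstance(rec_or_ts, Recording):
        rec = rec_or_ts
        _check_channels(extractor, rec.channel_labels)
        win = int(round(extractor.window * rec.sfreq))
        blocks = []
        for i, band in enumerate(extractor.bands):
            f = butter_filter(rec, FilterSpec("bandpass", band,
                                              extractor.filter_order, "causal"))
            data = f.data
            if extractor.band_scales is not None:
                data = data / extractor.band_scales[i][:, None]
            proj = extractor.stacked_filters(band) @ data
            blocks.append(_log_bandpower(proj ** 2, win, extractor.log_floor))
        values = np.concatenate(blocks, axis=0).T  # samples x features
        times = np.arange(rec.n_samples) / rec.sfreq
        burn = np.arange(rec.n_samples) < win - 1
        return FeatureMatrix(values, times, burn_in=burn)

    ts = rec_or_ts
    _check_channels(extractor, ts.channel_labels)
    scales = extractor.band_scales
    filtered = band_filter_trials(ts, extractor.bands, extractor.filter_order, scales)
    return extract_from_filtered(extractor, filtered, ts)


def extract_from_filtered(extractor: FeatureExtractor,
                          filtered: list[TrialSet], ts: TrialSet) -> TrialFeatures:
    """Extraction fast path when band-filtered trials are precomputed."""
    win = int(round(extractor.window * ts.sfreq))
    blocks = []
    for band, fts in zip(extractor.bands, filtered):
        W = extractor.stacked_filters(band)
        proj = np.einsum("fc,tcs->tfs", W, fts.data)
        blocks.append(_log_bandpower(proj ** 2, win, extractor.log_floor))
    values = np.concatenate(blocks, axis=1)  # trials x features x samples
    return TrialFeatures(np.transpose(values, (0, 2, 1)), ts.time_axis,
                         ts.labels, ts.sfreq)


def _check_channels(extractor: FeatureExtractor, labels: list[str]) -> None:
    if list(labels) != list(extractor.channel_labels):
        missing = set(extractor.channel_labels) - set(labels)
        extra = set(labels) - set(extractor.channel_labels)
        raise ValueError(
            f"channel set mismatch: missing {sorted(missing)}, extra {sorted(extra)}"
        )
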