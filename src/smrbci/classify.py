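"""Shrinkage LDA and the offline evaluation harness.

The decoder is linear discriminant analysis with the pooled covariance
shrunk toward scaled identity,

    S_hat = (1 - gamma) S + gamma (tr S / p) I,

("auto" gamma via Ledoit-Wolf), equal class priors, and class probabilities
from a softmax over the linear discriminant scores.

Evaluation follows the repeated stratified k-fold convention: spatial
filters (CSP) and the classifier are fitted strictly inside training folds,
accuracy is traced over trial time on the test folds, trials are scored by
majority vote over a feedback window, confusion matrices are row-normalized
percentages, and the above-chance threshold is the upper bound of an
adjusted Wald (Agresti-Coull) binomial confidence interval.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations

import numpy as np
import pandas as pd
from scipy.stats import norm
from sklearn.covariance import ledoit_wolf_shrinkage
from sklearn.model_selection import StratifiedKFold

from .containers import TrialSet
from .features import (FeatureMatrix, band_filter_trials, build_extractor,
                       extract_from_filtered, fit_csp, FeatureExtractor)

__all__ = [
    "SLDAModel",
    "PipelineSpec",
    "CVResult",
    "ChanceLevel",
    "fit_slda",
    "crossvalidate",
    "trial_majority_accuracy",
    "majority_label",
    "confusion_rownorm",
    "chance_level",
    "rank_combinations",
]


@dataclass
class SLDAModel:
    class_list: list[str]
    means: np.ndarray  # classes x features
    pooled_cov: np.ndarray  # after shrinkage
    weights: np.ndarray  # classes x features
    bias: np.ndarray  # per class
    shrinkage_intensity: float

    def scores(self, X: np.ndarray) -> np.ndarray:
        return X @ self.weights.T + self.bias

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        s = self.scores(X)
        s = s - s.max(axis=-1, keepdims=True)
        e = np.exp(s)
        return e / e.sum(axis=-1, keepdims=True)

    def predict(self, X: np.ndarray) -> np.ndarray:
        idx = np.argmax(self.scores(X), axis=-1)
        return np.asarray(self.class_list, dtype=object)[idx]

    def to_dict(self) -> dict:
        return {
            "class_list": list(self.class_list),
            "means": self.means.tolist(),
            "pooled_cov": self.pooled_cov.tolist(),
            "weights": self.weights.tolist(),
            "bias": self.bias.tolist(),
            "shrinkage_intensity": self.shrinkage_intensity,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SLDAModel":
        return cls(
            class_list=list(d["class_list"]),
            means=np.array(d["means"]),
            pooled_cov=np.array(d["pooled_cov"]),
            weights=np.array(d["weights"]),
            bias=np.array(d["bias"]),
            shrinkage_intensity=float(d["shrinkage_intensity"]),
        )


def fit_slda(X, labels=None, shrinkage: float | str = "auto") -> SLDAModel:
    """Fit shrinkage LDA with equal class priors.

    ``X`` may be a :class:`FeatureMatrix` (labels taken from it) or a plain
    (n, p) array with a label vector.
    """
    if isinstance(X, FeatureMatrix):
        labels = X.labels if labels is None else labels
        X = X.values
    X = np.asarray(X, dtype=float)
    labels = np.asarray(labels)
    classes = _ordered_classes(labels)
    if len(classes) < 2:
        raise ValueError("need at least 2 classes")
    n, p = X.shape
    means = np.stack([X[labels == c].mean(axis=0) for c in classes])
    for c in classes:
        if (labels == c).sum() < 2:
            raise ValueError(f"class {c!r} has fewer than 2 observations")

    resid = X - means[[list(classes).index(l) for l in labels]]
    pooled = resid.T @ resid / max(n - len(classes), 1)
    if shrinkage == "auto":
        gamma = float(ledoit_wolf_shrinkage(resid, assume_centered=True))
    else:
        gamma = float(shrinkage)
        if not 0 <= gamma <= 1:
            raise ValueError("shrinkage must be in [0, 1]")
    shrunk = (1 - gamma) * pooled + gamma * (np.trace(pooled) / p) * np.eye(p)

    inv = np.linalg.pinv(shrunk)
    weights = means @ inv
    bias = -0.5 * np.einsum("kf,kf->k", weights, means) + np.log(1.0 / len(classes))
    return SLDAModel(list(classes), means, shrunk, weights, bias, gamma)


def _ordered_classes(labels: np.ndarray) -> list[str]:
    _, first = np.unique(labels, return_index=True)
    return [labels[i] for i in np.sort(first)]


# ---------------------------------------------------------------------------
# evaluation


@dataclass
class ChanceLevel:
    n_trials: int
    n_classes: int
    alpha: float
    upper_bound: float


def chance_level(n_trials: int, n_classes: int, alpha: float = 0.05) -> ChanceLevel:
    """Upper bound of the adjusted Wald (Agresti-Coull) CI at p = 1/k.

    Accuracy above this bound is unlikely (at confidence 1 - alpha) under
    random guessing with ``n_trials`` evaluated trials.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    p = 1.0 / n_classes
    z = norm.isf(alpha / 2.0)
    n_adj = n_trials + z * z
    p_adj = (n_trials * p + z * z / 2.0) / n_adj
    upper = p_adj + z * np.sqrt(p_adj * (1 - p_adj) / n_adj)
    return ChanceLevel(n_trials, n_classes, alpha, float(min(upper, 1.0)))


def trial_majority_accuracy(predictions: np.ndarray, truth: np.ndarray,
                            eval_window: tuple[float, float],
                            time_axis: np.ndarray) -> float:
    """Fraction of trials whose in-window predictions are majority-correct.

    ``predictions`` is trials x samples of class labels.  A trial counts as
    correct iff strictly more than half of the predictions inside
    ``eval_window`` equal the true class; exact ties count as incorrect.
    """
    mask = (time_axis >= eval_window[0] - 1e-9) & (time_axis <= eval_window[1] + 1e-9)
    if not mask.any():
        raise ValueError("eval_window contains no samples")
    win = predictions[:, mask]
    correct = (win == np.asarray(truth, dtype=object)[:, None]).sum(axis=1)
    return float(np.mean(correct * 2 > mask.sum()))


def majority_label(predictions: np.ndarray, eval_window: tuple[float, float],
                   time_axis: np.ndarray, class_order: list[str]) -> np.ndarray:
    """Modal predicted label per trial inside the window (ties -> earlier class)."""
    mask = (time_axis >= eval_window[0] - 1e-9) & (time_axis <= eval_window[1] + 1e-9)
    win = predictions[:, mask]
    counts = np.stack([(win == c).sum(axis=1) for c in class_order], axis=1)
    return np.asarray(class_order, dtype=object)[np.argmax(counts, axis=1)]


def confusion_rownorm(predictions: np.ndarray, truth: np.ndarray,
                      class_order: list[str] | None = None) -> np.ndarray:
    """Row-normalized confusion matrix in percent (rows = true class)."""
    predictions = np.asarray(predictions, dtype=object)
    truth = np.asarray(truth, dtype=object)
    if len(predictions) != len(truth):
        raise ValueError("predictions and truth must have the same length")
    classes = class_order if class_order is not None else _ordered_classes(truth)
    mat = np.zeros((len(classes), len(classes)))
    for i, tc in enumerate(classes):
        row = predictions[truth == tc]
        if row.size == 0:
            import warnings

            warnings.warn(f"no trials with true class {tc!r}; row left at zero",
                          stacklevel=2)
            continue
        for j, pc in enumerate(classes):
            mat[i, j] = 100.0 * np.mean(row == pc)
    return mat


@dataclass
class PipelineSpec:
    """End-to-end decoding pipeline parameters used inside each CV fold."""

    bands: tuple = ((8.0, 16.0), (16.0, 30.0))
    fit_window: tuple[float, float] = (1.0, 3.0)
    train_times: tuple = (2.5,)
    csp_shrinkage: float | str = "auto"
    lda_shrinkage: float | str = "auto"
    filter_order: int = 4
    fit_scope: str = "fold"  # guard: anything else is refused


@dataclass
class CVResult:
    scheme: tuple[int, int]
    time_axis: np.ndarray
    accuracy_curve: np.ndarray  # mean over folds, per time point
    accuracy_sd: np.ndarray  # SD across folds
    peak: tuple[float, float]  # (time s, accuracy)
    trial_accuracy: float
    confusion: np.ndarray
    class_order: list[str]
    chance: ChanceLevel
    fold_trial_accuracies: np.ndarray = field(default_factory=lambda: np.zeros(0))
    oof_probs: np.ndarray | None = None  # trials x repeats? see estimate_bias
    oof_true: np.ndarray | None = None

    def median_accuracy(self, window: tuple[float, float] = (1.0, 4.0)) -> float:
        m = (self.time_axis >= window[0]) & (self.time_axis <= window[1])
        return float(np.median(self.accuracy_curve[m]))

    def to_dict(self) -> dict:
        return {
            "scheme": list(self.scheme),
            "time_axis": self.time_axis.tolist(),
            "accuracy_curve": self.accuracy_curve.tolist(),
            "accuracy_sd": self.accuracy_sd.tolist(),
            "peak_time": self.peak[0],
            "peak_accuracy": self.peak[1],
            "trial_accuracy": self.trial_accuracy,
            "confusion_percent": self.confusion.tolist(),
            "class_order": list(self.class_order),
            "chance_upper_bound": self.chance.upper_bound,
            "fold_trial_accuracies": self.fold_trial_accuracies.tolist(),
        }


def crossvalidate(
    ts: TrialSet,
    classes: list[str] | None = None,
    pipeline_spec: PipelineSpec | None = None,
    scheme: tuple[int, int] = (10, 5),
    eval_window: tuple[float, float] = (1.0, 4.0),
    seed: int = 0,
    collect_probs: bool = False,
) -> CVResult:
    """Repeated stratified k-fold CV with in-fold CSP and sLDA fitting.

    Per repeat, folds are stratified by class with shuffling seeded by
    ``seed + repeat``.  Band filtering of the trials is label-independent
    and precomputed once; everything label-dependent (CSP, sLDA) is fitted
    on training folds only.
    """
    spec = pipeline_spec or PipelineSpec()
    if spec.fit_scope != "fold":
        raise ValueError(
            "pipeline_spec requests fitting outside CV folds; refusing (leakage)"
        )
    classes = list(classes) if classes is not None else list(ts.classes)
    keep = np.isin(ts.labels, classes)
    ts = ts.select(keep)
    labels = ts.labels
    repeats, folds = scheme
    counts = {c: int((labels == c).sum()) for c in classes}
    if min(counts.values()) < folds:
        raise ValueError(f"per-class trial count {counts} below fold count {folds}")

    filtered = band_filter_trials(ts, spec.bands, spec.filter_order)
    n_trials, _, n_samples = ts.data.shape
    curves, fold_accs = [], []
    maj_preds = np.empty((repeats, n_trials), dtype=object)
    probs_acc: list[np.ndarray] = []
    true_acc: list[np.ndarray] = []

    for r in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + r)
        for train_idx, test_idx in skf.split(np.zeros(n_trials), labels):
            model, extractor = _fit_fold(filtered, ts, train_idx, classes, spec)
            test_filtered = [f.select(test_idx) for f in filtered]
            feats = extract_from_filtered(extractor, test_filtered, ts.select(test_idx))
            preds = model.predict(feats.values)  # trials x samples
            truth = labels[test_idx]
            curves.append((preds == truth[:, None]).mean(axis=0))
            fold_accs.append(
                trial_majority_accuracy(preds, truth, eval_window, ts.time_axis)
            )
            maj_preds[r, test_idx] = majority_label(
                preds, eval_window, ts.time_axis, classes
            )
            if collect_probs:
                tcols = [ts.time_to_sample(t) for t in spec.train_times]
                pv = model.predict_proba(feats.values[:, tcols, :].mean(axis=1))
                probs_acc.append(pv)
                true_acc.append(truth)

    curves = np.stack(curves)
    mean_curve = curves.mean(axis=0)
    sd_curve = curves.std(axis=0, ddof=1) if len(curves) > 1 else np.zeros(n_samples)
    ipk = int(np.argmax(mean_curve))
    confusion = confusion_rownorm(maj_preds.ravel(), np.tile(labels, repeats), classes)
    trial_acc = float(np.mean(fold_accs))  # majority vote with ties incorrect
    return CVResult(
        scheme=scheme,
        time_axis=ts.time_axis,
        accuracy_curve=mean_curve,
        accuracy_sd=sd_curve,
        peak=(float(ts.time_axis[ipk]), float(mean_curve[ipk])),
        trial_accuracy=trial_acc,
        confusion=confusion,
        class_order=classes,
        chance=chance_level(n_trials, len(classes)),
        fold_trial_accuracies=np.array(fold_accs),
        oof_probs=np.concatenate(probs_acc) if probs_acc else None,
        oof_true=np.concatenate(true_acc) if true_acc else None,
    )


def _fit_fold(filtered, ts, train_idx, classes, spec: PipelineSpec):
    """CSP models + sLDA fitted on the training indices only."""
    models = []
    for band, fts in zip(spec.bands, filtered):
        sub = fts.select(train_idx)
        for pair in combinations(classes, 2):
            models.append(fit_csp(sub, pair, spec.fit_window,
                                  spec.csp_shrinkage, tuple(band)))
    extractor = FeatureExtractor(
        bands=[tuple(b) for b in spec.bands], csp_models=models, sfreq=ts.sfreq,
        channel_labels=list(ts.channel_labels), filter_order=spec.filter_order,
    )
    train_filtered = [f.select(train_idx) for f in filtered]
    feats = extract_from_filtered(extractor, train_filtered, ts.select(train_idx))
    fm = feats.at_times(list(spec.train_times))
    model = fit_slda(fm.values, fm.labels, spec.lda_shrinkage)
    # keep prediction order aligned with the requested class order
    order = [model.class_list.index(c) for c in classes]
    model = SLDAModel(list(classes), model.means[order], model.pooled_cov,
                      model.weights[order], model.bias[order],
                      model.shrinkage_intensity)
    return model, extractor


def rank_combinations(
    ts: TrialSet,
    task_pool: list[str],
    k: int = 4,
    scheme: tuple[int, int] = (10, 5),
    seed: int = 0,
    pipeline_spec: PipelineSpec | None = None,
    eval_window: tuple[float, float] = (1.0, 4.0),
    median_window: tuple[float, float] = (1.0, 4.0),
) -> pd.DataFrame:
    """Cross-validated discriminability of every k-task subset of a pool.

    For a pool of 8 tasks and k = 4 this evaluates all C(8, 4) = 70
    combinations and reports peak accuracy (with SD across folds at the
    peak) and the median of the accuracy curve over ``median_window``,
    sorted by peak accuracy.
    """
    missing = [c for c in task_pool if c not in ts.labels]
    if missing:
        raise ValueError(f"pool classes missing from data: {missing}")
    rows = []
    for combo in combinations(task_pool, k):
        res = crossvalidate(ts, list(combo), pipeline_spec, scheme,
                            eval_window, seed)
        ipk = int(np.argmax(res.accuracy_curve))
        rows.append({
            "combination": "-".join(combo),
            "peak_accuracy_pct": 100.0 * res.peak[1],
            "peak_sd_pct": 100.0 * float(res.accuracy_sd[ipk]),
            "median_accuracy_pct": 100.0 * res.median_accuracy(median_window),
            "peak_time_s": res.peak[0],
        })
    df = pd.DataFrame(rows).sort_values("peak_accuracy_pct", ascending=False)
    return df.reset_index(drop=True)
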