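"""Core in-memory containers for continuous EEG and cue-locked trials.

A :class:`Recording` is a plain channels-by-samples array in microvolts with a
sampling rate, ordered channel labels and an event stream (sample index,
integer code).  A :class:`TrialSet` is the cue-locked 3-D counterpart:
trials x channels x samples with a time axis relative to the cue, one class
label per trial and a boolean mask of trials retained after artifact
rejection.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = ["Recording", "TrialSet", "LabelledSession"]


@dataclass
class Recording:
    """Continuous multichannel EEG.

    Parameters
    ----------
    data
        ``(n_channels, n_samples)`` float array, microvolts.
    sfreq
        Sampling rate in Hz, > 0.
    channel_labels
        Ordered channel names, one per row of ``data``.
    events
        ``(sample_index, code)`` pairs, sorted by sample index.
    """

    data: np.ndarray
    sfreq: float
    channel_labels: list[str]
    events: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (channels x samples)")
        if self.sfreq <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_labels) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for {self.data.shape[0]} data rows"
            )
        self.channel_labels = list(self.channel_labels)
        self.events = [(int(s), int(c)) for s, c in self.events]
        if any(b[0] < a[0] for a, b in zip(self.events, self.events[1:])):
            raise ValueError("events must be sorted by sample index")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        """Length in seconds."""
        return self.n_samples / self.sfreq

    def index(self, label: str) -> int:
        """Row index of a channel label; raises ``KeyError`` if absent."""
        try:
            return self.channel_labels.index(label)
        except ValueError:
            raise KeyError(f"channel {label!r} not in recording") from None

    def pick(self, labels: list[str]) -> "Recording":
        """Sub-recording restricted to ``labels`` (in the given order)."""
        idx = [self.index(lb) for lb in labels]
        return Recording(self.data[idx].copy(), self.sfreq, list(labels), list(self.events))

    def copy(self) -> "Recording":
        return Recording(
            self.data.copy(), self.sfreq, list(self.channel_labels), list(self.events)
        )


@dataclass
class TrialSet:
    """Cue-locked segments: ``data`` is trials x channels x samples."""

    data: np.ndarray
    time_axis: np.ndarray
    labels: np.ndarray
    sfreq: float
    channel_labels: list[str]
    kept_mask: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.time_axis = np.asarray(self.time_axis, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.data.ndim != 3:
            raise ValueError("data must be 3-D (trials x channels x samples)")
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("one label per trial required")
        if len(self.time_axis) != self.data.shape[2]:
            raise ValueError("time_axis length must match sample count")
        if self.kept_mask is None:
            self.kept_mask = np.ones(self.data.shape[0], dtype=bool)
        else:
            self.kept_mask = np.asarray(self.kept_mask, dtype=bool)

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    @property
    def classes(self) -> np.ndarray:
        """Unique labels in first-appearance order."""
        _, first = np.unique(self.labels, return_index=True)
        return self.labels[np.sort(first)]

    def kept(self) -> "TrialSet":
        """Trials surviving rejection, with a fresh all-true mask."""
        m = self.kept_mask
        return TrialSet(
            self.data[m], self.time_axis, self.labels[m], self.sfreq,
            list(self.channel_labels),
        )

    def select(self, idx: np.ndarray) -> "TrialSet":
        """Trial subset by integer or boolean index."""
        return TrialSet(
            self.data[idx], self.time_axis, self.labels[idx], self.sfreq,
            list(self.channel_labels), np.asarray(self.kept_mask)[idx],
        )

    def time_to_sample(self, t: float) -> int:
        """Index of the sample closest to time ``t`` (seconds, cue-relative)."""
        return int(np.argmin(np.abs(self.time_axis - t)))

    def window_slice(self, window: tuple[float, float]) -> slice:
        lo, hi = window
        i0 = int(np.searchsorted(self.time_axis, lo - 1e-9))
        i1 = int(np.searchsorted(self.time_axis, hi + 1e-9))
        return slice(i0, i1)


@dataclass
class LabelledSession:
    """A recording with its trial labels, resting span and artifact truth.

    ``rest_segment`` is a ``(start, stop)`` sample span of artifact-free
    resting EEG used for variance normalization and artifact-gate
    calibration.  ``artifact_intervals`` holds ground-truth contaminated
    intervals ``(start_s, stop_s, kind)`` when the session was produced by
    the simulator.
    """

    recording: Recording
    events: list[tuple[int, int]]
    labels: list[str]
    rest_segment: tuple[int, int]
    artifact_intervals: list[tuple[float, float, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.events = [(int(s), int(c)) for s, c in self.events]
        if any(b[0] <= a[0] for a, b in zip(self.events, self.events[1:])):
            raise ValueError("events must be strictly increasing in sample index")

    @property
    def cue_events(self) -> list[tuple[int, int]]:
        return list(self.events)

    def resting(self) -> Recording:
        """The resting span as its own Recording (events dropped)."""
        a, b = self.rest_segment
        rec = self.recording
        return Recording(rec.data[:, a:b].copy(), rec.sfreq, list(rec.channel_labels))

    def copy(self) -> "LabelledSession":
        return LabelledSession(
            self.recording.copy(), list(self.events), list(self.labels),
            tuple(self.rest_segment), list(self.artifact_intervals),
        )
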