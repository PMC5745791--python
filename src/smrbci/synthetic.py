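"""Synthetic sensorimotor-rhythm EEG.

The generator produces multichannel EEG with the statistical structure a
motor/mental-imagery BCI assumes: a 1/f background, band-limited oscillatory
sources (mu ~8-16 Hz, beta ~16-30 Hz) with fixed scalp topographies, and
class-dependent event-related desynchronization (ERD) — a fractional drop in
source band power while a mental task is performed.  Blink and step
artifacts can be injected with ground truth, so artifact gates can be
evaluated against known contamination.

Model: each channel is a linear mixture of sources plus independent
1/f-shaped noise,

    x_c(t) = sum_s M[s, c] * g_s(t) * u_s(t) + n_c(t)

where ``u_s`` is unit-variance band-limited noise, ``M`` the mixing matrix
and ``g_s(t)`` a slowly varying amplitude envelope.  ERD of depth ``d``
(fractional power change, > -1) scales the envelope by ``sqrt(1 + d)``
during the imagery window, with 250 ms ramps at the boundaries so the
modulation itself does not create broadband transients.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal

from .containers import LabelledSession, Recording

__all__ = [
    "Source",
    "SimConfig",
    "ParadigmSpec",
    "DEFAULT_MONTAGE",
    "LAPLACIAN_NEIGHBOURS",
    "generate_resting",
    "generate_calibration_session",
    "generate_race_stream",
    "inject_artifacts",
    "RaceStreamSimulator",
]

# 32-channel layout: C3/Cz/C4 each with four orthogonal close neighbours
# (10-5-style names), AFz, and frontal/parietal coverage.
LAPLACIAN_NEIGHBOURS: dict[str, list[str]] = {
    "C3": ["FCC3h", "CCP3h", "C5h", "C1h"],
    "Cz": ["FCCz", "CCPz", "C1", "C2"],
    "C4": ["FCC4h", "CCP4h", "C2h", "C6h"],
}

DEFAULT_MONTAGE: list[str] = (
    ["C3", "Cz", "C4"]
    + LAPLACIAN_NEIGHBOURS["C3"]
    + LAPLACIAN_NEIGHBOURS["Cz"]
    + LAPLACIAN_NEIGHBOURS["C4"]
    + ["AFz"]
    + ["Fp1", "Fp2", "F7", "F3", "Fz", "F4", "F8", "FC5", "FC6",
       "P7", "P3", "Pz", "P4", "P8", "O1", "O2"]
)

# Blink topography: frontal-dominant, maximal at AFz.
_BLINK_WEIGHTS = {
    "AFz": 1.0, "Fp1": 0.85, "Fp2": 0.85, "F7": 0.35, "F3": 0.45,
    "Fz": 0.5, "F4": 0.45, "F8": 0.35, "FCC3h": 0.1, "FCCz": 0.12,
    "FCC4h": 0.1,
}

DEFAULT_CLASSES = ["HAND", "FEET", "SUB", "REST"]


@dataclass
class Source:
    """One band-limited oscillatory source."""

    name: str
    band: tuple[float, float]
    amplitude: float  # uV RMS at unit mixing weight


def _default_sources() -> list[Source]:
    return [
        Source("mu_C3", (8.0, 16.0), 10.0),
        Source("beta_C3", (16.0, 30.0), 6.0),
        Source("mu_Cz", (8.0, 16.0), 10.0),
        Source("beta_Cz", (16.0, 30.0), 6.0),
        Source("mu_Pz", (8.0, 16.0), 10.0),
        Source("beta_Pz", (16.0, 30.0), 6.0),
    ]


def _default_mixing(sources: list[Source], channels: list[str]) -> np.ndarray:
    """Focal projection: weight 1 at the source's centre, 0.5 at neighbours."""
    centre_map = {
        "mu_C3": "C3", "beta_C3": "C3",
        "mu_Cz": "Cz", "beta_Cz": "Cz",
        "mu_Pz": "Pz", "beta_Pz": "Pz",
    }
    neigh_map = dict(LAPLACIAN_NEIGHBOURS)
    neigh_map["Pz"] = ["P3", "P4"]
    M = np.zeros((len(sources), len(channels)))
    for i, src in enumerate(sources):
        centre = centre_map.get(src.name)
        if centre is None or centre not in channels:
            continue
        M[i, channels.index(centre)] = 1.0
        for nb in neigh_map.get(centre, []):
            if nb in channels:
                M[i, channels.index(nb)] = 0.5
    return M


def _default_erd_depth() -> dict[str, dict[str, float]]:
    return {
        "HAND": {"mu_C3": -0.5, "beta_C3": -0.5},
        "FEET": {"mu_Cz": -0.5, "beta_Cz": -0.5},
        "SUB": {"mu_Pz": -0.5, "beta_Pz": -0.5},
        "REST": {},
    }


@dataclass
class SimConfig:
    """Simulator parameters.

    ``erd_depth`` maps class -> source name -> fractional band-power change
    in ``(-1, inf)`` (negative = desynchronization); each source carries its
    own band.  ``mixing_matrix`` has one row per source and one column per
    channel.  ``artifact_rates`` is (blinks/min, steps/min) for spontaneous
    contamination of generated streams.
    """

    sampling_rate: float = 512.0
    channel_labels: list[str] = field(default_factory=lambda: list(DEFAULT_MONTAGE))
    class_set: list[str] = field(default_factory=lambda: list(DEFAULT_CLASSES))
    sources: list[Source] = field(default_factory=_default_sources)
    erd_depth: dict[str, dict[str, float]] = field(default_factory=_default_erd_depth)
    mixing_matrix: np.ndarray | None = None
    background_slope: float = 1.0
    noise_sd: float = 10.0
    artifact_rates: tuple[float, float] = (0.0, 0.0)
    blink_amplitude: float = 150.0
    step_amplitude: float = 80.0
    erd_ramp: float = 0.25  # s, envelope transition length
    seed: int = 0

    def __post_init__(self) -> None:
        if self.sampling_rate <= 0:
            raise ValueError("sampling_rate must be positive")
        if self.mixing_matrix is None:
            self.mixing_matrix = _default_mixing(self.sources, self.channel_labels)
        self.mixing_matrix = np.asarray(self.mixing_matrix, dtype=float)
        if self.mixing_matrix.shape != (len(self.sources), len(self.channel_labels)):
            raise ValueError(
                "mixing_matrix must be sources x channels "
                f"({len(self.sources)} x {len(self.channel_labels)})"
            )
        for cls, per_src in self.erd_depth.items():
            for name, d in per_src.items():
                if d <= -1:
                    raise ValueError(
                        f"erd_depth[{cls}][{name}] = {d} <= -1: power cannot go negative"
                    )
            unknown = set(per_src) - {s.name for s in self.sources}
            if unknown:
                raise ValueError(f"erd_depth for unknown sources {sorted(unknown)}")

    @property
    def source_names(self) -> list[str]:
        return [s.name for s in self.sources]


@dataclass
class ParadigmSpec:
    """Cue-based calibration timing: fixation cross at -3 s, cue at 0,
    imagery for 5 s, then a 2-3 s inter-trial break drawn uniformly.  A
    resting baseline of ``rest_duration`` seconds opens the session."""

    pre_cue: float = 3.0
    imagery: float = 5.0
    break_range: tuple[float, float] = (2.0, 3.0)
    rest_duration: float = 30.0
    cue_duration: float = 1.25


# ---------------------------------------------------------------------------
# low-level signal builders


def _background(rng: np.random.Generator, n_ch: int, n: int, sfreq: float,
                slope: float, sd: float) -> np.ndarray:
    """1/f^slope-shaped Gaussian noise, per channel, total SD ``sd`` uV."""
    if sd == 0 or n == 0:
        return np.zeros((n_ch, n))
    freqs = np.fft.rfftfreq(n, 1.0 / sfreq)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-slope / 2.0)
    shaping[0] = 0.0
    spec = (rng.standard_normal((n_ch, freqs.size))
            + 1j * rng.standard_normal((n_ch, freqs.size))) * shaping
    x = np.fft.irfft(spec, n=n, axis=1)
    x *= sd / np.maximum(x.std(axis=1, keepdims=True), 1e-30)
    return x


def _band_noise(rng: np.random.Generator, n: int, sfreq: float,
                band: tuple[float, float]) -> np.ndarray:
    """Unit-variance band-limited noise (4th-order Butterworth of white noise)."""
    if n == 0:
        return np.zeros(0)
    sos = signal.butter(4, band, btype="bandpass", fs=sfreq, output="sos")
    x = signal.sosfilt(sos, rng.standard_normal(n))
    sd = x.std()
    return x / sd if sd > 0 else x


def _smooth_gain(power_gain: np.ndarray, ramp_samples: int) -> np.ndarray:
    """Amplitude envelope from a piecewise-constant power-gain timeline.

    The power timeline is smoothed with a Hann kernel of the ramp length
    (raised-cosine transitions) before taking the square root.
    """
    if ramp_samples >= 2:
        kern = np.hanning(ramp_samples + 2)[1:-1]
        kern /= kern.sum()
        padded = np.pad(power_gain, (ramp_samples, ramp_samples), mode="edge")
        power_gain = np.convolve(padded, kern, mode="same")[ramp_samples:-ramp_samples]
    return np.sqrt(np.maximum(power_gain, 0.0))


def _render(config: SimConfig, rng: np.random.Generator, n: int,
            power_gains: np.ndarray) -> np.ndarray:
    """Mix sources under per-source power-gain timelines onto channels.

    ``power_gains`` is (n_sources, n) of piecewise-constant power scalings
    (1 = baseline).
    """
    sfreq = config.sampling_rate
    ramp = int(round(config.erd_ramp * sfreq))
    data = _background(rng, len(config.channel_labels), n, sfreq,
                       config.background_slope, config.noise_sd)
    for i, src in enumerate(config.sources):
        u = _band_noise(rng, n, sfreq, src.band) * src.amplitude
        g = _smooth_gain(power_gains[i], ramp)
        data += np.outer(config.mixing_matrix[i], u * g)
    return data


def _spontaneous_artifacts(config: SimConfig, rng: np.random.Generator,
                           duration: float) -> tuple[list[float], list[float]]:
    """Poisson blink/step times (seconds) per ``artifact_rates``."""
    out = []
    for rate in config.artifact_rates:
        lam = rate / 60.0 * duration
        k = rng.poisson(lam) if lam > 0 else 0
        out.append(sorted(rng.uniform(0.5, max(duration - 0.5, 0.5), size=k).tolist()))
    return out[0], out[1]


# ---------------------------------------------------------------------------
# public generators


def generate_resting(config: SimConfig, duration: float,
                     seed: int | None = None) -> Recording:
    """Stationary background EEG with idling (unmodulated) rhythms.

    No class modulation is applied; sources run at baseline amplitude.
    Spontaneous artifacts are added at ``config.artifact_rates`` (default
    none).  Deterministic for a fixed config/seed.
    """
    if duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    n = int(round(duration * config.sampling_rate))
    gains = np.ones((len(config.sources), n))
    data = _render(config, rng, n, gains)
    rec = Recording(data, config.sampling_rate, list(config.channel_labels))
    blink_t, step_t = _spontaneous_artifacts(config, rng, duration)
    if blink_t or step_t:
        sess = inject_artifacts(
            LabelledSession(rec, [], [], (0, 0)), blink_t, step_t,
            config.blink_amplitude, step_amplitude=config.step_amplitude,
            rng=rng,
        )
        rec = sess.recording
    return rec


def generate_calibration_session(
    config: SimConfig,
    trials_per_class: int,
    paradigm: ParadigmSpec | None = None,
    seed: int | None = None,
) -> LabelledSession:
    """Cue-based calibration run in pseudorandomized class order.

    Each trial is ``pre_cue`` seconds of baseline, a cue event at t=0, an
    imagery window of ``paradigm.imagery`` seconds during which the trial
    class's sources are power-scaled by ``1 + erd_depth``, and a uniform
    2-3 s break.  Cue event codes are ``1 + index`` of the class in
    ``config.class_set``.
    """
    if trials_per_class < 1:
        raise ValueError("trials_per_class must be >= 1")
    paradigm = paradigm or ParadigmSpec()
    for cls in config.class_set:
        if cls not in config.erd_depth:
            raise ValueError(f"class {cls!r} has no erd_depth entry in config")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sfreq = config.sampling_rate
    classes = config.class_set
    order = rng.permutation(np.repeat(classes, trials_per_class))
    breaks = rng.uniform(*paradigm.break_range, size=len(order))

    # build the sample timeline
    cue_samples: list[int] = []
    spans: list[tuple[int, int, str]] = []  # imagery spans per trial
    t = paradigm.rest_duration
    for cls, br in zip(order, breaks):
        cue = t + paradigm.pre_cue
        cue_samples.append(int(round(cue * sfreq)))
        spans.append((int(round(cue * sfreq)),
                      int(round((cue + paradigm.imagery) * sfreq)), cls))
        t = cue + paradigm.imagery + br
    n = int(round(t * sfreq))

    gains = np.ones((len(config.sources), n))
    name_to_row = {s.name: i for i, s in enumerate(config.sources)}
    for a, b, cls in spans:
        for src_name, depth in config.erd_depth.get(cls, {}).items():
            gains[name_to_row[src_name], a:b] = 1.0 + depth

    data = _render(config, rng, n, gains)
    rec = Recording(data, sfreq, list(config.channel_labels))
    events = [(s, 1 + classes.index(cls)) for s, cls in zip(cue_samples, order)]
    rec.events = list(events)
    sess = LabelledSession(
        rec, events, [str(c) for c in order],
        (0, int(round(paradigm.rest_duration * sfreq))),
    )
    blink_t, step_t = _spontaneous_artifacts(config, rng, t)
    # keep the resting span clean by construction
    rest_end = paradigm.rest_duration
    blink_t = [x for x in blink_t if x > rest_end]
    step_t = [x for x in step_t if x > rest_end]
    if blink_t or step_t:
        sess = inject_artifacts(sess, blink_t, step_t, config.blink_amplitude,
                                step_amplitude=config.step_amplitude, rng=rng)
    return sess


def generate_race_stream(config: SimConfig, track, paradigm: ParadigmSpec | None = None,
                         seed: int | None = None) -> LabelledSession:
    """Continuous EEG following the pad-race training paradigm.

    Each pad lasts 10 s: on action pads the pad's class modulation is active
    for the first 5 s (the performed mental task) and off for the second 5 s
    (relaxation); on REST pads there is no modulation at all.  A pad-onset
    event is emitted at each pad entry.  A resting baseline opens the stream.
    """
    pads = list(getattr(track, "pads", track))
    if not pads:
        raise ValueError("track must contain at least one pad")
    paradigm = paradigm or ParadigmSpec()
    rng = np.random.default_rng(config.seed if seed is None else seed)
    sfreq = config.sampling_rate
    task_s, break_s = 5.0, 5.0
    pad_dur = task_s + break_s
    rest_n = int(round(paradigm.rest_duration * sfreq))
    n = rest_n + int(round(len(pads) * pad_dur * sfreq))

    gains = np.ones((len(config.sources), n))
    name_to_row = {s.name: i for i, s in enumerate(config.sources)}
    events = []
    labels = []
    for i, pad in enumerate(pads):
        onset = rest_n + int(round(i * pad_dur * sfreq))
        events.append((onset, 1 + config.class_set.index(pad)))
        labels.append(str(pad))
        if pad != "REST":
            stop = onset + int(round(task_s * sfreq))
            for src_name, depth in config.erd_depth.get(pad, {}).items():
                gains[name_to_row[src_name], onset:stop] = 1.0 + depth

    data = _render(config, rng, n, gains)
    rec = Recording(data, sfreq, list(config.channel_labels), events)
    sess = LabelledSession(rec, events, labels, (0, rest_n))
    blink_t, step_t = _spontaneous_artifacts(config, rng, n / sfreq)
    blink_t = [x for x in blink_t if x > paradigm.rest_duration]
    step_t = [x for x in step_t if x > paradigm.rest_duration]
    if blink_t or step_t:
        sess = inject_artifacts(sess, blink_t, step_t, config.blink_amplitude,
                                step_amplitude=config.step_amplitude, rng=rng)
    return sess


def _blink_waveform(sfreq: float, amplitude: float) -> np.ndarray:
    """0.4 s raised-cosine transient — energy below 10 Hz."""
    n = int(round(0.4 * sfreq))
    return amplitude * np.hanning(n)


def inject_artifacts(
    session: LabelledSession,
    blink_times: list[float],
    step_times: list[float],
    blink_amplitude: float = 150.0,
    step_amplitude: float = 80.0,
    step_duration: float = 3.0,
    step_channels: list[str] | None = None,
    rng: np.random.Generator | None = None,
) -> LabelledSession:
    """Add blink and step artifacts at given times (seconds).

    Blinks are low-frequency (< 10 Hz) transients with frontal-dominant
    topography, maximal at AFz.  Steps are sustained baseline shifts on
    ``step_channels`` (default: a fixed frontal/central pair).  Ground-truth
    contaminated intervals are appended to ``artifact_intervals``.
    """
    sess = session.copy()
    rec = sess.recording
    sfreq = rec.sfreq
    dur = rec.duration
    for t in list(blink_times) + list(step_times):
        if not (0 <= t <= dur):
            raise ValueError(f"artifact time {t} s outside recording span (0, {dur:.2f})")

    blink = _blink_waveform(sfreq, blink_amplitude)
    weights = np.array([_BLINK_WEIGHTS.get(lb, 0.0) for lb in rec.channel_labels])
    for t in blink_times:
        a = int(round(t * sfreq)) - blink.size // 2
        b = a + blink.size
        lo, hi = max(a, 0), min(b, rec.n_samples)
        if hi > lo:
            rec.data[:, lo:hi] += np.outer(weights, blink[lo - a:hi - a])
        sess.artifact_intervals.append((max(t - 0.2, 0.0), min(t + 0.2, dur), "blink"))

    if step_channels is None:
        step_channels = [lb for lb in ("Fz", "C3") if lb in rec.channel_labels] \
            or rec.channel_labels[:1]
    idx = [rec.index(lb) for lb in step_channels]
    for t in step_times:
        a = int(round(t * sfreq))
        b = min(a + int(round(step_duration * sfreq)), rec.n_samples)
        rec.data[np.ix_(idx, range(a, b))] += step_amplitude
        sess.artifact_intervals.append((t, min(t + step_duration, dur), "step"))
    return sess


class RaceStreamSimulator:
    """Incremental EEG source for closed-loop race simulation.

    Pre-renders unit-amplitude source signals and background for up to
    ``max_duration`` seconds, then serves channel-space blocks on demand
    with the envelope of the currently active class applied.  Envelope
    transitions use the same ramp length as the batch generators, tracked
    across block boundaries, so the stream is continuous.
    """

    def __init__(self, config: SimConfig, max_duration: float = 600.0,
                 seed: int | None = None):
        self.config = config
        rng = np.random.default_rng(config.seed if seed is None else seed)
        sfreq = config.sampling_rate
        self._n_max = int(round(max_duration * sfreq))
        self._bg = _background(rng, len(config.channel_labels), self._n_max,
                               sfreq, config.background_slope, config.noise_sd)
        self._src = np.stack([
            _band_noise(rng, self._n_max, sfreq, s.band) * s.amplitude
            for s in config.sources
        ]) if config.sources else np.zeros((0, self._n_max))
        self._pos = 0
        self._ramp = max(int(round(config.erd_ramp * sfreq)), 1)
        self._gain = np.ones(len(config.sources))  # current power gains
        self._target = np.ones(len(config.sources))

    def set_active_class(self, cls: str | None) -> None:
        """Switch the modulation state (None = baseline everywhere)."""
        self._target = np.ones(len(self.config.sources))
        if cls is not None:
            name_to_row = {s.name: i for i, s in enumerate(self.config.sources)}
            for src_name, depth in self.config.erd_depth.get(cls, {}).items():
                self._target[name_to_row[src_name]] = 1.0 + depth

    def next_block(self, n: int) -> np.ndarray:
        """Next ``n`` samples as channels x n; raises when exhausted."""
        if self._pos + n > self._n_max:
            raise RuntimeError("RaceStreamSimulator exhausted; increase max_duration")
        sl = slice(self._pos, self._pos + n)
        # linear power-gain ramp toward the target across the block
        steps = np.arange(1, n + 1) / self._ramp
        frac = np.minimum(steps, 1.0)
        gains = self._gain[:, None] + (self._target - self._gain)[:, None] * frac[None, :]
        block = self.config.mixing_matrix.T @ (self._src[:, sl] * np.sqrt(gains)) \
            if len(self.config.sources) else np.zeros((len(self.config.channel_labels), n))
        block = block + self._bg[:, sl]
        self._gain = gains[:, -1].copy()
        self._pos += n
        return block
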