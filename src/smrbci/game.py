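"""Pad-race game simulator.

The avatar moves along a straight track of pads — three action pad types
(one per mental-task command) and a rest pad, in a pseudorandom order with
exact per-class counts.  On an action pad the correct command boosts the
avatar, a wrong command slows it, and no command leaves the base speed; on
rest pads any command slows it (there is no correct command).  The race
score is the runtime: the time to traverse the whole track.

Speed constants are not dictated by any official game; the defaults are
chosen so a fully passive run over a 16-pad track takes ~180 s and a
perfect run ~90 s, bracketing the scale of competitive runtimes, and are
fully configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RaceTrack",
    "RaceConfig",
    "RaceResult",
    "ACTION_CLASSES",
    "generate_track",
    "run_race",
    "random_baseline",
    "paradigm_triggers",
    "closed_loop_race",
]

ACTION_CLASSES = ["HAND", "FEET", "SUB"]
REST = "REST"


@dataclass
class RaceTrack:
    pads: list[str]
    pad_length: float = 11.25  # distance units
    trials_per_class: int = 4

    @property
    def n_pads(self) -> int:
        return len(self.pads)

    @property
    def total_length(self) -> float:
        return self.n_pads * self.pad_length


@dataclass
class RaceConfig:
    base_speed: float = 1.0  # units/s
    boost_factor: float = 2.0
    slow_factor: float = 0.5
    tick: float = 1.0 / 16.0  # s, command effect duration

    def __post_init__(self) -> None:
        if not (self.boost_factor > 1.0 > self.slow_factor > 0.0):
            raise ValueError("need boost_factor > 1 > slow_factor > 0")


@dataclass
class RaceResult:
    runtime: float
    pad_log: list[dict] = field(default_factory=list)
    correct: int = 0
    wrong: int = 0
    none: int = 0

    @property
    def n_commands(self) -> int:
        return self.correct + self.wrong + self.none


def generate_track(trials_per_class: int = 4, seed: int = 0,
                   pad_length: float = 11.25,
                   classes: list[str] | None = None) -> RaceTrack:
    """Pseudorandom pad sequence with exact per-class counts.

    ``trials_per_class`` pads of each of the three action classes plus the
    rest class: 16 pads at 4 TPC (the competition setting), 20 at 5 TPC.
    """
    if trials_per_class < 1:
        raise ValueError("trials_per_class must be >= 1")
    classes = list(classes) if classes is not None else ACTION_CLASSES + [REST]
    rng = np.random.default_rng(seed)
    pads = list(rng.permutation(np.repeat(classes, trials_per_class)))
    return RaceTrack([str(p) for p in pads], pad_length, trials_per_class)


def _speed(pad: str, cmd: str | None, cfg: RaceConfig) -> tuple[float, str]:
    """Per-tick speed and command outcome (correct/wrong/none).

    A decoder output equal to the rest class is "no command" — the rest
    class exists so the pilot can deliberately send nothing.
    """
    if cmd is None or cmd == REST:
        return cfg.base_speed, "none"
    if pad == REST:
        return cfg.base_speed * cfg.slow_factor, "wrong"
    if cmd == pad:
        return cfg.base_speed * cfg.boost_factor, "correct"
    return cfg.base_speed * cfg.slow_factor, "wrong"


def run_race(track: RaceTrack, cfg: RaceConfig, commands) -> RaceResult:
    """Replay a command stream over a track; deterministic.

    ``commands`` may be a CommandStream (entries at their own times) or a
    plain sequence of commands taken one per tick.  A command's effect
    lasts until the next decision tick.  Runtime has tick resolution.
    """
    entries = getattr(commands, "entries", None)
    if entries is not None:
        times = np.array([t for t, _, _ in entries])
        cmds = [c for _, c, _ in entries]
    else:
        times = None
        cmds = list(commands)

    pos = 0.0
    t = 0.0
    result = RaceResult(runtime=0.0)
    pad_idx_prev = 0
    pad_enter_t = 0.0
    i_seq = 0
    total = track.total_length
    max_t = total / (cfg.base_speed * cfg.slow_factor) * 2 + 60.0
    while pos < total and t < max_t:
        pad_idx = min(int(pos / track.pad_length), track.n_pads - 1)
        if pad_idx != pad_idx_prev:
            result.pad_log.append({"pad": track.pads[pad_idx_prev],
                                   "entered": pad_enter_t, "left": t})
            pad_enter_t = t
            pad_idx_prev = pad_idx
        if times is not None:
            j = np.searchsorted(times, t + 1e-9) - 1
            cmd = cmds[j] if j >= 0 else None
        else:
            cmd = cmds[i_seq] if i_seq < len(cmds) else None
            i_seq += 1
        v, outcome = _speed(track.pads[pad_idx], cmd, cfg)
        setattr(result, outcome, getattr(result, outcome) + 1)
        pos += v * cfg.tick
        t += cfg.tick
    result.pad_log.append({"pad": track.pads[pad_idx_prev],
                           "entered": pad_enter_t, "left": t})
    result.runtime = t
    return result


def random_baseline(track_spec: dict | RaceTrack, cfg: RaceConfig,
                    n_runs: int = 1000, seed: int = 0,
                    classes: list[str] | None = None) -> float:
    """Median runtime with uniformly random commands at the tick rate.

    This is the significance threshold for real races: a closed-loop run
    only demonstrates control if it beats the runtime a random input
    achieves.  Each run uses a freshly generated track (same per-class
    counts) and an independent random command stream.
    """
    if n_runs < 100:
        raise ValueError("n_runs must be >= 100 for a stable median")
    classes = list(classes) if classes is not None else ACTION_CLASSES + [REST]
    rng = np.random.default_rng(seed)
    if isinstance(track_spec, RaceTrack):
        tpc, pad_len = track_spec.trials_per_class, track_spec.pad_length
    else:
        tpc = track_spec.get("trials_per_class", 4)
        pad_len = track_spec.get("pad_length", 11.25)
    # upper bound on ticks per run: full track at the slow factor
    max_ticks = int(np.ceil(
        len(classes) * tpc * pad_len / (cfg.base_speed * cfg.slow_factor)
        / cfg.tick)) + 16
    runtimes = np.empty(n_runs)
    for i in range(n_runs):
        track = generate_track(tpc, seed=int(rng.integers(2 ** 31)),
                               pad_length=pad_len, classes=classes)
        cmds = rng.choice(classes, size=max_ticks)
        runtimes[i] = run_race(track, cfg, list(cmds)).runtime
    return float(np.median(runtimes))


def paradigm_triggers(track: RaceTrack, cfg: RaceConfig) -> list[tuple[float, str]]:
    """Training-paradigm events under passive (no-command) dynamics.

    Per pad: a task-onset trigger at pad entry carrying the pad's class,
    and a rest marker ("BREAK") at half-pad — the pilot performs the task
    on the first half of each pad and relaxes on the second half.
    """
    pad_time = track.pad_length / cfg.base_speed
    if pad_time < 10.0:
        raise ValueError(
            f"pad traversal time {pad_time:.1f} s < 10 s: too short for the "
            "5 s task + 5 s break paradigm"
        )
    events = []
    for i, pad in enumerate(track.pads):
        events.append((i * pad_time, pad))
        events.append((i * pad_time + pad_time / 2.0, "BREAK"))
    return events


def closed_loop_race(
    decoder,
    stream,
    track: RaceTrack,
    cfg: RaceConfig,
    max_duration: float = 400.0,
) -> RaceResult:
    """Co-simulate EEG generation, decoding and avatar dynamics.

    ``stream`` is a :class:`~smrbci.synthetic.RaceStreamSimulator`; at every
    decision tick it renders the next EEG block with the modulation of the
    pad the avatar currently occupies (no modulation on rest pads), the
    decoder turns it into a command, and the command drives the avatar for
    one tick.
    """
    sfreq = decoder.sfreq
    n_block = int(round(cfg.tick * sfreq))
    pos, t = 0.0, 0.0
    result = RaceResult(runtime=0.0)
    total = track.total_length
    current_pad = None
    while pos < total and t < max_duration:
        pad_idx = min(int(pos / track.pad_length), track.n_pads - 1)
        pad = track.pads[pad_idx]
        if pad != current_pad:
            stream.set_active_class(None if pad == REST else pad)
            current_pad = pad
        block = stream.next_block(n_block)
        out = decoder.process(block)
        cmd = out.entries[-1][1] if out.entries else None
        v, outcome = _speed(pad, cmd, cfg)
        setattr(result, outcome, getattr(result, outcome) + 1)
        pos += v * cfg.tick
        t += cfg.tick
    result.runtime = t
    return result
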