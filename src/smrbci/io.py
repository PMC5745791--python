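"""File formats and the session store.

Recordings travel as EDF (16-bit, physical dimension uV) with a TSV event
sidecar, or as the package's HDF5 container which also holds labels, the
resting span and ground-truth artifact intervals.  EDF reading goes through
mne; writing uses a minimal EDF+-compatible writer (no installed library
writes EDF), whose output is cross-checked against mne's reader in the test
suite.
"""

from __future__ import annotations

import datetime as _dt
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .containers import LabelledSession, Recording, TrialSet
from .features import CSPModel, FeatureExtractor
from .preprocess import segment, variance_normalize

__all__ = [
    "write_edf", "read_edf",
    "write_events_tsv", "read_events_tsv",
    "write_h5", "read_h5",
    "save_extractor", "load_extractor",
    "SessionStore", "assemble_calibration",
]


# ---------------------------------------------------------------------------
# EDF


def _pad(s: str, n: int) -> bytes:
    b = s.encode("ascii", "replace")[:n]
    return b + b" " * (n - len(b))


def write_edf(rec: Recording, path: str | Path) -> None:
    """Write a recording as 16-bit EDF, physical dimension uV.

    Data records are 1 s long; the final partial record, if any, is
    zero-padded.  Per-channel physical min/max are tight around the data,
    so quantization error is at most (max - min) / 65535 per channel.
    """
    path = Path(path)
    sfreq = rec.sfreq
    spr = int(round(sfreq))
    if abs(spr - sfreq) > 1e-9:
        raise ValueError("EDF writer requires an integer sampling rate")
    n_ch = rec.n_channels
    n_rec = int(np.ceil(rec.n_samples / spr))
    data = np.zeros((n_ch, n_rec * spr))
    data[:, :rec.n_samples] = rec.data

    pmin = data.min(axis=1)
    pmax = data.max(axis=1)
    flat = pmax - pmin < 1e-12
    pmax[flat] = pmin[flat] + 1.0
    dmin, dmax = -32768, 32767
    scale = (dmax - dmin) / (pmax - pmin)
    digital = np.round((data - pmin[:, None]) * scale[:, None] + dmin).astype("<i2")

    now = _dt.datetime(2000, 1, 1)
    header = b"".join([
        _pad("0", 8),
        _pad("X X X X", 80),
        _pad("Startdate X X X X", 80),
        _pad(now.strftime("%d.%m.%y"), 8),
        _pad(now.strftime("%H.%M.%S"), 8),
        _pad(str(256 * (n_ch + 1)), 8),
        _pad("", 44),
        _pad(str(n_rec), 8),
        _pad("1", 8),
        _pad(str(n_ch), 4),
    ])
    sig = b"".join([
        b"".join(_pad(lb, 16) for lb in rec.channel_labels),
        b"".join(_pad("AgAgCl electrode", 80) for _ in range(n_ch)),
        b"".join(_pad("uV", 8) for _ in range(n_ch)),
        b"".join(_pad(f"{v:.8g}"[:8], 8) for v in pmin),
        b"".join(_pad(f"{v:.8g}"[:8], 8) for v in pmax),
        b"".join(_pad(str(dmin), 8) for _ in range(n_ch)),
        b"".join(_pad(str(dmax), 8) for _ in range(n_ch)),
        b"".join(_pad("", 80) for _ in range(n_ch)),
        b"".join(_pad(str(spr), 8) for _ in range(n_ch)),
        b"".join(_pad("", 32) for _ in range(n_ch)),
    ])
    with open(path, "wb") as fh:
        fh.write(header)
        fh.write(sig)
        for r in range(n_rec):
            fh.write(digital[:, r * spr:(r + 1) * spr].tobytes())


def read_edf(path: str | Path) -> Recording:
    """Read an EDF file via mne; amplitudes converted to uV."""
    import mne

    path = Path(path)
    try:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    except Exception as err:
        raise ValueError(f"cannot parse EDF file {path}: {err}") from err
    data = raw.get_data() * 1e6  # volts -> uV
    return Recording(data, float(raw.info["sfreq"]), list(raw.ch_names))


# ---------------------------------------------------------------------------
# events TSV


def write_events_tsv(events: list[tuple[int, int]], path: str | Path,
                     labels: list[str] | None = None) -> None:
    """Columns: sample_index, code and (optionally) label."""
    df = pd.DataFrame(events, columns=["sample_index", "code"])
    if labels is not None:
        if len(labels) != len(events):
            raise ValueError("one label per event required")
        df["label"] = labels
    df.to_csv(path, sep="\t", index=False)


def read_events_tsv(path: str | Path) -> tuple[list[tuple[int, int]], list[str] | None]:
    df = pd.read_csv(path, sep="\t")
    events = [(int(r.sample_index), int(r.code)) for r in df.itertuples()]
    labels = [str(x) for x in df["label"]] if "label" in df.columns else None
    return events, labels


def _dec(x) -> str:
    return x.decode() if isinstance(x, bytes) else str(x)


# ---------------------------------------------------------------------------
# HDF5 container


def write_h5(obj: LabelledSession | Recording, path: str | Path) -> None:
    """Session (or bare recording) to the package HDF5 container."""
    if isinstance(obj, Recording):
        obj = LabelledSession(obj, list(obj.events), [], (0, 0))
    rec = obj.recording
    with h5py.File(path, "w") as f:
        g = f.create_group("eeg")
        g.create_dataset("data", data=rec.data, compression="gzip", compression_opts=1)
        g.attrs["sfreq"] = rec.sfreq
        g.attrs["channel_labels"] = [s.encode() for s in rec.channel_labels]
        f.create_dataset("events", data=np.array(obj.events, dtype=np.int64).reshape(-1, 2))
        f.create_dataset("labels", data=[s.encode() for s in obj.labels])
        f.create_dataset("rest_segment", data=np.array(obj.rest_segment, dtype=np.int64))
        art = np.array([(a, b) for a, b, _ in obj.artifact_intervals], dtype=float
                       ).reshape(-1, 2)
        f.create_dataset("artifact_spans", data=art)
        f.create_dataset("artifact_kinds",
                         data=[k.encode() for _, _, k in obj.artifact_intervals])


def read_h5(path: str | Path) -> LabelledSession:
    with h5py.File(path, "r") as f:
        g = f["eeg"]
        rec = Recording(
            g["data"][()], float(g.attrs["sfreq"]),
            [_dec(s) for s in g.attrs["channel_labels"]],
        )
        events = [tuple(e) for e in f["events"][()]]
        labels = [_dec(s) for s in f["labels"][()]]
        rest = tuple(int(x) for x in f["rest_segment"][()])
        spans = f["artifact_spans"][()]
        kinds = [_dec(k) for k in f["artifact_kinds"][()]]
    rec.events = [(int(s), int(c)) for s, c in events]
    arts = [(float(a), float(b), k) for (a, b), k in zip(spans, kinds)]
    return LabelledSession(rec, rec.events, labels, rest, arts)


# ---------------------------------------------------------------------------
# model serialization


def save_extractor(extractor: FeatureExtractor, path: str | Path) -> None:
    with h5py.File(path, "w") as f:
        f.attrs["bands"] = np.array(extractor.bands)
        f.attrs["sfreq"] = extractor.sfreq
        f.attrs["window"] = extractor.window
        f.attrs["log_floor"] = extractor.log_floor
        f.attrs["filter_order"] = extractor.filter_order
        f.attrs["channel_labels"] = [s.encode() for s in extractor.channel_labels]
        if extractor.band_scales is not None:
            f.create_dataset("band_scales", data=np.stack(extractor.band_scales))
        for i, m in enumerate(extractor.csp_models):
            g = f.create_group(f"csp/{i:03d}")
            g.attrs["pair"] = [m.pair[0].encode(), m.pair[1].encode()]
            g.attrs["band"] = np.array(m.band)
            g.attrs["shrinkage"] = m.shrinkage
            g.create_dataset("filters", data=m.filters)
            g.create_dataset("eigenvalues", data=m.eigenvalues)
            g.create_dataset("selected", data=np.array(m.selected))


def load_extractor(path: str | Path) -> FeatureExtractor:
    with h5py.File(path, "r") as f:
        bands = [tuple(b) for b in f.attrs["bands"]]
        scales = None
        if "band_scales" in f:
            scales = [row for row in f["band_scales"][()]]
        models = []
        for key in sorted(f["csp"].keys()):
            g = f[f"csp/{key}"]
            models.append(CSPModel(
                pair=tuple(_dec(p) for p in g.attrs["pair"]),
                band=tuple(g.attrs["band"]),
                filters=g["filters"][()],
                eigenvalues=g["eigenvalues"][()],
                selected=[int(i) for i in g["selected"][()]],
                shrinkage=float(g.attrs["shrinkage"]),
            ))
        return FeatureExtractor(
            bands=bands, csp_models=models, sfreq=float(f.attrs["sfreq"]),
            channel_labels=[_dec(s) for s in f.attrs["channel_labels"]],
            window=float(f.attrs["window"]), log_floor=float(f.attrs["log_floor"]),
            filter_order=int(f.attrs["filter_order"]), band_scales=scales,
        )


# ---------------------------------------------------------------------------
# session store and calibration transfer


@dataclass
class SessionStore:
    """Ordered history of training sessions for calibration transfer."""

    sessions: list[LabelledSession] = field(default_factory=list)
    dates: list[str] = field(default_factory=list)
    transfer_policy: tuple[int, int] = (30, 30)  # (old TPC, new TPC)

    def add(self, session: LabelledSession, date: str = "") -> None:
        if self.sessions and (session.recording.channel_labels
                              != self.sessions[-1].recording.channel_labels):
            raise ValueError("transfer across different montages is not allowed")
        self.sessions.append(session)
        self.dates.append(date)

    @property
    def previous(self) -> LabelledSession | None:
        return self.sessions[-1] if self.sessions else None


def _normalized_trials(session: LabelledSession, code_map: dict[int, str],
                       window: tuple[float, float]) -> TrialSet:
    rec = variance_normalize(session.recording, session.resting())
    rec.events = list(session.events)
    return segment(rec, code_map, window)


def assemble_calibration(
    store: SessionStore,
    current: LabelledSession,
    code_map: dict[int, str],
    n_old: int = 30,
    n_new: int = 30,
    window: tuple[float, float] = (-3.0, 5.0),
) -> TrialSet:
    """Merge previous-session and current-session calibration trials.

    Both sessions are variance-normalized against their own resting
    segments before merging, so day-to-day amplitude differences do not
    dominate.  Takes up to ``n_old`` trials per class from the most recent
    stored session (its last trials) and ``n_new`` per class from the
    current one.  Recording 30 new instead of the historical 50 per class
    cuts newly recorded calibration trials by 40%.
    """
    cur = _normalized_trials(current, code_map, window)
    prev_sess = store.previous
    if prev_sess is None or n_old == 0:
        if n_old > 0:
            warnings.warn("no previous session in store; using current only",
                          stacklevel=2)
        return _take_per_class(cur, n_new, from_end=False)
    if prev_sess.recording.channel_labels != current.recording.channel_labels:
        raise ValueError("transfer across different montages is not allowed")
    prev = _normalized_trials(prev_sess, code_map, window)
    prev_sel = _take_per_class(prev, n_old, from_end=True)
    cur_sel = _take_per_class(cur, n_new, from_end=False)
    data = np.concatenate([prev_sel.data, cur_sel.data], axis=0)
    labels = np.concatenate([prev_sel.labels, cur_sel.labels])
    return TrialSet(data, cur.time_axis, labels, cur.sfreq,
                    list(cur.channel_labels))


def _take_per_class(ts: TrialSet, n: int, from_end: bool) -> TrialSet:
    idx: list[int] = []
    for c in ts.classes:
        where = np.flatnonzero(ts.labels == c)
        idx.extend(where[-n:] if from_end else where[:n])
    return ts.select(np.sort(np.array(idx, dtype=int)))


def save_json(obj: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True))
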