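"""File readers/writers for recordings and event lists.

Recording CSV layout: first column ``time_s``, one column per channel
(header row carries channel names), amplitudes in µV.  The sampling rate is
inferred from the time column and validated uniform to 1e-6 relative
tolerance.  Event lists are CSV or JSON with ``onset_s`` and ``label``
fields.  EDF reading is available behind the same contract when ``mne`` is
installed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .signal_model import EventList, Recording

__all__ = [
    "read_recording_csv", "write_recording_csv",
    "read_events", "write_events_csv", "write_events_json",
    "read_recording_edf",
]


def read_recording_csv(path: str | Path) -> Recording:
    df = pd.read_csv(path)
    if df.columns[0] != "time_s":
        raise ValueError(f"first column must be 'time_s', got {df.columns[0]!r}")
    t = df["time_s"].to_numpy(dtype=float)
    if len(t) < 2:
        raise ValueError("need at least 2 samples")
    dt = np.diff(t)
    if np.any(np.abs(dt - dt[0]) > 1e-6 * abs(dt[0])):
        raise ValueError("time column is not uniformly sampled "
                         "(1e-6 relative tolerance)")
    fs = 1.0 / dt[0]
    names = list(df.columns[1:])
    data = df[names].to_numpy(dtype=float).T
    return Recording(data, fs, names, t0=float(t[0]))


def write_recording_csv(rec: Recording, path: str | Path) -> None:
    df = pd.DataFrame(rec.data.T, columns=rec.channel_names)
    df.insert(0, "time_s", rec.times())
    df.to_csv(path, index=False, float_format="%.6f")


def read_events(path: str | Path) -> EventList:
    """Read an event list from .csv (onset_s,label) or .json."""
    path = Path(path)
    if path.suffix == ".json":
        items = json.loads(path.read_text())
        if isinstance(items, dict) and "events" in items:
            items = items["events"]
        return EventList([e["onset_s"] for e in items],
                         [e["label"] for e in items],
                         [e.get("metadata", {}) for e in items])
    df = pd.read_csv(path)
    return EventList(df["onset_s"].to_numpy(dtype=float),
                     df["label"].astype(str).tolist())


def write_events_csv(events: EventList, path: str | Path) -> None:
    pd.DataFrame({"onset_s": events.onsets,
                  "label": events.labels}).to_csv(path, index=False)


def write_events_json(events: EventList, path: str | Path) -> None:
    items = [{"onset_s": float(o), "label": l, "metadata": m}
             for o, l, m in zip(events.onsets, events.labels, events.metadata)]
    Path(path).write_text(json.dumps(items, indent=2))


def read_recording_edf(path: str | Path) -> tuple[Recording, EventList]:
    """Read an EDF file (signals + annotations); requires ``mne``."""
    try:
        import mne
    except ImportError as exc:  # pragma: no cover
        raise ImportError("EDF reading requires the 'mne' package") from exc
    raw = mne.io.read_raw_edf(str(path), preload=True, verbose="error")
    data = raw.get_data() * 1e6  # volts -> µV
    rec = Recording(data, float(raw.info["sfreq"]), list(raw.ch_names))
    ann = raw.annotations
    events = EventList(list(ann.onset), [str(d) for d in ann.description])
    return rec, events
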