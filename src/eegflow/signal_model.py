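"""Core data types for multichannel EEG: continuous recordings, stimulus
event lists, and epoch sets, plus epoch segmentation with timestamp-offset
correction.

Conventions fixed once for the whole package:

* amplitudes are in microvolts (µV); file readers convert on load;
* sample indexing is 0-based and epoch windows are half-open ``[start, end)``
  both in time and in samples;
* onset-to-sample conversion uses ``floor``; window length in samples uses
  ``round`` — deterministic tie-breaking for windows that are not an integer
  number of samples;
* a single scalar ``offset`` models constant acquisition latency (network or
  driver delay between stimulus timestamps and recorded data); per-event
  jitter is not modeled.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "Recording",
    "EventList",
    "EpochSet",
    "segment_epochs",
    "channel_subset",
]


@dataclass
class Recording:
    """Continuous multichannel signal.

    Parameters
    ----------
    data : ndarray, shape (n_channels, n_samples)
        Signal in µV.
    fs : float
        Sampling rate in Hz, > 0.
    channel_names : list of str
        One unique name per row.
    t0 : float
        Acquisition start time in seconds (timestamps of events are on the
        same clock).
    """

    data: np.ndarray
    fs: float
    channel_names: list[str]
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("Recording.data must be 2-D (channels x samples)")
        if self.fs <= 0:
            raise ValueError(f"sampling rate must be positive, got {self.fs}")
        self.channel_names = list(self.channel_names)
        if len(self.channel_names) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.channel_names)} channel names for "
                f"{self.data.shape[0]} data rows"
            )
        if len(set(self.channel_names)) != len(self.channel_names):
            raise ValueError("duplicate channel names")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("Recording contains non-finite samples")

    @property
    def n_channels(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs

    def times(self) -> np.ndarray:
        """Per-sample timestamps in seconds."""
        return self.t0 + np.arange(self.n_samples) / self.fs

    def copy(self) -> "Recording":
        return Recording(self.data.copy(), self.fs, list(self.channel_names), self.t0)


@dataclass
class EventList:
    """Ordered stimulus onsets with class labels.

    ``onsets`` are seconds on the recording clock and must be non-decreasing;
    ``metadata`` holds one free-form dict per event.
    """

    onsets: np.ndarray
    labels: list[str]
    metadata: list[dict] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.onsets = np.asarray(self.onsets, dtype=float)
        self.labels = [str(l) for l in self.labels]
        if self.onsets.ndim != 1:
            raise ValueError("onsets must be 1-D")
        if len(self.onsets) != len(self.labels):
            raise ValueError("onsets and labels length mismatch")
        if len(self.onsets) > 1 and np.any(np.diff(self.onsets) < 0):
            raise ValueError("onsets must be non-decreasing")
        if not self.metadata:
            self.metadata = [{} for _ in self.labels]
        if len(self.metadata) != len(self.labels):
            raise ValueError("metadata length mismatch")

    def __len__(self) -> int:
        return len(self.labels)


@dataclass
class EpochSet:
    """Stimulus-locked EEG segments.

    ``data`` has shape (n_epochs, n_channels, n_samples); ``window`` is
    (t_start, t_end) in seconds relative to the (offset-corrected) onset.
    """

    data: np.ndarray
    labels: list[str]
    fs: float
    window: tuple[float, float]
    channel_names: list[str]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("EpochSet.data must be 3-D (epochs x channels x samples)")
        self.labels = [str(l) for l in self.labels]
        if len(self.labels) != self.data.shape[0]:
            raise ValueError("labels length != epoch count")
        if len(self.channel_names) != self.data.shape[1]:
            raise ValueError("channel_names length != channel count")
        n_expect = round((self.window[1] - self.window[0]) * self.fs)
        if abs(n_expect - self.data.shape[2]) > 1:
            raise ValueError(
                f"window length x fs = {n_expect} samples but data has "
                f"{self.data.shape[2]}"
            )

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]

    def copy(self) -> "EpochSet":
        return EpochSet(
            self.data.copy(), list(self.labels), self.fs, self.window,
            list(self.channel_names),
        )


def segment_epochs(
    rec: Recording,
    events: EventList,
    window: tuple[float, float],
    offset: float = 0.0,
) -> EpochSet:
    """Cut stimulus-locked epochs out of a continuous recording.

    For event onset ``o`` the epoch spans samples
    ``floor((o + offset + t_start - t0) * fs)`` (inclusive) to that index
    plus ``round((t_end - t_start) * fs)`` (exclusive).  ``offset`` corrects
    a constant mismatch between stimulus timestamps and the recording clock.
    Events whose window exceeds the recording bounds are dropped with a
    warning; labels of retained events are preserved in event order.
    """
    t_start, t_end = window
    if not t_start < t_end:
        raise ValueError(f"window t_start must be < t_end, got {window}")
    n_win = round((t_end - t_start) * rec.fs)
    if n_win < 1:
        raise ValueError("window shorter than one sample")

    segments, labels, kept = [], [], []
    for i, onset in enumerate(events.onsets):
        start = math.floor((onset + offset + t_start - rec.t0) * rec.fs)
        stop = start + n_win
        if start < 0 or stop > rec.n_samples:
            continue
        segments.append(rec.data[:, start:stop])
        labels.append(events.labels[i])
        kept.append(i)

    n_dropped = len(events) - len(kept)
    if n_dropped:
        warnings.warn(
            f"segment_epochs: dropped {n_dropped} of {len(events)} events "
            "whose window falls outside the recording", stacklevel=2,
        )
    if segments:
        data = np.stack(segments)
    else:
        warnings.warn("segment_epochs: no events in bounds, empty EpochSet",
                      stacklevel=2)
        data = np.empty((0, rec.n_channels, n_win))
    return EpochSet(data, labels, rec.fs, (t_start, t_end), rec.channel_names)


def channel_subset(x: Recording | EpochSet, names: list[str]):
    """Subset/reorder channels by name; all other fields are unchanged.

    Raises ``KeyError`` listing any requested channel absent from ``x``.
    """
    missing = [n for n in names if n not in x.channel_names]
    if missing:
        raise KeyError(f"unknown channels: {missing}")
    idx = [x.channel_names.index(n) for n in names]
    if isinstance(x, Recording):
        return Recording(x.data[idx], x.fs, list(names), x.t0)
    if isinstance(x, EpochSet):
        return EpochSet(x.data[:, idx], list(x.labels), x.fs, x.window, list(names))
    raise TypeError(f"unsupported type {type(x).__name__}")
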