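"""Stimulus-schedule construction for ERP, SSVEP and calibration sessions.

An ERP session presents ``trial_count`` stimuli, each visible for
``cue_time`` seconds and separated by ``buffer_time`` seconds, after a single
``fixation_time`` lead-in (the fixation cross shown once before the
experiment starts).  Total session duration therefore follows the closed
form::

    duration = (cue_time + buffer_time) * trial_count + fixation_time

Class labels are apportioned to trials by per-class weights (e.g. a
three-oddball design with weights 0.1 : 0.1 : 0.8 — two rare "deviant"
classes and one frequent "standard" class) using largest-remainder
apportionment, then shuffled with a seeded RNG, so the per-class counts are
deterministic and only the order varies with the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .signal_model import EventList

__all__ = [
    "ERPParams",
    "SSVEPParams",
    "StimulusSchedule",
    "total_duration",
    "assign_classes",
    "build_erp_schedule",
    "build_ssvep_schedule",
    "build_calibration_schedule",
    "schedule_to_json",
    "schedule_from_json",
]


@dataclass
class ERPParams:
    """Tunable ERP-session parameters.

    cue_time
        Duration (s) each stimulus remains visible.
    buffer_time
        Inter-stimulus interval (s).
    fixation_time
        Lead-in fixation-cross period (s), shown once.
    classes / weights
        Stimulus class ids and their non-negative presentation weights.
    trial_count
        Total number of stimuli flashed in the session.
    """

    cue_time: float
    buffer_time: float
    fixation_time: float
    classes: list[str]
    trial_count: int
    weights: list[float] | None = None

    def __post_init__(self) -> None:
        if self.weights is None:
            self.weights = [1.0] * len(self.classes)
        if len(self.weights) != len(self.classes):
            raise ValueError("weights length must equal classes length")
        if any(w < 0 for w in self.weights):
            raise ValueError("weights must be non-negative")
        if sum(self.weights) <= 0:
            raise ValueError("weights must not all be zero")
        if min(self.cue_time, self.buffer_time, self.fixation_time) < 0:
            raise ValueError("times must be non-negative")
        if self.trial_count < 0:
            raise ValueError("trial_count must be >= 0")


@dataclass
class SSVEPParams:
    """Flickering-stimulus session: one flicker frequency per on-screen target."""

    stimuli: list[tuple[str, float]]
    duration: float

    def __post_init__(self) -> None:
        freqs = [f for _, f in self.stimuli]
        if any(f <= 0 for f in freqs):
            raise ValueError("flicker frequencies must be positive")
        if len(set(freqs)) != len(freqs):
            raise ValueError(f"duplicate flicker frequencies: {freqs}")
        if self.duration <= 0:
            raise ValueError("duration must be positive")


@dataclass
class StimulusSchedule:
    """Ordered stimulus events plus total session duration."""

    events: EventList
    total_duration: float
    kind: str  # "erp" | "ssvep" | "calibration"
    params: dict = field(default_factory=dict)


def total_duration(p: ERPParams) -> float:
    """Total ERP session duration: (cue + buffer) * trials + fixation."""
    return (p.cue_time + p.buffer_time) * p.trial_count + p.fixation_time


def assign_classes(
    classes: list[str],
    weights: list[float],
    trial_count: int,
    seed: int | None = 0,
) -> list[str]:
    """Apportion ``trial_count`` trials to classes by weight, then shuffle.

    Counts follow largest-remainder apportionment of the normalized weights
    (remainder ties broken by class index), so counts are independent of the
    seed; only the order is randomized.
    """
    w = np.asarray(weights, dtype=float)
    if np.any(w < 0) or w.sum() <= 0:
        raise ValueError("weights must be non-negative with positive sum")
    if len(classes) != len(w):
        raise ValueError("classes and weights length mismatch")
    quota = w / w.sum() * trial_count
    counts = np.floor(quota).astype(int)
    short = trial_count - counts.sum()
    # distribute leftover seats by descending remainder, ties to lower index
    order = sorted(range(len(w)), key=lambda i: (-(quota[i] - counts[i]), i))
    for i in order[:short]:
        counts[i] += 1
    labels = [c for c, k in zip(classes, counts) for _ in range(k)]
    rng = np.random.default_rng(seed)
    rng.shuffle(labels)
    return labels


def build_erp_schedule(p: ERPParams, seed: int | None = 0) -> StimulusSchedule:
    """Lay out an ERP session: onset_k = fixation + k*(cue + buffer)."""
    onsets = p.fixation_time + np.arange(p.trial_count) * (p.cue_time + p.buffer_time)
    labels = assign_classes(p.classes, p.weights, p.trial_count, seed)
    events = EventList(onsets, labels)
    return StimulusSchedule(
        events, total_duration(p), "erp",
        params={
            "cue_time": p.cue_time, "buffer_time": p.buffer_time,
            "fixation_time": p.fixation_time, "trial_count": p.trial_count,
            "classes": list(p.classes), "weights": list(p.weights),
        },
    )


def build_ssvep_schedule(p: SSVEPParams) -> StimulusSchedule:
    """All SSVEP stimuli flicker simultaneously from t = 0."""
    onsets = np.zeros(len(p.stimuli))
    labels = [sid for sid, _ in p.stimuli]
    metadata = [{"flicker_hz": f} for _, f in p.stimuli]
    events = EventList(onsets, labels, metadata)
    return StimulusSchedule(events, p.duration, "ssvep",
                            params={"stimuli": list(map(list, p.stimuli)),
                                    "duration": p.duration})


def build_calibration_schedule(
    n_beeps: int, interval_s: float, lead_in_s: float = 0.0
) -> StimulusSchedule:
    """Regularly spaced beeps prompting the subject to blink (EOG calibration)."""
    if interval_s <= 0:
        raise ValueError("interval must be positive")
    onsets = lead_in_s + np.arange(n_beeps) * interval_s
    events = EventList(onsets, ["blink"] * n_beeps)
    total = lead_in_s + n_beeps * interval_s
    return StimulusSchedule(events, total, "calibration",
                            params={"n_beeps": n_beeps, "interval_s": interval_s,
                                    "lead_in_s": lead_in_s})


def schedule_to_json(s: StimulusSchedule) -> str:
    return json.dumps({
        "kind": s.kind,
        "params": s.params,
        "events": [
            {"onset_s": float(o), "label": l, "metadata": m}
            for o, l, m in zip(s.events.onsets, s.events.labels, s.events.metadata)
        ],
        "total_duration_s": s.total_duration,
    }, indent=2)


def schedule_from_json(text: str) -> StimulusSchedule:
    d = json.loads(text)
    ev = d["events"]
    events = EventList(
        [e["onset_s"] for e in ev],
        [e["label"] for e in ev],
        [e.get("metadata", {}) for e in ev],
    )
    return StimulusSchedule(events, d["total_duration_s"], d["kind"],
                            d.get("params", {}))
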