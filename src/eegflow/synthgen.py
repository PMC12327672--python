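"""Synthetic EEG generation with known ground truth.

Emulates the statistical structure real pipelines rely on:

* band-limited 1/f^β "pink" background activity (β = 0 gives white noise,
  β ≈ 1 is typical resting EEG);
* SSVEP frequency tagging — sinusoids at a fundamental flicker frequency
  plus its harmonics on occipital-like target channels;
* time-locked ERP deflections — a Gaussian-windowed bump at a fixed latency
  after each stimulus onset;
* high-amplitude EOG blink artifacts mixed into frontal-like channels with a
  known per-channel mixing vector, together with a clean EOG reference
  channel.

All injections are additive, so output − background equals the analytic
injected waveform exactly, and everything is deterministic under a seed —
every downstream stage (epoching, channel selection, artifact removal, CSP,
RMDM) is testable against constructed ground truth without hardware.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .paradigm import StimulusSchedule
from .signal_model import EventList, Recording

__all__ = [
    "SynthSpec",
    "gen_background",
    "inject_ssvep",
    "inject_erp",
    "inject_blinks",
    "gen_dataset",
    "BLINK_DURATION_S",
]

#: fixed blink-bump duration in seconds (half-sine waveform)
BLINK_DURATION_S = 0.3


@dataclass
class SynthSpec:
    """Parameters of the synthetic recording.

    background: ``sigma_uv`` sample SD (µV) and spectral exponent ``beta``
    (power ∝ 1/f^β, 0 ≤ β ≤ 2).  Optional ``ssvep``, ``erp`` and ``blinks``
    dicts configure the respective injections (see the inject_* functions).
    """

    n_channels: int
    fs: float
    duration: float
    sigma_uv: float = 10.0
    beta: float = 1.0
    ssvep: dict | None = None
    erp: dict | None = None
    blinks: dict | None = None
    seed: int = 0
    channel_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 0 <= self.beta <= 2:
            raise ValueError(f"spectral exponent must be in [0, 2], got {self.beta}")
        if self.sigma_uv < 0:
            raise ValueError("sigma_uv must be >= 0")
        if not self.channel_names:
            self.channel_names = [f"ch{i}" for i in range(self.n_channels)]


def gen_background(spec: SynthSpec) -> Recording:
    """Per-channel independent Gaussian noise spectrally shaped to 1/f^β.

    White Gaussian noise is shaped in the frequency domain by f^(−β/2)
    (DC untouched) and rescaled so each channel's sample SD equals
    ``sigma_uv``.  Deterministic under ``spec.seed``.
    """
    n = round(spec.duration * spec.fs)
    if n < 2:
        raise ValueError("duration * fs must be at least 2 samples")
    rng = np.random.default_rng(spec.seed)
    white = rng.standard_normal((spec.n_channels, n))
    if spec.beta == 0:
        shaped = white
    else:
        spec_w = np.fft.rfft(white, axis=1)
        f = np.fft.rfftfreq(n, d=1.0 / spec.fs)
        gain = np.ones_like(f)
        gain[1:] = f[1:] ** (-spec.beta / 2.0)
        gain[0] = 0.0  # drop DC
        shaped = np.fft.irfft(spec_w * gain, n=n, axis=1)
    sd = shaped.std(axis=1, keepdims=True)
    sd[sd == 0] = 1.0
    data = shaped / sd * spec.sigma_uv
    return Recording(data, spec.fs, list(spec.channel_names))


def inject_ssvep(
    rec: Recording,
    freq: float,
    n_harmonics: int,
    amps_uv: list[float],
    channels: list[int],
    seed: int = 0,
    t_start: float = 0.0,
    t_stop: float | None = None,
) -> Recording:
    """Add Σ_h amps[h]·sin(2π·h·freq·t + φ_h) to the listed channels.

    Harmonic index h runs 1..n_harmonics; phases φ_h are seeded uniform.
    Raises if any harmonic reaches the Nyquist frequency.
    """
    if len(amps_uv) != n_harmonics:
        raise ValueError("need one amplitude per harmonic")
    top = n_harmonics * freq
    if top >= rec.fs / 2:
        raise ValueError(
            f"harmonic {top} Hz violates Nyquist (fs/2 = {rec.fs / 2} Hz)")
    rng = np.random.default_rng(seed)
    phases = rng.uniform(0, 2 * np.pi, n_harmonics)
    t = np.arange(rec.n_samples) / rec.fs
    wave = np.zeros(rec.n_samples)
    for h in range(1, n_harmonics + 1):
        wave += amps_uv[h - 1] * np.sin(2 * np.pi * h * freq * t + phases[h - 1])
    if t_stop is None:
        t_stop = rec.n_samples / rec.fs
    mask = (t >= t_start) & (t < t_stop)
    out = rec.copy()
    out.data[np.asarray(channels)[:, None], np.where(mask)[0][None, :]] += wave[mask]
    return out


def erp_kernel(fs: float, latency_s: float, width_s: float,
               amplitude_uv: float) -> tuple[np.ndarray, int]:
    """Gaussian bump peaking ``latency_s`` after onset; returns (kernel, peak_idx).

    The kernel spans latency ± 3 widths, truncated at the onset sample.
    """
    sigma = width_s
    t = np.arange(0, latency_s + 3 * sigma, 1 / fs)
    k = amplitude_uv * np.exp(-0.5 * ((t - latency_s) / sigma) ** 2)
    return k, int(np.argmax(np.abs(k))) if amplitude_uv != 0 else 0


def inject_erp(
    rec: Recording,
    events: EventList,
    kernel: dict,
    channels: list[int],
) -> Recording:
    """Add a Gaussian-windowed deflection after each event onset.

    ``kernel`` keys: ``latency_s`` (peak delay after onset), ``width_s``
    (Gaussian SD), ``amplitude_uv`` (peak height).  Kernels extending past
    the recording end are truncated with a warning.
    """
    import warnings

    k, _ = erp_kernel(rec.fs, kernel["latency_s"], kernel["width_s"],
                      kernel["amplitude_uv"])
    out = rec.copy()
    chan = np.asarray(channels)
    for onset in events.onsets:
        start = round((onset - rec.t0) * rec.fs)
        stop = start + len(k)
        if start < 0:
            continue
        if stop > rec.n_samples:
            warnings.warn("inject_erp: kernel truncated at recording end",
                          stacklevel=2)
            stop = rec.n_samples
        out.data[chan[:, None], np.arange(start, stop)[None, :]] += k[: stop - start]
    return out


def blink_waveform(fs: float) -> np.ndarray:
    """Unit-amplitude half-sine blink bump of 0.3 s."""
    n = round(BLINK_DURATION_S * fs)
    return np.sin(np.pi * np.arange(n) / n)


def inject_blinks(
    rec: Recording,
    times: list[float],
    amplitude_uv: float,
    mixing: list[float],
    seed: int = 0,
    ref_noise_uv: float = 1.0,
) -> tuple[Recording, Recording]:
    """Add EOG blink bumps; return (contaminated EEG, 1-channel EOG reference).

    The blink waveform scaled by ``mixing[c]`` is added to channel c; the
    reference carries the unscaled waveform (amplitude ``amplitude_uv``)
    plus small sensor noise.
    """
    mixing = np.asarray(mixing, dtype=float)
    if len(mixing) != rec.n_channels:
        raise ValueError(
            f"mixing length {len(mixing)} != n_channels {rec.n_channels}")
    bump = blink_waveform(rec.fs) * amplitude_uv
    eog = np.zeros(rec.n_samples)
    for t in times:
        start = round((t - rec.t0) * rec.fs)
        stop = min(start + len(bump), rec.n_samples)
        if start < 0 or start >= rec.n_samples:
            continue
        eog[start:stop] += bump[: stop - start]
    out = rec.copy()
    out.data += mixing[:, None] * eog[None, :]
    rng = np.random.default_rng(seed)
    ref = eog + rng.standard_normal(rec.n_samples) * ref_noise_uv
    eog_rec = Recording(ref[None, :], rec.fs, ["EOG"], rec.t0)
    return out, eog_rec


def gen_dataset(
    schedule: StimulusSchedule,
    spec: SynthSpec,
    class_effects: dict[str, dict] | None = None,
) -> tuple[Recording, EventList, Recording | None]:
    """Compose background + class-conditional effects (+ optional blinks).

    ``class_effects`` maps a schedule label to one effect dict:

    * ``{"kind": "variance", "channels": [...], "sigma_uv": s, "duration_s": d}``
      — adds independent Gaussian noise of SD ``s`` on the listed channels
      for ``d`` seconds after each onset of that class (a second-order,
      motor-imagery-like effect that CSP/RMDM can exploit);
    * ``{"kind": "erp", "channels": [...], "latency_s": .., "width_s": ..,
      "amplitude_uv": ..}`` — a time-locked deflection per onset;
    * ``{"kind": "ssvep", "channels": [...], "freq": f, "n_harmonics": nh,
      "amps_uv": [...], "duration_s": d}`` — frequency tagging per onset.

    Returns (recording, events aligned to the schedule, EOG reference or
    None).  Raises if the schedule outlasts ``spec.duration``.
    """
    if schedule.total_duration > spec.duration + 1e-9:
        raise ValueError(
            f"schedule ({schedule.total_duration} s) longer than recording "
            f"({spec.duration} s)")
    rec = gen_background(spec)
    rng = np.random.default_rng(spec.seed + 1)
    class_effects = class_effects or {}

    for i, (onset, label) in enumerate(
            zip(schedule.events.onsets, schedule.events.labels)):
        eff = class_effects.get(label)
        if eff is None:
            continue
        kind = eff["kind"]
        chans = np.asarray(eff["channels"])
        if kind == "variance":
            start = round(onset * rec.fs)
            stop = min(start + round(eff["duration_s"] * rec.fs), rec.n_samples)
            extra = rng.standard_normal((len(chans), stop - start)) * eff["sigma_uv"]
            rec.data[chans[:, None], np.arange(start, stop)[None, :]] += extra
        elif kind == "erp":
            ev = EventList([onset], [label])
            rec = inject_erp(rec, ev, eff, list(chans))
        elif kind == "ssvep":
            rec = inject_ssvep(
                rec, eff["freq"], eff["n_harmonics"], eff["amps_uv"],
                list(chans), seed=spec.seed + 100 + i,
                t_start=onset, t_stop=onset + eff["duration_s"])
        else:
            raise ValueError(f"unknown effect kind {kind!r}")

    eog_ref = None
    if spec.blinks is not None:
        rec, eog_ref = inject_blinks(
            rec, spec.blinks["times"], spec.blinks["amplitude_uv"],
            spec.blinks["mixing"], seed=spec.seed + 2,
            ref_noise_uv=spec.blinks.get("ref_noise_uv", 1.0))

    events = EventList(schedule.events.onsets.copy(),
                       list(schedule.events.labels),
                       [dict(m) for m in schedule.events.metadata])
    return rec, events, eog_ref
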