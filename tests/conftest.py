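"""Shared synthetic fixtures: blink-contaminated recordings and two-class
variance datasets, all generated programmatically with fixed seeds."""

import numpy as np
import pytest

from eegflow.paradigm import ERPParams, build_erp_schedule, total_duration
from eegflow.signal_model import segment_epochs
from eegflow.synthgen import SynthSpec, gen_background, gen_dataset, inject_blinks


@pytest.fixture(scope="session")
def blink_fixture():
    """60 s, 4-channel 1/f background + 200 µV blinks with known mixing.

    Returns dict with clean/contaminated recordings, the EOG reference,
    blink times and the mixing vector.
    """
    spec = SynthSpec(4, 250.0, 60.0, sigma_uv=10.0, beta=1.0, seed=7)
    clean = gen_background(spec)
    times = list(np.arange(2.0, 56.0, 3.7))
    mixing = [1.0, 0.6, 0.3, 0.1]
    cont, eog = inject_blinks(clean, times, 200.0, mixing, seed=7)
    return {"clean": clean, "cont": cont, "eog": eog, "times": times,
            "mixing": mixing}


def make_two_class_dataset(seed, n_trials_per_class=40, n_channels=8,
                           fs=250.0, epoch_s=1.0, extra_sigma=15.0,
                           chans_a=(0, 1), chans_b=(6, 7)):
    """Motor-imagery-like dataset: class-conditional variance boosts.

    Class A boosts channels ``chans_a``, class B boosts ``chans_b`` during
    the cue window.  Returns the segmented EpochSet.
    """
    p = ERPParams(epoch_s, 0.5, 2.0, ["A", "B"], 2 * n_trials_per_class,
                  weights=[0.5, 0.5])
    sched = build_erp_schedule(p, seed=seed)
    spec = SynthSpec(n_channels, fs, total_duration(p) + 1.0, sigma_uv=10.0,
                     beta=1.0, seed=seed)
    effects = {
        "A": {"kind": "variance", "channels": list(chans_a),
              "sigma_uv": extra_sigma, "duration_s": epoch_s},
        "B": {"kind": "variance", "channels": list(chans_b),
              "sigma_uv": extra_sigma, "duration_s": epoch_s},
    }
    rec, events, _ = gen_dataset(sched, spec, effects)
    return segment_epochs(rec, events, (0.0, epoch_s))


def make_planted_channel_epochs(seed, n_epochs=200, n_channels=8, fs=250.0,
                                epoch_s=1.0, planted=3, extra_sigma=15.0):
    """Binary-labeled epochs where only ``planted`` carries a class effect."""
    p = ERPParams(epoch_s, 0.5, 2.0, ["A", "B"], n_epochs,
                  weights=[0.5, 0.5])
    sched = build_erp_schedule(p, seed=seed)
    spec = SynthSpec(n_channels, fs, total_duration(p) + 1.0, sigma_uv=10.0,
                     beta=1.0, seed=seed)
    effects = {"A": {"kind": "variance", "channels": [planted],
                     "sigma_uv": extra_sigma, "duration_s": epoch_s}}
    rec, events, _ = gen_dataset(sched, spec, effects)
    return segment_epochs(rec, events, (0.0, epoch_s))


@pytest.fixture(scope="session")
def two_class_epochs():
    return make_two_class_dataset(seed=11)


@pytest.fixture(scope="session")
def planted_channel_epochs():
    return make_planted_channel_epochs(seed=13)
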