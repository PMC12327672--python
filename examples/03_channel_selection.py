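"""Score channels by class-relevance and select the top 2 of 8.

A synthetic two-class dataset plants variance effects on channels 0/1
(class A) and 6/7 (class B); every criterion should rank those channels
highly.
"""

from eegflow.chansel import score_channels, select_top_n
from eegflow.paradigm import ERPParams, build_erp_schedule, total_duration
from eegflow.signal_model import segment_epochs
from eegflow.synthgen import SynthSpec, gen_dataset

p = ERPParams(1.0, 0.5, 2.0, ["A", "B"], 80, weights=[0.5, 0.5])
sched = build_erp_schedule(p, seed=5)
spec = SynthSpec(8, 250.0, total_duration(p) + 1.0, sigma_uv=10.0, seed=5)
effects = {
    "A": {"kind": "variance", "channels": [0, 1], "sigma_uv": 15.0,
          "duration_s": 1.0},
    "B": {"kind": "variance", "channels": [6, 7], "sigma_uv": 15.0,
          "duration_s": 1.0},
}
rec, events, _ = gen_dataset(sched, spec, effects)
epochs = segment_epochs(rec, events, (0.0, 1.0))

for method in ("correlation", "mutual_information", "chi_squared", "csp"):
    scores = score_channels(epochs, method)
    top = select_top_n(scores, 2)
    print(f"{method:20s} top-2: {top}  "
          f"(scores: {dict(zip(scores.channel_names, scores.scores.round(3)))})")
# All four criteria should return channels from {ch0, ch1, ch6, ch7} — the
# channels that actually carry class information.
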