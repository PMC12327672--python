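"""Build a three-oddball stimulus schedule and check its duration accounting.

A three-oddball paradigm presents two rare "deviant" classes and one
frequent "standard" class (weights 0.1 : 0.1 : 0.8).  The session duration
follows (cue + buffer) * trials + fixation exactly.
"""

from collections import Counter

from eegflow.paradigm import ERPParams, build_erp_schedule, total_duration

params = ERPParams(cue_time=1.0, buffer_time=0.5, fixation_time=2.0,
                   classes=["deviant1", "deviant2", "standard"],
                   trial_count=50, weights=[0.1, 0.1, 0.8])
schedule = build_erp_schedule(params, seed=42)

print(f"total duration: {schedule.total_duration} s "
      f"(closed form: {total_duration(params)} s)")
print(f"first onsets:   {schedule.events.onsets[:5]}")
print(f"class counts:   {dict(Counter(schedule.events.labels))}")
# The counts are fixed by largest-remainder apportionment of the weights
# (5 / 5 / 40 of 50 trials); only the presentation order depends on the seed.
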