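"""Generate the dual-domain SRTT protocol and inspect its bookkeeping.

Builds one subject's full scanning protocol (8 runs, 3 conditions, 5
streams of 8 elements per condition per run) and prints the counts that
make the downstream GLMs well-posed.
"""

from pathlib import Path

import seqrsa as sq

subject = sq.build_full_protocol(n_subjects=1, seed=42)[0]
events = subject.events

print("rotated motor sequence:", subject.sequences.motor_sequence)
print("rotated object sequence:", subject.sequences.object_sequence[:3], "...")
print("events per run:", len(subject.runs[0].events))
print("stream repetitions per condition (across 8 runs):",
      dict(events.groupby("condition")["block"].count() // 8))
per = events.groupby(["run", "condition", "key"]).size()
print("events per (run, condition, key): always",
      sorted(per.unique()))

out = Path("scratch_events")
out.mkdir(exist_ok=True)
path = out / sq.protocol.events_filename(1, 1)
sq.write_events(subject.runs[0].events, path)
print("run 1 written as BIDS-style TSV:", path)

# Every key, object and position occurs exactly 5 times per condition per
# run, which is what gives each of the 192 GLM regressors its 5 events.
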