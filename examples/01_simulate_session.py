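"""Generate a synthetic HD-EMG data-collection session and inspect it.

Builds the default 256-channel montage (four 8x8 grids, 10 mm pitch), runs
the 24-task protocol (8 gestures x 3 wrist positions, each task a
two-trapezoid contraction at 30% and 60% MVC) and prints what was recorded.
"""

import numpy as np

import myogrid as mg
from myogrid.synth import SimulationConfig, simulate_session

session = simulate_session(SimulationConfig(), seed=42)

print(f"montage: {session.layout.n_channels} channels, "
      f"{session.layout.n_ring_columns} ring columns")
print(f"task recordings: {len(session.recordings)}")
first = session.recordings[0]
print(f"first task: {first.task_id}  ({first.duration_s:.0f} s at {first.fs:.0f} Hz, "
      f"MVC reference {first.mvc:.2f} uV)")

# MVC table: the amplitude reference used for %MVC normalisation, per
# (gesture, wrist); higher values mean stronger simulated muscle activity.
mvcs = sorted(session.mvc_table.items())
print("\nMVC range over gestures/wrists: "
      f"{min(v for _, v in mvcs):.2f} .. {max(v for _, v in mvcs):.2f} uV")

# Cut one task into its two contraction segments (10% MVC onset rule).
segs = mg.segment_contractions(first)
for s in segs:
    print(f"segment {s.label.level:9s}: {s.n_samples / s.fs:.2f} s "
          f"(samples {s.start_sample}..{s.end_sample})")
# The first segment is the 30% MVC contraction, the second the 60% one; each
# spans ramp + plateau + ramp, trimmed where activity crosses 10% MVC.
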