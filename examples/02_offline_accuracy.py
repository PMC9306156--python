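"""Offline gesture classification: full montage vs reduced channel sets.

Extracts the five time-domain features (MAV, ZC, SSC, WL, LogVar) in 250-ms
windows with 50% overlap, splits 70/30 stratified, and compares shrinkage-LDA
accuracy using ALL channels, 8 SFS-selected channels and the fixed CIRC ring.
"""

import myogrid as mg
from myogrid.synth import SimulationConfig, simulate_session

SEED = 42
session = simulate_session(SimulationConfig(), seed=SEED)
fm = mg.session_features(session)  # combined wrists, both levels merged
train, test = mg.stratified_split(fm, 0.70, SEED)
print(f"feature matrix: {fm.X.shape[0]} windows x {fm.X.shape[1]} features")

_, acc_all = mg.score_on_channels(train, test)
print(f"ALL   (256 channels): {100 * acc_all:.1f}% test accuracy")

trace = mg.sfs_select(train, 8, seed=SEED)  # ~20 s: greedy 10-fold CV search
_, acc_sfs = mg.score_on_channels(train, test, trace.channel_prefix(8))
print(f"SFS-8 {tuple(trace.channels)}: {100 * acc_sfs:.1f}%")

circ = mg.circ_select(session.layout)
_, acc_circ = mg.score_on_channels(train, test, circ)
print(f"CIRC-8 {circ.channels}: {100 * acc_circ:.1f}%")

# Single-wrist analyses are easier than the combined one: training a
# classifier per wrist position and averaging the three accuracies shows the
# cost of pooling wrist positions at a fixed channel budget.
swa = mg.single_wrist_average_accuracy(session, circ, seed=SEED)
print(f"CIRC-8, single-wrist average: {100 * swa:.1f}% "
      f"(vs {100 * acc_circ:.1f}% combined)")
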