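# myogrid

Hand-gesture classification from high-density surface EMG (HD-EMG) under
changing wrist positions and contraction levels — an offline + online
analysis pipeline with a synthetic HD-EMG generator standing in for human
recordings.

## The problem

Myoelectric interfaces decode hand gestures from forearm EMG. With a
256-channel grid montage (four 8×8 electrode grids, 10 mm pitch: three
ringing the proximal forearm, one distal-ventral) classification is easy but
impractical; the engineering question is how few channels suffice, and
*where* they should sit, when the classifier must also survive wrist
rotation (pronation/neutral/supination) and two contraction levels (30% and
60% MVC). `myogrid` implements the full comparison between three channel
configurations:

- **SFS** — sequential forward selection: greedily add the feature column
  maximizing 10-fold cross-validated LDA accuracy; map selected features back
  to their parent channels; stop at the desired channel count; then use all
  five features of those channels.
- **CIRC** — a fixed ring of 8 equidistant channels around the proximal
  forearm (row 4 of the ring grids, every 3rd column; corrupted members fall
  back to the row below).
- **ALL** — every clean channel (the benchmark).

The classifier is shrinkage-LDA on the classic time-domain feature set
(250-ms windows, 50% overlap): MAV, ZC, SSC, WL, LogVar, with

Σ̂ = (1−λ)S + λ·(tr S/d)·I,  δ_k(x) = xᵀΣ̂⁻¹μ_k − ½μ_kᵀΣ̂⁻¹μ_k + ln π_k.

Class separability across wrist conditions is quantified by the mean
pairwise Bhattacharyya distance between Gaussian class models,

D = ⅛(μ_a−μ_b)ᵀΣ̄⁻¹(μ_a−μ_b) + ½ ln(det Σ̄ / √(det Σ_a det Σ_b)),
Σ̄ = (Σ_a+Σ_b)/2,

and an online control task is simulated in closed loop: predictions every
125 ms from 250-ms windows, gated by %MVC activation windows (low 10–35%,
moderate 45–75%), success after a 2-s dwell on the target, failure at 10 s.
Since no recordings are distributed for this protocol, a synthetic generator
produces sessions with the structure the analysis depends on: localized
gesture-specific "hot spots" with Gaussian spatial mixing on the forearm
cylinder, wrist-dependent spot drift, %MVC amplitude scaling along
two-trapezoid profiles, per-source spectral diversity and a measured (not
assumed) MVC reference. See `docs/methods.md` for the model and all
parameter choices.

## Worked example

```python
import myogrid as mg
from myogrid.synth import SimulationConfig, simulate_session

session = simulate_session(SimulationConfig(), seed=42)   # 24 tasks, 256 ch
fm = mg.session_features(session)          # windows × (channels × 5 features)
train, test = mg.stratified_split(fm, 0.70, seed=42)

_, acc_all = mg.score_on_channels(train, test)            # ALL channels
trace = mg.sfs_select(train, 8, seed=42)                  # SFS to 8 channels
_, acc_sfs = mg.score_on_channels(train, test, trace.channel_prefix(8))
_, acc_circ = mg.score_on_channels(train, test, mg.circ_select(session.layout))
```

Running `python examples/02_offline_accuracy.py` prints:

```
feature matrix: 2023 windows x 1280 features
ALL   (256 channels): 100.0% test accuracy
SFS-8 (165, 69, 160, 149, 25, 46, 59, 197): 95.4%
CIRC-8 (88, 91, 94, 153, 156, 159, 218, 221): 81.9%
CIRC-8, single-wrist average: 98.0% (vs 81.9% combined)
```

The full montage saturates; 8 targeted channels stay above 90%; the blind
circumferential ring loses ~16 points once wrist positions are pooled —
but recovers when each wrist is classified separately, which is the entire
story of why wrist position matters. `examples/03_separability.py` shows the
same effect upstream of the classifier (Bhattacharyya index 13–15 per single
wrist vs 7.9 combined), and `examples/04_online_eval.py` closes the loop:

```
low contraction level (72 trials):
  ALL   completion 100.0%  median time 2.50 s  median dwellings 0.0
  CIRC  completion  70.8%  median time 2.62 s  median dwellings 1.0
  SFS   completion  91.7%  median time 2.62 s  median dwellings 1.0
```

i.e. targeted placement beats the uniform ring during online control,
especially at low contraction force, and prediction stability (dwellings)
improves at the moderate level.

A thin CLI mirrors these flows for shell use:
`myogrid simulate | offline-curve | separability | online-eval | report`
(see `examples/05_session_bundles.py` for the session container format).

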