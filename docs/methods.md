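# Methods

`myogrid` re-creates, end to end, an offline + online analysis for hand-gesture
recognition from high-density surface EMG (HD-EMG) under changing wrist
positions and contraction levels.  Because no public recordings exist for this
protocol, a synthetic HD-EMG generator stands in for the human sessions; every
stage of the analysis — segmentation, feature extraction, channel selection,
classification, separability, and the closed-loop online task — runs on its
output exactly as it would on real data.

## The recording model

**Montage.**  Four 8×8 electrode grids with 10 mm inter-electrode distance,
256 monopolar channels.  Grids 2–4 close a ring around the proximal forearm
(24 circumferential columns); grid 1 sits distally on the ventral side.
Channels carry cylindrical coordinates: θ steps of 2π/24 around the ring
(ring column 1 anchored at grid 2, column 1 — the anchor is a convention; any
fixed anchor preserves equidistance), z in mm growing toward the elbow (row 1
of the proximal grids is taken as their distal edge).  The implied forearm
radius is 240 mm/2π ≈ 38 mm.

**Signal model.**  Each gesture activates 2–4 localized sources ("hot spots")
at fixed (θ, z) positions plus one spatially uniform *diffuse* source
representing volume-conducted distant activity, which monopolar montages see
everywhere.  Each source is an independent Gaussian carrier band-limited to
(10 Hz, f_hi); f_hi differs per source (180–470 Hz) because surface EMG
spectra vary with fibre conduction velocity and tissue filtering — this is
what gives the rate-type features (ZC, SSC, WL relative to amplitude) their
discriminative content in real recordings, and without it those features are
collinear noise.  Source k mixes into channel c with Gaussian spatial weight
`w_ck = snr · baseline · rel_amp_k · exp(−d(c,k)² / 2σ²)` where d is geodesic
distance on the forearm cylinder.  Independent sources add in variance, so
the per-channel RMS at full activation is the quadrature sum
`sqrt(baseline² + D² + Σ_k w_ck²)` (this is the map `channel_rms_map`
returns, and what the generated signals reproduce empirically to within a few
percent).  An additive band-limited noise floor of `baseline` µV RMS models
amplifier/electrode noise; "corrupted" channels carry 20× that noise and are
excluded from all analysis.

**Wrist positions.**  Pronation/supination displace every hot spot by ±2 ring
columns circumferentially and ∓1 row proximo-distally (neutral: no shift).
The magnitude of this drift is a free parameter of the generator — no
quantitative displacement is established for this protocol — and the default
is chosen so that the combined-wrist classification problem remains solvable
with the full montage while clearly degrading small fixed channel sets.

**Contraction profile.**  Each task follows the data-collection profile: two
trapezoids (1-s ramps, 4-s plateaus at 30% and 60% MVC, 5-s separation; 17 s
total).  MVC is *measured*, not assumed: per (gesture, wrist), a 3.5-s
full-activation recording is simulated and the MVC reference computed from it
as the channel-averaged 250-ms RMS averaged over 3 s, mirroring the
experimental procedure.  Each task recording carries the MVC of its own
(gesture, wrist), since the activation feedback is expressed in %MVC of the
gesture being performed.

**Defaults and what they mean.**

| parameter | default | meaning |
| --- | --- | --- |
| `baseline_uv` | 0.5 µV | noise floor (RMS) per channel |
| `snr` | 80 | hot-spot RMS at MVC relative to the noise floor |
| `diffuse_rel` | 0.15 | diffuse component relative to `snr · baseline` |
| `diffuse_f_hi` | 250 Hz | spectral edge of the diffuse (distant) activity |
| `spatial_sigma_mm` | 12 mm | spatial extent of a hot spot |
| `wrist_dtheta_cols`, `wrist_dz_mm` | 2 cols, 10 mm | wrist-induced map drift |
| `jitter_mm` | 0 | per-"subject" seeded jitter of spot positions |

The amplitude scale (hot channels ≈ 40 µV RMS at MVC over a 0.5 µV floor) is
representative of monopolar surface EMG.  The `snr` default also respects a
protocol constraint: below snr ≈ 50 the channel-averaged envelope no longer
separates cleanly from the noise floor at the 10%-MVC threshold and the
segmentation rule itself becomes ill-posed.

## Offline pipeline

**Preprocessing.**  2nd-order Butterworth band-pass 10–500 Hz (zero-phase for
offline analysis; the generator's output already carries the acquisition
filter, so the pipeline does not re-filter).  Activation envelopes are 250-ms
RMS windows with 125-ms hop (the hop is a choice; only the window length is a
protocol constant).  Contraction onset = first window whose channel-averaged
RMS crosses 10% MVC; offset = first window after onset below threshold for 2
consecutive windows (the offset rule is this package's choice — hysteresis
avoids chatter at the threshold).  Each task yields two contraction segments,
labelled low/moderate by order per the profile design; rest recordings yield
one 4-s segment.

**Features.**  MAV, ZC, SSC, WL, LogVar per channel in 250-ms windows, 50%
overlap.  ZC/SSC use a deadband ε of 1% of the window RMS by default (the
feature literature uses a noise deadband but no value is standard; ε = 0
recovers the textbook definitions and is used in the analytic unit tests).
LogVar is the natural log of the (population) variance floored at 1e−12 µV².
Class labels are the gesture only: the two contraction levels — and, in
combined mode, the three wrist positions — are merged into one class.  The
70/30 stratified holdout stratifies on the full (gesture, wrist, level)
composite so each sub-condition appears proportionally on both sides.

**Classifier.**  Shrinkage-LDA: pooled within-class covariance
`Σ̂ = (1−λ)S + λ(tr S/d)I`, discriminant `δ_k(x) = xᵀΣ̂⁻¹μ_k − ½μ_kᵀΣ̂⁻¹μ_k +
ln π_k`, equal priors by default, ties broken toward the lowest class index.
λ defaults to 1e−4, escalating tenfold (to at most 0.1) if the Cholesky
factorization fails.  The default is deliberately small: the identity target
is scaled by the *mean* feature variance, which the amplitude features
dominate, so large λ crushes the log-scale dimensions (measured on the
default benchmark: 96.0% test accuracy at λ=1e−3 vs 99.3% at λ=1e−4, with
n_train > d so the pooled covariance is well-posed).

**Channel selection.**  Three strategies.  *SFS*: greedy forward selection
over all remaining feature columns, scoring each candidate by mean 10-fold
CV accuracy (folds stratified by gesture, fixed per run, seeded) of LDA on
the selected-so-far features plus the candidate; selected features map back
to parent channels, and selection stops when the requested number of
*distinct channels* is reached (a feature whose parent is already selected
still counts as a step).  After selection, all five features of the selected
channels are used — the expansion happens after, not during, the search.
Ties break toward the lowest (channel, feature) column index with no
floating-point tolerance.  *CIRC*: row 4 of the proximal grids at every 3rd
ring column — 8 equidistant circumferential channels; a corrupted member is
replaced by the row-5 channel of the same column (one fallback level only).
"Row 4" is counted from the distal edge and "below" means one row toward the
elbow; both are conventions fixed by this package.  *ALL*: every clean
channel.

**Separability.**  Bhattacharyya distance between Gaussian class models
(means + per-class covariances regularized with the same shrinkage rule as
the LDA, log-determinants via Cholesky), averaged over the 28 unordered class
pairs.  Reported per wrist condition and combined, in the SFS feature space
(default: the features of the 8-channel SFS run; which dimensionality the
index should use is not pinned down externally, so it is configurable).

## Online simulation

A trial: after the target is displayed, EMG arrives in 125-ms blocks; each
block is concatenated with the previous one and the 250-ms window is
featurized on the active channel set and classified — one prediction per
tick.  Predictions count toward the dwell only while the activation estimate
is inside the target window (low: 10–35% MVC, moderate: 45–75%).  Success =
16 consecutive valid target ticks (2 s); failure at 10 s.  Completion time is
measured from target display to the tick completing the dwell, *inclusive* of
the dwell (whether the reported times include the dwell is unstated in the
protocol; inclusion is this package's choice).  The dwell counter resets on
any non-target prediction or out-of-window tick ("continuously" is read
strictly — no grace ticks).  Dwellings = prediction changes between
*consecutive* in-window ticks; a gap in gating breaks adjacency and is not
itself a change.  The activation estimate is computed from the newest 125-ms
block (the "current" level a GUI displays); a first 125-ms pre-roll precedes
the target display so the first prediction tick falls at t = 0.125 s.

The participant is replaced by an open-loop synthetic subject: a reaction
delay (0.5 s), then activation at the window midpoint with multiplicative
Gaussian noise (σ = 8%), and per tick a 5% probability of producing an
off-target spatial pattern (another gesture's mixing weights).  The rest
gesture appears as an online target but has no meaningful %MVC window; rest
targets are gated at activation ≤ the window's lower bound.

A block = 8 gestures × 3 wrists × the active channel sets (normally SFS,
CIRC, ALL → 72 trials) in seeded random order at one contraction level.
Outcome measures: completion rate over all trials; median completion time and
median dwellings over successful trials only.

## Numerical and design notes

- All randomness flows from one seed per run through `numpy` `SeedSequence`
  spawning; identical seeds give bit-identical sessions, splits, folds,
  traces and trials.
- Signals are stored float32 (µV); feature computation promotes to float64.
- Session bundles: `session.json` sidecar + `signals_<task>.f32`
  (little-endian float32, channel-major); CSV export/import is provided for
  interoperability and round-trips at float32 precision.
- The montage is parameterized (`build_layout(n_grids, rows, cols, ied_mm)`);
  heavy property tests run on a 4-grid 4×4 montage, which exercises the same
  code paths at a fraction of the cost.  Benchmarks and defaults always use
  the full 256-channel montage.
- Benchmark problem size: one session = 24 tasks of 17 s at 2048 Hz × 256
  channels (~2,000 feature windows, 1,280 feature columns); SFS to 8 channels
  evaluates ~10⁵ small CV fits and runs in well under a minute on one core.

## What the generator does and does not show

The generator reproduces the *structure* the analysis relies on: localized,
gesture-specific, spatially correlated activity; wrist-dependent map drift;
amplitude scaling with %MVC; spectral heterogeneity across sources; corrupted
channels.  It does **not** model motor-unit physiology, fatigue, electrode
shift between sessions, force-feedback dynamics, or — most importantly — a
human's corrective behaviour in the online task: the synthetic subject is
open-loop, so online results quantify the controller/state machine under a
fixed behaviour model rather than human-in-the-loop performance.  Passing
tests therefore certify the pipeline's correctness and its qualitative
orderings (full montage ≳ targeted subset ≫ blind ring under combined
wrists; combined wrists less separable than single; fewer dwellings at
moderate force), not quantitative agreement with any human dataset.

## Known limitations

- Class sizes are mildly unbalanced (rest contributes 4-s segments vs ~11.5 s
  per active gesture); equal priors are kept as the default regardless.
- The diffuse component uses one shared spatial weight; real volume
  conduction decays with distance.
- CIRC is defined at 8 channels; other counts exist only behind an explicit
  generalized-equidistant flag and require the ring to divide the count.
- The wrist-shift magnitude and hot-spot table are stipulated defaults, not
  fitted to any recording.
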