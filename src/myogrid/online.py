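"""Closed-loop simulation of the online gesture-recognition task.

Every 125 ms a new block of EMG is recorded and concatenated with the
previous 125 ms; TD features of the resulting 250-ms segment (restricted to
the active channel set) feed the classifier, producing a prediction per tick.
Predictions count toward the dwell only while the muscle activation estimate
lies inside the target %MVC window (low: 10-35%, moderate: 45-75%).  A trial
succeeds when the target class is held for 2 s of consecutive valid ticks
(16 ticks); it fails at the 10-s timeout.

The human participant is replaced by an open-loop synthetic subject: after a
reaction delay it drives its activation toward the middle of the target
window with multiplicative noise, and with a small probability per tick it
produces an off-target spatial pattern (another gesture's hot spots).  The
activation gate is evaluated on the newest 125-ms block (the "current"
activation a GUI would display); classification uses the full 250-ms window.

Outcome measures follow the protocol: completion rate over all trials;
completion time (from target display to the tick completing the dwell,
dwell included) and number of dwellings (prediction changes between
consecutive in-window ticks) over successful trials only.

The rest gesture appears as a target in the online blocks; since a %MVC
window is meaningless at rest, rest targets are gated at activation <= the
lower bound of the block's window.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np

from .classify import LdaModel
from .core import GESTURES, REST, WRISTS, TaskLabel
from .features import features_from_windows
from .layout import ChannelSet, GridLayout
from .synth import (GestureModel, Session, SimulationConfig, _band_noise,
                    gesture_mixing, gesture_sources)
from .preprocessing import bandpass_sos

__all__ = [
    "GATING_WINDOWS",
    "TrialSpec",
    "SubjectPolicy",
    "TrialResult",
    "TrialRecord",
    "run_trial",
    "run_block",
    "count_dwellings",
    "outcome_measures",
    "results_frame",
]

#: Target activation windows as fractions of MVC.
GATING_WINDOWS: Dict[str, Tuple[float, float]] = {
    "low": (0.10, 0.35),
    "moderate": (0.45, 0.75),
}

TICK_S = 0.125
DWELL_S = 2.0
TIMEOUT_S = 10.0


@dataclass(frozen=True)
class TrialSpec:
    """One online trial: target task and the gating/timing constants."""

    target: TaskLabel  # level set to the block's contraction level
    gate: Tuple[float, float]
    dwell_s: float = DWELL_S
    timeout_s: float = TIMEOUT_S
    tick_s: float = TICK_S

    def __post_init__(self):
        if not self.gate[0] < self.gate[1]:
            raise ValueError("gating window must have lo < hi")
        if not self.dwell_s < self.timeout_s:
            raise ValueError("dwell time must be shorter than the timeout")

    @classmethod
    def for_level(cls, target: TaskLabel, level: str) -> "TrialSpec":
        return cls(TaskLabel(target.gesture, target.wrist, level),
                   GATING_WINDOWS[level])


@dataclass(frozen=True)
class SubjectPolicy:
    """Open-loop synthetic subject.

    reaction_delay_s: time before any muscle activity after target display.
    activation_sigma: multiplicative noise on the produced activation level.
    off_target_prob: per-tick probability of an off-target spatial pattern.
    """

    reaction_delay_s: float = 0.5
    activation_sigma: float = 0.08
    off_target_prob: float = 0.05

    def __post_init__(self):
        if self.reaction_delay_s < 0 or self.activation_sigma < 0:
            raise ValueError("delay and noise must be non-negative")


@dataclass
class TrialResult:
    """Outcome of one simulated trial."""

    success: bool
    completion_time_s: Optional[float]  # None on failure
    dwellings: int
    predictions: List[str] = field(default_factory=list)  # per tick
    in_gate: List[bool] = field(default_factory=list)
    activation: List[float] = field(default_factory=list)  # estimate, %MVC fraction


@dataclass
class TrialRecord:
    """A trial plus the condition it ran under."""

    method: str
    gesture: str
    wrist: str
    level: str
    result: TrialResult


def _gate_check(est: float, spec: TrialSpec) -> bool:
    lo, hi = spec.gate
    if spec.target.gesture == REST:
        return est <= lo
    return lo <= est <= hi


def count_dwellings(predictions: Sequence[str], in_gate: Sequence[bool]) -> int:
    """Prediction changes between consecutive in-window ticks."""
    n = 0
    for i in range(1, len(predictions)):
        if in_gate[i] and in_gate[i - 1] and predictions[i] != predictions[i - 1]:
            n += 1
    return n


def run_trial(model, cs: ChannelSet, spec: TrialSpec, policy: SubjectPolicy,
              config: SimulationConfig, layout: GridLayout,
              gesture_model: GestureModel, mvc: float,
              seed: Optional[int] = None,
              predictor: Optional[Callable[[np.ndarray], str]] = None
              ) -> TrialResult:
    """Simulate one trial tick by tick.

    ``model`` must be trained on the 5-features-per-channel expansion of
    ``cs``; a ``predictor`` callable (features row -> class label) overrides
    it (used for oracle/adversarial probes).
    """
    rng = np.random.default_rng(seed)
    fs = config.fs
    block = int(round(spec.tick_s * fs))
    n_ticks = int(round(spec.timeout_s / spec.tick_s))
    dwell_ticks = int(round(spec.dwell_s / spec.tick_s))
    target = spec.target
    mid = 0.0 if target.gesture == REST else 0.5 * (spec.gate[0] + spec.gate[1])

    # --- per-tick subject behaviour (open loop) -----------------------------
    act = np.zeros(n_ticks + 1)  # index 0 = 125-ms pre-roll before display
    gestures = [target.gesture] * (n_ticks + 1)
    others = [g for g in GESTURES if g not in (target.gesture, REST)]
    for i in range(1, n_ticks + 1):
        if (i - 1) * spec.tick_s < policy.reaction_delay_s:
            act[i] = 0.0
            continue
        act[i] = np.clip(mid * (1.0 + policy.activation_sigma * rng.standard_normal()),
                         0.0, 1.0)
        if target.gesture != REST and rng.random() < policy.off_target_prob:
            gestures[i] = others[rng.integers(len(others))]

    # --- synthesize the whole stream ----------------------------------------
    sos = bandpass_sos(fs, config.band)
    total = (n_ticks + 1) * block
    used = sorted(set(gestures))
    mixing = {g: gesture_mixing(config, layout, gesture_model,
                                TaskLabel(g, target.wrist)) for g in used}
    sources = {g: gesture_sources(config, f_his, total, rng)
               for g, (_, f_his) in mixing.items()}
    signal = config.baseline_uv * _band_noise(rng, sos, (layout.n_channels, total))
    for i in range(n_ticks + 1):
        if act[i] <= 0:
            continue
        sl = slice(i * block, (i + 1) * block)
        wd, _ = mixing[gestures[i]]
        signal[:, sl] += act[i] * (wd @ sources[gestures[i]][:, sl])
    if config.corrupted:
        bad = list(config.corrupted)
        signal[bad] = (config.corrupted_noise_factor * config.baseline_uv
                       * _band_noise(rng, sos, (len(bad), total)))

    # --- tick loop: gate, classify, dwell -----------------------------------
    clean = list(layout.clean_channels)
    cs_sorted = sorted(cs.channels)
    result = TrialResult(False, None, 0)
    dwell = 0
    for i in range(1, n_ticks + 1):
        newest = signal[clean, i * block:(i + 1) * block]
        est = float(np.mean(np.sqrt(np.mean(newest ** 2, axis=1))) / mvc)
        window = signal[cs_sorted, (i - 1) * block:(i + 1) * block]
        feats = features_from_windows(window[:, None, :]).reshape(1, -1)
        if predictor is not None:
            pred = predictor(feats)
        else:
            pred = str(model.predict(feats)[0])
        gate = _gate_check(est, spec)
        result.predictions.append(pred)
        result.in_gate.append(gate)
        result.activation.append(est)
        dwell = dwell + 1 if (gate and pred == target.gesture) else 0
        if dwell >= dwell_ticks:
            result.success = True
            result.completion_time_s = i * spec.tick_s
            break
    result.dwellings = count_dwellings(result.predictions, result.in_gate)
    return result


def run_block(session: Session, models: Dict[str, LdaModel],
              channel_sets: Dict[str, ChannelSet], level: str,
              seed: Optional[int] = None,
              policy: SubjectPolicy = SubjectPolicy()) -> List[TrialRecord]:
    """One online block: 8 gestures x 3 wrists x the given channel-selection
    methods, in seeded random order, all gated at ``level``."""
    methods = list(channel_sets)
    combos = [(m, g, w) for m in methods for g in GESTURES for w in WRISTS]
    ss = np.random.SeedSequence(seed)
    order = np.random.default_rng(ss.spawn(1)[0]).permutation(len(combos))
    child = ss.spawn(len(combos))
    records = []
    for pos, j in enumerate(order):
        m, g, w = combos[j]
        spec = TrialSpec.for_level(TaskLabel(g, w), level)
        mvc = session.mvc_for(spec.target)
        res = run_trial(models[m], channel_sets[m], spec, policy,
                        session.config, session.layout, session.model, mvc,
                        seed=child[j])
        records.append(TrialRecord(m, g, w, level, res))
    return records


def outcome_measures(records: Sequence[TrialRecord],
                     by: Optional[str] = None):
    """Completion rate (%), median completion time and median dwellings.

    Rate is over all trials; time and dwellings over successful trials only
    (None when there are no successes).  ``by`` groups by a TrialRecord field
    ("method", "gesture", "wrist", "level") and returns a dict of summaries.
    """
    if not records:
        raise ValueError("no trial records")
    if by is not None:
        keys = sorted({getattr(r, by) for r in records})
        return {k: outcome_measures([r for r in records if getattr(r, by) == k])
                for k in keys}
    n = len(records)
    succ = [r for r in records if r.result.success]
    rate = 100.0 * len(succ) / n
    times = [r.result.completion_time_s for r in succ]
    dwells = [r.result.dwellings for r in succ]
    return {
        "n_trials": n,
        "n_success": len(succ),
        "completion_rate_pct": rate,
        "median_completion_time_s": float(np.median(times)) if times else None,
        "median_dwellings": float(np.median(dwells)) if dwells else None,
    }


def results_frame(records: Sequence[TrialRecord]):
    """One row per trial, for CSV export."""
    import pandas as pd

    return pd.DataFrame({
        "method": [r.method for r in records],
        "gesture": [r.gesture for r in records],
        "wrist": [r.wrist for r in records],
        "level": [r.level for r in records],
        "success": [r.result.success for r in records],
        "time_s": [r.result.completion_time_s for r in records],
        "dwellings": [r.result.dwellings for r in records],
    })
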