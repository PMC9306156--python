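"""Synthetic HD-EMG session generator.

Generates multichannel surface-EMG recordings with the statistical structure
the downstream analysis assumes:

* gesture-specific spatial "hot spots" of muscle activity on the forearm
  cylinder, mixed into the grid channels with Gaussian spatial weights, so
  neighbouring channels are correlated as in real HD-EMG;
* a diffuse volume-conducted component present on all channels during a
  contraction (monopolar montages see widespread distant activity, and the
  channel-averaged envelope must track %MVC for the activation feedback to
  make sense);
* wrist-position-dependent displacement of the hot spots (default: +/-2 ring
  columns circumferentially and -/+1 row proximo-distally for pronation /
  supination);
* contraction-level scaling through a two-trapezoid activation profile
  (1-s ramps, 4-s plateaus at 30% and 60% MVC, 5-s separation);
* band-limited (10-500 Hz) Gaussian carriers for both sources and the
  additive baseline noise floor;
* optional "corrupted" channels carrying high-variance noise.

Amplitudes are in uV; per-channel RMS at full activation is given by
:func:`channel_rms_map` (independent sources add in variance, so the map is a
quadrature sum of baseline, diffuse and hot-spot contributions).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy import signal as sps

from .core import GESTURES, LEVEL_FRACTION, REST, WRISTS, EmgRecording, TaskLabel
from .layout import GridLayout, build_default_layout
from .preprocessing import bandpass_sos, compute_mvc

__all__ = [
    "ActivationProfile",
    "make_activation_profile",
    "HotSpot",
    "GestureModel",
    "default_gesture_model",
    "SimulationConfig",
    "channel_rms_map",
    "simulate_task",
    "simulate_mvc_recording",
    "simulate_session",
    "Session",
]

# ---------------------------------------------------------------------------
# Activation profile

RAMP_S = 1.0
PLATEAU_S = 4.0
SEPARATION_S = 5.0
PLATEAU_LEVELS = (LEVEL_FRACTION["low"], LEVEL_FRACTION["moderate"])  # 0.30, 0.60


@dataclass(frozen=True)
class ActivationProfile:
    """Two-trapezoid target activation, as a fraction of MVC per sample."""

    fs: float
    samples: np.ndarray
    ramp_s: float = RAMP_S
    plateau_s: float = PLATEAU_S
    separation_s: float = SEPARATION_S
    plateau_levels: Tuple[float, float] = PLATEAU_LEVELS

    @property
    def duration_s(self) -> float:
        return self.samples.shape[0] / self.fs


def make_activation_profile(fs: float) -> ActivationProfile:
    """The data-collection profile: ramp 1 s - plateau 4 s at 30% - ramp down,
    5 s rest, ramp - plateau 4 s at 60% - ramp down; 17 s total."""
    if fs <= 0:
        raise ValueError("fs must be positive")
    lo, hi = PLATEAU_LEVELS
    r, p, s = RAMP_S, PLATEAU_S, SEPARATION_S
    knots_t = [0.0, r, r + p, 2 * r + p,
               2 * r + p + s, 3 * r + p + s, 3 * r + 2 * p + s, 4 * r + 2 * p + s]
    knots_v = [0.0, lo, lo, 0.0, 0.0, hi, hi, 0.0]
    total = knots_t[-1]
    n = int(round(total * fs))
    t = np.arange(n) / fs
    return ActivationProfile(fs, np.interp(t, knots_t, knots_v))


# ---------------------------------------------------------------------------
# Gesture model

@dataclass(frozen=True)
class HotSpot:
    """A localized source of muscle activity on the forearm cylinder.

    ``f_hi`` is the source's upper spectral edge (Hz): surface EMG spectra
    differ with fibre conduction velocity and tissue filtering, which is what
    makes the rate-type features (ZC, SSC, WL-to-amplitude ratio) carry
    information in real recordings.
    """

    theta: float  # radians
    z: float  # mm
    rel_amp: float  # relative amplitude; scaled by snr * baseline to uV at MVC
    f_hi: float = 400.0  # Hz, within the acquisition band


@dataclass(frozen=True)
class GestureModel:
    """Hot-spot geometry per gesture.  Rest (RE) has no hot spots."""

    spots: Dict[str, Tuple[HotSpot, ...]]

    def __post_init__(self):
        if self.spots.get(REST):
            raise ValueError("rest gesture must have no hot spots")
        for g, ss in self.spots.items():
            for s in ss:
                if s.rel_amp <= 0:
                    raise ValueError(f"non-positive hot-spot amplitude for {g}")

    def max_spots(self) -> int:
        return max((len(s) for s in self.spots.values()), default=0)


#: Default hot spots as fractions of the montage extent:
#: (theta / 2pi, z fraction, relative amplitude, f_hi Hz).
#: Ventral arc is theta/2pi in [0, 1/3); its z fraction spans the full
#: ventral surface (distal grid + ring), so low fractions fall on the distal
#: ventral grid.  Dorsal/lateral spots span the ring's z-range only (no
#: distal grid there).  Placements and spectra are distinct between every
#: pair of gestures.
_DEFAULT_SPOT_FRACTIONS: Dict[str, Tuple[Tuple[float, float, float, float], ...]] = {
    "PG": ((0.05, 0.25, 1.00, 430.0), (0.13, 0.60, 0.80, 320.0), (0.55, 0.55, 0.50, 260.0)),
    "OP": ((0.02, 0.40, 0.90, 390.0), (0.60, 0.48, 0.70, 240.0)),
    "TP2": ((0.10, 0.45, 0.90, 360.0), (0.66, 0.58, 0.60, 300.0), (0.30, 0.32, 0.40, 210.0)),
    "LG": ((0.20, 0.52, 1.00, 450.0), (0.47, 0.36, 0.60, 280.0)),
    "TP3": ((0.08, 0.64, 0.80, 340.0), (0.71, 0.38, 0.70, 220.0), (0.35, 0.56, 0.50, 410.0)),
    "IP": ((0.55, 0.64, 1.00, 470.0), (0.76, 0.46, 0.80, 310.0)),
    "HO": ((0.50, 0.30, 0.90, 420.0), (0.81, 0.62, 0.70, 250.0), (0.62, 0.20, 0.50, 180.0)),
    "RE": (),
}


def default_gesture_model(layout: GridLayout, jitter_mm: float = 0.0,
                          seed: Optional[int] = None) -> GestureModel:
    """Published default hot-spot table, scaled to the layout extent.

    ``jitter_mm`` adds seeded per-"subject" Gaussian jitter to spot positions,
    emulating inter-individual anatomy.
    """
    zs = [c.z for c in layout.channels]
    z_min, z_max = min(zs), max(zs)
    ring_z_min = 0.0  # distal edge of the proximal ring
    ventral_arc = 1.0 / (layout.n_grids - 1)  # fraction of the circle
    rng = np.random.default_rng(seed)
    radius = layout.radius_mm
    spots: Dict[str, Tuple[HotSpot, ...]] = {}
    for gesture, rows in _DEFAULT_SPOT_FRACTIONS.items():
        ss = []
        for tf, zf, amp, f_hi in rows:
            theta = 2.0 * math.pi * tf
            lo = z_min if tf < ventral_arc else ring_z_min
            z = lo + zf * (z_max - lo)
            if jitter_mm > 0:
                theta += rng.normal(0.0, jitter_mm) / radius
                z += rng.normal(0.0, jitter_mm)
            ss.append(HotSpot(theta % (2.0 * math.pi), z, amp, f_hi))
        spots[gesture] = tuple(ss)
    return GestureModel(spots)


# ---------------------------------------------------------------------------
# Simulation configuration

@dataclass(frozen=True)
class SimulationConfig:
    """Generator parameters.

    snr is the ratio of a unit-relative-amplitude hot spot's RMS at MVC to
    the baseline noise RMS; diffuse_rel sets the volume-conducted floor as a
    fraction of that reference.
    """

    fs: float = 2048.0
    baseline_uv: float = 0.5
    snr: float = 80.0
    diffuse_rel: float = 0.15
    diffuse_f_hi: float = 250.0  # distant activity is tissue-low-passed
    spatial_sigma_mm: float = 12.0
    wrist_dtheta_cols: float = 2.0  # circumferential shift, in ring columns
    wrist_dz_mm: float = 10.0  # proximo-distal shift (one row)
    band: Tuple[float, float] = (10.0, 500.0)
    corrupted: Tuple[int, ...] = ()
    corrupted_noise_factor: float = 20.0
    jitter_mm: float = 0.0
    rest_duration_s: float = 6.0
    mvc_duration_s: float = 3.5
    seed: Optional[int] = None

    def __post_init__(self):
        if self.snr <= 0:
            raise ValueError("snr must be positive")
        if self.baseline_uv <= 0:
            raise ValueError("baseline_uv must be positive")
        for name in ("rest_duration_s", "mvc_duration_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_dict(self) -> dict:
        return {
            "fs": self.fs, "baseline_uv": self.baseline_uv, "snr": self.snr,
            "diffuse_rel": self.diffuse_rel, "diffuse_f_hi": self.diffuse_f_hi,
            "spatial_sigma_mm": self.spatial_sigma_mm,
            "wrist_dtheta_cols": self.wrist_dtheta_cols, "wrist_dz_mm": self.wrist_dz_mm,
            "band": list(self.band), "corrupted": list(self.corrupted),
            "corrupted_noise_factor": self.corrupted_noise_factor,
            "jitter_mm": self.jitter_mm, "rest_duration_s": self.rest_duration_s,
            "mvc_duration_s": self.mvc_duration_s, "seed": self.seed,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if "band" in d:
            d["band"] = tuple(d["band"])
        if "corrupted" in d:
            d["corrupted"] = tuple(d["corrupted"])
        return cls(**d)


_WRIST_SIGN = {"pronation": 1.0, "neutral": 0.0, "supination": -1.0}


def _shifted_spots(config: SimulationConfig, layout: GridLayout,
                   model: GestureModel, label: TaskLabel) -> Tuple[HotSpot, ...]:
    sign = _WRIST_SIGN[label.wrist]
    dtheta = sign * config.wrist_dtheta_cols * 2.0 * math.pi / layout.n_ring_columns
    dz = -sign * config.wrist_dz_mm
    return tuple(HotSpot((s.theta + dtheta) % (2.0 * math.pi), s.z + dz,
                         s.rel_amp, s.f_hi)
                 for s in model.spots.get(label.gesture, ()))


def _spot_weights(config: SimulationConfig, layout: GridLayout,
                  spots: Sequence[HotSpot]) -> np.ndarray:
    """(channels, n_spots) Gaussian mixing weights in uV RMS at full activation."""
    thetas = np.array([c.theta for c in layout.channels])
    zs = np.array([c.z for c in layout.channels])
    radius = layout.radius_mm
    w = np.zeros((layout.n_channels, len(spots)))
    for k, s in enumerate(spots):
        dtheta = np.angle(np.exp(1j * (thetas - s.theta)))  # wrapped to [-pi, pi]
        d2 = (radius * dtheta) ** 2 + (zs - s.z) ** 2
        amp = config.snr * config.baseline_uv * s.rel_amp
        w[:, k] = amp * np.exp(-d2 / (2.0 * config.spatial_sigma_mm ** 2))
    return w


def _diffuse_amp(config: SimulationConfig, gesture: str) -> float:
    if gesture == REST:
        return 0.0
    return config.snr * config.baseline_uv * config.diffuse_rel


def channel_rms_map(config: SimulationConfig, label: TaskLabel, layout: GridLayout,
                    model: Optional[GestureModel] = None) -> np.ndarray:
    """Per-channel RMS (uV) at full activation, deterministic in (config, label).

    Independent sources add in variance, so the map is the quadrature sum of
    the baseline floor, the diffuse component and the wrist-shifted hot-spot
    weights.  Rest has neither spots nor diffuse activity: the map is the
    baseline everywhere.
    """
    if model is None:
        model = default_gesture_model(layout, config.jitter_mm, config.seed)
    w = _spot_weights(config, layout, _shifted_spots(config, layout, model, label))
    d = _diffuse_amp(config, label.gesture)
    return np.sqrt(config.baseline_uv ** 2 + d ** 2 + np.sum(w ** 2, axis=1))


# ---------------------------------------------------------------------------
# Signal synthesis

def _band_noise(rng: np.random.Generator, sos: np.ndarray, shape) -> np.ndarray:
    """Band-limited Gaussian noise, normalized to unit RMS per row."""
    x = rng.standard_normal(shape)
    x = sps.sosfiltfilt(sos, x, axis=-1)
    rms = np.sqrt(np.mean(x ** 2, axis=-1, keepdims=True))
    return x / np.maximum(rms, 1e-30)


def gesture_mixing(config: SimulationConfig, layout: GridLayout,
                   model: GestureModel, label: TaskLabel
                   ) -> Tuple[np.ndarray, List[float]]:
    """Mixing matrix (channels x sources, uV RMS at MVC) and the per-source
    upper spectral edges.  The last source is the diffuse component (for
    non-rest gestures)."""
    spots = _shifted_spots(config, layout, model, label)
    w = _spot_weights(config, layout, spots)
    f_his = [s.f_hi for s in spots]
    d = _diffuse_amp(config, label.gesture)
    if d > 0:
        w = np.concatenate([w, np.full((layout.n_channels, 1), d)], axis=1)
        f_his.append(config.diffuse_f_hi)
    return w, f_his


def gesture_sources(config: SimulationConfig, f_his: Sequence[float], n: int,
                    rng: np.random.Generator) -> np.ndarray:
    """Unit-RMS Gaussian carriers, one per source, each band-limited to
    (band lo, f_hi)."""
    out = np.empty((len(f_his), n))
    lo = config.band[0]
    for k, f_hi in enumerate(f_his):
        sos = bandpass_sos(config.fs, (lo, min(f_hi, config.band[1])))
        out[k] = _band_noise(rng, sos, n)
    return out


def _synthesize(config: SimulationConfig, label: TaskLabel, layout: GridLayout,
                model: GestureModel, activation: np.ndarray,
                rng: np.random.Generator) -> np.ndarray:
    """channels x samples signal for one task, uV, float32."""
    n = activation.shape[0]
    sos = bandpass_sos(config.fs, config.band)
    weights, f_his = gesture_mixing(config, layout, model, label)

    signal = np.zeros((layout.n_channels, n))
    if f_his:
        sources = gesture_sources(config, f_his, n, rng) * activation[None, :]
        signal += weights @ sources
    signal += config.baseline_uv * _band_noise(rng, sos, (layout.n_channels, n))

    if config.corrupted:
        bad = list(config.corrupted)
        noise = _band_noise(rng, sos, (len(bad), n))
        signal[bad] = config.corrupted_noise_factor * config.baseline_uv * noise
    return signal.astype(np.float32)


def simulate_task(config: SimulationConfig, label: TaskLabel, layout: GridLayout,
                  seed: Optional[int] = None, model: Optional[GestureModel] = None,
                  task_id: Optional[str] = None) -> EmgRecording:
    """One task recording following the two-trapezoid activation profile
    (rest: baseline noise for ``config.rest_duration_s``).  Reproducible for a
    fixed seed."""
    if model is None:
        model = default_gesture_model(layout, config.jitter_mm, config.seed)
    rng = np.random.default_rng(seed)
    if label.gesture == REST:
        n = int(round(config.rest_duration_s * config.fs))
        activation = np.zeros(n)
    else:
        activation = make_activation_profile(config.fs).samples
    signal = _synthesize(config, label, layout, model, activation, rng)
    return EmgRecording(signal, config.fs, label, layout, task_id=task_id)


def simulate_mvc_recording(config: SimulationConfig, label: TaskLabel,
                           layout: GridLayout, seed: Optional[int] = None,
                           model: Optional[GestureModel] = None,
                           task_id: Optional[str] = None) -> EmgRecording:
    """Sustained full-activation contraction used for MVC estimation."""
    if model is None:
        model = default_gesture_model(layout, config.jitter_mm, config.seed)
    rng = np.random.default_rng(seed)
    n = int(round(config.mvc_duration_s * config.fs))
    activation = np.ones(n)
    if label.gesture == REST:
        activation = np.zeros(n)
    signal = _synthesize(config, label, layout, model, activation, rng)
    return EmgRecording(signal, config.fs, label, layout, task_id=task_id)


# ---------------------------------------------------------------------------
# Sessions

@dataclass
class Session:
    """One synthetic data-collection session: 24 task recordings (8 gestures x
    3 wrist positions, pseudorandom order), MVC recordings per non-rest
    (gesture, wrist), and the derived MVC table."""

    layout: GridLayout
    config: SimulationConfig
    model: GestureModel
    recordings: List[EmgRecording]
    mvc_recordings: Dict[Tuple[str, str], EmgRecording]
    mvc_table: Dict[Tuple[str, str], float]
    seed: Optional[int]

    @property
    def session_mvc(self) -> float:
        """Session-level reference: mean MVC over non-rest (gesture, wrist)."""
        return float(np.mean(list(self.mvc_table.values())))

    def mvc_for(self, label: TaskLabel) -> float:
        return self.mvc_table.get((label.gesture, label.wrist), self.session_mvc)


def simulate_session(config: SimulationConfig, layout: Optional[GridLayout] = None,
                     seed: Optional[int] = None,
                     model: Optional[GestureModel] = None) -> Session:
    """Generate a full session.

    Task order is a seeded pseudorandom permutation of the 24 (gesture, wrist)
    combinations.  Each recording is annotated with the MVC value of its
    matching MVC recording.
    """
    if layout is None:
        layout = build_default_layout(config.corrupted)
    elif config.corrupted and not layout.corrupted:
        layout = layout.with_corrupted(config.corrupted)
    if seed is None:
        seed = config.seed
    if model is None:
        model = default_gesture_model(layout, config.jitter_mm, seed)

    ss = np.random.SeedSequence(seed)
    order_rng = np.random.default_rng(ss.spawn(1)[0])
    combos = [(g, w) for g in GESTURES for w in WRISTS]
    order = order_rng.permutation(len(combos))
    child_seeds = ss.spawn(2 * len(combos))

    mvc_recordings: Dict[Tuple[str, str], EmgRecording] = {}
    mvc_table: Dict[Tuple[str, str], float] = {}
    for i, (g, w) in enumerate(combos):
        if g == REST:
            continue
        rec = simulate_mvc_recording(config, TaskLabel(g, w), layout,
                                     seed=child_seeds[i], model=model,
                                     task_id=f"mvc_{g}_{w}")
        mvc_recordings[(g, w)] = rec
        mvc_table[(g, w)] = compute_mvc(rec)

    session_mvc = float(np.mean(list(mvc_table.values())))
    recordings: List[EmgRecording] = []
    for pos, j in enumerate(order):
        g, w = combos[j]
        rec = simulate_task(config, TaskLabel(g, w), layout,
                            seed=child_seeds[len(combos) + j], model=model,
                            task_id=f"task{pos:02d}_{g}_{w}")
        rec.mvc = mvc_table.get((g, w), session_mvc)
        recordings.append(rec)

    return Session(layout, config, model, recordings, mvc_recordings, mvc_table, seed)
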