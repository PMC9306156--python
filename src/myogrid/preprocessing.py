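"""Filtering, RMS envelopes, MVC estimation, onset detection and segmentation.

Conventions follow the recording protocol the pipeline assumes: 2nd-order
Butterworth band-pass 10-500 Hz, 250-ms RMS windows for activation estimates,
a 10% MVC threshold for contraction onset, and two-trapezoid task profiles
(plateaus at 30% and 60% MVC) from which two contraction segments are cut.

Offline filtering is zero-phase (forward-backward) so group delay does not
bias onset estimates; the online path uses a causal single pass.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
from scipy import signal as sps

from .core import REST, EmgRecording, Segment, TaskLabel

__all__ = [
    "bandpass",
    "bandpass_sos",
    "Envelope",
    "rms_envelope",
    "compute_mvc",
    "detect_onset",
    "segment_contractions",
]

BAND_HZ = (10.0, 500.0)
FILTER_ORDER = 2
ENVELOPE_WINDOW_S = 0.250
ENVELOPE_HOP_S = 0.125
ONSET_THRESHOLD = 0.10  # fraction of MVC
MVC_PERIOD_S = 3.0
REST_SEGMENT_S = 4.0
#: consecutive sub-threshold windows required to call a contraction offset
OFFSET_HYSTERESIS = 2


def bandpass_sos(fs: float, band=BAND_HZ, order: int = FILTER_ORDER) -> np.ndarray:
    """Second-order-sections of the standard band-pass filter."""
    lo, hi = band
    if fs <= 2.0 * hi:
        raise ValueError(f"sampling rate {fs} Hz puts the {hi} Hz band edge at/above Nyquist")
    return sps.butter(order, [lo, hi], btype="bandpass", fs=fs, output="sos")


def bandpass(signal: np.ndarray, fs: float, band=BAND_HZ, order: int = FILTER_ORDER,
             zero_phase: bool = True) -> np.ndarray:
    """Band-pass filter along the last axis (10-500 Hz, 2nd-order Butterworth).

    Zero-phase by default (offline analysis); set ``zero_phase=False`` for a
    causal single pass as used online.
    """
    sos = bandpass_sos(fs, band, order)
    if zero_phase:
        return sps.sosfiltfilt(sos, signal, axis=-1)
    return sps.sosfilt(sos, signal, axis=-1)


@dataclass
class Envelope:
    """Windowed RMS activity: per channel and averaged across channels."""

    per_channel: np.ndarray  # (channels, windows), uV
    mean: np.ndarray  # (windows,), channel-averaged RMS
    fs: float
    window_s: float
    hop_s: float

    @property
    def n_windows(self) -> int:
        return self.mean.shape[0]

    def window_start_sample(self, w: int) -> int:
        return int(round(w * self.hop_s * self.fs))

    def window_time_s(self, w: int) -> float:
        """Centre time of window ``w``."""
        return w * self.hop_s + self.window_s / 2.0


def _window_view(x: np.ndarray, w: int, h: int) -> np.ndarray:
    """(..., n_win, w) sliding windows with hop h over the last axis."""
    if x.shape[-1] < w:
        raise ValueError(f"signal of {x.shape[-1]} samples shorter than one "
                         f"{w}-sample window")
    return np.lib.stride_tricks.sliding_window_view(x, w, axis=-1)[..., ::h, :]


def rms_envelope(signal: np.ndarray, fs: float, window_s: float = ENVELOPE_WINDOW_S,
                 hop_s: float = ENVELOPE_HOP_S) -> Envelope:
    """Per-channel windowed RMS plus the cross-channel mean."""
    signal = np.atleast_2d(np.asarray(signal))
    w = int(round(window_s * fs))
    h = int(round(hop_s * fs))
    wins = _window_view(signal, w, h)
    per_channel = np.sqrt(np.mean(np.square(wins, dtype=np.float64), axis=-1))
    return Envelope(per_channel, per_channel.mean(axis=0), fs, window_s, hop_s)


def compute_mvc(recording: EmgRecording, period_s: float = MVC_PERIOD_S) -> float:
    """MVC reference: channel-averaged 250-ms RMS, averaged over the first
    ``period_s`` seconds of a sustained maximal contraction.

    Corrupted channels are excluded.
    """
    n_needed = int(round(period_s * recording.fs))
    if recording.n_samples < n_needed:
        raise ValueError(
            f"MVC recording of {recording.duration_s:.2f} s shorter than the "
            f"{period_s} s contraction period"
        )
    env = rms_envelope(recording.clean_signal()[:, :n_needed], recording.fs)
    return float(env.mean.mean())


def detect_onset(envelope: Envelope, mvc: float,
                 threshold: float = ONSET_THRESHOLD, start: int = 0) -> Optional[int]:
    """First window index (>= start) whose channel-averaged RMS crosses
    ``threshold * mvc``; None if never crossed."""
    if mvc <= 0:
        raise ValueError("mvc must be positive")
    above = envelope.mean[start:] >= threshold * mvc
    hits = np.flatnonzero(above)
    return int(hits[0]) + start if hits.size else None


def _detect_offset(envelope: Envelope, mvc: float, onset: int,
                   threshold: float = ONSET_THRESHOLD) -> int:
    """First window after ``onset`` below threshold for OFFSET_HYSTERESIS
    consecutive windows; returns the last supra-threshold window index."""
    below = envelope.mean[onset:] < threshold * mvc
    run = 0
    for i, b in enumerate(below):
        run = run + 1 if b else 0
        if run == OFFSET_HYSTERESIS:
            return onset + i - OFFSET_HYSTERESIS  # last window before the run
    return envelope.n_windows - 1


def segment_contractions(recording: EmgRecording, mvc: Optional[float] = None,
                         rest_start_s: float = 1.0) -> List[Segment]:
    """Cut a task recording into its two contraction segments (10% MVC rule),
    or a rest recording into one 4-s segment.

    The two contractions are labelled by order: first = low (30% MVC),
    second = moderate (60% MVC), per the two-trapezoid profile design.
    """
    lab = recording.label
    if lab.gesture == REST:
        start = int(round(rest_start_s * recording.fs))
        end = start + int(round(REST_SEGMENT_S * recording.fs))
        if end > recording.n_samples:
            raise ValueError(f"rest recording {recording.task_id} shorter than "
                             f"{rest_start_s + REST_SEGMENT_S} s")
        return [Segment(recording.signal[:, start:end], recording.fs, lab,
                        recording.layout, start, end, recording.task_id)]

    if mvc is None:
        mvc = recording.mvc
    if mvc is None:
        raise ValueError("mvc required to segment a task recording")

    env = rms_envelope(recording.clean_signal(), recording.fs)
    h = int(round(env.hop_s * recording.fs))
    w = int(round(env.window_s * recording.fs))

    segments: List[Segment] = []
    cursor = 0
    for level in ("low", "moderate"):
        onset = detect_onset(env, mvc, start=cursor)
        if onset is None:
            raise ValueError(
                f"task {recording.task_id} ({lab.gesture}/{lab.wrist}): found "
                f"{len(segments)} contraction(s), expected 2 (no 10% MVC crossing)"
            )
        offset = _detect_offset(env, mvc, onset)
        start = onset * h
        end = min(offset * h + w, recording.n_samples)
        seg_label = TaskLabel(lab.gesture, lab.wrist, level)
        segments.append(Segment(recording.signal[:, start:end], recording.fs,
                                seg_label, recording.layout, start, end,
                                recording.task_id))
        cursor = offset + OFFSET_HYSTERESIS + 1
    return segments
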