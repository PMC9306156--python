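"""Shared domain types: task labels, recordings and signal segments."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .layout import GridLayout

__all__ = [
    "GESTURES",
    "WRISTS",
    "LEVELS",
    "LEVEL_FRACTION",
    "REST",
    "TaskLabel",
    "EmgRecording",
    "Segment",
]

#: The eight gesture classes: power grasp, one-finger pinch, two-finger pinch,
#: lateral grasp, three-finger pinch, index pointing, hand open, rest.
GESTURES = ("PG", "OP", "TP2", "LG", "TP3", "IP", "HO", "RE")
REST = "RE"

#: Wrist orientations: full pronation, neutral, full supination.
WRISTS = ("pronation", "neutral", "supination")

#: Contraction levels as fractions of maximum voluntary contraction (MVC).
LEVELS = ("low", "moderate")
LEVEL_FRACTION = {"low": 0.30, "moderate": 0.60}


@dataclass(frozen=True)
class TaskLabel:
    """(gesture, wrist, level) label.

    ``level`` is None for whole task recordings, which contain contractions at
    both levels; it is set on the segments cut from them.
    """

    gesture: str
    wrist: str
    level: Optional[str] = None

    def __post_init__(self):
        if self.gesture not in GESTURES:
            raise ValueError(f"unknown gesture {self.gesture!r}")
        if self.wrist not in WRISTS:
            raise ValueError(f"unknown wrist position {self.wrist!r}")
        if self.level is not None and self.level not in LEVELS:
            raise ValueError(f"unknown contraction level {self.level!r}")


@dataclass
class EmgRecording:
    """Multichannel EMG of one task: channels x samples, fixed sampling rate.

    ``mvc`` is the maximum-voluntary-contraction reference (uV RMS) matching
    this recording's gesture and wrist, used for %MVC normalisation.
    """

    signal: np.ndarray  # (channels, samples), uV
    fs: float
    label: TaskLabel
    layout: GridLayout
    mvc: Optional[float] = None
    task_id: Optional[str] = None

    def __post_init__(self):
        if self.signal.ndim != 2:
            raise ValueError("signal must be channels x samples")
        if self.signal.shape[0] != self.layout.n_channels:
            raise ValueError(
                f"signal has {self.signal.shape[0]} channels, layout has "
                f"{self.layout.n_channels}"
            )

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def clean_signal(self) -> np.ndarray:
        """Signal restricted to non-corrupted channels."""
        return self.signal[list(self.layout.clean_channels)]


@dataclass
class Segment:
    """A contraction (or rest) slice of a parent recording."""

    signal: np.ndarray  # (channels, samples)
    fs: float
    label: TaskLabel  # level set: "low" | "moderate" | None for rest
    layout: GridLayout
    start_sample: int
    end_sample: int
    task_id: Optional[str] = None

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]
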