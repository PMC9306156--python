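"""Windowing, time-domain feature extraction and labelled feature matrices.

The feature set is the classic time-domain quintet used in myoelectric
pattern recognition: mean absolute value (MAV), zero crossings (ZC), slope
sign changes (SSC), waveform length (WL) and log-variance (LogVar), computed
in 250-ms windows with 50% overlap.

ZC and SSC use an amplitude deadband eps to reject noise-floor crossings; by
default eps = 0.01 x the window RMS (per channel, per window).  Pass eps=0
for the textbook definitions.  LogVar uses the natural logarithm with a tiny
floor so constant windows stay finite.

Class labels are the gesture only: windows of the same gesture recorded at
different contraction levels — and, in combined mode, different wrist
positions — share one class.  The stratified 70/30 split stratifies on the
full (gesture, wrist, level) composite so every sub-condition is covered
proportionally in both halves.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd
from sklearn.model_selection import train_test_split

from .core import Segment
from .layout import ChannelSet, GridLayout

__all__ = [
    "FEATURE_NAMES",
    "FeatureRef",
    "FeatureMatrix",
    "extract_windows",
    "td_features",
    "features_from_windows",
    "build_feature_matrix",
    "stratified_split",
]

FEATURE_NAMES = ("MAV", "ZC", "SSC", "WL", "LogVar")
WINDOW_S = 0.250
OVERLAP = 0.5
EPS_RMS_FRACTION = 0.01
LOGVAR_FLOOR = 1e-12  # uV^2


@dataclass(frozen=True)
class FeatureRef:
    """One feature column: (parent channel, feature name)."""

    channel: int
    name: str

    def __post_init__(self):
        if self.name not in FEATURE_NAMES:
            raise ValueError(f"unknown feature {self.name!r}")

    def __str__(self) -> str:
        return f"ch{self.channel}_{self.name}"


def window_count(n_samples: int, window: int, hop: int) -> int:
    if n_samples < window:
        raise ValueError(f"segment of {n_samples} samples shorter than one "
                         f"{window}-sample window")
    return (n_samples - window) // hop + 1


def extract_windows(signal: np.ndarray, fs: float, window_s: float = WINDOW_S,
                    overlap: float = OVERLAP) -> np.ndarray:
    """Sliding windows over the last axis: (channels, L) -> (n_win, channels, W).

    hop = window * (1 - overlap); n_win = floor((L - W) / H) + 1.
    """
    signal = np.atleast_2d(np.asarray(signal))
    w = int(round(window_s * fs))
    h = int(round(w * (1.0 - overlap)))
    window_count(signal.shape[-1], w, h)  # raises if too short
    wins = np.lib.stride_tricks.sliding_window_view(signal, w, axis=-1)[:, ::h, :]
    return np.moveaxis(wins, 0, 1)


def _deadband(wins: np.ndarray, eps: Optional[float]) -> np.ndarray:
    """Per-window deadband threshold, broadcastable against (..., W)."""
    if eps is not None:
        return np.full(wins.shape[:-1] + (1,), float(eps))
    rms = np.sqrt(np.mean(np.square(wins, dtype=np.float64), axis=-1, keepdims=True))
    return EPS_RMS_FRACTION * rms


def features_from_windows(wins: np.ndarray, eps: Optional[float] = None) -> np.ndarray:
    """TD features for an array of windows: (..., W) -> (..., 5).

    Feature order follows FEATURE_NAMES.  ``eps=None`` uses the default
    RMS-fraction deadband; a float fixes it (0 disables it).
    """
    wins = np.asarray(wins, dtype=np.float64)
    if wins.shape[-1] < 3:
        raise ValueError("windows must have at least 3 samples")
    e = _deadband(wins, eps)

    mav = np.mean(np.abs(wins), axis=-1)
    dx = np.diff(wins, axis=-1)
    wl = np.sum(np.abs(dx), axis=-1)

    a, b = wins[..., :-1], wins[..., 1:]
    zc = np.sum((a * b < 0) & (np.abs(a) > e) & (np.abs(b) > e), axis=-1)

    d1, d2 = dx[..., :-1], dx[..., 1:]  # slopes around interior samples
    ssc = np.sum((d1 * -d2 > 0) & ((np.abs(d1) > e) | (np.abs(d2) > e)), axis=-1)

    logvar = np.log(np.var(wins, axis=-1) + LOGVAR_FLOOR)
    return np.stack([mav, zc.astype(float), ssc.astype(float), wl, logvar], axis=-1)


def td_features(window: np.ndarray, eps: Optional[float] = None) -> np.ndarray:
    """The five TD features of a single-channel window, in FEATURE_NAMES order."""
    return features_from_windows(np.asarray(window, dtype=np.float64), eps)


@dataclass
class FeatureMatrix:
    """windows x features with per-window gesture labels and condition metadata.

    Columns are ordered channel-major (all five features of the lowest channel
    first), restricted to non-corrupted channels.
    """

    X: np.ndarray  # (n_windows, n_features)
    columns: List[FeatureRef]
    y: np.ndarray  # (n_windows,) gesture class labels
    meta: pd.DataFrame  # per-window: wrist, level, task_id

    def __post_init__(self):
        if self.X.shape[0] != len(self.y) or self.X.shape[0] != len(self.meta):
            raise ValueError("rows of X, y and meta must agree")
        if self.X.shape[1] != len(self.columns):
            raise ValueError("columns of X and column list must agree")

    @property
    def n_windows(self) -> int:
        return self.X.shape[0]

    @property
    def channels(self) -> Tuple[int, ...]:
        """Distinct parent channels, ascending."""
        return tuple(sorted({c.channel for c in self.columns}))

    def column_index(self, ref: FeatureRef) -> int:
        try:
            return self.columns.index(ref)
        except ValueError:
            raise KeyError(f"feature {ref} not in matrix") from None

    def select_channels(self, cs: Union[ChannelSet, Sequence[int]]) -> "FeatureMatrix":
        """All five features of the given channels (column sub-selection)."""
        channels = cs.channels if isinstance(cs, ChannelSet) else tuple(cs)
        have = set(self.channels)
        missing = [c for c in channels if c not in have]
        if missing:
            raise KeyError(f"channels {missing} not present in feature matrix")
        want = sorted(set(channels))
        idx = [i for i, ref in enumerate(self.columns) if ref.channel in set(want)]
        return FeatureMatrix(self.X[:, idx], [self.columns[i] for i in idx],
                             self.y, self.meta.reset_index(drop=True))

    def select_columns(self, refs: Sequence[FeatureRef]) -> "FeatureMatrix":
        idx = [self.column_index(r) for r in refs]
        return FeatureMatrix(self.X[:, idx], list(refs), self.y,
                             self.meta.reset_index(drop=True))

    def subset_rows(self, mask: np.ndarray) -> "FeatureMatrix":
        return FeatureMatrix(self.X[mask], self.columns, self.y[mask],
                             self.meta.loc[mask].reset_index(drop=True))

    def to_csv(self, features_path, labels_path) -> None:
        df = pd.DataFrame(self.X, columns=[str(c) for c in self.columns])
        df.to_csv(features_path, index=False)
        side = self.meta.copy()
        side.insert(0, "gesture", self.y)
        side.to_csv(labels_path, index=False)

    @classmethod
    def from_csv(cls, features_path, labels_path) -> "FeatureMatrix":
        df = pd.read_csv(features_path)
        cols = []
        for name in df.columns:
            ch, feat = name.split("_", 1)
            cols.append(FeatureRef(int(ch[2:]), feat))
        side = pd.read_csv(labels_path)
        y = side.pop("gesture").to_numpy()
        return cls(df.to_numpy(), cols, y, side)


def build_feature_matrix(segments: Sequence[Segment], layout: GridLayout,
                         mode: str = "combined",
                         eps: Optional[float] = None) -> FeatureMatrix:
    """Extract TD features from contraction segments into one labelled matrix.

    mode="combined" pools all wrist positions; mode=<wrist> keeps only that
    wrist.  Corrupted channels are excluded.  Class labels are the gesture
    only (levels — and in combined mode, wrists — are merged).
    """
    if mode != "combined":
        segments = [s for s in segments if s.label.wrist == mode]
        if not segments:
            raise ValueError(f"no segments for wrist position {mode!r}")
    if not segments:
        raise ValueError("no segments given")

    clean = list(layout.clean_channels)
    columns = [FeatureRef(ch, name) for ch in clean for name in FEATURE_NAMES]
    blocks, ys, meta_rows = [], [], []
    for seg in segments:
        wins = extract_windows(seg.signal[clean], seg.fs)  # (n_win, C, W)
        feats = features_from_windows(wins, eps)  # (n_win, C, 5)
        blocks.append(feats.reshape(feats.shape[0], -1))
        ys.extend([seg.label.gesture] * feats.shape[0])
        meta_rows.extend([(seg.label.wrist, seg.label.level, seg.task_id)]
                         * feats.shape[0])
    X = np.concatenate(blocks, axis=0)
    meta = pd.DataFrame(meta_rows, columns=["wrist", "level", "task_id"])
    return FeatureMatrix(X, columns, np.array(ys), meta)


def stratified_split(fm: FeatureMatrix, train_frac: float = 0.70,
                     seed: Optional[int] = None) -> Tuple[FeatureMatrix, FeatureMatrix]:
    """Stratified holdout split on the (gesture, wrist, level) composite."""
    strata = [f"{g}|{w}|{l}" for g, w, l in
              zip(fm.y, fm.meta["wrist"], fm.meta["level"].astype(str))]
    uniq, counts = np.unique(strata, return_counts=True)
    singletons = uniq[counts < 2]
    if singletons.size:
        raise ValueError(f"strata with fewer than 2 windows: {list(singletons)}")
    idx = np.arange(fm.n_windows)
    tr, te = train_test_split(idx, train_size=train_frac, stratify=strata,
                              random_state=seed)
    return fm.subset_rows(np.sort(tr)), fm.subset_rows(np.sort(te))
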