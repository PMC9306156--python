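"""End-to-end orchestration helpers tying the modules together.

These are the flows the examples, CLI and acceptance checks run: session ->
segments -> feature matrices -> split -> channel selection -> LDA -> scores.
Recordings from the simulator already carry the acquisition band-pass
(10-500 Hz), so no re-filtering happens here; :func:`myogrid.preprocessing.
bandpass` is for raw imported data.
"""

from __future__ import annotations

from typing import List, Optional, Tuple

import numpy as np

from .classify import LdaModel, accuracy, fit_lda
from .core import WRISTS, Segment
from .features import FeatureMatrix, build_feature_matrix, stratified_split
from .layout import ChannelSet
from .preprocessing import segment_contractions
from .selection import features_for_channels
from .synth import Session

__all__ = [
    "session_segments",
    "session_features",
    "fit_on_channels",
    "score_on_channels",
    "single_wrist_average_accuracy",
]


def session_segments(session: Session) -> List[Segment]:
    """Contraction (and rest) segments of every task recording."""
    segs: List[Segment] = []
    for rec in session.recordings:
        segs.extend(segment_contractions(rec))
    return segs


def session_features(session: Session, mode: str = "combined",
                     eps: Optional[float] = None,
                     segments: Optional[List[Segment]] = None) -> FeatureMatrix:
    """Labelled TD-feature matrix of a session (see build_feature_matrix)."""
    if segments is None:
        segments = session_segments(session)
    return build_feature_matrix(segments, session.layout, mode, eps)


def fit_on_channels(fm_train: FeatureMatrix, cs: Optional[ChannelSet] = None,
                    lam: float = 1e-4) -> LdaModel:
    """LDA on the 5-features-per-channel expansion of ``cs`` (None = all)."""
    sub = fm_train if cs is None else features_for_channels(fm_train, cs)
    return fit_lda(sub.X, sub.y, lam)


def score_on_channels(fm_train: FeatureMatrix, fm_test: FeatureMatrix,
                      cs: Optional[ChannelSet] = None, lam: float = 1e-4
                      ) -> Tuple[LdaModel, float]:
    model = fit_on_channels(fm_train, cs, lam)
    te = fm_test if cs is None else features_for_channels(fm_test, cs)
    return model, accuracy(model, te.X, te.y)


def single_wrist_average_accuracy(session: Session, cs: Optional[ChannelSet],
                                  seed: Optional[int] = None, lam: float = 1e-4,
                                  train_frac: float = 0.70,
                                  segments: Optional[List[Segment]] = None
                                  ) -> float:
    """Mean test accuracy over the three wrist-specific analyses.

    For each wrist the classifier is trained and tested on that wrist's data
    only (both contraction levels merged into the gesture class), and the
    three accuracies are averaged.
    """
    if segments is None:
        segments = session_segments(session)
    accs = []
    for w in WRISTS:
        fm = build_feature_matrix(segments, session.layout, mode=w)
        tr, te = stratified_split(fm, train_frac, seed)
        _, acc = score_on_channels(tr, te, cs, lam)
        accs.append(acc)
    return float(np.mean(accs))
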