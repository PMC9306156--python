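"""Channel selection: sequential forward selection (SFS) and accuracy curves.

SFS is a greedy wrapper: starting from an empty feature set, each step adds
the single feature column that maximizes mean 10-fold cross-validated LDA
accuracy of the current set plus the candidate.  Every selected feature is
mapped back to its parent channel; because several features can share a
parent, the number of distinct channels can be smaller than the number of
selected features.  Selection stops when the requested number of distinct
channels is reached.  Once a channel set is fixed, ALL five TD features of
the selected channels are used downstream ("expand after selection").

Fold assignment is stratified by gesture class and seeded; folds are fixed
for the whole run.  Ties in CV accuracy are broken toward the lowest
(channel, feature) column index, with no floating-point tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import linalg as sla
from sklearn.model_selection import StratifiedKFold

from .classify import LdaModel, accuracy, fit_lda, shrink_covariance
from .features import FeatureMatrix, FeatureRef
from .layout import ChannelSet, GridLayout, all_select, circ_select

__all__ = [
    "SfsTrace",
    "sfs_select",
    "features_for_channels",
    "accuracy_vs_channels",
    "channels_to_reach",
]

CV_FOLDS = 10


@dataclass
class SfsTrace:
    """SFS history: selected features in order, their distinct parent channels
    (first-appearance order) and the per-step CV accuracy."""

    features: List[FeatureRef]
    channels: List[int]
    cv_accuracy: List[float]
    cv_folds: int = CV_FOLDS

    def channel_prefix(self, n: int) -> ChannelSet:
        """The first n distinct channels selected."""
        if n > len(self.channels):
            raise ValueError(f"trace holds {len(self.channels)} channels, "
                             f"{n} requested")
        return ChannelSet(tuple(self.channels[:n]), "SFS")


class _FoldedLda:
    """Fast shrinkage-LDA cross-validation over a fixed column subset.

    Re-implements the fit of :func:`myogrid.classify.fit_lda` on raw arrays
    (equal priors, fixed lam, no escalation) to keep the SFS candidate loop
    cheap; agreement with the reference path is covered by tests.
    """

    def __init__(self, X: np.ndarray, y, n_folds: int, seed: Optional[int],
                 lam: float):
        self.X = np.asarray(X, dtype=np.float64)
        classes, y_idx = np.unique(np.asarray(y), return_inverse=True)
        self.n_classes = len(classes)
        self.lam = lam
        skf = StratifiedKFold(n_folds, shuffle=True, random_state=seed)
        self.folds = []
        for tr, va in skf.split(self.X, y_idx):
            ytr = y_idx[tr]
            counts = np.bincount(ytr, minlength=self.n_classes).astype(float)
            onehot = np.zeros((self.n_classes, len(tr)))
            onehot[ytr, np.arange(len(tr))] = 1.0
            self.folds.append((tr, va, ytr, y_idx[va], counts, onehot))

    def cv_accuracy(self, cols: Sequence[int]) -> float:
        cols = list(cols)
        accs = []
        for tr, va, ytr, yva, counts, onehot in self.folds:
            Xtr = self.X[np.ix_(tr, cols)]
            Xva = self.X[np.ix_(va, cols)]
            M = (onehot @ Xtr) / counts[:, None]  # class means (K, d)
            Xc = Xtr - M[ytr]
            S = (Xc.T @ Xc) / (len(tr) - self.n_classes)
            Sigma = shrink_covariance(S, self.lam)
            cho = sla.cho_factor(Sigma, lower=True, check_finite=False)
            A = sla.cho_solve(cho, M.T, check_finite=False)  # (d, K)
            scores = Xva @ A - 0.5 * np.sum(M.T * A, axis=0)
            accs.append(np.mean(np.argmax(scores, axis=1) == yva))
        return float(np.mean(accs))


def sfs_select(fm_train: FeatureMatrix, n_channels: int,
               seed: Optional[int] = None, lam: float = 1e-4,
               cv_folds: int = CV_FOLDS) -> SfsTrace:
    """Greedy sequential forward selection until ``n_channels`` distinct
    parent channels are selected.

    The candidate pool at each step is every not-yet-selected feature column;
    the CV classifier sees only the features selected so far plus the
    candidate (the five-feature expansion happens after selection).
    """
    available = fm_train.channels
    if not 1 <= n_channels <= len(available):
        raise ValueError(f"n_channels={n_channels} outside 1..{len(available)} "
                         "(distinct channels in the training matrix)")

    folded = _FoldedLda(fm_train.X, fm_train.y, cv_folds, seed, lam)
    n_cols = fm_train.X.shape[1]
    selected_cols: List[int] = []
    remaining = list(range(n_cols))
    trace = SfsTrace([], [], [], cv_folds)

    while len(trace.channels) < n_channels:
        best_acc, best_col = -1.0, None
        for col in remaining:  # column order = (channel, feature) order
            acc = folded.cv_accuracy(selected_cols + [col])
            if acc > best_acc:
                best_acc, best_col = acc, col
        selected_cols.append(best_col)
        remaining.remove(best_col)
        ref = fm_train.columns[best_col]
        trace.features.append(ref)
        trace.cv_accuracy.append(best_acc)
        if ref.channel not in trace.channels:
            trace.channels.append(ref.channel)
    return trace


def features_for_channels(fm: FeatureMatrix, cs: ChannelSet) -> FeatureMatrix:
    """All five TD features of the channels in ``cs`` (order-insensitive)."""
    return fm.select_channels(cs)


def _fit_on_channels(fm_train: FeatureMatrix, channels: ChannelSet,
                     lam: float) -> Tuple[LdaModel, FeatureMatrix]:
    sub = features_for_channels(fm_train, channels)
    return fit_lda(sub.X, sub.y, lam), sub


def accuracy_vs_channels(fm_train: FeatureMatrix, fm_test: FeatureMatrix,
                         method: str, n_grid: Sequence[int],
                         seed: Optional[int] = None, lam: float = 1e-4,
                         layout: Optional[GridLayout] = None,
                         allow_generalized_circ: bool = False,
                         trace: Optional[SfsTrace] = None
                         ) -> List[Tuple[int, float]]:
    """Test accuracy as a function of channel count.

    SFS: one trace to max(n_grid) channels; prefixes give the smaller sets
    (greedy nesting).  CIRC: defined at n=8 (every 3rd ring column); other n
    only with ``allow_generalized_circ`` and a layout whose ring divides n.
    Each point uses all five features per channel.
    """
    n_grid = list(n_grid)
    if sorted(n_grid) != n_grid:
        raise ValueError("n_grid must be sorted ascending")
    curve = []
    if method == "SFS":
        if trace is None:
            trace = sfs_select(fm_train, max(n_grid), seed=seed, lam=lam)
        for n in n_grid:
            cs = trace.channel_prefix(n)
            model, sub = _fit_on_channels(fm_train, cs, lam)
            te = features_for_channels(fm_test, cs)
            curve.append((n, accuracy(model, te.X, te.y)))
    elif method == "CIRC":
        if layout is None:
            raise ValueError("CIRC needs the grid layout")
        for n in n_grid:
            if n != 8 and not allow_generalized_circ:
                raise ValueError("CIRC is defined for 8 channels; pass "
                                 "allow_generalized_circ=True for other counts")
            cs = circ_select(layout, n)
            model, sub = _fit_on_channels(fm_train, cs, lam)
            te = features_for_channels(fm_test, cs)
            curve.append((n, accuracy(model, te.X, te.y)))
    else:
        raise ValueError(f"unknown selection method {method!r}")
    return curve


def channels_to_reach(fm_train: FeatureMatrix, fm_test: FeatureMatrix,
                      target_accuracy: float, seed: Optional[int] = None,
                      lam: float = 1e-4, max_channels: Optional[int] = None
                      ) -> Tuple[int, SfsTrace]:
    """Smallest SFS channel count whose 5-feature expansion reaches the target
    test accuracy; returns (count, trace).  Raises if never reached."""
    available = fm_train.channels
    cap = max_channels or len(available)
    folded_trace = sfs_select(fm_train, 1, seed=seed, lam=lam)
    n = 1
    while True:
        cs = folded_trace.channel_prefix(n)
        model, _ = _fit_on_channels(fm_train, cs, lam)
        te = features_for_channels(fm_test, cs)
        if accuracy(model, te.X, te.y) >= target_accuracy:
            return n, folded_trace
        n += 1
        if n > cap:
            raise ValueError(f"target accuracy {target_accuracy} not reached "
                             f"within {cap} channels")
        folded_trace = _extend_trace(fm_train, folded_trace, n, seed, lam)


def _extend_trace(fm_train: FeatureMatrix, trace: SfsTrace, n_channels: int,
                  seed: Optional[int], lam: float) -> SfsTrace:
    """Continue a greedy trace to more channels (same folds: same seed)."""
    folded = _FoldedLda(fm_train.X, fm_train.y, trace.cv_folds, seed, lam)
    col_of = {ref: i for i, ref in enumerate(fm_train.columns)}
    selected_cols = [col_of[r] for r in trace.features]
    remaining = [i for i in range(len(fm_train.columns)) if i not in set(selected_cols)]
    while len(trace.channels) < n_channels:
        best_acc, best_col = -1.0, None
        for col in remaining:
            acc = folded.cv_accuracy(selected_cols + [col])
            if acc > best_acc:
                best_acc, best_col = acc, col
        selected_cols.append(best_col)
        remaining.remove(best_col)
        ref = fm_train.columns[best_col]
        trace.features.append(ref)
        trace.cv_accuracy.append(best_acc)
        if ref.channel not in trace.channels:
            trace.channels.append(ref.channel)
    return trace


def sfs_trace_to_frame(trace: SfsTrace):
    """Trace as a DataFrame (step, feature, channel, cv_accuracy) for export."""
    import pandas as pd

    return pd.DataFrame({
        "step": np.arange(1, len(trace.features) + 1),
        "feature": [str(f) for f in trace.features],
        "channel": [f.channel for f in trace.features],
        "cv_accuracy": trace.cv_accuracy,
    })


def select_channels(method: str, layout: GridLayout,
                    fm_train: Optional[FeatureMatrix] = None, n: int = 8,
                    seed: Optional[int] = None, lam: float = 1e-4) -> ChannelSet:
    """Dispatch: SFS (needs training data), CIRC or ALL."""
    if method == "ALL":
        return all_select(layout)
    if method == "CIRC":
        return circ_select(layout, n)
    if method == "SFS":
        if fm_train is None:
            raise ValueError("SFS needs a training feature matrix")
        return ChannelSet(tuple(sfs_select(fm_train, n, seed=seed, lam=lam).channels),
                          "SFS")
    raise ValueError(f"unknown selection method {method!r}")
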