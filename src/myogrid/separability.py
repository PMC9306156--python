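"""Bhattacharyya class-separability index.

For two Gaussians (mu_a, Sigma_a), (mu_b, Sigma_b) with Sigma_bar =
(Sigma_a + Sigma_b) / 2, the Bhattacharyya distance is

    D = 1/8 (mu_a - mu_b)' Sigma_bar^-1 (mu_a - mu_b)
      + 1/2 ln( det Sigma_bar / sqrt(det Sigma_a * det Sigma_b) ).

The multi-class separability index of a labelled feature matrix is the mean
distance over all unordered class pairs, with one Gaussian fitted per gesture
class on a chosen feature subspace (typically the features picked by SFS).
Class covariances are regularized with the same diagonal shrinkage used by
the LDA, and determinants are computed from Cholesky log-determinants to
avoid overflow.  The index is affine-invariant, hence unchanged by feature
scaling.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Dict, List, Optional, Sequence

import numpy as np
from scipy import linalg as sla

from .classify import shrink_covariance
from .features import FeatureMatrix, FeatureRef

__all__ = ["ClassGaussian", "bhattacharyya_pair", "separability_index",
           "separability_by_condition"]


@dataclass
class ClassGaussian:
    """Gaussian class model: mean, (regularized) covariance, label."""

    mean: np.ndarray
    cov: np.ndarray
    label: str = ""


def _chol_logdet(S: np.ndarray, what: str):
    try:
        c = sla.cholesky(S, lower=True, check_finite=False)
    except (np.linalg.LinAlgError, sla.LinAlgError):
        raise np.linalg.LinAlgError(
            f"{what} covariance is not positive-definite; regularize (lam > 0)"
        ) from None
    return c, 2.0 * float(np.sum(np.log(np.diag(c))))


def bhattacharyya_pair(a: ClassGaussian, b: ClassGaussian) -> float:
    """Closed-form Bhattacharyya distance between two Gaussian classes."""
    if a.mean.shape != b.mean.shape:
        raise ValueError("dimension mismatch between class Gaussians")
    Sbar = 0.5 * (a.cov + b.cov)
    c_bar, ld_bar = _chol_logdet(Sbar, "averaged")
    _, ld_a = _chol_logdet(a.cov, f"class {a.label!r}")
    _, ld_b = _chol_logdet(b.cov, f"class {b.label!r}")
    dmu = a.mean - b.mean
    u = sla.solve_triangular(c_bar, dmu, lower=True, check_finite=False)
    mahal = float(u @ u)
    return 0.125 * mahal + 0.5 * (ld_bar - 0.5 * (ld_a + ld_b))


def fit_class_gaussians(X: np.ndarray, y, lam: float = 1e-4) -> List[ClassGaussian]:
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    out = []
    for cls in np.unique(y):
        Xi = X[y == cls]
        if Xi.shape[0] < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
        mean = Xi.mean(axis=0)
        Xc = Xi - mean
        S = (Xc.T @ Xc) / (Xi.shape[0] - 1)
        out.append(ClassGaussian(mean, shrink_covariance(S, lam), str(cls)))
    return out


def separability_index(fm: FeatureMatrix,
                       feature_refs: Optional[Sequence[FeatureRef]] = None,
                       lam: float = 1e-4) -> float:
    """Mean pairwise Bhattacharyya distance between gesture classes.

    ``feature_refs`` restricts the space (e.g. the SFS-selected features);
    None uses all columns.
    """
    sub = fm if feature_refs is None else fm.select_columns(list(feature_refs))
    if len(np.unique(sub.y)) < 2:
        raise ValueError("need at least 2 classes")
    gs = fit_class_gaussians(sub.X, sub.y, lam)
    return float(np.mean([bhattacharyya_pair(a, b)
                          for a, b in combinations(gs, 2)]))


def separability_by_condition(fm: FeatureMatrix,
                              feature_refs: Optional[Sequence[FeatureRef]] = None,
                              lam: float = 1e-4) -> Dict[str, float]:
    """The index per wrist condition plus all wrists combined.

    Keys: 'P', 'N', 'S' (pronation/neutral/supination) and 'comb'.
    """
    short = {"pronation": "P", "neutral": "N", "supination": "S"}
    out: Dict[str, float] = {}
    for wrist, key in short.items():
        mask = (fm.meta["wrist"] == wrist).to_numpy()
        out[key] = separability_index(fm.subset_rows(mask), feature_refs, lam)
    out["comb"] = separability_index(fm, feature_refs, lam)
    return out
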