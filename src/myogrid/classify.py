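"""Linear discriminant analysis with diagonal shrinkage.

LDA is the de-facto standard classifier in myoelectric control: a Gaussian
model with per-class means and a shared (pooled) within-class covariance,
giving linear decision boundaries.  The pooled covariance is shrunk toward
a scaled identity,

    Sigma_hat = (1 - lam) * S + lam * (tr S / d) * I,

which keeps the discriminant well conditioned in the full-montage setting
(1280 features from a few thousand windows).  If the Cholesky factorization
fails at the requested lam, lam is escalated tenfold up to 0.1 before giving
up.  Priors are equal by default (balanced collection protocol); empirical
priors are available.

Discriminant:  delta_k(x) = x' Sigma^-1 mu_k - mu_k' Sigma^-1 mu_k / 2 + ln pi_k.
Ties are broken toward the lowest class index.
"""

from __future__ import annotations

from dataclasses import dataclass
import numpy as np
from scipy import linalg as sla

__all__ = ["LdaModel", "fit_lda", "predict", "accuracy"]

DEFAULT_SHRINKAGE = 1e-4
MAX_SHRINKAGE = 0.1


@dataclass
class LdaModel:
    """Fitted shrinkage-LDA: class table, Gaussian parameters, linear form."""

    classes: np.ndarray  # (K,) sorted class labels
    means: np.ndarray  # (K, d)
    covariance: np.ndarray  # (d, d) shrunk pooled covariance
    priors: np.ndarray  # (K,)
    shrinkage: float  # lam actually used (after any escalation)
    coef: np.ndarray  # (d, K): Sigma^-1 mu_k
    intercept: np.ndarray  # (K,): -mu' Sigma^-1 mu / 2 + ln pi

    @property
    def n_features(self) -> int:
        return self.means.shape[1]

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(np.asarray(X, dtype=np.float64))
        if X.shape[1] != self.n_features:
            raise ValueError(f"X has {X.shape[1]} features, model expects "
                             f"{self.n_features}")
        return X @ self.coef + self.intercept

    def predict(self, X: np.ndarray) -> np.ndarray:
        # argmax returns the first maximum -> lowest class index wins ties
        return self.classes[np.argmax(self.decision_function(X), axis=1)]


def shrink_covariance(S: np.ndarray, lam: float) -> np.ndarray:
    """(1 - lam) * S + lam * (mean diagonal variance) * I."""
    d = S.shape[0]
    mu = np.trace(S) / d
    return (1.0 - lam) * S + lam * mu * np.eye(d)


def fit_lda(X: np.ndarray, y, lam: float = DEFAULT_SHRINKAGE,
            priors: str = "uniform") -> LdaModel:
    """Fit shrinkage-LDA.

    Requires at least 2 classes and 2 samples per class.  With lam=0 a
    singular pooled covariance raises, advising lam > 0.
    """
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y)
    classes, y_idx = np.unique(y, return_inverse=True)
    K, (n, d) = len(classes), X.shape
    if K < 2:
        raise ValueError("need at least 2 classes")
    counts = np.bincount(y_idx, minlength=K)
    if counts.min() < 2:
        raise ValueError("each class needs at least 2 samples")

    means = np.zeros((K, d))
    np.add.at(means, y_idx, X)
    means /= counts[:, None]
    Xc = X - means[y_idx]
    S = (Xc.T @ Xc) / (n - K)

    if priors == "uniform":
        pi = np.full(K, 1.0 / K)
    elif priors == "empirical":
        pi = counts / n
    else:
        raise ValueError("priors must be 'uniform' or 'empirical'")

    cur = lam
    while True:
        Sigma = shrink_covariance(S, cur)
        try:
            cho = sla.cho_factor(Sigma, lower=True, check_finite=False)
            break
        except (np.linalg.LinAlgError, sla.LinAlgError):
            if cur == 0.0:
                raise np.linalg.LinAlgError(
                    "pooled covariance is singular with lam=0; use lam > 0 "
                    "(shrinkage) to regularize"
                ) from None
            nxt = min(cur * 10.0, MAX_SHRINKAGE)
            if nxt == cur:
                raise np.linalg.LinAlgError(
                    f"covariance not positive-definite even at lam={cur}"
                ) from None
            cur = nxt

    coef = sla.cho_solve(cho, means.T, check_finite=False)  # (d, K)
    intercept = -0.5 * np.sum(means.T * coef, axis=0) + np.log(pi)
    return LdaModel(classes, means, Sigma, pi, cur, coef, intercept)


def predict(model: LdaModel, X: np.ndarray) -> np.ndarray:
    """Class labels by maximum discriminant (ties -> lowest class index)."""
    return model.predict(X)


def accuracy(model: LdaModel, X: np.ndarray, y) -> float:
    """Fraction of correct predictions."""
    y = np.asarray(y)
    if y.size == 0:
        raise ValueError("empty evaluation set")
    return float(np.mean(model.predict(X) == y))
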