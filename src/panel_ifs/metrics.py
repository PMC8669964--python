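"""Multiclass performance measures.

The key statistic is the multiclass Matthews correlation coefficient in its
covariance (R_K) form: predictions and truth are one-hot encoded as n x C
indicator matrices X and Y and MCC is their matrix correlation

    MCC = sum_ij (x_ij - xbar_j)(y_ij - ybar_j)
          / sqrt( sum_ij (x_ij - xbar_j)^2 * sum_ij (y_ij - ybar_j)^2 )

with column means taken over all n rows.  For two classes this reduces
algebraically to the classical binary MCC.  When either variance term is
zero (e.g. a constant prediction) the coefficient is undefined; it is
reported as 0.0 with a warning, so feature-selection curves stay defined.
"""

from __future__ import annotations

import warnings

import numpy as np

__all__ = [
    "one_hot",
    "mcc_from_indicators",
    "multiclass_mcc",
    "per_class_accuracy",
    "overall_accuracy",
    "class_counts",
]


def one_hot(labels: np.ndarray, n_classes: int) -> np.ndarray:
    """n x C 0/1 indicator matrix; row i has a single 1 at column labels[i]."""
    labels = np.asarray(labels, dtype=int)
    if labels.size and (labels.min() < 0 or labels.max() >= n_classes):
        raise ValueError(
            f"labels must lie in 0..{n_classes - 1}, "
            f"got range [{labels.min()}, {labels.max()}]"
        )
    out = np.zeros((labels.shape[0], n_classes), dtype=float)
    out[np.arange(labels.shape[0]), labels] = 1.0
    return out


def mcc_from_indicators(X: np.ndarray, Y: np.ndarray) -> float:
    """MCC of one-hot predicted (X) vs actual (Y) indicator matrices."""
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if X.shape != Y.shape:
        raise ValueError(f"shape mismatch: X {X.shape} vs Y {Y.shape}")
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    cov_xy = float((Xc * Yc).sum())
    cov_xx = float((Xc * Xc).sum())
    cov_yy = float((Yc * Yc).sum())
    if cov_xx == 0.0 or cov_yy == 0.0:
        warnings.warn(
            "MCC undefined (zero variance in predictions or truth); returning 0.0",
            RuntimeWarning,
            stacklevel=2,
        )
        return 0.0
    return cov_xy / np.sqrt(cov_xx * cov_yy)


def multiclass_mcc(
    y_true: np.ndarray, y_pred: np.ndarray, n_classes: int | None = None
) -> float:
    """Convenience wrapper: MCC from integer label vectors."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    if n_classes is None:
        n_classes = int(max(y_true.max(), y_pred.max())) + 1
    return mcc_from_indicators(one_hot(y_pred, n_classes), one_hot(y_true, n_classes))


def class_counts(
    y_true: np.ndarray, y_pred: np.ndarray, n_classes: int
) -> tuple[np.ndarray, np.ndarray]:
    """(N, n_correct): per-class sample counts and correct-prediction counts."""
    y_true = np.asarray(y_true, dtype=int)
    y_pred = np.asarray(y_pred, dtype=int)
    N = np.bincount(y_true, minlength=n_classes)
    n_correct = np.bincount(y_true[y_true == y_pred], minlength=n_classes)
    return N, n_correct


def per_class_accuracy(N: np.ndarray, n_correct: np.ndarray) -> np.ndarray:
    """Accuracy_i = n_i / N_i for each class i."""
    N = np.asarray(N, dtype=int)
    n_correct = np.asarray(n_correct, dtype=int)
    if N.shape != n_correct.shape:
        raise ValueError("N and n_correct must have equal length")
    if np.any(n_correct > N) or np.any(n_correct < 0):
        raise ValueError("need 0 <= n_correct[i] <= N[i]")
    if np.any(N == 0):
        raise ValueError(f"class(es) with zero samples: {np.where(N == 0)[0].tolist()}")
    return n_correct / N


def overall_accuracy(N: np.ndarray, n_correct: np.ndarray) -> float:
    """Pooled accuracy sum(n_i) / sum(N_i)."""
    N = np.asarray(N, dtype=int)
    n_correct = np.asarray(n_correct, dtype=int)
    total = N.sum()
    if total <= 0:
        raise ValueError("no samples")
    return float(n_correct.sum() / total)
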