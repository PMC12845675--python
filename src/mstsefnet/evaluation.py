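"""Decoding metrics: accuracy, Cohen's kappa, information transfer rate.

Accuracy is the fraction of correctly classified trials (as a percentage);
for multi-class problems this is the trace of the confusion matrix over
its total.  Cohen's kappa corrects observed agreement for the agreement
expected from the marginal label/prediction frequencies:

    kappa = (p_o − p_e) / (1 − p_e)

ITR is the classic Wolpaw formula — the bits per decision,

    log2 N + P log2 P + (1 − P) log2((1 − P)/(N − 1)),

scaled by 60/D decisions per minute, where D is the decision-window
duration in seconds.  0·log 0 is taken as 0 by continuity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["accuracy", "cohen_kappa", "itr", "confusion_matrix", "EvalReport"]


def _check_pair(y_true, y_pred):
    yt = np.asarray(y_true, dtype=np.int64).ravel()
    yp = np.asarray(y_pred, dtype=np.int64).ravel()
    if yt.size == 0:
        raise ValueError("empty label arrays")
    if yt.shape != yp.shape:
        raise ValueError(f"length mismatch: {yt.shape} vs {yp.shape}")
    return yt, yp


def accuracy(y_true, y_pred) -> float:
    """Percentage of trials classified correctly."""
    yt, yp = _check_pair(y_true, y_pred)
    return 100.0 * float(np.mean(yt == yp))


def cohen_kappa(y_true, y_pred) -> float:
    """Chance-corrected agreement (p_o − p_e)/(1 − p_e) from the marginals."""
    yt, yp = _check_pair(y_true, y_pred)
    if np.unique(yt).size < 2:
        raise ValueError("kappa needs at least 2 observed classes in y_true")
    n = yt.size
    classes = np.unique(np.concatenate([yt, yp]))
    po = float(np.mean(yt == yp))
    pe = sum(float(np.mean(yt == c)) * float(np.mean(yp == c)) for c in classes)
    if pe >= 1.0:
        raise ValueError("degenerate marginals: chance agreement is 1")
    return (po - pe) / (1.0 - pe)


def itr(P: float, N: int, D: float) -> float:
    """Information transfer rate in bits/min for accuracy P, N classes and
    decision duration D seconds."""
    if N < 2:
        raise ValueError("N must be at least 2")
    if not 0.0 <= P <= 1.0:
        raise ValueError(f"P must lie in [0, 1], got {P}")
    if D <= 0:
        raise ValueError("D must be positive")
    bits = np.log2(N)
    if P > 0:
        bits += P * np.log2(P)
    if P < 1:
        bits += (1.0 - P) * np.log2((1.0 - P) / (N - 1))
    return 60.0 / D * float(bits)


def confusion_matrix(y_true, y_pred, n_classes: int) -> np.ndarray:
    """Counts matrix: entry (i, j) is trials with truth i predicted j."""
    yt, yp = _check_pair(y_true, y_pred)
    if yt.min() < 0 or yt.max() >= n_classes or yp.min() < 0 or yp.max() >= n_classes:
        raise ValueError(f"labels outside [0, {n_classes})")
    out = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(out, (yt, yp), 1)
    return out


def normalize_confusion(conf: np.ndarray) -> np.ndarray:
    """Row-normalised view; rows with no trials stay zero."""
    conf = np.asarray(conf, dtype=float)
    sums = conf.sum(axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(sums > 0, conf / sums, 0.0)
    return out


@dataclass
class EvalReport:
    """Per-fold and aggregate metrics from a cross-validated experiment."""

    fold_accuracy: list[float]
    fold_kappa: list[float]
    confusion: np.ndarray
    n_classes: int
    non_converged_folds: int = 0
    itr_bits_per_min: float | None = None
    extras: dict = field(default_factory=dict)

    @property
    def mean_accuracy(self) -> float:
        return float(np.mean(self.fold_accuracy))

    @property
    def std_accuracy(self) -> float:
        return float(np.std(self.fold_accuracy))

    @property
    def mean_kappa(self) -> float:
        return float(np.mean(self.fold_kappa))

    @property
    def std_kappa(self) -> float:
        return float(np.std(self.fold_kappa))

    @property
    def n_folds(self) -> int:
        return len(self.fold_accuracy)

    def to_dict(self) -> dict:
        return {
            "fold_accuracy": [float(a) for a in self.fold_accuracy],
            "fold_kappa": [float(k) for k in self.fold_kappa],
            "mean_accuracy": self.mean_accuracy,
            "std_accuracy": self.std_accuracy,
            "mean_kappa": self.mean_kappa,
            "std_kappa": self.std_kappa,
            "confusion": self.confusion.tolist(),
            "confusion_normalized": normalize_confusion(self.confusion).tolist(),
            "n_classes": self.n_classes,
            "non_converged_folds": self.non_converged_folds,
            "itr_bits_per_min": self.itr_bits_per_min,
            **({"extras": self.extras} if self.extras else {}),
        }
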