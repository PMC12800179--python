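"""AUC-weighted soft-voting ensemble of the SVM and CNN probabilities.

Member weights are the validation AUCs normalized to sum to one,
``w_i = AUC_i / (AUC_SVM + AUC_CNN)``, and the final score is the convex
combination ``p_final = w_SVM * p_SVM + w_CNN * p_CNN``. A score at or above
the 0.5 threshold is flagged "manipulated" — exact ties flag, since in a
screening setting the ambiguous case is the suspicious one.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._exceptions import ParameterError
from .data import LABEL_MANIPULATED, LABEL_REAL

DEFAULT_THRESHOLD = 0.5


@dataclass(frozen=True)
class EnsembleWeights:
    """Normalized nonnegative member weights (sum to 1)."""

    w_svm: float
    w_cnn: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.w_svm <= 1.0 and 0.0 <= self.w_cnn <= 1.0):
            raise ParameterError(f"weights must lie in [0, 1], got {self}")
        if abs(self.w_svm + self.w_cnn - 1.0) > 1e-12:
            raise ParameterError(f"weights must sum to 1, got {self.w_svm + self.w_cnn}")


def compute_weights(auc_svm: float, auc_cnn: float) -> EnsembleWeights:
    """Normalize validation AUCs into ensemble weights."""
    for name, auc in (("auc_svm", auc_svm), ("auc_cnn", auc_cnn)):
        if not 0.0 <= auc <= 1.0:
            raise ParameterError(f"{name} must be in [0, 1], got {auc}")
    total = auc_svm + auc_cnn
    if total <= 0.0:
        raise ParameterError("both AUCs are zero; weights are undefined")
    return EnsembleWeights(w_svm=auc_svm / total, w_cnn=auc_cnn / total)


def ensemble_predict(
    p_svm: np.ndarray | float,
    p_cnn: np.ndarray | float,
    weights: EnsembleWeights,
    threshold: float = DEFAULT_THRESHOLD,
):
    """Fuse member probabilities and threshold into labels.

    Returns ``(p_final, labels)``; scalars in give scalars out. Labels are
    "manipulated" iff ``p_final >= threshold``.
    """
    if not 0.0 <= threshold <= 1.0:
        raise ParameterError(f"threshold must be in [0, 1], got {threshold}")
    ps = np.atleast_1d(np.asarray(p_svm, dtype=np.float64))
    pc = np.atleast_1d(np.asarray(p_cnn, dtype=np.float64))
    if ps.shape != pc.shape:
        raise ParameterError(f"probability shapes differ: {ps.shape} vs {pc.shape}")
    for name, p in (("p_svm", ps), ("p_cnn", pc)):
        if p.size and (p.min() < 0 or p.max() > 1):
            raise ParameterError(f"{name} must lie in [0, 1]")
    p_final = weights.w_svm * ps + weights.w_cnn * pc
    labels = np.where(p_final >= threshold, LABEL_MANIPULATED, LABEL_REAL)
    if np.isscalar(p_svm) or np.asarray(p_svm).ndim == 0:
        return float(p_final[0]), str(labels[0])
    return p_final, labels
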