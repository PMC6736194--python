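"""Recovery and fit metrics: Tucker congruence, zero/nonzero
classification rate, and percentage of variance accounted for.

Component order and sign are not identified in component models, so the
comparison metrics first align the estimated components to the truth:
an optimal assignment on absolute column-wise congruence fixes the
permutation, and each matched column is sign-flipped to nonnegative
congruence.  Congruence is then the cosine between the two *vectorized*
weight matrices.  Values >= 0.85 indicate fair similarity, >= 0.95 near
equality.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import linear_sum_assignment

from .estimation import ScadsModel

__all__ = [
    "RecoveryReport",
    "align_components",
    "tucker_congruence",
    "classification_rate",
    "recovery_report",
    "congruence_band",
    "vaf",
]

FAIR_SIMILARITY = 0.85
NEAR_EQUALITY = 0.95


def _column_congruence(A: np.ndarray, B: np.ndarray) -> np.ndarray:
    """Cosine between every column pair (zero columns give 0)."""
    na = np.linalg.norm(A, axis=0)
    nb = np.linalg.norm(B, axis=0)
    denom = np.outer(na, nb)
    with np.errstate(invalid="ignore", divide="ignore"):
        C = np.where(denom > 0, (A.T @ B) / np.where(denom > 0, denom, 1.0), 0.0)
    return C


def align_components(W_true: np.ndarray, W_hat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Permutation and sign vector matching estimated to true components.

    Returns ``(perm, signs)`` such that ``W_hat[:, perm] * signs`` is the
    aligned estimate (optimal assignment on absolute column congruence;
    signs make each matched column's congruence nonnegative).
    """
    C = _column_congruence(np.asarray(W_true, float), np.asarray(W_hat, float))
    rows, cols = linear_sum_assignment(-np.abs(C))
    perm = cols[np.argsort(rows)]
    signs = np.array([1.0 if C[q, perm[q]] >= 0 else -1.0 for q in range(len(perm))])
    return perm, signs


def _aligned(W_true, W_hat, align):
    W_true = np.asarray(W_true, dtype=float)
    W_hat = np.asarray(W_hat, dtype=float)
    if W_true.shape != W_hat.shape:
        raise ValueError("weight matrices must have equal shapes")
    if align:
        perm, signs = align_components(W_true, W_hat)
        W_hat = W_hat[:, perm] * signs
    else:
        perm = np.arange(W_true.shape[1])
        signs = np.ones(W_true.shape[1])
    return W_true, W_hat, perm, signs


def tucker_congruence(W_true: np.ndarray, W_hat: np.ndarray, align: bool = True) -> float:
    """Cosine of the angle between the vectorized (aligned) matrices."""
    W_true, W_hat, _, _ = _aligned(W_true, W_hat, align)
    nt = np.linalg.norm(W_true)
    nh = np.linalg.norm(W_hat)
    if nt == 0 or nh == 0:
        raise ValueError("Tucker congruence is undefined for an all-zero matrix")
    return float(np.sum(W_true * W_hat) / (nt * nh))


def congruence_band(value: float) -> str:
    """Interpretation band for a congruence value."""
    if value >= NEAR_EQUALITY:
        return "near equal"
    if value >= FAIR_SIMILARITY:
        return "fair"
    return "poor"


def classification_rate(
    W_true: np.ndarray,
    W_hat: np.ndarray,
    align: bool = True,
    zero_tol: float = 1e-12,
) -> float:
    """Percentage of weights whose zero/nonzero status agrees (after
    alignment).  Truth is zero iff exactly 0; estimates below ``zero_tol``
    in magnitude count as zero (coordinate descent yields exact zeros)."""
    W_true, W_hat, _, _ = _aligned(W_true, W_hat, align)
    agree = (W_true != 0) == (np.abs(W_hat) > zero_tol)
    return 100.0 * float(agree.mean())


@dataclass
class RecoveryReport:
    """Alignment-aware comparison of an estimated weight matrix to truth."""

    tucker: float
    pct_correct_classified: float
    permutation: np.ndarray
    signs: np.ndarray

    @property
    def band(self) -> str:
        return congruence_band(self.tucker)

    def to_dict(self) -> dict:
        return {
            "tucker": self.tucker,
            "band": self.band,
            "pct_correct_classified": self.pct_correct_classified,
            "permutation": self.permutation.tolist(),
            "signs": self.signs.tolist(),
        }


def recovery_report(W_true: np.ndarray, W_hat: np.ndarray, align: bool = True) -> RecoveryReport:
    W_true_a, W_hat_a, perm, signs = _aligned(W_true, W_hat, align)
    nt, nh = np.linalg.norm(W_true_a), np.linalg.norm(W_hat_a)
    if nt == 0 or nh == 0:
        raise ValueError("Tucker congruence is undefined for an all-zero matrix")
    tucker = float(np.sum(W_true_a * W_hat_a) / (nt * nh))
    agree = (W_true_a != 0) == (np.abs(W_hat_a) > 1e-12)
    return RecoveryReport(tucker, 100.0 * float(agree.mean()), perm, signs)


def vaf(X: np.ndarray, model: ScadsModel) -> tuple[float, np.ndarray]:
    """Percent variance accounted for: total and per component.

    total = 100 (1 - ||X - X W Pᵀ||² / ||X||²); component q contributes
    100 ||X w_q p_qᵀ||² / ||X||².  Per-component values sum to the total
    only when the score columns are orthogonal.
    """
    X = np.asarray(X, dtype=float)
    ssq = float(np.sum(X * X))
    if ssq == 0:
        raise ValueError("X has zero sum of squares")
    W, P = model.weights, model.loadings
    resid = X - X @ W @ P.T
    total = 100.0 * (1.0 - float(np.sum(resid * resid)) / ssq)
    T = X @ W
    per = 100.0 * (T * T).sum(axis=0) * (P * P).sum(axis=0) / ssq
    return total, per
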