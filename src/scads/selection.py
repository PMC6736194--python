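"""Model selection by Eigenvector-method cross-validation.

The Eigenvector method predicts each entry of a held-out row without
using that entry: after fitting on the retained rows, the scores of a
held-out row for the purpose of predicting variable j are computed from
all variables except j through the model's weights,
``t̂ = Wᵀ x_{-j}``, and the prediction solves the self-consistency
equation ``x̂_j = p_jᵀ (t̂ + w_j x̂_j)``, i.e.

    x̂_j = p_jᵀ Wᵀ x_{-j} / (1 - p_jᵀ w_j).

The correction factor treats x_j as a missing entry imputed under the
model, so the prediction is exact when the model reconstructs the data
exactly; for plain PCA (W = P, orthonormal) the formula reduces to the
classic eigenvector expression ``p_jᵀ Pᵀ x_{-j} / (1 - ||p_j||²)``.
Because the scores come from the *weights*, constraint masks and
sparsity directly influence the MPRESS, which is what makes the
structure and penalty searches informative.  The mean of the squared
prediction errors over all held-out entries is the MPRESS; its standard
error is the standard deviation of the per-fold mean PRESS over the
folds, divided by the square root of the number of folds.

Selection uses the one-standard-error rule: among all candidates whose
MPRESS is within one standard error of the minimum, the simplest is
chosen.  The sequential strategy applies this three times: number of
components, then common/distinctive structure, then penalty strength.

Preprocessing (standardization, optional block scaling) is re-estimated
on the training rows of every fold and applied to the held-out rows, so
no information leaks from the held-out data into the fit.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .data import MultiBlockData
from .estimation import ScadsModel, fit_scads, lambda_max
from .structures import (
    ConstraintMask,
    StructureTemplate,
    count_structures,
    enumerate_structures,
    template_to_mask,
)

__all__ = [
    "CVResult",
    "CVTable",
    "eigenvector_cv",
    "one_se_rule",
    "select_n_components",
    "select_structure",
    "tune_lambda",
    "sequential_select",
    "SequentialSelection",
    "plot_cv",
]

DEFAULT_FOLDS = 10


def _values_and_data(data) -> tuple[np.ndarray, MultiBlockData | None]:
    if isinstance(data, MultiBlockData):
        return data.values, data
    return np.asarray(data, dtype=float), None


def _fold_indices(I: int, n_folds: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Seeded partition of the rows into ``n_folds`` near-equal folds."""
    perm = rng.permutation(I)
    return [np.sort(part) for part in np.array_split(perm, n_folds)]


def _standardize_pair(Xtr, Xte, scale_blocks, data, ddof=1):
    mean = Xtr.mean(axis=0)
    std = Xtr.std(axis=0, ddof=ddof)
    if np.any(std == 0):
        raise ValueError("constant column in a training fold; cannot standardize")
    Xtr = (Xtr - mean) / std
    Xte = (Xte - mean) / std
    if scale_blocks and data is not None:
        for b in data.blocks:
            Xtr[:, b.slice] /= np.sqrt(b.size)
            Xte[:, b.slice] /= np.sqrt(b.size)
    return Xtr, Xte


@dataclass
class CVResult:
    """MPRESS and its standard error from one cross-validated fit spec."""

    mpress: float
    se: float
    fold_press: np.ndarray
    flagged: bool = False            # a leave-one-variable-out system was near-singular
    predictions: np.ndarray | None = None
    fold_assignment: np.ndarray | None = None


PREDICTION_RULES = ("corrected", "deleted", "projection")


def _predict_fold(
    W: np.ndarray, P: np.ndarray, Xte: np.ndarray, prediction: str,
) -> tuple[np.ndarray, bool]:
    """Eigenvector predictions for every entry of the held-out rows,
    vectorized over rows and variables.

    ``"deleted"`` is the plug-in per-variable prediction
    ``x̂_ij = p_jᵀ Wᵀ x_{i,-j}`` (scores from all variables except the
    one being predicted).  ``"corrected"`` divides it by ``1 - b_j``
    (``b_j = p_jᵀ w_j``), the self-consistency factor that makes the
    prediction exact for an exactly reconstructing model; a denominator
    near zero falls back to the plug-in value and is flagged.
    ``"projection"`` is the fast whole-row reconstruction
    ``x̂_i = x_i W Pᵀ`` (scores from all variables, including the
    predicted one), the variant that deliberately trades a small
    optimistic bias for speed and stability.
    """
    if prediction == "projection":
        return Xte @ W @ P.T, False
    b = np.sum(W * P, axis=1)                   # J
    raw = Xte @ W @ P.T - Xte * b               # p_jᵀ Wᵀ x_{-j}
    if prediction == "deleted":
        return raw, False
    if prediction != "corrected":
        raise ValueError(f"unknown prediction rule {prediction!r}")
    denom = 1.0 - b
    bad = np.abs(denom) < 1e-8
    flagged = bool(bad.any())
    xhat = raw / np.where(bad, 1.0, denom)
    return xhat, flagged


def eigenvector_cv(
    data,
    Q: int,
    mask: np.ndarray | ConstraintMask | None = None,
    lambda1=0.0,
    lambda2: float = 0.0,
    n_folds: int = DEFAULT_FOLDS,
    seed: int | np.random.Generator | None = None,
    standardize: bool = True,
    scale_blocks: bool = False,
    prediction: str = "corrected",
    return_predictions: bool = False,
    **fit_kwargs,
) -> CVResult:
    """K-fold Eigenvector cross-validation of one fit specification.

    ``data`` is a :class:`MultiBlockData` or a plain matrix.  Rows are
    partitioned into seeded folds; per fold the preprocessing and the
    model are estimated on the retained rows only.
    """
    X, mbd = _values_and_data(data)
    I = X.shape[0]
    if not 2 <= n_folds <= I:
        raise ValueError(f"n_folds must be between 2 and {I}")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    folds = _fold_indices(I, n_folds, rng)

    fold_means = []
    flagged = False
    preds = np.full_like(X, np.nan) if return_predictions else None
    assign = np.empty(I, dtype=int) if return_predictions else None
    sq_total, n_total = 0.0, 0
    for f, test_idx in enumerate(folds):
        if test_idx.size < 1 or I - test_idx.size < 2:
            raise ValueError("fold with fewer than 2 training rows")
        train_idx = np.setdiff1d(np.arange(I), test_idx)
        Xtr, Xte = X[train_idx].copy(), X[test_idx].copy()
        if standardize:
            Xtr, Xte = _standardize_pair(Xtr, Xte, scale_blocks, mbd)
        model = fit_scads(X=Xtr, Q=Q, lambda1=lambda1, lambda2=lambda2,
                          mask=mask, **fit_kwargs)
        xhat, fl = _predict_fold(model.weights, model.loadings, Xte, prediction)
        flagged = flagged or fl
        sq = (Xte - xhat) ** 2
        fold_means.append(float(sq.mean()))
        sq_total += float(sq.sum())
        n_total += sq.size
        if return_predictions:
            preds[test_idx] = xhat
            assign[test_idx] = f

    fold_means = np.asarray(fold_means)
    mpress = sq_total / n_total
    se = float(fold_means.std(ddof=1) / np.sqrt(n_folds))
    return CVResult(mpress, se, fold_means, flagged, preds, assign)


# ---------------------------------------------------------------------------
# candidate tables and the one-standard-error rule
# ---------------------------------------------------------------------------

@dataclass
class CVTable:
    """Per-candidate MPRESS, standard error and complexity.

    ``complexity`` is comparable within a table and oriented so that
    *lower means simpler* (free-weight count for structures, Q for
    component counts, -λ for penalty grids).
    """

    labels: list[str]
    mpress: list[float]
    se: list[float]
    complexity: list[float]
    payload: list[object]
    folds: int = DEFAULT_FOLDS
    seed: int | None = None

    def add(self, label, mpress, se, complexity, payload=None) -> None:
        self.labels.append(str(label))
        self.mpress.append(float(mpress))
        self.se.append(float(se))
        self.complexity.append(float(complexity))
        self.payload.append(payload)

    @classmethod
    def empty(cls, folds: int = DEFAULT_FOLDS, seed: int | None = None) -> "CVTable":
        return cls([], [], [], [], [], folds, seed)

    def __len__(self) -> int:
        return len(self.labels)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "label": self.labels,
            "mpress": self.mpress,
            "se": self.se,
            "complexity": self.complexity,
        })


def one_se_rule(table: CVTable) -> int:
    """Index of the simplest candidate within one standard error of the
    minimum-MPRESS candidate.

    Ties on complexity break toward lower MPRESS, then label order.
    """
    if len(table) == 0:
        raise ValueError("empty candidate table")
    mpress = np.asarray(table.mpress)
    best = int(np.argmin(mpress))
    threshold = mpress[best] + table.se[best]
    eligible = [i for i in range(len(table)) if mpress[i] <= threshold]
    return min(eligible, key=lambda i: (table.complexity[i], table.mpress[i], table.labels[i]))


def select_n_components(
    data,
    Q_max: int,
    n_folds: int = DEFAULT_FOLDS,
    seed: int | None = None,
    **cv_kwargs,
) -> tuple[int, CVTable]:
    """Choose the number of components by CV of unconstrained, unpenalized
    SC models for Q = 1..Q_max, then the one-standard-error rule."""
    X, _ = _values_and_data(data)
    I, J = X.shape
    if not 1 <= Q_max <= min(I - 1, J):
        raise ValueError(f"Q_max must be between 1 and min(I-1, J)={min(I - 1, J)}")
    table = CVTable.empty(n_folds, seed)
    for q in range(1, Q_max + 1):
        res = eigenvector_cv(data, q, n_folds=n_folds, seed=seed, **cv_kwargs)
        table.add(f"Q={q}", res.mpress, res.se, complexity=q, payload=q)
    return table.payload[one_se_rule(table)], table


def _default_ridge(X: np.ndarray) -> float:
    return 1e-6 * float(np.sum(X * X)) / X.shape[1]


def select_structure(
    data,
    Q: int,
    lambda2: float | None = None,
    n_folds: int = DEFAULT_FOLDS,
    seed: int | None = None,
    candidates: Sequence[StructureTemplate] | None = None,
    candidate_cap: int = 10_000,
    **cv_kwargs,
) -> tuple[StructureTemplate, CVTable]:
    """Choose the common/distinctive structure by CV of every candidate
    template (λ1 = 0, fixed small ridge), then the one-SE rule.

    Complexity is the number of free weights, so the rule prefers the
    structure with the most imposed zeros among those within one SE.
    """
    X, mbd = _values_and_data(data)
    if mbd is None:
        raise TypeError("select_structure needs MultiBlockData (block map required)")
    K = mbd.K
    if candidates is None:
        n = count_structures(K, Q)
        if n > candidate_cap:
            raise ValueError(
                f"{n} candidate structures exceeds the cap ({candidate_cap}); "
                "pass an explicit candidate list"
            )
        candidates = enumerate_structures(K, Q)
    if lambda2 is None:
        lambda2 = _default_ridge(X)
    if K == 1:
        table = CVTable.empty(n_folds, seed)
        t = candidates[0]
        table.add(t.label(K), np.nan, 0.0, template_to_mask(t, mbd).n_free, t)
        return t, table

    table = CVTable.empty(n_folds, seed)
    for t in candidates:
        cmask = template_to_mask(t, mbd)
        res = eigenvector_cv(data, Q, mask=cmask, lambda1=0.0, lambda2=lambda2,
                             n_folds=n_folds, seed=seed, **cv_kwargs)
        table.add(t.label(K), res.mpress, res.se, complexity=cmask.n_free, payload=t)
    return table.payload[one_se_rule(table)], table


def tune_lambda(
    data,
    Q: int,
    mask: np.ndarray | ConstraintMask | None,
    grid: Sequence[float],
    which: str = "lasso",
    lambda2: float = 0.0,
    n_folds: int = DEFAULT_FOLDS,
    seed: int | None = None,
    **cv_kwargs,
) -> tuple[float, CVTable]:
    """Tune the lasso or ridge penalty on a grid by CV and the one-SE rule.

    Larger penalties are simpler, so the rule returns the largest value
    within one standard error of the minimum MPRESS.
    """
    grid = [float(g) for g in grid]
    if len(grid) < 1:
        raise ValueError("empty penalty grid")
    if which not in ("lasso", "ridge"):
        raise ValueError("which must be 'lasso' or 'ridge'")
    table = CVTable.empty(n_folds, seed)
    for lam in grid:
        l1, l2 = (lam, lambda2) if which == "lasso" else (0.0, lam)
        res = eigenvector_cv(data, Q, mask=mask, lambda1=l1, lambda2=l2,
                             n_folds=n_folds, seed=seed, **cv_kwargs)
        table.add(f"{which[0]}{lam:.6g}", res.mpress, res.se, complexity=-lam, payload=lam)
    return table.payload[one_se_rule(table)], table


@dataclass
class SequentialSelection:
    """Everything chosen by the sequential strategy, with all CV tables."""

    Q: int
    template: StructureTemplate
    lambda1: float
    lambda2: float
    model: ScadsModel
    q_table: CVTable
    structure_table: CVTable
    ridge_table: CVTable | None
    lasso_table: CVTable


def sequential_select(
    data: MultiBlockData,
    Q_max: int,
    n_folds: int = DEFAULT_FOLDS,
    seed: int | None = None,
    ridge_grid: Sequence[float] | None = None,
    lasso_grid_size: int = 10,
    standardize: bool = True,
    scale_blocks: bool = False,
    **cv_kwargs,
) -> SequentialSelection:
    """The three-step sequential strategy.

    1. number of components by CV + one-SE rule;
    2. common/distinctive structure by CV over all candidates;
    3. ridge (only when J >= I; otherwise λ2 = 0) and then lasso tuning
       on a grid from 0 to λ_max.

    The returned model is fitted on the fully preprocessed data with the
    selected Q, structure and penalties.
    """
    cv_common = dict(n_folds=n_folds, seed=seed, standardize=standardize,
                     scale_blocks=scale_blocks, **cv_kwargs)
    Q, q_table = select_n_components(data, Q_max, **cv_common)
    template, structure_table = select_structure(data, Q, **cv_common)
    mask = template_to_mask(template, data)

    from .data import block_scale, center_scale  # local import to avoid cycle at module load
    pp = center_scale(data) if standardize else data
    if scale_blocks:
        pp = block_scale(pp)
    X = pp.values
    I, J = X.shape

    ridge_table = None
    if J >= I:
        if ridge_grid is None:
            unit = float(np.sum(X * X)) / J
            ridge_grid = unit * np.geomspace(1e-4, 1e2, 7)
        lambda2, ridge_table = tune_lambda(data, Q, mask, ridge_grid, which="ridge",
                                           **cv_common)
    else:
        lambda2 = 0.0

    lam_hi = lambda_max(X, Q, mask)
    lasso_grid = np.linspace(0.0, lam_hi, max(2, lasso_grid_size))
    lambda1, lasso_table = tune_lambda(data, Q, mask, lasso_grid, which="lasso",
                                       lambda2=lambda2, **cv_common)

    model = fit_scads(X, Q, lambda1=lambda1, lambda2=lambda2, mask=mask, seed=seed)
    return SequentialSelection(Q, template, lambda1, lambda2, model,
                               q_table, structure_table, ridge_table, lasso_table)


def plot_cv(table: CVTable, ax=None, sort_by_complexity: bool = True):
    """MPRESS ± SE per candidate, ordered by complexity (simplest last).

    Requires matplotlib (optional dependency); returns the axes.
    """
    import matplotlib.pyplot as plt

    order = (np.argsort(table.complexity)[::-1] if sort_by_complexity
             else np.arange(len(table)))
    if ax is None:
        _, ax = plt.subplots(figsize=(1 + 0.6 * len(table), 4))
    x = np.arange(len(table))
    ax.errorbar(x, np.asarray(table.mpress)[order],
                yerr=np.asarray(table.se)[order], fmt="o", capsize=3)
    ax.set_xticks(x, [table.labels[i] for i in order], rotation=45, ha="right")
    ax.set_ylabel("MPRESS")
    best = int(np.argmin(table.mpress))
    ax.axhline(table.mpress[best] + table.se[best], ls="--", lw=0.8, color="gray")
    return ax
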