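"""Penalized alternating estimation of sparse common/distinctive SC models.

The model approximates preprocessed multi-block data X (I x J) by
``X W Pᵀ`` with component weights W (J x Q, possibly carrying structural
zeros) and loadings P (J x Q, orthonormal columns).  Estimates minimize

    L(W, P) = ||X - X W Pᵀ||²_F + λ1 Σ_jq |w_jq| + λ2 Σ_jq w_jq²,
    subject to PᵀP = I and w_jq = 0 wherever the constraint mask is 0.

The algorithm alternates two conditional updates until the relative
decrease of L falls below a tolerance:

* loadings — for fixed W the minimizing orthonormal P has the analytic
  reduced-rank Procrustes form ``P = U Vᵀ`` with ``XᵀX W = U D Vᵀ``;
* weights — for fixed orthonormal P, one full cycle of coordinate
  descent over the free entries of W; each coordinate minimizer is the
  soft-threshold expression
  ``w_jq = S(r_jq, λ1/2) / ((XᵀX)_jj + λ2)`` where
  ``r_jq = (XᵀX P)_jq - Σ_{j'≠j} (XᵀX)_{jj'} w_{j'q}`` and
  ``S(a, t) = sign(a) max(|a| - t, 0)``.

Both updates decrease L, so the loss trace is non-increasing and the
iteration converges to a fixed point (usually a local minimum); multiple
random starts can be used.  With λ1 = λ2 = 0 and no constraints the
model reduces to plain (simultaneous-component) PCA; with penalties but
no constraints it is sparse PCA on the concatenated blocks.

Two numerically identical inner kernels are provided: one works on the
precomputed J x J Gram matrix (cheapest when J <= I), the other streams
through X itself (cheapest when J > I, and bounds memory for very wide
data).
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numba
import numpy as np

from .structures import ConstraintMask

__all__ = [
    "ScadsModel",
    "objective",
    "update_loadings",
    "update_weights",
    "fit_scads",
    "fit_sparse_pca",
    "lambda_max",
    "tune_lasso_to_cardinality",
    "CardinalityTuneResult",
    "predict_scores",
]


# ---------------------------------------------------------------------------
# numba kernels: one full coordinate-descent sweep (column-major over
# components, variables in natural order).  W and the cached product
# (G @ W, resp. X @ W) are updated in place.
# ---------------------------------------------------------------------------

@numba.njit(cache=False)
def _sweep_gram(G, GP, diag, W, GW, mask, lam1, lam2):
    J, Q = W.shape
    for q in range(Q):
        thr = 0.5 * lam1[q]
        for j in range(J):
            if mask[j, q] == 0:
                continue
            old = W[j, q]
            r = GP[j, q] - GW[j, q] + diag[j] * old
            denom = diag[j] + lam2
            if denom <= 0.0:
                new = 0.0
            else:
                a = abs(r) - thr
                if a <= 0.0:
                    new = 0.0
                else:
                    new = a / denom if r > 0.0 else -a / denom
            if new != old:
                d = new - old
                for i in range(J):
                    GW[i, q] += G[i, j] * d
                W[j, q] = new


@numba.njit(cache=False)
def _sweep_tall(X, GP, diag, W, U, mask, lam1, lam2):
    # U = X @ W is maintained; r_jq needs only x_jᵀ u_q (O(I) per coordinate).
    I, J = X.shape
    Q = W.shape[1]
    for q in range(Q):
        thr = 0.5 * lam1[q]
        for j in range(J):
            if mask[j, q] == 0:
                continue
            old = W[j, q]
            s = 0.0
            for i in range(I):
                s += X[i, j] * U[i, q]
            r = GP[j, q] - s + diag[j] * old
            denom = diag[j] + lam2
            if denom <= 0.0:
                new = 0.0
            else:
                a = abs(r) - thr
                if a <= 0.0:
                    new = 0.0
                else:
                    new = a / denom if r > 0.0 else -a / denom
            if new != old:
                d = new - old
                for i in range(I):
                    U[i, q] += X[i, j] * d
                W[j, q] = new


# ---------------------------------------------------------------------------
# model container
# ---------------------------------------------------------------------------

@dataclass
class ScadsModel:
    """A fitted sparse common/distinctive SC model."""

    weights: np.ndarray          # W, J x Q; exactly zero wherever mask is 0
    loadings: np.ndarray         # P, J x Q, orthonormal columns
    lambda1: np.ndarray          # per-component lasso weights (shape Q)
    lambda2: float
    mask: np.ndarray             # boolean J x Q
    loss_trace: np.ndarray
    converged: bool
    n_iter: int
    start_id: int
    dead_components: tuple[int, ...] = ()   # components thresholded to all-zero

    @property
    def n_components(self) -> int:
        return self.weights.shape[1]

    @property
    def n_nonzero(self) -> int:
        return int(np.count_nonzero(self.weights))

    def nonzero_per_component(self) -> np.ndarray:
        return np.count_nonzero(self.weights, axis=0)

    def scores(self, X: np.ndarray) -> np.ndarray:
        return predict_scores(X, self)

    def objective(self, X: np.ndarray) -> float:
        return objective(X, self.weights, self.loadings, self.lambda1, self.lambda2)


# ---------------------------------------------------------------------------
# single operations
# ---------------------------------------------------------------------------

def _as_lam1(lambda1, Q: int) -> np.ndarray:
    lam = np.asarray(lambda1, dtype=float)
    if lam.ndim == 0:
        lam = np.full(Q, float(lam))
    if lam.shape != (Q,):
        raise ValueError(f"lambda1 must be a scalar or a length-{Q} vector")
    if (lam < 0).any():
        raise ValueError("lambda1 must be nonnegative")
    return lam


def objective(
    X: np.ndarray,
    weights: np.ndarray,
    loadings: np.ndarray,
    lambda1=0.0,
    lambda2: float = 0.0,
) -> float:
    """The penalized loss ``||X - X W Pᵀ||² + λ1 Σ|w| + λ2 Σ w²``.

    Computed directly from the residual matrix; penalties apply to the
    weights only, never to the loadings.
    """
    X = np.asarray(X, dtype=float)
    W = np.asarray(weights, dtype=float)
    P = np.asarray(loadings, dtype=float)
    if X.shape[1] != W.shape[0] or W.shape != P.shape:
        raise ValueError("dimension mismatch between X, W and P")
    lam1 = _as_lam1(lambda1, W.shape[1])
    resid = X - X @ W @ P.T
    return float(
        np.sum(resid * resid)
        + np.sum(lam1 * np.abs(W).sum(axis=0))
        + lambda2 * np.sum(W * W)
    )


def _procrustes(M: np.ndarray) -> np.ndarray:
    U, _, Vt = np.linalg.svd(M, full_matrices=False)
    return U @ Vt


def update_loadings(X: np.ndarray, W: np.ndarray) -> np.ndarray:
    """Analytic loadings update: ``P = U Vᵀ`` from the thin SVD of XᵀXW.

    Minimizes ``||X - X W Pᵀ||²`` over column-orthonormal P for fixed W
    (reduced-rank orthogonal Procrustes).  Rank deficiency is resolved by
    the deterministic SVD of the backing LAPACK driver.
    """
    X = np.asarray(X, dtype=float)
    W = np.asarray(W, dtype=float)
    if not np.any(W):
        raise ValueError("no active components: W is entirely zero")
    return _procrustes(X.T @ (X @ W))


def update_weights(
    X: np.ndarray,
    P: np.ndarray,
    lambda1,
    lambda2: float,
    mask: np.ndarray | ConstraintMask | None,
    W: np.ndarray,
) -> np.ndarray:
    """One full coordinate-descent sweep over the free entries of W.

    Each free coordinate is set to the exact univariate minimizer of the
    loss (soft threshold at λ1/2, curvature ``(XᵀX)_jj + λ2``); masked
    coordinates are never touched.  P must have orthonormal columns.
    """
    X = np.asarray(X, dtype=float)
    P = np.asarray(P, dtype=float)
    Q = P.shape[1]
    if np.max(np.abs(P.T @ P - np.eye(Q))) > 1e-6:
        raise ValueError("P must have orthonormal columns")
    m = _mask_array(mask, (X.shape[1], Q))
    lam1 = _as_lam1(lambda1, Q)
    W = np.array(W, dtype=float, copy=True)
    W[~m] = 0.0
    G = X.T @ X
    GP = G @ P
    GW = G @ W
    _sweep_gram(G, GP, np.diag(G).copy(), W, GW, m.astype(np.uint8), lam1, float(lambda2))
    return W


def _mask_array(mask, shape) -> np.ndarray:
    if mask is None:
        return np.ones(shape, dtype=bool)
    if isinstance(mask, ConstraintMask):
        m = mask.mask
    else:
        m = np.asarray(mask, dtype=bool)
    if m.shape != shape:
        raise ValueError(f"mask shape {m.shape} does not match expected {shape}")
    return m


# ---------------------------------------------------------------------------
# full fit
# ---------------------------------------------------------------------------

def _svd_start(X: np.ndarray, Q: int, m: np.ndarray) -> np.ndarray:
    """Masked leading-Q right singular vectors, columns renormalized."""
    _, _, Vt = np.linalg.svd(X, full_matrices=False)
    W0 = Vt[:Q].T * m
    for q in range(Q):
        nrm = np.linalg.norm(W0[:, q])
        if nrm < 1e-12:
            free = np.flatnonzero(m[:, q])
            W0[free, q] = 1.0 / np.sqrt(free.size)
        else:
            W0[:, q] /= nrm
    return W0


def _apply_sign_convention(W: np.ndarray, P: np.ndarray) -> None:
    """Flip each component jointly in W and P so the largest-magnitude
    weight (or loading, for an all-zero weight column) is positive."""
    for q in range(W.shape[1]):
        col = W[:, q] if np.any(W[:, q]) else P[:, q]
        j = int(np.argmax(np.abs(col)))
        if col[j] < 0:
            W[:, q] *= -1.0
            P[:, q] *= -1.0


def fit_scads(
    X: np.ndarray,
    Q: int,
    lambda1=0.0,
    lambda2: float = 0.0,
    mask: np.ndarray | ConstraintMask | None = None,
    n_starts: int = 1,
    tol: float = 1e-8,
    max_iter: int = 500,
    seed: int | np.random.Generator | None = None,
    W0: np.ndarray | None = None,
    method: str = "auto",
) -> ScadsModel:
    """Fit the sparse common/distinctive SC model by alternating minimization.

    Parameters
    ----------
    X:
        Preprocessed I x J data matrix.
    Q:
        Number of components, at most ``min(I, J)``.
    lambda1, lambda2:
        Lasso (scalar or per-component vector) and ridge penalty weights.
    mask:
        Boolean J x Q constraint mask (1 = free); ``None`` means
        unconstrained.
    n_starts:
        Start 0 is the deterministic masked-SVD start; additional starts
        draw standard-normal free entries from ``seed``.  The start with
        the lowest final loss wins.
    W0:
        Optional explicit warm start (replaces the SVD start).
    method:
        ``"gram"``, ``"tall"`` or ``"auto"`` (gram when J <= I).  The two
        kernels give identical results to numerical precision.
    """
    X = np.asarray(X, dtype=float)
    I, J = X.shape
    if not 1 <= Q <= min(I, J):
        raise ValueError(f"Q={Q} must be between 1 and min(I, J)={min(I, J)}")
    m = _mask_array(mask, (J, Q))
    lam1 = _as_lam1(lambda1, Q)
    lam2 = float(lambda2)
    if lam2 < 0:
        raise ValueError("lambda2 must be nonnegative")
    if method == "auto":
        method = "gram" if J <= I else "tall"
    if method not in ("gram", "tall"):
        raise ValueError(f"unknown method {method!r}")

    m8 = m.astype(np.uint8)
    if method == "gram":
        G = X.T @ X
        diag = np.ascontiguousarray(np.diag(G))
        ssq_X = float(np.trace(G))
    else:
        Xf = np.asfortranarray(X)
        diag = np.ascontiguousarray((X * X).sum(axis=0))
        ssq_X = float(diag.sum())

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    start0 = np.array(W0, dtype=float, copy=True) if W0 is not None else _svd_start(X, Q, m)
    start0[~m] = 0.0
    if not np.any(start0):
        raise ValueError("starting weights are entirely zero")

    best: ScadsModel | None = None
    for start_id in range(max(1, int(n_starts))):
        if start_id == 0:
            W = start0.copy()
        else:
            W = rng.standard_normal((J, Q)) * m
            for q in range(Q):
                W[:, q] /= max(np.linalg.norm(W[:, q]), 1e-12)

        if method == "gram":
            GW = G @ W
            P = _procrustes(GW)
        else:
            U = X @ W
            M = Xf.T @ U
            P = _procrustes(M)

        def _loss(P_, cache_PtGW, cache_WtGW):
            rec = ssq_X - 2.0 * cache_PtGW + cache_WtGW
            pen = float(np.sum(lam1 * np.abs(W).sum(axis=0)) + lam2 * np.sum(W * W))
            return rec + pen

        if method == "gram":
            trace = [_loss(P, float(np.sum(P * GW)), float(np.sum(W * GW)))]
        else:
            trace = [_loss(P, float(np.sum(P * M)), float(np.sum(U * U)))]

        converged = False
        n_iter = 0
        for it in range(1, max_iter + 1):
            n_iter = it
            if method == "gram":
                GP = G @ P
                _sweep_gram(G, GP, diag, W, GW, m8, lam1, lam2)
                if it % 50 == 0:
                    GW = G @ W  # refresh incrementally-updated cache
                if np.any(W):
                    P = _procrustes(GW)
                loss = _loss(P, float(np.sum(P * GW)), float(np.sum(W * GW)))
            else:
                V = X @ P
                GP = Xf.T @ V
                _sweep_tall(Xf, GP, diag, W, U, m8, lam1, lam2)
                if it % 50 == 0:
                    U = X @ W
                M = Xf.T @ U
                if np.any(W):
                    P = _procrustes(M)
                loss = _loss(P, float(np.sum(P * M)), float(np.sum(U * U)))
            if not np.isfinite(loss):
                raise FloatingPointError("non-finite objective: divergence bug")
            trace.append(loss)
            if trace[-2] - loss <= tol * max(trace[-2], 1e-300):
                converged = True
                break

        W_out, P_out = W.copy(), P.copy()
        _apply_sign_convention(W_out, P_out)
        dead = tuple(int(q) for q in range(Q) if not np.any(W_out[:, q]))
        model = ScadsModel(
            weights=W_out,
            loadings=P_out,
            lambda1=lam1.copy(),
            lambda2=lam2,
            mask=m,
            loss_trace=np.asarray(trace),
            converged=converged,
            n_iter=n_iter,
            start_id=start_id,
            dead_components=dead,
        )
        if best is None or model.loss_trace[-1] < best.loss_trace[-1]:
            best = model
    return best


def fit_sparse_pca(
    X: np.ndarray,
    Q: int,
    lambda1=0.0,
    lambda2: float = 0.0,
    **kwargs,
) -> ScadsModel:
    """Sparse PCA of the concatenated data: the unconstrained special case
    (all-ones mask) of :func:`fit_scads`."""
    kwargs.pop("mask", None)
    return fit_scads(X, Q, lambda1=lambda1, lambda2=lambda2, mask=None, **kwargs)


# ---------------------------------------------------------------------------
# lasso tuning to a target cardinality
# ---------------------------------------------------------------------------

def lambda_max(
    X: np.ndarray,
    Q: int,
    mask: np.ndarray | ConstraintMask | None = None,
) -> float:
    """Smallest λ1 at which one sweep from W = 0 leaves every free weight
    at zero: ``2 max_{free (j,q)} |(XᵀX P⁰)_jq|`` with P⁰ from the SVD start."""
    X = np.asarray(X, dtype=float)
    J = X.shape[1]
    m = _mask_array(mask, (J, Q))
    W0 = _svd_start(X, Q, m)
    GW0 = X.T @ (X @ W0)
    P0 = _procrustes(GW0)
    GP0 = X.T @ (X @ P0)
    return 2.0 * float(np.max(np.abs(GP0)[m]))


@dataclass
class CardinalityTuneResult:
    """Outcome of bisection tuning of λ1 toward a nonzero-count target."""

    lambda1: np.ndarray        # shape (Q,)
    model: ScadsModel
    n_nonzero: int
    target: int
    exact: bool                # True if the target was hit within tolerance
    n_steps: int


def tune_lasso_to_cardinality(
    X: np.ndarray,
    Q: int,
    mask: np.ndarray | ConstraintMask | None,
    lambda2: float,
    target_nonzeros: int | Sequence[int],
    tol_fraction: float = 1e-4,
    max_steps: int = 50,
    **fit_kwargs,
) -> CardinalityTuneResult:
    """Bisection on λ1 until the fitted nonzero-weight count matches a target.

    A scalar target tunes one shared λ1 against the total count; a
    per-component target tunes a per-component λ1 vector against the
    per-component counts (each bracket bisected simultaneously).  If the
    bracket collapses before the count is within ``tol_fraction`` of the
    target, the best bracket endpoint seen is returned with
    ``exact=False``.
    """
    X = np.asarray(X, dtype=float)
    J = X.shape[1]
    m = _mask_array(mask, (J, Q))
    free_per_comp = m.sum(axis=0)
    per_component = np.ndim(target_nonzeros) > 0
    if per_component:
        target = np.asarray(target_nonzeros, dtype=int)
        if target.shape != (Q,):
            raise ValueError(f"per-component target must have length {Q}")
        if (target < 0).any() or (target > free_per_comp).any():
            raise ValueError("target outside [0, free entries] for some component")
        total_target = int(target.sum())
    else:
        total_target = int(target_nonzeros)
        if not 0 <= total_target <= int(m.sum()):
            raise ValueError("target outside [0, number of free mask entries]")

    lam_hi = lambda_max(X, Q, m)
    tol_count = tol_fraction * max(total_target, 1)

    fit_kwargs.setdefault("tol", 1e-8)
    # continuation: bisection fits warm-start from the λ1 = 0 solution
    # (unique under the ridge, so the path avoids rotated local minima)
    # and then from the previous accepted weights along the bracket
    warm = fit_kwargs.pop("W0", None)

    def _fit(lam1):
        nonlocal warm
        model = fit_scads(
            X, Q, lambda1=lam1, lambda2=lambda2, mask=m,
            W0=warm, **fit_kwargs,
        )
        if np.any(model.weights):
            warm = model.weights
        return model

    if total_target == 0:
        # λ_max is defined by a sweep from W = 0 staying at zero, so the
        # all-zero model is the fixed point there; build it directly.
        W0 = _svd_start(X, Q, np.ones((J, Q), dtype=bool))
        P0 = _procrustes(X.T @ (X @ W0))
        lam = np.full(Q, lam_hi)
        model = ScadsModel(
            weights=np.zeros((J, Q)), loadings=P0, lambda1=lam,
            lambda2=float(lambda2), mask=m,
            loss_trace=np.array([float(np.sum(X * X))]), converged=True,
            n_iter=0, start_id=0, dead_components=tuple(range(Q)),
        )
        return CardinalityTuneResult(lam, model, 0, 0, True, 0)

    if warm is None:
        warm = fit_scads(X, Q, lambda1=0.0, lambda2=lambda2, mask=m,
                         **fit_kwargs).weights

    lo = np.zeros(Q)
    hi = np.full(Q, lam_hi)
    best = None  # (gap, lam, model)
    n_steps = 0
    for n_steps in range(1, max_steps + 1):
        mid = 0.5 * (lo + hi)
        model = _fit(mid)
        counts = model.nonzero_per_component()
        if per_component:
            gap = int(np.abs(counts - target).sum())
            too_many = counts > target
        else:
            gap = abs(int(counts.sum()) - total_target)
            too_many = np.full(Q, counts.sum() > total_target)
        if best is None or gap < best[0]:
            best = (gap, mid.copy(), model)
        if gap <= tol_count:
            return CardinalityTuneResult(mid, model, model.n_nonzero,
                                         total_target, True, n_steps)
        lo = np.where(too_many, mid, lo)
        hi = np.where(too_many, hi, mid)
        if np.all(hi - lo <= 1e-12 * lam_hi):
            break
    gap, lam, model = best
    return CardinalityTuneResult(lam, model, model.n_nonzero, total_target,
                                 gap <= tol_count, n_steps)


def predict_scores(X_new: np.ndarray, model: ScadsModel) -> np.ndarray:
    """Component scores ``T = X_new W`` for new units (same preprocessing
    as the training data).  Only variables with nonzero weights enter."""
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    if X_new.shape[1] != model.weights.shape[0]:
        raise ValueError(
            f"X_new has {X_new.shape[1]} columns, model expects {model.weights.shape[0]}"
        )
    return X_new @ model.weights
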