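"""Independent numerical oracles shared by the test modules."""
import numpy as np


def random_orthonormal(rng, J, Q):
    M = rng.standard_normal((J, Q))
    Qm, R = np.linalg.qr(M)
    return Qm * np.sign(np.diag(R))


def grid_search_coordinate(X, W, P, lam1, lam2, j, q, lo=-10.0, hi=10.0, step=1e-4):
    """Independent 1-D oracle: evaluate the penalized loss on a dense grid
    of values for w_jq, all other weights held fixed.

    Uses the exact rank-one identity ||A - c u vᵀ||² = ||A||² - 2c uᵀAv
    + c²||u||²||v||² so the whole grid can be evaluated without the
    coordinate-descent formulas.
    """
    W0 = W.copy()
    W0[j, q] = 0.0
    A = X - X @ W0 @ P.T
    u, v = X[:, j], P[:, q]
    uAv = float(u @ A @ v)
    uu_vv = float(u @ u) * float(v @ v)
    base_l1 = np.abs(W0).sum()
    base_l2 = np.sum(W0 * W0)
    grid = np.arange(lo, hi + step / 2, step)
    f = (np.sum(A * A) - 2 * grid * uAv + grid**2 * uu_vv
         + lam1 * (base_l1 + np.abs(grid)) + lam2 * (base_l2 + grid**2))
    return grid[np.argmin(f)]
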