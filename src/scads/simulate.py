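"""Synthetic multi-block data under a sparse SC model with known truth.

The generator produces data ``X = T Pᵀ + E`` in which

* ``P`` (J x Q) carries the requested common/distinctive zero-block
  pattern plus extra, randomly placed zeros per component, and has
  orthonormal columns *within* that pattern (alternating projections
  between the orthonormal manifold and the zero pattern);
* ``T`` (I x Q) are orthonormalized standard-normal scores;
* ``W`` is the minimum-norm weight matrix with the same zero pattern
  satisfying ``(T Pᵀ) W = T`` exactly, so the ground truth is a valid
  weight-side model for the noiseless data;
* ``E`` is homoscedastic Gaussian noise rescaled so that the realized
  noise fraction ``||E||² / ||X||²`` equals the request exactly.

Per-component sparsity is a zero fraction of the component's *free*
entries (``floor(fraction * n_free)`` zeros placed uniformly without
replacement, keeping at least one nonzero in every participating block).
Two ready-made fully crossed designs are provided: a high-dimensional
one (I = 100, two blocks of 250 variables) and a low-dimensional one
(I = 195, two blocks of 10), each crossing noise fractions
{5%, 25%, 50%} with high (60% zeros in every component) and low
(2% zeros in the common, 52% in the distinctive components) sparsity,
with 20 replications per cell and true structure "D1 D2 C".
"""
from __future__ import annotations

import json
import zlib
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .data import Block, MultiBlockData, write_matrix_csv
from .structures import StructureTemplate, template_to_mask

__all__ = [
    "SyntheticDataset",
    "SimulationCondition",
    "generate",
    "generate_condition",
    "high_dim_conditions",
    "low_dim_conditions",
    "total_to_free_zero_fractions",
]

_TEMPLATE_2BLOCK = StructureTemplate.from_string("D1 D2 C", K=2)


@dataclass
class SyntheticDataset:
    """Generated multi-block data plus its generating model."""

    data: MultiBlockData
    W_true: np.ndarray
    P_true: np.ndarray
    T_true: np.ndarray
    noise_fraction: float
    template: StructureTemplate
    seed: object

    @property
    def signal(self) -> np.ndarray:
        return self.T_true @ self.P_true.T

    def save(self, directory: str | Path) -> None:
        """Write the data (one CSV per block) and a ground-truth sidecar."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        comp = [f"comp{q + 1}" for q in range(self.W_true.shape[1])]
        for b in self.data.blocks:
            write_matrix_csv(self.data.values[:, b.slice], d / f"{b.name}.csv",
                             col_labels=[f"{b.name}_{j + 1}" for j in range(b.size)],
                             write_index=False)
        write_matrix_csv(self.W_true, d / "W_true.csv", col_labels=comp)
        write_matrix_csv(self.P_true, d / "P_true.csv", col_labels=comp)
        write_matrix_csv(self.T_true, d / "T_true.csv", col_labels=comp)
        meta = {
            "template": self.template.to_string(),
            "template_label": self.template.label(self.data.K),
            "noise_fraction": self.noise_fraction,
            "seed": repr(self.seed),
            "block_sizes": list(self.data.block_sizes),
        }
        (d / "truth.json").write_text(json.dumps(meta, indent=2))


@dataclass(frozen=True)
class SimulationCondition:
    """One cell of a fully crossed simulation design."""

    name: str
    I: int
    block_sizes: tuple[int, ...]
    template: StructureTemplate
    sparsity: str                       # "high" | "low"
    total_zero_fractions: tuple[float, ...]   # per component, of ALL entries
    noise_fraction: float
    n_reps: int = 20

    def free_zero_fractions(self) -> tuple[float, ...]:
        return total_to_free_zero_fractions(
            self.template, self.block_sizes, self.total_zero_fractions
        )


def total_to_free_zero_fractions(
    template: StructureTemplate,
    block_sizes: Sequence[int],
    total_fractions: Sequence[float],
) -> tuple[float, ...]:
    """Convert zero fractions of a component's *total* J entries into zero
    fractions of its *free* (unconstrained) entries."""
    mask = template_to_mask(template, block_sizes).mask
    J = mask.shape[0]
    out = []
    for q, frac in enumerate(total_fractions):
        free = int(mask[:, q].sum())
        constrained = J - free
        wanted = frac * J - constrained
        if wanted < -1e-9:
            raise ValueError(
                f"component {q}: requested total zero fraction {frac} is below "
                f"the {constrained / J:.2f} already imposed by the structure"
            )
        out.append(max(wanted, 0.0) / free)
    return tuple(out)


# ---------------------------------------------------------------------------
# generation
# ---------------------------------------------------------------------------

def _pattern_orthonormalize(P: np.ndarray, support: np.ndarray,
                            max_iter: int = 2000, tol: float = 1e-12) -> np.ndarray | None:
    """Alternating projections between column-orthonormal matrices and the
    zero pattern; returns None on failure (rank collapse / no convergence)."""
    P = P * support
    for _ in range(max_iter):
        U, s, Vt = np.linalg.svd(P, full_matrices=False)
        if s[-1] < 1e-10:
            return None
        P = (U @ Vt) * support
        gram = P.T @ P
        if np.max(np.abs(gram - np.eye(P.shape[1]))) < tol:
            return P
    return None


def _choose_support(
    mask_q: np.ndarray,
    zero_fraction: float,
    blocks: Sequence[Block],
    subset: tuple[int, ...],
    rng: np.random.Generator,
) -> np.ndarray:
    """Free-entry support for one component: drop ``floor(f * n_free)``
    entries uniformly, keeping >= 1 nonzero per participating block."""
    free = np.flatnonzero(mask_q)
    n_zero = int(np.floor(zero_fraction * free.size))
    if n_zero > free.size - len(subset):
        raise ValueError(
            f"zero fraction {zero_fraction} leaves no nonzero entry in some block"
        )
    support = mask_q.copy()
    if n_zero == 0:
        return support
    for _ in range(1000):
        drop = rng.choice(free, size=n_zero, replace=False)
        trial = mask_q.copy()
        trial[drop] = False
        if all(trial[blocks[b - 1].slice].any() for b in subset):
            return trial
    # fall back: protect one random entry per participating block
    protected = np.array([rng.choice(np.flatnonzero(mask_q[blocks[b - 1].slice]))
                          + blocks[b - 1].start for b in subset])
    candidates = np.setdiff1d(free, protected)
    drop = rng.choice(candidates, size=n_zero, replace=False)
    support = mask_q.copy()
    support[drop] = False
    return support


def generate(
    I: int,
    block_sizes: Sequence[int],
    template: StructureTemplate,
    sparsity_per_component: Sequence[float] | float,
    noise_fraction: float,
    seed: int | np.random.SeedSequence | np.random.Generator | None = None,
    block_names: Sequence[str] | None = None,
    max_retries: int = 10,
) -> SyntheticDataset:
    """Generate one multi-block dataset under the sparse SC model.

    ``sparsity_per_component`` gives, per component, the zero fraction of
    that component's free entries (a scalar is broadcast).
    ``noise_fraction`` in [0, 1) is the exact fraction of total variation
    contributed by noise.
    """
    if not 0 <= noise_fraction < 1:
        raise ValueError("noise_fraction must be in [0, 1)")
    block_sizes = tuple(int(s) for s in block_sizes)
    Q = template.n_components
    fracs = np.broadcast_to(np.asarray(sparsity_per_component, dtype=float), (Q,))
    if (fracs < 0).any() or (fracs >= 1).any():
        raise ValueError("sparsity fractions must be in [0, 1)")
    mask = template_to_mask(template, block_sizes).mask
    J = mask.shape[0]
    names = list(block_names) if block_names else [f"block{k + 1}" for k in range(len(block_sizes))]
    blocks, pos = [], 0
    for name, size in zip(names, block_sizes):
        blocks.append(Block(name, pos, pos + size))
        pos += size

    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    last_err = "exhausted retries"
    for _ in range(max_retries):
        support = np.empty_like(mask)
        for q in range(Q):
            support[:, q] = _choose_support(mask[:, q], fracs[q], blocks,
                                            template.components[q], rng)
        P = _pattern_orthonormalize(rng.standard_normal((J, Q)), support)
        if P is None:
            last_err = "pattern orthonormalization failed"
            continue

        # orthonormal scores with a deterministic sign fix
        Traw = rng.standard_normal((I, Q))
        T, R = np.linalg.qr(Traw)
        T = T * np.sign(np.diag(R))

        X_signal = T @ P.T

        # minimum-norm W on the pattern with Pᵀ w_q = e_q (=> X_signal W = T)
        W = np.zeros((J, Q))
        ok = True
        for q in range(Q):
            S = np.flatnonzero(support[:, q])
            A = P[S, :].T                                   # Q x |S|
            e = np.zeros(Q)
            e[q] = 1.0
            w_S, *_ = np.linalg.lstsq(A, e, rcond=None)
            if np.max(np.abs(A @ w_S - e)) > 1e-9 or np.min(np.abs(w_S)) < 1e-14:
                ok = False
                break
            W[S, q] = w_S
        if not ok:
            last_err = "weight system inconsistent or produced spurious zeros"
            continue

        if noise_fraction > 0:
            E = rng.standard_normal((I, J))
            # exact rescaling: ||cE||² = f ||X_signal + cE||², i.e. the
            # positive root of  c²e(1-f) - 2fcx - fs = 0  with
            # e = ||E||², s = ||X_signal||², x = <X_signal, E>
            f = noise_fraction
            e = float(np.sum(E * E))
            s = float(np.sum(X_signal * X_signal))
            x = float(np.sum(X_signal * E))
            c = (f * x + np.sqrt(f * f * x * x + e * f * s * (1 - f))) / (e * (1 - f))
            E *= c
        else:
            E = np.zeros((I, J))
        X = X_signal + E

        data = MultiBlockData(X, tuple(blocks))
        return SyntheticDataset(data, W, P, T, float(noise_fraction), template, seed)
    raise RuntimeError(f"could not generate a valid dataset after {max_retries} retries: {last_err}")


# ---------------------------------------------------------------------------
# the two crossed designs
# ---------------------------------------------------------------------------

_NOISE_LEVELS = (0.05, 0.25, 0.50)
_SPARSITY_LEVELS = {
    # per component (D1, D2, C): zero fraction of ALL J entries
    "high": (0.60, 0.60, 0.60),
    "low": (0.52, 0.52, 0.02),
}


def _crossed_design(I: int, block_sizes: tuple[int, ...], n_reps: int) -> list[SimulationCondition]:
    conditions = []
    for sparsity in ("high", "low"):
        for noise in _NOISE_LEVELS:
            conditions.append(SimulationCondition(
                name=f"{sparsity}_noise{int(round(noise * 100))}",
                I=I,
                block_sizes=block_sizes,
                template=_TEMPLATE_2BLOCK,
                sparsity=sparsity,
                total_zero_fractions=_SPARSITY_LEVELS[sparsity],
                noise_fraction=noise,
                n_reps=n_reps,
            ))
    return conditions


def high_dim_conditions(n_reps: int = 20) -> list[SimulationCondition]:
    """High-dimensional crossed design: I=100, two blocks of 250 variables,
    {5, 25, 50}% noise x {high, low} sparsity, true structure D1 D2 C."""
    return _crossed_design(100, (250, 250), n_reps)


def low_dim_conditions(n_reps: int = 20) -> list[SimulationCondition]:
    """Low-dimensional crossed design: I=195, two blocks of 10 variables."""
    return _crossed_design(195, (10, 10), n_reps)


def generate_condition(
    condition: SimulationCondition,
    replication: int,
    seed: int,
) -> SyntheticDataset:
    """Generate one replication of a design cell with an independent,
    reproducible random stream keyed by (condition, replication)."""
    ss = np.random.SeedSequence(
        entropy=seed,
        spawn_key=(zlib.crc32(condition.name.encode()), int(replication)),
    )
    return generate(
        condition.I,
        condition.block_sizes,
        condition.template,
        condition.free_zero_fractions(),
        condition.noise_fraction,
        seed=np.random.default_rng(ss),
    )
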