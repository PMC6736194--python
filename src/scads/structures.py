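"""Common/distinctive component structures and their constraint masks.

A structure assigns to each of Q components a nonempty subset of the K
blocks: a component drawing on every block is *common*, one restricted to
a proper subset is *distinctive* for those blocks.  A structure expands
into a binary J x Q mask in which 1 marks a free component weight and 0 a
weight constrained to zero.

Because component order inside a model carries no meaning, templates are
kept in a canonical form (subsets sorted by size, then lexicographically)
and compare equal under permutation of their components.
"""
from __future__ import annotations

import itertools
import math
import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

__all__ = [
    "StructureTemplate",
    "ConstraintMask",
    "all_nonempty_subsets",
    "count_structures",
    "enumerate_structures",
    "template_to_mask",
]

ENUMERATION_WARN_THRESHOLD = 10_000


def all_nonempty_subsets(K: int) -> list[tuple[int, ...]]:
    """All 2^K - 1 nonempty subsets of blocks {1..K}, in canonical order."""
    if K < 1:
        raise ValueError("K must be >= 1")
    subsets = []
    for r in range(1, K + 1):
        subsets.extend(itertools.combinations(range(1, K + 1), r))
    return sorted(subsets, key=lambda s: (len(s), s))


@dataclass(frozen=True)
class StructureTemplate:
    """Ordered multiset of Q nonempty block subsets (1-based indices).

    Instances are always in canonical form; build them via
    :meth:`from_subsets` or :meth:`from_string`.
    """

    components: tuple[tuple[int, ...], ...]

    @classmethod
    def from_subsets(cls, subsets: Iterable[Iterable[int]]) -> "StructureTemplate":
        comps = []
        for s in subsets:
            t = tuple(sorted(set(int(b) for b in s)))
            if not t:
                raise ValueError("every component must use at least one block")
            if t[0] < 1:
                raise ValueError("block indices are 1-based")
            comps.append(t)
        if not comps:
            raise ValueError("a template needs at least one component")
        return cls(tuple(sorted(comps, key=lambda s: (len(s), s))))

    @classmethod
    def from_string(cls, text: str, K: int | None = None) -> "StructureTemplate":
        """Parse ``"D1 D2 C"`` (needs K for ``C``) or ``"{1},{2},{1,2}"``."""
        text = text.strip()
        if "{" in text:
            subsets = [
                [int(b) for b in re.findall(r"\d+", part)]
                for part in re.findall(r"\{[^}]*\}", text)
            ]
            return cls.from_subsets(subsets)
        subsets = []
        for tok in text.replace(",", " ").split():
            if tok.upper() == "C":
                if K is None:
                    raise ValueError("parsing a 'C' label requires K")
                subsets.append(range(1, K + 1))
            elif tok.upper().startswith("D"):
                subsets.append(int(ch) for ch in tok[1:])
            else:
                raise ValueError(f"cannot parse component label {tok!r}")
        return cls.from_subsets(subsets)

    @property
    def n_components(self) -> int:
        return len(self.components)

    def max_block(self) -> int:
        return max(b for s in self.components for b in s)

    def label(self, K: int | None = None) -> str:
        """Field-style labels: ``C`` for a full subset, ``D<blocks>`` otherwise."""
        K = K or self.max_block()
        out = []
        for s in self.components:
            out.append("C" if len(s) == K else "D" + "".join(str(b) for b in s))
        return " ".join(out)

    def to_string(self) -> str:
        return ",".join("{" + ",".join(str(b) for b in s) + "}" for s in self.components)

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.to_string()


@dataclass(frozen=True)
class ConstraintMask:
    """Binary J x Q mask: 1 = free weight, 0 = constrained to zero."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.mask, dtype=bool)
        object.__setattr__(self, "mask", m)
        if m.ndim != 2:
            raise ValueError("mask must be 2-D")
        if not m.any(axis=0).all():
            raise ValueError("mask has an all-zero component column")

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape

    @property
    def n_free(self) -> int:
        return int(self.mask.sum())


def count_structures(K: int, Q: int) -> int:
    """Number of distinct structures: multisets of size Q over the
    2^K - 1 nonempty block subsets, i.e. C(2^K - 1 + Q - 1, Q)."""
    if K < 1 or Q < 1:
        raise ValueError("K and Q must be >= 1")
    return math.comb(2**K - 2 + Q, Q)


def enumerate_structures(K: int, Q: int) -> list[StructureTemplate]:
    """All distinct common/distinctive structures for K blocks, Q components."""
    if K < 1 or Q < 1:
        raise ValueError("K and Q must be >= 1")
    n = count_structures(K, Q)
    if n > ENUMERATION_WARN_THRESHOLD:
        warnings.warn(
            f"enumerating {n} candidate structures (K={K}, Q={Q}); "
            "consider an explicit candidate list",
            stacklevel=2,
        )
    subsets = all_nonempty_subsets(K)
    return [
        StructureTemplate(combo)
        for combo in itertools.combinations_with_replacement(subsets, Q)
    ]


def template_to_mask(template: StructureTemplate, data_or_sizes) -> ConstraintMask:
    """Expand a template into its J x Q zero-block constraint mask.

    ``data_or_sizes`` is a :class:`~scads.data.MultiBlockData` or a
    sequence of block sizes.  Column q of the mask is 1 exactly on the
    variables of the blocks in ``template.components[q]``.
    """
    if hasattr(data_or_sizes, "block_sizes"):
        sizes: Sequence[int] = data_or_sizes.block_sizes
    else:
        sizes = tuple(int(s) for s in data_or_sizes)
    K = len(sizes)
    if template.max_block() > K:
        raise ValueError(
            f"template references block {template.max_block()} but data has only {K} blocks"
        )
    starts = np.concatenate([[0], np.cumsum(sizes)])
    J = int(starts[-1])
    mask = np.zeros((J, template.n_components), dtype=bool)
    for q, subset in enumerate(template.components):
        for b in subset:
            mask[starts[b - 1]:starts[b], q] = True
    return ConstraintMask(mask)
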