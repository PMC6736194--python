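"""Multi-block data container, delimited-file I/O and preprocessing.

Linked (multi-block) data are K groups of continuous variables measured on
the same I observation units.  The blocks are concatenated column-wise into
one I x J matrix (J = sum of the block widths) together with a map that
records which contiguous column range belongs to which block.

Two preprocessing steps are provided: per-variable standardization
(mean 0, variance 1) and block scaling (dividing each block by the square
root of its number of variables so that standardized blocks contribute
equal total sums of squares).
"""
from __future__ import annotations

import csv
import io
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Block",
    "MultiBlockData",
    "read_blocks",
    "read_combined",
    "center_scale",
    "block_scale",
    "write_matrix_csv",
]

_DELIMITERS = (",", "\t", ";")


@dataclass(frozen=True)
class Block:
    """A named, contiguous column range ``[start, stop)`` of the matrix."""

    name: str
    start: int
    stop: int

    @property
    def size(self) -> int:
        return self.stop - self.start

    @property
    def slice(self) -> slice:
        return slice(self.start, self.stop)


@dataclass
class MultiBlockData:
    """Column-wise concatenation of K linked data blocks.

    Parameters
    ----------
    values:
        I x J matrix of finite floats; row i is the same observation unit
        in every block.
    blocks:
        Ordered block descriptors whose column ranges are disjoint,
        contiguous, ordered and jointly cover all J columns.
    unit_ids, variable_names:
        Optional row / column labels.
    """

    values: np.ndarray
    blocks: tuple[Block, ...]
    unit_ids: list[str] | None = None
    variable_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.blocks = tuple(self.blocks)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        I, J = self.values.shape
        if I < 2:
            raise ValueError(f"need at least 2 observation units, got {I}")
        if not self.blocks:
            raise ValueError("need at least one block")
        pos = 0
        for b in self.blocks:
            if b.start != pos:
                raise ValueError(
                    f"block {b.name!r} starts at column {b.start}, expected {pos}: "
                    "block ranges must be contiguous and ordered"
                )
            if b.size < 1:
                raise ValueError(f"block {b.name!r} is empty")
            pos = b.stop
        if pos != J:
            raise ValueError(f"blocks cover {pos} columns but matrix has {J}")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite entries found; missing values are not accepted")
        if self.unit_ids is not None and len(self.unit_ids) != I:
            raise ValueError("unit_ids length does not match row count")
        if self.variable_names is not None and len(self.variable_names) != J:
            raise ValueError("variable_names length does not match column count")

    # -- bookkeeping ---------------------------------------------------
    @property
    def I(self) -> int:  # noqa: E743 - field-standard symbol
        return self.values.shape[0]

    @property
    def J(self) -> int:
        return self.values.shape[1]

    @property
    def K(self) -> int:
        return len(self.blocks)

    @property
    def block_sizes(self) -> tuple[int, ...]:
        return tuple(b.size for b in self.blocks)

    @property
    def block_names(self) -> tuple[str, ...]:
        return tuple(b.name for b in self.blocks)

    def block_values(self, key: int | str) -> np.ndarray:
        """Return the sub-matrix of one block (``key`` is an index or a name)."""
        return self.values[:, self._block(key).slice]

    def _block(self, key: int | str) -> Block:
        if isinstance(key, str):
            for b in self.blocks:
                if b.name == key:
                    return b
            raise KeyError(f"no block named {key!r}")
        return self.blocks[key]

    def with_values(self, values: np.ndarray) -> "MultiBlockData":
        return replace(self, values=np.asarray(values, dtype=float))

    def to_frame(self) -> pd.DataFrame:
        cols = self.variable_names or [f"x{j + 1}" for j in range(self.J)]
        idx = self.unit_ids or list(range(1, self.I + 1))
        return pd.DataFrame(self.values, index=idx, columns=cols)


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _detect_delimiter(sample: str) -> str:
    counts = {d: sample.count(d) for d in _DELIMITERS}
    best = max(counts, key=counts.get)
    return best if counts[best] > 0 else ","


def _is_number(s: str) -> bool:
    try:
        float(s)
        return True
    except ValueError:
        return False


def _read_matrix(
    path: str | Path,
    delimiter: str | None = None,
    header: bool | None = None,
    row_labels: bool | None = None,
) -> tuple[np.ndarray, list[str] | None, list[str] | None]:
    """Read one delimited numeric matrix.

    ``header`` / ``row_labels`` default to auto-detection: a first row (or
    first column) whose cells do not all parse as numbers is treated as
    labels.
    """
    text = Path(path).read_text()
    delim = delimiter or _detect_delimiter(text.splitlines()[0] if text else "")
    rows = [r for r in csv.reader(io.StringIO(text), delimiter=delim) if any(c.strip() for c in r)]
    if not rows:
        raise ValueError(f"{path}: empty file")
    widths = {len(r) for r in rows}
    if len(widths) > 1:
        raise ValueError(f"{path}: ragged rows (widths {sorted(widths)})")

    if header is None:
        header = not all(_is_number(c) for c in rows[0][1:])
    col_names = [c.strip() for c in rows[0]] if header else None
    body = rows[1:] if header else rows
    if not body:
        raise ValueError(f"{path}: no data rows")

    if row_labels is None:
        # an empty top-left header cell marks a row-label column
        row_labels = (header and col_names[0] == "") or not all(
            _is_number(r[0]) for r in body
        )
    ids: list[str] | None = None
    if row_labels:
        ids = [r[0].strip() for r in body]
        body = [r[1:] for r in body]
        if col_names is not None and len(col_names) == len(body[0]) + 1:
            col_names = col_names[1:]

    values = np.empty((len(body), len(body[0])), dtype=float)
    for i, r in enumerate(body):
        for j, cell in enumerate(r):
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric value {cell!r} at row {i + 1}, column {j + 1}"
                ) from None
    return values, ids, col_names


def read_blocks(
    paths: Sequence[str | Path],
    block_names: Sequence[str] | None = None,
    delimiter: str | None = None,
    header: bool | None = None,
    row_labels: bool | None = None,
) -> MultiBlockData:
    """Read one delimited file per block and concatenate them column-wise.

    Row alignment is positional: row i of every file must belong to the
    same observation unit.  Raises on row-count mismatch, ragged or
    non-numeric input, or an empty block.
    """
    if not paths:
        raise ValueError("no input files given")
    names = list(block_names) if block_names else [Path(p).stem for p in paths]
    if len(names) != len(paths):
        raise ValueError("block_names length does not match number of files")

    parts, ids0, var_names, have_names = [], None, [], False
    for name, path in zip(names, paths):
        vals, ids, cols = _read_matrix(path, delimiter, header, row_labels)
        if parts and vals.shape[0] != parts[0].shape[0]:
            raise ValueError(
                f"row-count mismatch: {path} has {vals.shape[0]} rows, "
                f"expected {parts[0].shape[0]}"
            )
        if ids0 is None:
            ids0 = ids
        if cols is not None:
            have_names = True
        var_names.extend(cols if cols is not None else [f"{name}_{j + 1}" for j in range(vals.shape[1])])
        parts.append(vals)

    values = np.hstack(parts)
    blocks, pos = [], 0
    for name, part in zip(names, parts):
        blocks.append(Block(name, pos, pos + part.shape[1]))
        pos += part.shape[1]
    return MultiBlockData(values, tuple(blocks), ids0, var_names if have_names else None)


def read_combined(matrix_path: str | Path, block_map_path: str | Path, **kwargs) -> MultiBlockData:
    """Read one combined matrix plus a two-column ``variable,block`` map.

    Columns are grouped by block (preserving within-block order and the
    order in which blocks first appear in the map).
    """
    values, ids, cols = _read_matrix(matrix_path, **kwargs)
    bmap = pd.read_csv(block_map_path, header=None, names=["variable", "block"], dtype=str)
    if len(bmap) != values.shape[1]:
        # a header line was present
        if bmap.iloc[0, 0].strip().lower() in ("variable", "variable_name"):
            bmap = bmap.iloc[1:].reset_index(drop=True)
        if len(bmap) != values.shape[1]:
            raise ValueError("block map length does not match number of columns")
    bmap["variable"] = bmap["variable"].str.strip()
    bmap["block"] = bmap["block"].str.strip()
    if cols is not None:
        order = {v: i for i, v in enumerate(cols)}
        missing = [v for v in bmap["variable"] if v not in order]
        if missing:
            raise ValueError(f"block map names not found in matrix header: {missing[:5]}")
        col_idx = [order[v] for v in bmap["variable"]]
    else:
        col_idx = list(range(values.shape[1]))

    block_order = list(dict.fromkeys(bmap["block"]))
    take, blocks, pos = [], [], 0
    for name in block_order:
        members = [col_idx[i] for i in range(len(bmap)) if bmap["block"].iloc[i] == name]
        take.extend(members)
        blocks.append(Block(name, pos, pos + len(members)))
        pos += len(members)
    names_out = [bmap["variable"].iloc[i] for name in block_order
                 for i in range(len(bmap)) if bmap["block"].iloc[i] == name]
    return MultiBlockData(values[:, take], tuple(blocks), ids, names_out)


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def center_scale(data: MultiBlockData, ddof: int = 1) -> MultiBlockData:
    """Standardize every column to mean 0 and variance 1.

    The variance uses the sample convention (``ddof=1``) by default; pass
    ``ddof=0`` for the population convention.  A constant column is an
    error (it cannot be scaled).
    """
    X = data.values
    mean = X.mean(axis=0)
    std = X.std(axis=0, ddof=ddof)
    bad = np.flatnonzero(std == 0)
    if bad.size:
        names = data.variable_names or [f"x{j + 1}" for j in range(data.J)]
        raise ValueError(f"constant column(s) cannot be standardized: {[names[j] for j in bad[:5]]}")
    return data.with_values((X - mean) / std)


def block_scale(data: MultiBlockData) -> MultiBlockData:
    """Divide each block by the square root of its number of variables.

    After standardization this gives every block the same total sum of
    squares, so that a wide block does not dominate the analysis.
    """
    X = data.values.copy()
    for b in data.blocks:
        X[:, b.slice] /= np.sqrt(b.size)
    return data.with_values(X)


def write_matrix_csv(
    values: np.ndarray,
    path: str | Path,
    row_labels: Sequence[str] | None = None,
    col_labels: Sequence[str] | None = None,
    float_format: str = "%.12g",
    write_index: bool = True,
) -> None:
    """Write a labeled numeric matrix as CSV (used for W, P, scores, data)."""
    values = np.asarray(values)
    df = pd.DataFrame(
        values,
        index=list(row_labels) if row_labels is not None else range(1, values.shape[0] + 1),
        columns=list(col_labels) if col_labels is not None else [f"c{q + 1}" for q in range(values.shape[1])],
    )
    df.to_csv(path, float_format=float_format, index=write_index)
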