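"""Response-matrix I/O, observation masks, and train/test splitting.

A drug sensitivity screen is stored as a partially observed real matrix
``R`` with drugs on the rows and cell lines on the columns.  The canonical
in-memory form is :class:`ResponseMatrix`: a float array whose missing
cells hold NaN, plus a boolean observation mask and the row/column
identifiers.  All downstream code (effect removal, model fitting,
evaluation) consumes this type.

Splitting utilities cover the two evaluation protocols used throughout the
package: entry-level k-fold cross-validation over the observed cells, and
cold-start splits that hold out one whole drug (row) or cell line (column)
at a time.
"""

from __future__ import annotations

import logging
import os
from dataclasses import dataclass, replace
from typing import Iterator, Literal

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: tokens (lower-cased) accepted as "missing" on read, besides the empty cell
_NA_TOKENS = {"", "na", "nan"}


@dataclass
class ResponseMatrix:
    """A partially observed drug x cell-line response matrix.

    Parameters
    ----------
    values : ndarray of shape (m_drugs, n_celllines)
        Measured responses; unobserved cells are NaN.
    mask : ndarray of bool, same shape
        True where the response is observed.  Derived from ``values`` when
        omitted.
    drug_ids, cellline_ids : list of str
        Unique identifiers for rows and columns.
    unit_label : str
        Free-text unit, e.g. ``"activity_area"`` or ``"ln_IC50"``.
    """

    values: np.ndarray
    mask: np.ndarray = None  # type: ignore[assignment]
    drug_ids: list[str] = None  # type: ignore[assignment]
    cellline_ids: list[str] = None  # type: ignore[assignment]
    unit_label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be a 2-D matrix")
        m, n = self.values.shape
        if m < 1 or n < 1:
            raise ValueError("matrix must have at least one row and one column")
        if self.mask is None:
            self.mask = np.isfinite(self.values)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != self.values.shape:
            raise ValueError("mask shape does not match values shape")
        if not np.all(np.isfinite(self.values[self.mask])):
            raise ValueError("observed entries (mask=1) must be finite")
        if np.any(np.isfinite(self.values[~self.mask])):
            # normalise: unobserved cells always carry NaN
            self.values = self.values.copy()
            self.values[~self.mask] = np.nan
        if self.drug_ids is None:
            self.drug_ids = [f"drug_{i}" for i in range(m)]
        if self.cellline_ids is None:
            self.cellline_ids = [f"cellline_{j}" for j in range(n)]
        self.drug_ids = [str(d) for d in self.drug_ids]
        self.cellline_ids = [str(c) for c in self.cellline_ids]
        if len(self.drug_ids) != m:
            raise ValueError(f"expected {m} drug ids, got {len(self.drug_ids)}")
        if len(self.cellline_ids) != n:
            raise ValueError(
                f"expected {n} cell-line ids, got {len(self.cellline_ids)}"
            )
        for axis_name, ids in (("drug", self.drug_ids), ("cell-line", self.cellline_ids)):
            dup = _first_duplicate(ids)
            if dup is not None:
                raise ValueError(f"duplicate {axis_name} id: {dup!r}")
        if not self.mask.any():
            raise ValueError("matrix has no observed entries")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def n_observed(self) -> int:
        return int(self.mask.sum())

    def copy(self) -> "ResponseMatrix":
        return replace(
            self,
            values=self.values.copy(),
            mask=self.mask.copy(),
            drug_ids=list(self.drug_ids),
            cellline_ids=list(self.cellline_ids),
        )

    def transpose(self) -> "ResponseMatrix":
        """Swap the drug and cell-line axes (used by the row-input network)."""
        return ResponseMatrix(
            values=self.values.T.copy(),
            mask=self.mask.T.copy(),
            drug_ids=list(self.cellline_ids),
            cellline_ids=list(self.drug_ids),
            unit_label=self.unit_label,
        )


@dataclass
class FoldAssignment:
    """Entry-level fold labels for k-fold cross-validation.

    ``fold_index`` has the matrix shape; observed entries carry a label in
    ``0..k-1`` and unobserved entries carry -1.
    """

    fold_index: np.ndarray
    k: int
    seed: int

    def test_mask(self, fold: int) -> np.ndarray:
        """Boolean mask of the entries held out in ``fold``."""
        if not 0 <= fold < self.k:
            raise ValueError(f"fold must be in 0..{self.k - 1}")
        return self.fold_index == fold

    def fold_sizes(self) -> np.ndarray:
        return np.array([(self.fold_index == f).sum() for f in range(self.k)])


def _first_duplicate(ids: list[str]) -> str | None:
    seen: set[str] = set()
    for x in ids:
        if x in seen:
            return x
        seen.add(x)
    return None


def _delimiter_for(path: str, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    ext = os.path.splitext(path)[1].lower()
    return "\t" if ext in {".tsv", ".tab", ".txt"} else ","


def read_response_csv(
    path: str,
    orientation: Literal["drugs_as_rows", "celllines_as_rows"] = "drugs_as_rows",
    delimiter: str | None = None,
    unit_label: str = "",
) -> ResponseMatrix:
    """Read a response matrix from a delimited text file.

    The first row holds column identifiers and the first column row
    identifiers.  Cells are numbers; empty cells and the tokens
    ``NA``/``NaN`` (case-insensitive) mark missing responses.  The result
    is always returned in the canonical drugs-as-rows orientation;
    ``orientation="celllines_as_rows"`` transposes on read.
    """
    sep = _delimiter_for(path, delimiter)
    df = pd.read_csv(path, sep=sep, index_col=0, dtype=str, keep_default_na=False)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: matrix is empty")
    row_ids = [str(x) for x in df.index]
    col_ids = [str(x) for x in df.columns]
    for axis_name, ids in (("row", row_ids), ("column", col_ids)):
        dup = _first_duplicate(ids)
        if dup is not None:
            raise ValueError(f"{path}: duplicate {axis_name} id {dup!r}")

    values = np.full(df.shape, np.nan)
    raw = df.to_numpy()
    for i in range(raw.shape[0]):
        for j in range(raw.shape[1]):
            cell = str(raw[i, j]).strip()
            if cell.lower() in _NA_TOKENS:
                continue
            try:
                values[i, j] = float(cell)
            except ValueError:
                raise ValueError(
                    f"{path}: non-numeric cell {cell!r} at row {row_ids[i]!r}, "
                    f"column {col_ids[j]!r}"
                ) from None
    if orientation == "celllines_as_rows":
        values = values.T
        row_ids, col_ids = col_ids, row_ids
    elif orientation != "drugs_as_rows":
        raise ValueError(f"unknown orientation {orientation!r}")
    return ResponseMatrix(
        values=values, drug_ids=row_ids, cellline_ids=col_ids, unit_label=unit_label
    )


def write_response_csv(
    rm: ResponseMatrix, path: str, delimiter: str | None = None
) -> None:
    """Write a response matrix; missing cells become empty fields.

    ``read_response_csv(write_response_csv(x))`` reproduces ``x`` (values on
    observed entries, mask, identifiers).
    """
    sep = _delimiter_for(path, delimiter)
    df = pd.DataFrame(rm.values, index=rm.drug_ids, columns=rm.cellline_ids)
    df.to_csv(path, sep=sep, na_rep="", index_label="id")


def sparsity_percent(rm: ResponseMatrix) -> float:
    """Percentage of missing entries, 100 * |unobserved| / (m*n).

    Note: "sparsity" here counts the *missing* fraction of the matrix, the
    convention used for screens like CCLE (3.75% of 23 x 491 missing).
    """
    m, n = rm.shape
    return 100.0 * (m * n - rm.n_observed) / (m * n)


def assign_folds(rm: ResponseMatrix, k: int, seed: int) -> FoldAssignment:
    """Partition the observed entries into ``k`` near-equal random folds.

    The observed coordinates are shuffled with a seeded PRNG and dealt
    round-robin, so fold sizes differ by at most one and the assignment is
    reproducible from ``seed``.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    obs = np.argwhere(rm.mask)
    if k > len(obs):
        raise ValueError(f"k={k} exceeds the {len(obs)} observed entries")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(obs))
    fold_index = np.full(rm.shape, -1, dtype=int)
    for rank_pos, entry in enumerate(order):
        i, j = obs[entry]
        fold_index[i, j] = rank_pos % k
    return FoldAssignment(fold_index=fold_index, k=k, seed=seed)


def cold_start_splits(
    rm: ResponseMatrix, axis: Literal["drug", "cellline"]
) -> Iterator[tuple[np.ndarray, int]]:
    """Yield leave-one-unit-out splits for cold-start evaluation.

    For ``axis="drug"`` each split hides one entire row: the held-out
    row's observed entries form the test set and every other observed
    entry is available for training.  ``axis="cellline"`` does the same
    per column.  Units with no observed entries are skipped with a logged
    warning.

    Yields
    ------
    (train_mask, held_out_index) : (ndarray of bool, int)
    """
    if axis not in ("drug", "cellline"):
        raise ValueError(f"axis must be 'drug' or 'cellline', got {axis!r}")
    n_units = rm.shape[0] if axis == "drug" else rm.shape[1]
    if n_units < 2:
        raise ValueError("need at least 2 units on the held-out axis")
    for u in range(n_units):
        unit_mask = np.zeros(rm.shape, dtype=bool)
        if axis == "drug":
            unit_mask[u, :] = True
        else:
            unit_mask[:, u] = True
        if not (rm.mask & unit_mask).any():
            logger.warning("cold-start: %s %d has no observed entries; skipped", axis, u)
            continue
        yield rm.mask & ~unit_mask, u


def hide_entries(rm: ResponseMatrix, test_mask: np.ndarray) -> ResponseMatrix:
    """Return a copy of ``rm`` with ``test_mask`` entries made unobserved."""
    out = rm.copy()
    out.values[test_mask] = np.nan
    out.mask &= ~test_mask
    if not out.mask.any():
        raise ValueError("hiding these entries leaves no training data")
    return out
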