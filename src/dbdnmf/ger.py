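"""Global Effect Removal (GER).

Drug screens mix several additive sources of variation: an overall response
level, a per-drug offset (potency differs wildly between compounds), and a
per-cell-line offset (some lines are broadly sensitive or resistant).  GER
decomposes the observed matrix as

    R = R_global + R_drug + R_cell + R_res

by sequential mean removal in the Netflix-prize "global effects" style:
the global mean of the observed entries first, then per-drug (row) means of
what is left, then per-cell-line (column) means of what is left after that.
The interaction residual R_res is what the factorization model is trained
on; predictions are mapped back to the response scale by adding the effects
back.  The decomposition is exact on observed entries by construction.

No shrinkage is applied to the effect estimates; rows or columns with no
observed entries receive effect 0, which makes cold-start units fall back
to the global-plus-opposite-axis prediction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from .io_data import ResponseMatrix


@dataclass
class GlobalEffects:
    """Fitted additive effects: global mean, per-drug and per-cell-line offsets."""

    global_mean: float
    drug_effects: np.ndarray  # shape (m,)
    cell_effects: np.ndarray  # shape (n,)

    def __post_init__(self) -> None:
        self.drug_effects = np.asarray(self.drug_effects, dtype=float)
        self.cell_effects = np.asarray(self.cell_effects, dtype=float)
        if not np.isfinite(self.global_mean):
            raise ValueError("global_mean must be finite")
        if not (np.all(np.isfinite(self.drug_effects)) and np.all(np.isfinite(self.cell_effects))):
            raise ValueError("effects must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return len(self.drug_effects), len(self.cell_effects)

    def baseline(self) -> np.ndarray:
        """Full additive reconstruction global + drug_i + cell_j, shape (m, n)."""
        return (
            self.global_mean
            + self.drug_effects[:, None]
            + self.cell_effects[None, :]
        )

    def _check_shape(self, rm_shape: tuple[int, int]) -> None:
        if self.shape != rm_shape:
            raise ValueError(
                f"effects fitted for shape {self.shape}, matrix has {rm_shape}"
            )


def fit_global_effects(rm: ResponseMatrix) -> GlobalEffects:
    """Estimate global, per-drug and per-cell-line effects from observed entries.

    Sequential (unshrunk) means: ``global_mean`` is the mean over all
    observed values; ``drug_effects[i]`` the observed-row mean of
    ``values - global_mean``; ``cell_effects[j]`` the observed-column mean
    after both previous removals.  Empty rows/columns get effect 0.
    """
    if not rm.mask.any():
        raise ValueError("cannot fit effects: no observed entries")
    M = rm.mask
    V = np.where(M, rm.values, 0.0)
    global_mean = float(V.sum() / M.sum())

    row_counts = M.sum(axis=1)
    with np.errstate(invalid="ignore"):
        drug_effects = np.where(
            row_counts > 0,
            (V - global_mean * M).sum(axis=1) / np.maximum(row_counts, 1),
            0.0,
        )

    resid1 = V - (global_mean + drug_effects[:, None]) * M
    col_counts = M.sum(axis=0)
    cell_effects = np.where(
        col_counts > 0, resid1.sum(axis=0) / np.maximum(col_counts, 1), 0.0
    )
    return GlobalEffects(global_mean, drug_effects, cell_effects)


def remove_effects(rm: ResponseMatrix, ge: GlobalEffects) -> ResponseMatrix:
    """Subtract the additive effects, returning the interaction residual matrix.

    Mask and identifiers are unchanged; only observed values move.
    """
    ge._check_shape(rm.shape)
    out = rm.copy()
    out.values = np.where(rm.mask, rm.values - ge.baseline(), np.nan)
    return out


def restore_effects(rm_res: ResponseMatrix, ge: GlobalEffects) -> ResponseMatrix:
    """Add the effects back onto every entry; exact inverse of :func:`remove_effects`.

    Applied to completed matrices too, so predicted residuals land back on
    the original response scale.
    """
    ge._check_shape(rm_res.shape)
    out = rm_res.copy()
    finite = np.isfinite(rm_res.values)
    out.values = np.where(finite, rm_res.values + ge.baseline(), np.nan)
    return out


def effects_to_csv(ge: GlobalEffects, path: str, drug_ids=None, cellline_ids=None) -> None:
    """Serialize fitted effects to a three-section CSV for provenance."""
    m, n = ge.shape
    drug_ids = drug_ids or [f"drug_{i}" for i in range(m)]
    cellline_ids = cellline_ids or [f"cellline_{j}" for j in range(n)]
    with open(path, "w") as fh:
        fh.write("section,id,value\n")
        fh.write(f"global,,{ge.global_mean!r}\n")
        for d, v in zip(drug_ids, ge.drug_effects):
            fh.write(f"drug,{d},{v!r}\n")
        for c, v in zip(cellline_ids, ge.cell_effects):
            fh.write(f"cellline,{c},{v!r}\n")


class GlobalEffectRemover(TransformerMixin, BaseEstimator):
    """Scikit-learn style transformer for global effect removal.

    Operates on 2-D float arrays with NaN at unobserved cells (the array
    form of :class:`~dbdnmf.io_data.ResponseMatrix`).  ``transform``
    subtracts the fitted global/drug/cell-line effects; ``inverse_transform``
    adds them back.

    Attributes
    ----------
    effects_ : GlobalEffects
        Effects fitted by :meth:`fit`.
    """

    def fit(self, X, y=None):
        rm = X if isinstance(X, ResponseMatrix) else ResponseMatrix(np.asarray(X, dtype=float))
        self.effects_ = fit_global_effects(rm)
        self.n_features_in_ = rm.shape[1]
        return self

    def transform(self, X):
        X = X.values if isinstance(X, ResponseMatrix) else np.asarray(X, dtype=float)
        self.effects_._check_shape(X.shape)
        return X - self.effects_.baseline()

    def inverse_transform(self, X):
        X = X.values if isinstance(X, ResponseMatrix) else np.asarray(X, dtype=float)
        self.effects_._check_shape(X.shape)
        return X + self.effects_.baseline()
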