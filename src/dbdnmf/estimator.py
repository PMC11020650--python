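"""The DBDNMF matrix-completion estimator and its evaluation harnesses.

:class:`DBDNMF` is a scikit-learn-style transformer over partially
observed drug x cell-line matrices (2-D float arrays with NaN at missing
cells, or :class:`~dbdnmf.io_data.ResponseMatrix`).  ``fit`` optionally
removes global/drug/cell-line effects, then trains up to two dual-branch
networks on the residual:

* the **column net** feeds a trainable latent code per cell line through
  the stack to reconstruct the matrix columns;
* the **row net** does the same on the transposed matrix, one latent code
  per drug.

``transform`` fills the missing cells with the alpha-blended network
prediction (averaged over the two nets when ``side="both_mean"``), mapped
back to the response scale.  Completion is transductive: the latent input
is tied to the training matrix, so ``transform`` applies to matrices of
the fitted shape.

Module-level functions (:func:`fit`, :func:`complete`,
:func:`cross_validate`, :func:`cold_start_evaluate`, :func:`alpha_sweep`)
are thin wrappers that keep a functional surface over the estimator.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, replace

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .evaluation import MetricReport, metric_report
from .ger import GlobalEffects, fit_global_effects, remove_effects
from .io_data import (
    ResponseMatrix,
    assign_folds,
    cold_start_splits,
    hide_entries,
)
from .network import LatentInput, NetworkParams, predict_blend
from .optimizer import RpropHyper, TrainOptions, TrainResult, train

logger = logging.getLogger(__name__)

_SIDES = ("column_net", "row_net", "both_mean")


@dataclass(frozen=True)
class DBDNMFConfig:
    """Hyperparameters of one DBDNMF run.

    ``hidden_sizes=None`` means the default architecture (4r, 2r).  The
    column and row networks are trained with seeds ``seed`` and
    ``seed + 1``.
    """

    rank: int = 10
    hidden_sizes: tuple[int, ...] | None = None
    alpha: float = 0.5
    lam: float = 0.001
    use_ger: bool = True
    side: str = "both_mean"
    activation: str = "tanh"
    tied_branches: bool = True
    max_epochs: int = 2000
    rel_tol: float = 1e-6
    patience: int = 5
    eta_plus: float = 1.2
    eta_minus: float = 0.5
    delta0: float = 0.0125
    delta_min: float = 1e-6
    delta_max: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must be in [0, 1]")
        if self.lam < 0:
            raise ValueError("lam must be >= 0")
        if self.rank < 1:
            raise ValueError("rank must be >= 1")
        if self.side not in _SIDES:
            raise ValueError(f"side must be one of {_SIDES}")

    def to_estimator(self) -> "DBDNMF":
        kw = asdict(self)
        kw["random_state"] = kw.pop("seed")
        return DBDNMF(**kw)


class DBDNMF(TransformerMixin, BaseEstimator):
    """Dual-branch deep neural matrix factorization completer.

    Parameters mirror :class:`DBDNMFConfig`; ``random_state`` seeds the
    Gaussian weight initialization (column net) and ``random_state + 1``
    the row net.  Fitting is deterministic for a fixed seed.

    Attributes
    ----------
    effects_ : GlobalEffects or None
        Fitted additive effects when ``use_ger``.
    column_model_, row_model_ : TrainResult or None
        Trained network(s), depending on ``side``.
    prediction_ : ndarray (m, n)
        Blended model prediction for *every* cell, on the response scale.
    completion_ : ndarray (m, n)
        ``prediction_`` overwritten with the observed values.
    """

    def __init__(
        self,
        rank: int = 10,
        hidden_sizes: tuple[int, ...] | None = None,
        alpha: float = 0.5,
        lam: float = 0.001,
        use_ger: bool = True,
        side: str = "both_mean",
        activation: str = "tanh",
        tied_branches: bool = True,
        max_epochs: int = 2000,
        rel_tol: float = 1e-6,
        patience: int = 5,
        eta_plus: float = 1.2,
        eta_minus: float = 0.5,
        delta0: float = 0.0125,
        delta_min: float = 1e-6,
        delta_max: float = 1.0,
        random_state: int = 0,
    ):
        self.rank = rank
        self.hidden_sizes = hidden_sizes
        self.alpha = alpha
        self.lam = lam
        self.use_ger = use_ger
        self.side = side
        self.activation = activation
        self.tied_branches = tied_branches
        self.max_epochs = max_epochs
        self.rel_tol = rel_tol
        self.patience = patience
        self.eta_plus = eta_plus
        self.eta_minus = eta_minus
        self.delta0 = delta0
        self.delta_min = delta_min
        self.delta_max = delta_max
        self.random_state = random_state

    # -- helpers -----------------------------------------------------------
    def _as_rm(self, X) -> ResponseMatrix:
        if isinstance(X, ResponseMatrix):
            return X
        return ResponseMatrix(np.asarray(X, dtype=float))

    def _options(self) -> TrainOptions:
        return TrainOptions(
            max_epochs=self.max_epochs,
            rel_tol=self.rel_tol,
            patience=self.patience,
            hyper=RpropHyper(
                eta_plus=self.eta_plus,
                eta_minus=self.eta_minus,
                delta0=self.delta0,
                delta_min=self.delta_min,
                delta_max=self.delta_max,
            ),
        )

    def _arch(self) -> tuple[int, ...]:
        if self.hidden_sizes is None:
            return (4 * self.rank, 2 * self.rank)
        return tuple(self.hidden_sizes)

    # -- estimator API -----------------------------------------------------
    def fit(self, X, y=None) -> "DBDNMF":
        rm = self._as_rm(X)
        m, n = rm.shape
        if self.side not in _SIDES:
            raise ValueError(f"side must be one of {_SIDES}")
        if not self.rank < min(m, n):
            raise ValueError(
                f"rank {self.rank} must be < min(m, n) = {min(m, n)}"
            )
        if self.use_ger:
            self.effects_ = fit_global_effects(rm)
            work = remove_effects(rm, self.effects_)
        else:
            self.effects_ = None
            work = rm

        opts = self._options()
        hidden = self._arch()
        self.column_model_: TrainResult | None = None
        self.row_model_: TrainResult | None = None
        if self.side in ("column_net", "both_mean"):
            self.column_model_ = train(
                work, self.rank, hidden, self.alpha, self.lam,
                activation=self.activation, options=opts,
                seed=self.random_state, tied_branches=self.tied_branches,
            )
        if self.side in ("row_net", "both_mean"):
            self.row_model_ = train(
                work.transpose(), self.rank, hidden, self.alpha, self.lam,
                activation=self.activation, options=opts,
                seed=self.random_state + 1, tied_branches=self.tied_branches,
            )

        self.shape_ = (m, n)
        self.n_features_in_ = n
        self.drug_ids_ = list(rm.drug_ids)
        self.cellline_ids_ = list(rm.cellline_ids)
        self.train_mask_ = rm.mask.copy()
        self.prediction_ = self.predict_side(self.side)
        self.completion_ = np.where(rm.mask, rm.values, self.prediction_)
        return self

    def predict_side(self, side: str) -> np.ndarray:
        """Response-scale prediction matrix from one side (or their mean)."""
        if side not in _SIDES:
            raise ValueError(f"side must be one of {_SIDES}")
        preds = []
        if side in ("column_net", "both_mean"):
            if self.column_model_ is None:
                raise ValueError("column net was not trained (side mismatch)")
            r = self.column_model_
            preds.append(
                predict_blend(r.params, r.latent, self.alpha, r.params_linear)
            )
        if side in ("row_net", "both_mean"):
            if self.row_model_ is None:
                raise ValueError("row net was not trained (side mismatch)")
            r = self.row_model_
            preds.append(
                predict_blend(r.params, r.latent, self.alpha, r.params_linear).T
            )
        pred = np.mean(preds, axis=0)
        if self.effects_ is not None:
            pred = pred + self.effects_.baseline()
        return pred

    def transform(self, X) -> np.ndarray:
        """Fill the missing cells of ``X`` with the fitted predictions."""
        if not hasattr(self, "prediction_"):
            raise ValueError("estimator is not fitted")
        V = X.values if isinstance(X, ResponseMatrix) else np.asarray(X, dtype=float)
        if V.shape != self.shape_:
            raise ValueError(f"expected shape {self.shape_}, got {V.shape}")
        finite = np.isfinite(V)
        return np.where(finite, V, self.prediction_)

    def complete(self, rm: ResponseMatrix) -> ResponseMatrix:
        """Fully observed copy of ``rm``: observed values kept, gaps predicted."""
        if not hasattr(self, "prediction_"):
            raise ValueError("estimator is not fitted")
        if rm.shape != self.shape_:
            raise ValueError(f"expected shape {self.shape_}, got {rm.shape}")
        if list(rm.drug_ids) != self.drug_ids_ or list(rm.cellline_ids) != self.cellline_ids_:
            raise ValueError("matrix identifiers do not match the fitted model")
        values = np.where(rm.mask, rm.values, self.prediction_)
        return ResponseMatrix(
            values=values,
            mask=np.ones(rm.shape, dtype=bool),
            drug_ids=list(rm.drug_ids),
            cellline_ids=list(rm.cellline_ids),
            unit_label=rm.unit_label,
        )


# -- functional surface ----------------------------------------------------

def fit(rm: ResponseMatrix, cfg: DBDNMFConfig) -> DBDNMF:
    """Fit a DBDNMF model; returns the fitted estimator."""
    return cfg.to_estimator().fit(rm)


def complete(model: DBDNMF, rm: ResponseMatrix) -> ResponseMatrix:
    """Complete ``rm`` with a fitted model (wrapper for :meth:`DBDNMF.complete`)."""
    return model.complete(rm)


def _fold_seed(seed: int, fold: int) -> int:
    return int(np.random.SeedSequence([seed, fold]).generate_state(1)[0] % (2**31))


def cross_validate(
    rm: ResponseMatrix,
    cfg: DBDNMFConfig,
    k: int = 10,
    seed: int = 0,
) -> tuple[ResponseMatrix, dict]:
    """Entry-level k-fold cross-validation.

    Each fold's observed entries are hidden in turn (treated exactly like
    missing cells, with GER effects re-fitted on the remaining training
    entries), the model is fitted on the rest, and the hidden entries
    receive that fold's predictions.  Returns the assembled prediction
    matrix (originally-missing cells carry the across-fold mean
    prediction) and a report with the overall and per-fold metrics.
    """
    fa = assign_folds(rm, k, seed)
    pred = np.zeros(rm.shape)
    never_observed_acc = np.zeros(rm.shape)
    fold_reports: list[MetricReport] = []
    fold_masks = []
    for f in range(k):
        test_mask = fa.test_mask(f)
        train_rm = hide_entries(rm, test_mask)
        est = replace(cfg, seed=_fold_seed(seed, f)).to_estimator().fit(train_rm)
        pred[test_mask] = est.prediction_[test_mask]
        never_observed_acc += est.prediction_
        fold_reports.append(metric_report(rm, est.prediction_, test_mask))
        fold_masks.append(test_mask)
        logger.info(
            "fold %d/%d: ave_PCC=%.4f ave_RMSE=%.4f",
            f + 1, k, fold_reports[-1].ave_pcc, fold_reports[-1].ave_rmse,
        )
    pred = np.where(rm.mask, pred, never_observed_acc / k)
    overall = metric_report(rm, pred, rm.mask)
    pred_rm = ResponseMatrix(
        values=pred,
        mask=np.ones(rm.shape, dtype=bool),
        drug_ids=list(rm.drug_ids),
        cellline_ids=list(rm.cellline_ids),
        unit_label=rm.unit_label,
    )
    return pred_rm, {"overall": overall, "per_fold": fold_reports, "fold_masks": fold_masks}


def cold_start_evaluate(
    rm: ResponseMatrix,
    cfg: DBDNMFConfig,
    axis: str = "drug",
) -> tuple[pd.DataFrame, dict]:
    """Leave-one-drug-out (or one-cell-line-out) blind-test evaluation.

    For every unit on ``axis`` the model is fitted with that unit's
    observed entries hidden and scored on them.  A cold unit is only
    predictable through the network whose *latent input* runs over that
    axis (its code stays at the zero initialization, and GER supplies the
    additive fallback), so with ``side="both_mean"`` the row net is used
    for new drugs and the column net for new cell lines; an explicitly
    single-sided config is honoured as given.  Returns the per-unit
    metric table and the across-unit averages.
    """
    if cfg.side == "both_mean":
        cfg = replace(cfg, side="row_net" if axis == "drug" else "column_net")
    unit_ids = rm.drug_ids if axis == "drug" else rm.cellline_ids
    rows = []
    for split_no, (train_mask, u) in enumerate(cold_start_splits(rm, axis)):
        test_mask = rm.mask & ~train_mask
        train_rm = hide_entries(rm, test_mask)
        est = replace(cfg, seed=_fold_seed(cfg.seed, split_no)).to_estimator().fit(train_rm)
        # orient so the held-out unit is a row, then reuse the per-drug metrics
        truth, pred, emask = rm, est.prediction_, test_mask
        if axis == "cellline":
            truth, pred, emask = rm.transpose(), pred.T, test_mask.T
        rep = metric_report(truth, pred, emask)
        row = rep.per_drug.iloc[u]
        rows.append(
            {
                "unit_id": unit_ids[u],
                "pcc": row["pcc"],
                "rmse": row["rmse"],
                "pcc_sr": row["pcc_sr"],
                "rmse_sr": row["rmse_sr"],
                "n_test": int(row["n_test"]),
            }
        )
    table = pd.DataFrame(rows)
    summary = {
        "ave_pcc": float(table["pcc"].mean(skipna=True)),
        "ave_rmse": float(table["rmse"].mean(skipna=True)),
        "ave_pcc_sr": float(table["pcc_sr"].mean(skipna=True)),
        "ave_rmse_sr": float(table["rmse_sr"].mean(skipna=True)),
        "n_units": len(table),
    }
    return table, summary


def alpha_sweep(
    rm: ResponseMatrix,
    cfg: DBDNMFConfig,
    alphas: tuple[float, ...] = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9),
    k: int = 10,
    seed: int = 0,
) -> pd.DataFrame:
    """Cross-validated metrics over a grid of branch-blend weights.

    For each alpha both networks are trained per fold and the column-net,
    row-net and averaged completions are scored separately, mirroring the
    per-side comparison of the nonlinear-branch weight.
    """
    fa = assign_folds(rm, k, seed)
    records = []
    for a in alphas:
        acfg = replace(cfg, alpha=float(a), side="both_mean")
        preds = {s: np.full(rm.shape, np.nan) for s in _SIDES}
        for f in range(k):
            test_mask = fa.test_mask(f)
            train_rm = hide_entries(rm, test_mask)
            est = replace(acfg, seed=_fold_seed(seed, f)).to_estimator().fit(train_rm)
            for s in _SIDES:
                preds[s][test_mask] = est.predict_side(s)[test_mask]
        for s in _SIDES:
            rep = metric_report(rm, np.where(rm.mask, preds[s], 0.0), rm.mask)
            records.append({"alpha": float(a), "side": s, **rep.to_dict()})
        logger.info("alpha=%.2f done", a)
    return pd.DataFrame(records)


# -- model persistence -----------------------------------------------------

def save_model(est: DBDNMF, path: str) -> None:
    """Serialize a fitted estimator to a single ``.npz`` archive."""
    if not hasattr(est, "prediction_"):
        raise ValueError("estimator is not fitted")
    params = est.get_params()
    if params.get("hidden_sizes") is not None:
        params["hidden_sizes"] = list(params["hidden_sizes"])
    meta = {
        "params": params,
        "shape": list(est.shape_),
        "drug_ids": est.drug_ids_,
        "cellline_ids": est.cellline_ids_,
        "use_ger": est.effects_ is not None,
        "sides": [s for s in ("column", "row")
                  if getattr(est, f"{s}_model_") is not None],
    }
    arrays: dict[str, np.ndarray] = {
        "prediction": est.prediction_,
        "completion": est.completion_,
        "train_mask": est.train_mask_,
    }
    if est.effects_ is not None:
        arrays["ge_global"] = np.array([est.effects_.global_mean])
        arrays["ge_drug"] = est.effects_.drug_effects
        arrays["ge_cell"] = est.effects_.cell_effects
    for s in meta["sides"]:
        r: TrainResult = getattr(est, f"{s}_model_")
        for l, (W, b) in enumerate(zip(r.params.weights, r.params.biases)):
            arrays[f"{s}_W{l}"] = W
            arrays[f"{s}_b{l}"] = b
        arrays[f"{s}_Z"] = r.latent.Z
        arrays[f"{s}_loss"] = r.loss_history
        meta[f"{s}_n_layers"] = len(r.params.weights)
        meta[f"{s}_status"] = r.status
        meta[f"{s}_activation"] = r.params.activation
    np.savez(path, meta=np.array(json.dumps(meta)), **arrays)


def load_model(path: str) -> DBDNMF:
    """Load a fitted estimator saved by :func:`save_model`."""
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["meta"]))
        params = meta["params"]
        if params.get("hidden_sizes") is not None:
            params["hidden_sizes"] = tuple(params["hidden_sizes"])
        est = DBDNMF(**params)
        est.shape_ = tuple(meta["shape"])
        est.n_features_in_ = est.shape_[1]
        est.drug_ids_ = meta["drug_ids"]
        est.cellline_ids_ = meta["cellline_ids"]
        est.prediction_ = z["prediction"]
        est.completion_ = z["completion"]
        est.train_mask_ = z["train_mask"]
        est.effects_ = None
        if meta["use_ger"]:
            est.effects_ = GlobalEffects(
                float(z["ge_global"][0]), z["ge_drug"], z["ge_cell"]
            )
        est.column_model_ = None
        est.row_model_ = None
        for s in meta["sides"]:
            nl = meta[f"{s}_n_layers"]
            net = NetworkParams(
                [z[f"{s}_W{l}"] for l in range(nl)],
                [z[f"{s}_b{l}"] for l in range(nl)],
                meta[f"{s}_activation"],
            )
            res = TrainResult(
                params=net,
                latent=LatentInput(z[f"{s}_Z"]),
                loss_history=z[f"{s}_loss"],
                status=meta[f"{s}_status"],
            )
            setattr(est, f"{s}_model_", res)
    return est
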