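"""Per-drug evaluation metrics for response-matrix completion.

Accuracy is summarized drug by drug, because clinical use ranks cell
lines (or patients) *within* a drug: for each drug the Pearson
correlation and RMSE between predicted and measured responses are
computed over that drug's evaluated entries, then averaged over drugs
(ave_PCC, ave_RMSE).  The ``_sr`` variants restrict each drug to its most
informative cell lines — those in the first and fourth quartile of the
drug's measured responses, i.e. the clearly sensitive and clearly
resistant ones.

A drug enters the PCC average only if it has at least two evaluated
entries and nonzero variance in both the measured and predicted vectors;
it enters the RMSE average with at least one entry.  Skipped drugs are
reported, never silently dropped into NaN.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_data import ResponseMatrix

logger = logging.getLogger(__name__)


@dataclass
class PerDrugMetric:
    """One averaged metric plus its per-drug breakdown."""

    value: float
    per_drug: np.ndarray  # NaN for skipped drugs
    skipped: list[int]


@dataclass
class MetricReport:
    """ave_PCC / ave_RMSE and their sensitive/resistant-restricted variants."""

    ave_pcc: float
    ave_rmse: float
    ave_pcc_sr: float
    ave_rmse_sr: float
    per_drug: pd.DataFrame
    skipped_drugs: list[str]

    def to_dict(self) -> dict:
        return {
            "ave_pcc": self.ave_pcc,
            "ave_rmse": self.ave_rmse,
            "ave_pcc_sr": self.ave_pcc_sr,
            "ave_rmse_sr": self.ave_rmse_sr,
        }


def _coerce(truth, pred, eval_mask):
    T = truth.values if isinstance(truth, ResponseMatrix) else np.asarray(truth, float)
    P = np.asarray(pred, dtype=float)
    E = np.asarray(eval_mask, dtype=bool)
    if not (T.shape == P.shape == E.shape):
        raise ValueError("truth, pred and eval_mask must share one shape")
    if isinstance(truth, ResponseMatrix) and np.any(E & ~truth.mask):
        raise ValueError("eval_mask selects unobserved entries of the truth matrix")
    if not E.any():
        raise ValueError("eval_mask is empty")
    return T, P, E


def ave_pcc(truth, pred, eval_mask) -> PerDrugMetric:
    """Mean over drugs of the per-drug Pearson correlation on evaluated entries."""
    T, P, E = _coerce(truth, pred, eval_mask)
    m = T.shape[0]
    vals = np.full(m, np.nan)
    skipped = []
    for i in range(m):
        sel = E[i]
        t, p = T[i, sel], P[i, sel]
        if len(t) < 2 or np.ptp(t) == 0 or np.ptp(p) == 0:
            skipped.append(i)
            continue
        vals[i] = np.corrcoef(t, p)[0, 1]
    ok = ~np.isnan(vals)
    if not ok.any():
        logger.warning("no drug has enough evaluated entries for a correlation")
        return PerDrugMetric(float("nan"), vals, skipped)
    return PerDrugMetric(float(vals[ok].mean()), vals, skipped)


def ave_rmse(truth, pred, eval_mask) -> PerDrugMetric:
    """Mean over drugs of the per-drug RMSE on evaluated entries."""
    T, P, E = _coerce(truth, pred, eval_mask)
    m = T.shape[0]
    vals = np.full(m, np.nan)
    skipped = []
    for i in range(m):
        sel = E[i]
        if not sel.any():
            skipped.append(i)
            continue
        d = T[i, sel] - P[i, sel]
        vals[i] = np.sqrt(np.mean(d * d))
    ok = ~np.isnan(vals)
    return PerDrugMetric(float(vals[ok].mean()), vals, skipped)


def sr_mask(truth, eval_mask) -> np.ndarray:
    """Restrict each drug's evaluated entries to its response quartile tails.

    Keeps entries whose measured value is <= Q1 or >= Q3 of that drug's
    evaluated values (linear-interpolation quantiles).  Drugs with fewer
    than 4 evaluated entries keep everything (degenerate quartiles).
    """
    T, _, E = _coerce(truth, np.zeros_like(np.asarray(eval_mask, float)), eval_mask)
    out = np.zeros_like(E)
    for i in range(T.shape[0]):
        sel = E[i]
        t = T[i, sel]
        if len(t) == 0:
            continue
        if len(t) < 4:
            logger.debug("drug row %d: < 4 evaluated entries, quartile filter skipped", i)
            out[i, sel] = True
            continue
        q1, q3 = np.quantile(t, [0.25, 0.75])
        keep = (t <= q1) | (t >= q3)
        out[i, np.flatnonzero(sel)[keep]] = True
    return out


def metric_report(truth: ResponseMatrix, pred, eval_mask) -> MetricReport:
    """Full metric table: plain and sensitive/resistant-restricted averages."""
    pcc = ave_pcc(truth, pred, eval_mask)
    rmse = ave_rmse(truth, pred, eval_mask)
    sr = sr_mask(truth, eval_mask)
    pcc_sr = ave_pcc(truth, pred, sr)
    rmse_sr = ave_rmse(truth, pred, sr)
    E = np.asarray(eval_mask, dtype=bool)
    per_drug = pd.DataFrame(
        {
            "drug_id": truth.drug_ids,
            "pcc": pcc.per_drug,
            "rmse": rmse.per_drug,
            "pcc_sr": pcc_sr.per_drug,
            "rmse_sr": rmse_sr.per_drug,
            "n_test": E.sum(axis=1),
        }
    )
    skipped = sorted(
        {truth.drug_ids[i] for i in pcc.skipped}
        | {truth.drug_ids[i] for i in rmse.skipped}
    )
    return MetricReport(
        ave_pcc=pcc.value,
        ave_rmse=rmse.value,
        ave_pcc_sr=pcc_sr.value,
        ave_rmse_sr=rmse_sr.value,
        per_drug=per_drug,
        skipped_drugs=skipped,
    )


def top_k_drugs(
    completed: ResponseMatrix,
    k: int,
    direction: str = "sensitive",
    sensitivity_convention: str = "higher_is_sensitive",
) -> tuple[dict[str, list[str]], pd.DataFrame]:
    """Rank each cell line's top-k most sensitive (or resistant) drugs.

    Under ``higher_is_sensitive`` (activity area) large values mean
    sensitivity; under ``lower_is_sensitive`` (ln IC50) small values do.
    Ties break by drug-id order (row order), deterministically.  Returns
    the per-cell-line ranked lists and a per-drug frequency table with the
    count and percentage of cell lines listing each drug.
    """
    if direction not in ("sensitive", "resistant"):
        raise ValueError(f"direction must be 'sensitive' or 'resistant', got {direction!r}")
    if sensitivity_convention not in ("higher_is_sensitive", "lower_is_sensitive"):
        raise ValueError(f"unknown sensitivity convention {sensitivity_convention!r}")
    if not completed.mask.all():
        raise ValueError("top-k ranking requires a fully completed matrix")
    m, n = completed.shape
    if k > m:
        raise ValueError(f"k={k} exceeds the {m} drugs")
    # pick largest values iff the direction/convention pair points upward
    want_max = (direction == "sensitive") == (
        sensitivity_convention == "higher_is_sensitive"
    )
    V = completed.values if want_max else -completed.values
    lists: dict[str, list[str]] = {}
    counts = np.zeros(m, dtype=int)
    for j, cl in enumerate(completed.cellline_ids):
        order = np.argsort(-V[:, j], kind="stable")[:k]
        lists[cl] = [completed.drug_ids[i] for i in order]
        counts[order] += 1
    freq = pd.DataFrame(
        {
            "drug_id": completed.drug_ids,
            "count": counts,
            "percent": 100.0 * counts / n,
        }
    ).sort_values("count", ascending=False, kind="stable").reset_index(drop=True)
    return lists, freq
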