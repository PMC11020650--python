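"""Synthetic response matrices with the generative structure the model assumes.

The generator draws low-rank factors C* (m x r) and D* (r x n), passes D*
through a random tanh network to obtain a nonlinear signal f*(D*), blends
the two as ``alpha_true * f*(D*) + (1 - alpha_true) * C* D*``, rescales
the blend to unit standard deviation (so ``noise_std`` reads as a
noise-to-signal ratio), then adds a global offset, Gaussian per-drug and
per-cell-line effects, and entrywise Gaussian noise.  A uniformly random
exact-count mask hides ``1 - observed_fraction`` of the cells.

Ground truth (noiseless full matrix, true factors, true effects) is kept
alongside the observed matrix so recovery benchmarks can score against
the signal instead of the noise.  The generator emulates structure, not
the marginal distributions of any particular public screen.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .ger import GlobalEffects, fit_global_effects
from .io_data import ResponseMatrix
from .network import LatentInput, forward_nonlinear, init_params


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator settings; defaults are the package's standard benchmark.

    ``effect_scales`` is (global offset, per-drug effect std, per-cell-line
    effect std).  ``signal_scale`` multiplies the unit-std blended signal
    (0 gives a pure effects+noise matrix).
    """

    m: int = 60
    n: int = 40
    r: int = 4
    alpha_true: float = 0.5
    effect_scales: tuple[float, float, float] = (1.0, 0.5, 0.5)
    noise_std: float = 0.1
    observed_fraction: float = 0.7
    hidden_sizes_true: tuple[int, ...] = (8,)
    signal_scale: float = 1.0
    seed: int = 20240404

    def __post_init__(self) -> None:
        if not self.r < min(self.m, self.n):
            raise ValueError("rank must satisfy r < min(m, n)")
        if not 0.0 < self.observed_fraction <= 1.0:
            raise ValueError("observed_fraction must be in (0, 1]")
        if not 0.0 <= self.alpha_true <= 1.0:
            raise ValueError("alpha_true must be in [0, 1]")
        if self.noise_std < 0:
            raise ValueError("noise_std must be >= 0")


@dataclass
class SyntheticTruth:
    """Generated instance: observed matrix plus the ground truth behind it."""

    full_matrix: np.ndarray  # signal + effects, pre-noise, pre-masking
    C_true: np.ndarray
    D_true: np.ndarray
    effects_true: GlobalEffects
    observed: ResponseMatrix
    spec: SyntheticSpec


def generate(spec: SyntheticSpec) -> SyntheticTruth:
    """Draw one synthetic instance; deterministic per ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    C = rng.standard_normal((spec.m, spec.r))
    D = rng.standard_normal((spec.r, spec.n))
    gen_net = init_params(spec.r, spec.hidden_sizes_true, spec.m, "tanh", rng)
    nonlin = forward_nonlinear(gen_net, LatentInput(D))
    signal = spec.alpha_true * nonlin + (1.0 - spec.alpha_true) * (C @ D)
    sd = signal.std()
    if sd > 0:
        signal = signal / sd
    signal = spec.signal_scale * signal

    g0, drug_sd, cell_sd = spec.effect_scales
    drug_eff = rng.normal(0.0, drug_sd, size=spec.m) if drug_sd > 0 else np.zeros(spec.m)
    cell_eff = rng.normal(0.0, cell_sd, size=spec.n) if cell_sd > 0 else np.zeros(spec.n)
    effects = GlobalEffects(float(g0), drug_eff, cell_eff)
    full = signal + effects.baseline()

    noisy = full + rng.normal(0.0, spec.noise_std, size=full.shape)
    n_obs = int(round(spec.observed_fraction * spec.m * spec.n))
    n_obs = max(n_obs, 1)
    flat = rng.choice(spec.m * spec.n, size=n_obs, replace=False)
    mask = np.zeros(spec.m * spec.n, dtype=bool)
    mask[flat] = True
    mask = mask.reshape(spec.m, spec.n)
    values = np.where(mask, noisy, np.nan)
    observed = ResponseMatrix(values=values, mask=mask, unit_label="synthetic_response")
    return SyntheticTruth(
        full_matrix=full,
        C_true=C,
        D_true=D,
        effects_true=effects,
        observed=observed,
        spec=spec,
    )


def oracle_baselines(st: SyntheticTruth, eval_mask: np.ndarray) -> pd.DataFrame:
    """RMSE of simple imputation baselines against the noiseless truth.

    Baselines are fitted on the observed (training) entries only and
    scored on ``eval_mask`` cells, which must be disjoint from the
    training mask: global mean, per-drug mean, per-cell-line mean, and the
    full additive global-effects reconstruction.
    """
    E = np.asarray(eval_mask, dtype=bool)
    if not E.any():
        raise ValueError("eval_mask is empty")
    if np.any(E & st.observed.mask):
        raise ValueError("eval_mask overlaps the training (observed) mask")
    rm = st.observed
    M, V = rm.mask, np.where(rm.mask, rm.values, 0.0)
    gmean = V.sum() / M.sum()
    row_n = M.sum(axis=1)
    drug_mean = np.where(row_n > 0, V.sum(axis=1) / np.maximum(row_n, 1), gmean)
    col_n = M.sum(axis=0)
    cell_mean = np.where(col_n > 0, V.sum(axis=0) / np.maximum(col_n, 1), gmean)
    ger = fit_global_effects(rm).baseline()

    preds = {
        "global_mean": np.full(rm.shape, gmean),
        "per_drug_mean": np.broadcast_to(drug_mean[:, None], rm.shape),
        "per_cellline_mean": np.broadcast_to(cell_mean[None, :], rm.shape),
        "ger_additive": ger,
    }
    rows = []
    truth = st.full_matrix
    for name, P in preds.items():
        d = truth[E] - P[E]
        rows.append({"baseline": name, "rmse": float(np.sqrt(np.mean(d * d)))})
    return pd.DataFrame(rows)
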