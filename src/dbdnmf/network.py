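"""The dual-branch deep factorization network.

One stack of fully connected layers is traversed twice over the same
trainable latent input ``Z`` (each column of ``Z`` is the latent code of
one cell line, or of one drug for the transposed network):

* the **nonlinear branch** applies the activation at every layer,
  including the output layer, giving ``f(Z)``;
* the **linear branch** composes the same affine maps with no activation,
  so with zero biases it collapses to the weight product ``(prod_l W^l) Z``
  — a classical bilinear factorization whose left factor is
  :func:`implied_factor_matrix`.

Predictions blend the branches as ``alpha * f(Z) + (1 - alpha) * lin(Z)``.
Training minimizes a half mean-squared error over the observed entries
plus a quadratic penalty on the latent input and the weights (biases are
not penalized):

    loss = 1/(2 eta) ||M . (R - pred)||_F^2
           + lam * ( 1/(2 n) ||Z||_F^2 + 1/2 sum_l ||W^l||_F^2 )

with ``eta`` the number of observed entries and ``n`` the number of
columns of ``Z``.  :func:`gradients` returns the exact gradient of this
loss with respect to every weight, bias and ``Z``; because the weights are
shared, both branches contribute to the weight gradients.

An untied variant (a second, independent stack for the linear branch) is
supported for ablation via the ``params_linear`` argument.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.special import expit

from .io_data import ResponseMatrix

# activation -> (function, derivative as a function of (preactivation, output))
_ACTIVATIONS: dict[str, tuple[Callable, Callable]] = {
    "tanh": (np.tanh, lambda a, h: 1.0 - h * h),
    "sigmoid": (expit, lambda a, h: h * (1.0 - h)),
    "relu": (lambda a: np.maximum(a, 0.0), lambda a, h: (a > 0).astype(float)),
    "identity": (lambda a: a, lambda a, h: np.ones_like(a)),
}


@dataclass
class NetworkParams:
    """Weights and biases of one layer stack, shared by both branches.

    ``weights[l]`` maps layer ``l`` inputs to outputs (shape
    ``dim_l x dim_{l-1}``); ``biases[l]`` has length ``dim_l``.  With ``L``
    hidden layers there are ``L + 1`` weight matrices; ``dim_0`` is the
    latent rank and ``dim_{L+1}`` the number of output rows.
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    activation: str = "tanh"

    def __post_init__(self) -> None:
        if self.activation not in _ACTIVATIONS:
            raise ValueError(
                f"unknown activation {self.activation!r}; "
                f"choose from {sorted(_ACTIVATIONS)}"
            )
        if len(self.weights) != len(self.biases):
            raise ValueError("need one bias vector per weight matrix")
        if not self.weights:
            raise ValueError("need at least one layer")
        self.weights = [np.asarray(W, dtype=float) for W in self.weights]
        self.biases = [np.asarray(b, dtype=float).ravel() for b in self.biases]
        for l, (W, b) in enumerate(zip(self.weights, self.biases), start=1):
            if W.ndim != 2:
                raise ValueError(f"layer {l}: weight must be a matrix")
            if b.shape[0] != W.shape[0]:
                raise ValueError(
                    f"layer {l}: bias length {b.shape[0]} != output dim {W.shape[0]}"
                )
            if l > 1 and W.shape[1] != self.weights[l - 2].shape[0]:
                raise ValueError(
                    f"layer {l}: input dim {W.shape[1]} does not chain with "
                    f"layer {l - 1} output dim {self.weights[l - 2].shape[0]}"
                )

    @property
    def n_hidden(self) -> int:
        """Number of hidden layers L (stack depth minus the output layer)."""
        return len(self.weights) - 1

    @property
    def in_dim(self) -> int:
        return self.weights[0].shape[1]

    @property
    def out_dim(self) -> int:
        return self.weights[-1].shape[0]

    def copy(self) -> "NetworkParams":
        return NetworkParams(
            [W.copy() for W in self.weights],
            [b.copy() for b in self.biases],
            self.activation,
        )


@dataclass
class LatentInput:
    """The trainable latent input matrix (rank x n_columns).

    Each column is the latent code of one unit on the input axis; it is
    optimized jointly with the network weights rather than provided as
    data.
    """

    Z: np.ndarray
    r: int = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.ndim != 2:
            raise ValueError("latent input must be a 2-D matrix")
        if self.r is None:
            self.r = self.Z.shape[0]
        if self.r != self.Z.shape[0] or self.r < 1:
            raise ValueError("rank must equal the number of latent rows and be >= 1")
        if not np.all(np.isfinite(self.Z)):
            raise ValueError("latent input must be finite")

    @property
    def n_cols(self) -> int:
        return self.Z.shape[1]

    def copy(self) -> "LatentInput":
        return LatentInput(self.Z.copy(), self.r)


def _as_Z(Z) -> np.ndarray:
    return Z.Z if isinstance(Z, LatentInput) else np.asarray(Z, dtype=float)


def _check_input(params: NetworkParams, Z: np.ndarray) -> None:
    if Z.shape[0] != params.in_dim:
        raise ValueError(
            f"layer 1 expects {params.in_dim} input rows, latent input has {Z.shape[0]}"
        )


def _forward_cache(params: NetworkParams, Z: np.ndarray, nonlinear: bool):
    """Run one branch, returning (activations h_0..h_K, preactivations a_1..a_K)."""
    sigma = _ACTIVATIONS[params.activation][0]
    hs = [Z]
    pre = []
    h = Z
    for W, b in zip(params.weights, params.biases):
        a = W @ h + b[:, None]
        pre.append(a)
        h = sigma(a) if nonlinear else a
        hs.append(h)
    return hs, pre


def forward_nonlinear(params: NetworkParams, Z) -> np.ndarray:
    """Nonlinear branch f(Z): activation applied at every layer, output included."""
    Z = _as_Z(Z)
    _check_input(params, Z)
    return _forward_cache(params, Z, nonlinear=True)[0][-1]


def forward_linear(params: NetworkParams, Z) -> np.ndarray:
    """Linear branch: the same affine layers composed without activations."""
    Z = _as_Z(Z)
    _check_input(params, Z)
    return _forward_cache(params, Z, nonlinear=False)[0][-1]


def implied_factor_matrix(params: NetworkParams) -> np.ndarray:
    """Ordered product of all weight matrices (output side first).

    This is the learned linear latent-factor matrix: with zero biases,
    ``forward_linear(params, Z) == implied_factor_matrix(params) @ Z``.
    """
    P = params.weights[0]
    for W in params.weights[1:]:
        P = W @ P
    return P


def predict_blend(params: NetworkParams, Z, alpha: float,
                  params_linear: NetworkParams | None = None) -> np.ndarray:
    """Blended prediction ``alpha * f(Z) + (1 - alpha) * lin(Z)`` (full matrix).

    The caller restricts to the unobserved entries when completing a
    matrix.  ``params_linear`` supplies an untied linear-branch stack; by
    default the branches share ``params``.
    """
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    lin_params = params if params_linear is None else params_linear
    return alpha * forward_nonlinear(params, Z) + (1.0 - alpha) * forward_linear(
        lin_params, Z
    )


def _check_against(params: NetworkParams, Z: np.ndarray, rm: ResponseMatrix) -> None:
    if Z.shape[1] != rm.shape[1]:
        raise ValueError(
            f"latent input has {Z.shape[1]} columns, matrix has {rm.shape[1]}"
        )
    if params.out_dim != rm.shape[0]:
        raise ValueError(
            f"network outputs {params.out_dim} rows, matrix has {rm.shape[0]}"
        )


def masked_loss(params: NetworkParams, Z, rm: ResponseMatrix, alpha: float,
                lam: float, params_linear: NetworkParams | None = None) -> float:
    """Regularized half mean-squared reconstruction error on observed entries."""
    if lam < 0:
        raise ValueError(f"lam must be >= 0, got {lam}")
    Zm = _as_Z(Z)
    _check_input(params, Zm)
    _check_against(params, Zm, rm)
    pred = predict_blend(params, Zm, alpha, params_linear)
    M = rm.mask
    eta = M.sum()
    R = np.where(M, rm.values, 0.0)
    resid = np.where(M, R - pred, 0.0)
    data = 0.5 / eta * float((resid * resid).sum())
    stacks = [params] if params_linear is None else [params, params_linear]
    wpen = sum(float((W * W).sum()) for p in stacks for W in p.weights)
    reg = 0.5 / Zm.shape[1] * float((Zm * Zm).sum()) + 0.5 * wpen
    return data + lam * reg


@dataclass
class Gradients:
    """Exact loss gradients: per-layer weight/bias arrays plus the latent input.

    ``weights_linear``/``biases_linear`` are populated only when the
    branches are untied.
    """

    weights: list[np.ndarray]
    biases: list[np.ndarray]
    Z: np.ndarray
    weights_linear: list[np.ndarray] | None = None
    biases_linear: list[np.ndarray] | None = None


def gradients(params: NetworkParams, Z, rm: ResponseMatrix, alpha: float,
              lam: float, params_linear: NetworkParams | None = None) -> Gradients:
    """Backpropagated gradient of :func:`masked_loss` w.r.t. all trainables.

    With tied branches the weight/bias gradients accumulate both the
    nonlinear- and linear-branch contributions; the latent-input gradient
    always does.
    """
    if lam < 0:
        raise ValueError(f"lam must be >= 0, got {lam}")
    if not 0.0 <= alpha <= 1.0:
        raise ValueError(f"alpha must be in [0, 1], got {alpha}")
    Zm = _as_Z(Z)
    _check_input(params, Zm)
    _check_against(params, Zm, rm)
    tied = params_linear is None
    lin_params = params if tied else params_linear

    hs_nl, pre_nl = _forward_cache(params, Zm, nonlinear=True)
    hs_li, _ = _forward_cache(lin_params, Zm, nonlinear=False)
    pred = alpha * hs_nl[-1] + (1.0 - alpha) * hs_li[-1]

    M = rm.mask
    eta = M.sum()
    R = np.where(M, rm.values, 0.0)
    # dLoss/dpred; residual convention (pred - R) gives the descent gradient
    G = np.where(M, pred - R, 0.0) / eta

    dW_nl = [np.zeros_like(W) for W in params.weights]
    db_nl = [np.zeros_like(b) for b in params.biases]
    dW_li = [np.zeros_like(W) for W in lin_params.weights]
    db_li = [np.zeros_like(b) for b in lin_params.biases]
    dZ = np.zeros_like(Zm)

    # nonlinear branch
    dsigma = _ACTIVATIONS[params.activation][1]
    delta = alpha * G * dsigma(pre_nl[-1], hs_nl[-1])
    for l in range(len(params.weights) - 1, -1, -1):
        dW_nl[l] += delta @ hs_nl[l].T
        db_nl[l] += delta.sum(axis=1)
        upstream = params.weights[l].T @ delta
        if l > 0:
            delta = upstream * dsigma(pre_nl[l - 1], hs_nl[l])
        else:
            dZ += upstream

    # linear branch (identity activation derivative)
    delta = (1.0 - alpha) * G
    for l in range(len(lin_params.weights) - 1, -1, -1):
        dW_li[l] += delta @ hs_li[l].T
        db_li[l] += delta.sum(axis=1)
        delta = lin_params.weights[l].T @ delta
    dZ += delta

    # quadratic penalties (biases excluded)
    dZ += lam / Zm.shape[1] * Zm
    for l, W in enumerate(params.weights):
        dW_nl[l] += lam * W
    if tied:
        dW = [a + b for a, b in zip(dW_nl, dW_li)]
        db = [a + b for a, b in zip(db_nl, db_li)]
        return Gradients(weights=dW, biases=db, Z=dZ)
    for l, W in enumerate(lin_params.weights):
        dW_li[l] += lam * W
    return Gradients(
        weights=dW_nl, biases=db_nl, Z=dZ,
        weights_linear=dW_li, biases_linear=db_li,
    )


def init_params(in_dim: int, hidden_sizes: tuple[int, ...], out_dim: int,
                activation: str, rng: np.random.Generator) -> NetworkParams:
    """Gaussian initialization, std sqrt(2 / (fan_in + fan_out)) per layer."""
    dims = [in_dim, *hidden_sizes, out_dim]
    weights, biases = [], []
    for d_in, d_out in zip(dims[:-1], dims[1:]):
        std = np.sqrt(2.0 / (d_in + d_out))
        weights.append(rng.normal(0.0, std, size=(d_out, d_in)))
        biases.append(rng.normal(0.0, std, size=d_out))
    return NetworkParams(weights, biases, activation)
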