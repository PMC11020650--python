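"""Full-batch iRprop+ training of the dual-branch network.

iRprop+ (resilient backpropagation with weight backtracking) adapts one
positive step size per scalar parameter from the *sign* of its gradient
alone: the step grows by ``eta_plus`` while the gradient sign persists,
shrinks by ``eta_minus`` on a sign flip, and — the "+" part — when a sign
flip coincides with a loss increase the previous update of that parameter
is reverted.  The magnitudes of the gradients never enter, which makes the
method insensitive to the overall loss scale and well suited to a model
whose input itself is a trainable unknown.

:func:`train` wires the loss/gradient of :mod:`dbdnmf.network` to the
update rule: weights and biases start as Gaussian draws (std
``sqrt(2 / (fan_in + fan_out))``) and the latent input starts at zero, the
full batch of observed entries is used every epoch, and training stops at
``max_epochs`` or when the relative loss change stays below ``rel_tol``
for ``patience`` consecutive epochs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .io_data import ResponseMatrix
from .network import (
    Gradients,
    LatentInput,
    NetworkParams,
    gradients,
    init_params,
    masked_loss,
)

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class RpropHyper:
    """iRprop+ constants (customary Igel–Huesken values, reduced step cap)."""

    eta_plus: float = 1.2
    eta_minus: float = 0.5
    delta0: float = 0.0125
    delta_min: float = 1e-6
    delta_max: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 < self.eta_minus < 1.0 < self.eta_plus:
            raise ValueError("require 0 < eta_minus < 1 < eta_plus")
        if not 0.0 < self.delta_min <= self.delta0 <= self.delta_max:
            raise ValueError("require 0 < delta_min <= delta0 <= delta_max")


@dataclass
class RpropState:
    """Per-parameter optimizer state mirroring the parameter list's shapes."""

    step_sizes: list[np.ndarray]
    prev_grad: list[np.ndarray]
    prev_update: list[np.ndarray]
    prev_loss: float = np.inf
    hyper: RpropHyper = field(default_factory=RpropHyper)

    @classmethod
    def init(cls, theta: list[np.ndarray], hyper: RpropHyper | None = None) -> "RpropState":
        hyper = hyper or RpropHyper()
        return cls(
            step_sizes=[np.full_like(t, hyper.delta0) for t in theta],
            prev_grad=[np.zeros_like(t) for t in theta],
            prev_update=[np.zeros_like(t) for t in theta],
            hyper=hyper,
        )


def irprop_plus_step(
    theta: list[np.ndarray],
    grad: list[np.ndarray],
    loss: float,
    state: RpropState,
) -> tuple[list[np.ndarray], RpropState]:
    """Apply one iRprop+ update in place; returns (theta, state).

    ``loss`` is the objective at the *current* ``theta`` (before this
    update); it is compared against the previous epoch's loss to decide
    whether sign-flipped parameters revert their last update.
    """
    h = state.hyper
    worse = loss > state.prev_loss
    for t, g, delta, pg, pu in zip(
        theta, grad, state.step_sizes, state.prev_grad, state.prev_update
    ):
        if not np.all(np.isfinite(g)):
            raise FloatingPointError("non-finite gradient encountered")
        prod = pg * g
        inc = prod > 0
        dec = prod < 0
        delta[inc] = np.minimum(delta[inc] * h.eta_plus, h.delta_max)
        delta[dec] = np.maximum(delta[dec] * h.eta_minus, h.delta_min)
        update = np.where(dec, 0.0, -np.sign(g) * delta)
        if worse:
            update[dec] = -pu[dec]  # backtrack: undo the step that overshot
        t += update
        pg[...] = np.where(dec, 0.0, g)
        pu[...] = update
    state.prev_loss = loss
    return theta, state


@dataclass
class TrainOptions:
    """Stopping rules and iRprop+ constants for :func:`train`."""

    max_epochs: int = 2000
    rel_tol: float = 1e-6
    patience: int = 5
    hyper: RpropHyper = field(default_factory=RpropHyper)
    log_every: int = 50


@dataclass
class TrainResult:
    params: NetworkParams
    latent: LatentInput
    loss_history: np.ndarray
    status: str  # "converged" | "max_epochs" | "diverged"
    params_linear: NetworkParams | None = None


def _flatten(params: NetworkParams, Z: LatentInput,
             params_linear: NetworkParams | None) -> list[np.ndarray]:
    theta = list(params.weights) + list(params.biases)
    if params_linear is not None:
        theta += list(params_linear.weights) + list(params_linear.biases)
    theta.append(Z.Z)
    return theta


def _flatten_grads(g: Gradients) -> list[np.ndarray]:
    theta = list(g.weights) + list(g.biases)
    if g.weights_linear is not None:
        theta += list(g.weights_linear) + list(g.biases_linear)
    theta.append(g.Z)
    return theta


def train(
    rm: ResponseMatrix,
    rank: int,
    hidden_sizes: tuple[int, ...],
    alpha: float,
    lam: float,
    activation: str = "tanh",
    options: TrainOptions | None = None,
    seed: int = 0,
    tied_branches: bool = True,
    init: tuple[NetworkParams, LatentInput] | None = None,
) -> TrainResult:
    """Fit one network side to a (residual) response matrix with iRprop+.

    The network maps the rank-``rank`` latent input (one column per matrix
    column) through ``hidden_sizes`` to the matrix rows.  Weights/biases
    are Gaussian-initialized from ``seed`` and the latent input starts at
    zero, unless an explicit ``init`` pair is given.  Deterministic for a
    fixed seed.
    """
    options = options or TrainOptions()
    m, n = rm.shape
    rng = np.random.default_rng(seed)
    if init is not None:
        params, Z = init[0].copy(), init[1].copy()
    else:
        params = init_params(rank, tuple(hidden_sizes), m, activation, rng)
        Z = LatentInput(np.zeros((rank, n)))
    params_linear = None
    if not tied_branches:
        params_linear = init_params(rank, tuple(hidden_sizes), m, activation, rng)

    theta = _flatten(params, Z, params_linear)
    state = RpropState.init(theta, options.hyper)
    history: list[float] = []
    status = "max_epochs"
    quiet = 0
    backup = [t.copy() for t in theta]
    for epoch in range(options.max_epochs):
        loss = masked_loss(params, Z, rm, alpha, lam, params_linear)
        if not np.isfinite(loss):
            logger.warning("training diverged at epoch %d; keeping last finite model", epoch)
            for t, b in zip(theta, backup):
                t[...] = b
            status = "diverged"
            break
        backup = [t.copy() for t in theta]
        g = gradients(params, Z, rm, alpha, lam, params_linear)
        irprop_plus_step(theta, _flatten_grads(g), loss, state)
        history.append(loss)
        if epoch % options.log_every == 0:
            logger.debug("epoch %d: loss %.6g", epoch, loss)
        if epoch > 0:
            rel = abs(history[-1] - history[-2]) / max(abs(history[-2]), 1e-300)
            quiet = quiet + 1 if rel < options.rel_tol else 0
            if quiet >= options.patience:
                status = "converged"
                break
    return TrainResult(
        params=params,
        latent=Z,
        loss_history=np.asarray(history),
        status=status,
        params_linear=params_linear,
    )
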