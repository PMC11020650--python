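"""Forward branches, masked loss, and analytic gradients of the dual-branch net.

The independent oracles here are deliberately dumb: per-column, per-layer
Python loops for the forward passes and a scalar summation loop for the
loss, so they share no code path with the vectorized implementation.
"""

import numpy as np
import pytest

from dbdnmf.io_data import ResponseMatrix
from dbdnmf.network import (
    LatentInput,
    NetworkParams,
    forward_linear,
    forward_nonlinear,
    gradients,
    implied_factor_matrix,
    init_params,
    masked_loss,
    predict_blend,
)

from conftest import random_masked_matrix


def _random_instance(rng, m, n, r, hidden, activation="tanh"):
    params = init_params(r, hidden, m, activation, rng)
    Z = LatentInput(rng.standard_normal((r, n)))
    rm = random_masked_matrix(rng, m=m, n=n)
    return params, Z, rm


def _loop_forward(params, Z, nonlinear):
    """Column-by-column, layer-by-layer re-evaluation with explicit loops."""
    act = {"tanh": np.tanh, "identity": lambda a: a}[
        params.activation if nonlinear else "identity"
    ]
    out = np.empty((params.out_dim, Z.shape[1]))
    for j in range(Z.shape[1]):
        h = Z[:, j]
        for W, b in zip(params.weights, params.biases):
            h = act(W @ h + b)
        out[:, j] = h
    return out


class TestForward:
    def test_zero_network_outputs_zero(self):
        p = NetworkParams([np.zeros((3, 2))], [np.zeros(3)], "tanh")
        Z = LatentInput(np.ones((2, 4)))
        np.testing.assert_array_equal(forward_nonlinear(p, Z), 0.0)

    def test_single_identity_layer_applies_tanh_entrywise(self):
        p = NetworkParams([np.eye(2)], [np.zeros(2)], "tanh")
        Z = LatentInput(np.array([[0.5], [-0.5]]))
        np.testing.assert_allclose(
            forward_nonlinear(p, Z), np.tanh([[0.5], [-0.5]]), atol=1e-15
        )
        np.testing.assert_allclose(forward_linear(p, Z), [[0.5], [-0.5]], atol=1e-15)

    def test_matches_loop_oracle(self, rng):
        params, Z, _ = _random_instance(rng, m=5, n=6, r=3, hidden=(4, 3))
        np.testing.assert_allclose(
            forward_nonlinear(params, Z), _loop_forward(params, Z.Z, True), atol=1e-12
        )
        np.testing.assert_allclose(
            forward_linear(params, Z), _loop_forward(params, Z.Z, False), atol=1e-12
        )

    def test_identity_activation_makes_branches_agree(self, rng):
        params, Z, _ = _random_instance(rng, 4, 5, 2, (3,), activation="identity")
        np.testing.assert_allclose(
            forward_nonlinear(params, Z), forward_linear(params, Z), atol=1e-13
        )

    def test_dimension_mismatch_names_layer(self):
        with pytest.raises(ValueError, match="layer 2"):
            NetworkParams(
                [np.zeros((3, 2)), np.zeros((4, 5))], [np.zeros(3), np.zeros(4)]
            )
        p = NetworkParams([np.zeros((3, 2))], [np.zeros(3)])
        with pytest.raises(ValueError, match="layer 1"):
            forward_nonlinear(p, LatentInput(np.zeros((4, 2))))


class TestImpliedFactor:
    def test_single_layer_is_the_weight_itself(self, rng):
        W = rng.standard_normal((4, 2))
        p = NetworkParams([W], [np.zeros(4)])
        np.testing.assert_array_equal(implied_factor_matrix(p), W)

    def test_scalar_pull_out(self, rng):
        W1 = rng.standard_normal((3, 2))
        p = NetworkParams([W1, 2 * np.eye(3)], [np.zeros(3), np.zeros(3)])
        np.testing.assert_allclose(implied_factor_matrix(p), 2 * W1, atol=1e-14)

    def test_zero_bias_linear_branch_is_factor_product(self, rng):
        params = init_params(3, (5, 4), 6, "tanh", rng)
        params.biases = [np.zeros_like(b) for b in params.biases]
        Z = LatentInput(rng.standard_normal((3, 7)))
        np.testing.assert_allclose(
            forward_linear(params, Z), implied_factor_matrix(params) @ Z.Z, atol=1e-12
        )


class TestPredictBlend:
    @pytest.mark.parametrize("alpha", [0.0, 0.5, 1.0])
    def test_blend_interpolates_branches(self, rng, alpha):
        params, Z, _ = _random_instance(rng, 4, 5, 2, (3,))
        expected = alpha * forward_nonlinear(params, Z) + (1 - alpha) * forward_linear(
            params, Z
        )
        np.testing.assert_allclose(predict_blend(params, Z, alpha), expected, atol=1e-14)

    def test_alpha_out_of_range(self, rng):
        params, Z, _ = _random_instance(rng, 3, 3, 2, ())
        with pytest.raises(ValueError, match="alpha"):
            predict_blend(params, Z, 1.5)


def _loop_loss(params, Z, rm, alpha, lam):
    """Scalar-summation oracle for the masked regularized loss."""
    f = _loop_forward(params, Z, True)
    g = _loop_forward(params, Z, False)
    acc = 0.0
    eta = 0
    for i in range(rm.shape[0]):
        for j in range(rm.shape[1]):
            if rm.mask[i, j]:
                eta += 1
                d = rm.values[i, j] - alpha * f[i, j] - (1 - alpha) * g[i, j]
                acc += d * d
    reg = 0.0
    for col in Z.T:
        for z in col:
            reg += z * z / (2 * Z.shape[1])
    for W in params.weights:
        for w in W.ravel():
            reg += 0.5 * w * w
    return acc / (2 * eta) + lam * reg


class TestMaskedLoss:
    def test_zero_residual_zero_lambda_gives_zero(self):
        p = NetworkParams([np.zeros((1, 1))], [np.zeros(1)], "tanh")
        rm = ResponseMatrix(np.array([[0.0]]))
        assert masked_loss(p, LatentInput(np.zeros((1, 1))), rm, 0.5, 0.0) == 0.0

    def test_single_entry_residual_two(self):
        p = NetworkParams([np.zeros((1, 1))], [np.zeros(1)], "tanh")
        rm = ResponseMatrix(np.array([[2.0]]))
        assert masked_loss(p, LatentInput(np.zeros((1, 1))), rm, 0.5, 0.0) == pytest.approx(2.0)

    def test_matches_scalar_loop_oracle(self):
        rng = np.random.default_rng(424242)
        params, Z, _ = _random_instance(rng, m=3, n=4, r=2, hidden=(3,))
        values = rng.standard_normal((3, 4))
        values[0, 2] = np.nan
        values[2, 1] = np.nan
        rm = ResponseMatrix(values)
        got = masked_loss(params, Z, rm, 0.35, 0.7)
        want = _loop_loss(params, Z.Z, rm, 0.35, 0.7)
        assert got == pytest.approx(want, abs=1e-12)

    def test_invariant_to_values_at_masked_entries(self, rng):
        params, Z, rm = _random_instance(rng, 4, 5, 2, (3,))
        base = masked_loss(params, Z, rm, 0.5, 0.1)
        tweaked = rm.copy()
        tweaked.values[~tweaked.mask] = 1e9  # poison the unobserved cells
        tweaked = ResponseMatrix(tweaked.values, tweaked.mask)  # renormalizes to NaN
        assert masked_loss(params, Z, tweaked, 0.5, 0.1) == base

    def test_negative_lambda_rejected(self, rng):
        params, Z, rm = _random_instance(rng, 3, 3, 2, ())
        with pytest.raises(ValueError, match="lam"):
            masked_loss(params, Z, rm, 0.5, -1.0)


def _fd_grad(fun, arr, eps=1e-6):
    out = np.zeros_like(arr)
    it = np.nditer(arr, flags=["multi_index"])
    for _ in it:
        idx = it.multi_index
        orig = arr[idx]
        arr[idx] = orig + eps
        fp = fun()
        arr[idx] = orig - eps
        fm = fun()
        arr[idx] = orig
        out[idx] = (fp - fm) / (2 * eps)
    return out


def _max_rel_err(analytic, numeric):
    denom = np.maximum(np.abs(numeric), 1e-6)
    return np.max(np.abs(analytic - numeric) / denom)


class TestGradients:
    def test_finite_difference_agreement(self):
        """Backprop vs central differences on 20 random small instances."""
        rng = np.random.default_rng(777)
        worst = 0.0
        for _ in range(20):
            m = int(rng.integers(2, 6))
            n = int(rng.integers(2, 7))
            r = int(rng.integers(1, 4))
            L = int(rng.integers(0, 3))
            hidden = tuple(int(rng.integers(2, 5)) for _ in range(L))
            params, Z, rm = _random_instance(rng, m, n, r, hidden)
            alpha = float(rng.uniform(0, 1))
            lam = float(rng.uniform(0, 0.5))
            g = gradients(params, Z, rm, alpha, lam)
            loss = lambda: masked_loss(params, Z, rm, alpha, lam)
            for arr, ga in (
                *zip(params.weights, g.weights),
                *zip(params.biases, g.biases),
                (Z.Z, g.Z),
            ):
                worst = max(worst, _max_rel_err(ga, _fd_grad(loss, arr)))
        assert worst < 1e-5

    def test_untied_branches_finite_difference(self):
        rng = np.random.default_rng(778)
        params, Z, rm = _random_instance(rng, 4, 5, 2, (3,))
        params_lin = init_params(2, (3,), 4, "tanh", rng)
        g = gradients(params, Z, rm, 0.4, 0.2, params_linear=params_lin)
        loss = lambda: masked_loss(params, Z, rm, 0.4, 0.2, params_linear=params_lin)
        for arr, ga in (
            *zip(params.weights, g.weights),
            *zip(params_lin.weights, g.weights_linear),
            *zip(params_lin.biases, g.biases_linear),
            (Z.Z, g.Z),
        ):
            assert _max_rel_err(ga, _fd_grad(loss, arr)) < 1e-5

    def test_stationary_at_perfect_fit_without_penalty(self, rng):
        params, Z, _ = _random_instance(rng, 4, 5, 2, (3,))
        pred = predict_blend(params, Z, 0.5)
        mask = rng.random((4, 5)) < 0.7
        mask[0, 0] = True
        rm = ResponseMatrix(np.where(mask, pred, np.nan), mask)
        g = gradients(params, Z, rm, 0.5, 0.0)
        for arr in (*g.weights, *g.biases, g.Z):
            np.testing.assert_allclose(arr, 0.0, atol=1e-14)

    def test_penalty_gradient_is_lambda_times_weight(self, rng):
        """With a residual-free fit the weight gradient reduces to lam * W."""
        params, Z, _ = _random_instance(rng, 4, 5, 2, (3,))
        pred = predict_blend(params, Z, 0.5)
        rm = ResponseMatrix(pred.copy())
        lam = 0.7
        g = gradients(params, Z, rm, 0.5, lam)
        for W, gW in zip(params.weights, g.weights):
            np.testing.assert_allclose(gW, lam * W, atol=1e-12)
        np.testing.assert_allclose(g.Z, lam / Z.n_cols * Z.Z, atol=1e-12)

    def test_reduces_to_bilinear_mf_gradient(self, rng):
        """L=0, alpha=0, zero biases: closed-form regularized MF gradient."""
        m, n, r = 5, 6, 2
        W = rng.standard_normal((m, r))
        params = NetworkParams([W], [np.zeros(m)], "tanh")
        Z = LatentInput(rng.standard_normal((r, n)))
        rm = random_masked_matrix(rng, m=m, n=n)
        lam = 0.3
        g = gradients(params, Z, rm, 0.0, lam)
        M = rm.mask
        eta = M.sum()
        E = np.where(M, W @ Z.Z - rm.values, 0.0)
        np.testing.assert_allclose(g.weights[0], E @ Z.Z.T / eta + lam * W, atol=1e-12)
        np.testing.assert_allclose(g.Z, W.T @ E / eta + lam / n * Z.Z, atol=1e-12)

    def test_shared_weights_drive_both_branches(self, rng):
        params, Z, _ = _random_instance(rng, 3, 4, 2, ())
        before_nl = forward_nonlinear(params, Z).copy()
        before_li = forward_linear(params, Z).copy()
        params.weights[0][0, 0] += 0.5
        assert not np.allclose(forward_nonlinear(params, Z), before_nl)
        assert not np.allclose(forward_linear(params, Z), before_li)
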