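"""Network core: forward pass, backprop gradients, momentum, Quickprop."""

import numpy as np
import pytest

from aoanet import Hyperparams, NetworkState, init_network, forward
from aoanet.network import (
    backprop_update,
    gradients,
    quickprop_step,
    quickprop_update,
    sigmoid,
    sse,
)


def sigma(z):
    return 1.0 / (1.0 + np.exp(-z))


def numeric_gradient(state, x, t, h=1e-5):
    """Central finite differences of E = 1/2 sum (o - t)^2 over every parameter."""
    out = {}
    for key, arr in state.params().items():
        g = np.zeros_like(arr)
        flat = arr.ravel()
        gf = g.ravel()
        for i in range(flat.size):
            orig = flat[i]
            flat[i] = orig + h
            _, o = forward(state, x)
            ep = 0.5 * sse(o, t)
            flat[i] = orig - h
            _, o = forward(state, x)
            em = 0.5 * sse(o, t)
            flat[i] = orig
            gf[i] = (ep - em) / (2 * h)
        out[key] = g
    return out


def small_net(seed, n_in=3, n_hidden=4, n_out=2):
    return init_network(n_in, n_hidden, n_out, init_range=0.5, seed=seed)


class TestInitForward:
    def test_default_shapes(self):
        net = init_network(seed=0)
        assert net.W_ih.shape == (100, 132)
        assert net.W_ho.shape == (112, 100)

    def test_init_range_bound_and_determinism(self):
        a, b = init_network(seed=5), init_network(seed=5)
        assert np.abs(a.W_ih).max() <= 0.5
        np.testing.assert_array_equal(a.W_ih, b.W_ih)
        assert not np.array_equal(a.W_ih, init_network(seed=6).W_ih)

    def test_nonpositive_size_rejected(self):
        with pytest.raises(ValueError):
            init_network(n_in=0, n_hidden=3, n_out=2)

    def test_zero_net_gives_half_activations(self):
        net = small_net(0)
        for k, v in net.params().items():
            v[:] = 0.0
        h, o = forward(net, np.array([1.0, 0.0, 1.0]))
        np.testing.assert_allclose(h, 0.5)
        np.testing.assert_allclose(o, 0.5)

    def test_hand_built_2_2_1_closed_form(self):
        net = init_network(2, 2, 1, seed=0)
        net.W_ih[:] = [[0.3, -0.2], [0.1, 0.4]]
        net.b_h[:] = [0.05, -0.05]
        net.W_ho[:] = [[0.7, -0.6]]
        net.b_o[:] = [0.2]
        x = np.array([1.0, 1.0])
        h_exp = sigma(np.array([0.3 - 0.2 + 0.05, 0.1 + 0.4 - 0.05]))
        o_exp = sigma(0.7 * h_exp[0] - 0.6 * h_exp[1] + 0.2)
        h, o = forward(net, x)
        np.testing.assert_allclose(h, h_exp, atol=1e-12)
        np.testing.assert_allclose(o, [o_exp], atol=1e-12)

    def test_activations_bounded(self, rng):
        net = small_net(3)
        for _ in range(10):
            h, o = forward(net, rng.random(3))
            assert np.all((h > 0) & (h < 1)) and np.all((o > 0) & (o < 1))

    def test_logistic_slope_peaks_at_quarter(self):
        s = sigmoid(np.array([0.0]))
        assert s[0] * (1 - s[0]) == pytest.approx(0.25)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            forward(small_net(0), np.zeros(5))


class TestBackprop:
    @pytest.mark.parametrize("seed", range(20))
    def test_gradient_matches_finite_differences(self, seed):
        rng = np.random.default_rng(seed)
        net = small_net(seed)
        x = rng.random(3)
        t = (rng.random(2) > 0.5).astype(float)
        analytic = gradients(net, x, t)
        numeric = numeric_gradient(net, x, t)
        for k in analytic:
            denom = np.maximum(np.abs(numeric[k]), 1e-8)
            rel = np.abs(analytic[k] - numeric[k]) / denom
            assert rel.max() < 1e-6, k

    def test_momentum_zero_is_plain_gradient_descent(self):
        rng = np.random.default_rng(0)
        x, t = rng.random(3), np.array([1.0, 0.0])
        net = small_net(1)
        expected = {k: v - 0.1 * g for (k, v), g in zip(net.params().items(), gradients(net, x, t).values())}
        hp = Hyperparams(learning_rate=0.1, momentum=0.0)
        backprop_update(net, x, t, hp)
        for k, v in net.params().items():
            np.testing.assert_allclose(v, expected[k], atol=1e-14)

    def test_zero_error_leaves_state_unchanged(self):
        # a saturated-free construction: target equals the exact output
        net = small_net(2)
        x = np.array([1.0, 0.5, 0.0])
        _, o = forward(net, x)
        before = {k: v.copy() for k, v in net.params().items()}
        backprop_update(net, x, o.copy(), Hyperparams(learning_rate=0.1, momentum=0.0))
        for k, v in net.params().items():
            np.testing.assert_allclose(v, before[k], atol=1e-15)

    def test_repeated_updates_decrease_error(self):
        rng = np.random.default_rng(4)
        net = small_net(4)
        x = rng.random(3)
        t = np.array([1.0, 0.0])
        hp = Hyperparams(learning_rate=0.01, momentum=0.0)
        errors = []
        for _ in range(100):
            _, o = forward(net, x)
            errors.append(sse(o, t))
            backprop_update(net, x, t, hp)
        assert all(b <= a + 1e-12 for a, b in zip(errors, errors[1:]))

    def test_momentum_accumulates_previous_delta(self):
        rng = np.random.default_rng(7)
        x, t = rng.random(3), np.array([0.0, 1.0])
        hp = Hyperparams(learning_rate=0.05, momentum=0.9)
        net = small_net(7)
        backprop_update(net, x, t, hp)
        first_delta = {k: v.copy() for k, v in net.prev_delta.items()}
        g2 = gradients(net, x, t)
        net2 = net.copy()
        backprop_update(net2, x, t, hp)
        for k in first_delta:
            expected = -hp.learning_rate * g2[k] + hp.momentum * first_delta[k]
            np.testing.assert_allclose(net2.prev_delta[k], expected, atol=1e-14)


class TestQuickprop:
    def test_quadratic_secant_step_is_exact(self):
        """On E(w) = 0.5 k (w - w*)^2, one gradient bootstrap step followed
        by one secant step lands exactly on the minimum."""
        k, w_star, lr = 1.0, 0.3, 0.5
        w0 = -1.2
        g0 = k * (w0 - w_star)
        step0 = -lr * g0  # bootstrap: plain gradient step
        w1 = w0 + step0
        g1 = k * (w1 - w_star)
        step1 = quickprop_step(
            np.array([g1]), np.array([g0]), np.array([step0]), lr=lr, mu=1.75
        )[0]
        assert w1 + step1 == pytest.approx(w_star, abs=1e-12)

    def test_zero_gradient_zero_step(self):
        step = quickprop_step(np.array([0.0]), np.array([0.5]), np.array([0.1]), 0.1, 1.75)
        assert step[0] == 0.0

    def test_growth_cap(self):
        # construct gradients whose secant step is 10x the previous step
        prev_step, g_prev = 1.0, 1.0
        g = 10.0 / 11.0 * g_prev  # prev_step * g / (g_prev - g) = 10
        step = quickprop_step(np.array([-g]), np.array([-g_prev]), np.array([prev_step]), 0.1, 1.75)
        assert step[0] == pytest.approx(1.75 * prev_step)

    def test_vanishing_denominator_falls_back_to_gradient(self):
        step = quickprop_step(np.array([0.4]), np.array([0.4]), np.array([0.2]), 0.1, 1.75)
        assert step[0] == pytest.approx(-0.1 * 0.4)

    def test_no_previous_step_falls_back_to_gradient(self):
        step = quickprop_step(np.array([0.4]), np.array([0.0]), np.array([0.0]), 0.1, 1.75)
        assert step[0] == pytest.approx(-0.04)

    def test_uphill_secant_rejected(self):
        # gradient shrank along the previous (uphill) step: the fitted
        # parabola opens downward and the secant step heads for its maximum
        g_prev, g, prev_step = 0.4, 0.2, 0.1
        step = quickprop_step(np.array([g]), np.array([g_prev]), np.array([prev_step]), 0.1, 1.75)
        assert step[0] == pytest.approx(-0.1 * g)

    def test_batch_update_trains_xor(self):
        """Quickprop drives a 2-4-1 net below the backprop-one-epoch error on
        a small boolean mapping task."""
        net = init_network(2, 4, 1, seed=3)
        X = np.array([[0.0, 0.0], [0.0, 1.0], [1.0, 0.0], [1.0, 1.0]])
        T = np.array([[0.0], [1.0], [1.0], [0.0]])
        batch = list(zip(X, T))
        hp = Hyperparams(learning_rate=0.5, optimizer="quickprop")
        e0 = sum(sse(forward(net, x)[1], t) for x, t in batch)
        for _ in range(300):
            quickprop_update(net, batch, hp)
        e1 = sum(sse(forward(net, x)[1], t) for x, t in batch)
        assert e1 < 0.05 * e0

    def test_empty_batch_rejected(self):
        with pytest.raises(ValueError, match="nonempty"):
            quickprop_update(small_net(0), [], Hyperparams(optimizer="quickprop"))

    def test_optimizer_field_enforced(self):
        net = small_net(0)
        with pytest.raises(ValueError):
            quickprop_update(net, [(np.zeros(3), np.zeros(2))], Hyperparams(optimizer="backprop"))


class TestHyperparams:
    @pytest.mark.parametrize(
        "kwargs", [{"learning_rate": 0.0}, {"momentum": 1.0}, {"optimizer": "adam"}]
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValueError):
            Hyperparams(**kwargs)


class TestSaveLoad:
    def test_round_trip(self, tmp_path):
        net = small_net(9)
        path = tmp_path / "net.json"
        net.save(path)
        back = NetworkState.load(path)
        for k in net.params():
            np.testing.assert_array_equal(net.params()[k], back.params()[k])
        assert back.rng_seed == net.rng_seed

    def test_rejects_foreign_file(self, tmp_path):
        path = tmp_path / "x.json"
        path.write_text("{}")
        with pytest.raises(ValueError):
            NetworkState.load(path)
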