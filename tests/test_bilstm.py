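import numpy as np
import pytest

from graphesi import (
    BiLSTMModel,
    BiLSTMRegressor,
    LSTMCellParams,
    bilstm_forward,
    count_parameters,
    lstm_cell_step,
    mse_loss,
)
from graphesi.bilstm import Standardizer, _sigmoid


def make_cell(hidden, input_dim, fill=0.0, rng=None):
    shape_w = (hidden, hidden + input_dim)
    if rng is None:
        w = {f"W_{g}": np.full(shape_w, fill) for g in "fico"}
        b = {f"b_{g}": np.zeros(hidden) for g in "fico"}
    else:
        w = {f"W_{g}": rng.standard_normal(shape_w) * 0.5 for g in "fico"}
        b = {f"b_{g}": rng.standard_normal(hidden) * 0.1 for g in "fico"}
    return LSTMCellParams(**w, **b)


def make_model(hidden, input_dim, k_out, rng=None, activation="identity"):
    if rng is None:
        ws = np.zeros((k_out, 2 * hidden))
        bs = np.zeros(k_out)
        fwd = make_cell(hidden, input_dim)
        bwd = make_cell(hidden, input_dim)
    else:
        ws = rng.standard_normal((k_out, 2 * hidden)) * 0.3
        bs = rng.standard_normal(k_out) * 0.1
        fwd = make_cell(hidden, input_dim, rng=rng)
        bwd = make_cell(hidden, input_dim, rng=rng)
    return BiLSTMModel(
        forward_cell=fwd, backward_cell=bwd, W_s=ws, b_s=bs,
        output_activation=activation,
    )


class TestLSTMCell:
    def test_zero_parameters_zero_state(self):
        cell = make_cell(3, 2)
        h, c = lstm_cell_step(cell, np.zeros(2), np.zeros(3), np.zeros(3))
        np.testing.assert_array_equal(h, 0.0)
        np.testing.assert_array_equal(c, 0.0)

    def test_zero_weights_halve_memory_cell(self):
        # all gates sit at sigmoid(0) = 0.5, candidate at tanh(0) = 0
        cell = make_cell(3, 2)
        c_prev = np.array([1.0, -2.0, 0.5])
        h, c = lstm_cell_step(cell, np.ones(2), np.zeros(3), c_prev)
        np.testing.assert_allclose(c, 0.5 * c_prev)
        np.testing.assert_allclose(h, 0.5 * np.tanh(0.5 * c_prev))

    def test_scalar_unit_weights_hand_case(self):
        """hidden = input = 1, unit weights, zero biases, x = 1: every gate
        is sigmoid(1) and the candidate tanh(1)."""
        cell = make_cell(1, 1, fill=1.0)
        h, c = lstm_cell_step(cell, np.array([1.0]), np.zeros(1), np.zeros(1))
        sig1 = 1.0 / (1.0 + np.exp(-1.0))
        expected_c = sig1 * np.tanh(1.0)
        expected_h = sig1 * np.tanh(expected_c)
        np.testing.assert_allclose(c, expected_c, rtol=1e-12)
        np.testing.assert_allclose(h, expected_h, rtol=1e-12)
        assert abs(c[0] - 0.5568) < 2e-3
        assert abs(h[0] - 0.3690) < 2e-3

    def test_gate_ranges_on_random_inputs(self, rng):
        cell = make_cell(4, 3, rng=rng)
        h = np.zeros(4)
        c = np.zeros(4)
        for _ in range(20):
            x = rng.standard_normal(3) * 3
            hx = np.concatenate([h, x])
            for w, b in ((cell.W_f, cell.b_f), (cell.W_i, cell.b_i),
                         (cell.W_o, cell.b_o)):
                gate = _sigmoid(hx @ w.T + b)
                assert np.all((gate > 0) & (gate < 1))
            cand = np.tanh(hx @ cell.W_c.T + cell.b_c)
            assert np.all((cand > -1) & (cand < 1))
            h, c = lstm_cell_step(cell, x, h, c)

    def test_shape_mismatch_rejected(self):
        cell = make_cell(3, 2)
        with pytest.raises(ValueError):
            lstm_cell_step(cell, np.zeros(5), np.zeros(3), np.zeros(3))


class TestBiLSTMForward:
    def test_zero_parameters_zero_output(self, rng):
        model = make_model(4, 3, 2)
        y = bilstm_forward(model, rng.standard_normal((3, 7)))
        np.testing.assert_array_equal(y, 0.0)

    def test_single_step_sequence(self, rng):
        model = make_model(4, 3, 2, rng=rng)
        x = rng.standard_normal((3, 1))
        y = bilstm_forward(model, x)
        assert y.shape == (2, 1)
        # with T = 1 both directions see exactly the one input
        h_f, _ = lstm_cell_step(model.forward_cell, x[:, 0], np.zeros(4),
                                np.zeros(4))
        h_b, _ = lstm_cell_step(model.backward_cell, x[:, 0], np.zeros(4),
                                np.zeros(4))
        expected = model.W_s @ np.concatenate([h_f, h_b]) + model.b_s
        np.testing.assert_allclose(y[:, 0], expected, rtol=1e-9)

    def test_matches_stepwise_reference(self, rng):
        """The vectorized scan agrees with the explicit per-step cell."""
        model = make_model(5, 3, 4, rng=rng)
        x = rng.standard_normal((3, 6))
        y = bilstm_forward(model, x)
        h = np.zeros(5); c = np.zeros(5)
        fwd_states = []
        for t in range(6):
            h, c = lstm_cell_step(model.forward_cell, x[:, t], h, c)
            fwd_states.append(h)
        h = np.zeros(5); c = np.zeros(5)
        bwd_states = [None] * 6
        for t in range(5, -1, -1):
            h, c = lstm_cell_step(model.backward_cell, x[:, t], h, c)
            bwd_states[t] = h
        for t in range(6):
            expected = model.W_s @ np.concatenate(
                [fwd_states[t], bwd_states[t]]
            ) + model.b_s
            np.testing.assert_allclose(y[:, t], expected, rtol=1e-9)

    def test_time_reversal_symmetry(self, rng):
        """Swapping the two directions (cells and output blocks) and
        reversing the input reverses the output."""
        H = 4
        model = make_model(H, 3, 2, rng=rng)
        swapped = BiLSTMModel(
            forward_cell=model.backward_cell,
            backward_cell=model.forward_cell,
            W_s=np.concatenate([model.W_s[:, H:], model.W_s[:, :H]], axis=1),
            b_s=model.b_s,
        )
        x = rng.standard_normal((3, 9))
        y = bilstm_forward(model, x)
        y_rev = bilstm_forward(swapped, x[:, ::-1])
        np.testing.assert_allclose(y_rev, y[:, ::-1], rtol=1e-9, atol=1e-12)

    def test_empty_sequence_rejected(self, rng):
        model = make_model(4, 3, 2, rng=rng)
        with pytest.raises(ValueError, match="empty"):
            bilstm_forward(model, np.zeros((3, 0)))


class TestMSELoss:
    def test_identical_inputs_zero(self, rng):
        a = rng.standard_normal((3, 4))
        assert mse_loss(a, a) == 0.0

    def test_constant_offset(self):
        a = np.zeros((2, 5))
        assert mse_loss(a + 2.0, a) == 4.0

    def test_direct_arithmetic(self):
        assert mse_loss(np.array([1.0, 2.0]), np.zeros(2)) == 2.5

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mse_loss(np.zeros(3), np.zeros(4))


class TestStandardizer:
    def test_per_channel_moments(self, rng):
        x = rng.standard_normal((10, 4, 20)) * 3 + 1
        s = Standardizer().fit(x)
        z = np.stack([s.transform(xi) for xi in x])
        flat = z.transpose(1, 0, 2).reshape(4, -1)
        np.testing.assert_allclose(flat.mean(axis=1), 0.0, atol=1e-6)
        np.testing.assert_allclose(flat.std(axis=1), 1.0, atol=1e-6)

    def test_round_trip(self, rng):
        x = rng.standard_normal((5, 3, 7))
        s = Standardizer().fit(x)
        np.testing.assert_allclose(
            s.inverse_transform(s.transform(x[0])), x[0], rtol=1e-9
        )

    def test_global_scaling_preserves_channel_ratios(self, rng):
        x = rng.standard_normal((6, 2, 50))
        x[:, 1] *= 10  # channel 1 much larger
        s = Standardizer(scaling="global").fit(x)
        assert s.std[0] == s.std[1]

    def test_zero_variance_flagged(self):
        x = np.zeros((4, 2, 5))
        x[:, 0] = np.arange(5)
        s = Standardizer().fit(x)
        assert not s.zero_variance[0]
        assert s.zero_variance[1]
        assert s.std[1] == 1.0


class TestTraining:
    def test_smoke_two_epochs(self, rng):
        X = rng.standard_normal((12, 4, 10)).astype(np.float32)
        Y = rng.standard_normal((12, 3, 10)).astype(np.float32)
        reg = BiLSTMRegressor(hidden_size=8, epochs=2, batch_size=4,
                              random_state=0)
        reg.fit(X, Y, validation_data=(X[:4], Y[:4]))
        assert len(reg.history_) == 2
        assert np.isfinite(reg.history_[-1]["val_mse"])
        assert reg.predict(X).shape == (12, 3, 10)

    def test_same_seed_identical_result(self, rng):
        X = rng.standard_normal((10, 3, 8)).astype(np.float32)
        Y = rng.standard_normal((10, 2, 8)).astype(np.float32)
        losses = []
        for _ in range(2):
            reg = BiLSTMRegressor(hidden_size=8, epochs=3, batch_size=4,
                                  random_state=11)
            reg.fit(X, Y)
            losses.append(reg.history_[-1]["train_mse"])
        assert losses[0] == losses[1]

    def test_learns_linear_teacher(self, rng):
        """A fixed linear map from input to target is representable; the
        trained network should explain almost all target variance."""
        n, k, T = 6, 3, 15
        M = rng.standard_normal((k, n)) * 0.5
        X = rng.standard_normal((80, n, T)).astype(np.float32)
        Y = np.einsum("kn,bnt->bkt", M, X).astype(np.float32)
        reg = BiLSTMRegressor(hidden_size=48, epochs=220, batch_size=16,
                              learning_rate=5e-3, patience=220, random_state=2)
        reg.fit(X, Y, validation_data=(X[:20], Y[:20]))
        pred = reg.predict(X[:20])
        ratio = np.mean((pred - Y[:20]) ** 2) / np.var(Y[:20])
        assert ratio < 0.01

    def test_divergence_raises_with_epoch(self, rng):
        X = (rng.standard_normal((8, 3, 10)) * 1e3).astype(np.float32)
        Y = (rng.standard_normal((8, 2, 10)) * 1e3).astype(np.float32)
        reg = BiLSTMRegressor(hidden_size=8, epochs=5, learning_rate=1e30,
                              standardize=False, random_state=0)
        with pytest.raises(FloatingPointError, match="epoch"):
            reg.fit(X, Y)


class TestParameterCounts:
    def test_low_band_output_layer_is_smaller(self, rng):
        m, k, hidden, n = 642, 193, 128, 64
        small = make_model(hidden, n, k, rng=rng)
        full = make_model(hidden, n, m, rng=rng)
        c_small = count_parameters(small)
        c_full = count_parameters(full)
        assert c_small["output"] < c_full["output"]
        assert c_small["total"] < c_full["total"]
        ratio = c_full["output"] / c_small["output"]
        np.testing.assert_allclose(ratio, m / k, rtol=0.01)
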