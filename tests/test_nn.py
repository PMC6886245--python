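"""Embedding, char-CNN, LSTM and BiLSTM building blocks."""

import math

import numpy as np
import pytest

from bactner.nn import (
    Affine,
    CharCNNParams,
    Dropout,
    LSTMParams,
    bilstm_encode,
    char_cnn_encode,
    init_uniform,
    lstm_forward,
    lstm_step,
)


class TestInitUniform:
    def test_dim_3_bound_is_one(self, rng):
        table = init_uniform(100, 3, rng)
        assert np.all(np.abs(table) <= 1.0)

    @pytest.mark.parametrize("dim", [1, 5, 25, 300])
    def test_bound(self, dim, rng):
        table = init_uniform(50, dim, rng)
        assert np.abs(table).max() <= math.sqrt(3.0 / dim)

    def test_moments(self, rng):
        dim = 25
        table = init_uniform(10_000, dim, rng)
        b = math.sqrt(3.0 / dim)
        sigma = math.sqrt((2 * b) ** 2 / 12.0)
        assert abs(table.mean()) < 3 * sigma / math.sqrt(table.size)

    def test_deterministic_under_seed(self):
        a = init_uniform(10, 4, np.random.default_rng(7))
        b = init_uniform(10, 4, np.random.default_rng(7))
        np.testing.assert_array_equal(a, b)

    def test_nonpositive_dim_rejected(self, rng):
        with pytest.raises(ValueError):
            init_uniform(10, 0, rng)


@pytest.fixture
def charcnn(rng):
    return CharCNNParams.create("abcdefgh", char_dim=4, k=3, N=5, rng=rng)


class TestCharCnn:
    def test_zero_params_zero_output(self, charcnn):
        charcnn.W1.value[...] = 0.0
        charcnn.b1.value[...] = 0.0
        np.testing.assert_array_equal(char_cnn_encode("abc", charcnn), np.zeros(5))

    def test_relu_clips_negative_bias(self, charcnn):
        charcnn.W1.value[...] = 0.0
        charcnn.b1.value[...] = 0.0
        charcnn.b1.value[2] = -5.0
        assert char_cnn_encode("abcd", charcnn)[2] == 0.0

    def test_single_char_single_window(self, charcnn):
        # one character: the only window is [pad, e(c), pad]; max-pool is identity
        e = charcnn.char_table.param.value[charcnn.char_table.index("a")]
        window = np.concatenate([np.zeros(4), e, np.zeros(4)])
        expected = np.maximum(
            charcnn.W1.value @ window + charcnn.b1.value, 0.0
        )
        np.testing.assert_allclose(char_cnn_encode("a", charcnn), expected)

    def test_empty_word_zero_vector(self, charcnn):
        np.testing.assert_array_equal(char_cnn_encode("", charcnn), np.zeros(5))

    def test_unknown_chars_use_unk_row(self, charcnn):
        a = char_cnn_encode("xyz", charcnn)
        b = char_cnn_encode("qqq", charcnn)
        np.testing.assert_allclose(a, b)


class TestLstmStep:
    def test_zero_everything(self):
        params = LSTMParams.create(3, 2, np.random.default_rng(0))
        for p in params.params():
            p.value[...] = 0.0
        h, C = lstm_step(np.zeros(3), np.zeros(2), np.zeros(2), params)
        np.testing.assert_array_equal(h, np.zeros(2))
        np.testing.assert_array_equal(C, np.zeros(2))

    def test_zero_params_carry_cell(self):
        # zero weights: f = i = o = 0.5, candidate 0, so C = C_prev / 2
        params = LSTMParams.create(3, 2, np.random.default_rng(0))
        for p in params.params():
            p.value[...] = 0.0
        h, C = lstm_step(np.ones(3), np.zeros(2), np.full(2, 2.0), params)
        np.testing.assert_allclose(C, np.ones(2))
        np.testing.assert_allclose(h, 0.5 * math.tanh(1.0), rtol=1e-6)
        assert h[0] == pytest.approx(0.380797, abs=1e-6)

    def test_saturated_forget_gate_is_perfect_memory(self):
        params = LSTMParams.create(3, 2, np.random.default_rng(0))
        for p in params.params():
            p.value[...] = 0.0
        params.b_f.value[...] = 50.0
        params.b_i.value[...] = -50.0
        params.b_o.value[...] = -50.0
        c = np.array([0.7, -1.3])
        _, C = lstm_step(np.zeros(3), np.zeros(2), c, params)
        np.testing.assert_allclose(C, c, rtol=1e-10)

    def test_dimension_mismatch_rejected(self):
        params = LSTMParams.create(3, 2, np.random.default_rng(0))
        with pytest.raises(ValueError):
            lstm_step(np.zeros(4), np.zeros(2), np.zeros(2), params)


class TestBiLstm:
    def test_single_position_matches_single_steps(self, rng):
        fwd = LSTMParams.create(3, 2, rng)
        bwd = LSTMParams.create(3, 2, rng)
        x = rng.standard_normal((1, 3))
        H = bilstm_encode(x, fwd, bwd)
        hf, _ = lstm_step(x[0], np.zeros(2), np.zeros(2), fwd)
        hb, _ = lstm_step(x[0], np.zeros(2), np.zeros(2), bwd)
        np.testing.assert_allclose(H[0], np.concatenate([hf, hb]))

    def test_reversal_symmetry(self, rng):
        fwd = LSTMParams.create(3, 2, rng)
        bwd = LSTMParams.create(3, 2, rng)
        x = rng.standard_normal((5, 3))
        H = bilstm_encode(x, fwd, bwd)
        H_rev = bilstm_encode(x[::-1], bwd, fwd)
        np.testing.assert_allclose(H, np.concatenate(
            [H_rev[::-1, 2:], H_rev[::-1, :2]], axis=1
        ), atol=1e-12)

    def test_zero_params_zero_output(self, rng):
        fwd = LSTMParams.create(3, 2, rng)
        bwd = LSTMParams.create(3, 2, rng)
        for p in fwd.params() + bwd.params():
            p.value[...] = 0.0
        H = bilstm_encode(np.ones((4, 3)), fwd, bwd)
        np.testing.assert_array_equal(H, np.zeros((4, 4)))

    def test_causality(self, rng):
        """Perturbing a later input leaves earlier forward states unchanged."""
        fwd = LSTMParams.create(3, 4, rng)
        bwd = LSTMParams.create(3, 4, rng)
        x = rng.standard_normal((6, 3))
        H1 = bilstm_encode(x, fwd, bwd)
        x2 = x.copy()
        x2[4] += 10.0
        H2 = bilstm_encode(x2, fwd, bwd)
        np.testing.assert_array_equal(H1[:4, :4], H2[:4, :4])   # forward half
        np.testing.assert_array_equal(H1[5:, 4:], H2[5:, 4:])   # backward half

    def test_empty_sequence_rejected(self, rng):
        fwd = LSTMParams.create(3, 2, rng)
        bwd = LSTMParams.create(3, 2, rng)
        with pytest.raises(ValueError):
            bilstm_encode(np.zeros((0, 3)), fwd, bwd)

    def test_lengths_preserved(self, rng):
        fwd = LSTMParams.create(3, 2, rng)
        bwd = LSTMParams.create(3, 2, rng)
        for n in (1, 2, 9):
            H = bilstm_encode(rng.standard_normal((n, 3)), fwd, bwd)
            assert H.shape == (n, 4)


class TestAffine:
    def test_zero_map(self, rng):
        aff = Affine(4, 3, rng)
        aff.W.value[...] = 0.0
        np.testing.assert_array_equal(aff.forward(rng.standard_normal((5, 4))),
                                      np.zeros((5, 3)))

    def test_matches_dense_multiply(self, rng):
        aff = Affine(4, 3, rng)
        aff.b.value[...] = rng.standard_normal(3)
        x = rng.standard_normal((6, 4))
        np.testing.assert_allclose(
            aff.forward(x), x @ aff.W.value.T + aff.b.value
        )


class TestDropout:
    def test_identity_at_inference(self, rng):
        d = Dropout(0.5)
        x = rng.standard_normal((4, 4))
        out, mask = d.forward(x, rng, train=False)
        assert mask is None and out is x

    def test_rate_zero_identity_in_train(self, rng):
        d = Dropout(0.0)
        x = rng.standard_normal((4, 4))
        out, mask = d.forward(x, rng, train=True)
        assert mask is None and out is x

    def test_inverted_scaling_preserves_mean(self, rng):
        d = Dropout(0.5)
        x = np.ones((200, 200))
        out, _ = d.forward(x, rng, train=True)
        assert out.mean() == pytest.approx(1.0, abs=0.02)
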