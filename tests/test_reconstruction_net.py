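import numpy as np
import pytest
from scipy.special import expit

from ecgcs.compression import (init_conv_compressor, make_fixed_matrix,
                               make_sensing_config)
from ecgcs.reconstruction_net import (ActivationConfig, InceptionLineParams,
                                      InitialReconParams, LstmParams,
                                      final_reconstruct, inception_block,
                                      inception_line, init_network,
                                      initial_reconstruct, leaky_relu,
                                      load_checkpoint, lstm_step,
                                      network_from_flat, reconstruct,
                                      save_checkpoint)
from ecgcs.training import model_forward

ALL_SENSING_RATES = (0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6)


class TestLeakyRelu:
    def test_positive_passthrough_and_negative_scaling(self):
        act = ActivationConfig(leaky_slope=0.01)
        assert leaky_relu(3.0, act) == 3.0
        assert leaky_relu(-1.0, act) == pytest.approx(-0.01)

    def test_idempotent_on_nonnegative(self, rng):
        act = ActivationConfig()
        x = np.abs(rng.standard_normal(32))
        np.testing.assert_array_equal(leaky_relu(leaky_relu(x, act), act),
                                      leaky_relu(x, act))

    def test_slope_must_be_fractional(self):
        with pytest.raises(ValueError):
            ActivationConfig(leaky_slope=1.5)


class TestInitialReconstruct:
    @pytest.mark.parametrize("sr", ALL_SENSING_RATES)
    def test_output_length_256(self, sr, rng):
        cfg = make_sensing_config(sr)
        c = cfg.channel_count
        params = InitialReconParams(weight=rng.standard_normal((64, c)),
                                    bias=np.zeros(64))
        out = initial_reconstruct(rng.standard_normal(cfg.measurement_length), params)
        assert out.shape == (256,)

    def test_zero_weights_give_constant_bias(self, rng):
        c = 8
        beta = 0.4
        params = InitialReconParams(weight=np.zeros((64, c)), bias=np.full(64, beta))
        out = initial_reconstruct(rng.standard_normal(4 * c), params)
        np.testing.assert_allclose(out, beta)

    def test_position_major_reshape_layout(self):
        """Flat index 64*p + c holds channel c of measurement position p."""
        c = 64  # square 1x1 conv so channels pass straight through
        params = InitialReconParams(weight=np.eye(64), bias=np.zeros(64))
        meas_grid = np.arange(64 * 4, dtype=float).reshape(64, 4)  # (C, P), all >= 0
        out = initial_reconstruct(meas_grid, params)
        for p in range(4):
            for ch in range(64):
                assert out[64 * p + ch] == meas_grid[ch, p]


def _rand_line(k, rng, scale=0.3):
    return InceptionLineParams(
        kernel_length=k,
        w1=scale * rng.standard_normal((16, 16, k)), b1=scale * rng.standard_normal(16),
        w2=scale * rng.standard_normal((16, 16, k)), b2=scale * rng.standard_normal(16))


def _zero_line(k):
    return InceptionLineParams(kernel_length=k, w1=np.zeros((16, 16, k)),
                               b1=np.zeros(16), w2=np.zeros((16, 16, k)),
                               b2=np.zeros(16))


def _conv_same_oracle(x, w, b):
    """Direct triple-loop same-padded correlation (independent of the engine)."""
    c_out, c_in, k = w.shape
    pad = k // 2
    length = x.shape[1]
    xpad = np.pad(x, ((0, 0), (pad, pad)))
    out = np.zeros((c_out, length))
    for o in range(c_out):
        for l in range(length):
            acc = b[o]
            for c in range(c_in):
                for j in range(k):
                    acc += w[o, c, j] * xpad[c, l + j]
            out[o, l] = acc
    return out


class TestInceptionLine:
    def test_zero_filters_is_identity(self, rng):
        x = rng.standard_normal((16, 256))
        out = inception_line(x, _zero_line(9))
        np.testing.assert_array_equal(out, x)

    @pytest.mark.parametrize("k", [7, 9, 11, 13])
    def test_shape_preserved(self, k, rng):
        x = rng.standard_normal((16, 64))
        assert inception_line(x, _rand_line(k, rng)).shape == (16, 64)

    def test_against_hand_rolled_convolution(self, rng):
        """sigma(f2(sigma(f1(x)))) + x computed by explicit loops."""
        act = ActivationConfig(leaky_slope=0.01)
        line = _rand_line(7, rng)
        x = rng.standard_normal((16, 32))

        def lre(v):
            return np.where(v >= 0, v, 0.01 * v)

        a1 = lre(_conv_same_oracle(x, line.w1, line.b1))
        expected = lre(_conv_same_oracle(a1, line.w2, line.b2)) + x
        np.testing.assert_allclose(inception_line(x, line, act), expected, atol=1e-6)

    def test_channel_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            inception_line(rng.standard_normal((8, 64)), _zero_line(7))


class TestInceptionBlock:
    def test_concatenation_to_64_channels(self, rng):
        lines = [_rand_line(k, rng) for k in (7, 9, 11, 13)]
        x = rng.standard_normal((16, 128))
        out = inception_block(x, lines)
        assert out.shape == (64, 128)
        np.testing.assert_array_equal(out[:16], inception_line(x, lines[0]))

    def test_all_zero_lines_tile_the_input(self, rng):
        x = rng.standard_normal((16, 64))
        out = inception_block(x, [_zero_line(k) for k in (7, 9, 11, 13)])
        np.testing.assert_array_equal(out, np.tile(x, (4, 1)))

    def test_wrong_line_count_rejected(self, rng):
        with pytest.raises(ValueError):
            inception_block(rng.standard_normal((16, 64)), [_zero_line(7)] * 3)


def _zero_lstm(h=4, f=6):
    z = np.zeros((h, h + f))
    return LstmParams(W_f=z.copy(), W_i=z.copy(), W_c=z.copy(), W_o=z.copy(),
                      b_f=np.zeros(h), b_i=np.zeros(h), b_c=np.zeros(h),
                      b_o=np.zeros(h), proj_w=np.zeros(h), proj_b=0.0)


def lstm_step_scalar_oracle(x_t, h_prev, c_prev, params):
    """Element-by-element LSTM update with explicit python loops."""
    hx = list(h_prev) + list(x_t)
    h_size = len(h_prev)

    def gate(w, b, fn):
        out = []
        for r in range(h_size):
            acc = b[r]
            for j, v in enumerate(hx):
                acc += w[r][j] * v
            out.append(fn(acc))
        return out

    sig = lambda z: 1.0 / (1.0 + np.exp(-z))
    f = gate(params.W_f, params.b_f, sig)
    i = gate(params.W_i, params.b_i, sig)
    g = gate(params.W_c, params.b_c, np.tanh)
    o = gate(params.W_o, params.b_o, sig)
    c = [f[r] * c_prev[r] + i[r] * g[r] for r in range(h_size)]
    h = [o[r] * np.tanh(c[r]) for r in range(h_size)]
    return np.array(h), np.array(c)


class TestLstmStep:
    def test_zero_parameter_closed_form(self):
        params = _zero_lstm()
        h, c = lstm_step(np.ones(6), np.zeros(4), np.zeros(4), params)
        np.testing.assert_array_equal(h, np.zeros(4))
        np.testing.assert_array_equal(c, np.zeros(4))

    def test_zero_weights_halve_cell_state(self, rng):
        params = _zero_lstm()
        c0 = rng.standard_normal(4)
        h, c = lstm_step(np.zeros(6), np.zeros(4), c0, params)
        np.testing.assert_allclose(c, 0.5 * c0)
        np.testing.assert_allclose(h, 0.5 * np.tanh(0.5 * c0))

    def test_against_scalar_oracle(self, rng):
        for _ in range(20):
            h_size, f_size = 5, 7
            mk = lambda *s: 0.5 * rng.standard_normal(s)
            params = LstmParams(
                W_f=mk(h_size, h_size + f_size), W_i=mk(h_size, h_size + f_size),
                W_c=mk(h_size, h_size + f_size), W_o=mk(h_size, h_size + f_size),
                b_f=mk(h_size), b_i=mk(h_size), b_c=mk(h_size), b_o=mk(h_size),
                proj_w=mk(h_size), proj_b=0.0)
            x_t, h0, c0 = mk(f_size), mk(h_size), mk(h_size)
            h, c = lstm_step(x_t, h0, c0, params)
            h_ref, c_ref = lstm_step_scalar_oracle(x_t, h0, c0, params)
            np.testing.assert_allclose(h, h_ref, atol=1e-6)
            np.testing.assert_allclose(c, c_ref, atol=1e-6)

    def test_dimension_mismatch_rejected(self):
        params = _zero_lstm(4, 6)
        with pytest.raises(ValueError):
            lstm_step(np.ones(3), np.zeros(4), np.zeros(4), params)


class TestFullNetwork:
    @pytest.mark.parametrize("sr", ALL_SENSING_RATES)
    def test_shapes_at_every_sensing_rate(self, sr, rng):
        cfg = make_sensing_config(sr)
        net = init_network(cfg.channel_count, seed=1)
        y = rng.standard_normal(cfg.measurement_length)
        out = reconstruct(y, net)
        assert out.shape == (256,)

    def test_zero_parameter_network_is_zero_map(self, rng):
        cfg = make_sensing_config(0.2)
        net = init_network(cfg.channel_count, seed=0)
        flat = {k: np.zeros_like(v) for k, v in net.to_flat().items()}
        zero_net = network_from_flat(flat, net.activation)
        out = reconstruct(rng.standard_normal(cfg.measurement_length), zero_net)
        np.testing.assert_array_equal(out, np.zeros(256))

    def test_deterministic(self, rng):
        cfg = make_sensing_config(0.1)
        net = init_network(cfg.channel_count, seed=3)
        y = rng.standard_normal(cfg.measurement_length)
        np.testing.assert_array_equal(reconstruct(y, net), reconstruct(y, net))

    def test_batched_engine_matches_stagewise_composition(self, rng):
        """The training-path forward equals the composed public stage ops."""
        cfg = make_sensing_config(0.5)
        comp = init_conv_compressor(cfg, seed=4)
        net = init_network(cfg.channel_count, seed=5)
        x = rng.random((3, 256))
        batched = model_forward(comp, net, x)
        from ecgcs.compression import compress_conv
        for i in range(3):
            stagewise = reconstruct(compress_conv(x[i], comp), net)
            np.testing.assert_allclose(batched[i], stagewise, atol=1e-5)


class TestCheckpoints:
    def test_round_trip_bit_exact_conv(self, tmp_path, rng):
        cfg = make_sensing_config(0.3)
        comp = init_conv_compressor(cfg, seed=6)
        net = init_network(cfg.channel_count, seed=7)
        path = tmp_path / "model.npz"
        save_checkpoint(path, net, cfg, comp)
        net2, cfg2, comp2 = load_checkpoint(path)
        assert cfg2 == cfg
        for k, v in net.to_flat().items():
            np.testing.assert_array_equal(net2.to_flat()[k], v)
        for a, b in zip(comp.weights, comp2.weights):
            np.testing.assert_array_equal(a, b)

    def test_round_trip_fixed_matrix(self, tmp_path):
        cfg = make_sensing_config(0.1)
        op = make_fixed_matrix("bernoulli", cfg, seed=8)
        net = init_network(cfg.channel_count, seed=9)
        path = tmp_path / "model.npz"
        save_checkpoint(path, net, cfg, op)
        net2, cfg2, op2 = load_checkpoint(path)
        assert op2.family == "bernoulli"
        np.testing.assert_array_equal(op.matrix, op2.matrix)
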