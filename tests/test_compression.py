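import numpy as np
import pytest

from ecgcs.compression import (ConvCompressorParams, compress_conv,
                               compress_matrix, extract_effective_matrix,
                               init_conv_compressor, make_fixed_matrix,
                               make_sensing_config, rip_ratio)

ALL_SENSING_RATES = (0.05, 0.1, 0.2, 0.3, 0.4, 0.5, 0.6)


class TestSensingConfig:
    def test_half_rate(self):
        cfg = make_sensing_config(0.5, 256)
        assert (cfg.channel_count, cfg.measurement_length) == (32, 128)

    def test_low_rate_rounding(self):
        cfg = make_sensing_config(0.05, 256)
        assert (cfg.channel_count, cfg.measurement_length) == (3, 12)
        assert cfg.realized_sensing_rate == 0.046875

    def test_full_rate_is_identity_size(self):
        cfg = make_sensing_config(1.0, 256)
        assert (cfg.channel_count, cfg.measurement_length) == (64, 256)

    @pytest.mark.parametrize("sr", ALL_SENSING_RATES)
    def test_realized_rate_close_to_requested(self, sr):
        cfg = make_sensing_config(sr, 256)
        assert cfg.channel_count == max(1, round(64 * sr))
        assert abs(cfg.realized_sensing_rate - sr) <= 1 / 128

    def test_invalid_inputs_rejected(self):
        with pytest.raises(ValueError):
            make_sensing_config(0.5, 250)
        with pytest.raises(ValueError):
            make_sensing_config(0.0, 256)
        with pytest.raises(ValueError):
            make_sensing_config(1.5, 256)


def _zero_compressor(cfg, biases):
    c = cfg.channel_count
    return ConvCompressorParams(
        weights=[np.zeros((c, 1, 4)), np.zeros((c, c, 4)), np.zeros((c, c, 4))],
        biases=biases, config=cfg)


class TestConvCompressor:
    def test_output_length_at_half_rate(self, rng):
        cfg = make_sensing_config(0.5)
        comp = init_conv_compressor(cfg, seed=0)
        y = compress_conv(rng.random(256), comp)
        assert y.shape == (128,)

    def test_zero_weights_propagate_biases_only(self, rng):
        cfg = make_sensing_config(0.1)
        c = cfg.channel_count
        comp = _zero_compressor(cfg, [np.full(c, 0.3), np.full(c, -0.1), np.full(c, 0.7)])
        y1 = compress_conv(rng.random(256), comp)
        y2 = compress_conv(rng.random(256), comp)
        np.testing.assert_array_equal(y1, y2)
        # with w=0 only the final bias survives, identical at every position
        np.testing.assert_allclose(y1, np.tile([0.7] * c, 4))

    def test_affinity(self, rng):
        """y(x1+x2) - y(x1) - y(x2) + y(0) = 0: the stack is affine."""
        cfg = make_sensing_config(0.3)
        comp = init_conv_compressor(cfg, seed=5)
        for b, w in zip(comp.biases, (0.1, -0.2, 0.05)):
            b += w
        x1, x2 = rng.standard_normal(256), rng.standard_normal(256)
        gap = (compress_conv(x1 + x2, comp) - compress_conv(x1, comp)
               - compress_conv(x2, comp) + compress_conv(np.zeros(256), comp))
        assert np.abs(gap).max() < 1e-5

    def test_length_mismatch_rejected(self, rng):
        cfg = make_sensing_config(0.5)
        comp = init_conv_compressor(cfg)
        with pytest.raises(ValueError):
            compress_conv(rng.random(255), comp)


class TestEffectiveMatrix:
    def test_zero_weight_compressor(self):
        cfg = make_sensing_config(0.05)
        c = cfg.channel_count
        comp = _zero_compressor(cfg, [np.zeros(c), np.zeros(c), np.ones(c)])
        phi, offset = extract_effective_matrix(comp)
        np.testing.assert_array_equal(phi, np.zeros((12, 256)))
        np.testing.assert_allclose(offset, np.ones(12))

    def test_oracle_equivalence(self, rng):
        cfg = make_sensing_config(0.4)
        comp = init_conv_compressor(cfg, seed=11)
        for b in comp.biases:
            b += rng.standard_normal(b.size) * 0.1
        phi, offset = extract_effective_matrix(comp)
        xs = rng.standard_normal((100, 256))
        direct = compress_conv(xs, comp)
        assert np.abs(direct - (xs @ phi.T + offset)).max() < 1e-5

    def test_receptive_field_block_structure(self):
        """Each measurement value depends on <= 64 consecutive samples."""
        cfg = make_sensing_config(0.5)
        comp = init_conv_compressor(cfg, seed=2)
        phi, _ = extract_effective_matrix(comp)
        c = cfg.channel_count
        for row in range(phi.shape[0]):
            position = row // c  # position-major flattening
            support = np.nonzero(phi[row])[0]
            assert support.size <= 64
            assert support.min() >= 64 * position
            assert support.max() < 64 * (position + 1)


class TestFixedMatrices:
    def test_bernoulli_entries(self):
        cfg = make_sensing_config(1 / 64)  # C=1, M=4
        op = make_fixed_matrix("bernoulli", cfg, seed=0)
        assert set(np.unique(op.matrix)) == {-0.5, 0.5}

    def test_gaussian_variance(self):
        cfg = make_sensing_config(0.25)
        op = make_fixed_matrix("gaussian", cfg, seed=1)
        assert op.matrix.size >= 10_000
        var = op.matrix.var()
        m = cfg.measurement_length
        assert abs(var - 1 / m) < 0.05 / m

    def test_seeded_determinism(self):
        cfg = make_sensing_config(0.2)
        a = make_fixed_matrix("gaussian", cfg, seed=7)
        b = make_fixed_matrix("gaussian", cfg, seed=7)
        np.testing.assert_array_equal(a.matrix, b.matrix)

    def test_unknown_family_rejected(self):
        with pytest.raises(ValueError):
            make_fixed_matrix("uniform", make_sensing_config(0.2), seed=0)

    def test_compress_matrix_against_double_loop(self, rng):
        cfg = make_sensing_config(0.05)
        op = make_fixed_matrix("gaussian", cfg, seed=3)
        x = rng.standard_normal(256)
        y = compress_matrix(x, op)
        oracle = np.array([
            sum(op.matrix[i, j] * x[j] for j in range(256))
            for i in range(cfg.measurement_length)])
        np.testing.assert_allclose(y, oracle, atol=1e-12)

    def test_zero_input_gives_zero(self):
        cfg = make_sensing_config(0.1)
        op = make_fixed_matrix("bernoulli", cfg, seed=0)
        np.testing.assert_array_equal(compress_matrix(np.zeros(256), op),
                                      np.zeros(cfg.measurement_length))


class TestRipRatio:
    def test_identity_matrix(self, rng):
        x = rng.standard_normal(16)
        assert rip_ratio(np.eye(16), x) == pytest.approx(1.0)
        assert rip_ratio(2 * np.eye(16), x) == pytest.approx(4.0)

    def test_gaussian_concentration(self, rng):
        cfg = make_sensing_config(0.5)
        op = make_fixed_matrix("gaussian", cfg, seed=9)
        ratios = [rip_ratio(op, rng.standard_normal(256)) for _ in range(1000)]
        assert 0.8 < np.mean(ratios) < 1.2

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            rip_ratio(np.eye(4), np.zeros(4))


class TestMeasurementContainer:
    def test_wraps_conv_output_with_provenance(self, rng):
        from ecgcs.compression import Measurement, measure
        cfg = make_sensing_config(0.5)
        comp = init_conv_compressor(cfg, seed=0)
        x = rng.random(256)
        m = measure(x, comp)
        assert isinstance(m, Measurement)
        assert len(m) == cfg.measurement_length
        assert m.operator_family == "conv"
        np.testing.assert_array_equal(m.values, compress_conv(x, comp))

    def test_length_contract_enforced(self):
        from ecgcs.compression import Measurement
        with pytest.raises(ValueError):
            Measurement(values=np.zeros(10), config=make_sensing_config(0.5))
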