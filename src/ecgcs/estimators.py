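"""scikit-learn style estimators wrapping the compressive-sensing pipeline.

``DeepCompressiveSensing`` is a transformer: ``fit`` trains the measurement
operator and decoder end-to-end on normalized segments, ``transform``
compresses segments to measurements, and ``inverse_transform`` reconstructs
segments from measurements.  ``GreedyCompressedSensing`` exposes the
classical fixed-matrix + greedy-recovery baselines behind the same surface,
so the two compose interchangeably in pipelines and model selection.
"""

from __future__ import annotations

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin
from sklearn.utils.validation import check_array, check_is_fitted

from . import _nn
from .baselines import GreedyConfig, baseline_reconstruct, build_basis, default_config
from .compression import (compress_conv, compress_matrix, make_fixed_matrix,
                          make_sensing_config)
from .reconstruction_net import ActivationConfig
from .training import TrainingConfig, evaluate, train


class DeepCompressiveSensing(TransformerMixin, BaseEstimator):
    """Learned convolutional compression with Inception/LSTM reconstruction.

    Parameters
    ----------
    sensing_rate : float in (0, 1]
        Requested M/N; the realized rate is ``sensing_config_.realized_sensing_rate``.
    measurement : {'conv', 'gaussian', 'bernoulli'}
        'conv' learns the three-layer strided compressor jointly with the
        decoder; the other two fix a seeded random matrix and train the
        decoder only.
    epochs, batch_size, learning_rate, high_sr_learning_rate
        Adam protocol (moment decays 0.9/0.999).
    random_state : int
        Seeds initialization, the train/validation split and shuffling.
    """

    def __init__(self, sensing_rate: float = 0.5, segment_length: int = 256,
                 measurement: str = "conv", hidden_size: int = 64,
                 leaky_slope: float = 0.01, learning_rate: float = 5e-4,
                 high_sr_learning_rate: float | None = None,
                 epochs: int = 30, batch_size: int = 32,
                 validation_fraction: float = 0.2,
                 train_compressor: bool = True,
                 matrix_seed: int = 0, random_state: int = 0):
        self.sensing_rate = sensing_rate
        self.segment_length = segment_length
        self.measurement = measurement
        self.hidden_size = hidden_size
        self.leaky_slope = leaky_slope
        self.learning_rate = learning_rate
        self.high_sr_learning_rate = high_sr_learning_rate
        self.epochs = epochs
        self.batch_size = batch_size
        self.validation_fraction = validation_fraction
        self.train_compressor = train_compressor
        self.matrix_seed = matrix_seed
        self.random_state = random_state

    def _validate(self, x) -> np.ndarray:
        x = check_array(x, dtype=float, ensure_2d=True)
        if x.shape[1] != self.segment_length:
            raise ValueError(
                f"X has {x.shape[1]} features, expected segment_length={self.segment_length}")
        return x

    def fit(self, X, y=None):
        """Train compressor + decoder on (n_segments, N) normalized data."""
        x = self._validate(X)
        config = make_sensing_config(self.sensing_rate, self.segment_length)
        if self.measurement == "conv":
            op = "conv"
        else:
            op = make_fixed_matrix(self.measurement, config, seed=self.matrix_seed)
        tcfg = TrainingConfig(
            learning_rate=self.learning_rate,
            high_sr_learning_rate=self.high_sr_learning_rate,
            epochs=self.epochs, batch_size=self.batch_size,
            seed=self.random_state,
            validation_fraction=self.validation_fraction)
        compressor, network, trace = train(
            x, config, tcfg, measurement=op,
            train_compressor=self.train_compressor,
            hidden_size=self.hidden_size,
            activation=ActivationConfig(leaky_slope=self.leaky_slope))
        self.sensing_config_ = config
        self.compressor_ = compressor
        self.network_ = network
        self.trace_ = trace
        self.n_features_in_ = x.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        """Compress segments to (n_segments, M) measurements."""
        check_is_fitted(self, "network_")
        x = self._validate(X)
        if self.measurement == "conv":
            return compress_conv(x, self.compressor_)
        return compress_matrix(x, self.compressor_)

    def inverse_transform(self, Y) -> np.ndarray:
        """Reconstruct (n_segments, N) segments from measurements."""
        check_is_fitted(self, "network_")
        y = check_array(Y, dtype=float, ensure_2d=True)
        cfg = self.sensing_config_
        if y.shape[1] != cfg.measurement_length:
            raise ValueError(
                f"measurements have {y.shape[1]} values, expected M={cfg.measurement_length}")
        c = cfg.channel_count
        y3 = y.reshape(y.shape[0], -1, c).transpose(0, 2, 1)
        out, _ = _nn.decode(self.network_.to_flat(), y3,
                            self.network_.activation.leaky_slope,
                            return_cache=False)
        return out

    def score(self, X, y=None) -> float:
        """Mean reconstruction SNR (dB) over X; higher is better."""
        check_is_fitted(self, "network_")
        x = self._validate(X)
        _, mean_snr, _ = evaluate((self.compressor_, self.network_), x)
        return mean_snr


class GreedyCompressedSensing(TransformerMixin, BaseEstimator):
    """Fixed random-matrix measurement with OMP/SP greedy reconstruction.

    ``fit`` draws the seeded measuring matrix and builds the sparsifying
    basis; no training data is consumed (X may be None).
    """

    def __init__(self, sensing_rate: float = 0.5, segment_length: int = 256,
                 method: str = "omp", basis: str = "dwt-db4",
                 matrix_family: str = "gaussian", sparsity: int | None = None,
                 max_iterations: int = 50, residual_tolerance: float = 1e-10,
                 random_state: int = 0):
        self.sensing_rate = sensing_rate
        self.segment_length = segment_length
        self.method = method
        self.basis = basis
        self.matrix_family = matrix_family
        self.sparsity = sparsity
        self.max_iterations = max_iterations
        self.residual_tolerance = residual_tolerance
        self.random_state = random_state

    def fit(self, X=None, y=None):
        if self.method not in ("omp", "sp"):
            raise ValueError(f"method must be 'omp' or 'sp', got {self.method!r}")
        config = make_sensing_config(self.sensing_rate, self.segment_length)
        self.sensing_config_ = config
        self.operator_ = make_fixed_matrix(self.matrix_family, config,
                                           seed=self.random_state)
        self.basis_ = build_basis(self.basis, self.segment_length)
        k = self.sparsity if self.sparsity is not None else max(
            1, config.measurement_length // 4)
        self.greedy_config_ = GreedyConfig(
            sparsity=k, max_iterations=self.max_iterations,
            residual_tolerance=self.residual_tolerance)
        self.n_features_in_ = self.segment_length
        return self

    def _validate(self, x) -> np.ndarray:
        x = check_array(x, dtype=float, ensure_2d=True)
        if x.shape[1] != self.segment_length:
            raise ValueError(
                f"X has {x.shape[1]} features, expected segment_length={self.segment_length}")
        return x

    def transform(self, X) -> np.ndarray:
        check_is_fitted(self, "operator_")
        return compress_matrix(self._validate(X), self.operator_)

    def inverse_transform(self, Y) -> np.ndarray:
        check_is_fitted(self, "operator_")
        y = check_array(Y, dtype=float, ensure_2d=True)
        return np.stack([
            baseline_reconstruct(row, self.operator_, self.basis_,
                                 method=self.method, config=self.greedy_config_)
            for row in y])

    def score(self, X, y=None) -> float:
        """Mean reconstruction SNR (dB) over X; higher is better."""
        check_is_fitted(self, "operator_")
        x = self._validate(X)
        recon = self.inverse_transform(self.transform(x))
        _, mean_snr, _ = evaluate(lambda _: recon, x)
        return mean_snr
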