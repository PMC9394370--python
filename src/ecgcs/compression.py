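"""Measurement operators: learned convolutional stack and fixed random matrices.

The adaptive compressor is three successive 1-D convolutions, each with
kernel length 4 and stride 4 and no padding, so an N-sample segment shrinks
by a factor 4 per layer (256 -> 64 -> 16 -> 4 positions) while carrying
C = max(1, round(64 * SR)) channels; the M = 4*C output values are the
measurement.  No nonlinearity sits between the layers, so the whole stack is
an affine map y = Phi_eff @ x + offset — exactly the role of a measuring
matrix in classical compressed sensing, but with entries learned from data.

Classical baselines use a fixed M x N Gaussian (i.i.d. N(0, 1/M)) or
Bernoulli (+-1/sqrt(M)) matrix, scaled for near-isometry.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass(frozen=True)
class SensingConfig:
    """Sensing rate bookkeeping for the convolutional compressor.

    ``channel_count`` C = max(1, round(64 * SR)); the measurement has
    M = 4*C values, so the realized rate 4C/N can differ slightly from the
    requested one (by at most 1/128 for N = 256).
    """

    sensing_rate: float
    segment_length: int = 256
    channel_count: int = 0
    measurement_length: int = 0

    @property
    def realized_sensing_rate(self) -> float:
        return self.measurement_length / self.segment_length


def make_sensing_config(sensing_rate: float, segment_length: int = 256) -> SensingConfig:
    """Derive (C, M) from a requested sensing rate.

    ``segment_length`` must be divisible by 64 so three stride-4 layers land
    on an integer length.
    """
    if not (0 < sensing_rate <= 1):
        raise ValueError(f"sensing_rate must be in (0, 1], got {sensing_rate}")
    if segment_length % 64 != 0:
        raise ValueError(f"segment_length must be divisible by 64, got {segment_length}")
    # C = 64 * SR rounded to the nearest filter count, never below 1; the
    # measurement then has N/64 coarse positions of C channels each.
    c = max(1, int(round(64 * sensing_rate)))
    m = (segment_length // 64) * c
    return SensingConfig(sensing_rate=sensing_rate, segment_length=segment_length,
                         channel_count=c, measurement_length=m)


@dataclass
class ConvCompressorParams:
    """Weights/biases of the three stride-4 measurement convolutions.

    ``weights[i]`` has shape (C_out, C_in, 4) with C_in = 1 for the first
    layer and C for the later two; ``biases[i]`` has shape (C,).
    """

    weights: list
    biases: list
    config: SensingConfig

    def validate(self) -> None:
        c = self.config.channel_count
        expected_in = (1, c, c)
        if len(self.weights) != 3 or len(self.biases) != 3:
            raise ValueError("compressor needs exactly 3 conv layers")
        for i, (w, b) in enumerate(zip(self.weights, self.biases)):
            if w.shape != (c, expected_in[i], 4):
                raise ValueError(
                    f"layer {i}: weight shape {w.shape} != {(c, expected_in[i], 4)}")
            if b.shape != (c,):
                raise ValueError(f"layer {i}: bias shape {b.shape} != {(c,)}")


def init_conv_compressor(config: SensingConfig, seed: int = 0) -> ConvCompressorParams:
    """Glorot-uniform initialized compressor with zero biases."""
    rng = np.random.default_rng(seed)
    c = config.channel_count
    weights, biases = [], []
    for c_in in (1, c, c):
        limit = np.sqrt(6.0 / (c_in * 4 + c * 4))
        weights.append(rng.uniform(-limit, limit, size=(c, c_in, 4)))
        biases.append(np.zeros(c))
    return ConvCompressorParams(weights=weights, biases=biases, config=config)


def _conv_stride4(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Valid stride-4 conv: x (B, C_in, L) -> (B, C_out, L//4)."""
    bsz, c_in, length = x.shape
    if length % 4 != 0:
        raise ValueError(f"length {length} not divisible by 4")
    xr = x.reshape(bsz, c_in, length // 4, 4)
    return np.einsum("bcpk,ock->bop", xr, w, optimize=True) + b[None, :, None]


def compress_conv(segment, params: ConvCompressorParams) -> np.ndarray:
    """Apply the three-layer convolutional measurement operator.

    ``segment`` is an N-vector (or an object with ``.samples``); the return
    value is the flattened M-vector measurement, laid out position-major
    (value ``C*p + c`` is channel ``c`` at coarse position ``p``).
    """
    x = np.asarray(getattr(segment, "samples", segment), dtype=float)
    squeeze = x.ndim == 1
    x2 = np.atleast_2d(x)
    n = params.config.segment_length
    if x2.shape[1] != n:
        raise ValueError(f"segment length {x2.shape[1]} != configured N={n}")
    params.validate()
    h = x2[:, None, :]
    for w, b in zip(params.weights, params.biases):
        h = _conv_stride4(h, w, b)
    meas = np.transpose(h, (0, 2, 1)).reshape(x2.shape[0], -1)  # (B, 4*C)
    return meas[0] if squeeze else meas


def extract_effective_matrix(params: ConvCompressorParams) -> tuple[np.ndarray, np.ndarray]:
    """Recover (Phi_eff, offset) with compress_conv(x) == Phi_eff @ x + offset.

    The affine map is probed with the canonical basis: offset = y(0) and
    column j of Phi_eff is y(e_j) - y(0).
    """
    n = params.config.segment_length
    probes = np.vstack([np.zeros(n), np.eye(n)])
    ys = compress_conv(probes, params)
    offset = ys[0]
    phi_eff = (ys[1:] - offset).T  # (M, N)
    return phi_eff, offset


@dataclass(frozen=True)
class Measurement:
    """An M-value measurement with its sensing config and operator provenance.

    ``values`` is laid out position-major (channel c of coarse position p at
    flat index ``C*p + c``).  The compression functions return bare arrays
    for batch ergonomics; :func:`measure` wraps a single segment's result in
    this container.
    """

    values: np.ndarray
    config: SensingConfig
    operator_family: str = "conv"

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float).ravel())
        if self.values.size != self.config.measurement_length:
            raise ValueError(
                f"measurement of {self.values.size} values != M={self.config.measurement_length}")

    def __len__(self) -> int:
        return self.values.size


def measure(segment, operator) -> Measurement:
    """Compress one segment and wrap the result with provenance."""
    if isinstance(operator, ConvCompressorParams):
        return Measurement(compress_conv(segment, operator), operator.config, "conv")
    if isinstance(operator, FixedMatrixOperator):
        m, n = operator.shape
        cfg = SensingConfig(sensing_rate=m / n, segment_length=n,
                            channel_count=m // (n // 64), measurement_length=m)
        return Measurement(compress_matrix(segment, operator), cfg, operator.family)
    raise TypeError(f"unsupported operator {type(operator).__name__}")


@dataclass(frozen=True)
class FixedMatrixOperator:
    """A fixed M x N random measuring matrix (Gaussian or Bernoulli)."""

    matrix: np.ndarray
    family: str
    seed: int

    @property
    def shape(self) -> tuple[int, int]:
        return self.matrix.shape


def make_fixed_matrix(family: str, sensing_config: SensingConfig, seed: int = 0) -> FixedMatrixOperator:
    """Draw a seeded random measuring matrix.

    ``gaussian``: i.i.d. N(0, 1/M); ``bernoulli``: equiprobable +-1/sqrt(M).
    Both scalings make E||Phi x||^2 = ||x||^2 (near-isometry in expectation).
    """
    m, n = sensing_config.measurement_length, sensing_config.segment_length
    rng = np.random.default_rng(seed)
    if family == "gaussian":
        mat = rng.standard_normal((m, n)) / np.sqrt(m)
    elif family == "bernoulli":
        mat = rng.choice([-1.0, 1.0], size=(m, n)) / np.sqrt(m)
    else:
        raise ValueError(f"unknown matrix family {family!r} (use 'gaussian' or 'bernoulli')")
    return FixedMatrixOperator(matrix=mat, family=family, seed=seed)


def compress_matrix(segment, operator: FixedMatrixOperator) -> np.ndarray:
    """Classical linear measurement y = Phi @ x (row batches allowed)."""
    x = np.asarray(getattr(segment, "samples", segment), dtype=float)
    squeeze = x.ndim == 1
    x2 = np.atleast_2d(x)
    m, n = operator.shape
    if x2.shape[1] != n:
        raise ValueError(f"segment length {x2.shape[1]} != matrix N={n}")
    y = x2 @ operator.matrix.T
    return y[0] if squeeze else y


def rip_ratio(operator, x) -> float:
    """Diagnostic isometry ratio ||Phi x||^2 / ||x||^2.

    ``operator`` may be a FixedMatrixOperator, a raw matrix, or a
    ConvCompressorParams (whose linear part is used).  Values concentrated
    near 1 over random inputs indicate RIP-like behaviour.
    """
    xv = np.asarray(getattr(x, "samples", x), dtype=float).ravel()
    energy = float(np.dot(xv, xv))
    if energy == 0.0:
        raise ValueError("RIP ratio undefined for x = 0")
    if isinstance(operator, ConvCompressorParams):
        phi, _ = extract_effective_matrix(operator)
    elif isinstance(operator, FixedMatrixOperator):
        phi = operator.matrix
    else:
        phi = np.asarray(operator, dtype=float)
    y = phi @ xv
    return float(np.dot(y, y) / energy)
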