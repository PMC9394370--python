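"""Two-stage reconstruction network: initial expansion, Inception block, LSTM.

The decoder maps an M-value measurement back to a 256-sample segment:

1. *Initial reconstruction* — a 1x1 convolution lifts the C measurement
   channels at each of the N/64 coarse positions to 64 channels
   (LeakyReLU), and a position-major reshape lays them out as an N-sample
   vector.
2. *Final reconstruction* — an entry 1x11 convolution produces 16 feature
   channels; a modified Inception block runs four parallel residual lines
   with kernel lengths 7/9/11/13 (two same-padded convolutions with
   LeakyReLU plus an additive skip per line) and concatenates them into 64
   channels; a single-layer unidirectional LSTM (hidden size 64, zero
   initial state) consumes the 64-channel feature sequence one time step
   per sample, and a per-step linear head projects each hidden state to one
   output sample.  No activation follows the head.

The dataclasses here are the user-facing parameter containers; the batched
training path in :mod:`ecgcs._nn` uses the same math over a flat dict, and
``to_flat``/``network_from_flat`` convert losslessly between the two.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from . import _nn
from .compression import ConvCompressorParams, FixedMatrixOperator, SensingConfig

SEGMENT_LENGTH = 256


@dataclass(frozen=True)
class ActivationConfig:
    """LeakyReLU slope for negative inputs (1/a with a in (1, inf))."""

    leaky_slope: float = 0.01

    def __post_init__(self) -> None:
        if not (0.0 < self.leaky_slope < 1.0):
            raise ValueError(f"leaky_slope must be in (0, 1), got {self.leaky_slope}")


@dataclass
class InitialReconParams:
    """1x1 conv lifting C measurement channels to 64."""

    weight: np.ndarray  # (64, C)
    bias: np.ndarray    # (64,)

    @property
    def channel_count(self) -> int:
        return self.weight.shape[1]


@dataclass
class InceptionLineParams:
    """One residual line: two same-padded 16->16 convs of a given kernel."""

    kernel_length: int
    w1: np.ndarray  # (16, 16, k)
    b1: np.ndarray
    w2: np.ndarray
    b2: np.ndarray


@dataclass
class LstmParams:
    """Gate weights acting on the concatenation [h_{t-1}, x_t], plus head."""

    W_f: np.ndarray
    W_i: np.ndarray
    W_c: np.ndarray
    W_o: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_c: np.ndarray
    b_o: np.ndarray
    proj_w: np.ndarray  # (H,)
    proj_b: float

    @property
    def hidden_size(self) -> int:
        return self.W_f.shape[0]


@dataclass
class NetworkParams:
    """All decoder weights: initial recon + entry conv + Inception + LSTM."""

    initial: InitialReconParams
    entry_w: np.ndarray  # (16, 1, 11)
    entry_b: np.ndarray
    lines: list          # 4 x InceptionLineParams
    lstm: LstmParams
    activation: ActivationConfig = field(default_factory=ActivationConfig)

    def to_flat(self) -> dict:
        flat = {
            "init.w": self.initial.weight, "init.b": self.initial.bias,
            "entry.w": self.entry_w, "entry.b": self.entry_b,
            "lstm.W": np.concatenate(
                [self.lstm.W_f, self.lstm.W_i, self.lstm.W_c, self.lstm.W_o]),
            "lstm.b": np.concatenate(
                [self.lstm.b_f, self.lstm.b_i, self.lstm.b_c, self.lstm.b_o]),
            "proj.w": self.lstm.proj_w,
            "proj.b": np.asarray(self.lstm.proj_b, dtype=float),
        }
        for n, line in enumerate(self.lines):
            flat[f"inc{n}.w1"] = line.w1
            flat[f"inc{n}.b1"] = line.b1
            flat[f"inc{n}.w2"] = line.w2
            flat[f"inc{n}.b2"] = line.b2
        return flat


def network_from_flat(flat: dict, activation: ActivationConfig | None = None) -> NetworkParams:
    """Rebuild the dataclass view from a flat parameter dict."""
    act = activation or ActivationConfig()
    hidden = flat["lstm.W"].shape[0] // 4
    w, b = flat["lstm.W"], flat["lstm.b"]
    lstm = LstmParams(
        W_f=w[:hidden], W_i=w[hidden:2 * hidden],
        W_c=w[2 * hidden:3 * hidden], W_o=w[3 * hidden:],
        b_f=b[:hidden], b_i=b[hidden:2 * hidden],
        b_c=b[2 * hidden:3 * hidden], b_o=b[3 * hidden:],
        proj_w=flat["proj.w"], proj_b=float(flat["proj.b"]),
    )
    lines = [
        InceptionLineParams(
            kernel_length=flat[f"inc{n}.w1"].shape[2],
            w1=flat[f"inc{n}.w1"], b1=flat[f"inc{n}.b1"],
            w2=flat[f"inc{n}.w2"], b2=flat[f"inc{n}.b2"])
        for n in range(4)
    ]
    return NetworkParams(
        initial=InitialReconParams(weight=flat["init.w"], bias=flat["init.b"]),
        entry_w=flat["entry.w"], entry_b=flat["entry.b"],
        lines=lines, lstm=lstm, activation=act,
    )


def init_network(channel_count: int, hidden: int = 64, seed: int = 0,
                 activation: ActivationConfig | None = None) -> NetworkParams:
    """Glorot-initialized decoder (biases zero), seeded."""
    flat = _nn.init_params(channel_count, hidden=hidden, seed=seed,
                           include_compressor=False)
    return network_from_flat(flat, activation)


# ---------------------------------------------------------------------------
# stage operations
# ---------------------------------------------------------------------------

def leaky_relu(x, config: ActivationConfig = ActivationConfig()):
    """y = x for x >= 0, y = leaky_slope * x otherwise (elementwise)."""
    return _nn.leaky_relu(np.asarray(x, dtype=float), config.leaky_slope)


def _measurement_grid(measurement, channel_count: int) -> np.ndarray:
    """Coerce a measurement to (C, P): accepts flat position-major or 2-D."""
    y = np.asarray(getattr(measurement, "values", measurement), dtype=float)
    if y.ndim == 1:
        if y.size % channel_count != 0:
            raise ValueError(
                f"measurement of {y.size} values not divisible by C={channel_count}")
        return y.reshape(-1, channel_count).T
    if y.ndim == 2 and y.shape[0] == channel_count:
        return y
    raise ValueError(f"cannot interpret measurement of shape {y.shape} with C={channel_count}")


def initial_reconstruct(measurement, params: InitialReconParams,
                        act: ActivationConfig = ActivationConfig()) -> np.ndarray:
    """1x1 conv (C -> 64) + LeakyReLU + position-major reshape to N samples.

    Output index ``64*p + c`` holds channel ``c`` of coarse position ``p``.
    """
    c = params.channel_count
    y3 = _measurement_grid(measurement, c)          # (C, P)
    z = params.weight @ y3 + params.bias[:, None]   # (64, P)
    a = _nn.leaky_relu(z, act.leaky_slope)
    return a.T.reshape(-1)                          # (64*P,)


def inception_line(features: np.ndarray, line: InceptionLineParams,
                   act: ActivationConfig = ActivationConfig()) -> np.ndarray:
    """x_out = LeakyReLU(f2(LeakyReLU(f1(x)))) + x on a (16, L) feature map."""
    f = np.asarray(features, dtype=float)
    if f.ndim != 2 or f.shape[0] != _nn.LINE_CHANNELS:
        raise ValueError(f"expected (16, L) features, got {f.shape}")
    s = act.leaky_slope
    a1 = _nn.leaky_relu(_nn.conv_same(f[None], line.w1, line.b1), s)
    a2 = _nn.leaky_relu(_nn.conv_same(a1, line.w2, line.b2), s)
    return a2[0] + f


def inception_block(features: np.ndarray, lines,
                    act: ActivationConfig = ActivationConfig()) -> np.ndarray:
    """Concatenate the four residual lines channel-wise into (64, L)."""
    if len(lines) != 4:
        raise ValueError(f"inception block needs 4 lines, got {len(lines)}")
    outs = [inception_line(features, line, act) for line in lines]
    return np.concatenate(outs, axis=0)


def lstm_step(x_t: np.ndarray, h_prev: np.ndarray, c_prev: np.ndarray,
              params: LstmParams) -> tuple[np.ndarray, np.ndarray]:
    """One LSTM cell update on the concatenated input [h_{t-1}, x_t].

    f = sig(W_f.[h,x]+b_f); i likewise; c~ = tanh(W_c.[h,x]+b_c);
    c = f*c_prev + i*c~; o = sig(W_o.[h,x]+b_o); h = o*tanh(c).
    """
    x_t = np.asarray(x_t, dtype=float)
    h_prev = np.asarray(h_prev, dtype=float)
    c_prev = np.asarray(c_prev, dtype=float)
    hx = np.concatenate([h_prev, x_t])
    if params.W_f.shape[1] != hx.size:
        raise ValueError(
            f"gate matrices expect input of {params.W_f.shape[1]}, got {hx.size}")
    f = expit(params.W_f @ hx + params.b_f)
    i = expit(params.W_i @ hx + params.b_i)
    g = np.tanh(params.W_c @ hx + params.b_c)
    c = f * c_prev + i * g
    o = expit(params.W_o @ hx + params.b_o)
    h = o * np.tanh(c)
    return h, c


def final_reconstruct(initial: np.ndarray, params: NetworkParams) -> np.ndarray:
    """Entry conv -> Inception block -> LSTM over time -> linear head."""
    x = np.asarray(initial, dtype=float).ravel()
    act = params.activation
    e = _nn.leaky_relu(
        _nn.conv_same(x[None, None, :], params.entry_w, params.entry_b),
        act.leaky_slope)[0]                          # (16, N)
    feat = inception_block(e, params.lines, act)     # (64, N)
    hidden = params.lstm.hidden_size
    h = np.zeros(hidden)
    c = np.zeros(hidden)
    out = np.empty(x.size)
    for t in range(x.size):
        h, c = lstm_step(feat[:, t], h, c, params.lstm)
        out[t] = float(h @ params.lstm.proj_w) + params.lstm.proj_b
    return out


def reconstruct(measurement, network: NetworkParams) -> np.ndarray:
    """Full decode: initial then final reconstruction (normalized scale)."""
    return final_reconstruct(
        initial_reconstruct(measurement, network.initial, network.activation),
        network)


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, network: NetworkParams, sensing_config: SensingConfig,
                    compressor: ConvCompressorParams | FixedMatrixOperator | None = None) -> None:
    """Write every tensor plus configs to a single ``.npz`` container."""
    arrays = {f"net/{k}": v for k, v in network.to_flat().items()}
    meta = {
        "sensing_rate": sensing_config.sensing_rate,
        "segment_length": sensing_config.segment_length,
        "channel_count": sensing_config.channel_count,
        "measurement_length": sensing_config.measurement_length,
        "leaky_slope": network.activation.leaky_slope,
        "compressor": None,
    }
    if isinstance(compressor, ConvCompressorParams):
        meta["compressor"] = "conv"
        for i in range(3):
            arrays[f"comp/w{i}"] = compressor.weights[i]
            arrays[f"comp/b{i}"] = compressor.biases[i]
    elif isinstance(compressor, FixedMatrixOperator):
        meta["compressor"] = compressor.family
        meta["matrix_seed"] = compressor.seed
        arrays["comp/matrix"] = compressor.matrix
    arrays["meta"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path):
    """Inverse of :func:`save_checkpoint`.

    Returns ``(network, sensing_config, compressor)`` with ``compressor``
    None, a ConvCompressorParams, or a FixedMatrixOperator.
    """
    with np.load(path) as data:
        arrays = {k: data[k] for k in data.files}
    meta = json.loads(bytes(arrays.pop("meta")).decode())
    config = SensingConfig(
        sensing_rate=meta["sensing_rate"], segment_length=meta["segment_length"],
        channel_count=meta["channel_count"], measurement_length=meta["measurement_length"])
    act = ActivationConfig(leaky_slope=meta["leaky_slope"])
    flat = {k[len("net/"):]: v for k, v in arrays.items() if k.startswith("net/")}
    network = network_from_flat(flat, act)
    compressor = None
    if meta["compressor"] == "conv":
        compressor = ConvCompressorParams(
            weights=[arrays[f"comp/w{i}"] for i in range(3)],
            biases=[arrays[f"comp/b{i}"] for i in range(3)],
            config=config)
    elif meta["compressor"] in ("gaussian", "bernoulli"):
        compressor = FixedMatrixOperator(
            matrix=arrays["comp/matrix"], family=meta["compressor"],
            seed=int(meta.get("matrix_seed", 0)))
    return network, config, compressor
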