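"""End-to-end training of compressor + decoder with MSE loss and Adam.

The optimization protocol mirrors common practice for compressive
autoencoders on ECG: Adam with initial learning rate 5e-4 (moment decays
0.9/0.999), batch size 32, a fixed number of epochs, no schedule, no weight
decay, no clipping.  The loss is the squared Euclidean error per segment
averaged over the batch.  An optional lower learning rate can be switched in
for high sensing rates (>= 0.4), where the larger measurement makes the
loss surface steeper.

Everything is deterministic under the config seed: parameter init, the
train/validation split, and the per-epoch shuffle all derive from it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _nn
from .compression import (ConvCompressorParams, FixedMatrixOperator,
                          SensingConfig, init_conv_compressor)
from .metrics import EvalResult, aggregate, evaluate_pair
from .reconstruction_net import (ActivationConfig, NetworkParams,
                                 network_from_flat)

HIGH_SR_THRESHOLD = 0.4


@dataclass(frozen=True)
class TrainingConfig:
    """Optimizer protocol: Adam(lr, 0.9, 0.999), fixed epochs, batch 32."""

    learning_rate: float = 5e-4
    first_moment_decay: float = 0.9
    second_moment_decay: float = 0.999
    epochs: int = 200
    batch_size: int = 32
    seed: int = 0
    high_sr_learning_rate: float | None = None
    validation_fraction: float = 0.2
    loss_reduction: str = "sum"  # per-segment 'sum' of squares, or 'mean'

    def __post_init__(self) -> None:
        if self.learning_rate <= 0 or self.batch_size < 1 or self.epochs < 1:
            raise ValueError("learning_rate, batch_size and epochs must be positive")
        if not (0.0 <= self.validation_fraction < 1.0):
            raise ValueError("validation_fraction must be in [0, 1)")
        if self.loss_reduction not in ("sum", "mean"):
            raise ValueError("loss_reduction must be 'sum' or 'mean'")

    def effective_learning_rate(self, sensing_rate: float) -> float:
        if self.high_sr_learning_rate is not None and sensing_rate >= HIGH_SR_THRESHOLD:
            return self.high_sr_learning_rate
        return self.learning_rate


@dataclass
class TrainingTrace:
    """Per-epoch mean loss and held-out PRD/SNR."""

    epochs: list = field(default_factory=list)  # dicts: epoch, loss, val_prd, val_snr

    def append(self, epoch: int, loss: float, val_prd: float | None,
               val_snr: float | None) -> None:
        self.epochs.append({"epoch": epoch, "loss": loss,
                            "val_prd": val_prd, "val_snr": val_snr})

    @property
    def losses(self) -> list:
        return [e["loss"] for e in self.epochs]

    def to_rows(self) -> list:
        header = ["epoch", "loss", "val_prd", "val_snr"]
        rows = [header]
        for e in self.epochs:
            rows.append([e["epoch"], e["loss"], e["val_prd"], e["val_snr"]])
        return rows


def mse_loss(reconstructions, targets, reduction: str = "sum") -> float:
    """(1/n) sum_i ||recon_i - target_i||_2^2 over the n segments.

    ``reduction='mean'`` divides additionally by the segment length (a pure
    gradient rescaling, provided for convenience).
    """
    r = np.atleast_2d(np.asarray(reconstructions, dtype=float))
    t = np.atleast_2d(np.asarray(targets, dtype=float))
    if r.shape != t.shape:
        raise ValueError(f"shape mismatch: {r.shape} vs {t.shape}")
    per_segment = np.sum((r - t) ** 2, axis=1)
    if reduction == "mean":
        per_segment = per_segment / r.shape[1]
    return float(np.mean(per_segment))


def _as_matrix(dataset) -> np.ndarray:
    if isinstance(dataset, np.ndarray):
        x = dataset
    else:
        x = np.stack([np.asarray(getattr(s, "samples", s), dtype=float) for s in dataset])
    x = np.atleast_2d(np.asarray(x, dtype=float))
    if x.size == 0:
        raise ValueError("empty dataset")
    return x


def model_forward(compressor, network: NetworkParams, x: np.ndarray,
                  batch_size: int = 256) -> np.ndarray:
    """Compress and reconstruct rows of ``x`` with the trained pair."""
    x = _as_matrix(x)
    flat = dict(network.to_flat())
    fixed = None
    if isinstance(compressor, FixedMatrixOperator):
        fixed = compressor.matrix
        c = network.initial.channel_count
    elif isinstance(compressor, ConvCompressorParams):
        for i in range(3):
            flat[f"comp.w{i}"] = compressor.weights[i]
            flat[f"comp.b{i}"] = compressor.biases[i]
        c = compressor.config.channel_count
    else:
        raise TypeError(f"unsupported compressor {type(compressor).__name__}")
    outs = []
    for start in range(0, x.shape[0], batch_size):
        out, _ = _nn.forward(flat, x[start:start + batch_size], c,
                             network.activation.leaky_slope,
                             fixed_matrix=fixed, return_cache=False)
        outs.append(out)
    return np.vstack(outs)


def train(dataset, sensing_config: SensingConfig, training_config: TrainingConfig,
          measurement: str | FixedMatrixOperator = "conv",
          train_compressor: bool = True,
          hidden_size: int = 64,
          activation: ActivationConfig | None = None,
          track_validation: bool = True):
    """Jointly optimize compressor and decoder on normalized segments.

    ``dataset`` is an (n, N) array (or list of segments) on the [0, 1]
    normalized scale.  ``measurement`` selects the learned convolutional
    compressor (``'conv'``) or a fixed random-matrix operator, in which case
    only the decoder trains (the classical-matrix comparison arm).

    Returns ``(compressor, network, trace)`` where ``compressor`` is
    ConvCompressorParams or the FixedMatrixOperator passed in.
    """
    x = _as_matrix(dataset)
    n_total, n = x.shape
    if n != sensing_config.segment_length:
        raise ValueError(f"segments of length {n} != configured N={sensing_config.segment_length}")
    act = activation or ActivationConfig()
    cfg = training_config
    rng = np.random.default_rng(cfg.seed)

    # 80/20 (by default) seeded split
    perm = rng.permutation(n_total)
    n_val = int(round(cfg.validation_fraction * n_total))
    val_idx, train_idx = perm[:n_val], perm[n_val:]
    if train_idx.size == 0:
        raise ValueError("no training segments left after the validation split")
    x_train, x_val = x[train_idx], x[val_idx]

    c = sensing_config.channel_count
    learn_comp = measurement == "conv"
    fixed = None
    if isinstance(measurement, FixedMatrixOperator):
        fixed = measurement.matrix
        if fixed.shape != (sensing_config.measurement_length, n):
            raise ValueError(f"fixed matrix shape {fixed.shape} inconsistent with config")
    elif measurement != "conv":
        raise ValueError(f"measurement must be 'conv' or a FixedMatrixOperator, got {measurement!r}")

    params = _nn.init_params(c, hidden=hidden_size, seed=cfg.seed,
                             include_compressor=learn_comp)
    frozen = set()
    if learn_comp and not train_compressor:
        frozen = {k for k in params if k.startswith("comp.")}

    opt = _nn.Adam(params,
                   learning_rate=cfg.effective_learning_rate(sensing_config.sensing_rate),
                   beta1=cfg.first_moment_decay, beta2=cfg.second_moment_decay)
    trace = TrainingTrace()
    n_train = x_train.shape[0]

    for epoch in range(1, cfg.epochs + 1):
        order = rng.permutation(n_train)
        epoch_losses = []
        for start in range(0, n_train, cfg.batch_size):
            batch = x_train[order[start:start + cfg.batch_size]]
            out, cache = _nn.forward(params, batch, c, act.leaky_slope,
                                     fixed_matrix=fixed)
            diff = out - batch
            loss = float(np.mean(np.sum(diff ** 2, axis=1)))
            if cfg.loss_reduction == "mean":
                loss /= n
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch} (step {opt.t + 1}); "
                    "lower the learning rate")
            dout = 2.0 * diff / batch.shape[0]
            if cfg.loss_reduction == "mean":
                dout /= n
            grads = _nn.backward(params, cache, dout)
            for k in frozen:
                grads.pop(k, None)
            opt.step(params, grads)
            epoch_losses.append(loss)
        val_prd = val_snr = None
        if track_validation and x_val.shape[0] > 0:
            out_val, _ = _nn.forward(params, x_val, c, act.leaky_slope,
                                     fixed_matrix=fixed, return_cache=False)
            results = [evaluate_pair(t, r) for t, r in zip(x_val, out_val)]
            val_prd, val_snr = aggregate(results)
        trace.append(epoch, float(np.mean(epoch_losses)), val_prd, val_snr)

    network = network_from_flat(params, act)
    if learn_comp:
        compressor = ConvCompressorParams(
            weights=[params[f"comp.w{i}"] for i in range(3)],
            biases=[params[f"comp.b{i}"] for i in range(3)],
            config=sensing_config)
    else:
        compressor = measurement
    return compressor, network, trace


def evaluate(model, segments, scale: str = "normalized"):
    """Mean PRD/SNR of a model over test segments.

    ``model`` is either a ``(compressor, network)`` pair or any callable
    mapping an (n, N) array to reconstructions.  PRD and SNR are computed
    per segment and averaged independently.  Returns
    ``(mean_prd, mean_snr, per_segment_results)``.
    """
    x = _as_matrix(segments)
    if callable(model):
        recon = np.atleast_2d(np.asarray(model(x), dtype=float))
    else:
        compressor, network = model
        recon = model_forward(compressor, network, x)
    if recon.shape != x.shape:
        raise ValueError(f"model returned shape {recon.shape}, expected {x.shape}")
    results = [evaluate_pair(t, r, scale=scale) for t, r in zip(x, recon)]
    mean_prd, mean_snr = aggregate(results)
    return mean_prd, mean_snr, results
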