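"""Canned end-to-end experiment: the synthetic training/evaluation protocol.

This module fixes the package's reference study conditions on synthetic ECG:
1,000 training segments and 250 held-out test segments of 256 samples at
360 Hz (72 +- 3 bpm, mild baseline wander), Adam at learning rate 5e-4 with
batch size 32 for 15 epochs.  Three arms are trained and evaluated on the
normalized scale:

* the learned convolutional compressor at SR = 0.5 (jointly trained),
* the same at SR = 0.05 (the low-rate end of the sensing-rate sweep),
* a fixed Gaussian random matrix at SR = 0.5 with decoder-only training.

The SR = 0.5 checkpoint is additionally evaluated on noisy copies of the
test set (additive Gaussian noise at 32 dB and 24 dB SNR), and greedy
OMP/SP baselines (Gaussian matrix, db4 wavelet basis) are run on the same
test segments.  All randomness derives from one seed.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np

from .baselines import GreedyConfig, baseline_reconstruct, build_basis
from .compression import make_fixed_matrix, make_sensing_config
from .preprocess import normalize_batch
from .synthetic_data import NoiseSpec, add_noise, make_dataset
from .training import TrainingConfig, evaluate, train

DEFAULT_N_TRAIN = 1000
DEFAULT_N_TEST = 250
DEFAULT_EPOCHS = 15
NOISE_SNRS_DB = (32.0, 24.0)


def make_protocol_data(seed: int, n_train: int = DEFAULT_N_TRAIN,
                       n_test: int = DEFAULT_N_TEST):
    """Training and test sets: raw segments plus normalized matrices."""
    train_segs = make_dataset(n_train, seed=seed)
    test_segs = make_dataset(n_test, seed=seed + 7919)
    x_train, _ = normalize_batch(train_segs)
    x_test, _ = normalize_batch(test_segs)
    return train_segs, test_segs, x_train, x_test


def train_arm(x_train: np.ndarray, sensing_rate: float, seed: int,
              measurement: str = "conv", epochs: int = DEFAULT_EPOCHS,
              track_validation: bool = False):
    """Train one protocol arm; returns (compressor, network, trace)."""
    cfg = make_sensing_config(sensing_rate, x_train.shape[1])
    if measurement == "conv":
        op = "conv"
    else:
        op = make_fixed_matrix(measurement, cfg, seed=seed)
    tcfg = TrainingConfig(epochs=epochs, seed=seed)
    return train(x_train, cfg, tcfg, measurement=op,
                 track_validation=track_validation)


def noisy_normalized_test(test_segs, snr_db: float, seed: int) -> np.ndarray:
    """Noise the raw test segments at an exact SNR, then normalize."""
    noisy = [
        add_noise(s, NoiseSpec(snr_db, seed=(seed + 104729 * i) % (2**31 - 1)))
        for i, s in enumerate(test_segs)
    ]
    x, _ = normalize_batch(noisy)
    return x


def greedy_baseline_eval(x_test: np.ndarray, sensing_rate: float, seed: int,
                         method: str) -> tuple[float, float]:
    """Mean PRD/SNR of OMP or SP (Gaussian matrix, db4 basis) on the test set."""
    n = x_test.shape[1]
    cfg = make_sensing_config(sensing_rate, n)
    phi = make_fixed_matrix("gaussian", cfg, seed=seed)
    psi = build_basis("dwt-db4", n)
    gcfg = GreedyConfig(sparsity=max(1, cfg.measurement_length // 4))
    recon = np.stack([
        baseline_reconstruct(phi.matrix @ row, phi, psi, method=method, config=gcfg)
        for row in x_test])
    mean_prd, mean_snr, _ = evaluate(lambda _: recon, x_test)
    return mean_prd, mean_snr


def run_smoke_protocol(seed: int = 1, n_train: int = DEFAULT_N_TRAIN,
                       n_test: int = DEFAULT_N_TEST,
                       epochs: int = DEFAULT_EPOCHS,
                       include_greedy: bool = True) -> dict:
    """Run the full protocol; returns a nested dict of computed quantities.

    Keys: ``conv_sr0.5``, ``conv_sr0.05``, ``gaussian_sr0.5`` (each with
    ``prd``, ``snr``, ``first_loss``, ``last_loss``), ``noise`` (clean and
    per-SNR PRD/SNR of the SR = 0.5 model), and optionally ``omp``/``sp``.
    """
    _, test_segs, x_train, x_test = make_protocol_data(seed, n_train, n_test)
    out: dict = {"n_train": x_train.shape[0], "n_test": x_test.shape[0]}

    arms = {
        "conv_sr0.5": (0.5, "conv"),
        "conv_sr0.05": (0.05, "conv"),
        "gaussian_sr0.5": (0.5, "gaussian"),
    }
    models = {}
    for name, (sr, meas) in arms.items():
        comp, net, trace = train_arm(x_train, sr, seed, measurement=meas,
                                     epochs=epochs)
        prd_m, snr_m, _ = evaluate((comp, net), x_test)
        models[name] = (comp, net)
        out[name] = {"prd": prd_m, "snr": snr_m,
                     "first_loss": trace.losses[0],
                     "last_loss": trace.losses[-1]}

    ref = models["conv_sr0.5"]
    noise = {"clean": {"prd": out["conv_sr0.5"]["prd"],
                       "snr": out["conv_sr0.5"]["snr"]}}
    for snr_db in NOISE_SNRS_DB:
        x_noisy = noisy_normalized_test(test_segs, snr_db, seed)
        prd_m, snr_m, _ = evaluate(ref, x_noisy)
        noise[f"{snr_db:g}dB"] = {"prd": prd_m, "snr": snr_m}
    out["noise"] = noise

    if include_greedy:
        for method in ("omp", "sp"):
            prd_m, snr_m = greedy_baseline_eval(x_test, 0.5, seed, method)
            out[method] = {"prd": prd_m, "snr": snr_m}
    return out
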