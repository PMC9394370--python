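"""Synthetic single-lead ECG for training and testing without PhysioNet data.

The generator emulates the quasi-periodic P-QRS-T morphology of a surface ECG
as a sum of five Gaussian bumps per beat, placed at fixed time offsets around
each R peak, with i.i.d. normally distributed RR intervals (truncated to stay
positive), mild per-beat amplitude jitter, and an optional low-frequency
baseline-wander sinusoid.  This is a deliberately simple stand-in for real
recordings: it reproduces the features the compressive-sensing pipeline
exercises (sharp QRS transients, smooth P/T waves, beat-to-beat variability)
but makes no claim of physiological fidelity.

Additive Gaussian measurement noise is injected at an exact per-realization
SNR: the noise vector is rescaled so that ``10*log10(||x||^2/||n||^2)``
equals the requested dB figure for the realized draw, not merely in
expectation.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .preprocess import SignalSegment

# Per-beat wave layout: time offset of each wave centre relative to the R
# peak (seconds) and default widths/amplitudes (dimensionless mV-like units).
WAVE_ORDER = ("P", "Q", "R", "S", "T")
WAVE_OFFSETS_S = {"P": -0.20, "Q": -0.035, "R": 0.0, "S": 0.035, "T": 0.30}
DEFAULT_WAVE_AMPLITUDES = {"P": 0.15, "Q": -0.12, "R": 1.0, "S": -0.25, "T": 0.35}
DEFAULT_WAVE_WIDTHS_S = {"P": 0.045, "Q": 0.012, "R": 0.022, "S": 0.015, "T": 0.11}


@dataclass(frozen=True)
class SyntheticEcgSpec:
    """Parameters of the Gaussian-bump ECG model.

    ``sampling_rate`` defaults to 360 samples/s (the MIT-BIH convention, so a
    256-sample window covers about 0.71 s); ``heart_rate_mean``/``sd`` control
    the RR-interval distribution in beats/min.
    """

    sampling_rate: float = 360.0
    duration: float = 10.0
    heart_rate_mean: float = 72.0
    heart_rate_sd: float = 3.0
    wave_amplitudes: dict = field(default_factory=lambda: dict(DEFAULT_WAVE_AMPLITUDES))
    wave_widths: dict = field(default_factory=lambda: dict(DEFAULT_WAVE_WIDTHS_S))
    baseline_wander_amplitude: float = 0.05
    amplitude_jitter: float = 0.05
    seed: int = 0

    def validate(self) -> None:
        if not (self.sampling_rate > 0):
            raise ValueError(f"sampling_rate must be > 0, got {self.sampling_rate}")
        if not (self.duration > 0):
            raise ValueError(f"duration must be > 0, got {self.duration}")
        if not (self.heart_rate_mean > 0):
            raise ValueError(f"heart_rate_mean must be > 0, got {self.heart_rate_mean}")
        if self.heart_rate_sd < 0:
            raise ValueError("heart_rate_sd must be >= 0")
        for w in WAVE_ORDER:
            if w not in self.wave_amplitudes or w not in self.wave_widths:
                raise ValueError(f"wave_amplitudes/wave_widths must cover wave {w!r}")
            if not (self.wave_widths[w] > 0):
                raise ValueError(f"wave width for {w!r} must be > 0")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive white Gaussian noise at an exact realized SNR (dB)."""

    target_snr: float
    seed: int = 0

    def validate(self) -> None:
        if not np.isfinite(self.target_snr):
            raise ValueError(f"target_snr must be finite, got {self.target_snr}")


def generate_ecg(spec: SyntheticEcgSpec) -> np.ndarray:
    """Generate ``round(sampling_rate * duration)`` samples of synthetic ECG.

    Deterministic under ``spec.seed``: identical specs yield bit-identical
    sample vectors.
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.sampling_rate * spec.duration))
    t = np.arange(n) / spec.sampling_rate
    signal = np.zeros(n)

    mean_rr = 60.0 / spec.heart_rate_mean
    sd_rr = spec.heart_rate_sd * mean_rr / spec.heart_rate_mean  # dRR ~ RR/HR * dHR

    # Beat schedule: R-peak times from truncated-normal RR intervals.  Start
    # half a mean RR before zero so the first window already holds a beat.
    r_times = []
    tcur = -0.5 * mean_rr
    tail = 0.6  # allow a T wave from a beat just past the end
    while tcur < spec.duration + tail:
        r_times.append(tcur)
        rr = mean_rr + sd_rr * rng.standard_normal() if sd_rr > 0 else mean_rr
        tcur += max(rr, 0.2 * mean_rr)

    for r_t in r_times:
        gain = 1.0 + spec.amplitude_jitter * rng.standard_normal() if spec.amplitude_jitter > 0 else 1.0
        for w in WAVE_ORDER:
            centre = r_t + WAVE_OFFSETS_S[w]
            width = spec.wave_widths[w]
            amp = spec.wave_amplitudes[w] * (gain if w in ("Q", "R", "S") else 1.0)
            # only touch samples within 5 sigma of the bump centre
            lo = max(0, int(np.floor((centre - 5 * width) * spec.sampling_rate)))
            hi = min(n, int(np.ceil((centre + 5 * width) * spec.sampling_rate)) + 1)
            if lo >= hi:
                continue
            tt = t[lo:hi] - centre
            signal[lo:hi] += amp * np.exp(-0.5 * (tt / width) ** 2)

    if spec.baseline_wander_amplitude > 0:
        phase = rng.uniform(0, 2 * np.pi)
        freq = rng.uniform(0.15, 0.35)  # Hz, respiration-band drift
        signal += spec.baseline_wander_amplitude * np.sin(2 * np.pi * freq * t + phase)
    return signal


def segment_signal(signal: np.ndarray, segment_length: int, count: int,
                   strategy: str = "tile", sampling_rate: float = 360.0,
                   record_id: str = "synthetic") -> list[SignalSegment]:
    """Cut ``count`` windows of ``segment_length`` samples out of a signal.

    ``strategy='tile'`` takes consecutive non-overlapping windows from the
    start; ``strategy='even'`` spreads ``count`` non-overlapping windows
    evenly across the record (mirroring "selected segments evenly" from the
    source databases).  Raises if the signal is too short for the request.
    """
    signal = np.asarray(signal, dtype=float)
    n = signal.size
    if segment_length <= 0 or count <= 0:
        raise ValueError("segment_length and count must be positive")
    if n < segment_length:
        raise ValueError(f"signal of {n} samples shorter than one segment ({segment_length})")
    if count * segment_length > n:
        raise ValueError(
            f"cannot cut {count} non-overlapping windows of {segment_length} "
            f"from {n} samples"
        )
    if strategy == "tile":
        starts = [i * segment_length for i in range(count)]
    elif strategy == "even":
        if count == 1:
            starts = [0]
        else:
            stride = (n - segment_length) / (count - 1)
            starts = [int(round(i * stride)) for i in range(count)]
    else:
        raise ValueError(f"unknown segmentation strategy {strategy!r}")
    return [
        SignalSegment(signal[s:s + segment_length], sampling_rate=sampling_rate,
                      record_id=record_id, index=i)
        for i, s in enumerate(starts)
    ]


def add_noise(segment: SignalSegment, noise: NoiseSpec) -> SignalSegment:
    """Add white Gaussian noise at an *exact* realized SNR.

    The drawn noise vector is rescaled so that
    ``10*log10(||x||^2 / ||n||^2) == noise.target_snr`` holds for the
    returned realization (not just in expectation).  Raises on an all-zero
    segment, for which SNR is undefined.
    """
    noise.validate()
    x = segment.samples
    sig_energy = float(np.dot(x, x))
    if sig_energy == 0.0:
        raise ValueError("cannot set an SNR on an all-zero segment")
    rng = np.random.default_rng(noise.seed)
    n_vec = rng.standard_normal(x.size)
    n_energy = float(np.dot(n_vec, n_vec))
    scale = np.sqrt(sig_energy / n_energy) * 10.0 ** (-noise.target_snr / 20.0)
    return SignalSegment(x + scale * n_vec, segment.sampling_rate,
                         segment.record_id, segment.index)


def make_dataset(n_segments: int, segment_length: int = 256,
                 spec: SyntheticEcgSpec | None = None,
                 noise: NoiseSpec | None = None,
                 seed: int = 0) -> list[SignalSegment]:
    """Convenience: one long synthetic record tiled into ``n_segments`` windows.

    ``seed`` reseeds the generator spec (and shifts the noise seed per
    segment when ``noise`` is given) so that datasets are reproducible from a
    single integer.
    """
    base = spec if spec is not None else SyntheticEcgSpec()
    fs = base.sampling_rate
    duration = (n_segments * segment_length) / fs + 2.0
    base = replace(base, duration=duration, seed=seed)
    signal = generate_ecg(base)
    segments = segment_signal(signal, segment_length, n_segments,
                              strategy="tile", sampling_rate=fs)
    if noise is not None:
        segments = [
            add_noise(seg, replace(noise, seed=(noise.seed + 92821 * i) % (2**31 - 1)))
            for i, seg in enumerate(segments)
        ]
    return segments
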