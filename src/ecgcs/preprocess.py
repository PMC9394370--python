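"""Per-segment min-max normalization and its inverse.

Every 256-sample window is mapped affinely onto [0, 1] using its own minimum
and maximum before it enters the compressor; the stored ``NormalizationParams``
undo the map after reconstruction.  A constant (flat-line) segment has no
well-defined map and is sent to the all-zero vector with a degenerate flag
rather than raising, so batch pipelines survive flat-line artifacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

DEFAULT_SEGMENT_LENGTH = 256


@dataclass
class SignalSegment:
    """A fixed-length 1-D signal window with provenance metadata."""

    samples: np.ndarray
    sampling_rate: float = 360.0
    record_id: str = ""
    index: int = 0
    degenerate: bool = False

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 1:
            raise ValueError("segment samples must be 1-D")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("segment samples must be finite")

    def __len__(self) -> int:
        return self.samples.size


@dataclass(frozen=True)
class NormalizationParams:
    """min/max of the raw window; the inverse map is y*(max-min)+min."""

    min_value: float
    max_value: float

    def __post_init__(self) -> None:
        if self.max_value < self.min_value:
            raise ValueError("max_value must be >= min_value")

    @property
    def span(self) -> float:
        return self.max_value - self.min_value


def normalize(segment: SignalSegment) -> tuple[SignalSegment, NormalizationParams]:
    """Min-max normalize one segment onto [0, 1].

    Returns the normalized segment and the parameters needed to invert the
    map.  A constant segment yields the all-zero vector, a ``degenerate``
    flag on the returned segment, and a ``UserWarning``.
    """
    x = segment.samples
    lo, hi = float(np.min(x)), float(np.max(x))
    params = NormalizationParams(lo, hi)
    if hi == lo:
        warnings.warn(
            f"constant segment (record={segment.record_id!r}, index={segment.index}): "
            "min-max normalization degenerate, emitting zeros",
            UserWarning,
            stacklevel=2,
        )
        y = np.zeros_like(x)
        out = SignalSegment(y, segment.sampling_rate, segment.record_id, segment.index, degenerate=True)
        return out, params
    y = (x - lo) / (hi - lo)
    out = SignalSegment(y, segment.sampling_rate, segment.record_id, segment.index)
    return out, params


def denormalize(segment: SignalSegment, params: NormalizationParams) -> SignalSegment:
    """Invert :func:`normalize`: x = y*(max-min) + min."""
    x = segment.samples * params.span + params.min_value
    return SignalSegment(x, segment.sampling_rate, segment.record_id, segment.index)


def normalize_batch(segments: list[SignalSegment]) -> tuple[np.ndarray, list[NormalizationParams]]:
    """Normalize a list of segments into an (n_segments, N) matrix."""
    if not segments:
        raise ValueError("empty segment list")
    rows, params = [], []
    for seg in segments:
        norm, p = normalize(seg)
        rows.append(norm.samples)
        params.append(p)
    return np.stack(rows), params


def batch_from_array(data: np.ndarray, sampling_rate: float = 360.0,
                     record_id: str = "") -> list[SignalSegment]:
    """Wrap the rows of an (n, N) array as segments."""
    data = np.atleast_2d(np.asarray(data, dtype=float))
    return [
        SignalSegment(row, sampling_rate=sampling_rate, record_id=record_id, index=i)
        for i, row in enumerate(data)
    ]
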