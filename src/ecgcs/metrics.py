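"""Reconstruction-quality metrics for compressed-sensing ECG.

Two standard figures of merit compare an original segment ``x`` with its
reconstruction ``x_bar``:

* PRD, the percentage root-mean-square difference,
  ``100 * ||x - x_bar||_2 / ||x||_2``.  Smaller is better; the clinical
  quality bands (Very good / Good / No good / Bad) are keyed to PRD.
* SNR in dB, ``10 * log10(||x||^2 / ||x - x_bar||^2)``.  Per segment the
  two are algebraically locked together: ``SNR = -20 * log10(PRD / 100)``.

Averaging over a test set is done on PRD and SNR *separately*; because of
Jensen's inequality the mean SNR is not a function of the mean PRD, so both
are reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

#: dB value reported for a numerically perfect reconstruction, keeping
#: aggregate means finite.
SNR_CAP_DB = 300.0

#: PRD (%) band edges and labels; bands are left-closed/right-open, and
#: everything at or above the last edge is labelled "Bad".
QUALITY_BANDS: tuple[tuple[float, str], ...] = (
    (2.0, "Very good"),
    (9.0, "Good"),
    (19.0, "No good"),
    (60.0, "Bad"),
)


@dataclass(frozen=True)
class EvalResult:
    """PRD/SNR/quality for one (original, reconstruction) pair."""

    prd: float
    snr: float
    quality_label: str
    scale: str = "normalized"


def _as_vector(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float).ravel()
    if arr.size == 0:
        raise ValueError(f"{name} must be non-empty")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite")
    return arr


def prd(x, x_bar) -> float:
    """Percentage root-mean-square difference between ``x`` and ``x_bar``.

    Raises ``ValueError`` on a zero reference signal (the ratio is undefined)
    or mismatched lengths.  The mean is *not* subtracted from ``x``.
    """
    xv = _as_vector(x, "x")
    rv = _as_vector(x_bar, "x_bar")
    if xv.shape != rv.shape:
        raise ValueError(f"length mismatch: {xv.size} vs {rv.size}")
    denom = np.linalg.norm(xv)
    if denom == 0.0:
        raise ValueError("PRD undefined for an all-zero reference signal")
    return float(np.linalg.norm(xv - rv) / denom * 100.0)


def snr(x, x_bar) -> float:
    """Reconstruction SNR in dB; capped at ``SNR_CAP_DB`` for exact matches."""
    xv = _as_vector(x, "x")
    rv = _as_vector(x_bar, "x_bar")
    if xv.shape != rv.shape:
        raise ValueError(f"length mismatch: {xv.size} vs {rv.size}")
    sig = float(np.dot(xv, xv))
    if sig == 0.0:
        raise ValueError("SNR undefined for an all-zero reference signal")
    err = float(np.dot(xv - rv, xv - rv))
    if err == 0.0:
        return SNR_CAP_DB
    return min(float(10.0 * np.log10(sig / err)), SNR_CAP_DB)


def quality_label(prd_percent: float) -> str:
    """Map a PRD (%) to its clinical reconstruction-quality label."""
    p = float(prd_percent)
    if not np.isfinite(p) or p < 0:
        raise ValueError(f"PRD must be a finite non-negative percent, got {p}")
    for edge, label in QUALITY_BANDS:
        if p < edge:
            return label
    return "Bad"


def sensing_rate(m: int, n: int) -> float:
    """Sensing rate SR = M/N for M measurements of an N-sample segment."""
    if not (0 < m <= n):
        raise ValueError(f"need 0 < M <= N, got M={m}, N={n}")
    return m / n


def evaluate_pair(x, x_bar, scale: str = "normalized") -> EvalResult:
    """Bundle PRD, SNR and the quality label for one pair."""
    p = prd(x, x_bar)
    return EvalResult(prd=p, snr=snr(x, x_bar), quality_label=quality_label(p), scale=scale)


def aggregate(results: Iterable[EvalResult] | Sequence[EvalResult]) -> tuple[float, float]:
    """Mean PRD (%) and mean SNR (dB) over a set of per-segment results.

    The two means are taken independently; the per-segment PRD/SNR identity
    does not survive averaging.
    """
    items = list(results)
    if not items:
        raise ValueError("cannot aggregate an empty result list")
    return (
        float(np.mean([r.prd for r in items])),
        float(np.mean([r.snr for r in items])),
    )
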