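"""Classical greedy compressed-sensing baselines: OMP and Subspace Pursuit.

Both solve y = A alpha with A = Phi Psi, where Phi is a fixed random
measuring matrix and Psi an orthonormal sparsifying basis, by greedily
selecting dictionary atoms and least-squares refitting on the selected
support.  The reconstruction is x_hat = Psi alpha_hat.

The default basis is an orthonormal Daubechies-4 wavelet transform (full
periodized decomposition), a standard sparsifying choice for ECG; an
orthonormal DCT-II and the identity are provided for testing and
comparison.  The sparsity budget defaults to K = floor(M/4), keeping the
least-squares subproblems well-posed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pywt
from scipy.fft import idct

from .compression import FixedMatrixOperator

BASIS_FAMILIES = ("dwt-db4", "dct", "identity")


@dataclass(frozen=True)
class SparsifyingBasis:
    """Orthonormal N x N synthesis matrix Psi (x = Psi alpha)."""

    matrix: np.ndarray
    family: str

    @property
    def n(self) -> int:
        return self.matrix.shape[0]


@dataclass(frozen=True)
class SparseCoefficients:
    """Greedy solution: coefficient vector and its support set."""

    alpha: np.ndarray
    support: tuple

    @property
    def sparsity(self) -> int:
        return len(self.support)


@dataclass(frozen=True)
class GreedyConfig:
    """Sparsity budget and stopping rules for OMP/SP."""

    sparsity: int
    max_iterations: int = 50
    residual_tolerance: float = 1e-10

    def __post_init__(self) -> None:
        if self.sparsity < 1:
            raise ValueError("sparsity budget must be >= 1")


def default_config(m: int) -> GreedyConfig:
    """K = floor(M/4), clipped to at least 1."""
    return GreedyConfig(sparsity=max(1, m // 4))


def build_basis(family: str, n: int) -> SparsifyingBasis:
    """Construct an orthonormal synthesis basis of size N.

    ``dwt-db4`` requires N to be a power of two (full periodized wavelet
    decomposition); ``dct`` is the orthonormal DCT-II synthesis; ``identity``
    is for signals already sparse in the sample domain.
    """
    if n < 1:
        raise ValueError("N must be positive")
    if family == "identity":
        return SparsifyingBasis(matrix=np.eye(n), family=family)
    if family == "dct":
        return SparsifyingBasis(matrix=idct(np.eye(n), axis=0, norm="ortho"),
                                family=family)
    if family == "dwt-db4":
        if n & (n - 1) != 0:
            raise ValueError(f"dwt-db4 basis needs N a power of two, got {n}")
        wavelet = pywt.Wavelet("db4")
        level = pywt.dwt_max_level(n, wavelet.dec_len)
        # synthesis columns: inverse transform of unit coefficient vectors
        template = pywt.wavedec(np.zeros(n), wavelet, mode="periodization", level=level)
        psi = np.empty((n, n))
        col = 0
        for band_idx, band in enumerate(template):
            for j in range(band.size):
                coeffs = [np.zeros_like(b) for b in template]
                coeffs[band_idx][j] = 1.0
                psi[:, col] = pywt.waverec(coeffs, wavelet, mode="periodization")
                col += 1
        return SparsifyingBasis(matrix=psi, family=family)
    raise ValueError(f"unknown basis family {family!r}; choose from {BASIS_FAMILIES}")


def _lstsq_on_support(a: np.ndarray, y: np.ndarray, support: np.ndarray) -> np.ndarray:
    """Least-squares coefficients on the selected atoms (pinv fallback)."""
    sub = a[:, support]
    try:
        coef, _, rank, _ = np.linalg.lstsq(sub, y, rcond=None)
        if rank < sub.shape[1]:
            warnings.warn("rank-deficient support; using minimum-norm solution",
                          RuntimeWarning, stacklevel=3)
    except np.linalg.LinAlgError:  # pragma: no cover - defensive
        warnings.warn("least squares failed; falling back to pseudo-inverse",
                      RuntimeWarning, stacklevel=3)
        coef = np.linalg.pinv(sub) @ y
    return coef


def _column_norms(a: np.ndarray) -> np.ndarray:
    norms = np.linalg.norm(a, axis=0)
    if np.any(norms == 0):
        raise ValueError("dictionary contains an all-zero column")
    return norms


def omp(y: np.ndarray, a: np.ndarray, config: GreedyConfig) -> SparseCoefficients:
    """Orthogonal Matching Pursuit.

    Iteratively picks the atom with the largest normalized correlation with
    the residual, refits by least squares on the grown support, and stops
    after ``config.sparsity`` atoms or once the residual norm drops below
    ``config.residual_tolerance``.
    """
    y = np.asarray(y, dtype=float).ravel()
    a = np.asarray(a, dtype=float)
    m, n = a.shape
    if y.size != m:
        raise ValueError(f"measurement of {y.size} values vs dictionary of {m} rows")
    norms = _column_norms(a)
    alpha = np.zeros(n)
    support: list = []
    residual = y.copy()
    if np.linalg.norm(residual) <= config.residual_tolerance:
        return SparseCoefficients(alpha=alpha, support=())
    k = min(config.sparsity, m)
    for _ in range(k):
        corr = np.abs(a.T @ residual) / norms
        corr[support] = -np.inf
        support.append(int(np.argmax(corr)))
        idx = np.asarray(support)
        coef = _lstsq_on_support(a, y, idx)
        residual = y - a[:, idx] @ coef
        if np.linalg.norm(residual) <= config.residual_tolerance:
            break
    alpha[np.asarray(support)] = coef
    return SparseCoefficients(alpha=alpha, support=tuple(support))


def sp(y: np.ndarray, a: np.ndarray, config: GreedyConfig) -> SparseCoefficients:
    """Subspace Pursuit.

    Starts from the K best-correlated atoms, then repeatedly merges in the K
    atoms most correlated with the residual, solves least squares on the
    merged set, prunes back to the K largest coefficients, and refits;
    accepts the update only while the residual decreases.
    """
    y = np.asarray(y, dtype=float).ravel()
    a = np.asarray(a, dtype=float)
    m, n = a.shape
    if y.size != m:
        raise ValueError(f"measurement of {y.size} values vs dictionary of {m} rows")
    norms = _column_norms(a)
    an = a / norms
    k = min(config.sparsity, m)
    alpha = np.zeros(n)
    if np.linalg.norm(y) <= config.residual_tolerance:
        return SparseCoefficients(alpha=alpha, support=())

    corr = np.abs(an.T @ y)
    support = np.sort(np.argpartition(corr, -k)[-k:])
    coef = _lstsq_on_support(a, y, support)
    residual = y - a[:, support] @ coef
    best_norm = np.linalg.norm(residual)

    for _ in range(config.max_iterations):
        if best_norm <= config.residual_tolerance:
            break
        corr = np.abs(an.T @ residual)
        corr[support] = 0.0
        extra = np.argpartition(corr, -k)[-k:]
        merged = np.union1d(support, extra)
        coef_m = _lstsq_on_support(a, y, merged)
        keep = np.argsort(np.abs(coef_m))[-k:]
        candidate = np.sort(merged[keep])
        coef_c = _lstsq_on_support(a, y, candidate)
        res_c = y - a[:, candidate] @ coef_c
        norm_c = np.linalg.norm(res_c)
        if norm_c < best_norm - 1e-15:
            support, coef, residual, best_norm = candidate, coef_c, res_c, norm_c
        else:
            break
    alpha[support] = coef
    return SparseCoefficients(alpha=alpha, support=tuple(int(i) for i in support))


def baseline_reconstruct(y: np.ndarray, phi, psi: SparsifyingBasis,
                         method: str = "omp",
                         config: GreedyConfig | None = None) -> np.ndarray:
    """Greedy CS reconstruction x_hat = Psi alpha_hat from y = Phi x.

    ``phi`` is a FixedMatrixOperator or a raw M x N matrix; ``method`` is
    ``'omp'`` or ``'sp'``; ``config`` defaults to K = floor(M/4).
    """
    phi_mat = phi.matrix if isinstance(phi, FixedMatrixOperator) else np.asarray(phi, dtype=float)
    m = phi_mat.shape[0]
    if phi_mat.shape[1] != psi.n:
        raise ValueError(f"Phi of shape {phi_mat.shape} vs Psi of size {psi.n}")
    cfg = config or default_config(m)
    dictionary = phi_mat @ psi.matrix
    solver = {"omp": omp, "sp": sp}.get(method)
    if solver is None:
        raise ValueError(f"unknown method {method!r} (use 'omp' or 'sp')")
    coeffs = solver(np.asarray(y, dtype=float), dictionary, cfg)
    return psi.matrix @ coeffs.alpha
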