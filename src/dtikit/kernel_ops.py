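"""Kernel algebra: PSD correction, weighted fusion, tensor-product kernels.

The tensor-product kernel over (drug, protein) pairs is exposed blockwise so
that pair spaces of hundreds of thousands of pairs never require the full
Gram matrix in memory at once.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
from scipy.linalg import eigvalsh

from .core_io import SimilarityMatrix, aligned

__all__ = [
    "FusionCoefficients",
    "make_psd",
    "fuse_kernels",
    "tensor_product_kernel",
    "tensor_product_blocks",
]

PSD_TOL = -1e-9


@dataclass(frozen=True)
class FusionCoefficients:
    """Non-negative weight per kernel; at least one must be positive."""

    weights: tuple[float, ...]

    def __post_init__(self):
        w = tuple(float(x) for x in self.weights)
        object.__setattr__(self, "weights", w)
        if any(x < 0 for x in w):
            raise ValueError("fusion weights must be >= 0")
        if not any(x > 0 for x in w):
            raise ValueError("at least one fusion weight must be > 0")


def make_psd(m: SimilarityMatrix, delta: float = 1e-8) -> SimilarityMatrix:
    """Shift the diagonal so all eigenvalues are non-negative.

    If the minimum eigenvalue is already >= 0 the input is returned unchanged;
    otherwise (|lambda_min| + delta) * I is added in a single shot, which is
    the fixed point of repeatedly adding small identity multiples.  Idempotent.
    """
    if delta < 0:
        raise ValueError("delta must be >= 0")
    lam_min = eigvalsh(m.values, subset_by_index=[0, 0])[0]
    if lam_min >= 0:
        return m
    shift = abs(lam_min) + delta
    return SimilarityMatrix(m.entities, m.values + shift * np.eye(len(m.entities)))


def fuse_kernels(ms: Sequence[SimilarityMatrix], c: FusionCoefficients) -> SimilarityMatrix:
    """Weighted sum of kernels sharing one entity registry."""
    ms = aligned(ms)
    if len(c.weights) != len(ms):
        raise ValueError(f"{len(c.weights)} weights for {len(ms)} kernels")
    out = np.zeros_like(ms[0].values)
    for w, m in zip(c.weights, ms):
        out += w * m.values
    return SimilarityMatrix(ms[0].entities, out)


def tensor_product_kernel(
    kc: SimilarityMatrix,
    kp: SimilarityMatrix,
    drug_pairs: Sequence[tuple[int, int]] | None = None,
    protein_pairs: Sequence[tuple[int, int]] | None = None,
) -> np.ndarray:
    """Pairwise-kernel entries K((c,p),(c',p')) = Kc(c,c') * Kp(p,p').

    With explicit index pairs, returns the vector of products for the zipped
    (drug_pairs, protein_pairs) requests; with neither, returns the full
    Kronecker product over all (drug, protein) x (drug, protein) pairs in
    row-major (drug-major) pair order.
    """
    if (drug_pairs is None) != (protein_pairs is None):
        raise ValueError("provide both drug_pairs and protein_pairs, or neither")
    if drug_pairs is None:
        return np.kron(kc.values, kp.values)
    dp = np.asarray(drug_pairs, dtype=np.intp)
    pp = np.asarray(protein_pairs, dtype=np.intp)
    if dp.shape != pp.shape:
        raise ValueError("drug_pairs and protein_pairs must have matching shapes")
    return kc.values[dp[..., 0], dp[..., 1]] * kp.values[pp[..., 0], pp[..., 1]]


def tensor_product_blocks(
    kc: SimilarityMatrix,
    kp: SimilarityMatrix,
    block_size: int = 15,
) -> Iterator[tuple[np.ndarray, np.ndarray]]:
    """Yield the full pairwise kernel in blocks of ``block_size`` proteins.

    Each yielded item is ``(pair_rows, block)``: ``block`` holds the rows of
    the pair-space Gram matrix for all pairs whose protein falls in the
    current protein block, and ``pair_rows`` gives their global pair indices
    (drug-major, pair (c, p) -> c * n_proteins + p).  Scattering every block
    into ``full[pair_rows, :] = block`` reproduces
    ``tensor_product_kernel(kc, kp)`` exactly.
    """
    if block_size < 1:
        raise ValueError("block_size must be >= 1")
    n_d = len(kc.entities)
    n_p = len(kp.entities)
    for start in range(0, n_p, block_size):
        idx = np.arange(start, min(start + block_size, n_p))
        block = np.kron(kc.values, kp.values[idx, :])
        pair_rows = (np.arange(n_d)[:, None] * n_p + idx[None, :]).ravel()
        yield pair_rows, block
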