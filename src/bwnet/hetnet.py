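"""Heterogeneous network assembly, node weights, and edge normalization.

The disease and microbe similarity networks are merged with the known
associations into one heterogeneous network over N_d + N_m nodes,
encoded as the symmetric block matrix

    P = [[KD, A ],
         [A.T, KM]]

Each node then receives a weight inversely proportional to the squared
norm of its row of P — hub nodes with many strong connections carry less
evidence per connection — collected in the diagonal matrix W. Finally the
kernels are column-normalized into directed edge weights KM*, KD*
(asymmetric in general), shrinking entries so that longer paths cannot
outscore shorter ones during propagation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "HeteroNetwork",
    "build_P",
    "node_weights",
    "nz_row_counts",
    "normalize_kernel",
    "build_hetnet",
]

NORMALIZATION_VARIANTS = ("full_denominator", "postmultiply")


@dataclass
class HeteroNetwork:
    P: np.ndarray
    W: np.ndarray  # diagonal node-weight matrix, same node order as P
    KM_star: np.ndarray
    KD_star: np.ndarray
    nz_m: np.ndarray
    nz_d: np.ndarray


def build_P(KD: np.ndarray, A: np.ndarray, KM: np.ndarray) -> np.ndarray:
    """Assemble the symmetric heterogeneous block matrix [[KD, A], [A.T, KM]]."""
    KD, A, KM = (np.asarray(x, dtype=float) for x in (KD, A, KM))
    n_d, n_m = A.shape
    if KD.shape != (n_d, n_d) or KM.shape != (n_m, n_m):
        raise ValueError(
            f"dimension mismatch: KD {KD.shape}, A {A.shape}, KM {KM.shape}"
        )
    return np.block([[KD, A], [A.T, KM]])


def node_weights(P: np.ndarray) -> np.ndarray:
    """Diagonal node-weight matrix W with W_ii = 1 / (P P^T)_ii.

    (P P^T)_ii is the squared norm of row i, so high-degree, strongly
    connected nodes get small weights. With unit kernel diagonals every
    row norm is >= 1, hence 0 < W_ii <= 1.
    """
    P = np.asarray(P, dtype=float)
    row_sq = np.einsum("ij,ij->i", P, P)
    if np.any(row_sq == 0.0):
        raise ValueError("zero row in P: node weight undefined")
    return np.diag(1.0 / row_sq)


def nz_row_counts(K: np.ndarray, eps: float = 0.0) -> np.ndarray:
    """Per-row count of entries strictly greater than eps.

    With eps=0 and a Gaussian kernel (all entries positive) every count
    equals the matrix dimension; the threshold only bites when entries
    underflow or a non-Gaussian similarity with exact zeros is supplied.
    """
    K = np.asarray(K, dtype=float)
    return (K > eps).sum(axis=1)


def normalize_kernel(K: np.ndarray, variant: str = "full_denominator", eps: float = 0.0) -> np.ndarray:
    """Column-normalize a kernel into directed edge weights.

    ``full_denominator`` (default): K*(i,j) = K(i,j) / (sum_k K(k,j) * NZ(i)),
    where NZ(i) counts the nonzero entries of row i. When NZ(i) = N for all
    rows (the generic all-positive case) every column of K* sums to 1/N.

    ``postmultiply``: K*(i,j) = K(i,j) / sum_k K(k,j) * NZ(i), the
    alternative grouping of the same expression.

    Either way the result is asymmetric in general; K*(i,j) is the weight
    of the directed edge i -> j.
    """
    if variant not in NORMALIZATION_VARIANTS:
        raise ValueError(f"variant must be one of {NORMALIZATION_VARIANTS}, got {variant!r}")
    K = np.asarray(K, dtype=float)
    col_sums = K.sum(axis=0)
    if np.any(col_sums <= 0.0):
        raise ValueError("zero column sum: cannot normalize")
    nz = nz_row_counts(K, eps)
    if variant == "full_denominator":
        return K / (col_sums[None, :] * nz[:, None])
    return K / col_sums[None, :] * nz[:, None]


def build_hetnet(
    A: np.ndarray,
    KM: np.ndarray,
    KD: np.ndarray,
    variant: str = "full_denominator",
    eps: float = 0.0,
) -> HeteroNetwork:
    """Assemble P, W and the normalized kernels in one step.

    W is computed from P built with the original adjacency and the raw
    (unnormalized) kernels.
    """
    P = build_P(KD, A, KM)
    return HeteroNetwork(
        P=P,
        W=node_weights(P),
        KM_star=normalize_kernel(KM, variant, eps),
        KD_star=normalize_kernel(KD, variant, eps),
        nz_m=nz_row_counts(KM, eps),
        nz_d=nz_row_counts(KD, eps),
    )
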