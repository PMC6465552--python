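"""Gaussian interaction-profile (GIP) kernel similarity.

Two microbes that share many associated diseases are assumed functionally
similar; likewise two diseases sharing many associated microbes. The GIP
kernel encodes this as

    K(i, j) = exp(-gamma * ||IP(i) - IP(j)||^2)

where IP(i) is node i's binary interaction profile — a column of the
adjacency matrix for a microbe, a row for a disease — and the bandwidth

    gamma = gamma' / mean_i ||IP(i)||^2

is scaled by the mean squared profile norm so that the kernel adapts to
the overall density of the association network. ``gamma'`` defaults to 1,
the standard choice for GIP kernels in link-prediction models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["KernelPair", "gip_bandwidth", "gip_kernel", "kernel_pair"]

_AXES = ("microbe", "disease")


@dataclass
class KernelPair:
    """GIP kernels for both node classes with their bandwidths.

    ``KM`` is the microbe-microbe kernel (N_m x N_m), ``KD`` the
    disease-disease kernel (N_d x N_d). Both are symmetric with unit
    diagonal and entries in (0, 1].
    """

    KM: np.ndarray
    KD: np.ndarray
    gamma_m: float
    gamma_d: float
    gamma_prime_m: float = 1.0
    gamma_prime_d: float = 1.0


def _profiles(A: np.ndarray, axis: str) -> np.ndarray:
    """Interaction profiles as rows: adjacency columns for microbes, rows for diseases."""
    A = np.asarray(A, dtype=float)
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {_AXES}, got {axis!r}")
    return A.T if axis == "microbe" else A


def gip_bandwidth(A: np.ndarray, axis: str, gamma_prime: float = 1.0) -> float:
    """Kernel bandwidth gamma for the given axis.

    Raises if every profile on the axis is zero (the mean squared norm,
    and hence the bandwidth denominator, would be zero).
    """
    if gamma_prime <= 0:
        raise ValueError("gamma_prime must be positive")
    P = _profiles(A, axis)
    mean_sq = float((P * P).sum(axis=1).mean())
    if mean_sq == 0.0:
        raise ValueError("zero bandwidth denominator: all profiles are zero")
    return gamma_prime / mean_sq


def gip_kernel(A: np.ndarray, axis: str, gamma_prime: float = 1.0) -> np.ndarray:
    """GIP kernel matrix over the nodes of one axis.

    Symmetric with exact unit diagonal; strictly positive entries.
    """
    P = _profiles(A, axis)
    gamma = gip_bandwidth(A, axis, gamma_prime)
    sq = (P * P).sum(axis=1)
    # ||x - y||^2 = ||x||^2 + ||y||^2 - 2 x.y, clipped against roundoff
    d2 = np.maximum(sq[:, None] + sq[None, :] - 2.0 * (P @ P.T), 0.0)
    K = np.exp(-gamma * d2)
    K = 0.5 * (K + K.T)
    np.fill_diagonal(K, 1.0)
    return K


def kernel_pair(A: np.ndarray, gamma_prime_m: float = 1.0, gamma_prime_d: float = 1.0) -> KernelPair:
    """Compute both kernels from one adjacency matrix."""
    return KernelPair(
        KM=gip_kernel(A, "microbe", gamma_prime_m),
        KD=gip_kernel(A, "disease", gamma_prime_d),
        gamma_m=gip_bandwidth(A, "microbe", gamma_prime_m),
        gamma_d=gip_bandwidth(A, "disease", gamma_prime_d),
        gamma_prime_m=gamma_prime_m,
        gamma_prime_d=gamma_prime_d,
    )
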