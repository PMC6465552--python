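"""Truncated KATZ-style propagation and score fusion.

The directed weighted network is encoded as

    S = [[KD*,   A_d],
         [A_m.T, KM*]]

mixing the normalized (asymmetric) similarity blocks with the two
side-specific densified adjacencies, so S is asymmetric whenever
A_m != A_d. Propagation interleaves the node-weight diagonal W:

    S_2 = S W S,

and for n > 2 either squares the previous step (``squaring``,
S_n = S_{n-1} W S_{n-1}) or multiplies one step at a time (``stepwise``,
S_n = S_{n-1} W S). Both coincide at n = 2, the recommended setting —
with so few known associations, longer paths add noise rather than
signal. Unlike the classical KATZ index there is no damped sum over all
path lengths; only the single length-n matrix is used.

S_n splits into four blocks; the disease->microbe block S_n2 and the
transposed microbe->disease block S_n3.T both score the same pairs from
opposite directions and are averaged with equal weight into the final
prediction matrix A*_n.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .dataio import AssociationDataset
from .gip import gip_kernel
from .hetnet import build_hetnet
from .recommend import DEFAULT_K, augment_adjacency

__all__ = [
    "PredictParams",
    "ScoreMatrix",
    "build_S",
    "propagate",
    "fuse_scores",
    "score_matrix",
    "predict",
]

RECURSION_VARIANTS = ("squaring", "stepwise")


@dataclass
class PredictParams:
    """Pipeline settings; defaults reproduce the recommended configuration
    (n=2, K=3 neighbors, gamma'=1, full-denominator normalization)."""

    n: int = 2
    k: int = DEFAULT_K
    gamma_prime_m: float = 1.0
    gamma_prime_d: float = 1.0
    normalization: str = "full_denominator"
    recursion: str = "squaring"
    eps: float = 0.0

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.recursion not in RECURSION_VARIANTS:
            raise ValueError(f"recursion must be one of {RECURSION_VARIANTS}")


@dataclass
class ScoreMatrix:
    """Fused prediction scores (N_d x N_m, non-negative) with the
    parameters that produced them."""

    scores: np.ndarray = field(repr=False)
    params: PredictParams = field(default_factory=PredictParams)


def build_S(
    KD_star: np.ndarray,
    A_d: np.ndarray,
    A_m: np.ndarray,
    KM_star: np.ndarray,
) -> np.ndarray:
    """Assemble the directed block matrix [[KD*, A_d], [A_m.T, KM*]].

    Both adjacencies are disease x microbe; the microbe-side one enters
    transposed so walks respect edge direction.
    """
    KD_star, A_d, A_m, KM_star = (
        np.asarray(x, dtype=float) for x in (KD_star, A_d, A_m, KM_star)
    )
    n_d, n_m = A_d.shape
    if A_m.shape != (n_d, n_m) or KD_star.shape != (n_d, n_d) or KM_star.shape != (n_m, n_m):
        raise ValueError("dimension mismatch between blocks")
    return np.block([[KD_star, A_d], [A_m.T, KM_star]])


def _diag(W: np.ndarray) -> np.ndarray:
    W = np.asarray(W, dtype=float)
    return np.diag(W) if W.ndim == 2 else W


def propagate(S: np.ndarray, W: np.ndarray, n: int, variant: str = "squaring") -> np.ndarray:
    """Propagate S for n steps with the node-weight diagonal interleaved.

    ``W`` may be the diagonal matrix or its diagonal as a vector.
    """
    if n < 2:
        raise ValueError("n must be >= 2")
    if variant not in RECURSION_VARIANTS:
        raise ValueError(f"variant must be one of {RECURSION_VARIANTS}")
    S = np.asarray(S, dtype=float)
    w = _diag(W)
    S_n = S @ (w[:, None] * S)
    for _ in range(n - 2):
        right = S_n if variant == "squaring" else S
        S_n = S_n @ (w[:, None] * right)
    return S_n


def fuse_scores(S_n: np.ndarray, n_diseases: int) -> np.ndarray:
    """Average the two directed disease-microbe blocks: (S_n2 + S_n3.T) / 2."""
    S_n = np.asarray(S_n, dtype=float)
    S_n2 = S_n[:n_diseases, n_diseases:]
    S_n3 = S_n[n_diseases:, :n_diseases]
    return 0.5 * (S_n2 + S_n3.T)


def score_matrix(A: np.ndarray, params: PredictParams | None = None) -> np.ndarray:
    """Run the full pipeline on a raw adjacency matrix.

    Stages: GIP kernels on both axes -> heterogeneous matrix P and node
    weights W -> column normalization -> bidirectional recommendation ->
    directed matrix S -> n-step propagation -> block fusion.
    """
    params = params or PredictParams()
    A = np.asarray(A, dtype=float)
    KM = gip_kernel(A, "microbe", params.gamma_prime_m)
    KD = gip_kernel(A, "disease", params.gamma_prime_d)
    net = build_hetnet(A, KM, KD, params.normalization, params.eps)
    aug = augment_adjacency(A, KM, KD, params.k)
    S = build_S(net.KD_star, aug.A_d, aug.A_m, net.KM_star)
    S_n = propagate(S, net.W, params.n, params.recursion)
    return fuse_scores(S_n, A.shape[0])


def predict(dataset: AssociationDataset, params: PredictParams | None = None) -> ScoreMatrix:
    """End-to-end prediction for a dataset; scores[i, j] estimates the
    plausibility of an association between disease i and microbe j."""
    params = params or PredictParams()
    return ScoreMatrix(scores=score_matrix(dataset.adjacency, params), params=params)
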