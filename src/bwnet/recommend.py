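"""Bidirectional neighbor-based recommendation to densify the adjacency.

The known association matrix is extremely sparse, which starves any
propagation-based scorer of paths. This step adds, for every microbe, at
most one recommended disease (giving A_m) and, for every disease, at most
one recommended microbe (giving A_d). Both sides start independently from
the same original adjacency.

For a subject node i on one axis:

1. its K most similar same-axis neighbors are selected from the raw GIP
   kernel (K = 3 by default), ties broken by ascending index;
2. each neighbor j gets a ratio R(i,j) = K(i,j) / sum over the neighbor
   set — the ratios sum to 1;
3. every opposite-axis node associated with at least one neighbor becomes
   a candidate; a candidate's first-order score is the sum of the ratios
   of the neighbors it is associated with;
4. candidates also reachable through the neighbors' own neighbor sets
   (second-order) receive a boost: for each neighbor p and each member q
   of p's neighbor set associated with the candidate, R(i,p) * R(p,q) is
   added;
5. the top-scoring candidate (ties by ascending index) is recommended and
   its cell set to 1. A subject whose neighbors have no associations at
   all yields no recommendation.

The procedure is fully deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "RecommendationTrace",
    "AugmentedAssociations",
    "top_k_neighbors",
    "neighbor_ratio",
    "recommend_one",
    "augment_adjacency",
]

DEFAULT_K = 3


@dataclass
class RecommendationTrace:
    """Full record of one recommendation decision, for audit and debugging."""

    subject: int
    axis: str
    neighbor_set: list[int]
    neighbor_ratios: dict[int, float]
    candidate_targets: list[int]
    second_order_sets: dict[int, dict] = field(default_factory=dict)
    scores: dict[int, float] = field(default_factory=dict)
    chosen: int | None = None


@dataclass
class AugmentedAssociations:
    """Adjacency after one round of recommendations on each side."""

    A_m: np.ndarray  # microbe-side recommendations applied
    A_d: np.ndarray  # disease-side recommendations applied
    traces: list[RecommendationTrace] = field(default_factory=list)


def top_k_neighbors(K_mat: np.ndarray, i: int, k: int) -> list[int]:
    """Indices of the min(k, N-1) nearest neighbors of node i, descending
    similarity, ties broken by ascending index; node i itself excluded."""
    if k < 1:
        raise ValueError("k must be >= 1")
    K_mat = np.asarray(K_mat, dtype=float)
    n = K_mat.shape[0]
    order = np.lexsort((np.arange(n), -K_mat[i]))
    return [int(j) for j in order if j != i][: min(k, n - 1)]


def neighbor_ratio(K_mat: np.ndarray, i: int, neighbors: list[int]) -> dict[int, float]:
    """Recommendation ratios R(i, j) = K(i,j) / sum_{k in neighbors} K(i,k)."""
    if not neighbors:
        raise ValueError("empty neighbor set")
    K_mat = np.asarray(K_mat, dtype=float)
    denom = float(K_mat[i, neighbors].sum())
    if denom <= 0.0:
        raise ValueError("zero ratio denominator")
    return {int(j): float(K_mat[i, j]) / denom for j in neighbors}


def _oriented(A: np.ndarray, axis: str) -> np.ndarray:
    """Association matrix as (targets x subjects): subjects live on `axis`,
    targets on the opposite axis."""
    A = np.asarray(A, dtype=float)
    if axis == "microbe":
        return A  # targets = diseases (rows), subjects = microbes (cols)
    if axis == "disease":
        return A.T  # targets = microbes, subjects = diseases
    raise ValueError(f"axis must be 'microbe' or 'disease', got {axis!r}")


def _targets_of(assoc: np.ndarray, nodes: list[int]) -> set[int]:
    if not nodes:
        return set()
    return set(np.nonzero(assoc[:, nodes].sum(axis=1) > 0)[0].tolist())


def recommend_one(
    A: np.ndarray,
    K_mat: np.ndarray,
    subject: int,
    axis: str,
    k: int = DEFAULT_K,
) -> RecommendationTrace:
    """Score opposite-axis candidates for one subject and pick the best.

    Returns a trace with ``chosen=None`` when the subject's neighbors have
    no associated targets (an isolated corner of the network) — a valid
    outcome, not an error.
    """
    assoc = _oriented(A, axis)
    nbrs = top_k_neighbors(K_mat, subject, k)
    trace = RecommendationTrace(
        subject=subject, axis=axis, neighbor_set=nbrs,
        neighbor_ratios={}, candidate_targets=[],
    )
    if not nbrs:
        return trace
    ratios = neighbor_ratio(K_mat, subject, nbrs)
    trace.neighbor_ratios = ratios
    candidates = sorted(_targets_of(assoc, nbrs))
    trace.candidate_targets = candidates
    if not candidates:
        return trace

    # second-order structures: each neighbor p brings its own neighbor set
    # and ratios; the boosted set is the union over p of
    # (candidates ∩ targets-of-p's-neighbors)
    boosted: set[int] = set()
    per_neighbor: dict[int, dict] = {}
    for p in nbrs:
        p_nbrs = top_k_neighbors(K_mat, p, k)
        p_ratios = neighbor_ratio(K_mat, p, p_nbrs) if p_nbrs else {}
        p_targets = _targets_of(assoc, p_nbrs)
        matched = set(candidates) & p_targets
        boosted |= matched
        per_neighbor[p] = {
            "neighbors": p_nbrs,
            "ratios": p_ratios,
            "targets": p_targets,
            "matched": matched,
        }
    trace.second_order_sets = per_neighbor

    scores: dict[int, float] = {}
    for t in candidates:
        s = sum(ratios[j] for j in nbrs if assoc[t, j] == 1)
        if t in boosted:
            s += sum(
                ratios[p] * info["ratios"][q]
                for p, info in per_neighbor.items()
                for q in info["neighbors"]
                if assoc[t, q] == 1
            )
        scores[t] = s
    trace.scores = scores

    best = candidates[0]
    for t in candidates[1:]:
        if scores[t] > scores[best]:
            best = t
    trace.chosen = best
    return trace


def augment_adjacency(
    A: np.ndarray,
    KM: np.ndarray,
    KD: np.ndarray,
    k: int = DEFAULT_K,
) -> AugmentedAssociations:
    """Apply one recommendation round on each side of the adjacency.

    Recommendations use the raw (unnormalized) kernels. A recommendation
    landing on an already-known pair is a no-op, so
    nnz(A_m) <= nnz(A) + N_m and nnz(A_d) <= nnz(A) + N_d.
    """
    A = np.asarray(A, dtype=float)
    n_d, n_m = A.shape
    A_m = A.copy()
    A_d = A.copy()
    traces: list[RecommendationTrace] = []
    for j in range(n_m):
        tr = recommend_one(A, KM, j, "microbe", k)
        traces.append(tr)
        if tr.chosen is not None:
            A_m[tr.chosen, j] = 1.0
    for i in range(n_d):
        tr = recommend_one(A, KD, i, "disease", k)
        traces.append(tr)
        if tr.chosen is not None:
            A_d[i, tr.chosen] = 1.0
    return AugmentedAssociations(A_m=A_m, A_d=A_d, traces=traces)
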