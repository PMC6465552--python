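"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written as plain loops over the documented procedures
and shares no code with the package.
"""

from __future__ import annotations

import numpy as np


def gip_double_loop(A: np.ndarray, axis: str, gamma_prime: float = 1.0) -> np.ndarray:
    """Naive GIP kernel: explicit profile loops."""
    profiles = [A[:, j] for j in range(A.shape[1])] if axis == "microbe" else [
        A[i, :] for i in range(A.shape[0])
    ]
    n = len(profiles)
    mean_sq = sum(float(p @ p) for p in profiles) / n
    gamma = gamma_prime / mean_sq
    K = np.empty((n, n))
    for i in range(n):
        for j in range(n):
            diff = profiles[i] - profiles[j]
            K[i, j] = np.exp(-gamma * float(diff @ diff))
    return K


def brute_recommend(A: np.ndarray, K: np.ndarray, subject: int, axis: str, k: int):
    """Exhaustive enumeration of the recommendation procedure.

    Returns (chosen, scores-dict); chosen is None when the subject's
    neighbors have no associated opposite-axis nodes.
    """
    assoc = A if axis == "microbe" else A.T
    n = K.shape[0]

    def top(node):
        others = sorted(
            (j for j in range(n) if j != node), key=lambda j: (-K[node, j], j)
        )
        return others[: min(k, n - 1)]

    q_m1 = top(subject)
    if not q_m1:
        return None, {}
    denom = sum(K[subject, j] for j in q_m1)
    R = {j: K[subject, j] / denom for j in q_m1}
    q_d1 = sorted(
        {t for t in range(assoc.shape[0]) for j in q_m1 if assoc[t, j] == 1}
    )
    if not q_d1:
        return None, {}
    union, info = set(), {}
    for p in q_m1:
        q_pm1 = top(p)
        pden = sum(K[p, q] for q in q_pm1)
        Rp = {q: K[p, q] / pden for q in q_pm1}
        q_pd1 = {t for t in range(assoc.shape[0]) for q in q_pm1 if assoc[t, q] == 1}
        union |= set(q_d1) & q_pd1
        info[p] = (q_pm1, Rp)
    scores = {}
    for t in q_d1:
        s = sum(R[j] for j in q_m1 if assoc[t, j] == 1)
        if t in union:
            s += sum(
                R[p] * Rp[q]
                for p, (q_pm1, Rp) in info.items()
                for q in q_pm1
                if assoc[t, q] == 1
            )
        scores[t] = s
    chosen = min(q_d1, key=lambda t: (-scores[t], t))
    return chosen, scores


def path_sum_step(S: np.ndarray, w: np.ndarray) -> np.ndarray:
    """Explicit two-edge path sums through the weighted middle node."""
    n = S.shape[0]
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            out[i, j] = sum(S[i, k] * w[k] * S[k, j] for k in range(n))
    return out


def trapezoid_auc(pos: np.ndarray, neg: np.ndarray) -> float:
    """ROC area by threshold sweep and trapezoidal integration.

    Thresholds are the pooled unique scores, swept high to low, which
    groups ties and makes the area equal the pairwise statistic exactly.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    thresholds = np.unique(np.concatenate([pos, neg]))[::-1]
    fpr = [0.0]
    tpr = [0.0]
    for t in thresholds:
        tpr.append(float((pos >= t).mean()))
        fpr.append(float((neg >= t).mean()))
    fpr.append(1.0)
    tpr.append(1.0)
    return float(np.trapezoid(tpr, fpr))


def pairwise_auc_quadratic(pos, neg) -> float:
    """Quadratic-time pairwise AUC: explicit loop over all (pos, neg) pairs."""
    total = 0.0
    for p in pos:
        for q in neg:
            total += 1.0 if p > q else (0.5 if p == q else 0.0)
    return total / (len(pos) * len(neg))


def random_bipartite(rng: np.random.Generator, max_d: int, max_m: int, p: float = 0.4):
    """Random binary adjacency with at least one association."""
    nd = int(rng.integers(2, max_d + 1))
    nm = int(rng.integers(2, max_m + 1))
    A = (rng.random((nd, nm)) < p).astype(float)
    if A.sum() == 0:
        A[int(rng.integers(nd)), int(rng.integers(nm))] = 1.0
    return A
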