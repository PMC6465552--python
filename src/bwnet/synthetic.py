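"""Synthetic bipartite association data with planted co-cluster structure.

Real curated microbe-disease catalogs are sparse (the reference catalog
holds 450 associations over 39 diseases and 292 microbes, ~4% density)
but far from random: diseases sharing a physiological context tend to
share microbes. The generator emulates this with a planted-partition
model — each disease and microbe is assigned one of ``n_blocks`` latent
communities, and a pair is associated with probability ``p_in`` when the
blocks match and ``p_out`` otherwise. Held-out edges are then recoverable
from community structure, giving cross-validation a signal to measure.
Any all-zero row or column is repaired with a single association so every
node has an interaction profile.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dataio import AssociationDataset

__all__ = [
    "SyntheticSpec",
    "generate_synthetic",
    "worked_toy",
    "scaled_benchmark",
    "shuffle_associations",
]


@dataclass
class SyntheticSpec:
    """Planted-partition generator settings.

    Defaults match the shape and within/between-block association rates of
    the reference catalog (39 x 292, ~6 communities, ~4-7% density).
    """

    n_diseases: int = 39
    n_microbes: int = 292
    n_blocks: int = 6
    p_in: float = 0.35
    p_out: float = 0.01
    seed: int = 1

    def __post_init__(self) -> None:
        if not (0.0 <= self.p_out < self.p_in <= 1.0):
            raise ValueError("require 0 <= p_out < p_in <= 1")
        if self.n_blocks < 1 or self.n_blocks > min(self.n_diseases, self.n_microbes):
            raise ValueError("n_blocks must be in [1, min(n_diseases, n_microbes)]")


def scaled_benchmark(seed: int = 1) -> SyntheticSpec:
    """Desk-scale benchmark: the reference catalog's shape scaled to
    20 x 60 with 4 communities, same within/between-block rates."""
    return SyntheticSpec(
        n_diseases=20, n_microbes=60, n_blocks=4, p_in=0.35, p_out=0.01, seed=seed
    )


def generate_synthetic(spec: SyntheticSpec) -> AssociationDataset:
    """Sample a dataset from the planted-partition model; deterministic
    given ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    d_blocks = rng.integers(0, spec.n_blocks, spec.n_diseases)
    m_blocks = rng.integers(0, spec.n_blocks, spec.n_microbes)
    match = d_blocks[:, None] == m_blocks[None, :]
    p = np.where(match, spec.p_in, spec.p_out)
    A = (rng.random((spec.n_diseases, spec.n_microbes)) < p).astype(float)

    # repair empty profiles with one edge, to a matched-block partner when
    # one exists, else to any partner
    for i in np.nonzero(A.sum(axis=1) == 0)[0]:
        pool = np.nonzero(m_blocks == d_blocks[i])[0]
        if pool.size == 0:
            pool = np.arange(spec.n_microbes)
        A[i, rng.choice(pool)] = 1.0
    for j in np.nonzero(A.sum(axis=0) == 0)[0]:
        pool = np.nonzero(d_blocks == m_blocks[j])[0]
        if pool.size == 0:
            pool = np.arange(spec.n_diseases)
        A[rng.choice(pool), j] = 1.0

    return AssociationDataset(
        disease_names=[f"disease_{i + 1}" for i in range(spec.n_diseases)],
        microbe_names=[f"microbe_{j + 1}" for j in range(spec.n_microbes)],
        adjacency=A,
    )


def worked_toy() -> AssociationDataset:
    """Fixed 3 x 4 example used across the documentation and tests:
    d1-{m1,m2}, d2-{m2,m3}, d3-{m4}."""
    A = np.array(
        [
            [1.0, 1.0, 0.0, 0.0],
            [0.0, 1.0, 1.0, 0.0],
            [0.0, 0.0, 0.0, 1.0],
        ]
    )
    return AssociationDataset(
        disease_names=["d1", "d2", "d3"],
        microbe_names=["m1", "m2", "m3", "m4"],
        adjacency=A,
    )


def shuffle_associations(dataset: AssociationDataset, seed: int = 0) -> AssociationDataset:
    """Permutation null: scatter the same number of associations uniformly
    over the matrix cells, destroying any planted structure.

    Note that merely relabeling rows or columns would not make a null —
    the whole pipeline is permutation-equivariant, so relabeled data give
    identical cross-validation results.
    """
    rng = np.random.default_rng(seed)
    flat = dataset.adjacency.ravel()
    A = rng.permutation(flat).reshape(dataset.adjacency.shape)
    return AssociationDataset(
        disease_names=list(dataset.disease_names),
        microbe_names=list(dataset.microbe_names),
        adjacency=A,
    )
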