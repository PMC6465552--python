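"""Reading and writing association edge lists and ranked prediction tables.

The on-disk format is a plain TSV edge list: one ``disease<TAB>microbe``
pair per line (extra columns such as evidence identifiers are ignored),
with ``#``-prefixed comment lines skipped. Diseases index the rows of the
binary adjacency matrix and microbes the columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AssociationDataset",
    "read_associations",
    "write_associations",
    "write_rankings",
]


@dataclass
class AssociationDataset:
    """Named binary disease x microbe association matrix.

    Row ``i`` of ``adjacency`` is the interaction profile of disease ``i``;
    column ``j`` is the interaction profile of microbe ``j``. Entries are
    0/1 with 1 marking a curated association.
    """

    disease_names: list[str]
    microbe_names: list[str]
    adjacency: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.adjacency = np.asarray(self.adjacency, dtype=float)
        n_d, n_m = self.adjacency.shape
        if len(self.disease_names) != n_d or len(self.microbe_names) != n_m:
            raise ValueError("name lists do not match adjacency shape")
        if len(set(self.disease_names)) != n_d:
            raise ValueError("duplicate disease names")
        if len(set(self.microbe_names)) != n_m:
            raise ValueError("duplicate microbe names")
        if not np.isin(self.adjacency, (0.0, 1.0)).all():
            raise ValueError("adjacency must be binary")

    @property
    def n_diseases(self) -> int:
        return self.adjacency.shape[0]

    @property
    def n_microbes(self) -> int:
        return self.adjacency.shape[1]

    @property
    def nnz(self) -> int:
        """Number of known associations."""
        return int(self.adjacency.sum())

    def positive_pairs(self) -> list[tuple[int, int]]:
        """Known (disease, microbe) index pairs in row-major order."""
        rows, cols = np.nonzero(self.adjacency)
        return list(zip(rows.tolist(), cols.tolist()))


def read_associations(path, dialect: str = "edge_list") -> AssociationDataset:
    """Read a TSV edge list into an :class:`AssociationDataset`.

    Names are ordered by first appearance; duplicate (disease, microbe)
    lines collapse to a single association. Fields are trimmed of
    surrounding whitespace but otherwise matched exactly (no case folding:
    curated taxon names may differ only in case).
    """
    if dialect != "edge_list":
        raise ValueError(f"unknown dialect: {dialect!r}")
    diseases: dict[str, int] = {}
    microbes: dict[str, int] = {}
    pairs: set[tuple[int, int]] = set()
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            stripped = line.strip()
            if not stripped or stripped.startswith("#"):
                continue
            fields = [f.strip() for f in stripped.split("\t")]
            if len(fields) < 2 or not fields[0] or not fields[1]:
                raise ValueError(
                    f"{path}: malformed line {lineno}: expected at least "
                    f"2 tab-separated fields, got {stripped!r}"
                )
            d, m = fields[0], fields[1]
            di = diseases.setdefault(d, len(diseases))
            mi = microbes.setdefault(m, len(microbes))
            pairs.add((di, mi))
    if not pairs:
        raise ValueError(f"{path}: no associations")
    A = np.zeros((len(diseases), len(microbes)))
    for di, mi in pairs:
        A[di, mi] = 1.0
    return AssociationDataset(list(diseases), list(microbes), A)


def write_associations(dataset: AssociationDataset, path, header: list[str] | None = None) -> None:
    """Write the known pairs back out as the standard TSV edge list."""
    with open(path, "w", encoding="utf-8") as fh:
        for line in header or []:
            fh.write(f"# {line}\n")
        for i, j in dataset.positive_pairs():
            fh.write(f"{dataset.disease_names[i]}\t{dataset.microbe_names[j]}\n")


def write_rankings(
    scores: np.ndarray,
    dataset: AssociationDataset,
    path,
    only_unknown: bool = False,
    header: list[str] | None = None,
) -> None:
    """Write a ranked prediction table as TSV.

    Columns are disease, microbe, score, rank; rows are sorted by
    descending score with ties broken by (disease index, microbe index)
    so output is deterministic. With ``only_unknown`` the already-known
    pairs (adjacency 1) are dropped, leaving only novel candidates.
    Scores are printed with 6 significant digits.
    """
    scores = np.asarray(getattr(scores, "scores", scores), dtype=float)
    if scores.shape != dataset.adjacency.shape:
        raise ValueError("score matrix does not match dataset dimensions")
    rows = []
    for i in range(dataset.n_diseases):
        for j in range(dataset.n_microbes):
            if only_unknown and dataset.adjacency[i, j] == 1:
                continue
            rows.append((-scores[i, j], i, j))
    rows.sort()
    with open(path, "w", encoding="utf-8") as fh:
        for line in header or []:
            fh.write(f"# {line}\n")
        fh.write("disease\tmicrobe\tscore\trank\n")
        for rank, (neg, i, j) in enumerate(rows, start=1):
            fh.write(
                f"{dataset.disease_names[i]}\t{dataset.microbe_names[j]}\t"
                f"{-neg:.6g}\t{rank}\n"
            )
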