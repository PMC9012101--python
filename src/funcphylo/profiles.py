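"""Per-genome term profiles and the matrices derived from them.

Each genome contributes a leaf term set T (the unique GO terms annotated
to any of its genes).  Ancestor closure over ``is_a`` yields S, and the
S sets drive both tree-building routes:

* a symmetric matrix of Jaccard distances
  ``d_ab = 1 - |S_a ∩ S_b| / |S_a ∪ S_b|`` feeding neighbor joining;
* a genome x term presence/absence matrix (rows = genomes, columns =
  sorted term union) feeding binary-character parsimony.

Distances are computed on the closed sets S by default; ``use_closed=
False`` switches to the raw T sets for sensitivity analysis.  Two empty
sets have distance 0 by convention (identity of indiscernibles).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import IO, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .ontology import OntologyGraph

__all__ = [
    "TermProfile",
    "DistanceMatrix",
    "BinaryMatrix",
    "build_profiles",
    "jaccard_distance",
    "pairwise_distances",
    "to_binary_matrix",
    "write_phylip_distances",
    "read_phylip_distances",
    "write_phylip_characters",
]


@dataclass(frozen=True)
class TermProfile:
    """A genome's leaf term set T and its ancestor closure S (T ⊆ S)."""

    genome_label: str
    T: frozenset[str]
    S: frozenset[str]

    def __post_init__(self) -> None:
        if not self.T <= self.S:
            raise ValueError(f"{self.genome_label}: T must be a subset of S")


@dataclass
class DistanceMatrix:
    """Symmetric genome-by-genome distance matrix with zero diagonal."""

    labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.labels = tuple(self.labels)
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("matrix shape does not match label count")
        if len(set(self.labels)) != n:
            raise ValueError("duplicate genome labels")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix must be symmetric")
        if np.any(np.diag(self.values) != 0):
            raise ValueError("distance matrix diagonal must be zero")
        if np.any(self.values < 0) or np.any(self.values > 1 + 1e-12):
            raise ValueError("Jaccard distances must lie in [0, 1]")

    def __getitem__(self, pair: tuple[str, str]) -> float:
        i = self.labels.index(pair[0])
        j = self.labels.index(pair[1])
        return float(self.values[i, j])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)


@dataclass
class BinaryMatrix:
    """Genome x term 0/1 presence matrix; columns lexicographically sorted."""

    row_labels: tuple[str, ...]
    column_labels: tuple[str, ...]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.row_labels = tuple(self.row_labels)
        self.column_labels = tuple(self.column_labels)
        self.values = np.asarray(self.values, dtype=np.uint8)
        if self.values.shape != (len(self.row_labels), len(self.column_labels)):
            raise ValueError("matrix shape does not match labels")
        if list(self.column_labels) != sorted(set(self.column_labels)):
            raise ValueError("column labels must be unique and sorted")
        if not np.isin(self.values, (0, 1)).all():
            raise ValueError("cells must be 0 or 1")

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=self.row_labels, columns=self.column_labels
        )


def build_profiles(
    term_sets: Mapping[str, Iterable[str]], graph: OntologyGraph
) -> list[TermProfile]:
    """Close each genome's T into S, reporting unknown terms per genome."""
    profiles = []
    errors = []
    for genome in term_sets:
        T = frozenset(term_sets[genome])
        try:
            S = graph.close_term_set(T)
        except Exception as exc:
            errors.append(f"{genome}: {exc}")
            continue
        profiles.append(TermProfile(genome_label=genome, T=T, S=S))
    if errors:
        raise ValueError("; ".join(errors))
    return profiles


def jaccard_distance(set_a: Iterable[str], set_b: Iterable[str]) -> float:
    """1 - |A ∩ B| / |A ∪ B|; 0 when both sets are empty."""
    a, b = set(set_a), set(set_b)
    union = len(a | b)
    if union == 0:
        return 0.0
    return 1.0 - len(a & b) / union


def pairwise_distances(
    profiles: Sequence[TermProfile], use_closed: bool = True
) -> DistanceMatrix:
    """Jaccard distance matrix over the profiles' S (or T) sets."""
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    labels = tuple(p.genome_label for p in profiles)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate genome labels")
    sets = [p.S if use_closed else p.T for p in profiles]
    n = len(sets)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = jaccard_distance(sets[i], sets[j])
    return DistanceMatrix(labels=labels, values=d)


def to_binary_matrix(
    profiles: Sequence[TermProfile], use_closed: bool = True
) -> BinaryMatrix:
    """Presence/absence matrix over the sorted union of all S sets.

    Constant (all-0 / all-1) columns are retained; the column order is
    independent of the input profile order.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two profiles")
    sets = [p.S if use_closed else p.T for p in profiles]
    columns = tuple(sorted(set().union(*sets)))
    index = {t: j for j, t in enumerate(columns)}
    values = np.zeros((len(profiles), len(columns)), dtype=np.uint8)
    for i, s in enumerate(sets):
        for t in s:
            values[i, index[t]] = 1
    return BinaryMatrix(
        row_labels=tuple(p.genome_label for p in profiles),
        column_labels=columns,
        values=values,
    )


def _phylip_names(labels: Sequence[str], strict: bool) -> list[str]:
    if not strict:
        return list(labels)
    truncated = [lab[:10] for lab in labels]
    if len(set(truncated)) != len(truncated):
        clashes = sorted(
            {t for t in truncated if truncated.count(t) > 1}
        )
        raise ValueError(
            "strict PHYLIP names collide after 10-character truncation: "
            + ", ".join(clashes)
        )
    return [t.ljust(10) for t in truncated]


def write_phylip_distances(
    matrix: DistanceMatrix, stream: IO[str], strict: bool = False
) -> None:
    """Square PHYLIP distance format: count line, then name + row."""
    names = _phylip_names(matrix.labels, strict)
    stream.write(f"{len(matrix.labels)}\n")
    for name, row in zip(names, matrix.values):
        vals = "  ".join(f"{v:.6f}" for v in row)
        stream.write(f"{name}  {vals}\n")


def read_phylip_distances(stream: IO[str] | str) -> DistanceMatrix:
    if isinstance(stream, str):
        lines = stream.splitlines()
    else:
        lines = stream.read().splitlines()
    n = int(lines[0].split()[0])
    labels, rows = [], []
    for line in lines[1 : n + 1]:
        parts = line.split()
        labels.append(parts[0])
        rows.append([float(x) for x in parts[1 : n + 1]])
    return DistanceMatrix(labels=tuple(labels), values=np.array(rows))


def write_phylip_characters(
    matrix: BinaryMatrix, stream: IO[str], strict: bool = False
) -> None:
    """PHYLIP discrete-character (0/1) matrix."""
    names = _phylip_names(matrix.row_labels, strict)
    stream.write(f"{len(matrix.row_labels)} {len(matrix.column_labels)}\n")
    for name, row in zip(names, matrix.values):
        stream.write(f"{name}  {''.join(str(int(v)) for v in row)}\n")
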