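"""Genome-ablation diagnostics against a reference cladogram.

When a functional-profile dendrogram conflicts with the accepted
species phylogeny, the genomes responsible can be located by rebuilding
the tree with genomes left out.  Two strategies are provided:

* ``leave_one_out`` — rebuild with each configured exclusion set
  removed (singletons, or named multi-genome sets such as "both
  Medicago accessions") and report whether the resulting topology
  agrees with the reference.
* ``minimal_removal_search`` — enumerate all genome subsets of size
  0, 1, ..., kmax in order and return *every* smallest subset whose
  removal restores agreement, together with how often each genome
  participates in a solution.

Agreement is deliberately one-sided: after contracting the configured
"disregard" groups (e.g. the within-species maize accessions, whose
internal arrangement carries no phylogenetic expectation) and
restricting the reference to the surviving taxa, the candidate agrees
iff every *resolved* split of the reference occurs in it.  Polytomies
in the reference therefore impose no constraint.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .ontology import OntologyGraph
from .resampling import _build_tree
from . import trees as _trees

__all__ = [
    "ReferenceComparison",
    "AblationResult",
    "RemovalSearchResult",
    "topology_agrees",
    "leave_one_out",
    "minimal_removal_search",
]


@dataclass
class ReferenceComparison:
    reference: _trees.Tree
    disregard_groups: dict[str, frozenset[str]] = field(default_factory=dict)
    outgroup: str | None = None

    def __post_init__(self) -> None:
        leaves = _trees.leaf_labels(self.reference)
        if self.outgroup is not None and self.outgroup not in leaves:
            raise ValueError(f"outgroup {self.outgroup!r} not in reference")
        self.disregard_groups = {
            name: frozenset(members)
            for name, members in self.disregard_groups.items()
        }
        for name, members in self.disregard_groups.items():
            extra = members - leaves
            if extra:
                raise ValueError(
                    f"disregard group {name!r}: unknown taxa {sorted(extra)}"
                )


def _contract_restricted(
    tree: _trees.Tree,
    groups: Mapping[str, frozenset[str]],
    taxa: frozenset[str],
) -> _trees.Tree:
    """Restrict to ``taxa`` then contract the surviving part of each
    disregard group."""
    work = _trees.restrict_to_taxa(tree, taxa & _trees.leaf_labels(tree))
    surviving = {
        name: members & taxa
        for name, members in groups.items()
        if len(members & taxa) >= 1
    }
    if surviving:
        work = _trees.contract_groups(work, surviving)
    return work


def topology_agrees(
    tree: _trees.Tree,
    comparison: ReferenceComparison,
    taxa: Iterable[str] | None = None,
) -> bool:
    """True iff every resolved split of the (restricted, contracted)
    reference is present in the candidate tree.  A disregard group that
    is not monophyletic in the candidate counts as disagreement."""
    if taxa is None:
        taxa = _trees.leaf_labels(tree)
    taxa = frozenset(taxa)
    try:
        cand = _contract_restricted(tree, comparison.disregard_groups, taxa)
    except ValueError:
        return False
    ref = _contract_restricted(
        comparison.reference, comparison.disregard_groups, taxa
    )
    return _trees.splits(ref) <= _trees.splits(cand)


@dataclass
class AblationResult:
    trees: dict[str, _trees.Tree]
    agreement: dict[str, bool]

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                {"exclusion": name, "agrees": self.agreement[name]}
                for name in self.trees
            ]
        )


def leave_one_out(
    term_sets: Mapping[str, frozenset[str]],
    graph: OntologyGraph,
    comparison: ReferenceComparison,
    exclusion_sets: Mapping[str, Iterable[str]] | None = None,
    tree_method: str = "nj",
) -> AblationResult:
    """Rebuild the tree under each exclusion and test reference
    agreement.  By default every genome is excluded singly."""
    genomes = sorted(term_sets)
    if exclusion_sets is None:
        exclusion_sets = {g: {g} for g in genomes}
    result_trees: dict[str, _trees.Tree] = {}
    agreement: dict[str, bool] = {}
    for name in exclusion_sets:
        excluded = set(exclusion_sets[name])
        unknown = excluded - set(genomes)
        if unknown:
            raise ValueError(
                f"exclusion {name!r}: unknown genomes {sorted(unknown)}"
            )
        remaining = {g: term_sets[g] for g in genomes if g not in excluded}
        if len(remaining) < 3:
            raise ValueError(
                f"exclusion {name!r} leaves fewer than 3 genomes"
            )
        tree = _build_tree(remaining, graph, tree_method)
        result_trees[name] = tree
        agreement[name] = topology_agrees(tree, comparison)
    return AblationResult(trees=result_trees, agreement=agreement)


@dataclass
class RemovalSearchResult:
    k: int | None  # size of the minimal removal sets; None if no solution
    solutions: list[tuple[str, ...]]
    frequencies: pd.DataFrame  # genome, n_solutions
    n_evaluated: int

    @property
    def found(self) -> bool:
        return self.k is not None


def minimal_removal_search(
    term_sets: Mapping[str, frozenset[str]],
    graph: OntologyGraph,
    comparison: ReferenceComparison,
    kmax: int,
    tree_method: str = "nj",
    stop_at_first_k: bool = True,
) -> RemovalSearchResult:
    """Find every smallest genome subset whose removal restores
    agreement with the reference.

    Subsets are enumerated in size order (all C(n, k) subsets at each
    k); by default the search stops at the first size with at least one
    solution.  ``stop_at_first_k=False`` keeps enumerating up to
    ``kmax`` so non-minimal solutions can be inspected too.
    """
    genomes = sorted(term_sets)
    if kmax < 0:
        raise ValueError("kmax must be >= 0")
    if len(genomes) - kmax < 3:
        raise ValueError("removing kmax genomes would leave fewer than 3")
    solutions: list[tuple[str, ...]] = []
    minimal_k: int | None = None
    n_evaluated = 0
    for k in range(kmax + 1):
        level: list[tuple[str, ...]] = []
        for removal in itertools.combinations(genomes, k):
            n_evaluated += 1
            remaining = {
                g: term_sets[g] for g in genomes if g not in removal
            }
            tree = _build_tree(remaining, graph, tree_method)
            if topology_agrees(tree, comparison):
                level.append(removal)
        if level:
            if minimal_k is None:
                minimal_k = k
            solutions.extend(sorted(level))
            if stop_at_first_k:
                break
    counts = {g: 0 for g in genomes}
    minimal_solutions = [s for s in solutions if len(s) == (minimal_k or 0)]
    for sol in minimal_solutions:
        for g in sol:
            counts[g] += 1
    freq = (
        pd.DataFrame(
            [{"genome": g, "n_solutions": c} for g, c in counts.items()]
        )
        .sort_values(["n_solutions", "genome"], ascending=[False, True])
        .reset_index(drop=True)
    )
    return RemovalSearchResult(
        k=minimal_k,
        solutions=solutions,
        frequencies=freq,
        n_evaluated=n_evaluated,
    )
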