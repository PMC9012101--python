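"""Term-jackknife branch support and the stability (deviation) sweep.

Branch support is assessed by deleting a fixed fraction of the GO terms
(columns of the underlying data) without replacement, re-adding
ancestors of the surviving leaf terms, rebuilding the tree, and
repeating.  The defaults — remove 40% of terms, 100 replicates,
majority-rule consensus with per-split frequencies — follow standard
practice for character jackknifing of presence/absence profiles.

Sampling is over the *global union* of all genomes' leaf term sets by
default (every genome loses the same terms, the column reading);
``per_genome=True`` instead removes the fraction independently within
each genome's T.  Sampling always precedes ancestor closure, so an
ancestor survives only if one of its retained descendants does.

The stability sweep removes 5%..95% of terms in 5% increments and
reports the smallest removal fraction at which the consensus topology
deviates (Robinson–Foulds > 0) from the full-data tree.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .ontology import OntologyGraph
from .profiles import build_profiles, pairwise_distances, to_binary_matrix
from . import trees as _trees

__all__ = [
    "JackknifeConfig",
    "JackknifeResult",
    "StabilityResult",
    "jackknife_replicate",
    "jackknife_support",
    "stability_sweep",
    "DEFAULT_SWEEP_FRACTIONS",
    "retained_term_count",
]

DEFAULT_SWEEP_FRACTIONS = tuple(round(0.05 * k, 2) for k in range(1, 20))


def retained_term_count(n_terms: int, fraction: float) -> int:
    """Number of terms surviving a jackknife draw:
    floor((1 - fraction) * n_terms)."""
    return int(np.floor((1.0 - fraction) * n_terms))


@dataclass(frozen=True)
class JackknifeConfig:
    fraction: float = 0.40
    replicates: int = 100
    seed: int = 0
    tree_method: str = "nj"
    per_genome: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction < 1.0:
            raise ValueError("fraction must lie strictly between 0 and 1")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")
        if self.tree_method not in ("nj", "parsimony"):
            raise ValueError("tree_method must be 'nj' or 'parsimony'")


def _build_tree(
    term_sets: Mapping[str, frozenset[str]],
    graph: OntologyGraph,
    tree_method: str,
    seed: int = 0,
) -> _trees.Tree:
    profiles = build_profiles(term_sets, graph)
    if tree_method == "nj":
        return _trees.neighbor_joining(pairwise_distances(profiles))
    result = _trees.parsimony_search(to_binary_matrix(profiles), seed=seed)
    return result.tree


def jackknife_replicate(
    term_sets: Mapping[str, frozenset[str]],
    graph: OntologyGraph,
    fraction: float,
    rng: np.random.Generator,
    tree_method: str = "nj",
    per_genome: bool = False,
) -> _trees.Tree:
    """One jackknife tree: drop ``fraction`` of terms, close, rebuild.

    In global mode ``floor((1 - fraction) * |union|)`` terms of the
    union of all T sets are retained and each genome keeps its
    intersection with them.
    """
    if per_genome:
        reduced = {}
        for genome in sorted(term_sets):
            terms = sorted(term_sets[genome])
            n_keep = retained_term_count(len(terms), fraction)
            if n_keep == 0:
                raise ValueError(
                    f"{genome}: jackknife fraction {fraction} retains no terms"
                )
            keep = rng.choice(len(terms), size=n_keep, replace=False)
            reduced[genome] = frozenset(terms[i] for i in keep)
    else:
        union = sorted(set().union(*(term_sets[g] for g in term_sets)))
        n_keep = retained_term_count(len(union), fraction)
        if n_keep == 0:
            raise ValueError(
                f"jackknife fraction {fraction} retains no terms "
                f"(union size {len(union)})"
            )
        keep_idx = rng.choice(len(union), size=n_keep, replace=False)
        retained = frozenset(union[i] for i in keep_idx)
        reduced = {
            genome: frozenset(term_sets[genome]) & retained
            for genome in sorted(term_sets)
        }
    replicate_seed = int(rng.integers(0, 2**31 - 1))
    return _build_tree(reduced, graph, tree_method, seed=replicate_seed)


@dataclass
class JackknifeResult:
    consensus: _trees.Tree
    annotated_full: _trees.Tree
    frequencies: dict[frozenset[str], float]
    config: JackknifeConfig

    def split_table(self) -> pd.DataFrame:
        rows = [
            {"split": "|".join(sorted(side)), "support_pct": round(freq, 4)}
            for side, freq in self.frequencies.items()
        ]
        return (
            pd.DataFrame(rows, columns=["split", "support_pct"])
            .sort_values(["support_pct", "split"], ascending=[False, True])
            .reset_index(drop=True)
        )


def jackknife_support(
    term_sets: Mapping[str, frozenset[str]],
    graph: OntologyGraph,
    config: JackknifeConfig,
    full_tree: _trees.Tree | None = None,
) -> JackknifeResult:
    """Run the full jackknife: replicates, consensus, and the full-data
    tree annotated with each split's replicate frequency."""
    if full_tree is None:
        full_tree = _build_tree(
            term_sets, graph, config.tree_method, seed=config.seed
        )
    rng = np.random.default_rng(config.seed)
    replicate_trees = [
        jackknife_replicate(
            term_sets, graph, config.fraction, rng,
            tree_method=config.tree_method, per_genome=config.per_genome,
        )
        for _ in range(config.replicates)
    ]
    frequencies = _trees.split_frequencies(replicate_trees)
    consensus = _trees.majority_rule_consensus(replicate_trees)
    annotated = _trees.annotate_supports(full_tree, frequencies)
    return JackknifeResult(
        consensus=consensus,
        annotated_full=annotated,
        frequencies=frequencies,
        config=config,
    )


@dataclass
class StabilityResult:
    table: pd.DataFrame  # fraction, rf_consensus_vs_full, n_replicates
    consensus_trees: dict[float, _trees.Tree]
    deviation_threshold: float | None

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"StabilityResult(threshold={self.deviation_threshold}, "
            f"fractions={len(self.table)})"
        )


def stability_sweep(
    term_sets: Mapping[str, frozenset[str]],
    graph: OntologyGraph,
    fractions: Sequence[float] = DEFAULT_SWEEP_FRACTIONS,
    replicates: int = 100,
    seed: int = 0,
    tree_method: str = "nj",
    full_tree: _trees.Tree | None = None,
) -> StabilityResult:
    """Jackknife at each fraction; the deviation threshold is the
    smallest fraction whose majority-rule consensus differs from the
    full-data tree (unrooted RF > 0), or None if none does."""
    if full_tree is None:
        full_tree = _build_tree(term_sets, graph, tree_method, seed=seed)
    rows = []
    consensus_trees: dict[float, _trees.Tree] = {}
    threshold = None
    for fraction in fractions:
        config = JackknifeConfig(
            fraction=fraction, replicates=replicates, seed=seed,
            tree_method=tree_method,
        )
        result = jackknife_support(term_sets, graph, config, full_tree)
        rf = _trees.rf_distance(result.consensus, full_tree)
        consensus_trees[fraction] = result.consensus
        rows.append(
            {"fraction": fraction, "rf_vs_full": rf, "n_replicates": replicates}
        )
        if threshold is None and rf > 0:
            threshold = fraction
    table = pd.DataFrame(rows)
    return StabilityResult(
        table=table,
        consensus_trees=consensus_trees,
        deviation_threshold=threshold,
    )
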