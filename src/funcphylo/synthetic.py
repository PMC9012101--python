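"""Synthetic ontologies and annotation sets with planted structure.

Every stage of the profile pipeline can be exercised without external
downloads by generating:

* a GO-like ontology — three aspects, one root each, terms arranged in
  levels with ``is_a`` parents drawn from strictly shallower levels
  (acyclicity by construction), plus a configurable number of
  alternative identifiers and obsolete terms;
* per-genome leaf term sets evolved along a planted tree under
  independent per-term gain/loss: over a branch of length ``l`` a
  present term is lost with probability ``1 - exp(-loss_rate * l)`` and
  an absent eligible term gained with probability
  ``1 - exp(-gain_rate * l)``, so expected profile divergence grows
  with path length;
* GAF 2.1 files for those profiles, optionally with injected "dirt"
  (exact duplicates, qualifier rows, obsolete-term rows, and alt-id
  rows that collide after merging) whose true counts are recorded so
  cleaning can be verified against ground truth.

Dirt is appended, never substituted, so cleaning a dirty file recovers
exactly the true leaf term set.  All outputs are reproducible from
(config, seed).
"""

from __future__ import annotations

import io
import json
import math
from dataclasses import asdict, dataclass
from typing import Mapping

import numpy as np

from .annotations import AnnotationRecord, AnnotationSet, read_gaf, write_gaf
from .ontology import OntologyGraph, TermRecord, write_obo
from . import trees as _trees

__all__ = [
    "DirtConfig",
    "SyntheticConfig",
    "TruthBundle",
    "SyntheticBundle",
    "generate_ontology",
    "eligible_terms",
    "evolve_profiles",
    "profiles_to_gaf",
    "inject_dirt",
    "generate_bundle",
    "DEFAULT_PLANTED_TREE",
]

#: 12 genomes, three balanced quartets, unit branch lengths throughout.
DEFAULT_PLANTED_TREE = (
    "(((G01:1,G02:1):1,(G03:1,G04:1):1):1,"
    "((G05:1,G06:1):1,(G07:1,G08:1):1):1,"
    "((G09:1,G10:1):1,(G11:1,G12:1):1):1);"
)


@dataclass(frozen=True)
class DirtConfig:
    duplicates: int = 5
    qualifier_rows: int = 3
    obsolete_rows: int = 2
    alt_id_rows: int = 2

    def total(self) -> int:
        return (
            self.duplicates + self.qualifier_rows
            + self.obsolete_rows + self.alt_id_rows
        )


@dataclass(frozen=True)
class SyntheticConfig:
    """Defaults give ~600 eligible terms, a 12-genome planted tree and
    moderate gain/loss, enough signal for exact topology recovery."""

    aspect_term_counts: tuple[tuple[str, int], ...] = (
        ("C", 120), ("F", 160), ("P", 320)
    )
    depth: int = 6
    max_parents: int = 2
    n_alt_ids: int = 12
    n_obsolete: int = 10
    planted_tree: str = DEFAULT_PLANTED_TREE
    root_profile_size: int = 240
    loss_rate: float = 0.05
    gain_rate: float = 0.05
    n_genes: int = 200
    dirt: DirtConfig = DirtConfig()

    def __post_init__(self) -> None:
        if self.loss_rate < 0 or self.gain_rate < 0:
            raise ValueError("rates must be >= 0")
        total = sum(c for _, c in self.aspect_term_counts)
        if self.root_profile_size > total:
            raise ValueError("root_profile_size exceeds eligible term count")
        if self.depth < 1 or self.max_parents < 1:
            raise ValueError("depth and max_parents must be >= 1")


@dataclass
class TruthBundle:
    planted_tree: str
    true_T: dict[str, frozenset[str]]
    dirt_counts: dict[str, dict[str, int]]
    seed: int
    config: SyntheticConfig

    def to_json(self) -> str:
        return json.dumps(
            {
                "planted_tree": self.planted_tree,
                "true_T": {g: sorted(t) for g, t in self.true_T.items()},
                "dirt_counts": self.dirt_counts,
                "seed": self.seed,
                "config": asdict(self.config),
            },
            indent=2,
            sort_keys=True,
        )


def _term_id(k: int) -> str:
    return f"GO:{k:07d}"


def generate_ontology(
    config: SyntheticConfig, seed: int
) -> tuple[OntologyGraph, str]:
    """Build a layered random DAG per aspect; returns the validated
    graph and its (deterministic) OBO serialisation."""
    rng = np.random.default_rng(seed)
    terms: dict[str, TermRecord] = {}
    next_id = 1
    alt_candidates: list[str] = []
    for aspect, count in config.aspect_term_counts:
        root_id = _term_id(next_id)
        next_id += 1
        terms[root_id] = TermRecord(
            id=root_id, name=f"{aspect} root", aspect=aspect
        )
        levels: list[list[str]] = [[root_id]]
        # spread the aspect's terms over the configured depth
        per_level = [
            count // config.depth + (1 if k < count % config.depth else 0)
            for k in range(config.depth)
        ]
        for level_idx, n_terms in enumerate(per_level, start=1):
            shallower = [t for lvl in levels for t in lvl]
            level: list[str] = []
            for _ in range(n_terms):
                tid = _term_id(next_id)
                next_id += 1
                n_parents = min(
                    int(rng.integers(1, config.max_parents + 1)),
                    len(shallower),
                )
                parent_idx = rng.choice(
                    len(shallower), size=n_parents, replace=False
                )
                terms[tid] = TermRecord(
                    id=tid,
                    name=f"{aspect} term level {level_idx}",
                    aspect=aspect,
                    parents=frozenset(shallower[i] for i in parent_idx),
                )
                level.append(tid)
                alt_candidates.append(tid)
            levels.append(level)
    aspects = [a for a, _ in config.aspect_term_counts]
    for k in range(config.n_obsolete):
        tid = _term_id(next_id)
        next_id += 1
        terms[tid] = TermRecord(
            id=tid,
            name=f"obsolete term {k}",
            aspect=aspects[k % len(aspects)],
            obsolete=True,
        )
    # alt ids: fresh identifiers attached to distinct non-root terms
    if config.n_alt_ids > len(alt_candidates):
        raise ValueError("more alt_ids requested than non-root terms")
    target_idx = rng.choice(
        len(alt_candidates), size=config.n_alt_ids, replace=False
    )
    alt_index: dict[str, str] = {}
    for i in sorted(target_idx):
        alt = _term_id(next_id)
        next_id += 1
        target = alt_candidates[i]
        rec = terms[target]
        terms[target] = TermRecord(
            id=rec.id, name=rec.name, aspect=rec.aspect,
            parents=rec.parents, alt_ids=rec.alt_ids | {alt},
            obsolete=rec.obsolete,
        )
        alt_index[alt] = target
    graph = OntologyGraph(terms=terms, alt_index=alt_index)
    graph.validate()
    buf = io.StringIO()
    write_obo(graph, buf)
    return graph, buf.getvalue()


def eligible_terms(graph: OntologyGraph) -> list[str]:
    """Annotatable terms: non-obsolete, non-root, sorted."""
    roots = set(graph.roots.values())
    return sorted(
        t for t, rec in graph.terms.items()
        if not rec.obsolete and t not in roots
    )


def evolve_profiles(
    graph: OntologyGraph, config: SyntheticConfig, seed: int,
    max_retries: int = 20,
) -> tuple[dict[str, frozenset[str]], TruthBundle]:
    """Evolve leaf term sets along the planted tree by per-term
    gain/loss; retries (bounded) if any genome ends up with no terms."""
    eligible = np.array(eligible_terms(graph))
    tree = _trees.parse_newick(config.planted_tree)
    rng = np.random.default_rng(seed)
    for _ in range(max_retries):
        root_idx = rng.choice(
            len(eligible), size=config.root_profile_size, replace=False
        )
        root_mask = np.zeros(len(eligible), dtype=bool)
        root_mask[root_idx] = True
        masks: dict = {tree.seed_node: root_mask}
        profiles: dict[str, frozenset[str]] = {}
        for node in tree.preorder_node_iter():
            if node is tree.seed_node:
                continue
            length = node.edge.length or 0.0
            p_loss = 1.0 - math.exp(-config.loss_rate * length)
            p_gain = 1.0 - math.exp(-config.gain_rate * length)
            parent_mask = masks[node.parent_node]
            u = rng.random(len(eligible))
            mask = np.where(parent_mask, u >= p_loss, u < p_gain)
            masks[node] = mask
            if node.is_leaf():
                profiles[node.taxon.label] = frozenset(eligible[mask])
        if all(profiles.values()):
            truth = TruthBundle(
                planted_tree=config.planted_tree,
                true_T=dict(profiles),
                dirt_counts={},
                seed=seed,
                config=config,
            )
            return profiles, truth
    raise RuntimeError(
        f"failed to produce nonempty leaf profiles in {max_retries} tries"
    )


def profiles_to_gaf(
    profiles: Mapping[str, frozenset[str]],
    graph: OntologyGraph,
    config: SyntheticConfig,
    seed: int,
) -> dict[str, str]:
    """One GAF 2.1 document per genome: each term annotated (evidence
    IEA) to a uniformly chosen synthetic gene, so re-reading and
    collecting the term set recovers exactly the true T."""
    rng = np.random.default_rng(seed)
    out: dict[str, str] = {}
    for genome in sorted(profiles):
        records = []
        for lineno, term in enumerate(sorted(profiles[genome]), start=1):
            gene_no = int(rng.integers(config.n_genes))
            records.append(
                AnnotationRecord(
                    gene=f"{genome}_g{gene_no:04d}",
                    qualifiers=(),
                    term=term,
                    evidence="IEA",
                    aspect=graph.terms[term].aspect,
                    source_line=lineno,
                )
            )
        aset = AnnotationSet(
            genome_label=genome, records=records,
            provenance="funcphylo synthetic",
        )
        buf = io.StringIO()
        write_gaf(aset, buf)
        out[genome] = buf.getvalue()
    return out


def inject_dirt(
    gaf_text: str,
    graph: OntologyGraph,
    config: SyntheticConfig,
    seed: int,
) -> tuple[str, dict[str, int]]:
    """Append dirt rows to a clean GAF and return the true counts that
    :func:`funcphylo.annotations.clean_annotations` must report.

    Appended rows: exact copies of existing rows; rows carrying NOT /
    contributes_to / colocalizes_with qualifiers; rows using obsolete
    terms; and rows re-annotating an existing (gene, term) pair through
    the term's alternative identifier, which become duplicates once the
    alt id is merged.
    """
    dirt = config.dirt
    rng = np.random.default_rng(seed)
    base = read_gaf(gaf_text, genome_label="_dirt_target")
    if not base.records:
        raise ValueError("cannot inject dirt into an empty GAF")
    extra: list[AnnotationRecord] = []

    dup_idx = rng.integers(0, len(base.records), size=dirt.duplicates)
    for i in dup_idx:
        extra.append(base.records[int(i)])

    qualifiers = ("NOT", "contributes_to", "colocalizes_with")
    elig = eligible_terms(graph)
    for k in range(dirt.qualifier_rows):
        term = elig[int(rng.integers(len(elig)))]
        extra.append(
            AnnotationRecord(
                gene=f"dirtq{k:03d}",
                qualifiers=(qualifiers[k % 3],),
                term=term,
                evidence="IEA",
                aspect=graph.terms[term].aspect,
            )
        )

    obsolete = sorted(t for t, r in graph.terms.items() if r.obsolete)
    if dirt.obsolete_rows and not obsolete:
        raise ValueError("obsolete dirt requested but ontology has none")
    for k in range(dirt.obsolete_rows):
        term = obsolete[k % len(obsolete)]
        extra.append(
            AnnotationRecord(
                gene=f"dirto{k:03d}",
                qualifiers=(),
                term=term,
                evidence="IEA",
                aspect=graph.terms[term].aspect,
            )
        )

    # rows whose alt id resolves onto an existing record -> post-merge dup
    alt_of: dict[str, str] = {}
    for alt, primary in graph.alt_index.items():
        alt_of.setdefault(primary, alt)
    candidates = [r for r in base.records if r.term in alt_of]
    if len(candidates) < dirt.alt_id_rows:
        raise ValueError(
            f"alt-id dirt unsatisfiable: {len(candidates)} annotated "
            f"alt-bearing terms < {dirt.alt_id_rows} requested"
        )
    pick = rng.choice(len(candidates), size=dirt.alt_id_rows, replace=False)
    for i in pick:
        rec = candidates[int(i)]
        extra.append(
            AnnotationRecord(
                gene=rec.gene,
                qualifiers=rec.qualifiers,
                term=alt_of[rec.term],
                evidence=rec.evidence,
                aspect=rec.aspect,
            )
        )

    dirty = AnnotationSet(
        genome_label="_dirty",
        records=base.records + extra,
        provenance="funcphylo synthetic (dirty)",
    )
    buf = io.StringIO()
    write_gaf(dirty, buf)
    truth = {
        "exact_duplicates": dirt.duplicates,
        "qualifier_rows": dirt.qualifier_rows,
        "obsolete_terms": dirt.obsolete_rows,
        "alt_ids_merged": dirt.alt_id_rows,
        "duplicates_after_merge": dirt.alt_id_rows,
    }
    return buf.getvalue(), truth


def random_binary_tree(
    n_leaves: int,
    rng: np.random.Generator,
    min_length: float = 0.1,
    max_length: float = 2.0,
    label_prefix: str = "T",
) -> _trees.Tree:
    """Uniform-ish random unrooted binary tree (sequential attachment
    at a random edge) with branch lengths drawn from
    U(min_length, max_length); used for inference consistency checks."""
    if n_leaves < 3:
        raise ValueError("need at least 3 leaves")
    labels = [f"{label_prefix}{i:03d}" for i in range(n_leaves)]
    adj: dict[int, list[int]] = {n_leaves: [0, 1, 2]}
    for i in range(3):
        adj[i] = [n_leaves]
    nxt = n_leaves + 1
    for k in range(3, n_leaves):
        edges = sorted((u, v) for u in adj for v in adj[u] if u < v)
        u, v = edges[int(rng.integers(len(edges)))]
        _trees._insert_leaf(adj, k, nxt, u, v)
        nxt += 1
    tree = _trees._adjacency_to_tree(adj, labels)
    for edge in tree.preorder_edge_iter():
        if edge.head_node is not tree.seed_node:
            edge.length = float(rng.uniform(min_length, max_length))
    return tree


@dataclass
class SyntheticBundle:
    graph: OntologyGraph
    obo_text: str
    clean_gafs: dict[str, str]
    dirty_gafs: dict[str, str]
    truth: TruthBundle


def generate_bundle(
    config: SyntheticConfig | None = None, seed: int = 0
) -> SyntheticBundle:
    """Full synthetic study: ontology, evolved profiles, clean and
    dirty GAFs, and the truth manifest.  Child seeds are spawned from
    ``seed`` so each stage is independently reproducible."""
    config = config or SyntheticConfig()
    ss = np.random.SeedSequence(seed)
    s_onto, s_evo, s_gaf, s_dirt = (
        int(c.generate_state(1)[0] % (2**31 - 1))
        for c in ss.spawn(4)
    )
    graph, obo_text = generate_ontology(config, s_onto)
    profiles, truth = evolve_profiles(graph, config, s_evo)
    clean = profiles_to_gaf(profiles, graph, config, s_gaf)
    dirty: dict[str, str] = {}
    for i, genome in enumerate(sorted(clean)):
        cfg_g = config
        try:
            text, counts = inject_dirt(clean[genome], graph, cfg_g, s_dirt + i)
        except ValueError:
            # genome annotates fewer alt-bearing terms than requested
            # alt-dirt rows; scale that class down for this genome
            alt_of = set(graph.alt_index.values())
            aset = read_gaf(clean[genome], genome_label=genome)
            avail = sum(1 for r in aset.records if r.term in alt_of)
            cfg_g = SyntheticConfig(
                **{
                    **asdict(config),
                    "dirt": DirtConfig(
                        duplicates=config.dirt.duplicates,
                        qualifier_rows=config.dirt.qualifier_rows,
                        obsolete_rows=config.dirt.obsolete_rows,
                        alt_id_rows=min(config.dirt.alt_id_rows, avail),
                    ),
                    "aspect_term_counts": config.aspect_term_counts,
                }
            )
            text, counts = inject_dirt(clean[genome], graph, cfg_g, s_dirt + i)
        dirty[genome] = text
        truth.dirt_counts[genome] = counts
    return SyntheticBundle(
        graph=graph,
        obo_text=obo_text,
        clean_gafs=clean,
        dirty_gafs=dirty,
        truth=truth,
    )
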