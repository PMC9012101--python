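"""Ontology handling: OBO parsing, validation, and ancestor closure.

The Gene Ontology is a directed acyclic graph of terms partitioned into
three aspects (sub-ontologies): cellular component (C), molecular
function (F) and biological process (P).  For profile construction only
the transitive ``is_a`` relation matters: a genome annotated with a term
implicitly carries every ancestor of that term up to the aspect root.
This module parses the OBO flat-file subset needed for that closure
(``id``, ``name``, ``namespace``, ``is_a``, ``alt_id``, ``is_obsolete``,
plus ``replaced_by``/``consider`` which are recorded but never applied
automatically) and validates the result into an :class:`OntologyGraph`.

Other relationship types (``part_of``, ``regulates``, ...) are ignored
by design: closure is defined over ``is_a`` only.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field
from typing import IO, Iterable

import networkx as nx
import obonet

__all__ = [
    "TermRecord",
    "OntologyGraph",
    "OntologyError",
    "parse_obo",
    "write_obo",
]

_NAMESPACE_TO_ASPECT = {
    "cellular_component": "C",
    "molecular_function": "F",
    "biological_process": "P",
}
_ASPECT_TO_NAMESPACE = {v: k for k, v in _NAMESPACE_TO_ASPECT.items()}


class OntologyError(ValueError):
    """Raised when an OBO document violates the graph contract."""


@dataclass(frozen=True)
class TermRecord:
    """A single ontology term.

    ``parents`` holds ``is_a`` parents only.  ``alt_ids`` are secondary
    identifiers that downstream annotation cleaning rewrites to ``id``.
    """

    id: str
    name: str
    aspect: str
    parents: frozenset[str] = frozenset()
    alt_ids: frozenset[str] = frozenset()
    obsolete: bool = False
    replaced_by: tuple[str, ...] = ()
    consider: tuple[str, ...] = ()

    @property
    def namespace(self) -> str:
        return _ASPECT_TO_NAMESPACE[self.aspect]


@dataclass
class OntologyGraph:
    """Validated ``is_a`` DAG over :class:`TermRecord` objects.

    Invariants (enforced by :func:`parse_obo` / :meth:`validate`):

    * the ``is_a`` relation is acyclic;
    * primary identifiers are unique and disjoint from alternative ids;
    * every non-obsolete, non-root term has at least one ``is_a`` parent;
    * ``is_a`` edges never cross aspects.
    """

    terms: dict[str, TermRecord]
    alt_index: dict[str, str] = field(default_factory=dict)
    roots: dict[str, str] = field(default_factory=dict)
    _ancestor_cache: dict[str, frozenset[str]] = field(
        default_factory=dict, repr=False, compare=False
    )

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def is_primary(self, term_id: str) -> bool:
        return term_id in self.terms

    def is_obsolete(self, term_id: str) -> bool:
        rec = self.terms.get(term_id)
        return rec is not None and rec.obsolete

    def resolve(self, term_id: str) -> str | None:
        """Map a primary or alternative identifier to its primary id."""
        if term_id in self.terms:
            return term_id
        return self.alt_index.get(term_id)

    # -- closure ---------------------------------------------------------

    def ancestors(self, term_id: str) -> frozenset[str]:
        """All terms reachable from ``term_id`` via one or more ``is_a``
        steps (the term itself excluded)."""
        if term_id not in self.terms:
            raise OntologyError(f"unknown term identifier: {term_id!r}")
        cached = self._ancestor_cache.get(term_id)
        if cached is not None:
            return cached
        acc: set[str] = set()
        for parent in self.terms[term_id].parents:
            acc.add(parent)
            acc |= self.ancestors(parent)
        result = frozenset(acc)
        self._ancestor_cache[term_id] = result
        return result

    def close_term_set(self, term_set: Iterable[str]) -> frozenset[str]:
        """Ancestor closure: T -> S = T plus every ``is_a`` ancestor.

        The result is a superset of the input and the operation is
        idempotent.  Obsolete terms are invalid closure inputs.
        """
        terms = set(term_set)
        bad = sorted(
            t for t in terms if t not in self.terms or self.terms[t].obsolete
        )
        if bad:
            raise OntologyError(
                "terms not valid for closure (unknown or obsolete): "
                + ", ".join(bad)
            )
        closed = set(terms)
        for t in terms:
            closed |= self.ancestors(t)
        return frozenset(closed)

    # -- validation ------------------------------------------------------

    def validate(self) -> None:
        ids = set(self.terms)
        colliding = sorted(ids & set(self.alt_index))
        if colliding:
            raise OntologyError(
                "alternative identifiers collide with primary ids: "
                + ", ".join(colliding)
            )
        dag = nx.DiGraph()
        dag.add_nodes_from(ids)
        for rec in self.terms.values():
            for parent in rec.parents:
                if parent not in ids:
                    raise OntologyError(
                        f"{rec.id}: is_a target {parent!r} is not a known term"
                    )
                dag.add_edge(rec.id, parent)
        if not nx.is_directed_acyclic_graph(dag):
            cycle = nx.find_cycle(dag)
            path = " -> ".join(edge[0] for edge in cycle) + f" -> {cycle[-1][1]}"
            raise OntologyError(f"is_a cycle detected: {path}")
        for rec in self.terms.values():
            if rec.obsolete:
                continue
            for parent in rec.parents:
                prec = self.terms[parent]
                if prec.obsolete:
                    warnings.warn(
                        f"{rec.id} has obsolete is_a parent {parent}",
                        stacklevel=2,
                    )
                elif prec.aspect != rec.aspect:
                    raise OntologyError(
                        f"cross-aspect is_a edge {rec.id} ({rec.aspect}) -> "
                        f"{parent} ({prec.aspect})"
                    )
        roots: dict[str, str] = {}
        for rec in sorted(self.terms.values(), key=lambda r: r.id):
            if rec.obsolete or rec.parents:
                continue
            if rec.aspect in roots:
                raise OntologyError(
                    f"multiple roots in aspect {rec.aspect}: "
                    f"{roots[rec.aspect]} and {rec.id}"
                )
            roots[rec.aspect] = rec.id
        self.roots = roots


def _as_list(value) -> list[str]:
    if value is None:
        return []
    if isinstance(value, str):
        return [value]
    return list(value)


def parse_obo(stream: IO[str] | str) -> OntologyGraph:
    """Parse OBO 1.2/1.4 text into a validated :class:`OntologyGraph`.

    Only ``[Term]`` stanzas are interpreted; typedefs and relationship
    types other than ``is_a`` are ignored.  Raises :class:`OntologyError`
    on duplicate ids, alt-id/primary collisions, dangling ``is_a``
    targets, cross-aspect edges, or cycles.
    """
    if isinstance(stream, str):
        stream = io.StringIO(stream)
    graph = obonet.read_obo(stream, ignore_obsolete=False)

    terms: dict[str, TermRecord] = {}
    alt_index: dict[str, str] = {}
    for node_id, data in graph.nodes(data=True):
        if "name" not in data and "is_obsolete" not in data:
            # obonet materialises dangling is_a targets as bare nodes
            continue
        namespace = data.get("namespace", "")
        aspect = _NAMESPACE_TO_ASPECT.get(namespace)
        obsolete = str(data.get("is_obsolete", "false")).lower() == "true"
        if aspect is None:
            if not obsolete:
                raise OntologyError(
                    f"{node_id}: missing or unknown namespace {namespace!r}"
                )
            aspect = "P"  # obsolete stanzas may omit the namespace
        rec = TermRecord(
            id=node_id,
            name=data.get("name", ""),
            aspect=aspect,
            parents=frozenset(_as_list(data.get("is_a"))),
            alt_ids=frozenset(_as_list(data.get("alt_id"))),
            obsolete=obsolete,
            replaced_by=tuple(_as_list(data.get("replaced_by"))),
            consider=tuple(_as_list(data.get("consider"))),
        )
        if node_id in terms:
            raise OntologyError(f"duplicate primary identifier: {node_id}")
        terms[node_id] = rec
        for alt in rec.alt_ids:
            if alt in alt_index and alt_index[alt] != node_id:
                raise OntologyError(
                    f"alt_id {alt} claimed by both {alt_index[alt]} and {node_id}"
                )
            alt_index[alt] = node_id

    # dangling is_a targets: nodes obonet created without a stanza
    known = set(terms)
    for rec in terms.values():
        for parent in rec.parents:
            if parent not in known:
                raise OntologyError(
                    f"{rec.id}: is_a target {parent!r} is not a known term"
                )

    onto = OntologyGraph(terms=terms, alt_index=alt_index)
    onto.validate()
    return onto


def write_obo(graph: OntologyGraph, stream: IO[str]) -> None:
    """Write a deterministic OBO document (terms sorted by identifier)."""
    stream.write("format-version: 1.2\n")
    stream.write("ontology: funcphylo-synthetic\n")
    for term_id in sorted(graph.terms):
        rec = graph.terms[term_id]
        stream.write("\n[Term]\n")
        stream.write(f"id: {rec.id}\n")
        stream.write(f"name: {rec.name}\n")
        stream.write(f"namespace: {rec.namespace}\n")
        for alt in sorted(rec.alt_ids):
            stream.write(f"alt_id: {alt}\n")
        for parent in sorted(rec.parents):
            stream.write(f"is_a: {parent}\n")
        if rec.obsolete:
            stream.write("is_obsolete: true\n")
        for rb in rec.replaced_by:
            stream.write(f"replaced_by: {rb}\n")
        for c in rec.consider:
            stream.write(f"consider: {c}\n")


def ancestors(graph: OntologyGraph, term_id: str) -> frozenset[str]:
    """Functional alias for :meth:`OntologyGraph.ancestors`."""
    return graph.ancestors(term_id)


def close_term_set(graph: OntologyGraph, term_set: Iterable[str]) -> frozenset[str]:
    """Functional alias for :meth:`OntologyGraph.close_term_set`."""
    return graph.close_term_set(term_set)
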