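"""GAF 2.1 annotation sets: reading, cleaning, filtering, quantifying.

A GAF (GO Annotation File) row associates a gene product with a GO term,
carrying qualifier tokens (column 4), an evidence code (column 7) and the
term's aspect (column 9).  Genome-scale annotation sets routinely contain
exact duplicates, negated or modifier-qualified rows (``NOT``,
``contributes_to``, ``colocalizes_with``), rows pointing at obsolete
terms, and rows using secondary (alternative) term identifiers.  All of
these must be removed or normalised before the term sets of different
genomes can be compared, and the removals must be accounted for.

Cleaning applies five ordered rules:

1. drop exact duplicate records on (gene, term, evidence, qualifiers);
2. drop records whose qualifiers intersect
   {NOT, contributes_to, colocalizes_with};
3. drop records whose term is obsolete;
4. rewrite alternative term identifiers to their primary identifier
   (a rewrite whose primary target is itself obsolete is dropped and
   counted as obsolete);
5. drop duplicates newly created by step 4.

The :class:`CleaningReport` satisfies
``input_count - (exact_duplicates + qualifier_rows + obsolete_terms +
duplicates_after_merge) = output_count`` — alt-id merging rewrites
records rather than removing them.
"""

from __future__ import annotations

import re
import statistics
from dataclasses import dataclass, field, replace
from typing import IO, Iterable

import pandas as pd

from .ontology import OntologyGraph

__all__ = [
    "AnnotationRecord",
    "AnnotationSet",
    "CleaningReport",
    "GafError",
    "read_gaf",
    "write_gaf",
    "clean_annotations",
    "filter_by_evidence",
    "term_set",
    "quantify_annotations",
    "REMOVAL_QUALIFIERS",
    "ASPECTS",
]

ASPECTS = ("C", "F", "P")
REMOVAL_QUALIFIERS = frozenset({"NOT", "contributes_to", "colocalizes_with"})
_GO_ID = re.compile(r"^GO:\d{7}$")
_GAF_COLUMNS = 17


class GafError(ValueError):
    """Raised on malformed GAF input."""


@dataclass(frozen=True)
class AnnotationRecord:
    """One gene-to-term association (one GAF data line)."""

    gene: str
    qualifiers: tuple[str, ...]
    term: str
    evidence: str
    aspect: str
    source_line: int = 0

    def key(self) -> tuple:
        """Identity used for duplicate detection."""
        return (self.gene, self.term, self.evidence, self.qualifiers)


@dataclass
class AnnotationSet:
    genome_label: str
    records: list[AnnotationRecord] = field(default_factory=list)
    provenance: str = ""
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.genome_label:
            raise ValueError("genome_label must be nonempty")
        if not self.records:
            self.warnings.append("annotation set is empty")

    def __len__(self) -> int:
        return len(self.records)


@dataclass(frozen=True)
class CleaningReport:
    input_count: int
    exact_duplicates: int
    qualifier_rows: int
    obsolete_terms: int
    alt_ids_merged: int
    duplicates_after_merge: int
    output_count: int

    def __post_init__(self) -> None:
        removed = (
            self.exact_duplicates
            + self.qualifier_rows
            + self.obsolete_terms
            + self.duplicates_after_merge
        )
        if self.input_count - removed != self.output_count:
            raise ValueError(
                "cleaning report arithmetic violated: "
                f"{self.input_count} - {removed} != {self.output_count}"
            )

    def to_dict(self) -> dict[str, int]:
        return {
            "input_count": self.input_count,
            "exact_duplicates": self.exact_duplicates,
            "qualifier_rows": self.qualifier_rows,
            "obsolete_terms": self.obsolete_terms,
            "alt_ids_merged": self.alt_ids_merged,
            "duplicates_after_merge": self.duplicates_after_merge,
            "output_count": self.output_count,
        }


def read_gaf(stream: IO[str] | Iterable[str], genome_label: str,
             provenance: str = "") -> AnnotationSet:
    """Parse GAF 2.1 text into an :class:`AnnotationSet`.

    Lines starting with ``!`` are comments.  Data lines must have at
    least 15 tab-separated columns; the qualifier column is split on
    ``|``.  Raises :class:`GafError` with the offending line number on
    short lines, malformed term ids, or unknown aspects.
    """
    if isinstance(stream, str):
        stream = stream.splitlines()
    records: list[AnnotationRecord] = []
    for lineno, raw in enumerate(stream, start=1):
        line = raw.rstrip("\n")
        if not line or line.startswith("!"):
            continue
        cols = line.split("\t")
        if len(cols) < 15:
            raise GafError(
                f"line {lineno}: expected >=15 tab-separated columns, "
                f"got {len(cols)}"
            )
        gene, qualifier, term, evidence, aspect = (
            cols[1], cols[3], cols[4], cols[6], cols[8]
        )
        if not _GO_ID.match(term):
            raise GafError(f"line {lineno}: malformed term identifier {term!r}")
        if aspect not in ASPECTS:
            raise GafError(f"line {lineno}: aspect {aspect!r} not in C/F/P")
        qualifiers = tuple(q for q in qualifier.split("|") if q)
        records.append(
            AnnotationRecord(
                gene=gene, qualifiers=qualifiers, term=term,
                evidence=evidence, aspect=aspect, source_line=lineno,
            )
        )
    return AnnotationSet(genome_label=genome_label, records=records,
                         provenance=provenance)


def write_gaf(aset: AnnotationSet, stream: IO[str]) -> None:
    """Write GAF 2.1 (records only carry the columns this package uses;
    the remaining columns are filled with fixed placeholders)."""
    stream.write("!gaf-version: 2.1\n")
    for rec in aset.records:
        cols = [""] * _GAF_COLUMNS
        cols[0] = "FP"
        cols[1] = rec.gene
        cols[2] = rec.gene
        cols[3] = "|".join(rec.qualifiers)
        cols[4] = rec.term
        cols[5] = "FP:ref"
        cols[6] = rec.evidence
        cols[8] = rec.aspect
        cols[11] = "gene"
        cols[12] = f"taxon:0"
        cols[13] = "20200101"
        cols[14] = "funcphylo"
        stream.write("\t".join(cols) + "\n")


def clean_annotations(
    aset: AnnotationSet, graph: OntologyGraph
) -> tuple[AnnotationSet, CleaningReport]:
    """Apply the five ordered cleaning rules; see module docstring.

    Terms that are neither primary, alternative, nor known-obsolete
    identifiers raise :class:`GafError` listing them.
    """
    unknown = sorted(
        {r.term for r in aset.records}
        - set(graph.terms) - set(graph.alt_index)
    )
    if unknown:
        raise GafError(
            f"{aset.genome_label}: unknown term identifiers: "
            + ", ".join(unknown)
        )

    # rule 1: exact duplicates
    seen: set[tuple] = set()
    deduped: list[AnnotationRecord] = []
    n_dup = 0
    for rec in aset.records:
        k = rec.key()
        if k in seen:
            n_dup += 1
        else:
            seen.add(k)
            deduped.append(rec)

    # rule 2: qualifier rows
    kept: list[AnnotationRecord] = []
    n_qual = 0
    for rec in deduped:
        if REMOVAL_QUALIFIERS & set(rec.qualifiers):
            n_qual += 1
        else:
            kept.append(rec)

    # rule 3 + 4: obsolete removal (before and after alt-id rewrite)
    merged: list[AnnotationRecord] = []
    n_obsolete = 0
    n_merged = 0
    for rec in kept:
        if graph.is_obsolete(rec.term):
            n_obsolete += 1
            continue
        primary = graph.resolve(rec.term)
        if primary != rec.term:
            if graph.is_obsolete(primary):
                n_obsolete += 1
                continue
            rec = replace(rec, term=primary)
            n_merged += 1
        merged.append(rec)

    # rule 5: duplicates uncovered by the merge
    seen2: set[tuple] = set()
    final: list[AnnotationRecord] = []
    n_dup2 = 0
    for rec in merged:
        k = rec.key()
        if k in seen2:
            n_dup2 += 1
        else:
            seen2.add(k)
            final.append(rec)

    report = CleaningReport(
        input_count=len(aset.records),
        exact_duplicates=n_dup,
        qualifier_rows=n_qual,
        obsolete_terms=n_obsolete,
        alt_ids_merged=n_merged,
        duplicates_after_merge=n_dup2,
        output_count=len(final),
    )
    cleaned = AnnotationSet(
        genome_label=aset.genome_label,
        records=final,
        provenance=(aset.provenance + " | cleaned").strip(" |"),
    )
    return cleaned, report


def filter_by_evidence(
    aset: AnnotationSet,
    keep: Iterable[str] | None = None,
    exclude: Iterable[str] | None = None,
) -> AnnotationSet:
    """Keep records whose evidence code passes the filter.

    Exactly one of ``keep``/``exclude`` must be given.  The canonical
    use is the IEA / non-IEA split (electronic vs curated evidence).
    """
    if (keep is None) == (exclude is None):
        raise ValueError("give exactly one of keep= or exclude=")
    if keep is not None:
        keep = set(keep)
        records = [r for r in aset.records if r.evidence in keep]
        note = f"evidence keep={sorted(keep)}"
    else:
        exclude = set(exclude)
        records = [r for r in aset.records if r.evidence not in exclude]
        note = f"evidence exclude={sorted(exclude)}"
    return AnnotationSet(
        genome_label=aset.genome_label,
        records=records,
        provenance=(aset.provenance + " | " + note).strip(" |"),
    )


def term_set(aset: AnnotationSet, aspects: Iterable[str] = ASPECTS) -> frozenset[str]:
    """Unique terms annotated to any gene, restricted to ``aspects``.

    With all three aspects this is the genome's leaf term set T.
    """
    aspects = set(aspects)
    bad = aspects - set(ASPECTS)
    if bad:
        raise ValueError(f"unknown aspects: {sorted(bad)}")
    return frozenset(r.term for r in aset.records if r.aspect in aspects)


def quantify_annotations(aset: AnnotationSet, n_genes: int) -> pd.DataFrame:
    """Annotation metrics per aspect plus the aggregate row ``A``.

    For each aspect: percentage of the ``n_genes`` gene universe with at
    least one annotation, total annotation count, and the median number
    of annotations per gene over genes present in that aspect.  The
    aggregate row counts A = CC + MF + BP annotations and the union of
    annotated genes; its median is over each annotated gene's total
    annotation count.
    """
    genes_by_aspect: dict[str, dict[str, int]] = {a: {} for a in ASPECTS}
    for rec in aset.records:
        per = genes_by_aspect[rec.aspect]
        per[rec.gene] = per.get(rec.gene, 0) + 1
    all_genes: dict[str, int] = {}
    for per in genes_by_aspect.values():
        for g, c in per.items():
            all_genes[g] = all_genes.get(g, 0) + c
    if n_genes < len(all_genes):
        raise ValueError(
            f"n_genes={n_genes} is smaller than the {len(all_genes)} "
            "distinct annotated genes"
        )
    rows = []
    for aspect in ASPECTS + ("A",):
        per = all_genes if aspect == "A" else genes_by_aspect[aspect]
        counts = list(per.values())
        rows.append(
            {
                "aspect": aspect,
                "n_annotations": sum(counts),
                "n_genes_annotated": len(per),
                "pct_genes_annotated": 100.0 * len(per) / n_genes if n_genes else 0.0,
                "median_annotations_per_gene":
                    float(statistics.median(counts)) if counts else 0.0,
            }
        )
    return pd.DataFrame(rows).set_index("aspect")
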