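# Methods

## Profiles and distances

A genome's annotation set is reduced to the set *T* of distinct GO
terms attached to any of its genes (optionally restricted to one
aspect). *T* is closed over the transitive `is_a` relation — every
ancestor up to the aspect root is added — giving *S*. Closure uses
`is_a` only; `part_of`, `regulates` and other relationship types are
ignored, so *S* is the smallest `is_a`-upward-closed superset of *T*.
Aspect roots are included in *S* like any other ancestor: they are
shared by all non-empty profiles and therefore contribute a uniform
additive term to every intersection and union, slightly compressing
all distances equally without affecting relative structure.

Dissimilarity between genomes *a* and *b* is the Jaccard distance

    d_ab = 1 − |S_a ∩ S_b| / |S_a ∪ S_b|,

a true metric on sets. Two empty sets get distance 0 (identity of
indiscernibles; the case never arises on real data). Distances are
computed on the closed sets *S* by default; `use_closed=False` gives
the leaf-set (*T*) variant for sensitivity analysis. Closure means two
genomes annotated with different but related specific terms still share
the ancestors of those terms, so profile distance reflects semantic,
not just lexical, overlap.

The same *S* sets populate a genome × term 0/1 matrix (columns = the
lexicographically sorted union of all *S*, for determinism; constant
columns retained — they are uninformative for parsimony but document
profile sizes).

## Annotation cleaning

Five ordered rules, each with a counted removal class:

1. exact duplicates on (gene, term, evidence, qualifiers);
2. rows whose qualifiers intersect {NOT, contributes_to,
   colocalizes_with} — negated or modifier annotations that must not
   enter presence profiles;
3. rows whose term is obsolete;
4. rewrite alternative (secondary) identifiers to their primary term;
   a rewrite landing on an obsolete primary is dropped and counted
   under rule 3 (the obsolete check applies both before and after the
   merge);
5. duplicates newly created by rule 4.

The report satisfies `input − (r1 + r2 + r3 + r5) = output`; rule 4
rewrites rather than removes. Duplicate identity includes the evidence
code — two identical gene–term pairs with different evidence are kept
as distinct records (the counting is annotation-level, not pair-level);
this is configurable only by pre-filtering evidence. Cleaning is
idempotent. The aspect is taken from GAF column 9 as written; the
ontology namespace is not consulted to overrule it.

## Tree inference

**Neighbor joining** is the standard Saitou–Nei agglomeration with the
Q-criterion and Studier–Keppler updates. On an additive matrix it
recovers the generating topology and branch lengths exactly (checked
to 1e−9). Negative branch lengths, which arise on non-additive input,
are retained by default (matching classic distance-program behaviour);
`clamp_negative=True` floors them at 0. Q-ties join the pair of
clusters whose (smallest-leaf-label) pair is lexicographically
smallest, so output is deterministic and input-order independent.

**Parsimony** scores a candidate topology by the Fitch bottom-up pass
per binary character, summed over columns; identical columns are
collapsed into weighted patterns and constant columns dropped before
scoring. The tree is rooted for scoring on the smallest leaf's pendant
edge, which keeps every internal node binary; for multifurcating input
the children are folded sequentially, which upper-bounds the true
polytomy score (all search-generated trees are binary). The search
enumerates all (2n−5)!! unrooted topologies exhaustively up to 9 taxa;
beyond that it uses stepwise addition under 10 random leaf-addition
orders followed by nearest-neighbor-interchange hill climbing, seeded
and deterministic. Equal-score ties are resolved toward the canonical
(sorted) split representation. A matrix with no variable columns has
an arbitrary optimum; a canonical label-sorted caterpillar is returned
with a warning.

**Comparisons.** Splits are non-trivial bipartitions represented as
leaf-label sets normalised to the side excluding the smallest label.
Robinson–Foulds distance is the size of the symmetric difference of
split sets. Majority-rule consensus keeps splits occurring in strictly
more than 50% of trees (a split in exactly half is excluded) and labels
them with their percentage; supports are also re-mapped onto the
full-data topology, whose splits' labels are then plain replicate
frequencies in [0, 100]. Rooting places the root at the midpoint of
the outgroup's pendant edge.

## Jackknife support and the stability sweep

Each replicate removes a fixed fraction (default 0.40) of the terms
from the **global union** of all genomes' *T* sets — the
"columns-of-the-data" reading, so every genome loses the same terms —
keeping `floor((1−fraction)·|union|)` terms; each genome retains its
intersection with the kept set, ancestors are re-added by closure, and
the tree is rebuilt. A per-genome independent-removal mode is available
(`per_genome=True`) because the alternative reading of "terms in T" is
defensible; the global mode is the default. 100 replicates feed the
strict majority-rule consensus. The stability sweep repeats this for
fractions 0.05–0.95 in steps of 0.05 and reports the smallest fraction
whose consensus differs (RF > 0) from the full-data tree. Note RF > 0
includes loss of resolution, not only conflict — a split falling to
≤50% support registers as deviation.

## Ablation against a reference

Agreement with a reference cladogram is one-sided: after contracting
the configured disregard groups in both trees (groups whose internal
arrangement carries no expectation, e.g. within-species accessions)
and restricting the reference to the candidate's taxa, the candidate
agrees iff every resolved reference split is present in it. Reference
polytomies impose no constraint; a disregard group that is not
monophyletic in the candidate counts as disagreement. The
minimal-removal search enumerates all genome subsets of size 0, 1, …,
kmax in order, rebuilds the tree (NJ by default — the point-estimate
tree, not a jackknife consensus) without each subset, and returns
*all* subsets of the first size admitting a solution, plus per-genome
solution-membership counts. A flag continues past the first solution
size for non-minimal solutions.

## Synthetic data

The generator emulates the statistical structure the pipeline assumes,
not real GO data:

* **Ontology** — per aspect, one root and terms arranged in levels;
  each term draws 1..`max_parents` parents uniformly from strictly
  shallower levels (acyclic by construction). Defaults: 120/160/320
  terms for C/F/P over depth 6 (~600 terms, comfortably above the
  ~500-term scale at which closure effects are non-trivial), 12 alt
  ids, 10 obsolete terms.
* **Profiles** — a root profile of 240 terms drawn uniformly from the
  non-root, non-obsolete terms evolves along a planted tree (default:
  12 genomes in three balanced quartets, all branch lengths 1). Over a
  branch of length ℓ each present term is lost with probability
  1−exp(−λℓ) and each absent eligible term gained with probability
  1−exp(−γℓ), the independent-Poisson-process approximation — the
  simplest model in which expected Jaccard distance grows with path
  length. Default λ = γ = 0.05: ~5% turnover per unit branch, enough
  signal for exact recovery while leaving the shortest splits' support
  below 100.
* **GAF and dirt** — each term is annotated (evidence IEA) to one of
  200 synthetic genes; dirt rows are appended, never substituted, so
  cleaning provably recovers the true *T*: exact copies of real rows,
  fresh-gene qualifier and obsolete rows, and alt-id re-annotations of
  existing (gene, term) pairs that become duplicates after merging.

What passing on this generator does **not** show: real GO term-frequency
distributions (highly skewed), evidence-code mixtures, annotation
depth heterogeneity between pipelines, gene duplication, or horizontal
signal — conclusions about real annotation sets still require the real
data.

## Numerical and interface choices

* All RNG is `numpy.random.default_rng`; stage seeds are spawned from
  one master seed via `SeedSequence` and kept below 2³¹.
* Retained-term counts use floor; support percentages are printed to
  one decimal; genome-size Mb rounds half away from zero.
* PHYLIP export defaults to relaxed (long) names; strict mode enforces
  10-character names and errors on post-truncation collisions.
* Problem sizes in the analysis scripts and acceptance run: 12-genome
  bundle (~600 terms), 100 jackknife replicates per fraction, 19-point
  sweep, removal search to k ≤ 3, 200 random trees (n ≤ 20) for NJ
  consistency and 100 six-taxon matrices against brute-force parsimony
  oracles — sizes chosen so every check is exact or exhaustively
  verifiable while the whole study runs in seconds.

## Known limitations

Distances are unweighted presence/absence — term counts and
information content are deliberately ignored. GAF 2.2/GPAD dialects,
protein-level objects, and OBO constructs beyond `is_a`
(intersections, cross-products, `replaced_by` auto-application) are out
of scope; `replaced_by`/`consider` are parsed and exposed but never
applied automatically. The parsimony heuristic carries no optimality
guarantee beyond its restarts; branch lengths are not estimated under
parsimony. Tree visualisation is left to external tools (e.g. iTOL via
the exported Newick files).
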