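"""Build ancestor-closed term profiles and both inter-genome matrices.

For every genome: collect the cleaned leaf term set T, close it over
is_a into S, then compute the Jaccard distance matrix on the S sets and
the genome x term presence/absence matrix.  Matrices are written as TSV
and in PHYLIP formats.
"""

from pathlib import Path

import pandas as pd

from funcphylo import (
    build_profiles,
    clean_annotations,
    pairwise_distances,
    read_gaf,
    term_set,
    to_binary_matrix,
)
from funcphylo.ontology import parse_obo
from funcphylo.profiles import write_phylip_characters, write_phylip_distances

ROOT = Path(__file__).resolve().parent.parent / "results"
SYN = ROOT / "synthetic"


def load_term_sets():
    graph = parse_obo((SYN / "ontology.obo").read_text())
    term_sets = {}
    for path in sorted(SYN.glob("*.gaf")):
        cleaned, _ = clean_annotations(
            read_gaf(path.read_text(), path.stem), graph
        )
        term_sets[path.stem] = term_set(cleaned)
    return graph, term_sets


def main() -> None:
    graph, term_sets = load_term_sets()
    profiles = build_profiles(term_sets, graph)
    sizes = pd.DataFrame(
        [{"genome": p.genome_label, "n_leaf_terms": len(p.T),
          "n_closed_terms": len(p.S)} for p in profiles]
    )
    sizes.to_csv(ROOT / "profile_sizes.tsv", sep="\t", index=False)
    dm = pairwise_distances(profiles)
    dm.to_dataframe().to_csv(ROOT / "distances.tsv", sep="\t")
    with open(ROOT / "distances.phylip", "w") as fh:
        write_phylip_distances(dm, fh)
    bm = to_binary_matrix(profiles)
    with open(ROOT / "characters.phylip", "w") as fh:
        write_phylip_characters(bm, fh)
    print(f"{len(profiles)} profiles; closed sizes "
          f"{sizes.n_closed_terms.min()}-{sizes.n_closed_terms.max()} terms")
    print(f"binary matrix: {len(bm.row_labels)} x {len(bm.column_labels)}")
    print(f"max pairwise Jaccard distance: {dm.values.max():.3f}")
    print(f"wrote distances.tsv/.phylip and characters.phylip under {ROOT}")


if __name__ == "__main__":
    main()
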