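"""Infer NJ and parsimony trees and compare them to the planted tree.

Neighbor joining runs on the Jaccard distance matrix, parsimony search
on the binary matrix.  Both unrooted topologies are compared to the
generator's planted tree by Robinson–Foulds distance and rooted at the
last genome as a stand-in outgroup for display.
"""

import importlib
import sys
from pathlib import Path

from funcphylo import (
    build_profiles,
    neighbor_joining,
    pairwise_distances,
    parsimony_search,
    rf_distance,
    root_at_outgroup,
    to_binary_matrix,
    write_newick,
)
from funcphylo import trees as T

sys.path.insert(0, str(Path(__file__).resolve().parent))
load_term_sets = importlib.import_module("03_build_profiles").load_term_sets

ROOT = Path(__file__).resolve().parent.parent / "results"
SYN = ROOT / "synthetic"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 1


def main() -> None:
    graph, term_sets = load_term_sets()
    planted = T.parse_newick((SYN / "planted_tree.nwk").read_text())
    profiles = build_profiles(term_sets, graph)
    outgroup = sorted(term_sets)[-1]

    nj = neighbor_joining(pairwise_distances(profiles))
    (ROOT / "nj_tree.nwk").write_text(write_newick(nj) + "\n")
    (ROOT / "nj_tree_rooted.nwk").write_text(
        write_newick(root_at_outgroup(nj, outgroup)) + "\n"
    )
    print(f"NJ tree: RF to planted = {rf_distance(nj, planted)}")

    pars = parsimony_search(to_binary_matrix(profiles), seed=SEED)
    (ROOT / "parsimony_tree.nwk").write_text(write_newick(pars.tree) + "\n")
    print(f"parsimony tree ({pars.method}): score = {pars.score} changes, "
          f"RF to planted = {rf_distance(pars.tree, planted)}")
    print(f"trees rooted at {outgroup}; newick files under {ROOT}")


if __name__ == "__main__":
    main()
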