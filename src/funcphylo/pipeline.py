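"""End-to-end orchestration and small reporting utilities.

``run_pipeline`` composes the whole analysis from files on disk —
ontology and GAF parsing, cleaning, profile closure, distance and
binary matrices, NJ and/or parsimony trees, outgroup rooting, term
jackknifing, the stability sweep, and reference-based ablation — and
writes every artifact plus a JSON manifest (seeds, input checksums,
per-stage counts, output checksums) into an output directory.

``estimate_genome_size`` converts a C-value (haploid DNA content in
picograms) to an estimated genome size via
``bp = pg * 0.978e9``; megabases are reported rounded half away from
zero to the nearest integer.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import trees as _trees
from .ablation import ReferenceComparison, leave_one_out, minimal_removal_search
from .annotations import clean_annotations, read_gaf, term_set
from .ontology import parse_obo
from .profiles import (
    build_profiles,
    pairwise_distances,
    to_binary_matrix,
    write_phylip_characters,
    write_phylip_distances,
)
from .resampling import JackknifeConfig, jackknife_support, stability_sweep

__all__ = [
    "CValueRecord",
    "estimate_genome_size",
    "RunConfig",
    "run_pipeline",
]

logger = logging.getLogger("funcphylo")

_BP_PER_PG = 0.978e9


@dataclass(frozen=True)
class CValueRecord:
    species: str
    c_value_pg: float
    bp: float
    mb: int


def estimate_genome_size(c_value_pg: float, species: str = "") -> CValueRecord:
    """Genome size from C-value: bp = pg * 0.978e9; Mb rounded half
    away from zero.  Raises on non-positive input."""
    if c_value_pg <= 0:
        raise ValueError("C-value must be positive")
    bp = c_value_pg * _BP_PER_PG
    mb = int(
        Decimal(repr(bp / 1e6)).quantize(Decimal("1"), rounding=ROUND_HALF_UP)
    )
    return CValueRecord(species=species, c_value_pg=c_value_pg, bp=bp, mb=mb)


@dataclass
class RunConfig:
    obo_path: Path
    gaf_paths: Mapping[str, Path]  # genome label -> GAF file
    out_dir: Path
    aspects: tuple[str, ...] = ("C", "F", "P")
    tree_method: str = "nj"
    outgroup: str | None = None
    reference_newick_path: Path | None = None
    disregard_groups: Mapping[str, frozenset[str]] = field(default_factory=dict)
    jackknife: JackknifeConfig | None = JackknifeConfig()
    sweep_fractions: Sequence[float] | None = None
    ablation_kmax: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        self.obo_path = Path(self.obo_path)
        self.out_dir = Path(self.out_dir)
        self.gaf_paths = {g: Path(p) for g, p in self.gaf_paths.items()}
        missing = [
            str(p)
            for p in [self.obo_path, *self.gaf_paths.values()]
            if not p.exists()
        ]
        if self.reference_newick_path is not None:
            self.reference_newick_path = Path(self.reference_newick_path)
            if not self.reference_newick_path.exists():
                missing.append(str(self.reference_newick_path))
        if missing:
            raise FileNotFoundError(
                "missing input files: " + ", ".join(missing)
            )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write(path: Path, text: str, manifest: dict) -> None:
    path.write_text(text)
    manifest["outputs"][path.name] = _sha256(path)


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages; returns the manifest dict (also
    written to ``manifest.json`` in the output directory)."""
    out = config.out_dir
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "seed": config.seed,
        "tree_method": config.tree_method,
        "aspects": list(config.aspects),
        "inputs": {},
        "stages": {},
        "outputs": {},
    }
    manifest["inputs"]["obo"] = _sha256(config.obo_path)

    logger.info("stage ontology: parsing %s", config.obo_path)
    graph = parse_obo(config.obo_path.read_text())
    manifest["stages"]["ontology"] = {"n_terms": len(graph)}

    logger.info("stage clean: %d annotation sets", len(config.gaf_paths))
    term_sets: dict[str, frozenset[str]] = {}
    reports = []
    for genome in sorted(config.gaf_paths):
        path = config.gaf_paths[genome]
        manifest["inputs"][f"gaf:{genome}"] = _sha256(path)
        aset = read_gaf(path.read_text(), genome_label=genome,
                        provenance=str(path))
        cleaned, report = clean_annotations(aset, graph)
        reports.append({"genome": genome, **report.to_dict()})
        term_sets[genome] = term_set(cleaned, aspects=config.aspects)
    report_df = pd.DataFrame(reports)
    _write(out / "cleaning_reports.tsv",
           report_df.to_csv(sep="\t", index=False), manifest)
    manifest["stages"]["clean"] = {
        "n_genomes": len(term_sets),
        "total_removed": int(
            report_df["input_count"].sum() - report_df["output_count"].sum()
        ),
    }

    logger.info("stage profiles: closure and matrices")
    profiles = build_profiles(term_sets, graph)
    dm = pairwise_distances(profiles)
    bm = to_binary_matrix(profiles)
    with open(out / "distances.phylip", "w") as fh:
        write_phylip_distances(dm, fh)
    manifest["outputs"]["distances.phylip"] = _sha256(out / "distances.phylip")
    with open(out / "characters.phylip", "w") as fh:
        write_phylip_characters(bm, fh)
    manifest["outputs"]["characters.phylip"] = _sha256(out / "characters.phylip")
    _write(out / "distances.tsv", dm.to_dataframe().to_csv(sep="\t"), manifest)
    manifest["stages"]["profiles"] = {
        "n_profiles": len(profiles),
        "n_terms_union": len(bm.column_labels),
    }

    logger.info("stage trees: %s", config.tree_method)
    if config.tree_method == "nj":
        tree = _trees.neighbor_joining(dm)
    else:
        tree = _trees.parsimony_search(bm, seed=config.seed).tree
    _write(out / "tree.nwk", _trees.write_newick(tree) + "\n", manifest)
    if config.outgroup is not None:
        rooted = _trees.root_at_outgroup(tree, config.outgroup)
        _write(out / "tree_rooted.nwk",
               _trees.write_newick(rooted) + "\n", manifest)

    if config.jackknife is not None:
        jk = dataclasses.replace(
            config.jackknife, tree_method=config.tree_method,
            seed=config.seed,
        )
        logger.info("stage jackknife: fraction=%.2f replicates=%d",
                    jk.fraction, jk.replicates)
        result = jackknife_support(term_sets, graph, jk, tree)
        _write(out / "consensus.nwk",
               _trees.write_newick(result.consensus) + "\n", manifest)
        _write(out / "tree_supports.nwk",
               _trees.write_newick(result.annotated_full) + "\n", manifest)
        _write(out / "split_supports.tsv",
               result.split_table().to_csv(sep="\t", index=False), manifest)
        manifest["stages"]["jackknife"] = {
            "fraction": jk.fraction, "replicates": jk.replicates,
        }

    if config.sweep_fractions is not None:
        logger.info("stage sweep: %d fractions", len(config.sweep_fractions))
        replicates = (
            config.jackknife.replicates if config.jackknife else 100
        )
        sweep = stability_sweep(
            term_sets, graph, fractions=config.sweep_fractions,
            replicates=replicates, seed=config.seed,
            tree_method=config.tree_method, full_tree=tree,
        )
        _write(out / "stability_sweep.tsv",
               sweep.table.to_csv(sep="\t", index=False), manifest)
        manifest["stages"]["sweep"] = {
            "deviation_threshold": sweep.deviation_threshold,
        }

    if config.reference_newick_path is not None:
        reference = _trees.parse_newick(
            config.reference_newick_path.read_text()
        )
        comparison = ReferenceComparison(
            reference=reference,
            disregard_groups=dict(config.disregard_groups),
            outgroup=config.outgroup,
        )
        logger.info("stage ablation: leave-one-out")
        loo = leave_one_out(term_sets, graph, comparison,
                            tree_method=config.tree_method)
        _write(out / "leave_one_out.tsv",
               loo.table().to_csv(sep="\t", index=False), manifest)
        manifest["stages"]["leave_one_out"] = {
            "n_agreeing": int(sum(loo.agreement.values())),
        }
        if config.ablation_kmax is not None:
            logger.info("stage removal search: kmax=%d", config.ablation_kmax)
            search = minimal_removal_search(
                term_sets, graph, comparison, kmax=config.ablation_kmax,
                tree_method=config.tree_method,
            )
            _write(
                out / "removal_search.tsv",
                search.frequencies.to_csv(sep="\t", index=False),
                manifest,
            )
            manifest["stages"]["removal_search"] = {
                "k": search.k,
                "n_solutions": len(search.solutions),
                "n_evaluated": search.n_evaluated,
            }

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
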