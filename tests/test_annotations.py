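"""GAF reading, the ordered cleaning rules, filtering and metrics."""

import io

import pytest
from Bio.UniProt import GOA

from funcphylo.annotations import (
    AnnotationSet,
    GafError,
    clean_annotations,
    filter_by_evidence,
    quantify_annotations,
    read_gaf,
    term_set,
    write_gaf,
)


def gaf_line(gene, term, aspect, qualifier="", evidence="IEA"):
    cols = [""] * 17
    cols[0], cols[1], cols[2] = "DB", gene, gene
    cols[3], cols[4], cols[5] = qualifier, term, "REF:1"
    cols[6], cols[8] = evidence, aspect
    cols[11], cols[12], cols[13], cols[14] = "gene", "taxon:1", "20200101", "src"
    return "\t".join(cols)


def gaf_doc(*lines):
    return "!gaf-version: 2.1\n" + "\n".join(lines) + "\n"


class TestReadGaf:
    def test_comments_skipped_and_qualifiers_split(self):
        doc = gaf_doc(
            gaf_line("g1", "GO:0000001", "P"),
            gaf_line("g2", "GO:0000002", "F", qualifier="NOT|contributes_to"),
        )
        aset = read_gaf(doc, "genomeA")
        assert len(aset) == 2
        assert aset.records[0].qualifiers == ()
        assert set(aset.records[1].qualifiers) == {"NOT", "contributes_to"}

    def test_short_line_errors_with_line_number(self):
        doc = "!gaf-version: 2.1\n" + "\t".join(["x"] * 10) + "\n"
        with pytest.raises(GafError, match="line 2"):
            read_gaf(doc, "g")

    def test_bad_aspect_errors(self):
        with pytest.raises(GafError, match="aspect"):
            read_gaf(gaf_doc(gaf_line("g1", "GO:0000001", "X")), "g")

    def test_roundtrip_preserves_record_multiset(self):
        doc = gaf_doc(
            gaf_line("g1", "GO:0000001", "P"),
            gaf_line("g1", "GO:0000001", "P"),  # duplicate kept on read
            gaf_line("g2", "GO:0000002", "C", qualifier="NOT"),
        )
        aset = read_gaf(doc, "g")
        buf = io.StringIO()
        write_gaf(aset, buf)
        again = read_gaf(buf.getvalue(), "g")
        key = lambda r: (r.gene, r.term, r.evidence, r.qualifiers, r.aspect)
        assert sorted(map(key, again.records)) == sorted(map(key, aset.records))

    def test_written_gaf_readable_by_biopython(self):
        aset = read_gaf(gaf_doc(
            gaf_line("g1", "GO:0000001", "P"),
            gaf_line("g2", "GO:0000002", "C", evidence="EXP"),
        ), "g")
        buf = io.StringIO()
        write_gaf(aset, buf)
        buf.seek(0)
        ref = list(GOA.gafiterator(buf))
        ours = [(r.gene, r.term, r.evidence, r.aspect) for r in aset.records]
        theirs = [
            (r["DB_Object_ID"], r["GO_ID"], r["Evidence"], r["Aspect"])
            for r in ref
        ]
        assert sorted(ours) == sorted(theirs)


class TestCleaning:
    def test_clean_set_is_fixpoint(self, diamond_graph):
        aset = read_gaf(gaf_doc(
            gaf_line("g1", "GO:0000002", "P"),
            gaf_line("g2", "GO:0000003", "P"),
        ), "g")
        cleaned, report = clean_annotations(aset, diamond_graph)
        assert len(cleaned) == 2
        assert report.to_dict() == {
            "input_count": 2, "exact_duplicates": 0, "qualifier_rows": 0,
            "obsolete_terms": 0, "alt_ids_merged": 0,
            "duplicates_after_merge": 0, "output_count": 2,
        }
        again, report2 = clean_annotations(cleaned, diamond_graph)
        assert report2.output_count == 2
        assert report2.input_count - report2.output_count == 0

    def test_qualifier_rules(self, diamond_graph):
        aset = read_gaf(gaf_doc(
            gaf_line("g1", "GO:0000002", "P", qualifier="NOT"),
            gaf_line("g2", "GO:0000002", "P"),
        ), "g")
        cleaned, report = clean_annotations(aset, diamond_graph)
        assert report.qualifier_rows == 1
        assert [r.gene for r in cleaned.records] == ["g2"]

    def test_seven_row_fixture_hand_traced(self, diamond_graph):
        """One exact dup, NOT + colocalizes rows, one obsolete-term row,
        one alt-id row colliding after merge, two informative rows.

        Independent set-based recount: the distinct surviving
        (gene, term) pairs are {(g1, GO:0000003), (g2, GO:0000002)},
        so 2 rows survive and 5 of 7 are removed.
        """
        doc = gaf_doc(
            gaf_line("g1", "GO:0000003", "P"),
            gaf_line("g1", "GO:0000003", "P"),                    # exact dup
            gaf_line("g2", "GO:0000002", "P", qualifier="NOT"),
            gaf_line("g3", "GO:0000002", "P",
                     qualifier="colocalizes_with"),
            gaf_line("g4", "GO:0000005", "P"),                    # obsolete
            gaf_line("g1", "GO:0099999", "P"),                    # alt of 3
            gaf_line("g2", "GO:0000002", "P"),
        )
        aset = read_gaf(doc, "g")
        cleaned, report = clean_annotations(aset, diamond_graph)
        assert report.exact_duplicates == 1
        assert report.qualifier_rows == 2
        assert report.obsolete_terms == 1
        assert report.alt_ids_merged == 1
        assert report.duplicates_after_merge == 1
        recount = {(r.gene, r.term) for r in cleaned.records}
        assert recount == {("g1", "GO:0000003"), ("g2", "GO:0000002")}
        assert report.output_count == len(recount) == 2

    def test_unknown_term_listed(self, diamond_graph):
        aset = read_gaf(gaf_doc(gaf_line("g1", "GO:0555555", "P")), "g")
        with pytest.raises(GafError, match="GO:0555555"):
            clean_annotations(aset, diamond_graph)

    def test_alt_id_rewritten_without_removal(self, diamond_graph):
        aset = read_gaf(gaf_doc(gaf_line("g9", "GO:0099999", "P")), "g")
        cleaned, report = clean_annotations(aset, diamond_graph)
        assert report.alt_ids_merged == 1
        assert report.duplicates_after_merge == 0
        assert cleaned.records[0].term == "GO:0000003"


class TestFilterAndTermSet:
    def test_keep_and_exclude(self, diamond_graph):
        aset = read_gaf(gaf_doc(
            gaf_line("g1", "GO:0000002", "P", evidence="IEA"),
            gaf_line("g2", "GO:0000003", "P", evidence="EXP"),
        ), "g")
        assert {r.evidence for r in filter_by_evidence(aset, keep={"IEA"}).records} == {"IEA"}
        assert {r.evidence for r in filter_by_evidence(aset, exclude={"IEA"}).records} == {"EXP"}
        assert len(filter_by_evidence(aset, exclude=set()).records) == 2

    def test_exactly_one_filter_argument(self, diamond_graph):
        aset = read_gaf(gaf_doc(gaf_line("g1", "GO:0000002", "P")), "g")
        with pytest.raises(ValueError):
            filter_by_evidence(aset)
        with pytest.raises(ValueError):
            filter_by_evidence(aset, keep={"IEA"}, exclude={"EXP"})

    def test_term_set_dedup_and_aspects(self):
        aset = read_gaf(gaf_doc(
            gaf_line("g1", "GO:0000010", "P"),
            gaf_line("g1", "GO:0000011", "C"),
            gaf_line("g2", "GO:0000010", "P"),
        ), "g")
        assert term_set(aset) == {"GO:0000010", "GO:0000011"}
        assert term_set(aset, aspects={"P"}) == {"GO:0000010"}
        empty = AnnotationSet(genome_label="e", records=[])
        assert term_set(empty) == frozenset()
        assert empty.warnings


class TestQuantify:
    def test_single_gene_bp(self):
        aset = read_gaf(gaf_doc(
            gaf_line("g1", "GO:0000010", "P"),
            gaf_line("g1", "GO:0000011", "P"),
            gaf_line("g1", "GO:0000012", "P"),
        ), "g")
        table = quantify_annotations(aset, n_genes=2)
        assert table.loc["P", "n_annotations"] == 3
        assert table.loc["P", "pct_genes_annotated"] == 50.0
        assert table.loc["P", "median_annotations_per_gene"] == 3.0

    def test_aggregate_row_sums_aspects(self):
        aset = read_gaf(gaf_doc(
            gaf_line("g1", "GO:0000010", "C"),
            gaf_line("g1", "GO:0000011", "C"),
            gaf_line("g1", "GO:0000012", "F"),
            gaf_line("g2", "GO:0000013", "P"),
        ), "g")
        table = quantify_annotations(aset, n_genes=2)
        assert table.loc["A", "n_annotations"] == 4
        assert (
            table.loc["A", "n_annotations"]
            == table.loc[["C", "F", "P"], "n_annotations"].sum()
        )
        assert table.loc["A", "pct_genes_annotated"] == 100.0

    def test_median_over_annotated_genes(self):
        lines = (
            [gaf_line("g1", f"GO:00000{10+i}", "P") for i in range(1)]
            + [gaf_line("g2", f"GO:00000{20+i}", "P") for i in range(2)]
            + [gaf_line("g3", f"GO:00000{30+i}", "P") for i in range(3)]
        )
        aset = read_gaf(gaf_doc(*lines), "g")
        table = quantify_annotations(aset, n_genes=10)
        assert table.loc["P", "median_annotations_per_gene"] == 2.0

    def test_universe_smaller_than_annotated_errors(self):
        aset = read_gaf(gaf_doc(
            gaf_line("g1", "GO:0000010", "P"),
            gaf_line("g2", "GO:0000011", "P"),
        ), "g")
        with pytest.raises(ValueError):
            quantify_annotations(aset, n_genes=1)
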