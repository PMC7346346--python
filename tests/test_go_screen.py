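"""GAF loading, immune keyword screening and candidate-triple output."""

import pytest

from phenomine.go_screen import (
    CandidateTriple,
    GoAnnotation,
    ScreenConfig,
    immune_filter,
    load_gaf,
    read_go_names,
    read_triples,
    screen,
    write_triples,
)
from phenomine.phenotype_map import PhenotypeTerm
from phenomine.term_match import MatchResult, normalize


def gaf_line(gene, go_id, aspect="P"):
    cols = ["DB", f"ACC_{gene}", gene, "", go_id, "REF:1", "IEA", "",
            aspect, "", "", "protein", "taxon:9606", "20240101", "DB"]
    return "\t".join(cols)


class TestLoadGaf:
    def test_name_join_and_fields(self, tmp_path):
        p = tmp_path / "a.gaf"
        p.write_text("!gaf-version: 2.2\n" + gaf_line("BTK", "GO:0042113") + "\n")
        (ann,) = load_gaf(p, {"GO:0042113": "B cell activation"})
        assert (ann.gene_symbol, ann.go_id, ann.aspect) == \
            ("BTK", "GO:0042113", "P")
        assert ann.go_name == "B cell activation"

    def test_comment_only_file(self, tmp_path):
        p = tmp_path / "a.gaf"
        p.write_text("!gaf-version: 2.2\n! nothing\n")
        assert load_gaf(p, {}) == []

    def test_unknown_id_kept_with_empty_name(self, tmp_path):
        p = tmp_path / "a.gaf"
        p.write_text(gaf_line("BTK", "GO:0009999") + "\n")
        (ann,) = load_gaf(p, {})
        assert ann.go_name == ""

    def test_short_line_names_lineno(self, tmp_path):
        p = tmp_path / "a.gaf"
        p.write_text(gaf_line("BTK", "GO:0042113") + "\nBTK\tGO:0042113\n")
        with pytest.raises(ValueError, match=":2"):
            load_gaf(p, {})

    def test_go_names_table(self, tmp_path):
        p = tmp_path / "names.tsv"
        p.write_text("# id\tname\nGO:0042113\tB cell activation\n")
        assert read_go_names(p) == {"GO:0042113": "B cell activation"}


def ann(gene, go_id, name, aspect="P"):
    return GoAnnotation(gene, go_id, name, aspect)


class TestImmuneFilter:
    def test_keyword_substring_match(self):
        out = immune_filter(
            ["A"], [ann("A", "GO:0000001",
                        "positive regulation of T cell proliferation")],
            ScreenConfig(keywords=("t cell proliferation", "immune")))
        assert out == {"A": ["GO:0000001"]}

    def test_non_immune_gene_dropped(self):
        out = immune_filter(["A"], [ann("A", "GO:0000002",
                                        "ribosome biogenesis")])
        assert out == {}

    def test_default_keywords_select_expected_genes(self):
        # fixture mirroring the three-gene outcome of the default screen
        anns = [
            ann("AKT1", "GO:0000001", "regulation of immune response"),
            ann("ACTG2", "GO:0000002", "T cell activation"),
            ann("BTK", "GO:0000003", "B cell activation"),
            ann("RPL3", "GO:0000004", "ribosome biogenesis"),
            ann("TUBB", "GO:0000005", "microtubule polymerization"),
        ]
        out = immune_filter(["AKT1", "ACTG2", "BTK", "RPL3", "TUBB"], anns)
        assert set(out) == {"ACTG2", "AKT1", "BTK"}

    def test_aspect_restriction(self):
        anns = [ann("A", "GO:0000001", "immune response", aspect="C")]
        assert immune_filter(["A"], anns) == {}
        cfg = ScreenConfig(aspects=("P", "C"))
        assert immune_filter(["A"], anns, cfg) == {"A": ["GO:0000001"]}

    def test_allowlist_bypasses_name(self):
        anns = [ann("A", "GO:0000007", "")]
        cfg = ScreenConfig(keywords=("immune",),
                           go_allowlist=frozenset({"GO:0000007"}))
        assert immune_filter(["A"], anns, cfg) == {"A": ["GO:0000007"]}

    def test_evidence_sorted(self):
        anns = [ann("A", "GO:0000009", "immune x"),
                ann("A", "GO:0000001", "immune y")]
        assert immune_filter(["A"], anns)["A"] == ["GO:0000001", "GO:0000009"]

    def test_shrinking_keywords_never_adds(self):
        anns = [ann("A", "GO:0000001", "immune response"),
                ann("B", "GO:0000002", "t cell activation")]
        full = immune_filter(["A", "B"], anns,
                             ScreenConfig(keywords=("immune",
                                                    "t cell activation")))
        fewer = immune_filter(["A", "B"], anns,
                              ScreenConfig(keywords=("immune",)))
        assert set(fewer) <= set(full)

    def test_empty_config_rejected(self):
        with pytest.raises(ValueError):
            ScreenConfig(keywords=())


def match(drug, adr, gene, hid="HP:0100658", name="Cellulitis", score=1.0):
    return MatchResult(drug, normalize(adr), PhenotypeTerm(hid, name),
                       gene, score)


RETAINED = {"BTK": ["GO:0042113"]}


class TestScreen:
    def test_retained_gene_yields_triple(self):
        triples = screen([match("Pembrolizumab", "cellulitis", "BTK")],
                         RETAINED)
        (t,) = triples
        assert (t.drug, t.side_effect, t.gene) == \
            ("Pembrolizumab", "cellulitis", "BTK")
        assert t.evidence_go == ("GO:0042113",)

    def test_same_gene_multiple_drugs(self):
        triples = screen([match("Pembrolizumab", "cellulitis", "BTK"),
                          match("Avelumab", "cellulitis", "BTK")], RETAINED)
        assert [(t.drug, t.gene) for t in triples] == \
            [("Avelumab", "BTK"), ("Pembrolizumab", "BTK")]

    def test_unretained_gene_dropped(self):
        assert screen([match("d", "sepsis", "RPL3")], RETAINED) == []

    def test_duplicate_side_effects_keep_max_score(self):
        ms = [match("d", "Cellulitis", "BTK", score=0.9),
              match("d", "cellulitis ", "BTK", score=0.95)]
        (t,) = screen(ms, RETAINED)
        assert t.match_score == 0.95

    def test_idempotent(self):
        ms = [match("d", "cellulitis", "BTK"), match("e", "sepsis", "BTK")]
        first = screen(ms, RETAINED)
        again = screen([match(t.drug, t.side_effect, t.gene,
                              t.hpo_id, score=t.match_score)
                        for t in first], RETAINED)
        assert [(t.drug, t.side_effect, t.gene) for t in first] == \
            [(t.drug, t.side_effect, t.gene) for t in again]

    def test_empty_evidence_rejected(self):
        with pytest.raises(ValueError):
            CandidateTriple("d", "s", "g", "HP:0000001", 1.0, ())


class TestTriplesIo:
    TRIPLES = [
        CandidateTriple("Atezolizumab", "Sepsis", "ACTG2", "HP:0100806",
                        1.0, ("GO:0042110",)),
        CandidateTriple("Pembrolizumab", "Cellulitis", "BTK", "HP:0100658",
                        0.9123, ("GO:0042113", "GO:0050776")),
    ]

    def test_round_trip(self, tmp_path):
        p = tmp_path / "triples.tsv"
        write_triples(p, self.TRIPLES)
        back = read_triples(p)
        assert back == [
            CandidateTriple(t.drug, t.side_effect, t.gene, t.hpo_id,
                            round(t.match_score, 4), t.evidence_go)
            for t in self.TRIPLES]

    def test_zero_triples_header_only(self, tmp_path):
        p = tmp_path / "triples.tsv"
        write_triples(p, [])
        assert p.read_text().strip() == \
            "drug\tside_effect\tgene\thpo_id\tscore\tevidence_go"

    def test_deterministic_bytes(self, tmp_path):
        p1, p2 = tmp_path / "a.tsv", tmp_path / "b.tsv"
        write_triples(p1, self.TRIPLES)
        write_triples(p2, self.TRIPLES)
        assert p1.read_bytes() == p2.read_bytes()
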