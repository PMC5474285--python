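"""Readers, writers, round-trips and packaged-fixture integrity."""

import pytest

from herbnet import core_io
from herbnet.errors import ParseError, ValidationError
from herbnet.netanalysis import build_bipartite


class TestFixtureIntegrity:
    def test_compound_fixture_has_32_rows(self, compound_fixture):
        assert len(compound_fixture) == 32
        ids = [c.compound_id for c in compound_fixture]
        assert len(set(ids)) == 32

    def test_ursolic_acid_values(self, compound_fixture):
        c30 = {c.compound_id: c for c in compound_fixture}["C30"]
        assert c30.name == "Ursolic acid"
        assert c30.ob_percent == pytest.approx(16.77)
        assert c30.caco2 == pytest.approx(0.67)
        assert c30.dl == pytest.approx(0.75)

    def test_target_fixture_has_182_unique_accessions(self, target_fixture):
        assert len(target_fixture) == 182
        assert len({t.uniprot_id for t in target_fixture}) == 182

    def test_ptgs2_row(self, target_fixture):
        by_acc = {t.uniprot_id: t for t in target_fixture}
        assert by_acc["P35354"].gene_symbol == "PTGS2"

    def test_obsolete_calmodulin_accession_kept_verbatim(self, target_fixture):
        by_acc = {t.uniprot_id: t for t in target_fixture}
        assert by_acc["P62158"].gene_symbol == "CALM1"

    def test_common_gene_fixture_contained_in_targets(self, target_fixture,
                                                      common_gene_fixture):
        # 24 distinct rows, every accession of which appears in the
        # target table
        assert len(common_gene_fixture) == 24
        accs = {t.uniprot_id for t in target_fixture}
        assert all(g.uniprot_id in accs for g in common_gene_fixture)

    def test_rescue_ids_are_exactly_the_threshold_failures(
            self, compound_fixture, rescue_ids):
        failing = {c.compound_id for c in compound_fixture
                   if not (c.ob_percent >= 15 and c.caco2 >= -0.4
                           and c.dl >= 0.18)}
        assert set(rescue_ids) == failing
        assert len(rescue_ids) == 14

    def test_organ_panel_has_17_tissues(self, organ_panel):
        assert len(organ_panel) == 17
        assert "CD33+ myeloid" in organ_panel
        assert "Small intestine" in organ_panel and "Colon" in organ_panel


class TestCompoundReader:
    def test_header_only_gives_empty_list(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("compound_id\tname\tob_percent\tcaco2\tdl\n")
        assert core_io.read_compound_table(p) == []

    def test_non_numeric_value_names_row_and_column(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("compound_id\tname\tob_percent\tcaco2\tdl\n"
                     "C1\tfoo\tabc\t0.5\t0.2\n")
        with pytest.raises(ParseError) as exc:
            core_io.read_compound_table(p)
        assert exc.value.row == 1
        assert exc.value.column == "ob_percent"

    def test_duplicate_compound_id_rejected(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("compound_id\tname\tob_percent\tcaco2\tdl\n"
                     "C1\ta\t10\t0\t0.2\nC1\tb\t20\t0\t0.3\n")
        with pytest.raises(ParseError, match="duplicate"):
            core_io.read_compound_table(p)

    def test_missing_column_rejected(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("compound_id\tname\tob_percent\tcaco2\n"
                     "C1\ta\t10\t0\n")
        with pytest.raises(ParseError, match="missing required column"):
            core_io.read_compound_table(p)

    def test_comma_separated_input_rejected_not_sniffed(self, tmp_path):
        p = tmp_path / "c.csv"
        p.write_text("compound_id,name,ob_percent,caco2,dl\nC1,a,10,0,0.2\n")
        with pytest.raises(ParseError, match="tab-separated"):
            core_io.read_compound_table(p)

    def test_negative_ob_rejected(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("compound_id\tname\tob_percent\tcaco2\tdl\n"
                     "C1\ta\t-3\t0\t0.2\n")
        with pytest.raises(ValidationError, match="ob_percent"):
            core_io.read_compound_table(p)

    def test_unicode_minus_parsed(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text("compound_id\tname\tob_percent\tcaco2\tdl\n"
                     "C1\ta\t10\t−0.5\t0.2\n")
        [rec] = core_io.read_compound_table(p)
        assert rec.caco2 == pytest.approx(-0.5)


class TestTargetReader:
    def test_lowercase_symbol_uppercased(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("uniprot_id\tprotein_name\tgene_symbol\n"
                     "P35354\tProstaglandin G/H synthase 2\tptgs2\n")
        [rec] = core_io.read_target_table(p)
        assert rec.gene_symbol == "PTGS2"

    def test_header_only_gives_empty_list(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("uniprot_id\tprotein_name\tgene_symbol\n")
        assert core_io.read_target_table(p) == []

    def test_malformed_accession_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("uniprot_id\tprotein_name\tgene_symbol\n"
                     "NOTANACC\tfoo\tBAR\n")
        with pytest.raises(ParseError, match="accession"):
            core_io.read_target_table(p)

    def test_duplicate_accession_rejected(self, tmp_path):
        p = tmp_path / "t.tsv"
        p.write_text("uniprot_id\tprotein_name\tgene_symbol\n"
                     "P35354\ta\tPTGS2\nP35354\tb\tPTGS1\n")
        with pytest.raises(ParseError, match="duplicate"):
            core_io.read_target_table(p)


class TestGmtReader:
    def test_single_line(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("IBD\tKEGG IBD\tIL6\tTNF\tRELA\n")
        coll = core_io.read_gmt(p)
        assert len(coll) == 1
        assert coll.members("IBD") == {"IL6", "TNF", "RELA"}

    def test_duplicate_member_stored_once(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("S\tdesc\tIL6\til6\tTNF\n")
        coll = core_io.read_gmt(p)
        assert coll.members("S") == {"IL6", "TNF"}

    def test_short_line_names_line_number(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("S1\tdesc\tIL6\nS2\tonly-two-fields\n")
        with pytest.raises(ParseError) as exc:
            core_io.read_gmt(p)
        assert exc.value.line == 2

    def test_duplicate_set_id_rejected(self, tmp_path):
        p = tmp_path / "s.gmt"
        p.write_text("S\td\tIL6\nS\td\tTNF\n")
        with pytest.raises(ValidationError, match="duplicate set_id"):
            core_io.read_gmt(p)


class TestExpressionReader:
    def test_toy_shape(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("gene\tA\tB\tC\ng1\t1\t2\t3\ng2\t4\t5\t6\n")
        m = core_io.read_expression_matrix(p)
        assert m.values.shape == (2, 3)
        assert m.col_ids == ["A", "B", "C"]

    def test_negative_value_rejected(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("gene\tA\tB\ng1\t1\t−1.0\n")
        with pytest.raises(ValidationError, match="nonnegative"):
            core_io.read_expression_matrix(p)

    def test_ragged_row_rejected(self, tmp_path):
        p = tmp_path / "e.tsv"
        p.write_text("gene\tA\tB\ng1\t1\n")
        with pytest.raises(ParseError, match="ragged"):
            core_io.read_expression_matrix(p)


class TestRoundTrips:
    def test_compound_table_roundtrip(self, tmp_path, compound_fixture):
        p = tmp_path / "c.tsv"
        core_io.write_compound_table(compound_fixture, p)
        assert core_io.read_compound_table(p) == compound_fixture

    def test_target_table_roundtrip(self, tmp_path, target_fixture):
        p = tmp_path / "t.tsv"
        core_io.write_target_table(target_fixture, p)
        assert core_io.read_target_table(p) == target_fixture

    def test_edge_table_roundtrip_remerges_sources(self, tmp_path):
        edges = [core_io.InteractionEdge("C1", "P35354",
                                         frozenset({"TCMSP", "SEA"}))]
        p = tmp_path / "e.tsv"
        core_io.write_edge_table(edges, p)
        rows = core_io.read_edge_table(p)
        assert len(rows) == 2  # one row per provenance tag
        assert {tuple(sorted(r.sources))[0] for r in rows} == {"SEA", "TCMSP"}

    def test_network_edge_tsv_roundtrip(self, tmp_path):
        net = build_bipartite([("c1", "t1"), ("c1", "t2"), ("c2", "t1")],
                              ["c1", "c2"], ["t1", "t2"])
        p = tmp_path / "n.tsv"
        core_io.write_network(net, p, "edge-tsv")
        back = core_io.read_network_edge_tsv(p)
        expect = {(min(u, v), max(u, v)) for u, v in net.edges()}
        assert back == expect

    def test_sif_line_count(self, tmp_path):
        net = build_bipartite([("c1", "t1"), ("c2", "t2")],
                              ["c1", "c2"], ["t1", "t2"])
        p = tmp_path / "n.sif"
        core_io.write_network(net, p, "sif")
        lines = p.read_text().strip().splitlines()
        assert len(lines) == 2
        assert all("\tinteracts\t" in ln for ln in lines)

    def test_attribute_less_nodes_get_empty_fields(self, tmp_path):
        net = build_bipartite([("c1", "t1")], ["c1"], ["t1", "t2"])
        p = tmp_path / "n.tsv"
        core_io.write_network(net, p, "edge-tsv", attributes=None)
        attr = (tmp_path / "n.tsv.nodes.tsv").read_text().splitlines()
        assert len(attr) == 4  # header + 3 nodes, isolated t2 included
        assert any(ln.startswith("t2\tright\t\t") for ln in attr)

    def test_unknown_dialect_rejected(self, tmp_path):
        net = build_bipartite([("c1", "t1")], ["c1"], ["t1"])
        with pytest.raises(ValidationError, match="dialect"):
            core_io.write_network(net, tmp_path / "x", "xlsx")
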