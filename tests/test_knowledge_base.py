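"""Data-model invariants and TSV round-trips for the knowledge-base layer."""

import random

import pytest

from toxilink import (
    AnnotationSource,
    ChemProtAssociation,
    Evidence,
    IdMap,
    InteractomeGraph,
    ProteinSet,
    Relation,
    SourceKind,
    Stage,
)
from toxilink.knowledge_base import (
    KnowledgeBaseError,
    Provenance,
    read_annotation_table,
    read_chem_protein_table,
    read_idmap,
    read_interactome,
    read_protein_set,
    write_annotation_table,
    write_chem_protein_table,
    write_idmap,
    write_interactome,
    write_protein_set,
)


def write(path, text):
    path.write_text(text, encoding="utf-8")
    return path


class TestChemProtTable:
    def test_duplicates_collapse(self, tmp_path, caplog):
        p = write(
            tmp_path / "cp.tsv",
            "chemical_id\tprotein_id\tevidence\tsource_tag\n"
            "C1\tP1\tbinding\tx\n"
            "C1\tP2\texpression\ty\n"
            "C1\tP1\tbinding\tx\n",
        )
        with caplog.at_level("INFO", logger="toxilink"):
            assocs = read_chem_protein_table(p)
        assert len(assocs) == 2
        assert "1 duplicate" in caplog.text

    def test_header_only_is_empty(self, tmp_path):
        p = write(tmp_path / "cp.tsv", "chemical_id\tprotein_id\tevidence\tsource_tag\n")
        assert read_chem_protein_table(p) == frozenset()

    def test_missing_file_names_path(self, tmp_path):
        with pytest.raises(KnowledgeBaseError, match="missing.tsv"):
            read_chem_protein_table(tmp_path / "missing.tsv")

    @pytest.mark.parametrize(
        "row, message",
        [
            ("C1\tP1\tbinding", "expected 4 columns, got 3"),
            ("C1\t\tbinding\tx", "empty protein_id"),
            ("C1\tP1\tguessed\tx", "guessed"),
        ],
    )
    def test_malformed_rows_fail_with_location(self, tmp_path, row, message):
        p = write(
            tmp_path / "cp.tsv",
            f"chemical_id\tprotein_id\tevidence\tsource_tag\n{row}\n",
        )
        with pytest.raises(KnowledgeBaseError, match=message):
            read_chem_protein_table(p)

    def test_error_reports_line_number(self, tmp_path):
        p = write(
            tmp_path / "cp.tsv",
            "# comment\nchemical_id\tprotein_id\tevidence\tsource_tag\n"
            "C1\tP1\tbinding\tx\nC1\tP2\n",
        )
        with pytest.raises(KnowledgeBaseError, match=":4:"):
            read_chem_protein_table(p)

    def test_round_trip_permutation_invariant(self, tmp_path, five_associations):
        rows = sorted(
            (a.chemical_id, a.protein_id, a.evidence.value, a.source_tag)
            for a in five_associations
        )
        random.Random(3).shuffle(rows)
        body = "".join("\t".join(r) + "\n" for r in rows)
        p = write(
            tmp_path / "cp.tsv",
            "chemical_id\tprotein_id\tevidence\tsource_tag\n" + body,
        )
        assert read_chem_protein_table(p) == five_associations
        write_chem_protein_table(five_associations, tmp_path / "out.tsv")
        assert read_chem_protein_table(tmp_path / "out.tsv") == five_associations


class TestInteractome:
    def test_reversed_edge_is_same_edge(self, tmp_path):
        p = write(
            tmp_path / "ppi.tsv",
            "protein_a\tprotein_b\tconfidence\nA\tB\t0.9\nB\tA\t0.9\n",
        )
        graph = read_interactome(p)
        assert graph.n_edges == 1

    def test_self_loop_rejected(self):
        with pytest.raises(KnowledgeBaseError, match="self-loop"):
            InteractomeGraph([("A", "A", 0.5)])

    def test_confidence_out_of_range_rejected(self):
        with pytest.raises(KnowledgeBaseError, match=r"\[0, 1\]"):
            InteractomeGraph([("A", "B", 1.5)])

    def test_one_member_pathway_rejected(self):
        with pytest.raises(KnowledgeBaseError, match="at least 2"):
            InteractomeGraph([], {"P1": ["A"]})

    def test_pathway_singletons_are_proteins(self, chain_graph):
        # E appears only in a pathway, with no interaction partner
        assert "E" in chain_graph.proteins
        assert chain_graph.neighbors_above("E", 0.0) == set()

    def test_round_trip(self, tmp_path, chain_graph):
        write_interactome(chain_graph, tmp_path / "ppi.tsv", tmp_path / "pw.tsv")
        again = read_interactome(tmp_path / "ppi.tsv", tmp_path / "pw.tsv")
        assert again == chain_graph

    def test_induced_edge_count(self, chain_graph):
        assert chain_graph.induced_edge_count({"A", "B", "C"}) == 2
        assert chain_graph.induced_edge_count({"A", "C"}) == 0


class TestAnnotationSource:
    def test_direct_beats_inferred_on_duplicate_pair(self):
        src = AnnotationSource(
            SourceKind.CTD_LIKE,
            [("G1", "D1", Relation.INFERRED), ("G1", "D1", Relation.DIRECT)],
        )
        assert src.annotations == {("G1", "D1", Relation.DIRECT)}

    def test_omim_like_rejects_inferred(self):
        with pytest.raises(KnowledgeBaseError, match="direct"):
            AnnotationSource(SourceKind.OMIM_LIKE, [("G1", "D1", Relation.INFERRED)])

    def test_universe_and_diseases_are_projections(self, tiny_annotation_source):
        src = tiny_annotation_source
        assert src.universe == {"G1", "G2", "G3", "G4", "G5"}
        assert src.diseases == {"D1", "D2", "D3"}

    def test_round_trip(self, tmp_path, tiny_annotation_source):
        write_annotation_table(tiny_annotation_source, tmp_path / "ann.tsv")
        again = read_annotation_table(tmp_path / "ann.tsv", SourceKind.CTD_LIKE)
        assert again == tiny_annotation_source


class TestIdMap:
    def test_one_to_many_targets_sorted(self):
        idmap = IdMap([("M1", "O2"), ("M1", "O1"), ("M2", "O3")], "mesh->omim")
        assert idmap.targets("M1") == ("O1", "O2")
        assert idmap.targets("missing") == ()

    def test_round_trip(self, tmp_path, gene_idmap):
        write_idmap(gene_idmap, tmp_path / "map.tsv")
        assert read_idmap(tmp_path / "map.tsv") == gene_idmap


class TestProteinSet:
    def test_write_sorts_rows(self, tmp_path):
        ps = ProteinSet(
            "C1",
            Stage.SEED,
            {"B": Provenance.CHEMPROT_SEED, "A": Provenance.CHEMPROT_SEED},
        )
        write_protein_set(ps, tmp_path / "ps.tsv")
        lines = (tmp_path / "ps.tsv").read_text().splitlines()
        assert [l.split("\t")[2] for l in lines[1:]] == ["A", "B"]

    def test_round_trip_randomized_members(self, tmp_path):
        rng = random.Random(11)
        members = [f"P{rng.randrange(10**6)}" for _ in range(10)]
        provs = list(Provenance)
        ps = ProteinSet(
            "C1", Stage.EXPANDED, {m: rng.choice(provs) for m in members}
        )
        write_protein_set(ps, tmp_path / "ps.tsv")
        (again,) = read_protein_set(tmp_path / "ps.tsv")
        assert again == ps

    def test_empty_set_writes_header_only(self, tmp_path):
        write_protein_set(ProteinSet("C1", Stage.SEED, {}), tmp_path / "ps.tsv")
        assert (
            (tmp_path / "ps.tsv").read_text()
            == "chemical_id\tstage\tprotein_id\tprovenance\n"
        )

    def test_non_empty_ids_enforced(self):
        with pytest.raises(KnowledgeBaseError):
            ChemProtAssociation("", "P1", Evidence.BINDING)
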