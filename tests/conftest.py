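import pytest

from toxilink import (
    AnnotationSource,
    ChemProtAssociation,
    Evidence,
    IdMap,
    InteractomeGraph,
    Provenance,
    ProteinSet,
    Relation,
    SourceKind,
    Stage,
)


@pytest.fixture
def five_associations():
    """Five associations for C1, two of them merely predicted."""
    return frozenset(
        [
            ChemProtAssociation("C1", "P1", Evidence.BINDING, "assayDB"),
            ChemProtAssociation("C1", "P2", Evidence.EXPRESSION, "exprDB"),
            ChemProtAssociation("C1", "P3", Evidence.BINDING, "assayDB"),
            ChemProtAssociation("C1", "P4", Evidence.PREDICTED, "structpred"),
            ChemProtAssociation("C1", "P5", Evidence.PREDICTED, "structpred"),
            ChemProtAssociation("C2", "P9", Evidence.BINDING, "assayDB"),
        ]
    )


@pytest.fixture
def chain_graph():
    """A - B - C - D chain (all confidence 0.9) plus two pathways."""
    return InteractomeGraph(
        edges=[("A", "B", 0.9), ("B", "C", 0.9), ("C", "D", 0.9)],
        pathways={"P1": ["A", "D"], "P2": ["D", "E"]},
    )


def make_seed(chemical_id, members):
    return ProteinSet(
        chemical_id, Stage.SEED, {m: Provenance.CHEMPROT_SEED for m in members}
    )


def make_mapped(chemical_id, members):
    return ProteinSet(
        chemical_id, Stage.MAPPED, {m: Provenance.CHEMPROT_SEED for m in members}
    )


@pytest.fixture
def tiny_annotation_source():
    """Universe of 5 genes, 3 diseases; direct/inferred mix."""
    return AnnotationSource(
        SourceKind.CTD_LIKE,
        [
            ("G1", "D1", Relation.DIRECT),
            ("G2", "D1", Relation.INFERRED),
            ("G3", "D2", Relation.INFERRED),
            ("G4", "D2", Relation.DIRECT),
            ("G5", "D3", Relation.INFERRED),
            ("G1", "D3", Relation.INFERRED),
        ],
    )


@pytest.fixture
def gene_idmap():
    return IdMap([(f"P{i}", f"G{i}") for i in range(1, 9)], "protein->gene")
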