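"""Data model and tabular I/O for the knowledge bases the pipeline consumes.

The pipeline reads five kinds of TSV tables: chemical-protein associations
(a ChemProt-like layer with evidence flags), a scored protein-protein
interaction table plus pathway memberships (the interactome), protein-disease
annotation catalogs of two kinds (a sparse curated OMIM-like source and a
dense CTD-like source mixing curated and inferred records), and one-to-many
identifier maps (MeSH disease ids to OMIM ids; protein ids to Entrez-style
gene ids).

All tables are UTF-8 TSV with a mandatory header row; lines starting with
``#`` are comments.  Malformed rows abort with the file name and line number
so that a bad knowledge base is diagnosable.  Duplicate rows are collapsed
and counted.  Loading is permutation-invariant: row order never affects the
in-memory structures.
"""

from __future__ import annotations

import csv
import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path

import networkx as nx

logger = logging.getLogger("toxilink")

__all__ = [
    "Evidence",
    "Relation",
    "Stage",
    "Provenance",
    "SourceKind",
    "ChemProtAssociation",
    "InteractomeGraph",
    "AnnotationSource",
    "IdMap",
    "ProteinSet",
    "KnowledgeBase",
    "KnowledgeBaseError",
    "read_chem_protein_table",
    "write_chem_protein_table",
    "read_interactome",
    "write_interactome",
    "read_annotation_table",
    "write_annotation_table",
    "read_idmap",
    "write_idmap",
    "read_protein_set",
    "write_protein_set",
    "load_knowledge_base",
]


class KnowledgeBaseError(ValueError):
    """Raised for malformed tables or invariant violations."""


class Evidence(str, Enum):
    """Evidence class of a chemical-protein association.

    Only experimentally supported links (binding assays or differential gene
    expression) seed the pipeline; structure-based predictions are carried in
    the table but discarded by the extraction step.
    """

    BINDING = "binding"
    EXPRESSION = "expression"
    PREDICTED = "predicted"


class Relation(str, Enum):
    """Curation status of a protein-disease annotation record."""

    DIRECT = "direct"
    INFERRED = "inferred"


class Stage(str, Enum):
    """Pipeline stage of a protein set."""

    SEED = "seed"
    EXPANDED = "expanded"
    MAPPED = "mapped"


class Provenance(str, Enum):
    """How a protein entered a chemical's set."""

    CHEMPROT_SEED = "chemprot_seed"
    FIRST_ORDER_NEIGHBOR = "first_order_neighbor"
    PATHWAY_COMEMBER = "pathway_comember"


# seed evidence always beats network-derived provenance
PROVENANCE_PRIORITY = {
    Provenance.CHEMPROT_SEED: 0,
    Provenance.FIRST_ORDER_NEIGHBOR: 1,
    Provenance.PATHWAY_COMEMBER: 2,
}


class SourceKind(str, Enum):
    """Annotation catalog flavor: sparse curated vs dense mixed-evidence."""

    OMIM_LIKE = "omim_like"
    CTD_LIKE = "ctd_like"


@dataclass(frozen=True)
class ChemProtAssociation:
    """One chemical-to-protein edge with its evidence flag."""

    chemical_id: str
    protein_id: str
    evidence: Evidence
    source_tag: str = ""

    def __post_init__(self) -> None:
        if not self.chemical_id:
            raise KnowledgeBaseError("chemical_id must be non-empty")
        if not self.protein_id:
            raise KnowledgeBaseError("protein_id must be non-empty")
        if not isinstance(self.evidence, Evidence):
            object.__setattr__(self, "evidence", Evidence(self.evidence))


class InteractomeGraph:
    """Undirected, confidence-scored PPI graph plus pathway memberships.

    Edges are undirected and self-loops are rejected; proteins that appear in
    a pathway but have no interaction partner are legitimate singletons and
    are retained.  Backed by a :class:`networkx.Graph` with a ``confidence``
    edge attribute.
    """

    def __init__(
        self,
        edges: Iterable[tuple[str, str, float]] = (),
        pathways: Mapping[str, Iterable[str]] | None = None,
    ) -> None:
        g = nx.Graph()
        for a, b, conf in edges:
            if a == b:
                raise KnowledgeBaseError(f"self-loop on protein {a!r} is not allowed")
            if not a or not b:
                raise KnowledgeBaseError("protein ids in PPI edges must be non-empty")
            conf = float(conf)
            if not 0.0 <= conf <= 1.0:
                raise KnowledgeBaseError(
                    f"confidence {conf} for edge ({a}, {b}) outside [0, 1]"
                )
            if g.has_edge(a, b):
                # keep the strongest record of a duplicated edge
                g[a][b]["confidence"] = max(g[a][b]["confidence"], conf)
            else:
                g.add_edge(a, b, confidence=conf)
        self.graph = g
        self.pathways: dict[str, frozenset[str]] = {}
        for pid, members in (pathways or {}).items():
            mset = frozenset(members)
            if len(mset) < 2:
                raise KnowledgeBaseError(
                    f"pathway {pid!r} has {len(mset)} member(s); at least 2 required"
                )
            self.pathways[pid] = mset
            g.add_nodes_from(mset)

    @property
    def proteins(self) -> frozenset[str]:
        return frozenset(self.graph.nodes)

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def neighbors_above(self, protein_id: str, min_confidence: float) -> set[str]:
        """Interaction partners of *protein_id* with confidence >= threshold."""
        if protein_id not in self.graph:
            return set()
        return {
            v
            for v, attr in self.graph[protein_id].items()
            if attr["confidence"] >= min_confidence
        }

    def induced_edge_count(self, proteins: Iterable[str]) -> int:
        """Number of PPI edges with both endpoints inside *proteins*."""
        nodes = [p for p in set(proteins) if p in self.graph]
        return self.graph.subgraph(nodes).number_of_edges()

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, InteractomeGraph):
            return NotImplemented
        return (
            self.pathways == other.pathways
            and set(self.graph.nodes) == set(other.graph.nodes)
            and {
                (min(a, b), max(a, b), d["confidence"])
                for a, b, d in self.graph.edges(data=True)
            }
            == {
                (min(a, b), max(a, b), d["confidence"])
                for a, b, d in other.graph.edges(data=True)
            }
        )


class AnnotationSource:
    """A protein-disease annotation catalog with its own protein universe.

    The universe (all proteins carrying at least one annotation) defines the
    sampling frame N of the enrichment test; the disease vocabulary defines
    the Bonferroni family for CTD-like sources.  When the same (protein,
    disease) pair carries both a direct and an inferred record, the direct
    one wins.  OMIM-like sources must be purely direct.
    """

    def __init__(
        self,
        kind: SourceKind,
        annotations: Iterable[tuple[str, str, Relation]],
    ) -> None:
        self.kind = SourceKind(kind)
        best: dict[tuple[str, str], Relation] = {}
        for protein_id, disease_id, relation in annotations:
            if not protein_id or not disease_id:
                raise KnowledgeBaseError("annotation ids must be non-empty")
            relation = Relation(relation)
            key = (protein_id, disease_id)
            if key not in best or relation is Relation.DIRECT:
                best[key] = relation
        if self.kind is SourceKind.OMIM_LIKE and any(
            r is not Relation.DIRECT for r in best.values()
        ):
            raise KnowledgeBaseError("omim_like sources admit only relation=direct")
        self.annotations: frozenset[tuple[str, str, Relation]] = frozenset(
            (p, d, r) for (p, d), r in best.items()
        )

    @property
    def universe(self) -> frozenset[str]:
        return frozenset(p for p, _, _ in self.annotations)

    @property
    def diseases(self) -> frozenset[str]:
        return frozenset(d for _, d, _ in self.annotations)

    def restricted(self, relation: Relation) -> "AnnotationSource":
        """Sub-catalog keeping only records of the given relation."""
        return AnnotationSource(
            self.kind, [a for a in self.annotations if a[2] is relation]
        )

    def __len__(self) -> int:
        return len(self.annotations)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotationSource):
            return NotImplemented
        return self.kind == other.kind and self.annotations == other.annotations


class IdMap:
    """One-to-many identifier map (e.g. MeSH disease id -> OMIM ids)."""

    def __init__(
        self, pairs: Iterable[tuple[str, str]], direction_label: str = ""
    ) -> None:
        self.direction_label = direction_label
        self.pairs: frozenset[tuple[str, str]] = frozenset(
            (str(s), str(t)) for s, t in pairs
        )
        for s, t in self.pairs:
            if not s or not t:
                raise KnowledgeBaseError("idmap identifiers must be non-empty")
        mapping: dict[str, set[str]] = {}
        for s, t in self.pairs:
            mapping.setdefault(s, set()).add(t)
        self._mapping = {s: tuple(sorted(ts)) for s, ts in mapping.items()}

    def targets(self, source_id: str) -> tuple[str, ...]:
        """Mapped target ids for *source_id* (empty tuple if unmapped)."""
        return self._mapping.get(source_id, ())

    def __contains__(self, source_id: str) -> bool:
        return source_id in self._mapping

    def __len__(self) -> int:
        return len(self.pairs)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, IdMap):
            return NotImplemented
        return self.pairs == other.pairs


@dataclass
class ProteinSet:
    """A chemical's protein set at one pipeline stage, with provenance.

    ``provenance`` records how each member entered the set (direct ChemProt
    evidence, first-order interaction partner, or pathway co-membership);
    every member has exactly one provenance entry by construction.
    """

    chemical_id: str
    stage: Stage
    provenance: dict[str, Provenance] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.stage = Stage(self.stage)
        self.provenance = {p: Provenance(v) for p, v in self.provenance.items()}

    @property
    def members(self) -> frozenset[str]:
        return frozenset(self.provenance)

    def __len__(self) -> int:
        return len(self.provenance)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, ProteinSet):
            return NotImplemented
        return (
            self.chemical_id == other.chemical_id
            and self.stage == other.stage
            and self.provenance == other.provenance
        )


@dataclass
class KnowledgeBase:
    """All tables of one knowledge base, loaded and validated."""

    associations: frozenset[ChemProtAssociation]
    interactome: InteractomeGraph
    sources: dict[SourceKind, AnnotationSource]
    idmaps: dict[str, IdMap]

    @property
    def chemicals(self) -> frozenset[str]:
        return frozenset(a.chemical_id for a in self.associations)


# ---------------------------------------------------------------------------
# TSV plumbing
# ---------------------------------------------------------------------------


def _read_rows(path: Path | str, expected_header: list[str]) -> list[list[str]]:
    """Read a TSV, enforcing the header and per-row column counts.

    Returns data rows; raises :class:`KnowledgeBaseError` naming the file and
    line number on any malformation. '#'-prefixed lines are comments.
    """
    path = Path(path)
    if not path.exists():
        raise KnowledgeBaseError(f"missing knowledge-base file: {path}")
    rows: list[list[str]] = []
    header_seen = False
    with path.open(newline="", encoding="utf-8") as fh:
        for lineno, row in enumerate(csv.reader(fh, delimiter="\t"), start=1):
            if not row or (row[0].startswith("#")):
                continue
            if not header_seen:
                if [c.strip() for c in row] != expected_header:
                    raise KnowledgeBaseError(
                        f"{path}:{lineno}: expected header {expected_header}, "
                        f"got {row}"
                    )
                header_seen = True
                continue
            if len(row) != len(expected_header):
                raise KnowledgeBaseError(
                    f"{path}:{lineno}: expected {len(expected_header)} columns, "
                    f"got {len(row)}"
                )
            for col, value in zip(expected_header, row):
                if col.endswith("_id") and not value:
                    raise KnowledgeBaseError(f"{path}:{lineno}: empty {col}")
            rows.append(row)
    if not header_seen:
        raise KnowledgeBaseError(f"{path}: empty file, header row required")
    return rows


def _write_rows(path: Path | str, header: list[str], rows: Iterable[Iterable]) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(header)
        for row in rows:
            writer.writerow(row)


def _log_duplicates(n_raw: int, n_unique: int, what: str, path) -> None:
    if n_raw != n_unique:
        logger.info("%s: collapsed %d duplicate %s row(s)", path, n_raw - n_unique, what)


CHEM_PROTEIN_HEADER = ["chemical_id", "protein_id", "evidence", "source_tag"]
PPI_HEADER = ["protein_a", "protein_b", "confidence"]
PATHWAY_HEADER = ["pathway_id", "protein_id"]
ANNOTATION_HEADER = ["protein_id", "disease_id", "relation"]
IDMAP_HEADER = ["source_id", "target_id"]
PROTEIN_SET_HEADER = ["chemical_id", "stage", "protein_id", "provenance"]


def read_chem_protein_table(path: Path | str) -> frozenset[ChemProtAssociation]:
    """Load a chemical-protein association table."""
    rows = _read_rows(path, CHEM_PROTEIN_HEADER)
    assocs = set()
    for lineno_row in rows:
        chem, prot, evidence, tag = lineno_row
        try:
            ev = Evidence(evidence)
        except ValueError:
            raise KnowledgeBaseError(
                f"{path}: unknown evidence value {evidence!r} "
                f"(expected one of {[e.value for e in Evidence]})"
            ) from None
        assocs.add(ChemProtAssociation(chem, prot, ev, tag))
    _log_duplicates(len(rows), len(assocs), "chemical-protein", path)
    return frozenset(assocs)


def write_chem_protein_table(
    associations: Iterable[ChemProtAssociation], path: Path | str
) -> None:
    rows = sorted(
        (a.chemical_id, a.protein_id, a.evidence.value, a.source_tag)
        for a in associations
    )
    _write_rows(path, CHEM_PROTEIN_HEADER, rows)


def read_interactome(
    ppi_path: Path | str, pathways_path: Path | str | None = None
) -> InteractomeGraph:
    """Load the scored PPI table and (optionally) pathway memberships."""
    edge_rows = _read_rows(ppi_path, PPI_HEADER)
    edges = []
    for a, b, conf in edge_rows:
        try:
            c = float(conf)
        except ValueError:
            raise KnowledgeBaseError(
                f"{ppi_path}: non-numeric confidence {conf!r} for edge ({a}, {b})"
            ) from None
        edges.append((a, b, c))
    pathways: dict[str, set[str]] = {}
    if pathways_path is not None:
        for pid, prot in _read_rows(pathways_path, PATHWAY_HEADER):
            pathways.setdefault(pid, set()).add(prot)
    graph = InteractomeGraph(edges, pathways)
    _log_duplicates(len(edges), graph.n_edges, "PPI", ppi_path)
    return graph


def write_interactome(
    graph: InteractomeGraph,
    ppi_path: Path | str,
    pathways_path: Path | str | None = None,
) -> None:
    edge_rows = sorted(
        (min(a, b), max(a, b), repr(d["confidence"]))
        for a, b, d in graph.graph.edges(data=True)
    )
    _write_rows(ppi_path, PPI_HEADER, edge_rows)
    if pathways_path is not None:
        pw_rows = sorted(
            (pid, prot) for pid, members in graph.pathways.items() for prot in members
        )
        _write_rows(pathways_path, PATHWAY_HEADER, pw_rows)


def read_annotation_table(path: Path | str, kind: SourceKind) -> AnnotationSource:
    """Load a protein-disease annotation catalog of the given kind."""
    rows = _read_rows(path, ANNOTATION_HEADER)
    records = []
    for prot, dis, rel in rows:
        try:
            relation = Relation(rel)
        except ValueError:
            raise KnowledgeBaseError(
                f"{path}: unknown relation value {rel!r} "
                f"(expected one of {[r.value for r in Relation]})"
            ) from None
        records.append((prot, dis, relation))
    source = AnnotationSource(kind, records)
    _log_duplicates(len(rows), len(source), "annotation", path)
    return source


def write_annotation_table(source: AnnotationSource, path: Path | str) -> None:
    rows = sorted((p, d, r.value) for p, d, r in source.annotations)
    _write_rows(path, ANNOTATION_HEADER, rows)


def read_idmap(path: Path | str, direction_label: str = "") -> IdMap:
    rows = _read_rows(path, IDMAP_HEADER)
    idmap = IdMap([(s, t) for s, t in rows], direction_label)
    _log_duplicates(len(rows), len(idmap), "idmap", path)
    return idmap


def write_idmap(idmap: IdMap, path: Path | str) -> None:
    _write_rows(path, IDMAP_HEADER, sorted(idmap.pairs))


def read_protein_set(path: Path | str) -> list[ProteinSet]:
    """Load protein sets; one per (chemical, stage) group in the file."""
    rows = _read_rows(path, PROTEIN_SET_HEADER)
    grouped: dict[tuple[str, Stage], dict[str, Provenance]] = {}
    for chem, stage, prot, prov in rows:
        try:
            st, pv = Stage(stage), Provenance(prov)
        except ValueError as exc:
            raise KnowledgeBaseError(f"{path}: {exc}") from None
        grouped.setdefault((chem, st), {})[prot] = pv
    return [
        ProteinSet(chem, stage, prov)
        for (chem, stage), prov in sorted(grouped.items(), key=lambda kv: (kv[0][0], kv[0][1].value))
    ]


def write_protein_set(ps: ProteinSet, path: Path | str) -> None:
    """Write one protein set; rows sorted by protein_id for byte-stable output."""
    rows = [
        (ps.chemical_id, ps.stage.value, prot, ps.provenance[prot].value)
        for prot in sorted(ps.provenance)
    ]
    _write_rows(path, PROTEIN_SET_HEADER, rows)


DEFAULT_FILENAMES = {
    "chem_protein": "chem_protein.tsv",
    "ppi": "ppi.tsv",
    "pathways": "pathways.tsv",
    "annotations_omim": "annotations_omim.tsv",
    "annotations_ctd": "annotations_ctd.tsv",
    "idmap_mesh_omim": "idmap_mesh_omim.tsv",
    "idmap_protein_gene": "idmap_protein_gene.tsv",
}


def load_knowledge_base(directory: Path | str) -> KnowledgeBase:
    """Load and validate a complete knowledge base from a directory.

    Expects the conventional file names (``chem_protein.tsv``, ``ppi.tsv``,
    ``pathways.tsv``, ``annotations_omim.tsv``, ``annotations_ctd.tsv``,
    ``idmap_mesh_omim.tsv``, ``idmap_protein_gene.tsv``).
    """
    d = Path(directory)
    paths = {key: d / name for key, name in DEFAULT_FILENAMES.items()}
    for key, p in paths.items():
        if not p.exists():
            raise KnowledgeBaseError(f"missing knowledge-base file: {p}")
    associations = read_chem_protein_table(paths["chem_protein"])
    interactome = read_interactome(paths["ppi"], paths["pathways"])
    sources = {
        SourceKind.OMIM_LIKE: read_annotation_table(
            paths["annotations_omim"], SourceKind.OMIM_LIKE
        ),
        SourceKind.CTD_LIKE: read_annotation_table(
            paths["annotations_ctd"], SourceKind.CTD_LIKE
        ),
    }
    idmaps = {
        "mesh_omim": read_idmap(paths["idmap_mesh_omim"], "mesh->omim"),
        "protein_gene": read_idmap(paths["idmap_protein_gene"], "protein->gene"),
    }
    return KnowledgeBase(associations, interactome, sources, idmaps)
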