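"""Synthetic knowledge-base generator with planted enrichment signals.

Real chemical-protein, interactome, and disease-annotation databases are
proprietary or version-locked, so the pipeline is exercised against
synthetic knowledge bases that reproduce the statistical structure the
analysis assumes:

* a bipartite chemical-protein layer mixing experimental (binding,
  expression) and predicted evidence;
* an Erdős–Rényi-like PPI layer with uniform confidence scores, densified
  by planted pathway cliques so neighborhood expansion has modules to find;
* two annotation catalogs of very different density — a sparse, curated,
  OMIM-like source and a CTD-like source roughly two orders of magnitude
  denser, mixing direct and inferred records — with a one-to-many
  MeSH-to-OMIM disease-id map between their vocabularies;
* a protein-to-gene identifier map with a configurable unmapped fraction.

Under the null configuration annotations are drawn independently of
chemical membership, so any apparent chemical-disease association is a
false positive; this is the substrate for family-wise-error calibration.
A planted link (chemical, disease, enrichment factor f) instead annotates
the chemical's expanded gene set to that disease at f times the background
rate (capped at 1), giving a recoverable signal of known strength.

Default sizes are a roughly tenfold scale-down of the databases the
pipeline is aimed at (a ~23k-protein proteome with a CTD-like catalog of
~250k annotations against an OMIM-like catalog of ~4k), keeping generation
well under a second while preserving the density contrast that drives the
statistics.

All sampling flows through one ``numpy.random.default_rng`` instance
seeded from ``rng_seed``; identical configurations produce byte-identical
files.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .chem_protein import extract_seed_proteins
from .interactome_expand import expand_and_map
from .knowledge_base import (
    AnnotationSource,
    ChemProtAssociation,
    Evidence,
    IdMap,
    InteractomeGraph,
    KnowledgeBase,
    Relation,
    SourceKind,
    write_annotation_table,
    write_chem_protein_table,
    write_idmap,
    write_interactome,
)

__all__ = ["GeneratorConfig", "GroundTruth", "generate_knowledge_base",
           "write_knowledge_base", "make_worked_example_fixture"]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the synthetic knowledge base.

    Sizes and rates default to a ~1/10 scale-down of the target databases:
    2,000 proteins stand in for a ~23k proteome; the OMIM-like source
    annotates ~8% of proteins sparsely (rate 3e-4 over 270 diseases,
    ~1.6e-2 annotations per protein) while the CTD-like source is ~65x
    denser (rate 2e-2 over 260 diseases, ~5 annotations per protein),
    mirroring the 3,748-vs-252,056 annotation contrast between the two
    catalog styles.  Seed sets of 12 proteins and a mean PPI degree of 6
    yield expanded sets of a few percent of the proteome, as in the
    motivating analyses.
    """

    n_proteins: int = 2000
    n_chemicals: int = 3
    n_diseases_omim: int = 270
    n_diseases_ctd: int = 260
    seed_set_size: int = 12
    predicted_fraction: float = 0.25
    ppi_mean_degree: float = 6.0
    confidence_distribution: tuple[float, float] = (0.5, 1.0)
    n_pathways: int = 40
    pathway_size: tuple[int, int] = (4, 12)
    omim_annotation_rate: float = 3e-4
    ctd_annotation_rate: float = 2e-2
    inferred_fraction: float = 0.8
    mesh_multi_map_fraction: float = 0.1
    unmapped_protein_fraction: float = 0.04
    planted_links: tuple[tuple[int, int, float], ...] = ()
    rng_seed: int = 0

    def validate(self) -> None:
        for name in (
            "predicted_fraction",
            "omim_annotation_rate",
            "ctd_annotation_rate",
            "inferred_fraction",
            "mesh_multi_map_fraction",
            "unmapped_protein_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for name in (
            "n_proteins",
            "n_chemicals",
            "n_diseases_omim",
            "n_diseases_ctd",
            "seed_set_size",
            "n_pathways",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.seed_set_size > self.n_proteins:
            raise ValueError(
                f"seed_set_size {self.seed_set_size} exceeds n_proteins "
                f"{self.n_proteins}"
            )
        lo, hi = self.confidence_distribution
        if not 0.0 <= lo <= hi <= 1.0:
            raise ValueError("confidence_distribution bounds must satisfy 0<=lo<=hi<=1")
        lo, hi = self.pathway_size
        if not 2 <= lo <= hi <= self.n_proteins:
            raise ValueError("pathway_size range must satisfy 2 <= lo <= hi <= n_proteins")
        for chem_idx, dis_idx, factor in self.planted_links:
            if not 0 <= chem_idx < self.n_chemicals:
                raise ValueError(f"planted chemical index {chem_idx} out of range")
            if not 0 <= dis_idx < self.n_diseases_ctd:
                raise ValueError(f"planted disease index {dis_idx} out of range")
            if factor < 1.0:
                raise ValueError(f"enrichment_factor must be >= 1, got {factor}")


@dataclass
class GroundTruth:
    """What the generator actually planted, for validation against output."""

    config: GeneratorConfig
    seeds: dict[str, list[str]]  # chemical -> experimental seed proteins
    planted: list[dict]  # chemical/mesh id/translated omim ids/factor/genes
    omim_annotation_count: int
    ctd_annotation_count: int

    def to_json(self) -> str:
        payload = {
            "config": dataclasses.asdict(self.config),
            "seeds": {c: sorted(v) for c, v in sorted(self.seeds.items())},
            "planted": self.planted,
            "omim_annotation_count": self.omim_annotation_count,
            "ctd_annotation_count": self.ctd_annotation_count,
        }
        return json.dumps(payload, indent=2, sort_keys=True)


def _protein_id(i: int) -> str:
    return f"PROT_{i:05d}"


def _gene_id(i: int) -> str:
    return f"GENE_{i:05d}"


def generate_knowledge_base(
    cfg: GeneratorConfig = GeneratorConfig(),
) -> tuple[KnowledgeBase, GroundTruth]:
    """Generate one synthetic knowledge base in memory.

    Returns the loaded-and-validated :class:`KnowledgeBase` plus the
    :class:`GroundTruth` of planted structure.  Use
    :func:`write_knowledge_base` to materialize it as TSV files.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.rng_seed)
    proteins = [_protein_id(i) for i in range(cfg.n_proteins)]
    chemicals = [f"CHEM_{i + 1:02d}" for i in range(cfg.n_chemicals)]

    # --- protein -> gene map (a fraction of proteins has no gene id) -------
    n_unmapped = int(round(cfg.unmapped_protein_fraction * cfg.n_proteins))
    unmapped = set(
        rng.choice(cfg.n_proteins, size=n_unmapped, replace=False).tolist()
    )
    gene_pairs = [
        (_protein_id(i), _gene_id(i)) for i in range(cfg.n_proteins) if i not in unmapped
    ]
    idmap_gene = IdMap(gene_pairs, "protein->gene")
    gene_index = {i for i in range(cfg.n_proteins) if i not in unmapped}

    # --- chemical-protein layer -------------------------------------------
    associations: list[ChemProtAssociation] = []
    seeds: dict[str, list[str]] = {}
    f = cfg.predicted_fraction
    n_predicted = int(round(cfg.seed_set_size * f / (1.0 - f))) if f < 1.0 else 0
    tags = ["assayDB", "exprDB", "structpred"]
    for chem in chemicals:
        picked = rng.choice(
            cfg.n_proteins, size=cfg.seed_set_size + n_predicted, replace=False
        )
        seed_ids = [_protein_id(i) for i in picked[: cfg.seed_set_size]]
        seeds[chem] = seed_ids
        for pid in seed_ids:
            ev = Evidence.BINDING if rng.random() < 0.5 else Evidence.EXPRESSION
            tag = tags[0] if ev is Evidence.BINDING else tags[1]
            associations.append(ChemProtAssociation(chem, pid, ev, tag))
        for i in picked[cfg.seed_set_size :]:
            associations.append(
                ChemProtAssociation(chem, _protein_id(i), Evidence.PREDICTED, tags[2])
            )

    # --- PPI layer: ER background + pathway cliques ------------------------
    lo, hi = cfg.confidence_distribution
    n_edges = int(round(cfg.n_proteins * cfg.ppi_mean_degree / 2.0))
    a = rng.integers(0, cfg.n_proteins, size=n_edges)
    b = rng.integers(0, cfg.n_proteins, size=n_edges)
    keep = a != b
    # dedupe loses a little density; degrees stay exchangeable across proteins
    pairs = sorted({(min(x, y), max(x, y)) for x, y in zip(a[keep], b[keep])})
    edges = [
        (_protein_id(x), _protein_id(y), round(float(rng.uniform(lo, hi)), 4))
        for x, y in pairs
    ]
    pathways: dict[str, list[str]] = {}
    seen_pairs = set(pairs)
    clique_lo = (lo + hi) / 2.0  # planted modules are high-confidence
    for p in range(cfg.n_pathways):
        size = int(rng.integers(cfg.pathway_size[0], cfg.pathway_size[1] + 1))
        members = sorted(rng.choice(cfg.n_proteins, size=size, replace=False).tolist())
        pathways[f"PATH_{p + 1:03d}"] = [_protein_id(i) for i in members]
        for i, x in enumerate(members):
            for y in members[i + 1 :]:
                if (x, y) not in seen_pairs and rng.random() < 0.5:
                    seen_pairs.add((x, y))
                    edges.append(
                        (
                            _protein_id(x),
                            _protein_id(y),
                            round(float(rng.uniform(clique_lo, hi)), 4),
                        )
                    )
    interactome = InteractomeGraph(edges, pathways)

    # --- annotation catalogs ------------------------------------------------
    # annotations live on gene ids: enrichment happens after gene mapping
    genes_arr = np.array(sorted(gene_index))
    n_genes = len(genes_arr)

    omim_diseases = [f"OMIM:D{i:04d}" for i in range(cfg.n_diseases_omim)]
    ctd_diseases = [f"MESH:D{i:04d}" for i in range(cfg.n_diseases_ctd)]

    omim_matrix = rng.random((n_genes, cfg.n_diseases_omim)) < cfg.omim_annotation_rate
    ctd_matrix = rng.random((n_genes, cfg.n_diseases_ctd)) < cfg.ctd_annotation_rate

    # --- MeSH -> OMIM disease map (one-to-many for a configured fraction) ---
    mesh_pairs = []
    n_multi = int(round(cfg.mesh_multi_map_fraction * cfg.n_diseases_ctd))
    multi = set(rng.choice(cfg.n_diseases_ctd, size=n_multi, replace=False).tolist())
    mesh_to_omim: dict[int, list[str]] = {}
    for j in range(cfg.n_diseases_ctd):
        targets = [omim_diseases[j % cfg.n_diseases_omim]]
        if j in multi:
            targets.append(omim_diseases[(j + 7) % cfg.n_diseases_omim])
        mesh_to_omim[j] = targets
        for t in targets:
            mesh_pairs.append((ctd_diseases[j], t))
    idmap_mesh = IdMap(mesh_pairs, "mesh->omim")

    # --- planted chemical-disease signals -----------------------------------
    gene_row = {g: r for r, g in enumerate(genes_arr.tolist())}
    planted_records = []
    for chem_idx, dis_idx, factor in cfg.planted_links:
        chem = chemicals[chem_idx]
        seed_ps = extract_seed_proteins(associations, chem)
        _, mapped, _ = expand_and_map(interactome, seed_ps, idmap_gene)
        rows = [gene_row[int(g.split("_")[1])] for g in mapped.members]
        rate = min(1.0, factor * cfg.ctd_annotation_rate)
        ctd_matrix[rows, dis_idx] = rng.random(len(rows)) < rate
        planted_records.append(
            {
                "chemical_id": chem,
                "mesh_id": ctd_diseases[dis_idx],
                "omim_ids": mesh_to_omim[dis_idx],
                "enrichment_factor": factor,
                "n_target_genes": len(rows),
            }
        )

    omim_rows, omim_cols = np.nonzero(omim_matrix)
    omim_records = [
        (_gene_id(int(genes_arr[r])), omim_diseases[c], Relation.DIRECT)
        for r, c in zip(omim_rows.tolist(), omim_cols.tolist())
    ]
    ctd_rows, ctd_cols = np.nonzero(ctd_matrix)
    inferred_flags = rng.random(len(ctd_rows)) < cfg.inferred_fraction
    ctd_records = [
        (
            _gene_id(int(genes_arr[r])),
            ctd_diseases[c],
            Relation.INFERRED if inf else Relation.DIRECT,
        )
        for r, c, inf in zip(ctd_rows.tolist(), ctd_cols.tolist(), inferred_flags.tolist())
    ]

    kb = KnowledgeBase(
        associations=frozenset(associations),
        interactome=interactome,
        sources={
            SourceKind.OMIM_LIKE: AnnotationSource(SourceKind.OMIM_LIKE, omim_records),
            SourceKind.CTD_LIKE: AnnotationSource(SourceKind.CTD_LIKE, ctd_records),
        },
        idmaps={"mesh_omim": idmap_mesh, "protein_gene": idmap_gene},
    )
    truth = GroundTruth(
        config=cfg,
        seeds=seeds,
        planted=planted_records,
        omim_annotation_count=len(omim_records),
        ctd_annotation_count=len(ctd_records),
    )
    return kb, truth


def write_knowledge_base(
    kb: KnowledgeBase, directory: Path | str, truth: GroundTruth | None = None
) -> None:
    """Write a knowledge base (and optional ground truth) as TSV files.

    Output is deterministic: rows are sorted, so regenerating with the same
    configuration gives byte-identical files.
    """
    d = Path(directory)
    d.mkdir(parents=True, exist_ok=True)
    write_chem_protein_table(kb.associations, d / "chem_protein.tsv")
    write_interactome(kb.interactome, d / "ppi.tsv", d / "pathways.tsv")
    write_annotation_table(kb.sources[SourceKind.OMIM_LIKE], d / "annotations_omim.tsv")
    write_annotation_table(kb.sources[SourceKind.CTD_LIKE], d / "annotations_ctd.tsv")
    write_idmap(kb.idmaps["mesh_omim"], d / "idmap_mesh_omim.tsv")
    write_idmap(kb.idmaps["protein_gene"], d / "idmap_protein_gene.tsv")
    if truth is not None:
        (d / "ground_truth.json").write_text(truth.to_json() + "\n", encoding="utf-8")


# ---------------------------------------------------------------------------
# deterministic worked-example fixture
# ---------------------------------------------------------------------------

WORKED_EXAMPLE = {
    "chemical": "DDT_PP",
    "asthma_omim": "OMIM:600807",
    "asthma_mesh": "MESH:D001249",
    "omim": {"N": 2387, "K": 13, "n": 29, "k": 1},
    "ctd": {"N": 10509, "K": 1977, "n": 131, "k": 48, "m": 2580},
}


def make_worked_example_fixture() -> KnowledgeBase:
    """Deterministic knowledge base reproducing the printed asthma example.

    Engineered so that one chemical's pipeline run yields a mapped set of
    175 genes of which exactly 29 fall in an OMIM-like universe of 2,387
    proteins (asthma annotated to 13, one of them — a TNF-like gene — in
    the set) and exactly 131 fall in a CTD-like universe of 10,509 proteins
    (asthma annotated to 1,977, 48 of them in the set), with 2,580 unique
    CTD diseases driving the Bonferroni family.  The seed set has 38
    proteins, expands to 182 (130 first-order partners + 14 pathway
    co-members) and maps to 175 genes (7 partners lack a gene id),
    mirroring the bookkeeping of the motivating analysis.
    """
    chem = WORKED_EXAMPLE["chemical"]

    seeds = [f"S_{i:03d}" for i in range(1, 39)]  # 38 seed proteins
    partners = [f"F_{i:03d}" for i in range(1, 131)]  # 130 first-order partners
    comembers = [f"C_{i:03d}" for i in range(1, 15)]  # 14 pathway co-members

    associations = [
        ChemProtAssociation(
            chem, s, Evidence.BINDING if i % 2 == 0 else Evidence.EXPRESSION, "assayDB"
        )
        for i, s in enumerate(seeds)
    ]
    # predicted rows exercise the evidence filter without touching the seed
    associations += [
        ChemProtAssociation(chem, f"X_{i:03d}", Evidence.PREDICTED, "structpred")
        for i in range(1, 5)
    ]

    edges = [
        (seeds[i % len(seeds)], partner, 0.9) for i, partner in enumerate(partners)
    ]
    edges += [(seeds[0], seeds[1], 0.95), (partners[0], partners[1], 0.8)]
    pathways = {"PATH_001": [seeds[0], *comembers]}
    interactome = InteractomeGraph(edges, pathways)

    # 182 expanded proteins; the last 7 partners have no gene id -> 175 mapped
    expanded = seeds + partners + comembers
    mapped_proteins = seeds + partners[:-7] + comembers
    gene_of = {p: _gene_id(i + 1) for i, p in enumerate(mapped_proteins)}
    idmap_gene = IdMap(list(gene_of.items()), "protein->gene")
    assert len(expanded) == 182 and len(gene_of) == 175

    mapped_genes = [gene_of[p] for p in mapped_proteins]  # GENE_00001..GENE_00175

    # OMIM-like catalog: universe 2,387 = 29 mapped genes + 2,358 fillers
    omim = WORKED_EXAMPLE["omim"]
    in_omim = mapped_genes[: omim["n"]]  # 29 genes; the first is TNF-like
    omim_fillers = [f"OGENE_{i:05d}" for i in range(1, omim["N"] - omim["n"] + 1)]
    omim_universe = in_omim + omim_fillers
    asthma_omim = WORKED_EXAMPLE["asthma_omim"]
    omim_records = [(in_omim[0], asthma_omim, Relation.DIRECT)]
    omim_records += [
        (g, asthma_omim, Relation.DIRECT) for g in omim_fillers[: omim["K"] - 1]
    ]
    # every universe gene carries >= 1 annotation, spread round-robin over
    # 60 filler diseases so no filler concentrates the chemical's genes
    for i, g in enumerate(omim_universe):
        omim_records.append((g, f"OMIM:F{i % 60:04d}", Relation.DIRECT))

    # CTD-like catalog: universe 10,509 = 131 mapped genes + 10,378 fillers
    ctd = WORKED_EXAMPLE["ctd"]
    in_ctd = mapped_genes[: ctd["n"]]  # 131 genes, superset of the 29
    ctd_fillers = [f"CGENE_{i:05d}" for i in range(1, ctd["N"] - ctd["n"] + 1)]
    ctd_universe = in_ctd + ctd_fillers
    asthma_mesh = WORKED_EXAMPLE["asthma_mesh"]
    ctd_records = [(g, asthma_mesh, Relation.DIRECT) for g in in_ctd[: ctd["k"]]]
    ctd_records += [
        (g, asthma_mesh, Relation.INFERRED)
        for g in ctd_fillers[: ctd["K"] - ctd["k"]]
    ]
    # 2,579 filler diseases + asthma = 2,580 unique CTD diseases
    n_filler_diseases = ctd["m"] - 1
    for i, g in enumerate(ctd_universe):
        ctd_records.append((g, f"MESH:F{i % n_filler_diseases:04d}", Relation.INFERRED))

    # MeSH -> OMIM disease map: asthma ids correspond; fillers map 1:1
    mesh_pairs = [(asthma_mesh, asthma_omim)]
    mesh_pairs += [(f"MESH:F{i:04d}", f"OMIM:M{i:04d}") for i in range(n_filler_diseases)]

    return KnowledgeBase(
        associations=frozenset(associations),
        interactome=interactome,
        sources={
            SourceKind.OMIM_LIKE: AnnotationSource(SourceKind.OMIM_LIKE, omim_records),
            SourceKind.CTD_LIKE: AnnotationSource(SourceKind.CTD_LIKE, ctd_records),
        },
        idmaps={
            "mesh_omim": IdMap(mesh_pairs, "mesh->omim"),
            "protein_gene": idmap_gene,
        },
    )
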