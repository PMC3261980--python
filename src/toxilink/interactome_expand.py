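"""Step 2: expand seed sets through the interactome, then map to gene ids.

A chemical's seed proteins are extended with (a) their first-order
interaction partners whose edge confidence clears a threshold and (b)
proteins sharing an annotated pathway with a seed protein.  Pathway
co-membership is computed with respect to seed proteins only — never
transitively through first-order additions — so expansion is a single
round, not a closure.  Finally the expanded set is translated to
Entrez-style gene identifiers; proteins without a gene id are dropped
(with the dropout count logged), mirroring the retention rule used when
cross-referencing protein catalogs against gene-keyed disease annotations.
"""

from __future__ import annotations

import logging

from .knowledge_base import (
    IdMap,
    InteractomeGraph,
    Provenance,
    ProteinSet,
    Stage,
)

logger = logging.getLogger("toxilink")


def expand_first_order(
    graph: InteractomeGraph, seed: ProteinSet, min_confidence: float = 0.0
) -> ProteinSet:
    """Add first-order interaction partners of the seed proteins.

    Seed members absent from the graph (singletons) are retained.  The
    result is extensive (superset of the input) and monotone in
    ``min_confidence``: lowering the threshold never shrinks it.
    """
    if not 0.0 <= min_confidence <= 1.0:
        raise ValueError(f"min_confidence {min_confidence} outside [0, 1]")
    if seed.stage is not Stage.SEED:
        raise ValueError(f"expected a seed-stage protein set, got {seed.stage.value}")
    provenance = dict(seed.provenance)
    for s in seed.members:
        for v in graph.neighbors_above(s, min_confidence):
            provenance.setdefault(v, Provenance.FIRST_ORDER_NEIGHBOR)
    return ProteinSet(seed.chemical_id, Stage.EXPANDED, provenance)


def expand_pathways(graph: InteractomeGraph, ps: ProteinSet) -> ProteinSet:
    """Add proteins sharing an annotated pathway with a seed protein.

    Co-membership is evaluated against members whose provenance is
    ``chemprot_seed``; proteins brought in by first-order expansion do not
    recruit their own pathway partners.  Existing provenance is never
    overwritten.
    """
    if ps.stage not in (Stage.SEED, Stage.EXPANDED):
        raise ValueError(f"cannot pathway-expand a {ps.stage.value}-stage set")
    seed_members = {
        p for p, prov in ps.provenance.items() if prov is Provenance.CHEMPROT_SEED
    }
    provenance = dict(ps.provenance)
    for members in graph.pathways.values():
        if members & seed_members:
            for v in members:
                provenance.setdefault(v, Provenance.PATHWAY_COMEMBER)
    return ProteinSet(ps.chemical_id, Stage.EXPANDED, provenance)


def map_to_gene_ids(ps: ProteinSet, idmap: IdMap) -> ProteinSet:
    """Translate an expanded protein set to gene identifiers.

    Unmapped proteins are dropped and counted; several proteins mapping to
    the same gene id collapse to one member.  A mapped member inherits the
    highest-priority provenance among the proteins that produced it.
    """
    if ps.stage is not Stage.EXPANDED:
        raise ValueError(f"expected an expanded-stage protein set, got {ps.stage.value}")
    if len(idmap) == 0 and len(ps) > 0:
        logger.warning(
            "empty identifier map: all %d proteins of %r dropped",
            len(ps),
            ps.chemical_id,
        )
    from .knowledge_base import PROVENANCE_PRIORITY

    provenance: dict[str, Provenance] = {}
    dropped = 0
    for prot, prov in ps.provenance.items():
        targets = idmap.targets(prot)
        if not targets:
            dropped += 1
            continue
        for gene in targets:
            if (
                gene not in provenance
                or PROVENANCE_PRIORITY[prov] < PROVENANCE_PRIORITY[provenance[gene]]
            ):
                provenance[gene] = prov
    if dropped:
        logger.info(
            "%s: dropped %d unmapped protein(s) (%d -> %d)",
            ps.chemical_id,
            dropped,
            len(ps),
            len(provenance),
        )
    return ProteinSet(ps.chemical_id, Stage.MAPPED, provenance)


def expand_and_map(
    graph: InteractomeGraph,
    seed: ProteinSet,
    idmap: IdMap,
    min_confidence: float = 0.0,
    use_pathways: bool = True,
) -> tuple[ProteinSet, ProteinSet, int]:
    """Run the full step-2 chain: first-order + pathways, then gene mapping.

    Returns ``(expanded, mapped, induced_ppi_edges)`` where the last item is
    the number of interactome edges with both endpoints inside the expanded
    set — the parenthesized PPI count reported next to expanded-set sizes.
    """
    expanded = expand_first_order(graph, seed, min_confidence)
    if use_pathways:
        expanded = expand_pathways(graph, expanded)
    mapped = map_to_gene_ids(expanded, idmap)
    return expanded, mapped, graph.induced_edge_count(expanded.members)
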