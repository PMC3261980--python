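"""Presentation artifacts: chemical-disease network, Venn overlaps, summaries.

The chemical-disease network is a bipartite graph whose edges connect a
chemical to a disease whenever the enrichment test passes the chosen alpha
in at least one source; the edge weight is the number of distinct proteins
linking the pair across contributing sources, so heavier edges mean more
molecular support.  Disease categories (reproductive, neurodevelopmental,
cancer, ...) come from a user-supplied map, never from built-in clinical
judgment.
"""

from __future__ import annotations

import csv
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field
from itertools import combinations
from pathlib import Path

import networkx as nx
import pandas as pd

from .disease_enrich import EnrichmentResult
from .knowledge_base import SourceKind

__all__ = [
    "ChemicalDiseaseNetwork",
    "build_disease_network",
    "venn_counts",
    "stage_summary_tables",
    "write_graphml",
    "write_sif",
    "write_venn_table",
    "read_category_map",
    "plot_disease_network",
    "plot_venn",
]

CATEGORIES = ("reproductive", "neurodevelopmental", "cancer", "other", "unassigned")


@dataclass
class ChemicalDiseaseNetwork:
    """Bipartite chemical-disease graph with protein-count edge weights."""

    # node id -> (node_type, category)
    nodes: dict[str, tuple[str, str]] = field(default_factory=dict)
    # (chemical, disease) -> (weight, source kinds)
    edges: dict[tuple[str, str], tuple[int, frozenset[SourceKind]]] = field(
        default_factory=dict
    )

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        for node, (node_type, category) in sorted(self.nodes.items()):
            g.add_node(node, node_type=node_type, category=category)
        for (chem, dis), (weight, kinds) in sorted(self.edges.items()):
            g.add_edge(
                chem,
                dis,
                weight=weight,
                sources=",".join(sorted(k.value for k in kinds)),
            )
        return g


def build_disease_network(
    results: Iterable[EnrichmentResult],
    alpha: float = 0.05,
    category_map: Mapping[str, str] | None = None,
) -> ChemicalDiseaseNetwork:
    """Build the chemical-disease network from enrichment results.

    One edge per (chemical, disease) pair with ``p_adj <= alpha`` in at
    least one source; ``alpha=1`` keeps every tested link.  The weight is
    the size of the union of linking proteins over contributing sources.
    """
    if not 0.0 < alpha <= 1.0:
        raise ValueError(f"alpha {alpha} outside (0, 1]")
    category_map = category_map or {}
    linking: dict[tuple[str, str], set[str]] = {}
    kinds: dict[tuple[str, str], set[SourceKind]] = {}
    for r in results:
        if r.p_adj > alpha:
            continue
        key = (r.chemical_id, r.disease_id)
        linking.setdefault(key, set()).update(r.linking_proteins)
        kinds.setdefault(key, set()).add(r.source_kind)
    net = ChemicalDiseaseNetwork()
    for (chem, dis), proteins in linking.items():
        net.nodes[chem] = ("chemical", "unassigned")
        category = category_map.get(dis, "unassigned")
        if category not in CATEGORIES:
            raise ValueError(f"unknown disease category {category!r} for {dis!r}")
        net.nodes[dis] = ("disease", category)
        net.edges[(chem, dis)] = (len(proteins), frozenset(kinds[(chem, dis)]))
    return net


def _passing_disease_sets(
    results_by_chemical: Mapping[str, Iterable[EnrichmentResult]],
    source_kind: SourceKind,
    alpha: float,
) -> dict[str, set[str]]:
    return {
        chem: {
            r.disease_id
            for r in results
            if r.source_kind is source_kind and r.p_adj <= alpha
        }
        for chem, results in results_by_chemical.items()
    }


def venn_counts(
    results_by_chemical: Mapping[str, Iterable[EnrichmentResult]],
    source_kind: SourceKind,
    alpha: float = 0.05,
) -> dict[frozenset[str], int]:
    """Venn-region counts of per-chemical disease sets for one source.

    Supports 2 or 3 chemicals.  Keys are the chemical combinations defining
    each region (e.g. ``frozenset({'C1'})`` = diseases exclusive to C1,
    ``frozenset({'C1','C2'})`` = shared by exactly those two); counts over
    all regions sum to the size of the union.
    """
    sets = _passing_disease_sets(results_by_chemical, source_kind, alpha)
    chems = sorted(sets)
    if len(chems) not in (2, 3):
        raise ValueError(f"Venn partition supports 2 or 3 chemicals, got {len(chems)}")
    counts: dict[frozenset[str], int] = {}
    for size in range(1, len(chems) + 1):
        for combo in combinations(chems, size):
            inside = set.intersection(*(sets[c] for c in combo))
            outside = set.union(
                *(sets[c] for c in chems if c not in combo), set()
            ) if len(combo) < len(chems) else set()
            counts[frozenset(combo)] = len(inside - outside)
    return counts


def write_venn_table(
    counts: Mapping[frozenset[str], int], path: Path | str
) -> None:
    rows = sorted(
        (("&".join(sorted(region)), count) for region, count in counts.items()),
        key=lambda rc: (rc[0].count("&"), rc[0]),
    )
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["region", "count"])
        w.writerows(rows)


def stage_summary_tables(
    chemical_runs: Sequence["ChemicalRun"],
    alpha: float = 0.05,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-chemical protein-stage and disease-count summary tables.

    The first table gives, per chemical, the seed-set size, the expanded-set
    size with the number of PPI edges induced inside the expanded set, and
    the gene-mapped size.  The second gives per-source disease counts: all
    candidate diseases (k >= 1) and those passing alpha.
    """
    t1_rows, t2_rows = [], []
    for run in chemical_runs:
        t1_rows.append(
            {
                "chemical_id": run.chemical_id,
                "n_seed": len(run.seed),
                "n_expanded": len(run.expanded),
                "induced_ppi_edges": run.induced_ppi_edges,
                "n_mapped": len(run.mapped),
            }
        )
        row = {"chemical_id": run.chemical_id}
        for kind in (SourceKind.OMIM_LIKE, SourceKind.CTD_LIKE):
            results = run.enrichment.get(kind, [])
            row[f"n_diseases_{kind.value}"] = len(results)
            row[f"n_significant_{kind.value}"] = sum(
                1 for r in results if r.p_adj <= alpha
            )
        t2_rows.append(row)
    t1 = pd.DataFrame(
        t1_rows,
        columns=[
            "chemical_id",
            "n_seed",
            "n_expanded",
            "induced_ppi_edges",
            "n_mapped",
        ],
    )
    t2 = pd.DataFrame(
        t2_rows,
        columns=[
            "chemical_id",
            "n_diseases_omim_like",
            "n_significant_omim_like",
            "n_diseases_ctd_like",
            "n_significant_ctd_like",
        ],
    )
    return t1, t2


def write_graphml(net: ChemicalDiseaseNetwork, path: Path | str) -> None:
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    nx.write_graphml(net.to_networkx(), str(path))


def write_sif(net: ChemicalDiseaseNetwork, path: Path | str) -> None:
    """Simple-interaction-format export: chemical <TAB> linked_to <TAB> disease."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8") as fh:
        for chem, dis in sorted(net.edges):
            fh.write(f"{chem}\tlinked_to\t{dis}\n")


def read_category_map(path: Path | str) -> dict[str, str]:
    """Read a disease->category TSV (columns disease_id, category)."""
    from .knowledge_base import _read_rows

    rows = _read_rows(path, ["disease_id", "category"])
    out = {}
    for disease_id, category in rows:
        if category not in CATEGORIES:
            raise ValueError(f"{path}: unknown category {category!r}")
        out[disease_id] = category
    return out


# ---------------------------------------------------------------------------
# optional figures
# ---------------------------------------------------------------------------

_CATEGORY_COLORS = {
    "reproductive": "#d62728",
    "neurodevelopmental": "#1f77b4",
    "cancer": "#9467bd",
    "other": "#2ca02c",
    "unassigned": "#7f7f7f",
}


def plot_disease_network(net: ChemicalDiseaseNetwork, path: Path | str) -> None:
    """Draw the bipartite network; edge width scales with linking-protein count."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    g = net.to_networkx()
    fig, ax = plt.subplots(figsize=(9, 7))
    if g.number_of_nodes():
        pos = nx.spring_layout(g, seed=7)
        colors = []
        shapes = {"chemical": "s", "disease": "o"}
        for node_type in ("chemical", "disease"):
            nodes = [v for v in g if g.nodes[v]["node_type"] == node_type]
            colors = [
                "#ff7f0e"
                if node_type == "chemical"
                else _CATEGORY_COLORS[g.nodes[v]["category"]]
                for v in nodes
            ]
            nx.draw_networkx_nodes(
                g, pos, nodelist=nodes, node_color=colors,
                node_shape=shapes[node_type], node_size=240, ax=ax,
            )
        widths = [0.5 + g[u][v]["weight"] * 0.4 for u, v in g.edges]
        nx.draw_networkx_edges(g, pos, width=widths, alpha=0.6, ax=ax)
        nx.draw_networkx_labels(g, pos, font_size=6, ax=ax)
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def plot_venn(counts: Mapping[frozenset[str], int], path: Path | str) -> None:
    """Two- or three-circle Venn diagram with region counts as labels."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    from matplotlib.patches import Circle

    chems = sorted({c for region in counts for c in region})
    fig, ax = plt.subplots(figsize=(6, 6))
    if len(chems) == 2:
        centers = {chems[0]: (-0.5, 0.0), chems[1]: (0.5, 0.0)}
        label_pos = {
            frozenset([chems[0]]): (-0.9, 0.0),
            frozenset([chems[1]]): (0.9, 0.0),
            frozenset(chems): (0.0, 0.0),
        }
    else:
        centers = {
            chems[0]: (-0.5, -0.3),
            chems[1]: (0.5, -0.3),
            chems[2]: (0.0, 0.55),
        }
        label_pos = {
            frozenset([chems[0]]): (-0.9, -0.5),
            frozenset([chems[1]]): (0.9, -0.5),
            frozenset([chems[2]]): (0.0, 1.0),
            frozenset([chems[0], chems[1]]): (0.0, -0.5),
            frozenset([chems[0], chems[2]]): (-0.55, 0.35),
            frozenset([chems[1], chems[2]]): (0.55, 0.35),
            frozenset(chems): (0.0, 0.0),
        }
    for chem, (x, y), color in zip(
        centers, centers.values(), ("#1f77b4", "#d62728", "#2ca02c")
    ):
        ax.add_patch(Circle((x, y), 1.0, alpha=0.3, color=color))
        ax.annotate(chem, (x, y + 1.05), ha="center", fontsize=10)
    for region, count in counts.items():
        x, y = label_pos[region]
        ax.annotate(str(count), (x, y), ha="center", fontsize=12)
    ax.set_xlim(-2.2, 2.2)
    ax.set_ylim(-2.0, 2.4)
    ax.set_aspect("equal")
    ax.set_axis_off()
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
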