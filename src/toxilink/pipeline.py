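"""One-command orchestration: extract -> expand -> enrich -> report.

``run_chemical`` executes the three analysis steps for one chemical against
an in-memory knowledge base; ``run_pipeline`` drives the whole bundle from
a knowledge-base directory to a report directory, writing per-stage protein
sets, the enrichment table, network exports, Venn and summary tables, and a
machine-readable manifest (input checksums, parameters, per-stage counts).
Reruns with identical inputs and configuration are byte-identical.
"""

from __future__ import annotations

import csv
import hashlib
import json
import logging
import shutil
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .chem_protein import extract_seed_proteins, seed_summary
from .disease_enrich import EnrichmentResult, enrich_diseases, translate_disease_ids
from .interactome_expand import expand_and_map
from .knowledge_base import (
    DEFAULT_FILENAMES,
    KnowledgeBase,
    ProteinSet,
    SourceKind,
    load_knowledge_base,
    write_protein_set,
)
from .reporting import (
    build_disease_network,
    plot_disease_network,
    plot_venn,
    read_category_map,
    stage_summary_tables,
    venn_counts,
    write_graphml,
    write_sif,
    write_venn_table,
)

logger = logging.getLogger("toxilink")

__all__ = ["RunConfig", "ChemicalRun", "run_chemical", "run_pipeline", "PipelineError"]


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name and cause."""


@dataclass
class RunConfig:
    """Run configuration; mirrors the CLI flags one-to-one."""

    kb_dir: str
    out_dir: str
    chemicals: list[str] = field(default_factory=list)
    min_confidence: float = 0.0
    use_pathways: bool = True
    alpha: float = 0.05
    bonferroni_m: int | None = None
    direct_only: bool = False
    categories_path: str | None = None
    plots: bool = False

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)


@dataclass
class ChemicalRun:
    """All per-chemical artifacts of one pipeline execution."""

    chemical_id: str
    seed: ProteinSet
    expanded: ProteinSet
    mapped: ProteinSet
    induced_ppi_edges: int
    enrichment: dict[SourceKind, list[EnrichmentResult]]


def run_chemical(
    kb: KnowledgeBase,
    chemical_id: str,
    min_confidence: float = 0.0,
    use_pathways: bool = True,
    bonferroni_m: int | None = None,
    direct_only: bool = False,
    translated_ctd=None,
) -> ChemicalRun:
    """Run the three analysis steps for one chemical, in memory.

    ``translated_ctd`` lets callers pre-translate the CTD-like source's
    disease ids once and reuse it across chemicals.
    """
    seed = extract_seed_proteins(kb.associations, chemical_id)
    expanded, mapped, induced = expand_and_map(
        kb.interactome,
        seed,
        kb.idmaps["protein_gene"],
        min_confidence=min_confidence,
        use_pathways=use_pathways,
    )
    if translated_ctd is None:
        translated_ctd = translate_disease_ids(
            kb.sources[SourceKind.CTD_LIKE], kb.idmaps["mesh_omim"]
        )
    enrichment = {
        SourceKind.OMIM_LIKE: enrich_diseases(
            mapped, kb.sources[SourceKind.OMIM_LIKE], direct_only=direct_only
        ),
        SourceKind.CTD_LIKE: enrich_diseases(
            mapped, translated_ctd, bonferroni_m=bonferroni_m, direct_only=direct_only
        ),
    }
    return ChemicalRun(chemical_id, seed, expanded, mapped, induced, enrichment)


ENRICHMENT_HEADER = [
    "chemical_id",
    "disease_id",
    "source_kind",
    "N",
    "K",
    "n",
    "k",
    "p_raw",
    "p_adj",
    "linking_proteins",
]


def _write_enrichment_table(runs: list[ChemicalRun], path: Path) -> None:
    with path.open("w", newline="", encoding="utf-8") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(ENRICHMENT_HEADER)
        for run in runs:
            for kind in (SourceKind.OMIM_LIKE, SourceKind.CTD_LIKE):
                for r in run.enrichment[kind]:
                    w.writerow(
                        [
                            r.chemical_id,
                            r.disease_id,
                            r.source_kind.value,
                            r.N,
                            r.K,
                            r.n,
                            r.k,
                            repr(r.p_raw),
                            repr(r.p_adj),
                            ",".join(sorted(r.linking_proteins)),
                        ]
                    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: RunConfig) -> list[ChemicalRun]:
    """Execute the full pipeline and write the report bundle.

    Any stage failure aborts with :class:`PipelineError`; partial outputs
    are removed so a bundle directory is either complete or absent.
    """
    out_dir = Path(config.out_dir)
    created = not out_dir.exists()
    try:
        return _run_pipeline_inner(config, out_dir)
    except Exception:
        if created and out_dir.exists():
            shutil.rmtree(out_dir)
        raise


def _run_pipeline_inner(config: RunConfig, out_dir: Path) -> list[ChemicalRun]:
    if not config.chemicals:
        raise PipelineError("config: at least one chemical is required")
    if not 0.0 < config.alpha <= 1.0:
        raise PipelineError(f"config: alpha {config.alpha} outside (0, 1]")
    kb_dir = Path(config.kb_dir)
    try:
        kb = load_knowledge_base(kb_dir)
    except Exception as exc:
        raise PipelineError(f"load: {exc}") from exc
    category_map = (
        read_category_map(config.categories_path) if config.categories_path else {}
    )

    try:
        translated_ctd = translate_disease_ids(
            kb.sources[SourceKind.CTD_LIKE], kb.idmaps["mesh_omim"]
        )
        runs = [
            run_chemical(
                kb,
                chem,
                min_confidence=config.min_confidence,
                use_pathways=config.use_pathways,
                bonferroni_m=config.bonferroni_m,
                direct_only=config.direct_only,
                translated_ctd=translated_ctd,
            )
            for chem in config.chemicals
        ]
    except Exception as exc:
        raise PipelineError(f"analysis: {exc}") from exc

    out_dir.mkdir(parents=True, exist_ok=True)
    ps_dir = out_dir / "protein_sets"
    for run in runs:
        for ps in (run.seed, run.expanded, run.mapped):
            write_protein_set(ps, ps_dir / f"{run.chemical_id}_{ps.stage.value}.tsv")
        logger.info(
            "%s: %d seed -> %d expanded (%d PPIs) -> %d mapped",
            run.chemical_id,
            len(run.seed),
            len(run.expanded),
            run.induced_ppi_edges,
            len(run.mapped),
        )

    _write_enrichment_table(runs, out_dir / "enrichment.tsv")

    all_results = [r for run in runs for rs in run.enrichment.values() for r in rs]
    network = build_disease_network(all_results, config.alpha, category_map)
    write_graphml(network, out_dir / "network.graphml")
    write_sif(network, out_dir / "network.sif")

    results_by_chem = {
        run.chemical_id: [r for rs in run.enrichment.values() for r in rs]
        for run in runs
    }
    venns = {}
    if len(runs) in (2, 3):
        for kind in (SourceKind.OMIM_LIKE, SourceKind.CTD_LIKE):
            counts = venn_counts(results_by_chem, kind, config.alpha)
            venns[kind] = counts
            write_venn_table(counts, out_dir / f"venn_{kind.value}.tsv")

    t1, t2 = stage_summary_tables(runs, config.alpha)
    t1.to_csv(out_dir / "summary_table1.tsv", sep="\t", index=False)
    t2.to_csv(out_dir / "summary_table2.tsv", sep="\t", index=False)
    seed_summary([run.seed for run in runs]).to_csv(
        out_dir / "seed_summary.tsv", sep="\t", index=False
    )

    if config.plots:
        plot_disease_network(network, out_dir / "network.png")
        for kind, counts in venns.items():
            if counts:
                plot_venn(counts, out_dir / f"venn_{kind.value}.png")

    manifest = {
        "inputs": {
            name: _sha256(kb_dir / name)
            for name in sorted(DEFAULT_FILENAMES.values())
            if (kb_dir / name).exists()
        },
        "parameters": {
            "chemicals": list(config.chemicals),
            "min_confidence": config.min_confidence,
            "use_pathways": config.use_pathways,
            "alpha": config.alpha,
            "bonferroni_m": config.bonferroni_m,
            "direct_only": config.direct_only,
        },
        "counts": {
            run.chemical_id: {
                "seed": len(run.seed),
                "expanded": len(run.expanded),
                "induced_ppi_edges": run.induced_ppi_edges,
                "mapped": len(run.mapped),
                "diseases_omim_like": len(run.enrichment[SourceKind.OMIM_LIKE]),
                "diseases_ctd_like": len(run.enrichment[SourceKind.CTD_LIKE]),
            }
            for run in runs
        },
    }
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
    )
    return runs
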