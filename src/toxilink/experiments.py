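"""Monte-Carlo calibration harnesses for the enrichment pipeline.

Two experiments characterize the statistical behaviour of the full
pipeline on synthetic knowledge bases:

* the null family-wise error rate — how often a run with no planted
  chemical-disease signal reports *any* significant CTD-like disease —
  which should stay near the nominal Bonferroni level; and
* planted-signal recovery — how often a single planted link of given
  strength is ranked first (smallest adjusted p-value) for its chemical.

Both run the genuine pipeline stages (seed extraction, expansion, gene
mapping, disease-id translation, enrichment) in memory, one replicate per
seed, so they measure the procedure end to end rather than the test
statistic in isolation.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass

from .knowledge_base import SourceKind
from .pipeline import run_chemical
from .synthetic_data import GeneratorConfig, generate_knowledge_base


@dataclass
class FwerResult:
    n_replicates: int
    n_false_positive_runs: int

    @property
    def rate(self) -> float:
        return self.n_false_positive_runs / self.n_replicates


def _run_all_chemicals(kb):
    from .disease_enrich import translate_disease_ids

    translated = translate_disease_ids(
        kb.sources[SourceKind.CTD_LIKE], kb.idmaps["mesh_omim"]
    )
    return [
        run_chemical(kb, chem, translated_ctd=translated)
        for chem in sorted(kb.chemicals)
    ]


def null_fwer(
    n_replicates: int = 500,
    alpha: float = 0.05,
    base_config: GeneratorConfig = GeneratorConfig(),
    first_seed: int = 1,
) -> FwerResult:
    """Fraction of null replicate pipelines with any significant CTD disease.

    Each replicate generates a fresh knowledge base with no planted links
    (seeds ``first_seed .. first_seed + n_replicates - 1``), runs the full
    pipeline for every chemical, and counts the run as a false positive if
    any CTD-like disease reaches ``p_adj < alpha`` for any chemical.
    """
    hits = 0
    for seed in range(first_seed, first_seed + n_replicates):
        cfg = dataclasses.replace(base_config, planted_links=(), rng_seed=seed)
        kb, _ = generate_knowledge_base(cfg)
        runs = _run_all_chemicals(kb)
        if any(
            r.p_adj < alpha
            for run in runs
            for r in run.enrichment[SourceKind.CTD_LIKE]
        ):
            hits += 1
    return FwerResult(n_replicates, hits)


@dataclass
class RecoveryResult:
    n_replicates: int
    n_recovered: int

    @property
    def rate(self) -> float:
        return self.n_recovered / self.n_replicates


def planted_recovery(
    n_replicates: int = 100,
    enrichment_factor: float = 8.0,
    base_config: GeneratorConfig = GeneratorConfig(),
    first_seed: int = 1,
) -> RecoveryResult:
    """How often a single planted link is the top-ranked CTD disease.

    One link (chemical 0, disease 0, the given enrichment factor) is
    planted per replicate; recovery means a translated id of the planted
    disease attains the minimum adjusted p-value among the chemical's
    CTD-like results.
    """
    recovered = 0
    for seed in range(first_seed, first_seed + n_replicates):
        cfg = dataclasses.replace(
            base_config,
            planted_links=((0, 0, enrichment_factor),),
            rng_seed=seed,
        )
        kb, truth = generate_knowledge_base(cfg)
        planted = truth.planted[0]
        run = _run_all_chemicals(kb)[0]
        assert run.chemical_id == planted["chemical_id"]
        results = run.enrichment[SourceKind.CTD_LIKE]
        if not results:
            continue
        best = min(r.p_adj for r in results)
        top = {r.disease_id for r in results if r.p_adj == best}
        if top & set(planted["omim_ids"]):
            recovered += 1
    return RecoveryResult(n_replicates, recovered)
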