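"""Step 1: derive each chemical's seed protein set from association tables.

Only experimentally supported chemical-protein links (binding or gene
expression evidence) seed the downstream network analysis; purely predicted
connections are discarded by default.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable

import pandas as pd

from .knowledge_base import (
    ChemProtAssociation,
    Evidence,
    Provenance,
    ProteinSet,
    Stage,
)

logger = logging.getLogger("toxilink")

#: evidence classes counted as experimental support
EXPERIMENTAL_EVIDENCE = frozenset({Evidence.BINDING, Evidence.EXPRESSION})


def extract_seed_proteins(
    associations: Iterable[ChemProtAssociation],
    chemical_id: str,
    allowed_evidence: Iterable[Evidence] = EXPERIMENTAL_EVIDENCE,
) -> ProteinSet:
    """Seed protein set of one chemical, filtered by evidence class.

    Parameters
    ----------
    associations
        The chemical-protein association records.
    chemical_id
        Chemical to extract; a chemical absent from the table yields an
        empty seed set with a warning (absence of data is a legitimate
        state, not an error).
    allowed_evidence
        Evidence classes to keep; defaults to binding and expression,
        excluding predicted links.
    """
    allowed = frozenset(Evidence(e) for e in allowed_evidence)
    if not allowed:
        raise ValueError("allowed_evidence must be non-empty")
    members = {
        a.protein_id
        for a in associations
        if a.chemical_id == chemical_id and a.evidence in allowed
    }
    if not members:
        logger.warning(
            "no supported chemical-protein associations found for %r", chemical_id
        )
    return ProteinSet(
        chemical_id=chemical_id,
        stage=Stage.SEED,
        provenance={p: Provenance.CHEMPROT_SEED for p in members},
    )


def seed_summary(seeds: Iterable[ProteinSet]) -> pd.DataFrame:
    """One row per chemical with its seed-set size."""
    rows = [
        {"chemical_id": ps.chemical_id, "n_seed": len(ps)}
        for ps in seeds
    ]
    return pd.DataFrame(rows, columns=["chemical_id", "n_seed"])
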