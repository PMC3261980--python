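"""Step 3: hypergeometric disease enrichment against annotation catalogs.

For one chemical and one annotation source, every disease sharing at least
one protein with the chemical's mapped gene set is scored with the one-sided
(upper-tail, inclusive) hypergeometric test:

    N = size of the source's protein universe (proteins with >= 1 annotation)
    K = universe proteins annotated to the disease
    n = chemical's mapped proteins found in the universe
    k = of those, the number annotated to the disease

    p = P(X >= k),  X ~ Hypergeometric(N, K, n)

Dense CTD-like catalogs list thousands of candidate diseases, so their raw
p-values are Bonferroni-adjusted with the number of unique diseases in the
(translated) catalog as the family size; sparse curated OMIM-like catalogs
are reported unadjusted.  Diseases linked through a single protein are kept
in the output with their (typically large) p-values rather than filtered —
significance is a property of the report, not of the candidate list.

The tail probability is computed in log-space from exact log-binomial terms
(log-gamma differences combined with log-sum-exp), which stays accurate for
universes of tens of thousands of proteins and tail masses near underflow.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln, logsumexp

from .knowledge_base import (
    AnnotationSource,
    IdMap,
    ProteinSet,
    Relation,
    SourceKind,
    Stage,
)

logger = logging.getLogger("toxilink")

__all__ = [
    "EnrichmentResult",
    "hypergeom_upper_tail",
    "bonferroni_adjust",
    "translate_disease_ids",
    "enrich_diseases",
]


@dataclass(frozen=True)
class EnrichmentResult:
    """One (chemical, disease, source) enrichment test and its parameters."""

    chemical_id: str
    disease_id: str
    source_kind: SourceKind
    N: int
    K: int
    n: int
    k: int
    p_raw: float
    p_adj: float
    linking_proteins: frozenset[str]

    def __post_init__(self) -> None:
        if not (0 <= self.k <= min(self.K, self.n) and self.K <= self.N and self.n <= self.N):
            raise ValueError(
                f"inconsistent test parameters N={self.N} K={self.K} "
                f"n={self.n} k={self.k}"
            )
        if len(self.linking_proteins) != self.k:
            raise ValueError("linking_proteins must have exactly k members")
        if self.p_adj < self.p_raw:
            raise ValueError("p_adj must be >= p_raw")


def _check_bounds(N: int, K: int, n: int, k: int) -> None:
    if k < 0:
        raise ValueError(f"violated 0 <= k: k={k}")
    if K > N:
        raise ValueError(f"violated K <= N: K={K}, N={N}")
    if n > N:
        raise ValueError(f"violated n <= N: n={n}, N={N}")
    if k > min(K, n):
        raise ValueError(f"violated k <= min(K, n): k={k}, K={K}, n={n}")


def _log_binom(a, b):
    return gammaln(a + 1) - gammaln(b + 1) - gammaln(a - b + 1)


def hypergeom_upper_tail(N: int, K: int, n: int, k: int) -> float:
    """Inclusive upper-tail probability P(X >= k), X ~ Hypergeometric(N, K, n).

    Computed as sum_{i=k}^{min(K, n)} C(K, i) C(N-K, n-i) / C(N, n) with all
    binomial coefficients in log-space.  Returns exactly 1.0 for k = 0.
    """
    _check_bounds(N, K, n, k)
    if k == 0:
        return 1.0
    i = np.arange(k, min(K, n) + 1)
    # support constraint: n - i <= N - K
    i = i[(n - i) <= (N - K)]
    if i.size == 0:
        return 0.0
    log_terms = _log_binom(K, i) + _log_binom(N - K, n - i) - _log_binom(N, n)
    p = float(math.exp(logsumexp(log_terms)))
    return min(p, 1.0)


def bonferroni_adjust(p_raw: float, m: int) -> float:
    """Family-wise-error Bonferroni adjustment: min(1, m * p_raw)."""
    if m < 1:
        raise ValueError(f"Bonferroni family size must be >= 1, got {m}")
    if not 0.0 < p_raw <= 1.0:
        raise ValueError(f"p_raw {p_raw} outside (0, 1]")
    return min(1.0, m * p_raw)


def translate_disease_ids(source: AnnotationSource, idmap: IdMap) -> AnnotationSource:
    """Translate a source's disease vocabulary through a one-to-many id map.

    Each annotation fans out to one record per mapped target id; annotations
    whose disease has no mapping are retained under the original id (their
    count is logged).  Deduplication and the direct-over-inferred rule are
    re-applied by the :class:`AnnotationSource` constructor.
    """
    records = []
    unmapped_diseases = set()
    for protein_id, disease_id, relation in source.annotations:
        targets = idmap.targets(disease_id)
        if targets:
            for t in targets:
                records.append((protein_id, t, relation))
        else:
            unmapped_diseases.add(disease_id)
            records.append((protein_id, disease_id, relation))
    if unmapped_diseases:
        logger.info(
            "disease-id translation: %d disease(s) had no mapping and were "
            "retained under their original ids",
            len(unmapped_diseases),
        )
    return AnnotationSource(source.kind, records)


def enrich_diseases(
    ps: ProteinSet,
    source: AnnotationSource,
    bonferroni_m: int | None = None,
    direct_only: bool = False,
) -> list[EnrichmentResult]:
    """Score every candidate disease of one chemical against one source.

    Parameters
    ----------
    ps
        The chemical's mapped (gene-identifier) protein set.
    source
        Annotation catalog; its universe defines N and restricts n.
    bonferroni_m
        Family size for the adjustment of CTD-like results.  Defaults to the
        number of unique diseases in the source.  OMIM-like results are
        always reported unadjusted.
    direct_only
        Restrict the catalog to manually curated records before testing.

    Returns results for every disease with k >= 1, sorted by ascending
    adjusted p-value with ties broken by disease id.
    """
    if ps.stage is not Stage.MAPPED:
        raise ValueError(f"expected a mapped-stage protein set, got {ps.stage.value}")
    if direct_only:
        source = source.restricted(Relation.DIRECT)
    universe = source.universe
    N = len(universe)
    members_in_universe = ps.members & universe
    n = len(members_in_universe)
    if n == 0:
        logger.warning(
            "%r has no proteins in the %s universe; no enrichment computed",
            ps.chemical_id,
            source.kind.value,
        )
        return []

    disease_genes: dict[str, set[str]] = {}
    for protein_id, disease_id, _ in source.annotations:
        disease_genes.setdefault(disease_id, set()).add(protein_id)

    m = bonferroni_m if bonferroni_m is not None else len(disease_genes)
    results = []
    for disease_id in sorted(disease_genes):
        genes = disease_genes[disease_id]
        linking = frozenset(genes & members_in_universe)
        k = len(linking)
        if k == 0:
            continue
        K = len(genes)
        p_raw = hypergeom_upper_tail(N, K, n, k)
        if source.kind is SourceKind.CTD_LIKE:
            p_adj = bonferroni_adjust(p_raw, m)
        else:
            p_adj = p_raw
        results.append(
            EnrichmentResult(
                chemical_id=ps.chemical_id,
                disease_id=disease_id,
                source_kind=source.kind,
                N=N,
                K=K,
                n=n,
                k=k,
                p_raw=p_raw,
                p_adj=p_adj,
                linking_proteins=linking,
            )
        )
    results.sort(key=lambda r: (r.p_adj, r.disease_id))
    return results
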