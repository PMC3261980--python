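# Methods

## The procedure

toxilink implements a three-step knowledge-integration procedure that turns
a chemical identifier into a ranked list of candidate diseases.

**Step 1 — seed extraction.** The chemical–protein layer is a table of
(chemical, protein, evidence, source) records with evidence one of
`binding`, `expression`, `predicted`. Only the first two — experimental
evidence — seed the analysis; predicted links are carried in the data model
but excluded by the default filter (`allowed_evidence`). Binding and
expression links are treated identically downstream: no evidence weighting
is applied anywhere. Extraction is strictly per-chemical; overlap between
chemicals' sets is a reporting concern, never merged during analysis. A
chemical absent from the table yields an empty seed set with a warning, not
an error — absence of knowledge is a legitimate result.

**Step 2 — interactome expansion.** The interactome is an undirected PPI
graph with per-edge confidence in [0, 1] plus pathway membership sets.
Expansion adds (a) every first-order neighbor of a seed protein whose edge
confidence is ≥ `min_confidence`, and (b) every co-member of a pathway that
contains a seed protein. Three deliberate restrictions:

* *Seed-relative pathway rule.* Pathway co-membership is evaluated against
  seed proteins only. First-order additions do not recruit their own
  pathway partners; a transitive rule would cascade through the pathway
  layer and the expanded set would lose its per-chemical meaning.
* *Single round.* Expansion runs once; there is no iteration to a fixed
  point. "First-order" is the definition, not an approximation.
* *Default `min_confidence` = 0.* Supplied interactomes are assumed
  pre-filtered to high confidence; the threshold exists so users can
  tighten a noisier input, not to re-derive the upstream scoring scheme,
  which this package deliberately does not model.

Provenance (seed / first-order / pathway co-member) is recorded per member
and never overwritten, with priority seed > first-order > pathway. The
"induced PPI count" reported beside the expanded size is the number of
interactome edges with both endpoints inside the expanded set — one of two
defensible readings of such a statistic (the other being seed-incident
edges); it is a reporting field only and feeds nothing downstream.

Gene mapping applies a one-to-many protein→gene map; unmapped proteins are
dropped (count logged), several proteins mapping to one gene collapse to a
single member carrying the highest-priority provenance.

**Step 3 — enrichment.** Each annotation source defines its own protein
universe: the set of proteins with at least one annotation. N and n are
computed within that universe, so a chemical's usable sample size differs
per source (a mapped set of 175 genes may contribute n = 29 to a sparse
curated catalog and n = 131 to a dense one). Every disease with k ≥ 1 is
scored and reported — including single-protein links with their large
p-values — so that "not significant" remains distinguishable from "not
tested". Diseases with k = 0 are omitted: their upper-tail p-value is 1 by
construction and they would only pad the output.

The test statistic is the inclusive upper tail P(X ≥ k) of the
hypergeometric distribution. The inclusive convention is the standard one
for over-representation and the one the package's anchored example
(p = 0.147 at N=2387, K=13, n=29, k=1) pins down. The implementation sums
exp(log C(K,i) + log C(N−K,n−i) − log C(N,n)) over the tail via
`scipy.special.gammaln` and `logsumexp`; this stays exact to ~1e-13
relative for universes of tens of thousands and tail masses below 1e-300
territory, where naive factorial ratios would overflow and summing the
survival function term-by-term in linear space would underflow. P(X ≥ 0)
returns exactly 1.0; results are clipped to (0, 1].

Multiple testing: CTD-like results are Bonferroni-adjusted,
p_adj = min(1, m·p_raw). The family size m defaults to the number of
unique diseases in the *translated* catalog — the whole vocabulary, not
the per-chemical candidate list. Rationale: the dense source nominates
thousands of diseases per chemical, and the whole-vocabulary family is the
choice consistent with the package's anchored adjusted value
(2580 · P(X ≥ 48; 10509, 1977, 131) ≈ 0.0028); per-chemical family sizes
do not reproduce it. `bonferroni_m` overrides the default. OMIM-like
results are reported unadjusted: the curated catalog nominates few
candidates and its role is descriptive. No FDR-style procedures are
offered; family-wise control is the method's choice.

A caveat that follows from the per-chemical family: when several chemicals
are run in one batch, the run-level probability of at least one false
positive is bounded by (number of chemicals) × 0.05, not 0.05. The
Monte-Carlo harness (below) measures exactly this: with three chemicals
per knowledge base the realized run-level rate is ≈ 0.08 — each chemical's
family is controlled well below nominal (≈ 0.03, thanks to the
discreteness of the hypergeometric), but their union is not the
single-family rate. Users who need run-level control should divide alpha
by the number of chemicals or pass a larger `bonferroni_m`.

Disease-id translation (MeSH → OMIM) fans each annotation out to one
record per mapped target (one-to-many is expected), keeps unmappable
diseases under their original ids (count logged), and re-applies
deduplication with direct records dominating inferred ones for the same
(protein, disease) pair.

## Reporting

The chemical–disease network has one edge per (chemical, disease) pair
significant at alpha in at least one source; `alpha = 1` draws every
tested link (both modes exist because either could be wanted for a survey
figure). Edge weight is the size of the union of linking proteins across
sources. Disease categories are supplied by the user as a TSV; the package
embeds no clinical judgment. Venn partitions support two or three
chemicals (regions of higher-order partitions stop being drawable circles).
Exports are GraphML and SIF; all artifacts are byte-stable given fixed
inputs — rows sorted, ties in p-value ranking broken by disease id,
manifests free of timestamps.

## The synthetic knowledge-base generator

The generator emulates the statistical structure the analysis assumes, at
roughly one tenth the scale of the databases the method targets:

| parameter | default | rationale |
|---|---|---|
| `n_proteins` | 2000 | ~1/10 of a ~23k human proteome |
| `n_chemicals` | 3 | the motivating screen analyzed three related compounds |
| `n_diseases_omim` / `n_diseases_ctd` | 270 / 260 | the two vocabularies are of comparable size |
| `omim_annotation_rate` | 3e-4 | per protein–disease pair; universe ≈ 8% of the proteome, matching a curated catalog covering ~10% |
| `ctd_annotation_rate` | 2e-2 | ≈ 65× the curated density, reproducing the two-orders-of-magnitude annotation contrast (≈ 4k vs ≈ 250k records at full scale) |
| `inferred_fraction` | 0.8 | dense catalogs are dominated by inferred records |
| `seed_set_size` | 12 | scaled from seed sets of ~20–80 proteins |
| `ppi_mean_degree` | 6.0 | yields expanded sets a few percent of the proteome after one expansion round |
| `confidence_distribution` | (0.5, 1.0) | a pre-filtered, high-confidence interactome |
| `n_pathways` / `pathway_size` | 40 / (4, 12) | planted cliques give pathway expansion real modules |
| `mesh_multi_map_fraction` | 0.1 | share of MeSH diseases mapping to two OMIM ids |
| `unmapped_protein_fraction` | 0.04 | matches observed ~4% loss at the gene-mapping step |

The PPI layer is Erdős–Rényi-like (uniform random pairs) densified by
partial cliques over pathway members with upper-half confidences. All
randomness flows through a single `numpy.random.default_rng(rng_seed)`;
regeneration is byte-identical.

Annotations are independent Bernoulli draws per (gene, disease) pair. This
is the null the error-rate calibration needs, but it is also the
generator's main infidelity: real annotation catalogs concentrate records
on well-studied genes, so a real dense catalog can annotate 24 genes per
protein *and* cover only half the proteome, which independent draws cannot
do simultaneously. The defaults preserve the density contrast and the
curated source's sparseness and accept a too-large dense-source universe
(≈ 99% vs ≈ 46% of genes). Degree distributions are likewise binomial, not
scale-free, and identifiers are synthetic. Consequently, passing tests
demonstrate the correctness and calibration of the *procedure* under its
stated assumptions — they do not validate any biological claim about real
chemicals.

A planted link (chemical c, disease d, factor f ≥ 1) re-draws d's
annotations over c's expanded-and-mapped gene set at rate min(1, f × base
rate), using the very expansion code under test to determine the target
set; ground truth (seed memberships, planted ids pre- and
post-translation) is emitted alongside. With no planted links, annotations
are independent of chemical membership by construction.

## Monte-Carlo calibration

`toxilink.experiments` runs the full pipeline (not the bare statistic) per
replicate, one synthetic knowledge base per seed:

* **Null FWER** — 500 replicates at default configuration, counting runs
  where any CTD-like disease reaches p_adj < 0.05 for any of the three
  chemicals. Realized: ≈ 0.08 at run level / ≈ 0.03 per chemical (see the
  caveat above).
* **Planted recovery** — 100 replicates with one link planted at factor 8;
  the planted disease attains its chemical's minimum p_adj in 100/100
  replicates.

Problem sizes (2,000 proteins, ~10k dense-catalog annotations per
replicate) keep a replicate near 0.2 s, so the full calibration runs on a
laptop in ~2 minutes.

## Worked-example fixture

`make_worked_example_fixture` is a fully deterministic knowledge base
engineered so the real pipeline reproduces a published pair of asthma
computations end to end: 38 seed proteins → 182 expanded (130 first-order
partners + 14 pathway co-members) → 175 mapped genes; 29 of them inside a
2,387-protein curated universe with asthma at K = 13, k = 1
(p = 0.147); 131 inside a 10,509-protein dense universe with asthma at
K = 1,977, k = 48 and a 2,580-disease family (p_adj = 0.0028, i.e. ≈ 0.003;
the anchored presentation rounds it to one significant figure as 0.002 —
the exact value is what the package reports). Filler genes and diseases
give every universe member an annotation without disturbing those counts.

## Numerical and degenerate-input conventions

* Bounds are validated before any tail computation; violations name the
  inequality (e.g. `k <= min(K, n)`).
* `p_raw` of an empty intersection never occurs (k ≥ 1 by construction);
  n = 0 yields an empty result list with a warning.
* Duplicate table rows collapse with a logged count; duplicate PPI edges
  keep the maximum confidence; (a,b) and (b,a) are one edge; self-loops
  are rejected.
* Human-readable reports round p-values to 3 decimals; machine outputs
  (`enrichment.tsv`, JSON) carry full `repr` precision.
* Pipeline output directories are all-or-nothing: a failed stage removes
  partial output (when the pipeline created the directory).

## Known limitations

* Annotation independence and binomial degrees, as discussed — calibration
  transfers to real catalogs only to the extent their dependence structure
  is benign for the conditional (fixed N, K, n) test, which is exact
  regardless.
* The Bonferroni family is per chemical; batch-level control is the
  user's responsibility (see caveat).
* The upstream interactome confidence scoring and any significance-based
  pathway filtering are consumed as inputs, not modeled.
* No disease-ontology reasoning beyond the flat one-to-many id map, no
  chemical-structure handling, and no reconstruction of any real
  database's contents.
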