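# Methods

## Model and assumptions

`mirderep` infers a candidate miRNA-controlled transcriptional program
from correlation, not perturbation: a gene counts as *derepressed* when it
(a) is an experimentally validated target of at least one miRNA in the
panel and (b) rises significantly in aged tissue. The chain of reasoning
assumes that mRNA destabilization is the dominant mode of miRNA action
(so target loss is visible at the transcript level), that validated
human interactions transfer to mouse when the miRNA seed (nucleotides
2–8 of the mature sequence) is strictly conserved, and that the DEG
tables' adjusted p-values are taken as published — the pipeline never
re-tests or re-adjusts them.

### miRNA orthology

Mouse and human mature miRNAs are paired by name stem (species prefix
stripped) or an explicit override map. Sequence identity is computed as
left-anchored positionwise matches over the longer length — mature
miRNAs of one family are 5′-aligned, so a full alignment would add
machinery without changing the decision; the statistic is descriptive
only. The filtering criterion is exact equality of the 7-mer seed
(positions 2–8, 1-based, the standard seed convention). DNA-alphabet
input is converted T→U with a warning rather than rejected.

### Evidence tiers

A (miRNA, gene) interaction is *strong* as soon as any listed experiment
matches the strong-assay vocabulary (substring match, case-insensitive;
defaults: reporter assay, luciferase, western blot, qPCR/qRT-PCR) and
*weak* otherwise (CLIP-seq family, CLASH, …). Duplicate rows collapse to
the strongest evidence seen, pooling reference counts. Whether a run uses
both tiers or strong-only is a config knob (`evidence_policy`, default
`all`); the choice is echoed in every output header because published
analyses are often ambiguous on this point.

### Over-representation

For query size *n*, universe size *N*, pathway size *K* (all after
intersection with the universe) and overlap *k*, the p-value is the
exact hypergeometric upper tail

    P(X >= k) = Σ_{i=k}^{min(K,n)} C(K,i) C(N−K, n−i) / C(N,n)

computed in log space (`lgamma` + logsumexp over the feasible support),
one-sided, since the question is over-representation only. Agreement
with a rational-arithmetic enumeration is ≤ 1e-12 relative error over
the full parameter grid N ≤ 25 (and matches `scipy.stats.hypergeom.sf`
at large N to ~1e-9, limited by scipy's own accuracy). BH adjustment is
the textbook step-up, q(i) = min_{j≥i} p(j)·m/j, applied **per query**
(per miRNA), mirroring one enrichment submission per target set; a
pooled family is not offered because per-query families are what the
shared-pathway summary (pathways significant for ≥ `min_shared` = 3
miRNAs at q < 0.05) assumes.

The background universe is configurable because published analyses
rarely state it: default `pathway-union` (all genes annotated to ≥ 1
pathway), alternative `interaction-genes` (all target genes in the
interaction table). The choice is written into output headers.

### DEG filters and integration

Boundary semantics follow the published operators literally and are
frozen into named specs:

| dataset | direction | effect rule | p rule |
|---|---|---|---|
| aging brain atlas (25 types) | up | linear FC **≥ 1.5** (inclusive) | p_adj **< 0.05** |
| heterochronic parabiosis (31 types) | down | logFC **< 0** (strict) | p_adj < 0.05 |
| aged hypothalamus (11 types) | up | log2FC **> 0.1** (strict) | p_adj < 0.05 |

Effects are stored on their declared scale and never converted; a filter
applied to the wrong scale raises rather than guessing a base (for the
parabiosis sign test the base is irrelevant anyway). Mouse DEG symbols
reach the human-keyed target index through an orthology-prediction
bridge; under the default `best-support` policy each human gene maps to
the single mouse symbol with the highest support count (ties broken
lexicographically and logged). Gene-symbol comparison is
case-insensitive throughout, while output preserves the species
convention (mouse `Cdkn2a`, human `CDKN2A`); hyphens are part of the
symbol (mitochondrial `mt-Co2`).

Recurrence counts distinct cell types per gene (an optional rollup map
can coarsen types into classes first; the atlases' own class partition
is not assumed). Widespread upregulation requires ≥ `min_types` = 5
distinct cell types within one dataset. Reversal requires an aging hit
whose gene also passes the parabiosis down-filter in the *corresponding*
cell type; the 25↔31-type correspondence is an explicit input table,
never inferred by string matching — a hit cell type missing from the
table is an error, a mapped type absent from the parabiosis data is
logged and skipped.

### Networks

Bipartite miRNA→gene graphs are assembled from hits: one gene node per
gene carrying the maximum effect across its cell types (effects are all
positive after an up-filter, so the maximum is "the greatest change")
and the sorted cell-type list; edges are distinct (miRNA, gene) pairs.
Node ids are namespaced (`mirna:`, `gene:`) so symbols cannot collide in
GraphML; GraphML round-trips losslessly through the paired reader.

## Synthetic data: what it emulates, and what it does not

The generator produces the five inputs with planted ground truth:

* **Universe** — human genes `GENE0001…`, one-to-one mouse orthologs
  `Gene0001…` with random support counts; 150 pathways of 10–200 members
  sampled uniformly; 10 miRNAs with random 22-nt sequences, the mouse
  copy identical except for `n_decoy_nonconserved` = 1 decoy with a
  mutated seed position (so the conservation filter provably drops
  exactly the decoys); mouse CSF log-fold-changes drawn negative,
  matching a panel depleted with age.
* **Planted enrichment** — for each planted (miRNA, pathway) pair with
  factor f = 4, the in-pathway fraction of the miRNA's targets is
  min(1, f·K/N) in expectation and exceeds K/N deterministically.
  Planted pairs are restricted to pathways with ≥ 100 members and target
  sets of ≥ 200 genes: at f = 4 a size-10 pathway with a size-50 target
  set yields an expected overlap of ~1 gene and a tail probability of
  ~0.2 — such a "plant" would be statistically non-identifiable and
  therefore not ground truth. Infeasible requests (more in-pathway
  targets than min(n, K)) raise.
* **DEG tables** — a full gene × cell-type grid per dataset. Null cells:
  log2FC ~ Normal(0, σ₀ = 0.5), p_adj ~ Uniform(0,1), independent.
  Planted cells draw from shifted distributions (effects
  Normal(μ_up = 2.0, 0.5), reversal effects −|Normal(1.0, 0.5)|, p_adj ~
  Beta(0.05, 1)) and are **rejection-sampled until they pass the
  published filter**, so every planted instance is re-derivable from the
  emitted tables by applying the filters — planted sensitivity is 100%
  by construction, which is the property the recovery tests verify.
  Aging effects are emitted as linear FC = 2^log2FC, parabiosis as
  logFC, hypothalamus as log2FC. p-values are generated directly as
  adjusted p-values: the pipeline consumes p_adj as given, so simulating
  upstream testing would add unused machinery.

Deliberately **not** emulated: single-cell count distributions, dropout,
gene–gene correlation, realistic effect-size spectra, many-to-many
orthology, or pathway hierarchy. Passing tests therefore demonstrate
correctness of the inference chain under its stated assumptions, not
robustness to real scRNA-seq noise.

Determinism: each generator stage uses `numpy.random.default_rng([seed,
stage])`, so identical scenario + seed yields byte-identical files
regardless of call order.

## Numerical and design notes

* Enrichment p-values under random queries are *conservative* (observed
  p < 0.05 rate ≈ 0.03–0.04 for pathways with K ≥ 5) — a consequence of
  the discreteness of the hypergeometric tail, expected and tolerated.
* In the planted-recovery experiment the pooled false-discovery
  proportion (all discoveries of all 10 queries pooled per seed) runs
  near, and for some seed streams slightly above, the per-family 5%
  level: unplanted queries contribute false-only discoveries (their FDP
  is 1 whenever they discover anything), and planting induces *real*
  enrichment in pathways that overlap the planted one, which the
  ground-truth labels count as false. Recall of planted pairs is 100% in
  every seed examined.
* Tie-breaks are deterministic everywhere: pathway ranking by
  (q, p, pathway id), ortholog ties lexicographic, sorted cell-type and
  miRNA lists in every output.
* Reruns are byte-identical by design: provenance headers carry the
  package version and a config hash (inputs and parameters, excluding
  the output directory) but no timestamps, and per-stage wall-clock goes
  to the stderr log rather than `report.json`. Reproducibility was
  judged the stronger contract than embedding timings in the report.
* Degenerate inputs: k = 0 gives p = 1; a query fully outside the
  universe yields an empty result with a warning; an empty universe, a
  mixed-scale hit list, or a malformed table row raise with the offending
  row/line named.

## Problem sizes used in verification

The test suite and `scripts/acceptance.py` use: the full hypergeometric
grid N ≤ 25 against the rational oracle; 1,000 random p-vectors (lengths
1–500) against the reference BH; 200 random-query replicates for null
calibration; 100 generator seeds for planted-pathway recovery; and the
default scenario (2,000 genes × 25/31/11 cell types) for the end-to-end
recovery and determinism checks.

## Known limitations

Identity is left-anchored (no indel handling) — adequate for
family-conserved mature miRNAs, wrong for diverged pairs; only exact
seed equality counts as conserved (no 6-mer/offset-seed variants);
pathway hierarchy is ignored (parent and child pathways are tested
independently, so shared-pathway counts can double-count nested sets);
the evidence vocabulary is substring-based and will misclassify exotic
assay labels unless extended via configuration.
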