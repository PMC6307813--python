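# Methods

This note documents the statistical procedures, the synthetic-data model,
the numerical choices, and the limits of what the test suite demonstrates.

## Data model and scales

Input is a gene-by-sample matrix of non-negative, MAS5-style intensities
(normalisation is upstream and out of scope) with per-sample metadata:
subject, sex, one of 17 cortical regions, a four-level neuropathological
stage (normal, possible, probable, definite AD) and four clinical trait
scores. Probe-level matrices are collapsed to gene level by discarding
probes that map to more than one gene *before* aggregation and averaging
the remaining probes per gene, per sample, on the intensity scale.

The source analysis does not state the scale on which tests and
correlations were run. We compute fold changes on the intensity scale
(the 1.5 and 2/3 bounds are ratio-style) and everything else —
t-tests and Pearson correlations — on log2(value + 1), the standard
variance-stabilising choice for microarray intensities. Both are
toggleable (`log_transform=`), and the choice is recorded in network
provenance. Genes with zero variance in a stratum are retained in the
matrix but skipped by operations that need variance (correlation, t-test),
with a logged count or a flagged p = 1 respectively.

## Differential expression

A gene is called in a region iff FC > 1.5 or FC < 2/3 **and** p < 0.05,
all inequalities strict. The two-group test is unnamed in the source;
Welch's t is the default (it does not assume equal variances), with
Student's t and the Wilcoxon rank-sum as explicit alternatives. No
multiple-testing correction is applied by default, matching the raw-p
convention of the source; Benjamini-Hochberg q-values are available.
"Shared by over three regions" is read as ≥ 3 regions — the only reading
consistent with the reference table, where 17 genes occur in ≥ 3 regions
and exactly four (ASPA, ESRRB, GRM2, KIF26B) in 4.

## Co-expression networks

All-pairs Pearson correlation is computed blockwise (configurable block
size) so 10⁴-gene matrices stay within desk memory. The correlation
p-value uses the exact t-transform with n − 2 degrees of freedom; at the
default |r| > 0.9 threshold with n ≳ 10 the p < 0.01 clause is nearly
always implied, but both thresholds are enforced independently because
small strata (the n ≥ 4 stage networks) can violate it. `signed=True`
restricts edges to positive correlations; module detection uses this mode
at r > 0.95. Edges are canonical sorted gene pairs; partition into
sex-specific/overlap networks is exact set arithmetic and conserves edge
counts by construction.

## MCODE

Re-implemented from the published three-phase description (Bader & Hogue
2003), since the source invokes it only as "default settings". Defaults
are the Cytoscape plug-in's: degree cutoff 2, node score cutoff 0.2,
k-core 2, max depth 100, haircut on, fluff off. Vertex weight is
k_max × density of the highest k-core of the node's **open**
neighbourhood graph (so star centres and isolated nodes weigh 0).
Complex prediction seeds at the highest-weight unvisited node and
breadth-first includes neighbours whose weight ≥ seed weight × (1 − node
score cutoff); accepted members join exactly one complex, while rejected
boundary nodes remain eligible to seed later complexes. Zero-weight seeds
are skipped: their inclusion threshold would be 0 and the "complex" would
be an arbitrary connected sweep with no density signal. Haircut
iteratively removes members with fewer than two in-complex connections
(idempotent); complexes that end below two nodes or lack a 2-core are
dropped. Score = density × node count; ranking ties break by node count,
then lexicographic seed id, so output is reproducible. One behaviour
worth noting: two K4 cliques joined by a single bridge merge into one
complex under the default cutoff, because every vertex (bridge endpoints
included) carries the same weight — the algorithm chains through
high-weight nodes and nothing in the weighting penalises the bridge.
Tests pin this trace and verify the whole engine against an independent
straight-line reimplementation on every connected graph with ≤ 7 nodes.

Module crosstalk between the sexes compares **gene sets** (the reported
intersections are genes, e.g. SORT1/KLF13), with edge-level comparison
behind a flag.

## Trait-adapted survival screen

The split point of the expression dichotomisation is unstated in the
source; we split at the median with ties going to "low" (configurable
quantile). Trait scores are ordinal severities with no censoring
mechanism, so all events are treated as observed; the product-limit
estimator then equals 1 − ECDF (right-continuous), but censoring support
is retained and tested for generality. The log-rank statistic uses the
grouped-ties formulation: at each distinct trait value, observed minus
expected events in group 1 with hypergeometric variance, χ² = (O−E)²/V on
1 df. The statistic is rank-based, hence invariant under monotone
transforms of the trait. Degenerate tables (V = 0, e.g. identical
groups) return χ² = 0, p = 1. The implementation is cross-checked against
lifelines and against a hand-computed 6-event table plus its exhaustive
20-permutation null.

## Dynamic score and conserved networks

Per region × sex, stage networks use the standard edge thresholds with a
floor of four samples per stage; stages under the floor are *unavailable*
and excluded from the cross-stage intersection rather than treated as
empty (treating them as empty would force score = 1, contradicting
reference rows that have unavailable stages and scores < 1). normalNum is
the normal-stage edge count; since the intersection includes the normal
network, 0 ≤ overlapNum ≤ normalNum and the score lies in [0, 1], and
adding a stage can only shrink the overlap, never lower the score. The
male-vs-female comparison across regions is a paired exact Wilcoxon
signed-rank by default (sign test as alternative); the source does not
name its test and we do not claim to reproduce its exact p-value.

Three female rows of the bundled reference stage table (middle temporal
gyrus, precentral gyrus, putamen) are internally inconsistent: the score
printed at the source does not equal 1 − overlap/normal for the printed
counts, and no other stage column reproduces it (the duplicated values in
the female normal column suggest row-shift typos). The fixture ships the
counts as printed; `fixtures_check` and the acceptance tests report these
three rows as failures rather than papering over them. The other 31 rows
reproduce exactly to the printed precision (9 decimals male, 6 female).

## Enrichment

Plain one-sided upper-tail hypergeometric over-representation,
P[X ≥ k] for k query hits in a K-gene set from an N-gene universe with an
n-gene query. DAVID's EASE-modified score is deliberately not replicated
(its k − 1 adjustment and term database are service-specific and not
reproducible locally). The default background is the analysed expression
matrix's gene universe — the honest background for expression-derived
queries. Both the 0.01 and 0.05 significance conventions appear in the
source; both are surfaced as flags rather than reconciled.

## Synthetic cohort

The generator produces exactly the statistical features the pipeline
consumes, and nothing more. On the log2 scale,

    x_gs = baseline + loading · f_ms · [module m active for sample s]
           + log2FC · [planted contrast matches s] + ε_gs

with f ~ N(0,1) drawn per module × sample, ε ~ N(0, noise_sd), then
exponentiated. Within an active module the population PCC is
loading²/(loading² + noise_sd²); the defaults (loading 0.95,
noise 0.1) give ≈ 0.989, so edge recovery at |r| > 0.9 is expected but
not trivial. Module activity is gated by sex scope and stage scope; stage
rewiring is planted by silencing a module in definite AD — the minimal
mechanism that makes the dynamic score discriminate. Planted DEGs shift
the AD stages (probable + definite) of one region; a log2FC of 1.58
appears as FC ≈ 3.0 on the intensity scale. Traits are
base(stage) + effect · z(driver) + N(0, 1), clamped at 0, constant within
subject, with base strictly increasing in stage (1, 3, 5, 7).

Defaults mirror the validated recovery conditions: 60 subjects per sex,
two regions, uniform stage distribution, 500 genes, three planted modules
of 10-15 genes at loading 0.95, ten planted DEGs at |log2FC| ∈ {1, 1.58},
and GSK3B driving all four traits at 1.5 trait-SD. A single global seed
feeds deterministic substreams (subjects, noise, factors, traits), so
identical configs are bit-identical.

What the generator does **not** emulate: probe-level structure, batch and
platform effects, heavy-tailed or count-like noise (a heavier-tailed
option is exposed but not default), trait-stage interactions, missing
samples beyond whole-stage absence, and realistic correlation background
between non-module genes. Passing recovery tests therefore demonstrate
correctness of the *analysis machinery* under the assumed model, not
robustness to real microarray artefacts.

## Problem sizes in the test suite

Simulation-based tests run at the default cohort scale (500 genes, 240
samples) over 20 seeds for parameter recovery, 400 replicates for
log-rank null calibration, 1000 null genes for the DEG type-I check, and
10⁵ permutations for the correlation p-value oracle; the full suite
completes in well under a minute on one CPU. These sizes were chosen to
put Monte-Carlo error comfortably below the asserted tolerances.

## Known limitations

* The per-region pipeline calls DEGs on pooled sexes (the planted
  contrast); sex-stratified calling is available through `subset_cohort`
  but is not the demo default.
* `stage_networks` rebuilds the correlation matrix per stage rather than
  caching shared computation; at reference scale (~1.5 × 10⁴ genes) the
  blockwise path keeps memory bounded but wall time grows with stages.
* The exact Wilcoxon comparison assumes no zero differences and no ties
  across regions; scipy's exact method degrades gracefully otherwise.
* Reproducing the source's absolute edge counts, module counts (15/8) or
  K-M p-values requires the original accession and is out of scope; the
  bundled tables cover everything the source prints.
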