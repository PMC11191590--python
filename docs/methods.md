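# Methods

## Scope and model

`addscreen` screens a registry of plastic additives for predicted cancer
relevance by combining three public-data shapes: carcinogenicity
classifications (IARC monograph groups; EPA IRIS descriptors),
chemical–gene regulation events (CTD-style exports), and pathway gene-set
collections (GMT). The statistical core is gene-set over-representation:
for one chemical with gene list of size *N* drawn from a background
universe of *M* genes, the overlap *k* with a pathway of size *n* is tested
with the upper-tail hypergeometric probability P(X ≥ k), and the effect
size is the enrichment ratio ER = k / expect with expect = N·n/M. P-values
are adjusted per chemical with Benjamini–Hochberg across all collections
pooled (one submission = one family; per-collection adjustment is
available by flag), and pairs with FDR ≤ 0.25 are retained.

## Classification harmonization

IARC groups 1/2A/2B are *carcinogens*; adding group 3 gives *classified*;
everything else (absent, or present without a group) is *unclassified*.
"Present without a group" is a distinct enum value so database-coverage
tallies can count it inside IARC while analyses group it with
unclassified. IRIS entries are per exposure route; the most severe
descriptor represents the chemical (carcinogen > likely > probable >
possible > suggestive > noncancer). Cross-database consistency compares
binary cancer verdicts under an explicit correspondence table whose
default treats IRIS "suggestive evidence" as a cancer verdict; both the
table and that choice are overridable, since published consistency counts
do not document the rule they used. Printed-percentage reproduction uses
half-up rounding at the printed precision.

## Registry conventions

CAS numbers are validated with the modulo-10 check digit (digits weighted
1, 2, 3, … from the right, excluding the check digit) and canonicalized by
stripping leading zeros, which prevents silent duplicate keys. Rows
failing validation are quarantined to a rejects table, never dropped
silently. Merging source records for one CAS takes the best confidence
grade ("highest score wins"), unions the usage annotations, and keeps the
highest-confidence name (lexicographic tie-break) with all other names as
aliases. Product strings map to categories through positive/negative
substring rules, case-insensitive on whitespace-normalized text (e.g.
"tablecloth" is vetoed out of a clothing category matched by "cloth").

## Ortholog remapping

Nonhuman gene IDs are substituted by all of their mapped human Entrez IDs
(one record per ortholog, direction preserved); records with no mapping go
to an unmapped bucket and are excluded from ORA with a warning. The dedup
key is (cas, gene_id, direction): ORA uses presence, not report
multiplicity, and a gene reported both up- and downregulated stays in both
direction sets but enters the combined ORA input once.

## ER matrix and eligibility

The ER matrix holds chemicals as rows and tested pathways as columns, with
the ER of FDR-passing pairs and 0 elsewhere (whether non-significant ERs
should enter is genuinely undocumented; zero-fill is the default and the
alternative is a flag away at matrix-construction time via the explicit
`set_ids`/`chemicals` arguments). Rows default to chemicals with at least
one significant pathway — the chemicals for which the ORA "produced
results"; batch ORA engines return nothing for a submission with no
significant set, and the published eligible-chemical counts match that
reading. A caller can pass any explicit row set instead.

## Clustering

PCA keeps the smallest number of leading components whose cumulative
explained variance reaches 95% (full SVD, deterministic). UMAP then embeds
to 2 components over a grid of n_neighbors 2..20 and min_dist
{0.0, 0.1, 0.25, 0.5, 0.8, 0.99}; k-means (10 restarts) partitions each
embedding for k 3..10. Both stochastic stages run under five seeds
(defaults {0,1,2,3,4}; the same seed value drives UMAP and k-means at a
grid point). Every candidate is scored by mean silhouette in the embedding
where k-means ran; the grid iterates in a fixed order (n_neighbors,
min_dist, seed, k ascending) and keeps the best silhouette, ties going to
the smaller k and then the earlier grid position, so reruns are
bit-identical. A best solution below the 0.70 silhouette floor is returned
as an explicit failure report rather than an accepted clustering. Keyword
subsetting retains pathway columns whose names contain "cancer", "carcin",
"metasta" or "tumor" (case-insensitive) and drops chemicals with no
nonzero retained cell.

## Cluster profiles

Within a cluster, candidate (cancer-collection) pathways whose raw ER
standard deviation across the cluster's additives exceeds a per-cluster
threshold are selected; SD uses the sample convention (n−1) and is
computed on raw ERs over all cluster additives (computing it after
scaling, or over enriching additives only, are plausible alternatives the
source material does not pin down; both remain accessible by pre-filtering
the input frame). Additives enriching none of the selected pathways are
dropped. The selected submatrix is column-standardized (constant columns
zeroed with a warning) and both axes are ordered by agglomerative
clustering, Euclidean distance with complete linkage — the defaults of the
heatmap tooling this mirrors — with scipy's deterministic tie handling.
Headline lists: *central* = top 50 pathways by number of enriching
additives (ties by set_id), *uniquely enriched* = central here and in no
other cluster's central list, *highly enriched* = maximum ER over the
cluster ≥ 100. Cancer-relation categories (cancer type, cell
cycle/proliferation, cell death/survival, DNA damage, immune, metabolism)
are a user-supplied lookup validated for coverage; the package never
invents one.

## Group overlap

Overlap between chemicals is reported as raw intersection counts of
upregulated genes, downregulated genes and significant pathways — no
significance is attached, matching the descriptive use of these counts.
Rankings against a reference group aggregate per-pair overlaps by sum
(max available by flag; the published figures do not state the
aggregation). Pathway-union profiles report, per query chemical, the
percentage of the reference group's pooled significant pathways that the
query also enriches.

## Synthetic data

The generator emulates the statistical shape of the screen's inputs with
known ground truth. Defaults mirror the screen's composition: 2,712
additives of which 23/36/108/112 fall in IARC groups 1/2A/2B/3, 12 are
present unassigned and the rest absent (drawn multinomially, or as exact
rounded counts on request); a 13,049-gene human background; ~16% of
chemicals with any gene interactions. Planted clusters draw a fraction
*f* of each member's genes from cluster-specific signature pathways.
Surrogate nonhuman IDs occupy a reserved numeric range (≥ 10,000,000) and
the emitted ortholog map restores them (multiplicity-k mappings add k−1
random human genes), so remapping is exercised without destroying planted
signal. Directions are independent 50/50. All outputs are deterministic
per seed.

Two presets define the evaluation conditions:

* **strong_signal_config** — 3 clusters × 32 chemicals, f = 0.9, three
  disjoint signature pathways of 10–15 genes per cluster, exactly 50 genes
  per chemical. Because 45 signal genes always cover the ≤ 45-gene
  signature pool, planted profiles are exact within-cluster replicas with
  ER ≈ 261 per signature pathway, an order of magnitude above the
  spurious enrichments the FDR gate admits. This is a deliberate design:
  silhouette-maximization over a UMAP grid will prefer *any* discrete
  substructure (UMAP equalizes local density, so even modest within-cluster
  noise strata re-emerge as separable clumps), and a "strong signal"
  fixture is one where the planted partition is the only discrete structure
  present. The preset therefore tests that the pipeline recovers structure
  that is unambiguously there; it does not show robustness to
  within-cluster heterogeneity, which real enrichment profiles certainly
  have.
* **null_config** — the same scale with f = 0 and 220 chemicals: every
  gene list is a uniform draw, for type-I checks (the per-chemical
  probability of any FDR ≤ 0.25 discovery stays below the nominal level;
  BH on discrete hypergeometric p-values is conservative, and the measured
  rate is ≈ 0.06) and for verifying that the grid search reports failure
  instead of a confident clustering.

## Problem sizes and numerics

Tests and the acceptance script run the full grid-search pipeline at a
reduced grid (n_neighbors {5, 10, 15}, min_dist {0.0, 0.5}, seeds 0–4,
k 3–10) on the 96-chemical fixture — about a minute end to end — and the
oracle checks enumerate all draws exactly (rational arithmetic) for
backgrounds up to 15 genes, where complete enumeration is cheap.
Hypergeometric tails come from scipy (`hypergeom.sf(k−1, M, n, N)`); the
BH step-up is implemented directly (sorted cumulative minimum from the
largest p, restored to input order, capped at 1) and cross-checked against
statsmodels in the tests. Zero-overlap pairs score p = 1 and ER = 0.
Degenerate inputs fail loudly: empty backgrounds, gene lists with no
background genes, constant matrices entering PCA, and single-cluster
silhouettes all raise.

## Known limitations

* The generator plants block-structured, near-replica enrichment
  profiles; it does not emulate CTD evidence codes, report multiplicity,
  dose, correlated pathway overlap between collections, or heterogeneous
  per-chemical list sizes within a cluster.
* Published cluster memberships and silhouettes from the real
  CTD/IARC/IRIS extracts depend on those full databases and are not
  reproducible offline; the pipeline reproduces the screen's printed
  arithmetic and its procedures, and validates recovery on synthetic
  ground truth instead.
* The UMAP stage is a pluggable contract (fixed-seed determinism, 2-D
  default); conclusions about cluster counts are conditional on the
  silhouette-max selection rule over the configured grid.
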