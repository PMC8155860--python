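# Methods

## The integration model

`mirpair` treats a miRNA–mRNA regulatory candidate as a triple of evidence:
the two features are each differentially expressed between conditions, their
expression is negatively correlated across the same samples, and a sequence-
based target-prediction database lists the pair. None of the three alone is
specific in a small design — with 7 samples the group shift dominates the
pooled variance, so almost every DE-miRNA/DE-mRNA combination is strongly
correlated (positively or negatively) — but the conjunction prunes the
candidate space by more than an order of magnitude. The pipeline makes each
filter explicit and keeps a counter funnel (candidates → negative →
significant-negative → predicted) so the contribution of every step is
auditable.

All statistics run on log2-scale expression values. Raw-count input can be
passed through the `log2p1` convenience transform; the package deliberately
does not model counts (no voom-style weighting, no dispersion estimation) —
its target data are processed array/NGS intensity matrices.

### Differential expression

Two per-feature tests are exposed:

* `plain`: Welch two-sample t with Satterthwaite df. Analytically simple;
  used by the formula-oracle tests.
* `moderated` (default): pooled-variance t with empirical-Bayes variance
  moderation. Per-feature pooled variances s² (df d = n₁+n₂−2) are assumed
  to follow s₀²·χ²_d/d around a scaled-inverse-chi-square prior with d₀ df;
  (d₀, s₀²) are fitted by the standard moment method on log s² (digamma/
  trigamma corrections, trigamma inversion by Newton), the posterior
  variance is s²_post = (d₀s₀² + d·s²)/(d₀ + d), and t is referred to a
  t-distribution with d + d₀ df (normal when d₀ = ∞, i.e. when the observed
  spread of s² does not exceed chi-square sampling noise; in that degenerate
  case s₀² is the mean variance). The test suite cross-checks this
  implementation against limma's `lmFit`/`eBayes` via Rscript and agrees to
  machine precision.

Signed fold changes follow the signed-magnitude convention: with
ratio = 2^(mean_lesion − mean_control), the reported FC is +ratio when
ratio ≥ 1 and −1/ratio otherwise, so |FC| ≥ 1 always and a 4-fold drop reads
−4.00. Zero-variance features get p = 1 (with a warning), never NaN. BH is
computed within each molecule type separately, since the DE universes of
miRNAs and mRNAs are separate families.

### Pair inference

Pearson correlation is computed across all samples pooled (both groups
jointly — the design that makes anti-coupling visible on top of the DE
shift); a per-group option is intentionally absent. Two-sided p-values use
the exact transform t = r√(n−2)/√(1−r²) with n−2 df; |r| within 1e−12 of 1
is assigned p = 0 (the transform diverges there, and perfectly
anti-correlated pairs must survive the significance filter). BH runs jointly
over the full candidate family (all |DE miRNAs|×|DE mRNAs| pairs), not
per-miRNA. Thresholds are strict inequalities (adj p < α, dat_sum ≥ min_dbs
with min_dbs = 1 by default). Identifier matching against prediction
databases is exact and case-sensitive; no -5p/-3p arm normalization is
attempted. Zero-variance vectors are dropped from the correlation pass with
a warning rather than propagating undefined correlations.

The report table is sorted by adjusted p ascending, then |r| descending,
then (miRNA, mRNA) lexicographic; Cor and FCs print to 2 decimals, adjusted
p in 3-significant-digit scientific notation.

### Comparison

Pair-set intersection is exact on (mirna_id, mrna_id). The ranked
targets-per-miRNA table reports cumulative unique-target coverage: Cum% at
rank k is 100·|∪ targets of ranks 1..k|/universe, **truncated** (not
rounded) to 2 decimals — the floor convention means a rank never appears to
cover more of the universe than it does (60/189 prints 31.74). The universe
defaults to the unique mRNAs of the analyzed pair set; `universe_size` can
widen it to the DE-mRNA universe, since both denominators are legitimate
views and published figures have used each. Ties in target counts break
lexicographically. Threshold queries ("more than 5 regulators") are strict.

### Enrichment

Over-representation uses the upper-tail hypergeometric probability
P(X ≥ k) for X ~ Hypergeometric(N, K, n), where gene sets are intersected
with the universe before testing and the query must be a subset of the
universe. The universe defaults to all mRNAs measured on the platform and is
configurable. The tail probability is evaluated with
`scipy.stats.hypergeom.sf`; tests verify it against exhaustive enumeration
of all C(N, n) draws for every N ≤ 12. BH uses the same step-up routine as
pair inference (one implementation, shared).

Each significant set gets a structure composition score: the fraction of its
*overlap* genes present in a user-supplied structure-gene list
(cytoskeleton, cell adhesion, extracellular matrix), normalized by the
maximum fraction among the significant sets, so the most structural pathway
scores exactly 1. Max-normalization is an interpretation choice (documented
here, not derivable from first principles), as is scoring overlap genes
rather than all pathway members. The headline "fraction of
structure-dominant pathways" counts sets whose raw fraction strictly
exceeds 0.5. Structure membership comes from a flat gene list rather than
live GO queries, because GO set contents are database-version-dependent.

### Network

The regulatory graph is directed and bipartite by construction: one edge per
retained pair, always miRNA → mRNA, nodes typed by kind and DE direction.
Since retained pairs are negatively correlated, up-miRNAs point at
down-mRNAs and vice versa; an edge joining same-direction nodes triggers a
validation warning (it indicates a positive-correlation pair leaked
through), but the two-component layout is emergent, not enforced.

Closeness is reachable-set-normalized out-closeness: (number of
out-reachable nodes)/(sum of shortest-path distances to them), 0 for sink
nodes. In a pure bipartite graph every connected regulator's reachable set
sits at distance 1, so its closeness is exactly 1 — which makes the hub
criterion (closeness ≥ 1 and outdegree strictly > 25, both configurable)
effectively an outdegree cut, matching how hub regulators are read off such
networks. Different graph tools normalize closeness differently; this
convention is fixed and tested against a brute-force BFS oracle. Export
formats are SIF (one `mirna targets mrna` line per edge) and GraphML with
node attributes, both round-trippable.

### Report

`summarize_run` recomputes every percentage from raw counts at full
precision and formats it once, centrally: funnel and intersection
percentages to 1 decimal, the targeted-mRNA percentage to the nearest
integer, Cum% truncated to 2 decimals. The JSON report is validated by a
pydantic schema; reruns on identical inputs are identical up to the
timestamp.

## The synthetic-data generator

The generator emulates a paired miRNome/transcriptome case-control study on
log2 scale. Defaults define the study conditions:

| parameter | default | meaning |
|---|---|---|
| n_control / n_lesion | 3 / 4 | sample sizes of the emulated design |
| n_mirna / n_mrna | 200 / 1500 | platform sizes (kept modest; the DE universes, not the platforms, set the correlation cost) |
| n_de_mirna / n_de_mrna | 75 / 562 | planted DE features, matching the emulated study's DE counts |
| fc_range | (4, 16) | linear fold-change magnitudes of planted DE, log-uniform, random sign — strong effects, as expected of FDR-surviving features in a 7-sample design |
| n_planted_pairs | 330 | planted anti-couplings; each target mRNA couples to exactly one regulator, so 330 of the 562 DE mRNAs (~59%) are under miRNA control |
| coupling_strength | 1.0 | slope of target = baseline − strength·miRNA + noise |
| noise_sd | 0.2 | per-sample Gaussian noise, log2 units — tight residual noise consistent with the near-perfect correlations such designs report |
| db_count / db_coverage | 3 / 0.7 | three synthetic databases; each lists a planted pair with probability 0.7, so P(listed ≥ once) = 1 − 0.3³ ≈ 97% |
| decoy_rate | 1000 | expected decoys per database, drawn uniformly from non-planted DE×DE pairs |

Baseline feature means are Normal(6, 2) on log2 scale (resembling processed
intensities; the exact values are immaterial to every test). Anti-coupling
is applied across **all** samples, not only lesions, so the pooled-sample
correlation is genuinely negative; with noise_sd = 0 every planted pair has
r = −1 exactly. The coupled target's true log2FC is induced by its
regulator's shift (−strength·log2FC of the miRNA) and recorded as such in
the ground truth.

What the simulator does *not* emulate: sequencing count noise and library
size effects, microarray probe effects, normalization artifacts,
between-sample batch structure, correlated co-regulation (each target has
one regulator), and miRNA arm ambiguity. Passing tests therefore demonstrate
the correctness of the statistical machinery on cleanly generated log2 data,
not robustness to real-data preprocessing pathologies.

One consequence worth knowing: because *all* planted-DE features shift
between groups, even non-coupled DE×DE combinations correlate strongly
across 7 pooled samples, so the significance filter retains most negative
pairs and the prediction-database filter does nearly all of the specificity
work. Published analyses of this design show the same funnel shape.

## Numerical choices and degenerate inputs

- BH step-up is one shared vectorized implementation (stable sort;
  cumulative minimum from the largest p down), property-tested against both
  a hand-rolled step-up and `statsmodels.multipletests`.
- Trigamma inversion for the variance prior uses Newton on the convexity-
  corrected update with a 1/x asymptotic start; d₀ = ∞ handled explicitly.
- Correlation p at |r| = 1 is 0 by definition (within 1e−12 float
  tolerance).
- Zero-variance features: p = 1 in DE, dropped in correlation — both logged.
- Empty inputs: empty pair sets filter to empty sets with zero counters;
  an empty enrichment record list yields 0.0 structure-dominance with a
  warning; empty-universe percentages are 0.
- Tie-breaks are deterministic everywhere (documented lexicographic rules),
  and all sorts use stable algorithms, so identical inputs give
  byte-identical outputs (golden-file tested).

## Problem sizes used in tests and the acceptance run

The full study design (75 × 562 = 42,150 candidate pairs, 7 samples) runs in
about a second, so the acceptance script and the recovery tests use it
directly. Module tests use a scaled configuration (30 miRNAs, 120 mRNAs,
10 × 40 DE universes, 20 planted pairs) with the same sample design, chosen
to keep the suite fast while preserving every code path.

## Known limitations

- Correlation is Pearson on all samples pooled; no Spearman, partial
  correlation, or regression-based pair inference.
- Target predictions are inputs; the package never computes sequence-based
  predictions.
- The enrichment stage tests mRNA lists only, with a user-supplied GMT; no
  GSEA-style ranked testing, no GO/KEGG retrieval or ID mapping.
- Network metrics are limited to outdegree and out-closeness (the two used
  for hub calling); no betweenness/eigenvector centrality, no layout.
- Multi-factor designs and batch correction are out of scope; exactly two
  groups are supported.
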