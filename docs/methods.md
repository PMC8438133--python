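# Methods

`modnet-germ` re-implements, as a tested library, a comparative time-series
transcriptome workflow for germinating low-phytic-acid (lpa) soybean seeds:
differential expression between lpa and normal sibling lines at three
germination stages, model-based co-expression module discovery, GO
over-representation, module-network ensemble inference of TF → module
regulation with 4-of-5 consensus voting, expansion to TF–gene edges, and
cross-species validation against DAP-seq interactions. A synthetic-data
generator reproduces the study design with known ground truth so that every
stage can be validated quantitatively.

## Study design

Eight experimental lines in three genotypic subsets, each pairing lpa
mutants with normal phytic-acid siblings:

| subset  | lpa line | normal line(s)        | mutations in lpa line  |
|---------|----------|-----------------------|------------------------|
| Mips    | 1mlpa    | 1MWT                  | mips1                  |
| MRP     | 2mlpa    | 2MWT, 2MWT-L, 2MWT-N  | mrp-l + mrp-n          |
| MipsMRP | 3mlpa    | 3MWT                  | mips1 + mrp-l + mrp-n  |

A line is lpa when it carries *mips1* or both epistatically interacting
*mrp* mutations; a single *mrp* mutation leaves the seed normal (the two
single-mutant MRP lines are therefore normal controls). Each line is
sampled at three germination stages (dry seed, 8 h imbibed, radicle
emergence) in biological triplicate: 8 × 3 × 3 = 72 libraries. Analyses run
per subset; MRP supplies 4 lines × 3 stages = 12 replicate-averaged
conditions, the other subsets 6.

## Differential expression

A deliberately simple negative-binomial Wald test, built from:

- **Size factors** — median-of-ratios: s_j = median over all-positive
  genes of counts[g, j] / geometric mean of gene g across samples. If no
  gene is positive everywhere, geometric means fall back to positive
  entries only (logged).
- **Dispersion** — method of moments, Var = μ + αμ²: per gene,
  α_c = (var − mean)/mean² within each (line, stage) replicate cell,
  pooled with degrees-of-freedom weights and floored at 1e−8; the common
  dispersion is the per-gene median. No shrinkage toward a trend.
- **Wald test** — with normalized group means m_A (lpa), m_B (normal),
  pseudocount c = 1: lfc = log2((m_A+c)/(m_B+c)),
  se = √[(1/n_A)(1/(m_A+c) + α_g) + (1/n_B)(1/(m_B+c) + α_g)]/ln 2
  (delta method), z = lfc/se, two-sided normal p, Benjamini–Hochberg
  within each comparison.
- **DEG filters** — strict inequalities, jointly: padj < 0.01,
  |log2 FC| > 1, base mean > 10 (base mean over both groups' samples of
  the comparison only).
- **Subset combination** — Mips and MipsMRP have one contrast per stage;
  in MRP a gene is a DEG only if it passes in all three contrasts of
  2mlpa against the near-isogenic normals. Per-stage DEG sets are also
  reported as the seven disjoint Venn regions.

The normal-tail Wald statistic with pooled method-of-moments dispersion is
well calibrated under the full design (48 residual df; observed null
p < 0.05 rate 0.03–0.06) but is mildly anti-conservative when only a
couple of replicate cells are available; with n = 3 replicates this test
is a screening tool, not an inferential endpoint.

## Variance stabilization and condition profiles

Normalized counts q are transformed with the closed form
v(q) = (2/√α) · asinh(√(αq)) at the common dispersion α (v(0) = 0,
v → 2√q as α → 0). Per subset, replicates are averaged into (line, stage)
condition profiles and z-scored per gene (sd floor 1e−12; z-scoring is
configurable off).

## Co-expression modules

DEG condition profiles are clustered with hand-rolled EM over Gaussian
finite mixtures in six covariance families — spherical, diagonal, and full,
each either shared across components or per-component (free parameters:
1, K, d, Kd, d(d+1)/2, Kd(d+1)/2 respectively, plus Kd means and K−1
weights). Initialization is a seeded k-means partition; the ridge 1e−6 is
added to every covariance diagonal (z-scored rows are rank-deficient by
construction); iteration stops at relative log-likelihood change < 1e−6 or
500 rounds, with the monotone log-likelihood trace retained for testing.
The sweep (K = 2..15 by default, all six families, best of `restarts`
seeded starts each) selects the maximum of BIC = 2·loglik − ν·ln(n); ties
go to smaller K, then family order. Genes are hard-assigned to their
maximum-responsibility component because the downstream module-network
stage requires disjoint modules. Module ids are labelled M1..MK and module
mean profiles are unweighted member averages.

## GO enrichment

Per module, every term annotated to at least one module gene is tested by
the hypergeometric upper tail (the one-sided Fisher exact test for
over-representation), with the background equal to all genes carrying at
least one annotation. BH adjustment is applied within each module across
its tested terms; a term is enriched at FDR < 0.05. No GO-graph
propagation is performed — terms are tested exactly as annotated.

## Ensemble network inference

Candidate regulators (DE TFs) and module means share one conditions ×
(TFs + modules) matrix; zero-variance columns are dropped. Mutual
information is the rank-based Gaussian-copula closed form
MI = −½ ln(1 − ρ²), ρ = 2 sin(π ρ_s/6) from Spearman's ρ_s, capped at
|ρ| ≤ 0.9999 — with 6–12 conditions, histogram and k-NN MI estimators are
not usable. The five scorers:

- **aracne** — pairwise MI over the full TF + module node set; an edge
  (i, j) is pruned when some k has MI(i,j) < (1−ε)·min(MI(i,k), MI(j,k))
  (strict; ε = 0.1 default); only TF × module entries are reported.
- **clr** — bipartite TF × module MI; z-scores against the TF row and
  module column backgrounds, combined as √(max(z_r,0)² + max(z_c,0)²).
- **lars** — least-angle-regression path of each module profile on the
  standardized TF columns; a TF entering at step t ≤ T scores
  (T − t + 1)/T.
- **pcor** — shrinkage partial correlation: R* = (1−λ)R + λI with λ from
  the variance-of-entries analytic estimator (clipped to [0.01, 1]; λ
  lands around 0.5–0.6 at n = 12, which in our experiments ranked edges
  better than lighter fixed shrinkage), scores |−P_tm/√(P_tt P_mm)| with
  P = (R*)⁻¹.
- **rf** — per module, a 1000-tree random-forest regression on the TF
  columns (√p feature subsampling, bootstrap rows, seeded); scores are
  normalized impurity importances.

Each method keeps its top E = d·M edges by score (zero scores never kept;
boundary ties broken lexicographically), and edges kept by at least 4 of
the 5 methods form the consensus. The library default d = 10 targets
full-scale problems (hundreds of candidate TFs, where E is a few percent
of all pairs); the synthetic benchmark uses d = 2 (see below). Consensus
edges are expanded to one TF–gene edge per module member (self-edges
excluded), then validated two ways: through best cross-species homologs
(top hit by bitscore, ties by E-value then subject id, kept only at
E ≤ 1e−5) looked up in a DAP-seq interaction set, and against a
precomputed motif-match table ((module, TF) pairs from upstream motif
discovery over 1,000 bp 5′ flanks, consumed as data — running the motif
tools themselves is out of scope). Edges with unmapped endpoints are
reported as unmapped, never dropped, so support rates stay interpretable.

## Synthetic data generator

The generator emits counts for the full 72-sample design with known truth.
Per gene g and sample j, log2 μ = baseline(g) + structure + N(0, σ), and
counts are gamma-Poisson (exact negative binomial, Var = μ + αμ²) after a
per-sample library factor drawn log-uniform in [0.5, 2]. The structure
term depends on the gene's role:

- **TFs** (default 30) carry a *driver* profile: a stage-common component
  (sd 0.5), a line-specific deviation per (line, stage) cell (sd 1.25),
  and an lpa-vs-normal offset (|offset| in [1.2, 2], random sign). The
  line-specific component is essential, not cosmetic: stage-only profiles
  live in a 3-dimensional subspace of the condition space, so without
  line-level heterogeneity any two of the 30 driver profiles would be
  strongly correlated by subspace geometry alone and no inference method
  could separate regulators from a handful of averaged conditions. TF
  baselines start at log2 5 (≈32 counts): candidate regulators stand in
  for DE TFs, which must be detectably expressed.
- **Module genes** (a 1 − background share of the non-TF genes, ≥ 3 per
  module) share a module stage profile (sd 0.5) plus Σ β·driver over the
  module's planted regulators, |β| uniform in [effect_scale/2,
  effect_scale] with random sign. Each module gets one distinct primary
  TF; extra edges spread over modules with the fewest regulators, so the
  planted in-degree stays ≤ 2 at the default edge count — with a dozen
  conditions, a module whose variance splits over three or more comparable
  regulators is unidentifiable in principle, which is outside the sparse
  regime the module-network approach assumes.
- **Background genes** (default 60% of non-TF genes) have independent
  stage-only profiles (sd 1.0) and no line dependence: they are exactly
  null in every lpa-vs-normal contrast. Keeping them in the majority is
  required by median-of-ratios normalization (which assumes most genes are
  not DE; with a mostly-regulated transcriptome, size factors absorb
  composition shifts and nulls acquire spurious fold changes) and gives
  the false-discovery evaluation a well-defined null population.
- **Planted DE** lands on background genes — `de_genes_per_cell` (default
  30) genes per (subset, stage) receive |Δ| in [lfc_scale, 1.25·lfc_scale]
  in the subset's lpa lines — so the DE recovery channel is not
  confounded with, or cancelled by, regulatory lpa effects flowing through
  the drivers.

Everything is deterministic given the seed, and
`expected_log2_means`/`expected_lfc` return the exact noise-free means, so
tests can classify any gene as truly null or truly DE without Monte-Carlo
error. `generate_annotations` emits matching synthetic annotation tables
(module-characteristic GO terms, TF families, homology hits at E = 1e−50
for ~95% of genes, a DAP edge set containing ~70% of the expanded true
edges plus decoys, and a motif-match table) so the complete pipeline runs
end to end on generated inputs.

What the generator does **not** emulate: sequence-level effects (GC/length
bias), gene–gene correlation beyond module membership, outlier samples,
batch structure, unbalanced designs, or realistic GO topology. Passing the
recovery benchmarks therefore demonstrates internal correctness of the
pipeline under its own assumptions — not performance on real libraries,
where effect sizes are smaller and confounding is richer.

## Benchmark protocol and problem sizes

The standard benchmark preset is 800 genes, 30 TFs, 8 modules, 12 planted
edges, effect_scale 2, lfc_scale 2, α = 0.02, σ = 0.1 under the full
72-sample design; inference runs on the MRP-like subset (12 conditions).
Edge recovery conditions on the planted module memberships (module means
from truth) so it measures the scoring–binarization–voting stages in
isolation; clustering recovery instead clusters the subset's DEGs and
scores the adjusted Rand index against planted labels; DE recovery scores
sensitivity on planted |Δ| ≥ 2 genes at base mean ≥ 50 and empirical FDR
against the exact nulls.

The benchmark's inference configuration is d = 2 edges per module
(per-method budget E = 16 of 240 candidate pairs, roughly twice the
planted mean in-degree) and LARS depth T = 2 (= the maximum planted
in-degree). At this problem size the library default d = 10 would keep a
third of all candidate pairs per method, and because all five methods see
the same 12-condition sample correlation matrix, the 4-of-5 vote cannot
remove noise that the data themselves share — precision collapses while
recall saturates. Two structural limits are worth knowing: (i) edges into
two-regulator modules have marginal correlations near the √½ asymptote,
overlapping the chance-correlation tail over 224 null pairs at n = 12, so
consensus recall hovers around 7–8 of 12 edges; (ii) edges visible only
conditionally (a weak β next to a strong partner) can be found by lars,
pcor and rf but not by the two marginal methods (aracne, clr), capping
their support at 3 of 5. Ten-seed medians under this protocol are
precision ≈ 0.75–0.88 and recall ≈ 0.58–0.67 depending on the seed base —
the consensus is precision-oriented by construction, exactly the behavior
the 4-of-5 rule is chosen for.

Problem sizes throughout the test-suite protocols (800-gene preset, 10
benchmark seeds, K sweeps to 8–10 with 2–3 restarts, 500-observation
Gaussian chains, 80-point clusters for the K-selection check) were chosen
as the smallest sizes at which the statistical properties under test are
stable.

## Numerical choices and degenerate inputs

- BH step-up: sorted p·m/rank with a reverse cumulative minimum; ties are
  handled by stable sort (verified to 1e−12 against brute force and
  statsmodels).
- EM: covariance ridge 1e−6; component weights floored at tiny; k-means
  initialization is seeded per restart; a failed Cholesky marks that
  (K, family) fit failed, and only if every fit in a sweep fails is a
  convergence error raised.
- Zero-variance profiles z-score to all-zero rows; zero-variance columns
  are dropped (with a log warning) before inference; constant vectors are
  rejected by the MI estimator.
- Determinism: one global pipeline seed fans out per stage as the first
  four bytes of SHA-256("seed:stage:subset") mod 2³¹; the random forest is
  reseeded per module from the stage seed. Two runs with the same config
  and seed produce byte-identical output trees (tested).
- All TSV output uses fixed float formats and sorted, stable orderings so
  artifacts diff cleanly.

## Known limitations

- The DE test has no dispersion shrinkage, GLM covariates, outlier
  handling, or independent filtering; with triplicates it is mildly
  anti-conservative when few replicate cells inform the dispersion.
- Whether the base-mean filter should be applied before or after multiple
  testing is ambiguous in the underlying workflow; here the three DEG
  filters are applied jointly after adjustment.
- The random forest scorer is permutation-invariant only in distribution:
  bootstrap draws are tied to the seed, so reordering conditions changes
  individual importances (the other four scorers are exactly invariant).
- GO enrichment ignores the ontology graph; annotations are tested as
  given.
- Module ids are arbitrary labels; nothing aligns module numbering across
  subsets or seeds.
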