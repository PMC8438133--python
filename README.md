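# modnet-germ

Module-network gene-regulatory-network inference for germinating
low-phytic-acid (lpa) soybean seeds.

Low-phytic-acid soybean lines — carrying loss-of-function mutations in the
*myo*-inositol phosphate synthase gene (*mips1*) and/or two epistatic ABC
transporter genes (*mrp-l*, *mrp-n*) — germinate poorly, and the
transcriptional basis of that defect is the scientific question this
pipeline addresses. It compares lpa lines with their normal phytic-acid
sibling lines across three germination stages (dry seed, imbibed seed,
radicle emergence) in three genotypic subsets (Mips, MRP, Mips-MRP; eight
lines × three stages × three replicates = 72 RNA-seq libraries), and asks
which transcription factors putatively drive the differentially expressed
gene modules. It is written for computational biologists who want each
stage as a tested, reusable library function rather than a one-off script.

The workflow:

1. **Differential expression** — a simplified negative-binomial Wald test
   (median-of-ratios size factors s_j = median_g c_gj / (∏_k c_gk)^(1/m);
   method-of-moments dispersion with Var = μ + αμ²; delta-method SE on
   log2 FC; BH adjustment). DEGs satisfy padj < 0.01 ∧ |log2 FC| > 1 ∧
   baseMean > 10; in the MRP subset a gene must pass against all three
   near-isogenic normal lines.
2. **Co-expression modules** — replicate-averaged, variance-stabilized
   (v(q) = (2/√α)·asinh√(αq)), z-scored condition profiles clustered by
   Gaussian finite mixtures (EM over six covariance families), selecting
   K and family by BIC = 2·log L − ν·ln n.
3. **GO enrichment** — per-module hypergeometric upper-tail test
   p = Σ_{i≥k} C(K,i)C(N−K,n−i)/C(N,n), BH FDR < 0.05.
4. **Ensemble GRN inference** — five algorithms (ARACNE, CLR, LARS,
   shrinkage partial correlation, random-forest importance) score every
   TF → module edge on the conditions × (TFs + module means) matrix; each
   method keeps its top d·M edges and edges detected by ≥ 4 of 5 methods
   form the consensus.
5. **Validation** — consensus edges expand to TF–gene edges over module
   members and are checked against cross-species DAP-seq interactions
   (through best homology hits at E ≤ 1e−5) and precomputed motif matches.

A synthetic-data generator reproduces the 72-sample design with planted
DE genes, planted modules, and planted TF → module regulation, so every
stage is benchmarked against known truth. `docs/methods.md` has the full
model descriptions and design rationale.

## Worked example

Generate a synthetic study (full 8-line design, 800 genes, 30 TFs,
8 modules, 12 regulatory edges) and run the whole pipeline on the MRP
subset:

```
$ modnet-germ generate --preset paper_full --n-genes 800 --n-tfs 30 \
      --n-modules 8 --n-edges 12 --seed 7 --out demo/data
wrote 800 genes x 72 samples to demo/data

$ modnet-germ run-all --data-dir demo/data --subset MRP --seed 5 \
      --kmax 10 --restarts 2 --out demo/run
MRP: 24 consensus edges
```

`demo/run/MRP/manifest.json` records every stage; this run found 179, 153,
and 99 DEGs at stages 1–3 (314 distinct genes; the Venn partition is in
`venn.json` — e.g. 76 genes are stage-1-exclusive, 7 differential at all
three stages), clustered them into K = 6 modules (full-covariance family
selected by BIC), found 12 enriched GO terms, and kept 24 TF → module
consensus edges among 23 DE TFs, for example:

```
regulator  target  support  methods
TF002      M4      5        aracne,clr,lars,pcor,rf
TF003      M5      5        aracne,clr,lars,pcor,rf
```

Expansion yields 1,195 TF–gene edges (18 regulators, 314 targets);
`validated.tsv` marks each edge's DAP-seq and motif support (here 200 of
1,138 homology-mapped edges, 17.6%, have DAP-seq support — the synthetic
DAP table contains 70% of the true edges plus decoys, and expansion
necessarily dilutes module-level support across member genes).

Every stage is also callable directly (`modnet-germ de / cluster / enrich /
benchmark`, or the `modnet_germ` API: `size_factors`, `vst`,
`nb_wald_test`, `select_model`, `fisher_enrich`, `infer_consensus`,
`expand_edges`, ...).

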