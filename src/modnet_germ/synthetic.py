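"""Synthetic germination time-series counts with known regulatory truth.

The generator emulates the study design behind the pipeline: eight soybean
lines (three genotypic subsets, each pairing low-phytic-acid mutants with
normal sibling lines) sampled at three germination stages in biological
triplicate, 72 RNA-seq libraries in total.

The generative model, per gene ``g`` and sample ``j``::

    log2 mu = baseline(g)
              + module stage profile[module(g), stage(j)]
              + sum over regulatory edges into module(g) of
                    beta * driver(tf, line(j), stage(j))
              + driver(g, ...)                if g is a TF
              + delta(g, subset(j), stage(j)) if planted DE and line is lpa
              + Normal(0, sigma)              replicate noise

    count ~ NegativeBinomial(mean = libsize(j) * 2**log2mu,
                             var  = mu + alpha * mu**2)

TF "driver" profiles are piecewise-constant over stages, carry an
lpa-vs-normal offset, and add a line-specific deviation per (line, stage)
cell, so a TF -> module signal is identifiable from the handful of
replicate-averaged conditions the real analysis has to work with.  Module
intrinsic profiles and background-gene profiles depend on stage only,
never on line, so lpa-vs-normal contrasts of unregulated genes are
exactly null.

Everything is deterministic given the seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import CountMatrix, SampleMeta, phytic_class_for

# Magnitude bounds for the lpa-vs-normal offset of TF driver profiles, in
# log2 units.  Offsets exceed 1 so differentially expressed TFs clear the
# |log2FC| > 1 filter and are available as candidate regulators.
TF_OFFSET_RANGE = (1.2, 2.0)

# Standard deviations (log2) of the generative profile components.  TF
# activity must be dominated by line-specific variation: stage-only
# profiles live in a 3-dimensional subspace of the condition space, so if
# the stage-common part dominated, every pair of unrelated TF and module
# profiles would be strongly correlated by subspace geometry alone and no
# inference method could tell 30 TFs apart from a handful of averaged
# conditions.  Lines differ in regulatory background beyond the lpa locus,
# which is what the line-specific deviation emulates.
TF_STAGE_SD = 0.5
DRIVER_JITTER_SD = 1.25
MODULE_STAGE_SD = 0.5
BACKGROUND_STAGE_SD = 1.0

# Per-sample library-size factors are drawn log-uniform in this range, wide
# enough to exercise median-of-ratios normalization.
LIBSIZE_RANGE = (0.5, 2.0)


@dataclass(frozen=True)
class LineSpec:
    """One soybean line: name, (mips1, mrp_l, mrp_n) mutation flags, subset."""

    name: str
    genotype_flags: tuple[bool, bool, bool]
    subset: str

    @property
    def phytic_class(self) -> str:
        return phytic_class_for(self.genotype_flags)


#: The eight experimental lines of the full design.  Flags mark *mutated*
#: loci: e.g. 2mlpa carries intact MIPS1 but both mrp mutations.
PAPER_LINES = (
    LineSpec("1mlpa", (True, False, False), "Mips"),
    LineSpec("1MWT", (False, False, False), "Mips"),
    LineSpec("2mlpa", (False, True, True), "MRP"),
    LineSpec("2MWT", (False, False, False), "MRP"),
    LineSpec("2MWT-L", (False, False, True), "MRP"),
    LineSpec("2MWT-N", (False, True, False), "MRP"),
    LineSpec("3mlpa", (True, True, True), "MipsMRP"),
    LineSpec("3MWT", (False, False, False), "MipsMRP"),
)

MINI_LINES = (
    LineSpec("mlpa", (True, False, False), "Mips"),
    LineSpec("MWT", (False, False, False), "Mips"),
)


@dataclass(frozen=True)
class StudyDesign:
    """Lines x germination stages x replicates factorial design."""

    lines: tuple[LineSpec, ...]
    stages: tuple[int, ...]
    replicates: int

    @property
    def n_samples(self) -> int:
        return len(self.lines) * len(self.stages) * self.replicates

    @property
    def subsets(self) -> tuple[str, ...]:
        seen: list[str] = []
        for line in self.lines:
            if line.subset not in seen:
                seen.append(line.subset)
        return tuple(seen)

    def samples(self) -> list[SampleMeta]:
        out = []
        for line in self.lines:
            for stage in self.stages:
                for rep in range(1, self.replicates + 1):
                    out.append(
                        SampleMeta(
                            sample_id=f"{line.name}_s{stage}_r{rep}",
                            line=line.name,
                            subset=line.subset,
                            genotype_flags=line.genotype_flags,
                            phytic_class=line.phytic_class,
                            stage=stage,
                            replicate=rep,
                        )
                    )
        return out

    def comparisons(self, subset: str) -> list[tuple[str, str]]:
        """(lpa line, normal line) contrasts analyzed within a subset."""
        lpa = [l.name for l in self.lines if l.subset == subset and l.phytic_class == "lpa"]
        normal = [
            l.name for l in self.lines if l.subset == subset and l.phytic_class == "normal"
        ]
        return [(a, b) for a in lpa for b in normal]


def generate_design(preset: str) -> StudyDesign:
    """Return a named study design.

    ``paper_full``: the 8-line x 3-stage x 3-replicate design (72 samples).
    ``mini``: 2 lines x 3 stages x 2 replicates for fast tests.
    """
    if preset == "paper_full":
        return StudyDesign(lines=PAPER_LINES, stages=(1, 2, 3), replicates=3)
    if preset == "mini":
        return StudyDesign(lines=MINI_LINES, stages=(1, 2, 3), replicates=2)
    raise ValueError(f"unknown design preset {preset!r}")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth of a synthetic run.

    ``module_of`` covers module genes only: TF expression tracks the TF's
    own driver profile (TFs stay out of co-expression modules), and the
    remaining non-TF genes are line-independent background.  ``de_genes``
    maps (subset, stage) to {gene: planted log2 FC}; fold changes are
    planted on background genes so the DE channel stays orthogonal to the
    regulatory channel.
    """

    gene_ids: tuple[str, ...]
    module_of: dict[str, int]  # module genes only; other non-TF genes are background
    tf_set: frozenset[str]
    true_edges: tuple[tuple[str, int, float], ...]  # (tf, module, beta)
    de_genes: dict[tuple[str, int], dict[str, float]]
    baseline_logmean: dict[str, float]
    alpha: float
    sigma: float
    # internal generative parameters, stored so expected means are exact
    module_profile: dict[tuple[int, int], float] = field(default_factory=dict)
    tf_stage_profile: dict[tuple[str, int], float] = field(default_factory=dict)
    tf_lpa_offset: dict[str, float] = field(default_factory=dict)
    tf_line_jitter: dict[tuple[str, str, int], float] = field(default_factory=dict)
    background_profile: dict[tuple[str, int], float] = field(default_factory=dict)

    def driver(self, tf: str, line_name: str, stage: int, lpa: bool) -> float:
        """TF activity in one (line, stage) cell, on the log2 scale."""
        val = self.tf_stage_profile[(tf, stage)]
        val += self.tf_line_jitter.get((tf, line_name, stage), 0.0)
        if lpa:
            val += self.tf_lpa_offset[tf]
        return val

    @property
    def n_modules(self) -> int:
        return max(self.module_of.values(), default=0)

    @property
    def background_genes(self) -> list[str]:
        return [
            g
            for g in self.gene_ids
            if g not in self.tf_set and g not in self.module_of
        ]

    def module_genes(self, module: int) -> list[str]:
        return [g for g, m in self.module_of.items() if m == module]

    def edge_set(self) -> set[tuple[str, int]]:
        return {(tf, m) for tf, m, _ in self.true_edges}


def plant_truth(
    design: StudyDesign,
    n_genes: int = 800,
    n_tfs: int = 30,
    n_modules: int = 8,
    n_edges: int = 12,
    effect_scale: float = 2.0,
    lfc_scale: float = 2.0,
    alpha: float = 0.02,
    sigma: float = 0.1,
    seed: int = 0,
    background_frac: float = 0.6,
    de_genes_per_cell: int = 30,
) -> PlantedTruth:
    """Draw a ground-truth regulatory structure for ``simulate_counts``.

    A ``background_frac`` share of the non-TF genes stays outside every
    module with stage-only expression profiles -- these genes are exactly
    null in every lpa-vs-normal contrast, anchor the false-discovery
    evaluation, and keep the majority of the transcriptome non-DE, which
    median-of-ratios normalization assumes (the default is a majority
    share for exactly that reason).  The rest are distributed over modules of >= 3 genes.
    Every module receives at least one regulating TF whenever
    ``n_edges >= n_modules`` (distinct primary TFs whenever enough TFs
    exist); effect sizes |beta| are uniform in [effect_scale/2,
    effect_scale] with random sign.  Planted DE fold changes land on
    ``de_genes_per_cell`` background genes per (subset, stage), with
    per-gene |delta| in [lfc_scale, 1.25 * lfc_scale] and random sign.
    """
    if n_tfs >= n_genes:
        raise ValueError("n_tfs must be < n_genes")
    if n_edges > n_tfs * n_modules:
        raise ValueError(f"n_edges={n_edges} exceeds n_tfs * n_modules")
    if not 0.0 <= background_frac < 1.0:
        raise ValueError("background_frac must be in [0, 1)")
    n_targets = n_genes - n_tfs
    n_background = int(round(background_frac * n_targets))
    n_module_genes = n_targets - n_background
    if n_module_genes < 3 * n_modules:
        raise ValueError("need at least 3 non-TF module genes per module")

    rng = np.random.default_rng(seed)
    tf_ids = tuple(f"TF{i:03d}" for i in range(1, n_tfs + 1))
    target_ids = tuple(f"G{i:05d}" for i in range(1, n_targets + 1))
    gene_ids = tf_ids + target_ids

    # module assignment: guarantee >= 3 members, remainder uniform;
    # genes beyond n_module_genes stay background
    perm = rng.permutation(n_targets)
    module_gene_idx = perm[:n_module_genes]
    assignment = np.empty(n_module_genes, dtype=int)
    base = np.tile(np.arange(1, n_modules + 1), 3)
    assignment[: 3 * n_modules] = base
    assignment[3 * n_modules :] = rng.integers(
        1, n_modules + 1, size=n_module_genes - 3 * n_modules
    )
    module_of = {
        target_ids[int(i)]: int(m) for i, m in zip(module_gene_idx, assignment)
    }

    # regulatory edges: cover every module first (distinct TFs when
    # possible, so modules remain mutually distinguishable), then spread
    # extra edges over modules with the fewest regulators.  Keeping the
    # planted in-degree low matches the sparse regime the module-network
    # approach assumes: with only a dozen averaged conditions, a module
    # whose variance is split over many comparable regulators is
    # unidentifiable for any inference method.
    edges: list[tuple[str, int]] = []
    indegree = {m: 0 for m in range(1, n_modules + 1)}
    if n_edges >= n_modules:
        if n_tfs >= n_modules:
            primaries = rng.choice(n_tfs, size=n_modules, replace=False)
        else:
            primaries = rng.integers(0, n_tfs, size=n_modules)
        for m, t in enumerate(primaries, start=1):
            edges.append((tf_ids[int(t)], m))
            indegree[m] += 1
    while len(edges) < n_edges:
        lowest = min(indegree.values())
        candidates = sorted(m for m, k in indegree.items() if k == lowest)
        m = int(candidates[int(rng.integers(0, len(candidates)))])
        cand = (tf_ids[int(rng.integers(0, n_tfs))], m)
        if cand not in edges:
            edges.append(cand)
            indegree[m] += 1
    betas = rng.uniform(effect_scale / 2.0, effect_scale, size=len(edges))
    betas *= rng.choice([-1.0, 1.0], size=len(edges))
    true_edges = tuple((tf, m, float(b)) for (tf, m), b in zip(edges, betas))

    # TFs double as candidate regulators, which in the real pipeline must
    # be DEGs passing the base-mean filter; their baselines start at
    # clearly detectable expression so TF profiles are measurable at all
    baseline = {g: float(v) for g, v in zip(tf_ids, rng.uniform(5.0, 9.0, n_tfs))}
    baseline.update(
        {g: float(v) for g, v in zip(target_ids, rng.uniform(3.0, 9.0, n_targets))}
    )

    module_profile = {
        (m, s): float(rng.normal(0.0, MODULE_STAGE_SD))
        for m in range(1, n_modules + 1)
        for s in design.stages
    }
    tf_stage_profile = {
        (tf, s): float(rng.normal(0.0, TF_STAGE_SD))
        for tf in tf_ids
        for s in design.stages
    }
    tf_lpa_offset = {
        tf: float(rng.uniform(*TF_OFFSET_RANGE) * rng.choice([-1.0, 1.0]))
        for tf in tf_ids
    }
    tf_line_jitter = {
        (tf, line.name, s): float(rng.normal(0.0, DRIVER_JITTER_SD))
        for tf in tf_ids
        for line in design.lines
        for s in design.stages
    }
    background_genes = [g for g in target_ids if g not in module_of]
    background_profile = {
        (g, s): float(rng.normal(0.0, BACKGROUND_STAGE_SD))
        for g in background_genes
        for s in design.stages
    }

    # planted DE: per (subset, stage), a random draw of background genes
    # receives a stage-specific log2 fold change in the subset's lpa lines.
    # Planting on background genes keeps the DE channel orthogonal to the
    # regulatory channel (module genes are already differentially expressed
    # through their lpa-offset drivers).
    de_genes: dict[tuple[str, int], dict[str, float]] = {}
    n_de = min(de_genes_per_cell, len(background_genes))
    for subset in design.subsets:
        for stage in design.stages:
            chosen = rng.choice(len(background_genes), size=n_de, replace=False)
            de_genes[(subset, stage)] = {
                background_genes[int(i)]: float(
                    rng.uniform(lfc_scale, 1.25 * lfc_scale) * rng.choice([-1.0, 1.0])
                )
                for i in chosen
            }

    return PlantedTruth(
        gene_ids=gene_ids,
        module_of=module_of,
        tf_set=frozenset(tf_ids),
        true_edges=true_edges,
        de_genes=de_genes,
        baseline_logmean=baseline,
        alpha=float(alpha),
        sigma=float(sigma),
        module_profile=module_profile,
        tf_stage_profile=tf_stage_profile,
        tf_lpa_offset=tf_lpa_offset,
        tf_line_jitter=tf_line_jitter,
        background_profile=background_profile,
    )


def expected_log2_means(design: StudyDesign, truth: PlantedTruth) -> pd.DataFrame:
    """Noise-free expected log2 mean per gene and (line, stage) condition.

    Library-size factors and replicate noise are excluded, so the
    difference of two columns is the exact expected log2 fold change of the
    corresponding contrast.  Columns are labelled ``"{line}|s{stage}"``.
    """
    conditions = [(line, stage) for line in design.lines for stage in design.stages]
    cols = [f"{line.name}|s{stage}" for line, stage in conditions]
    mat = np.zeros((len(truth.gene_ids), len(conditions)))

    edges_by_module: dict[int, list[tuple[str, float]]] = {}
    for tf, m, beta in truth.true_edges:
        edges_by_module.setdefault(m, []).append((tf, beta))

    for i, g in enumerate(truth.gene_ids):
        base = truth.baseline_logmean[g]
        is_tf = g in truth.tf_set
        module = truth.module_of.get(g)
        for j, (line, stage) in enumerate(conditions):
            lpa = line.phytic_class == "lpa"
            val = base
            if is_tf:
                val += truth.driver(g, line.name, stage, lpa)
            elif module is None:
                val += truth.background_profile[(g, stage)]
                if lpa:
                    delta = truth.de_genes.get((line.subset, stage), {})
                    val += delta.get(g, 0.0)
            else:
                val += truth.module_profile[(module, stage)]
                for tf, beta in edges_by_module.get(module, ()):
                    val += beta * truth.driver(tf, line.name, stage, lpa)
                if lpa:
                    delta = truth.de_genes.get((line.subset, stage), {})
                    val += delta.get(g, 0.0)
            mat[i, j] = val
    return pd.DataFrame(mat, index=list(truth.gene_ids), columns=cols)


def expected_lfc(
    design: StudyDesign, truth: PlantedTruth, comparison: tuple[str, str], stage: int
) -> pd.Series:
    """Exact expected log2 fold change (lpa/normal) for one contrast."""
    lm = expected_log2_means(design, truth)
    return lm[f"{comparison[0]}|s{stage}"] - lm[f"{comparison[1]}|s{stage}"]


def simulate_counts(
    design: StudyDesign, truth: PlantedTruth, seed: int = 0
) -> tuple[CountMatrix, PlantedTruth]:
    """Simulate the count matrix for ``design`` under ``truth``.

    Counts are negative binomial with Var = mu + alpha * mu^2, drawn as a
    gamma-Poisson mixture (exact, and numerically stable down to
    alpha -> 0), after per-sample library-size scaling.
    """
    rng = np.random.default_rng(seed)
    samples = design.samples()
    lm_cond = expected_log2_means(design, truth)

    cond_idx = [f"{s.line}|s{s.stage}" for s in samples]
    log2mu = lm_cond[cond_idx].to_numpy(copy=True)
    log2mu = log2mu + rng.normal(0.0, truth.sigma, size=log2mu.shape)

    libsize = np.exp(
        rng.uniform(np.log(LIBSIZE_RANGE[0]), np.log(LIBSIZE_RANGE[1]), len(samples))
    )
    mu = np.exp2(log2mu) * libsize[None, :]

    if truth.alpha > 0:
        shape = 1.0 / truth.alpha
        lam = rng.gamma(shape, truth.alpha * mu)
    else:
        lam = mu
    counts = rng.poisson(lam).astype(np.int64)

    df = pd.DataFrame(
        counts, index=list(truth.gene_ids), columns=[s.sample_id for s in samples]
    )
    return CountMatrix(counts=df, samples=tuple(samples)), truth


def generate_annotations(
    truth: PlantedTruth, seed: int = 0
) -> dict[str, object]:
    """Synthetic annotation tables consistent with the planted truth.

    Produces, with the same shapes as their real counterparts:

    - a GO map in which each module has two characteristic terms (annotating
      ~60% of its members plus a 2% background leak) on top of 20 uniform
      background terms,
    - a TF-family map covering the planted TFs,
    - 12-column homology hits mapping ~95% of genes to synthetic
      cross-species ids at E-values far below 1e-5,
    - a DAP-seq-style edge list containing ~70% of the expanded true
      TF -> gene pairs (mapped through the homology) plus random decoys,
    - a motif-match table containing ~70% of the true (module, TF) pairs
      plus decoys.
    """
    rng = np.random.default_rng(seed)
    genes = list(truth.gene_ids)
    n_modules = truth.n_modules

    go_map: dict[str, set[str]] = {}
    go_names: dict[str, tuple[str, str]] = {}
    term_no = 0

    def new_term(desc: str) -> str:
        nonlocal term_no
        term_no += 1
        term = f"GO:{term_no:07d}"
        go_names[term] = (desc, "biological_process")
        return term

    for m in range(1, n_modules + 1):
        members = truth.module_genes(m)
        for t in range(2):
            term = new_term(f"synthetic module {m} process {t + 1}")
            for g in members:
                if rng.random() < 0.6:
                    go_map.setdefault(g, set()).add(term)
            for g in genes:
                if rng.random() < 0.02:
                    go_map.setdefault(g, set()).add(term)
    for b in range(20):
        term = new_term(f"synthetic background process {b + 1}")
        for g in genes:
            if rng.random() < 0.1:
                go_map.setdefault(g, set()).add(term)

    families = ("ERF", "NAC", "MYB", "bZIP", "C2H2", "Trihelix", "WRKY")
    tf_map = {tf: families[i % len(families)] for i, tf in enumerate(sorted(truth.tf_set))}

    homolog_of: dict[str, str] = {}
    hit_rows: list[str] = []
    for i, g in enumerate(genes):
        if rng.random() < 0.05:
            continue  # unmapped gene
        subject = f"AT1G{(i + 1) * 10:05d}"
        homolog_of[g] = subject
        bitscore = float(np.round(150.0 + rng.uniform(0, 100), 1))
        hit_rows.append(
            f"{g}\t{subject}\t{np.round(70 + rng.uniform(0, 29), 1)}\t400\t10\t2\t"
            f"1\t400\t1\t400\t1e-50\t{bitscore}"
        )

    dap_edges: set[tuple[str, str]] = set()
    for tf, m, _beta in truth.true_edges:
        for g in truth.module_genes(m):
            if tf in homolog_of and g in homolog_of and rng.random() < 0.7:
                dap_edges.add((homolog_of[tf], homolog_of[g]))
    subjects = sorted(set(homolog_of.values()))
    for _ in range(200):
        a, b = rng.choice(len(subjects), size=2, replace=False)
        dap_edges.add((subjects[int(a)], subjects[int(b)]))

    motif_matches: set[tuple[str, str]] = set()
    for tf, m, _beta in truth.true_edges:
        if rng.random() < 0.7:
            motif_matches.add((f"M{m}", tf))
    tf_list = sorted(truth.tf_set)
    for _ in range(5):
        motif_matches.add(
            (f"M{int(rng.integers(1, n_modules + 1))}", tf_list[int(rng.integers(0, len(tf_list)))])
        )

    return {
        "go_map": go_map,
        "go_names": go_names,
        "tf_map": tf_map,
        "hit_rows": hit_rows,
        "dap_edges": dap_edges,
        "motif_matches": motif_matches,
    }
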