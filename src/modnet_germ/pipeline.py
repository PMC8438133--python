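"""Orchestration: run every stage for one genotypic subset, reproducibly.

A single JSON-serializable config carries all input paths and stage
parameters.  One global seed fans out to per-stage seeds through a hashed
splitting rule, so stages stay independent while the whole run is
deterministic: rerunning with the same config and seed reproduces
byte-identical outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import pandas as pd

from . import clustering, diffexpr, enrichment, grn, io_formats, validation

log = logging.getLogger(__name__)

STAGES = ("de", "cluster", "enrich", "infer", "consensus", "expand", "validate")


def stage_seed(global_seed: int, stage: str, subset: str) -> int:
    """Per-stage seed: truncated SHA-256 of (global seed, stage, subset)."""
    digest = hashlib.sha256(f"{global_seed}:{stage}:{subset}".encode()).digest()
    return int.from_bytes(digest[:4], "big") % (2**31)


@dataclass
class PipelineConfig:
    """All inputs and stage parameters of one pipeline run."""

    counts: str
    meta: str
    go: str
    tf: str
    hits: str
    dap: str
    motifs: str
    seed: int = 0
    # DEG filters (strict inequalities)
    deg_padj: float = diffexpr.PADJ_MAX
    deg_lfc: float = diffexpr.LFC_MIN
    deg_basemean: float = diffexpr.BASEMEAN_MIN
    # clustering
    k_min: int = 2
    k_max: int = 15
    families: tuple[str, ...] = clustering.FAMILIES
    restarts: int = 3
    zscore: bool = True
    # enrichment
    enrich_fdr: float = enrichment.FDR_MAX
    # inference
    inference: grn.InferenceConfig = field(default_factory=grn.InferenceConfig)
    # validation
    evalue_max: float = validation.DEFAULT_EVALUE_MAX

    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["families"] = list(self.families)
        return d

    @classmethod
    def from_dict(cls, d: dict[str, Any]) -> "PipelineConfig":
        d = dict(d)
        if "inference" in d and isinstance(d["inference"], dict):
            d["inference"] = grn.InferenceConfig(**d["inference"])
        if "families" in d:
            d["families"] = tuple(d["families"])
        return cls(**d)

    @classmethod
    def from_json(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _write_json(obj: Any, path: Path) -> None:
    path.write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")


def run_subset(config: PipelineConfig, subset: str, out_dir: str | Path) -> dict:
    """Execute de -> cluster -> enrich -> infer -> consensus -> expand ->
    validate for one genotypic subset, writing every intermediate artifact.

    Returns (and writes) a manifest recording the resolved config, stage
    seeds, and per-stage row counts.  Any stage error aborts the run; the
    failing stage is recorded in the manifest before the exception is
    re-raised.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict[str, Any] = {
        "subset": subset,
        "config": config.to_dict(),
        "stage_seeds": {s: stage_seed(config.seed, s, subset) for s in STAGES},
        "stages": {},
    }
    current = "de"
    try:
        cm = io_formats.read_counts(config.counts, config.meta)
        subset_lines = sorted(
            {s.line for s in cm.samples if s.subset == subset}
        )
        if not subset_lines:
            raise ValueError(f"no samples for subset {subset!r}")
        lpa_lines = sorted(
            {s.line for s in cm.samples if s.subset == subset and s.phytic_class == "lpa"}
        )
        normal_lines = sorted(
            {
                s.line
                for s in cm.samples
                if s.subset == subset and s.phytic_class == "normal"
            }
        )
        stages_present = sorted({s.stage for s in cm.samples if s.subset == subset})
        comparisons = [(a, b) for a in lpa_lines for b in normal_lines]

        # ---- de
        sf = diffexpr.size_factors(cm)
        disp = diffexpr.estimate_dispersion(cm, sf)
        records = []
        for comparison in comparisons:
            for stg in stages_present:
                rec = diffexpr.nb_wald_test(
                    cm,
                    sf,
                    disp,
                    comparison,
                    stg,
                    padj_max=config.deg_padj,
                    lfc_min=config.deg_lfc,
                    basemean_min=config.deg_basemean,
                )
                records.append(rec)
                rec.reset_index(names="gene").to_csv(
                    out / f"de_{comparison[0]}_vs_{comparison[1]}_s{stg}.tsv",
                    sep="\t",
                    index=False,
                    float_format="%.8g",
                )
        deg_by_stage = diffexpr.call_degs_subset(records, subset)
        for stg, genes in deg_by_stage.items():
            pd.DataFrame({"gene": sorted(genes)}).to_csv(
                out / f"degs_stage{stg}.tsv", sep="\t", index=False
            )
        venn = diffexpr.venn_partition(deg_by_stage)
        _write_json(venn, out / "venn.json")
        deg_union = sorted(set.union(*deg_by_stage.values()))
        manifest["stages"]["de"] = {
            "comparisons": len(comparisons),
            "degs_per_stage": {str(k): len(v) for k, v in deg_by_stage.items()},
            "deg_union": len(deg_union),
        }
        if not deg_union:
            raise diffexpr.DegenerateInputError("no DEGs called; nothing to cluster")

        # ---- cluster
        current = "cluster"
        vst_mat = diffexpr.vst(cm, sf, disp)
        profiles = clustering.build_profiles(
            vst_mat, cm.samples, deg_union, subset, zscore=config.zscore
        )
        k_max = min(config.k_max, len(deg_union) - 1)
        assignment = clustering.select_model(
            profiles,
            k_range=range(config.k_min, k_max + 1),
            families=config.families,
            restarts=config.restarts,
            seed=stage_seed(config.seed, "cluster", subset),
        )
        assignment.to_frame().to_csv(out / "modules.tsv", sep="\t", index=False)
        assignment.sweep.to_csv(
            out / "bic_sweep.tsv", sep="\t", index=False, float_format="%.8g"
        )
        manifest["stages"]["cluster"] = {
            "n_genes": len(assignment.module_of),
            "K_selected": assignment.n_modules,
            "family_selected": assignment.fit.family,
        }

        # ---- enrich
        current = "enrich"
        go_map, _go_names = io_formats.read_go_map(config.go)
        module_gene_sets = {
            f"M{m}": assignment.module_genes(m)
            for m in range(1, assignment.n_modules + 1)
            if assignment.module_genes(m)
        }
        enrich_df = enrichment.enrich_all_modules(
            module_gene_sets, go_map, fdr_max=config.enrich_fdr
        )
        enrich_df.to_csv(out / "enrichment.tsv", sep="\t", index=False, float_format="%.8g")
        manifest["stages"]["enrich"] = {
            "terms_tested": len(enrich_df),
            "enriched": int(enrich_df["enriched"].sum()) if len(enrich_df) else 0,
        }

        # ---- infer
        current = "infer"
        tf_map = io_formats.read_tf_map(config.tf)
        de_tfs = sorted(set(deg_union) & set(tf_map))
        if len(de_tfs) < 2:
            raise diffexpr.DegenerateInputError(
                f"subset {subset!r} has {len(de_tfs)} differentially expressed TFs"
            )
        mod_means = clustering.module_means(profiles, assignment)
        inference = dataclasses.replace(
            config.inference, rf_seed=stage_seed(config.seed, "infer", subset)
        )
        matrix, tf_cols, module_cols = grn.build_regulator_matrix(
            vst_mat, cm.samples, de_tfs, mod_means, subset
        )
        scores = grn.score_all_methods(matrix, tf_cols, module_cols, inference)
        for method, sdf in scores.items():
            sdf.reset_index(names="tf").to_csv(
                out / f"scores_{method}.tsv", sep="\t", index=False, float_format="%.8g"
            )
        manifest["stages"]["infer"] = {
            "n_tfs": len(tf_cols),
            "n_modules": len(module_cols),
        }

        # ---- consensus
        current = "consensus"
        budget = inference.edges_per_module * len(module_cols)
        method_edges = {m: grn.binarize(s, budget) for m, s in scores.items()}
        edges = grn.consensus(method_edges, inference.consensus_threshold)
        io_formats.write_edge_list(
            [(e.tf, e.module, e.support, e.methods) for e in edges],
            out / "network.tsv",
        )
        manifest["stages"]["consensus"] = {"edges": len(edges)}

        # ---- expand
        current = "expand"
        tf_gene_edges = validation.expand_edges(edges, module_gene_sets)
        manifest["stages"]["expand"] = {
            "tf_gene_edges": len(tf_gene_edges),
            "regulators": len({e.tf_gene for e in tf_gene_edges}),
            "targets": len({e.target_gene for e in tf_gene_edges}),
        }

        # ---- validate
        current = "validate"
        hits = io_formats.read_tabular_hits(config.hits)
        hmap = validation.best_hits(hits, config.evalue_max)
        dap = io_formats.read_dap_edges(config.dap)
        motifs = io_formats.read_motif_matches(config.motifs)
        annotated, summary = validation.dap_overlap(tf_gene_edges, hmap, dap)
        annotated = validation.annotate_motif_support(annotated, motifs)
        pd.DataFrame(
            [
                {
                    "tf": e.tf_gene,
                    "target": e.target_gene,
                    "module": e.module,
                    "support": e.support,
                    "dap_mapped": int(e.dap_mapped),
                    "dap_supported": int(e.dap_supported),
                    "motif_supported": int(e.motif_supported),
                }
                for e in annotated
            ],
            columns=[
                "tf",
                "target",
                "module",
                "support",
                "dap_mapped",
                "dap_supported",
                "motif_supported",
            ],
        ).to_csv(out / "validated.tsv", sep="\t", index=False)
        _write_json(summary, out / "validation_summary.json")
        manifest["stages"]["validate"] = summary
    except Exception as exc:
        manifest["failed_stage"] = current
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        _write_json(manifest, out / "manifest.json")
        raise
    manifest["completed"] = list(STAGES)
    _write_json(manifest, out / "manifest.json")
    return manifest
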