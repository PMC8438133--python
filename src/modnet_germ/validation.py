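"""Expansion of TF-module edges to TF-gene edges and cross-species checks.

Consensus TF -> module edges are expanded to one TF -> gene edge per module
member (self-edges excluded), then validated two ways: by mapping both
endpoints to their best cross-species homologs (top hit by bitscore at
E <= 1e-5) and looking the pair up in a published DAP-seq interaction set,
and by checking the regulator against precomputed motif matches for the
module.  Edges with unmapped endpoints are reported as unmapped, never
silently dropped, so validation rates stay interpretable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

from .grn import ConsensusEdge
from .io_formats import AlignmentHit

DEFAULT_EVALUE_MAX = 1e-5


@dataclass(frozen=True)
class TFGeneEdge:
    tf_gene: str
    target_gene: str
    module: str
    support: int
    dap_supported: bool = False
    dap_mapped: bool = False
    motif_supported: bool = False

    def __post_init__(self) -> None:
        if self.tf_gene == self.target_gene:
            raise ValueError("self-edges are excluded")


def expand_edges(
    consensus_edges: Sequence[ConsensusEdge],
    module_genes: Mapping[str, Iterable[str]],
) -> list[TFGeneEdge]:
    """One TF -> gene edge per (consensus edge, module member).

    Self-edges (the TF regulating itself through module averaging) are
    excluded; duplicates are removed.  Unknown modules raise ``KeyError``.
    """
    seen: set[tuple[str, str, str]] = set()
    out: list[TFGeneEdge] = []
    for edge in consensus_edges:
        if edge.module not in module_genes:
            raise KeyError(f"unknown module {edge.module!r}")
        for gene in module_genes[edge.module]:
            if gene == edge.tf:
                continue
            key = (edge.tf, gene, edge.module)
            if key in seen:
                continue
            seen.add(key)
            out.append(
                TFGeneEdge(
                    tf_gene=edge.tf,
                    target_gene=gene,
                    module=edge.module,
                    support=edge.support,
                )
            )
    return out


def best_hits(
    hits: Sequence[AlignmentHit], evalue_max: float = DEFAULT_EVALUE_MAX
) -> dict[str, tuple[str, float, float]]:
    """Best homolog per query: max bitscore, then min E-value, then
    lexicographically smallest subject; queries whose best hit has
    E-value above ``evalue_max`` are absent from the map.

    Returns query -> (subject, evalue, bitscore).
    """
    if evalue_max <= 0:
        raise ValueError("evalue_max must be positive")
    best: dict[str, AlignmentHit] = {}
    for hit in hits:
        cur = best.get(hit.query)
        if cur is None:
            best[hit.query] = hit
            continue
        key = (-hit.bitscore, hit.evalue, hit.subject)
        cur_key = (-cur.bitscore, cur.evalue, cur.subject)
        if key < cur_key:
            best[hit.query] = hit
    return {
        q: (h.subject, h.evalue, h.bitscore)
        for q, h in best.items()
        if h.evalue <= evalue_max
    }


def dap_overlap(
    edges: Sequence[TFGeneEdge],
    homology_map: Mapping[str, tuple[str, float, float]],
    dap_edges: set[tuple[str, str]],
) -> tuple[list[TFGeneEdge], dict[str, float]]:
    """Annotate edges with DAP-seq support through the homology map.

    An edge is supported iff both endpoints map and the mapped pair is in
    the DAP set.  The summary reports mapped / unmapped counts, supported
    count, and the support rate among mapped edges.
    """
    annotated = []
    mapped = unmapped = supported = 0
    for edge in edges:
        tf_hit = homology_map.get(edge.tf_gene)
        target_hit = homology_map.get(edge.target_gene)
        if tf_hit is None or target_hit is None:
            unmapped += 1
            annotated.append(replace(edge, dap_mapped=False, dap_supported=False))
            continue
        mapped += 1
        hit = (tf_hit[0], target_hit[0]) in dap_edges
        supported += hit
        annotated.append(replace(edge, dap_mapped=True, dap_supported=hit))
    summary = {
        "mapped": mapped,
        "unmapped": unmapped,
        "supported": supported,
        "support_rate_mapped": supported / mapped if mapped else 0.0,
    }
    return annotated, summary


def motif_overlap(
    consensus_edges: Sequence[ConsensusEdge],
    motif_matches: set[tuple[str, str]],
) -> list[tuple[ConsensusEdge, bool]]:
    """Mark each consensus edge supported iff (module, tf) is motif-matched."""
    return [
        (edge, (edge.module, edge.tf) in motif_matches) for edge in consensus_edges
    ]


def annotate_motif_support(
    edges: Sequence[TFGeneEdge], motif_matches: set[tuple[str, str]]
) -> list[TFGeneEdge]:
    """Propagate motif support of (module, tf) pairs to expanded edges."""
    return [
        replace(e, motif_supported=(e.module, e.tf_gene) in motif_matches)
        for e in edges
    ]
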