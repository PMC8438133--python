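"""Per-module GO-term over-representation by the hypergeometric tail test.

The one-sided Fisher exact test for a 2x2 over-representation table is the
upper tail of the hypergeometric distribution: with N background genes, K
of them annotated to a term, and a module of n genes containing k annotated
members,

    p = sum_{i=k}^{min(n, K)} C(K, i) C(N-K, n-i) / C(N, n).

The background is every gene carrying at least one annotation in the
supplied table; Benjamini-Hochberg adjustment is applied within each
module across its tested terms (terms with k = 0 are not tested).
"""

from __future__ import annotations

from typing import Iterable, Mapping

import pandas as pd
from scipy.stats import hypergeom

from .diffexpr import bh_adjust

#: FDR threshold for calling a term enriched.
FDR_MAX = 0.05


def hypergeom_upper_tail(k: int, n: int, K: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n)."""
    if not (0 <= k <= min(n, K)):
        raise ValueError(f"need 0 <= k <= min(n, K); got k={k}, n={n}, K={K}")
    return float(hypergeom.sf(k - 1, N, K, n))


def fisher_enrich(
    module_genes: Iterable[str],
    go_map: Mapping[str, set[str]],
    background_genes: Iterable[str] | None = None,
    fdr_max: float = FDR_MAX,
) -> pd.DataFrame:
    """Over-representation test of every term present in a module.

    ``background_genes`` defaults to all annotated genes in ``go_map``;
    when given, it is intersected with the annotated universe.  Module
    genes outside the background are ignored.  Returns a DataFrame with
    columns term, k, n, K, N, p, padj, enriched, sorted by (padj, term).
    """
    annotated = {g for g, terms in go_map.items() if terms}
    if background_genes is None:
        background = annotated
    else:
        background = set(background_genes) & annotated
    if not background:
        raise ValueError("empty annotated background")

    module = set(module_genes) & background
    n = len(module)
    N = len(background)

    term_module: dict[str, int] = {}
    for g in module:
        for t in go_map.get(g, ()):
            term_module[t] = term_module.get(t, 0) + 1
    term_background: dict[str, int] = {}
    for g in background:
        for t in go_map.get(g, ()):
            term_background[t] = term_background.get(t, 0) + 1

    rows = []
    for term in sorted(term_module):
        k = term_module[term]
        K = term_background[term]
        rows.append(
            {
                "term": term,
                "k": k,
                "n": n,
                "K": K,
                "N": N,
                "p": hypergeom_upper_tail(k, n, K, N),
            }
        )
    df = pd.DataFrame(rows, columns=["term", "k", "n", "K", "N", "p"])
    if len(df):
        df["padj"] = bh_adjust(df["p"].to_numpy())
        df["enriched"] = df["padj"] < fdr_max
        df = df.sort_values(["padj", "term"], kind="mergesort").reset_index(drop=True)
    else:
        df["padj"] = pd.Series(dtype=float)
        df["enriched"] = pd.Series(dtype=bool)
    return df


def enrich_all_modules(
    module_genes: Mapping[str, Iterable[str]],
    go_map: Mapping[str, set[str]],
    background_genes: Iterable[str] | None = None,
    fdr_max: float = FDR_MAX,
) -> pd.DataFrame:
    """Run :func:`fisher_enrich` per module and stack the results."""
    frames = []
    background = None if background_genes is None else list(background_genes)
    for module in sorted(module_genes):
        df = fisher_enrich(module_genes[module], go_map, background, fdr_max)
        df.insert(0, "module", module)
        frames.append(df)
    if not frames:
        return pd.DataFrame(
            columns=["module", "term", "k", "n", "K", "N", "p", "padj", "enriched"]
        )
    return pd.concat(frames, ignore_index=True)
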