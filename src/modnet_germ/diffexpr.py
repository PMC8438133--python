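"""Normalization, variance stabilization, and negative-binomial DE calling.

The differential-expression test is a deliberately simple negative-binomial
Wald test: median-of-ratios size factors, method-of-moments dispersion
pooled across replicate cells, a delta-method standard error on the log2
fold change with pseudocount 1, and Benjamini-Hochberg adjustment within
each comparison.  It preserves the semantics of the published DEG filters
(adjusted p < 0.01, |log2 FC| > 1, base mean > 10) without any dispersion
shrinkage, GLM machinery, or outlier handling.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import CountMatrix, DegenerateInputError

log = logging.getLogger(__name__)

#: Joint DEG filters, strict inequalities.
PADJ_MAX = 0.01
LFC_MIN = 1.0
BASEMEAN_MIN = 10.0

#: Floor for per-gene dispersion estimates.
ALPHA_MIN = 1e-8

#: Pseudocount added to group means in the fold-change and its SE.
PSEUDOCOUNT = 1.0

#: Comparisons each subset must supply to the intersection rule.
COMPARISONS_PER_SUBSET = {"Mips": 1, "MRP": 3, "MipsMRP": 1}


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values.

    adj_(i) = min_{j >= i} ( p_(j) * m / j ), capped at 1.
    """
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


@dataclass(frozen=True)
class SizeFactors:
    """Per-sample median-of-ratios normalization constants."""

    s: pd.Series  # indexed by sample id, all > 0

    def __post_init__(self) -> None:
        if (self.s <= 0).any():
            raise ValueError("size factors must be positive")


@dataclass(frozen=True)
class DispersionEstimate:
    """Per-gene and common NB dispersion (Var = mu + alpha * mu^2)."""

    per_gene: pd.Series
    common: float
    alpha_min: float = ALPHA_MIN


def size_factors(cm: CountMatrix, allow_fallback: bool = True) -> SizeFactors:
    """Median-of-ratios size factors.

    s_j = median over genes g (positive in every sample) of
    counts[g, j] / geometric_mean_over_samples(counts[g, .]).

    When no gene is positive everywhere, geometric means fall back to the
    mean log of positive entries only (logged), unless ``allow_fallback``
    is False, in which case a degenerate-input error is raised.
    """
    counts = cm.counts.to_numpy(dtype=float)
    all_positive = (counts > 0).all(axis=1)
    if all_positive.any():
        sub = counts[all_positive]
        log_geomean = np.log(sub).mean(axis=1)
        ratios = np.log(sub) - log_geomean[:, None]
    else:
        if not allow_fallback:
            raise DegenerateInputError(
                "no gene has positive counts in every sample"
            )
        log.warning(
            "no all-positive gene; geometric means use positive entries only"
        )
        with np.errstate(divide="ignore"):
            logs = np.where(counts > 0, np.log(counts), np.nan)
        keep = (counts > 0).any(axis=1)
        if not keep.any():
            raise DegenerateInputError("count matrix is all zero")
        logs = logs[keep]
        log_geomean = np.nanmean(logs, axis=1)
        ratios = logs - log_geomean[:, None]
    s = np.exp(np.nanmedian(ratios, axis=0))
    return SizeFactors(s=pd.Series(s, index=cm.counts.columns, name="size_factor"))


def normalized_counts(cm: CountMatrix, sf: SizeFactors) -> pd.DataFrame:
    return cm.counts.div(sf.s, axis=1)


def estimate_dispersion(cm: CountMatrix, sf: SizeFactors) -> DispersionEstimate:
    """Method-of-moments dispersion pooled across replicate cells.

    Per gene, alpha_c = (var_c - mean_c) / mean_c^2 is computed within each
    (line, stage) cell having >= 2 replicates and pooled with weights equal
    to the cell's degrees of freedom; the result is floored at
    ``ALPHA_MIN``.  The common dispersion is the median per-gene value.
    """
    q = normalized_counts(cm, sf)
    cells: dict[tuple[str, int], list[str]] = {}
    for s in cm.samples:
        cells.setdefault((s.line, s.stage), []).append(s.sample_id)
    num = np.zeros(len(q))
    total_df = 0.0
    any_cell = False
    for members in cells.values():
        n = len(members)
        if n < 2:
            continue
        any_cell = True
        sub = q[members].to_numpy()
        mean = sub.mean(axis=1)
        var = sub.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = np.where(mean > 0, (var - mean) / np.maximum(mean, 1e-300) ** 2, 0.0)
        num += (n - 1) * a
        total_df += n - 1
    if not any_cell:
        raise DegenerateInputError("no (line, stage) cell has >= 2 replicates")
    per_gene = np.maximum(num / total_df, ALPHA_MIN)
    per_gene = pd.Series(per_gene, index=q.index, name="alpha")
    return DispersionEstimate(per_gene=per_gene, common=float(per_gene.median()))


def vst(cm: CountMatrix, sf: SizeFactors, disp: DispersionEstimate) -> pd.DataFrame:
    """Variance-stabilizing transform of normalized counts.

    v(q) = (2 / sqrt(alpha)) * asinh(sqrt(alpha * q)) with the common
    dispersion alpha; strictly increasing with v(0) = 0 and v ~ 2 sqrt(q)
    as alpha -> 0.
    """
    alpha = disp.common
    if alpha <= 0:
        raise ValueError("common dispersion must be positive")
    q = normalized_counts(cm, sf).to_numpy()
    v = (2.0 / np.sqrt(alpha)) * np.arcsinh(np.sqrt(alpha * q))
    return pd.DataFrame(v, index=cm.counts.index, columns=cm.counts.columns)


def nb_wald_test(
    cm: CountMatrix,
    sf: SizeFactors,
    disp: DispersionEstimate,
    comparison: tuple[str, str],
    stage: int,
    padj_max: float = PADJ_MAX,
    lfc_min: float = LFC_MIN,
    basemean_min: float = BASEMEAN_MIN,
) -> pd.DataFrame:
    """Wald test of an (lpa line, normal line) contrast at one stage.

    Per gene, with normalized group means m_A (lpa), m_B (normal),
    pseudocount c = 1 and per-gene dispersion a:

        lfc = log2((m_A + c) / (m_B + c))
        se  = sqrt( (1/n_A)(1/(m_A + c) + a) + (1/n_B)(1/(m_B + c) + a) ) / ln 2
        z   = lfc / se,   p = two-sided normal tail,  padj = BH

    Returns a DataFrame indexed by gene with columns ``baseMean``, ``lfc``,
    ``se``, ``stat``, ``p``, ``padj``, ``is_deg`` and attrs recording the
    comparison and stage.
    """
    lpa_line, normal_line = comparison
    stages = {s.stage for s in cm.samples}
    if stage not in stages:
        raise ValueError(f"stage {stage} absent from sample metadata")
    group_a = [s.sample_id for s in cm.samples if s.line == lpa_line and s.stage == stage]
    group_b = [
        s.sample_id for s in cm.samples if s.line == normal_line and s.stage == stage
    ]
    if len(group_a) < 2 or len(group_b) < 2:
        raise DegenerateInputError(
            f"comparison {comparison} at stage {stage} needs >= 2 replicates per line"
        )
    q = normalized_counts(cm, sf)
    qa, qb = q[group_a].to_numpy(), q[group_b].to_numpy()
    mu_a, mu_b = qa.mean(axis=1), qb.mean(axis=1)
    n_a, n_b = qa.shape[1], qb.shape[1]
    alpha = disp.per_gene.to_numpy()

    c = PSEUDOCOUNT
    lfc = np.log2((mu_a + c) / (mu_b + c))
    se = (
        np.sqrt((1.0 / n_a) * (1.0 / (mu_a + c) + alpha) + (1.0 / n_b) * (1.0 / (mu_b + c) + alpha))
        / np.log(2.0)
    )
    z = lfc / se
    p = np.minimum(2.0 * stats.norm.sf(np.abs(z)), 1.0)
    padj = bh_adjust(p)
    base_mean = np.concatenate([qa, qb], axis=1).mean(axis=1)
    is_deg = (padj < padj_max) & (np.abs(lfc) > lfc_min) & (base_mean > basemean_min)

    out = pd.DataFrame(
        {
            "baseMean": base_mean,
            "lfc": lfc,
            "se": se,
            "stat": z,
            "p": p,
            "padj": padj,
            "is_deg": is_deg,
        },
        index=q.index,
    )
    out.attrs["comparison"] = comparison
    out.attrs["stage"] = stage
    return out


def call_degs_subset(
    records: list[pd.DataFrame], subset: str
) -> dict[int, set[str]]:
    """Combine per-comparison DE tables into per-stage DEG sets.

    Mips and MipsMRP supply one comparison; MRP supplies three, and a gene
    is a DEG at a stage only if it passes the filters in *every* comparison
    at that stage (the near-isogenic intersection rule).
    """
    expected = COMPARISONS_PER_SUBSET[subset]
    by_stage: dict[int, list[pd.DataFrame]] = {}
    for rec in records:
        by_stage.setdefault(rec.attrs["stage"], []).append(rec)
    out: dict[int, set[str]] = {}
    for stage, recs in sorted(by_stage.items()):
        n_comp = len({r.attrs["comparison"] for r in recs})
        if n_comp != expected or len(recs) != expected:
            raise ValueError(
                f"subset {subset} expects {expected} comparison(s) per stage, "
                f"got {len(recs)} at stage {stage}"
            )
        sets = [set(r.index[r["is_deg"]]) for r in recs]
        out[stage] = set.intersection(*sets)
    return out


VENN_REGIONS = ("only_1", "only_2", "only_3", "s1_s2", "s2_s3", "s1_s3", "all")


def venn_partition(deg_by_stage: dict[int, set[str]]) -> dict[str, int]:
    """Counts of the 7 disjoint regions of the three per-stage DEG sets."""
    for stage in (1, 2, 3):
        if stage not in deg_by_stage:
            raise ValueError(f"stage {stage} missing from DEG sets")
    a, b, c = (deg_by_stage[s] for s in (1, 2, 3))
    return {
        "only_1": len(a - b - c),
        "only_2": len(b - a - c),
        "only_3": len(c - a - b),
        "s1_s2": len((a & b) - c),
        "s2_s3": len((b & c) - a),
        "s1_s3": len((a & c) - b),
        "all": len(a & b & c),
    }
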