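"""Module-network ensemble GRN inference with five algorithms and voting.

Candidate regulators (differentially expressed TFs) and module-mean
profiles share a conditions x (TFs + modules) matrix.  Five inference
methods score every TF -> module edge:

- ``aracne``: Gaussian-copula mutual information with data-processing-
  inequality pruning over the full TF + module node set,
- ``clr``: background-corrected MI z-scores combined over the TF row and
  module column of the bipartite MI matrix,
- ``lars``: least-angle-regression entry order of TFs into each module's
  regression path,
- ``pcor``: shrinkage partial correlation from the ridge-shrunk
  correlation matrix (usable when variables outnumber conditions),
- ``rf``: random-forest regression importance of TFs for each module.

Each method's continuous scores are binarized to its top ``d * M`` edges
(d = edges-per-module budget, M = module count), and edges detected by at
least ``kmin`` of the five methods (default 4) form the consensus.

With only 6-12 replicate-averaged conditions per subset, the MI estimator
is the rank-based Gaussian-copula closed form; histogram or k-NN
estimators are hopeless at these sample sizes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestRegressor
from sklearn.linear_model import lars_path

from .io_formats import METHOD_ORDER, DegenerateInputError, SampleMeta

log = logging.getLogger(__name__)

RHO_CAP = 0.9999


@dataclass(frozen=True)
class InferenceConfig:
    """Tunable parameters of the five-method ensemble."""

    dpi_tolerance: float = 0.1  # ARACNE DPI slack, in [0, 1)
    edges_per_module: int = 10  # per-method budget E = d * M
    consensus_threshold: int = 4  # methods required to keep an edge
    lars_max_steps: int = 3  # path steps scored; small because n is small
    rf_trees: int = 1000
    rf_seed: int = 0
    shrinkage_mode: str = "analytic"  # or "fixed"
    shrinkage_lambda: float = 0.1  # used when shrinkage_mode == "fixed"

    def __post_init__(self) -> None:
        if not 0.0 <= self.dpi_tolerance < 1.0:
            raise ValueError("dpi_tolerance must be in [0, 1)")
        if not 1 <= self.consensus_threshold <= 5:
            raise ValueError("consensus_threshold must be in 1..5")
        if self.edges_per_module < 1:
            raise ValueError("edges_per_module must be >= 1")
        if self.shrinkage_mode not in ("analytic", "fixed"):
            raise ValueError("shrinkage_mode must be 'analytic' or 'fixed'")


@dataclass(frozen=True)
class ConsensusEdge:
    tf: str
    module: str
    support: int
    methods: frozenset[str]

    def __post_init__(self) -> None:
        if self.support != len(self.methods):
            raise ValueError("support must equal |methods|")


def _copula_rho(x: np.ndarray) -> np.ndarray:
    """Pairwise Gaussian-copula correlations of the columns of x.

    Spearman correlation of ranks mapped to the equivalent Pearson
    correlation of a bivariate normal via rho = 2 sin(pi rho_s / 6),
    capped at +/- 0.9999.
    """
    ranks = np.column_stack([rankdata(col) for col in x.T])
    sd = ranks.std(axis=0)
    if (sd == 0).any():
        raise ValueError("zero-variance column in MI computation")
    rho_s = np.corrcoef(ranks, rowvar=False)
    rho = 2.0 * np.sin(np.pi * rho_s / 6.0)
    np.fill_diagonal(rho, 1.0)
    return np.clip(rho, -RHO_CAP, RHO_CAP)


def gaussian_mi(x: np.ndarray, y: np.ndarray) -> float:
    """Mutual information (nats) of two condition vectors.

    MI = -1/2 ln(1 - rho^2) with rho the Gaussian-copula correlation.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3 or y.size != x.size:
        raise ValueError("vectors must share length n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("non-finite values")
    rho = _copula_rho(np.column_stack([x, y]))[0, 1]
    return float(-0.5 * np.log1p(-rho * rho))


def _mi_matrix(matrix: pd.DataFrame) -> pd.DataFrame:
    rho = _copula_rho(matrix.to_numpy(dtype=float))
    mi = -0.5 * np.log1p(-rho * rho)
    np.fill_diagonal(mi, 0.0)
    return pd.DataFrame(mi, index=matrix.columns, columns=matrix.columns)


def dpi_prune(mi: pd.DataFrame, tolerance: float) -> pd.DataFrame:
    """Data-processing-inequality pruning of an MI matrix.

    Edge (i, j) is removed when some third node k satisfies
    MI(i,j) < (1 - tolerance) * min(MI(i,k), MI(j,k)); strict inequality,
    so exactly tied triangles lose no edge.
    """
    m = mi.to_numpy(dtype=float)
    n = m.shape[0]
    keep = np.ones((n, n), dtype=bool)
    for i in range(n):
        for j in range(i + 1, n):
            bound = np.minimum(m[i], m[j])
            bound[i] = bound[j] = -np.inf
            if m[i, j] < (1.0 - tolerance) * bound.max():
                keep[i, j] = keep[j, i] = False
    out = np.where(keep, m, 0.0)
    return pd.DataFrame(out, index=mi.index, columns=mi.columns)


def aracne_scores(
    matrix: pd.DataFrame,
    tf_cols: Sequence[str],
    module_cols: Sequence[str],
    tolerance: float = 0.1,
) -> pd.DataFrame:
    """ARACNE scores: pairwise MI with DPI pruning over all nodes.

    DPI runs on the full TF + module node set; only TF x module entries
    are reported (pruned pairs score 0).
    """
    nodes = list(tf_cols) + list(module_cols)
    mi = _mi_matrix(matrix[nodes])
    pruned = dpi_prune(mi, tolerance)
    return pruned.loc[list(tf_cols), list(module_cols)]


def clr_from_mi(mi: pd.DataFrame) -> pd.DataFrame:
    """CLR combination of a bipartite (TF x module) MI matrix."""
    m = mi.to_numpy(dtype=float)
    row_sd = m.std(axis=1, ddof=0)
    col_sd = m.std(axis=0, ddof=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        z_row = np.where(
            row_sd[:, None] > 0, (m - m.mean(axis=1)[:, None]) / row_sd[:, None], 0.0
        )
        z_col = np.where(
            col_sd[None, :] > 0, (m - m.mean(axis=0)[None, :]) / col_sd[None, :], 0.0
        )
    score = np.sqrt(np.maximum(z_row, 0.0) ** 2 + np.maximum(z_col, 0.0) ** 2)
    return pd.DataFrame(score, index=mi.index, columns=mi.columns)


def clr_scores(
    matrix: pd.DataFrame, tf_cols: Sequence[str], module_cols: Sequence[str]
) -> pd.DataFrame:
    """Context-likelihood-of-relatedness scores on the bipartite MI matrix."""
    if len(tf_cols) < 2 or len(module_cols) < 2:
        raise ValueError("CLR needs >= 2 TFs and >= 2 modules")
    nodes = list(tf_cols) + list(module_cols)
    mi = _mi_matrix(matrix[nodes]).loc[list(tf_cols), list(module_cols)]
    return clr_from_mi(mi)


def lars_scores(
    matrix: pd.DataFrame,
    tf_cols: Sequence[str],
    module_cols: Sequence[str],
    max_steps: int = 3,
) -> pd.DataFrame:
    """LARS path-entry scores: a TF entering at step t gets (T - t + 1) / T.

    TFs never entering within T steps score 0.  T may not exceed
    n_conditions - 1.
    """
    n = matrix.shape[0]
    if max_steps > n - 1:
        raise ValueError(f"max_steps={max_steps} exceeds n_conditions - 1 = {n - 1}")
    X = matrix[list(tf_cols)].to_numpy(dtype=float)
    X = (X - X.mean(axis=0)) / np.where(X.std(axis=0) > 0, X.std(axis=0), 1.0)
    scores = pd.DataFrame(0.0, index=list(tf_cols), columns=list(module_cols))
    for mod in module_cols:
        y = matrix[mod].to_numpy(dtype=float)
        y = y - y.mean()
        _, active, _ = lars_path(X, y, method="lar", max_iter=max_steps)
        for t, idx in enumerate(active[:max_steps], start=1):
            scores.iloc[int(idx), scores.columns.get_loc(mod)] = (
                max_steps - t + 1
            ) / max_steps
    return scores


def _analytic_lambda(x: np.ndarray) -> float:
    """Shrinkage intensity for correlation matrices (variance-of-entries
    estimator), clipped to [0.01, 1]."""
    n, p = x.shape
    xs = (x - x.mean(axis=0)) / x.std(axis=0, ddof=1)
    # w[k, i, j] = xs[k, i] * xs[k, j]; var of r_ij over samples
    r = xs.T @ xs / (n - 1)
    w_mean = r * (n - 1) / n
    var_sum = 0.0
    r2_sum = 0.0
    for i in range(p):
        wi = xs[:, i, None] * xs
        var_r = (n / (n - 1.0) ** 3) * ((wi - w_mean[i]) ** 2).sum(axis=0)
        var_sum += var_r.sum() - var_r[i]
        r2_sum += (r[i] ** 2).sum() - r[i, i] ** 2
    if r2_sum <= 0:
        return 1.0
    return float(np.clip(var_sum / r2_sum, 0.01, 1.0))


def pcor_scores(
    matrix: pd.DataFrame,
    tf_cols: Sequence[str],
    module_cols: Sequence[str],
    shrinkage_mode: str = "analytic",
    shrinkage_lambda: float = 0.1,
) -> pd.DataFrame:
    """|Partial correlation| from the shrunk correlation matrix.

    R* = (1 - lambda) R + lambda I; score(tf, m) = |P_tm| / sqrt(P_tt P_mm)
    with P = (R*)^-1.
    """
    if matrix.shape[0] < 3:
        raise DegenerateInputError("partial correlation needs >= 3 conditions")
    nodes = list(tf_cols) + list(module_cols)
    x = matrix[nodes].to_numpy(dtype=float)
    r = np.corrcoef(x, rowvar=False)
    if shrinkage_mode == "analytic":
        lam = _analytic_lambda(x)
    else:
        lam = float(shrinkage_lambda)
    r_star = (1.0 - lam) * r + lam * np.eye(len(nodes))
    prec = np.linalg.inv(r_star)
    denom = np.sqrt(np.outer(np.diag(prec), np.diag(prec)))
    pcor = np.abs(prec / denom)
    df = pd.DataFrame(pcor, index=nodes, columns=nodes)
    return df.loc[list(tf_cols), list(module_cols)]


def rf_scores(
    matrix: pd.DataFrame,
    tf_cols: Sequence[str],
    module_cols: Sequence[str],
    trees: int = 1000,
    seed: int = 0,
) -> pd.DataFrame:
    """Random-forest importances of TFs for each module profile.

    Per module, a regression forest (sqrt-feature subsampling, bootstrap
    rows) is fit on the TF columns; the score is the normalized impurity
    reduction attributed to each TF, summing to 1 whenever any split was
    made.  Deterministic given the seed.
    """
    if matrix.shape[0] < 3:
        raise DegenerateInputError("random forest needs >= 3 conditions")
    X = matrix[list(tf_cols)].to_numpy(dtype=float)
    scores = pd.DataFrame(0.0, index=list(tf_cols), columns=list(module_cols))
    for i, mod in enumerate(module_cols):
        y = matrix[mod].to_numpy(dtype=float)
        forest = RandomForestRegressor(
            n_estimators=trees,
            max_features="sqrt",
            bootstrap=True,
            random_state=(seed + 7919 * i) % (2**31),
            n_jobs=1,
        )
        forest.fit(X, y)
        scores[mod] = forest.feature_importances_
    return scores


def binarize(scores: pd.DataFrame, budget: int) -> set[tuple[str, str]]:
    """Top-``budget`` edges by descending score; zero scores never kept.

    Ties at the boundary are broken by (tf, module) lexicographic order.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    entries = [
        (float(scores.at[tf, mod]), tf, mod)
        for tf in scores.index
        for mod in scores.columns
    ]
    entries.sort(key=lambda e: (-e[0], e[1], e[2]))
    return {(tf, mod) for score, tf, mod in entries[:budget] if score > 0}


def consensus(
    method_edges: Mapping[str, set[tuple[str, str]]], kmin: int = 4
) -> list[ConsensusEdge]:
    """Vote the five methods' binarized edge sets.

    Keeps edges detected by at least ``kmin`` methods, sorted by
    (-support, tf, module).
    """
    if set(method_edges) != set(METHOD_ORDER):
        raise ValueError(f"need exactly the method sets {METHOD_ORDER}")
    support: dict[tuple[str, str], set[str]] = {}
    for method in METHOD_ORDER:
        for edge in method_edges[method]:
            support.setdefault(edge, set()).add(method)
    out = [
        ConsensusEdge(tf=tf, module=mod, support=len(methods), methods=frozenset(methods))
        for (tf, mod), methods in support.items()
        if len(methods) >= kmin
    ]
    out.sort(key=lambda e: (-e.support, e.tf, e.module))
    return out


def build_regulator_matrix(
    vst_matrix: pd.DataFrame,
    samples: Sequence[SampleMeta],
    tf_list: Sequence[str],
    module_mean_profiles: pd.DataFrame,
    subset: str,
) -> tuple[pd.DataFrame, list[str], list[str]]:
    """Conditions x (TFs + modules) matrix for one subset.

    TF columns are replicate-averaged, z-scored profiles; module columns
    are the module-mean profiles (columns must match the subset's
    conditions).  Zero-variance columns are dropped with a warning.
    Returns (matrix, kept TF columns, kept module columns).
    """
    from .clustering import build_profiles

    tf_profiles = build_profiles(vst_matrix, samples, sorted(tf_list), subset, zscore=True)
    conditions = list(tf_profiles.columns)
    if len(conditions) < 3:
        raise DegenerateInputError(f"subset {subset!r} has < 3 conditions")
    if set(module_mean_profiles.columns) != set(conditions):
        raise ValueError("module means and TF profiles disagree on conditions")

    def _module_key(label: str) -> tuple:
        tail = label[1:] if label.startswith("M") else label
        return (0, int(tail)) if tail.isdigit() else (1, label)

    module_order = sorted(module_mean_profiles.index, key=_module_key)
    mat = pd.concat(
        [tf_profiles.T[sorted(tf_list)], module_mean_profiles.loc[module_order, conditions].T],
        axis=1,
    )
    tf_cols, module_cols = [], []
    for col in mat.columns:
        if mat[col].std(ddof=0) == 0:
            log.warning("dropping zero-variance column %r", col)
            mat = mat.drop(columns=[col])
        elif col in module_order:
            module_cols.append(col)
        else:
            tf_cols.append(col)
    return mat, tf_cols, module_cols


def score_all_methods(
    matrix: pd.DataFrame,
    tf_cols: Sequence[str],
    module_cols: Sequence[str],
    config: InferenceConfig = InferenceConfig(),
) -> dict[str, pd.DataFrame]:
    """Run the five scorers on a prepared regulator matrix."""
    return {
        "aracne": aracne_scores(matrix, tf_cols, module_cols, config.dpi_tolerance),
        "clr": clr_scores(matrix, tf_cols, module_cols),
        "lars": lars_scores(
            matrix, tf_cols, module_cols, min(config.lars_max_steps, matrix.shape[0] - 1)
        ),
        "pcor": pcor_scores(
            matrix, tf_cols, module_cols, config.shrinkage_mode, config.shrinkage_lambda
        ),
        "rf": rf_scores(matrix, tf_cols, module_cols, config.rf_trees, config.rf_seed),
    }


def infer_consensus(
    matrix: pd.DataFrame,
    tf_cols: Sequence[str],
    module_cols: Sequence[str],
    config: InferenceConfig = InferenceConfig(),
) -> tuple[list[ConsensusEdge], dict[str, set[tuple[str, str]]]]:
    """Score, binarize (budget = edges_per_module * M) and vote."""
    scores = score_all_methods(matrix, tf_cols, module_cols, config)
    budget = config.edges_per_module * len(module_cols)
    method_edges = {m: binarize(s, budget) for m, s in scores.items()}
    edges = consensus(method_edges, config.consensus_threshold)
    return edges, method_edges
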