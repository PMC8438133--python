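"""Gaussian finite-mixture co-expression modules with BIC model selection.

DEG expression is replicate-averaged into condition profiles (optionally
z-scored per gene), then clustered by EM over six covariance families --
spherical/diagonal/full, each with shared or per-component parameters --
sweeping the component count and keeping the fit that maximizes
BIC = 2 loglik - nu ln(n).  Genes are hard-assigned to their maximum
responsibility component, because the downstream module-network stage
needs disjoint modules.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp
from sklearn.cluster import KMeans

from .io_formats import SampleMeta

log = logging.getLogger(__name__)

FAMILIES = (
    "spherical_equal",
    "spherical_varying",
    "diagonal_equal",
    "diagonal_varying",
    "full_shared",
    "full_varying",
)

RIDGE = 1e-6
EM_TOL = 1e-6
EM_MAX_ITER = 500
SD_FLOOR = 1e-12


class ConvergenceError(RuntimeError):
    """Every mixture fit in a sweep failed."""


def n_mixture_params(family: str, K: int, d: int) -> int:
    """Free-parameter count nu of a K-component, d-dimensional mixture."""
    cov = {
        "spherical_equal": 1,
        "spherical_varying": K,
        "diagonal_equal": d,
        "diagonal_varying": K * d,
        "full_shared": d * (d + 1) // 2,
        "full_varying": K * d * (d + 1) // 2,
    }[family]
    return K * d + (K - 1) + cov


@dataclass
class MixtureFit:
    """One converged EM fit; covariances are stored as full K x d x d."""

    K: int
    family: str
    weights: np.ndarray
    means: np.ndarray
    covariances: np.ndarray
    loglik: float
    n_params: int
    bic: float
    responsibilities: np.ndarray
    loglik_trace: list[float] = field(default_factory=list)
    converged: bool = True


def _log_gaussian(X: np.ndarray, mean: np.ndarray, cov: np.ndarray) -> np.ndarray:
    from scipy.linalg import solve_triangular

    d = X.shape[1]
    chol = np.linalg.cholesky(cov)
    diff = X - mean
    sol = solve_triangular(chol, diff.T, lower=True)
    maha = (sol**2).sum(axis=0)
    logdet = 2.0 * np.log(np.diag(chol)).sum()
    return -0.5 * (d * np.log(2.0 * np.pi) + logdet + maha)


def _m_step_covariances(
    X: np.ndarray, resp: np.ndarray, means: np.ndarray, family: str
) -> np.ndarray:
    n, d = X.shape
    K = means.shape[0]
    nk = np.maximum(resp.sum(axis=0), 10 * np.finfo(float).tiny)
    covs = np.empty((K, d, d))
    if family in ("full_varying", "full_shared"):
        for k in range(K):
            diff = X - means[k]
            covs[k] = (resp[:, k, None] * diff).T @ diff / nk[k]
        if family == "full_shared":
            pooled = np.einsum("k,kij->ij", nk / n, covs)
            covs[:] = pooled
    else:
        variances = np.empty((K, d))
        for k in range(K):
            diff = X - means[k]
            variances[k] = (resp[:, k] * (diff**2).T).sum(axis=1) / nk[k]
        if family == "spherical_varying":
            variances = np.repeat(variances.mean(axis=1, keepdims=True), d, axis=1)
        elif family == "diagonal_equal":
            pooled = (nk / n) @ variances
            variances = np.tile(pooled, (K, 1))
        elif family == "spherical_equal":
            pooled = float((nk / n) @ variances.mean(axis=1))
            variances = np.full((K, d), pooled)
        for k in range(K):
            covs[k] = np.diag(variances[k])
    covs += RIDGE * np.eye(d)[None, :, :]
    return covs


def fit_gmm(
    profiles: pd.DataFrame | np.ndarray,
    K: int,
    family: str,
    seed: int = 0,
) -> MixtureFit:
    """EM fit of a K-component Gaussian mixture of one covariance family.

    Initialization is a seeded k-means partition; iteration stops when the
    relative log-likelihood change falls below 1e-6 or after 500 rounds.
    A ridge of 1e-6 is added to every covariance diagonal.  The
    log-likelihood trace is monotone nondecreasing and stored on the fit.
    """
    X = np.asarray(profiles, dtype=float)
    n, d = X.shape
    if family not in FAMILIES:
        raise ValueError(f"unknown covariance family {family!r}")
    if K < 1:
        raise ValueError("K must be >= 1")
    if K >= n:
        raise ValueError(f"K={K} must be < n_genes={n}")

    if K == 1:
        labels = np.zeros(n, dtype=int)
    else:
        km = KMeans(n_clusters=K, n_init=1, random_state=seed % (2**32))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            labels = km.fit_predict(X)
    resp = np.zeros((n, K))
    resp[np.arange(n), labels] = 1.0

    loglik = -np.inf
    trace: list[float] = []
    converged = False
    for _ in range(EM_MAX_ITER):
        # M-step
        nk = np.maximum(resp.sum(axis=0), 10 * np.finfo(float).tiny)
        weights = nk / n
        means = (resp.T @ X) / nk[:, None]
        covs = _m_step_covariances(X, resp, means, family)
        # E-step
        log_comp = np.column_stack(
            [_log_gaussian(X, means[k], covs[k]) for k in range(K)]
        )
        weighted = log_comp + np.log(np.maximum(weights, 1e-300))
        new_loglik = float(logsumexp(weighted, axis=1).sum())
        resp = np.exp(weighted - logsumexp(weighted, axis=1)[:, None])
        trace.append(new_loglik)
        if np.isfinite(loglik) and abs(new_loglik - loglik) <= EM_TOL * abs(loglik):
            loglik = new_loglik
            converged = True
            break
        loglik = new_loglik

    nu = n_mixture_params(family, K, d)
    bic = 2.0 * loglik - nu * np.log(n)
    return MixtureFit(
        K=K,
        family=family,
        weights=weights,
        means=means,
        covariances=covs,
        loglik=loglik,
        n_params=nu,
        bic=bic,
        responsibilities=resp,
        loglik_trace=trace,
        converged=converged,
    )


@dataclass
class ModuleAssignment:
    """Hard module assignment plus the BIC sweep that selected it."""

    module_of: dict[str, int]  # gene -> module id, 1..K
    fit: MixtureFit
    sweep: pd.DataFrame  # columns: K, family, loglik, n_params, bic

    @property
    def n_modules(self) -> int:
        return self.fit.K

    def module_genes(self, module: int) -> list[str]:
        return [g for g, m in self.module_of.items() if m == module]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": list(self.module_of), "module": list(self.module_of.values())}
        )


def _pick_best(sweep: pd.DataFrame) -> int:
    """Index of the winning sweep row: max BIC, ties to smaller K, then
    family order as listed in FAMILIES."""
    fam_rank = {f: i for i, f in enumerate(FAMILIES)}
    best = None
    best_key = None
    for idx, row in sweep.iterrows():
        key = (-row["bic"], row["K"], fam_rank[row["family"]])
        if best_key is None or key < best_key:
            best, best_key = idx, key
    return best


def select_model(
    profiles: pd.DataFrame,
    k_range: Iterable[int] = range(2, 16),
    families: Sequence[str] = FAMILIES,
    restarts: int = 3,
    seed: int = 0,
) -> ModuleAssignment:
    """Sweep (K, family), keep the best-loglik restart of each, select max BIC.

    Genes are assigned to their maximum-responsibility component (ties to
    the lower component index).  Raises :class:`ConvergenceError` when no
    fit in the sweep succeeds.
    """
    k_range = [k for k in k_range]
    if not k_range:
        raise ValueError("k_range must be nonempty")
    X = profiles.to_numpy(dtype=float)
    n = X.shape[0]

    rows = []
    fits: dict[tuple[int, str], MixtureFit] = {}
    failures = []
    for K in k_range:
        if K >= n:
            continue
        for family in families:
            best = None
            for r in range(restarts):
                try:
                    fit = fit_gmm(X, K, family, seed=seed + 10_007 * r + 101 * K)
                except (np.linalg.LinAlgError, FloatingPointError) as exc:
                    failures.append((K, family, r, repr(exc)))
                    continue
                if best is None or fit.loglik > best.loglik:
                    best = fit
            if best is None:
                continue
            fits[(K, family)] = best
            rows.append(
                {
                    "K": K,
                    "family": family,
                    "loglik": best.loglik,
                    "n_params": best.n_params,
                    "bic": best.bic,
                }
            )
    if not rows:
        raise ConvergenceError(f"all mixture fits failed: {failures}")
    sweep = pd.DataFrame(rows)
    best_fit = fits[
        (
            int(sweep.loc[_pick_best(sweep), "K"]),
            str(sweep.loc[_pick_best(sweep), "family"]),
        )
    ]
    labels = best_fit.responsibilities.argmax(axis=1) + 1
    module_of = {g: int(m) for g, m in zip(profiles.index, labels)}
    return ModuleAssignment(module_of=module_of, fit=best_fit, sweep=sweep)


def build_profiles(
    vst_matrix: pd.DataFrame,
    samples: Sequence[SampleMeta],
    genes: Iterable[str],
    subset: str,
    zscore: bool = True,
) -> pd.DataFrame:
    """Replicate-averaged condition profiles for one genotypic subset.

    Columns are the subset's (line, stage) cells labelled
    ``"{line}|s{stage}"`` in design order; each gene row is the mean over
    that cell's replicates, optionally standardized to mean 0, sd 1
    (sd floored at 1e-12 so constant genes become all-zero rows).
    """
    genes = list(genes)
    missing = [g for g in genes if g not in vst_matrix.index]
    if missing:
        raise KeyError(f"genes absent from expression matrix: {missing[:5]}")
    cells: dict[str, list[str]] = {}
    for s in samples:
        if s.subset != subset:
            continue
        cells.setdefault(f"{s.line}|s{s.stage}", []).append(s.sample_id)
    if not cells:
        raise ValueError(f"no samples for subset {subset!r}")
    cols = {label: vst_matrix.loc[genes, ids].mean(axis=1) for label, ids in cells.items()}
    profiles = pd.DataFrame(cols)
    if zscore:
        mean = profiles.mean(axis=1)
        sd = profiles.std(axis=1, ddof=0).clip(lower=SD_FLOOR)
        profiles = profiles.sub(mean, axis=0).div(sd, axis=0)
    return profiles


def module_means(profiles: pd.DataFrame, assignment: ModuleAssignment) -> pd.DataFrame:
    """Unweighted mean profile of each module's member genes.

    Rows are labelled ``"M{k}"``; empty modules are excluded with a
    warning.
    """
    missing = [g for g in profiles.index if g not in assignment.module_of]
    if missing:
        raise KeyError(f"assignment does not cover genes: {missing[:5]}")
    rows = {}
    for m in range(1, assignment.n_modules + 1):
        members = [g for g in profiles.index if assignment.module_of[g] == m]
        if not members:
            log.warning("module %d is empty; excluded from module means", m)
            continue
        rows[f"M{m}"] = profiles.loc[members].mean(axis=0)
    return pd.DataFrame(rows).T
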