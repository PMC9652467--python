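"""Stage 3: cohort-level descriptive statistics.

Young-vs-old effect-size concordance per ASP category, PCA of continuous
phenotypes (after single-imputation chained equations with predictive mean
matching for missing values), and the forest-plot table of standardized
factorial coefficients sorted by age effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import core_stats as cs
from .core_stats import ConcordanceStats, StandardizedCoefs
from .intervention import InterventionCall, TwoWayFit


@dataclass(frozen=True)
class PcaResult:
    scores: pd.DataFrame          # animals x components
    loadings: pd.DataFrame        # phenotypes x components
    variance_explained: np.ndarray


@dataclass(frozen=True)
class ImputationReport:
    n_missing_filled: int
    iterations: int
    seed: int
    converged: bool


def concordance_by_category(
    fits: list[TwoWayFit],
    calls: list[InterventionCall],
    category: str = "countered",
    alpha: float = cs.DEFAULT_ALPHA,
) -> ConcordanceStats:
    """Concordance of young vs old treatment effect sizes for one category
    of phenotypes (countered / accentuated / intervention_only / all)."""
    call_by_id = {c.phenotype_id: c for c in calls}
    xs, ys = [], []
    for f in fits:
        c = call_by_id[f.phenotype_id]
        if not (f.d_treat_young.defined and f.d_treat_old.defined):
            continue
        sig_treat = f.p_intervention < alpha or (
            np.isfinite(f.p_interaction) and f.p_interaction < alpha
        )
        if category == "all":
            keep = c.direction in ("countered", "accentuated") or (
                not c.is_asp and sig_treat
            )
        elif category == "intervention_only":
            keep = not c.is_asp and sig_treat
        else:
            keep = c.direction == category
        if keep:
            xs.append(f.d_treat_young.d)
            ys.append(f.d_treat_old.d)
    if len(xs) < 3:
        raise ValueError(
            f"insufficient pairs in category {category!r}: {len(xs)} < 3"
        )
    return cs.concordance(np.asarray(xs), np.asarray(ys))


def impute_chained(
    matrix: pd.DataFrame,
    iterations: int = 10,
    seed: int = 0,
    donor_pool: int = 5,
) -> tuple[pd.DataFrame, ImputationReport]:
    """Single-imputation chained equations with predictive mean matching.

    Missing cells are initialized at column means; columns are then cycled
    a fixed number of times, each regressed (OLS) on all other columns, and
    missing entries refreshed with a value drawn from the ``donor_pool``
    observed cases whose predictions are nearest. Observed cells are never
    altered. Deterministic given the seed.
    """
    X = matrix.to_numpy(dtype=float).copy()
    miss = np.isnan(X)
    n_missing = int(miss.sum())
    if n_missing == 0:
        return matrix.copy(), ImputationReport(0, 0, seed, True)
    n, p = X.shape
    for j in range(p):
        obs = ~miss[:, j]
        if obs.sum() < 2:
            raise ValueError(f"column {matrix.columns[j]!r} has < 2 observed values")
        if miss[:, j].mean() >= 0.5:
            warnings.warn(
                f"column {matrix.columns[j]!r} is >=50% missing"
            )
        X[miss[:, j], j] = X[obs, j].mean()
    rng = np.random.default_rng(seed)
    order = [j for j in range(p) if miss[:, j].any()]
    for _ in range(iterations):
        for j in order:
            obs = ~miss[:, j]
            others = [k for k in range(p) if k != j]
            A = np.column_stack([np.ones(n), X[:, others]])
            coef, *_ = np.linalg.lstsq(A[obs], X[obs, j], rcond=None)
            pred = A @ coef
            # PMM: for each missing row, draw among nearest observed donors
            obs_idx = np.flatnonzero(obs)
            for i in np.flatnonzero(miss[:, j]):
                dist = np.abs(pred[obs_idx] - pred[i])
                k = min(donor_pool, obs_idx.size)
                donors = obs_idx[np.argpartition(dist, k - 1)[:k]]
                X[i, j] = X[rng.choice(donors), j]
    out = pd.DataFrame(X, index=matrix.index, columns=matrix.columns)
    return out, ImputationReport(n_missing, iterations, seed, True)


def pca_phenotypes(matrix: pd.DataFrame, standardize: bool = True) -> PcaResult:
    """PCA of an animals x phenotypes matrix via SVD of the (optionally
    z-scored) centered data. Zero-variance columns are dropped with a
    warning. Sign convention: each component's largest-magnitude loading is
    positive. Retains min(rows - 1, columns) components.
    """
    X = matrix.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError("matrix contains missing values; impute first")
    sd = X.std(axis=0, ddof=1)
    keep = sd > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance phenotypes")
        X = X[:, keep]
        sd = sd[keep]
    cols = matrix.columns[keep]
    n, p = X.shape
    Xc = X - X.mean(axis=0)
    if standardize:
        Xc = Xc / sd
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    k = min(n - 1, p)
    U, S, Vt = U[:, :k], S[:k], Vt[:k]
    # deterministic sign: largest |loading| positive per component
    for i in range(k):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0
    scores = U * S
    var = S**2 / (n - 1)
    total = Xc.var(axis=0, ddof=1).sum()
    comp_names = [f"PC{i+1}" for i in range(k)]
    return PcaResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp_names),
        loadings=pd.DataFrame(Vt.T, index=cols, columns=comp_names),
        variance_explained=var / total,
    )


def forest_table(coefs_by_phenotype: dict[str, StandardizedCoefs]) -> pd.DataFrame:
    """One row per phenotype with standardized age / intervention /
    interaction coefficients and CIs, sorted by the age coefficient
    (ties broken by phenotype id). The row order is shared by all terms so
    forest panels line up across effects."""
    if not coefs_by_phenotype:
        raise ValueError("no fits")
    rows = []
    for pid, sc in coefs_by_phenotype.items():
        row = {"phenotype_id": pid}
        for term in ("age", "intervention", "interaction"):
            b, lo, hi = sc.coefficients[term]
            row[f"{term}_coef"] = b
            row[f"{term}_lo"] = lo
            row[f"{term}_hi"] = hi
        rows.append(row)
    df = pd.DataFrame(rows)
    return df.sort_values(
        ["age_coef", "phenotype_id"], kind="mergesort"
    ).reset_index(drop=True)
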