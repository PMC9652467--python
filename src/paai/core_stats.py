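"""Statistical primitives for trajectory and intervention analyses.

Every pipeline stage is built on the routines here: group summaries,
omnibus tests (one-way / two-way ANOVA, Kruskal-Wallis, r x c Fisher exact,
aligned rank transform), unadjusted posthoc comparisons (Fisher LSD, Dunn,
Mann-Whitney, pairwise exact tests), Cohen's d effect sizes with their
large-sample variance and two-sided z-comparison, young-vs-old concordance
statistics (Pearson r, absolute-agreement ICC, OLS slope tested against 1)
and exact hypergeometric set-overlap statistics.

All p-values are two-sided and unadjusted for multiplicity; the analysis
framework deliberately works with raw p-values at a fixed alpha.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import gammaln

__all__ = [
    "GroupStats",
    "EffectSize",
    "TestResult",
    "PosthocSet",
    "EffectSizeComparison",
    "ConcordanceStats",
    "OverlapResult",
    "StandardizedCoefs",
    "summarize_groups",
    "cohens_d",
    "cohens_d_from_samples",
    "d_variance",
    "compare_effect_sizes",
    "anova_oneway",
    "fisher_lsd",
    "kruskal_dunn",
    "fisher_exact_table",
    "anova_twoway",
    "art_anova",
    "mann_whitney",
    "concordance",
    "hypergeom_overlap",
    "standardized_lm",
]

DEFAULT_ALPHA = 0.05


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupStats:
    """Per-group summary: n, mean and sample SD (n-1 denominator).

    ``sd`` is NaN for singleton groups, where the sample SD is undefined.
    """

    label: str
    n: int
    mean: float
    sd: float


@dataclass(frozen=True)
class EffectSize:
    """Cohen's d standardized mean difference with its large-sample variance.

    Sign convention: (second group - reference group) / pooled SD.
    ``defined`` is False when the pooled SD is zero or either group has
    fewer than two observations; ``reason`` says which.
    """

    d: float
    n1: int
    n2: int
    variance: float
    defined: bool
    reason: str | None = None


@dataclass(frozen=True)
class TestResult:
    method: str
    statistic: float
    df: tuple[float, ...] | None
    p: float
    term: str | None = None


@dataclass(frozen=True)
class PosthocSet:
    """Unadjusted pairwise comparisons of every group against a reference.

    ``comparisons`` is an ordered list of (group_label, p, direction_sign)
    where direction_sign is the sign of (group location - reference
    location) on the scale of the underlying test (means, mean ranks or
    category proportions).
    """

    reference_label: str
    comparisons: tuple[tuple[str, float, int], ...]

    def p_for(self, label: str) -> float:
        for lab, p, _ in self.comparisons:
            if lab == label:
                return p
        raise KeyError(f"no comparison for group {label!r}")

    def sign_for(self, label: str) -> int:
        for lab, _, s in self.comparisons:
            if lab == label:
                return s
        raise KeyError(f"no comparison for group {label!r}")


@dataclass(frozen=True)
class EffectSizeComparison:
    """Two-sided z-test comparing two independent Cohen's d values."""

    d_young: EffectSize
    d_old: EffectSize
    z: float
    p: float
    old_larger: bool
    evaluable: bool = True


@dataclass(frozen=True)
class ConcordanceStats:
    """Agreement statistics for young-vs-old effect-size pairs."""

    n_pairs: int
    pearson_r: float
    p_r: float
    icc: float
    p_icc: float
    icc_variant: str
    slope: float
    intercept: float
    se_slope: float
    ci95: tuple[float, float]
    p_slope_vs_1: float


@dataclass(frozen=True)
class OverlapResult:
    universe_n: int
    setA_n: int
    setB_n: int
    overlap_n: int
    expected: float
    representation_factor: float
    p: float


@dataclass(frozen=True)
class StandardizedCoefs:
    """Standardized model coefficients with normal-approximation 95% CIs.

    ``coefficients`` maps term name (age, intervention, interaction) to
    (coefficient, ci_low, ci_high) in SD units of the outcome; predictors
    are 0/1 treatment-coded indicators (reference = young control).
    """

    coefficients: dict[str, tuple[float, float, float]]
    coding: str = "treatment(young,control)"


# ---------------------------------------------------------------------------
# Group summaries and effect sizes
# ---------------------------------------------------------------------------

def summarize_groups(values_by_group: dict[str, "np.ndarray | list"]) -> list[GroupStats]:
    """Compute n / mean / sample SD for each labelled group."""
    if not values_by_group:
        raise ValueError("no data")
    out = []
    for label, vals in values_by_group.items():
        v = np.asarray(vals, dtype=float)
        if v.size == 0:
            raise ValueError(f"no data for group {label!r}")
        sd = float(np.std(v, ddof=1)) if v.size >= 2 else float("nan")
        out.append(GroupStats(str(label), int(v.size), float(np.mean(v)), sd))
    return out


def cohens_d(ref: GroupStats, other: GroupStats) -> EffectSize:
    """Cohen's d of ``other`` relative to ``ref`` using the pooled sample SD."""
    n1, n2 = ref.n, other.n
    if n1 < 2 or n2 < 2:
        return EffectSize(float("nan"), n1, n2, float("nan"), False, "n < 2")
    pooled_var = ((n1 - 1) * ref.sd**2 + (n2 - 1) * other.sd**2) / (n1 + n2 - 2)
    pooled_sd = math.sqrt(pooled_var)
    if pooled_sd == 0.0:
        return EffectSize(float("nan"), n1, n2, float("nan"), False, "zero pooled SD")
    d = (other.mean - ref.mean) / pooled_sd
    es = EffectSize(d, n1, n2, float("nan"), True)
    return EffectSize(d, n1, n2, d_variance(es), True)


def cohens_d_from_samples(ref, other, labels=("ref", "other")) -> EffectSize:
    g = summarize_groups({labels[0]: ref, labels[1]: other})
    return cohens_d(g[0], g[1])


def d_variance(es: EffectSize) -> float:
    """Large-sample variance of an independent-groups Cohen's d:
    (n1+n2)/(n1*n2) + d^2 / (2*(n1+n2))."""
    if not es.defined and not math.isfinite(es.d):
        raise ValueError("variance undefined for an undefined effect size")
    n1, n2 = es.n1, es.n2
    return (n1 + n2) / (n1 * n2) + es.d**2 / (2 * (n1 + n2))


def compare_effect_sizes(
    young: EffectSize, old: EffectSize, alpha: float = DEFAULT_ALPHA
) -> EffectSizeComparison:
    """Two-sided z-test of (old.d - young.d); flags whether the old-group
    effect is both significantly different and larger in magnitude."""
    if not (young.defined and old.defined):
        return EffectSizeComparison(
            young, old, float("nan"), float("nan"), False, evaluable=False
        )
    z = (old.d - young.d) / math.sqrt(old.variance + young.variance)
    p = 2.0 * stats.norm.sf(abs(z))
    old_larger = (p < alpha) and (abs(old.d) > abs(young.d))
    return EffectSizeComparison(young, old, float(z), float(p), bool(old_larger))


# ---------------------------------------------------------------------------
# One-way ANOVA + Fisher's LSD
# ---------------------------------------------------------------------------

def _as_groups(values_by_group) -> dict[str, np.ndarray]:
    return {str(k): np.asarray(v, dtype=float) for k, v in values_by_group.items()}


def anova_oneway(values_by_group: dict) -> TestResult:
    """Classic one-way fixed-effects ANOVA (F = MS_between / MS_within)."""
    groups = _as_groups(values_by_group)
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    allv = np.concatenate(list(groups.values()))
    N, k = allv.size, len(groups)
    if np.ptp(allv) == 0:
        raise ValueError("degenerate: all values identical")
    grand = allv.mean()
    ss_between = sum(g.size * (g.mean() - grand) ** 2 for g in groups.values())
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups.values())
    df1, df2 = k - 1, N - k
    if df2 < 1:
        raise ValueError("no residual degrees of freedom")
    if ss_within == 0.0:
        # all spread is between groups: evidence is overwhelming by convention
        return TestResult("anova1", float("inf"), (df1, df2), 0.0)
    F = (ss_between / df1) / (ss_within / df2)
    p = float(stats.f.sf(F, df1, df2))
    return TestResult("anova1", float(F), (float(df1), float(df2)), p)


def fisher_lsd(
    values_by_group: dict, reference_label: str
) -> PosthocSet:
    """Fisher's least-significant-difference posthoc t-tests vs a reference.

    Uses the pooled one-way MSE on N-k df; p-values are unadjusted.
    """
    groups = _as_groups(values_by_group)
    reference_label = str(reference_label)
    if reference_label not in groups:
        raise ValueError(f"reference group {reference_label!r} missing")
    N = sum(g.size for g in groups.values())
    k = len(groups)
    ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups.values())
    df = N - k
    mse = ss_within / df if df > 0 else float("nan")
    ref = groups[reference_label]
    comps = []
    for label, g in groups.items():
        if label == reference_label:
            continue
        diff = g.mean() - ref.mean()
        sign = int(np.sign(diff))
        if mse == 0.0:
            p = 1.0 if diff == 0.0 else 0.0
        else:
            t = diff / math.sqrt(mse * (1.0 / g.size + 1.0 / ref.size))
            p = float(2.0 * stats.t.sf(abs(t), df))
        comps.append((label, p, sign))
    return PosthocSet(reference_label, tuple(comps))


# ---------------------------------------------------------------------------
# Kruskal-Wallis + Dunn
# ---------------------------------------------------------------------------

def kruskal_dunn(
    values_by_group: dict, reference_label: str
) -> tuple[TestResult, PosthocSet]:
    """Kruskal-Wallis omnibus (tie-corrected, chi-square approximation) and
    Dunn z-tests of each group's mean rank against the reference group.

    Dunn variance uses the tie-corrected form
    (N(N+1)/12 - T/(12(N-1))) * (1/n_i + 1/n_j) with T = sum(t^3 - t).
    """
    groups = _as_groups(values_by_group)
    reference_label = str(reference_label)
    if reference_label not in groups:
        raise ValueError(f"reference group {reference_label!r} missing")
    labels = list(groups)
    allv = np.concatenate([groups[l] for l in labels])
    N = allv.size
    if np.ptp(allv) == 0:
        omni = TestResult("kruskal", 0.0, (float(len(labels) - 1),), 1.0)
        comps = tuple((l, 1.0, 0) for l in labels if l != reference_label)
        return omni, PosthocSet(reference_label, comps)
    H, p = stats.kruskal(*[groups[l] for l in labels])
    omni = TestResult("kruskal", float(H), (float(len(labels) - 1),), float(p))

    ranks = stats.rankdata(allv)
    mean_ranks, idx = {}, 0
    for l in labels:
        n = groups[l].size
        mean_ranks[l] = ranks[idx : idx + n].mean()
        idx += n
    _, counts = np.unique(allv, return_counts=True)
    tie_sum = float(np.sum(counts**3 - counts))
    base_var = N * (N + 1) / 12.0 - tie_sum / (12.0 * (N - 1))
    comps = []
    for l in labels:
        if l == reference_label:
            continue
        diff = mean_ranks[l] - mean_ranks[reference_label]
        var = base_var * (1.0 / groups[l].size + 1.0 / groups[reference_label].size)
        if var <= 0:
            comps.append((l, 1.0, 0))
            continue
        z = diff / math.sqrt(var)
        comps.append((l, float(2.0 * stats.norm.sf(abs(z))), int(np.sign(diff))))
    return omni, PosthocSet(reference_label, tuple(comps))


# ---------------------------------------------------------------------------
# r x c Fisher exact test
# ---------------------------------------------------------------------------

def _log_table_prob(table: np.ndarray, lf_rows, lf_cols, lf_N) -> float:
    return lf_rows + lf_cols - lf_N - gammaln(table + 1.0).sum()


def _rxc_exact_p(table: np.ndarray) -> float:
    """Exact conditional p for an r x c table: sum of the probabilities of
    all margin-fixed tables no more probable than the observed one."""
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    N = int(table.sum())
    lf_rows = gammaln(rows + 1.0).sum()
    lf_cols = gammaln(cols + 1.0).sum()
    lf_N = gammaln(N + 1.0)
    obs_logp = _log_table_prob(table, lf_rows, lf_cols, lf_N)
    cutoff = obs_logp + 1e-7
    r, c = table.shape
    total = 0.0

    work = np.zeros((r, c), dtype=np.int64)
    rem = cols.astype(np.int64).copy()  # column counts still unassigned

    def fill(i: int, j: int, left: int):
        nonlocal total
        if i == r - 1:
            work[i, :] = rem
            lp = _log_table_prob(work, lf_rows, lf_cols, lf_N)
            if lp <= cutoff:
                total += math.exp(lp)
            return
        if j == c - 1:
            if left <= rem[j]:
                work[i, j] = left
                rem[j] -= left
                fill(i + 1, 0, int(rows[i + 1]))
                rem[j] += left
            return
        hi = min(left, int(rem[j]))
        for v in range(hi + 1):
            work[i, j] = v
            rem[j] -= v
            fill(i, j + 1, left - v)
            rem[j] += v

    fill(0, 0, int(rows[0]))
    return min(1.0, total)


def _rxc_montecarlo_p(table: np.ndarray, n_mc: int, seed: int) -> float:
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    N = int(table.sum())
    lf_rows = gammaln(rows + 1.0).sum()
    lf_cols = gammaln(cols + 1.0).sum()
    lf_N = gammaln(N + 1.0)
    obs = _log_table_prob(table, lf_rows, lf_cols, lf_N)
    rng = np.random.default_rng(seed)
    sampler = stats.random_table(rows, cols)
    sims = sampler.rvs(n_mc, random_state=rng)
    logps = lf_rows + lf_cols - lf_N - gammaln(sims + 1.0).sum(axis=(1, 2))
    hits = int(np.sum(logps <= obs + 1e-7))
    return (hits + 1) / (n_mc + 1)


def fisher_exact_table(
    counts,
    column_labels=None,
    reference_label=None,
    exact_max_n: int = 200,
    exact_max_dim: int = 4,
    n_mc: int = 100_000,
    mc_seed: int = 0,
) -> tuple[TestResult, PosthocSet | None]:
    """Fisher's exact test for an r x c contingency table of category (rows)
    by group (columns), with optional pairwise 2-column exact tests against a
    reference column.

    Exact enumeration is used for tables up to ``exact_max_n`` total counts
    and ``exact_max_dim`` rows/columns; larger tables fall back to a seeded
    Monte-Carlo estimate. Zero-margin rows/columns are dropped with a warning.
    Pairwise direction signs are the sign of the difference in the mean
    category index (a proportion difference for two-category tables).
    """
    table = np.asarray(counts, dtype=np.int64)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("need at least a 2x2 table")
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if column_labels is None:
        column_labels = [str(j) for j in range(table.shape[1])]
    column_labels = [str(l) for l in column_labels]

    keep_rows = table.sum(axis=1) > 0
    keep_cols = table.sum(axis=0) > 0
    if not keep_rows.all() or not keep_cols.all():
        warnings.warn("dropping zero-margin rows/columns from contingency table")
        table = table[keep_rows][:, keep_cols]
        column_labels = [l for l, k in zip(column_labels, keep_cols) if k]
        if table.shape[0] < 2 or table.shape[1] < 2:
            # no contrast left after dropping margins
            omni = TestResult("fisher_exact", float("nan"), None, 1.0)
            return omni, None

    r, c = table.shape
    N = int(table.sum())
    if N <= exact_max_n and r <= exact_max_dim and c <= exact_max_dim:
        p = _rxc_exact_p(table)
    else:
        p = _rxc_montecarlo_p(table, n_mc, mc_seed)
    omni = TestResult("fisher_exact", float("nan"), None, float(p))

    posthocs = None
    if reference_label is not None:
        reference_label = str(reference_label)
        if reference_label not in column_labels:
            raise ValueError(f"reference column {reference_label!r} missing")
        ref_j = column_labels.index(reference_label)
        scores = np.arange(r, dtype=float)
        comps = []
        for j, lab in enumerate(column_labels):
            if j == ref_j:
                continue
            sub = table[:, [ref_j, j]]
            sub = sub[sub.sum(axis=1) > 0]
            if sub.shape[0] < 2:
                comps.append((lab, 1.0, 0))
                continue
            pj = _rxc_exact_p(sub) if sub.sum() <= exact_max_n else _rxc_montecarlo_p(
                sub, n_mc, mc_seed
            )
            col_ref, col_j = table[:, ref_j], table[:, j]
            m_ref = float(scores @ col_ref) / col_ref.sum()
            m_j = float(scores @ col_j) / col_j.sum()
            comps.append((lab, float(pj), int(np.sign(m_j - m_ref))))
        posthocs = PosthocSet(reference_label, tuple(comps))
    return omni, posthocs


# ---------------------------------------------------------------------------
# Two-way factorial ANOVA (numeric nested-model computation)
# ---------------------------------------------------------------------------

def _rss(X: np.ndarray, y: np.ndarray) -> float:
    coef, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    return float(resid @ resid)


def _twoway_terms(
    y: np.ndarray, a: np.ndarray, b: np.ndarray, ss_type: str
) -> list[tuple[str, float, float]]:
    """Return [(term, SS, df)] for the full model y ~ A*B.

    A, B are 0/1 indicators. Type II (default elsewhere) tests each main
    effect adjusted for the other main effect; Type I is sequential A, B, AB.
    For balanced designs the two coincide.
    """
    n = y.size
    one = np.ones(n)
    ab = a * b
    X_full = np.column_stack([one, a, b, ab])
    X_ab_ = np.column_stack([one, a, b])
    rss_full = _rss(X_full, y)
    rss_ab_ = _rss(X_ab_, y)
    if ss_type == "II":
        ss_a = _rss(np.column_stack([one, b]), y) - rss_ab_
        ss_b = _rss(np.column_stack([one, a]), y) - rss_ab_
    elif ss_type == "I":
        rss_1 = _rss(one[:, None], y)
        rss_a = _rss(np.column_stack([one, a]), y)
        ss_a = rss_1 - rss_a
        ss_b = rss_a - rss_ab_
    else:
        raise ValueError(f"unknown sums-of-squares type {ss_type!r}")
    ss_ab = rss_ab_ - rss_full
    return [
        ("age", max(ss_a, 0.0), 1.0),
        ("intervention", max(ss_b, 0.0), 1.0),
        ("interaction", max(ss_ab, 0.0), 1.0),
    ], rss_full


def _check_2x2(age_old: np.ndarray, treated: np.ndarray):
    for a in (0, 1):
        for b in (0, 1):
            if int(np.sum((age_old == a) & (treated == b))) < 2:
                raise ValueError("incomplete design: every 2x2 cell needs n >= 2")


def _encode_factors(age_label, arm) -> tuple[np.ndarray, np.ndarray]:
    age = np.asarray([str(x) for x in age_label])
    arm_ = np.asarray([str(x) for x in arm])
    a = (age == "old").astype(float)
    t = (arm_ == "treated").astype(float)
    if not set(age) <= {"young", "old"}:
        raise ValueError("age_label must be 'young' or 'old'")
    if not set(arm_) <= {"control", "treated"}:
        raise ValueError("arm must be 'control' or 'treated'")
    return a, t


def anova_twoway(values, age_label, arm, ss_type: str = "II") -> list[TestResult]:
    """Full two-factor ANOVA (age x intervention with interaction).

    Returns one TestResult per term (age, intervention, interaction).
    """
    y = np.asarray(values, dtype=float)
    a, t = _encode_factors(age_label, arm)
    _check_2x2(a, t)
    terms, rss_full = _twoway_terms(y, a, t, ss_type)
    df2 = y.size - 4
    mse = rss_full / df2
    out = []
    for name, ss, df1 in terms:
        if mse == 0.0:
            F = float("inf") if ss > 0 else 0.0
            p = 0.0 if ss > 0 else 1.0
        else:
            F = (ss / df1) / mse
            p = float(stats.f.sf(F, df1, df2))
        out.append(TestResult("anova2", float(F), (df1, float(df2)), p, term=name))
    return out


# ---------------------------------------------------------------------------
# Aligned Rank Transform
# ---------------------------------------------------------------------------

def _cell_effects(y, a, t):
    """Unweighted cell-mean decomposition of a 2x2 design."""
    cell = {}
    for ai in (0.0, 1.0):
        for ti in (0.0, 1.0):
            cell[(ai, ti)] = y[(a == ai) & (t == ti)].mean()
    mu = np.mean(list(cell.values()))
    a_eff = {ai: np.mean([cell[(ai, ti)] for ti in (0.0, 1.0)]) - mu for ai in (0.0, 1.0)}
    t_eff = {ti: np.mean([cell[(ai, ti)] for ai in (0.0, 1.0)]) - mu for ti in (0.0, 1.0)}
    ab_eff = {
        k: cell[k] - mu - a_eff[k[0]] - t_eff[k[1]] for k in cell
    }
    return cell, mu, a_eff, t_eff, ab_eff


def aligned_responses(values, age_label, arm, term: str) -> np.ndarray:
    """ART alignment: residual from the cell means plus the estimated effect
    of the single term of interest."""
    y = np.asarray(values, dtype=float)
    a, t = _encode_factors(age_label, arm)
    cell, mu, a_eff, t_eff, ab_eff = _cell_effects(y, a, t)
    cell_mean = np.array([cell[(ai, ti)] for ai, ti in zip(a, t)])
    resid = y - cell_mean
    if term == "age":
        eff = np.array([a_eff[ai] for ai in a])
    elif term == "intervention":
        eff = np.array([t_eff[ti] for ti in t])
    elif term == "interaction":
        eff = np.array([ab_eff[(ai, ti)] for ai, ti in zip(a, t)])
    else:
        raise ValueError(f"unknown term {term!r}")
    return resid + eff


def art_anova(values, age_label, arm, ss_type: str = "II") -> list[TestResult]:
    """Aligned Rank Transform factorial analysis for 2x2 designs.

    For each term, responses are aligned for that term, mid-ranked, and a
    full two-factor ANOVA is run on the ranks; only the aligned term's F and
    p are reported. A fully tied alignment is a degenerate case reported as
    F = 0, p = 1.
    """
    y = np.asarray(values, dtype=float)
    a, t = _encode_factors(age_label, arm)
    _check_2x2(a, t)
    out = []
    for term in ("age", "intervention", "interaction"):
        aligned = aligned_responses(y, age_label, arm, term)
        if np.ptp(aligned) == 0:
            warnings.warn(f"degenerate alignment for term {term!r}")
            out.append(TestResult("art", 0.0, (1.0, float(y.size - 4)), 1.0, term=term))
            continue
        ranks = stats.rankdata(aligned)
        res = anova_twoway(ranks, age_label, arm, ss_type=ss_type)
        sel = next(r for r in res if r.term == term)
        out.append(TestResult("art", sel.statistic, sel.df, sel.p, term=term))
    return out


def mann_whitney(values_a, values_b) -> TestResult:
    """Mann-Whitney U; exact when both samples are small with no ties,
    otherwise the tie-corrected normal approximation without continuity
    correction (so that the two-group Dunn identity holds)."""
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("empty sample")
    pooled = np.concatenate([a, b])
    no_ties = np.unique(pooled).size == pooled.size
    if np.ptp(pooled) == 0:
        return TestResult("mwu", float(a.size * b.size / 2.0), None, 1.0)
    method = "exact" if (a.size + b.size <= 12 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(
        a, b, alternative="two-sided", method=method, use_continuity=False
    )
    return TestResult("mwu", float(res.statistic), None, float(min(1.0, res.pvalue)))


# ---------------------------------------------------------------------------
# Concordance of young-vs-old effect sizes
# ---------------------------------------------------------------------------

def _icc_absolute_agreement(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Single-measurement, absolute-agreement, two-way random-effects ICC
    (the ICC(2,1) / ICC(A,1) variant) via pingouin, with its F-test p."""
    import pingouin as pg

    n = x.size
    df = pd.DataFrame(
        {
            "targets": np.tile(np.arange(n), 2),
            "raters": np.repeat(["young", "old"], n),
            "ratings": np.concatenate([x, y]),
        }
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        tab = pg.intraclass_corr(
            data=df, targets="targets", raters="raters", ratings="ratings"
        )
    sel = tab[tab["Type"].isin(["ICC2", "ICC(A,1)"])]
    row = sel.iloc[0]
    icc = float(row["ICC"])
    p = float(row["pval"])
    if not math.isfinite(icc):
        icc = 1.0 if np.allclose(x, y) else float("nan")
    if not math.isfinite(p):
        p = 0.0
    return icc, p


def concordance(x, y, icc_variant: str = "ICC2") -> ConcordanceStats:
    """Pearson r, absolute-agreement ICC, and the OLS slope of y on x with a
    two-sided t-test against slope 1, for paired effect sizes.

    x is the young-group effect size, y the old-group effect size.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n = x.size
    if n < 3:
        raise ValueError("insufficient pairs: need n >= 3")
    if np.ptp(x) == 0:
        raise ValueError("constant x: slope undefined")
    xbar, ybar = x.mean(), y.mean()
    sxx = float(((x - xbar) ** 2).sum())
    sxy = float(((x - xbar) * (y - ybar)).sum())
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    resid = y - (intercept + slope * x)
    sse = float(resid @ resid)
    df = n - 2
    if sse <= 1e-300:
        se = 0.0
        p_slope = 1.0 if math.isclose(slope, 1.0) else 0.0
        ci = (slope, slope)
    else:
        se = math.sqrt(sse / df / sxx)
        tq = stats.t.ppf(0.975, df)
        ci = (slope - tq * se, slope + tq * se)
        t1 = (slope - 1.0) / se
        p_slope = float(2.0 * stats.t.sf(abs(t1), df))
    if np.ptp(y) == 0:
        r, p_r = 0.0, 1.0
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r, p_r = stats.pearsonr(x, y)
    icc, p_icc = _icc_absolute_agreement(x, y)
    return ConcordanceStats(
        n_pairs=int(n),
        pearson_r=float(r),
        p_r=float(p_r),
        icc=icc,
        p_icc=p_icc,
        icc_variant=icc_variant,
        slope=float(slope),
        intercept=float(intercept),
        se_slope=float(se),
        ci95=(float(ci[0]), float(ci[1])),
        p_slope_vs_1=float(p_slope),
    )


# ---------------------------------------------------------------------------
# Hypergeometric set overlap
# ---------------------------------------------------------------------------

def hypergeom_overlap(
    universe_n: int, setA_n: int, setB_n: int, overlap_n: int
) -> OverlapResult:
    """Exact hypergeometric upper-tail test of a two-set overlap and the
    representation factor observed/expected under independence."""
    if setA_n > universe_n or setB_n > universe_n:
        raise ValueError("set sizes exceed universe")
    if overlap_n > min(setA_n, setB_n):
        raise ValueError("overlap exceeds set sizes")
    expected = setA_n * setB_n / universe_n
    if expected == 0:
        raise ValueError("expected overlap is zero; representation factor undefined")
    rf = overlap_n / expected
    p = float(stats.hypergeom.sf(overlap_n - 1, universe_n, setA_n, setB_n))
    return OverlapResult(
        int(universe_n), int(setA_n), int(setB_n), int(overlap_n),
        float(expected), float(rf), p,
    )


# ---------------------------------------------------------------------------
# Standardized linear-model coefficients
# ---------------------------------------------------------------------------

def standardized_lm(values, age_label, arm) -> StandardizedCoefs:
    """Fit y ~ age * intervention on the z-scored outcome with 0/1
    treatment-coded indicators (reference young control); report each
    coefficient with a normal-approximation 95% CI in outcome-SD units."""
    import statsmodels.api as sm

    y = np.asarray(values, dtype=float)
    a, t = _encode_factors(age_label, arm)
    _check_2x2(a, t)
    sd = y.std(ddof=1)
    if sd == 0:
        raise ValueError("constant phenotype: cannot standardize")
    z = (y - y.mean()) / sd
    X = np.column_stack([np.ones(y.size), a, t, a * t])
    fit = sm.OLS(z, X).fit()
    names = ["intercept", "age", "intervention", "interaction"]
    coefs = {}
    crit = stats.norm.ppf(0.975)
    for i, name in enumerate(names):
        if name == "intercept":
            continue
        b = float(fit.params[i])
        se = float(fit.bse[i])
        coefs[name] = (b, b - crit * se, b + crit * se)
    return StandardizedCoefs(coefficients=coefs)
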