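"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written by a different route than the
library code: exhaustive enumeration, literal rule application, textbook
formulas evaluated step by step, or a different library.
"""

from __future__ import annotations

import itertools
import math
from math import comb, factorial

import numpy as np
import pandas as pd
from scipy import stats


def exact_rxc_p(table: np.ndarray) -> float:
    """Fisher exact p by exhaustive enumeration of every nonnegative table,
    filtered to the observed margins. Only feasible for tiny totals."""
    table = np.asarray(table, dtype=int)
    rows, cols = table.sum(1), table.sum(0)
    r, c = table.shape

    def prob(t):
        num = math.prod(factorial(int(x)) for x in rows) * math.prod(
            factorial(int(x)) for x in cols
        )
        den = factorial(int(table.sum())) * math.prod(
            factorial(int(x)) for x in np.ravel(t)
        )
        return num / den

    p_obs = prob(table)
    total = 0.0
    ranges = [range(min(int(rows[i]), int(cols[j])) + 1) for i in range(r) for j in range(c)]
    for flat in itertools.product(*ranges):
        t = np.array(flat).reshape(r, c)
        if (t.sum(1) == rows).all() and (t.sum(0) == cols).all():
            p = prob(t)
            if p <= p_obs * (1 + 1e-9):
                total += p
    return total


def kruskal_h(groups: dict) -> float:
    """Kruskal-Wallis H from the textbook rank-sum formula with the
    tie-correction divisor."""
    labels = list(groups)
    allv = np.concatenate([np.asarray(groups[l], float) for l in labels])
    N = allv.size
    ranks = stats.rankdata(allv)
    h = 0.0
    idx = 0
    for l in labels:
        n = len(groups[l])
        R = ranks[idx : idx + n].sum()
        h += R**2 / n
        idx += n
    h = 12.0 / (N * (N + 1)) * h - 3 * (N + 1)
    _, counts = np.unique(allv, return_counts=True)
    corr = 1.0 - np.sum(counts**3 - counts) / (N**3 - N)
    return h / corr


def mwu_exact_p(a, b) -> float:
    """Exact two-sided Mann-Whitney p by enumerating every assignment of
    pooled ranks to group A (no ties assumed)."""
    a, b = list(a), list(b)
    pooled = sorted(a + b)
    ranks_a = sum(pooled.index(v) + 1 for v in a)
    n1, n2 = len(a), len(b)
    u_obs = ranks_a - n1 * (n1 + 1) / 2
    u_obs = min(u_obs, n1 * n2 - u_obs)
    count = 0
    total = 0
    allranks = range(1, n1 + n2 + 1)
    for combo in itertools.combinations(allranks, n1):
        u = sum(combo) - n1 * (n1 + 1) / 2
        u = min(u, n1 * n2 - u)
        total += 1
        if u <= u_obs:
            count += 1
    return count / total


def hypergeom_tail(N, A, B, k) -> float:
    return sum(
        comb(A, i) * comb(N - A, B - i) / comb(N, B)
        for i in range(k, min(A, B) + 1)
    )


def art_oracle(y, age, arm) -> dict[str, tuple[float, float]]:
    """Step-by-step aligned-rank-transform via pandas cell means and a
    statsmodels factorial ANOVA on the ranks; returns {term: (F, p)}."""
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = pd.DataFrame({"y": np.asarray(y, float), "a": age, "b": arm})
    cell = df.groupby(["a", "b"])["y"].transform("mean")
    cm = df.groupby(["a", "b"])["y"].mean()
    mu = cm.mean()
    a_eff = cm.groupby("a").mean() - mu
    b_eff = cm.groupby("b").mean() - mu
    out = {}
    for term, est in (
        ("age", df["a"].map(a_eff)),
        ("intervention", df["b"].map(b_eff)),
        (
            "interaction",
            cell
            - df["a"].map(a_eff + mu)
            - df["b"].map(b_eff + mu)
            + mu,
        ),
    ):
        aligned = df["y"] - cell + est
        df["rank"] = stats.rankdata(aligned)
        fit = smf.ols("rank ~ C(a) * C(b)", df).fit()
        an = sm.stats.anova_lm(fit, typ=2)
        row = {
            "age": "C(a)",
            "intervention": "C(b)",
            "interaction": "C(a):C(b)",
        }[term]
        out[term] = (float(an.loc[row, "F"]), float(an.loc[row, "PR(>F)"]))
    return out


def twoway_ss_balanced(y, a, b) -> dict[str, float]:
    """Cell-mean sums-of-squares decomposition for a balanced 2x2 design."""
    y = np.asarray(y, float)
    a = np.asarray(a)
    b = np.asarray(b)
    levels_a, levels_b = np.unique(a), np.unique(b)
    n_cell = y.size // 4
    cm = {
        (la, lb): y[(a == la) & (b == lb)].mean()
        for la in levels_a
        for lb in levels_b
    }
    grand = np.mean(list(cm.values()))
    ma = {la: np.mean([cm[(la, lb)] for lb in levels_b]) for la in levels_a}
    mb = {lb: np.mean([cm[(la, lb)] for la in levels_a]) for lb in levels_b}
    ss_a = 2 * n_cell * sum((ma[la] - grand) ** 2 for la in levels_a)
    ss_b = 2 * n_cell * sum((mb[lb] - grand) ** 2 for lb in levels_b)
    ss_ab = n_cell * sum(
        (cm[(la, lb)] - ma[la] - mb[lb] + grand) ** 2
        for la in levels_a
        for lb in levels_b
    )
    ss_err = sum(
        ((y[(a == la) & (b == lb)] - cm[(la, lb)]) ** 2).sum()
        for la in levels_a
        for lb in levels_b
    )
    return {"age": ss_a, "intervention": ss_b, "interaction": ss_ab, "error": ss_err}


def onset_rule_literal(pattern: dict[int, bool], ages=(5, 8, 14, 20, 26)) -> str:
    """The age-at-first-change rule applied literally to a significance
    pattern: earliest age m such that every earlier comparison is
    non-significant, the comparison at m is significant, and the remaining
    later comparisons are all significant with at most one exception."""
    for i, m in enumerate(ages):
        earlier_ok = all(not pattern[x] for x in ages[:i])
        later = ages[i + 1 :]
        later_ok = sum(not pattern[x] for x in later) <= 1
        if earlier_ok and pattern[m] and later_ok:
            return f"m{m}"
    return "other"


def icc_a1(x, y) -> float:
    """Two-way random-effects, absolute-agreement, single-measurement ICC
    from its variance-component formula (k = 2 raters)."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    n, k = x.size, 2
    data = np.column_stack([x, y])
    grand = data.mean()
    row_means = data.mean(axis=1)
    col_means = data.mean(axis=0)
    msr = k * ((row_means - grand) ** 2).sum() / (n - 1)
    msc = n * ((col_means - grand) ** 2).sum() / (k - 1)
    sse = ((data - row_means[:, None] - col_means[None, :] + grand) ** 2).sum()
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k * (msc - mse) / n)


def normal_equations_coefs(y, a, b) -> np.ndarray:
    """(X'X)^-1 X'y for the z-scored outcome on [1, A, B, AB]."""
    y = np.asarray(y, float)
    z = (y - y.mean()) / y.std(ddof=1)
    X = np.column_stack([np.ones(y.size), a, b, a * b])
    return np.linalg.solve(X.T @ X, X.T @ z)
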