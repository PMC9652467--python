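"""Stage 1: lifetime-trajectory classification of phenotypes.

Each phenotype measured across a multi-age-group cohort (default ages 3, 5,
8, 14, 20, 26 months, reference 3 months) is called age-sensitive when its
omnibus test across age groups is significant, and is then assigned an age
at first detectable change from the pattern of unadjusted posthoc
comparisons against the young reference: the earliest candidate age whose
comparison is significant, all earlier comparisons are non-significant, and
at most one later comparison is non-significant (the single allowed
exception). Patterns fitting no candidate age are labelled ``other`` — this
is where non-monotonic trajectories such as a midlife fat-mass peak land.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import core_stats as cs
from .core_stats import DEFAULT_ALPHA, PosthocSet, TestResult

DEFAULT_AGES = (3, 5, 8, 14, 20, 26)

SCALES = ("continuous", "ordinal", "count_category")

ONSET_CATEGORIES = ("m5", "m8", "m14", "m20", "m26", "other", "none")


@dataclass(frozen=True)
class PhenotypeMeta:
    phenotype_id: str
    scale: str
    direction_hint: str | None = None

    def __post_init__(self):
        if self.scale not in SCALES:
            raise ValueError(f"unknown scale {self.scale!r}")


@dataclass(frozen=True)
class TrajectoryCall:
    phenotype_id: str
    omnibus: TestResult
    age_sensitive: bool
    onset: str
    posthocs: PosthocSet | None
    exception_used: bool


@dataclass(frozen=True)
class TrajectorySummary:
    n_phenotypes: int
    n_asp: int
    pct_asp: float
    onset_counts: dict[str, int]
    onset_pct: dict[str, float]


def round_pct(x: float) -> float:
    """Round a percentage half-up to one decimal (18/96 -> 18.8)."""
    import decimal

    return float(
        decimal.Decimal(repr(x)).quantize(
            decimal.Decimal("0.1"), rounding=decimal.ROUND_HALF_UP
        )
    )


def classify_age_sensitivity(
    sub: pd.DataFrame,
    meta: PhenotypeMeta,
    alpha: float = DEFAULT_ALPHA,
    ages=DEFAULT_AGES,
    always_posthoc: bool = False,
) -> tuple[TestResult, PosthocSet | None]:
    """Omnibus test across age groups with posthocs vs the youngest group.

    Dispatch by declared scale: continuous -> one-way ANOVA + Fisher LSD;
    ordinal -> Kruskal-Wallis + Dunn; count/category -> r x c Fisher exact
    with pairwise exact tests. Posthocs are computed only when the omnibus
    is significant (set ``always_posthoc`` for diagnostics).
    """
    reference = str(ages[0])
    groups = {
        str(age): sub.loc[sub["age_group"].astype(str) == str(age), "value"]
        for age in ages
    }
    if groups[reference].size == 0:
        raise ValueError(f"missing reference age group {reference}")
    if meta.scale == "continuous":
        vals = {k: v.astype(float).to_numpy() for k, v in groups.items()}
        omni = cs.anova_oneway(vals)
        post = None
        if always_posthoc or omni.p < alpha:
            post = cs.fisher_lsd(vals, reference)
        return omni, post
    if meta.scale == "ordinal":
        vals = {k: v.astype(float).to_numpy() for k, v in groups.items()}
        omni, post = cs.kruskal_dunn(vals, reference)
        if not (always_posthoc or omni.p < alpha):
            post = None
        return omni, post
    # count/category: build category x age contingency table
    cats = sorted(pd.unique(sub["value"].astype(str)))
    if len(cats) < 2:  # no variation at all: trivially age-insensitive
        return TestResult("fisher_exact", float("nan"), None, 1.0), None
    table = np.zeros((len(cats), len(ages)), dtype=np.int64)
    for j, age in enumerate(ages):
        vc = groups[str(age)].astype(str).value_counts()
        for i, cat in enumerate(cats):
            table[i, j] = int(vc.get(cat, 0))
    omni, post = cs.fisher_exact_table(
        table, column_labels=[str(a) for a in ages], reference_label=reference
    )
    if not (always_posthoc or omni.p < alpha):
        post = None
    return omni, post


def assign_onset(
    posthoc_p: dict,
    omnibus_significant: bool,
    alpha: float = DEFAULT_ALPHA,
    ages=DEFAULT_AGES,
) -> tuple[str, bool]:
    """Age-at-first-detectable-change rule.

    ``posthoc_p`` maps each non-reference age to the unadjusted p of its
    comparison against the reference. Scanning candidate onsets in ascending
    age order, a candidate qualifies iff every earlier comparison is
    non-significant, its own comparison is significant, and at most one
    later comparison is non-significant. The exception never applies to the
    candidate itself or to earlier ages. Returns (onset, exception_used).
    """
    if not omnibus_significant:
        return "none", False
    later_ages = list(ages[1:])
    ps = {}
    for age in later_ages:
        key = age if age in posthoc_p else str(age)
        if key not in posthoc_p:
            raise ValueError(f"incomplete posthoc set: missing age {age}")
        ps[age] = float(posthoc_p[key])
    sig = {age: ps[age] < alpha for age in later_ages}
    for i, m in enumerate(later_ages):
        earlier = later_ages[:i]
        later = later_ages[i + 1 :]
        if any(sig[a] for a in earlier):
            continue
        if not sig[m]:
            continue
        n_later_ns = sum(not sig[a] for a in later)
        if n_later_ns <= 1:
            return f"m{m}", n_later_ns == 1
    return "other", False


def call_phenotype(
    sub: pd.DataFrame,
    meta: PhenotypeMeta,
    alpha: float = DEFAULT_ALPHA,
    ages=DEFAULT_AGES,
) -> TrajectoryCall:
    omni, post = classify_age_sensitivity(sub, meta, alpha=alpha, ages=ages)
    age_sensitive = omni.p < alpha
    if not age_sensitive:
        return TrajectoryCall(meta.phenotype_id, omni, False, "none", post, False)
    if post is None:  # degenerate table with no posthoc contrasts left
        return TrajectoryCall(meta.phenotype_id, omni, True, "other", None, False)
    p_by_age = {lab: p for lab, p, _ in post.comparisons}
    onset, exc = assign_onset(p_by_age, True, alpha=alpha, ages=ages)
    return TrajectoryCall(meta.phenotype_id, omni, True, onset, post, exc)


def classify_cohort(
    table: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
    ages=DEFAULT_AGES,
) -> list[TrajectoryCall]:
    """Run the trajectory classification for every phenotype in a tidy table
    with columns phenotype_id, scale, age_group, value."""
    calls = []
    for pid, sub in table.groupby("phenotype_id", sort=True):
        scale = str(sub["scale"].iloc[0])
        meta = PhenotypeMeta(str(pid), scale)
        calls.append(call_phenotype(sub, meta, alpha=alpha, ages=ages))
    return calls


def summarize_trajectories(calls: list[TrajectoryCall]) -> TrajectorySummary:
    """Cohort-level counts: fraction of phenotypes that are age-sensitive
    and the distribution of onset categories among ASPs."""
    if not calls:
        raise ValueError("no calls")
    n = len(calls)
    asps = [c for c in calls if c.age_sensitive]
    n_asp = len(asps)
    counts: dict[str, int] = {}
    for c in asps:
        counts[c.onset] = counts.get(c.onset, 0) + 1
    pct = {
        k: round_pct(100.0 * v / n_asp) for k, v in counts.items()
    } if n_asp else {}
    return TrajectorySummary(
        n_phenotypes=n,
        n_asp=n_asp,
        pct_asp=round_pct(100.0 * n_asp / n),
        onset_counts=counts,
        onset_pct=pct,
    )


def calls_to_frame(calls: list[TrajectoryCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "phenotype_id": c.phenotype_id,
                "method": c.omnibus.method,
                "statistic": c.omnibus.statistic,
                "p_omnibus": c.omnibus.p,
                "age_sensitive": c.age_sensitive,
                "onset": c.onset,
                "exception_used": c.exception_used,
            }
        )
    return pd.DataFrame(rows)
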