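"""Stage 2: rate-vs-baseline classification of intervention effects.

For a 2x2 young/old x control/treated cohort, each phenotype gets a full
factorial fit (two-way ANOVA, aligned rank transform, or Fisher exact
depending on scale), Cohen's d effect sizes for the three informative cell
contrasts (age effect in controls; treatment effect within old; treatment
effect within young), and a z-comparison of the young vs old treatment
effect sizes.

Age-sensitive phenotypes (significant age main effect within the study
itself) are then classified:

* direction — ``countered`` when the old-group treatment effect opposes the
  direction of the age effect, ``accentuated`` when it matches it,
  ``unaffected`` when neither the intervention main effect nor the
  interaction is significant, ``unevaluable`` when the required Cohen's d
  values cannot be computed (zero pooled SD).
* model label, by two routes that may legitimately disagree:
  - interaction route: ``rate_or_combined`` when the interaction is
    significant with a larger old-group effect, else ``baseline``;
  - effect-size route: ``rate_or_combined`` when the z-test finds a
    significantly larger old-group effect, else ``baseline``.

A baseline effect shifts the phenotype equally at both ages (mimicking but
not constituting slowed aging); a rate or combined effect requires the
treatment effect to be larger in old animals.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import core_stats as cs
from .core_stats import DEFAULT_ALPHA, EffectSize, EffectSizeComparison
from .trajectory import PhenotypeMeta, round_pct

DIRECTIONS = ("countered", "accentuated", "unaffected", "unevaluable")
MODEL_LABELS = ("baseline", "rate_or_combined", "not_applicable")

SIGN_TOL = 1e-12


@dataclass(frozen=True)
class TwoWayFit:
    phenotype_id: str
    scale: str
    p_age: float
    p_intervention: float
    p_interaction: float
    d_age: EffectSize
    d_treat_old: EffectSize
    d_treat_young: EffectSize
    comparison: EffectSizeComparison
    prop_shift_old: float = float("nan")  # count-scale direction surrogate


@dataclass(frozen=True)
class InterventionCall:
    phenotype_id: str
    is_asp: bool
    direction: str
    model_interaction_route: str
    model_effectsize_route: str
    onset_from_baseline_study: str | None = None


@dataclass(frozen=True)
class CategoryFractions:
    route: str
    n_asp: int
    counts: dict[str, int]
    percentages: dict[str, float]


_CELLS = (("young", "control"), ("young", "treated"),
          ("old", "control"), ("old", "treated"))


def _cell_values(sub: pd.DataFrame) -> dict[tuple[str, str], pd.Series]:
    cells = {}
    for age, arm in _CELLS:
        mask = (sub["age_group"].astype(str) == age) & (sub["arm"].astype(str) == arm)
        cells[(age, arm)] = sub.loc[mask, "value"]
        if cells[(age, arm)].size == 0:
            raise ValueError(f"incomplete design: empty cell ({age}, {arm})")
    return cells


def fit_phenotype(
    sub: pd.DataFrame,
    meta: PhenotypeMeta,
    alpha: float = DEFAULT_ALPHA,
    ss_type: str = "II",
) -> TwoWayFit:
    """Factorial fit and effect sizes for one phenotype of a 2x2 cohort."""
    cells = _cell_values(sub)
    age = sub["age_group"].astype(str).to_numpy()
    arm = sub["arm"].astype(str).to_numpy()

    if meta.scale in ("continuous", "ordinal"):
        y = sub["value"].astype(float).to_numpy()
        if meta.scale == "continuous":
            res = cs.anova_twoway(y, age, arm, ss_type=ss_type)
        else:
            res = cs.art_anova(y, age, arm, ss_type=ss_type)
        p = {r.term: r.p for r in res}
        num = {k: v.astype(float).to_numpy() for k, v in cells.items()}
        d_age = cs.cohens_d_from_samples(num[("young", "control")], num[("old", "control")])
        d_to = cs.cohens_d_from_samples(num[("old", "control")], num[("old", "treated")])
        d_ty = cs.cohens_d_from_samples(num[("young", "control")], num[("young", "treated")])
        comp = cs.compare_effect_sizes(d_ty, d_to, alpha=alpha)
        return TwoWayFit(
            meta.phenotype_id, meta.scale,
            p["age"], p["intervention"], p["interaction"],
            d_age, d_to, d_ty, comp,
        )

    # count/category scale: Fisher exact on margin-collapsed tables;
    # no per-term interaction p is available, and Cohen's d is undefined.
    cats = sorted(pd.unique(sub["value"].astype(str)))
    nd = EffectSize(float("nan"), 0, 0, float("nan"), False, "count scale")
    comp = cs.compare_effect_sizes(nd, nd, alpha=alpha)
    if len(cats) < 2:  # no variation at all: nothing to test
        return TwoWayFit(meta.phenotype_id, meta.scale, 1.0, 1.0, float("nan"),
                         nd, nd, nd, comp, prop_shift_old=float("nan"))
    scores = np.arange(len(cats), dtype=float)

    def _table(by: np.ndarray, levels: tuple[str, str]) -> np.ndarray:
        t = np.zeros((len(cats), 2), dtype=np.int64)
        vals = sub["value"].astype(str).to_numpy()
        for j, lev in enumerate(levels):
            vc = pd.Series(vals[by == lev]).value_counts()
            for i, cat in enumerate(cats):
                t[i, j] = int(vc.get(cat, 0))
        return t

    t_age = _table(age, ("young", "old"))
    t_arm = _table(arm, ("control", "treated"))
    p_age = cs.fisher_exact_table(t_age)[0].p
    p_arm = cs.fisher_exact_table(t_arm)[0].p
    # direction surrogate: shift of the mean category score under treatment
    # within the old group, and of age within controls
    old_mask = age == "old"
    ctrl_mask = arm == "control"
    vals = pd.Categorical(sub["value"].astype(str), categories=cats).codes.astype(float)
    shift_age = vals[old_mask & ctrl_mask].mean() - vals[~old_mask & ctrl_mask].mean()
    shift_trt = vals[old_mask & ~ctrl_mask].mean() - vals[old_mask & ctrl_mask].mean()
    prop = shift_age * shift_trt
    return TwoWayFit(
        meta.phenotype_id, meta.scale,
        float(p_age), float(p_arm), float("nan"),
        nd, nd, nd, comp, prop_shift_old=float(prop),
    )


def classify_direction(fit: TwoWayFit, alpha: float = DEFAULT_ALPHA) -> str:
    """Countered / accentuated / unaffected / unevaluable for one ASP."""
    sig_int = fit.p_intervention < alpha
    sig_x = math.isfinite(fit.p_interaction) and fit.p_interaction < alpha
    if not (sig_int or sig_x):
        return "unaffected"
    if fit.scale == "count_category":
        # category-proportion surrogate: product of age and treatment shifts
        if not math.isfinite(fit.prop_shift_old) or abs(fit.prop_shift_old) < SIGN_TOL:
            return "unevaluable"
        return "countered" if fit.prop_shift_old < 0 else "accentuated"
    if not (fit.d_age.defined and fit.d_treat_old.defined):
        return "unevaluable"
    s_age = _sign(fit.d_age.d)
    s_trt = _sign(fit.d_treat_old.d)
    if s_trt == 0:
        # tie-break: fall back to the young-group treatment direction
        s_trt = _sign(fit.d_treat_young.d) if fit.d_treat_young.defined else 0
        if s_trt == 0:
            warnings.warn(
                f"{fit.phenotype_id}: significant effect with ~zero d; unaffected"
            )
            return "unaffected"
    if s_age == 0:
        return "unevaluable"
    return "countered" if s_age * s_trt < 0 else "accentuated"


def _sign(x: float) -> int:
    if abs(x) < SIGN_TOL:
        return 0
    return 1 if x > 0 else -1


def classify_model_interaction_route(
    fit: TwoWayFit, direction: str, alpha: float = DEFAULT_ALPHA
) -> str:
    """Model label from the factorial terms: a significant interaction with a
    larger old-group effect is evidence of a rate or combined effect; a main
    effect without that is the age-independent baseline pattern."""
    if direction != "countered":
        return "not_applicable"
    if fit.scale == "count_category":
        return "not_applicable"
    sig_x = math.isfinite(fit.p_interaction) and fit.p_interaction < alpha
    if (
        sig_x
        and fit.d_treat_old.defined
        and fit.d_treat_young.defined
        and abs(fit.d_treat_old.d) > abs(fit.d_treat_young.d)
    ):
        return "rate_or_combined"
    return "baseline"


def classify_model_effectsize_route(
    fit: TwoWayFit, direction: str, alpha: float = DEFAULT_ALPHA
) -> str:
    """Model label from the young-vs-old effect-size z-comparison."""
    if direction != "countered":
        return "not_applicable"
    if not fit.comparison.evaluable:
        return "not_applicable"
    return "rate_or_combined" if fit.comparison.old_larger else "baseline"


def call_intervention_phenotype(
    fit: TwoWayFit, alpha: float = DEFAULT_ALPHA
) -> InterventionCall:
    is_asp = fit.p_age < alpha
    if not is_asp:
        return InterventionCall(
            fit.phenotype_id, False, "not_applicable",
            "not_applicable", "not_applicable",
        )
    direction = classify_direction(fit, alpha=alpha)
    return InterventionCall(
        fit.phenotype_id,
        True,
        direction,
        classify_model_interaction_route(fit, direction, alpha=alpha),
        classify_model_effectsize_route(fit, direction, alpha=alpha),
    )


def fit_cohort(
    table: pd.DataFrame, alpha: float = DEFAULT_ALPHA, ss_type: str = "II"
) -> tuple[list[TwoWayFit], list[InterventionCall]]:
    fits, calls = [], []
    for pid, sub in table.groupby("phenotype_id", sort=True):
        meta = PhenotypeMeta(str(pid), str(sub["scale"].iloc[0]))
        fit = fit_phenotype(sub, meta, alpha=alpha, ss_type=ss_type)
        fits.append(fit)
        calls.append(call_intervention_phenotype(fit, alpha=alpha))
    return fits, calls


# ---------------------------------------------------------------------------
# Category fractions
# ---------------------------------------------------------------------------

CATEGORY_KEYS = (
    "unaffected",
    "accentuated",
    "unevaluable",
    "countered_baseline",
    "countered_rate_or_combined",
)


def fractions_from_counts(counts: dict[str, int]) -> CategoryFractions:
    """Percentages of ASP categories from raw counts (half-up, 1 decimal)."""
    n_asp = sum(counts.values())
    if n_asp == 0:
        raise ValueError("n_asp is zero")
    pct = {k: round_pct(100.0 * v / n_asp) for k, v in counts.items()}
    return CategoryFractions("counts", n_asp, dict(counts), pct)


def category_fractions(
    calls: list[InterventionCall], route: str = "effectsize"
) -> CategoryFractions:
    """Tally ASP categories for one classification route.

    ``route`` is ``"interaction"`` (factorial-term route) or ``"effectsize"``
    (z-comparison route); the two may disagree for countered ASPs.
    """
    if route not in ("interaction", "effectsize"):
        raise ValueError(f"unknown route {route!r}")
    asps = [c for c in calls if c.is_asp]
    if not asps:
        raise ValueError("n_asp is zero")
    counts = {k: 0 for k in CATEGORY_KEYS}
    for c in asps:
        if c.direction in ("unaffected", "accentuated", "unevaluable"):
            counts[c.direction] += 1
            continue
        model = (
            c.model_interaction_route
            if route == "interaction"
            else c.model_effectsize_route
        )
        if model == "rate_or_combined":
            counts["countered_rate_or_combined"] += 1
        elif model == "baseline":
            counts["countered_baseline"] += 1
        else:
            counts["unevaluable"] += 1
    frac = fractions_from_counts(counts)
    return CategoryFractions(route, frac.n_asp, frac.counts, frac.percentages)


def annotate_with_baseline_onsets(
    calls: list[InterventionCall], trajectory_calls
) -> list[InterventionCall]:
    """Left-join stage-1 onset categories onto intervention calls by
    phenotype id; unmatched phenotypes keep onset None."""
    onset_by_id = {t.phenotype_id: t.onset for t in trajectory_calls}
    out = []
    missing = 0
    for c in calls:
        onset = onset_by_id.get(c.phenotype_id)
        if onset is None:
            missing += 1
        out.append(
            InterventionCall(
                c.phenotype_id, c.is_asp, c.direction,
                c.model_interaction_route, c.model_effectsize_route,
                onset_from_baseline_study=onset,
            )
        )
    if missing:
        warnings.warn(f"{missing} phenotypes had no baseline trajectory call")
    return out


def fits_to_frame(fits: list[TwoWayFit], calls: list[InterventionCall]) -> pd.DataFrame:
    call_by_id = {c.phenotype_id: c for c in calls}
    rows = []
    for f in fits:
        c = call_by_id[f.phenotype_id]
        rows.append(
            {
                "phenotype_id": f.phenotype_id,
                "scale": f.scale,
                "p_age": f.p_age,
                "p_intervention": f.p_intervention,
                "p_interaction": f.p_interaction,
                "d_age": f.d_age.d,
                "d_treat_old": f.d_treat_old.d,
                "d_treat_young": f.d_treat_young.d,
                "z_young_vs_old": f.comparison.z,
                "p_young_vs_old": f.comparison.p,
                "is_asp": c.is_asp,
                "direction": c.direction,
                "model_interaction_route": c.model_interaction_route,
                "model_effectsize_route": c.model_effectsize_route,
                "onset_from_baseline_study": c.onset_from_baseline_study,
            }
        )
    return pd.DataFrame(rows)
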