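"""Validation experiments on synthetic cohorts.

These are the package's own checks of the statistical machinery under
known ground truth: type-I calibration of every test family, recovery of
onset categories and intervention-model labels, and the discriminating
behaviour of the young-vs-old effect-size concordance slope between pure
baseline effects (slope 1) and pure rate effects (slope far below 1).

Problem sizes default to the study-design values (six age groups or a 2x2
design with 12 animals per cell); the concordance-slope experiment uses
larger cells so that effect-size estimation error stays small relative to
the between-phenotype spread of true effects — with 12 animals per cell
the OLS slope is visibly attenuated by errors-in-variables, which is a
property of the estimator, not of the implementation.
"""

from __future__ import annotations

import numpy as np

from . import core_stats as cs
from . import intervention, synthetic, trajectory


def _subseed(seed: int, k: int) -> int:
    return (int(seed) * 1_000_003 + k) % (2**31 - 1)


def null_calibration(
    n_phenotypes: int = 2000,
    n_per_group: int = 12,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict[str, float]:
    """Rejection rates at ``alpha`` under a global Gaussian null for every
    test family: one-way ANOVA, Kruskal-Wallis, each two-way ANOVA term and
    each aligned-rank-transform term. All should be ~alpha."""
    rng = np.random.default_rng(_subseed(seed, 1))
    ages = [str(a) for a in trajectory.DEFAULT_AGES]
    age22 = np.repeat(["young", "old"], 2 * n_per_group)
    arm22 = np.tile(np.repeat(["control", "treated"], n_per_group), 2)
    hits = {
        "anova1": 0, "kruskal": 0,
        "anova2_age": 0, "anova2_intervention": 0, "anova2_interaction": 0,
        "art_age": 0, "art_intervention": 0, "art_interaction": 0,
    }
    for _ in range(n_phenotypes):
        groups = {a: rng.normal(size=n_per_group) for a in ages}
        if cs.anova_oneway(groups).p < alpha:
            hits["anova1"] += 1
        if cs.kruskal_dunn(groups, ages[0])[0].p < alpha:
            hits["kruskal"] += 1
        y = rng.normal(size=4 * n_per_group)
        for r in cs.anova_twoway(y, age22, arm22):
            if r.p < alpha:
                hits[f"anova2_{r.term}"] += 1
        for r in cs.art_anova(y, age22, arm22):
            if r.p < alpha:
                hits[f"art_{r.term}"] += 1
    return {k: v / n_phenotypes for k, v in hits.items()}


def onset_recovery(
    n_phenotypes: int = 500,
    n_per_cell: int = 12,
    effect: float = 3.0,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Recovery of the age-at-first-detectable-change category on step
    phenotypes with a large (``effect`` SD) change, equal mix over the five
    onset ages. Returns overall accuracy and per-category recall."""
    spec = synthetic.SyntheticSpec(
        n_phenotypes=n_phenotypes,
        n_per_cell=n_per_cell,
        seed=_subseed(seed, 2),
        scale_mix={"continuous": 1.0},
        onset_mix={k: 0.2 for k in ("m5", "m8", "m14", "m20", "m26")},
        shape_mix={"step": 1.0},
        aging_effect=effect,
    )
    table, truth = synthetic.generate_baseline_cohort(spec)
    calls = trajectory.classify_cohort(table, alpha=alpha)
    call_by_id = {c.phenotype_id: c.onset for c in calls}
    per_cat_hits: dict[str, list[int]] = {}
    correct = 0
    for t in truth:
        hit = int(call_by_id[t.phenotype_id] == t.onset)
        correct += hit
        per_cat_hits.setdefault(t.onset, []).append(hit)
    return {
        "accuracy": correct / len(truth),
        "per_category": {k: float(np.mean(v)) for k, v in sorted(per_cat_hits.items())},
        "n": len(truth),
    }


EXPECTED_LABEL = {
    "null": "unaffected",
    "baseline": "countered_baseline",
    "rate": "countered_rate_or_combined",
    "combined": "countered_rate_or_combined",
    "accentuate": "accentuated",
}


def _call_category(call: intervention.InterventionCall) -> str:
    if call.direction != "countered":
        return call.direction
    if call.model_effectsize_route == "rate_or_combined":
        return "countered_rate_or_combined"
    return "countered_baseline"


def label_recovery(
    n_phenotypes: int = 400,
    n_per_cell: int = 12,
    aging_effect: float = 3.0,
    intervention_effect: float = 1.5,
    seed: int = 0,
    alpha: float = 0.05,
) -> dict:
    """Effect-size-route recovery of the generative intervention model on a
    mixed 2x2 cohort (equal mix over the five models, all phenotypes
    age-sensitive). Returns per-generative-label recall plus the fraction of
    pure-rate phenotypes miscalled as baseline."""
    spec = synthetic.SyntheticSpec(
        n_phenotypes=n_phenotypes,
        n_per_cell=n_per_cell,
        seed=_subseed(seed, 3),
        scale_mix={"continuous": 1.0},
        onset_mix={"m8": 1.0},
        model_mix={m: 0.2 for m in synthetic.MODELS},
        aging_effect=aging_effect,
        intervention_effect=intervention_effect,
    )
    table, truth = synthetic.generate_intervention_cohort(spec)
    _, calls = intervention.fit_cohort(table, alpha=alpha)
    cat_by_id = {c.phenotype_id: _call_category(c) for c in calls}
    hits: dict[str, list[int]] = {}
    rate_as_baseline = []
    for t in truth:
        got = cat_by_id[t.phenotype_id]
        hits.setdefault(t.model, []).append(int(got == EXPECTED_LABEL[t.model]))
        if t.model == "rate":
            rate_as_baseline.append(int(got == "countered_baseline"))
    return {
        "per_label": {k: float(np.mean(v)) for k, v in sorted(hits.items())},
        "rate_called_baseline": float(np.mean(rate_as_baseline)),
        "n": len(truth),
    }


def _d_pairs(table) -> tuple[np.ndarray, np.ndarray]:
    """(d_treat_young, d_treat_old) per phenotype, straight from the cells."""
    xs, ys = [], []
    for _, sub in table.groupby("phenotype_id", sort=True):
        age = sub["age_group"].to_numpy()
        arm = sub["arm"].to_numpy()
        v = sub["value"].astype(float).to_numpy()
        dy = cs.cohens_d_from_samples(
            v[(age == "young") & (arm == "control")],
            v[(age == "young") & (arm == "treated")],
        )
        do = cs.cohens_d_from_samples(
            v[(age == "old") & (arm == "control")],
            v[(age == "old") & (arm == "treated")],
        )
        if dy.defined and do.defined:
            xs.append(dy.d)
            ys.append(do.d)
    return np.asarray(xs), np.asarray(ys)


def slope_discrimination(
    n_reps: int = 200,
    n_phenotypes: int = 40,
    n_per_cell: int = 100,
    seed: int = 0,
) -> dict:
    """Coverage behaviour of the concordance-slope 95% CI.

    Pure-baseline cohorts (heterogeneous age-independent shifts, identical
    at both ages; true slope 1) should yield CIs covering 1; pure-rate
    cohorts (treatment effect only in old; young effects pure noise) should
    yield CIs excluding 1.
    """
    cover, exclude = 0, 0
    for rep in range(n_reps):
        spec_b = synthetic.SyntheticSpec(
            n_phenotypes=n_phenotypes,
            n_per_cell=n_per_cell,
            seed=_subseed(seed, 10_000 + rep),
            scale_mix={"continuous": 1.0},
            onset_mix={"m8": 1.0},
            model_mix={"baseline": 1.0},
            intervention_effect_range=(1.2, 3.0),
        )
        tb, _ = synthetic.generate_intervention_cohort(spec_b)
        x, y = _d_pairs(tb)
        st = cs.concordance(x, y)
        if st.ci95[0] <= 1.0 <= st.ci95[1]:
            cover += 1
        spec_r = synthetic.SyntheticSpec(
            n_phenotypes=n_phenotypes,
            n_per_cell=n_per_cell,
            seed=_subseed(seed, 20_000 + rep),
            scale_mix={"continuous": 1.0},
            onset_mix={"m8": 1.0},
            model_mix={"rate": 1.0},
            orient_age_effects=True,
        )
        tb, _ = synthetic.generate_intervention_cohort(spec_r)
        x, y = _d_pairs(tb)
        st = cs.concordance(x, y)
        if not (st.ci95[0] <= 1.0 <= st.ci95[1]):
            exclude += 1
    return {
        "baseline_ci_covers_1": cover / n_reps,
        "rate_ci_excludes_1": exclude / n_reps,
        "n_reps": n_reps,
    }
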