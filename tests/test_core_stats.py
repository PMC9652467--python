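"""Unit tests of the statistical primitives against hand computations,
closed forms, enumeration oracles and independent library routes."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from paai import core_stats as cs

import oracles


# ---------------------------------------------------------------------------
# Summaries and effect sizes
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "values, n, mean, sd",
    [
        ([2, 2, 2], 3, 2.0, 0.0),
        ([1, 2, 3], 3, 2.0, 1.0),
        ([5], 1, 5.0, float("nan")),
    ],
)
def test_summarize_groups(values, n, mean, sd):
    (g,) = cs.summarize_groups({"A": values})
    assert (g.n, g.mean) == (n, mean)
    assert math.isnan(g.sd) if math.isnan(sd) else g.sd == pytest.approx(sd)


def test_summarize_groups_rejects_empty():
    with pytest.raises(ValueError, match="no data"):
        cs.summarize_groups({})


def test_cohens_d_worked_examples():
    assert cs.cohens_d_from_samples([1, 2, 3], [1, 2, 3]).d == 0.0
    es = cs.cohens_d_from_samples([1, 2, 3], [3, 4, 5])
    assert es.d == pytest.approx(2.0)  # pooled SD is exactly 1
    const = cs.cohens_d_from_samples([2, 2, 2], [2, 2, 2])
    assert not const.defined and "SD" in const.reason
    tiny = cs.cohens_d_from_samples([1], [1, 2])
    assert not tiny.defined


@given(
    st.lists(st.floats(-50, 50), min_size=3, max_size=8),
    st.lists(st.floats(-50, 50), min_size=3, max_size=8),
)
@settings(max_examples=60, derandomize=True)
def test_cohens_d_antisymmetry(a, b):
    ab = cs.cohens_d_from_samples(a, b)
    ba = cs.cohens_d_from_samples(b, a)
    assert ab.defined == ba.defined
    if ab.defined:
        assert ab.d == pytest.approx(-ba.d, abs=1e-10)


def test_d_variance_formula():
    assert cs.d_variance(cs.EffectSize(0, 10, 10, 0, True)) == pytest.approx(0.2)
    assert cs.d_variance(cs.EffectSize(1, 10, 10, 0, True)) == pytest.approx(0.225)
    big = cs.d_variance(cs.EffectSize(1, 10**7, 10**7, 0, True))
    assert big < 1e-6


def test_compare_effect_sizes():
    d0 = cs.EffectSize(0.0, 10, 10, cs.d_variance(cs.EffectSize(0, 10, 10, 0, True)), True)
    d1 = cs.EffectSize(1.0, 10, 10, cs.d_variance(cs.EffectSize(1, 10, 10, 0, True)), True)
    same = cs.compare_effect_sizes(d1, d1)
    assert same.z == 0 and same.p == pytest.approx(1.0) and not same.old_larger
    cmp01 = cs.compare_effect_sizes(d0, d1)
    assert cmp01.z == pytest.approx(1 / math.sqrt(0.425), rel=1e-6)
    assert cmp01.p == pytest.approx(0.1250, abs=5e-4)
    swapped = cs.compare_effect_sizes(d1, d0)
    assert swapped.z == pytest.approx(-cmp01.z) and swapped.p == pytest.approx(cmp01.p)
    undef = cs.EffectSize(float("nan"), 2, 2, float("nan"), False)
    assert not cs.compare_effect_sizes(undef, d1).evaluable


# ---------------------------------------------------------------------------
# One-way ANOVA / LSD
# ---------------------------------------------------------------------------

THREE_GROUPS = {"a": [1, 2, 3], "b": [2, 3, 4], "c": [3, 4, 5]}


def test_anova_oneway_hand_example():
    r = cs.anova_oneway(THREE_GROUPS)
    assert r.statistic == pytest.approx(3.0)
    assert r.df == (2, 6)
    # closed form for df1=2: p = (1 + 2F/df2)^(-df2/2) = 2^-3
    assert r.p == pytest.approx(0.125)


def test_anova_oneway_equal_means():
    r = cs.anova_oneway({"a": [1, 3], "b": [1, 3], "c": [2, 2]})
    assert r.statistic == pytest.approx(0.0) and r.p == pytest.approx(1.0)


def test_anova_oneway_matches_scipy(rng):
    groups = {k: rng.normal(size=7) for k in "abcd"}
    r = cs.anova_oneway(groups)
    F, p = stats.f_oneway(*groups.values())
    assert r.statistic == pytest.approx(F) and r.p == pytest.approx(p)


def test_anova_oneway_two_groups_is_t_squared(rng):
    a, b = rng.normal(size=8), rng.normal(0.5, 1, size=6)
    r = cs.anova_oneway({"a": a, "b": b})
    t, p = stats.ttest_ind(a, b)
    assert r.statistic == pytest.approx(t**2)
    assert r.p == pytest.approx(p)


def test_anova_oneway_degenerate():
    with pytest.raises(ValueError, match="degenerate"):
        cs.anova_oneway({"a": [1, 1], "b": [1, 1]})
    r = cs.anova_oneway({"a": [1, 1], "b": [2, 2]})
    assert r.p == 0.0


def test_fisher_lsd_hand_example():
    post = cs.fisher_lsd(THREE_GROUPS, "a")
    # t = 2 / sqrt(MSE * 2/3) with MSE = 1, df = 6
    assert post.p_for("c") == pytest.approx(0.0499, abs=2e-4)
    assert post.sign_for("c") == 1


def test_fisher_lsd_identical_to_reference():
    post = cs.fisher_lsd({"a": [1, 2, 3], "b": [1, 2, 3]}, "a")
    assert post.p_for("b") == pytest.approx(1.0) and post.sign_for("b") == 0


def test_fisher_lsd_two_groups_equals_pooled_t(rng):
    a, b = rng.normal(size=9), rng.normal(0.3, 1.2, size=5)
    post = cs.fisher_lsd({"a": a, "b": b}, "a")
    _, p = stats.ttest_ind(a, b)
    assert post.p_for("b") == pytest.approx(p)


# ---------------------------------------------------------------------------
# Kruskal-Wallis / Dunn
# ---------------------------------------------------------------------------

def test_kruskal_matches_rank_formula(rng):
    groups = {"a": [1, 2], "b": [3, 4], "c": [5, 6]}
    omni, _ = cs.kruskal_dunn(groups, "a")
    assert omni.statistic == pytest.approx(oracles.kruskal_h(groups))
    tied = {k: np.round(rng.normal(size=8), 0) for k in "abc"}
    omni, _ = cs.kruskal_dunn(tied, "a")
    assert omni.statistic == pytest.approx(oracles.kruskal_h(tied))


def test_kruskal_label_invariance(rng):
    vals = [rng.normal(size=6) for _ in range(3)]
    h1 = cs.kruskal_dunn({"a": vals[0], "b": vals[1], "c": vals[2]}, "a")[0]
    h2 = cs.kruskal_dunn({"x": vals[2], "y": vals[0], "z": vals[1]}, "y")[0]
    assert h1.statistic == pytest.approx(h2.statistic)


def test_kruskal_all_tied():
    omni, post = cs.kruskal_dunn({"a": [1, 1], "b": [1, 1]}, "a")
    assert omni.p == 1.0 and post.p_for("b") == 1.0


def test_dunn_two_groups_equals_mwu_normal_approx(rng):
    a = np.round(rng.normal(size=10), 0)  # ties on purpose
    b = np.round(rng.normal(0.8, 1, size=8), 0)
    _, post = cs.kruskal_dunn({"a": a, "b": b}, "a")
    mwu = cs.mann_whitney(a, b)
    assert post.p_for("b") == pytest.approx(mwu.p, rel=1e-10)


# ---------------------------------------------------------------------------
# Fisher exact r x c
# ---------------------------------------------------------------------------

def test_fisher_exact_2x2_enumeration():
    omni, _ = cs.fisher_exact_table([[3, 0], [0, 3]])
    assert omni.p == pytest.approx(2 / 20)  # 2 / C(6,3)


def test_fisher_exact_identical_columns():
    omni, _ = cs.fisher_exact_table([[2, 2], [3, 3]])
    assert omni.p == pytest.approx(1.0)


def test_fisher_exact_transpose_invariance():
    t = np.array([[3, 1], [1, 4]])
    assert cs.fisher_exact_table(t)[0].p == pytest.approx(
        cs.fisher_exact_table(t.T)[0].p
    )


def test_fisher_exact_matches_scipy_2x2(rng):
    for _ in range(10):
        t = rng.integers(0, 6, size=(2, 2))
        if (t.sum(0) == 0).any() or (t.sum(1) == 0).any():
            continue
        ours = cs.fisher_exact_table(t)[0].p
        _, p = stats.fisher_exact(t)
        assert ours == pytest.approx(p, rel=1e-9)


def test_fisher_exact_matches_enumeration_oracle(rng):
    for shape in [(2, 2), (2, 3), (3, 3)]:
        for _ in range(5):
            t = rng.integers(0, 3, size=shape)
            if (t.sum(0) == 0).any() or (t.sum(1) == 0).any() or t.sum() < 2:
                continue
            assert cs.fisher_exact_table(t)[0].p == pytest.approx(
                oracles.exact_rxc_p(t), rel=1e-9
            )


def test_fisher_exact_montecarlo_close_to_exact(rng):
    t = rng.integers(0, 8, size=(2, 4)) + 1
    exact = cs.fisher_exact_table(t)[0].p
    mc = cs.fisher_exact_table(t, exact_max_n=1, n_mc=40_000, mc_seed=5)[0].p
    assert mc == pytest.approx(exact, abs=0.02)


def test_fisher_exact_zero_margin_dropped():
    with pytest.warns(UserWarning, match="zero-margin"):
        omni, _ = cs.fisher_exact_table([[3, 0, 1], [2, 0, 4]])
    assert 0 <= omni.p <= 1


def test_fisher_exact_pairwise_reference():
    t = [[5, 5, 0], [0, 0, 5]]
    _, post = cs.fisher_exact_table(t, column_labels=["3", "5", "8"], reference_label="3")
    assert post.p_for("5") == pytest.approx(1.0)
    assert post.p_for("8") < 0.02
    assert post.sign_for("8") == 1


# ---------------------------------------------------------------------------
# Two-way ANOVA
# ---------------------------------------------------------------------------

def _design(n):
    age = np.repeat(["young", "old"], 2 * n)
    arm = np.tile(np.repeat(["control", "treated"], n), 2)
    return age, arm


def test_anova_twoway_matches_statsmodels_unbalanced(rng):
    import pandas as pd
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    age = np.array(["young"] * 9 + ["old"] * 13)
    arm = np.array(["control"] * 5 + ["treated"] * 4 + ["control"] * 6 + ["treated"] * 7)
    y = rng.normal(size=22) + (age == "old") * 0.5
    df = pd.DataFrame({"y": y, "a": age, "b": arm})
    fit = smf.ols("y ~ C(a) * C(b)", df).fit()
    for typ, ss in ((2, "II"), (1, "I")):
        an = sm.stats.anova_lm(fit, typ=typ)
        ours = {r.term: r for r in cs.anova_twoway(y, age, arm, ss_type=ss)}
        rows = (
            {"age": "C(a)", "intervention": "C(b)", "interaction": "C(a):C(b)"}
        )
        for term, row in rows.items():
            assert ours[term].statistic == pytest.approx(an.loc[row, "F"], rel=1e-8)
            assert ours[term].p == pytest.approx(an.loc[row, "PR(>F)"], rel=1e-8)


def test_anova_twoway_matches_cellmean_oracle(rng):
    age, arm = _design(3)
    y = rng.normal(size=12)
    ss = oracles.twoway_ss_balanced(y, age, arm)
    mse = ss["error"] / (12 - 4)
    ours = {r.term: r for r in cs.anova_twoway(y, age, arm)}
    for term in ("age", "intervention", "interaction"):
        assert ours[term].statistic == pytest.approx(ss[term] / mse, rel=1e-9)


def test_anova_twoway_pure_age_effect(rng):
    age, arm = _design(8)
    y = (age == "old") * 3.0 + rng.normal(0, 0.05, size=32)
    res = {r.term: r for r in cs.anova_twoway(y, age, arm)}
    assert res["age"].p < 1e-6
    assert res["intervention"].p > 0.05 and res["interaction"].p > 0.05


def test_anova_twoway_additive_means_zero_interaction():
    age, arm = _design(3)
    y = 1.0 + (age == "old") * 2.0 + (arm == "treated") * 0.7
    y = y + np.tile([-0.1, 0.0, 0.1], 4)  # within-cell spread, no interaction
    res = {r.term: r for r in cs.anova_twoway(y, age, arm)}
    assert res["interaction"].statistic == pytest.approx(0.0, abs=1e-18)


def test_anova_twoway_incomplete_design():
    age = np.array(["young"] * 4 + ["old"] * 2)
    arm = np.array(["control", "control", "treated", "treated", "control", "control"])
    with pytest.raises(ValueError, match="incomplete"):
        cs.anova_twoway(np.arange(6.0), age, arm)


# ---------------------------------------------------------------------------
# Aligned Rank Transform
# ---------------------------------------------------------------------------

def test_art_alignment_strips_other_terms(rng):
    # alignment removes the *estimated* effects of the stripped terms, so on
    # a balanced design their SS on the aligned responses is exactly zero
    age, arm = _design(3)
    y = 0.5 + (age == "old") * 2.0 + (arm == "treated") * 1.0 + rng.normal(0, 0.3, 12)
    for term in ("age", "intervention", "interaction"):
        aligned = cs.aligned_responses(y, age, arm, term)
        assert abs(aligned.sum()) < 1e-8
        res = {r.term: r for r in cs.anova_twoway(aligned, age, arm)}
        for other in set(res) - {term}:
            assert res[other].statistic < 1e-8


def test_art_matches_stepwise_oracle(rng):
    age, arm = _design(5)
    y = rng.normal(size=20) + (age == "old") * 0.8
    ours = {r.term: r for r in cs.art_anova(y, age, arm)}
    ref = oracles.art_oracle(y, age, arm)
    for term, (F, p) in ref.items():
        assert ours[term].statistic == pytest.approx(F, rel=1e-8)
        assert ours[term].p == pytest.approx(p, rel=1e-8)


def test_art_degenerate_alignment():
    age, arm = _design(2)
    y = (age == "old") * 1.0  # pure age effect, nothing left for interaction
    with pytest.warns(UserWarning, match="degenerate alignment"):
        res = {r.term: r for r in cs.art_anova(y, age, arm)}
    assert res["interaction"].p == 1.0


# ---------------------------------------------------------------------------
# Mann-Whitney
# ---------------------------------------------------------------------------

def test_mwu_exact_enumeration():
    r = cs.mann_whitney([1, 2, 3], [4, 5, 6])
    assert r.p == pytest.approx(0.1)
    assert r.p == pytest.approx(oracles.mwu_exact_p([1, 2, 3], [4, 5, 6]))


def test_mwu_identical_samples():
    assert cs.mann_whitney([1, 2, 2], [1, 2, 2]).p == pytest.approx(1.0)


@given(st.lists(st.floats(-10, 10), min_size=2, max_size=6, unique=True))
@settings(max_examples=40, derandomize=True)
def test_mwu_swap_symmetry(a):
    b = [x + 0.3 for x in a]
    assert cs.mann_whitney(a, b).p == pytest.approx(cs.mann_whitney(b, a).p)


# ---------------------------------------------------------------------------
# Concordance
# ---------------------------------------------------------------------------

def test_concordance_identity_pairs():
    c = cs.concordance([1, 2, 3, 4], [1, 2, 3, 4])
    assert c.pearson_r == pytest.approx(1.0)
    assert c.icc == pytest.approx(1.0)
    assert c.slope == pytest.approx(1.0)
    assert c.p_slope_vs_1 == 1.0


def test_concordance_shifted_pairs_agreement_icc():
    # consistency correlation is 1 but absolute agreement is 10/13
    c = cs.concordance([1, 2, 3, 4], [2, 3, 4, 5])
    assert c.pearson_r == pytest.approx(1.0)
    assert c.icc == pytest.approx(10 / 13, abs=1e-9)


def test_concordance_hand_ols_example():
    c = cs.concordance([0, 1, 2, 3], [0, 2, 2, 4])
    assert c.slope == pytest.approx(1.2)
    assert c.se_slope == pytest.approx(math.sqrt(0.08), rel=1e-9)
    assert c.p_slope_vs_1 == pytest.approx(0.553, abs=2e-3)
    assert c.ci95[0] < c.slope < c.ci95[1]


def test_concordance_icc_matches_variance_component_oracle(rng):
    x = rng.normal(size=12)
    y = 0.8 * x + rng.normal(0, 0.4, size=12)
    c = cs.concordance(x, y)
    assert c.icc == pytest.approx(oracles.icc_a1(x, y), abs=1e-8)


def test_concordance_errors():
    with pytest.raises(ValueError, match="insufficient"):
        cs.concordance([1, 2], [1, 2])
    with pytest.raises(ValueError, match="constant"):
        cs.concordance([1, 1, 1], [1, 2, 3])


# ---------------------------------------------------------------------------
# Hypergeometric overlap
# ---------------------------------------------------------------------------

def test_hypergeom_overlap_enumeration():
    r = cs.hypergeom_overlap(10, 5, 4, 4)
    assert r.expected == pytest.approx(2.0)
    assert r.representation_factor == pytest.approx(2.0)
    assert r.p == pytest.approx(5 / 210)
    assert r.p == pytest.approx(oracles.hypergeom_tail(10, 5, 4, 4))


def test_hypergeom_overlap_monotone_in_overlap():
    rs = [cs.hypergeom_overlap(100, 20, 30, k) for k in range(2, 10)]
    rf = [r.representation_factor for r in rs]
    ps = [r.p for r in rs]
    assert all(a < b for a, b in zip(rf, rf[1:]))
    assert all(a > b for a, b in zip(ps, ps[1:]))


def test_hypergeom_overlap_errors():
    with pytest.raises(ValueError):
        cs.hypergeom_overlap(10, 5, 4, 5)
    with pytest.raises(ValueError):
        cs.hypergeom_overlap(10, 0, 4, 0)


# ---------------------------------------------------------------------------
# Standardized coefficients
# ---------------------------------------------------------------------------

def test_standardized_lm_recovers_pure_age_effect():
    age, arm = _design(4)
    y = (age == "old") * 1.0 + np.tile([0.0, 1e-6, -1e-6, 2e-6], 4)
    sc = cs.standardized_lm(y, age, arm)
    b_age = sc.coefficients["age"][0]
    assert b_age == pytest.approx(1.0 / np.std(y, ddof=1), rel=1e-3)
    assert abs(sc.coefficients["interaction"][0]) < 1e-2


def test_standardized_lm_scale_invariance(rng):
    age, arm = _design(4)
    y = rng.normal(size=16) + (arm == "treated") * 0.6
    a = cs.standardized_lm(y, age, arm)
    b = cs.standardized_lm(2.5 * y, age, arm)
    for term in ("age", "intervention", "interaction"):
        assert a.coefficients[term] == pytest.approx(b.coefficients[term], rel=1e-9)


def test_standardized_lm_matches_normal_equations(rng):
    age, arm = _design(4)
    y = rng.normal(size=16)
    sc = cs.standardized_lm(y, age, arm)
    beta = oracles.normal_equations_coefs(
        y, (age == "old").astype(float), (arm == "treated").astype(float)
    )
    assert sc.coefficients["age"][0] == pytest.approx(beta[1], rel=1e-9)
    assert sc.coefficients["intervention"][0] == pytest.approx(beta[2], rel=1e-9)
    assert sc.coefficients["interaction"][0] == pytest.approx(beta[3], rel=1e-9)
    lo, hi = sc.coefficients["age"][1:]
    assert lo < beta[1] < hi
    assert (beta[1] - lo) == pytest.approx(hi - beta[1], rel=1e-9)  # symmetric CI


def test_standardized_lm_constant_outcome():
    age, arm = _design(2)
    with pytest.raises(ValueError, match="constant"):
        cs.standardized_lm(np.ones(8), age, arm)
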