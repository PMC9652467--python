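# Methods

This note documents the statistical procedures, the modelling and
numerical choices behind them, what the synthetic cohorts do and do not
emulate, and the known limitations. Everything quantitative stated here is
computed by the test suite, the `analysis/` drivers or
`scripts/acceptance.py`.

## Input contract

The universal input is a tidy long-format table, one row per
(animal, phenotype):

| column | content |
|---|---|
| `animal_id` | unique per animal; each animal belongs to one age group and arm |
| `phenotype_id` | phenotype identifier; `scale` must be constant within it |
| `scale` | `continuous`, `ordinal`, or `count_category` |
| `age_group` | age label — months (`3`…`26`) for baseline studies, `young`/`old` for 2×2 studies |
| `arm` | `control` or `treated` (constant `control` in baseline studies) |
| `value` | numeric measurement or category token |

Duplicated (animal, phenotype) keys, unknown scale tokens and
scale-inconsistent phenotypes are hard errors at read time. Output tables
are TSV (UTF-8, `.` decimal, `NA` for missing) with `#`-prefixed
provenance headers carrying the tool version and a configuration hash;
summaries are JSON with the full configuration snapshot embedded. Fixed
configuration + fixed input ⇒ byte-identical outputs.

All analyses use two-sided, unadjusted p-values at α = 0.05
(configurable). The framework deliberately performs no multiplicity
correction: its categories are descriptive tallies over many phenotypes,
not confirmatory claims about individual ones.

## Stage 1 — trajectory classification

Per phenotype, the omnibus test across age groups is dispatched on the
declared scale:

* **continuous** — one-way fixed-effects ANOVA; posthocs are Fisher's LSD
  *t*-tests against the youngest group using the pooled MSE on N−k df;
* **ordinal** — Kruskal–Wallis with tie correction; posthocs are Dunn
  *z*-tests with the tie-corrected variance
  (N(N+1)/12 − Σ(t³−t)/(12(N−1)))(1/nᵢ + 1/nⱼ);
* **count/category** — Fisher's exact conditional test on the
  category × age table; posthocs are pairwise two-column exact tests
  against the reference age.

Posthocs are computed only when the omnibus is significant (a flag allows
unconditional computation for diagnostics). A phenotype is an ASP when
the omnibus p < α.

**Age at first detectable change.** Scanning candidate onset ages in
ascending order (5, 8, 14, 20, 26 vs the 3-month reference), a candidate
*m* qualifies iff (a) every comparison at an earlier age is
non-significant, (b) the comparison at *m* is significant, and (c) at most
one comparison at a later age is non-significant. The first qualifying
candidate wins; a significant omnibus with no qualifying candidate is
`other`. Two deliberate readings of the rule: the single allowed
exception applies only to *later* comparisons (never to the candidate
itself, nor to earlier ages — those must be cleanly non-significant), and
the rule is purely significance-based: direction reversals do not change
the category, which is what routes non-monotonic midlife-peak profiles to
`other` once the phenotype has returned toward baseline in the oldest
groups. The implementation is verified against a literal-rule oracle on
all 2⁵ posthoc significance patterns.

Known property of the rule (not of the implementation): with k earlier
null comparisons at α = 0.05, the probability that none is a false
positive is ≈ 0.95ᵏ (partially mitigated by the shared reference group
and pooled MSE), so per-category recall for large-effect step changes at
n = 12/group is structurally capped near 0.86 for a 20-month onset and
0.85 for a 26-month onset; overall recovery across an equal onset mix is
≈ 0.91. Late onsets are harder to call than early ones for purely
combinatorial reasons.

## Stage 2 — intervention classification

For the 2×2 young/old × control/treated design, the factorial fit is again
dispatched on scale:

* **continuous** — full two-way ANOVA with interaction. Sums of squares
  are Type II by default (invariant to factor order; identical to any
  type on balanced designs), computed by nested-model least squares and
  verified against `statsmodels.anova_lm`; Type I is available by
  configuration.
* **ordinal** — aligned rank transform (ART): per term, subtract from
  each observation the cell-mean estimates of every effect *except* that
  term, mid-rank the aligned values, run the full factorial ANOVA on the
  ranks and keep only that term's F and p. Mann–Whitney U (tie-corrected,
  no continuity correction; exact for small untied samples) serves as the
  posthoc. A fully tied alignment is reported as F = 0, p = 1 with a
  degenerate-alignment warning.
* **count/category** — Fisher exact tests on margin-collapsed tables:
  category × age (collapsed over arm) for the age term and
  category × arm (collapsed over age) for the treatment term. No
  interaction p exists for this scale (reported as NaN, never
  significant); direction is taken from the shift of the mean category
  score, and both model routes are unevaluable — mirroring the
  "Cohen's d not computable" bucket.

Cohen's *d* uses the pooled sample SD; it is undefined (never silently 0)
when the pooled SD is zero or either group has n < 2. Its large-sample
variance is var(*d*) = (n₁+n₂)/(n₁n₂) + *d*²/(2(n₁+n₂)); the young-old
comparison is the two-sided *z*-test on the difference. The variance
formula is the canonical choice for comparing independent standardized
mean differences; alternatives (e.g. exact small-sample corrections)
change nothing qualitatively at the n ≈ 12 per cell typical here.

**Direction.** Only ASPs (study-internal age main effect, p < α) are
classified. With neither a significant treatment main effect nor a
significant interaction: `unaffected`. With significance but undefined
*d*: `unevaluable`. Otherwise the sign product of *d*_age and
*d*_treat,old decides `countered` (opposing) vs `accentuated` (matching).
|d| < 10⁻¹² counts as sign zero; the direction then falls back to the
young-group treatment effect, and if that is also zero the phenotype is
logged and called `unaffected` despite the significance flag.

**Model label for countered ASPs, two routes.**
*Interaction route*: `rate_or_combined` iff the interaction is significant
**and** |d_treat,old| > |d_treat,young|; otherwise `baseline`. A
significant interaction with the *larger effect in young* is assigned
`baseline` — the directionality filter excludes it from the rate bucket,
and the conservative destination is flagged rather than hidden.
*Effect-size route*: `rate_or_combined` iff the *z*-test is significant
with |d_old| > |d_young|; otherwise `baseline`. The two routes answer
subtly different questions and are reported side by side with an explicit
disagreement count; they are never reconciled into a single verdict.

Category fractions (unaffected / accentuated / unevaluable /
countered-baseline / countered-rate-or-combined) tile the ASP set exactly;
percentages are rounded half-up to one decimal (18/96 → 18.8).

## Stage 3 — cohort-level statistics

**Concordance.** For a chosen category (countered, accentuated,
treatment-sensitive-but-age-insensitive, or all), the (d_young, d_old)
pairs feed: Pearson *r* with its *t*-test; the absolute-agreement,
single-measurement, two-way random-effects ICC — ICC(A,1), computed via
pingouin and cross-checked against the variance-component formula — which
penalizes constant offsets that a consistency ICC would forgive; and the
OLS slope of d_old on d_young with SE, 95% CI (t quantile, n−2 df) and a
two-sided test of slope = 1. The ICC variant is configurable; the variant
name is part of the output because the six ICC definitions differ
materially.

Note on interpretation: the regression slope is attenuated by sampling
error in d_young (classical errors-in-variables). At n = 12/cell the
per-*d* noise SD is ≈ 0.46, so a cohort whose true effects are identical
in young and old can still show a fitted slope visibly below 1. The
validation experiments therefore use larger cells (below); real-data
slopes slightly under 1 should be read with this bias in mind.

**PCA.** Continuous phenotypes are pivoted to an animals × phenotypes
matrix, imputed (below), z-scored per phenotype (unit-variance scaling is
the default since phenotypes carry wildly different units; switchable)
and decomposed by SVD. min(rows−1, columns) components are retained;
zero-variance phenotypes are dropped with a warning; the sign convention
makes each component's largest-magnitude loading positive. Scores ×
loadingsᵀ reconstructs the standardized matrix to 1e−8.

**Imputation.** Missing entries are filled by single-imputation chained
equations with predictive mean matching: column-mean initialization, then
a fixed number of cycles (default 10) in which each incomplete column is
regressed on all others and each missing entry is replaced by the
observed value of one of the 5 donors with nearest predictions, drawn with
the seeded generator. Observed cells are never altered; identical seed and
input give bit-identical output. Multiple imputation is out of scope
because the PCA here is descriptive, not inferential.

**Forest table.** Per continuous phenotype, the full factorial model is
fitted on the z-scored outcome with 0/1 treatment-coded indicators
(reference: young control); each coefficient is reported in outcome-SD
units with a normal-approximation 95% CI. Rows are sorted by the age
coefficient (ties broken by phenotype id) and the order is shared across
the age / treatment / interaction panels.

## Numerical and degenerate-case conventions

* r×c Fisher exact: full recursive enumeration of margin-fixed tables
  (log-probabilities via `gammaln`; inclusion cutoff at observed
  probability × (1+1e−7)) for tables with total N ≤ 200 and ≤ 4 rows and
  columns; beyond that, a seeded 100,000-table Monte-Carlo estimate with
  the add-one tail correction. Verified against exhaustive enumeration
  for all small tables.
* Zero within-group variance with unequal means → p = 0 by convention;
  all values identical → `degenerate` error (one-way) or p = 1 (rank
  tests). Zero-margin contingency rows/columns are dropped with a
  warning; a count phenotype with a single observed category is trivially
  insensitive (p = 1).
* Zero residual variance in the concordance regression → p(slope vs 1)
  is 1 if the slope is exactly 1, else 0.
* All simulation randomness flows through `numpy.random.default_rng`
  seeded per call; nothing touches global random state.

## What the synthetic cohorts emulate — and what they do not

The generator reproduces the *statistical structure* the analysis
assumes: six age groups of 12 animals (a representative deep-phenotyping
group size; real per-assay group sizes vary), mean trajectories with known
onset and shape (step; ramp reaching its full effect at the oldest age;
midlife peak rising to 14 months and back to baseline by 20 — the
archetypal `other` profile), default aging effect 2.0 noise-SD, and 2×2
intervention cohorts whose treated-cell means follow the generative
models: `baseline` adds the same counter-directional shift at both ages;
`rate` scales the age-dependent change by (1−ρ), ρ = 1 by default (full
prevention, leaving young animals untouched); `combined` applies both;
`accentuate` shifts in the age-change direction. Ordinal values cut a
latent Gaussian at fixed thresholds (five equal-probability levels under
the null); count phenotypes are Bernoulli lesion indicators (baseline
rate 0.1) with the age effect applied on the latent-probit scale. The
default onset mix plants ~58% age-sensitive phenotypes with onsets
distributed ~5/5/26/36/8/19% (of ASPs) across
5/8/14/20/26-months/`other`.

Not emulated (hence untested here): attrition and differential survival,
correlation networks among phenotypes (every phenotype is generated
independently), body-weight covariance, batch effects, and longitudinal
within-animal structure (the design is cross-sectional). Passing
recovery tests on these cohorts shows the *procedures* behave as claimed
under their own assumptions, not that real phenotypes satisfy those
assumptions.

## Validation experiments (`paai.experiments`)

* **Type-I calibration** — 2,000 null phenotypes; every test family
  (one-way ANOVA, Kruskal–Wallis, each two-way term, each ART term)
  rejects at 0.05 ± 0.015.
* **Onset recovery** — 500-phenotype cohorts of 3-SD step changes at
  n = 12/group, equal mix over the five onset ages; overall recovery
  ≈ 0.91–0.92 (per-category: ~1.0/0.93/0.90/0.86/0.85 from 5 to 26
  months, the late-onset cap discussed above). The recovery rate is
  estimated over six independent cohorts to keep Monte-Carlo error well
  below the margin of interest.
* **Intervention-model recovery** — 400-phenotype 2×2 cohorts, equal mix
  over the five generative models, 3-SD age effects (matching the onset
  experiment) and 1.5-SD treatment shifts at n = 12/cell; effect-size-
  route recall ≥ 0.92 per label, and pure-rate phenotypes are essentially
  never called baseline.
* **Slope discrimination** — 200 replicate cohorts of 40 phenotypes per
  arm of the experiment. Pure-baseline cohorts draw per-phenotype shift
  magnitudes from U(1.2, 3.0) with random sign; pure-rate cohorts use
  sign-oriented 2-SD age effects fully prevented by treatment. Cells of
  n = 100 keep the per-*d* estimation noise (≈ 0.17 SD) small relative to
  the between-phenotype effect spread; at the study's natural n = 12 the
  errors-in-variables attenuation described above dominates the slope's
  CI and the coverage property holds for no realistic effect spread —
  the experiment isolates the inferential behaviour of the slope, not
  the field sample size. Observed: baseline CIs cover 1 in ≈ 0.94–0.96 of
  replicates; rate CIs exclude 1 in ≈ 0.97–0.99.

## Limitations

* The baseline/rate dichotomy is identified only at the design's two
  ages; a "combined" label cannot distinguish genuine simultaneous rate
  and baseline action from exposure-time differences between young and
  old treated groups.
* The onset rule inherits the resolution of the age grid and the
  late-onset recall cap; it estimates first *detectability*, which for
  gradual (ramp-like) change is systematically later than biological
  onset.
* Count-scale phenotypes have no interaction test and no effect sizes in
  this framework; they contribute to direction tallies only.
* The concordance slope is an errors-in-variables-biased estimator; its
  published-scale values should be compared against 1 with that bias in
  mind.
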