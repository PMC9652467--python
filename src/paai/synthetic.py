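"""Synthetic cohorts with known ground truth.

The generator emulates the two study designs the analysis framework is
built for:

* a baseline aging cohort — six age groups (3, 5, 8, 14, 20, 26 months) of
  male mice, each phenotype following a lifetime trajectory with a known
  onset age and shape (step, ramp, or a midlife-peak archetype of the
  non-monotonic "other" class);
* a 2x2 intervention cohort — young/old x control/treated, with treatment
  effects generated under known models: ``null`` (no effect), ``baseline``
  (the same counter-directional shift at both ages), ``rate`` (the
  age-dependent change scaled by 1 - rho, no effect in young), ``combined``
  (both), or ``accentuate`` (a shift in the direction of the age change).

Measurement scales: continuous phenotypes are Gaussian around the mean
trajectory; ordinal phenotypes cut a latent Gaussian at fixed thresholds
into five levels (equal probability under the null); count/category
phenotypes are Bernoulli lesion indicators with an age-dependent rate.

All randomness flows through one seeded numpy Generator.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from scipy import stats

DEFAULT_AGES = (3, 5, 8, 14, 20, 26)
ONSETS = ("m5", "m8", "m14", "m20", "m26", "other", "null")
SHAPES = ("step", "ramp", "midlife_peak")
MODELS = ("null", "baseline", "rate", "combined", "accentuate")

GT_SCHEMA_VERSION = 1

# five ordinal levels, equal probability under a standard-normal latent
ORDINAL_CUTS = stats.norm.ppf([0.2, 0.4, 0.6, 0.8])


@dataclass(frozen=True)
class SyntheticSpec:
    """Generative settings for a synthetic cohort.

    Effect sizes are in units of the residual (noise) SD; ``aging_effect``
    is the full young-to-old change of an age-sensitive phenotype,
    ``intervention_effect`` the age-independent (baseline) treatment shift,
    ``rate_rho`` the fraction of age-dependent change prevented by a rate
    effect (1 = full prevention).
    """

    n_phenotypes: int = 100
    n_per_cell: int = 12
    seed: int = 0
    age_groups: tuple = DEFAULT_AGES
    scale_mix: dict = field(
        default_factory=lambda: {"continuous": 0.7, "ordinal": 0.2, "count_category": 0.1}
    )
    onset_mix: dict = field(
        default_factory=lambda: {
            # ~59% of phenotypes age-sensitive, with the observed onset
            # distribution (~5/5/26/36/8/19% of ASPs) among those
            "m5": 0.03, "m8": 0.03, "m14": 0.15, "m20": 0.21, "m26": 0.05,
            "other": 0.11, "null": 0.42,
        }
    )
    shape_mix: dict = field(default_factory=lambda: {"step": 0.7, "ramp": 0.3})
    aging_effect: float = 2.0
    model_mix: dict = field(
        default_factory=lambda: {
            "null": 0.3, "baseline": 0.3, "rate": 0.15, "combined": 0.1,
            "accentuate": 0.15,
        }
    )
    intervention_effect: float = 1.5
    rate_rho: float = 1.0
    noise_sd: float = 1.0
    lesion_base_rate: float = 0.1
    # per-phenotype heterogeneity of the treatment shift: when set, the
    # baseline/combined/accentuate shift magnitude is drawn uniformly from
    # this (low, high) range instead of being fixed at intervention_effect
    intervention_effect_range: tuple | None = None
    # orient every phenotype so the age effect is positive (by default each
    # phenotype's direction of age-dependent change is a random sign)
    orient_age_effects: bool = False

    def validate(self):
        for name, mix, domain in (
            ("scale_mix", self.scale_mix, ("continuous", "ordinal", "count_category")),
            ("onset_mix", self.onset_mix, ONSETS),
            ("shape_mix", self.shape_mix, SHAPES),
            ("model_mix", self.model_mix, MODELS),
        ):
            if not set(mix) <= set(domain):
                raise ValueError(f"{name} has unknown keys: {set(mix) - set(domain)}")
            if any(v < 0 for v in mix.values()) or not np.isclose(sum(mix.values()), 1.0):
                raise ValueError(f"{name} must be a probability vector")
        if self.n_phenotypes < 1 or self.n_per_cell < 2:
            raise ValueError("n_phenotypes >= 1 and n_per_cell >= 2 required")


@dataclass(frozen=True)
class PhenotypeTruth:
    phenotype_id: str
    scale: str
    onset: str
    shape: str
    model: str
    d_age: float
    d_treat_young: float
    d_treat_old: float


def _pick(rng: np.random.Generator, mix: dict) -> str:
    keys = sorted(mix)
    probs = np.array([mix[k] for k in keys], dtype=float)
    return keys[rng.choice(len(keys), p=probs / probs.sum())]


def trajectory_means(
    onset: str, shape: str, effect: float, ages=DEFAULT_AGES
) -> np.ndarray:
    """Population mean at each age for one phenotype (noise-SD units)."""
    ages = np.asarray(ages, dtype=float)
    mu = np.zeros(len(ages))
    if onset == "null":
        return mu
    if onset == "other":
        # midlife-peak archetype: rise to a peak at 14 months, back to the
        # young-adult baseline by 20 months (fat-mass-like profile)
        peak, back = 14.0, 20.0
        up = (ages > ages[0]) & (ages <= peak)
        mu[up] = effect * (ages[up] - ages[0]) / (peak - ages[0])
        down = ages > peak
        mu[down] = effect * np.clip(1.0 - (ages[down] - peak) / (back - peak), 0.0, None)
        return mu
    onset_age = float(onset[1:])
    if shape == "step":
        mu[ages >= onset_age] = effect
    else:  # ramp from onset to the last age
        ramp = ages >= onset_age
        mu[ramp] = effect * (ages[ramp] - onset_age + (ages[1] - ages[0])) / (
            ages[-1] - onset_age + (ages[1] - ages[0])
        )
        mu[ages >= onset_age] = np.maximum(
            mu[ages >= onset_age], effect * 1e-9
        )
    return mu


def _emit_values(
    rng: np.random.Generator, scale: str, mu: np.ndarray, n: int, noise_sd: float,
    lesion_base_rate: float,
) -> list:
    """Sample n observations per condition given per-condition means."""
    out = []
    for m in mu:
        latent = rng.normal(m, noise_sd, size=n)
        if scale == "continuous":
            out.append(latent)
        elif scale == "ordinal":
            out.append(np.searchsorted(ORDINAL_CUTS, latent).astype(float))
        else:
            base = stats.norm.ppf(lesion_base_rate)
            prob = stats.norm.cdf(base + m)
            out.append((rng.random(n) < prob).astype(int))
    return out


def generate_baseline_cohort(spec: SyntheticSpec) -> tuple[pd.DataFrame, list[PhenotypeTruth]]:
    """Six-age-group cohort; returns a tidy PhenotypeTable and ground truth."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    ages = spec.age_groups
    rows, truth = [], []
    for i in range(spec.n_phenotypes):
        pid = f"ph{i:04d}"
        scale = _pick(rng, spec.scale_mix)
        onset = _pick(rng, spec.onset_mix)
        shape = "midlife_peak" if onset == "other" else (
            "step" if onset == "null" else _pick(rng, spec.shape_mix)
        )
        sign = 1.0 if spec.orient_age_effects else rng.choice([-1.0, 1.0])
        mu = sign * trajectory_means(onset, shape, spec.aging_effect, ages)
        vals = _emit_values(
            rng, scale, mu, spec.n_per_cell, spec.noise_sd, spec.lesion_base_rate
        )
        for j, age in enumerate(ages):
            for k, v in enumerate(vals[j]):
                rows.append(
                    (f"a{age}_{k:03d}", pid, scale, str(age), "control", v)
                )
        truth.append(
            PhenotypeTruth(pid, scale, onset, shape, "null",
                           float(mu[-1] - mu[0]) / spec.noise_sd, 0.0, 0.0)
        )
    table = pd.DataFrame(
        rows, columns=["animal_id", "phenotype_id", "scale", "age_group", "arm", "value"]
    )
    return table, truth


def _intervention_cell_means(
    model: str, a: float, beta: float, rho: float, sign: float
) -> dict[tuple[str, str], float]:
    """Population means for the 2x2 cells; ``a`` is the (signed) aging
    effect, ``beta`` the baseline treatment shift, ``rho`` the prevented
    fraction of age change."""
    counter = -np.sign(a) if a != 0 else -1.0
    cells = {
        ("young", "control"): 0.0,
        ("old", "control"): a,
    }
    if model == "null":
        ty, to = 0.0, a
    elif model == "baseline":
        ty, to = counter * beta, a + counter * beta
    elif model == "rate":
        ty, to = 0.0, a * (1.0 - rho)
    elif model == "combined":
        ty, to = counter * beta, a * (1.0 - rho) + counter * beta
    elif model == "accentuate":
        s = np.sign(a) if a != 0 else sign
        ty, to = s * beta, a + s * beta
    else:
        raise ValueError(f"unknown model {model!r}")
    cells[("young", "treated")] = ty
    cells[("old", "treated")] = to
    return cells


def generate_intervention_cohort(
    spec: SyntheticSpec,
) -> tuple[pd.DataFrame, list[PhenotypeTruth]]:
    """2x2 young/old x control/treated cohort with known effect models.

    Phenotypes with a ``null`` onset carry no age effect (the intervention
    model still applies via its young-group shift where the model has one).
    """
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    rows, truth = [], []
    cells_order = [("young", "control"), ("young", "treated"),
                   ("old", "control"), ("old", "treated")]
    for i in range(spec.n_phenotypes):
        pid = f"ph{i:04d}"
        scale = _pick(rng, spec.scale_mix)
        onset = _pick(rng, spec.onset_mix)
        model = _pick(rng, spec.model_mix)
        sign = 1.0 if spec.orient_age_effects else rng.choice([-1.0, 1.0])
        a = 0.0 if onset == "null" else sign * spec.aging_effect
        if spec.intervention_effect_range is not None:
            lo, hi = spec.intervention_effect_range
            beta = float(rng.uniform(lo, hi))
        else:
            beta = spec.intervention_effect
        cells = _intervention_cell_means(model, a, beta, spec.rate_rho, sign)
        mu = np.array([cells[c] for c in cells_order])
        vals = _emit_values(
            rng, scale, mu, spec.n_per_cell, spec.noise_sd, spec.lesion_base_rate
        )
        for j, (age, arm) in enumerate(cells_order):
            for k, v in enumerate(vals[j]):
                rows.append(
                    (f"{age[0]}{arm[0]}_{k:03d}", pid, scale, age, arm, v)
                )
        truth.append(
            PhenotypeTruth(
                pid, scale, onset, "step", model,
                d_age=(cells[("old", "control")] - cells[("young", "control")])
                / spec.noise_sd,
                d_treat_young=(cells[("young", "treated")] - cells[("young", "control")])
                / spec.noise_sd,
                d_treat_old=(cells[("old", "treated")] - cells[("old", "control")])
                / spec.noise_sd,
            )
        )
    table = pd.DataFrame(
        rows, columns=["animal_id", "phenotype_id", "scale", "age_group", "arm", "value"]
    )
    return table, truth


# ---------------------------------------------------------------------------
# Ground-truth round trip
# ---------------------------------------------------------------------------

def write_ground_truth(truth: list[PhenotypeTruth], path) -> None:
    doc = {
        "schema_version": GT_SCHEMA_VERSION,
        "phenotypes": [asdict(t) for t in truth],
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)


def read_ground_truth(path) -> list[PhenotypeTruth]:
    with open(path) as fh:
        doc = json.load(fh)
    if not isinstance(doc, dict) or doc.get("schema_version") != GT_SCHEMA_VERSION:
        raise ValueError("unrecognized ground-truth schema")
    out = []
    for rec in doc["phenotypes"]:
        try:
            out.append(PhenotypeTruth(**rec))
        except TypeError as e:
            raise ValueError(f"malformed ground-truth record: {e}") from e
    return out
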