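"""I/O, configuration and orchestration of the analysis stages.

The universal input is the tidy PhenotypeTable (TSV/CSV): one row per
(animal, phenotype) with columns animal_id, phenotype_id, scale, age_group,
arm, value. ``run_trajectory_study`` drives stage 1 (+ PCA) for a
multi-age-group baseline cohort; ``run_intervention_study`` drives stages
2-3 for a 2x2 young/old x control/treated cohort.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from . import aggregate, core_stats as cs, intervention, trajectory

log = logging.getLogger("paai")

REQUIRED_COLUMNS = ("animal_id", "phenotype_id", "scale", "age_group", "arm", "value")


@dataclass
class StudyConfig:
    study_type: str = "trajectory"  # trajectory | intervention
    alpha: float = 0.05
    age_groups: tuple = trajectory.DEFAULT_AGES
    reference_age: int = 3
    ss_type: str = "II"
    icc_variant: str = "ICC2"
    always_posthoc: bool = False
    imputation_iterations: int = 10
    seed: int = 0
    out_dir: str = "."

    @classmethod
    def from_file(cls, path) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "age_groups" in raw:
            raw["age_groups"] = tuple(raw["age_groups"])
        return cls(**raw)

    def snapshot(self) -> dict:
        d = dataclasses.asdict(self)
        d["age_groups"] = list(self.age_groups)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.snapshot(), sort_keys=True).encode()
        ).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Table I/O
# ---------------------------------------------------------------------------

def read_table(path) -> pd.DataFrame:
    """Read and validate a PhenotypeTable from TSV (default) or CSV."""
    path = Path(path)
    sep = "," if path.suffix.lower() == ".csv" else "\t"
    df = pd.read_csv(path, sep=sep, comment="#", dtype={"age_group": str})
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"missing columns: {missing}")
    dup = df.duplicated(subset=["animal_id", "phenotype_id"])
    if dup.any():
        rows = (df.index[dup] + 2).tolist()[:5]
        raise ValueError(f"duplicate (animal_id, phenotype_id) at file rows {rows}")
    bad_scale = ~df["scale"].isin(trajectory.SCALES)
    if bad_scale.any():
        tokens = sorted(df.loc[bad_scale, "scale"].unique())
        raise ValueError(f"unknown scale tokens: {tokens}")
    n_scales = df.groupby("phenotype_id")["scale"].nunique()
    mixed = n_scales[n_scales > 1]
    if len(mixed):
        raise ValueError(f"phenotypes with inconsistent scale: {list(mixed.index)}")
    return df


def write_table(df: pd.DataFrame, path, config: StudyConfig | None = None) -> None:
    """Write a TSV with a provenance header ('#'-prefixed comment lines)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# paai {__version__}\n")
        if config is not None:
            fh.write(f"# config_hash {config.config_hash()}\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="NA")


def _write_json(obj, path, config: StudyConfig | None = None) -> None:
    doc = {"tool": f"paai {__version__}"}
    if config is not None:
        doc["config_hash"] = config.config_hash()
        doc["config"] = config.snapshot()
    doc["result"] = obj
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1, default=_json_default)


def _json_default(o):
    if isinstance(o, (np.floating, np.integer)):
        return o.item()
    if isinstance(o, np.ndarray):
        return o.tolist()
    if dataclasses.is_dataclass(o):
        return dataclasses.asdict(o)
    raise TypeError(f"not JSON serializable: {type(o)}")


def continuous_wide_matrix(table: pd.DataFrame) -> pd.DataFrame:
    """Animals x continuous-phenotypes wide matrix (NaN where missing)."""
    cont = table[table["scale"] == "continuous"]
    if cont.empty:
        raise ValueError("no continuous phenotypes")
    wide = cont.pivot(index="animal_id", columns="phenotype_id", values="value")
    return wide.astype(float)


# ---------------------------------------------------------------------------
# Study drivers
# ---------------------------------------------------------------------------

def run_trajectory_study(config: StudyConfig, table: pd.DataFrame, out_dir=None) -> dict:
    """Stage 1 for a baseline cohort: per-phenotype trajectory calls,
    cohort summary, and PCA of the continuous phenotypes."""
    if table.empty:
        raise ValueError("empty table")
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log.info("trajectory study: alpha=%s ages=%s", config.alpha, config.age_groups)
    calls = trajectory.classify_cohort(
        table, alpha=config.alpha, ages=config.age_groups
    )
    summary = trajectory.summarize_trajectories(calls)
    calls_df = trajectory.calls_to_frame(calls)
    write_table(calls_df, out / "trajectory_calls.tsv", config)
    _write_json(dataclasses.asdict(summary), out / "trajectory_summary.json", config)

    pca_info = None
    try:
        wide = continuous_wide_matrix(table)
        completed, report = aggregate.impute_chained(
            wide, iterations=config.imputation_iterations, seed=config.seed
        )
        pca = aggregate.pca_phenotypes(completed)
        write_table(
            pca.scores.reset_index(), out / "pca_scores.tsv", config
        )
        write_table(
            pca.loadings.reset_index(), out / "pca_loadings.tsv", config
        )
        pca_info = {
            "variance_explained": pca.variance_explained[:10].tolist(),
            "imputation": dataclasses.asdict(report),
        }
        _write_json(pca_info, out / "pca_summary.json", config)
    except ValueError as e:
        log.warning("PCA skipped: %s", e)
    return {"calls": calls, "summary": summary, "pca": pca_info}


def run_intervention_study(
    config: StudyConfig,
    table: pd.DataFrame,
    baseline_calls=None,
    out_dir=None,
) -> dict:
    """Stages 2-3 for a 2x2 cohort: factorial fits and direction/model
    calls, category fractions by both routes, per-category concordance, and
    the standardized-coefficient forest table."""
    if table.empty:
        raise ValueError("empty table")
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    fits, calls = intervention.fit_cohort(
        table, alpha=config.alpha, ss_type=config.ss_type
    )
    if baseline_calls is not None:
        calls = intervention.annotate_with_baseline_onsets(calls, baseline_calls)
    calls_df = intervention.fits_to_frame(fits, calls)
    write_table(calls_df, out / "intervention_calls.tsv", config)

    fractions = {}
    for route in ("interaction", "effectsize"):
        try:
            fractions[route] = dataclasses.asdict(
                intervention.category_fractions(calls, route)
            )
        except ValueError as e:
            log.warning("category fractions (%s) unavailable: %s", route, e)
    n_disagree = sum(
        1
        for c in calls
        if c.direction == "countered"
        and c.model_interaction_route != c.model_effectsize_route
    )
    fractions["route_disagreements"] = n_disagree
    _write_json(fractions, out / "category_fractions.json", config)

    concord = {}
    for cat in ("countered", "accentuated", "intervention_only", "all"):
        try:
            concord[cat] = dataclasses.asdict(
                aggregate.concordance_by_category(fits, calls, cat, alpha=config.alpha)
            )
        except ValueError as e:
            log.warning("concordance (%s) unavailable: %s", cat, e)
    _write_json(concord, out / "concordance.json", config)

    coefs = {}
    for pid, sub in table.groupby("phenotype_id", sort=True):
        if str(sub["scale"].iloc[0]) != "continuous":
            continue
        try:
            coefs[str(pid)] = cs.standardized_lm(
                sub["value"].astype(float).to_numpy(),
                sub["age_group"].astype(str).to_numpy(),
                sub["arm"].astype(str).to_numpy(),
            )
        except ValueError as e:
            log.warning("standardized lm skipped for %s: %s", pid, e)
    forest = aggregate.forest_table(coefs) if coefs else pd.DataFrame()
    if len(forest):
        write_table(forest, out / "forest_table.tsv", config)
    return {
        "fits": fits,
        "calls": calls,
        "fractions": fractions,
        "concordance": concord,
        "forest": forest,
    }
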