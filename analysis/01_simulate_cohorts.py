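#!/usr/bin/env python
"""Simulate the two study designs with known ground truth.

Writes a six-age-group baseline cohort (222 phenotypes, mixed measurement
scales, onset mix matching the observed distribution of ages at first
detectable change) and a 2x2 young/old x control/treated intervention
cohort (206 phenotypes, mixed intervention models) under results/cohorts/.
"""

from pathlib import Path

from paai import pipeline, synthetic

OUT = Path(__file__).resolve().parent.parent / "results" / "cohorts"
SEED = 42


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    base_spec = synthetic.SyntheticSpec(n_phenotypes=222, seed=SEED)
    base_table, base_truth = synthetic.generate_baseline_cohort(base_spec)
    pipeline.write_table(base_table, OUT / "baseline_table.tsv")
    synthetic.write_ground_truth(base_truth, OUT / "baseline_truth.json")
    print(f"baseline cohort: {len(base_truth)} phenotypes, "
          f"{base_table.animal_id.nunique()} animals/{len(base_table)} rows")

    int_spec = synthetic.SyntheticSpec(n_phenotypes=206, seed=SEED + 1)
    int_table, int_truth = synthetic.generate_intervention_cohort(int_spec)
    pipeline.write_table(int_table, OUT / "intervention_table.tsv")
    synthetic.write_ground_truth(int_truth, OUT / "intervention_truth.json")
    models = {}
    for t in int_truth:
        models[t.model] = models.get(t.model, 0) + 1
    print(f"intervention cohort: {len(int_truth)} phenotypes; "
          f"generative model mix: {dict(sorted(models.items()))}")


if __name__ == "__main__":
    main()
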