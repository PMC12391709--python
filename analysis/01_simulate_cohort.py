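#!/usr/bin/env python
"""Generate the synthetic validation cohort.

Simulates 626 PAH admissions matching the study cohort's marginals (sex
split, age, length of stay, comorbidity/prior-admission counts, targeted
drug classes), injects ADEs from the logistic risk model with their trigger
signatures plus per-trigger false-positive noise, and writes the five
cohort CSV streams and the ground-truth ledger under results/cohort/.
"""

import sys
from pathlib import Path

from pahgtt.records import write_cohort
from pahgtt.synthetic_data import SimulationConfig, simulate_cohort

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"


def main(seed: int = 20220101) -> None:
    config = SimulationConfig(seed=seed)
    cohort, ledger = simulate_cohort(config)
    OUT.mkdir(parents=True, exist_ok=True)
    write_cohort(cohort, OUT)
    (OUT / "ledger.json").write_text(ledger.model_dump_json(indent=2))

    n_ade_patients = sum(pl.has_ade for pl in ledger.patients.values())
    n_ades = sum(len(pl.ades) for pl in ledger.patients.values())
    print(f"cohort: {len(cohort)} admissions (seed {seed})")
    print(f"  ADE patients: {n_ade_patients} ({100 * n_ade_patients / len(cohort):.2f}%)")
    print(f"  ADEs injected: {n_ades}")
    print(f"  silent (non-emitted) ADEs: "
          f"{sum(1 for pl in ledger.patients.values() for a in pl.ades if not a.emitted)}")
    print(f"wrote cohort streams + ledger to {OUT}")


if __name__ == "__main__":
    main(int(sys.argv[1]) if len(sys.argv) > 1 else 20220101)
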