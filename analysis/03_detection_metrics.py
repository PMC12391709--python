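#!/usr/bin/env python
"""Detection-performance metrics, on the simulated cohort and on the
published counts.

Builds the full metric set (per-trigger and overall PPV, patient-level
sensitivity/specificity/Youden, prevalence, the three ADE rates) twice:
once from the simulated cohort's screening output and ground-truth
adjudications, and once from the packaged published counts for reference.
Writes results/metrics/.
"""

import json
from pathlib import Path

from pahgtt.metrics import build_report
from pahgtt.records import read_cohort
from pahgtt.synthetic_data import GroundTruthLedger, paper_fixture_report
from pahgtt.trigger_engine import default_ruleset, screen_cohort

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = read_cohort(ROOT / "cohort")
    ledger = GroundTruthLedger.model_validate(
        json.loads((ROOT / "cohort" / "ledger.json").read_text())
    )
    screening = screen_cohort(cohort, default_ruleset())
    simulated = build_report(screening, ledger.ade_records(), cohort)
    reference = paper_fixture_report()

    out = ROOT / "metrics"
    out.mkdir(parents=True, exist_ok=True)
    (out / "metrics_simulated.json").write_text(simulated.to_json(indent=2, sort_keys=True))
    (out / "metrics_reference.json").write_text(reference.to_json(indent=2, sort_keys=True))
    simulated.per_trigger_frame().to_csv(out / "per_trigger_simulated.csv", index=False)
    reference.per_trigger_frame().to_csv(out / "per_trigger_reference.csv", index=False)

    print("                         simulated   reference")
    for label, attr in [
        ("overall PPV (%)", "overall_ppv"),
        ("sensitivity (%)", "sensitivity"),
        ("specificity (%)", "specificity"),
        ("Youden index", "youden"),
        ("prevalence (%)", "prevalence"),
        ("per 1000 patient-days", "rate_per_1000_patient_days"),
        ("per 100 patients", "rate_per_100_patients"),
        ("per 1000 drugs (printed formula)", "rate_per_1000_drugs"),
    ]:
        print(f"{label:32s} {getattr(simulated, attr)!s:>9}   {getattr(reference, attr)!s:>9}")
    print(f"wrote metric reports to {out}")


if __name__ == "__main__":
    main()
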