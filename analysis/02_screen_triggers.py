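#!/usr/bin/env python
"""Screen the simulated cohort with the 24-trigger rule set.

Reads results/cohort/, runs the trigger engine, verifies the hits against
the generator's ground-truth ledger, and writes trigger_hits.csv and
patient_flags.csv under results/screening/.
"""

import json
from pathlib import Path

import pandas as pd

from pahgtt.records import read_cohort
from pahgtt.synthetic_data import GroundTruthLedger
from pahgtt.trigger_engine import default_ruleset, screen_cohort

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = read_cohort(ROOT / "cohort")
    ledger = GroundTruthLedger.model_validate(
        json.loads((ROOT / "cohort" / "ledger.json").read_text())
    )
    result = screen_cohort(cohort, default_ruleset())

    out = ROOT / "screening"
    out.mkdir(parents=True, exist_ok=True)
    result.to_frame().to_csv(out / "trigger_hits.csv", index=False)
    pd.DataFrame(
        sorted(result.per_patient_flag.items()), columns=["patient_id", "trigger_positive"]
    ).to_csv(out / "patient_flags.csv", index=False)

    hits = {(h.patient_id, h.trigger_id) for h in result.hits}
    expected = ledger.expected_hit_set()
    flagged = sum(result.per_patient_flag.values())
    print(f"screened {len(cohort)} admissions: {len(hits)} trigger instances, "
          f"{flagged} flagged patients")
    print(f"  ledger agreement: {'exact' if hits == expected else 'MISMATCH'} "
          f"({len(hits & expected)}/{len(expected)} expected hits found)")
    per_trigger = result.positives_per_trigger()
    top = sorted(per_trigger.items(), key=lambda kv: -kv[1])[:5]
    print("  most frequent triggers:", ", ".join(f"{t} ({n})" for t, n in top))


if __name__ == "__main__":
    main()
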