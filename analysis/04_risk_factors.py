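#!/usr/bin/env python
"""Risk-factor analyses on the simulated cohort.

Univariate chi-square screen over the binned covariates, the multivariable
binary logistic regression (dummy coding against each scheme's reference
bin), and the paired comparison of trigger-based detection against
simulated spontaneous reporting. Writes results/risk_factors/.
"""

import json
from pathlib import Path

from pahgtt.records import read_cohort
from pahgtt.risk_factors import (
    SeparationError,
    compare_detection_methods,
    fit_logistic,
    univariate_chisq,
)
from pahgtt.synthetic_data import GroundTruthLedger
from pahgtt.trigger_engine import default_ruleset, screen_cohort

ROOT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    cohort = read_cohort(ROOT / "cohort")
    ledger = GroundTruthLedger.model_validate(
        json.loads((ROOT / "cohort" / "ledger.json").read_text())
    )
    screening = screen_cohort(cohort, default_ruleset())
    counts = screening.trigger_counts_per_patient()
    flags = ledger.ade_flags()

    out = ROOT / "risk_factors"
    out.mkdir(parents=True, exist_ok=True)

    chis = univariate_chisq(cohort, counts, flags)
    chis.to_csv(out / "univariate_chisq.csv")
    print("univariate chi-square p-values:")
    for cov, row in chis.iterrows():
        flag = "*" if row.p_value < 0.05 else " "
        print(f"  {cov:26s} p = {row.p_value:.4f} {flag}")

    try:
        fit = fit_logistic(cohort, counts, flags)
    except SeparationError as exc:
        print(f"logistic fit failed: {exc} (covariate: {exc.covariate})")
        return
    fit.table.to_csv(out / "logistic_or.csv", index=False)
    (out / "fit_stats.json").write_text(
        json.dumps({"nagelkerke_r2": fit.nagelkerke_r2, "n": fit.n, "notes": fit.notes}, indent=2)
    )
    print(f"\nlogistic regression (n={fit.n}, Nagelkerke R2={fit.nagelkerke_r2:.3f}):")
    sig = fit.table[(~fit.table.reference) & (fit.table.p_value < 0.05)]
    for _, row in sig.iterrows():
        print(f"  {row.covariate} {row.level}: OR {row.odds_ratio:.3f} (p={row.p_value:.4f})")

    # detection = trigger-positive AND adjudicated ADE (the surveillance
    # outcome), paired against spontaneous reporting per patient
    gtt_detected = {
        pid: bool(screening.per_patient_flag[pid] and flags[pid]) for pid in flags
    }
    paired = compare_detection_methods(gtt_detected, ledger.spontaneous_flags())
    (out / "paired_comparison.json").write_text(
        json.dumps(
            {
                "table": paired["table"].tolist(),
                "discordant": list(paired["discordant"]),
                "mcnemar_exact_p": paired["mcnemar_exact_p"],
                "chi2_p": paired["chi2_p"],
            },
            indent=2,
        )
    )
    print(f"\ntrigger surveillance vs spontaneous reporting: "
          f"discordant {paired['discordant']}, exact McNemar p = {paired['mcnemar_exact_p']:.3g}")


if __name__ == "__main__":
    main()
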