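import random

import pytest

from pahgtt.synthetic_data import SimulationConfig, simulate_cohort
from pahgtt.trigger_engine import (
    RulesetError,
    default_ruleset,
    evaluate_trigger,
    load_ruleset,
    screen_cohort,
)

from conftest import event, intervention, lab, make_record, med
from oracle_triggers import brute_force_triggers

RULES = {r.trigger_id: r for r in default_ruleset()}


class TestRulesetLoading:
    def test_default_set_is_24_rules_in_four_categories(self):
        rules = default_ruleset()
        assert len(rules) == 24
        by_cat = {}
        for r in rules:
            by_cat[r.category.value] = by_cat.get(r.category.value, 0) + 1
        assert by_cat == {"laboratory": 7, "antidote": 6, "symptom": 8, "treatment": 3}

    def test_duplicate_trigger_id_rejected(self):
        cfg = {
            "triggers": [
                {"id": "X1", "category": "symptom", "condition": {"shape": "symptom", "group": "S1"}},
                {"id": "X1", "category": "symptom", "condition": {"shape": "symptom", "group": "S2"}},
            ]
        }
        with pytest.raises(RulesetError, match="duplicate"):
            load_ruleset(cfg)

    def test_unknown_condition_shape_rejected(self):
        cfg = {"triggers": [{"id": "X1", "category": "symptom", "condition": {"shape": "psychic"}}]}
        with pytest.raises(RulesetError, match="unknown condition shape"):
            load_ruleset(cfg)

    def test_user_can_add_a_25th_rule(self):
        import yaml

        from pahgtt.records import _data_path

        with open(_data_path("triggers_default.yaml")) as fh:
            cfg = yaml.safe_load(fh)
        cfg["triggers"].append(
            {
                "id": "L8",
                "category": "laboratory",
                "condition": {"shape": "threshold", "analyte": "sodium", "comparator": "<", "bound": 130.0},
            }
        )
        rules = load_ruleset(cfg)
        assert len(rules) == 25
        rec = make_record(labs=[lab("sodium", 125)])
        hits = {r.trigger_id for r in rules if evaluate_trigger(r, rec) is not None}
        assert "L8" in hits

    def test_overlapping_strata_rejected(self):
        cfg = {
            "triggers": [
                {
                    "id": "X1",
                    "category": "laboratory",
                    "condition": {
                        "shape": "threshold",
                        "analyte": "hemoglobin",
                        "comparator": "<",
                        "strata": [
                            {"age_min": 0.5, "age_max": 6.0, "bound": 110},
                            {"age_min": 5.0, "bound": 115},
                        ],
                    },
                }
            ]
        }
        with pytest.raises(RulesetError, match="overlapping"):
            load_ruleset(cfg)


# One minimal firing record and one boundary non-firing record per trigger.
SIGNATURES = {
    "L1": (dict(labs=[lab("eosinophils_abs", 0.31)]), dict(labs=[lab("eosinophils_abs", 0.3)])),
    "L2": (dict(labs=[lab("platelets", 49.0)]), dict(labs=[lab("platelets", 50.0)])),
    "L3": (dict(labs=[lab("leukocytes", 2.9)]), dict(labs=[lab("leukocytes", 3.0)])),
    "L4": (dict(labs=[lab("alt", 121.0)]), dict(labs=[lab("alt", 120.0)])),
    "L5": (
        dict(labs=[lab("creatinine", 60, day=1), lab("creatinine", 130, day=3)]),
        dict(labs=[lab("creatinine", 60, day=1), lab("creatinine", 120, day=3)]),
    ),
    "L6": (dict(labs=[lab("hemoglobin", 100.0)]), dict(labs=[lab("hemoglobin", 110.0)])),
    "L7": (dict(labs=[lab("sodium", 146.0)]), dict(labs=[lab("sodium", 145.0)])),
    "A1": (dict(medications=[med("norepinephrine")]), dict()),
    "A2": (dict(medications=[med("ondansetron")]), dict()),
    "A3": (dict(medications=[med("loperamide")]), dict()),
    "A4": (dict(medications=[med("glutathione")]), dict()),
    "A5": (dict(medications=[med("lactulose")]), dict()),
    "A6": (dict(medications=[med("cetirizine")]), dict()),
    "S1": (dict(events=[event("gastrointestinal_bleeding")]), dict()),
    "S2": (dict(events=[event("nausea")]), dict()),
    "S3": (dict(events=[event("jaw_pain")]), dict()),
    "S4": (dict(events=[event("rash")]), dict()),
    "S5": (dict(events=[event("peripheral_edema")]), dict()),
    "S6": (dict(events=[event("headache")]), dict()),
    "S7": (dict(events=[event("fainting")]), dict()),
    "S8": (dict(events=[event("proteinuria")]), dict()),
    "T1": (dict(interventions=[intervention("icu_transfer")]), dict()),
    "T2": (dict(interventions=[intervention("salvage")]), dict()),
    "T3": (
        dict(medications=[med("sildenafil", target=True, abrupt=True, drug_class="pah_sildenafil")]),
        dict(medications=[med("sildenafil", target=True, drug_class="pah_sildenafil")]),
    ),
}


class TestSignatureCompleteness:
    @pytest.mark.parametrize("trigger_id", sorted(SIGNATURES))
    def test_minimal_record_fires_and_boundary_record_does_not(self, trigger_id):
        fire_kw, quiet_kw = SIGNATURES[trigger_id]
        rule = RULES[trigger_id]
        firing = make_record(**fire_kw)
        hit = evaluate_trigger(rule, firing)
        assert hit is not None, f"{trigger_id} should fire"
        assert hit.trigger_id == trigger_id and hit.patient_id == firing.patient_id
        assert hit.evidence, "a hit must cite its evidence rows"
        quiet = make_record(**quiet_kw)
        assert evaluate_trigger(rule, quiet) is None, f"{trigger_id} must not fire at the boundary"


class TestRuleSemantics:
    def test_hemoglobin_bands_by_age_and_sex(self):
        rule = RULES["L6"]
        # adult male bound is 120, adult female 110
        assert evaluate_trigger(rule, make_record(sex="male", labs=[lab("hemoglobin", 115)]))
        assert not evaluate_trigger(rule, make_record(sex="female", labs=[lab("hemoglobin", 115)]))
        # child bands
        assert evaluate_trigger(rule, make_record(age=3, labs=[lab("hemoglobin", 105)]))
        assert not evaluate_trigger(rule, make_record(age=3, labs=[lab("hemoglobin", 112)]))
        assert evaluate_trigger(rule, make_record(age=8, labs=[lab("hemoglobin", 112)]))
        # under 6 months the rule is not evaluated
        assert not evaluate_trigger(rule, make_record(age=0.3, labs=[lab("hemoglobin", 80)]))

    def test_liver_rule_requires_conjunction_for_bilirubin_arm(self):
        rule = RULES["L4"]
        # bilirubin alone above 2x ULN does not fire; with ALP it does
        assert not evaluate_trigger(rule, make_record(labs=[lab("total_bilirubin", 52.5)]))
        assert evaluate_trigger(
            rule, make_record(labs=[lab("total_bilirubin", 52.5), lab("alp", 260.0)])
        )
        assert evaluate_trigger(rule, make_record(labs=[lab("ast", 125.0)]))

    def test_baseline_ratio_uses_first_in_stay_value(self):
        rule = RULES["L5"]
        # first value is the baseline even if a later pair would satisfy the ratio
        rec = make_record(
            labs=[lab("creatinine", 100, day=1), lab("creatinine", 45, day=2), lab("creatinine", 150, day=4)]
        )
        assert evaluate_trigger(rule, rec) is None  # 150 < 2*100
        rec2 = make_record(labs=[lab("bun", 4.0, day=1), lab("bun", 9.0, day=3)])
        assert evaluate_trigger(rule, rec2) is not None

    def test_single_observation_cannot_fire_baseline_rule(self):
        assert evaluate_trigger(RULES["L5"], make_record(labs=[lab("creatinine", 500)])) is None

    def test_target_drug_does_not_fire_exposure_rules(self):
        # sildenafil only; no A-class hit even though it is a medication row
        rec = make_record()
        for tid in ("A1", "A2", "A3", "A4", "A5", "A6"):
            assert evaluate_trigger(RULES[tid], rec) is None

    def test_symptom_alias_fires_via_vocabulary(self):
        rec = make_record(events=[event("puffiness")])
        assert evaluate_trigger(RULES["S5"], rec) is not None


class TestScreening:
    def test_one_hit_per_patient_trigger_pair(self):
        rec = make_record(labs=[lab("sodium", 150, day=1), lab("sodium", 152, day=2)])
        result = screen_cohort([rec])
        assert len([h for h in result.hits if h.trigger_id == "L7"]) == 1
        # first satisfying observation is cited
        hit = result.hits[0]
        assert hit.first_satisfied_at.day == 2  # admission Mar 1 + 1 day

    def test_per_patient_flag_and_empty_cohort(self):
        recs = [
            make_record(patient_id="P1", labs=[lab("sodium", 150)]),
            make_record(patient_id="P2"),
        ]
        result = screen_cohort(recs)
        assert result.per_patient_flag == {"P1": True, "P2": False}
        empty = screen_cohort([])
        assert empty.hits == [] and empty.per_patient_flag == {}

    def test_order_independence(self):
        labs = [lab("sodium", 150, day=3), lab("creatinine", 60, day=1), lab("creatinine", 130, day=4)]
        events = [event("nausea", day=2), event("rash", day=1)]
        rec_a = make_record(labs=labs, events=events)
        rec_b = make_record(labs=list(reversed(labs)), events=list(reversed(events)))
        ha = {(h.trigger_id, h.first_satisfied_at) for h in screen_cohort([rec_a]).hits}
        hb = {(h.trigger_id, h.first_satisfied_at) for h in screen_cohort([rec_b]).hits}
        assert ha == hb

    def test_monotonicity_adding_observations_never_removes_hits(self):
        rng = random.Random(7)
        pool = [
            lambda: lab("sodium", rng.uniform(130, 160), day=rng.randint(0, 5)),
            lambda: lab("hemoglobin", rng.uniform(90, 140), day=rng.randint(0, 5)),
            lambda: lab("creatinine", rng.uniform(40, 200), day=rng.randint(0, 5)),
            lambda: event(rng.choice(["nausea", "rash", "headache"]), day=rng.randint(0, 5)),
        ]
        for _ in range(25):
            base_labs = [pool[rng.randrange(3)]() for _ in range(rng.randint(0, 4))]
            base_events = [pool[3]() for _ in range(rng.randint(0, 2))]
            rec = make_record(labs=base_labs, events=base_events)
            before = {h.trigger_id for h in screen_cohort([rec]).hits}
            extra = pool[rng.randrange(4)]()
            if hasattr(extra, "analyte"):
                rec2 = make_record(labs=base_labs + [extra], events=base_events)
            else:
                rec2 = make_record(labs=base_labs, events=base_events + [extra])
            after = {h.trigger_id for h in screen_cohort([rec2]).hits}
            missing = before - after
            # the only legitimate loss is a baseline-ratio rule whose baseline
            # moved earlier -- excluded by keeping added observations latest
            assert not missing or missing == {"L5"}

    def test_brute_force_oracle_equivalence_on_small_cohorts(self):
        for seed in (0, 1, 2):
            cohort, _ = simulate_cohort(SimulationConfig(n_patients=50, seed=seed))
            result = screen_cohort(cohort)
            engine = {}
            for h in result.hits:
                engine.setdefault(h.patient_id, set()).add(h.trigger_id)
            for rec in cohort:
                assert engine.get(rec.patient_id, set()) == brute_force_triggers(rec), (
                    f"seed {seed}, patient {rec.patient_id}"
                )

    def test_screening_matches_generator_ledger_exactly(self):
        cohort, ledger = simulate_cohort(SimulationConfig(n_patients=80, seed=5))
        hits = {(h.patient_id, h.trigger_id) for h in screen_cohort(cohort).hits}
        assert hits == ledger.expected_hit_set()
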