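import numpy as np
import pytest

from pahgtt.risk_factors import (
    DEFAULT_BINNING,
    MODEL_COVARIATES,
    SeparationError,
    bin_covariates,
    chisq_table,
    compare_detection_methods,
    covariate_frame,
    fit_logistic,
    fit_logistic_binned,
    univariate_chisq,
)
from pahgtt.synthetic_data import SimulationConfig, make_paper_fixture, simulate_flags

from conftest import make_record


class TestBinning:
    @pytest.mark.parametrize(
        "scheme,value,label",
        [
            ("age", 0.33, "0-17"), ("age", 17.9, "0-17"), ("age", 18, "18-40"),
            ("age", 40.9, "18-40"), ("age", 41, "41-60"), ("age", 61, ">60"),
            ("los", 1, "1-10"), ("los", 10, "1-10"), ("los", 11, "11-20"),
            ("los", 30, "21-30"), ("los", 31, ">30"),
            ("comorbidities", 3, "1-3"), ("comorbidities", 9, "7-9"), ("comorbidities", 10, ">9"),
            ("prior_hospitalizations", 3, "1-3"), ("prior_hospitalizations", 7, ">6"),
            ("drug_classes", 1, "1"), ("drug_classes", 3, "3"), ("drug_classes", 4, ">3"),
        ],
    )
    def test_bin_assignment(self, scheme, value, label):
        assert getattr(DEFAULT_BINNING, scheme).assign(value) == label

    def test_two_trigger_schemes_agree_on_integer_counts(self):
        uni = DEFAULT_BINNING.triggers_univariate
        reg = DEFAULT_BINNING.triggers_regression
        for count in range(0, 12):
            # labels differ in spelling (">=5" vs ">4") but partition identically
            assert (uni.assign(count) == ">=5") == (reg.assign(count) == ">4")
            assert (uni.assign(count) == "0-1") == (reg.assign(count) == "0-1")

    def test_covariate_frame_from_records(self):
        recs = [
            make_record(patient_id="P1", age=45, los_days=12, n_comorbidities=10),
            make_record(patient_id="P2", age=8, los_days=3),
        ]
        frame = covariate_frame(recs, {"P1": 3})
        assert frame.loc["P1", "age"] == "41-60"
        assert frame.loc["P1", "los"] == "11-20"
        assert frame.loc["P1", "comorbidities"] == ">9"
        assert frame.loc["P1", "triggers"] == "2-4"
        assert frame.loc["P2", "triggers"] == "0-1"


class TestChiSquare:
    def test_published_los_rows_are_highly_significant(self):
        fx = make_paper_fixture()
        _, labels_wo_wi = "los", fx.table2["los"]
        _, wo, wi = labels_wo_wi
        stat, p, dof = chisq_table(np.column_stack([wo, wi]))
        assert dof == 3
        assert p < 0.0005  # printed as "0.000"

    def test_published_sex_rows_are_nonsignificant(self):
        fx = make_paper_fixture()
        _, wo, wi = fx.table2["sex"]
        _, p, _ = chisq_table(np.column_stack([wo, wi]))
        assert p == pytest.approx(0.972, abs=0.001)

    def test_proportional_rows_give_statistic_zero(self):
        stat, p, _ = chisq_table([[10, 20], [5, 10]])
        assert stat == pytest.approx(0.0, abs=1e-12)
        assert p == pytest.approx(1.0)

    def test_univariate_screen_matches_direct_tables(self):
        recs = [
            make_record(patient_id=f"P{i}", age=30 if i % 2 else 70, los_days=5 + (i % 3))
            for i in range(40)
        ]
        flags = {f"P{i}": i % 4 == 0 for i in range(40)}
        out = univariate_chisq(recs, {}, flags)
        assert set(out.index) == set(MODEL_COVARIATES)
        # hand-build the age table and compare
        wo = [sum(1 for i in range(40) if (i % 2) and not (i % 4 == 0)),
              sum(1 for i in range(40) if not (i % 2) and not (i % 4 == 0))]
        wi = [sum(1 for i in range(40) if (i % 2) and (i % 4 == 0)),
              sum(1 for i in range(40) if not (i % 2) and (i % 4 == 0))]
        stat, p, _ = chisq_table(np.column_stack([wo, wi]))
        assert out.loc["age", "p_value"] == pytest.approx(p)


class TestLogistic:
    def test_parameter_recovery_single_fit(self):
        cfg = SimulationConfig(n_patients=5000, seed=17)
        cov, flags, _ = simulate_flags(cfg)
        frame = bin_covariates(cov)
        res = fit_logistic_binned(
            frame, flags, covariates=[c for c in MODEL_COVARIATES if c != "triggers"]
        )
        t = res.table
        for cov_name, level, true_or in [("los", "11-20", 2.185), ("comorbidities", ">9", 2.515)]:
            row = t[(t.covariate == cov_name) & (t.level == level)].iloc[0]
            assert abs(row.beta - np.log(true_or)) < 4 * row.se

    def test_reference_rows_have_or_one(self):
        cfg = SimulationConfig(n_patients=800, seed=2)
        cov, flags, _ = simulate_flags(cfg)
        res = fit_logistic_binned(bin_covariates(cov), flags,
                                  covariates=["sex", "age", "los"])
        refs = res.table[res.table.reference]
        assert (refs.odds_ratio == 1.0).all() and (refs.beta == 0.0).all()

    def test_all_reference_cohort_reduces_to_intercept_only(self):
        recs = [make_record(patient_id=f"P{i}", age=10, sex="male", los_days=5,
                            n_comorbidities=2, n_prior=1) for i in range(30)]
        flags = {f"P{i}": i < 10 for i in range(30)}
        res = fit_logistic(recs, {}, flags)
        assert (res.table.odds_ratio == 1.0).all()

    def test_perfect_separation_reported_with_covariate(self):
        recs = [make_record(patient_id=f"P{i}", sex="male" if i < 15 else "female")
                for i in range(30)]
        flags = {f"P{i}": i < 15 for i in range(30)}  # sex perfectly predicts
        with pytest.raises(SeparationError) as exc:
            fit_logistic(recs, {}, flags, covariates=["sex"])
        assert exc.value.covariate in ("sex", None)

    def test_nagelkerke_r2_in_unit_interval(self):
        cfg = SimulationConfig(n_patients=1500, seed=4)
        cov, flags, _ = simulate_flags(cfg)
        res = fit_logistic_binned(bin_covariates(cov), flags,
                                  covariates=["los", "comorbidities"])
        assert 0.0 <= res.nagelkerke_r2 <= 1.0

    def test_or_invariant_to_covariate_order(self):
        cfg = SimulationConfig(n_patients=1200, seed=6)
        cov, flags, _ = simulate_flags(cfg)
        frame = bin_covariates(cov)
        a = fit_logistic_binned(frame, flags, covariates=["los", "comorbidities"])
        b = fit_logistic_binned(frame, flags, covariates=["comorbidities", "los"])
        assert a.odds_ratio("los", "11-20") == pytest.approx(b.odds_ratio("los", "11-20"))


class TestPairedComparison:
    def test_published_paired_table(self):
        flags_gtt = {}
        flags_spont = {}
        i = 0
        for g, s, n in [(True, True, 2), (True, False, 108), (False, False, 516)]:
            for _ in range(n):
                flags_gtt[f"P{i}"] = g
                flags_spont[f"P{i}"] = s
                i += 1
        out = compare_detection_methods(flags_gtt, flags_spont)
        assert out["table"].tolist() == [[2, 108], [0, 516]]
        assert out["discordant"] == (108, 0)
        assert out["mcnemar_exact_p"] < 1e-30
        assert out["chi2_p"] < 0.01

    def test_identical_flags_give_p_one(self):
        flags = {f"P{i}": i % 3 == 0 for i in range(30)}
        out = compare_detection_methods(flags, dict(flags))
        assert out["mcnemar_exact_p"] == 1.0

    def test_balanced_discordance_not_significant(self):
        flags_a = {"P1": True, "P2": False, "P3": True, "P4": False}
        flags_b = {"P1": False, "P2": True, "P3": True, "P4": False}
        out = compare_detection_methods(flags_a, flags_b)
        assert out["mcnemar_exact_p"] == 1.0

    def test_mismatched_patient_sets_rejected(self):
        with pytest.raises(ValueError, match="same patient set"):
            compare_detection_methods({"P1": True}, {"P2": True})
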