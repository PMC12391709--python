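"""Risk-factor analysis: chi-square screening, logistic regression, paired tests.

Covariates are binned exactly as in the source tables: age {0-17, 18-40,
41-60, >60}, length of stay {1-10, 11-20, 21-30, >30} days, prior
hospitalizations {1-3, 4-6, >6}, targeted drug classes {1, 2, 3, >3},
comorbidities {1-3, 4-6, 7-9, >9}, positive triggers {0-1, 2-4, >=5}
(univariate scheme) or {0-1, 2-4, >4} (regression scheme; identical for
integer counts but kept as two named schemes), sex {male, female}. The first
bin of each scheme is the reference category.

Univariate screening is a Pearson chi-square on each r x 2 contingency table
(no continuity correction, matching SPSS crosstab output). The multivariable
model is a binary logistic regression with dummy coding against the
reference bins, fit by maximum likelihood; Nagelkerke R^2 is reported as the
fit statistic. The paired GTT-vs-spontaneous comparison defaults to the
exact McNemar test; the plain chi-square on the same 2x2 is also emitted.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.contingency_tables import mcnemar
from statsmodels.tools.sm_exceptions import PerfectSeparationError

from .records import HospitalizationRecord, length_of_stay

__all__ = [
    "CovariateBinning",
    "DEFAULT_BINNING",
    "RiskFactorResult",
    "SeparationError",
    "bin_covariates",
    "covariate_frame",
    "chisq_table",
    "univariate_chisq",
    "fit_logistic",
    "fit_logistic_binned",
    "compare_detection_methods",
]


@dataclass(frozen=True)
class BinScheme:
    """Ordered labelled bins over a numeric covariate; first bin = reference."""

    name: str
    edges: tuple[float, ...]  # upper bounds, half-open [lo, hi); last bin unbounded
    labels: tuple[str, ...]
    lower: float = 0.0

    def assign(self, value: float) -> str:
        if value < self.lower:
            raise ValueError(f"{self.name}: value {value} below the scheme's range")
        for hi, label in zip(self.edges, self.labels):
            if value < hi:
                return label
        return self.labels[-1]

    @property
    def reference(self) -> str:
        return self.labels[0]


@dataclass(frozen=True)
class CovariateBinning:
    """The named binning schemes used by both analyses."""

    age: BinScheme = BinScheme("age", (18, 41, 61), ("0-17", "18-40", "41-60", ">60"))
    los: BinScheme = BinScheme("los", (11, 21, 31), ("1-10", "11-20", "21-30", ">30"), lower=1)
    prior_hospitalizations: BinScheme = BinScheme(
        "prior_hospitalizations", (4, 7), ("1-3", "4-6", ">6"), lower=1
    )
    drug_classes: BinScheme = BinScheme("drug_classes", (2, 3, 4), ("1", "2", "3", ">3"), lower=1)
    comorbidities: BinScheme = BinScheme(
        "comorbidities", (4, 7, 10), ("1-3", "4-6", "7-9", ">9"), lower=0
    )
    # the two published trigger-count schemes; numerically identical on integers
    triggers_univariate: BinScheme = BinScheme(
        "triggers_univariate", (2, 5), ("0-1", "2-4", ">=5")
    )
    triggers_regression: BinScheme = BinScheme(
        "triggers_regression", (2, 5), ("0-1", "2-4", ">4")
    )


DEFAULT_BINNING = CovariateBinning()

#: covariates entering the multivariable model, in published order
MODEL_COVARIATES = (
    "sex",
    "age",
    "los",
    "comorbidities",
    "drug_classes",
    "triggers",
    "prior_hospitalizations",
)


def bin_covariates(
    numeric: pd.DataFrame,
    binning: CovariateBinning = DEFAULT_BINNING,
    scheme: str = "regression",
) -> pd.DataFrame:
    """Bin a numeric covariate frame (columns sex, age, los, comorbidities,
    drug_classes, prior_hospitalizations, optionally triggers) to scheme labels."""
    trig_scheme = (
        binning.triggers_regression if scheme == "regression" else binning.triggers_univariate
    )
    out = pd.DataFrame(index=numeric.index)
    out["sex"] = numeric["sex"].astype(str)
    out["age"] = [binning.age.assign(v) for v in numeric["age"]]
    out["los"] = [binning.los.assign(v) for v in numeric["los"]]
    out["comorbidities"] = [binning.comorbidities.assign(v) for v in numeric["comorbidities"]]
    out["drug_classes"] = [binning.drug_classes.assign(v) for v in numeric["drug_classes"]]
    out["prior_hospitalizations"] = [
        binning.prior_hospitalizations.assign(v) for v in numeric["prior_hospitalizations"]
    ]
    if "triggers" in numeric.columns:
        out["triggers"] = [trig_scheme.assign(v) for v in numeric["triggers"]]
    return out


def covariate_frame(
    cohort: Sequence[HospitalizationRecord],
    trigger_counts: dict[str, int],
    binning: CovariateBinning = DEFAULT_BINNING,
    scheme: str = "regression",
) -> pd.DataFrame:
    """One row per patient with every covariate binned to its scheme label."""
    numeric = pd.DataFrame(
        {
            "sex": [r.sex.value for r in cohort],
            "age": [r.age_at_admission for r in cohort],
            "los": [length_of_stay(r) for r in cohort],
            "comorbidities": [r.n_comorbidities for r in cohort],
            "drug_classes": [len(r.target_drug_classes) for r in cohort],
            "prior_hospitalizations": [r.n_prior_hospitalizations for r in cohort],
            "triggers": [trigger_counts.get(r.patient_id, 0) for r in cohort],
        },
        index=pd.Index([r.patient_id for r in cohort], name="patient_id"),
    )
    return bin_covariates(numeric, binning, scheme)


def chisq_table(observed) -> tuple[float, float, int]:
    """Pearson chi-square (no continuity correction) on a contingency table."""
    stat, p, dof, _ = stats.chi2_contingency(np.asarray(observed), correction=False)
    return float(stat), float(p), int(dof)


def _bin_order(covariate: str, binning: CovariateBinning, scheme: str) -> list[str]:
    if covariate == "sex":
        return ["male", "female"]
    if covariate == "triggers":
        s = binning.triggers_regression if scheme == "regression" else binning.triggers_univariate
        return list(s.labels)
    return list(getattr(binning, covariate).labels)


def univariate_chisq(
    cohort: Sequence[HospitalizationRecord],
    trigger_counts: dict[str, int],
    ade_flags: dict[str, bool],
    binning: CovariateBinning = DEFAULT_BINNING,
) -> pd.DataFrame:
    """Pearson chi-square per covariate on its r x 2 (bin x ADE-status) table.

    Returns one row per covariate with the statistic, dof, p-value, and a
    note listing any empty bins that were collapsed out of the table.
    """
    frame = covariate_frame(cohort, trigger_counts, binning, scheme="univariate")
    frame["ade"] = [bool(ade_flags.get(pid, False)) for pid in frame.index]
    rows = []
    for cov in MODEL_COVARIATES:
        order = _bin_order(cov, binning, "univariate")
        table = (
            frame.groupby([cov, "ade"], observed=False).size().unstack(fill_value=0)
        )
        table = table.reindex(order, fill_value=0)
        table = table.reindex(columns=[False, True], fill_value=0)
        empty = [str(b) for b in table.index[(table.sum(axis=1) == 0)]]
        observed = table.loc[table.sum(axis=1) > 0].to_numpy()
        if observed.shape[0] < 2 or observed.sum(axis=0).min() == 0:
            stat, p, dof = np.nan, np.nan, 0
        else:
            stat, p, dof, _ = stats.chi2_contingency(observed, correction=False)
        rows.append(
            {
                "covariate": cov,
                "chi2": stat,
                "dof": dof,
                "p_value": p,
                "collapsed_bins": ";".join(empty),
            }
        )
    out = pd.DataFrame(rows).set_index("covariate")
    return out


class SeparationError(RuntimeError):
    """The logistic fit failed to converge (e.g., perfect separation)."""

    def __init__(self, message: str, covariate: Optional[str] = None):
        super().__init__(message)
        self.covariate = covariate


@dataclass
class RiskFactorResult:
    """Multivariable logistic-regression output in published-table shape."""

    table: pd.DataFrame  # covariate, level, beta, odds_ratio, p_value, reference flag
    nagelkerke_r2: float
    llf: float
    llnull: float
    n: int
    converged: bool = True
    notes: list[str] = field(default_factory=list)

    def odds_ratio(self, covariate: str, level: str) -> float:
        m = self.table[(self.table.covariate == covariate) & (self.table.level == level)]
        if m.empty:
            raise KeyError((covariate, level))
        return float(m.odds_ratio.iloc[0])


def fit_logistic(
    cohort: Sequence[HospitalizationRecord],
    trigger_counts: dict[str, int],
    ade_flags: dict[str, bool],
    binning: CovariateBinning = DEFAULT_BINNING,
    covariates: Sequence[str] = MODEL_COVARIATES,
) -> RiskFactorResult:
    """Maximum-likelihood binary logistic regression on the binned covariates.

    Dummy coding against each scheme's first bin; reports beta, OR = exp(beta),
    Wald SE and p per non-reference level, with reference rows fixed at OR 1.
    Nagelkerke R^2 is the fit statistic. Raises :class:`SeparationError` when
    the fit cannot converge, naming the offending covariate when one level
    perfectly predicts the outcome.
    """
    frame = covariate_frame(cohort, trigger_counts, binning, scheme="regression")
    y = np.array([bool(ade_flags.get(pid, False)) for pid in frame.index], dtype=float)
    return fit_logistic_binned(frame, y, binning, covariates)


def fit_logistic_binned(
    frame: pd.DataFrame,
    y: np.ndarray,
    binning: CovariateBinning = DEFAULT_BINNING,
    covariates: Sequence[str] = MODEL_COVARIATES,
) -> RiskFactorResult:
    """Core ML fit on an already-binned covariate frame (see fit_logistic)."""
    y = np.asarray(y, dtype=float)
    if y.sum() == 0 or y.sum() == len(y):
        raise SeparationError("need at least one event and one non-event")

    design_cols: list[tuple[str, str]] = []
    X_parts = [np.ones((len(frame), 1))]
    dropped: list[str] = []
    for cov in covariates:
        order = _bin_order(cov, binning, "regression")
        present = [lvl for lvl in order if (frame[cov] == lvl).any()]
        dropped += [f"{cov}={lvl}" for lvl in order if lvl not in present]
        for lvl in present[1:]:
            design_cols.append((cov, lvl))
            X_parts.append((frame[cov] == lvl).to_numpy(dtype=float).reshape(-1, 1))
    X = np.hstack(X_parts)

    try:
        with np.errstate(all="ignore"):
            fit = sm.Logit(y, X).fit(disp=False, maxiter=200)
    except (PerfectSeparationError, np.linalg.LinAlgError) as exc:
        raise SeparationError(str(exc), covariate=_suspect_covariate(frame, y, covariates))
    if not fit.mle_retvals.get("converged", True):
        raise SeparationError(
            "logistic fit did not converge",
            covariate=_suspect_covariate(frame, y, covariates),
        )

    rows = []
    for cov in covariates:
        order = _bin_order(cov, binning, "regression")
        rows.append(
            {
                "covariate": cov,
                "level": order[0],
                "beta": 0.0,
                "se": np.nan,
                "odds_ratio": 1.0,
                "p_value": np.nan,
                "reference": True,
            }
        )
        for j, (c, lvl) in enumerate(design_cols, start=1):
            if c != cov:
                continue
            rows.append(
                {
                    "covariate": cov,
                    "level": lvl,
                    "beta": float(fit.params[j]),
                    "se": float(fit.bse[j]),
                    "odds_ratio": float(np.exp(fit.params[j])),
                    "p_value": float(fit.pvalues[j]),
                    "reference": False,
                }
            )
    n = len(y)
    cox_snell = 1.0 - np.exp((fit.llnull - fit.llf) * 2.0 / n)
    max_cs = 1.0 - np.exp(fit.llnull * 2.0 / n)
    notes = []
    if dropped:
        notes.append("empty levels dropped: " + ", ".join(dropped))
    return RiskFactorResult(
        table=pd.DataFrame(rows),
        nagelkerke_r2=float(cox_snell / max_cs),
        llf=float(fit.llf),
        llnull=float(fit.llnull),
        n=n,
        notes=notes,
    )


def _suspect_covariate(
    frame: pd.DataFrame, y: np.ndarray, covariates: Sequence[str]
) -> Optional[str]:
    """Name a covariate with a level that perfectly predicts the outcome."""
    for cov in covariates:
        for lvl in frame[cov].unique():
            mask = (frame[cov] == lvl).to_numpy()
            if mask.any() and (y[mask].min() == y[mask].max()) and mask.sum() > 1:
                sub = y[mask]
                if (sub == 1).all() or (sub == 0).all():
                    other = y[~mask]
                    if len(other) and ((sub[0] == 1 and other.max() == 0) or (sub[0] == 0 and other.min() == 1)):
                        return cov
    return None


def compare_detection_methods(
    gtt_flags: dict[str, bool], spontaneous_flags: dict[str, bool]
) -> dict:
    """Paired per-patient comparison of two surveillance methods.

    Builds the 2x2 of paired outcomes (rows: GTT yes/no, cols: spontaneous
    yes/no) and reports the exact McNemar test (binomial on discordant
    pairs) plus, for comparability with published practice, the Pearson
    chi-square p on the same table.
    """
    if set(gtt_flags) != set(spontaneous_flags):
        raise ValueError("both methods must flag the same patient set")
    both = gtt_only = spont_only = neither = 0
    for pid, g in gtt_flags.items():
        s = spontaneous_flags[pid]
        if g and s:
            both += 1
        elif g:
            gtt_only += 1
        elif s:
            spont_only += 1
        else:
            neither += 1
    table = np.array([[both, gtt_only], [spont_only, neither]])
    if gtt_only + spont_only == 0:
        mcnemar_p = 1.0
    else:
        mcnemar_p = float(mcnemar(table, exact=True).pvalue)
    with np.errstate(all="ignore"):
        try:
            _, chi2_p, _, _ = stats.chi2_contingency(table, correction=False)
        except ValueError:  # a zero margin
            chi2_p = np.nan
    return {
        "table": table,
        "discordant": (gtt_only, spont_only),
        "mcnemar_exact_p": mcnemar_p,
        "chi2_p": float(chi2_p),
    }
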