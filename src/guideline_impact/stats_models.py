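"""Count-regression, Kaplan–Meier and Cox layers with sensitivity variants.

The count outcomes (impact-on-CPGs, impacted-CPGs, associated-CPGs) are
modelled by NB2 negative binomial regression (variance μ + αμ², dispersion
estimated by maximum likelihood) with the log of each trial's observed time
(start to the guideline-search cutoff) as an exposure offset.  Effects are
reported as incidence rate ratios with two-sided Wald 95% CIs at α = 0.05.
The time-to-guideline-impact is summarised by per-cohort Kaplan–Meier
cumulative event curves with a log-rank test, and modelled by Cox
proportional-hazards regression (Efron tie handling) with the same
covariates; Schoenfeld-residual trend tests screen the proportionality
assumption.  The reference cohort is German IITs throughout; study size is
dichotomized at the cohort median of 150 and primary outcomes as one vs.
more than one (reference: more than one).  No multiplicity adjustment is
applied.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from datetime import date
from enum import Enum
from typing import Any, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test, proportional_hazard_test

from .citation_graph import COHORT_ORDER, CitationNetwork, Cohort, subset_guidelines
from .impact_scoring import DEFAULT_CONFIG, ImpactConfig, score_network
from .time_to_impact import (
    DAYS_PER_YEAR,
    DEFAULT_CENSOR_DATE,
    SurvivalRecord,
    build_survival_dataset,
)

logger = logging.getLogger(__name__)

ALPHA_LEVEL = 0.05


class Outcome(str, Enum):
    IMPACT_ON_CPGS = "impact_on_cpgs"
    IMPACTED_CPGS = "impacted_cpgs"
    ASSOCIATED_CPGS = "associated_cpgs"


class SpecError(ValueError):
    """Invalid regression specification for the data at hand."""


class DegenerateFitError(ValueError):
    """The outcome admits no informative fit (all-zero counts, no events)."""


#: Covariates usable in a RegressionSpec.
_SIZE_COVARIATES = ("size_dichotomized", "size_log10", "size_raw")
_KNOWN_COVARIATES = ("cohort", "drug_trial", "n_primary_outcomes_dichotomized",
                     "study_phase", "medical_domain") + _SIZE_COVARIATES

DEFAULT_COVARIATES = ("cohort", "drug_trial", "size_dichotomized",
                      "n_primary_outcomes_dichotomized")


@dataclass(frozen=True)
class RegressionSpec:
    outcome: Outcome = Outcome.IMPACT_ON_CPGS
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    offset: bool = True
    reference_cohort: Cohort = Cohort.GERMAN_IIT

    def validate(self) -> None:
        unknown = set(self.covariates) - set(_KNOWN_COVARIATES)
        if unknown:
            raise SpecError(f"unknown covariates {sorted(unknown)}")
        n_size = sum(c in self.covariates for c in _SIZE_COVARIATES)
        if n_size > 1:
            raise SpecError("select exactly one study-size representation")


@dataclass(frozen=True, slots=True)
class TermEstimate:
    term: str
    level: str
    estimate: float     # ratio scale (IRR or HR)
    ci_low: float
    ci_high: float
    p_value: float


@dataclass(slots=True)
class RegressionResult:
    model: str                      # "nb", "poisson" or "cox"
    outcome: str
    terms: list[TermEstimate]
    n_observations: int
    converged: bool
    dispersion_alpha: float | None = None
    log_likelihood: float | None = None
    fitted: Any = field(default=None, repr=False, compare=False)

    def term(self, name: str) -> TermEstimate:
        for t in self.terms:
            if t.term == name:
                return t
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([{
            "term": t.term, "level": t.level, "estimate": t.estimate,
            "ci_low": t.ci_low, "ci_high": t.ci_high, "p": t.p_value,
        } for t in self.terms])


@dataclass(slots=True)
class KMEstimate:
    times: np.ndarray                       # years since trial start
    cumulative_incidence: dict[str, np.ndarray]  # cohort value -> curve
    at_risk: pd.DataFrame                   # yearly at-risk counts per cohort
    logrank_p: float


@dataclass(frozen=True, slots=True)
class CovariateTrend:
    covariate: str
    p_value: float
    test_statistic: float


@dataclass(slots=True)
class SchoenfeldDiagnostics:
    available: bool
    trends: list[CovariateTrend] = field(default_factory=list)
    residuals: pd.DataFrame | None = None
    reason: str = ""


# ---------------------------------------------------------------------------
# analysis frame
# ---------------------------------------------------------------------------


_FRAME_COLUMNS = [
    "trial_id", "cohort", "drug_trial", "study_size", "size_dichotomized",
    "size_log10", "size_raw", "n_primary_outcomes",
    "n_primary_outcomes_dichotomized", "time_days", "time_years", "event",
    "observed_time_days", "observed_time_years", "negative_time",
]


def records_to_frame(records: Sequence[SurvivalRecord]) -> pd.DataFrame:
    if not records:
        return pd.DataFrame(columns=_FRAME_COLUMNS)
    rows = []
    for r in records:
        rows.append({
            "trial_id": r.trial_id,
            "cohort": r.cohort.value,
            "drug_trial": int(r.is_drug_trial),
            "study_size": r.study_size,
            "size_dichotomized": int(r.size_above_150),
            "size_log10": float(np.log10(r.study_size)),
            "size_raw": float(r.study_size),
            "n_primary_outcomes": r.n_primary_outcomes,
            "n_primary_outcomes_dichotomized": int(r.single_primary_outcome),
            "time_days": r.time_days,
            "time_years": r.time_days / DAYS_PER_YEAR,
            "event": r.event,
            "observed_time_days": r.observed_time_days,
            "observed_time_years": r.observed_time_days / DAYS_PER_YEAR,
            "negative_time": r.negative_time,
        })
    return pd.DataFrame(rows)


def build_analysis_frame(
    network: CitationNetwork,
    censor_date: date = DEFAULT_CENSOR_DATE,
    seed: int = 0,
    config: ImpactConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """Merged per-trial frame: covariates, impact counts and survival columns."""
    impacts = score_network(network, config)
    records = build_survival_dataset(network, censor_date, seed, config, impacts)
    df = records_to_frame(records)
    phases, domains, imp_on, imp_cpgs, assoc = [], [], [], [], []
    for tid in df["trial_id"]:
        t = network.trials[tid]
        phases.append(t.study_phase or "unknown")
        domains.append(t.medical_domain or "unknown")
        ti = impacts[tid]
        imp_on.append(ti.impact_on_cpgs)
        imp_cpgs.append(ti.impacted_cpgs)
        assoc.append(ti.associated_cpgs)
    df["study_phase"] = phases
    df["medical_domain"] = domains
    df["impact_on_cpgs"] = imp_on
    df["impacted_cpgs"] = imp_cpgs
    df["associated_cpgs"] = assoc
    return df


def _design_matrix(df: pd.DataFrame, spec: RegressionSpec) -> pd.DataFrame:
    """Dummy-coded design matrix (without intercept) in a fixed term order."""
    cols: dict[str, np.ndarray] = {}
    for cov in spec.covariates:
        if cov == "cohort":
            levels = [c.value for c in COHORT_ORDER if c is not spec.reference_cohort]
            present = set(df["cohort"].unique())
            if len(present) < 2:
                raise SpecError("cohort has a single level in the data")
            for lvl in levels:
                if lvl in present:
                    cols[f"cohort[{lvl}]"] = (df["cohort"] == lvl).to_numpy(float)
        elif cov in ("study_phase", "medical_domain"):
            levels = sorted(df[cov].unique())
            if len(levels) < 2:
                raise SpecError(f"{cov} has a single level in the data")
            for lvl in levels[1:]:  # first level is the reference
                cols[f"{cov}[{lvl}]"] = (df[cov] == lvl).to_numpy(float)
        else:
            col = {"size_dichotomized": "size_dichotomized",
                   "size_log10": "size_log10",
                   "size_raw": "size_raw",
                   "drug_trial": "drug_trial",
                   "n_primary_outcomes_dichotomized": "n_primary_outcomes_dichotomized",
                   }[cov]
            values = df[col].to_numpy(float)
            if np.unique(values).size < 2:
                raise SpecError(f"covariate {cov!r} has a single level in the data")
            cols[cov] = values
    return pd.DataFrame(cols, index=df.index)


_LEVEL_LABELS = {
    "size_dichotomized": ">150 vs <=150",
    "size_log10": "log10(size)",
    "size_raw": "per participant",
    "drug_trial": "yes vs no",
    "n_primary_outcomes_dichotomized": "1 vs >1",
}


def _terms_from_params(names, params, ci, pvals) -> list[TermEstimate]:
    out = []
    for i, name in enumerate(names):
        if name.startswith(("cohort[", "study_phase[", "medical_domain[")):
            term, level = name.split("[", 1)
            level = level.rstrip("]")
        else:
            term, level = name, _LEVEL_LABELS.get(name, name)
        out.append(TermEstimate(
            term=name, level=level,
            estimate=float(np.exp(params[i])),
            ci_low=float(np.exp(ci[i][0])),
            ci_high=float(np.exp(ci[i][1])),
            p_value=float(pvals[i]),
        ))
    return out


# ---------------------------------------------------------------------------
# count models
# ---------------------------------------------------------------------------


def fit_count_model(
    df: pd.DataFrame,
    spec: RegressionSpec | None = None,
    family: str = "nb",
) -> RegressionResult:
    """Fit the NB2 (or, for reference, Poisson) count model with the
    log-observed-time offset.

    Non-convergence is flagged on the result, not raised; an all-zero
    outcome raises :class:`DegenerateFitError`.
    """
    spec = spec or RegressionSpec()
    spec.validate()
    work = df.loc[~df.get("negative_time", pd.Series(False, index=df.index))].copy()
    y = work[spec.outcome.value].to_numpy(float)
    if (y == 0).all():
        raise DegenerateFitError(f"outcome {spec.outcome.value} is identically zero")
    X = _design_matrix(work, spec)
    names = list(X.columns)
    exog = sm.add_constant(X.to_numpy(float), prepend=True)
    offset = (np.log(work["observed_time_years"].to_numpy(float))
              if spec.offset else None)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if family == "nb":
            model = sm.NegativeBinomial(y, exog, offset=offset, loglike_method="nb2")
        elif family == "poisson":
            model = sm.Poisson(y, exog, offset=offset)
        else:
            raise ValueError(f"unknown family {family!r}")
        res = model.fit(method="bfgs", maxiter=200, disp=0)
        converged = bool(res.mle_retvals.get("converged", True))
        # polish with a tighter gradient tolerance for reproducible
        # estimates; skipped at the Poisson boundary (alpha ~ 0), where the
        # dispersion gradient cannot vanish and the polish cannot improve
        at_boundary = family == "nb" and res.params[-1] < 1e-4
        if not at_boundary:
            try:
                res2 = model.fit(start_params=res.params, method="bfgs",
                                 maxiter=300, gtol=1e-9, disp=0)
                if (np.isfinite(res2.params).all()
                        and res2.llf >= res.llf - 1e-8
                        and (family != "nb" or res2.params[-1] > 0)):
                    res = res2
                    converged = converged or bool(
                        res.mle_retvals.get("converged", False))
            except Exception:
                pass

    k = len(names)
    params = np.asarray(res.params)[1:1 + k]
    ci = np.asarray(res.conf_int(alpha=ALPHA_LEVEL))[1:1 + k]
    pvals = np.asarray(res.pvalues)[1:1 + k]
    alpha_hat = float(res.params[-1]) if family == "nb" else None

    return RegressionResult(
        model=family,
        outcome=spec.outcome.value,
        terms=_terms_from_params(names, params, ci, pvals),
        n_observations=int(len(work)),
        converged=converged,
        dispersion_alpha=alpha_hat,
        log_likelihood=float(res.llf),
        fitted=res,
    )


# ---------------------------------------------------------------------------
# survival models
# ---------------------------------------------------------------------------


def _survival_frame(df: pd.DataFrame, spec: RegressionSpec) -> tuple[pd.DataFrame, list[str]]:
    work = df.copy()
    flagged = work["negative_time"].sum() if "negative_time" in work else 0
    if flagged:
        logger.warning("dropping %d record(s) with non-positive event time "
                       "from the survival analysis", flagged)
        work = work.loc[~work["negative_time"]]
    X = _design_matrix(work, spec)
    names = list(X.columns)
    X = X.copy()
    X["time_years"] = work["time_years"].to_numpy(float)
    X["event"] = work["event"].to_numpy(int)
    return X, names


def km_fit(df: pd.DataFrame | Sequence[SurvivalRecord]) -> KMEstimate:
    """Per-cohort Kaplan–Meier cumulative event curves, yearly at-risk
    counts and the across-cohort log-rank test."""
    if not isinstance(df, pd.DataFrame):
        df = records_to_frame(df)
    if df.empty:
        raise DegenerateFitError("no records")
    work = df.loc[~df["negative_time"]] if "negative_time" in df else df
    grid = np.unique(np.concatenate([[0.0], work["time_years"].to_numpy(float)]))

    curves: dict[str, np.ndarray] = {}
    max_year = int(np.ceil(work["time_years"].max())) if len(work) else 0
    years = np.arange(0, max_year + 1)
    at_risk_rows = {}
    groups = ["all"] + [c.value for c in COHORT_ORDER if (work["cohort"] == c.value).any()]
    for grp in groups:
        sub = work if grp == "all" else work[work["cohort"] == grp]
        kmf = KaplanMeierFitter()
        kmf.fit(sub["time_years"], event_observed=sub["event"])
        surv = kmf.survival_function_at_times(grid).to_numpy(float)
        curves[grp] = 1.0 - surv
        at_risk_rows[grp] = [(sub["time_years"].to_numpy(float) >= y).sum() for y in years]

    n_cohorts = (work["cohort"].nunique())
    if n_cohorts >= 2 and work["event"].sum() > 0:
        lr = multivariate_logrank_test(work["time_years"], work["cohort"], work["event"])
        logrank_p = float(lr.p_value)
    else:
        logrank_p = float("nan")

    return KMEstimate(
        times=grid,
        cumulative_incidence=curves,
        at_risk=pd.DataFrame(at_risk_rows, index=pd.Index(years, name="year")),
        logrank_p=logrank_p,
    )


def fit_cox(df: pd.DataFrame, spec: RegressionSpec | None = None) -> RegressionResult:
    """Cox proportional-hazards fit (Efron ties) on time-to-guideline-impact.

    Raises :class:`DegenerateFitError` when no events are present;
    convergence/separation trouble is flagged, not raised.
    """
    spec = spec or RegressionSpec()
    spec.validate()
    if df["event"].sum() == 0:
        raise DegenerateFitError("no events in the survival dataset")
    data, names = _survival_frame(df, spec)

    cph = CoxPHFitter()
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        try:
            cph.fit(data, duration_col="time_years", event_col="event")
        except Exception as exc:  # separation / collinearity
            raise DegenerateFitError(f"Cox fit failed: {exc}") from exc
        if any("convergence" in str(w.message).lower()
               or "collinear" in str(w.message).lower() for w in caught):
            converged = False

    summary = cph.summary
    terms = []
    with np.errstate(over="ignore"):  # near-degenerate fits give unbounded CIs
        for name in names:
            row = summary.loc[name]
            terms.append(TermEstimate(
                term=name,
                level=(name.split("[", 1)[1].rstrip("]") if "[" in name
                       else _LEVEL_LABELS.get(name, name)),
                estimate=float(row["exp(coef)"]),
                ci_low=float(np.exp(row["coef lower 95%"])),
                ci_high=float(np.exp(row["coef upper 95%"])),
                p_value=float(row["p"]),
            ))
    return RegressionResult(
        model="cox",
        outcome="time_to_guideline_impact",
        terms=terms,
        n_observations=int(len(data)),
        converged=converged,
        log_likelihood=float(cph.log_likelihood_),
        fitted=(cph, data),
    )


def schoenfeld_check(cox_result: RegressionResult) -> SchoenfeldDiagnostics:
    """Scaled Schoenfeld residual trend tests per covariate.

    Unavailable (flagged, no exception) with fewer than two events.
    """
    if cox_result.model != "cox" or cox_result.fitted is None:
        raise ValueError("schoenfeld_check requires a fitted Cox result")
    cph, data = cox_result.fitted
    if int(data["event"].sum()) < 2:
        return SchoenfeldDiagnostics(available=False,
                                     reason="fewer than 2 events")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        test = proportional_hazard_test(cph, data, time_transform="rank")
        residuals = cph.compute_residuals(data, kind="scaled_schoenfeld")
    trends = [
        CovariateTrend(
            covariate=str(var),
            p_value=float(test.summary.loc[var, "p"].iloc[0]
                          if hasattr(test.summary.loc[var, "p"], "iloc")
                          else test.summary.loc[var, "p"]),
            test_statistic=float(
                test.summary.loc[var, "test_statistic"].iloc[0]
                if hasattr(test.summary.loc[var, "test_statistic"], "iloc")
                else test.summary.loc[var, "test_statistic"]),
        )
        for var in cph.params_.index
    ]
    return SchoenfeldDiagnostics(available=True, trends=trends, residuals=residuals)


# ---------------------------------------------------------------------------
# sensitivity analyses
# ---------------------------------------------------------------------------

SENSITIVITY_VARIANTS = (
    "continuous_size_log10",
    "undichotomized_with_phase_domain",
    "exclude_german_language_cpgs",
    "associated_cpgs_outcome",
)


def run_sensitivity(
    network: CitationNetwork,
    variant: str,
    censor_date: date = DEFAULT_CENSOR_DATE,
    seed: int = 0,
    config: ImpactConfig = DEFAULT_CONFIG,
    outcome: Outcome = Outcome.IMPACT_ON_CPGS,
) -> RegressionResult:
    """Refit the count model under one of the pre-registered sensitivity
    variants.  ``exclude_german_language_cpgs`` recomputes impact and
    survival on the filtered network before refitting."""
    if variant not in SENSITIVITY_VARIANTS:
        raise ValueError(f"unknown sensitivity variant {variant!r}")

    if variant == "exclude_german_language_cpgs":
        keep = [g.cpg_id for g in network.guidelines.values()
                if g.language.strip().lower() != "german"]
        network = subset_guidelines(network, keep)
        spec = RegressionSpec(outcome=outcome)
    elif variant == "continuous_size_log10":
        spec = RegressionSpec(
            outcome=outcome,
            covariates=("cohort", "drug_trial", "size_log10",
                        "n_primary_outcomes_dichotomized"))
    elif variant == "undichotomized_with_phase_domain":
        spec = RegressionSpec(
            outcome=outcome,
            covariates=("cohort", "drug_trial", "size_raw",
                        "n_primary_outcomes_dichotomized",
                        "study_phase", "medical_domain"))
    else:  # associated_cpgs_outcome
        spec = RegressionSpec(outcome=Outcome.ASSOCIATED_CPGS)

    df = build_analysis_frame(network, censor_date, seed, config)
    return fit_count_model(df, spec)
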