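"""Guideline date resolution and the censored time-to-guideline-impact dataset.

A guideline's publication date is the earliest date its text was publicly
visible.  Year is always known; a missing month or day is imputed by a
uniform draw over the valid values (1–12 for months, 1–n for days where n
respects month length and leap years).  Draws are derived per guideline
from one global seed combined with a stable hash of the guideline id, so
the imputation is reproducible and independent of iteration order.

The time-to-guideline-impact of a trial runs from its start date to the
earliest resolved publication date among the guidelines it *impacted*
(impactful path required); trials without impact are right-censored at the
end of the guideline search period (2019-08-31 by default).  Durations are
kept in days internally; the statistics layer converts to years.
"""

from __future__ import annotations

import calendar
import logging
import zlib
from dataclasses import dataclass
from datetime import date

import numpy as np

from .citation_graph import CitationNetwork, Cohort, Guideline
from .impact_scoring import DEFAULT_CONFIG, ImpactConfig, TrialImpact, score_network

logger = logging.getLogger(__name__)

#: Last look-up date of the guideline search; the default censoring date.
DEFAULT_CENSOR_DATE = date(2019, 8, 31)

#: Conversion used when reporting durations in years.
DAYS_PER_YEAR = 365.25

#: Median study size used for covariate dichotomization.
SIZE_DICHOTOMY_THRESHOLD = 150


class UnresolvableDateError(ValueError):
    """The guideline has no publication year."""


@dataclass(frozen=True, slots=True)
class ResolvedDate:
    date: date
    imputed_month: bool
    imputed_day: bool
    rng_seed_used: int


@dataclass(frozen=True, slots=True)
class SurvivalRecord:
    """One right-censored time-to-guideline-impact observation."""

    trial_id: str
    time_days: int           # start -> first impacted-CPG date, or censor
    event: int               # 1 = guideline impact observed
    cohort: Cohort
    is_drug_trial: bool
    size_above_150: bool
    single_primary_outcome: bool
    study_size: int
    n_primary_outcomes: int
    observed_time_days: int  # start -> censor date (regression exposure)
    negative_time: bool = False  # impacted guideline dated on/before start


def _guideline_rng(seed: int, cpg_id: str) -> tuple[np.random.Generator, int]:
    """Per-guideline generator from the global seed and a stable id hash."""
    child = zlib.crc32(cpg_id.encode("utf-8"))
    return np.random.default_rng([seed, child]), child


def resolve_publication_date(guideline: Guideline, seed: int = 0) -> ResolvedDate:
    """Resolve a possibly partial guideline date, imputing month/day uniformly.

    The draw depends only on ``seed`` and the guideline id.
    """
    if guideline.pub_year is None:
        raise UnresolvableDateError(f"guideline {guideline.cpg_id!r} has no year")
    rng, child = _guideline_rng(seed, guideline.cpg_id)
    month = guideline.pub_month
    imputed_month = month is None
    if imputed_month:
        month = int(rng.integers(1, 13))
    day = guideline.pub_day
    imputed_day = day is None
    if imputed_day:
        ndays = calendar.monthrange(guideline.pub_year, month)[1]
        day = int(rng.integers(1, ndays + 1))
    return ResolvedDate(
        date=date(guideline.pub_year, month, day),
        imputed_month=imputed_month,
        imputed_day=imputed_day,
        rng_seed_used=child,
    )


def resolve_all_dates(network: CitationNetwork, seed: int = 0) -> dict[str, ResolvedDate]:
    """Resolved dates for every guideline (sorted id order, one global seed)."""
    return {
        cpg_id: resolve_publication_date(network.guidelines[cpg_id], seed)
        for cpg_id in sorted(network.guidelines)
    }


def _record_for_trial(
    network: CitationNetwork,
    trial_id: str,
    censor_date: date,
    resolved: dict[str, ResolvedDate],
    impact: TrialImpact,
) -> SurvivalRecord | None:
    trial = network.trial(trial_id)
    if trial.start_date is None:
        logger.warning("trial %s has no start date; excluded from survival dataset",
                       trial_id)
        return None
    observed = (censor_date - trial.start_date).days

    event = 0
    time_days = observed
    negative = False
    if impact.impacted_cpg_ids:
        earliest = min(resolved[c].date for c in impact.impacted_cpg_ids)
        if earliest <= censor_date:
            event = 1
            time_days = (earliest - trial.start_date).days
            if time_days <= 0:
                negative = True
                logger.warning(
                    "trial %s: impacted guideline dated on/before trial start "
                    "(%s); record kept and flagged", trial_id, earliest,
                )

    return SurvivalRecord(
        trial_id=trial_id,
        time_days=time_days,
        event=event,
        cohort=trial.cohort,
        is_drug_trial=trial.is_drug_trial,
        size_above_150=trial.study_size > SIZE_DICHOTOMY_THRESHOLD,
        single_primary_outcome=trial.n_primary_outcomes == 1,
        study_size=trial.study_size,
        n_primary_outcomes=trial.n_primary_outcomes,
        observed_time_days=observed,
        negative_time=negative,
    )


def time_to_guideline_impact(
    network: CitationNetwork,
    trial_id: str,
    censor_date: date = DEFAULT_CENSOR_DATE,
    resolved_dates: dict[str, ResolvedDate] | None = None,
    config: ImpactConfig = DEFAULT_CONFIG,
    seed: int = 0,
) -> SurvivalRecord:
    """Survival record for one trial (event time to the earliest impacted
    guideline, censored at ``censor_date`` otherwise)."""
    from .impact_scoring import trial_impact

    if resolved_dates is None:
        resolved_dates = resolve_all_dates(network, seed)
    impact = trial_impact(network, trial_id, config)
    rec = _record_for_trial(network, trial_id, censor_date, resolved_dates, impact)
    if rec is None:
        raise UnresolvableDateError(f"trial {trial_id!r} has no start date")
    return rec


def build_survival_dataset(
    network: CitationNetwork,
    censor_date: date = DEFAULT_CENSOR_DATE,
    seed: int = 0,
    config: ImpactConfig = DEFAULT_CONFIG,
    impacts: dict[str, TrialImpact] | None = None,
) -> list[SurvivalRecord]:
    """One record per trial with a start date, deterministic given ``seed``.

    ``impacts`` may be supplied to reuse already-computed impact statistics.
    """
    resolved = resolve_all_dates(network, seed)
    if impacts is None:
        impacts = score_network(network, config)
    out: list[SurvivalRecord] = []
    for tid in sorted(network.trials):
        rec = _record_for_trial(network, tid, censor_date, resolved, impacts[tid])
        if rec is not None:
            out.append(rec)
    return out
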