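"""Path enumeration, seven-case classification and impact statistics.

A *path* is one unique chain of citations from a trial to a guideline:
either guideline→article (direct), guideline→SR→article (SR-mediated) or
guideline→registry-number (direct registry citation).  A path is
*impactful* when every citing step included the cited reference:

* the terminal reference (article, SR or registry number) is cited at least
  once in the guideline's **main text** (supplement/appendix citations do
  not count), and
* for SR-mediated paths, the article was *included* in the SR's synthesis
  (an ``OTHER`` status — introduction/summary mentions — counts as
  excluded).

In the canonical case table these are the article-direct-included and
SR-included-both-steps rows (cases 2 and 5); every other pattern is
non-impactful.  Direct registry citations that do appear in main text did
not occur in the motivating dataset; their classification is configurable
and impactful by default, consistent with the general every-step-included
rule.

Per trial, *impact-on-CPGs* sums the main-text mention counts of the
terminal references of impactful paths (each distinct reference counted
once per guideline even if several paths share it) and *impacted-CPGs*
counts distinct guidelines reached by at least one impactful path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from .citation_graph import (
    COHORT_ORDER,
    CitationNetwork,
    Cohort,
    Location,
    SRStatus,
    TargetKind,
    UnknownEntityError,
)

logger = logging.getLogger(__name__)


class ClassificationError(ValueError):
    """A path chain is inconsistent with the network's edges."""


@dataclass(frozen=True, slots=True)
class ImpactConfig:
    """Scoring options.

    direct_citation_impactful
        Whether a main-text registry-number citation (the hypothetical
        direct-included case) counts as impactful.  Default True, per the
        general rule that a path is impactful when every step included the
        reference.
    """

    direct_citation_impactful: bool = True


DEFAULT_CONFIG = ImpactConfig()


@dataclass(frozen=True, slots=True)
class CitationPath:
    """One classified trial→guideline citation chain."""

    trial_id: str
    article_id: str | None
    sr_id: str | None
    cpg_id: str
    article_in_sr: SRStatus | None  # normalized: INCLUDED or EXCLUDED
    reference_in_cpg: SRStatus      # INCLUDED iff >=1 main-text citation
    case_number: int                # 1-7, plus 8 for direct-included
    impactful: bool

    @property
    def terminal_reference(self) -> tuple[TargetKind, str]:
        """The reference the guideline actually cites on this path."""
        if self.sr_id is not None:
            return (TargetKind.SR, self.sr_id)
        if self.article_id is not None:
            return (TargetKind.ARTICLE, self.article_id)
        return (TargetKind.REGISTRY_NUMBER, self.trial_id)


@dataclass(frozen=True, slots=True)
class TrialImpact:
    """Per-trial impact statistics."""

    trial_id: str
    impact_on_cpgs: int      # total impactful main-text guideline citations
    impacted_cpgs: int       # distinct guidelines with >=1 impactful path
    guideline_impact: int    # binary status: 1 iff impacted_cpgs >= 1
    associated_cpgs: int     # distinct guidelines with any path
    impacted_cpg_ids: tuple[str, ...] = ()
    associated_cpg_ids: tuple[str, ...] = ()


#: FlowSummary count fields that are per-trial properties (per-cohort
#: vectors partition exactly).
_TRIAL_LEVEL_FIELDS = (
    "n_trials",
    "n_trials_with_article",
    "n_trials_cited_by_sr",
    "n_trials_sr_excluded",
    "n_trials_sr_included",
    "n_trials_direct_impactful",
    "n_trials_via_sr_impactful",
    "n_trials_associated_cpg",
    "n_trials_impactful",
    "n_trials_no_impact",
)
_CPG_LEVEL_FIELDS = ("n_cpgs_associated", "n_cpgs_impacted")
_CITATION_FIELDS = ("n_citations_total", "n_citations_main", "n_citations_supp")

FLOW_FIELDS = _TRIAL_LEVEL_FIELDS + _CPG_LEVEL_FIELDS + _CITATION_FIELDS


@dataclass(slots=True)
class FlowSummary:
    """Network-level evidence-flow counts (the flowchart marginals)."""

    n_trials: int = 0
    n_trials_with_article: int = 0
    n_trials_cited_by_sr: int = 0
    n_trials_sr_excluded: int = 0
    n_trials_sr_included: int = 0
    n_trials_direct_impactful: int = 0
    n_trials_via_sr_impactful: int = 0
    n_trials_associated_cpg: int = 0
    n_trials_impactful: int = 0
    n_trials_no_impact: int = 0
    n_cpgs_associated: int = 0
    n_cpgs_impacted: int = 0
    n_citations_total: int = 0
    n_citations_main: int = 0
    n_citations_supp: int = 0
    #: field name -> per-cohort counts in COHORT_ORDER
    per_cohort: dict[str, tuple[int, int, int, int]] = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {f: getattr(self, f) for f in FLOW_FIELDS}
        d["per_cohort"] = {k: list(v) for k, v in self.per_cohort.items()}
        d["cohort_order"] = [c.value for c in COHORT_ORDER]
        return d


@dataclass(frozen=True, slots=True)
class CohortStatistic:
    """One statistic overall and broken down by cohort (in COHORT_ORDER)."""

    name: str
    overall: float
    by_cohort: tuple[float, float, float, float]


# ---------------------------------------------------------------------------
# path enumeration and classification
# ---------------------------------------------------------------------------


def _normalize_sr_status(status: SRStatus) -> SRStatus:
    """Collapse OTHER (intro/summary mentions) to EXCLUDED."""
    return SRStatus.INCLUDED if status is SRStatus.INCLUDED else SRStatus.EXCLUDED


def classify_path(
    chain: tuple[str, str | None, str | None, str],
    network: CitationNetwork,
    config: ImpactConfig = DEFAULT_CONFIG,
) -> CitationPath:
    """Classify one (trial_id, article_id, sr_id, cpg_id) chain.

    Raises :class:`ClassificationError` if the chain is not realized by the
    network's edges.
    """
    trial_id, article_id, sr_id, cpg_id = chain
    if cpg_id not in network.guidelines:
        raise ClassificationError(f"unknown guideline {cpg_id!r}")

    article_in_sr: SRStatus | None = None

    if article_id is None:
        if sr_id is not None:
            raise ClassificationError("sr-mediated chain requires an article")
        terminal = (TargetKind.REGISTRY_NUMBER, trial_id)
    elif sr_id is None:
        art = network.articles.get(article_id)
        if art is None or art.trial_id != trial_id:
            raise ClassificationError(
                f"article {article_id!r} does not belong to trial {trial_id!r}"
            )
        terminal = (TargetKind.ARTICLE, article_id)
    else:
        art = network.articles.get(article_id)
        if art is None or art.trial_id != trial_id:
            raise ClassificationError(
                f"article {article_id!r} does not belong to trial {trial_id!r}"
            )
        statuses = [
            s for sid, s in network.srs_by_article.get(article_id, []) if sid == sr_id
        ]
        if not statuses:
            raise ClassificationError(
                f"sr {sr_id!r} does not cite article {article_id!r}"
            )
        # an SR cites each article once (enforced at build)
        article_in_sr = _normalize_sr_status(statuses[0])
        terminal = (TargetKind.SR, sr_id)

    if (cpg_id, *terminal) not in network.cpg_ref_counts:
        raise ClassificationError(
            f"guideline {cpg_id!r} does not cite {terminal[0].value} {terminal[1]!r}"
        )
    included_in_cpg = network.ref_main_count(cpg_id, *terminal) > 0
    reference_in_cpg = SRStatus.INCLUDED if included_in_cpg else SRStatus.EXCLUDED

    if terminal[0] is TargetKind.ARTICLE:
        case = 2 if included_in_cpg else 1
        impactful = included_in_cpg
    elif terminal[0] is TargetKind.SR:
        if article_in_sr is SRStatus.EXCLUDED:
            case = 4 if included_in_cpg else 3
            impactful = False
        else:
            case = 5 if included_in_cpg else 6
            impactful = included_in_cpg
    else:  # registry number
        case = 8 if included_in_cpg else 7
        impactful = included_in_cpg and config.direct_citation_impactful

    return CitationPath(
        trial_id=trial_id,
        article_id=article_id,
        sr_id=sr_id,
        cpg_id=cpg_id,
        article_in_sr=article_in_sr,
        reference_in_cpg=reference_in_cpg,
        case_number=case,
        impactful=impactful,
    )


def enumerate_paths(
    network: CitationNetwork,
    trial_id: str,
    config: ImpactConfig = DEFAULT_CONFIG,
) -> list[CitationPath]:
    """All unique citation chains from ``trial_id`` to any guideline,
    classified, in deterministic (cpg, article, sr) order."""
    network.trial(trial_id)  # raises UnknownEntityError

    chains: set[tuple[str, str | None, str | None, str]] = set()
    for aid in network.articles_by_trial.get(trial_id, []):
        for cpg in network.cpgs_by_ref.get((TargetKind.ARTICLE, aid), []):
            chains.add((trial_id, aid, None, cpg))
        for sr_id, _status in network.srs_by_article.get(aid, []):
            for cpg in network.cpgs_by_ref.get((TargetKind.SR, sr_id), []):
                chains.add((trial_id, aid, sr_id, cpg))
    for cpg in network.cpgs_by_ref.get((TargetKind.REGISTRY_NUMBER, trial_id), []):
        chains.add((trial_id, None, None, cpg))

    ordered = sorted(chains, key=lambda c: (c[3], c[1] or "", c[2] or ""))
    return [classify_path(c, network, config) for c in ordered]


# ---------------------------------------------------------------------------
# per-trial statistics
# ---------------------------------------------------------------------------


def _impact_from_paths(trial_id: str, paths: list[CitationPath]) -> TrialImpact:
    associated = sorted({p.cpg_id for p in paths})
    impactful = [p for p in paths if p.impactful]
    impacted = sorted({p.cpg_id for p in impactful})
    # distinct (guideline, terminal reference): a reference shared by several
    # impactful paths to the same guideline is counted once
    terminal_refs = {(p.cpg_id, *p.terminal_reference) for p in impactful}
    return TrialImpact(
        trial_id=trial_id,
        impact_on_cpgs=0,  # placeholder, filled by caller with network access
        impacted_cpgs=len(impacted),
        guideline_impact=1 if impacted else 0,
        associated_cpgs=len(associated),
        impacted_cpg_ids=tuple(impacted),
        associated_cpg_ids=tuple(associated),
    ), terminal_refs


def trial_impact(
    network: CitationNetwork,
    trial_id: str,
    config: ImpactConfig = DEFAULT_CONFIG,
) -> TrialImpact:
    """Impact statistics for one trial (0/0/status-0 when no paths exist)."""
    paths = enumerate_paths(network, trial_id, config)
    base, terminal_refs = _impact_from_paths(trial_id, paths)
    total = sum(network.ref_main_count(cpg, kind, tid)
                for cpg, kind, tid in terminal_refs)
    return TrialImpact(
        trial_id=base.trial_id,
        impact_on_cpgs=total,
        impacted_cpgs=base.impacted_cpgs,
        guideline_impact=base.guideline_impact,
        associated_cpgs=base.associated_cpgs,
        impacted_cpg_ids=base.impacted_cpg_ids,
        associated_cpg_ids=base.associated_cpg_ids,
    )


def score_network(
    network: CitationNetwork,
    config: ImpactConfig = DEFAULT_CONFIG,
) -> dict[str, TrialImpact]:
    """Impact statistics for every trial, keyed by trial id."""
    return {tid: trial_impact(network, tid, config)
            for tid in sorted(network.trials)}


# ---------------------------------------------------------------------------
# flow summary
# ---------------------------------------------------------------------------


def flow_summary(
    network: CitationNetwork,
    config: ImpactConfig = DEFAULT_CONFIG,
) -> FlowSummary:
    """All flowchart marginals, overall and per cohort.

    Trial-level fields count each trial once per category; the per-cohort
    vectors of CPG-level and citation-count fields attribute a guideline or
    citation edge to every cohort whose trials it reaches (so they sum to
    the overall count exactly when no SR or guideline spans cohorts).
    """
    cohort_idx = {c: i for i, c in enumerate(COHORT_ORDER)}
    counts = {f: 0 for f in FLOW_FIELDS}
    vectors = {f: [0, 0, 0, 0] for f in FLOW_FIELDS}

    cpg_cohorts_assoc: dict[str, set[int]] = {}
    cpg_cohorts_impacted: dict[str, set[int]] = {}

    for tid in sorted(network.trials):
        trial = network.trials[tid]
        k = cohort_idx[trial.cohort]
        paths = enumerate_paths(network, tid, config)

        has_article = bool(network.articles_by_trial.get(tid))
        sr_statuses = [
            _normalize_sr_status(s)
            for aid in network.articles_by_trial.get(tid, [])
            for _sr, s in network.srs_by_article.get(aid, [])
        ]
        flags = {
            "n_trials": True,
            "n_trials_with_article": has_article,
            "n_trials_cited_by_sr": bool(sr_statuses),
            "n_trials_sr_excluded": SRStatus.EXCLUDED in sr_statuses,
            "n_trials_sr_included": SRStatus.INCLUDED in sr_statuses,
            "n_trials_direct_impactful": any(
                p.impactful and p.sr_id is None and p.article_id is not None
                for p in paths
            ),
            "n_trials_via_sr_impactful": any(
                p.impactful and p.sr_id is not None for p in paths
            ),
            "n_trials_associated_cpg": bool(paths),
            "n_trials_impactful": any(p.impactful for p in paths),
        }
        flags["n_trials_no_impact"] = not flags["n_trials_impactful"]
        for f, v in flags.items():
            if v:
                counts[f] += 1
                vectors[f][k] += 1

        for p in paths:
            cpg_cohorts_assoc.setdefault(p.cpg_id, set()).add(k)
            if p.impactful:
                cpg_cohorts_impacted.setdefault(p.cpg_id, set()).add(k)

    counts["n_cpgs_associated"] = len(cpg_cohorts_assoc)
    counts["n_cpgs_impacted"] = len(cpg_cohorts_impacted)
    for cpg, ks in cpg_cohorts_assoc.items():
        for k in ks:
            vectors["n_cpgs_associated"][k] += 1
    for cpg, ks in cpg_cohorts_impacted.items():
        for k in ks:
            vectors["n_cpgs_impacted"][k] += 1

    # citation totals over all guideline edges; per-cohort attribution via
    # the cohorts of the trials behind the cited reference
    for g in network.guidelines.values():
        for e in g.citations:
            fieldname = ("n_citations_main" if e.location is Location.MAIN_TEXT
                         else "n_citations_supp")
            counts[fieldname] += e.count
            counts["n_citations_total"] += e.count
            for k in _edge_cohorts(network, e, cohort_idx):
                vectors[fieldname][k] += e.count
                vectors["n_citations_total"][k] += e.count

    return FlowSummary(
        **counts,
        per_cohort={f: tuple(v) for f, v in vectors.items()},
    )


def _edge_cohorts(network, edge, cohort_idx) -> set[int]:
    """Cohort indices of trials reachable from a guideline citation edge."""
    tids: set[str] = set()
    if edge.target_kind is TargetKind.ARTICLE:
        art = network.articles.get(edge.target_id)
        if art is not None:
            tids.add(art.trial_id)
    elif edge.target_kind is TargetKind.SR:
        sr = network.srs.get(edge.target_id)
        if sr is not None:
            for c in sr.citations:
                art = network.articles.get(c.article_id)
                if art is not None:
                    tids.add(art.trial_id)
    else:
        tids.add(edge.target_id)
    return {cohort_idx[network.trials[t].cohort] for t in tids if t in network.trials}


# ---------------------------------------------------------------------------
# cohort breakdown
# ---------------------------------------------------------------------------

_AGGREGATES = (
    "mean_impact_on_cpgs",
    "mean_impacted_cpgs",
    "mean_associated_cpgs",
    "impact_proportion",
)


def cohort_breakdown(
    network: CitationNetwork,
    statistic: str,
    config: ImpactConfig = DEFAULT_CONFIG,
) -> CohortStatistic:
    """One statistic overall and per cohort (overall is pooled, not a mean
    of cohort values).

    ``statistic`` is a :class:`FlowSummary` field name or one of
    ``mean_impact_on_cpgs``, ``mean_impacted_cpgs``, ``mean_associated_cpgs``,
    ``impact_proportion``.
    """
    if statistic in FLOW_FIELDS:
        fs = flow_summary(network, config)
        return CohortStatistic(
            statistic,
            float(getattr(fs, statistic)),
            tuple(float(v) for v in fs.per_cohort[statistic]),
        )
    if statistic not in _AGGREGATES:
        raise ValueError(f"unknown statistic {statistic!r}")

    impacts = score_network(network, config)
    field_map = {
        "mean_impact_on_cpgs": lambda ti: ti.impact_on_cpgs,
        "mean_impacted_cpgs": lambda ti: ti.impacted_cpgs,
        "mean_associated_cpgs": lambda ti: ti.associated_cpgs,
        "impact_proportion": lambda ti: ti.guideline_impact,
    }
    get = field_map[statistic]

    def _mean(tids: list[str]) -> float:
        if not tids:
            logger.warning("cohort breakdown %r: empty cohort, reporting 0", statistic)
            return 0.0
        return sum(get(impacts[t]) for t in tids) / len(tids)

    all_tids = sorted(network.trials)
    by_cohort = tuple(
        _mean([t for t in all_tids if network.trials[t].cohort is c])
        for c in COHORT_ORDER
    )
    return CohortStatistic(statistic, _mean(all_tids), by_cohort)
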