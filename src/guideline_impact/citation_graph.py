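"""Data model for the four-layer trial→article→SR→guideline citation network.

The network is a layered DAG: clinical practice guidelines (CPGs) cite
articles, systematic reviews (SRs) or trial registry numbers; SRs cite
articles; articles belong to a registered randomized controlled trial (RCT).
Edges never point from a lower layer to a higher one.

Guideline citations carry a *location* (main text vs. appendix/supplement)
and a mention *count*, because impact is quantified as a sum of main-text
citation mentions.  SR citations carry an inclusion status: ``INCLUDED``
means the article's findings entered the review's synthesis; ``EXCLUDED``
and ``OTHER`` (e.g. a mention in the introduction) both count as exclusion
for impact purposes.
"""

from __future__ import annotations

import calendar
import json
import logging
from dataclasses import dataclass, field, fields as dc_fields
from datetime import date
from enum import Enum
from pathlib import Path as FsPath
from typing import Any, Iterable, Mapping, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

SCHEMA_VERSION = 1

#: Eligibility window for trial start dates (strict validation only).
ELIGIBLE_START_MIN = date(2005, 1, 1)
ELIGIBLE_START_MAX = date(2016, 12, 31)


class SchemaError(ValueError):
    """A record violates the tabular schema (duplicate id, unknown label...)."""


class IntegrityError(ValueError):
    """An edge endpoint does not resolve to an existing entity."""


class UnknownEntityError(KeyError):
    """Lookup of an id that is not present in the network."""


class Cohort(str, Enum):
    """The four sampling cohorts: sponsor type crossed with study site."""

    GERMAN_IIT = "german_iit"
    INTL_IIT = "intl_iit"
    GERMAN_IST = "german_ist"
    INTL_IST = "intl_ist"


#: Canonical reporting order: [German IITs, international IITs, German ISTs,
#: international ISTs] — all per-cohort vectors follow it.
COHORT_ORDER: tuple[Cohort, ...] = (
    Cohort.GERMAN_IIT,
    Cohort.INTL_IIT,
    Cohort.GERMAN_IST,
    Cohort.INTL_IST,
)


class SRStatus(str, Enum):
    INCLUDED = "included"
    EXCLUDED = "excluded"
    OTHER = "other"


class Location(str, Enum):
    MAIN_TEXT = "main_text"
    SUPPLEMENT = "supplement"


class TargetKind(str, Enum):
    ARTICLE = "article"
    SR = "sr"
    REGISTRY_NUMBER = "registry_number"


@dataclass(slots=True)
class Trial:
    trial_id: str
    cohort: Cohort
    start_date: date | None
    study_size: int
    n_primary_outcomes: int = 1
    is_drug_trial: bool = False
    study_phase: str | None = None
    medical_domain: str | None = None
    registry_result_only: bool = False


@dataclass(slots=True)
class Article:
    article_id: str
    trial_id: str
    pub_date_electronic: date | None = None
    pub_date_print: date | None = None
    is_method_article: bool = False

    @property
    def pub_date(self) -> date | None:
        """Earliest available publication date (electronic or print)."""
        dates = [d for d in (self.pub_date_electronic, self.pub_date_print) if d]
        return min(dates) if dates else None


@dataclass(slots=True)
class SRCitation:
    article_id: str
    status: SRStatus


@dataclass(slots=True)
class SystematicReview:
    sr_id: str
    pub_date: date | None = None
    citations: list[SRCitation] = field(default_factory=list)


@dataclass(slots=True)
class CitationEdge:
    """One guideline citation record: (target, location) with a mention count."""

    target_kind: TargetKind
    target_id: str
    location: Location
    count: int = 1


@dataclass(slots=True)
class Guideline:
    cpg_id: str
    pub_year: int
    pub_month: int | None = None
    pub_day: int | None = None
    language: str = "English"
    is_journal_article: bool = False
    grades_evidence: bool = False
    marks_recommendations: bool = False
    links_evidence: bool = False
    citations: list[CitationEdge] = field(default_factory=list)


@dataclass(slots=True)
class Diagnostic:
    """One invariant violation found by :func:`validate_network`."""

    code: str
    entity: str
    message: str


# ---------------------------------------------------------------------------
# network container
# ---------------------------------------------------------------------------


class CitationNetwork:
    """Keyed collections of the four layers plus derived adjacency indices.

    Construct via :func:`build_network` (which validates referential
    integrity) rather than directly.
    """

    def __init__(
        self,
        trials: dict[str, Trial],
        articles: dict[str, Article],
        srs: dict[str, SystematicReview],
        guidelines: dict[str, Guideline],
    ) -> None:
        self.trials = trials
        self.articles = articles
        self.srs = srs
        self.guidelines = guidelines
        self._build_indices()

    # -- derived indices ----------------------------------------------------

    def _build_indices(self) -> None:
        self.articles_by_trial: dict[str, list[str]] = {t: [] for t in self.trials}
        for a in self.articles.values():
            self.articles_by_trial.setdefault(a.trial_id, []).append(a.article_id)
        for ids in self.articles_by_trial.values():
            ids.sort()

        # article_id -> [(sr_id, status)]
        self.srs_by_article: dict[str, list[tuple[str, SRStatus]]] = {}
        for sr in self.srs.values():
            for c in sr.citations:
                self.srs_by_article.setdefault(c.article_id, []).append(
                    (sr.sr_id, c.status)
                )
        for lst in self.srs_by_article.values():
            lst.sort()

        # (cpg_id, kind, target_id) -> [main_count, supp_count]
        self.cpg_ref_counts: dict[tuple[str, TargetKind, str], list[int]] = {}
        # (kind, target_id) -> sorted cpg ids citing it
        self.cpgs_by_ref: dict[tuple[TargetKind, str], list[str]] = {}
        for g in self.guidelines.values():
            for e in g.citations:
                key = (g.cpg_id, e.target_kind, e.target_id)
                counts = self.cpg_ref_counts.setdefault(key, [0, 0])
                counts[0 if e.location is Location.MAIN_TEXT else 1] += e.count
                rkey = (e.target_kind, e.target_id)
                lst = self.cpgs_by_ref.setdefault(rkey, [])
                if not lst or lst[-1] != g.cpg_id:
                    lst.append(g.cpg_id)
        for lst in self.cpgs_by_ref.values():
            lst.sort()
            # drop duplicates from multiple locations
            deduped = sorted(set(lst))
            lst[:] = deduped

    # -- lookups ------------------------------------------------------------

    def trial(self, trial_id: str) -> Trial:
        try:
            return self.trials[trial_id]
        except KeyError:
            raise UnknownEntityError(f"unknown trial {trial_id!r}") from None

    def ref_main_count(self, cpg_id: str, kind: TargetKind, target_id: str) -> int:
        return self.cpg_ref_counts.get((cpg_id, kind, target_id), (0, 0))[0]

    def ref_supp_count(self, cpg_id: str, kind: TargetKind, target_id: str) -> int:
        return self.cpg_ref_counts.get((cpg_id, kind, target_id), (0, 0))[1]

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, CitationNetwork):
            return NotImplemented
        return (
            self.trials == other.trials
            and self.articles == other.articles
            and self.srs == other.srs
            and self.guidelines == other.guidelines
        )

    def __repr__(self) -> str:
        return (
            f"CitationNetwork(trials={len(self.trials)}, "
            f"articles={len(self.articles)}, srs={len(self.srs)}, "
            f"guidelines={len(self.guidelines)})"
        )


# ---------------------------------------------------------------------------
# record parsing
# ---------------------------------------------------------------------------


def _parse_date(value: Any, context: str) -> date | None:
    if value is None or value == "" or (isinstance(value, float) and pd.isna(value)):
        return None
    if isinstance(value, date):
        return value
    if isinstance(value, str):
        try:
            return date.fromisoformat(value)
        except ValueError:
            raise SchemaError(f"{context}: unparseable date {value!r}") from None
    if isinstance(value, pd.Timestamp):
        return value.date()
    raise SchemaError(f"{context}: unparseable date {value!r}")


def _parse_bool(value: Any, context: str) -> bool:
    if isinstance(value, bool):
        return value
    if isinstance(value, (int, float)) and value in (0, 1):
        return bool(value)
    if isinstance(value, str):
        v = value.strip().lower()
        if v in ("true", "1", "yes"):
            return True
        if v in ("false", "0", "no", ""):
            return False
    raise SchemaError(f"{context}: unparseable boolean {value!r}")


def _parse_opt_int(value: Any, context: str) -> int | None:
    if value is None or value == "" or (isinstance(value, float) and pd.isna(value)):
        return None
    try:
        return int(value)
    except (TypeError, ValueError):
        raise SchemaError(f"{context}: unparseable integer {value!r}") from None


def _parse_opt_str(value: Any) -> str | None:
    if value is None or value == "" or (isinstance(value, float) and pd.isna(value)):
        return None
    return str(value)


def _parse_enum(enum_cls: type[Enum], value: Any, context: str):
    if isinstance(value, enum_cls):
        return value
    try:
        return enum_cls(str(value).strip().lower())
    except ValueError:
        raise SchemaError(
            f"{context}: unknown {enum_cls.__name__} label {value!r}"
        ) from None


def _records(source: Any) -> list[Any]:
    """Normalize a records argument (DataFrame, iterable of mappings or
    dataclass instances) to a list."""
    if source is None:
        return []
    if isinstance(source, pd.DataFrame):
        return source.to_dict("records")
    return list(source)


def _trial_from_record(rec: Any) -> Trial:
    if isinstance(rec, Trial):
        return rec
    ctx = f"trial {rec.get('trial_id')!r}"
    return Trial(
        trial_id=str(rec["trial_id"]),
        cohort=_parse_enum(Cohort, rec["cohort"], ctx),
        start_date=_parse_date(rec.get("start_date"), ctx),
        study_size=int(rec["study_size"]),
        n_primary_outcomes=int(rec.get("n_primary_outcomes", 1)),
        is_drug_trial=_parse_bool(rec.get("is_drug_trial", False), ctx),
        study_phase=_parse_opt_str(rec.get("study_phase")),
        medical_domain=_parse_opt_str(rec.get("medical_domain")),
        registry_result_only=_parse_bool(rec.get("registry_result_only", False), ctx),
    )


def _article_from_record(rec: Any) -> Article:
    if isinstance(rec, Article):
        return rec
    ctx = f"article {rec.get('article_id')!r}"
    return Article(
        article_id=str(rec["article_id"]),
        trial_id=str(rec["trial_id"]),
        pub_date_electronic=_parse_date(rec.get("pub_date_electronic"), ctx),
        pub_date_print=_parse_date(rec.get("pub_date_print"), ctx),
        is_method_article=_parse_bool(rec.get("is_method_article", False), ctx),
    )


def _sr_from_record(rec: Any) -> SystematicReview:
    if isinstance(rec, SystematicReview):
        return rec
    ctx = f"sr {rec.get('sr_id')!r}"
    citations = []
    for c in rec.get("citations", []):
        if isinstance(c, SRCitation):
            citations.append(c)
        else:
            citations.append(
                SRCitation(
                    article_id=str(c["article_id"]),
                    status=_parse_enum(SRStatus, c["status"], ctx),
                )
            )
    return SystematicReview(
        sr_id=str(rec["sr_id"]),
        pub_date=_parse_date(rec.get("pub_date"), ctx),
        citations=citations,
    )


def _guideline_from_record(rec: Any) -> Guideline:
    if isinstance(rec, Guideline):
        return rec
    ctx = f"guideline {rec.get('cpg_id')!r}"
    citations = []
    for e in rec.get("citations", []):
        if isinstance(e, CitationEdge):
            citations.append(e)
        else:
            citations.append(
                CitationEdge(
                    target_kind=_parse_enum(TargetKind, e["target_kind"], ctx),
                    target_id=str(e["target_id"]),
                    location=_parse_enum(Location, e["location"], ctx),
                    count=int(e.get("count", 1)),
                )
            )
    return Guideline(
        cpg_id=str(rec["cpg_id"]),
        pub_year=int(rec["pub_year"]),
        pub_month=_parse_opt_int(rec.get("pub_month"), ctx),
        pub_day=_parse_opt_int(rec.get("pub_day"), ctx),
        language=str(rec.get("language", "English")),
        is_journal_article=_parse_bool(rec.get("is_journal_article", False), ctx),
        grades_evidence=_parse_bool(rec.get("grades_evidence", False), ctx),
        marks_recommendations=_parse_bool(rec.get("marks_recommendations", False), ctx),
        links_evidence=_parse_bool(rec.get("links_evidence", False), ctx),
        citations=citations,
    )


def _merge_guideline_citations(g: Guideline) -> None:
    """Merge duplicate (target, location) citation records by summing counts."""
    merged: dict[tuple[TargetKind, str, Location], int] = {}
    seen_dup = False
    for e in g.citations:
        key = (e.target_kind, e.target_id, e.location)
        if key in merged:
            seen_dup = True
        merged[key] = merged.get(key, 0) + e.count
    if seen_dup:
        logger.warning(
            "guideline %s: duplicate citations of the same target/location "
            "merged by summing counts",
            g.cpg_id,
        )
    g.citations = [
        CitationEdge(k[0], k[1], k[2], count=c)
        for k, c in sorted(merged.items(), key=lambda kv: (kv[0][0].value, kv[0][1], kv[0][2].value))
    ]


# ---------------------------------------------------------------------------
# build / validate
# ---------------------------------------------------------------------------


def build_network(
    trial_records: Any = None,
    article_records: Any = None,
    sr_records: Any = None,
    guideline_records: Any = None,
) -> CitationNetwork:
    """Build and structurally validate a :class:`CitationNetwork`.

    Accepts DataFrames, iterables of mapping records (with nested
    ``citations`` lists for SRs and guidelines) or iterables of the
    dataclass entities themselves.

    Raises
    ------
    SchemaError
        on duplicate ids, unknown enum labels or malformed values.
    IntegrityError
        on dangling edge endpoints, naming the offending edge.
    """
    trials: dict[str, Trial] = {}
    for rec in _records(trial_records):
        t = _trial_from_record(rec)
        if t.trial_id in trials:
            raise SchemaError(f"duplicate trial id {t.trial_id!r}")
        trials[t.trial_id] = t

    articles: dict[str, Article] = {}
    for rec in _records(article_records):
        a = _article_from_record(rec)
        if a.article_id in articles:
            raise SchemaError(f"duplicate article id {a.article_id!r}")
        if a.trial_id not in trials:
            raise IntegrityError(
                f"article {a.article_id!r} references unknown trial {a.trial_id!r}"
            )
        articles[a.article_id] = a

    srs: dict[str, SystematicReview] = {}
    for rec in _records(sr_records):
        sr = _sr_from_record(rec)
        if sr.sr_id in srs:
            raise SchemaError(f"duplicate sr id {sr.sr_id!r}")
        seen: set[str] = set()
        for c in sr.citations:
            if c.article_id in seen:
                raise SchemaError(
                    f"sr {sr.sr_id!r}: duplicate citation of article {c.article_id!r}"
                )
            seen.add(c.article_id)
            if c.article_id not in articles:
                raise IntegrityError(
                    f"sr {sr.sr_id!r} cites unknown article {c.article_id!r}"
                )
        sr.citations.sort(key=lambda c: c.article_id)
        srs[sr.sr_id] = sr

    guidelines: dict[str, Guideline] = {}
    for rec in _records(guideline_records):
        g = _guideline_from_record(rec)
        if g.cpg_id in guidelines:
            raise SchemaError(f"duplicate guideline id {g.cpg_id!r}")
        for e in g.citations:
            if e.count < 1:
                raise SchemaError(
                    f"guideline {g.cpg_id!r} edge to {e.target_id!r}: count must be >= 1"
                )
            target_pool = {
                TargetKind.ARTICLE: articles,
                TargetKind.SR: srs,
                TargetKind.REGISTRY_NUMBER: trials,
            }[e.target_kind]
            if e.target_id not in target_pool:
                raise IntegrityError(
                    f"guideline {g.cpg_id!r} cites unknown "
                    f"{e.target_kind.value} {e.target_id!r}"
                )
        _merge_guideline_citations(g)
        guidelines[g.cpg_id] = g

    return CitationNetwork(trials, articles, srs, guidelines)


def validate_network(network: CitationNetwork, strict: bool = False) -> list[Diagnostic]:
    """Return all invariant violations as diagnostics (no exceptions).

    ``strict`` additionally checks the trial start-date eligibility window
    (2005-01-01 to 2016-12-31).
    """
    out: list[Diagnostic] = []

    for t in network.trials.values():
        if t.study_size < 1:
            out.append(Diagnostic("invalid-study-size", t.trial_id,
                                  f"study_size {t.study_size} < 1"))
        if t.n_primary_outcomes < 1:
            out.append(Diagnostic("invalid-primary-outcomes", t.trial_id,
                                  f"n_primary_outcomes {t.n_primary_outcomes} < 1"))
        if t.start_date is None:
            out.append(Diagnostic("missing-start-date", t.trial_id,
                                  "trial has no start date"))
        elif strict and not (ELIGIBLE_START_MIN <= t.start_date <= ELIGIBLE_START_MAX):
            out.append(Diagnostic("start-date-window", t.trial_id,
                                  f"start date {t.start_date} outside eligibility window"))

    for a in network.articles.values():
        if a.trial_id not in network.trials:
            out.append(Diagnostic("dangling-reference", a.article_id,
                                  f"article references unknown trial {a.trial_id!r}"))
        if a.pub_date_electronic is None and a.pub_date_print is None:
            out.append(Diagnostic("missing-date", a.article_id,
                                  "article has neither electronic nor print date"))

    for sr in network.srs.values():
        for c in sr.citations:
            if c.article_id not in network.articles:
                out.append(Diagnostic("dangling-reference", sr.sr_id,
                                      f"sr cites unknown article {c.article_id!r}"))

    for g in network.guidelines.values():
        if g.pub_day is not None and g.pub_month is None:
            out.append(Diagnostic("partial-date-order", g.cpg_id,
                                  "pub_day present without pub_month"))
        elif g.pub_month is not None:
            if not 1 <= g.pub_month <= 12:
                out.append(Diagnostic("invalid-date", g.cpg_id,
                                      f"pub_month {g.pub_month} out of range"))
            elif g.pub_day is not None:
                ndays = calendar.monthrange(g.pub_year, g.pub_month)[1]
                if not 1 <= g.pub_day <= ndays:
                    out.append(Diagnostic("invalid-date", g.cpg_id,
                                          f"pub_day {g.pub_day} invalid for "
                                          f"{g.pub_year}-{g.pub_month:02d}"))
        for e in g.citations:
            if e.count < 1:
                out.append(Diagnostic("invalid-count", g.cpg_id,
                                      f"edge to {e.target_id!r} has count {e.count}"))
            pool = {
                TargetKind.ARTICLE: network.articles,
                TargetKind.SR: network.srs,
                TargetKind.REGISTRY_NUMBER: network.trials,
            }[e.target_kind]
            if e.target_id not in pool:
                out.append(Diagnostic("dangling-reference", g.cpg_id,
                                      f"guideline cites unknown "
                                      f"{e.target_kind.value} {e.target_id!r}"))
    return out


def subset_guidelines(network: CitationNetwork, keep_ids: Iterable[str]) -> CitationNetwork:
    """New network containing only the guidelines in ``keep_ids``
    (trial/article/SR layers untouched)."""
    keep = set(keep_ids)
    return build_network(
        list(network.trials.values()),
        list(network.articles.values()),
        list(network.srs.values()),
        [g for g in network.guidelines.values() if g.cpg_id in keep],
    )


# ---------------------------------------------------------------------------
# serialization: directory of flat CSV tables + JSON schema sidecar
# ---------------------------------------------------------------------------

_TRIAL_COLS = ["trial_id", "cohort", "start_date", "study_size", "n_primary_outcomes",
               "is_drug_trial", "study_phase", "medical_domain", "registry_result_only"]
_ARTICLE_COLS = ["article_id", "trial_id", "pub_date_electronic", "pub_date_print",
                 "is_method_article"]
_SR_COLS = ["sr_id", "pub_date"]
_GUIDELINE_COLS = ["cpg_id", "pub_year", "pub_month", "pub_day", "language",
                   "is_journal_article", "grades_evidence", "marks_recommendations",
                   "links_evidence"]
_EDGE_COLS = ["source_kind", "source_id", "target_kind", "target_id", "status",
              "location", "count"]


def _iso(d: date | None) -> str:
    return d.isoformat() if d else ""


def write_network(network: CitationNetwork, path: str | FsPath) -> None:
    """Write the network as five CSV tables plus ``schema.json``.

    Tables: trials, articles, srs, guidelines and a single typed edge table
    holding both SR→article citations (with status) and guideline→reference
    citations (with location and mention count).
    """
    path = FsPath(path)
    path.mkdir(parents=True, exist_ok=True)

    pd.DataFrame(
        [
            {
                "trial_id": t.trial_id, "cohort": t.cohort.value,
                "start_date": _iso(t.start_date), "study_size": t.study_size,
                "n_primary_outcomes": t.n_primary_outcomes,
                "is_drug_trial": t.is_drug_trial,
                "study_phase": t.study_phase or "",
                "medical_domain": t.medical_domain or "",
                "registry_result_only": t.registry_result_only,
            }
            for t in sorted(network.trials.values(), key=lambda t: t.trial_id)
        ],
        columns=_TRIAL_COLS,
    ).to_csv(path / "trials.csv", index=False)

    pd.DataFrame(
        [
            {
                "article_id": a.article_id, "trial_id": a.trial_id,
                "pub_date_electronic": _iso(a.pub_date_electronic),
                "pub_date_print": _iso(a.pub_date_print),
                "is_method_article": a.is_method_article,
            }
            for a in sorted(network.articles.values(), key=lambda a: a.article_id)
        ],
        columns=_ARTICLE_COLS,
    ).to_csv(path / "articles.csv", index=False)

    pd.DataFrame(
        [
            {"sr_id": sr.sr_id, "pub_date": _iso(sr.pub_date)}
            for sr in sorted(network.srs.values(), key=lambda s: s.sr_id)
        ],
        columns=_SR_COLS,
    ).to_csv(path / "srs.csv", index=False)

    pd.DataFrame(
        [
            {
                "cpg_id": g.cpg_id, "pub_year": g.pub_year,
                "pub_month": "" if g.pub_month is None else g.pub_month,
                "pub_day": "" if g.pub_day is None else g.pub_day,
                "language": g.language,
                "is_journal_article": g.is_journal_article,
                "grades_evidence": g.grades_evidence,
                "marks_recommendations": g.marks_recommendations,
                "links_evidence": g.links_evidence,
            }
            for g in sorted(network.guidelines.values(), key=lambda g: g.cpg_id)
        ],
        columns=_GUIDELINE_COLS,
    ).to_csv(path / "guidelines.csv", index=False)

    edge_rows: list[dict[str, Any]] = []
    for sr in sorted(network.srs.values(), key=lambda s: s.sr_id):
        for c in sr.citations:
            edge_rows.append({
                "source_kind": "sr", "source_id": sr.sr_id,
                "target_kind": TargetKind.ARTICLE.value, "target_id": c.article_id,
                "status": c.status.value, "location": "", "count": 1,
            })
    for g in sorted(network.guidelines.values(), key=lambda g: g.cpg_id):
        for e in g.citations:
            edge_rows.append({
                "source_kind": "guideline", "source_id": g.cpg_id,
                "target_kind": e.target_kind.value, "target_id": e.target_id,
                "status": "", "location": e.location.value, "count": e.count,
            })
    pd.DataFrame(edge_rows, columns=_EDGE_COLS).to_csv(path / "edges.csv", index=False)

    (path / "schema.json").write_text(json.dumps({
        "format": "guideline-impact-network",
        "version": SCHEMA_VERSION,
        "tables": ["trials.csv", "articles.csv", "srs.csv", "guidelines.csv",
                   "edges.csv"],
        "dates": "ISO-8601; guideline dates stored as year/month/day columns "
                 "with month and day optional",
    }, indent=2) + "\n")


def read_network(path: str | FsPath) -> CitationNetwork:
    """Read a network written by :func:`write_network`.

    Raises :class:`SchemaError` with row context on malformed files.
    """
    path = FsPath(path)

    def _read(name: str) -> list[dict[str, Any]]:
        f = path / name
        if not f.exists():
            raise SchemaError(f"missing table {name} in {path}")
        df = pd.read_csv(f, dtype=str, keep_default_na=False)
        return df.to_dict("records")

    trial_recs = _read("trials.csv")
    article_recs = _read("articles.csv")
    sr_recs = {r["sr_id"]: {**r, "citations": []} for r in _read("srs.csv")}
    cpg_recs = {r["cpg_id"]: {**r, "citations": []} for r in _read("guidelines.csv")}

    for i, row in enumerate(_read("edges.csv")):
        ctx = f"edges.csv row {i + 2}"
        kind = row.get("source_kind", "")
        if kind == "sr":
            src = sr_recs.get(row["source_id"])
            if src is None:
                raise SchemaError(f"{ctx}: unknown sr {row['source_id']!r}")
            src["citations"].append(
                {"article_id": row["target_id"], "status": row["status"]}
            )
        elif kind == "guideline":
            src = cpg_recs.get(row["source_id"])
            if src is None:
                raise SchemaError(f"{ctx}: unknown guideline {row['source_id']!r}")
            src["citations"].append({
                "target_kind": row["target_kind"], "target_id": row["target_id"],
                "location": row["location"], "count": int(row["count"]),
            })
        else:
            raise SchemaError(f"{ctx}: unknown source_kind {kind!r}")

    return build_network(
        trial_recs, article_recs, list(sr_recs.values()), list(cpg_recs.values())
    )
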