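import pytest

from guideline_impact import (
    Article,
    CitationEdge,
    Cohort,
    Guideline,
    Location,
    SRCitation,
    SRStatus,
    SystematicReview,
    TargetKind,
    Trial,
    build_network,
    exemplar_fixture,
    reference_fixture,
)
from datetime import date


@pytest.fixture(scope="session")
def reference_net():
    return reference_fixture()


@pytest.fixture(scope="session")
def exemplar_net():
    return exemplar_fixture()


def make_trial(tid="T1", cohort=Cohort.GERMAN_IIT, start=date(2010, 1, 1),
               size=100, n_primary=1, drug=False):
    return Trial(trial_id=tid, cohort=cohort, start_date=start, study_size=size,
                 n_primary_outcomes=n_primary, is_drug_trial=drug)


def make_article(aid="A1", tid="T1", pub=date(2012, 1, 1)):
    return Article(article_id=aid, trial_id=tid, pub_date_electronic=pub)


def make_sr(sid="S1", cites=(("A1", SRStatus.INCLUDED),), pub=date(2013, 1, 1)):
    return SystematicReview(
        sr_id=sid, pub_date=pub,
        citations=[SRCitation(a, s) for a, s in cites])


def make_guideline(gid="G1", edges=(), year=2016, month=6, day=15, language="English"):
    return Guideline(
        cpg_id=gid, pub_year=year, pub_month=month, pub_day=day,
        language=language,
        citations=[CitationEdge(kind, target, loc, count) for kind, target, loc, count in edges])


def edge(kind, target, loc=Location.MAIN_TEXT, count=1):
    return (kind, target, loc, count)


@pytest.fixture
def single_path_net():
    """One trial, one article, one guideline citing the article in main text."""
    return build_network(
        [make_trial()], [make_article()], [],
        [make_guideline(edges=[edge(TargetKind.ARTICLE, "A1")])])
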