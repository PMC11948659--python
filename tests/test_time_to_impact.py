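"""Date resolution/imputation and the censored survival dataset."""

import calendar
import logging
from datetime import date, timedelta

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from guideline_impact import (
    Guideline,
    TargetKind,
    build_network,
    build_survival_dataset,
    flow_summary,
    resolve_publication_date,
    time_to_guideline_impact,
)
from guideline_impact.time_to_impact import (
    DEFAULT_CENSOR_DATE,
    UnresolvableDateError,
)
from conftest import edge, make_article, make_guideline, make_trial


def guideline_with(year, month, day):
    return Guideline(cpg_id="G1", pub_year=year, pub_month=month, pub_day=day)


class TestDateResolution:
    def test_complete_date_untouched(self):
        r = resolve_publication_date(guideline_with(2015, 3, 17), seed=0)
        assert r.date == date(2015, 3, 17)
        assert not r.imputed_month and not r.imputed_day

    def test_missing_year_unresolvable(self):
        g = Guideline(cpg_id="G1", pub_year=None)
        with pytest.raises(UnresolvableDateError):
            resolve_publication_date(g, seed=0)

    def test_january_day_uniform_over_seeds(self):
        """Imputed January days are uniform on 1..31 (chi-square GOF)."""
        days = [resolve_publication_date(guideline_with(2015, 1, None), seed=s).date.day
                for s in range(10_000)]
        counts = np.bincount(days, minlength=32)[1:]
        assert counts.sum() == 10_000 and set(np.nonzero(counts)[0] + 1) <= set(range(1, 32))
        p = stats.chisquare(counts).pvalue
        assert p > 0.001

    @pytest.mark.parametrize("year,ndays", [(2016, 29), (2015, 28)])
    def test_february_respects_leap_years(self, year, ndays):
        days = {resolve_publication_date(guideline_with(year, 2, None), seed=s).date.day
                for s in range(300)}
        assert max(days) <= ndays and min(days) >= 1
        assert len(days) > 20  # draws actually spread over the month

    @given(year=st.integers(2000, 2020), month=st.one_of(st.none(), st.integers(1, 12)),
           seed=st.integers(0, 2**20))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_resolved_date_always_valid(self, year, month, seed):
        g = guideline_with(year, month, None)
        r = resolve_publication_date(g, seed=seed)
        assert r.date.year == year
        if month is not None:
            assert r.date.month == month
            assert not r.imputed_month
        assert r.imputed_day
        assert r.date.day <= calendar.monthrange(year, r.date.month)[1]

    def test_reproducible_and_order_independent(self):
        a = resolve_publication_date(guideline_with(2014, None, None), seed=9)
        b = resolve_publication_date(guideline_with(2014, None, None), seed=9)
        assert a == b


def two_cpg_network(d1=date(2014, 5, 1), d2=date(2016, 1, 1), start=date(2010, 1, 1)):
    g1 = Guideline(cpg_id="G1", pub_year=d1.year, pub_month=d1.month, pub_day=d1.day,
                   citations=[])
    g2 = Guideline(cpg_id="G2", pub_year=d2.year, pub_month=d2.month, pub_day=d2.day,
                   citations=[])
    from guideline_impact import CitationEdge, Location
    for g in (g1, g2):
        g.citations.append(CitationEdge(TargetKind.ARTICLE, "A1", Location.MAIN_TEXT, 1))
    return build_network([make_trial(start=start)], [make_article()], [], [g1, g2])


class TestTimeToImpact:
    def test_earliest_impacted_guideline_defines_event_time(self):
        net = two_cpg_network()
        rec = time_to_guideline_impact(net, "T1")
        assert rec.event == 1
        assert rec.time_days == 1581  # 2010-01-01 -> 2014-05-01
        assert rec.time_days == (date(2014, 5, 1) - date(2010, 1, 1)).days

    def test_no_impact_censored_at_lookup_date(self):
        net = build_network([make_trial(start=date(2010, 1, 1))])
        rec = time_to_guideline_impact(net, "T1")
        assert rec.event == 0
        assert rec.time_days == rec.observed_time_days
        assert rec.time_days == (DEFAULT_CENSOR_DATE - date(2010, 1, 1)).days

    def test_guideline_on_censor_date_is_event(self):
        net = two_cpg_network(d1=DEFAULT_CENSOR_DATE, d2=DEFAULT_CENSOR_DATE)
        rec = time_to_guideline_impact(net, "T1")
        assert rec.event == 1
        assert rec.time_days == rec.observed_time_days

    def test_guideline_after_censor_date_is_censored(self):
        net = two_cpg_network(d1=date(2019, 12, 1), d2=date(2019, 12, 2))
        rec = time_to_guideline_impact(net, "T1")
        assert rec.event == 0 and rec.time_days == rec.observed_time_days

    def test_guideline_before_start_flagged_but_kept(self, caplog):
        net = two_cpg_network(d1=date(2009, 1, 1), start=date(2010, 1, 1))
        with caplog.at_level(logging.WARNING):
            rec = time_to_guideline_impact(net, "T1")
        assert rec.event == 1 and rec.negative_time
        assert rec.time_days <= 0
        assert "flagged" in caplog.text


class TestSurvivalDataset:
    def test_reference_fixture_event_count(self, reference_net):
        recs = build_survival_dataset(reference_net, seed=0)
        assert len(recs) == 691
        assert sum(r.event for r in recs) == 153
        assert sum(r.event for r in recs) == flow_summary(reference_net).n_trials_impactful

    def test_censoring_consistency(self, reference_net):
        for r in build_survival_dataset(reference_net, seed=0):
            if r.event == 0:
                assert r.time_days == r.observed_time_days
            else:
                assert r.time_days <= r.observed_time_days

    def test_empty_network_empty_dataset(self):
        assert build_survival_dataset(build_network()) == []

    def test_same_seed_identical(self):
        from guideline_impact import generate_network
        net = generate_network(seed=2)  # has imputed dates
        a = build_survival_dataset(net, seed=5)
        b = build_survival_dataset(net, seed=5)
        assert a == b

    def test_covariate_dichotomization(self):
        net = build_network([make_trial(size=151, n_primary=1),
                             make_trial(tid="T2", size=150, n_primary=3)])
        recs = build_survival_dataset(net)
        by_id = {r.trial_id: r for r in recs}
        assert by_id["T1"].size_above_150 and by_id["T1"].single_primary_outcome
        assert not by_id["T2"].size_above_150 and not by_id["T2"].single_primary_outcome

    def test_missing_start_date_excluded_with_warning(self, caplog):
        t = make_trial(tid="T2")
        t.start_date = None
        net = build_network([make_trial(), t])
        with caplog.at_level(logging.WARNING):
            recs = build_survival_dataset(net)
        assert [r.trial_id for r in recs] == ["T1"]
        assert "no start date" in caplog.text
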