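"""Path classification rules, impact statistics and flow aggregation."""

import itertools
import logging

import numpy as np
import pytest

from guideline_impact import (
    CitationEdge,
    Cohort,
    ImpactConfig,
    Location,
    SRStatus,
    TargetKind,
    UnknownEntityError,
    build_network,
    classify_path,
    cohort_breakdown,
    enumerate_paths,
    flow_summary,
    trial_impact,
)
from guideline_impact.impact_scoring import ClassificationError, _TRIAL_LEVEL_FIELDS
from conftest import edge, make_article, make_guideline, make_sr, make_trial
from oracles import brute_force_chains, brute_force_impact, random_small_network


def chain_net(*, art_loc=None, sr_status=None, sr_loc=None, registry_loc=None):
    """Minimal network realizing one chain pattern.

    ``art_loc``/``sr_loc``/``registry_loc``: where the guideline cites the
    article / SR / registry number (None = not cited).
    """
    srs = [make_sr(cites=[("A1", sr_status)])] if sr_status else []
    edges = []
    if art_loc:
        edges.append(edge(TargetKind.ARTICLE, "A1", art_loc))
    if sr_loc:
        edges.append(edge(TargetKind.SR, "S1", sr_loc))
    if registry_loc:
        edges.append(edge(TargetKind.REGISTRY_NUMBER, "T1", registry_loc))
    return build_network([make_trial()], [make_article()], srs,
                         [make_guideline(edges=edges)])


MAIN, SUPP = Location.MAIN_TEXT, Location.SUPPLEMENT


class TestClassification:
    @pytest.mark.parametrize(
        "kwargs,chain,case,impactful",
        [
            # direct article citation: excluded (supplement-only) vs included
            (dict(art_loc=SUPP), ("T1", "A1", None, "G1"), 1, False),
            (dict(art_loc=MAIN), ("T1", "A1", None, "G1"), 2, True),
            # SR-mediated: article excluded in SR
            (dict(sr_status=SRStatus.EXCLUDED, sr_loc=SUPP),
             ("T1", "A1", "S1", "G1"), 3, False),
            (dict(sr_status=SRStatus.EXCLUDED, sr_loc=MAIN),
             ("T1", "A1", "S1", "G1"), 4, False),
            # SR-mediated: article included in SR
            (dict(sr_status=SRStatus.INCLUDED, sr_loc=MAIN),
             ("T1", "A1", "S1", "G1"), 5, True),
            (dict(sr_status=SRStatus.INCLUDED, sr_loc=SUPP),
             ("T1", "A1", "S1", "G1"), 6, False),
            # direct registry citation
            (dict(registry_loc=SUPP), ("T1", None, None, "G1"), 7, False),
            (dict(registry_loc=MAIN), ("T1", None, None, "G1"), 8, True),
        ],
    )
    def test_case_table(self, kwargs, chain, case, impactful):
        net = chain_net(**kwargs)
        p = classify_path(chain, net)
        assert (p.case_number, p.impactful) == (case, impactful)

    def test_direct_included_configurable(self):
        net = chain_net(registry_loc=MAIN)
        p = classify_path(("T1", None, None, "G1"), net,
                          ImpactConfig(direct_citation_impactful=False))
        assert p.case_number == 8 and not p.impactful

    def test_other_status_counts_as_excluded(self):
        net = chain_net(sr_status=SRStatus.OTHER, sr_loc=MAIN)
        p = classify_path(("T1", "A1", "S1", "G1"), net)
        assert p.case_number == 4 and not p.impactful
        assert p.article_in_sr is SRStatus.EXCLUDED

    def test_main_and_supplement_citation_is_included(self):
        # a reference cited in both locations counts as included
        net = build_network(
            [make_trial()], [make_article()], [],
            [make_guideline(edges=[edge(TargetKind.ARTICLE, "A1", MAIN),
                                   edge(TargetKind.ARTICLE, "A1", SUPP)])])
        p = classify_path(("T1", "A1", None, "G1"), net)
        assert p.impactful

    def test_exhaustive_patterns_only_rows_2_and_5_impactful(self):
        """Over every enumerable 2- and 3-step status pattern, exactly the
        article-included and SR-included-both-steps rows are impactful."""
        impactful_patterns = []
        # 2-step: article cited at a location set
        for loc in (MAIN, SUPP):
            p = classify_path(("T1", "A1", None, "G1"), chain_net(art_loc=loc))
            if p.impactful:
                impactful_patterns.append(("article", loc))
        # 3-step: SR status x location
        for status, loc in itertools.product(SRStatus, (MAIN, SUPP)):
            net = chain_net(sr_status=status, sr_loc=loc)
            p = classify_path(("T1", "A1", "S1", "G1"), net)
            if p.impactful:
                impactful_patterns.append(("sr", status, loc))
        assert impactful_patterns == [
            ("article", MAIN), ("sr", SRStatus.INCLUDED, MAIN)]

    def test_inconsistent_chain_raises(self, single_path_net):
        with pytest.raises(ClassificationError):
            classify_path(("T1", "A1", "S9", "G1"), single_path_net)


class TestEnumeration:
    def test_isolated_trial_has_no_paths(self):
        net = build_network([make_trial()])
        assert enumerate_paths(net, "T1") == []

    def test_unknown_trial_raises(self, single_path_net):
        with pytest.raises(UnknownEntityError):
            enumerate_paths(single_path_net, "T9")

    def test_article_and_sr_routes_coexist(self):
        # guideline cites both the article and the SR including it: two paths
        net = build_network(
            [make_trial()], [make_article()],
            [make_sr(cites=[("A1", SRStatus.INCLUDED)])],
            [make_guideline(edges=[edge(TargetKind.ARTICLE, "A1", MAIN),
                                   edge(TargetKind.SR, "S1", MAIN)])])
        paths = enumerate_paths(net, "T1")
        assert [(p.article_id, p.sr_id, p.case_number) for p in paths] == [
            ("A1", None, 2), ("A1", "S1", 5)]
        ti = trial_impact(net, "T1")
        assert ti.impacted_cpgs == 1  # one guideline, counted once
        assert ti.impact_on_cpgs == 2  # but both terminal references count

    def test_matches_brute_force_join(self):
        rng = np.random.default_rng(42)
        for _ in range(100):
            net = random_small_network(rng)
            for tid in net.trials:
                paths = enumerate_paths(net, tid)
                assert {(p.article_id, p.sr_id, p.cpg_id) for p in paths} == \
                    brute_force_chains(net, tid)
                ti = trial_impact(net, tid)
                assert (ti.impact_on_cpgs, ti.impacted_cpgs, ti.associated_cpgs) == \
                    brute_force_impact(net, tid)


class TestTrialImpact:
    def test_no_path_trial_is_all_zero(self):
        net = build_network([make_trial()])
        ti = trial_impact(net, "T1")
        assert (ti.impact_on_cpgs, ti.impacted_cpgs, ti.guideline_impact,
                ti.associated_cpgs) == (0, 0, 0, 0)

    def test_exemplar_trial(self, exemplar_net):
        ti = trial_impact(exemplar_net, "TX001")
        assert ti.associated_cpgs == 16
        assert ti.impacted_cpgs == 15
        assert ti.guideline_impact == 1

    def test_supplement_citation_does_not_change_impact(self, single_path_net):
        base = trial_impact(single_path_net, "T1")
        net2 = build_network(
            [make_trial()], [make_article()], [],
            [make_guideline(edges=[edge(TargetKind.ARTICLE, "A1", MAIN),
                                   edge(TargetKind.ARTICLE, "A1", SUPP, 5)])])
        assert trial_impact(net2, "T1").impact_on_cpgs == base.impact_on_cpgs

    def test_adding_main_text_citation_is_monotone(self):
        """Adding a main-text edge never decreases impact; adding a
        supplement edge never changes it."""
        rng = np.random.default_rng(7)
        for _ in range(30):
            net = random_small_network(rng)
            if not net.guidelines or not net.articles:
                continue
            before = {t: trial_impact(net, t).impact_on_cpgs for t in net.trials}
            gid = sorted(net.guidelines)[int(rng.integers(0, len(net.guidelines)))]
            aid = sorted(net.articles)[int(rng.integers(0, len(net.articles)))]
            for loc in (MAIN, SUPP):
                guidelines = [g for g in net.guidelines.values()]
                import copy
                guidelines = copy.deepcopy(guidelines)
                next(g for g in guidelines if g.cpg_id == gid).citations.append(
                    CitationEdge(TargetKind.ARTICLE, aid, loc, 1))
                net2 = build_network(list(net.trials.values()),
                                     list(net.articles.values()),
                                     list(net.srs.values()), guidelines)
                after = {t: trial_impact(net2, t).impact_on_cpgs for t in net.trials}
                if loc is MAIN:
                    assert all(after[t] >= before[t] for t in before)
                else:
                    assert after == before


class TestFlowSummary:
    def test_empty_network_all_zero(self):
        fs = flow_summary(build_network())
        assert all(getattr(fs, f) == 0 for f in fs.to_dict() if f.startswith("n_"))

    def test_single_case2_path(self, single_path_net):
        fs = flow_summary(single_path_net)
        assert fs.n_trials_impactful == 1
        assert fs.n_cpgs_impacted == 1
        assert fs.n_trials_direct_impactful == 1
        assert fs.n_trials_via_sr_impactful == 0
        assert fs.n_citations_main == 1 and fs.n_citations_supp == 0

    def test_citation_split_consistency(self, reference_net):
        fs = flow_summary(reference_net)
        assert fs.n_citations_total == fs.n_citations_main + fs.n_citations_supp
        assert fs.n_trials_no_impact == fs.n_trials - fs.n_trials_impactful
        assert fs.n_trials_impactful <= fs.n_trials_associated_cpg
        assert fs.n_cpgs_impacted <= fs.n_cpgs_associated

    def test_per_cohort_vectors_conserve_totals(self, reference_net):
        fs = flow_summary(reference_net)
        for f in _TRIAL_LEVEL_FIELDS:
            assert sum(fs.per_cohort[f]) == getattr(fs, f), f

    def test_per_cohort_conservation_on_generated_network(self):
        from guideline_impact import generate_network
        fs = flow_summary(generate_network(seed=5))
        for f, vec in fs.per_cohort.items():
            assert sum(vec) == getattr(fs, f), f


class TestCohortBreakdown:
    def test_reference_impactful_counts(self, reference_net):
        stat = cohort_breakdown(reference_net, "n_trials_impactful")
        assert stat.by_cohort == (31, 51, 41, 30)
        assert stat.overall == 153

    def test_reference_no_impact_counts(self, reference_net):
        stat = cohort_breakdown(reference_net, "n_trials_no_impact")
        assert stat.by_cohort == (89, 149, 130, 170)
        assert stat.overall == 538

    def test_overall_is_pooled_not_mean_of_cohorts(self, reference_net):
        stat = cohort_breakdown(reference_net, "impact_proportion")
        assert stat.overall == pytest.approx(153 / 691)
        # cohort sizes differ, so the pooled value is not the cohort mean
        assert stat.overall != pytest.approx(sum(stat.by_cohort) / 4)

    def test_empty_cohort_reports_zero_with_warning(self, caplog):
        net = build_network([make_trial()])  # only German IITs present
        with caplog.at_level(logging.WARNING):
            stat = cohort_breakdown(net, "mean_impacted_cpgs")
        assert stat.by_cohort[1:] == (0.0, 0.0, 0.0)
        assert "empty cohort" in caplog.text

    def test_unknown_statistic_raises(self, reference_net):
        with pytest.raises(ValueError, match="unknown statistic"):
            cohort_breakdown(reference_net, "n_bogus")
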