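"""Independent brute-force oracles used to cross-check the scoring pipeline.

Deliberately naive: exhaustive nested joins over the raw entity records,
sharing no index structures or classification code with the package.
"""

from __future__ import annotations

from datetime import date, timedelta

import numpy as np

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
)


def _main_count(guideline: Guideline, kind: TargetKind, target: str) -> int:
    return sum(e.count for e in guideline.citations
               if e.target_kind == kind and e.target_id == target
               and e.location == Location.MAIN_TEXT)


def brute_force_chains(network, trial_id):
    """All (article, sr, cpg) chains by exhaustive triple join."""
    arts = {a.article_id for a in network.articles.values() if a.trial_id == trial_id}
    chains = set()
    for g in network.guidelines.values():
        for e in g.citations:
            if e.target_kind == TargetKind.ARTICLE and e.target_id in arts:
                chains.add((e.target_id, None, g.cpg_id))
            elif e.target_kind == TargetKind.SR:
                sr = network.srs[e.target_id]
                for c in sr.citations:
                    if c.article_id in arts:
                        chains.add((c.article_id, sr.sr_id, g.cpg_id))
            elif (e.target_kind == TargetKind.REGISTRY_NUMBER
                  and e.target_id == trial_id):
                chains.add((None, None, g.cpg_id))
    return chains


def brute_force_impact(network, trial_id, direct_impactful=True):
    """(impact_on_cpgs, impacted_cpgs, associated_cpgs) recomputed naively."""
    chains = brute_force_chains(network, trial_id)
    impacted = set()
    associated = set()
    terminal_refs = set()
    for art, sr_id, cpg_id in chains:
        g = network.guidelines[cpg_id]
        associated.add(cpg_id)
        if sr_id is not None:
            status = next(c.status for c in network.srs[sr_id].citations
                          if c.article_id == art)
            ok = (status == SRStatus.INCLUDED
                  and _main_count(g, TargetKind.SR, sr_id) > 0)
            ref = (TargetKind.SR, sr_id)
        elif art is not None:
            ok = _main_count(g, TargetKind.ARTICLE, art) > 0
            ref = (TargetKind.ARTICLE, art)
        else:
            ok = (direct_impactful
                  and _main_count(g, TargetKind.REGISTRY_NUMBER, trial_id) > 0)
            ref = (TargetKind.REGISTRY_NUMBER, trial_id)
        if ok:
            impacted.add(cpg_id)
            terminal_refs.add((cpg_id, ref))
    impact_on = sum(_main_count(network.guidelines[c], k, t)
                    for c, (k, t) in terminal_refs)
    return impact_on, len(impacted), len(associated)


def random_small_network(rng: np.random.Generator, max_per_layer: int = 10):
    """A random layered network with <= max_per_layer entities per layer,
    exercising every edge type and status/location combination."""
    n_t = int(rng.integers(1, max_per_layer + 1))
    n_a = int(rng.integers(0, max_per_layer + 1))
    n_s = int(rng.integers(0, max_per_layer + 1))
    n_g = int(rng.integers(0, max_per_layer + 1))
    cohorts = list(Cohort)

    trials = [Trial(trial_id=f"T{i}", cohort=cohorts[int(rng.integers(0, 4))],
                    start_date=date(2005, 1, 1) + timedelta(days=int(rng.integers(0, 4000))),
                    study_size=int(rng.integers(10, 500)),
                    n_primary_outcomes=int(rng.integers(1, 4)),
                    is_drug_trial=bool(rng.integers(0, 2)))
              for i in range(n_t)]
    articles = [Article(article_id=f"A{i}", trial_id=f"T{int(rng.integers(0, n_t))}",
                        pub_date_electronic=date(2012, 1, 1))
                for i in range(n_a)]
    statuses = list(SRStatus)
    srs = []
    for i in range(n_s):
        cited = (rng.choice(n_a, size=int(rng.integers(0, n_a + 1)), replace=False)
                 if n_a else [])
        srs.append(SystematicReview(
            sr_id=f"S{i}", pub_date=date(2014, 1, 1),
            citations=[SRCitation(f"A{int(j)}", statuses[int(rng.integers(0, 3))])
                       for j in cited]))
    guidelines = []
    for i in range(n_g):
        edges = []
        for _ in range(int(rng.integers(0, 5))):
            kind = [TargetKind.ARTICLE, TargetKind.SR, TargetKind.REGISTRY_NUMBER][
                int(rng.integers(0, 3))]
            pool = {TargetKind.ARTICLE: n_a, TargetKind.SR: n_s,
                    TargetKind.REGISTRY_NUMBER: n_t}[kind]
            if pool == 0:
                continue
            prefix = {TargetKind.ARTICLE: "A", TargetKind.SR: "S",
                      TargetKind.REGISTRY_NUMBER: "T"}[kind]
            loc = Location.MAIN_TEXT if rng.random() < 0.6 else Location.SUPPLEMENT
            edges.append(CitationEdge(kind, f"{prefix}{int(rng.integers(0, pool))}",
                                      loc, count=int(rng.integers(1, 4))))
        guidelines.append(Guideline(
            cpg_id=f"G{i}", pub_year=2017, pub_month=int(rng.integers(1, 13)),
            pub_day=None, citations=edges))
    return build_network(trials, articles, srs, guidelines)
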