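# Methods

## Data model

The citation network has four layers — registered trials, journal articles,
systematic reviews (SRs), clinical practice guidelines (CPGs) — and three
kinds of typed edges, always pointing from a higher layer to a lower one:
guideline → {article, SR, registry number}, SR → article, article → trial
(ownership).  Guideline citations are stored per (target, location) with a
mention count, because impact is defined as a *sum of citation mentions*
and multiplicity must survive ingestion; duplicate records of the same
target/location are merged by summing counts with a logged warning.  SR
citations carry the inclusion status assigned during data extraction:
`INCLUDED`, `EXCLUDED`, or `OTHER` for mentions in an SR's introduction or
summary.  Registry-number citations are first-class edges even though the
motivating dataset contained no included ones, so the classifier handles
the direct-citation case.

On disk a network is a directory of five CSV tables (trials, articles,
srs, guidelines, edges) with a JSON schema sidecar.  Dates are ISO-8601;
guideline dates are stored as year/month/day columns with month and day
optional (partial dates are common for guidelines published as web
documents).  Round-trips are lossless at field level.

## Path classification

A path is every unique chain from a trial to a guideline realized by the
edges.  Inclusion in a guideline means at least one **main-text** citation
of the path's terminal reference; supplement/appendix citations are
ignored.  For SR-mediated paths the article must additionally be
`INCLUDED` in the SR; `OTHER` is collapsed to excluded, on the argument
that findings can only be reflected in a guideline's statements if the
article entered the review's synthesis.  The resulting case table (internal
numbering follows the canonical figure of the motivating study):

| case | chain | SR step | CPG step | impactful |
|---|---|---|---|---|
| 1 | article | — | excluded | no |
| 2 | article | — | included | **yes** |
| 3 | SR-mediated | excluded | excluded | no |
| 4 | SR-mediated | excluded | included | no |
| 5 | SR-mediated | included | included | **yes** |
| 6 | SR-mediated | included | excluded | no |
| 7 | registry number | — | excluded | no |
| 8 | registry number | — | included | configurable |

Case 8 never occurred in the motivating dataset.  It defaults to impactful
— the general rule is "included at every step" and direct registry paths
were deliberately not excluded from the impact definition — with
`ImpactConfig(direct_citation_impactful=False)` to force the conservative
reading.

Per-trial statistics: `impact_on_cpgs` sums the main-text mention counts of
the terminal references of impactful paths, where a terminal reference
shared by several impactful paths to the same guideline (e.g. one SR
including two of the trial's articles) counts once; `impacted_cpgs` counts
distinct guidelines with ≥ 1 impactful path; `associated_cpgs` counts
distinct guidelines with any path.  The flow summary aggregates these at
network level.  Trial-level fields partition exactly by cohort; the
per-cohort vectors of guideline-level and citation-count fields attribute
an entity to every cohort it touches, which coincides with an exact
partition whenever no SR or guideline bridges trials of different cohorts
(true in both fixtures and in generated networks, which build per-trial
SRs and guidelines).

## Dates and the survival layer

A guideline's publication date is the earliest date its text was publicly
visible; for journal-published guidelines the earlier of electronic and
print dates is taken at ingestion (the `Article`/`Guideline` records store
what the extraction produced).  Missing month or day components are imputed
by a uniform draw over the valid values, respecting month lengths and leap
years.  Draws derive from a single global seed combined with a CRC-32 hash
of the guideline id, so imputation is reproducible and independent of
iteration order; the chi-square goodness-of-fit of imputed January days
against the uniform distribution over 1–31 is part of the test suite.  The
imputation is a single seeded draw per analysis; multi-draw sensitivity can
be run by varying the seed.

Time-to-guideline-impact runs from trial start to the earliest resolved
publication date among the trial's *impacted* guidelines; trials without
impact are right-censored at the guideline-search cutoff (2019-08-31
by default).  Durations are integers in days internally and converted to
years (365.25 d) for modelling and reporting, avoiding month-length
ambiguity.  A guideline dated on or before its trial's start yields a
non-positive duration: the record is kept, flagged (`negative_time`), and
excluded from KM/Cox fits with a warning — dropping it silently would
corrupt the event count, and the flag supports sensitivity exclusion.
Time from trial *completion* is deliberately unsupported: registry
completion dates have no common definition across registries.

## Statistical layer

Count outcomes (impact-on-CPGs, impacted-CPGs, associated-CPGs) are fitted
by NB2 negative binomial regression — variance μ + αμ², dispersion α
estimated by maximum likelihood — with log observed time (start →
censoring date) as offset, so covariate effects are incidence rate ratios
per unit of observed time.  NB2 is used because the motivating data are
overdispersed; zero inflation is not modelled (the data-generating process
gives no reason for a separate zero component, and NB models handle
zero-heavy counts well).  Optimization is BFGS with a tighter-tolerance
polish pass; at the Poisson boundary (α → 0) the dispersion gradient
cannot vanish, the polish is skipped and the fit may carry
`converged=False` while the IRRs agree with the Poisson fit (a unit test
holds this to 1%).  CIs are two-sided Wald intervals at α = 0.05, matching
the reporting convention of the tables being emulated; profile-likelihood
intervals were not used and the choice is recorded in run manifests.

The survival layer uses Kaplan–Meier per cohort (reported as cumulative
event probability, 1 − S), the multivariate log-rank test across the four
cohorts, and Cox proportional-hazards regression with the same covariates
and reference coding.  Ties use the Efron method — date resolution in days
makes ties rare and Efron is the least-biased common default.
Proportionality is screened by scaled Schoenfeld residual trend tests
(rank time transform); with fewer than two events the diagnostic is
flagged unavailable rather than raising.

Covariate coding throughout: cohort with German IITs as reference; drug
trial yes/no; study size above the cohort median of 150 (sensitivity
variants: log10 size, raw size); single vs. more-than-one primary outcome
with multiple as reference.  Pre-specified sensitivity analyses are
provided as `run_sensitivity` variants: continuous log10 size;
undichotomized size with study phase and medical domain added; exclusion
of German-language guidelines (recomputes impact and survival on the
filtered network before refitting, probing domestic-preference bias in
guideline retrieval); and associated-CPGs as outcome.  No multiplicity
adjustment is applied, matching the emulated analysis; this is a known
limitation.

## Synthetic-data generator

`generate_network` draws trials per cohort (sizes 120/200/171/200 by
default), covariates (lognormal study size with median 150, drug-trial
probability 0.6, primary outcomes 1 + Poisson(0.7)), and start dates
uniform over 2005–2016.  Articles appear with per-cohort probabilities
(defaults 0.75/0.84/0.66/0.51, the publication rates reported for the four
cohorts); SR citations arrive Poisson(2.0) per published trial with
inclusion probability 0.44.  Impactful guideline citations are
overdispersed: under the default `"count"` coupling the number of impacted
guidelines is NB2 with mean `base_citation_rate · t_i · exp(x_i'β)` —
exactly the count model the analysis fits — and the first-impact time given
≥ 1 impact is a truncated-exponential draw with hazard
`base_hazard · exp(x_i'γ)`.  Under the `"hazard"` coupling the first-impact
time is exponential proportional-hazards censored at `t_i` — exactly the
Cox model — and the count is 1 + Poisson given an event.  The two couplings
exist because no single arrival process makes both the NB-with-offset and
the proportional-hazards model exactly true at nonzero overdispersion
(a gamma-frailty arrival process yields NB counts but a non-proportional
marginal hazard); parameter-recovery studies use the coupling that matches
the model under test, and both share the same covariates and network
realization code.  IRR-scale and HR-scale effects are configured
separately, defaulting to the published point estimates (size 5.13 / 2.52,
international IST 0.42 / 0.61, …).

`base_citation_rate` defaults to 0.036 impactful citations per year for a
reference trial: the value at which the closed-form impact probability
(`expected_impact_proportion`, an exact mixture over the discrete covariate
distribution with quadrature over the start-date window) equals the
reported 22% of trials with guideline impact.  Guideline attributes
(language, journal publication, evidence grading) are drawn with the
reported prevalences; month/day missingness (10% / 30%) is only applied
when uniform re-imputation cannot push the date across the censoring
cutoff, keeping "events = impactful trials" an exact invariant.

What the generator does **not** emulate: citation text and matching noise,
SRs or guidelines spanning multiple trials of the cohort, correlation
between a trial's article count and its impact, guideline quality, or
recommendation strength.  Passing recovery tests therefore show the
estimators are correct under the assumed model, not that the model is
correct for any real cohort.

## Fixtures

The published record gives only *marginal* flow counts, so the reference
fixture freezes one admissible joint allocation: per-cohort counts for
articles [90, 168, 112, 102], SR-cited [68, 122, 90, 80], SR-included
[58, 105, 77, 69], SR-excluded [45, 80, 60, 53] (the 187-trial overlap
implied by 238 + 309 − 360), direct-impactful [23, 37, 30, 22], via-SR
impactful [23, 38, 30, 22] (overlap 72 = 112 + 113 − 153) and associated
[36, 59, 47, 35], all consistent with the printed totals and the
per-cohort impactful/no-impact splits [31, 51, 41, 30] / [89, 149, 130,
170].  The 405 guidelines decompose into 331 impacted (112 direct + 113
via-SR + 106 additional citations of direct-impactful articles) and 74
associated-only (24 supplement-only + 50 citing an SR that excluded the
article); mention counts are spread deterministically to total 1893 main
text and 109 supplement.  Start dates spread over 2005–2016 within each
cohort via a stride permutation (decorrelating calendar time from the
allocation's block structure); every guideline carries a complete 2017–2019
date after all trial starts, so the survival layer yields exactly 153
events regardless of seed.  All printed marginals are re-asserted at
construction and drift raises immediately.  Intermediate per-cohort splits
not printed in the source are frozen choices, not estimates.

The exemplar fixture is a one-trial network with 21 articles, 60 SRs and
16 guidelines, 15 reachable by an impactful path — the footprint of the
most prolific trial of the motivating cohort — used for transition-plot
exports and as a small end-to-end target.

## Numerical and design notes

* Deterministic ordering everywhere: paths sort by (guideline, article,
  SR); serialization sorts by id; generator draws follow a fixed entity
  order under one `numpy` Generator.
* `build_network` raises on structural defects (duplicate ids, dangling
  edges, non-positive counts); soft defects (missing dates, implausible
  sizes, start dates outside 2005–2016 in strict mode) surface as
  diagnostics from `validate_network` without exceptions.
* Degenerate fits raise `DegenerateFitError` (all-zero outcome, no events)
  or `SpecError` (a covariate without contrast); the pipeline skips such
  model stages with empty output tables instead of failing, so an empty or
  single-cohort network still produces a complete, consistent output
  directory.
* Known limitations: Wald CIs only; no multiplicity adjustment; per-cohort
  attribution of guideline-level counts is only a partition when no
  guideline bridges cohorts; the direct-included case (8) has no empirical
  anchor; fixture joint structure beyond the printed marginals is
  conventional.
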