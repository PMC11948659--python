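"""Count and hazard regressions for guideline impact.

Generates a synthetic cohort with known covariate effects, then fits the
two modelling layers: negative binomial regression (log observed time as
exposure offset) for the impact counts, and Cox proportional hazards for
the time-to-guideline-impact, both against the German-IIT reference
cohort.
"""

from guideline_impact import (
    GeneratorConfig,
    Outcome,
    RegressionSpec,
    build_analysis_frame,
    fit_count_model,
    fit_cox,
    generate_network,
    schoenfeld_check,
)

cfg = GeneratorConfig(cohort_sizes=(500, 500, 500, 500),
                      article_prob=(1.0, 1.0, 1.0, 1.0),
                      base_citation_rate=0.05,
                      missing_month_prob=0.0, missing_day_prob=0.0)
network = generate_network(cfg, seed=42)
df = build_analysis_frame(network, seed=42)


def show(res, label, unit):
    print(f"\n{label} (n={res.n_observations})")
    for t in res.terms:
        print(f"  {t.term:36s} {unit} {t.estimate:5.2f} "
              f"[{t.ci_low:5.2f}, {t.ci_high:5.2f}]  p={t.p_value:.3g}")


nb = fit_count_model(df, RegressionSpec(outcome=Outcome.IMPACTED_CPGS))
show(nb, "negative binomial: impacted guidelines per trial", "IRR")
print(f"  dispersion alpha = {nb.dispersion_alpha:.2f}")

cox = fit_cox(df, RegressionSpec())
show(cox, "Cox PH: time to first guideline impact", "HR ")
diag = schoenfeld_check(cox)
worst = min(t.p_value for t in diag.trends)
print(f"  Schoenfeld trend tests: smallest p = {worst:.2f} "
      f"(no proportional-hazards violation flagged at 0.05)" if worst > 0.05
      else f"  Schoenfeld trend tests: smallest p = {worst:.3f} (inspect!)")

# IRR > 1 means more impactful guideline citations per unit of observed
# time than the reference level; HR > 1 means earlier guideline impact.
# The generator's defaults embed the published effect pattern: larger
# trials gain impact, international industry-sponsored trials lag.
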