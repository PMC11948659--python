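"""Count models, Kaplan–Meier, Cox, Schoenfeld checks and sensitivities."""

import numpy as np
import pandas as pd
import pytest

from guideline_impact import (
    DegenerateFitError,
    GeneratorConfig,
    Outcome,
    RegressionSpec,
    SpecError,
    build_analysis_frame,
    fit_count_model,
    fit_cox,
    generate_network,
    km_fit,
    run_sensitivity,
    schoenfeld_check,
)


def count_frame(n=3000, seed=0, alpha=0.0, beta_size=0.8):
    """Synthetic regression frame with known Poisson/NB truth."""
    rng = np.random.default_rng(seed)
    cohort = rng.choice(["german_iit", "intl_iit", "german_ist", "intl_ist"], n)
    size = rng.integers(0, 2, n)
    drug = rng.integers(0, 2, n)
    single = rng.integers(0, 2, n)
    t = rng.uniform(3, 14, n)
    mu = t * 0.2 * np.exp(beta_size * size - 0.4 * (cohort == "intl_ist"))
    if alpha > 0:
        y = rng.negative_binomial(1 / alpha, 1 / (1 + alpha * mu))
    else:
        y = rng.poisson(mu)
    return pd.DataFrame({
        "cohort": cohort, "size_dichotomized": size, "drug_trial": drug,
        "n_primary_outcomes_dichotomized": single,
        "size_log10": rng.uniform(1, 3, n), "size_raw": rng.integers(10, 900, n),
        "impact_on_cpgs": y, "impacted_cpgs": y, "associated_cpgs": y,
        "observed_time_years": t, "negative_time": False,
    })


class TestCountModel:
    def test_nb_matches_poisson_in_the_poisson_limit(self):
        """On Poisson data the NB fit's IRRs agree with the Poisson fit
        within 1% (nested-model limit)."""
        df = count_frame(alpha=0.0)
        nb = fit_count_model(df)
        po = fit_count_model(df, family="poisson")
        for t_nb, t_po in zip(nb.terms, po.terms):
            assert t_nb.estimate == pytest.approx(t_po.estimate, rel=0.01)
        assert nb.dispersion_alpha < 0.05

    def test_dispersion_recovered_on_nb_data(self):
        df = count_frame(alpha=1.0, seed=3)
        res = fit_count_model(df)
        assert res.converged
        assert 0.8 < res.dispersion_alpha < 1.25
        assert res.term("size_dichotomized").estimate == pytest.approx(
            np.exp(0.8), rel=0.1)

    def test_offset_doubling_leaves_irrs_unchanged(self):
        df = count_frame(alpha=0.5, seed=4, beta_size=1.0)
        base = fit_count_model(df)
        doubled = df.copy()
        doubled["observed_time_years"] *= 2.0
        res = fit_count_model(doubled)
        for a, b in zip(base.terms, res.terms):
            assert b.estimate == pytest.approx(a.estimate, rel=1e-6)

    def test_all_zero_outcome_degenerate(self):
        df = count_frame(n=200)
        df["impact_on_cpgs"] = 0
        with pytest.raises(DegenerateFitError):
            fit_count_model(df)

    def test_single_level_covariate_is_spec_error(self):
        df = count_frame(n=200)
        df["drug_trial"] = 1
        with pytest.raises(SpecError, match="drug_trial"):
            fit_count_model(df)

    def test_two_size_representations_rejected(self):
        with pytest.raises(SpecError, match="size"):
            RegressionSpec(covariates=("cohort", "size_dichotomized",
                                       "size_log10")).validate()

    def test_ci_brackets_estimate(self):
        res = fit_count_model(count_frame(alpha=0.6, seed=5))
        for t in res.terms:
            assert t.ci_low <= t.estimate <= t.ci_high
            assert t.estimate > 0


def survival_frame(n=300, seed=0, hr_size=1.0, censor_at=10.0):
    rng = np.random.default_rng(seed)
    cohort = rng.choice(["german_iit", "intl_iit", "german_ist", "intl_ist"], n)
    size = rng.integers(0, 2, n)
    rate = 0.15 * np.exp(np.log(hr_size) * size)
    t_event = rng.exponential(1 / rate)
    time = np.minimum(t_event, censor_at)
    return pd.DataFrame({
        "cohort": cohort, "size_dichotomized": size,
        "drug_trial": rng.integers(0, 2, n),
        "n_primary_outcomes_dichotomized": rng.integers(0, 2, n),
        "time_years": time, "event": (t_event <= censor_at).astype(int),
        "observed_time_years": censor_at, "negative_time": False,
    })


class TestKaplanMeier:
    def test_no_events_curve_identically_zero(self):
        df = survival_frame(seed=1)
        df["event"] = 0
        km = km_fit(df)
        for curve in km.cumulative_incidence.values():
            assert np.allclose(curve, 0.0)
        assert np.isnan(km.logrank_p)

    def test_no_censoring_equals_empirical_cdf(self):
        """With every record an event at a distinct time, cumulative
        incidence equals the empirical CDF exactly."""
        times = np.array([1.0, 2.5, 3.0, 4.75, 7.0])
        df = pd.DataFrame({
            "cohort": ["german_iit"] * 5, "time_years": times, "event": 1,
            "observed_time_years": 10.0, "negative_time": False})
        km = km_fit(df)
        ecdf = np.searchsorted(np.sort(times), km.times, side="right") / len(times)
        assert np.allclose(km.cumulative_incidence["all"], ecdf)

    def test_at_risk_counts_non_increasing(self):
        km = km_fit(survival_frame(seed=2))
        for col in km.at_risk:
            assert (np.diff(km.at_risk[col].to_numpy()) <= 0).all()

    def test_logrank_detects_true_rate_difference(self):
        rng = np.random.default_rng(8)
        n = 2000
        cohort = np.repeat(["german_iit", "intl_iit", "german_ist", "intl_ist"], n // 4)
        rate = np.where(cohort == "intl_ist", 0.05, 0.2)
        t_event = rng.exponential(1 / rate)
        df = pd.DataFrame({
            "cohort": cohort, "time_years": np.minimum(t_event, 10.0),
            "event": (t_event <= 10.0).astype(int),
            "observed_time_years": 10.0, "negative_time": False})
        assert km_fit(df).logrank_p < 0.05


class TestCox:
    def test_all_censored_degenerate(self):
        df = survival_frame(seed=3)
        df["event"] = 0
        with pytest.raises(DegenerateFitError, match="no events"):
            fit_cox(df)

    def test_null_effect_estimate_near_one(self):
        res = fit_cox(survival_frame(n=2000, seed=4, hr_size=1.0))
        t = res.term("size_dichotomized")
        assert t.ci_low < 1.0 < t.ci_high

    def test_known_hazard_ratio_recovered(self):
        res = fit_cox(survival_frame(n=2000, seed=5, hr_size=2.0))
        t = res.term("size_dichotomized")
        assert t.ci_low < 2.0 < t.ci_high
        assert t.estimate == pytest.approx(2.0, rel=0.2)


class TestSchoenfeld:
    def test_proportional_hazards_generator_passes(self):
        """Under proportional hazards the trend tests are almost always
        non-significant."""
        n_sig = 0
        reps = 40
        for s in range(reps):
            res = fit_cox(survival_frame(n=400, seed=100 + s, hr_size=2.0))
            diag = schoenfeld_check(res)
            assert diag.available
            n_sig += any(t.p_value < 0.05 for t in
                         [tr for tr in diag.trends if "size" in tr.covariate])
        assert n_sig <= reps * 0.2

    def test_time_varying_effect_detected(self):
        """An effect that switches off over time violates proportionality."""
        rng = np.random.default_rng(11)
        n = 4000
        size = rng.integers(0, 2, n)
        # strong early hazard for size=1 that vanishes after t=1
        t_event = np.where(size == 1,
                           rng.exponential(0.25, n),
                           rng.exponential(5.0, n))
        t_event = np.where((size == 1) & (t_event > 1.0),
                           1.0 + rng.exponential(20.0, n), t_event)
        df = pd.DataFrame({
            "cohort": rng.choice(["german_iit", "intl_iit"], n),
            "size_dichotomized": size,
            "drug_trial": rng.integers(0, 2, n),
            "n_primary_outcomes_dichotomized": rng.integers(0, 2, n),
            "time_years": np.minimum(t_event, 10.0),
            "event": (t_event <= 10.0).astype(int),
            "observed_time_years": 10.0, "negative_time": False})
        diag = schoenfeld_check(fit_cox(df))
        assert any(t.p_value < 0.05 for t in diag.trends
                   if t.covariate == "size_dichotomized")

    def test_single_event_unavailable(self):
        df = survival_frame(n=60, seed=12)
        df["event"] = 0
        df.loc[0, "event"] = 1
        res = fit_cox(df)
        diag = schoenfeld_check(res)
        assert not diag.available and "events" in diag.reason


@pytest.fixture(scope="module")
def net():
    return generate_network(GeneratorConfig(german_language_frac=0.0), seed=21)


class TestSensitivity:
    def test_exclude_german_is_identity_without_german_cpgs(self, net):
        base = fit_count_model(build_analysis_frame(net, seed=0),
                               RegressionSpec(outcome=Outcome.IMPACT_ON_CPGS))
        filt = run_sensitivity(net, "exclude_german_language_cpgs", seed=0)
        for a, b in zip(base.terms, filt.terms):
            assert b.estimate == pytest.approx(a.estimate, rel=1e-9)

    def test_exclude_german_changes_fit_when_german_cpgs_exist(self):
        net = generate_network(GeneratorConfig(german_language_frac=0.5), seed=22)
        base = fit_count_model(build_analysis_frame(net, seed=0))
        filt = run_sensitivity(net, "exclude_german_language_cpgs", seed=0)
        assert any(abs(a.estimate - b.estimate) > 1e-6
                   for a, b in zip(base.terms, filt.terms))

    def test_continuous_size_concordant_direction(self, net):
        """log10(size) and the >150 dichotomy agree on the effect direction
        when the generator's size effect is monotone."""
        dich = fit_count_model(build_analysis_frame(net, seed=0))
        cont = run_sensitivity(net, "continuous_size_log10", seed=0)
        d = dich.term("size_dichotomized").estimate
        c = cont.term("size_log10").estimate
        assert (d > 1) == (c > 1)

    def test_associated_outcome_same_sign_pattern(self, net):
        """Associated-CPGs couples with impacted-CPGs in the generator, so
        effect directions agree."""
        imp = fit_count_model(build_analysis_frame(net, seed=0),
                              RegressionSpec(outcome=Outcome.IMPACTED_CPGS))
        assoc = run_sensitivity(net, "associated_cpgs_outcome", seed=0)
        for term in ("size_dichotomized", "cohort[intl_ist]"):
            assert (imp.term(term).estimate > 1) == (assoc.term(term).estimate > 1)

    def test_phase_domain_variant_runs(self, net):
        res = run_sensitivity(net, "undichotomized_with_phase_domain", seed=0)
        assert any(t.term.startswith("study_phase[") for t in res.terms)
        assert any(t.term == "size_raw" for t in res.terms)

    def test_unknown_variant_rejected(self, net):
        with pytest.raises(ValueError, match="unknown sensitivity"):
            run_sensitivity(net, "bogus")
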