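import math
from itertools import product

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import expit

from gmediate import (
    CohortTable,
    Scenario,
    bootstrap_effects,
    effects_from_prevalences,
    estimate_effects,
    exact_effects,
    exact_gformula,
    fit_model_system,
    generate_cohort,
    percent_odds_change,
    proportion_mediated,
    simulate_scenario,
    single_mediator_effects,
)
from gmediate.exceptions import ParameterError, UndefinedOddsError
from gmediate.gformula import ModelSystem
from gmediate.glm import FittedModel, INTERCEPT


def build_system(y_coefs, m_coefs, l_coefs=None, c_values=(0.0, 1.0), outcome_family="binomial"):
    """Hand-assemble a one-confounder model system from raw coefficient dicts.

    ``*_coefs`` map term name -> coefficient (must include '(Intercept)').
    """

    def model(coefs, family="binomial"):
        s = pd.Series(coefs)
        names = list(s.index)
        cov = pd.DataFrame(np.eye(len(names)) * 0.01, index=names, columns=names)
        return FittedModel(s, cov, family, True, len(c_values), 0.0)

    l_models = {"l": model(l_coefs)} if l_coefs else {}
    return ModelSystem(
        exposure="x",
        baseline=("c",),
        intermediate=("l",) if l_coefs else (),
        mediators=("m",),
        outcome="y",
        outcome_family=outcome_family,
        l_models=l_models,
        m_models={"m": model(m_coefs)},
        y_model=model(y_coefs, outcome_family),
        standardization=pd.DataFrame({"c": list(c_values)}),
    )


class TestExactEnumeration:
    def test_matches_hand_arithmetic_on_8_configuration_system(self):
        """One binary C, one mediator, no L: sum over (C, M) by hand."""
        bm = {INTERCEPT: -1.0, "x": 0.8, "c": 0.5}
        by = {INTERCEPT: -0.5, "x": 0.4, "m": 1.1, "c": -0.3}
        system = build_system(by, bm)
        for x_d, x_m in [(0, 0), (1, 0), (1, 1)]:
            hand = 0.0
            for c in (0.0, 1.0):  # empirical C rows, weight 1/2 each
                for m in (0.0, 1.0):
                    pm = expit(bm[INTERCEPT] + bm["x"] * x_m + bm["c"] * c)
                    pm = pm if m == 1.0 else 1.0 - pm
                    py = expit(by[INTERCEPT] + by["x"] * x_d + by["m"] * m + by["c"] * c)
                    hand += 0.5 * pm * py
            got = exact_gformula(system, Scenario(x_d, x_m))
            assert got == pytest.approx(hand, abs=1e-12)

    def test_all_zero_coefficients_give_intercept_prevalence(self):
        system = build_system(
            {INTERCEPT: -0.7, "x": 0.0, "m": 0.0, "c": 0.0},
            {INTERCEPT: 0.3, "x": 0.0, "c": 0.0},
        )
        for sc in (Scenario(0, 0), Scenario(1, 1)):
            assert exact_gformula(system, sc) == pytest.approx(float(expit(-0.7)), abs=1e-12)

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(-1.5, 1.5), min_size=8, max_size=8))
    def test_decomposition_identity_on_random_systems(self, coefs):
        """TCE = NDE x NIE to 1e-10 for any system, by construction of the
        three scenario prevalences."""
        by = {INTERCEPT: coefs[0], "x": coefs[1], "m": coefs[2], "c": coefs[3], "l": coefs[4]}
        bm = {INTERCEPT: coefs[5], "x": coefs[6], "c": coefs[7], "l": 0.4}
        bl = {INTERCEPT: 0.1, "x": 0.5, "c": -0.2}
        system = build_system(by, bm, l_coefs=bl)
        prev = {
            sc: exact_gformula(system, Scenario(*sc)) for sc in [(0, 0), (1, 0), (1, 1)]
        }
        assert all(0.0 < p < 1.0 for p in prev.values())
        est = effects_from_prevalences("y", prev[(0, 0)], prev[(1, 0)], prev[(1, 1)], "odds_ratio")
        assert est.tce == pytest.approx(est.nde * est.nie, abs=1e-10)


class TestMonteCarloSimulation:
    def test_constant_model_returns_intercept_prevalence(self):
        system = build_system(
            {INTERCEPT: -0.7, "x": 0.0, "m": 0.0, "c": 0.0},
            {INTERCEPT: 0.3, "x": 0.0, "c": 0.0},
        )
        got = simulate_scenario(system, Scenario(1, 0), copies=500, seed=3)
        assert got == pytest.approx(float(expit(-0.7)), abs=1e-12)

    def test_converges_to_exact_oracle(self, cohort4599):
        system = fit_model_system(cohort4599, "hazardous_alcohol")
        ex = exact_effects(system)
        mc = simulate_scenario(system, Scenario(1, 1), copies=200, seed=9)
        assert abs(mc - ex.p11) < 0.005

    def test_exposed_scenario_exceeds_unexposed_under_defaults(self, cohort4599):
        system = fit_model_system(cohort4599, "drug_use")
        p11 = simulate_scenario(system, Scenario(1, 1), copies=100, seed=4)
        p00 = simulate_scenario(system, Scenario(0, 0), copies=100, seed=4)
        assert p11 > p00


class TestEstimation:
    def test_determinism(self, cohort4599):
        a = estimate_effects(cohort4599, "hazardous_alcohol", copies=20, seed=5)
        b = estimate_effects(cohort4599, "hazardous_alcohol", copies=20, seed=5)
        assert (a.tce, a.nde, a.nie) == (b.tce, b.nde, b.nie)

    def test_no_intermediate_confounders_still_valid(self, cohort4599):
        est = estimate_effects(
            cohort4599, "hazardous_alcohol", intermediate=[], copies=20, seed=5
        )
        assert est.tce > 0 and est.tce == pytest.approx(est.nde * est.nie, abs=1e-10)

    def test_component_coefficients_recover_dgp_truth(self, params, cohort_large):
        system = fit_model_system(cohort_large, "drug_use")
        for name, model in {**system.l_models, **system.m_models}.items():
            truth = params.variable(name).coef_map()
            for term, b_true in truth.items():
                if term in model.params.index:
                    se = model.se(term)
                    assert abs(model.params[term] - b_true) < 4 * se, (name, term)

    def test_undefined_odds_error_names_scenario(self):
        with pytest.raises(UndefinedOddsError, match="x_direct=0"):
            effects_from_prevalences("y", 0.0, 0.5, 0.6, "odds_ratio")

    def test_numeric_outcome_uses_mean_differences(self, cohort4599):
        est = estimate_effects(cohort4599, "audit_consumption", copies=20, seed=5)
        assert est.scale == "mean_difference"
        assert est.tce == pytest.approx(est.nde + est.nie, abs=1e-10)


class TestBootstrap:
    def test_ci_determinism(self, cohort4599):
        a = bootstrap_effects(cohort4599, "hazardous_alcohol", B=5, copies=10, seed=6)
        b = bootstrap_effects(cohort4599, "hazardous_alcohol", B=5, copies=10, seed=6)
        assert a.tce_ci == b.tce_ci and a.nie_ci == b.nie_ci

    def test_ci_width_shrinks_with_sample_size(self, params):
        widths = {2500: [], 10_000: []}
        for n in widths:
            for rep in range(3):
                cohort = generate_cohort(params, n, seed=100 + rep)
                est = bootstrap_effects(cohort, "hazardous_alcohol", B=30, copies=10, seed=rep)
                widths[n].append(math.log(est.tce_ci[1]) - math.log(est.tce_ci[0]))
        assert np.median(widths[10_000]) < np.median(widths[2500])

    def test_b_below_two_rejected(self, cohort4599):
        with pytest.raises(ParameterError):
            bootstrap_effects(cohort4599, "drug_use", B=1)


class TestSingleMediator:
    def test_roles_not_mutated(self, cohort4599):
        before = dict(cohort4599.roles)
        single_mediator_effects(
            cohort4599, "school_noncompletion", "drug_use", copies=10, seed=1
        )
        assert cohort4599.roles == before

    def test_equals_block_nie_when_other_mediators_inert(self, params):
        """If arrest and gang have zero outgoing coefficients, the indirect
        effect via school noncompletion is the whole block effect."""
        p = params
        for child in ("gang_membership", "school_noncompletion", "hazardous_alcohol",
                      "drug_use", "audit_consumption", "audit_problems"):
            for parent in ("police_arrest", "gang_membership"):
                if parent in p.variable(child).parents:
                    p = p.set_coefficient(child, parent, 0.0)
        cohort = generate_cohort(p, 30_000, seed=13)
        block = estimate_effects(cohort, "drug_use", copies=100, seed=2)
        single = single_mediator_effects(
            cohort, "school_noncompletion", "drug_use", copies=100, seed=2
        )
        assert abs(math.log(single.nie) - math.log(block.nie)) < 0.05

    def test_null_pathway_gives_unit_nie(self, params):
        p = params.set_coefficient("school_noncompletion", "conduct_problems", 0.0)
        p = p.set_coefficient("drug_use", "school_noncompletion", 0.0)
        cohort = generate_cohort(p, 30_000, seed=14)
        est = single_mediator_effects(
            cohort, "school_noncompletion", "drug_use", copies=100, seed=3
        )
        assert abs(math.log(est.nie)) < 0.03

    def test_unknown_mediator_rejected(self, cohort4599):
        with pytest.raises(ParameterError):
            single_mediator_effects(cohort4599, "female", "drug_use")


class TestProportionMediated:
    @pytest.mark.parametrize(
        "tce,nie,expected",
        [
            (1.20, 1.16, 0.814),  # published worked example: rounds to 81%
            (1.5, 1.0, 0.0),
            (2.0, 2.0, 1.0),
        ],
    )
    def test_values(self, tce, nie, expected):
        assert proportion_mediated(tce, nie) == pytest.approx(expected, abs=2e-3)

    def test_not_applicable_cases(self):
        assert proportion_mediated(1.005, 1.10) is None  # tiny total effect
        assert proportion_mediated(1.50, 0.90) is None  # inconsistent mediation

    def test_domain_errors(self):
        with pytest.raises(ParameterError):
            proportion_mediated(-1.0, 1.1)
        with pytest.raises(ParameterError):
            proportion_mediated(1.2, 0.0)

    def test_percent_odds_change(self):
        assert percent_odds_change(1.08) == pytest.approx(8.0)
        with pytest.raises(ParameterError):
            percent_odds_change(0.0)
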