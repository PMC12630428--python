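import math

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit

from gmediate import (
    CohortTable,
    DGPParameters,
    MissingnessModel,
    ModelSpec,
    VariableDef,
    fit_glm,
    generate_cohort,
    implied_marginals,
    impose_missingness,
    odds_ratio_ci,
    true_mediation_effects,
)
from gmediate.dgp import TARGET_PREVALENCES, _linear_predictor, _sample_baseline
from gmediate.exceptions import DataError, ParameterError, StructuralSpecificationError

KEY_VARS = [
    "conduct_problems",
    "police_arrest",
    "gang_membership",
    "school_noncompletion",
    "hazardous_alcohol",
    "drug_use",
]


class TestGeneration:
    def test_shape_and_completeness(self, cohort4599):
        assert cohort4599.n == 4599
        assert cohort4599.n_missing() == 0
        assert set(cohort4599.with_role("mediator")) == {
            "police_arrest",
            "gang_membership",
            "school_noncompletion",
        }

    def test_bitwise_determinism(self, params):
        a = generate_cohort(params, 2000, seed=42)
        b = generate_cohort(params, 2000, seed=42)
        pd.testing.assert_frame_equal(a.data, b.data)
        c = generate_cohort(params, 2000, seed=43)
        assert not a.data.equals(c.data)

    def test_prevalences_match_enumeration_oracle(self, params, cohort_large):
        """Sampled prevalences agree with the semi-exact implied marginals."""
        marg = implied_marginals(params, n_c=20_000, seed=404)
        n, n_c = cohort_large.n, 20_000
        for var in KEY_VARS:
            p = marg[var]
            se = math.sqrt(p * (1 - p) * (1 / n + 1 / n_c))
            assert abs(cohort_large.data[var].mean() - p) < 3 * se, var

    def test_numeric_outcomes_respect_declared_ranges(self, cohort_large):
        ac = cohort_large.data["audit_consumption"]
        ap = cohort_large.data["audit_problems"]
        assert ac.min() >= 0 and ac.max() <= 12
        assert ap.min() >= 0 and ap.max() <= 28
        assert np.allclose(ac, np.round(ac))

    def test_null_exposure_paths_remove_associations(self, params):
        """Zeroing the exposure coefficients removes the conditional
        exposure-mediator association (given each mediator's other structural
        parents; the marginal OR stays confounded by shared baseline causes)."""
        null = params.zero_exposure_paths()
        cohort = generate_cohort(null, 100_000, seed=77)
        for med in ("police_arrest", "gang_membership", "school_noncompletion"):
            parents = [p for p in null.variable(med).parents if p != "conduct_problems"]
            model = fit_glm(cohort, ModelSpec(med, ("conduct_problems", *parents)))
            b = model.params["conduct_problems"]
            assert abs(b) < 3 * model.se("conduct_problems"), med

    def test_non_topological_order_rejected(self):
        with pytest.raises(StructuralSpecificationError):
            DGPParameters(
                (
                    VariableDef("x", "exposure", "binary", parents=("c",), coef=(("c", 1.0),)),
                    VariableDef("c", "baseline_confounder", "binary"),
                ),
                MissingnessModel(0.0, (), ()),
            )

    def test_calling_defaults_twice_identical(self, params):
        from gmediate import default_pelotas_params

        assert default_pelotas_params() == params


class TestMissingness:
    def test_rate_zero_is_identity(self, params):
        cohort = generate_cohort(params, 5000, seed=1)
        out = impose_missingness(cohort, params, seed=2, rate=0.0)
        pd.testing.assert_frame_equal(out.data, cohort.data)

    def test_realized_rate_matches_configured(self, params):
        cohort = generate_cohort(params, 20_000, seed=3)
        out = impose_missingness(cohort, params, seed=4, rate=0.25)
        frac = out.data[list(params.missingness.maskable)].isna().to_numpy().mean()
        assert abs(frac - 0.25) < 0.02

    def test_missingness_positively_associated_with_exposure(self, params):
        cohort = generate_cohort(params, 100_000, seed=5)
        masked = impose_missingness(cohort, params, seed=6)
        any_missing = masked.data.isna().any(axis=1).astype(float)
        df = pd.DataFrame(
            {"miss": any_missing, "x": cohort.data["conduct_problems"]}
        )
        t = CohortTable(df, {"miss": "outcome", "x": "exposure"})
        frag = odds_ratio_ci(fit_glm(t, ModelSpec("miss", ("x",))), "x")
        assert frag["or"] > 1.0 and frag["p_value"] < 0.05

    def test_baseline_columns_never_masked(self, params):
        cohort = generate_cohort(params, 10_000, seed=7)
        masked = impose_missingness(cohort, params, seed=8, rate=0.3)
        for col in ("female", "risk_score", "hyperactivity", "conduct_problems"):
            assert not masked.data[col].isna().any()

    def test_preconditions(self, params):
        cohort = generate_cohort(params, 1000, seed=9)
        with pytest.raises(ParameterError):
            impose_missingness(cohort, params, seed=1, rate=1.0)
        already = impose_missingness(cohort, params, seed=1, rate=0.1)
        with pytest.raises(DataError):
            impose_missingness(already, params, seed=1, rate=0.1)


class TestTrueEffects:
    def test_null_dag_gives_unit_effects(self, params):
        null = params.zero_exposure_paths()
        tr = true_mediation_effects(null, "drug_use", n_c=5_000)
        assert tr.tce == pytest.approx(1.0, abs=1e-12)
        assert tr.nde == pytest.approx(1.0, abs=1e-12)
        assert tr.nie == pytest.approx(1.0, abs=1e-12)

    def test_no_direct_pathway_gives_unit_nde(self, params):
        """With the exposure cut out of the outcome and L equations, the only
        open pathways run through the mediator block, so NDE = 1 exactly."""
        p = params.zero_exposure_paths(roles=("outcome", "intermediate_confounder"))
        tr = true_mediation_effects(p, "hazardous_alcohol", n_c=5_000)
        assert tr.nde == pytest.approx(1.0, abs=1e-12)
        assert tr.nie > 1.0

    def test_default_truth_positive_mediation_and_identity(self, params):
        tr = true_mediation_effects(params, "drug_use", n_c=30_000)
        assert tr.nie > 1.0
        assert tr.tce == pytest.approx(tr.nde * tr.nie, abs=1e-10)
        assert tr.is_truth and tr.tce_ci is None

    def test_enumeration_agrees_with_forward_simulation(self, params):
        """Independent oracle: brute-force counterfactual simulation from the
        structural equations reproduces the enumerated prevalences."""
        rng = np.random.default_rng(2024)
        n = 1_000_000
        c = _sample_baseline(params, n, seed=881)

        def draw_block(names, x, ctx):
            ctx = dict(ctx)
            ctx[params.exposure] = x
            for name in names:
                p = expit(_linear_predictor(params.variable(name), ctx))
                ctx[name] = (rng.random(n) < p).astype(float)
            return ctx

        for x_d, x_m in [(1, 0), (1, 1)]:
            ctx_d = draw_block(params.intermediate, float(x_d), c)
            ctx_m = draw_block(params.intermediate, float(x_m), c)
            ctx_m = draw_block(params.mediators, float(x_m), ctx_m)
            for m in params.mediators:
                ctx_d[m] = ctx_m[m]
            y = expit(_linear_predictor(params.variable("drug_use"), ctx_d))
            sim = float(np.mean(y))
            tr = true_mediation_effects(params, "drug_use", n_c=100_000)
            exact = {(0, 0): tr.p00, (1, 0): tr.p10, (1, 1): tr.p11}[(x_d, x_m)]
            assert abs(sim - exact) < 0.002

    def test_numeric_variable_in_block_rejected(self, params):
        bad_vars = tuple(
            v if v.name != "peer_deviance" else VariableDef(
                "peer_deviance", v.role, "numeric", v.parents, v.coef, v.intercept, noise_sd=1.0
            )
            for v in params.variables
        )
        bad = DGPParameters(bad_vars, params.missingness)
        with pytest.raises(StructuralSpecificationError):
            true_mediation_effects(bad, "drug_use", n_c=100)


def test_target_prevalences_are_the_study_conditions(params):
    """The frozen calibration targets drive the defaults (guards accidental edits)."""
    marg = implied_marginals(params, n_c=30_000, seed=5150)
    for var, target in TARGET_PREVALENCES.items():
        assert abs(marg[var] - target) < 0.01, var
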