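import math

import numpy as np
import pandas as pd
import pytest

from gmediate import CohortTable, ModelSpec, association_table, fit_glm, odds_ratio_ci
from gmediate.exceptions import DataError
from gmediate.glm import coefficient_ci, format_p
from tests.conftest import make_2x2_cohort


class TestLogisticFit:
    def test_2x2_matches_closed_form_log_odds_ratio(self):
        """On a saturated binary model the MLE equals ln(ad/bc)."""
        cohort = make_2x2_cohort(40, 10, 20, 30)
        model = fit_glm(cohort, ModelSpec("y", ("x",)))
        assert model.converged
        assert model.params["x"] == pytest.approx(math.log(6.0), abs=1e-8)
        # Woolf SE from the cell counts
        woolf = math.sqrt(1 / 40 + 1 / 10 + 1 / 20 + 1 / 30)
        assert model.se("x") == pytest.approx(woolf, rel=1e-6)

    def test_balanced_independence_gives_null_or(self):
        cohort = make_2x2_cohort(25, 25, 25, 25)
        model = fit_glm(cohort, ModelSpec("y", ("x",)))
        assert model.params["x"] == pytest.approx(0.0, abs=1e-8)
        assert odds_ratio_ci(model, "x")["or"] == pytest.approx(1.0, abs=1e-8)

    def test_separation_detected_and_annotated(self):
        # all exposed are cases: the MLE diverges
        cohort = make_2x2_cohort(30, 0, 10, 40)
        model = fit_glm(cohort, ModelSpec("y", ("x",)))
        assert not model.converged
        assert "separation" in (model.annotation or "")
        assert np.isfinite(model.params).all()

    def test_deviance_monotone_nonincreasing(self, cohort4599):
        model = fit_glm(
            cohort4599,
            ModelSpec("drug_use", ("conduct_problems", "female", "risk_score", "peer_drug_use")),
        )
        path = np.asarray(model.deviance_path)
        assert np.all(np.diff(path) <= 1e-9)

    def test_matches_statsmodels_mle(self, cohort4599):
        """Independent cross-check of coefficients and Wald SEs."""
        sm = pytest.importorskip("statsmodels.api")
        predictors = ["conduct_problems", "female", "risk_score", "hyperactivity", "alcohol_15"]
        model = fit_glm(cohort4599, ModelSpec("hazardous_alcohol", tuple(predictors)))
        X = sm.add_constant(cohort4599.data[predictors].to_numpy())
        ref = sm.GLM(cohort4599.data["hazardous_alcohol"], X, family=sm.families.Binomial()).fit()
        np.testing.assert_allclose(model.params.to_numpy(), ref.params, atol=1e-6)
        np.testing.assert_allclose(
            np.sqrt(np.diag(model.cov.to_numpy())), ref.bse, rtol=1e-4
        )

    def test_empty_or_underdetermined_data_raises(self):
        df = pd.DataFrame({"x": [np.nan, np.nan], "y": [1.0, 0.0]})
        cohort = CohortTable(df, {"x": "exposure", "y": "outcome"})
        with pytest.raises(DataError):
            fit_glm(cohort, ModelSpec("y", ("x",)))


class TestGaussianFit:
    def test_equals_normal_equations(self, cohort4599, rng):
        predictors = ["conduct_problems", "female", "alcohol_15", "risk_score"]
        model = fit_glm(cohort4599, ModelSpec("audit_consumption", tuple(predictors), "gaussian"))
        X = np.column_stack(
            [np.ones(cohort4599.n)] + [cohort4599.data[p] for p in predictors]
        )
        y = cohort4599.data["audit_consumption"].to_numpy()
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        np.testing.assert_allclose(model.params.to_numpy(), beta, atol=1e-10)


class TestWaldInference:
    def test_null_coefficient_ci(self):
        """b=0, SE=0.1 -> OR 1.00 with CI ~ (0.822, 1.217)."""
        cohort = make_2x2_cohort(25, 25, 25, 25)
        model = fit_glm(cohort, ModelSpec("y", ("x",)))
        model.params["x"] = 0.0
        model.cov.loc["x", "x"] = 0.01
        frag = odds_ratio_ci(model, "x")
        assert frag["or"] == pytest.approx(1.0)
        assert frag["ci_low"] == pytest.approx(0.822, abs=1e-3)
        assert frag["ci_high"] == pytest.approx(1.217, abs=1e-3)

    def test_recoded_exposure_inverts_or(self):
        cohort = make_2x2_cohort(40, 10, 20, 30)
        flipped = cohort.copy()
        flipped.data["x"] = 1.0 - flipped.data["x"]
        or1 = odds_ratio_ci(fit_glm(cohort, ModelSpec("y", ("x",))), "x")["or"]
        or2 = odds_ratio_ci(fit_glm(flipped, ModelSpec("y", ("x",))), "x")["or"]
        assert or1 == pytest.approx(1.0 / or2, rel=1e-8)

    def test_missing_term_raises(self):
        model = fit_glm(make_2x2_cohort(40, 10, 20, 30), ModelSpec("y", ("x",)))
        with pytest.raises(KeyError):
            odds_ratio_ci(model, "z")

    def test_p_value_formatting_floor(self):
        assert format_p(0.0004) == "<0.001"
        assert format_p(0.016) == "0.016"
        assert format_p(0.35) == "0.350"


def _confounded_dgp_cohort(n, rng, b_xm=0.7):
    """C -> X and C -> M confounding with a direct X -> M arrow of log-OR b_xm."""
    from scipy.special import expit

    c = (rng.random(n) < 0.5).astype(float)
    x = (rng.random(n) < expit(-0.5 + 1.2 * c)).astype(float)
    m = (rng.random(n) < expit(-1.0 + b_xm * x + 1.0 * c)).astype(float)
    df = pd.DataFrame({"c": c, "x": x, "m": m})
    return CohortTable(
        df, {"c": "baseline_confounder", "x": "exposure", "m": "mediator"}
    )


class TestAssociationTable:
    def test_unadjusted_stage_equals_plain_fit(self, cohort4599):
        rows = association_table(
            cohort4599, [("conduct_problems", "police_arrest")], {"unadjusted": []}
        )
        direct = odds_ratio_ci(
            fit_glm(cohort4599, ModelSpec("police_arrest", ("conduct_problems",))),
            "conduct_problems",
        )
        assert rows[0].estimate == pytest.approx(direct["or"], rel=1e-10)

    def test_adjustment_moves_or_toward_conditional_truth(self, rng):
        """With positive confounding the adjusted OR is closer to the structural log-OR."""
        cohort = _confounded_dgp_cohort(100_000, rng)
        rows = association_table(
            cohort, [("x", "m")], {"unadjusted": [], "adjusted": ["c"]}
        )
        errs = {r.stage: abs(math.log(r.estimate) - 0.7) for r in rows}
        assert errs["adjusted"] < errs["unadjusted"]

    def test_null_arrow_ci_covers_one(self, rng):
        """Zero structural X->M arrow: adjusted 95% CI covers OR=1 in >=90% of replicates."""
        covered = 0
        reps = 50
        for _ in range(reps):
            cohort = _confounded_dgp_cohort(10_000, rng, b_xm=0.0)
            (row,) = association_table(cohort, [("x", "m")], {"adjusted": ["c"]})
            covered += row.ci_low <= 1.0 <= row.ci_high
        assert covered >= 0.9 * reps

    def test_exposure_added_for_adjusted_mediator_outcome_rows(self, cohort4599):
        rows = association_table(
            cohort4599,
            [("police_arrest", "drug_use")],
            {"unadjusted": [], "adjusted": ["female"]},
        )
        # the adjusted fit conditions on the exposure; the OR must differ from
        # a fit on {mediator, female} alone
        manual = odds_ratio_ci(
            fit_glm(cohort4599, ModelSpec("drug_use", ("police_arrest", "conduct_problems", "female"))),
            "police_arrest",
        )
        adjusted = [r for r in rows if r.stage == "adjusted"][0]
        assert adjusted.estimate == pytest.approx(manual["or"], rel=1e-10)

    def test_failed_fit_annotated_but_table_returned(self):
        df = pd.DataFrame({"x": [1.0, 0.0], "y": [1.0, 0.0], "z": [np.nan, np.nan]})
        cohort = CohortTable(
            df, {"x": "exposure", "y": "outcome", "z": "baseline_confounder"},
            {"x": "binary", "y": "binary", "z": "numeric"},
        )
        rows = association_table(cohort, [("x", "y")], {"bad": ["z"]})
        assert rows[0].estimate is None and "failed" in rows[0].annotation


def test_coefficient_ci_linear_scale(cohort4599):
    model = fit_glm(cohort4599, ModelSpec("audit_consumption", ("alcohol_15",), "gaussian"))
    frag = coefficient_ci(model, "alcohol_15")
    assert frag["ci_low"] < frag["b"] < frag["ci_high"]
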