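"""Maximum-likelihood GLM fitting with staged adjustment sets.

Two families are supported, matching what the analyses need:

* binomial with logit link, fitted by iteratively reweighted least squares
  (IRLS) with step-halving so the deviance is monotone non-increasing;
* gaussian with identity link, fitted by the normal equations.

Quasi-complete separation — likely for a 2% mediator such as gang membership
inside bootstrap resamples — is detected (divergence of a coefficient past
``SEPARATION_BOUND`` or non-convergence) and handled by refitting with a small
ridge penalty on the non-intercept terms; the result is annotated and flagged
``converged=False`` so downstream code never uses a separated fit silently.

:func:`association_table` reproduces the staged exposure->mediator and
mediator->outcome association analyses: one fresh fit per (pair x adjustment
stage), with the exposure automatically added to adjusted mediator->outcome
models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .cohort import CohortTable
from .exceptions import DataError, GmediateError

INTERCEPT = "(Intercept)"
#: |coefficient| beyond which a logistic fit is treated as separated.
SEPARATION_BOUND = 15.0
#: Ridge penalty applied to non-intercept terms in the separation fallback.
RIDGE_LAMBDA = 1e-4
MAX_ITER = 100
GRAD_TOL = 1e-8


@dataclass(frozen=True)
class ModelSpec:
    """A single regression model: ``outcome ~ predictors`` under ``family``."""

    outcome: str
    predictors: tuple[str, ...]
    family: str = "binomial"  # 'binomial' (logit) or 'gaussian' (identity)

    def __post_init__(self) -> None:
        if self.family not in ("binomial", "gaussian"):
            raise DataError(f"unknown family {self.family!r}")
        if self.outcome in self.predictors:
            raise DataError(f"outcome {self.outcome!r} appears among its own predictors")
        object.__setattr__(self, "predictors", tuple(self.predictors))


@dataclass
class FittedModel:
    """Coefficients, covariance and fit diagnostics for one GLM."""

    params: pd.Series  # index: (Intercept) + predictors
    cov: pd.DataFrame
    family: str
    converged: bool
    n: int
    loglik: float
    annotation: str | None = None
    deviance_path: tuple[float, ...] = ()
    sigma2: float | None = None  # gaussian residual variance

    @property
    def terms(self) -> list[str]:
        return list(self.params.index)

    def se(self, term: str) -> float:
        return float(np.sqrt(self.cov.loc[term, term]))

    def linear_predictor(self, data: dict[str, np.ndarray] | pd.DataFrame) -> np.ndarray:
        """eta = b0 + sum_j b_j * data[j]; entries of ``data`` may be scalars or arrays."""
        eta = np.asarray(self.params[INTERCEPT], dtype=float)
        for term in self.params.index:
            if term == INTERCEPT:
                continue
            eta = eta + self.params[term] * np.asarray(data[term], dtype=float)
        return np.broadcast_to(eta, np.shape(eta)).astype(float, copy=False)

    def predict(self, data: dict[str, np.ndarray] | pd.DataFrame) -> np.ndarray:
        """Mean response: expit(eta) for binomial, eta for gaussian."""
        eta = self.linear_predictor(data)
        return expit(eta) if self.family == "binomial" else eta


@dataclass
class AssociationRow:
    """One row of a staged association table (OR or coefficient with Wald CI)."""

    predictor: str
    outcome: str
    stage: str
    estimate: float | None  # OR (binomial) or b (gaussian)
    scale: str  # 'odds_ratio' or 'coefficient'
    ci_low: float | None
    ci_high: float | None
    p_value: float | None
    n: int | None
    converged: bool = True
    annotation: str | None = None


# --------------------------------------------------------------------------- #
# fitting


def fit_glm(cohort: CohortTable, spec: ModelSpec) -> FittedModel:
    """Fit ``spec`` on the listwise-complete rows of ``cohort``.

    Binomial models are fitted by IRLS to gradient tolerance 1e-8 with the
    Wald covariance taken from the observed information; gaussian models by
    the normal equations.  Separation triggers a ridge-penalized refit with
    ``converged=False`` and an annotation.
    """
    cols = [spec.outcome, *spec.predictors]
    for c in cols:
        if c not in cohort.data.columns:
            raise DataError(f"model variable {c!r} not in cohort")
    df = cohort.data[cols].dropna()
    n = len(df)
    if n == 0:
        raise DataError("empty complete-case set for model " + spec.outcome)
    if n < len(spec.predictors) + 1:
        raise DataError(
            f"only {n} complete rows for {len(spec.predictors)} predictors in model "
            f"for {spec.outcome!r}"
        )
    y = df[spec.outcome].to_numpy(dtype=float)
    X = np.column_stack([np.ones(n)] + [df[p].to_numpy(dtype=float) for p in spec.predictors])
    names = [INTERCEPT, *spec.predictors]

    if spec.family == "gaussian":
        return _fit_gaussian(X, y, names, n)
    return _fit_binomial(X, y, names, n)


def _fit_gaussian(X: np.ndarray, y: np.ndarray, names: list[str], n: int) -> FittedModel:
    XtX = X.T @ X
    beta = np.linalg.solve(XtX, X.T @ y)
    resid = y - X @ beta
    dof = max(n - X.shape[1], 1)
    sigma2 = float(resid @ resid / dof)
    cov = sigma2 * np.linalg.inv(XtX)
    loglik = -0.5 * n * (np.log(2 * np.pi * max(sigma2, 1e-300)) + 1.0)
    return FittedModel(
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        family="gaussian",
        converged=True,
        n=n,
        loglik=loglik,
        sigma2=sigma2,
    )


def _binomial_deviance(y: np.ndarray, eta: np.ndarray, beta: np.ndarray, ridge: float) -> float:
    # -2 loglik, numerically stable via log1p(exp(.)), plus the ridge penalty term
    dev = 2.0 * float(np.sum(np.logaddexp(0.0, eta) - y * eta))
    if ridge:
        dev += ridge * float(beta[1:] @ beta[1:])
    return dev


def _irls(X: np.ndarray, y: np.ndarray, ridge: float = 0.0):
    """IRLS with step-halving; returns (beta, cov, converged, deviance path)."""
    n, p = X.shape
    beta = np.zeros(p)
    beta[0] = np.log((y.mean() + 1e-6) / (1 - y.mean() + 1e-6))
    eta = X @ beta
    dev = _binomial_deviance(y, eta, beta, ridge)
    path = [dev]
    converged = False
    penalty = np.zeros(p)
    penalty[1:] = ridge
    for _ in range(MAX_ITER):
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        grad = X.T @ (y - mu) - penalty * beta
        info = (X.T * w) @ X + np.diag(penalty)
        try:
            step = np.linalg.solve(info, grad)
        except np.linalg.LinAlgError:
            step = np.linalg.lstsq(info, grad, rcond=None)[0]
        # step-halving keeps the (penalized) deviance monotone non-increasing
        scale = 1.0
        for _half in range(40):
            cand = beta + scale * step
            cand_eta = X @ cand
            cand_dev = _binomial_deviance(y, cand_eta, cand, ridge)
            if cand_dev <= dev + 1e-12:
                break
            scale *= 0.5
        beta, eta, dev = cand, cand_eta, cand_dev
        path.append(dev)
        if np.max(np.abs(grad)) < GRAD_TOL:
            converged = True
            break
    mu = expit(eta)
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    info = (X.T * w) @ X + np.diag(penalty)
    cov = np.linalg.pinv(info)
    return beta, cov, converged, tuple(path)


def _fit_binomial(X: np.ndarray, y: np.ndarray, names: list[str], n: int) -> FittedModel:
    beta, cov, converged, path = _irls(X, y)
    separated = (not converged) or np.max(np.abs(beta)) > SEPARATION_BOUND
    annotation = None
    if separated:
        lam = RIDGE_LAMBDA * n  # penalty scales with n so its effect is O(1) on the fit
        beta, cov, _, path = _irls(X, y, ridge=lam)
        converged = False
        annotation = f"separation: ridge fallback (lambda={RIDGE_LAMBDA} per observation)"
    eta = X @ beta
    loglik = float(np.sum(y * eta - np.logaddexp(0.0, eta)))
    return FittedModel(
        params=pd.Series(beta, index=names),
        cov=pd.DataFrame(cov, index=names, columns=names),
        family="binomial",
        converged=converged,
        n=n,
        loglik=loglik,
        annotation=annotation,
        deviance_path=path,
    )


# --------------------------------------------------------------------------- #
# inference helpers


def wald_p(model: FittedModel, term: str) -> float:
    """Two-sided Wald p-value for ``term``."""
    z = model.params[term] / model.se(term)
    return float(2.0 * norm.sf(abs(z)))


def format_p(p: float) -> str:
    """p to three decimals with the '<0.001' floor used in published tables."""
    return "<0.001" if p < 0.001 else f"{p:.3f}"


def odds_ratio_ci(model: FittedModel, term: str, alpha: float = 0.05) -> dict:
    """OR = exp(b) with Wald CI exp(b +/- z * SE) and two-sided p for ``term``."""
    if term not in model.params.index:
        raise KeyError(f"term {term!r} not among fitted coefficients")
    if model.family != "binomial":
        raise DataError("odds ratios are defined for binomial models only")
    b = float(model.params[term])
    se = model.se(term)
    z = norm.ppf(1 - alpha / 2)
    return {
        "or": float(np.exp(b)),
        "ci_low": float(np.exp(b - z * se)),
        "ci_high": float(np.exp(b + z * se)),
        "p_value": wald_p(model, term),
    }


def coefficient_ci(model: FittedModel, term: str, alpha: float = 0.05) -> dict:
    """b with Wald CI and two-sided p (linear-scale analogue of :func:`odds_ratio_ci`)."""
    if term not in model.params.index:
        raise KeyError(f"term {term!r} not among fitted coefficients")
    b = float(model.params[term])
    se = model.se(term)
    z = norm.ppf(1 - alpha / 2)
    return {
        "b": b,
        "ci_low": b - z * se,
        "ci_high": b + z * se,
        "p_value": wald_p(model, term),
    }


# --------------------------------------------------------------------------- #
# staged association tables


def association_table(
    cohort: CohortTable,
    pairs: list[tuple[str, str]],
    stages: dict[str, list[str]],
) -> list[AssociationRow]:
    """One :class:`AssociationRow` per (predictor, outcome) pair per stage.

    Each row comes from a fresh :func:`fit_glm` on ``outcome ~ predictor +
    stage adjustment set``.  When the predictor is a mediator and the stage is
    adjusted (non-empty set), the exposure is added to the model, mirroring
    mediator->outcome tables that adjust for the exposure.  Fit failures are
    annotated per row; the table is still returned.
    """
    exposure_cols = cohort.with_role("exposure")
    rows: list[AssociationRow] = []
    for predictor, outcome in pairs:
        for stage_name, adjust in stages.items():
            predictors = [predictor]
            if (
                cohort.roles.get(predictor) == "mediator"
                and adjust
                and exposure_cols
                and exposure_cols[0] != predictor
            ):
                predictors += [x for x in exposure_cols if x != outcome]
            predictors += [a for a in adjust if a not in predictors and a != outcome]
            family = "binomial" if cohort.types.get(outcome) == "binary" else "gaussian"
            try:
                model = fit_glm(cohort, ModelSpec(outcome, tuple(predictors), family))
                if family == "binomial":
                    frag = odds_ratio_ci(model, predictor)
                    est, lo, hi = frag["or"], frag["ci_low"], frag["ci_high"]
                    scale = "odds_ratio"
                else:
                    frag = coefficient_ci(model, predictor)
                    est, lo, hi = frag["b"], frag["ci_low"], frag["ci_high"]
                    scale = "coefficient"
                rows.append(
                    AssociationRow(
                        predictor=predictor,
                        outcome=outcome,
                        stage=stage_name,
                        estimate=est,
                        scale=scale,
                        ci_low=lo,
                        ci_high=hi,
                        p_value=frag["p_value"],
                        n=model.n,
                        converged=model.converged,
                        annotation=model.annotation,
                    )
                )
            except GmediateError as exc:
                rows.append(
                    AssociationRow(
                        predictor=predictor,
                        outcome=outcome,
                        stage=stage_name,
                        estimate=None,
                        scale="odds_ratio" if family == "binomial" else "coefficient",
                        ci_low=None,
                        ci_high=None,
                        p_value=None,
                        n=None,
                        converged=False,
                        annotation=f"fit failed: {exc}",
                    )
                )
    return rows


def association_frame(rows: list[AssociationRow]) -> pd.DataFrame:
    """Association rows as a DataFrame with table-style p formatting."""
    recs = []
    for r in rows:
        rec = r.__dict__.copy()
        rec["p_formatted"] = format_p(r.p_value) if r.p_value is not None else ""
        recs.append(rec)
    return pd.DataFrame(recs)
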