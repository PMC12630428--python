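"""Multiple imputation by chained equations and Rubin's-rules pooling.

The imputer cycles through the incomplete columns, refitting a conditional
model for each (logistic for binary columns, linear for numeric) on the
currently completed data and redrawing the missing cells stochastically:
coefficients are perturbed by a draw from their estimated sampling
distribution, then binary cells are drawn Bernoulli(predicted probability)
and numeric cells from the linear prediction plus Gaussian noise.  Every
other column — including any outside the analysis roles — participates as a
predictor, keeping the imputation model at least as rich as the analysis
models (congeniality).

Pooling follows Rubin's rules: pooled point = mean of the per-imputation
points; total variance = within + (1 + 1/m) x between; normal-based CIs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit
from scipy.stats import norm

from .cohort import CohortTable
from .effects import MediationEstimates, effects_from_prevalences, proportion_mediated
from .exceptions import CannotImputeError, DataError, ParameterError
from .gformula import DEFAULT_B, DEFAULT_COPIES, bootstrap_effects
from .glm import _irls

DEFAULT_M = 40
DEFAULT_ITERATIONS = 10


@dataclass
class ImputationSet:
    """m completed copies of a cohort plus the settings that produced them."""

    datasets: list[CohortTable]
    families: dict[str, str]  # imputed column -> conditional-model family
    iterations: int
    seed: int

    @property
    def m(self) -> int:
        return len(self.datasets)


@dataclass
class PooledEstimate:
    """A Rubin-pooled estimate on the (log-)coefficient scale."""

    point: float
    within_variance: float
    between_variance: float
    m: int
    ci: tuple[float, float] = field(default=None)  # type: ignore[assignment]

    @property
    def total_variance(self) -> float:
        return self.within_variance + (1.0 + 1.0 / self.m) * self.between_variance

    @property
    def se(self) -> float:
        return math.sqrt(self.total_variance)

    def __post_init__(self) -> None:
        if self.ci is None:
            z = norm.ppf(0.975)
            self.ci = (self.point - z * self.se, self.point + z * self.se)


def mice_impute(
    cohort: CohortTable,
    m: int = DEFAULT_M,
    iterations: int = DEFAULT_ITERATIONS,
    seed: int = 0,
) -> ImputationSet:
    """Chained-equations imputation producing ``m`` completed cohorts.

    Missing cells are initialized by simple random draws from the observed
    values of their column, then refined by ``iterations`` full sweeps.
    Observed cells are never altered.  A 100%-missing column cannot be
    imputed and raises :class:`CannotImputeError`.
    """
    if m < 1:
        raise ParameterError("m must be >= 1")
    missing_cols = [c for c in cohort.columns if cohort.data[c].isna().any()]
    for c in missing_cols:
        if cohort.data[c].isna().all():
            raise CannotImputeError(f"column {c!r} is 100% missing")
    if not any(not cohort.data[c].isna().any() for c in cohort.columns):
        raise DataError("at least one fully observed column is required")
    families = {c: ("binomial" if cohort.types[c] == "binary" else "gaussian") for c in missing_cols}
    if not missing_cols:
        return ImputationSet([cohort.copy() for _ in range(m)], families, iterations, seed)

    predictors = {c: [o for o in cohort.columns if o != c] for c in missing_cols}
    na_masks = {c: cohort.data[c].isna().to_numpy() for c in missing_cols}
    datasets: list[CohortTable] = []
    streams = np.random.SeedSequence(seed).spawn(m)
    for ss in streams:
        rng = np.random.Generator(np.random.PCG64(ss))
        df = cohort.data.copy()
        for c in missing_cols:  # random-fill initialization from observed values
            obs = df[c].dropna().to_numpy()
            df.loc[na_masks[c], c] = rng.choice(obs, size=int(na_masks[c].sum()), replace=True)
        for _sweep in range(iterations):
            for c in missing_cols:
                mask = na_masks[c]
                X_cols = [df[p].to_numpy(dtype=float) for p in predictors[c]]
                X = np.column_stack([np.ones(len(df))] + X_cols)
                y = df[c].to_numpy(dtype=float)
                obs_rows = ~mask
                if families[c] == "binomial":
                    beta, cov, converged, _ = _irls(X[obs_rows], y[obs_rows])
                    if not converged or np.max(np.abs(beta)) > 15:
                        beta, cov, _, _ = _irls(
                            X[obs_rows], y[obs_rows], ridge=1e-4 * obs_rows.sum()
                        )
                    beta = _draw_beta(rng, beta, cov)
                    p = expit(X[mask] @ beta)
                    df.loc[mask, c] = (rng.random(mask.sum()) < p).astype(float)
                else:
                    Xo, yo = X[obs_rows], y[obs_rows]
                    XtX = Xo.T @ Xo + 1e-8 * np.eye(X.shape[1])
                    beta = np.linalg.solve(XtX, Xo.T @ yo)
                    resid = yo - Xo @ beta
                    dof = max(len(yo) - X.shape[1], 1)
                    # draw sigma^2 from its scaled inverse-chi-square posterior
                    sigma2 = float(resid @ resid) / rng.chisquare(dof)
                    cov = sigma2 * np.linalg.inv(XtX)
                    beta = _draw_beta(rng, beta, cov)
                    df.loc[mask, c] = X[mask] @ beta + math.sqrt(sigma2) * rng.standard_normal(
                        int(mask.sum())
                    )
        datasets.append(CohortTable(df, dict(cohort.roles), dict(cohort.types)))
    return ImputationSet(datasets, families, iterations, seed)


def _draw_beta(rng: np.random.Generator, beta: np.ndarray, cov: np.ndarray) -> np.ndarray:
    cov = (cov + cov.T) / 2.0
    try:
        chol = np.linalg.cholesky(cov + 1e-12 * np.eye(len(beta)))
    except np.linalg.LinAlgError:
        return beta
    return beta + chol @ rng.standard_normal(len(beta))


def pool_rubin(estimates: list[tuple[float, float]]) -> PooledEstimate:
    """Pool (point, SE) pairs by Rubin's rules with a normal reference."""
    if not estimates:
        raise ParameterError("at least one estimate is required")
    points = np.array([p for p, _ in estimates], dtype=float)
    ses = np.array([s for _, s in estimates], dtype=float)
    if not np.all(np.isfinite(points)) or not np.all(np.isfinite(ses)):
        raise ParameterError("estimates and SEs must be finite")
    m = len(points)
    point = float(points.mean())
    within = float(np.mean(ses**2))
    between = float(points.var(ddof=1)) if m > 1 else 0.0
    return PooledEstimate(point=point, within_variance=within, between_variance=between, m=m)


def pooled_mediation(
    cohort: CohortTable,
    outcome: str,
    baseline: list[str] | None = None,
    intermediate: list[str] | None = None,
    mediators: list[str] | None = None,
    m: int = DEFAULT_M,
    B: int = DEFAULT_B,
    copies: int = DEFAULT_COPIES,
    iterations: int = DEFAULT_ITERATIONS,
    seed: int = 0,
    imputation_set: ImputationSet | None = None,
) -> MediationEstimates:
    """Impute, run the bootstrapped g-formula per completed dataset, pool by Rubin.

    Within-imputation variance is the bootstrap variance of each effect; the
    pooled effects and CIs are formed on the log scale for odds ratios and
    exponentiated back.  Pass a precomputed ``imputation_set`` to share one
    imputation across several analyses.
    """
    imp = imputation_set or mice_impute(cohort, m=m, iterations=iterations, seed=seed)
    # one common estimation seed across the m datasets: imputation noise is
    # what should differ between them, and identical inputs (zero missingness)
    # then pool to exactly the single-dataset analysis
    per_dataset = [
        bootstrap_effects(
            ds, outcome, baseline, intermediate, mediators, B=B, copies=copies, seed=seed + 1000
        )
        for ds in imp.datasets
    ]
    scale = per_dataset[0].scale
    log_scale = scale == "odds_ratio"

    def pooled(effect: str) -> PooledEstimate:
        pairs = []
        for est in per_dataset:
            val = getattr(est, effect)
            se = est.metadata["bootstrap_se"][effect]
            pairs.append((math.log(val) if log_scale else val, se))
        return pool_rubin(pairs)

    p_tce, p_nde, p_nie = pooled("tce"), pooled("nde"), pooled("nie")

    def back(x: float) -> float:
        return math.exp(x) if log_scale else x

    prevs = np.array([[e.p00, e.p10, e.p11] for e in per_dataset]).mean(axis=0)
    est = MediationEstimates(
        outcome=outcome,
        scale=scale,
        p00=float(prevs[0]),
        p10=float(prevs[1]),
        p11=float(prevs[2]),
        tce=back(p_tce.point),
        nde=back(p_nde.point),
        nie=back(p_nie.point),
        tce_ci=(back(p_tce.ci[0]), back(p_tce.ci[1])),
        nde_ci=(back(p_nde.ci[0]), back(p_nde.ci[1])),
        nie_ci=(back(p_nie.ci[0]), back(p_nie.ci[1])),
        proportion_mediated=proportion_mediated(back(p_tce.point), back(p_nie.point), scale=scale),
        metadata={
            "m": imp.m,
            "B": B,
            "copies": copies,
            "seed": seed,
            "pooling": "rubin",
            "between_variance": {
                "tce": p_tce.between_variance,
                "nde": p_nde.between_variance,
                "nie": p_nie.between_variance,
            },
        },
    )
    return est


def pooled_association_rows(rows_per_dataset: list[list], log_scale: bool = True) -> list:
    """Pool matching association rows (by predictor/outcome/stage) across imputations."""
    from .glm import AssociationRow

    if not rows_per_dataset:
        return []
    pooled_rows = []
    first = rows_per_dataset[0]
    for i, row0 in enumerate(first):
        pairs = []
        for rows in rows_per_dataset:
            r = rows[i]
            if r.estimate is None:
                continue
            if log_scale and r.scale == "odds_ratio":
                point = math.log(r.estimate)
                se = (math.log(r.ci_high) - math.log(r.ci_low)) / (2 * norm.ppf(0.975))
            else:
                point = r.estimate
                se = (r.ci_high - r.ci_low) / (2 * norm.ppf(0.975))
            pairs.append((point, se))
        if not pairs:
            pooled_rows.append(row0)
            continue
        pe = pool_rubin(pairs)
        is_or = row0.scale == "odds_ratio"
        z = pe.point / pe.se if pe.se > 0 else float("inf")
        pooled_rows.append(
            AssociationRow(
                predictor=row0.predictor,
                outcome=row0.outcome,
                stage=row0.stage,
                estimate=math.exp(pe.point) if is_or else pe.point,
                scale=row0.scale,
                ci_low=math.exp(pe.ci[0]) if is_or else pe.ci[0],
                ci_high=math.exp(pe.ci[1]) if is_or else pe.ci[1],
                p_value=float(2 * norm.sf(abs(z))),
                n=row0.n,
                converged=True,
                annotation=f"pooled over {pe.m} imputations",
            )
        )
    return pooled_rows
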