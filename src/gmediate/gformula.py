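"""Parametric g-computation of natural direct and indirect effects.

The estimator fits a system of parametric models — one per intermediate
confounder L_j given (X, C, L_1..L_{j-1}), one per mediator M_k given
(X, C, L, M_1..M_{k-1}), and one for the outcome Y given (X, C, L, M) — and
standardizes over the fitting sample's baseline-confounder rows by Monte
Carlo simulation under counterfactual exposure assignments.

With intermediate confounders present, natural effects are not
nonparametrically identified; the implementation targets their randomized
interventional analogues: for scenario (x_direct, x_mediator) the mediator
block is drawn from its distribution under x_mediator marginalized over an
*independent* draw of L under x_mediator, while the outcome is evaluated at
L drawn under x_direct.  The three scenarios (0,0), (1,0), (1,1) give TCE,
NDE and NIE; since all three odds ratios come from the same three
prevalences, TCE = NDE x NIE holds exactly.

The three scenarios within one estimate share common random numbers (one
uniform stream per simulated variable), which cancels most Monte-Carlo noise
out of the effect contrasts.  Uncertainty comes from a full-procedure
bootstrap: every component model is refitted on each resample.

:func:`exact_gformula` computes the same counterfactual prevalences by exact
enumeration of the binary (L, M) block — the oracle the simulation is tested
against.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from ._enumerate import enumerate_prevalences
from .cohort import CohortTable
from .effects import MediationEstimates, effects_from_prevalences
from .exceptions import (
    DataError,
    GmediateError,
    ParameterError,
    UnsupportedConfigurationError,
)
from .glm import FittedModel, ModelSpec, fit_glm

#: Default number of Monte-Carlo replications of the confounder rows.
DEFAULT_COPIES = 100
#: Default bootstrap resamples (docs recommend >= 200 for production use).
DEFAULT_B = 50


@dataclass(frozen=True)
class Scenario:
    """A counterfactual exposure assignment.

    ``x_direct`` drives the intermediate confounders and the outcome model;
    ``x_mediator`` drives the mediator block.
    """

    x_direct: int
    x_mediator: int

    def __post_init__(self) -> None:
        if self.x_direct not in (0, 1) or self.x_mediator not in (0, 1):
            raise ParameterError("scenario exposure values must be 0 or 1")


@dataclass
class ModelSystem:
    """The fitted component models plus the standardization population."""

    exposure: str
    baseline: tuple[str, ...]
    intermediate: tuple[str, ...]
    mediators: tuple[str, ...]
    outcome: str
    outcome_family: str  # 'binomial' or 'gaussian'
    l_models: dict[str, FittedModel]
    m_models: dict[str, FittedModel]
    y_model: FittedModel
    standardization: pd.DataFrame  # baseline-confounder rows of the fitting sample
    annotations: dict[str, str] = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.standardization)


def fit_model_system(
    cohort: CohortTable,
    outcome: str,
    baseline: list[str] | None = None,
    intermediate: list[str] | None = None,
    mediators: list[str] | None = None,
) -> ModelSystem:
    """Fit every component model on the listwise-complete analysis rows.

    Adjustment sets default to the cohort's declared roles; pass explicit
    lists to run reduced tiers (e.g. ``baseline=[], intermediate=[]`` for the
    unadjusted model system).  Separated components are refitted with the
    ridge fallback and recorded in ``annotations`` — never silently.
    """
    cohort.require_analysis_roles()
    exposure = cohort.with_role("exposure")[0]
    baseline = list(cohort.with_role("baseline_confounder")) if baseline is None else list(baseline)
    intermediate = (
        list(cohort.with_role("intermediate_confounder")) if intermediate is None else list(intermediate)
    )
    mediators = list(cohort.with_role("mediator")) if mediators is None else list(mediators)
    if outcome not in cohort.data.columns:
        raise DataError(f"outcome {outcome!r} not in cohort")
    analysis_cols = [exposure, *baseline, *intermediate, *mediators, outcome]
    cc = cohort.complete_cases(analysis_cols)

    annotations: dict[str, str] = {}

    def fit(name: str, predictors: list[str], family: str) -> FittedModel:
        model = fit_glm(cc, ModelSpec(name, tuple(predictors), family))
        if model.annotation:
            annotations[name] = model.annotation
        return model

    l_models: dict[str, FittedModel] = {}
    prior: list[str] = []
    for l in intermediate:
        l_models[l] = fit(l, [exposure, *baseline, *prior], "binomial")
        prior.append(l)
    m_models: dict[str, FittedModel] = {}
    prior_m: list[str] = []
    for m in mediators:
        m_models[m] = fit(m, [exposure, *baseline, *intermediate, *prior_m], "binomial")
        prior_m.append(m)
    y_family = "binomial" if cohort.types.get(outcome) == "binary" else "gaussian"
    y_model = fit(outcome, [exposure, *baseline, *intermediate, *mediators], y_family)

    return ModelSystem(
        exposure=exposure,
        baseline=tuple(baseline),
        intermediate=tuple(intermediate),
        mediators=tuple(mediators),
        outcome=outcome,
        outcome_family=y_family,
        l_models=l_models,
        m_models=m_models,
        y_model=y_model,
        standardization=cc.data[baseline].copy() if baseline else pd.DataFrame(index=cc.data.index),
        annotations=annotations,
    )


# --------------------------------------------------------------------------- #
# Monte-Carlo simulation


def _simulate_scenarios(
    system: ModelSystem,
    scenarios: list[Scenario],
    copies: int,
    seed: int,
    max_rows_per_chunk: int = 2_000_000,
) -> dict[tuple[int, int], float]:
    """Counterfactual outcome means for each scenario, with common random numbers.

    For every copy of the standardization rows and every simulated variable a
    single uniform stream is drawn and shared across scenarios, so scenario
    contrasts are far less noisy than the individual prevalences.  The
    outcome is evaluated as its conditional mean (not drawn), which leaves
    the estimand unchanged and removes one layer of simulation noise.
    """
    if copies < 1:
        raise ParameterError("copies must be >= 1")
    n = max(system.n, 1)
    sim_vars = list(system.intermediate) + list(system.mediators)
    copies_per_chunk = max(1, min(copies, max_rows_per_chunk // n))
    totals = {(_s.x_direct, _s.x_mediator): 0.0 for _s in scenarios}
    done = 0
    chunk_idx = 0
    while done < copies:
        c = min(copies_per_chunk, copies - done)
        rows = c * n
        base = {
            col: np.tile(system.standardization[col].to_numpy(dtype=float), c)
            for col in system.baseline
        }
        # one uniform stream per simulated variable: L needs two independent
        # draws per scenario (L* for the outcome, L~ for the mediator block)
        ss = np.random.SeedSequence((seed, chunk_idx))
        children = ss.spawn(2 * len(system.intermediate) + len(system.mediators))
        uniforms = [np.random.Generator(np.random.PCG64(s)).random(rows) for s in children]
        for sc in scenarios:
            ctx_direct = dict(base)
            ctx_direct[system.exposure] = float(sc.x_direct)
            ctx_med = dict(base)
            ctx_med[system.exposure] = float(sc.x_mediator)
            ui = 0
            for l in system.intermediate:  # L* under x_direct (feeds the outcome model)
                p = system.l_models[l].predict(ctx_direct)
                ctx_direct[l] = (uniforms[ui] < p).astype(float)
                ui += 1
            for l in system.intermediate:  # independent L~ under x_mediator
                p = system.l_models[l].predict(ctx_med)
                ctx_med[l] = (uniforms[ui] < p).astype(float)
                ui += 1
            for m in system.mediators:  # mediator block under x_mediator given L~
                p = system.m_models[m].predict(ctx_med)
                drawn = (uniforms[ui] < p).astype(float)
                ctx_med[m] = drawn
                ctx_direct[m] = drawn
                ui += 1
            y = system.y_model.predict(ctx_direct)
            totals[(sc.x_direct, sc.x_mediator)] += float(np.sum(y))
        done += c
        chunk_idx += 1
    return {k: v / (copies * n) for k, v in totals.items()}


def simulate_scenario(
    system: ModelSystem, scenario: Scenario, copies: int, seed: int
) -> float:
    """Counterfactual outcome prevalence (binary Y) or mean (numeric Y) for one scenario."""
    return _simulate_scenarios(system, [scenario], copies, seed)[
        (scenario.x_direct, scenario.x_mediator)
    ]


def _effects_from_system(
    system: ModelSystem, copies: int, seed: int, metadata: dict | None = None
) -> MediationEstimates:
    scenarios = [Scenario(0, 0), Scenario(1, 0), Scenario(1, 1)]
    prev = _simulate_scenarios(system, scenarios, copies, seed)
    scale = "odds_ratio" if system.outcome_family == "binomial" else "mean_difference"
    meta = {"copies": copies, "seed": seed, "n": system.n, "mediator_order": list(system.mediators)}
    if system.annotations:
        meta["component_annotations"] = dict(system.annotations)
    if metadata:
        meta.update(metadata)
    return effects_from_prevalences(
        system.outcome, prev[(0, 0)], prev[(1, 0)], prev[(1, 1)], scale, metadata=meta
    )


def estimate_effects(
    cohort: CohortTable,
    outcome: str,
    baseline: list[str] | None = None,
    intermediate: list[str] | None = None,
    mediators: list[str] | None = None,
    copies: int = DEFAULT_COPIES,
    seed: int = 0,
) -> MediationEstimates:
    """Point estimates of TCE/NDE/NIE for ``outcome`` (no confidence intervals)."""
    system = fit_model_system(cohort, outcome, baseline, intermediate, mediators)
    return _effects_from_system(system, copies, seed)


def bootstrap_effects(
    cohort: CohortTable,
    outcome: str,
    baseline: list[str] | None = None,
    intermediate: list[str] | None = None,
    mediators: list[str] | None = None,
    B: int = DEFAULT_B,
    copies: int = DEFAULT_COPIES,
    seed: int = 0,
    strict: bool = False,
) -> MediationEstimates:
    """Full-procedure bootstrap: resample rows, refit every model, re-estimate.

    The SE of each effect is the standard deviation of its log (odds-ratio
    scale) or raw value (difference scale) across resamples; 95% CIs are
    normal-based around the full-sample point estimate, exponentiated for
    odds ratios.  Resamples that fail (separation-induced undefined odds,
    empty strata, ...) are dropped and counted; more than 20% failures is an
    error under ``strict`` and a recorded warning otherwise.
    """
    if B < 2:
        raise ParameterError("B must be >= 2")
    point = estimate_effects(cohort, outcome, baseline, intermediate, mediators, copies, seed)
    rng = np.random.default_rng(np.random.SeedSequence((seed, 0xB007)))
    log_scale = point.scale == "odds_ratio"
    draws: list[tuple[float, float, float]] = []
    n_failed = 0
    n = cohort.n
    for b in range(B):
        idx = rng.integers(0, n, size=n)
        resampled = CohortTable(
            cohort.data.iloc[idx].reset_index(drop=True), dict(cohort.roles), dict(cohort.types)
        )
        try:
            est = estimate_effects(
                resampled, outcome, baseline, intermediate, mediators, copies, seed=seed + 1 + b
            )
            if log_scale:
                draws.append((math.log(est.tce), math.log(est.nde), math.log(est.nie)))
            else:
                draws.append((est.tce, est.nde, est.nie))
        except GmediateError:
            n_failed += 1
    if not draws or n_failed > 0.2 * B:
        msg = f"{n_failed}/{B} bootstrap resamples failed"
        if strict or not draws:
            raise DataError(msg)
        point.metadata["bootstrap_warning"] = msg
    arr = np.asarray(draws)
    ses = arr.std(axis=0, ddof=1)
    z = norm.ppf(0.975)
    points = (
        (math.log(point.tce), math.log(point.nde), math.log(point.nie))
        if log_scale
        else (point.tce, point.nde, point.nie)
    )
    cis = []
    for p, se in zip(points, ses):
        lo, hi = p - z * se, p + z * se
        cis.append((math.exp(lo), math.exp(hi)) if log_scale else (lo, hi))
    point.tce_ci, point.nde_ci, point.nie_ci = cis
    point.metadata.update(
        {
            "B": B,
            "n_failed_resamples": n_failed,
            "bootstrap_se": {"tce": float(ses[0]), "nde": float(ses[1]), "nie": float(ses[2])},
        }
    )
    return point


# --------------------------------------------------------------------------- #
# exact enumeration oracle


def exact_gformula(system, scenario: Scenario, outcome: str | None = None) -> float:
    """Exact counterfactual prevalence for ``scenario`` — no simulation error.

    Accepts a fitted :class:`ModelSystem` (standardizing over its empirical
    baseline rows) or a :class:`~gmediate.dgp.DGPParameters` whose variables
    are all binary.  The intermediate-confounder and mediator blocks must be
    binary; enumeration runs over their 2^(|L|+|M|) configurations.
    """
    from .dgp import DGPParameters  # local import, no cycle at module load

    if isinstance(system, DGPParameters):
        for v in system.variables:
            if v.kind != "binary":
                raise UnsupportedConfigurationError(
                    f"exact enumeration requires all-binary variables; {v.name!r} is numeric"
                )
        if len(system.variables) > 20:
            raise UnsupportedConfigurationError("more than 20 binary variables")
        # enumerate the baseline block exactly via its joint probabilities
        return _exact_from_params(system, scenario, outcome)
    return _exact_from_system(system, [scenario])[(scenario.x_direct, scenario.x_mediator)]


def _exact_from_system(
    system: ModelSystem, scenarios: list[Scenario]
) -> dict[tuple[int, int], float]:
    def prob(name, ctx):
        model = system.l_models.get(name) or system.m_models.get(name)
        return model.predict(ctx)

    def outcome_mean(name, ctx):
        return system.y_model.predict(ctx)

    c_data = {c: system.standardization[c].to_numpy(dtype=float) for c in system.baseline}
    if not c_data:
        c_data = {"__const__": np.zeros(max(system.n, 1))}
    return enumerate_prevalences(
        prob,
        outcome_mean,
        c_data,
        system.exposure,
        list(system.intermediate),
        list(system.mediators),
        system.outcome,
        [(s.x_direct, s.x_mediator) for s in scenarios],
    )


def _exact_from_params(params, scenario: Scenario, outcome: str | None = None) -> float:
    from itertools import product

    from scipy.special import expit

    from .dgp import _linear_predictor

    # joint enumeration of the (all-binary) baseline block with weights
    baseline = params.baseline
    configs = list(product((0.0, 1.0), repeat=len(baseline)))
    c_data = {name: np.array([cfg[i] for cfg in configs]) for i, name in enumerate(baseline)}
    weights = np.ones(len(configs))
    for i, name in enumerate(baseline):
        v = params.variable(name)
        p = expit(np.broadcast_to(_linear_predictor(v, c_data), (len(configs),)))
        weights = weights * np.where(c_data[name] == 1.0, p, 1.0 - p)

    def prob(name, ctx):
        return expit(_linear_predictor(params.variable(name), ctx))

    def outcome_mean(name, ctx):
        return expit(_linear_predictor(params.variable(name), ctx))

    if outcome is None:
        outcome = params.names("outcome", "binary")[0]
    res = enumerate_prevalences(
        prob,
        outcome_mean,
        c_data,
        params.exposure,
        params.intermediate,
        params.mediators,
        outcome,
        [(scenario.x_direct, scenario.x_mediator)],
        weights=weights,
    )
    return res[(scenario.x_direct, scenario.x_mediator)]


def exact_effects(system: ModelSystem) -> MediationEstimates:
    """TCE/NDE/NIE from exact enumeration of a fitted model system."""
    prev = _exact_from_system(system, [Scenario(0, 0), Scenario(1, 0), Scenario(1, 1)])
    scale = "odds_ratio" if system.outcome_family == "binomial" else "mean_difference"
    return effects_from_prevalences(
        system.outcome,
        prev[(0, 0)],
        prev[(1, 0)],
        prev[(1, 1)],
        scale,
        is_truth=True,
        metadata={"method": "exact_enumeration"},
    )


# --------------------------------------------------------------------------- #
# sensitivity analysis: single-mediator model


def single_mediator_effects(
    cohort: CohortTable,
    primary_mediator: str,
    outcome: str,
    baseline: list[str] | None = None,
    intermediate: list[str] | None = None,
    B: int = 0,
    copies: int = DEFAULT_COPIES,
    seed: int = 0,
) -> MediationEstimates:
    """Specific indirect effect via ``primary_mediator`` alone.

    The other mediators are re-roled as intermediate confounders, appended to
    the L-block in their temporal (table) order, and the g-formula runs with a
    one-mediator block.  The input cohort's roles are not modified.
    """
    all_m = cohort.with_role("mediator")
    if primary_mediator not in all_m:
        raise ParameterError(f"{primary_mediator!r} is not a declared mediator")
    base = list(cohort.with_role("baseline_confounder")) if baseline is None else list(baseline)
    inter = (
        list(cohort.with_role("intermediate_confounder")) if intermediate is None else list(intermediate)
    )
    inter = inter + [m for m in all_m if m != primary_mediator]
    kwargs = dict(
        baseline=base, intermediate=inter, mediators=[primary_mediator], copies=copies, seed=seed
    )
    if B and B >= 2:
        est = bootstrap_effects(cohort, outcome, B=B, **kwargs)
    else:
        est = estimate_effects(cohort, outcome, **kwargs)
    est.metadata["single_mediator"] = primary_mediator
    return est
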