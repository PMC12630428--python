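"""Synthetic birth-cohort generator with known causal truth.

The generator simulates forward through a mediation DAG that mirrors the
structure assumed by the analysis: five baseline confounders C (three binary,
two standardized numeric scores), a binary exposure (high childhood conduct
problems), four binary intermediate confounders L (peer deviance, adolescent
smoking, adolescent alcohol use, peer drug use), three binary mediators M in
temporal order (police arrest -> gang membership -> school noncompletion,
each conditional on the earlier ones), two binary outcomes (hazardous alcohol
use, current illicit drug use) and two numeric outcome subscales (alcohol
consumption 0-12, alcohol problems 0-28, generated as rounded range-clipped
linear responses).

Binary variables follow logistic structural equations; numeric ones are
linear with Gaussian noise.  The default parameters are calibrated so that a
large generated cohort reproduces the marginal prevalences of the cohort the
package emulates (exposure 31%, arrest 4%, gang 2%, school noncompletion 43%,
hazardous alcohol 22%, illicit drug use 14%); every exposure->mediator,
mediator->outcome and confounding arrow carries a nonzero coefficient, so
mediation and confounding are present by construction.

Missingness is imposed separately under a MAR mechanism whose probability
depends on the exposure and baseline confounders (never on the masked value
itself) and touches only post-baseline variables, as in a birth cohort where
perinatal data are complete.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit
from scipy.stats import norm

from ._enumerate import enumerate_prevalences
from .cohort import CohortTable
from .effects import MediationEstimates, effects_from_prevalences
from .exceptions import DataError, ParameterError, StructuralSpecificationError

# --------------------------------------------------------------------------- #
# parameter containers


@dataclass(frozen=True)
class VariableDef:
    """Structural equation for one generated variable."""

    name: str
    role: str
    kind: str  # 'binary' (logit link) or 'numeric' (identity + Gaussian noise)
    parents: tuple[str, ...] = ()
    coef: tuple[tuple[str, float], ...] = ()  # parent -> structural coefficient
    intercept: float = 0.0
    noise_sd: float | None = None  # numeric only
    value_range: tuple[float, float] | None = None  # clip (and round) numeric scores

    def coef_map(self) -> dict[str, float]:
        return dict(self.coef)


@dataclass(frozen=True)
class MissingnessModel:
    """MAR cell-masking model: logit P(miss) = a_col + coef . (X, C)."""

    rate: float  # mean per-cell missingness over the maskable columns
    coef: tuple[tuple[str, float], ...]  # predictors (exposure + baseline confounders)
    maskable: tuple[str, ...]  # columns eligible for masking


@dataclass(frozen=True)
class DGPParameters:
    """Full data-generating process: variables in generation order + missingness."""

    variables: tuple[VariableDef, ...]
    missingness: MissingnessModel

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for v in self.variables:
            for p in v.parents:
                if p not in seen:
                    raise StructuralSpecificationError(
                        f"variable {v.name!r} lists parent {p!r} before it is generated"
                    )
            if set(dict(v.coef)) != set(v.parents):
                raise StructuralSpecificationError(
                    f"variable {v.name!r}: coefficient names do not match parents"
                )
            if not np.isfinite(v.intercept):
                raise StructuralSpecificationError(f"variable {v.name!r}: non-finite intercept")
            if v.kind == "numeric" and (v.noise_sd is None or v.noise_sd <= 0):
                raise StructuralSpecificationError(f"variable {v.name!r}: noise SD must be > 0")
            seen.add(v.name)

    # convenience views -------------------------------------------------- #
    def names(self, role: str | None = None, kind: str | None = None) -> list[str]:
        return [
            v.name
            for v in self.variables
            if (role is None or v.role == role) and (kind is None or v.kind == kind)
        ]

    @property
    def exposure(self) -> str:
        return self.names("exposure")[0]

    @property
    def baseline(self) -> list[str]:
        return self.names("baseline_confounder")

    @property
    def intermediate(self) -> list[str]:
        return self.names("intermediate_confounder")

    @property
    def mediators(self) -> list[str]:
        return self.names("mediator")

    def variable(self, name: str) -> VariableDef:
        for v in self.variables:
            if v.name == name:
                return v
        raise KeyError(name)

    def roles(self) -> dict[str, str]:
        return {v.name: v.role for v in self.variables}

    def types(self) -> dict[str, str]:
        return {v.name: v.kind for v in self.variables}

    # editing helpers (return new immutable parameter sets) --------------- #
    def set_coefficient(self, name: str, parent: str, value: float) -> "DGPParameters":
        new_vars = []
        for v in self.variables:
            if v.name == name:
                if parent not in v.parents:
                    raise KeyError(f"{parent!r} is not a parent of {name!r}")
                coef = tuple((p, value if p == parent else c) for p, c in v.coef)
                v = replace(v, coef=coef)
            new_vars.append(v)
        return DGPParameters(tuple(new_vars), self.missingness)

    def zero_exposure_paths(
        self, roles: tuple[str, ...] = ("intermediate_confounder", "mediator", "outcome")
    ) -> "DGPParameters":
        """Zero every coefficient on the exposure in equations of the given roles."""
        x = self.exposure
        out = self
        for v in self.variables:
            if v.role in roles and x in v.parents:
                out = out.set_coefficient(v.name, x, 0.0)
        return out

    # serialization ------------------------------------------------------- #
    def to_json(self, path: str | Path) -> None:
        obj = {
            "variables": [
                {
                    "name": v.name,
                    "role": v.role,
                    "kind": v.kind,
                    "parents": list(v.parents),
                    "coef": dict(v.coef),
                    "intercept": v.intercept,
                    "noise_sd": v.noise_sd,
                    "value_range": list(v.value_range) if v.value_range else None,
                }
                for v in self.variables
            ],
            "missingness": {
                "rate": self.missingness.rate,
                "coef": dict(self.missingness.coef),
                "maskable": list(self.missingness.maskable),
            },
        }
        Path(path).write_text(json.dumps(obj, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "DGPParameters":
        obj = json.loads(Path(path).read_text())
        variables = tuple(
            VariableDef(
                name=v["name"],
                role=v["role"],
                kind=v["kind"],
                parents=tuple(v["parents"]),
                coef=tuple((p, v["coef"][p]) for p in v["parents"]),
                intercept=v["intercept"],
                noise_sd=v["noise_sd"],
                value_range=tuple(v["value_range"]) if v["value_range"] else None,
            )
            for v in obj["variables"]
        )
        m = obj["missingness"]
        return cls(
            variables,
            MissingnessModel(m["rate"], tuple(m["coef"].items()), tuple(m["maskable"])),
        )


# --------------------------------------------------------------------------- #
# default parameters
#
# Structural coefficients are log odds ratios (binary targets) or linear
# slopes (numeric targets); intercepts of the non-root binary variables were
# solved once with `calibrate_intercepts` so the implied marginals match the
# target prevalences below, and are frozen here so `default_pelotas_params`
# is a pure constant.

TARGET_PREVALENCES = {
    "conduct_problems": 0.31,
    "peer_deviance": 0.47,
    "smoking_15": 0.06,
    "alcohol_15": 0.25,
    "peer_drug_use": 0.13,
    "police_arrest": 0.04,
    "gang_membership": 0.02,
    "school_noncompletion": 0.43,
    "hazardous_alcohol": 0.22,
    "drug_use": 0.14,
}

_ROOT_PREVALENCES = {
    "female": 0.51,
    "parental_smoking": 0.73,
    "parental_separation": 0.57,
}

# frozen output of calibrate_intercepts (n_c=200_000, seed=20250925)
_CALIBRATED_INTERCEPTS = {
    "conduct_problems": -1.0395511440372676,
    "peer_deviance": -0.2843740920670329,
    "smoking_15": -3.381155306449193,
    "alcohol_15": -1.4266632224868587,
    "peer_drug_use": -2.519677458763253,
    "police_arrest": -3.775608556890163,
    "gang_membership": -4.350776365221126,
    "school_noncompletion": -0.9162810811482275,
    "hazardous_alcohol": -1.503652969139153,
    "drug_use": -2.3170987950671007,
    "audit_consumption": 3.241033633525942,
    "audit_problems": 1.258914744584432,
}

TARGET_MEANS = {"audit_consumption": 3.2, "audit_problems": 1.8}


def _structure(intercepts: Mapping[str, float]) -> tuple[VariableDef, ...]:
    def var(name, role, kind, coef, noise_sd=None, value_range=None):
        return VariableDef(
            name=name,
            role=role,
            kind=kind,
            parents=tuple(p for p, _ in coef),
            coef=tuple(coef),
            intercept=float(intercepts.get(name, 0.0)),
            noise_sd=noise_sd,
            value_range=value_range,
        )

    B, X, L, M, Y = (
        "baseline_confounder",
        "exposure",
        "intermediate_confounder",
        "mediator",
        "outcome",
    )
    return (
        # baseline confounders (perinatal / age-11 block, always complete)
        var("female", B, "binary", []),
        var("parental_smoking", B, "binary", []),
        var("parental_separation", B, "binary", []),
        var("risk_score", B, "numeric", [], noise_sd=1.0),
        var("hyperactivity", B, "numeric", [], noise_sd=1.0),
        # exposure: high conduct problems at age 11
        var(
            "conduct_problems",
            X,
            "binary",
            [
                ("female", -0.50),
                ("parental_smoking", 0.25),
                ("parental_separation", 0.30),
                ("risk_score", 0.35),
                ("hyperactivity", 0.80),
            ],
        ),
        # intermediate confounders (ages 11-15)
        var(
            "peer_deviance",
            L,
            "binary",
            [
                ("female", -0.30),
                ("parental_smoking", 0.10),
                ("parental_separation", 0.15),
                ("risk_score", 0.20),
                ("hyperactivity", 0.20),
                ("conduct_problems", 0.50),
            ],
        ),
        var(
            "smoking_15",
            L,
            "binary",
            [
                ("female", -0.10),
                ("parental_separation", 0.20),
                ("risk_score", 0.25),
                ("hyperactivity", 0.25),
                ("conduct_problems", 0.40),
                ("peer_deviance", 0.60),
            ],
        ),
        var(
            "alcohol_15",
            L,
            "binary",
            [
                ("female", -0.20),
                ("risk_score", 0.10),
                ("hyperactivity", 0.15),
                ("conduct_problems", 0.30),
                ("peer_deviance", 0.50),
                ("smoking_15", 0.80),
            ],
        ),
        var(
            "peer_drug_use",
            L,
            "binary",
            [
                ("female", -0.15),
                ("risk_score", 0.15),
                ("hyperactivity", 0.10),
                ("conduct_problems", 0.35),
                ("peer_deviance", 0.70),
                ("smoking_15", 0.50),
                ("alcohol_15", 0.40),
            ],
        ),
        # mediators in temporal order: arrest (by 18) -> gang (18-22) -> noncompletion (by 22)
        var(
            "police_arrest",
            M,
            "binary",
            [
                ("female", -1.20),
                ("parental_smoking", 0.10),
                ("parental_separation", 0.20),
                ("risk_score", 0.30),
                ("hyperactivity", 0.30),
                ("conduct_problems", 0.55),
                ("peer_deviance", 0.50),
                ("smoking_15", 0.40),
                ("alcohol_15", 0.30),
                ("peer_drug_use", 0.40),
            ],
        ),
        var(
            "gang_membership",
            M,
            "binary",
            [
                ("female", -1.50),
                ("risk_score", 0.25),
                ("hyperactivity", 0.35),
                ("conduct_problems", 0.45),
                ("peer_deviance", 0.50),
                ("smoking_15", 0.30),
                ("alcohol_15", 0.20),
                ("peer_drug_use", 0.50),
                ("police_arrest", 1.20),
            ],
        ),
        var(
            "school_noncompletion",
            M,
            "binary",
            [
                ("female", -0.25),
                ("parental_smoking", 0.20),
                ("parental_separation", 0.25),
                ("risk_score", 0.45),
                ("hyperactivity", 0.35),
                ("conduct_problems", 0.45),
                ("peer_deviance", 0.30),
                ("smoking_15", 0.60),
                ("alcohol_15", 0.20),
                ("peer_drug_use", 0.30),
                ("police_arrest", 0.70),
                ("gang_membership", 0.60),
            ],
        ),
        # outcomes at age 22
        var(
            "hazardous_alcohol",
            Y,
            "binary",
            [
                ("female", -0.90),
                ("parental_smoking", 0.15),
                ("risk_score", 0.05),
                ("hyperactivity", 0.10),
                ("conduct_problems", 0.15),
                ("peer_deviance", 0.20),
                ("smoking_15", 0.30),
                ("alcohol_15", 0.70),
                ("peer_drug_use", 0.30),
                ("police_arrest", 0.45),
                ("gang_membership", 0.60),
                ("school_noncompletion", 0.12),
            ],
        ),
        var(
            "drug_use",
            Y,
            "binary",
            [
                ("female", -0.80),
                ("parental_separation", 0.15),
                ("risk_score", 0.10),
                ("hyperactivity", 0.10),
                ("conduct_problems", 0.10),
                ("peer_deviance", 0.30),
                ("smoking_15", 0.50),
                ("alcohol_15", 0.40),
                ("peer_drug_use", 0.90),
                ("police_arrest", 1.30),
                ("gang_membership", 1.90),
                ("school_noncompletion", 0.15),
            ],
        ),
        var(
            "audit_consumption",
            Y,
            "numeric",
            [
                ("female", -1.20),
                ("risk_score", 0.05),
                ("hyperactivity", 0.10),
                ("conduct_problems", 0.10),
                ("alcohol_15", 1.20),
                ("peer_drug_use", 0.30),
                ("police_arrest", 0.80),
                ("gang_membership", 0.80),
                ("school_noncompletion", 0.10),
            ],
            noise_sd=2.2,
            value_range=(0.0, 12.0),
        ),
        var(
            "audit_problems",
            Y,
            "numeric",
            [
                ("female", -0.90),
                ("risk_score", 0.06),
                ("hyperactivity", 0.12),
                ("conduct_problems", 0.12),
                ("alcohol_15", 0.90),
                ("peer_drug_use", 0.40),
                ("police_arrest", 0.90),
                ("gang_membership", 0.90),
                ("school_noncompletion", 0.12),
            ],
            noise_sd=2.6,
            value_range=(0.0, 28.0),
        ),
    )


_DEFAULT_MISSINGNESS = MissingnessModel(
    rate=0.06,
    coef=(
        ("conduct_problems", 0.50),
        ("female", -0.20),
        ("risk_score", 0.25),
        ("hyperactivity", 0.15),
    ),
    maskable=(
        "peer_deviance",
        "smoking_15",
        "alcohol_15",
        "peer_drug_use",
        "police_arrest",
        "gang_membership",
        "school_noncompletion",
        "hazardous_alcohol",
        "drug_use",
        "audit_consumption",
        "audit_problems",
    ),
)


def default_pelotas_params() -> DGPParameters:
    """The calibrated default data-generating process (a pure constant)."""
    intercepts = dict(_CALIBRATED_INTERCEPTS)
    for name, p in _ROOT_PREVALENCES.items():
        intercepts[name] = float(logit(p))
    return DGPParameters(_structure(intercepts), _DEFAULT_MISSINGNESS)


# --------------------------------------------------------------------------- #
# forward simulation


def _linear_predictor(v: VariableDef, ctx: Mapping[str, np.ndarray | float]) -> np.ndarray:
    eta = np.asarray(v.intercept, dtype=float)
    for parent, c in v.coef:
        eta = eta + c * np.asarray(ctx[parent], dtype=float)
    return eta


def generate_cohort(params: DGPParameters, n: int, seed: int) -> CohortTable:
    """Simulate ``n`` fully observed rows from ``params``.

    One root seed; each variable draws from its own deterministic substream,
    so identical (params, n, seed) give bitwise-identical tables.
    """
    if n < 1:
        raise ParameterError("n must be >= 1")
    streams = np.random.SeedSequence(seed).spawn(len(params.variables))
    data: dict[str, np.ndarray] = {}
    for v, ss in zip(params.variables, streams):
        rng = np.random.Generator(np.random.PCG64(ss))
        eta = np.broadcast_to(_linear_predictor(v, data), (n,))
        if v.kind == "binary":
            data[v.name] = (rng.random(n) < expit(eta)).astype(float)
        else:
            vals = eta + v.noise_sd * rng.standard_normal(n)
            if v.value_range is not None:
                vals = np.clip(np.round(vals), *v.value_range)
            data[v.name] = vals
    df = pd.DataFrame(data)
    return CohortTable(df, params.roles(), params.types())


def impose_missingness(
    cohort: CohortTable,
    params: DGPParameters,
    seed: int,
    rate: float | None = None,
) -> CohortTable:
    """Mask cells of the maskable columns under the MAR model in ``params``.

    The per-column masking intercept is solved on the cohort at hand so the
    realized expected per-cell rate equals ``rate`` exactly; the mask
    probability depends only on the exposure and baseline confounders, never
    on the masked value itself.
    """
    if cohort.n_missing() > 0:
        raise DataError("impose_missingness expects a fully observed cohort")
    miss = params.missingness
    r = miss.rate if rate is None else float(rate)
    if not 0.0 <= r < 1.0:
        raise ParameterError(f"missingness rate must be in [0, 1); got {r}")
    out = cohort.copy()
    if r == 0.0:
        return out
    score = np.zeros(cohort.n)
    for pred, c in miss.coef:
        score += c * cohort.data[pred].to_numpy(dtype=float)
    cols = [c for c in miss.maskable if c in out.data.columns]
    streams = np.random.SeedSequence(seed).spawn(len(cols))
    for col, ss in zip(cols, streams):
        a = brentq(lambda a: float(np.mean(expit(a + score))) - r, -40.0, 40.0, xtol=1e-12)
        rng = np.random.Generator(np.random.PCG64(ss))
        mask = rng.random(cohort.n) < expit(a + score)
        out.data.loc[mask, col] = np.nan
    return out


# --------------------------------------------------------------------------- #
# implied marginals and calibration (semi-exact: enumeration of the binary
# post-baseline block conditional on a sampled baseline-confounder population)


def _sample_baseline(params: DGPParameters, n_c: int, seed: int) -> dict[str, np.ndarray]:
    streams = np.random.SeedSequence(seed).spawn(len(params.baseline))
    data: dict[str, np.ndarray] = {}
    for name, ss in zip(params.baseline, streams):
        v = params.variable(name)
        rng = np.random.Generator(np.random.PCG64(ss))
        eta = np.broadcast_to(_linear_predictor(v, data), (n_c,))
        if v.kind == "binary":
            data[name] = (rng.random(n_c) < expit(eta)).astype(float)
        else:
            data[name] = eta + v.noise_sd * rng.standard_normal(n_c)
    return data


def _clipped_normal_mean(eta: np.ndarray, sd: float, lo: float, hi: float) -> np.ndarray:
    """E[clip(N(eta, sd), lo, hi)] (rounding to integers is ignored; bias is negligible)."""
    a = (lo - eta) / sd
    b = (hi - eta) / sd
    return (
        lo * norm.cdf(a)
        + hi * norm.sf(b)
        + eta * (norm.cdf(b) - norm.cdf(a))
        - sd * (norm.pdf(b) - norm.pdf(a))
    )


def _variable_mean(v: VariableDef, ctx: Mapping[str, np.ndarray | float]) -> np.ndarray:
    eta = _linear_predictor(v, ctx)
    if v.kind == "binary":
        return expit(eta)
    if v.value_range is not None:
        return _clipped_normal_mean(np.asarray(eta, dtype=float), v.noise_sd, *v.value_range)
    return np.asarray(eta, dtype=float)


def implied_marginals(
    params: DGPParameters, n_c: int = 50_000, seed: int = 20250925
) -> dict[str, float]:
    """Marginal prevalence/mean of every generated variable.

    Exact enumeration over the binary post-baseline block, averaged over a
    ``n_c``-row Monte-Carlo sample of the baseline confounders (exact when the
    baseline block is all binary is not attempted; the MC error of the
    baseline average is O(n_c^-1/2) and far below a tenth of a point at the
    default size).
    """
    c_data = _sample_baseline(params, n_c, seed)
    marginals = {
        name: float(np.mean(c_data[name])) for name in params.baseline
    }
    config_vars = [
        v for v in params.variables if v.role != "baseline_confounder" and v.kind == "binary"
    ]
    terminal = [
        v for v in params.variables if v.role != "baseline_confounder" and v.kind == "numeric"
    ]
    # baseline columns broadcast over rows as (n_c, 1); enumerated binary
    # configurations broadcast over columns as (1, K)
    values: dict[str, np.ndarray] = {k: a[:, None] for k, a in c_data.items()}
    weights = np.ones((n_c, 1))
    for v in config_vars:
        p = np.broadcast_to(_variable_mean(v, values), weights.shape)
        marginals[v.name] = float(np.mean((weights * p).sum(axis=1)))
        if v.role == "outcome":
            continue  # outcomes have no children; do not double the config space
        for name in [cv.name for cv in config_vars if cv.name in values]:
            values[name] = np.concatenate([values[name], values[name]], axis=1)
        ones = np.ones((1, weights.shape[1]))
        values[v.name] = np.concatenate([ones, 0.0 * ones], axis=1)
        weights = np.concatenate([weights * p, weights * (1.0 - p)], axis=1)
    for v in terminal:
        mu = np.broadcast_to(_variable_mean(v, values), weights.shape)
        marginals[v.name] = float(np.mean((weights * mu).sum(axis=1)))
    return marginals


def calibrate_intercepts(
    params: DGPParameters,
    targets: Mapping[str, float],
    n_c: int = 50_000,
    seed: int = 20250925,
) -> DGPParameters:
    """Solve each generated variable's intercept so its implied marginal hits ``targets``.

    Binary roots are set directly to logit(target); downstream variables are
    solved by 1-D root finding in generation order on the same semi-exact
    surface as :func:`implied_marginals`.
    """
    intercepts = {v.name: v.intercept for v in params.variables}
    for name, t in targets.items():
        v = params.variable(name)
        if v.role == "baseline_confounder" and v.kind == "binary":
            intercepts[name] = float(logit(t))

    def rebuild() -> DGPParameters:
        return DGPParameters(
            tuple(replace(v, intercept=intercepts[v.name]) for v in params.variables),
            params.missingness,
        )

    c_data = _sample_baseline(rebuild(), n_c, seed)
    values: dict[str, np.ndarray] = {k: a[:, None] for k, a in c_data.items()}
    config_names: list[str] = []
    weights = np.ones((n_c, 1))
    for v in params.variables:
        if v.role == "baseline_confounder":
            continue
        # intercept-free predictor computed once; the root-finder then only
        # shifts it, which keeps each bracketing iteration O(n_c * K)
        eta0 = np.broadcast_to(
            np.asarray(_linear_predictor(replace(v, intercept=0.0), values), dtype=float),
            weights.shape,
        )

        def mean_at(a: float) -> np.ndarray:
            if v.kind == "binary":
                return expit(eta0 + a)
            if v.value_range is not None:
                return _clipped_normal_mean(eta0 + a, v.noise_sd, *v.value_range)
            return eta0 + a

        def marginal(a: float) -> float:
            return float(np.mean((weights * mean_at(a)).sum(axis=1)))

        if v.name in targets:
            t = targets[v.name]
            intercepts[v.name] = brentq(lambda a: marginal(a) - t, -30.0, 30.0, xtol=1e-10)
        if v.kind == "binary" and v.role != "outcome":
            p = mean_at(intercepts[v.name])
            for name in config_names:
                values[name] = np.concatenate([values[name], values[name]], axis=1)
            ones = np.ones((1, weights.shape[1]))
            values[v.name] = np.concatenate([ones, 0.0 * ones], axis=1)
            config_names.append(v.name)
            weights = np.concatenate([weights * p, weights * (1.0 - p)], axis=1)
    return rebuild()


# --------------------------------------------------------------------------- #
# ground-truth mediation effects


def true_mediation_effects(
    params: DGPParameters,
    outcome: str,
    n_c: int = 150_000,
    seed: int = 20250925,
) -> MediationEstimates:
    """TCE/NDE/NIE implied by the structural equations themselves.

    The binary post-exposure block is enumerated exactly; the expectation over
    the baseline confounders uses an ``n_c``-row Monte-Carlo sample (required
    because the default baseline block contains numeric scores).  The result
    carries no confidence intervals and is flagged as truth.
    """
    v_out = params.variable(outcome)
    if v_out.role != "outcome":
        raise ParameterError(f"{outcome!r} is not an outcome variable")
    for name in params.intermediate + params.mediators:
        if params.variable(name).kind != "binary":
            raise StructuralSpecificationError(
                "enumeration requires a binary intermediate-confounder/mediator block"
            )
    c_data = _sample_baseline(params, n_c, seed)

    def prob(name: str, ctx: Mapping[str, np.ndarray | float]) -> np.ndarray:
        return np.asarray(expit(_linear_predictor(params.variable(name), ctx)))

    def outcome_mean(name: str, ctx: Mapping[str, np.ndarray | float]) -> np.ndarray:
        return np.asarray(_variable_mean(params.variable(name), ctx))

    scenarios = [(0, 0), (1, 0), (1, 1)]
    prev = enumerate_prevalences(
        prob,
        outcome_mean,
        c_data,
        params.exposure,
        params.intermediate,
        params.mediators,
        outcome,
        scenarios,
    )
    scale = "odds_ratio" if v_out.kind == "binary" else "mean_difference"
    return effects_from_prevalences(
        outcome,
        prev[(0, 0)],
        prev[(1, 0)],
        prev[(1, 1)],
        scale,
        is_truth=True,
        metadata={"method": "enumeration_over_binary_block", "n_c": n_c, "seed": seed},
    )
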