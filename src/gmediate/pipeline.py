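"""End-to-end study orchestration.

``run_study`` executes, in order: derived-variable construction
(dichotomization), a descriptive table, staged exposure->mediator and
mediator->outcome association tables, the three-mediator g-formula per
outcome across three adjustment tiers (unadjusted; baseline + intermediate
confounders; additionally comorbidity), and the sensitivity analyses
(single-mediator model, complete-case versus imputed comparison, numeric
outcome subscales).  When the cohort has missing cells the main analyses run
on multiply imputed data with Rubin pooling; otherwise directly.

All stochastic stages are seeded from one root seed, so regenerating a
report under the same configuration is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .cohort import CohortTable
from .exceptions import ConfigError, DataError, GmediateError
from .gformula import bootstrap_effects, single_mediator_effects
from .glm import association_frame, association_table
from .impute import mice_impute, pooled_association_rows, pooled_mediation

# --------------------------------------------------------------------------- #
# derived variables


def dichotomize(
    score: pd.Series, cutpoint: float, declared_range: tuple[float, float] | None = None
) -> pd.Series:
    """1 iff score >= cutpoint (the at-or-above convention); missing propagates."""
    if declared_range is not None and not (declared_range[0] <= cutpoint <= declared_range[1]):
        raise ConfigError(
            f"cutpoint {cutpoint} outside declared range {declared_range}"
        )
    out = (score >= cutpoint).astype(float)
    out[score.isna()] = np.nan
    return out


# --------------------------------------------------------------------------- #
# descriptives


def descriptive_table(cohort: CohortTable, ci_method: str = "wald") -> pd.DataFrame:
    """Per-variable % (binary) or mean (numeric) with 95% CI, ignoring missing cells.

    Wald intervals on proportions by default; Wilson behind the flag
    ``ci_method="wilson"``.  Degenerate proportions (0% or 100%) are flagged.
    """
    z = norm.ppf(0.975)
    rows = []
    for col in cohort.columns:
        obs = cohort.data[col].dropna().to_numpy(dtype=float)
        n = len(obs)
        degenerate = False
        if cohort.types[col] == "binary":
            p = float(obs.mean()) if n else float("nan")
            if ci_method == "wilson" and n:
                denom = 1 + z**2 / n
                center = (p + z**2 / (2 * n)) / denom
                half = z * np.sqrt(p * (1 - p) / n + z**2 / (4 * n**2)) / denom
                lo, hi = center - half, center + half
            else:
                se = np.sqrt(p * (1 - p) / n) if n else float("nan")
                lo, hi = p - z * se, p + z * se
            degenerate = n > 0 and (p == 0.0 or p == 1.0)
            est, lo, hi = 100 * p, 100 * lo, 100 * hi
            kind = "percent"
        else:
            est = float(obs.mean()) if n else float("nan")
            se = float(obs.std(ddof=1) / np.sqrt(n)) if n > 1 else float("nan")
            lo, hi = est - z * se, est + z * se
            kind = "mean"
        rows.append(
            {
                "variable": col,
                "role": cohort.roles[col],
                "statistic": kind,
                "n": n,
                "estimate": est,
                "ci_low": lo,
                "ci_high": hi,
                "degenerate": degenerate,
            }
        )
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------- #
# configuration


@dataclass
class StudyConfig:
    """Everything needed to run (and re-run, identically) the full study."""

    cohort_path: str | None = None
    outcomes: list[str] | None = None  # default: all binary outcome columns
    comorbidity: list[str] = field(default_factory=lambda: ["hyperactivity"])
    dichotomize: list[dict] = field(default_factory=list)  # {source, cutpoint, name, role, range}
    copies: int = 100
    bootstrap_B: int = 50
    m_imputations: int = 40
    mice_iterations: int = 10
    seed: int = 0
    run_descriptives: bool = True
    run_associations: bool = True
    run_mediation: bool = True
    run_sensitivity: bool = True
    single_mediator: str | None = "school_noncompletion"
    strict: bool = False
    output_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(
                f"unknown config keys {sorted(unknown)}; known keys are {sorted(known)}"
            )
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.copies < 1:
            raise ConfigError("copies must be >= 1")
        if self.bootstrap_B < 2:
            raise ConfigError("bootstrap_B must be >= 2")
        if self.m_imputations < 1:
            raise ConfigError("m_imputations must be >= 1")
        for d in self.dichotomize:
            for key in ("source", "cutpoint", "name"):
                if key not in d:
                    raise ConfigError(f"dichotomize entries need {key!r}: got {d}")


# --------------------------------------------------------------------------- #
# report


@dataclass
class StudyReport:
    """Structured study output; every requested section present or marked skipped."""

    sections: dict = field(default_factory=dict)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.sections, sort_keys=True, indent=1, default=_jsonify)
        if path is not None:
            Path(path).parent.mkdir(parents=True, exist_ok=True)
            Path(path).write_text(text)
        return text

    def write_tables(self, out_dir: str | Path) -> None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        if isinstance(self.sections.get("descriptives"), list):
            pd.DataFrame(self.sections["descriptives"]).to_csv(out / "table1.csv", index=False)
        assoc = self.sections.get("associations", {})
        if isinstance(assoc, dict):
            for key, fname in (
                ("exposure_mediator", "figure2.csv"),
                ("mediator_outcome", "table2.csv"),
            ):
                if isinstance(assoc.get(key), list):
                    pd.DataFrame(assoc[key]).to_csv(out / fname, index=False)
        med = self.sections.get("mediation")
        if isinstance(med, dict) and "tiers" not in med.get("skipped", ""):
            rows = []
            for outcome, tiers in med.items():
                if not isinstance(tiers, dict):
                    continue
                for tier, est in tiers.items():
                    if not isinstance(est, dict) or "tce" not in est:
                        continue
                    for eff in ("tce", "nde", "nie"):
                        ci = est.get(f"{eff}_ci") or [None, None]
                        rows.append(
                            {
                                "outcome": outcome,
                                "tier": tier,
                                "effect": eff.upper(),
                                "estimate": est[eff],
                                "ci_low": ci[0],
                                "ci_high": ci[1],
                            }
                        )
                    rows.append(
                        {
                            "outcome": outcome,
                            "tier": tier,
                            "effect": "PM",
                            "estimate": est.get("proportion_mediated"),
                            "ci_low": None,
                            "ci_high": None,
                        }
                    )
            pd.DataFrame(rows).to_csv(out / "table3.csv", index=False)


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


# --------------------------------------------------------------------------- #
# orchestration


def _tiers(cohort: CohortTable, config: StudyConfig) -> dict[str, dict[str, list[str]]]:
    baseline = cohort.with_role("baseline_confounder")
    intermediate = cohort.with_role("intermediate_confounder")
    comorbid = [c for c in config.comorbidity if c in baseline + intermediate]
    base_core = [c for c in baseline if c not in comorbid]
    inter_core = [c for c in intermediate if c not in comorbid]
    return {
        "unadjusted": {"baseline": [], "intermediate": []},
        "adjusted": {"baseline": base_core, "intermediate": inter_core},
        "adjusted_comorbidity": {"baseline": baseline, "intermediate": intermediate},
    }


def run_study(config: StudyConfig, cohort: CohortTable | None = None) -> StudyReport:
    """Execute the full study and return a structured report.

    Stage failures are recorded in the report and the pipeline continues,
    unless ``config.strict`` is set.
    """
    if cohort is None:
        if config.cohort_path is None:
            raise ConfigError("no cohort supplied and no cohort_path in config")
        cohort = CohortTable.from_csv(config.cohort_path)
    cohort = cohort.copy()
    cohort.require_analysis_roles()

    report = StudyReport()
    report.sections["metadata"] = {
        "n": cohort.n,
        "n_missing_cells": cohort.n_missing(),
        "seed": config.seed,
        "copies": config.copies,
        "bootstrap_B": config.bootstrap_B,
        "m_imputations": config.m_imputations,
    }

    def guarded(section: str, fn):
        try:
            report.sections[section] = fn()
        except GmediateError as exc:
            if config.strict:
                raise
            report.sections[section] = {"skipped": f"failed: {exc}"}

    # 1. derived variables
    applied = []
    for d in config.dichotomize:
        rng = tuple(d["range"]) if "range" in d else None
        cohort.data[d["name"]] = dichotomize(cohort.data[d["source"]], d["cutpoint"], rng)
        cohort.roles[d["name"]] = d.get("role", "outcome")
        cohort.types[d["name"]] = "binary"
        applied.append({"source": d["source"], "cutpoint": d["cutpoint"], "name": d["name"]})
    report.sections["dichotomization"] = applied

    exposure = cohort.with_role("exposure")[0]
    mediators = cohort.with_role("mediator")
    baseline = cohort.with_role("baseline_confounder")
    intermediate = cohort.with_role("intermediate_confounder")
    outcomes = config.outcomes or [
        c for c in cohort.with_role("outcome") if cohort.types[c] == "binary"
    ]
    numeric_outcomes = [c for c in cohort.with_role("outcome") if cohort.types[c] == "numeric"]
    comorbid = [c for c in config.comorbidity if c in baseline + intermediate]
    base_core = [c for c in baseline if c not in comorbid]
    inter_core = [c for c in intermediate if c not in comorbid]
    has_missing = cohort.n_missing() > 0
    tiers = _tiers(cohort, config)

    imputation = None
    if has_missing and config.m_imputations >= 1:
        imputation = mice_impute(
            cohort, m=config.m_imputations, iterations=config.mice_iterations, seed=config.seed
        )

    # 2. descriptives
    if config.run_descriptives:
        guarded("descriptives", lambda: descriptive_table(cohort).to_dict(orient="records"))
    else:
        report.sections["descriptives"] = {"skipped": "disabled in config"}

    # 3. staged associations
    if config.run_associations:

        def associations():
            xm_pairs = [(exposure, m) for m in mediators]
            xm_stages = {
                "unadjusted": [],
                "baseline": base_core,
                "baseline+comorbidity": base_core + comorbid,
            }
            my_pairs = [(m, y) for y in outcomes for m in mediators]
            my_stages = {
                "unadjusted": [],
                "adjusted": base_core + inter_core,
                "adjusted+comorbidity": baseline + intermediate,
                "adjusted+all_mediators": baseline + intermediate + mediators,
            }
            if imputation is None:
                xm_rows = association_table(cohort, xm_pairs, xm_stages)
                my_rows = association_table(cohort, my_pairs, my_stages)
            else:
                xm_rows = pooled_association_rows(
                    [association_table(ds, xm_pairs, xm_stages) for ds in imputation.datasets]
                )
                my_rows = pooled_association_rows(
                    [association_table(ds, my_pairs, my_stages) for ds in imputation.datasets]
                )
            return {
                "exposure_mediator": association_frame(xm_rows).to_dict(orient="records"),
                "mediator_outcome": association_frame(my_rows).to_dict(orient="records"),
            }

        guarded("associations", associations)
    else:
        report.sections["associations"] = {"skipped": "disabled in config"}

    # 4. mediation across tiers
    if config.run_mediation:

        def mediation():
            out = {}
            for j, outcome in enumerate(outcomes):
                out[outcome] = {}
                for k, (tier, sets) in enumerate(tiers.items()):
                    seed = config.seed + 10_000 * (j + 1) + 100 * (k + 1)
                    if imputation is None:
                        est = bootstrap_effects(
                            cohort,
                            outcome,
                            baseline=sets["baseline"],
                            intermediate=sets["intermediate"],
                            B=config.bootstrap_B,
                            copies=config.copies,
                            seed=seed,
                            strict=config.strict,
                        )
                    else:
                        est = pooled_mediation(
                            cohort,
                            outcome,
                            baseline=sets["baseline"],
                            intermediate=sets["intermediate"],
                            m=config.m_imputations,
                            B=config.bootstrap_B,
                            copies=config.copies,
                            iterations=config.mice_iterations,
                            seed=seed,
                            imputation_set=imputation,
                        )
                    out[outcome][tier] = est.to_dict()
            return out

        guarded("mediation", mediation)
    else:
        report.sections["mediation"] = {"skipped": "disabled in config"}

    # 5. sensitivity analyses
    if config.run_sensitivity:
        sens: dict = {}
        analysis_cohort = imputation.datasets[0] if imputation is not None else cohort

        if config.single_mediator and config.single_mediator in mediators:
            try:
                est = single_mediator_effects(
                    analysis_cohort,
                    config.single_mediator,
                    outcomes[0],
                    B=config.bootstrap_B,
                    copies=config.copies,
                    seed=config.seed + 77,
                )
                sens["single_mediator"] = est.to_dict()
            except GmediateError as exc:
                sens["single_mediator"] = {"skipped": f"failed: {exc}"}
        else:
            sens["single_mediator"] = {"skipped": "no single mediator configured"}

        if has_missing:
            try:
                sens["complete_case"] = complete_case_comparison(cohort, config, imputation)
            except GmediateError as exc:
                sens["complete_case"] = {"skipped": f"failed: {exc}"}
        else:
            sens["complete_case"] = {"skipped": "no missingness present"}

        numeric: dict = {}
        for j, outcome in enumerate(numeric_outcomes):
            try:
                est = bootstrap_effects(
                    analysis_cohort,
                    outcome,
                    baseline=base_core,
                    intermediate=inter_core,
                    B=config.bootstrap_B,
                    copies=config.copies,
                    seed=config.seed + 555 + j,
                )
                numeric[outcome] = est.to_dict()
            except GmediateError as exc:
                numeric[outcome] = {"skipped": f"failed: {exc}"}
        sens["numeric_outcomes"] = numeric or {"skipped": "no numeric outcomes declared"}
        report.sections["sensitivity"] = sens
    else:
        report.sections["sensitivity"] = {"skipped": "disabled in config"}

    if config.output_dir:
        report.to_json(Path(config.output_dir) / "report.json")
        report.write_tables(config.output_dir)
    return report


def complete_case_comparison(
    cohort: CohortTable, config: StudyConfig, imputation=None
) -> dict:
    """Side-by-side complete-case and pooled-imputation estimates.

    Refuses (``DataError``) when the complete-case sample is smaller than ten
    observations per parameter of the richest outcome model.
    """
    baseline = cohort.with_role("baseline_confounder")
    intermediate = cohort.with_role("intermediate_confounder")
    mediators = cohort.with_role("mediator")
    outcomes = config.outcomes or [
        c for c in cohort.with_role("outcome") if cohort.types[c] == "binary"
    ]
    analysis_cols = (
        cohort.with_role("exposure") + baseline + intermediate + mediators + outcomes
    )
    cc = cohort.complete_cases(analysis_cols)
    n_params = 2 + len(baseline) + len(intermediate) + len(mediators)
    if cc.n < 10 * n_params:
        raise DataError(
            f"complete-case n={cc.n} below 10x parameter count ({10 * n_params}); refusing"
        )
    comorbid = [c for c in config.comorbidity if c in baseline + intermediate]
    base_core = [c for c in baseline if c not in comorbid]
    inter_core = [c for c in intermediate if c not in comorbid]

    result: dict = {"complete_case_n": cc.n, "full_n": cohort.n, "outcomes": {}}
    for j, outcome in enumerate(outcomes):
        seed = config.seed + 333 + j
        cc_est = bootstrap_effects(
            cc,
            outcome,
            baseline=base_core,
            intermediate=inter_core,
            B=config.bootstrap_B,
            copies=config.copies,
            seed=seed,
        )
        if cohort.n_missing() > 0:
            imp_est = pooled_mediation(
                cohort,
                outcome,
                baseline=base_core,
                intermediate=inter_core,
                m=config.m_imputations,
                B=config.bootstrap_B,
                copies=config.copies,
                iterations=config.mice_iterations,
                seed=seed,
                imputation_set=imputation,
            )
        else:
            imp_est = cc_est
        result["outcomes"][outcome] = {
            "complete_case": cc_est.to_dict(),
            "imputed": imp_est.to_dict(),
        }
    return result
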