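"""Effect measures for counterfactual mediation.

The three counterfactual scenarios (x_direct, x_mediator) in {(0,0), (1,0),
(1,1)} yield outcome prevalences p00, p10, p11, from which

* TCE = odds(p11) / odds(p00)   (total causal effect)
* NDE = odds(p10) / odds(p00)   (natural direct effect)
* NIE = odds(p11) / odds(p10)   (natural indirect effect via the mediator block)

on the odds-ratio scale for binary outcomes; for numeric outcomes the same
contrasts are mean differences, with TCE = NDE + NIE.  Because all three
ratios are formed from the same three prevalences, TCE = NDE x NIE holds as
an algebraic identity.

The proportion mediated is ln(NIE)/ln(TCE) on the odds-ratio scale (NIE/TCE
on the difference scale) and is reported as not-applicable (None) under
inconsistent mediation or a very small total effect.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .exceptions import ParameterError, UndefinedOddsError

#: |ln TCE| below which the proportion mediated is not calculated.
PM_NULL_THRESHOLD = 0.01


@dataclass
class MediationEstimates:
    """Counterfactual prevalences, TCE/NDE/NIE, optional CIs, and metadata."""

    outcome: str
    scale: str  # 'odds_ratio' or 'mean_difference'
    p00: float
    p10: float
    p11: float
    tce: float
    nde: float
    nie: float
    tce_ci: tuple[float, float] | None = None
    nde_ci: tuple[float, float] | None = None
    nie_ci: tuple[float, float] | None = None
    proportion_mediated: float | None = None
    is_truth: bool = False
    metadata: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "outcome": self.outcome,
            "scale": self.scale,
            "p00": self.p00,
            "p10": self.p10,
            "p11": self.p11,
            "tce": self.tce,
            "nde": self.nde,
            "nie": self.nie,
            "proportion_mediated": self.proportion_mediated,
            "is_truth": self.is_truth,
            "metadata": self.metadata,
        }
        for name in ("tce_ci", "nde_ci", "nie_ci"):
            ci = getattr(self, name)
            d[name] = list(ci) if ci is not None else None
        return d


def _odds(p: float, scenario: str) -> float:
    if not 0.0 < p < 1.0:
        raise UndefinedOddsError(
            f"scenario {scenario} has outcome prevalence {p}; odds are undefined"
        )
    return p / (1.0 - p)


def effects_from_prevalences(
    outcome: str,
    p00: float,
    p10: float,
    p11: float,
    scale: str,
    is_truth: bool = False,
    metadata: dict | None = None,
) -> MediationEstimates:
    """Form TCE/NDE/NIE (and PM) from the three scenario prevalences."""
    if scale == "odds_ratio":
        o00 = _odds(p00, "(x_direct=0, x_mediator=0)")
        o10 = _odds(p10, "(x_direct=1, x_mediator=0)")
        o11 = _odds(p11, "(x_direct=1, x_mediator=1)")
        tce, nde, nie = o11 / o00, o10 / o00, o11 / o10
    elif scale == "mean_difference":
        tce, nde, nie = p11 - p00, p10 - p00, p11 - p10
    else:
        raise ParameterError(f"unknown effect scale {scale!r}")
    return MediationEstimates(
        outcome=outcome,
        scale=scale,
        p00=p00,
        p10=p10,
        p11=p11,
        tce=tce,
        nde=nde,
        nie=nie,
        proportion_mediated=proportion_mediated(tce, nie, scale=scale),
        is_truth=is_truth,
        metadata=metadata or {},
    )


def proportion_mediated(
    tce: float, nie: float, scale: str = "odds_ratio", null_threshold: float = PM_NULL_THRESHOLD
) -> float | None:
    """Share of the total effect running through the mediator block.

    Odds-ratio scale: ln(NIE)/ln(TCE).  Mean-difference scale: NIE/TCE.
    Returns None ("n/a") when the indirect and total effects point in opposite
    directions (inconsistent mediation) or the total effect is essentially
    null (|ln TCE| — or |TCE| on the difference scale — below
    ``null_threshold``).
    """
    if scale == "odds_ratio":
        if tce <= 0 or nie <= 0:
            raise ParameterError("odds ratios must be positive")
        num, den = math.log(nie), math.log(tce)
    elif scale == "mean_difference":
        num, den = nie, tce
    else:
        raise ParameterError(f"unknown effect scale {scale!r}")
    if abs(den) < null_threshold:
        return None
    if num == 0.0:
        return 0.0
    if (num > 0) != (den > 0):
        return None
    return num / den


def percent_odds_change(odds_ratio: float) -> float:
    """An OR restated as the percent change in the odds: (OR - 1) x 100."""
    if odds_ratio <= 0:
        raise ParameterError("odds ratio must be positive")
    return (odds_ratio - 1.0) * 100.0
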