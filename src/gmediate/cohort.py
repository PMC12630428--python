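"""Rectangular cohort data with per-column causal roles.

A :class:`CohortTable` is a thin wrapper around a :class:`pandas.DataFrame`
that attaches to every column a *role* in the mediation DAG (baseline
confounder, exposure, intermediate confounder, mediator, or outcome) and a
*type tag* (binary or numeric).  Missing cells are represented as NaN and are
therefore distinguishable from zero.

Cohorts round-trip to a plain CSV plus a sidecar JSON metadata file so they
can be exchanged with other tools; missing cells are written as empty fields.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import DataError

#: The five causal roles a column may take.
ROLES = (
    "baseline_confounder",
    "exposure",
    "intermediate_confounder",
    "mediator",
    "outcome",
)

TYPES = ("binary", "numeric")


@dataclass
class CohortTable:
    """Individual-level cohort data with declared column roles.

    Parameters
    ----------
    data
        One row per participant.  Binary columns contain only {0, 1, NaN}.
    roles
        Mapping column name -> role (one of :data:`ROLES`).
    types
        Mapping column name -> "binary" or "numeric".
    """

    data: pd.DataFrame
    roles: dict[str, str]
    types: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.types:
            self.types = {c: _infer_type(self.data[c]) for c in self.data.columns}
        self.validate()

    # ------------------------------------------------------------------ #
    # basic structure

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def columns(self) -> list[str]:
        return list(self.data.columns)

    def validate(self) -> None:
        """Check the container invariants; raise :class:`DataError` on violation."""
        if self.n < 1:
            raise DataError("a cohort must contain at least one row")
        for col in self.data.columns:
            if col not in self.roles:
                raise DataError(f"column {col!r} has no declared role")
            if self.roles[col] not in ROLES:
                raise DataError(f"column {col!r} has unknown role {self.roles[col]!r}")
            if self.types.get(col) not in TYPES:
                raise DataError(f"column {col!r} has unknown type {self.types.get(col)!r}")
            if self.types[col] == "binary":
                vals = self.data[col].dropna().unique()
                if not np.isin(vals, (0, 1)).all():
                    raise DataError(f"binary column {col!r} contains values outside {{0, 1}}")
        extra = set(self.roles) - set(self.data.columns)
        if extra:
            raise DataError(f"roles declared for absent columns: {sorted(extra)}")

    def require_analysis_roles(self) -> None:
        """An analysis needs at least one exposure and one outcome."""
        if not self.with_role("exposure"):
            raise DataError("no exposure column declared")
        if not self.with_role("outcome"):
            raise DataError("no outcome column declared")

    def with_role(self, role: str) -> list[str]:
        """Column names carrying ``role``, in table order."""
        return [c for c in self.data.columns if self.roles[c] == role]

    # ------------------------------------------------------------------ #
    # missingness helpers

    def n_missing(self) -> int:
        return int(self.data.isna().to_numpy().sum())

    def complete_cases(self, columns: list[str] | None = None) -> "CohortTable":
        """Rows listwise-complete on ``columns`` (default: all columns)."""
        cols = columns if columns is not None else self.columns
        mask = self.data[cols].notna().all(axis=1)
        sub = self.data.loc[mask].reset_index(drop=True)
        if len(sub) == 0:
            raise DataError("no complete cases remain")
        return CohortTable(sub, dict(self.roles), dict(self.types))

    def copy(self) -> "CohortTable":
        return CohortTable(self.data.copy(), dict(self.roles), dict(self.types))

    # ------------------------------------------------------------------ #
    # IO

    def to_csv(self, prefix: str | Path) -> tuple[Path, Path]:
        """Write ``<prefix>.csv`` and ``<prefix>.meta.json``; return both paths."""
        prefix = Path(prefix)
        prefix.parent.mkdir(parents=True, exist_ok=True)
        csv_path = prefix.with_suffix(".csv")
        meta_path = prefix.with_suffix(".meta.json")
        self.data.to_csv(csv_path, index=False, na_rep="")
        meta = {c: {"role": self.roles[c], "type": self.types[c]} for c in self.columns}
        meta_path.write_text(json.dumps(meta, indent=1))
        return csv_path, meta_path

    @classmethod
    def from_csv(cls, prefix: str | Path) -> "CohortTable":
        """Read a cohort written by :meth:`to_csv` (pass the same prefix or the CSV path)."""
        prefix = Path(prefix)
        if prefix.suffix == ".csv":
            prefix = prefix.with_suffix("")
        csv_path = prefix.with_suffix(".csv")
        meta_path = prefix.with_suffix(".meta.json")
        meta = json.loads(meta_path.read_text())
        data = pd.read_csv(csv_path)
        roles = {c: meta[c]["role"] for c in data.columns}
        types = {c: meta[c]["type"] for c in data.columns}
        return cls(data, roles, types)


def _infer_type(series: pd.Series) -> str:
    vals = series.dropna().unique()
    if len(vals) and np.isin(vals, (0, 1)).all():
        return "binary"
    return "numeric"
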