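"""Subject-by-variable cohort tables with per-variable role metadata.

A :class:`CohortTable` is the universal input of the pipeline: one row per
subject, one column per variable, and a metadata record per variable giving
its analysis *role* (cytokine, symptom, covariate, treatment, severity, or
screening), measurement *scale* (continuous, ordinal, binary), and optional
instrument tag (e.g. ``CDSS``, ``PANSS_P``) and timepoint tag.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

ROLES = ("cytokine", "symptom", "covariate", "treatment", "severity", "screening")
SCALES = ("continuous", "ordinal", "binary")

#: role -> position used for deterministic column ordering in node assembly
ROLE_ORDER = {r: i for i, r in enumerate(ROLES)}


class CohortError(ValueError):
    """Invalid cohort table or metadata."""


@dataclass
class VariableMeta:
    """Metadata for one cohort variable."""

    name: str
    role: str
    scale: str
    instrument: str = ""
    timepoint: str = ""

    def __post_init__(self) -> None:
        if self.role not in ROLES:
            raise CohortError(f"unknown role {self.role!r} for variable {self.name!r}")
        if self.scale not in SCALES:
            raise CohortError(f"unknown scale {self.scale!r} for variable {self.name!r}")


class CohortTable:
    """Subject-by-variable data matrix with variable roles.

    Parameters
    ----------
    data:
        DataFrame with one row per subject (index = subject id) and one
        column per variable.
    meta:
        One :class:`VariableMeta` per column of ``data`` (any order).
    timepoint:
        Optional tag for the whole table (e.g. ``"baseline"``).

    A treatment column, when present, must be coded 1 (placebo) / 2
    (active); 0/1 input is recoded to 1/2 with a warning.
    """

    def __init__(self, data: pd.DataFrame, meta: list[VariableMeta], timepoint: str = ""):
        if data.index.has_duplicates:
            raise CohortError("duplicate subject ids")
        if data.columns.has_duplicates:
            raise CohortError("duplicate variable names")
        by_name = {m.name: m for m in meta}
        if len(by_name) != len(meta):
            raise CohortError("duplicate variable metadata entries")
        missing = set(data.columns) - set(by_name)
        extra = set(by_name) - set(data.columns)
        if missing or extra:
            raise CohortError(
                f"metadata mismatch: missing={sorted(missing)}, extra={sorted(extra)}"
            )
        data = data.copy()
        for m in meta:
            if m.role == "treatment":
                vals = set(pd.unique(data[m.name].dropna()))
                if 0 in vals and vals <= {0, 1}:
                    warnings.warn(
                        f"treatment column {m.name!r} coded 0/1; recoding to 1/2",
                        stacklevel=2,
                    )
                    data[m.name] = data[m.name] + 1
                elif not vals <= {1, 2}:
                    raise CohortError(
                        f"treatment column {m.name!r} must be coded 1/2, got {sorted(vals)}"
                    )
        self.data = data
        self.meta = [by_name[c] for c in data.columns]
        self.timepoint = timepoint

    # -- basic introspection -------------------------------------------------

    @property
    def n_subjects(self) -> int:
        return len(self.data)

    @property
    def variables(self) -> list[str]:
        return list(self.data.columns)

    def meta_for(self, name: str) -> VariableMeta:
        for m in self.meta:
            if m.name == name:
                return m
        raise KeyError(name)

    def names_with(self, role: str | None = None, instrument: str | None = None) -> list[str]:
        """Variable names filtered by role and/or instrument, in column order."""
        out = []
        for m in self.meta:
            if role is not None and m.role != role:
                continue
            if instrument is not None and m.instrument != instrument:
                continue
            out.append(m.name)
        return out

    def matrix(self, columns: list[str] | None = None) -> np.ndarray:
        cols = columns if columns is not None else self.variables
        return self.data[cols].to_numpy(dtype=float)

    def subset(self, rows=None, columns: list[str] | None = None) -> "CohortTable":
        df = self.data
        if rows is not None:
            df = df.loc[rows]
        if columns is not None:
            df = df[columns]
        keep = set(df.columns)
        return CohortTable(df, [m for m in self.meta if m.name in keep], self.timepoint)

    # -- I/O ------------------------------------------------------------------

    def to_csv(self, path: str | Path, meta_path: str | Path | None = None) -> tuple[Path, Path]:
        """Write the data as CSV plus a role/scale sidecar CSV.

        The sidecar defaults to ``<stem>.meta.csv`` next to the data file.
        """
        path = Path(path)
        if meta_path is None:
            meta_path = path.with_name(path.stem + ".meta.csv")
        meta_path = Path(meta_path)
        self.data.to_csv(path, index_label="subject_id")
        pd.DataFrame(
            [
                {
                    "variable": m.name,
                    "role": m.role,
                    "scale": m.scale,
                    "instrument": m.instrument,
                    "timepoint": m.timepoint,
                }
                for m in self.meta
            ]
        ).to_csv(meta_path, index=False)
        return path, meta_path

    @classmethod
    def from_csv(
        cls, path: str | Path, meta_path: str | Path | None = None, timepoint: str = ""
    ) -> "CohortTable":
        path = Path(path)
        if meta_path is None:
            meta_path = path.with_name(path.stem + ".meta.csv")
        sep = "\t" if path.suffix.lower() in {".tsv", ".tab"} else ","
        df = pd.read_csv(path, sep=sep, index_col=0)
        mdf = pd.read_csv(meta_path).fillna("")
        meta = [
            VariableMeta(
                name=str(r["variable"]),
                role=str(r["role"]),
                scale=str(r["scale"]),
                instrument=str(r.get("instrument", "")),
                timepoint=str(r.get("timepoint", "")),
            )
            for _, r in mdf.iterrows()
        ]
        return cls(df, meta, timepoint=timepoint)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"CohortTable(n_subjects={self.n_subjects}, n_variables={len(self.variables)},"
            f" timepoint={self.timepoint!r})"
        )
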