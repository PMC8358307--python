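"""Subject-level parameter table: schema, container, and CSV round-trip.

The analysis operates on one row per subject with, for each session (pre-
and post-treatment), 28 variables: the 13 local-activation parameters
(ROI means), their 13 spatial Shannon entropies ``S(...)``, and the two
clinical scores (MMSE, DBD-13).  Age and a 0/1 gender indicator are carried
as covariates.  Session columns use a ``_pre`` / ``_post`` suffix, e.g.
``S(RP(Beta1))_post``.

External tables (such as a deposited study dataset) are ingested through a
column-mapping file rather than a hard-coded layout: the mapping sends
external column names to canonical ones, and any canonical column left
unmapped is reported by name.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .errors import AssemblyError, MappingError
from .spatial import sse_name

__all__ = ["PARAMETERS", "SCORES", "ANALYSIS_VARIABLES", "SESSIONS", "ParameterTable"]

PARAMETERS: tuple[str, ...] = (
    "RP(Delta)",
    "RP(Theta)",
    "RP(Alpha)",
    "RP(Beta1)",
    "RP(Beta2)",
    "RP(Gamma)",
    "MF",
    "IAF",
    "SE",
    "SEF",
    "LZC",
    "SampEn",
    "CTM",
)
SCORES: tuple[str, ...] = ("MMSE", "DBD-13")
#: the 28 variables entering every network, per session
ANALYSIS_VARIABLES: tuple[str, ...] = (
    PARAMETERS + tuple(sse_name(p) for p in PARAMETERS) + SCORES
)
SESSIONS: tuple[str, ...] = ("pre", "post")
COVARIATES: tuple[str, ...] = ("Age", "Gender")

_FLOAT_FMT = "%.12g"


def session_column(variable: str, session: str) -> str:
    return f"{variable}_{session}"


def expected_columns() -> list[str]:
    cols = ["Subject", *COVARIATES]
    for session in SESSIONS:
        cols.extend(session_column(v, session) for v in ANALYSIS_VARIABLES)
    return cols


@dataclass
class ParameterTable:
    """One row per subject; 28 analysis variables per session plus covariates."""

    df: pd.DataFrame = field(repr=False)

    def __post_init__(self) -> None:
        missing = [c for c in expected_columns() if c not in self.df.columns]
        if missing:
            raise AssemblyError(f"parameter table missing columns: {missing}")
        if self.df["Subject"].duplicated().any():
            raise AssemblyError("duplicate subject identifiers")
        numeric = [c for c in expected_columns() if c != "Subject"]
        block = self.df[numeric]
        if block.isna().any().any():
            bad = sorted(block.columns[block.isna().any()])
            raise AssemblyError(f"missing values in columns: {bad}")
        self.df = self.df[expected_columns()].reset_index(drop=True)

    # ---------------------------------------------------------------- access
    @property
    def n_subjects(self) -> int:
        return len(self.df)

    def session_values(self, session: str) -> pd.DataFrame:
        """The 28 analysis variables for one session, canonical names."""
        if session not in SESSIONS:
            raise KeyError(f"unknown session {session!r}")
        cols = {session_column(v, session): v for v in ANALYSIS_VARIABLES}
        return self.df[list(cols)].rename(columns=cols)

    def change_values(self) -> pd.DataFrame:
        """Post minus pre for every analysis variable."""
        return self.session_values("post") - self.session_values("pre")

    def covariates(self) -> pd.DataFrame:
        return self.df[list(COVARIATES)].astype(float)

    # ------------------------------------------------------------------- IO
    def to_csv(self, path: str | Path) -> None:
        self.df.to_csv(path, index=False, float_format=_FLOAT_FMT)

    @classmethod
    def from_csv(cls, path: str | Path) -> "ParameterTable":
        return cls(pd.read_csv(path))

    @classmethod
    def from_external(
        cls, path: str | Path, column_map: str | Path | dict[str, str]
    ) -> "ParameterTable":
        """Ingest an externally formatted CSV through a column mapping.

        ``column_map`` maps external column names to canonical ones and may
        be a dict or a path to a YAML/JSON key-value file.  All canonical
        columns must be covered; offenders are listed in the error.
        """
        if not isinstance(column_map, dict):
            text = Path(column_map).read_text()
            column_map = (
                json.loads(text)
                if str(column_map).endswith(".json")
                else yaml.safe_load(text)
            )
            if not isinstance(column_map, dict):
                raise MappingError("column map file must contain a key-value mapping")
        raw = pd.read_csv(path)
        unknown = [c for c in column_map if c not in raw.columns]
        if unknown:
            raise MappingError(f"mapped columns absent from external table: {unknown}")
        renamed = raw.rename(columns=column_map)
        missing = [c for c in expected_columns() if c not in renamed.columns]
        if missing:
            raise MappingError(f"external table does not provide: {missing}")
        return cls(renamed)


def assemble_parameter_table(
    records,
    summaries: dict[tuple[str, str], pd.Series],
) -> ParameterTable:
    """Join cohort records with per-subject/session feature summaries.

    ``summaries`` maps ``(subject_id, session)`` to the 26 neurophysiological
    values (13 parameter means + 13 SSEs) produced by the feature pipeline.
    """
    rows = []
    for rec in records:
        row: dict[str, object] = {
            "Subject": rec.subject_id,
            "Age": rec.age,
            "Gender": 1.0 if rec.gender == "M" else 0.0,
        }
        for session in SESSIONS:
            key = (rec.subject_id, session)
            if key not in summaries:
                raise AssemblyError(f"missing summary for subject/session {key}")
            summary = summaries[key]
            for name, value in summary.items():
                row[session_column(str(name), session)] = float(value)
            row[session_column("MMSE", session)] = float(
                rec.mmse_pre if session == "pre" else rec.mmse_post
            )
            row[session_column("DBD-13", session)] = float(
                rec.dbd_pre if session == "pre" else rec.dbd_post
            )
        rows.append(row)
    return ParameterTable(pd.DataFrame(rows))
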