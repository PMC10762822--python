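"""Claims data model: typed tables, I/O, diagnosis validation and cohorts.

The canonical in-memory containers are pandas DataFrames with stable column
names.  Visits carry ``patient_id, provider_id, specialty, year, quarter,
n_services``; diagnoses carry ``patient_id, code_group, year, quarter,
source``.  Arbitrary claims extracts are adapted through a column-name
mapping in :class:`ClaimsConfig` so no code change is needed per payer.

Cohorts are nested: a broad *psychiatric* cohort (any configured code group,
used only to quantify patient sharing between providers) contains an outcome
*subcohort* (one code group, e.g. schizophrenia) on which hospitalizations
are modelled.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pandas as pd
from pydantic import BaseModel, Field, field_validator

from .quarters import Quarter, lookback_quarters

__all__ = [
    "DEFAULT_SPECIALTIES",
    "DIAGNOSIS_SOURCES",
    "ClaimsConfig",
    "SchemaError",
    "read_visits",
    "read_diagnoses",
    "read_patients",
    "validate_diagnoses",
    "assign_cohorts",
    "lookback_quarters",
    "write_table",
    "read_table",
]

#: Default ordered provider-type registry: general practitioner,
#: psychiatrist, neurologist, neurologist/psychiatrist (a historically
#: combined discipline), psychotherapist.
DEFAULT_SPECIALTIES: tuple[str, ...] = ("GP", "PSY", "NEU", "NP", "PT")

#: Where a diagnosis was documented.  Hospital/clinic and specialist
#: diagnoses are trusted as-is; other outpatient diagnoses need
#: confirmation in two successive quarters.
DIAGNOSIS_SOURCES: tuple[str, ...] = (
    "hospital_or_clinic",
    "specialist",
    "other_outpatient",
)


class SchemaError(ValueError):
    """A required column is missing or a cell cannot be parsed."""


class ClaimsConfig(BaseModel):
    """Configuration for adapting and interpreting a claims extract."""

    specialties: tuple[str, ...] = DEFAULT_SPECIALTIES
    #: source column name -> canonical name, e.g. {"pat": "patient_id"}
    column_map: Mapping[str, str] = Field(default_factory=dict)
    #: code groups whose validated diagnoses define the psychiatric cohort
    cohort_code_groups: tuple[str, ...] = (
        "schizophrenia",
        "depression",
        "substance_abuse",
        "anxiety",
    )
    subcohort_code_group: str = "schizophrenia"
    index_year: int = 2015
    #: quarters between index quarter and first follow-up quarter
    followup_start_offset: int = 4
    n_followup_quarters: int = 8
    n_preperiod_quarters: int = 4
    #: which quarter of a confirmed two-quarter outpatient diagnosis counts
    outpatient_validated_quarter: str = "first"
    lookback_length: int = 2

    @field_validator("specialties")
    @classmethod
    def _distinct(cls, v):
        if len(set(v)) != len(v):
            raise ValueError("specialty registry labels must be distinct")
        return v

    @field_validator("outpatient_validated_quarter")
    @classmethod
    def _first_or_second(cls, v):
        if v not in ("first", "second"):
            raise ValueError("outpatient_validated_quarter must be 'first' or 'second'")
        return v


def _apply_column_map(df: pd.DataFrame, config: ClaimsConfig) -> pd.DataFrame:
    if config.column_map:
        df = df.rename(columns=dict(config.column_map))
    return df


def _require_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{what} table is missing column(s): {', '.join(missing)}")


def _read_raw(path: str | Path, fmt: Optional[str] = None) -> pd.DataFrame:
    path = Path(path)
    if fmt is None:
        fmt = "parquet" if path.suffix == ".parquet" else "csv"
    if fmt == "parquet":
        return pd.read_parquet(path)
    if fmt == "csv":
        return pd.read_csv(path)
    raise ValueError(f"unknown format {fmt!r}")


def _parse_quarter_columns(df: pd.DataFrame, what: str) -> pd.DataFrame:
    """Normalize to integer (year, quarter) columns, accepting a combined
    'quarter' string column like '2015Q2'."""
    if "year" in df.columns and "quarter" in df.columns:
        out = df.copy()
    elif "quarter" in df.columns:
        out = df.copy()
        parsed = []
        for i, v in enumerate(out["quarter"]):
            try:
                parsed.append(Quarter.parse(v))
            except ValueError as exc:
                raise SchemaError(f"{what} row {i}: {exc}") from exc
        out["year"] = [q.year for q in parsed]
        out["quarter"] = [q.q for q in parsed]
    else:
        raise SchemaError(f"{what} table is missing column(s): quarter")
    out["year"] = out["year"].astype(int)
    out["quarter"] = out["quarter"].astype(int)
    bad = ~out["quarter"].between(1, 4)
    if bad.any():
        row = int(bad.idxmax())
        raise SchemaError(
            f"{what} row {row}: quarter index {out.loc[row, 'quarter']} outside 1..4"
        )
    return out


def read_visits(path: str | Path, config: Optional[ClaimsConfig] = None,
                fmt: Optional[str] = None) -> pd.DataFrame:
    """Read and validate a long visit table.

    Returns columns ``patient_id, provider_id, specialty, year, quarter,
    n_services``.  Unknown specialties and non-positive service counts are
    rejected with errors naming the offending value.
    """
    config = config or ClaimsConfig()
    df = _apply_column_map(_read_raw(path, fmt), config)
    _require_columns(df, ["patient_id", "provider_id", "specialty"], "visit")
    df = _parse_quarter_columns(df, "visit")
    if "n_services" not in df.columns:
        df["n_services"] = 1
    df["n_services"] = df["n_services"].astype(int)
    if (df["n_services"] < 1).any():
        raise SchemaError("visit table contains n_services < 1")
    unknown = set(df["specialty"].unique()) - set(config.specialties)
    if unknown:
        raise SchemaError(
            f"visit table contains specialties outside the registry: {sorted(unknown)}"
        )
    cols = ["patient_id", "provider_id", "specialty", "year", "quarter", "n_services"]
    out = df[cols].copy()
    out["patient_id"] = out["patient_id"].astype(str)
    out["provider_id"] = out["provider_id"].astype(str)
    return out


def read_diagnoses(path: str | Path, config: Optional[ClaimsConfig] = None,
                   fmt: Optional[str] = None) -> pd.DataFrame:
    """Read a diagnosis table (columns ``patient_id, code_group, year,
    quarter, source``)."""
    config = config or ClaimsConfig()
    df = _apply_column_map(_read_raw(path, fmt), config)
    _require_columns(df, ["patient_id", "code_group", "source"], "diagnosis")
    df = _parse_quarter_columns(df, "diagnosis")
    bad = set(df["source"].unique()) - set(DIAGNOSIS_SOURCES)
    if bad:
        raise SchemaError(f"diagnosis table contains unknown source(s): {sorted(bad)}")
    out = df[["patient_id", "code_group", "year", "quarter", "source"]].copy()
    out["patient_id"] = out["patient_id"].astype(str)
    return out


def read_patients(path: str | Path, config: Optional[ClaimsConfig] = None,
                  fmt: Optional[str] = None) -> pd.DataFrame:
    """Read the patient table: ``patient_id`` plus covariate columns and the
    optional ``death_year/death_quarter`` pair."""
    config = config or ClaimsConfig()
    df = _apply_column_map(_read_raw(path, fmt), config)
    _require_columns(df, ["patient_id"], "patient")
    out = df.copy()
    out["patient_id"] = out["patient_id"].astype(str)
    return out


def validate_diagnoses(diagnoses: pd.DataFrame,
                       config: Optional[ClaimsConfig] = None) -> pd.DataFrame:
    """Filter diagnoses down to validated (patient, code group, quarter) rows.

    Hospital/clinic and specialist diagnoses are valid in their own quarter.
    Single outpatient diagnoses are of limited validity, so an
    ``other_outpatient`` diagnosis counts only when the same code group is
    documented for the same patient in two successive quarters; the validated
    quarter is by default the first of the pair (configurable).

    The operation is idempotent and deduplicates on
    ``(patient_id, code_group, year, quarter)``.
    """
    config = config or ClaimsConfig()
    cols = ["patient_id", "code_group", "year", "quarter"]
    if diagnoses.empty:
        return pd.DataFrame(columns=cols)

    trusted = diagnoses[diagnoses["source"] != "other_outpatient"][cols]

    outp = diagnoses[diagnoses["source"] == "other_outpatient"][cols].drop_duplicates()
    confirmed_rows = []
    if not outp.empty:
        idx = outp["year"] * 4 + (outp["quarter"] - 1)
        keyed = set(zip(outp["patient_id"], outp["code_group"], idx))
        pick_first = config.outpatient_validated_quarter == "first"
        for (pid, grp, i) in keyed:
            if (pid, grp, i + 1) in keyed:
                q = Quarter.from_index(i if pick_first else i + 1)
                confirmed_rows.append((pid, grp, q.year, q.q))
    confirmed = pd.DataFrame(confirmed_rows, columns=cols)

    out = pd.concat([trusted, confirmed], ignore_index=True)
    out = out.drop_duplicates().sort_values(cols).reset_index(drop=True)
    out["year"] = out["year"].astype(int)
    out["quarter"] = out["quarter"].astype(int)
    return out


def _coverage_ok(patient_row: pd.Series, window: Iterable[Quarter]) -> bool:
    cov = patient_row.get("coverage")
    if cov is None or (isinstance(cov, float) and pd.isna(cov)):
        return True  # no coverage info -> assume continuously covered
    covered = _parse_quarter_set(cov)
    return all(q in covered for q in window)


def _parse_quarter_set(value) -> set[Quarter]:
    if isinstance(value, str):
        parts = [p for p in value.replace(",", ";").split(";") if p.strip()]
        return {Quarter.parse(p) for p in parts}
    return {q if isinstance(q, Quarter) else Quarter.parse(q) for q in value}


def assign_cohorts(validated_dx: pd.DataFrame, patients: pd.DataFrame,
                   config: Optional[ClaimsConfig] = None) -> pd.DataFrame:
    """Assign patients to the psychiatric cohort and the outcome subcohort.

    Psychiatric cohort: any configured code group validated anywhere in the
    data period.  Subcohort: the subcohort code group validated in some
    quarter of the index year; the index quarter is the earliest such
    quarter.  Subcohort members must survive the observation window (index
    through end of follow-up) and have continuous coverage over it; patients
    failing either remain in the psychiatric cohort only.

    Returns one row per cohort member: ``patient_id, cohort ('psychiatric'
    or 'schizophrenia_subcohort'), index_year, index_quarter``.  Subcohort
    members appear with cohort='schizophrenia_subcohort' and are by
    construction a subset of the psychiatric cohort.
    """
    config = config or ClaimsConfig()
    if not config.cohort_code_groups:
        raise ValueError("configuration error: empty cohort code-group list")

    dx = validated_dx[validated_dx["code_group"].isin(config.cohort_code_groups)]
    psychiatric = set(dx["patient_id"].unique())

    sub_dx = dx[(dx["code_group"] == config.subcohort_code_group)
                & (dx["year"] == config.index_year)]
    pat_index = patients.set_index("patient_id") if not patients.empty else None

    rows = []
    for pid in sorted(psychiatric):
        mine = sub_dx[sub_dx["patient_id"] == pid]
        cohort = "psychiatric"
        index_q = None
        if not mine.empty:
            first = min(Quarter(int(r.year), int(r.quarter)) for r in mine.itertuples())
            fu_start = first + config.followup_start_offset
            fu_end = fu_start + (config.n_followup_quarters - 1)
            ok = True
            if pat_index is not None and pid in pat_index.index:
                prow = pat_index.loc[pid]
                dy, dq = prow.get("death_year"), prow.get("death_quarter")
                if dy is not None and not pd.isna(dy):
                    death = Quarter(int(dy), int(dq))
                    if first <= death <= fu_end:
                        ok = False
                if ok and not _coverage_ok(prow, first.range_to(fu_end)):
                    ok = False
            if ok:
                cohort = "schizophrenia_subcohort"
                index_q = first
        rows.append({
            "patient_id": pid,
            "cohort": cohort,
            "index_year": index_q.year if index_q else pd.NA,
            "index_quarter": index_q.q if index_q else pd.NA,
        })
    return pd.DataFrame(rows, columns=["patient_id", "cohort", "index_year", "index_quarter"])


def followup_quarters(index_quarter: Quarter,
                      config: Optional[ClaimsConfig] = None) -> tuple[Quarter, ...]:
    """The ordered follow-up quarters implied by an index quarter."""
    config = config or ClaimsConfig()
    start = index_quarter + config.followup_start_offset
    return tuple(start + k for k in range(config.n_followup_quarters))


def preperiod_quarters(index_quarter: Quarter,
                       config: Optional[ClaimsConfig] = None) -> tuple[Quarter, ...]:
    """The quarters immediately preceding the index quarter (covariate window)."""
    config = config or ClaimsConfig()
    return tuple(index_quarter - k for k in range(config.n_preperiod_quarters, 0, -1))


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Round-trippable table output; format chosen by extension."""
    path = Path(path)
    if path.suffix == ".parquet":
        df.to_parquet(path, index=False)
    else:
        df.to_csv(path, index=False)


def read_table(path: str | Path) -> pd.DataFrame:
    return _read_raw(path)
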