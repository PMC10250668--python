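"""CSV/JSON readers and writers for cohort, diary and pollen tables.

Schemas (all dates ISO-8601):

* cohort CSV — one row per patient: ``patient_id, age, sex, npt_positive,
  total_ige, spt_<allergen>..., sige_<analyte>..., vas_severity_retro,
  vas_drug_efficacy``
* diary CSV — long format: ``patient_id, date, rtss, csms, vas,
  medication_taken``
* pollen CSV — ``date, grains_m3``

Loaders validate ranges and report offending rows by number so that a
malformed input fails loudly, not three stages later.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .synthetic import PatientRecord

COHORT_BASE_COLUMNS = [
    "patient_id",
    "age",
    "sex",
    "npt_positive",
    "total_ige",
    "vas_severity_retro",
    "vas_drug_efficacy",
]
DIARY_COLUMNS = ["patient_id", "date", "rtss", "csms", "vas", "medication_taken"]


class SchemaError(ValueError):
    """An input table violates its documented schema."""


def cohort_to_frame(cohort: list[PatientRecord]) -> pd.DataFrame:
    """Flatten PatientRecord objects into the cohort CSV column layout."""
    rows = []
    for p in cohort:
        row = {
            "patient_id": p.patient_id,
            "age": p.age,
            "sex": p.sex,
            "npt_positive": p.npt_positive,
            "total_ige": p.total_ige,
        }
        row.update({f"spt_{k}": v for k, v in p.spt_wheal.items()})
        row.update({f"sige_{k}": v for k, v in p.specific_ige.items()})
        row["vas_severity_retro"] = p.vas_severity_retro
        row["vas_drug_efficacy"] = p.vas_drug_efficacy
        rows.append(row)
    return pd.DataFrame(rows)


def write_cohort_csv(cohort, path) -> None:
    df = cohort if isinstance(cohort, pd.DataFrame) else cohort_to_frame(cohort)
    df.to_csv(path, index=False)


def read_cohort_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_BASE_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"cohort CSV missing required columns: {missing}")
    if df["patient_id"].duplicated().any():
        dup = df.loc[df["patient_id"].duplicated(), "patient_id"].iloc[0]
        raise SchemaError(f"duplicate patient_id {dup!r} in cohort CSV")
    ige_cols = ["total_ige"] + [c for c in df.columns if c.startswith("sige_")]
    for col in ige_cols:
        vals = pd.to_numeric(df[col], errors="coerce")
        if vals.isna().any():
            row = int(df.index[vals.isna()][0]) + 2  # 1-based incl. header
            raise SchemaError(f"non-numeric value in column '{col}' at CSV row {row}")
        if (vals < 0).any():
            row = int(df.index[vals < 0][0]) + 2
            raise SchemaError(f"negative IgE in column '{col}' at CSV row {row}")
        df[col] = vals
    for col in ("vas_severity_retro", "vas_drug_efficacy"):
        bad = ~df[col].between(0, 10)
        if bad.any():
            row = int(df.index[bad][0]) + 2
            raise SchemaError(f"VAS outside [0, 10] in column '{col}' at CSV row {row}")
    if not set(df["npt_positive"].unique()) <= {0, 1}:
        raise SchemaError("npt_positive must be 0/1")
    return df


def write_diary_csv(diary: pd.DataFrame, path) -> None:
    out = diary.copy()
    out["date"] = pd.DatetimeIndex(out["date"]).strftime("%Y-%m-%d")
    out.to_csv(path, index=False)


def read_diary_csv(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in DIARY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"diary CSV missing required columns: {missing}")
    df["date"] = pd.to_datetime(df["date"], format="%Y-%m-%d")
    dup = df.duplicated(subset=["patient_id", "date"])
    if dup.any():
        pid = df.loc[dup, "patient_id"].iloc[0]
        day = df.loc[dup, "date"].iloc[0].date()
        raise SchemaError(f"duplicate diary row for patient {pid!r} on {day}")
    for col, (lo, hi) in {"rtss": (0, 18), "csms": (0, 6), "vas": (0, 10)}.items():
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = vals.notna() & ~vals.between(lo, hi)
        if bad.any():
            row = int(df.index[bad][0]) + 2
            raise SchemaError(f"{col} outside [{lo}, {hi}] at CSV row {row}")
        df[col] = vals
    return df


def write_pollen_csv(series: pd.Series, path) -> None:
    out = pd.DataFrame(
        {"date": pd.DatetimeIndex(series.index).strftime("%Y-%m-%d"), "grains_m3": series.values}
    )
    out.to_csv(path, index=False)


def read_pollen_csv(path) -> pd.Series:
    df = pd.read_csv(path)
    for col in ("date", "grains_m3"):
        if col not in df.columns:
            raise SchemaError(f"pollen CSV missing column '{col}'")
    vals = pd.to_numeric(df["grains_m3"], errors="coerce")
    if vals.isna().any():
        row = int(df.index[vals.isna()][0]) + 2
        raise SchemaError(f"non-numeric pollen concentration at CSV row {row}")
    if (vals < 0).any():
        row = int(df.index[vals < 0][0]) + 2
        raise SchemaError(f"negative pollen concentration at CSV row {row}")
    series = pd.Series(vals.to_numpy(), index=pd.DatetimeIndex(pd.to_datetime(df["date"])))
    series.name = "grains_m3"
    return series


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True, default=str) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())
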