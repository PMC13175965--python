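"""Readers and writers for FAERS-format quarterly ASCII tables.

FAERS distributes each quarter as a set of "$"-delimited text files with one
header line (DEMO, DRUG, REAC, OUTC, THER, ...).  This module loads them into
plain-string :class:`pandas.DataFrame` collections so that a write/read
round-trip is bit-for-bit, and keeps a per-table load report of how many rows
were parsed versus dropped.

Dates in FAERS are digit strings of 8 (YYYYMMDD), 6 (YYYYMM) or 4 (YYYY)
characters; partial dates are retained and their precision is recoverable via
:func:`date_precision`.  Day-level arithmetic treats anything below day
precision as missing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "FaersFormatError",
    "RawRecordSet",
    "read_quarter",
    "read_deletion_list",
    "write_tables",
    "date_precision",
    "date_to_timestamp",
    "age_to_years",
    "TABLE_SCHEMAS",
]


class FaersFormatError(ValueError):
    """A mandatory column is missing or a table is structurally unreadable."""


#: mandatory and optional columns per FAERS table (lower-cased header names).
TABLE_SCHEMAS: dict[str, dict[str, list[str]]] = {
    "demo": {
        "mandatory": ["primaryid", "caseid", "fda_dt"],
        "optional": [
            "event_dt",
            "age",
            "age_cod",
            "sex",
            "occp_cod",
            "reporter_country",
            "rept_cod",
        ],
    },
    "drug": {
        "mandatory": ["primaryid", "drug_seq", "role_cod", "drugname"],
        "optional": [],
    },
    "reac": {"mandatory": ["primaryid", "pt"], "optional": []},
    "outc": {"mandatory": ["primaryid", "outc_cod"], "optional": []},
    "ther": {
        "mandatory": ["primaryid", "dsg_drug_seq", "start_dt"],
        "optional": [],
    },
}

#: FAERS age-unit codes -> factor converting the stated age to years.
#: HR (hours) is below the resolution of any analysis here and maps to NaN.
AGE_UNIT_TO_YEARS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.0,
    "DY": 1.0 / 365.25,
    "HR": np.nan,
}


@dataclass
class RawRecordSet:
    """The five FAERS tables of one extract, as string DataFrames.

    All cells are kept exactly as read (empty string -> missing) so that
    writing and re-reading reproduces every field.  ``load_report`` maps each
    table name to ``{"data_lines": ..., "parsed": ..., "dropped": ...}``.
    """

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    outc: pd.DataFrame
    ther: pd.DataFrame
    load_report: dict = field(default_factory=dict)

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "demo": self.demo,
            "drug": self.drug,
            "reac": self.reac,
            "outc": self.outc,
            "ther": self.ther,
        }


def _empty_table(name: str) -> pd.DataFrame:
    cols = TABLE_SCHEMAS[name]["mandatory"] + TABLE_SCHEMAS[name]["optional"]
    return pd.DataFrame({c: pd.Series(dtype=object) for c in cols})


def date_precision(values) -> pd.Series:
    """Precision of FAERS date strings: 'day', 'month', 'year' or NA.

    A value is day-precise iff it is 8 digits, month-precise iff 6, year iff 4;
    anything else (including empty) has no usable precision.
    """
    s = pd.Series(values, dtype=object).astype("string")
    digits = s.str.fullmatch(r"\d+").fillna(False)
    n = s.str.len()
    out = pd.Series(pd.NA, index=s.index, dtype="string")
    out[digits & (n == 8)] = "day"
    out[digits & (n == 6)] = "month"
    out[digits & (n == 4)] = "year"
    return out


def date_to_timestamp(values, required_precision: str = "day") -> pd.Series:
    """Parse FAERS date strings to Timestamps, NaT below the required precision.

    With ``required_precision='day'`` only 8-digit dates parse; with 'month',
    6- and 8-digit dates parse to the first day of month / the exact day.
    """
    s = pd.Series(values, dtype=object).astype("string")
    prec = date_precision(s)
    ok_levels = {"day": ["day"], "month": ["day", "month"], "year": ["day", "month", "year"]}[
        required_precision
    ]
    padded = s.copy()
    if "month" in ok_levels:
        padded[prec == "month"] = s[prec == "month"] + "01"
    if "year" in ok_levels:
        padded[prec == "year"] = s[prec == "year"] + "0101"
    padded[~prec.isin(ok_levels)] = pd.NA
    return pd.to_datetime(padded, format="%Y%m%d", errors="coerce")


def age_to_years(age, age_cod) -> pd.Series:
    """Normalise FAERS (age, age-unit-code) pairs to years.

    A missing unit code with a numeric age is taken as years (the FAERS
    default); unknown codes and hour-coded ages become missing.
    """
    a = pd.to_numeric(pd.Series(age, dtype=object), errors="coerce")
    cod = pd.Series(age_cod, dtype=object).astype("string").str.strip().str.upper()
    factor = cod.map(AGE_UNIT_TO_YEARS)
    factor[cod.isna() | (cod == "")] = 1.0
    return (a * pd.to_numeric(factor, errors="coerce")).astype(float)


def _read_table(
    name: str, path: Path, delimiter: str, header: bool
) -> tuple[pd.DataFrame, dict]:
    dropped = {"bad_lines": 0}

    def _on_bad(line):  # too many fields (embedded delimiter): drop + count
        dropped["bad_lines"] += 1
        return None

    try:
        df = pd.read_csv(
            path,
            sep=delimiter,
            dtype=str,
            header=0 if header else None,
            keep_default_na=False,
            na_values=[""],
            engine="python",
            on_bad_lines=_on_bad,
            quoting=3,  # csv.QUOTE_NONE — FAERS has no quoting convention
        )
    except pd.errors.EmptyDataError:
        return _empty_table(name), {"data_lines": 0, "parsed": 0, "dropped": 0}
    df.columns = [str(c).strip().lower() for c in df.columns]
    schema = TABLE_SCHEMAS[name]
    missing = [c for c in schema["mandatory"] if c not in df.columns]
    if missing:
        raise FaersFormatError(
            f"table {name!r} ({path}): missing mandatory column(s) {missing}"
        )
    for c in schema["optional"]:
        if c not in df.columns:
            df[c] = pd.Series(pd.NA, index=df.index, dtype=object)
    n_in = len(df) + dropped["bad_lines"]

    # drop rows whose primaryid is not a non-empty digit string
    pid = df["primaryid"].astype("string")
    ok = pid.str.fullmatch(r"\d+").fillna(False)
    if name == "demo":
        # fda_dt is mandatory per record: a demo row without a parseable
        # report date cannot participate in deduplication
        ok &= date_precision(df["fda_dt"]).notna()
    df = df[ok].reset_index(drop=True)
    report = {
        "data_lines": int(n_in),
        "parsed": int(len(df)),
        "dropped": int(n_in - len(df)),
    }
    df = df.astype(object).where(pd.notna(df), pd.NA)
    return df, report


def read_quarter(
    paths: Mapping[str, str | Path],
    delimiter: str = "$",
    header: bool = True,
) -> RawRecordSet:
    """Read one quarter's DEMO/DRUG/REAC/OUTC/THER files into a RawRecordSet.

    Parameters
    ----------
    paths
        Mapping from table name (``demo``, ``drug``, ``reac``, ``outc``,
        optionally ``ther``) to file path.  Missing tables yield empty frames.
    delimiter, header
        FAERS dialect: "$"-separated with one header line.

    Rows with an unparseable ``primaryid`` (or, for DEMO, an unparseable
    ``fda_dt``) are dropped and counted in the load report, as are rows split
    by an embedded delimiter.  Child-table rows whose primaryid has no DEMO
    row are dropped and counted under ``orphans``.
    """
    tables: dict[str, pd.DataFrame] = {}
    report: dict[str, dict] = {}
    for name in TABLE_SCHEMAS:
        if name in paths:
            tables[name], report[name] = _read_table(
                name, Path(paths[name]), delimiter, header
            )
        else:
            tables[name] = _empty_table(name)
            report[name] = {"data_lines": 0, "parsed": 0, "dropped": 0}
    known = set(tables["demo"]["primaryid"].astype(str))
    for name in ("drug", "reac", "outc", "ther"):
        df = tables[name]
        keep = df["primaryid"].astype(str).isin(known)
        report[name]["orphans"] = int((~keep).sum())
        tables[name] = df[keep].reset_index(drop=True)
    return RawRecordSet(load_report=report, **tables)


def read_deletion_list(path: str | Path) -> set[str]:
    """Read an FDA deleted-case list: one CASEID per line, blanks ignored."""
    out: set[str] = set()
    with open(path) as fh:
        for line in fh:
            caseid = line.strip()
            if caseid:
                out.add(caseid)
    return out


def _write_faers_table(df: pd.DataFrame, path: Path, delimiter: str) -> None:
    df = df.astype(object).where(pd.notna(df), "")
    with open(path, "w", newline="") as fh:
        fh.write(delimiter.join(df.columns) + "\n")
        for row in df.itertuples(index=False):
            fh.write(delimiter.join(str(v) for v in row) + "\n")


def write_tables(
    obj,
    path: str | Path,
    format: str = "csv",
    delimiter: str = "$",
) -> list[str]:
    """Write a RawRecordSet or a result DataFrame; return the files written.

    A :class:`RawRecordSet` is written one file per table — in ``csv`` format
    using the FAERS "$" dialect so that :func:`read_quarter` round-trips it,
    or as JSON records.  A plain DataFrame goes to a single RFC-4180 CSV or a
    JSON records file at ``path``.
    """
    if format not in ("csv", "json"):
        raise ValueError(f"unknown format {format!r}; expected 'csv' or 'json'")
    path = Path(path)
    written: list[str] = []
    if isinstance(obj, RawRecordSet):
        path.mkdir(parents=True, exist_ok=True)
        for name, df in obj.tables().items():
            if format == "csv":
                fp = path / f"{name.upper()}.txt"
                _write_faers_table(df, fp, delimiter)
            else:
                fp = path / f"{name}.json"
                records = df.astype(object).where(pd.notna(df), None)
                fp.write_text(json.dumps(records.to_dict(orient="records")))
            written.append(str(fp))
        return written
    if isinstance(obj, pd.DataFrame):
        path.parent.mkdir(parents=True, exist_ok=True)
        if format == "csv":
            obj.to_csv(path, index=False)
        else:
            records = obj.astype(object).where(pd.notna(obj), None)
            path.write_text(json.dumps(records.to_dict(orient="records")))
        return [str(path)]
    raise TypeError(f"cannot write object of type {type(obj).__name__}")
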