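"""Reading and writing the FAERS quarterly ASCII dialect and lookup CSVs.

FAERS quarterly extracts are ``$``-delimited text files with a single header
line and no quoting. Each quarter ships one file per table (DEMO, DRUG, REAC,
THER, OUTC, INDI), all keyed by PRIMARYID (one row per report version) and
CASEID (one row per case). This module parses those files into pandas
DataFrames with a fixed column schema per table kind, validates dates, and
round-trips records back to disk.

Dates in FAERS are integers: full dates are 8-digit YYYYMMDD; partial dates
(YYYYMM, YYYY) occur and are retained for year-level summaries but are never
used for day-resolution arithmetic.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TABLE_KINDS",
    "TABLE_COLUMNS",
    "FaersFormatError",
    "FieldContentError",
    "LookupTables",
    "RawReportTables",
    "read_table",
    "write_table",
    "read_lookups",
    "parse_date_column",
    "to_datetime_full",
]

DELIMITER = "$"

#: Canonical column order per table kind. Extra columns found in a file are
#: preserved after these, in file order.
TABLE_COLUMNS: dict[str, list[str]] = {
    "DEMO": [
        "primaryid",
        "caseid",
        "fda_dt",
        "event_dt",
        "sex",
        "age",
        "age_cod",
        "reporter_country",
        "occp_cod",
    ],
    "DRUG": ["primaryid", "caseid", "drug_seq", "role_cod", "drugname", "prod_ai"],
    "REAC": ["primaryid", "caseid", "pt"],
    "THER": ["primaryid", "caseid", "dsg_drug_seq", "start_dt", "end_dt"],
    "OUTC": ["primaryid", "caseid", "outc_cod"],
    "INDI": ["primaryid", "caseid", "indi_drug_seq", "indi_pt"],
}

TABLE_KINDS = tuple(TABLE_COLUMNS)

#: Date-valued columns per kind. fda_dt must be a full valid calendar date;
#: the others admit partial (YYYYMM / YYYY) precision.
_DATE_COLUMNS: dict[str, dict[str, bool]] = {
    "DEMO": {"fda_dt": False, "event_dt": True},
    "THER": {"start_dt": True, "end_dt": True},
}

ROLE_CODES = ("PS", "SS", "C", "I")
OUTCOME_CODES = ("DE", "LT", "HO", "DS", "CA", "RI", "OT")


class FaersFormatError(ValueError):
    """A table file does not conform to the FAERS ASCII dialect."""


class FieldContentError(ValueError):
    """A field value cannot be represented in the dialect (delimiter collision)."""


@dataclasses.dataclass
class RawReportTables:
    """The six linked FAERS-style tables for one dataset.

    Every PRIMARYID appearing in drug/reac/ther/outc/indi must appear in demo
    (linkage closure); one report version spans one DEMO row and one or more
    DRUG/REAC rows.
    """

    demo: pd.DataFrame
    drug: pd.DataFrame
    reac: pd.DataFrame
    ther: pd.DataFrame
    outc: pd.DataFrame
    indi: pd.DataFrame

    def __iter__(self):
        return iter(
            (("DEMO", self.demo), ("DRUG", self.drug), ("REAC", self.reac),
             ("THER", self.ther), ("OUTC", self.outc), ("INDI", self.indi))
        )

    def copy(self) -> "RawReportTables":
        return RawReportTables(**{k.lower(): v.copy() for k, v in self})

    def write(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for kind, frame in self:
            write_table(frame, directory / f"{kind}.txt", kind)

    @classmethod
    def read(cls, directory: str | Path) -> "RawReportTables":
        directory = Path(directory)
        return cls(**{
            kind.lower(): read_table(directory / f"{kind}.txt", kind)
            for kind in TABLE_KINDS
        })


@dataclasses.dataclass
class LookupTables:
    """User-supplied reference lists consumed by the cleaning stage.

    pt_to_soc maps casefolded MedDRA Preferred Terms to their System Organ
    Class; ime_list / label_list are casefolded PT sets (important medical
    events, and events on the target drug's label); synonyms are the
    normalized (uppercased) trade and generic names of the target drug.
    """

    pt_to_soc: dict[str, str]
    ime_list: set[str]
    label_list: set[str]
    synonyms: set[str]


def _normalize_pt(term: str) -> str:
    return str(term).strip().casefold()


def parse_date_column(values: pd.Series, allow_partial: bool) -> tuple[pd.Series, int]:
    """Validate a FAERS integer-date column.

    Returns (cleaned string series, number of warnings). Full 8-digit values
    must be valid calendar dates; 6/4-digit values are kept verbatim when
    ``allow_partial``. Anything else becomes missing and counts one warning.
    """
    s = values.astype("string").str.strip()
    s = s.mask(s.isin(["", "nan", "<NA>"]))
    out = pd.Series(pd.NA, index=s.index, dtype="string")
    present = s.notna()
    digits = s.where(present).str.fullmatch(r"\d{4}|\d{6}|\d{8}").fillna(False)
    full = present & digits & (s.str.len() == 8)
    if full.any():
        parsed = pd.to_datetime(s[full], format="%Y%m%d", errors="coerce")
        out.loc[full & ~parsed.reindex(s.index).isna()] = s
    if allow_partial:
        partial = present & digits & (s.str.len() < 8)
        out.loc[partial] = s
    warnings = int((present & out.isna()).sum())
    return out, warnings


def to_datetime_full(values: pd.Series) -> pd.Series:
    """Day-resolution datetimes: valid 8-digit dates parse, all else is NaT."""
    s = values.astype("string").str.strip()
    s = s.where(s.str.fullmatch(r"\d{8}").fillna(False))
    return pd.to_datetime(s, format="%Y%m%d", errors="coerce")


def read_table(path: str | Path, kind: str) -> pd.DataFrame:
    """Read one FAERS-style ``$``-delimited table into a DataFrame.

    Header matching is case-insensitive. Required columns missing from the
    header raise :class:`FaersFormatError`; unknown extra columns are
    preserved. Unparseable dates become missing and are tallied in
    ``df.attrs["n_warnings"]``.
    """
    kind = kind.upper()
    if kind not in TABLE_COLUMNS:
        raise ValueError(f"unknown table kind {kind!r}")
    df = pd.read_csv(
        path, sep=DELIMITER, dtype="string", keep_default_na=False, engine="python"
    )
    df.columns = [c.strip().lower() for c in df.columns]
    required = TABLE_COLUMNS[kind]
    for col in required:
        if col not in df.columns:
            raise FaersFormatError(f"{kind} table at {path} is missing column {col!r}")
    extras = [c for c in df.columns if c not in required]
    df = df[required + extras]
    for col in df.columns:
        stripped = df[col].str.strip()
        df[col] = stripped.mask(stripped == "")
    n_warnings = 0
    for col, allow_partial in _DATE_COLUMNS.get(kind, {}).items():
        df[col], w = parse_date_column(df[col], allow_partial)
        n_warnings += w
    if kind == "DEMO":
        df["age"] = pd.to_numeric(df["age"], errors="coerce")
    for col in ("drug_seq", "dsg_drug_seq", "indi_drug_seq"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="coerce").astype("Int64")
    bad_key = df["primaryid"].isna() | df["caseid"].isna()
    if bad_key.any():
        raise FaersFormatError(
            f"{kind} table at {path} has {int(bad_key.sum())} rows with empty "
            "primaryid/caseid"
        )
    df.attrs["n_warnings"] = n_warnings
    df.attrs["kind"] = kind
    return df


def write_table(df: pd.DataFrame, path: str | Path, kind: str) -> None:
    """Write a table in the ``$``-delimited dialect (header first, no quoting).

    Missing values are written as empty fields. Any value containing the
    delimiter raises :class:`FieldContentError` — there is no quoting in the
    dialect, so collision would silently corrupt the file.
    """
    kind = kind.upper()
    required = TABLE_COLUMNS[kind]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FaersFormatError(f"cannot write {kind}: records lack columns {missing}")
    extras = [c for c in df.columns if c not in required]
    out = df[required + extras].copy()
    for col in out.columns:
        as_str = out[col].astype(object).where(out[col].notna(), "")
        as_str = pd.Series(
            ["" if v == "" else _format_field(v) for v in as_str], index=out.index
        )
        if as_str.str.contains(DELIMITER, regex=False).any():
            raise FieldContentError(
                f"column {col!r} contains the field delimiter {DELIMITER!r}"
            )
        out[col] = as_str
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep=DELIMITER, index=False, lineterminator="\n")


def _format_field(value) -> str:
    if isinstance(value, float) and float(value).is_integer():
        return str(int(value))
    if isinstance(value, (np.integer, int)):
        return str(int(value))
    return str(value)


def read_lookups(
    pt_to_soc: str | Path,
    ime_list: str | Path | None = None,
    label_list: str | Path | None = None,
    synonyms: str | Path | None = None,
) -> LookupTables:
    """Load the lookup CSVs (headers ``pt,soc`` / ``pt`` / ``pt`` / ``name``)."""
    soc_df = pd.read_csv(pt_to_soc, dtype=str)
    for col in ("pt", "soc"):
        if col not in soc_df.columns:
            raise FaersFormatError(f"pt_to_soc CSV is missing column {col!r}")
    mapping = {
        _normalize_pt(row.pt): str(row.soc).strip()
        for row in soc_df.itertuples(index=False)
    }

    def _pt_set(path, column):
        if path is None:
            return set()
        frame = pd.read_csv(path, dtype=str)
        if column not in frame.columns:
            raise FaersFormatError(f"lookup CSV {path} is missing column {column!r}")
        return {_normalize_pt(v) for v in frame[column].dropna()}

    syn = set()
    if synonyms is not None:
        frame = pd.read_csv(synonyms, dtype=str)
        if "name" not in frame.columns:
            raise FaersFormatError(f"synonym CSV {synonyms} is missing column 'name'")
        syn = {str(v).strip().upper() for v in frame["name"].dropna()}
    return LookupTables(
        pt_to_soc=mapping,
        ime_list=_pt_set(ime_list, "pt"),
        label_list=_pt_set(label_list, "pt"),
        synonyms=syn,
    )
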