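"""From raw report tables to the deduplicated, drug-specific case set.

Spontaneous-report databases accumulate multiple versions of the same case
(follow-up reports, corrections). The analysis set keeps, per CASEID, the
most recent version: the maximum FDA_DT, ties broken by the maximum
PRIMARYID; versions with a missing FDA_DT sort below any dated version.

The drug cohort is defined by matching DRUG rows against the target drug's
trade/generic synonym list (normalized uppercase exact match by default,
substring opt-in) with a required role code — by default the primary suspect
(PS) role, excluding reports where the drug was merely concomitant.

Event terms (MedDRA Preferred Terms) are normalized and rolled up to their
System Organ Class through a user-supplied PT→SOC map, and flagged as
important medical events (IME list membership) and as unlabeled (absence
from the drug-label list). The PT→SOC map is treated as authoritative: no
reclassification is applied even where the source hierarchy's choices are
debatable (e.g. cheilitis filed under gastrointestinal disorders).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .io import LookupTables, RawReportTables, to_datetime_full

__all__ = [
    "CleanCases",
    "CleaningConfigError",
    "deduplicate",
    "select_drug_reports",
    "standardize_events",
    "build_clean_cases",
    "normalize_age_years",
    "assign_age_group",
    "UNMAPPED_SOC",
    "REPORTER_CLASSES",
    "AGE_GROUPS",
]

UNMAPPED_SOC = "UNMAPPED"

AGE_GROUPS = ("<18", "18–65", "66–85", ">85", "missing")

#: Conversion factors from FAERS age units to years.
AGE_FACTORS = {
    "DEC": 10.0,
    "YR": 1.0,
    "MON": 1.0 / 12.0,
    "WK": 1.0 / 52.1775,
    "DY": 1.0 / 365.25,
    "HR": 1.0 / 8766.0,
}

REPORTER_CLASSES = {
    "MD": "Physician",
    "CN": "Consumer",
    "LW": "Lawyer",
    "HP": "Health professional",
    "OT": "Other health-professional",
    "PH": "Pharmacist",
    "RN": "Registered Nurse",
}


class CleaningConfigError(ValueError):
    """Invalid cleaning configuration (e.g. empty synonym set)."""


@dataclasses.dataclass
class CleanCases:
    """The deduplicated target-drug case set.

    cases: one row per CASEID (demographics, onset left to the TTO stage);
    events: one row per (case, PT) with SOC / IME / unlabeled flags;
    outcomes: one row per (case, outcome code);
    indications: one row per (case, indication PT).
    """

    cases: pd.DataFrame
    events: pd.DataFrame
    outcomes: pd.DataFrame
    indications: pd.DataFrame

    @property
    def n_cases(self) -> int:
        return len(self.cases)


def _pid_sort_keys(demo: pd.DataFrame) -> pd.DataFrame:
    fda = pd.to_numeric(demo["fda_dt"], errors="coerce").fillna(-1)
    pid_num = pd.to_numeric(demo["primaryid"], errors="coerce")
    # non-numeric PRIMARYIDs fall back to lexicographic order among themselves
    return demo.assign(_fda=fda, _pidn=pid_num.fillna(-np.inf), _pids=demo["primaryid"])


def deduplicate(demo: pd.DataFrame) -> set[str]:
    """PRIMARYIDs to retain: per CASEID the max FDA_DT, ties → max PRIMARYID.

    Versions with missing FDA_DT sort lowest (a dated version is considered
    more recent). Empty input yields an empty set. Idempotent by
    construction: rerunning on the retained rows returns the same set.
    """
    if demo.empty:
        return set()
    keyed = _pid_sort_keys(demo).sort_values(
        ["caseid", "_fda", "_pidn", "_pids"], kind="stable"
    )
    kept = keyed.groupby("caseid", sort=False).tail(1)
    return set(kept["primaryid"])


def _name_mask(values: pd.Series, synonyms: set[str], substring: bool) -> pd.Series:
    norm = values.astype("string").str.strip().str.upper()
    if substring:
        mask = pd.Series(False, index=values.index)
        for name in synonyms:
            mask |= norm.str.contains(name, regex=False).fillna(False)
        return mask
    return norm.isin(synonyms).fillna(False)


def match_drug_names(
    drug: pd.DataFrame,
    synonyms: set[str],
    substring: bool = False,
    search_prod_ai: bool = True,
) -> pd.Series:
    """Boolean mask of DRUG rows naming the target drug (role ignored)."""
    if not synonyms:
        raise CleaningConfigError("drug synonym set must be non-empty")
    synonyms = {s.strip().upper() for s in synonyms}
    if drug.empty:
        return pd.Series(dtype=bool)
    mask = _name_mask(drug["drugname"], synonyms, substring)
    if search_prod_ai and "prod_ai" in drug.columns:
        mask |= _name_mask(drug["prod_ai"], synonyms, substring)
    return mask


def select_drug_reports(
    drug: pd.DataFrame,
    synonyms: set[str],
    required_role: str | None = "PS",
    substring: bool = False,
    search_prod_ai: bool = True,
) -> set[str]:
    """PRIMARYIDs whose DRUG rows name the target drug in the required role.

    Matching is exact on normalized (uppercased, trimmed) drugname — and
    prod_ai unless disabled — with substring matching opt-in.
    ``required_role=None`` accepts any role code.
    """
    mask = match_drug_names(drug, synonyms, substring, search_prod_ai)
    if drug.empty:
        return set()
    if required_role is not None:
        mask &= (drug["role_cod"] == required_role).fillna(False)
    return set(drug.loc[mask, "primaryid"])


def standardize_events(reac: pd.DataFrame, lookups: LookupTables) -> pd.DataFrame:
    """Normalize REAC terms and attach SOC / IME / unlabeled flags.

    Returns one row per distinct (primaryid, PT) pair with columns
    ``primaryid, caseid, pt, soc, is_ime, is_unlabeled``. PTs absent from
    the PT→SOC map receive SOC ``"UNMAPPED"``; the count of such rows is in
    ``df.attrs["n_unmapped"]``.
    """
    if reac.empty:
        out = pd.DataFrame(
            columns=["primaryid", "caseid", "pt", "soc", "is_ime", "is_unlabeled"]
        )
        out.attrs["n_unmapped"] = 0
        return out
    events = reac.copy()
    events["pt"] = events["pt"].astype("string").str.strip()
    events = events.dropna(subset=["pt"])
    key = events["pt"].str.casefold()
    events["soc"] = key.map(lookups.pt_to_soc).fillna(UNMAPPED_SOC)
    events["is_ime"] = key.isin(lookups.ime_list)
    events["is_unlabeled"] = ~key.isin(lookups.label_list)
    events = events.drop_duplicates(["primaryid", "pt"]).reset_index(drop=True)
    events.attrs["n_unmapped"] = int((events["soc"] == UNMAPPED_SOC).sum())
    return events[["primaryid", "caseid", "pt", "soc", "is_ime", "is_unlabeled"]]


def normalize_age_years(age: pd.Series, age_cod: pd.Series) -> pd.Series:
    """Age in years from FAERS (age, age_cod) pairs; unknown units → missing."""
    value = pd.to_numeric(age, errors="coerce")
    factor = age_cod.astype("string").str.strip().str.upper().map(AGE_FACTORS)
    factor = factor.where(age_cod.notna(), 1.0)  # bare numbers default to years
    years = value * factor.astype(float)
    return years.where(years >= 0)


def assign_age_group(age_years: pd.Series) -> pd.Series:
    """Bin ages: <18, 18–65, 66–85, >85 (half-open lower bounds), missing."""
    bins = pd.cut(
        age_years.astype(float),
        bins=[-np.inf, 18, 66, 86, np.inf],
        right=False,
        labels=["<18", "18–65", "66–85", ">85"],
    ).astype("string")
    return bins.fillna("missing")


def build_clean_cases(
    tables: RawReportTables,
    lookups: LookupTables,
    retained: set[str],
    selected: set[str],
) -> CleanCases:
    """Assemble one clean case per CASEID from the retained ∩ selected reports."""
    keep = retained & selected
    demo = tables.demo[tables.demo["primaryid"].isin(keep)].copy()
    demo = demo.sort_values("caseid", kind="stable").reset_index(drop=True)

    age_years = normalize_age_years(demo["age"], demo["age_cod"])
    cases = pd.DataFrame(
        {
            "caseid": demo["caseid"],
            "primaryid": demo["primaryid"],
            "fda_dt": demo["fda_dt"],
            "event_dt": demo["event_dt"],
            "event_date": to_datetime_full(demo["event_dt"]),
            "sex": demo["sex"].where(demo["sex"].isin(["F", "M"]), pd.NA),
            "age_years": age_years,
            "age_group": assign_age_group(age_years),
            "reporter_class": demo["occp_cod"]
            .str.strip()
            .str.upper()
            .map(REPORTER_CLASSES)
            .where(demo["occp_cod"].notna(), pd.NA),
            "country": demo["reporter_country"],
        }
    )
    unknown_occp = demo["occp_cod"].notna() & cases["reporter_class"].isna()
    cases.loc[unknown_occp, "reporter_class"] = "Other"

    events = standardize_events(tables.reac, lookups)
    n_unmapped = events.attrs.get("n_unmapped", 0)
    events = events[events["primaryid"].isin(keep)].reset_index(drop=True)

    outcomes = tables.outc[tables.outc["primaryid"].isin(keep)]
    outcomes = outcomes.drop_duplicates(["primaryid", "outc_cod"]).reset_index(drop=True)
    indications = tables.indi[tables.indi["primaryid"].isin(keep)]
    indications = indications.drop_duplicates(["primaryid", "indi_pt"]).reset_index(
        drop=True
    )

    clean = CleanCases(
        cases=cases,
        events=events,
        outcomes=outcomes[["primaryid", "caseid", "outc_cod"]],
        indications=indications[["primaryid", "caseid", "indi_drug_seq", "indi_pt"]],
    )
    clean.cases.attrs["n_unmapped_events"] = n_unmapped
    return clean
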