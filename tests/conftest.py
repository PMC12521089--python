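"""Shared fixtures: tiny hand-built tables, lookup sets, and sim configs."""

import pandas as pd
import pytest

from faersignal.io import LookupTables
from faersignal.synthetic import SignalSpec, default_config


def _string_frame(rows: list[dict]) -> pd.DataFrame:
    return pd.DataFrame(rows).astype("string")


def make_lookups() -> LookupTables:
    return LookupTables(
        pt_to_soc={
            "inflammatory bowel disease": "Gastrointestinal disorders",
            "lip dry": "Gastrointestinal disorders",
            "cheilitis": "Gastrointestinal disorders",
            "nausea": "Gastrointestinal disorders",
            "diarrhoea": "Gastrointestinal disorders",
            "abdominal pain": "Gastrointestinal disorders",
            "depression": "Psychiatric disorders",
            "suicidal ideation": "Psychiatric disorders",
            "anxiety": "Psychiatric disorders",
            "insomnia": "Psychiatric disorders",
            "dry skin": "Skin and subcutaneous tissue disorders",
            "rash": "Skin and subcutaneous tissue disorders",
            "pruritus": "Skin and subcutaneous tissue disorders",
            "alopecia": "Skin and subcutaneous tissue disorders",
            "dandy-walker syndrome": "Congenital, familial and genetic disorders",
            "anotia": "Congenital, familial and genetic disorders",
            "blood triglycerides increased": "Investigations",
            "hepatic enzyme increased": "Investigations",
            "fatigue": "General disorders and administration site conditions",
            "headache": "General disorders and administration site conditions",
        },
        ime_list={
            "inflammatory bowel disease",
            "suicidal ideation",
            "dandy-walker syndrome",
            "anotia",
        },
        label_list={
            "inflammatory bowel disease",
            "lip dry",
            "cheilitis",
            "dry skin",
            "rash",
        },
        synonyms={"RETINOID-A", "ACCUTANE"},
    )


@pytest.fixture
def lookups() -> LookupTables:
    return make_lookups()


@pytest.fixture
def demo_versions() -> pd.DataFrame:
    """One case with three versions plus an unrelated singleton case."""
    return _string_frame(
        [
            {"primaryid": "1", "caseid": "100", "fda_dt": "20200101"},
            {"primaryid": "2", "caseid": "100", "fda_dt": "20200301"},
            {"primaryid": "3", "caseid": "100", "fda_dt": None},
            {"primaryid": "7", "caseid": "200", "fda_dt": "20210401"},
        ]
    )


@pytest.fixture
def signal_config():
    """Study-condition generator config with one strong and one null signal."""
    return default_config(
        n_cases=5_000,
        seed=11,
        dup_rate=0.10,
        signal_spec=[
            SignalSpec("RETINOID-A", "Inflammatory bowel disease", 10.0),
            SignalSpec("RETINOID-A", "Rash", 1.0),
        ],
    )


@pytest.fixture
def string_frame():
    return _string_frame
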