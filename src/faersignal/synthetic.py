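"""Synthetic FAERS-style datasets with known ground truth.

Spontaneous-report databases cannot be redistributed alongside a package, and
real extracts carry no ground truth. This module generates the six linked
tables (DEMO, DRUG, REAC, THER, OUTC, INDI) of a FAERS-style quarterly extract
from an explicit generative model:

* each case lists one or more drugs from a catalog (independent inclusion,
  with a guaranteed minimum of one), each with a role code drawn from that
  drug's role distribution;
* each report carries ``Poisson(1) + 1`` distinct adverse-event preferred
  terms (PTs), drawn without replacement with weights proportional to each
  PT's background reporting probability times any designed signal multiplier
  — a multiplier m for a (drug, PT) pair scales that PT's reporting odds by m
  in reports listing the drug, so the realized pair-level reporting ratio
  recovers m;
* therapy start and event dates follow a log-normal onset distribution, with
  configurable missingness, partial-precision dates, and occasional negative
  onset intervals (start/event swapped) to exercise exclusion rules;
* a configurable fraction of cases emits a second report version under a new,
  strictly larger PRIMARYID with a later (or, with probability 0.1, tied)
  FDA_DT, to exercise deduplication.

The accompanying :class:`SimTruth` records the designed multipliers, the
realized 2×2 pair counts for every designed (drug, PT) pair, and the full
duplicate ledger, so recovery can be asserted exactly.
"""

from __future__ import annotations

import dataclasses
import datetime as dt

import numpy as np
import pandas as pd

from .io import RawReportTables

__all__ = [
    "DrugSpec",
    "PtSpec",
    "SignalSpec",
    "SimConfig",
    "SimTruth",
    "SimConfigError",
    "default_config",
    "generate_faers_tables",
    "inject_duplicates",
]

ROLES = ("PS", "SS", "C", "I")

# Onset distribution: log-normal with median 81 days and quartiles near
# 31/169 days, the shape reported for isotretinoin-class FAERS cohorts.
ONSET_LOG_MEDIAN = np.log(81.0)
ONSET_LOG_SIGMA = 1.1


class SimConfigError(ValueError):
    """A simulation configuration field is invalid; the message names it."""


@dataclasses.dataclass
class DrugSpec:
    """One catalog drug: name, role-code distribution, inclusion probability."""

    name: str
    role_probs: dict[str, float]
    use_prob: float


@dataclasses.dataclass
class PtSpec:
    """One catalog adverse-event term: PT name, its SOC, background probability."""

    name: str
    soc: str
    base_prob: float


@dataclasses.dataclass
class SignalSpec:
    """A designed (drug, PT) reporting-rate multiplier (≥ 0; 1 = null)."""

    drug: str
    pt: str
    multiplier: float


@dataclasses.dataclass
class SimConfig:
    n_cases: int
    drug_catalog: list[DrugSpec]
    pt_catalog: list[PtSpec]
    signal_spec: list[SignalSpec] = dataclasses.field(default_factory=list)
    dup_rate: float = 0.0
    missing_start_rate: float = 0.10
    missing_event_rate: float = 0.10
    negative_onset_rate: float = 0.02
    partial_date_rate: float = 0.05
    date_window: tuple[dt.date, dt.date] = (dt.date(2004, 1, 1), dt.date(2024, 6, 30))
    seed: int = 0

    def validate(self) -> None:
        if self.n_cases < 1:
            raise SimConfigError("n_cases must be ≥ 1")
        for field in (
            "dup_rate",
            "missing_start_rate",
            "missing_event_rate",
            "negative_onset_rate",
            "partial_date_rate",
        ):
            v = getattr(self, field)
            if not 0.0 <= v <= 1.0:
                raise SimConfigError(f"{field} must be a probability in [0, 1], got {v}")
        if not self.drug_catalog:
            raise SimConfigError("drug_catalog must be non-empty")
        if not self.pt_catalog:
            raise SimConfigError("pt_catalog must be non-empty")
        for spec in self.drug_catalog:
            if not 0.0 <= spec.use_prob <= 1.0:
                raise SimConfigError(
                    f"drug_catalog[{spec.name!r}].use_prob must be in [0, 1]"
                )
            total = sum(spec.role_probs.get(r, 0.0) for r in ROLES)
            if not np.isclose(total, 1.0):
                raise SimConfigError(
                    f"drug_catalog[{spec.name!r}].role_probs must sum to 1 over {ROLES}"
                )
        for spec in self.pt_catalog:
            if not 0.0 <= spec.base_prob <= 1.0:
                raise SimConfigError(
                    f"pt_catalog[{spec.name!r}].base_prob must be in [0, 1]"
                )
        drugs = {d.name for d in self.drug_catalog}
        pts = {p.name for p in self.pt_catalog}
        for sig in self.signal_spec:
            if sig.drug not in drugs:
                raise SimConfigError(f"signal_spec drug {sig.drug!r} not in drug_catalog")
            if sig.pt not in pts:
                raise SimConfigError(f"signal_spec pt {sig.pt!r} not in pt_catalog")
            if sig.multiplier < 0:
                raise SimConfigError(
                    f"signal_spec multiplier for ({sig.drug!r}, {sig.pt!r}) must be ≥ 0"
                )
        if self.date_window[0] > self.date_window[1]:
            raise SimConfigError("date_window must be (earliest, latest)")


@dataclasses.dataclass
class SimTruth:
    """Ground truth behind one synthetic dataset.

    ``signal_counts`` holds, per designed (drug, PT) pair, the multiplier and
    the realized pair-level 2×2 counts a, b, c, d at generation time (target
    cohort = reports listing the drug in any role; counting unit = distinct
    (report, PT) pair). ``dup_ledger`` lists every emitted report version
    (caseid, primaryid, fda_dt) with ``expect_keep`` marking the version the
    deduplication rule must retain.
    """

    signal_counts: pd.DataFrame
    dup_ledger: pd.DataFrame
    n_cases: int

    def expected_retained(self) -> set[str]:
        """PRIMARYIDs the dedup rule (max FDA_DT, then max PRIMARYID) must keep."""
        return set(self.dup_ledger.loc[self.dup_ledger["expect_keep"], "primaryid"])

    def export(self, path) -> None:
        self.signal_counts.to_csv(path, index=False)


def default_config(
    n_cases: int = 50_000,
    seed: int = 0,
    signal_spec: list[SignalSpec] | None = None,
    dup_rate: float = 0.10,
) -> SimConfig:
    """Study-condition defaults: one analyzed retinoid plus background drugs.

    The target drug ("RETINOID-A", mostly primary-suspect) appears in roughly
    a fifth of cases; five background drugs fill the rest. The PT catalog
    spans six SOCs with background probabilities between 0.005 and 0.15,
    including the gastrointestinal / psychiatric / congenital terms the
    cleaning stage's lookup fixtures flag.
    """
    target_roles = {"PS": 0.90, "SS": 0.06, "C": 0.03, "I": 0.01}
    bg_roles = {"PS": 0.40, "SS": 0.20, "C": 0.35, "I": 0.05}
    drug_catalog = [
        DrugSpec("RETINOID-A", target_roles, 0.20),
        DrugSpec("ANTIBIOTIC-B", bg_roles, 0.30),
        DrugSpec("ANALGESIC-C", bg_roles, 0.35),
        DrugSpec("ANTIHISTAMINE-D", bg_roles, 0.25),
        DrugSpec("STATIN-E", bg_roles, 0.20),
        DrugSpec("PPI-F", bg_roles, 0.20),
    ]
    gi = "Gastrointestinal disorders"
    psy = "Psychiatric disorders"
    skin = "Skin and subcutaneous tissue disorders"
    cong = "Congenital, familial and genetic disorders"
    inv = "Investigations"
    gen = "General disorders and administration site conditions"
    pt_catalog = [
        PtSpec("Inflammatory bowel disease", gi, 0.010),
        PtSpec("Lip dry", gi, 0.020),
        PtSpec("Cheilitis", gi, 0.010),
        PtSpec("Nausea", gi, 0.120),
        PtSpec("Diarrhoea", gi, 0.100),
        PtSpec("Abdominal pain", gi, 0.080),
        PtSpec("Depression", psy, 0.060),
        PtSpec("Suicidal ideation", psy, 0.015),
        PtSpec("Anxiety", psy, 0.070),
        PtSpec("Insomnia", psy, 0.080),
        PtSpec("Dry skin", skin, 0.050),
        PtSpec("Rash", skin, 0.150),
        PtSpec("Pruritus", skin, 0.100),
        PtSpec("Alopecia", skin, 0.030),
        PtSpec("Dandy-Walker syndrome", cong, 0.005),
        PtSpec("Anotia", cong, 0.005),
        PtSpec("Blood triglycerides increased", inv, 0.020),
        PtSpec("Hepatic enzyme increased", inv, 0.030),
        PtSpec("Fatigue", gen, 0.140),
        PtSpec("Headache", gen, 0.130),
    ]
    return SimConfig(
        n_cases=n_cases,
        drug_catalog=drug_catalog,
        pt_catalog=pt_catalog,
        signal_spec=signal_spec or [],
        dup_rate=dup_rate,
        seed=seed,
    )


def _format_dates(days: np.ndarray, missing: np.ndarray) -> pd.Series:
    """int day offsets (vs epoch) → YYYYMMDD strings, NA where ``missing``."""
    stamps = pd.Series(np.datetime64("1970-01-01") + days.astype("timedelta64[D]"))
    out = stamps.dt.strftime("%Y%m%d").astype("string")
    out[missing] = pd.NA
    return out


def generate_faers_tables(config: SimConfig) -> tuple[RawReportTables, SimTruth]:
    """Generate the six linked tables plus their ground truth.

    Deterministic: identical (config, seed) reproduces byte-identical tables.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_cases
    nd = len(config.drug_catalog)
    npt = len(config.pt_catalog)

    caseid_num = 100_000_000 + np.arange(1, n + 1, dtype=np.int64)
    pid_num = caseid_num * 100 + 1
    caseid = caseid_num.astype(str)
    pid = pid_num.astype(str)

    # --- drug presence and roles -------------------------------------------
    use_probs = np.array([d.use_prob for d in config.drug_catalog])
    present = rng.random((n, nd)) < use_probs
    none = ~present.any(axis=1)
    if none.any():
        weights = use_probs if use_probs.sum() > 0 else np.ones(nd)
        forced = rng.choice(nd, size=int(none.sum()), p=weights / weights.sum())
        present[np.flatnonzero(none), forced] = True
    roles = np.empty((n, nd), dtype=object)
    for j, spec in enumerate(config.drug_catalog):
        p = np.array([spec.role_probs.get(r, 0.0) for r in ROLES])
        idx = np.flatnonzero(present[:, j])
        roles[idx, j] = rng.choice(np.array(ROLES, dtype=object), size=idx.size, p=p)

    # --- event PTs: Poisson(1)+1 distinct draws, signal-weighted ------------
    base = np.array([p.base_prob for p in config.pt_catalog])
    drug_index = {d.name: j for j, d in enumerate(config.drug_catalog)}
    pt_index = {p.name: j for j, p in enumerate(config.pt_catalog)}
    mult = np.ones((n, npt))
    for sig in config.signal_spec:
        carriers = present[:, drug_index[sig.drug]]
        mult[carriers, pt_index[sig.pt]] *= sig.multiplier
    w = base * mult
    with np.errstate(divide="ignore"):
        logw = np.where(w > 0, np.log(np.where(w > 0, w, 1.0)), -np.inf)
    keys = logw + rng.gumbel(size=(n, npt))
    order = np.argsort(-keys, axis=1, kind="stable")
    n_pos = (w > 0).sum(axis=1)
    k = np.minimum(rng.poisson(1.0, size=n) + 1, n_pos)
    maxk = int(k.max()) if n else 0
    sel = np.arange(maxk)[None, :] < k[:, None]
    ev_case = np.repeat(np.arange(n), k)
    ev_pt = order[:, :maxk][sel]

    # --- dates --------------------------------------------------------------
    w0 = (config.date_window[0] - dt.date(1970, 1, 1)).days
    w1 = (config.date_window[1] - dt.date(1970, 1, 1)).days
    fda_days = rng.integers(w0, w1 + 1, size=n)
    onset = np.maximum(
        0, np.round(rng.lognormal(ONSET_LOG_MEDIAN, ONSET_LOG_SIGMA, size=n))
    ).astype(np.int64)
    event_days = fda_days - rng.integers(0, 91, size=n)
    start_days = event_days - onset
    swap = rng.random(n) < config.negative_onset_rate
    start_days[swap], event_days[swap] = event_days[swap], start_days[swap].copy()
    end_days = start_days + rng.integers(30, 181, size=n)
    miss_start = rng.random(n) < config.missing_start_rate
    miss_event = rng.random(n) < config.missing_event_rate

    fda_dt = _format_dates(fda_days, np.zeros(n, dtype=bool))
    event_dt = _format_dates(event_days, miss_event)
    partial = (rng.random(n) < config.partial_date_rate) & ~miss_event
    trunc_to_month = rng.random(n) < 0.5
    keep = event_dt.notna() & partial
    event_dt[keep & trunc_to_month] = event_dt[keep & trunc_to_month].str[:6]
    event_dt[keep & ~trunc_to_month] = event_dt[keep & ~trunc_to_month].str[:4]
    start_dt = _format_dates(start_days, miss_start)
    end_dt = _format_dates(end_days, miss_start)

    # --- demographics -------------------------------------------------------
    sex = rng.choice(np.array(["F", "M", ""], dtype=object), size=n, p=[0.56, 0.33, 0.11])
    age_known = rng.random(n) >= 0.445
    grp = rng.choice(4, size=n, p=[0.342, 0.649, 0.0084, 0.0006])
    lo = np.array([1, 18, 66, 86])[grp]
    hi = np.array([18, 66, 86, 96])[grp]
    age_years = rng.integers(lo, hi)
    in_months = (rng.random(n) < 0.05) & (grp == 0)
    age_val = np.where(in_months, age_years * 12, age_years).astype(float)
    age = pd.Series(age_val).astype("string")
    age[~age_known] = pd.NA
    age_cod = pd.Series(np.where(in_months, "MON", "YR"), dtype="string")
    age_cod[~age_known] = pd.NA
    occp = rng.choice(
        np.array(["MD", "CN", "OT", "LW", "HP", "PH", "RN", ""], dtype=object),
        size=n,
        p=[0.332, 0.297, 0.126, 0.111, 0.060, 0.020, 0.001, 0.053],
    )
    country = rng.choice(
        np.array(["US", "GB", "CA", "BR", "AU", "FR", ""], dtype=object),
        size=n,
        p=[0.811, 0.022, 0.009, 0.005, 0.005, 0.048, 0.100],
    )

    demo = pd.DataFrame(
        {
            "primaryid": pid,
            "caseid": caseid,
            "fda_dt": fda_dt,
            "event_dt": event_dt,
            "sex": pd.Series(sex, dtype="string").replace("", pd.NA),
            "age": age.str.replace(r"\.0$", "", regex=True),
            "age_cod": age_cod,
            "reporter_country": pd.Series(country, dtype="string").replace("", pd.NA),
            "occp_cod": pd.Series(occp, dtype="string").replace("", pd.NA),
        }
    ).astype("string")

    # --- drug / therapy tables ----------------------------------------------
    d_case, d_drug = np.nonzero(present)
    seq = np.concatenate([np.arange(1, c + 1) for c in present.sum(axis=1)])
    drug = pd.DataFrame(
        {
            "primaryid": pid[d_case],
            "caseid": caseid[d_case],
            "drug_seq": seq.astype(str),
            "role_cod": roles[d_case, d_drug],
            "drugname": np.array([config.drug_catalog[j].name for j in d_drug]),
            "prod_ai": np.array([config.drug_catalog[j].name for j in d_drug]),
        }
    ).astype("string")
    ther = pd.DataFrame(
        {
            "primaryid": pid[d_case],
            "caseid": caseid[d_case],
            "dsg_drug_seq": seq.astype(str),
            "start_dt": start_dt.iloc[d_case].to_numpy(),
            "end_dt": end_dt.iloc[d_case].to_numpy(),
        }
    ).astype("string")

    pt_names = np.array([p.name for p in config.pt_catalog], dtype=object)
    reac = pd.DataFrame(
        {
            "primaryid": pid[ev_case],
            "caseid": caseid[ev_case],
            "pt": pt_names[ev_pt],
        }
    ).astype("string")

    # --- outcomes / indications ---------------------------------------------
    outc_codes = ["OT", "HO", "DE", "DS", "LT", "CA", "RI"]
    outc_probs = [0.453, 0.074, 0.017, 0.012, 0.010, 0.006, 0.002]
    o_rows = []
    for code, prob in zip(outc_codes, outc_probs):
        hit = np.flatnonzero(rng.random(n) < prob)
        o_rows.append(
            pd.DataFrame(
                {"primaryid": pid[hit], "caseid": caseid[hit], "outc_cod": code}
            )
        )
    outc = (
        pd.concat(o_rows, ignore_index=True)
        .sort_values(["caseid", "outc_cod"], kind="stable")
        .reset_index(drop=True)
        .astype("string")
    )
    indi_terms = rng.choice(
        np.array(
            ["Acne", "Acne cystic", "Neuroblastoma", "Rosacea",
             "Product used for unknown indication"],
            dtype=object,
        ),
        size=n,
        p=[0.35, 0.055, 0.004, 0.002, 0.589],
    )
    indi = pd.DataFrame(
        {
            "primaryid": pid,
            "caseid": caseid,
            "indi_drug_seq": "1",
            "indi_pt": indi_terms,
        }
    ).astype("string")

    tables = RawReportTables(demo, drug, reac, ther, outc, indi)

    # --- ground truth ---------------------------------------------------------
    signal_counts = _realized_counts(config, present, ev_case, ev_pt)
    ledger = pd.DataFrame(
        {"caseid": caseid, "primaryid": pid, "fda_dt": fda_dt, "expect_keep": True}
    )
    truth = SimTruth(signal_counts=signal_counts, dup_ledger=ledger, n_cases=n)

    if config.dup_rate > 0:
        tables, dup_entries = inject_duplicates(
            tables, config.dup_rate, seed=int(rng.integers(0, 2**31))
        )
        truth.dup_ledger = _merge_ledger(ledger, dup_entries)
    return tables, truth


def _realized_counts(config, present, ev_case, ev_pt) -> pd.DataFrame:
    """Pair-level 2×2 counts for every designed (drug, PT) pair.

    Target cohort = reports listing the drug in any role; unit = distinct
    (report, PT) pair, matching the pair-counting disproportionality mode.
    """
    drug_index = {d.name: j for j, d in enumerate(config.drug_catalog)}
    pt_index = {p.name: j for j, p in enumerate(config.pt_catalog)}
    n_total_pairs = len(ev_case)
    rows = []
    for sig in config.signal_spec:
        dj, pj = drug_index[sig.drug], pt_index[sig.pt]
        target = present[ev_case, dj]
        is_pt = ev_pt == pj
        a = int((target & is_pt).sum())
        b = int(target.sum()) - a
        c = int(is_pt.sum()) - a
        d = n_total_pairs - a - b - c
        rows.append(
            {"drug": sig.drug, "pt": sig.pt, "multiplier": sig.multiplier,
             "a": a, "b": b, "c": c, "d": d}
        )
    return pd.DataFrame(rows, columns=["drug", "pt", "multiplier", "a", "b", "c", "d"])


def _merge_ledger(base: pd.DataFrame, dups: pd.DataFrame) -> pd.DataFrame:
    ledger = pd.concat([base, dups], ignore_index=True)
    # expected keep: max FDA_DT per case, ties broken by max PRIMARYID
    key = ledger.assign(
        _fda=pd.to_numeric(ledger["fda_dt"], errors="coerce").fillna(-1),
        _pid=pd.to_numeric(ledger["primaryid"], errors="coerce"),
    ).sort_values(["caseid", "_fda", "_pid"], kind="stable")
    keep_idx = key.groupby("caseid", sort=False).tail(1).index
    ledger["expect_keep"] = False
    ledger.loc[keep_idx, "expect_keep"] = True
    return ledger.sort_values(["caseid", "primaryid"], kind="stable").reset_index(
        drop=True
    )


def inject_duplicates(
    tables: RawReportTables, dup_rate: float, seed: int
) -> tuple[RawReportTables, pd.DataFrame]:
    """Emit a second version of a random subset of cases.

    Each selected case's latest version is copied under a strictly larger
    PRIMARYID; the copy's FDA_DT is 1–180 days later, or identical with
    probability 0.1 (exercising the PRIMARYID tiebreak). Returns the widened
    tables and a ledger of the new versions (caseid, primaryid, fda_dt).
    """
    if not 0.0 <= dup_rate <= 1.0:
        raise SimConfigError("dup_rate must be a probability in [0, 1]")
    rng = np.random.default_rng(seed)
    demo = tables.demo
    latest = demo.assign(
        _pid=pd.to_numeric(demo["primaryid"], errors="coerce")
    ).sort_values(["caseid", "_pid"], kind="stable").groupby("caseid", sort=False).tail(1)
    chosen = latest[rng.random(len(latest)) < dup_rate]
    if chosen.empty:
        return tables.copy(), pd.DataFrame(
            columns=["caseid", "primaryid", "fda_dt", "expect_keep"]
        )
    old_pid = chosen["primaryid"]
    new_pid = (pd.to_numeric(old_pid) + 1).astype(np.int64).astype(str)
    pid_map = dict(zip(old_pid, new_pid))

    tie = rng.random(len(chosen)) < 0.1
    shift = rng.integers(1, 181, size=len(chosen))
    shift[tie] = 0
    old_days = (
        pd.to_datetime(chosen["fda_dt"], format="%Y%m%d")
        - pd.Timestamp("1970-01-01")
    ).dt.days.to_numpy()
    new_fda = _format_dates(old_days + shift, np.zeros(len(chosen), dtype=bool))

    fda_map = dict(zip(new_pid, new_fda))
    out = {}
    for kind, frame in tables:
        dup_rows = frame[frame["primaryid"].isin(pid_map)].copy()
        dup_rows["primaryid"] = dup_rows["primaryid"].map(pid_map)
        if kind == "DEMO":
            dup_rows["fda_dt"] = dup_rows["primaryid"].map(fda_map)
        out[kind.lower()] = pd.concat([frame, dup_rows], ignore_index=True)
    ledger = pd.DataFrame(
        {
            "caseid": chosen["caseid"].to_numpy(),
            "primaryid": new_pid.to_numpy(),
            "fda_dt": new_fda.to_numpy(),
            "expect_keep": True,
        }
    )
    return RawReportTables(**out), ledger
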