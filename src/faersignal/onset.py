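"""Time-to-onset analysis and descriptive case summaries.

Time to onset (TTO) is the calendar-day difference between the adverse-event
occurrence date (DEMO.event_dt, the FAERS field for event onset) and the
earliest therapy start date among the target drug's THER rows. Day-resolution
arithmetic requires full 8-digit dates on both sides: reports with missing or
partial dates are excluded (reason ``missing_date``), and negative
differences are excluded (reason ``negative``), mirroring standard
spontaneous-report TTO practice. Exclusions are accounted exactly:
included + missing_date + negative = number of cases.

Demographic summaries produce counts and percentages (denominator = all
cases) for sex, age groups, reporter classes, top-k countries, outcome codes
(one case can hit several outcome rows), top-k indications, and
reports-per-year keyed on the FDA receipt date.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .cleaning import AGE_GROUPS, CleanCases
from .io import to_datetime_full

__all__ = [
    "DEFAULT_BIN_EDGES",
    "OnsetSummary",
    "compute_tto",
    "summarize_tto",
    "summarize_demographics",
    "percentage",
]

#: Upper edges (inclusive, days) of the default onset bins:
#: [0–30], [31–60], [61–90], [91–180], [181–360], [>360].
DEFAULT_BIN_EDGES = (0, 30, 60, 90, 180, 360)


def percentage(count: float, denominator: float) -> float:
    """A percentage rounded to one decimal; NaN when the denominator is 0."""
    if denominator == 0:
        return float("nan")
    return round(100.0 * count / denominator, 1)


@dataclasses.dataclass
class OnsetSummary:
    """Median/IQR and binned distribution of included onset intervals."""

    n_included: int
    median_days: float
    q1: float
    q3: float
    bin_labels: list[str]
    bin_counts: list[int]
    bin_proportions: list[float]

    @property
    def empty(self) -> bool:
        return self.n_included == 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin": self.bin_labels,
                "count": self.bin_counts,
                "proportion": self.bin_proportions,
            }
        )


def compute_tto(
    cases: pd.DataFrame,
    ther: pd.DataFrame,
    target_drug_rows: pd.DataFrame,
) -> pd.DataFrame:
    """Per-case onset intervals with exact exclusion accounting.

    ``cases`` needs ``caseid``, ``primaryid`` and ``event_dt`` (raw FAERS
    integer-date strings); ``target_drug_rows`` are the DRUG rows matching
    the target drug (``primaryid``, ``drug_seq``), used to pick the THER
    rows whose ``dsg_drug_seq`` links to them. Onset = event date − earliest
    full-precision target start date. Returns one row per case with
    ``onset_days`` (Int64), ``included`` and ``exclusion_reason``
    (``none`` / ``missing_date`` / ``negative``).
    """
    link = target_drug_rows[["primaryid", "drug_seq"]].copy()
    link["drug_seq"] = pd.to_numeric(link["drug_seq"], errors="coerce").astype("Int64")
    t = ther.copy()
    t["dsg_drug_seq"] = pd.to_numeric(t["dsg_drug_seq"], errors="coerce").astype("Int64")
    t = t.merge(
        link, left_on=["primaryid", "dsg_drug_seq"], right_on=["primaryid", "drug_seq"]
    )
    t["start_date"] = to_datetime_full(t["start_dt"])
    starts = t.dropna(subset=["start_date"]).groupby("primaryid")["start_date"].min()

    out = cases[["caseid", "primaryid"]].copy()
    event_date = to_datetime_full(cases["event_dt"])
    start_date = cases["primaryid"].map(starts)
    onset = (event_date.to_numpy() - start_date.to_numpy()).astype("timedelta64[D]")
    onset_days = pd.Series(onset.astype("float"), index=cases.index)

    missing = event_date.isna() | start_date.isna()
    negative = ~missing & (onset_days < 0)
    out["onset_days"] = onset_days.where(~missing).astype("Int64")
    out["exclusion_reason"] = "none"
    out.loc[negative, "exclusion_reason"] = "negative"
    out.loc[missing, "exclusion_reason"] = "missing_date"
    out["included"] = out["exclusion_reason"] == "none"
    return out.reset_index(drop=True)


def _bin_labels(edges: tuple[int, ...]) -> list[str]:
    labels = [f"{edges[0]}–{edges[1]}"]
    labels += [f"{lo + 1}–{hi}" for lo, hi in zip(edges[1:], edges[2:])]
    labels.append(f">{edges[-1]}")
    return labels


def summarize_tto(
    onset: pd.DataFrame, bin_edges: tuple[int, ...] = DEFAULT_BIN_EDGES
) -> OnsetSummary:
    """Median, IQR (linear interpolation) and day-bin proportions.

    ``bin_edges`` are increasing inclusive upper cutoffs; the first bin is
    [edges[0], edges[1]] and a final open bin collects everything above the
    last edge. Proportions are over included records only.
    """
    edges = tuple(bin_edges)
    if len(edges) < 2 or any(b <= a for a, b in zip(edges, edges[1:])):
        raise ValueError("bin_edges must be strictly increasing day cutoffs")
    labels = _bin_labels(edges)
    days = onset.loc[onset["included"], "onset_days"].astype(float).to_numpy()
    if days.size == 0:
        return OnsetSummary(0, np.nan, np.nan, np.nan, labels, [0] * len(labels),
                            [np.nan] * len(labels))
    q1, med, q3 = np.percentile(days, [25, 50, 75], method="linear")
    cuts = np.concatenate([[edges[0] - 0.5], np.asarray(edges[1:]) + 0.5, [np.inf]])
    counts, _ = np.histogram(days, bins=cuts)
    props = counts / days.size
    return OnsetSummary(
        n_included=int(days.size),
        median_days=float(med),
        q1=float(q1),
        q3=float(q3),
        bin_labels=labels,
        bin_counts=counts.astype(int).tolist(),
        bin_proportions=props.tolist(),
    )


def _count_table(series: pd.Series, denom: int, order=None, top_k=None) -> pd.DataFrame:
    filled = series.astype("string").fillna("missing")
    counts = filled.value_counts()
    if order is not None:
        counts = counts.reindex(list(order), fill_value=0)
    elif top_k is not None:
        counts = counts[counts.index != "missing"].head(top_k)
    frame = counts.rename("count").rename_axis("value").reset_index()
    frame["pct"] = [percentage(c, denom) for c in frame["count"]]
    return frame


def summarize_demographics(clean: CleanCases, top_k: int = 5) -> dict[str, pd.DataFrame]:
    """Table-style descriptive summary of the clean case set.

    Returns a dict of DataFrames (columns ``value``, ``count``, ``pct``):
    ``sex``, ``age_group``, ``reporter_class``, ``country`` (top-k),
    ``outcome`` (a case may contribute several rows), ``indication``
    (top-k), and ``reports_per_year`` (``year``/``count``). Percentages use
    all cases as denominator and are rounded to one decimal; with no cases
    they are NaN.
    """
    cases = clean.cases
    denom = len(cases)
    summary = {
        "sex": _count_table(cases["sex"], denom, order=("F", "M", "missing")),
        "age_group": _count_table(cases["age_group"], denom, order=AGE_GROUPS),
        "reporter_class": _count_table(cases["reporter_class"], denom),
        "country": _count_table(cases["country"], denom, top_k=top_k),
        "indication": _count_table(clean.indications["indi_pt"], denom, top_k=top_k),
    }
    outc = clean.outcomes.drop_duplicates(["caseid", "outc_cod"])
    summary["outcome"] = _count_table(outc["outc_cod"], denom)
    years = cases["fda_dt"].astype("string").str[:4]
    per_year = (
        years.dropna().value_counts().sort_index().rename("count")
        .rename_axis("year").reset_index()
    )
    summary["reports_per_year"] = per_year
    return summary
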