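"""Onset arithmetic and exclusions, binning, and demographic summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from faersignal.cleaning import build_clean_cases, deduplicate, select_drug_reports
from faersignal.onset import (
    compute_tto,
    percentage,
    summarize_demographics,
    summarize_tto,
)
from faersignal.synthetic import default_config, generate_faers_tables


def _case(string_frame, event_dt, start_dt, caseid="1"):
    cases = string_frame(
        [{"caseid": caseid, "primaryid": caseid, "event_dt": event_dt}]
    )
    ther = string_frame(
        [{"primaryid": caseid, "caseid": caseid, "dsg_drug_seq": "1",
          "start_dt": start_dt, "end_dt": None}]
    )
    drug = string_frame(
        [{"primaryid": caseid, "caseid": caseid, "drug_seq": "1",
          "role_cod": "PS", "drugname": "X", "prod_ai": None}]
    )
    return cases, ther, drug


class TestComputeTto:
    def test_calendar_day_difference_across_leap_february(self, string_frame):
        cases, ther, drug = _case(string_frame, "20200401", "20200101")
        out = compute_tto(cases, ther, drug)
        assert out.iloc[0]["onset_days"] == 91  # 31 + 29 + 31
        assert out.iloc[0]["included"]

    def test_negative_interval_excluded(self, string_frame):
        cases, ther, drug = _case(string_frame, "20200201", "20200301")
        out = compute_tto(cases, ther, drug)
        assert not out.iloc[0]["included"]
        assert out.iloc[0]["exclusion_reason"] == "negative"

    def test_missing_start_excluded(self, string_frame):
        cases, ther, drug = _case(string_frame, "20200201", None)
        out = compute_tto(cases, ther, drug)
        assert out.iloc[0]["exclusion_reason"] == "missing_date"

    def test_partial_event_date_excluded_as_missing(self, string_frame):
        cases, ther, drug = _case(string_frame, "202002", "20200101")
        out = compute_tto(cases, ther, drug)
        assert out.iloc[0]["exclusion_reason"] == "missing_date"

    def test_earliest_target_start_used(self, string_frame):
        cases = string_frame(
            [{"caseid": "1", "primaryid": "1", "event_dt": "20200301"}]
        )
        ther = string_frame(
            [
                {"primaryid": "1", "caseid": "1", "dsg_drug_seq": "1",
                 "start_dt": "20200201", "end_dt": None},
                {"primaryid": "1", "caseid": "1", "dsg_drug_seq": "1",
                 "start_dt": "20200101", "end_dt": None},
            ]
        )
        drug = string_frame(
            [{"primaryid": "1", "caseid": "1", "drug_seq": "1", "role_cod": "PS",
              "drugname": "X", "prod_ai": None}]
        )
        out = compute_tto(cases, ther, drug)
        assert out.iloc[0]["onset_days"] == 60

    def test_exclusion_accounting_is_exact_on_synthetic_data(self, lookups):
        cfg = default_config(n_cases=2_000, seed=9)
        tables, _ = generate_faers_tables(cfg)
        retained = deduplicate(tables.demo)
        selected = select_drug_reports(tables.drug, {"RETINOID-A"})
        clean = build_clean_cases(tables, lookups, retained, selected)
        drug_rows = tables.drug[tables.drug["drugname"] == "RETINOID-A"]
        out = compute_tto(clean.cases, tables.ther, drug_rows)
        reasons = out["exclusion_reason"].value_counts()
        assert (
            reasons.get("none", 0) + reasons.get("missing_date", 0)
            + reasons.get("negative", 0)
        ) == clean.n_cases
        assert int(out["included"].sum()) == reasons.get("none", 0)


class TestSummarizeTto:
    def _records(self, days):
        return pd.DataFrame(
            {"onset_days": days, "included": [True] * len(days)}
        )

    def test_single_value_lands_in_first_bin(self):
        s = summarize_tto(self._records([5]))
        assert s.bin_counts == [1, 0, 0, 0, 0, 0]
        assert s.bin_proportions[0] == pytest.approx(1.0)

    def test_hand_binning(self):
        s = summarize_tto(self._records([10, 45, 100, 200, 400]))
        assert s.bin_counts == [1, 1, 0, 1, 1, 1]

    def test_median_is_middle_order_statistic(self):
        s = summarize_tto(self._records([31, 81, 169]))
        assert s.median_days == 81
        assert (s.q1, s.q3) == (56.0, 125.0)  # linear interpolation

    def test_proportions_sum_to_one(self):
        s = summarize_tto(self._records(list(range(0, 900, 7))))
        assert sum(s.bin_proportions) == pytest.approx(1.0, abs=1e-9)
        assert sum(s.bin_counts) == s.n_included

    def test_empty_input_marked_empty(self):
        s = summarize_tto(self._records([]))
        assert s.empty and s.n_included == 0

    def test_unordered_bin_edges_rejected(self):
        with pytest.raises(ValueError):
            summarize_tto(self._records([5]), bin_edges=(0, 60, 30))

    def test_empirical_median_within_order_statistic_ci(self):
        """Median of generated onsets covers the designed log-normal median."""
        from faersignal.synthetic import ONSET_LOG_MEDIAN

        true_median = np.exp(ONSET_LOG_MEDIAN)
        covered = 0
        for seed in range(20):
            cfg = default_config(n_cases=400, seed=100 + seed, dup_rate=0.0)
            cfg.missing_event_rate = 0.0
            cfg.missing_start_rate = 0.0
            cfg.negative_onset_rate = 0.0
            cfg.partial_date_rate = 0.0
            tables, _ = generate_faers_tables(cfg)
            drug_rows = tables.drug.drop_duplicates("primaryid")
            cases = tables.demo[["caseid", "primaryid", "event_dt"]]
            out = compute_tto(cases, tables.ther, drug_rows)
            days = np.sort(out.loc[out["included"], "onset_days"].astype(float))
            n = len(days)
            j = int(stats.binom.ppf(0.025, n, 0.5))
            k = int(stats.binom.ppf(0.975, n, 0.5))
            if days[max(j - 1, 0)] <= true_median <= days[min(k, n - 1)]:
                covered += 1
        assert covered >= 17


class TestDemographics:
    def test_sex_percentages(self, string_frame, lookups):
        from faersignal.cleaning import CleanCases

        cases = pd.DataFrame(
            {
                "caseid": list("1234"),
                "sex": ["F", "F", "F", "M"],
                "age_group": ["<18"] * 4,
                "reporter_class": ["Physician"] * 4,
                "country": ["US"] * 4,
                "fda_dt": ["20200101"] * 4,
            }
        )
        clean = CleanCases(
            cases=cases,
            events=pd.DataFrame(columns=["primaryid", "caseid", "pt"]),
            outcomes=pd.DataFrame(columns=["primaryid", "caseid", "outc_cod"]),
            indications=pd.DataFrame(
                columns=["primaryid", "caseid", "indi_drug_seq", "indi_pt"]
            ),
        )
        summary = summarize_demographics(clean)
        sex = summary["sex"].set_index("value")
        assert sex.loc["F", "pct"] == 75.0
        assert sex.loc["M", "pct"] == 25.0
        assert sex["pct"].sum() == pytest.approx(100.0, abs=0.1)

    def test_empty_input_counts_zero_percent_undefined(self):
        from faersignal.cleaning import CleanCases

        clean = CleanCases(
            cases=pd.DataFrame(
                columns=["caseid", "sex", "age_group", "reporter_class",
                         "country", "fda_dt"]
            ),
            events=pd.DataFrame(columns=["primaryid", "caseid", "pt"]),
            outcomes=pd.DataFrame(columns=["primaryid", "caseid", "outc_cod"]),
            indications=pd.DataFrame(
                columns=["primaryid", "caseid", "indi_drug_seq", "indi_pt"]
            ),
        )
        summary = summarize_demographics(clean)
        assert summary["sex"]["count"].sum() == 0
        assert summary["sex"]["pct"].isna().all()

    def test_single_valued_characteristics_sum_to_100(self, signal_config, lookups):
        tables, _ = generate_faers_tables(signal_config)
        retained = deduplicate(tables.demo)
        selected = select_drug_reports(tables.drug, {"RETINOID-A"})
        clean = build_clean_cases(tables, lookups, retained, selected)
        summary = summarize_demographics(clean)
        for key in ("sex", "age_group"):
            assert summary[key]["pct"].sum() == pytest.approx(100.0, abs=0.1)

    def test_percentage_helper_rounds_to_one_decimal(self):
        assert percentage(1, 3) == 33.3
        assert percentage(2, 3) == 66.7
        assert np.isnan(percentage(1, 0))
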