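"""Estimator arithmetic, shrinkage behaviour, and the consensus rule."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from faersignal.signals import (
    CANONICAL_PRIOR,
    CriteriaConfig,
    apply_criteria,
    build_contingency,
    compute_bcpnn,
    compute_ebgm,
    compute_prr,
    compute_ror,
    expected_counts,
    fit_mgps_prior,
)

CELLS = st.tuples(
    st.integers(1, 500), st.integers(0, 500), st.integers(0, 500), st.integers(0, 5000)
)


def _events(rows):
    return pd.DataFrame(rows, columns=["primaryid", "term", "is_target"])


class TestContingency:
    def test_two_report_hand_enumeration(self):
        events = _events(
            [("r1", "X", True), ("r1", "Y", True), ("r2", "X", False)]
        )
        table = build_contingency(events).set_index("term")
        assert tuple(table.loc["X", ["a", "b", "c", "d"]]) == (1, 1, 1, 0)
        assert tuple(table.loc["Y", ["a", "b", "c", "d"]]) == (1, 1, 0, 1)

    def test_duplicate_pt_in_one_report_counts_once(self):
        events = _events([("r1", "X", True), ("r1", "X", True), ("r2", "Y", False)])
        table = build_contingency(events).set_index("term")
        assert table.loc["X", "a"] == 1

    def test_terms_without_target_reports_suppressed(self):
        events = _events([("r1", "X", True), ("r2", "Z", False)])
        assert list(build_contingency(events)["term"]) == ["X"]

    def test_report_counting_mode(self):
        events = _events(
            [("r1", "X", True), ("r1", "Y", True), ("r2", "X", False),
             ("r3", "Y", False)]
        )
        table = build_contingency(events, counting="report").set_index("term")
        # 1 target report, 2 other reports
        assert tuple(table.loc["X", ["a", "b", "c", "d"]]) == (1, 0, 1, 1)
        assert tuple(table.loc["Y", ["a", "b", "c", "d"]]) == (1, 0, 1, 1)


class TestRor:
    def test_symmetric_table_is_null(self):
        ror, lo, hi = compute_ror(10, 10, 10, 10)
        assert ror == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_direct_arithmetic(self):
        ror, lo, hi = compute_ror(3, 7, 97, 893)
        se = np.sqrt(1 / 3 + 1 / 7 + 1 / 97 + 1 / 893)
        assert ror == pytest.approx(2679 / 679)
        assert lo == pytest.approx(np.exp(np.log(2679 / 679) - 1.96 * se))
        assert hi == pytest.approx(np.exp(np.log(2679 / 679) + 1.96 * se))
        assert lo == pytest.approx(1.004, abs=5e-3)
        assert hi == pytest.approx(15.5, abs=0.1)

    def test_haldane_correction_on_zero_cell(self):
        ror, lo, hi = compute_ror(3, 0, 97, 900)
        expected = (3.5 * 900.5) / (0.5 * 97.5)
        assert np.isfinite(ror) and ror == pytest.approx(expected)
        assert np.isfinite(lo) and np.isfinite(hi)


class TestPrr:
    def test_direct_arithmetic(self):
        prr, chi2 = compute_prr(3, 7, 97, 893)
        assert prr == pytest.approx(0.3 / (97 / 990))
        assert chi2 == pytest.approx(1000 * 2000**2 / (10 * 990 * 100 * 900))
        assert prr == pytest.approx(3.062, abs=1e-3)
        assert chi2 == pytest.approx(4.489, abs=1e-3)

    def test_independence_is_null(self):
        prr, chi2 = compute_prr(10, 10, 10, 10)
        assert prr == pytest.approx(1.0)
        assert chi2 == pytest.approx(0.0)

    def test_yates_correction_reduces_chi2(self):
        _, plain = compute_prr(3, 7, 97, 893)
        _, yates = compute_prr(3, 7, 97, 893, yates=True)
        assert yates < plain


class TestBcpnn:
    def test_absent_pair_has_negative_ic(self):
        ic, ic025 = compute_bcpnn(0, 100, 100, 9800)
        assert ic < 0

    def test_independence_at_large_n_is_near_zero(self):
        ic, _ = compute_bcpnn(100, 900, 900, 8100)
        assert abs(ic) <= 0.05

    def test_large_n_limit_matches_observed_to_expected_ratio(self):
        # proportions fixed, N = 1e6: shrinkage must vanish
        a, b, c, d = 2000, 18000, 18000, 962000
        n = a + b + c + d
        ic, _ = compute_bcpnn(a, b, c, d)
        limit = np.log2(a * n / ((a + b) * (a + c)))
        assert ic == pytest.approx(limit, abs=0.01)

    @settings(deadline=None, derandomize=True, max_examples=100)
    @given(CELLS)
    def test_ic025_never_exceeds_ic(self, cells):
        ic, ic025 = compute_bcpnn(*cells)
        assert ic025 <= ic


class TestEbgm:
    def test_large_count_escapes_shrinkage(self):
        ebgm, _ = compute_ebgm(1000, 100.0, CANONICAL_PRIOR)
        assert 9.0 < ebgm <= 10.0

    def test_small_count_is_strongly_shrunk(self):
        ebgm, _ = compute_ebgm(1, 1.0, CANONICAL_PRIOR)
        assert ebgm < 2.0

    def test_fifth_percentile_below_geometric_mean(self):
        rng = np.random.default_rng(0)
        a = rng.integers(1, 200, size=40)
        e = rng.uniform(0.2, 50.0, size=40)
        ebgm, ebgm05 = compute_ebgm(a, e, CANONICAL_PRIOR)
        assert np.all(ebgm05 < ebgm)

    def test_monotone_in_count_for_fixed_expected(self):
        counts = np.arange(1, 60)
        ebgm, _ = compute_ebgm(counts, np.full_like(counts, 5.0, dtype=float),
                               CANONICAL_PRIOR)
        assert np.all(np.diff(ebgm) >= -1e-12)

    def test_invalid_expected_count_is_missing(self):
        ebgm, ebgm05 = compute_ebgm(3, 0.0, CANONICAL_PRIOR)
        assert np.isnan(ebgm) and np.isnan(ebgm05)


class TestMgpsFit:
    def test_fewer_than_ten_tables_returns_canonical_unconverged(self):
        prior = fit_mgps_prior(np.array([1, 2, 3]), np.array([1.0, 1.0, 1.0]))
        assert prior.converged is False
        assert prior.as_array()[:4] == pytest.approx(
            CANONICAL_PRIOR.as_array()[:4]
        )

    def test_pure_null_tables_shrink_to_unity(self):
        rng = np.random.default_rng(1)
        e = rng.uniform(20, 200, size=2000)
        a = rng.poisson(e)
        prior = fit_mgps_prior(a, e)
        ebgm, _ = compute_ebgm(a, e, prior)
        assert np.mean(ebgm) == pytest.approx(1.0, abs=0.1)


class TestCriteria:
    IBD = dict(n=4570, ror_lo=471.69, prr=474.43, chi2=1019716.35, ic025=6.14,
               ebgm=224.57, ebgm05=216.71)

    def _frame(self, **over):
        row = {**self.IBD, **over}
        return pd.DataFrame([row])

    def test_strong_signal_passes_all_four(self):
        out = apply_criteria(self._frame())
        row = out.iloc[0]
        assert row[["ror_sig", "prr_sig", "bcpnn_sig", "ebgm_sig", "consensus"]].all()

    def test_two_reports_fail_the_count_gate(self):
        out = apply_criteria(self._frame(n=2, ror_lo=50.0))
        assert not out.iloc[0]["ror_sig"]
        assert not out.iloc[0]["consensus"]

    def test_null_statistics_fail_everything(self):
        out = apply_criteria(
            self._frame(n=100, ror_lo=0.8, prr=1.0, chi2=0.0, ic025=-0.5,
                        ebgm=1.0, ebgm05=0.9)
        )
        row = out.iloc[0]
        assert not row[["ror_sig", "prr_sig", "bcpnn_sig", "ebgm_sig"]].any()
        assert not row["consensus"]

    def test_missing_statistics_fail_their_flag(self):
        out = apply_criteria(self._frame(ic025=np.nan))
        assert not out.iloc[0]["bcpnn_sig"]
        assert not out.iloc[0]["consensus"]

    def test_ebgm05_gate_is_a_config_switch(self):
        frame = self._frame(ebgm=3.0, ebgm05=1.5)
        assert apply_criteria(frame, CriteriaConfig(ebgm_stat="EBGM")).iloc[0]["ebgm_sig"]
        assert not apply_criteria(frame, CriteriaConfig(ebgm_stat="EBGM05")).iloc[0]["ebgm_sig"]

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(
        CELLS,
        st.floats(0.0, 2.0),   # threshold weakening factors
        st.floats(0.0, 1.0),
    )
    def test_weakening_thresholds_never_unflags(self, cells, f1, f2):
        a, b, c, d = cells
        ror, lo, hi = compute_ror(a, b, c, d)
        prr, chi2 = compute_prr(a, b, c, d)
        ic, ic025 = compute_bcpnn(a, b, c, d)
        ebgm, ebgm05 = compute_ebgm(a, expected_counts(a, b, c, d), CANONICAL_PRIOR)
        frame = pd.DataFrame(
            [dict(n=a, ror_lo=lo, prr=prr, chi2=chi2, ic025=ic025,
                  ebgm=ebgm, ebgm05=ebgm05)]
        )
        strict = CriteriaConfig()
        weak = CriteriaConfig(
            min_count=int(strict.min_count * f2),
            prr_min=strict.prr_min * f2,
            chi2_min=strict.chi2_min * f2,
            ic025_min=strict.ic025_min - f1,
            ebgm_min=strict.ebgm_min * f2,
        )
        if apply_criteria(frame, strict).iloc[0]["consensus"]:
            assert apply_criteria(frame, weak).iloc[0]["consensus"]
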