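"""Disproportionality estimators, criteria engine, and scan behavior."""

from __future__ import annotations

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pvsignal as pv
from pvsignal.contingency import ContingencyTable
from conftest import make_report

cells = st.integers(min_value=1, max_value=500)


def T(a, b, c, d, **kw):
    return ContingencyTable(a, b, c, d, **kw)


class TestExpectedCount:
    @pytest.mark.parametrize(
        "table,expected",
        [
            (T(10, 90, 100, 9900), 100 * 110 / 10100),
            (T(1, 0, 0, 0), 1.0),
            (T(0, 10, 10, 80), 1.0),
        ],
    )
    def test_independence_baseline(self, table, expected):
        assert pv.expected_count(table) == pytest.approx(expected)

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            pv.expected_count(T(0, 0, 0, 0))


class TestROR:
    def test_symmetric_table_is_null(self):
        est, lo, hi = pv.ror(T(10, 10, 10, 10))
        assert est == pytest.approx(1.0)
        assert lo < 1.0 < hi

    def test_point_and_interval_match_oracle(self):
        from statsmodels.stats.contingency_tables import Table2x2

        table = T(10, 90, 100, 9900)
        est, lo, hi = pv.ror(table)
        assert est == pytest.approx(11.0)
        oracle = Table2x2(np.array([[10, 90], [100, 9900]]))
        olo, ohi = oracle.oddsratio_confint(0.05)
        assert (lo, hi) == pytest.approx((olo, ohi), rel=1e-10)
        assert (lo, hi) == pytest.approx((5.56, 21.77), abs=0.01)

    def test_zero_cell_haldane_correction(self):
        est, _, _ = pv.ror(T(0, 10, 10, 80), haldane="auto")
        assert est == pytest.approx((0.5 * 80.5) / (10.5 * 10.5))

    def test_zero_cell_without_correction_non_estimable(self):
        est, lo, hi = pv.ror(T(0, 10, 10, 80), haldane="none")
        assert math.isnan(est) and math.isnan(lo) and math.isnan(hi)


class TestPRR:
    def test_equal_proportions_give_unity(self):
        est, _, _ = pv.prr(T(10, 90, 100, 900))
        assert est == pytest.approx(1.0)

    def test_tenfold_reporting_rate(self):
        est, _, _ = pv.prr(T(10, 90, 100, 9900))
        assert est == pytest.approx(10.0)

    def test_zero_a_with_haldane_below_one_and_finite(self):
        est, _, _ = pv.prr(T(0, 10, 10, 80), haldane="auto")
        assert 0 < est < 1


class TestChiSquare:
    def test_independent_table_is_zero(self):
        assert pv.chi_square(T(10, 90, 100, 900), yates=False) == pytest.approx(0.0)
        assert pv.chi_square(T(10, 90, 100, 900), yates=True) == pytest.approx(0.0)

    def test_plain_matches_oracle(self):
        from scipy.stats import chi2_contingency

        table = T(10, 90, 100, 9900)
        plain = pv.chi_square(table, yates=False)
        assert plain == pytest.approx(74.45, abs=0.01)
        oracle = chi2_contingency(
            np.array([[10, 90], [100, 9900]]), correction=False
        ).statistic
        assert plain == pytest.approx(oracle, rel=1e-12)

    def test_yates_never_exceeds_plain(self):
        table = T(10, 90, 100, 9900)
        assert pv.chi_square(table, yates=True) <= pv.chi_square(table, yates=False)

    def test_zero_margin_non_estimable(self):
        assert math.isnan(pv.chi_square(T(0, 0, 10, 90)))


class TestIC:
    def test_observed_equal_expected_gives_zero(self):
        val, _ = pv.ic(T(10, 90, 100, 900), mode="plain")
        assert val == pytest.approx(0.0)

    def test_printed_rrr_convention(self):
        # an observed/expected reporting ratio of 2.22 corresponds to an
        # information component of 1.15 at two decimals
        val, _ = pv.ic_from_counts(2773, 2773 / 2.22, mode="plain")
        assert round(val, 2) == 1.15

    def test_plain_value_from_counts(self):
        table = T(10, 90, 100, 9900)
        val, low = pv.ic(table, mode="plain")
        assert val == pytest.approx(math.log2(10 / (100 * 110 / 10100)))
        assert val == pytest.approx(3.199, abs=5e-4)
        assert low < val

    def test_zero_a_plain_non_estimable_but_shrunk_finite(self):
        table = T(0, 10, 10, 80)
        assert math.isnan(pv.ic(table, mode="plain")[0])
        val, low = pv.ic(table, mode="shrunk")
        assert math.isfinite(val) and math.isfinite(low)

    def test_shrunk_formula(self):
        table = T(10, 90, 100, 9900)
        e = pv.expected_count(table)
        val, low = pv.ic(table, mode="shrunk")
        assert val == pytest.approx(math.log2(10.5 / (e + 0.5)))
        assert low == pytest.approx(val - 3.3 * 10.5**-0.5 - 2 * 10.5**-1.5)


class TestEBGM:
    def test_plain_null(self):
        val, low = pv.ebgm(T(10, 90, 100, 900))
        assert val == pytest.approx(1.0)
        assert low < 1.0

    def test_plain_equals_observed_over_expected(self):
        val, _ = pv.ebgm_from_counts(2773, 2773 / 2.22)
        assert val == pytest.approx(2.22)

    def test_mgps_mode_shrinks_toward_prior(self):
        prior = pv.MGPSPrior(1.0, 1.0, 1.0, 1.0, 0.5)
        table = T(10, 90, 100, 9900)
        val, low = pv.ebgm(table, mode="mgps", prior=prior)
        from scipy.special import digamma

        e = pv.expected_count(table)
        assert val == pytest.approx(math.exp(digamma(11)) / (1 + e), rel=1e-12)
        assert val == pytest.approx(5.03, abs=0.01)
        assert low < val < 10 / e  # shrunk from the plain estimate
        with pytest.raises(ValueError):
            pv.ebgm(table, mode="mgps", prior=None)


class TestCriteria:
    def test_strong_signal_passes_all_four(self):
        stats = pv.SignalStats(
            label="Investigations", n=2773, ror_low=2.32, prr=2.22,
            chi2=1989.46, ic025=1.09, ebgm=2.22,
        )
        out = pv.evaluate_criteria(stats)
        assert (out.ror_sig, out.prr_sig, out.bcpnn_sig, out.mgps_sig) == (
            True, True, True, True,
        )
        assert out.overall_sig

    def test_weak_ror_only_signal_fails_prr_and_ebgm(self):
        stats = pv.SignalStats(
            label="Nervous system disorders", n=1836, ror_low=1.02, prr=1.07,
            chi2=8.19, ic025=0.02, ebgm=1.07,
        )
        out = pv.evaluate_criteria(stats)
        assert out.ror_sig and out.bcpnn_sig
        assert not out.prr_sig and not out.mgps_sig
        assert not out.overall_sig

    def test_null_statistics_raise_no_flags(self):
        stats = pv.SignalStats(
            label="x", n=5, ror_low=1.0, prr=1.0, chi2=0.0, ic025=0.0, ebgm=1.0
        )
        out = pv.evaluate_criteria(stats)
        assert not any(
            [out.ror_sig, out.prr_sig, out.bcpnn_sig, out.mgps_sig, out.overall_sig]
        )

    def test_nan_statistics_never_significant(self):
        out = pv.evaluate_criteria(pv.SignalStats(label="x"))
        assert not out.overall_sig

    def test_optional_minimum_case_floor(self):
        stats = pv.SignalStats(
            label="x", n=2, ror_low=5.0, prr=9.0, chi2=50.0, ic025=2.0, ebgm=8.0
        )
        assert pv.evaluate_criteria(stats).overall_sig
        floored = pv.evaluate_criteria(
            stats, pv.CriteriaConfig(min_cases=3)
        )
        assert not floored.overall_sig


@given(a=cells, b=cells, c=cells, d=cells)
@settings(max_examples=300, deadline=None, derandomize=True)
def test_estimators_agree_in_direction(a, b, c, d):
    """ROR>1, PRR>1, a>E, plain IC>0 and plain EBGM>1 are equivalent."""
    table = T(a, b, c, d)
    e = pv.expected_count(table)
    directions = {
        "ror": pv.ror(table)[0] > 1,
        "prr": pv.prr(table)[0] > 1,
        "obs_gt_exp": a > e,
        "ic": pv.ic(table, mode="plain")[0] > 0,
        "ebgm": pv.ebgm(table, mode="plain")[0] > 1,
    }
    assert len(set(directions.values())) == 1 or a == pytest.approx(e)


@given(a=cells, b=cells, c=cells, d=cells)
@settings(max_examples=200, deadline=None, derandomize=True)
def test_interval_bounds_ordered_and_ic_matches_log2_ebgm(a, b, c, d):
    stats = pv.compute_signal_stats(T(a, b, c, d))
    assert stats.ror_low <= stats.ror <= stats.ror_high
    assert stats.prr_low <= stats.prr <= stats.prr_high
    assert stats.ic025 <= stats.ic
    assert stats.ebgm05 <= stats.ebgm
    assert min(stats.ror, stats.prr, stats.ebgm) >= 0
    assert stats.expected > 0
    # plain-mode convention: IC is exactly log2(EBGM)
    assert stats.ic == pytest.approx(math.log2(stats.ebgm), rel=1e-12)


class TestScan:
    def _reports(self):
        reports = []
        for i in range(12):
            drug = "X" if i < 6 else "other"
            pts = ["PT_A"] if i % 3 else ["PT_A", "PT_B"]
            reports.append(
                make_report(
                    f"C{i}",
                    drugs=((drug, pv.DrugRole.PRIMARY_SUSPECT, None),),
                    events=tuple((p, None) for p in pts),
                )
            )
        return reports

    def test_empty_focal_set_gives_empty_scan(self):
        result = pv.run_signal_scan(self._reports(), "absent")
        assert result.stats == []

    def test_invariant_under_report_permutation(self):
        import random

        reports = self._reports()
        shuffled = reports[:]
        random.Random(1).shuffle(shuffled)
        r1 = pv.run_signal_scan(reports, "X")
        r2 = pv.run_signal_scan(shuffled, "X")
        assert r1.stats == r2.stats

    def test_dual_rankings_with_deterministic_tie_break(self):
        result = pv.run_signal_scan(self._reports(), "X")
        by_n = result.ranked_by_n()
        assert [s.n for s in by_n] == sorted((s.n for s in by_n), reverse=True)
        by_ror = result.ranked_by_ror()
        rors = [s.ror for s in by_ror if not math.isnan(s.ror)]
        assert rors == sorted(rors, reverse=True)

    def test_planted_signal_ranks_first_by_ror(self, planted_scan):
        from conftest import PLANTED_PT

        top = planted_scan.ranked_by_ror()[0]
        assert top.label == PLANTED_PT
        assert top.overall_sig
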