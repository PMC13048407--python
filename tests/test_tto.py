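"""Time-to-onset: per-report computation, binning, quantiles, ECDF."""

from __future__ import annotations

from datetime import date

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pvsignal as pv
from pvsignal.tto import TTOExclusion, TTORecord
from conftest import make_report


class TestComputeTTO:
    def test_sixty_two_days(self):
        rep = make_report(
            drugs=(("X", pv.DrugRole.PRIMARY_SUSPECT, date(2023, 1, 1)),),
            events=(("PT0001", date(2023, 3, 4)),),
        )
        out = pv.compute_tto(rep, "X")
        assert isinstance(out, TTORecord) and out.days == 62

    def test_onset_on_start_date_is_day_zero(self):
        rep = make_report(
            drugs=(("X", pv.DrugRole.PRIMARY_SUSPECT, date(2023, 1, 1)),),
            events=(("PT0001", date(2023, 1, 1)),),
        )
        assert pv.compute_tto(rep, "X").days == 0

    def test_earliest_event_defines_the_report_tto(self):
        rep = make_report(
            drugs=(("X", pv.DrugRole.PRIMARY_SUSPECT, date(2023, 1, 1)),),
            events=(
                ("PT0001", date(2023, 5, 1)),
                ("PT0002", date(2023, 1, 11)),
            ),
        )
        assert pv.compute_tto(rep, "X").days == 10

    @pytest.mark.parametrize(
        "drugs,events,reason",
        [
            (
                (("X", pv.DrugRole.PRIMARY_SUSPECT, date(2023, 2, 1)),),
                (("PT0001", date(2023, 1, 1)),),
                "negative_tto",
            ),
            (
                (("X", pv.DrugRole.PRIMARY_SUSPECT, None),),
                (("PT0001", date(2023, 1, 1)),),
                "missing_start",
            ),
            (
                (("X", pv.DrugRole.PRIMARY_SUSPECT, date(2023, 1, 1)),),
                (("PT0001", None),),
                "missing_onset",
            ),
            (
                (("Y", pv.DrugRole.PRIMARY_SUSPECT, date(2023, 1, 1)),),
                (("PT0001", date(2023, 2, 1)),),
                "drug_absent",
            ),
        ],
    )
    def test_exclusions_carry_reason_codes(self, drugs, events, reason):
        rep = make_report(drugs=drugs, events=events)
        out = pv.compute_tto(rep, "X")
        assert isinstance(out, TTOExclusion) and out.reason == reason

    def test_collect_splits_records_from_audit(self):
        good = make_report(
            "C1",
            drugs=(("X", pv.DrugRole.PRIMARY_SUSPECT, date(2023, 1, 1)),),
            events=(("PT0001", date(2023, 1, 8)),),
        )
        bad = make_report(
            "C2",
            drugs=(("X", pv.DrugRole.PRIMARY_SUSPECT, None),),
            events=(("PT0001", date(2023, 1, 8)),),
        )
        records, audit = pv.collect_tto([good, bad], "X")
        assert [r.days for r in records] == [7]
        assert [(x.case_id, x.reason) for x in audit] == [("C2", "missing_start")]


class TestDistribution:
    def test_interval_percentages_from_counts(self):
        # 861 early, 450 late, remainder in between, out of 2209 reports
        records = (
            [TTORecord(f"E{i}", 10) for i in range(861)]
            + [TTORecord(f"M{i}", 100) for i in range(2209 - 861 - 450)]
            + [TTORecord(f"L{i}", 400) for i in range(450)]
        )
        summary = pv.tto_distribution(records)
        by_label = dict(
            zip(summary.bin_labels, zip(summary.bin_counts, summary.bin_percentages))
        )
        assert by_label["0-30"] == (861, 38.98)
        assert by_label[">360"] == (450, 20.37)

    def test_three_records_three_bins(self):
        records = [TTORecord(f"C{i}", d) for i, d in enumerate([5, 45, 400])]
        summary = pv.tto_distribution(records, [0, 30, 360, float("inf")])
        assert summary.bin_counts == [1, 1, 1]

    def test_bin_boundaries_left_open_after_first(self):
        records = [TTORecord(f"C{i}", d) for i, d in enumerate([0, 30, 31, 360, 361])]
        summary = pv.tto_distribution(records, [0, 30, 360, float("inf")])
        assert summary.bin_counts == [2, 2, 1]

    def test_percentages_sum_to_100_within_rounding(self):
        rng = np.random.default_rng(0)
        records = [
            TTORecord(f"C{i}", int(d))
            for i, d in enumerate(rng.integers(0, 700, size=997))
        ]
        summary = pv.tto_distribution(records)
        assert sum(summary.bin_counts) == summary.n_valid == 997
        # each of the 6 bins rounds by at most 0.005
        assert sum(summary.bin_percentages) == pytest.approx(100.0, abs=0.03)

    def test_empty_records_all_zero(self):
        summary = pv.tto_distribution([])
        assert summary.n_valid == 0 and set(summary.bin_counts) == {0}

    def test_bad_edges_rejected(self):
        with pytest.raises(ValueError):
            pv.tto_distribution([], [10, 30, float("inf")])


class TestSummary:
    def test_linear_interpolation_quartiles(self):
        records = [TTORecord(f"C{i}", d) for i, d in enumerate([1, 2, 3])]
        summary = pv.tto_summary(records)
        assert summary.median_days == 2.0
        assert (summary.iqr_low, summary.iqr_high) == (1.5, 2.5)

    def test_constant_sample_collapses_quartiles(self):
        records = [TTORecord(f"C{i}", 17) for i in range(5)]
        summary = pv.tto_summary(records)
        assert summary.median_days == summary.iqr_low == summary.iqr_high == 17

    def test_ecdf_nondecreasing_and_ends_at_one(self):
        rng = np.random.default_rng(1)
        records = [
            TTORecord(f"C{i}", int(d))
            for i, d in enumerate(rng.integers(0, 500, size=200))
        ]
        summary = pv.tto_summary(records)
        fracs = [f for _, f in summary.ecdf]
        assert fracs == sorted(fracs)
        assert fracs[-1] == pytest.approx(1.0)

    def test_empty_input_is_an_error(self):
        with pytest.raises(ValueError):
            pv.tto_summary([])

    @given(st.lists(st.integers(0, 1000), min_size=1, max_size=50))
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_appending_a_new_maximum_never_lowers_the_median(self, days):
        records = [TTORecord(f"C{i}", d) for i, d in enumerate(days)]
        before = pv.tto_summary(records).median_days
        extended = records + [TTORecord("CX", max(days) + 1)]
        after = pv.tto_summary(extended).median_days
        assert after >= before

    def test_generator_onset_median_matches_analytic_mixture(self):
        """A direct large draw from the onset mixture lands on the analytic
        median within Monte-Carlo tolerance."""
        config = pv.SyntheticConfig(
            n_reports=10_000,
            drug_prevalence=1.0,
            concomitant_fraction=0.0,
            p_missing_start=0.0,
            p_missing_onset=0.0,
            p_negative_onset=0.0,
            seed=123,
        )
        reports, _ = pv.generate_reports(config)
        records, audit = pv.collect_tto(reports, config.drug_name)
        assert not audit
        summary = pv.tto_summary(records)
        analytic = config.onset_model.quantile(0.5)
        # 3 SE via the density at the median, plus integer-rounding slack
        assert abs(summary.median_days - analytic) < 6.0
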