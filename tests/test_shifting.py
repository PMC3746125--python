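"""Shift classification, fiscal-year decomposition, multi-year averages,
reporting rounding, and the minimum-share filter."""

import pytest

from cigshift import (
    HalfYear,
    MissingDataError,
    average_yearly_deltas,
    build_segment_series,
    decompose_year,
    filter_panel_by_share,
    filtered_shift,
    multi_year_average,
    net_real_change,
    report_round,
    shifting_table,
    weighted_average_price,
)
from cigshift.shifting import FULL_SHIFT, OVERSHIFT, UNDERSHIFT, classify

from conftest import make_panel, make_series


class TestClassification:
    def test_identical_endpoints_full_shift(self):
        s = make_series("premium", ["2006H2", "2007H2"], [100.0, 100.0])
        res = net_real_change(s, HalfYear(2006, 2), HalfYear(2007, 2))
        assert res.delta_net_real == 0.0
        assert res.classification == FULL_SHIFT

    def test_positive_real_net_gain_is_overshift(self):
        s = make_series("premium", ["2006H2", "2007H2"], [100.0, 105.0])
        res = net_real_change(s, HalfYear(2006, 2), HalfYear(2007, 2))
        assert res.classification == OVERSHIFT

    def test_tolerance_boundary(self):
        assert classify(0.05) == FULL_SHIFT
        assert classify(0.051) == OVERSHIFT
        assert classify(-0.051) == UNDERSHIFT

    def test_missing_period_errors(self):
        s = make_series("premium", ["2006H2", "2007H2"], [100.0, 105.0])
        with pytest.raises(MissingDataError):
            net_real_change(s, HalfYear(2006, 2), HalfYear(2008, 2))


class TestDecomposition:
    def test_halves_sum_to_annual_ulp_style(self):
        # a -3.0 duty-window fall plus a +4.3 quiet-window rise is a +1.3 year
        s = make_series("ulp", ["2006H2", "2007H1", "2007H2"], [50.0, 47.0, 51.3])
        nov_may, may_nov, nov_nov = decompose_year(s, 2006)
        assert nov_may.delta_net_real == pytest.approx(-3.0)
        assert may_nov.delta_net_real == pytest.approx(4.3)
        assert nov_nov.delta_net_real == pytest.approx(1.3)
        assert nov_may.delta_net_real + may_nov.delta_net_real == pytest.approx(
            nov_nov.delta_net_real, abs=1e-12
        )

    def test_premium_style_halves(self):
        s = make_series("premium", ["2006H2", "2007H1", "2007H2"], [100.0, 102.9, 104.1])
        nov_may, may_nov, nov_nov = decompose_year(s, 2006)
        assert nov_may.delta_net_real == pytest.approx(2.9)
        assert may_nov.delta_net_real == pytest.approx(1.2)
        assert nov_nov.delta_net_real == pytest.approx(4.1)

    def test_zero_series_all_zero(self):
        s = make_series("mid", ["2006H2", "2007H1", "2007H2"], [80.0, 80.0, 80.0])
        assert all(r.delta_net_real == 0.0 for r in decompose_year(s, 2006))

    def test_missing_bounding_period_errors(self):
        s = make_series("mid", ["2006H2", "2007H1"], [80.0, 81.0])
        with pytest.raises(MissingDataError):
            decompose_year(s, 2006)


class TestAverages:
    def test_premium_style_three_year_mean(self):
        # yearly changes 4.6, 2.2, 5.7: mean 4.1667, within rounding slack of 4.1
        assert abs(average_yearly_deltas([4.6, 2.2, 5.7]) - 4.1) <= 0.07

    def test_ulp_style_three_year_mean(self):
        assert report_round(average_yearly_deltas([4.8, -3.6, 2.8])) == pytest.approx(1.3)

    def test_single_year_is_that_delta(self):
        assert average_yearly_deltas([2.5]) == pytest.approx(2.5)

    def test_rounded_vs_unrounded_average(self):
        deltas = [1.04, 1.04, 1.04]
        assert average_yearly_deltas(deltas, average_rounded_years=True) == pytest.approx(1.0)
        assert average_yearly_deltas(deltas, average_rounded_years=False) == pytest.approx(1.04)

    def test_series_mean_matches_yearly_deltas(self):
        s = make_series(
            "premium",
            ["2006H2", "2007H1", "2007H2", "2008H1", "2008H2", "2009H1", "2009H2"],
            [100.0, 102.9, 104.6, 105.0, 106.8, 109.0, 112.5],
        )
        years = [2006, 2007, 2008]
        by_hand = [
            s.net_real(HalfYear(y + 1, 2)) - s.net_real(HalfYear(y, 2)) for y in years
        ]
        assert multi_year_average(s, years, average_rounded_years=False) == pytest.approx(
            sum(by_hand) / 3
        )


class TestReportRound:
    @pytest.mark.parametrize(
        "value,expected",
        [(4.1667, 4.2), (0.25, 0.3), (-0.25, -0.3), (1.333, 1.3), (-3.04, -3.0), (0.0, 0.0)],
    )
    def test_half_away_from_zero(self, value, expected):
        assert report_round(value) == pytest.approx(expected)


class TestShareFilter:
    def _panel(self):
        rows = []
        for label in ("2006H2", "2007H1", "2007H2"):
            rows += [
                ("big", label, 500.0, 20, 0.30, "scan", "premium"),
                ("tiny", label, 400.0, 20, 0.002, "scan", "premium"),
            ]
        return make_panel(rows)

    def test_zero_threshold_is_identity(self):
        panel = self._panel()
        out = filter_panel_by_share(panel, 0.0, HalfYear(2006, 2))
        assert sorted(out.brands()) == ["big", "tiny"]

    def test_threshold_is_strict(self):
        out = filter_panel_by_share(self._panel(), 0.002, HalfYear(2006, 2))
        assert out.brands() == ["big"]

    def test_filter_moves_wap_toward_large_brand(self):
        panel = self._panel()
        before = weighted_average_price(panel, "premium", HalfYear(2006, 2))
        after = weighted_average_price(
            filter_panel_by_share(panel, 0.002, HalfYear(2006, 2)),
            "premium",
            HalfYear(2006, 2),
        )
        assert after == 500.0 > before

    def test_filtered_table_drops_emptied_segment(self, zero_schedule, flat_cpi):
        rows = []
        for label in ("2006H2", "2007H1", "2007H2"):
            rows += [
                ("big", label, 500.0, 20, 0.30, "scan", "premium"),
                ("u", label, 300.0, 20, 0.001, "scan", "ulp"),
            ]
        panel = make_panel(rows)
        table = filtered_shift(panel, zero_schedule, flat_cpi, 0.002, [2006])
        assert "ulp" not in set(table["segment"])
        assert "premium" in set(table["segment"])


class TestTable:
    def test_duty_event_flag(self, flat_cpi):
        from datetime import date

        from cigshift import RegimeSchedule, TaxRegime

        schedule = RegimeSchedule(
            (
                TaxRegime(date(2006, 1, 1), 0.0, 0.0, 0.0),
                TaxRegime(date(2007, 4, 1), 100.0, 0.0, 0.0),
            )
        )
        s = make_series("premium", ["2006H2", "2007H1", "2007H2"], [100.0, 101.0, 102.0])
        nov_may, may_nov, _ = decompose_year(s, 2006, schedule)
        assert nov_may.contains_duty_event
        assert not may_nov.contains_duty_event

    def test_table_layout_and_rounding(self, zero_schedule, flat_cpi):
        s = make_series(
            "premium",
            ["2006H2", "2007H1", "2007H2", "2008H1", "2008H2"],
            [100.0, 102.9, 104.14, 105.0, 107.0],
        )
        table = shifting_table({"premium": s}, [2006, 2007], zero_schedule)
        row = table.iloc[0]
        assert row["2006-07"] == pytest.approx(4.1)  # 4.14 rounds down
        assert row["2007-08"] == pytest.approx(2.9)  # 107.0 - 104.14 = 2.86 rounds up
        assert set(table.columns) >= {"segment", "nov_may", "may_nov", "nov_nov"}
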