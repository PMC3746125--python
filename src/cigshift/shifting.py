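"""Tax-shifting detection: real net-of-tax price changes by segment.

If a manufacturer passes a duty increase through one-for-one and otherwise
tracks inflation, the real net-of-tax revenue per pack is unchanged across
the window containing the increase. A rise in real net revenue means the
tax was **overshifted** (prices went up by more than tax plus inflation);
a fall means it was **undershifted** (part of the tax was absorbed).

The analysis windows follow the fiscal calendar: each analysis year runs
November to November and splits into a November-May half (containing the
annual March/April duty uplift) and a May-November half (duty-quiet). The
two half-window changes sum to the annual change exactly, because all
three are differences of the same real net-revenue series.

Reported figures are rounded to one decimal (half away from zero); by
default multi-year averages are taken over the already-rounded yearly
changes, mirroring how such tables are typically assembled, with the
full-precision variant available via ``average_rounded_years=False``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd

from .deflation import IndexSeries
from .errors import DomainError, MissingDataError
from .panel import Panel
from .periods import HalfYear
from .segments import SegmentSeries, build_all_series
from .tax import RegimeSchedule

#: Classification tolerance in real pence: half the one-decimal reporting
#: precision, so a change that would print as 0.0 counts as full shift.
CLASSIFICATION_TOL = 0.05

OVERSHIFT = "overshift"
FULL_SHIFT = "full_shift"
UNDERSHIFT = "undershift"


def report_round(x: float, ndigits: int = 1) -> float:
    """Round half away from zero, the convention for reported pence figures."""
    factor = 10.0**ndigits
    return math.copysign(math.floor(abs(x) * factor + 0.5), x) / factor


def classify(delta: float, tol: float = CLASSIFICATION_TOL) -> str:
    if delta > tol:
        return OVERSHIFT
    if delta < -tol:
        return UNDERSHIFT
    return FULL_SHIFT


@dataclass(frozen=True)
class ShiftResult:
    """Real net-of-tax change for one segment over one window."""

    segment: str
    window: tuple[HalfYear, HalfYear]
    delta_net_real: float
    classification: str
    contains_duty_event: bool


def net_real_change(series: SegmentSeries, from_period: HalfYear, to_period: HalfYear,
                    schedule: RegimeSchedule | None = None,
                    tol: float = CLASSIFICATION_TOL) -> ShiftResult:
    """Change in real net revenue between two periods of a segment series.

    ``contains_duty_event`` is true when a regime change date falls in the
    half-open window (from, to]; it requires ``schedule`` and is False
    otherwise.
    """
    delta = series.net_real(to_period) - series.net_real(from_period)
    event = False
    if schedule is not None:
        event = any(
            from_period.date < d <= to_period.date for d in schedule.change_dates()
        )
    return ShiftResult(
        segment=series.segment,
        window=(from_period, to_period),
        delta_net_real=delta,
        classification=classify(delta, tol),
        contains_duty_event=event,
    )


def decompose_year(series: SegmentSeries, year: int,
                   schedule: RegimeSchedule | None = None,
                   tol: float = CLASSIFICATION_TOL
                   ) -> tuple[ShiftResult, ShiftResult, ShiftResult]:
    """Split analysis year ``year`` (Nov ``year`` -> Nov ``year+1``) into its
    duty half (Nov-May) and quiet half (May-Nov).

    Returns (nov_may, may_nov, nov_nov); the two half deltas sum to the
    annual delta exactly (before any rounding).
    """
    start = HalfYear(year, 2)
    mid = HalfYear(year + 1, 1)
    end = HalfYear(year + 1, 2)
    nov_may = net_real_change(series, start, mid, schedule, tol)
    may_nov = net_real_change(series, mid, end, schedule, tol)
    nov_nov = net_real_change(series, start, end, schedule, tol)
    return nov_may, may_nov, nov_nov


def yearly_deltas(series: SegmentSeries, years: Sequence[int]) -> list[float]:
    """November-to-November real net-revenue change for each analysis year."""
    return [
        series.net_real(HalfYear(y + 1, 2)) - series.net_real(HalfYear(y, 2))
        for y in years
    ]


def average_yearly_deltas(deltas: Sequence[float],
                          average_rounded_years: bool = True) -> float:
    """Mean of yearly changes; by default each year is first rounded to the
    one-decimal reporting precision."""
    if not deltas:
        raise DomainError("need at least one yearly delta")
    if average_rounded_years:
        deltas = [report_round(d) for d in deltas]
    return sum(deltas) / len(deltas)


def multi_year_average(series: SegmentSeries, years: Sequence[int],
                       average_rounded_years: bool = True) -> float:
    """Average annual (Nov-Nov) real net-of-tax change over several years,
    in pence per pack per annum."""
    return average_yearly_deltas(yearly_deltas(series, years), average_rounded_years)


def shifting_table(series_by_segment: Mapping[str, SegmentSeries], years: Sequence[int],
                   schedule: RegimeSchedule | None = None,
                   average_rounded_years: bool = True) -> pd.DataFrame:
    """Per-segment table of yearly changes and multi-year window averages.

    Columns: one per analysis year (labelled by its November start, e.g.
    ``2006-07``), then the averages of the Nov-May, May-Nov and Nov-Nov
    window changes over all years. Values are reported at one decimal.
    """
    records = []
    for segment, series in series_by_segment.items():
        row: dict[str, object] = {"segment": segment}
        nov_may, may_nov, nov_nov = [], [], []
        for y in years:
            a, b, c = decompose_year(series, y, schedule)
            row[f"{y}-{(y + 1) % 100:02d}"] = report_round(c.delta_net_real)
            nov_may.append(a.delta_net_real)
            may_nov.append(b.delta_net_real)
            nov_nov.append(c.delta_net_real)
        row["nov_may"] = report_round(average_yearly_deltas(nov_may, average_rounded_years))
        row["may_nov"] = report_round(average_yearly_deltas(may_nov, average_rounded_years))
        row["nov_nov"] = report_round(average_yearly_deltas(nov_nov, average_rounded_years))
        records.append(row)
    return pd.DataFrame.from_records(records)


def filter_panel_by_share(panel: Panel, min_share: float, at_period: HalfYear) -> Panel:
    """Keep only brands whose whole-market share at ``at_period`` is strictly
    greater than ``min_share`` (a brand exactly at the threshold is dropped)."""
    if not (0 <= min_share < 1):
        raise DomainError(f"min_share must be in [0,1), got {min_share}")
    base = panel.rows(at_period)
    keep = set(base.loc[base["volume_share"] > min_share, "brand_id"])
    df = panel.df[panel.df["brand_id"].isin(keep)].reset_index(drop=True)
    return Panel(df, segment_map=panel.segment_map, archived=panel.archived)


def filtered_shift(panel: Panel, schedule: RegimeSchedule, cpi: IndexSeries,
                   min_share: float, years: Sequence[int],
                   at_period: HalfYear | None = None,
                   average_rounded_years: bool = True) -> pd.DataFrame:
    """Shifting table restricted to brands above a minimum market share.

    The filter is applied at the initial period (default: November of the
    first analysis year) before any WAP is computed, so dropping marginal
    brands changes segment composition for the whole window. A segment
    emptied by the filter is reported as missing (absent row).
    """
    if at_period is None:
        at_period = HalfYear(min(years), 2)
    filtered = filter_panel_by_share(panel, min_share, at_period)
    series: dict[str, SegmentSeries] = {}
    for seg, s in build_all_series(filtered, schedule, cpi).items():
        try:
            for y in years:
                decompose_year(s, y)
        except MissingDataError:
            continue  # segment emptied (or truncated) by the filter
        series[seg] = s
    return shifting_table(series, years, schedule, average_rounded_years)
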