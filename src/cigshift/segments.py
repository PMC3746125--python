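"""Per-segment time series: weighted average price, tax and net revenue.

For each price segment and semiannual period this module computes the
within-segment volume-weighted average price (WAP), the per-pack tax due
on that WAP under the regime in force at the observation date, and the
net-of-tax revenue WAP - tax, each in nominal and in real (CPI-deflated)
pence. Tax is deliberately computed on the segment WAP rather than
averaged over per-brand tax bills: with a mixed specific/ad-valorem/VAT
structure the two coincide in the specific component but can differ in the
price-proportional components when weights and the averaging order
interact with reporting conventions; computing on the WAP matches how
official per-pack tax burdens are quoted.

Periods where a segment has no observations (the ULP tier before its 2006
market entry) are gaps, not zeros.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .deflation import IndexSeries, deflate
from .errors import MissingDataError, ValidationError
from .panel import ALL_SEGMENTS, SEGMENTS, UNASSIGNED, Panel
from .periods import HalfYear
from .tax import RegimeSchedule, regime_at, tax_breakdown


def _segment_rows(panel: Panel, segment: str, period: HalfYear) -> pd.DataFrame:
    df = panel.rows(period)
    if segment == ALL_SEGMENTS:
        return df[df["segment"] != UNASSIGNED]
    return df[df["segment"] == segment]


def weighted_average_price(panel: Panel, segment: str, period: HalfYear,
                           renormalize: bool = True) -> float:
    """Volume-weighted mean price of the segment's brands in a period.

    With ``renormalize=True`` (default) weights are the brands' shares
    relative to the segment total; with ``False`` the denominator is the
    whole-market share mass observed that period (a sensitivity variant
    that scales the result by the segment's share of observed volume).
    """
    rows = _segment_rows(panel, segment, period)
    w = rows["volume_share"].to_numpy(dtype=float)
    p = rows["nominal_price"].to_numpy(dtype=float)
    if len(rows) == 0 or w.sum() <= 0:
        raise MissingDataError(f"segment {segment!r} has no share mass in {period}")
    denom = w.sum() if renormalize else panel.rows(period)["volume_share"].sum()
    return float((w * p).sum() / denom)


def segment_share(panel: Panel, segment: str, period: HalfYear) -> float:
    """Whole-market volume share held by the segment's brands in a period."""
    return float(_segment_rows(panel, segment, period)["volume_share"].sum())


def others_share(panel: Panel, period: HalfYear) -> float:
    """Share mass not assigned to any named segment: unassigned brands plus
    the remainder of the market the panel does not observe."""
    assigned = sum(segment_share(panel, s, period) for s in SEGMENTS)
    return float(1.0 - assigned)


@dataclass
class SegmentSeries:
    """Ordered per-period metrics for one segment (pence per pack)."""

    segment: str
    periods: list[HalfYear]
    wap_nominal: np.ndarray
    wap_real: np.ndarray
    tax_total: np.ndarray
    net_revenue_nominal: np.ndarray
    net_revenue_real: np.ndarray
    segment_share: np.ndarray

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.periods, self.periods[1:])):
            raise ValidationError("SegmentSeries periods must be strictly increasing")

    def index_of(self, period: HalfYear) -> int:
        try:
            return self.periods.index(period)
        except ValueError:
            raise MissingDataError(
                f"period {period} missing from {self.segment!r} series"
            ) from None

    def net_real(self, period: HalfYear) -> float:
        return float(self.net_revenue_real[self.index_of(period)])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "segment": self.segment,
                "period": [str(p) for p in self.periods],
                "wap_nominal": self.wap_nominal,
                "wap_real": self.wap_real,
                "tax_total": self.tax_total,
                "net_revenue_nominal": self.net_revenue_nominal,
                "net_revenue_real": self.net_revenue_real,
                "segment_share": self.segment_share,
            }
        )


def build_segment_series(panel: Panel, schedule: RegimeSchedule, cpi: IndexSeries,
                         segment: str, pack_size: int = 20,
                         renormalize: bool = True) -> SegmentSeries:
    """Assemble the full per-period series for one segment (or ``"all"``).

    Per period: WAP -> tax breakdown at the regime in force on the
    representative date -> net revenue; price and net revenue are then
    CPI-deflated. Only periods where the segment carries share mass enter
    the series.
    """
    periods, wap_n, wap_r, tax_t, net_n, net_r, shares = [], [], [], [], [], [], []
    for period in panel.periods():
        rows = _segment_rows(panel, segment, period)
        if len(rows) == 0 or rows["volume_share"].sum() <= 0:
            continue
        try:
            wap = weighted_average_price(panel, segment, period, renormalize=renormalize)
            bd = tax_breakdown(wap, pack_size, regime_at(period.date, schedule))
            wap_real = deflate(wap, period, cpi)
            net_real = deflate(bd.net_revenue, period, cpi)
        except MissingDataError as exc:
            raise MissingDataError(f"segment {segment!r}: {exc}") from exc
        periods.append(period)
        wap_n.append(wap)
        wap_r.append(wap_real)
        tax_t.append(bd.total)
        net_n.append(bd.net_revenue)
        net_r.append(net_real)
        shares.append(segment_share(panel, segment, period))
    if not periods:
        raise MissingDataError(f"segment {segment!r} has no observations")
    return SegmentSeries(
        segment=segment,
        periods=periods,
        wap_nominal=np.asarray(wap_n),
        wap_real=np.asarray(wap_r),
        tax_total=np.asarray(tax_t),
        net_revenue_nominal=np.asarray(net_n),
        net_revenue_real=np.asarray(net_r),
        segment_share=np.asarray(shares),
    )


def build_all_series(panel: Panel, schedule: RegimeSchedule, cpi: IndexSeries,
                     segments: Sequence[str] | None = None, include_market: bool = True,
                     pack_size: int = 20) -> dict[str, SegmentSeries]:
    """Series for every requested segment plus, optionally, the whole
    (assigned) market under the key ``"all"``. Segments with no data are
    silently omitted only if not explicitly requested."""
    if segments is None:
        present = {s for s in panel.df["segment"] if s != UNASSIGNED}
        segments = [s for s in SEGMENTS if s in present]
    out: dict[str, SegmentSeries] = {}
    for seg in segments:
        out[seg] = build_segment_series(panel, schedule, cpi, seg, pack_size=pack_size)
    if include_market:
        out[ALL_SEGMENTS] = build_segment_series(panel, schedule, cpi, ALL_SEGMENTS,
                                                 pack_size=pack_size)
    return out


def write_segment_series(series: Sequence[SegmentSeries] | dict[str, SegmentSeries],
                         path: str | Path, header_comments: Sequence[str] = ()) -> None:
    """Tidy CSV: segment,period,wap_nominal,wap_real,tax_total,
    net_revenue_nominal,net_revenue_real,segment_share."""
    if isinstance(series, dict):
        series = list(series.values())
    frame = pd.concat([s.to_frame() for s in series], ignore_index=True)
    with open(path, "w", newline="") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        frame.to_csv(fh, index=False)
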