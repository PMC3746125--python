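"""Conversion between nominal and real (base-period) money via a price index.

An :class:`IndexSeries` is a contiguous monthly consumer-price-index series
with a designated base month. Deflating a nominal amount observed in period
t gives ``nominal * index[base] / index[t]`` -- money expressed in
base-month purchasing power. Deflation is linear in the nominal amount, so
"deflate price then subtract deflated tax" and "subtract tax then deflate"
agree exactly.

Observation dates are matched to the latest monthly index value at or
before the date; months inside the covered span must be contiguous, so a
date outside the span raises rather than silently extrapolating.
"""

from __future__ import annotations

import csv
from bisect import bisect_right
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

from .errors import MissingDataError, ValidationError
from .periods import HalfYear


def _month(d: date) -> date:
    return date(d.year, d.month, 1)


def _month_index(d: date) -> int:
    return d.year * 12 + (d.month - 1)


@dataclass(frozen=True)
class IndexSeries:
    """Monthly price-index series with a base month.

    ``months`` are first-of-month dates, strictly increasing and contiguous;
    ``values`` are positive index levels; ``base`` must be one of ``months``.
    """

    months: tuple[date, ...]
    values: tuple[float, ...]
    base: date

    def __post_init__(self) -> None:
        if not self.months:
            raise ValidationError("index series is empty")
        if len(self.months) != len(self.values):
            raise ValidationError("months and values differ in length")
        if any(v <= 0 for v in self.values):
            raise ValidationError("index values must be positive")
        idx = [_month_index(m) for m in self.months]
        if any(b != a + 1 for a, b in zip(idx, idx[1:])):
            raise ValidationError("index months must be contiguous and increasing")
        if _month(self.base) not in set(self.months):
            raise ValidationError(f"base period {self.base} not present in the series")

    @classmethod
    def from_mapping(cls, mapping: Mapping[str | date, float], base: str | date) -> "IndexSeries":
        """Build from ``{'2001-01': 100.0, ...}`` (or date keys) plus a base month."""
        items = sorted((_coerce_month(k), float(v)) for k, v in mapping.items())
        return cls(
            months=tuple(m for m, _ in items),
            values=tuple(v for _, v in items),
            base=_coerce_month(base),
        )

    @property
    def base_value(self) -> float:
        return self.values[self.months.index(_month(self.base))]

    def value_at(self, when: date | HalfYear) -> float:
        """Index level for ``when``: the latest monthly value at or before it."""
        d = when.date if isinstance(when, HalfYear) else when
        i = bisect_right(self.months, _month(d)) - 1
        if i < 0 or _month(d) > self.months[-1]:
            raise MissingDataError(
                f"period {d} outside index span {self.months[0]}..{self.months[-1]}"
            )
        return self.values[i]

    def to_mapping(self) -> dict[str, float]:
        return {m.strftime("%Y-%m"): v for m, v in zip(self.months, self.values)}


def _coerce_month(key: str | date) -> date:
    if isinstance(key, date):
        return _month(key)
    key = str(key).strip()
    if len(key) == 7:  # YYYY-MM
        key += "-01"
    return _month(date.fromisoformat(key))


def deflate(nominal: float, when: date | HalfYear, series: IndexSeries) -> float:
    """Nominal pence observed at ``when`` -> real pence in base-month money."""
    return nominal * series.base_value / series.value_at(when)


def inflate(real: float, when: date | HalfYear, series: IndexSeries) -> float:
    """Inverse of :func:`deflate`: base-month pence -> nominal pence at ``when``."""
    return real * series.value_at(when) / series.base_value


def rebase(series: IndexSeries, new_base: str | date) -> IndexSeries:
    """Rescale so the new base month maps to 100; growth ratios are preserved."""
    nb = _coerce_month(new_base)
    if nb not in set(series.months):
        raise MissingDataError(f"new base {nb} not present in the series")
    ref = series.values[series.months.index(nb)]
    return IndexSeries(
        months=series.months,
        values=tuple(v * 100.0 / ref for v in series.values),
        base=nb,
    )


def read_index_series(path: str | Path, base: str | date) -> IndexSeries:
    """Read CSV with columns ``period`` (ISO month) and ``index_value``."""
    with open(path, newline="") as fh:
        rows = [r for r in csv.DictReader(_skip_comments(fh))]
    if not rows:
        raise ValidationError(f"{path}: empty index series")
    if not {"period", "index_value"} <= set(rows[0]):
        raise ValidationError(f"{path}: expected columns period,index_value")
    mapping: dict[date, float] = {}
    for i, row in enumerate(rows, start=2):
        try:
            mapping[_coerce_month(row["period"])] = float(row["index_value"])
        except ValueError as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
    return IndexSeries.from_mapping(mapping, base)


def write_index_series(series: IndexSeries, path: str | Path,
                       header_comments: Sequence[str] = ()) -> None:
    with open(path, "w", newline="") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        writer = csv.writer(fh)
        writer.writerow(["period", "index_value"])
        for m, v in zip(series.months, series.values):
            writer.writerow([m.strftime("%Y-%m"), repr(v)])


def _skip_comments(lines: Iterable[str]) -> Iterable[str]:
    for line in lines:
        if not line.lstrip().startswith("#"):
            yield line
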