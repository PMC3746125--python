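"""Semiannual observation periods.

Market observations come twice a year: an early-summer reading (May/June)
and a late-autumn reading (November/December). Each half-year carries one
fixed representative calendar date so that tax-regime and price-index
lookups are deterministic: H1 -> 1 June, H2 -> 1 November. Annual excise
uplifts land in March/April, so every November-to-June window brackets
exactly one duty event while June-to-November windows bracket none.
"""

from __future__ import annotations

import functools
import re
from dataclasses import dataclass
from datetime import date

from .errors import DomainError

_PERIOD_RE = re.compile(r"^(\d{4})H([12])$")


@functools.total_ordering
@dataclass(frozen=True)
class HalfYear:
    """One semiannual period, e.g. ``HalfYear(2006, 2)`` == "2006H2"."""

    year: int
    half: int

    def __post_init__(self) -> None:
        if self.half not in (1, 2):
            raise DomainError(f"half must be 1 or 2, got {self.half!r}")

    @property
    def date(self) -> date:
        """Representative calendar date: 1 June (H1) or 1 November (H2)."""
        return date(self.year, 6 if self.half == 1 else 11, 1)

    @classmethod
    def parse(cls, label: str) -> "HalfYear":
        m = _PERIOD_RE.match(str(label).strip())
        if not m:
            raise DomainError(f"cannot parse period label {label!r} (expected e.g. '2006H2')")
        return cls(int(m.group(1)), int(m.group(2)))

    def next(self) -> "HalfYear":
        return HalfYear(self.year + (self.half == 2), 3 - self.half)

    def prev(self) -> "HalfYear":
        return HalfYear(self.year - (self.half == 1), 3 - self.half)

    def _key(self) -> tuple[int, int]:
        return (self.year, self.half)

    def __lt__(self, other: "HalfYear") -> bool:
        if not isinstance(other, HalfYear):
            return NotImplemented
        return self._key() < other._key()

    def __str__(self) -> str:
        return f"{self.year}H{self.half}"


def period_range(start: HalfYear, end: HalfYear) -> list[HalfYear]:
    """All half-years from ``start`` to ``end`` inclusive."""
    if end < start:
        raise DomainError(f"period range end {end} precedes start {start}")
    out = [start]
    while out[-1] < end:
        out.append(out[-1].next())
    return out
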