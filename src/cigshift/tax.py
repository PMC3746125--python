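"""Mixed excise tax engine.

UK-style cigarette taxation combines three components on the tax-inclusive
retail price P of a pack of ``pack_size`` sticks:

* a **specific duty** ``s`` in pence per 1000 sticks, contributing
  ``s * pack_size / 1000`` per pack;
* an **ad valorem duty** at rate ``a`` levied on the retail selling price,
  contributing ``a * P``;
* **VAT** at rate ``v`` on the pre-VAT price, which on a tax-inclusive price
  is extracted as ``P * v / (1 + v)``.

Net-of-tax revenue -- the amount retained by manufacturer and retailer --
is ``P - total tax``, which is affine in P with slope ``1 - a - v/(1+v)``.
That slope must be positive for the regime to make sense (otherwise no
price yields positive net revenue), and its positivity is what makes the
price-for-target-net-revenue inverse well defined.

All money is held in floating-point pence; rounding to one decimal happens
only at reporting time.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from datetime import date
from pathlib import Path
from typing import Iterable, Sequence

from .errors import DomainError, MissingDataError, ValidationError


@dataclass(frozen=True)
class TaxRegime:
    """Fiscal parameters in force from a given date.

    Parameters
    ----------
    effective_from : date the regime takes effect (inclusive).
    specific_duty : pence per 1000 sticks, >= 0.
    ad_valorem_rate : fraction of the tax-inclusive retail price, in [0, 1).
    vat_rate : VAT fraction applied on the pre-VAT price, in [0, 1).
    """

    effective_from: date
    specific_duty: float
    ad_valorem_rate: float
    vat_rate: float

    def __post_init__(self) -> None:
        if self.specific_duty < 0:
            raise ValidationError(f"specific_duty must be >= 0, got {self.specific_duty}")
        if not (0 <= self.ad_valorem_rate < 1):
            raise ValidationError(f"ad_valorem_rate must be in [0,1), got {self.ad_valorem_rate}")
        if not (0 <= self.vat_rate < 1):
            raise ValidationError(f"vat_rate must be in [0,1), got {self.vat_rate}")
        if self.proportional_rate >= 1:
            raise ValidationError(
                "regime rejected: ad_valorem_rate + vat_rate/(1+vat_rate) = "
                f"{self.proportional_rate:.4f} >= 1, so net revenue is non-positive "
                "at every price"
            )

    @property
    def proportional_rate(self) -> float:
        """Combined price-proportional tax share: a + v/(1+v)."""
        return self.ad_valorem_rate + self.vat_rate / (1 + self.vat_rate)


@dataclass(frozen=True)
class TaxBreakdown:
    """Per-pack tax components in pence; ``total = specific + ad_valorem + vat``."""

    specific: float
    ad_valorem: float
    vat: float
    total: float
    net_revenue: float


@dataclass(frozen=True)
class RegimeSchedule:
    """Ordered sequence of regimes; each applies until the next takes effect."""

    regimes: tuple[TaxRegime, ...]

    def __post_init__(self) -> None:
        if not self.regimes:
            raise ValidationError("schedule must contain at least one regime")
        dates = [r.effective_from for r in self.regimes]
        if any(b <= a for a, b in zip(dates, dates[1:])):
            raise ValidationError("regime effective_from dates must be strictly increasing")

    def __iter__(self):
        return iter(self.regimes)

    def __len__(self) -> int:
        return len(self.regimes)

    @property
    def start(self) -> date:
        return self.regimes[0].effective_from

    def change_dates(self) -> list[date]:
        return [r.effective_from for r in self.regimes]


def tax_breakdown(price: float, pack_size: int, regime: TaxRegime) -> TaxBreakdown:
    """Decompose the tax paid on one pack sold at ``price`` pence.

    ``price`` is the tax-inclusive retail price; VAT is extracted from it
    via v/(1+v) rather than added on top.
    """
    if price <= 0:
        raise DomainError(f"price must be positive, got {price}")
    specific = regime.specific_duty * pack_size / 1000.0
    ad_valorem = regime.ad_valorem_rate * price
    vat = price * regime.vat_rate / (1 + regime.vat_rate)
    total = specific + ad_valorem + vat
    return TaxBreakdown(
        specific=specific,
        ad_valorem=ad_valorem,
        vat=vat,
        total=total,
        net_revenue=price - total,
    )


def price_for_net_revenue(target_net: float, pack_size: int, regime: TaxRegime) -> float:
    """Retail price whose net-of-tax revenue equals ``target_net`` pence.

    Inverts the affine map P -> P - tax(P):

        P = (target_net + specific_per_pack) / (1 - a - v/(1+v))

    The simulator uses this to impose a chosen pass-through exactly.
    """
    specific = regime.specific_duty * pack_size / 1000.0
    return (target_net + specific) / (1 - regime.proportional_rate)


def specific_share(breakdown: TaxBreakdown) -> float:
    """Fraction of the total tax burden (including VAT) that is specific duty."""
    if breakdown.total <= 0:
        raise DomainError("specific_share undefined: total tax is zero")
    return breakdown.specific / breakdown.total


def regime_at(when: date, schedule: RegimeSchedule) -> TaxRegime:
    """Regime in force on ``when``: latest effective_from <= when."""
    if when < schedule.start:
        raise MissingDataError(
            f"date {when} precedes the first regime ({schedule.start}); "
            "the schedule does not cover it"
        )
    current = schedule.regimes[0]
    for regime in schedule.regimes[1:]:
        if regime.effective_from <= when:
            current = regime
        else:
            break
    return current


def read_regime_schedule(path: str | Path) -> RegimeSchedule:
    """Read a schedule from CSV with columns
    effective_from, specific_duty_per_1000, ad_valorem_rate, vat_rate."""
    required = {"effective_from", "specific_duty_per_1000", "ad_valorem_rate", "vat_rate"}
    regimes: list[TaxRegime] = []
    with open(path, newline="") as fh:
        rows = [r for r in csv.DictReader(_skip_comments(fh))]
    if not rows:
        raise ValidationError(f"{path}: empty regime schedule")
    missing = required - set(rows[0])
    if missing:
        raise ValidationError(f"{path}: missing columns {sorted(missing)}")
    for i, row in enumerate(rows, start=2):
        try:
            regimes.append(
                TaxRegime(
                    effective_from=date.fromisoformat(row["effective_from"].strip()),
                    specific_duty=float(row["specific_duty_per_1000"]),
                    ad_valorem_rate=float(row["ad_valorem_rate"]),
                    vat_rate=float(row["vat_rate"]),
                )
            )
        except (ValueError, ValidationError) as exc:
            raise ValidationError(f"{path}: row {i}: {exc}") from exc
    return RegimeSchedule(tuple(regimes))


def write_regime_schedule(schedule: RegimeSchedule, path: str | Path,
                          header_comments: Sequence[str] = ()) -> None:
    with open(path, "w", newline="") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        writer = csv.writer(fh)
        writer.writerow(["effective_from", "specific_duty_per_1000", "ad_valorem_rate", "vat_rate"])
        for r in schedule:
            writer.writerow([r.effective_from.isoformat(), repr(r.specific_duty),
                             repr(r.ad_valorem_rate), repr(r.vat_rate)])


def _skip_comments(lines: Iterable[str]) -> Iterable[str]:
    for line in lines:
        if not line.lstrip().startswith("#"):
            yield line
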