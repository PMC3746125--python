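"""Synthetic cigarette-market generator with known ground-truth pass-through.

Real brand-level scan and survey data for this market are proprietary, so
every pipeline stage is exercised against a simulator that emulates the
relevant structure of the UK cigarette market in the 2000s:

* four price segments (premium / mid / economy / ultra-low-price), the ULP
  tier entering the market only from 2006;
* semiannual observations (June and November representative dates);
* an excise schedule with an annual specific-duty uplift every April —
  inside each November-May window — plus VAT changes (17.5% -> 15% in
  December 2008 -> 17.5% in January 2010);
* per-segment pass-through behaviour: a configured real net-revenue step
  ``delta_duty`` in each duty window (positive = overshift, negative =
  absorption) and ``delta_quiet`` in each duty-free window;
* gradual share drift toward cheaper brands (downtrading) via a
  multiplicative logit response to relative real price.

The key construction: each brand carries a latent *real net-of-tax
revenue* trajectory, advanced by the segment's configured deltas plus
Gaussian noise, and its nominal price is obtained by *inverting the tax
engine* under the regime and CPI level of the period. Overshifting by
delta is therefore exact by construction, making pass-through a
controllable parameter rather than an emergent behaviour. Noise enters on
the net-revenue scale (pence) so classification tolerances stay
interpretable.

Each brand draws from its own random stream derived from the master seed,
so adding a brand leaves every other trajectory unchanged.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field, replace
from datetime import date
from typing import Sequence

import numpy as np
import pandas as pd
import yaml

from .deflation import IndexSeries, deflate, inflate
from .errors import GenerationError, ValidationError
from .panel import Panel, SegmentEntry, SegmentMap
from .periods import HalfYear, period_range
from .tax import RegimeSchedule, TaxRegime, price_for_net_revenue, regime_at, tax_breakdown

_SHARE_TOL = 1e-9


@dataclass(frozen=True)
class SegmentScenario:
    """Generator parameters for one price segment.

    delta_duty / delta_quiet are the real net-revenue steps (pence per
    pack) applied in November-May (duty-event) and May-November windows;
    their sum is the segment's annual overshift. ``entry_year=None`` means
    the segment exists from the scenario start.
    """

    n_brands: int
    base_price: float          # nominal pence per pack at first observation
    price_spread: float        # brands span base_price +- spread/2
    delta_duty: float
    delta_quiet: float
    initial_share: float       # whole-market share at segment entry
    entry_year: int | None = None


@dataclass(frozen=True)
class ScenarioConfig:
    """Full simulator configuration; defaults mirror the UK market 2001-09."""

    segments: dict[str, SegmentScenario]
    start_year: int = 2001
    end_year: int = 2009
    others_share: float = 0.08
    noise_sd: float = 1.0              # pence, on the real net-revenue scale
    downtrading_beta: float = 0.45     # logit share response to relative real price
    duty_start: float = 9225.0         # pence per 1000 sticks at scenario start
    duty_uplift: float = 275.0         # pence per 1000 sticks, every April
    ad_valorem_rate: float = 0.22
    vat_changes: tuple[tuple[date, float], ...] = (
        (date(2008, 12, 1), 0.15),
        (date(2010, 1, 1), 0.175),
    )
    vat_initial: float = 0.175
    cpi_annual_inflation: float = 0.02
    cpi_base: date = date(2010, 1, 1)
    pack_size: int = 20
    source: str = "sim"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValidationError("noise_sd must be >= 0")
        if self.end_year < self.start_year:
            raise ValidationError("end_year precedes start_year")
        start_mass = self.others_share + sum(
            s.initial_share for s in self.segments.values() if s.entry_year is None
        )
        if abs(start_mass - 1.0) > _SHARE_TOL:
            raise ValidationError(
                f"initial shares plus others must sum to 1, got {start_mass:.6f}"
            )
        late_mass = sum(
            s.initial_share for s in self.segments.values() if s.entry_year is not None
        )
        if late_mass >= 1.0 - self.others_share:
            raise ValidationError("late-entry share mass exceeds the assigned market")

    # ---- serialisation -------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "start_year": self.start_year,
            "end_year": self.end_year,
            "others_share": self.others_share,
            "noise_sd": self.noise_sd,
            "downtrading_beta": self.downtrading_beta,
            "duty_start": self.duty_start,
            "duty_uplift": self.duty_uplift,
            "ad_valorem_rate": self.ad_valorem_rate,
            "vat_initial": self.vat_initial,
            "vat_changes": [[d.isoformat(), r] for d, r in self.vat_changes],
            "cpi_annual_inflation": self.cpi_annual_inflation,
            "cpi_base": self.cpi_base.isoformat(),
            "pack_size": self.pack_size,
            "source": self.source,
            "seed": self.seed,
            "segments": {
                name: {
                    "n_brands": s.n_brands,
                    "base_price": s.base_price,
                    "price_spread": s.price_spread,
                    "delta_duty": s.delta_duty,
                    "delta_quiet": s.delta_quiet,
                    "initial_share": s.initial_share,
                    "entry_year": s.entry_year,
                }
                for name, s in self.segments.items()
            },
        }

    @classmethod
    def from_dict(cls, data: dict) -> "ScenarioConfig":
        data = dict(data)
        segments = {
            name: SegmentScenario(**spec) for name, spec in data.pop("segments").items()
        }
        if "vat_changes" in data:
            data["vat_changes"] = tuple(
                (date.fromisoformat(d), float(r)) for d, r in data["vat_changes"]
            )
        if "cpi_base" in data:
            data["cpi_base"] = date.fromisoformat(data["cpi_base"])
        return cls(segments=segments, **data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "ScenarioConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


@dataclass
class GroundTruth:
    """What the simulator actually did, for recovery tests.

    ``config_deltas``: the configured per-window real net-revenue steps.
    ``realized``: per segment and consecutive-period window, the realized
    change in real net revenue of the segment WAP (noise and composition
    included). ``wap``: true per-period segment WAP, real net revenue and
    share, recomputable from the emitted panel.
    """

    config_deltas: dict[str, dict[str, float]]
    realized: pd.DataFrame = field(repr=False)
    wap: pd.DataFrame = field(repr=False)

    def to_frame(self) -> pd.DataFrame:
        cfg = pd.DataFrame(
            [
                {"record": "config_delta", "segment": seg, "window_type": wt,
                 "period_from": "", "period_to": "", "value": v}
                for seg, deltas in self.config_deltas.items()
                for wt, v in deltas.items()
            ]
        )
        realized = self.realized.assign(record="realized_delta")
        wap = self.wap.melt(
            id_vars=["segment", "period"], var_name="window_type", value_name="value"
        ).rename(columns={"period": "period_to"})
        wap = wap.assign(record="true_series", period_from="")
        cols = ["record", "segment", "window_type", "period_from", "period_to", "value"]
        realized = realized.rename(columns={"delta": "value"})
        return pd.concat(
            [cfg[cols], realized[cols], wap[cols]], ignore_index=True
        )


def default_uk_scenario(seed: int = 0) -> ScenarioConfig:
    """Reference scenario for the UK cigarette market, 2001-2009.

    Segment price levels, the excise path (specific duty rising ~275p/1000
    a year from 9225p/1000, ad valorem 22%, VAT 17.5% with the December
    2008 cut to 15%), and the per-segment pass-through pattern — premium,
    mid and economy overshifting in the duty window, ULP absorbing tax
    there and rebuilding margin in the quiet half — reflect the published
    duty schedule and segment behaviour of that market. Under the default
    downtrading response the ULP share roughly doubles over 2006-2009.
    """
    return ScenarioConfig(
        seed=seed,
        segments={
            "premium": SegmentScenario(
                n_brands=5, base_price=550.0, price_spread=24.0,
                delta_duty=2.9, delta_quiet=1.2, initial_share=0.30,
            ),
            "mid": SegmentScenario(
                n_brands=3, base_price=500.0, price_spread=10.0,
                delta_duty=3.9, delta_quiet=0.7, initial_share=0.10,
            ),
            "economy": SegmentScenario(
                n_brands=6, base_price=450.0, price_spread=18.0,
                delta_duty=2.1, delta_quiet=2.8, initial_share=0.52,
            ),
            "ulp": SegmentScenario(
                n_brands=4, base_price=400.0, price_spread=8.0,
                delta_duty=-3.0, delta_quiet=4.3, initial_share=0.05,
                entry_year=2006,
            ),
        },
    )


def build_schedule(config: ScenarioConfig) -> RegimeSchedule:
    """Regime schedule: annual April duty uplifts merged with VAT changes."""
    start = date(config.start_year, 1, 1)
    end = date(config.end_year + 1, 12, 31)
    duty_dates = [date(y, 4, 1) for y in range(config.start_year + 1, config.end_year + 1)]
    change_points = sorted(
        {start, *duty_dates, *(d for d, _ in config.vat_changes if start < d <= end)}
    )
    regimes = []
    for when in change_points:
        duty = config.duty_start + config.duty_uplift * sum(d <= when for d in duty_dates)
        vat = config.vat_initial
        for d, r in sorted(config.vat_changes):
            if d <= when:
                vat = r
        regimes.append(
            TaxRegime(effective_from=when, specific_duty=duty,
                      ad_valorem_rate=config.ad_valorem_rate, vat_rate=vat)
        )
    return RegimeSchedule(tuple(regimes))


def duty_event_dates(config: ScenarioConfig) -> list[date]:
    return [date(y, 4, 1) for y in range(config.start_year + 1, config.end_year + 1)]


def build_cpi(config: ScenarioConfig) -> IndexSeries:
    """Monthly CPI compounding at the configured annual rate, base = 100."""
    months: list[date] = []
    y, m = config.start_year, 1
    while (y, m) <= (config.cpi_base.year, 12):
        months.append(date(y, m, 1))
        y, m = (y + 1, 1) if m == 12 else (y, m + 1)
    rate = (1.0 + config.cpi_annual_inflation) ** (1.0 / 12.0)
    base_i = months.index(date(config.cpi_base.year, config.cpi_base.month, 1))
    values = tuple(100.0 * rate ** (i - base_i) for i in range(len(months)))
    return IndexSeries(months=tuple(months), values=values, base=months[base_i])


def build_segment_map(config: ScenarioConfig) -> SegmentMap:
    entries: dict[str, SegmentEntry] = {}
    for seg, spec in config.segments.items():
        entry_year = spec.entry_year if spec.entry_year is not None else config.start_year
        for i in range(spec.n_brands):
            # explicit validity start (segment entry), overriding the
            # reader-side ULP default of 2006
            entries[f"{seg}_{i + 1:02d}"] = SegmentEntry(
                seg, valid_from=date(entry_year, 1, 1)
            )
    return SegmentMap(entries)


def _brand_rng(master_seed: int, brand_id: str) -> np.random.Generator:
    # one independent stream per brand, stable under brand additions
    return np.random.default_rng([master_seed % (2**31), zlib.crc32(brand_id.encode())])


def generate(config: ScenarioConfig
             ) -> tuple[Panel, IndexSeries, RegimeSchedule, GroundTruth]:
    """Emit (panel, cpi, schedule, ground_truth) for one scenario.

    Deterministic under a fixed config (including its seed): the same
    configuration always yields a byte-identical panel CSV.
    """
    schedule = build_schedule(config)
    cpi = build_cpi(config)
    smap = build_segment_map(config)
    duty_dates = duty_event_dates(config)
    periods = period_range(
        HalfYear(config.start_year, 1), HalfYear(config.end_year, 2)
    )

    # --- latent real net-revenue paths and nominal prices per brand -----
    entry_period: dict[str, HalfYear] = {}
    brand_segment: dict[str, str] = {}
    prices: dict[str, dict[HalfYear, float]] = {}
    real_net: dict[str, dict[HalfYear, float]] = {}
    for seg, spec in config.segments.items():
        entry = (
            HalfYear(spec.entry_year, 1)
            if spec.entry_year is not None
            else periods[0]
        )
        offsets = (
            np.linspace(-0.5, 0.5, spec.n_brands) * spec.price_spread
            if spec.n_brands > 1
            else np.zeros(1)
        )
        for i in range(spec.n_brands):
            brand = f"{seg}_{i + 1:02d}"
            brand_segment[brand] = seg
            entry_period[brand] = entry
            rng = _brand_rng(config.seed, brand)
            p0 = spec.base_price + float(offsets[i])
            regime = regime_at(entry.date, schedule)
            r = deflate(
                tax_breakdown(p0, config.pack_size, regime).net_revenue, entry, cpi
            )
            brand_prices = {entry: p0}
            brand_net = {entry: r}
            prev = entry
            for cur in periods[periods.index(entry) + 1:]:
                has_duty = any(prev.date < d <= cur.date for d in duty_dates)
                step = spec.delta_duty if has_duty else spec.delta_quiet
                r = r + step + rng.normal(0.0, config.noise_sd)
                net_nominal = inflate(r, cur, cpi)
                price = price_for_net_revenue(
                    net_nominal, config.pack_size, regime_at(cur.date, schedule)
                )
                if price <= 0:
                    raise GenerationError(
                        f"non-positive price ({price:.2f}p) generated for brand "
                        f"{brand!r} at {cur}"
                    )
                brand_prices[cur] = price
                brand_net[cur] = r
                prev = cur
            prices[brand] = brand_prices
            real_net[brand] = brand_net

    # --- share dynamics -------------------------------------------------
    assigned_mass = 1.0 - config.others_share
    beta = config.downtrading_beta
    shares: dict[HalfYear, dict[str, float]] = {}
    current: dict[str, float] = {}
    for seg, spec in config.segments.items():
        if spec.entry_year is None:
            for i in range(spec.n_brands):
                current[f"{seg}_{i + 1:02d}"] = spec.initial_share / spec.n_brands
    for t_i, period in enumerate(periods):
        # late entrants: carve their initial mass proportionally from incumbents
        for seg, spec in config.segments.items():
            if spec.entry_year is not None and HalfYear(spec.entry_year, 1) == period:
                scale = (sum(current.values()) - spec.initial_share) / sum(current.values())
                if scale <= 0:
                    raise GenerationError(
                        f"segment {seg!r} entry share {spec.initial_share} exhausts "
                        f"the market at {period}"
                    )
                current = {b: w * scale for b, w in current.items()}
                for i in range(spec.n_brands):
                    current[f"{seg}_{i + 1:02d}"] = spec.initial_share / spec.n_brands
        if t_i > 0 and beta != 0.0:
            real_prices = {
                b: deflate(prices[b][period], period, cpi) for b in current
            }
            mean_price = sum(current[b] * real_prices[b] for b in current) / sum(
                current.values()
            )
            weights = {
                b: current[b] * float(np.exp(-beta * (real_prices[b] / mean_price - 1.0)))
                for b in current
            }
            z = sum(weights.values())
            current = {b: w * assigned_mass / z for b, w in weights.items()}
        for brand, w in current.items():
            if w < 0:
                raise GenerationError(f"negative share for brand {brand!r} at {period}")
        total = sum(current.values()) + config.others_share
        if abs(total - 1.0) > 1e-6:
            raise GenerationError(f"share mass {total:.8f} != 1 at {period}")
        shares[period] = dict(current)

    # --- assemble panel ---------------------------------------------------
    rows = []
    for period in periods:
        for brand in sorted(shares[period]):
            rows.append(
                {
                    "brand_id": brand,
                    "period": period,
                    "nominal_price": prices[brand][period],
                    "pack_size": config.pack_size,
                    "volume_share": shares[period][brand],
                    "source": config.source,
                }
            )
    panel = Panel(pd.DataFrame.from_records(rows), segment_map=smap)
    from .panel import assign_segments  # local import to avoid cycle at module load

    panel = assign_segments(panel, smap)

    truth = _ground_truth(config, panel, schedule, cpi, duty_dates)
    return panel, cpi, schedule, truth


def _ground_truth(config: ScenarioConfig, panel: Panel, schedule: RegimeSchedule,
                  cpi: IndexSeries, duty_dates: Sequence[date]) -> GroundTruth:
    config_deltas = {
        seg: {"duty": spec.delta_duty, "quiet": spec.delta_quiet}
        for seg, spec in config.segments.items()
    }
    wap_rows, realized_rows = [], []
    df = panel.df
    for seg in config.segments:
        sub = df[df["segment"] == seg]
        series: list[tuple[HalfYear, float, float, float]] = []
        for period in sorted(set(sub["period"])):
            rows = sub[sub["period"] == period]
            w = rows["volume_share"].to_numpy()
            p = rows["nominal_price"].to_numpy()
            wap = float((w * p).sum() / w.sum())
            net = tax_breakdown(
                wap, config.pack_size, regime_at(period.date, schedule)
            ).net_revenue
            net_real = deflate(net, period, cpi)
            series.append((period, wap, net_real, float(w.sum())))
            wap_rows.append(
                {"segment": seg, "period": str(period), "wap_nominal": wap,
                 "net_revenue_real": net_real, "segment_share": float(w.sum())}
            )
        for (p0, _, n0, _), (p1, _, n1, _) in zip(series, series[1:]):
            has_duty = any(p0.date < d <= p1.date for d in duty_dates)
            realized_rows.append(
                {"segment": seg, "period_from": str(p0), "period_to": str(p1),
                 "window_type": "duty" if has_duty else "quiet", "delta": n1 - n0}
            )
    return GroundTruth(
        config_deltas=config_deltas,
        realized=pd.DataFrame.from_records(realized_rows),
        wap=pd.DataFrame.from_records(wap_rows),
    )


def downtrading_scenario(seed: int = 0) -> ScenarioConfig:
    """Scenario emphasising downtrading for association analyses.

    All four segments trade from the start of a 2005-2009 span, and the
    configured real net-revenue growth is steeply increasing in segment
    price level — expensive brands raise real prices markedly while the
    cheapest tier holds its net revenue flat — so the share flow toward
    cheap brands induced by the logit response lines up with an inverse
    share-change / price-change relation at brand level.
    """
    return ScenarioConfig(
        seed=seed,
        start_year=2005,
        end_year=2009,
        downtrading_beta=0.3,
        segments={
            "premium": SegmentScenario(
                n_brands=5, base_price=550.0, price_spread=12.0,
                delta_duty=8.0, delta_quiet=4.0, initial_share=0.30,
            ),
            "mid": SegmentScenario(
                n_brands=3, base_price=500.0, price_spread=8.0,
                delta_duty=5.0, delta_quiet=3.0, initial_share=0.10,
            ),
            "economy": SegmentScenario(
                n_brands=6, base_price=450.0, price_spread=10.0,
                delta_duty=3.0, delta_quiet=2.0, initial_share=0.42,
            ),
            "ulp": SegmentScenario(
                n_brands=4, base_price=400.0, price_spread=6.0,
                delta_duty=-1.0, delta_quiet=1.0, initial_share=0.10,
            ),
        },
    )


def null_scenario(seed: int = 0) -> ScenarioConfig:
    """Default scenario with all pass-through effects, drift, noise and
    downtrading switched off: every downstream shift statistic is zero.

    All four segments trade from the start (a late ULP entry would move the
    whole-market composition, which is itself a nonzero statistic), with the
    economy share reduced to make room."""
    cfg = default_uk_scenario(seed=seed)
    segments = {}
    for name, spec in cfg.segments.items():
        spec = replace(spec, delta_duty=0.0, delta_quiet=0.0, entry_year=None)
        if name == "economy":
            spec = replace(spec, initial_share=0.47)
        segments[name] = spec
    return replace(cfg, noise_sd=0.0, downtrading_beta=0.0, segments=segments)
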