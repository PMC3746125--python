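"""Cigarette price indices: most-popular-price-category vs weighted average.

Until 2011 EU tobacco excise referenced the **most popular price category**
(MPPC) — the retail price point carrying the largest sales volume — which
in practice tracks the leading premium brand. The replacement reference,
the **weighted average price** (WAP), averages over the whole market and
therefore registers the growth of cheap segments that the MPPC ignores.
This module builds both indices from a brand panel, rebases them to 100 at
a chosen period, and compares their growth with an optional externally
supplied index series (e.g. an official cigarette component of a retail
price index).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .deflation import IndexSeries
from .errors import MissingDataError
from .panel import UNASSIGNED, Panel
from .periods import HalfYear


def mppc_price(panel: Panel, period: HalfYear, price_resolution: float = 1.0,
               brand_based: bool = False, include_unassigned: bool = True) -> float:
    """Most popular price category for one period.

    Prices are binned at ``price_resolution`` pence; the bin with the
    largest summed volume share wins and is represented by the
    volume-weighted mean price within it. Ties go to the lower-priced bin.
    With ``brand_based=True`` the single highest-share brand's price is
    returned instead of a price-point category.
    """
    rows = panel.rows(period)
    if not include_unassigned:
        rows = rows[rows["segment"] != UNASSIGNED]
    rows = rows[rows["volume_share"] > 0]
    if len(rows) == 0:
        raise MissingDataError(f"no observations with positive share in {period}")
    if brand_based:
        top = rows.loc[rows["volume_share"].idxmax()]
        return float(top["nominal_price"])
    bins = rows.assign(_bin=[math.floor(p / price_resolution) for p in rows["nominal_price"]])
    grouped = bins.groupby("_bin").agg(
        share=("volume_share", "sum"),
        wsum=("nominal_price", lambda p: float((p * bins.loc[p.index, "volume_share"]).sum())),
    )
    best_share = grouped["share"].max()
    # tie-break: among maximal-share bins pick the lowest price bin
    winner = grouped[grouped["share"] >= best_share - 1e-12].index.min()
    g = grouped.loc[winner]
    return float(g["wsum"] / g["share"])


def market_wap(panel: Panel, period: HalfYear, include_unassigned: bool = True) -> float:
    """Whole-market share-weighted mean price for one period."""
    rows = panel.rows(period)
    if not include_unassigned:
        rows = rows[rows["segment"] != UNASSIGNED]
    w = rows["volume_share"].to_numpy(dtype=float)
    if len(rows) == 0 or w.sum() <= 0:
        raise MissingDataError(f"no observations with positive share in {period}")
    p = rows["nominal_price"].to_numpy(dtype=float)
    return float((w * p).sum() / w.sum())


@dataclass
class PriceIndexComparison:
    """Rebased (base=100) index levels and full-span growth per series."""

    periods: list[HalfYear]
    mppc_index: list[float]
    wap_index: list[float]
    external_index: list[float] | None
    growth_pct: dict[str, float]

    def to_frame(self) -> pd.DataFrame:
        data = {
            "period": [str(p) for p in self.periods],
            "mppc_index": self.mppc_index,
            "wap_index": self.wap_index,
        }
        if self.external_index is not None:
            data["external_index"] = self.external_index
        return pd.DataFrame(data)


def compare_indices(panel: Panel, external: IndexSeries | None = None,
                    base_period: HalfYear | None = None,
                    price_resolution: float = 1.0,
                    brand_based: bool = False) -> PriceIndexComparison:
    """Build nominal MPPC and WAP indices rebased to 100 and compare growth.

    ``growth_pct`` maps series name to final/base x 100 - 100 over the
    compared span. If the external series does not cover the whole panel
    span, the comparison is trimmed to the intersection with a warning.
    """
    periods = panel.periods()
    if external is not None:
        covered = [p for p in periods
                   if external.months[0] <= p.date.replace(day=1) <= external.months[-1]]
        if len(covered) < len(periods):
            warnings.warn(
                "external index does not cover the full panel span; "
                f"comparison trimmed to {covered[0]}..{covered[-1]}",
                stacklevel=2,
            )
        periods = covered
    if not periods:
        raise MissingDataError("no overlap between panel and external index")
    if base_period is None:
        base_period = periods[0]
    if base_period not in periods:
        raise MissingDataError(f"base period {base_period} not covered by all series")

    mppc = [mppc_price(panel, p, price_resolution, brand_based) for p in periods]
    wap = [market_wap(panel, p) for p in periods]
    i0 = periods.index(base_period)

    def _rebase(levels: Sequence[float]) -> list[float]:
        return [v * 100.0 / levels[i0] for v in levels]

    mppc_idx, wap_idx = _rebase(mppc), _rebase(wap)
    growth = {
        "mppc": mppc_idx[-1] - 100.0,
        "wap": wap_idx[-1] - 100.0,
    }
    ext_idx = None
    if external is not None:
        levels = [external.value_at(p) for p in periods]
        ext_idx = _rebase(levels)
        growth["external"] = ext_idx[-1] - 100.0
    return PriceIndexComparison(
        periods=list(periods),
        mppc_index=mppc_idx,
        wap_index=wap_idx,
        external_index=ext_idx,
        growth_pct=growth,
    )


def write_index_comparison(cmp: PriceIndexComparison, path: str | Path,
                           header_comments: Sequence[str] = ()) -> None:
    with open(path, "w", newline="") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        cmp.to_frame().to_csv(fh, index=False)
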