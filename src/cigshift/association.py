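"""Brand-level price/share association analyses.

Two scatter analyses probe how pricing interacts with market structure
between two periods t0 and t1:

1. real price change (%) against initial market share (%), testing
   whether high-share brands take larger price increases;
2. market-share change (percentage points) against real price change (%),
   testing for downtrading — share flowing toward the brands whose real
   price rose least or fell.

Each brand's real price change uses the brand's own prices deflated by the
CPI series, not its segment average. The summary statistic is a Spearman
rank correlation (robust to the outliers typical of brand panels), with
Pearson available via ``method="pearson"``; a degenerate axis (zero
variance) yields an explicitly undefined correlation rather than a number.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .deflation import IndexSeries, deflate
from .errors import DomainError
from .panel import Panel
from .periods import HalfYear


@dataclass(frozen=True)
class ScatterPoint:
    brand_id: str
    segment: str
    x: float
    y: float
    included: bool


@dataclass
class ScatterResult:
    """Scatter points plus a rank-correlation summary.

    ``rho``/``p_value`` are ``None`` when the correlation is undefined
    (fewer than two included points, or an axis with zero variance).
    ``n_excluded_missing`` counts brands absent at either endpoint.
    """

    points: list[ScatterPoint]
    rho: float | None
    p_value: float | None
    n_excluded_missing: int
    x_label: str
    y_label: str

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "brand_id": [p.brand_id for p in self.points],
                "segment": [p.segment for p in self.points],
                "x": [p.x for p in self.points],
                "y": [p.y for p in self.points],
                "included": [p.included for p in self.points],
            }
        )


def _brand_endpoints(panel: Panel, t0: HalfYear, t1: HalfYear):
    """Brands present at both endpoints; returns (merged frame, n_missing)."""
    a = panel.rows(t0).set_index("brand_id")
    b = panel.rows(t1).set_index("brand_id")
    common = a.index.intersection(b.index)
    n_missing = len(a.index.union(b.index)) - len(common)
    return a.loc[common], b.loc[common], int(n_missing)


def _summarize(points: list[ScatterPoint], method: str):
    xs = np.array([p.x for p in points if p.included], dtype=float)
    ys = np.array([p.y for p in points if p.included], dtype=float)
    if len(xs) < 2 or np.ptp(xs) == 0 or np.ptp(ys) == 0:
        return None, None
    if method == "spearman":
        r = stats.spearmanr(xs, ys)
    elif method == "pearson":
        r = stats.pearsonr(xs, ys)
    else:
        raise DomainError(f"unknown correlation method {method!r}")
    return float(r.statistic), float(r.pvalue)


def price_change_vs_initial_share(panel: Panel, cpi: IndexSeries, t0: HalfYear,
                                  t1: HalfYear, min_share: float = 0.0,
                                  method: str = "spearman") -> ScatterResult:
    """x = brand share at t0 (%), y = brand real price change t0->t1 (%).

    Brands missing either endpoint are excluded and counted; brands at or
    below ``min_share`` at t0 are plotted but flagged ``included=False``
    and left out of the correlation.
    """
    a, b, n_missing = _brand_endpoints(panel, t0, t1)
    points = []
    for brand in a.index:
        p0 = deflate(float(a.loc[brand, "nominal_price"]), t0, cpi)
        p1 = deflate(float(b.loc[brand, "nominal_price"]), t1, cpi)
        share0 = float(a.loc[brand, "volume_share"])
        points.append(
            ScatterPoint(
                brand_id=brand,
                segment=str(a.loc[brand, "segment"]),
                x=share0 * 100.0,
                y=(p1 - p0) / p0 * 100.0,
                included=share0 > min_share,
            )
        )
    rho, pval = _summarize(points, method)
    return ScatterResult(points, rho, pval, n_missing,
                         x_label="initial market share (%)",
                         y_label="real price change (%)")


def share_change_vs_price_change(panel: Panel, cpi: IndexSeries, t0: HalfYear,
                                 t1: HalfYear, min_share: float = 0.0,
                                 method: str = "spearman") -> ScatterResult:
    """x = brand real price change t0->t1 (%), y = share change (pp).

    A negative correlation indicates downtrading: share moves toward the
    brands with the smallest (or negative) real price growth.
    """
    a, b, n_missing = _brand_endpoints(panel, t0, t1)
    points = []
    for brand in a.index:
        p0 = deflate(float(a.loc[brand, "nominal_price"]), t0, cpi)
        p1 = deflate(float(b.loc[brand, "nominal_price"]), t1, cpi)
        share0 = float(a.loc[brand, "volume_share"])
        share1 = float(b.loc[brand, "volume_share"])
        points.append(
            ScatterPoint(
                brand_id=brand,
                segment=str(a.loc[brand, "segment"]),
                x=(p1 - p0) / p0 * 100.0,
                y=(share1 - share0) * 100.0,
                included=share0 > min_share,
            )
        )
    rho, pval = _summarize(points, method)
    return ScatterResult(points, rho, pval, n_missing,
                         x_label="real price change (%)",
                         y_label="market share change (pp)")


def write_scatter(results: Sequence[tuple[str, ScatterResult]], path: str | Path,
                  header_comments: Sequence[str] = ()) -> None:
    """Tidy CSV of one or more scatter analyses, tagged by analysis name."""
    frames = []
    for name, res in results:
        frame = res.to_frame()
        frame.insert(0, "analysis", name)
        frames.append(frame)
    out = pd.concat(frames, ignore_index=True)
    with open(path, "w", newline="") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        out.to_csv(fh, index=False)
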