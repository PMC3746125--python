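"""Brand-level price/share panel: data model, validation and CSV I/O.

A :class:`Panel` holds one row per (brand, period, source): the nominal
pack price in pence, pack size in sticks, and the brand's volume share of
the *whole* market as a fraction. Per-period shares may sum to less than
one; the remainder is the "others" mass — brands that could not be
identified or assigned to a price segment — and is carried explicitly so
that market-share outputs account for the full market.

Brands are assigned to price segments (premium, mid, economy, ulp) through
a :class:`SegmentMap`, optionally windowed in time: ultra-low-price (ULP)
entries default to a validity start of 2006, the year transnational
manufacturers entered that tier, so a ULP label never leaks into earlier
periods.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from datetime import date
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .errors import ValidationError
from .periods import HalfYear

SEGMENTS = ("premium", "mid", "economy", "ulp")
UNASSIGNED = "unassigned"
ALL_SEGMENTS = "all"

PANEL_COLUMNS = ["brand_id", "period", "nominal_price", "pack_size", "volume_share", "source"]

#: Default earliest date at which a ULP assignment is considered valid.
ULP_DEFAULT_VALID_FROM = date(2006, 1, 1)

_SHARE_SUM_TOL = 1e-9


@dataclass(frozen=True)
class SegmentEntry:
    segment: str
    valid_from: date | None = None
    valid_to: date | None = None

    def active_at(self, when: date) -> bool:
        if self.valid_from is not None and when < self.valid_from:
            return False
        if self.valid_to is not None and when > self.valid_to:
            return False
        return True


class SegmentMap:
    """brand_id -> price segment, optionally windowed in time."""

    def __init__(self, entries: Mapping[str, Sequence[SegmentEntry] | SegmentEntry | str]):
        self._entries: dict[str, tuple[SegmentEntry, ...]] = {}
        for brand, spec in entries.items():
            if isinstance(spec, str):
                spec = [SegmentEntry(spec)]
            elif isinstance(spec, SegmentEntry):
                spec = [spec]
            normalized = tuple(self._normalize(brand, e) for e in spec)
            self._check_no_overlap(brand, normalized)
            self._entries[brand] = normalized

    @staticmethod
    def _normalize(brand: str, entry: SegmentEntry) -> SegmentEntry:
        if entry.segment not in SEGMENTS:
            raise ValidationError(
                f"brand {brand!r}: unknown segment {entry.segment!r} "
                f"(expected one of {SEGMENTS})"
            )
        if entry.segment == "ulp" and entry.valid_from is None:
            entry = replace(entry, valid_from=ULP_DEFAULT_VALID_FROM)
        return entry

    @staticmethod
    def _check_no_overlap(brand: str, entries: Sequence[SegmentEntry]) -> None:
        # every brand must resolve to at most one segment at any date
        def lo(e: SegmentEntry) -> date:
            return e.valid_from or date.min

        def hi(e: SegmentEntry) -> date:
            return e.valid_to or date.max

        ordered = sorted(entries, key=lo)
        for a, b in zip(ordered, ordered[1:]):
            if lo(b) <= hi(a):
                raise ValidationError(f"brand {brand!r}: overlapping segment validity windows")

    def brands(self) -> list[str]:
        return sorted(self._entries)

    def segment_for(self, brand: str, when: date) -> str:
        """Segment of ``brand`` on ``when``; UNASSIGNED if unmapped or out of window."""
        for entry in self._entries.get(brand, ()):
            if entry.active_at(when):
                return entry.segment
        return UNASSIGNED

    def has_brand(self, brand: str) -> bool:
        return brand in self._entries

    def items(self):
        return self._entries.items()


@dataclass
class Panel:
    """Validated brand/period observations plus an optional segment map.

    ``df`` columns: brand_id, period (:class:`HalfYear`), nominal_price,
    pack_size, volume_share, source, and — after :func:`assign_segments` —
    segment. ``archived`` keeps superseded rows from :func:`merge_sources`
    for cross-source consistency checks.
    """

    df: pd.DataFrame
    segment_map: SegmentMap | None = None
    archived: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.df = _validate_frame(self.df)

    # -- convenience accessors -------------------------------------------
    def periods(self) -> list[HalfYear]:
        return sorted(set(self.df["period"]))

    def brands(self) -> list[str]:
        return sorted(set(self.df["brand_id"]))

    def rows(self, period: HalfYear | None = None) -> pd.DataFrame:
        if period is None:
            return self.df
        return self.df[self.df["period"] == period]

    def __len__(self) -> int:
        return len(self.df)


def _validate_frame(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in PANEL_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"panel missing columns {missing}")
    df = df.copy().reset_index(drop=True)
    df["period"] = [p if isinstance(p, HalfYear) else HalfYear.parse(p) for p in df["period"]]
    df["nominal_price"] = pd.to_numeric(df["nominal_price"], errors="raise")
    df["volume_share"] = pd.to_numeric(df["volume_share"], errors="raise")
    df["pack_size"] = pd.to_numeric(df["pack_size"], errors="raise").astype(int)

    bad_price = df.index[df["nominal_price"] <= 0].tolist()
    if bad_price:
        raise ValidationError(f"non-positive nominal_price in rows {bad_price}")
    bad_share = df.index[df["volume_share"] < 0].tolist()
    if bad_share:
        raise ValidationError(f"negative volume_share in rows {bad_share}")

    keys = list(zip(df["brand_id"], df["period"], df["source"]))
    seen: dict[tuple, int] = {}
    for i, key in enumerate(keys):
        if key in seen:
            raise ValidationError(
                f"duplicate observation for brand={key[0]!r} period={key[1]} "
                f"source={key[2]!r} (rows {seen[key]} and {i})"
            )
        seen[key] = i

    sums = df.groupby("period")["volume_share"].sum()
    over = sums[sums > 1 + _SHARE_SUM_TOL]
    if not over.empty:
        detail = ", ".join(f"{p}: {s:.4f}" for p, s in over.items())
        raise ValidationError(f"volume shares exceed 1 in period(s) {detail}")
    if "segment" not in df.columns:
        df["segment"] = UNASSIGNED
    return df


def read_panel(path: str | Path, segment_map: SegmentMap | None = None) -> Panel:
    """Read a panel CSV (header: brand_id,period,nominal_price,pack_size,
    volume_share,source); rows violating the invariants are rejected with
    their locations."""
    df = pd.read_csv(path, comment="#", dtype={"brand_id": str, "source": str})
    try:
        panel = Panel(df, segment_map=segment_map)
    except ValidationError as exc:
        raise ValidationError(f"{path}: {exc}") from exc
    if segment_map is not None:
        panel = assign_segments(panel, segment_map)
    return panel


def write_panel(panel: Panel, path: str | Path, header_comments: Sequence[str] = ()) -> None:
    out = panel.df[PANEL_COLUMNS].copy()
    out["period"] = out["period"].astype(str)
    with open(path, "w", newline="") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        out.to_csv(fh, index=False)


def read_segment_map(path: str | Path) -> SegmentMap:
    """Read a segment map CSV: brand_id,segment[,valid_from,valid_to]."""
    df = pd.read_csv(path, comment="#", dtype=str).fillna("")
    if not {"brand_id", "segment"} <= set(df.columns):
        raise ValidationError(f"{path}: expected columns brand_id,segment")
    entries: dict[str, list[SegmentEntry]] = {}
    for _, row in df.iterrows():
        entries.setdefault(row["brand_id"], []).append(
            SegmentEntry(
                segment=row["segment"].strip(),
                valid_from=_opt_date(row.get("valid_from", "")),
                valid_to=_opt_date(row.get("valid_to", "")),
            )
        )
    return SegmentMap(entries)


def write_segment_map(smap: SegmentMap, path: str | Path,
                      header_comments: Sequence[str] = ()) -> None:
    lines = ["brand_id,segment,valid_from,valid_to"]
    for brand, entries in sorted(smap.items()):
        for e in entries:
            lines.append(
                f"{brand},{e.segment},"
                f"{e.valid_from.isoformat() if e.valid_from else ''},"
                f"{e.valid_to.isoformat() if e.valid_to else ''}"
            )
    with open(path, "w", newline="") as fh:
        for line in header_comments:
            fh.write(f"# {line}\n")
        fh.write("\n".join(lines) + "\n")


def _opt_date(value: str) -> date | None:
    value = (value or "").strip()
    return date.fromisoformat(value) if value else None


def normalize_pack(panel: Panel, target: int = 20) -> Panel:
    """Rescale prices to a common pack size (per-stick proportionality).

    A 475p pack of 19 becomes 500p for 20. The original pack size is kept
    in an ``orig_pack_size`` column the first time; the operation is
    idempotent.
    """
    if target <= 0:
        raise ValidationError(f"target pack size must be positive, got {target}")
    df = panel.df.copy()
    if "orig_pack_size" not in df.columns:
        df["orig_pack_size"] = df["pack_size"]
    df["nominal_price"] = df["nominal_price"] * target / df["pack_size"]
    df["pack_size"] = target
    return Panel(df, segment_map=panel.segment_map, archived=panel.archived)


def assign_segments(panel: Panel, smap: SegmentMap) -> Panel:
    """Label every observation with its segment at the observation date.

    Unmapped brands — and brands mapped only outside their validity window,
    e.g. a ULP brand observed before the tier existed — are labelled
    UNASSIGNED; their share mass stays in the panel and is reported through
    the "others" bucket, so total share mass is conserved.
    """
    df = panel.df.copy()
    labels = []
    warned: set[str] = set()
    for brand, period in zip(df["brand_id"], df["period"]):
        seg = smap.segment_for(brand, period.date)
        if seg == UNASSIGNED and smap.has_brand(brand) and brand not in warned:
            warnings.warn(
                f"brand {brand!r} observed at {period} outside its segment "
                "validity window; treated as unassigned there",
                stacklevel=2,
            )
            warned.add(brand)
        labels.append(seg)
    df["segment"] = labels
    return Panel(df, segment_map=smap, archived=panel.archived)


def merge_sources(panels: Iterable[Panel], precedence: Sequence[str]) -> Panel:
    """Combine panels from different data sources into one.

    For each (brand, period) the observation from the highest-precedence
    source present is kept; superseded overlap rows are retained in
    ``Panel.archived`` so overlapping years can be cross-checked between
    sources. Sources not listed in ``precedence`` rank last.
    """
    panels = list(panels)
    frames = [p.df for p in panels]
    if not frames:
        raise ValidationError("merge_sources needs at least one panel")
    combined = pd.concat(frames, ignore_index=True)

    rank = {src: i for i, src in enumerate(precedence)}
    combined["_rank"] = [rank.get(s, len(precedence)) for s in combined["source"]]
    combined = combined.sort_values(
        ["brand_id", "_rank"], kind="stable"
    ).reset_index(drop=True)
    keep_idx = combined.groupby(["brand_id", "period"], sort=False)["_rank"].idxmin()
    kept = combined.loc[sorted(keep_idx)].drop(columns="_rank")
    archived = combined.drop(index=keep_idx).drop(columns="_rank")

    for (brand, period), group in combined.groupby(["brand_id", "period"], sort=False):
        if group["pack_size"].nunique() > 1:
            raise ValidationError(
                f"conflicting pack sizes for brand={brand!r} period={period}: "
                f"{sorted(group['pack_size'].unique())}"
            )

    smap = next((p.segment_map for p in panels if p.segment_map is not None), None)
    return Panel(kept.reset_index(drop=True), segment_map=smap,
                 archived=archived.reset_index(drop=True))
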