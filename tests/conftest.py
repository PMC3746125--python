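from datetime import date

import numpy as np
import pandas as pd
import pytest

from cigshift import (
    HalfYear,
    IndexSeries,
    Panel,
    RegimeSchedule,
    SegmentSeries,
    TaxRegime,
)


@pytest.fixture
def regime_2009():
    """A 2009-style UK regime: 11431p/1000 specific, 24% ad valorem, 17.5% VAT."""
    return TaxRegime(
        effective_from=date(2009, 4, 22),
        specific_duty=11431.0,
        ad_valorem_rate=0.24,
        vat_rate=0.175,
    )


@pytest.fixture
def zero_regime():
    return TaxRegime(date(2000, 1, 1), 0.0, 0.0, 0.0)


@pytest.fixture
def zero_schedule(zero_regime):
    return RegimeSchedule((zero_regime,))


@pytest.fixture
def flat_cpi():
    """Constant index (no inflation), monthly 2000-2011, base January 2010."""
    months = {}
    for y in range(2000, 2012):
        for m in range(1, 13):
            months[date(y, m, 1)] = 100.0
    return IndexSeries.from_mapping(months, base=date(2010, 1, 1))


def make_panel(rows, segment_map=None):
    """rows: (brand_id, period_label, price, pack, share, source[, segment])."""
    records = []
    for row in rows:
        rec = {
            "brand_id": row[0],
            "period": HalfYear.parse(row[1]),
            "nominal_price": row[2],
            "pack_size": row[3],
            "volume_share": row[4],
            "source": row[5],
        }
        if len(row) > 6:
            rec["segment"] = row[6]
        records.append(rec)
    return Panel(pd.DataFrame.from_records(records), segment_map=segment_map)


def make_series(segment, period_labels, net_real, wap_nominal=None):
    """SegmentSeries with a prescribed real net-revenue path (zero tax)."""
    periods = [HalfYear.parse(p) for p in period_labels]
    net = np.asarray(net_real, dtype=float)
    wap = np.asarray(wap_nominal, dtype=float) if wap_nominal is not None else net.copy()
    return SegmentSeries(
        segment=segment,
        periods=periods,
        wap_nominal=wap,
        wap_real=wap.copy(),
        tax_total=wap - net,
        net_revenue_nominal=net.copy(),
        net_revenue_real=net,
        segment_share=np.full(len(periods), 0.5),
    )
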