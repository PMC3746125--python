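"""Synthetic market generator: determinism, exactness, conservation,
scenario structure, and pass-through recovery."""

from dataclasses import replace
from datetime import date

import numpy as np
import pytest

from cigshift import (
    GenerationError,
    HalfYear,
    ScenarioConfig,
    SegmentScenario,
    build_all_series,
    decompose_year,
    default_uk_scenario,
    generate,
    multi_year_average,
    null_scenario,
    write_panel,
)
from cigshift.segments import others_share, segment_share
from cigshift.shifting import FULL_SHIFT, net_real_change


@pytest.fixture(scope="module")
def default_run():
    cfg = default_uk_scenario(seed=42)
    return cfg, generate(cfg)


def tiny_scenario(**overrides):
    base = dict(
        seed=3,
        start_year=2005,
        end_year=2008,
        noise_sd=0.0,
        downtrading_beta=0.0,
        segments={
            "premium": SegmentScenario(
                n_brands=2, base_price=550.0, price_spread=10.0,
                delta_duty=4.0, delta_quiet=0.0, initial_share=0.5,
            ),
            "ulp": SegmentScenario(
                n_brands=2, base_price=400.0, price_spread=4.0,
                delta_duty=-3.0, delta_quiet=0.0, initial_share=0.42,
            ),
        },
    )
    base.update(overrides)
    return ScenarioConfig(**base)


class TestDeterminism:
    def test_same_config_gives_byte_identical_panel(self, tmp_path):
        cfg = default_uk_scenario(seed=7)
        p1, _, _, _ = generate(cfg)
        p2, _, _, _ = generate(cfg)
        f1, f2 = tmp_path / "a.csv", tmp_path / "b.csv"
        write_panel(p1, f1)
        write_panel(p2, f2)
        assert f1.read_bytes() == f2.read_bytes()

    def test_adding_a_brand_leaves_other_trajectories_unchanged(self):
        cfg = tiny_scenario(noise_sd=1.0)
        bigger = tiny_scenario(noise_sd=1.0)
        segs = dict(bigger.segments)
        segs["premium"] = replace(segs["premium"], n_brands=3)
        bigger = replace(bigger, segments=segs)
        small_panel, *_ = generate(cfg)
        big_panel, *_ = generate(bigger)
        for brand in ("premium_01", "ulp_02"):
            a = small_panel.df[small_panel.df["brand_id"] == brand]["nominal_price"]
            b = big_panel.df[big_panel.df["brand_id"] == brand]["nominal_price"]
            assert list(a) == list(b)


class TestNullScenario:
    def test_every_window_full_shift_with_zero_deltas(self):
        cfg = null_scenario(seed=5)
        panel, cpi, schedule, _ = generate(cfg)
        series = build_all_series(panel, schedule, cpi)
        for seg, s in series.items():
            for a, b in zip(s.periods, s.periods[1:]):
                res = net_real_change(s, a, b, schedule)
                assert abs(res.delta_net_real) < 1e-8
                assert res.classification == FULL_SHIFT

    def test_shares_constant_without_downtrading(self):
        cfg = null_scenario(seed=5)
        panel, *_ = generate(cfg)
        for seg in ("premium", "economy"):
            shares = [
                segment_share(panel, seg, p) for p in panel.periods()
            ]
            assert max(shares) - min(shares) < 1e-12


class TestExactConstruction:
    def test_configured_deltas_reproduced_exactly_without_noise(self):
        panel, cpi, schedule, _ = generate(tiny_scenario())
        series = build_all_series(panel, schedule, cpi, include_market=False)
        for year in (2005, 2006, 2007):
            nov_may, may_nov, _ = decompose_year(series["premium"], year, schedule)
            assert nov_may.delta_net_real == pytest.approx(4.0, abs=1e-9)
            assert may_nov.delta_net_real == pytest.approx(0.0, abs=1e-9)
            nov_may, may_nov, _ = decompose_year(series["ulp"], year, schedule)
            assert nov_may.delta_net_real == pytest.approx(-3.0, abs=1e-9)
            assert nov_may.contains_duty_event

    def test_decomposition_additivity_on_noisy_panel(self, default_run):
        _, (panel, cpi, schedule, _) = default_run
        series = build_all_series(panel, schedule, cpi)
        for seg, s in series.items():
            years = [2006, 2007, 2008] if seg == "ulp" else [2002, 2005, 2008]
            for year in years:
                nov_may, may_nov, nov_nov = decompose_year(s, year, schedule)
                assert nov_may.delta_net_real + may_nov.delta_net_real == pytest.approx(
                    nov_nov.delta_net_real, abs=1e-12
                )


class TestScenarioStructure:
    def test_default_scenario_shape(self, default_run):
        cfg, (panel, cpi, schedule, _) = default_run
        # ULP exists only from 2006
        assert segment_share(panel, "ulp", HalfYear(2005, 2)) == 0.0
        assert segment_share(panel, "ulp", HalfYear(2006, 1)) > 0.0
        # all four segments present from 2006 onward
        for seg in ("premium", "mid", "economy", "ulp"):
            assert segment_share(panel, seg, HalfYear(2006, 2)) > 0.0
        # VAT cut dated December 2008 appears in the schedule
        assert any(
            r.effective_from == date(2008, 12, 1) and r.vat_rate == 0.15
            for r in schedule
        )

    def test_share_conservation_every_period(self, default_run):
        _, (panel, *_rest) = default_run
        for p in panel.periods():
            assigned = panel.rows(p)["volume_share"].sum()
            assert assigned + others_share(panel, p) == pytest.approx(1.0, abs=1e-9)
            assert others_share(panel, p) == pytest.approx(0.08, abs=1e-9)

    def test_ulp_share_roughly_doubles(self, default_run):
        _, (panel, *_rest) = default_run
        start = segment_share(panel, "ulp", HalfYear(2006, 1))
        end = segment_share(panel, "ulp", HalfYear(2009, 2))
        assert 1.6 <= end / start <= 2.8

    def test_negative_price_fails_loudly(self):
        segs = {
            "ulp": SegmentScenario(
                n_brands=1, base_price=300.0, price_spread=0.0,
                delta_duty=-80.0, delta_quiet=-80.0, initial_share=0.92,
            )
        }
        cfg = tiny_scenario(segments=segs)
        with pytest.raises(GenerationError, match="ulp_01"):
            generate(cfg)

    def test_config_yaml_round_trip(self, tmp_path):
        cfg = default_uk_scenario(seed=11)
        path = tmp_path / "scenario.yaml"
        cfg.to_yaml(path)
        assert ScenarioConfig.from_yaml(path) == cfg


class TestRecovery:
    def test_three_year_average_recovers_configured_overshift(self, default_run):
        """With noise sd 1p per half-year window, the estimated 3-year average
        annual overshift stays within 3*sd/sqrt(3) of the configured value
        for every segment."""
        cfg, (panel, cpi, schedule, _) = default_run
        series = build_all_series(panel, schedule, cpi, include_market=False)
        years = [2006, 2007, 2008]
        tol = 3 * cfg.noise_sd / np.sqrt(len(years))
        for seg, spec in cfg.segments.items():
            annual = spec.delta_duty + spec.delta_quiet
            estimate = multi_year_average(series[seg], years, average_rounded_years=False)
            assert abs(estimate - annual) <= tol

    def test_ground_truth_realized_matches_pipeline(self, default_run):
        _, (panel, cpi, schedule, truth) = default_run
        series = build_all_series(panel, schedule, cpi, include_market=False)
        realized = truth.realized
        for _, row in realized.iterrows():
            s = series[row["segment"]]
            got = net_real_change(
                s, HalfYear.parse(row["period_from"]), HalfYear.parse(row["period_to"])
            ).delta_net_real
            assert got == pytest.approx(row["delta"], abs=1e-9)
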