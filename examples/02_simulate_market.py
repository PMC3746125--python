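"""Generate the synthetic UK-style cigarette market and look at its shape.

The default scenario spans 2001-2009 with four price segments; the
ultra-low-price (ULP) tier enters in 2006 and gains share through
downtrading. Prices come from inverting the tax engine against each
brand's latent real net-revenue path, so the configured pass-through per
segment is known exactly.
"""

from cigshift import HalfYear, default_uk_scenario, generate, segment_share

config = default_uk_scenario(seed=1)
panel, cpi, schedule, truth = generate(config)

print(f"panel: {len(panel)} observations, {len(panel.periods())} semiannual periods")
print(f"regimes: {len(schedule)} fiscal changes "
      f"({schedule.start} .. {schedule.change_dates()[-1]})")

print("\nvolume share by segment (whole market):")
print(f"{'period':8s} " + " ".join(f"{s:>8s}" for s in config.segments))
for label in ("2001H2", "2005H2", "2006H1", "2009H2"):
    period = HalfYear.parse(label)
    shares = [segment_share(panel, seg, period) for seg in config.segments]
    print(f"{label:8s} " + " ".join(f"{s:8.3f}" for s in shares))

ratio = segment_share(panel, "ulp", HalfYear(2006, 1)) and (
    segment_share(panel, "ulp", HalfYear(2009, 2))
    / segment_share(panel, "ulp", HalfYear(2006, 1))
)
print(f"\nULP share grew by a factor of {ratio:.2f} over 2006-2009 "
      "(cheap brands absorb demand as the price gap widens)")
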