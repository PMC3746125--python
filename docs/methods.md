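# Methods

## The question

Governments raise tobacco excise expecting retail prices to rise.
Manufacturers, however, choose how much of a tax increase to pass on: they
can *overshift* (raise prices by more than the tax, increasing their own
per-pack revenue), pass it through one-for-one, or *undershift* (absorb
part of the tax). If pass-through differs across price segments — say,
overshifting on premium brands while absorbing tax rises on the cheapest
tier — the price gap between expensive and cheap cigarettes widens, which
invites downtrading and blunts the public-health effect of the tax. This
package measures that behaviour from brand-level price/volume panels and
provides a synthetic market with known pass-through so every step is
testable without proprietary scan data.

## Core quantities

**Tax decomposition.** A UK-style mixed excise on a pack of `n` sticks
sold at tax-inclusive price `P` (pence) has three parts: specific duty
`s·n/1000` (with `s` in pence per 1000 sticks), ad valorem duty `a·P`
levied on the retail selling price (the EU convention; the base is a
regime parameter), and VAT extracted from the tax-inclusive price as
`P·v/(1+v)`. Net-of-tax revenue — what manufacturer and retailer keep —
is

    N(P) = P·(1 − a − v/(1+v)) − s·n/1000 ,

affine in `P` with positive slope whenever the regime is admissible
(`a + v/(1+v) < 1`, enforced at construction). The inverse
`P(N) = (N + s·n/1000)/(1 − a − v/(1+v))` is exact and is what the
simulator uses to impose pass-through by construction.

**Real terms.** Nominal pence observed in period `t` are deflated by a
contiguous monthly CPI series: `real = nominal · I(base)/I(t)`, matching
each semiannual observation (H1 → 1 June, H2 → 1 November) to the latest
monthly index at or before its representative date. Deflation is linear,
so computing net revenue before or after deflating gives identical
results.

**Shifting statistic.** For each segment, the within-segment
volume-weighted average price (WAP) is taxed under the regime in force at
the observation date; the change in *real net revenue of the WAP* across a
window is the shifting statistic. Analysis years run November to November
and split at the intervening June observation into a duty half (Nov–May,
containing the annual March/April uplift) and a quiet half (May–Nov); the
two half-window changes sum to the annual change exactly because all three
are differences of one series. Classification uses a ±0.05p tolerance —
half the one-decimal reporting precision — so a change printing as 0.0 is
a full shift. Multi-year averages default to averaging the
already-rounded yearly figures (`average_rounded_years=True`), mirroring
how such summary tables are usually assembled; full precision is a flag
away.

**Indices.** The most popular price category (MPPC) is operationalised as
a 1-penny price bin (configurable): the bin with the largest summed
volume share, represented by its volume-weighted mean price; ties go to
the lower-priced bin, and a brand-based variant (single top-share brand)
is available. The WAP index is the whole-market share-weighted mean.
Both are built on nominal prices and rebased to 100 at a chosen period; an
official external series can be compared on the intersection of spans.

**Association.** Brand-level scatter analyses use each brand's own
deflated prices (not its segment average): real price change (%) vs
initial share (%), and share change (percentage points) vs real price
change (%). The summary is a Spearman rank correlation — robust to the
outliers typical of brand panels — with Pearson behind a flag; an axis
with zero variance yields an explicitly undefined correlation rather than
a number.

## The synthetic market

The generator emulates the structure of the UK cigarette market in the
2000s rather than any behavioural price-setting process:

* **Segments.** premium / mid / economy / ULP with configurable brand
  counts, initial nominal prices (defaults 550 / 500 / 450 / 400 pence,
  brands spread symmetrically around the base), and initial whole-market
  shares (0.30 / 0.10 / 0.52 with 0.08 held by unobserved "others"); the
  ULP tier enters in 2006 with 5% share carved proportionally from
  incumbents.
* **Fiscal calendar.** Specific duty starts at 9225p/1000 and rises
  275p/1000 every April (so every Nov–May window contains exactly one duty
  event and the 2009 level ≈ 11425p/1000 matches the era); ad valorem is
  22%; VAT is 17.5% with the December 2008 cut to 15% and the January 2010
  restoration. CPI compounds at 2%/year monthly, base January 2010.
* **Pass-through by construction.** Each brand carries a latent real
  net-revenue path advanced by the segment's configured step — `delta_duty`
  in duty windows, `delta_quiet` in quiet windows — plus N(0, σ²) noise
  (σ = 1p by default, on the net-revenue scale so classification
  tolerances stay interpretable). The nominal price is then obtained by
  inverting the tax engine under that period's regime and CPI level, which
  makes "overshift by δ" exact when σ = 0. Default steps follow the
  observed per-segment pattern: premium +2.9/+1.2, mid +3.9/+0.7, economy
  +2.1/+2.8, ULP −3.0/+4.3 (duty/quiet, pence) — the cheapest tier absorbs
  tax at duty events and rebuilds margin in the quiet half.
* **Downtrading.** Shares update multiplicatively,
  `w_b ∝ w_b·exp(−β·p_b/p̄)` with `p̄` the share-weighted mean real price,
  renormalised to the assigned mass (others' share is constant). β = 0.45
  was set once so the default scenario's ULP share roughly doubles over
  2006–09; it makes the premium share fall faster than the real market's
  did, a known stylisation.
* **Reproducibility.** Each brand draws from its own `numpy` Generator
  seeded by (master seed, crc32(brand id)), so adding a brand never
  perturbs existing trajectories, and a fixed config yields byte-identical
  CSV output.

Two derived scenarios exist. `null_scenario` zeroes all steps, noise and
downtrading and lets all four segments trade from the start (a late ULP
entry would move whole-market composition, which is itself a nonzero
statistic); every downstream shift statistic is then exactly zero.
`downtrading_scenario` (2005–09, all segments from the start, β = 0.3)
makes configured net-revenue growth steeply increasing in segment price
level, so the share flow toward cheap brands lines up with an inverse
share-change/price-change relation at brand level. That separation is
needed because in the Table-1-calibrated default scenario the premium
segment has the *smallest percentage* retail price growth — its pence
overshift is diluted by its high price and by the VAT cut at the end of
the span — while losing the most share through the price-level logit,
which can mask the market-wide inverse relation in a brand-level rank
correlation.

## What the simulator does not emulate

Behavioural demand (price elasticities, addiction dynamics), illicit trade
and cross-border shopping, promotional pricing and price-marked packs,
within-year monthly price paths, survey measurement error in shares, and
the real market's brand births/deaths. Passing tests therefore show the
*pipeline* recovers known pass-through from data of the right shape, not
that the default parameters describe any real market year by year.

## Numerical choices

* Money is floating-point pence throughout; rounding (half away from zero,
  one decimal) happens only at reporting.
* Regimes apply from their effective date with no proration; a mid-window
  change is picked up by whichever observation dates fall after it.
* Missing data are errors or explicit gaps, never silent zeros: a segment
  with no share mass in a period is absent from its series (the ULP line
  starts in 2006), CPI lookups outside the covered span raise, and index
  months must be contiguous.
* Share filters use strict inequality ("over 0.2%" drops a brand exactly
  at the threshold) applied at the window's initial period.
* MPPC ties break to the lower price bin; the bin's representative price
  is its volume-weighted mean.
* Panel validation enforces per-period share mass ≤ 1 + 1e−9 and unique
  (brand, period, source) keys, reporting offending rows/periods.

## Problem sizes

The default scenario is 18 brands × 18 semiannual periods (284
observations; ULP brands absent before 2006); the full simulate→analyze
pipeline and the entire test suite run in seconds, and the acceptance
script performs one default-scenario run plus one downtrading-scenario run
per invocation.

## Known limitations

The all-brands ("weighted average") row of the shifting table mixes true
pass-through with composition drift: as share moves onto cheaper brands
the market WAP falls even when every segment overshifts, so the aggregate
row understates segment-level overshifting — visible in both the published
table and the simulator, and a reason the segment-level view matters. The
published premium-row three-year average is internally inconsistent by
0.1p (the printed yearly figures average to 4.17, printed as 4.1, the sum
of its printed half-window averages); the package reports the
arithmetically correct rounding and documents the discrepancy rather than
reproducing it.
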