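"""Decompose the tax on a pack of cigarettes under a mixed excise regime.

A 2009-style UK regime: 11431p per 1000 sticks specific duty, 24% ad
valorem on the retail price, 17.5% VAT. On a 500p pack of 20 the script
prints each component, the net-of-tax revenue the manufacturer and
retailer keep, and the share of the burden that is specific duty.
"""

from datetime import date

from cigshift import TaxRegime, price_for_net_revenue, specific_share, tax_breakdown

regime = TaxRegime(
    effective_from=date(2009, 4, 22),
    specific_duty=11431.0,
    ad_valorem_rate=0.24,
    vat_rate=0.175,
)

bd = tax_breakdown(price=500.0, pack_size=20, regime=regime)
print(f"specific duty : {bd.specific:7.2f}p")
print(f"ad valorem    : {bd.ad_valorem:7.2f}p")
print(f"VAT           : {bd.vat:7.2f}p")
print(f"total tax     : {bd.total:7.2f}p")
print(f"net revenue   : {bd.net_revenue:7.2f}p  (what industry keeps per pack)")
print(f"specific share: {specific_share(bd):7.1%}  (specific duty / total burden)")

# the inverse: what retail price yields a chosen net revenue?
target = bd.net_revenue + 5.0
print(f"\nto earn {target:.2f}p net the pack must sell at "
      f"{price_for_net_revenue(target, 20, regime):.2f}p "
      "(a 5p margin rise costs the smoker more than 5p)")
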