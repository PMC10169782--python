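"""Design a single-cell encapsulation run from an observed empty fraction.

Droplet loading is Poissonian: if 80% of droplets come up empty, the mean
occupancy is lambda = -ln(0.8) ~ 0.223, and the full occupancy distribution
(and every derived design number) follows from that single value.
"""

from dropgrow import (
    droplets_for_target,
    lambda_from_empty_fraction,
    multiplet_fraction,
    occupancy_pmf,
    single_cell_purity,
)

lam = lambda_from_empty_fraction(0.8)
dist = occupancy_pmf(lam, k_max=4)

print(f"mean occupancy lambda           : {lam:.5f}")
for k, p in enumerate(dist.pmf):
    print(f"P({k} cells per droplet)         : {p:.5f}")
print(f"P(>4 cells)                     : {dist.tail_mass:.2e}")
print(f"single-cell purity (occupied)   : {single_cell_purity(lam):.4f}")
print(f"multiplet fraction (all)        : {multiplet_fraction(lam):.5f}")

counts = droplets_for_target(lam, 14_400_000)  # ~4 h of collection at 1 kHz
print(f"\nof 14.4 million droplets: {counts.empty:,.0f} empty, "
      f"{counts.single:,.0f} single-cell, {counts.multiplet:,.0f} multiplets")

# Reading: ~20% of droplets carry one cell and ~2% carry two, so among
# occupied droplets ~89% are true single-cell cultures; to push multiplets
# below that you dilute further and accept more empties.
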