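"""Serial-transfer competition: shared nutrient pool versus privatized droplets.

A rate specialist (higher maximum growth rate, lower biomass yield) and a
yield specialist (slower but 1.5x more biomass per substrate, the ratio of
3 vs 2 ATP per glucose between mixed-acid and homolactic fermentation)
start at 20:80.  In a shared batch the fast strain takes the pool; when every
transfer grows single founders in private droplet cores, biomass per founder
is set by yield, and the efficient strain is enriched instead.
"""

import numpy as np

from dropgrow import (
    DropletEnsemble,
    TransferProtocol,
    generate_kinetics,
    serial_batch_transfers,
    serial_droplet_transfers,
)

rate, yld = generate_kinetics("rate-vs-yield")
print(f"{rate.name}:  mu_max={rate.mu_max}/h  Ks={rate.K_s} mM  Y={rate.yield_Y}/mM")
print(f"{yld.name}: mu_max={yld.mu_max}/h  Ks={yld.K_s} mM  Y={yld.yield_Y}/mM\n")

protocol = TransferProtocol(dilution_factor=0.01, duration_h=48, n_transfers=8,
                            substrate_S0=50.0)

batch = serial_batch_transfers([rate, yld], protocol, [0.2, 0.8])
ensemble = DropletEnsemble(
    n_droplets=100_000, core_substrate=50.0, founder_frequencies=[0.2, 0.8],
    founder_mode="exact-single", rng_seed=1,
)
droplet = serial_droplet_transfers([rate, yld], ensemble, protocol)

print("transfer   yield-specialist freq (batch)   (droplets)")
for t in range(protocol.n_transfers + 1):
    print(f"{t:8d}   {batch.frequencies[t, 1]:>28.6f}   {droplet.frequencies[t, 1]:.4f}")

# Reading: the same strain pair that collapses below 1e-4 in shared batches
# climbs toward fixation in droplets -- nutrient privatization flips the
# selection regime from rate to yield.
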