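"""Recovering the price-green coupling designed into synthetic data.

The generator can couple house prices to decay-weighted green
proximity (gamma > 0 emulates paying a premium to live near parks).
This script shows the price-accessibility correlation is near zero
when gamma = 0 and strongly positive when gamma = 0.5.
"""

import numpy as np

from ugsaccess import SyntheticCityConfig, generate_city, two_step_fca

for gamma in (0.0, 0.5):
    rs = []
    for seed in range(10):
        cfg = SyntheticCityConfig(
            n_communities=500, n_greenspots=30, price_green_coupling=gamma
        )
        communities, greenspaces = generate_city(cfg, seed=seed)
        field = two_step_fca(communities, greenspaces, d0=2_500.0, metric="euclidean")
        price = np.array([c.price for c in communities])
        rs.append(np.corrcoef(price, field.A)[0, 1])
    print(f"gamma = {gamma}: mean Pearson r(price, accessibility) over "
          f"10 seeds = {np.mean(rs):+.3f}")

print("\nWith no coupling the correlation fluctuates around zero; with "
      "gamma = 0.5 richer communities sit measurably closer to green space, "
      "the structure the equity analysis is designed to detect.")
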