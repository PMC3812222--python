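"""Simulate the standard Boltzmann Walker and check its diffusion limit.

Generates a batch of walkers with known speed, mean free path and
persistence, measures the long-time mean square displacement, and compares
it with the closed-form diffusion coefficient D = v*lambda / (2*(1-g)).
"""

import numpy as np

from boltzwalker import BWParameters, diffusion_coefficient, msd_over_time

params = BWParameters(speed=0.015, mean_free_path=0.01, g=0.6)
D = diffusion_coefficient(params.speed, params.mean_free_path, params.g)
print(f"walker: v={params.speed} m/s, lambda={params.mean_free_path} m, "
      f"g={params.g}  ->  D = {D:.3e} m^2/s")

rng = np.random.default_rng(1)
times = np.array([20.0, 60.0, 200.0])  # seconds; up to ~300 mean free times
msd = msd_over_time(params, times, n_walkers=3000, rng=rng)
for t, m in zip(times, msd):
    print(f"t = {t:6.0f} s   MSD = {m:.5f} m^2   MSD/(4Dt) = {m/(4*D*t):.3f}")
print("MSD/(4Dt) -> 1 is the diffusive limit: the population spreads like "
      "a pure random walk with transport mean free path lambda/(1-g).")
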