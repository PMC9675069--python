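"""Invasion fitness of rare mutants and the pairwise invasibility plot.

Invasion fitness lambda(theta_mut, theta_res) is the per-capita growth of a
rare mutant in the environment (M*, B*) set by the resident at equilibrium.
Its sign over all (resident, mutant) pairs — the PIP — summarizes the
model's global evolutionary behavior at one temperature.
"""

import numpy as np

from mixoevolve import ModelParams, compute_pip, invasion_fitness

params = ModelParams(z=0.0)  # linear trade-off
T = 23.0

for mutant in (0.3, 0.5, 0.7):
    lam = invasion_fitness(mutant, theta_res=0.5, T=T, params=params)
    print(f"lambda(theta_mut={mutant}, theta_res=0.5) = {lam:+.5f} /d")
print("  -> at 23 degC more phagotrophic mutants invade a half-invested "
      "resident (positive fitness); less phagotrophic ones die out.")

pip = compute_pip(T, params, grid_n=41)
counts = {name: int((pip.category == code).sum())
          for code, name in enumerate(
              ("mutant_invades", "mutant_excluded",
               "resident_nonviable_mutant_viable", "mutant_nonviable"))}
print(f"\nPIP at {T} degC on a 41x41 grid: {counts}")
diag = [pip.category_name(i, i) for i in range(41)]
print(f"diagonal categories: {set(diag)}")
print("  -> the diagonal is never 'mutant_invades': a strategy cannot "
      "invade itself (lambda(theta, theta) = 0).")
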