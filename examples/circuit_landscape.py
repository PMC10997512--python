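"""Bifurcation structure of the DNFL-B circuit and its treatment transforms.

Sweeps the oncogenic signal S from zero to its maximum, counts the
stable states of the effective transcriptome force, and shows how the
TOTO (signal silencing) and TKI (signal reduction) transformations
reshape the landscape.
"""
import numpy as np

from cmlstate.potentials import (CircuitParams, effective_force,
                                 find_critical_points)
from cmlstate.treatment import circuit_treatment

params = CircuitParams.reference()
grid = np.linspace(0, 2 * params.x0_b_on_a, 2049)

print("stable states vs signal level:")
for s in np.linspace(0.0, params.s_max, 6):
    cps = find_critical_points(lambda b: effective_force(b, s, params), grid)
    print(f"  S = {s:4.1f}: {cps.n_stable} stable "
          f"({len(cps)} critical points at {np.round(cps.locations, 2)})")

full = params.with_(s=params.s_max)
base = find_critical_points(lambda b: effective_force(b, full.s, full), grid)
print(f"\nuntreated disease landscape: c1..c5 = {np.round(base.locations, 2)}")
print("(the three odd-indexed points are the stable early/transition/late "
      "disease states; the two others are the basin boundaries)")

for kind in ("TOTO", "TKI"):
    treated = circuit_treatment(full, kind)
    cps = find_critical_points(
        lambda b: effective_force(b, treated.s, treated), grid)
    print(f"{kind}: signal -> {treated.s:.2f}, response modifier "
          f"{treated.gamma_circuit}; stable states at "
          f"{np.round(cps.stable_points, 2)}")
print("TOTO leaves a single near-health state inside the untreated "
      "transition basin; TKI keeps the signal partially on.")
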