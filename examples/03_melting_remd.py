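"""Melting thermodynamics of the 14 bp S1S2 duplex by parallel tempering.

Replica-exchange Langevin dynamics across a temperature ladder yields
per-temperature ensembles; a strand counts as hybridized when at least
half of its hydrogen-bonding sites sit within 1.5 sigma_HB of a
complementary site on the other strand.  The melting temperature is
estimated both from the half-melted crossing of the melting curve and
from the heat-capacity maximum.

This is a desk-scale reduction (16 replicas, 4 ns each) of the standard
protocol (32 replicas, 0.5 us each); the short runs under-sample the
dissociated state, which biases the apparent Tm upward.
"""

import numpy as np

from cgdna.protocols import melting_remd

curve, cvc, res, top = melting_remd(
    seed=3, n_steps=400_000, temperatures=np.linspace(250, 450, 16))

print("T (K)   melted fraction")
for t, f in zip(curve.temperatures, curve.fraction_melted):
    print(f"{t:6.1f}   {f:.2f}")
print(f"\nTm (melting-curve crossing) = {curve.tm:.1f} +- {curve.tm_err:.1f} K")
print(f"Tm (heat-capacity maximum)  = {cvc.tm:.1f} +- {cvc.tm_err:.1f} K")
print(f"mean neighbour swap acceptance = {np.nanmean(res.acceptance_ratio):.2f}")
print()
print("The sigmoidal melted fraction and the agreement of the two Tm")
print("estimators reflect two-state-like duplex melting; quantitative")
print("Tm values need the full-length protocol.")
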