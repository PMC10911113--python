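"""Protein-DNA binding free energy by umbrella sampling + WHAM.

A lysine-rich 10-residue peptide (one HPS bead per residue, +5 e) binds
an 8 bp duplex (2-bead DNA, -16 e backbone) through screened
electrostatics and hydropathy-scale short-range interactions.  Umbrella
windows restrain the peptide-DNA centre-of-mass distance; WHAM with the
radial Jacobian correction gives the potential of mean force, and the
volume integral of exp(-beta F) up to the PMF zero yields the molar
dissociation constant.
"""

import numpy as np

from cgdna import (ForceField, HpsParameterSet, LangevinSettings,
                   SimulationState, UmbrellaWindow, build_dna_topology,
                   build_protein_topology, combine, run_umbrella)
from cgdna.analysis import kd_from_pmf, wham_pmf
from cgdna.geometry import build_system_coordinates
from cgdna.parameters import ElectrostaticsContext

dna = build_dna_topology("GCGATCGC", "two_bead", duplex=True)
pep = build_protein_topology("KAKAKAKAKA")
system = combine(dna, pep)
ff = ForceField(system, hps_params=HpsParameterSet.urry(),
                elec=ElectrostaticsContext.from_salt(100.0))
state = SimulationState.from_coords(
    build_system_coordinates(system, box=1000.0, preset="relaxed"))

dna_beads = [b.index for b in system.beads if b.kind != "aa"]
pep_beads = [b.index for b in system.beads if b.kind == "aa"]
windows = [UmbrellaWindow(c) for c in np.arange(10.0, 60.1, 2.5)]

result = run_umbrella(windows, ff, state,
                      LangevinSettings(temperature=300.0, seed=2, stride=25),
                      n_steps=20000, group_a=dna_beads, group_b=pep_beads,
                      equil_steps=5000)
profile = wham_pmf(result.series, result.windows, 300.0, bins=100)
kd = kd_from_pmf(profile)

print(f"{len(windows)} windows, spring 0.5975 kcal/(mol A^2), 300 K, 100 mM")
print(f"PMF minimum: {profile.f.min():.2f} kcal/mol "
      f"at r = {profile.r[profile.f.argmin()]:.1f} A")
print(f"PMF reference distance b = {profile.b:.1f} A")
print(f"Kd = {kd:.2e} M")
print()
print("A negative PMF well of a few kcal/mol and a sub-mM Kd show the")
print("electrostatically driven association of the cationic peptide with")
print("the DNA; lambda and charge patterns of the sequence set the depth.")
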