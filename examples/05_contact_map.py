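"""Residue-level contact map between a bound peptide and DNA.

After a short Langevin run of a cationic peptide with an 8 bp duplex,
the probability that each peptide residue contacts each DNA residue
(any bead pair within 1.5 x the mean pair vdW diameter) is computed
over the trajectory.
"""

import numpy as np

from cgdna import (ForceField, HpsParameterSet, LangevinSettings,
                   SimulationState, build_dna_topology,
                   build_protein_topology, combine, run_langevin)
from cgdna.analysis import contact_map
from cgdna.geometry import build_system_coordinates
from cgdna.parameters import ElectrostaticsContext

dna = build_dna_topology("GCGATCGC", "two_bead", duplex=True)
pep = build_protein_topology("KAKAKAKAKA")
system = combine(dna, pep)
ff = ForceField(system, hps_params=HpsParameterSet.urry(),
                elec=ElectrostaticsContext.from_salt(100.0))
state = SimulationState.from_coords(
    build_system_coordinates(system, box=1000.0, preset="relaxed",
                             chain_offset=15.0))
traj = run_langevin(state, ff,
                    LangevinSettings(temperature=300.0, seed=4, stride=200),
                    150_000, save_frames=True)

dna_groups, dna_labels = [], []
for chain in (0, 1):
    for i, rec in enumerate(system.residues[chain]):
        dna_groups.append([rec["bb"], rec["base"]])
        dna_labels.append(f"S{chain + 1}:{rec['species']}{i + 1}")
pep_groups = [[rec["ca"]] for rec in system.residues[2]]
pep_labels = [f"{rec['species']}{i + 1}"
              for i, rec in enumerate(system.residues[2])]

cmap = contact_map(traj.frames[100:], pep_groups, dna_groups,
                   labels_a=pep_labels, labels_b=dna_labels)
print(f"contact probabilities over {cmap.metadata['n_frames']} frames "
      f"(cutoff rule: {cmap.metadata['factor']} x mean pair sigma)")
print("residue   mean P(contact with any DNA residue)")
for lab, row in zip(cmap.labels_a, cmap.probability):
    bar = "#" * int(20 * row.max())
    print(f"{lab:>4}      {row.mean():.2f}  {bar}")
print()
print("The map identifies the peptide's DNA-binding interface; on larger")
print("systems the same analysis resolves arginine/lysine-rich binding")
print("patches residue by residue.")
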