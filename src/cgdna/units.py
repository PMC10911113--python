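"""Unit system and physical constants.

The whole package works in one fixed unit system:

* length        Angstrom (A)
* energy        kcal/mol
* mass          amu (g/mol)
* charge        elementary charge e
* temperature   K
* time          ps internally; user-facing timesteps are given in fs

In these units a force is kcal/(mol A) and the conversion factor
``ENERGY_TO_MVSQ`` turns kcal/mol into amu A^2/ps^2 so that Newton's
equations can be integrated directly on (amu, A, ps) state.
"""

#: Boltzmann constant, kcal/(mol K)
KB = 0.0019872041

#: Coulomb constant k_e = 1/(4 pi eps0), kcal A / (mol e^2)
COULOMB = 332.06

#: 1 kcal/mol expressed in amu A^2 / ps^2
ENERGY_TO_MVSQ = 418.4

#: fs -> ps
FS = 1.0e-3

#: Avogadro's number, 1/mol
N_AVOGADRO = 6.02214076e23

#: A^3 -> litre
A3_TO_L = 1.0e-27
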