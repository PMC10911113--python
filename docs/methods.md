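# Methods

This note records the model definition, the numerical conventions, the
sampling protocols and the analysis algorithms implemented in `cgdna`,
together with the design choices made where the model description
leaves the implementation open, and what the desk-scale validation
does and does not establish.

## Model definition and conventions

**Representation.** DNA: one backbone bead per nucleotide (charge −1 e,
mass 178.08 amu) bonded to a base bead (A 134.1, T 125.1, C 110.1,
G 150.1 amu).  The 3-bead variant adds a dummy hydrogen-bonding site
per base (mass 0.5 × base mass, bonded at 1.95 Å) that carries all
hydrogen bonding; the site is kept collinear with the backbone–base
axis by a cosine-squared angle (K = 80 kcal/mol, θ₀ = 180°).
Proteins: one neutral-or-charged bead per residue at the Cα position
(Arg/Lys +1, Asp/Glu −1), bonded at 3.8 Å with K = 10 kcal/(mol Å²).

**Functional forms.** Harmonic terms use the K(x − x₀)² convention
without ½ prefactors, matching the convention under which the published
force constants reproduce the model.  The 12–10 attraction is
δ[5(σ/r)¹² − 6(σ/r)¹⁰], whose minimum is exactly −δ at r = σ; this is
the standard 12–10 form in coarse-grained DNA work and is an assumption
of this implementation.  Excluded volume is WCA with ε = 4 kcal/mol and
σ = 5.5 Å.  Electrostatics is Debye–Hückel with ε_r = 80, the Coulomb
constant fixed at 332.06 kcal·Å/(mol·e²), and a 3.5 κ cutoff; it acts
between *all* charged nonbonded beads (DNA–DNA, protein–protein and
protein–DNA), which is required for the λ = 0 limit of the protein–DNA
model to remain meaningful.  The HPS term is the Ashbaugh–Hatch split
of a Lennard-Jones potential at 2^{1/6}σ with global ε = 0.2 kcal/mol
and arithmetic mixing of λ and σ.

**Pair classification.** Stacking (consecutive intrastrand bases),
hydrogen bonding (complementary Watson–Crick partners, intra- and
interstrand, excluding intrastrand |i−j| ≤ 2), and excluded volume
(every other base–base pair) are mutually exclusive; directly bonded
pairs carry no nonbonded term.  1–3 and 1–4 pairs are *not* excluded.
Whether WCA also applies to backbone-involving pairs is ambiguous in
the model description; the literal base-only rule is the default and a
`wca_backbone` switch enables the broader reading.

**Parameter provenance.** The stacking/H-bonding tables ship with the
global melting-calibration factors (2.1 stacking, 0.95 H-bonding)
already folded in; `DnaParameterSet.scaled()` rescales *relative to the
defaults*, so the factors can never be applied twice.  The 3-bead
dummy-site well depths use the tabulated values 8.5/10.4 kcal/mol.
Amino-acid λ/σ tables for the Urry and Kapcha–Rossky scales are vendored
constants from the published HPS parameterisations (Regy et al. 2021,
Protein Sci. 30:1371; Dignon et al. 2018, PLoS Comput. Biol.
14:e1005941).  The HPS σ of DNA beads is not part of the published
model; the DNA excluded-volume diameter (5.5 Å) is adopted for backbone
and base beads.  HPS pairs are truncated at 25 Å (tail < 10⁻⁴ kcal/mol),
configurable.

**Cutoff treatment.** All cutoffs are plain truncation without
shifting.  The residual magnitudes at the published cutoffs are ~1.9%
of δ for stacking, ~4% of δ for 2-bead hydrogen bonding, ~0.6% of kT
for Debye–Hückel; WCA and the λ = 0 HPS branch vanish continuously by
construction.

**Units.** Å, kcal/mol, amu, elementary charge, K; time in ps
internally (user-facing timesteps in fs); k_B = 0.0019872041
kcal/(mol K); 1 kcal/mol = 418.4 amu Å²/ps².

## Starting structures

`build_bdna_coordinates` generates an ideal right-handed duplex with
36° twist and 3.4 Å rise by default.  The backbone radius follows
exactly from the backbone bond length, rise and twist; the remaining
radial constants were solved once (and frozen) so that every bond is
exact, Watson–Crick site separations fall inside the hydrogen-bond
capture range [σ_HB, 1.5 σ_HB] for both variants, and the 3-bead dummy
sites point exactly at their partners (zero angle strain).  Meeting all
three constraints simultaneously at 36°/3.4 Å forces an axial stagger
between paired bases; this is a property of the bead geometry (a 5.75 Å
backbone–base bond cannot point at a partner 6.2 Å away from a backbone
circle of radius 7 Å without it).

A second frozen preset, `relaxed` (29.2° twist, 3.25 Å rise, radial
backbone–base bonds, stacking at its rest distance), sits close to the
model's own energy minimum and is used to start production runs so the
quoted equilibration lengths suffice.  The 2-bead equilibrium ensemble
was verified to be independent of the starting twist over 33–45°.
`build_system_coordinates` lays protein chains out as extended Cα
chains parallel to the helix axis; umbrella protocols additionally run
steepest-descent minimization per window to remove overlaps.

## Sampling

**Langevin dynamics.** BAOAB splitting, default 10 fs timestep, chosen
for stability with the stiff K = 50 bonds; the thermostat damping time
defaults to 10 ps (the model description is ambiguous between 10 ps and
1000 ps; equilibrium observables were verified insensitive to τ over
1–100 ps, and τ is configurable).  All randomness flows from one
integer seed through `numpy.random.Generator`; identical seeds give
bitwise identical trajectories.  Integration aborts with the failing
step index if coordinates go non-finite or a sampled step displacement
exceeds 3 Å.

**Replica exchange.** Neighbour swaps every 100 steps (alternating
even/odd pairs), Metropolis probability min(1, exp[(β_i − β_j)(E_i −
E_j)]); configurations are exchanged between temperature slots with
velocity rescaling by √(T_new/T_old); every sample is tagged with its
temperature slot and replica id.

**Umbrella sampling.** The collective variable is the mass-weighted
COM–COM distance between two bead groups, biased by k_u(d − d₀)² with
k_u = 0.5975 kcal/(mol Å²) by default — the same no-½ convention WHAM
consumes, so the pipeline is internally consistent.  Windows are
visited from the largest centre inward, each starting from the previous
window's relaxed endpoint.

**Neighbour lists.** None: system sizes in the validation studies
(≤ ~200 beads) make precomputed class-resolved pair lists faster than
cell lists; this is purely an efficiency choice invisible to results.

## Analyses

**Hybridization.** A site (base bead, or dummy site in the 3-bead
variant) is engaged when any complementary site on the other strand is
within 1.5 σ_HB; a strand is hybridized when at least half its sites
are engaged (boundary inclusive); the duplex is melted when either
strand is melted (configurable to `either`).

**Melting.** Melted fraction per temperature with Tm at the 0.5
crossing of the isotonic-regressed curve; heat capacity from potential
energy fluctuations C_v = (⟨E²⟩ − ⟨E⟩²)/(k_B T²) with Tm at the maximum
after Gaussian smoothing (bandwidth = ladder spacing) and parabolic
refinement.  Uncertainties by block averaging over 3 blocks.

**Helical structure.** The local axis at each interior base pair comes
from the screw transformation (Kabsch superposition) mapping the
4-residue duplex window starting there onto the window shifted by one
base pair: its rotation axis is the local helix axis, the rotation
angle the local twist, and the axial translation the rise.  This
recovers the construction parameters of an ideal helix exactly for any
twist and azimuthal bead placement, which centroid-anchor schemes do
only when paired bases sit diametrically about the axis.  Base rise is
the projection of consecutive base-pair centres on the local axis;
helical width is twice the mean radial distance of backbone beads from
it (bead centres, no radius added); bp/turn = 360°/mean twist.  Three
terminal bases per end are excluded; melted frames are excluded and
counted.

**Groove widths.** Cross-strand backbone–backbone bead-centre distances
at a designated base-pair step (the TC step, step 19, of the 32 bp
validation sequence; 1-based as conventional).  The two groove-defining
index offsets are the local minima of the trajectory-mean distance
profile, one on each side of the Watson–Crick pairing offset; they are
calibrated on the analysed trajectory itself because frozen
ideal-fixture offsets do not survive the registration changes of
equilibration.  Following the bead-centre convention of this model
family, the *wider* separation is reported as the minor groove width
and the narrower as the major.

**WHAM and K_d.** Self-consistent WHAM over the window histograms,
iterated to 10⁻⁷ on the free-energy shifts in log space; the radial
PMF is F(r) = −k_BT ln P(r) + 2 k_BT ln r + C with C anchoring the top
decile of sampled distances to zero and b recorded where F reaches that
plateau.  Non-overlapping adjacent windows raise a diagnostic naming
the gap.  K_d⁻¹ = N_A ∫₀ᵇ 4π r² e^{−βF} dr (trapezoid on the profile
grid, Å³ → L); unsampled hard-core distances contribute nothing.

**Contacts.** Group-against-group probability that any bead pair is
within the cutoff rule, default 1.5 × the mean pair vdW diameter
(recorded in the output metadata).

## Validation protocols and problem sizes

The package's standard studies (in `cgdna.protocols`) define the
conditions everything is tested under:

* **Structure**: the 32 bp duplex 5′-ATACAAAGGTGCGAGGTTTCTATGCTCCCACG-3′
  at 290 K, 100 mM (κ = 10 Å), 300 Å box; 4×10⁵ equilibration +
  10⁶ production steps (10 ns) per variant, frames every 10 ps.
* **Stability**: the 14 bp duplex S1 = 5′-GCGTCATACAGTGC-3′ / S2 =
  5′-GCACTGTATGACGC-3′ at 120 mM (κ = 8.8 Å); 10⁶ steps at 290 K
  (stays fully hybridized) and at 420 K (dissociates).
* **Melting**: reduced parallel tempering of S1S2, 16 replicas over
  250–450 K, 4 ns each.  At this desk scale the dissociated state is
  under-sampled starting from a bound duplex, which biases the apparent
  melting temperature upward (≈365 K from the reduced run); quantitative
  Tm needs the full-scale ladder (32 replicas × 0.5 µs).

These are generated conditions, not measured data: passing the suite
shows the implementation is internally correct (exact forces, Boltzmann
statistics, closed-form oracle recovery) and that the model's
equilibrium duplex is stable and B-DNA-like in rise and bead-centre
groove widths.  It does not by itself establish agreement with
experimental melting curves, sequence-dependent mechanics, or binding
constants of real proteins, all of which need full-scale sampling.

## Known limitations

* Under the screw-axis definitions above, the model's 32 bp duplex
  equilibrates at ~12 bp per helical turn and a bead-centre helical
  width of ~17 Å for both variants.  A backbone of 5.5 Å bonds at
  ~3 Å rise geometrically ties the backbone radius to the twist
  (R = chord/(2 sin(twist/2))), so width and bp/turn cannot be varied
  independently; literature values for these two quantities quoted
  under other axis or width conventions (e.g. including bead surfaces)
  are not directly comparable.  Rise and groove widths are insensitive
  to this convention choice and agree with B-DNA-calibrated reference
  values within a few percent.
* Bonded parameters are sequence-independent; sequence-dependent
  bending/persistence mechanics is untuned.
* The dielectric is uniform (ε_r = 80) and salt enters only through κ;
  no dielectric saturation or ion correlations.
* The restraint COM is mass-weighted (the conventional choice); a
  geometric-COM restraint would shift window centres slightly.
* Desk-scale melting temperatures are kinetically biased upward, as
  noted above.
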