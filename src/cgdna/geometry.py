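"""Ideal B-form starting coordinates for CG DNA duplexes.

The builder produces a canonical right-handed double helix with a
configurable twist (default 36 deg, 10 bp/turn) and rise (3.4 A).  The
radial placement of the beads is *derived* from the model's bond
lengths rather than copied from atomistic B-DNA:

* the backbone radius follows exactly from the backbone-backbone bond
  length (5.5 A), the rise and the twist;
* the base radius, glycosidic swing angle and axial base offset were
  tuned once (see ``GEOM``) so that the backbone-base bond matches its
  5.75 A rest length, Watson-Crick partners sit inside the
  hydrogen-bonding capture range for both model variants, and the
  3-bead dummy sites point toward their partners with a near-straight
  dummy-base-backbone angle.

Strand 2 is generated from strand 1 by a C2 rotation about an axis
perpendicular to the helix (the standard duplex dyad), which makes the
two strands antiparallel and gives the duplex its two inequivalent
grooves.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .topology import Topology, THREE_BEAD


@dataclass
class CoordinateSet:
    """Per-bead positions (A) and an orthorhombic box (edge lengths, A)."""

    positions: np.ndarray        # (N, 3)
    box: np.ndarray              # (3,)

    def copy(self) -> "CoordinateSet":
        return CoordinateSet(self.positions.copy(), self.box.copy())


#: frozen helix geometries (angles in degrees, lengths A).  The
#: glycosidic swing of the base about the axis is not stored: it is
#: solved from the backbone-base bond length, so bonds stay exact under
#: any twist/rise override.
#:
#: ``canonical``  - B-form fixture at 36 deg twist / 3.4 A rise.  The
#:   radial constants were solved once so that, in addition to exact
#:   bond lengths, the backbone->base direction of each nucleotide
#:   points straight at its Watson-Crick partner; the 3-bead dummy
#:   sites are then exactly collinear (zero angle strain).
#: ``relaxed``    - a wider, more weakly twisted helix close to the CG
#:   model's own energy minimum (radial backbone-base bonds, stacking
#:   at its rest distance).  Used as the starting point of structural
#:   production runs to shorten equilibration.
GEOM_PRESETS = {
    "canonical": {
        "twist": 36.0,        # deg per base pair
        "rise": 3.4,          # A per base pair
        "r_base": 5.5746,     # base-bead radius from the axis
        "dz_base": -4.9504,   # axial offset of the base rel. to its backbone
        "gly_sign": 1.0,      # handedness of the glycosidic swing
        "pair_sign": -1.0,    # side on which the partner base approaches
        "z_stag": 5.3809,     # axial stagger between paired bases
        "s_bp": 6.25,         # target Watson-Crick base-base separation
        "hb_offset": 1.95,    # dummy site placed this far from the base centre
    },
    "relaxed": {
        "twist": 29.2,
        "rise": 3.25,
        "r_base": 3.10,
        "dz_base": 0.0,
        "gly_sign": 1.0,
        "pair_sign": -1.0,
        "z_stag": 0.0,
        "s_bp": 6.2,
        "hb_offset": 1.95,
    },
}

#: default fixture geometry (canonical B-form)
GEOM = GEOM_PRESETS["canonical"]


def _backbone_radius(r0_bb: float, rise: float, twist_rad: float) -> float:
    chord2 = r0_bb ** 2 - rise ** 2
    if chord2 <= 0:
        raise ValueError("rise exceeds the backbone bond length")
    return np.sqrt(chord2) / (2.0 * np.sin(twist_rad / 2.0))


def _glycosidic(rp: float, rb: float, dz: float, r0_bs: float,
                sign: float) -> float:
    """Swing angle (rad) of the base about the axis relative to its own
    backbone bead, solved so the backbone-base distance equals r0_bs."""
    c = (rp * rp + rb * rb + dz * dz - r0_bs * r0_bs) / (2.0 * rp * rb)
    if not -1.0 <= c <= 1.0:
        raise ValueError("no glycosidic angle satisfies the bond constraint")
    return sign * np.arccos(c)


def build_bdna_coordinates(topology: Topology, twist: float | None = None,
                           rise: float | None = None, box: float = 300.0,
                           r0_bb: float = 5.5, r0_bs: float = 5.75,
                           preset: str = "canonical") -> CoordinateSet:
    """Ideal B-form coordinates for a DNA duplex topology.

    Parameters
    ----------
    topology:
        A duplex topology from :func:`cgdna.topology.build_dna_topology`.
    twist, rise:
        Helical twist (deg/bp) and rise (A/bp); default canonical B-form
        values (36 deg, 3.4 A).
    box:
        Cubic box edge (A); the duplex is centred in the box.
    """
    topology.require_duplex()
    g = GEOM_PRESETS[preset]
    twist = g["twist"] if twist is None else twist
    rise = g["rise"] if rise is None else rise
    th = np.deg2rad(twist)
    rp = _backbone_radius(r0_bb, rise, th)
    rb = g["r_base"]
    dz = g["dz_base"]
    gly = _glycosidic(rp, rb, dz, r0_bs, g["gly_sign"])
    s_bp = g["s_bp"]
    # Watson-Crick lateral separation angle between paired bases; its
    # sign (pair_sign) picks the side from which the partner approaches,
    # chosen so the backbone->base directions of a pair nearly face
    # each other (small dummy-site tilt in the 3-bead variant)
    lat = np.sqrt(max(0.0, s_bp ** 2 - g["z_stag"] ** 2))
    phi_b = g["pair_sign"] * 2.0 * np.arcsin(min(1.0, lat / (2.0 * rb)))

    c1, c2 = topology.duplex_chains
    n = len(topology.residues[c1])
    # duplex dyad bookkeeping (see module docstring): strand-2 residue j
    # pairs strand-1 residue n-1-j; chi/z0 place the pair at equal z with
    # base-base angular separation phi_b
    chi = (n - 1) * th + 2.0 * gly - phi_b
    z0 = (n - 1) * rise + 2.0 * dz - g["z_stag"]

    pos = np.zeros((topology.n_beads, 3))

    def cyl(r, a, z):
        return np.array([r * np.cos(a), r * np.sin(a), z])

    bases1, bases2 = {}, {}
    for j, rec in enumerate(topology.residues[c1]):
        a = j * th
        pos[rec["bb"]] = cyl(rp, a, j * rise)
        pos[rec["base"]] = cyl(rb, a + gly, j * rise + dz)
        bases1[j] = rec["base"]
    for j, rec in enumerate(topology.residues[c2]):
        a = chi - j * th
        pos[rec["bb"]] = cyl(rp, a, z0 - j * rise)
        pos[rec["base"]] = cyl(rb, a - gly, z0 - j * rise - dz)
        bases2[j] = rec["base"]

    if topology.variant == THREE_BEAD:
        off = g["hb_offset"]
        for j, rec in enumerate(topology.residues[c1]):
            partner = pos[bases2[n - 1 - j]]
            u = partner - pos[rec["base"]]
            pos[rec["hb"]] = pos[rec["base"]] + off * u / np.linalg.norm(u)
        for j, rec in enumerate(topology.residues[c2]):
            partner = pos[bases1[n - 1 - j]]
            u = partner - pos[rec["base"]]
            pos[rec["hb"]] = pos[rec["base"]] + off * u / np.linalg.norm(u)

    # centre the duplex in the box (other chains, if any, are placed by
    # build_system_coordinates afterwards)
    placed = [i for ch in (c1, c2) for rec in topology.residues[ch]
              for i in (rec["bb"], rec["base"], rec.get("hb"))
              if i is not None]
    box_vec = np.array([float(box)] * 3)
    pos += box_vec / 2.0 - pos[placed].mean(axis=0)
    if not np.all(np.isfinite(pos[placed])):
        raise ValueError("non-finite coordinates generated")
    return CoordinateSet(pos, box_vec)


def build_system_coordinates(topology: Topology, box: float = 300.0,
                             preset: str = "canonical",
                             chain_offset: float = 30.0,
                             chain_spacing: float = 15.0) -> CoordinateSet:
    """Starting coordinates for a combined DNA-duplex + protein system.

    The duplex gets ideal B-form coordinates; every protein chain is
    laid out as an extended C-alpha chain (3.8 A spacing) parallel to
    the helix axis, ``chain_offset`` A away from the duplex centre
    (successive chains offset by ``chain_spacing``).  For a pure DNA
    duplex this reduces to :func:`build_bdna_coordinates`.
    """
    dna_coords = build_bdna_coordinates(topology, box=box, preset=preset)
    pos = dna_coords.positions
    centre = np.array([box / 2.0] * 3)
    k = 0
    for chain, recs in enumerate(topology.residues):
        if not recs or "ca" not in recs[0]:
            continue
        n = len(recs)
        start = centre + np.array([chain_offset + k * chain_spacing, 0.0,
                                   -1.9 * n])
        for i, rec in enumerate(recs):
            pos[rec["ca"]] = start + np.array([0.0, 0.0, 3.8 * i])
        k += 1
    return CoordinateSet(pos, dna_coords.box)
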