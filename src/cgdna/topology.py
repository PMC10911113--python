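"""Coarse-grained topologies for DNA and protein chains.

A :class:`Topology` holds beads, bonds, angles and - central to the DNA
model - the classification of every nonbonded bead pair into exactly
one interaction class:

``bonded``
    directly bonded; carries no nonbonded interaction.
``stacking``
    consecutive intrastrand base beads (12-10 attraction).
``hbond``
    complementary Watson-Crick partners: base beads in the 2-bead
    variant, dummy HB sites (a/t/c/g) in the 3-bead variant.  The
    nearest and next-nearest intrastrand partners (|i-j| <= 2) are
    excluded to prevent unphysical in-strand pairing.
``excluded``
    purely repulsive WCA pairs: every base-base pair that is neither
    stacking nor hydrogen bonding (including the intrastrand i,i+2
    neighbours).
``plain``
    everything else - pairs that interact only through electrostatics
    and/or the HPS potential (backbone pairs, protein pairs,
    protein-DNA pairs, inert dummy-bead pairs).

The classes ``stacking``/``hbond``/``excluded`` are mutually exclusive
by construction.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from .parameters import DNA_MASSES, AA_MASS, AA_CHARGE
from .sequences import validate_dna, validate_protein, reverse_complement, COMPLEMENT

TWO_BEAD = "two_bead"
THREE_BEAD = "three_bead"

#: HPS-Urry protein bond constants (Eq. 2 convention K (r-r0)^2)
PROTEIN_BOND_K = 10.0     # kcal/(mol A^2)
PROTEIN_BOND_R0 = 3.8     # A

_WC = {("A", "T"), ("T", "A"), ("C", "G"), ("G", "C")}
_WC_HB = {("a", "t"), ("t", "a"), ("c", "g"), ("g", "c")}


def complementary(sp_i: str, sp_j: str) -> bool:
    """True for a Watson-Crick complementary species pair (either case)."""
    return (sp_i, sp_j) in _WC or (sp_i, sp_j) in _WC_HB


@dataclass(frozen=True)
class Bead:
    index: int
    kind: str          # "backbone" | "base" | "hb" | "aa"
    species: str       # "BB", "A".."G", "a".."g", or amino-acid letter
    mass: float        # amu
    charge: float      # e
    chain: int
    resindex: int      # residue index within the chain, 0-based 5'->3' / N->C


@dataclass
class Topology:
    beads: list = field(default_factory=list)
    bonds: list = field(default_factory=list)    # (i, j, bond_class)
    angles: list = field(default_factory=list)   # (i, j, k, angle_class); j = apex
    variant: str | None = None                   # two_bead/three_bead for DNA
    duplex: bool = False
    #: per chain, list of residue records:
    #: DNA {"bb","base","hb","species"} / protein {"ca","species"}
    residues: list = field(default_factory=list)
    #: DNA chain indices forming the duplex (pairing i <-> n-1-i)
    duplex_chains: tuple | None = None

    # -- basic views -----------------------------------------------------
    @property
    def n_beads(self) -> int:
        return len(self.beads)

    @property
    def n_chains(self) -> int:
        return len(self.residues)

    def masses(self) -> np.ndarray:
        return np.array([b.mass for b in self.beads])

    def charges(self) -> np.ndarray:
        return np.array([b.charge for b in self.beads])

    def net_charge(self) -> float:
        return float(sum(b.charge for b in self.beads))

    def bonded_pairs(self) -> set:
        return {(min(i, j), max(i, j)) for i, j, _ in self.bonds}

    def chain_beads(self, chain: int) -> list:
        return [b.index for b in self.beads if b.chain == chain]

    # -- duplex helpers --------------------------------------------------
    def require_duplex(self):
        if not self.duplex or self.duplex_chains is None:
            raise ValueError("operation requires a DNA duplex topology")

    @property
    def n_bp(self) -> int:
        self.require_duplex()
        return len(self.residues[self.duplex_chains[0]])

    def paired_residues(self):
        """Yield (res_record_strand1, res_record_strand2) for the duplex,
        in strand-1 5'->3' order (pairing i <-> n-1-i)."""
        self.require_duplex()
        c1, c2 = self.duplex_chains
        n = len(self.residues[c1])
        for i in range(n):
            yield self.residues[c1][i], self.residues[c2][n - 1 - i]

    def hb_sites(self, chain: int) -> list:
        """Bead indices of the hydrogen-bonding sites of a DNA strand
        (base beads for 2-bead, dummy beads for 3-bead), 5'->3'."""
        key = "hb" if self.variant == THREE_BEAD else "base"
        return [r[key] for r in self.residues[chain]]

    # -- pair classification --------------------------------------------
    def _base_beads(self):
        return [b for b in self.beads if b.kind == "base"]

    def _hb_beads(self):
        return [b for b in self.beads if b.kind == "hb"]

    def stacking_pairs(self) -> list:
        """(i, j, species_i, species_j) for consecutive intrastrand bases."""
        out = []
        bases = self._base_beads()
        by_chain = {}
        for b in bases:
            by_chain.setdefault(b.chain, []).append(b)
        for chain_bases in by_chain.values():
            chain_bases.sort(key=lambda b: b.resindex)
            for a, b in zip(chain_bases, chain_bases[1:]):
                if b.resindex - a.resindex == 1:
                    out.append((a.index, b.index, a.species, b.species))
        return out

    def hbond_pairs(self) -> list:
        """(i, j, species_i, species_j) for all hydrogen-bonding pairs."""
        sites = self._base_beads() if self.variant != THREE_BEAD else self._hb_beads()
        out = []
        for a, b in itertools.combinations(sites, 2):
            if not complementary(a.species, b.species):
                continue
            if a.chain == b.chain and abs(a.resindex - b.resindex) <= 2:
                continue
            out.append((a.index, b.index, a.species, b.species))
        return out

    def excluded_pairs(self) -> list:
        """(i, j) base-base pairs carrying WCA excluded volume."""
        taken = {(min(i, j), max(i, j))
                 for i, j, *_ in self.stacking_pairs() + self.hbond_pairs()}
        out = []
        for a, b in itertools.combinations(self._base_beads(), 2):
            key = (min(a.index, b.index), max(a.index, b.index))
            if key not in taken:
                out.append(key)
        return out

    def pair_class(self, i: int, j: int) -> str:
        """Interaction class of the unordered nonbonded pair (i, j)."""
        if i == j:
            raise ValueError("pair requires two distinct beads")
        key = (min(i, j), max(i, j))
        if key in self.bonded_pairs():
            return "bonded"
        a, b = self.beads[key[0]], self.beads[key[1]]
        if a.kind == "base" and b.kind == "base":
            if a.chain == b.chain and abs(a.resindex - b.resindex) == 1:
                return "stacking"
            if (self.variant != THREE_BEAD and complementary(a.species, b.species)
                    and not (a.chain == b.chain and abs(a.resindex - b.resindex) <= 2)):
                return "hbond"
            return "excluded"
        if a.kind == "hb" and b.kind == "hb":
            if (complementary(a.species, b.species)
                    and not (a.chain == b.chain and abs(a.resindex - b.resindex) <= 2)):
                return "hbond"
            return "plain"
        return "plain"

    def iter_pair_map(self):
        """Yield (i, j, class) over every unordered nonbonded bead pair."""
        bonded = self.bonded_pairs()
        for i, j in itertools.combinations(range(self.n_beads), 2):
            if (i, j) in bonded:
                continue
            yield i, j, self.pair_class(i, j)


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def build_dna_topology(seq: str, variant: str = TWO_BEAD,
                       duplex: bool = False) -> Topology:
    """Build a 2- or 3-bead CG DNA topology from a 5'->3' sequence.

    With ``duplex=True`` the reverse complement strand is generated
    internally and residue i of strand 1 pairs residue n-1-i of
    strand 2 (both stored 5'->3').

    Bonds: backbone-backbone (r0 = 5.5 A), backbone-base (5.75 A) and,
    for the 3-bead variant, base-dummy (1.95 A), all with K = 50
    kcal/(mol A^2).  Angles: consecutive backbone triples (K = 40,
    theta0 = 180 deg) and dummy-base-backbone (K = 80, theta0 = 180).
    """
    if variant not in (TWO_BEAD, THREE_BEAD):
        raise ValueError(f"unknown model variant {variant!r}")
    s1 = validate_dna(seq)
    strands = [s1, reverse_complement(s1)] if duplex else [s1]

    top = Topology(variant=variant, duplex=duplex,
                   duplex_chains=(0, 1) if duplex else None)
    for chain, strand in enumerate(strands):
        records = []
        prev_bb = None
        bb_chain = []
        for ri, base in enumerate(strand):
            ib = len(top.beads)
            top.beads.append(Bead(ib, "backbone", "BB", DNA_MASSES["BB"],
                                  -1.0, chain, ri))
            ibase = len(top.beads)
            top.beads.append(Bead(ibase, "base", base, DNA_MASSES[base],
                                  0.0, chain, ri))
            rec = {"bb": ib, "base": ibase, "hb": None, "species": base}
            top.bonds.append((ib, ibase, "bb-base"))
            if prev_bb is not None:
                top.bonds.append((prev_bb, ib, "bb-bb"))
            if variant == THREE_BEAD:
                ihb = len(top.beads)
                top.beads.append(Bead(ihb, "hb", base.lower(),
                                      0.5 * DNA_MASSES[base], 0.0, chain, ri))
                top.bonds.append((ibase, ihb, "base-hb"))
                top.angles.append((ihb, ibase, ib, "hb"))
                rec["hb"] = ihb
            bb_chain.append(ib)
            prev_bb = ib
            records.append(rec)
        for a, b, c in zip(bb_chain, bb_chain[1:], bb_chain[2:]):
            top.angles.append((a, b, c, "backbone"))
        top.residues.append(records)
    return top


def build_protein_topology(aa_seq: str) -> Topology:
    """One-bead-per-residue (C-alpha) HPS protein topology.

    Charges: +1 for Arg/Lys, -1 for Asp/Glu, 0 otherwise; consecutive
    residues joined by harmonic bonds (r0 = 3.8 A, K = 10); no angles.
    """
    s = validate_protein(aa_seq)
    top = Topology(variant=None, duplex=False)
    records = []
    for ri, aa in enumerate(s):
        i = len(top.beads)
        top.beads.append(Bead(i, "aa", aa, AA_MASS[aa], AA_CHARGE[aa], 0, ri))
        if ri > 0:
            top.bonds.append((i - 1, i, "ca-ca"))
        records.append({"ca": i, "species": aa})
    top.residues.append(records)
    return top


def combine(*tops: Topology) -> Topology:
    """Merge topologies into one system (chains renumbered).

    Pair classification extends naturally: cross-molecule base pairs
    follow the same interstrand rules, protein-DNA pairs are ``plain``
    (electrostatics + HPS).  The duplex bookkeeping of the first DNA
    duplex found is preserved.
    """
    out = Topology()
    variants = {t.variant for t in tops if t.variant is not None}
    if len(variants) > 1:
        raise ValueError("cannot mix 2-bead and 3-bead DNA in one system")
    out.variant = variants.pop() if variants else None
    for top in tops:
        boff, coff = len(out.beads), len(out.residues)
        for b in top.beads:
            out.beads.append(Bead(b.index + boff, b.kind, b.species, b.mass,
                                  b.charge, b.chain + coff, b.resindex))
        out.bonds.extend((i + boff, j + boff, c) for i, j, c in top.bonds)
        out.angles.extend((i + boff, j + boff, k + boff, c)
                          for i, j, k, c in top.angles)
        for rec_chain in top.residues:
            out.residues.append([
                {k: (v + boff if isinstance(v, int) else v)
                 for k, v in rec.items()} for rec in rec_chain])
        if top.duplex and not out.duplex:
            out.duplex = True
            out.duplex_chains = (top.duplex_chains[0] + coff,
                                 top.duplex_chains[1] + coff)
    return out
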