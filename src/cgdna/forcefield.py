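"""Binding a topology to parameter sets: packed arrays, energies, forces."""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .geometry import CoordinateSet
from .parameters import DnaParameterSet, HpsParameterSet, ElectrostaticsContext
from .topology import Topology, PROTEIN_BOND_K, PROTEIN_BOND_R0


@dataclass
class EnergyReport:
    """Per-term potential energies (kcal/mol) and per-bead forces
    (kcal/(mol A)); ``total`` is the sum of the seven terms."""

    bond: float
    angle: float
    stacking: float
    hbond: float
    excluded: float
    electrostatics: float
    hps: float
    forces: np.ndarray = field(repr=False, default=None)

    @property
    def total(self) -> float:
        return (self.bond + self.angle + self.stacking + self.hbond
                + self.excluded + self.electrostatics + self.hps)

    def terms(self) -> dict:
        return {"bond": self.bond, "angle": self.angle,
                "stacking": self.stacking, "hbond": self.hbond,
                "excluded": self.excluded,
                "electrostatics": self.electrostatics, "hps": self.hps}


class ForceField:
    """Packs a :class:`Topology` plus parameter sets into flat arrays.

    Parameters
    ----------
    topology:
        DNA, protein, or combined topology.
    dna_params, hps_params:
        Parameter sets; defaults are the published model values.  The
        HPS set is only consulted when amino-acid beads are present.
    elec:
        Debye-Hueckel context (default 100 mM: kappa = 10 A).
    """

    def __init__(self, topology: Topology,
                 dna_params: DnaParameterSet | None = None,
                 hps_params: HpsParameterSet | None = None,
                 elec: ElectrostaticsContext | None = None):
        self.topology = topology
        self.dna = dna_params or DnaParameterSet()
        self.hps = hps_params or HpsParameterSet()
        self.elec = elec or ElectrostaticsContext()
        self.masses = topology.masses()
        self.charges = topology.charges()
        self._build()

    # ------------------------------------------------------------------
    def _build(self):
        top, dna = self.topology, self.dna
        bond_const = {
            "bb-bb": (dna.k_bond, dna.r0["bb-bb"]),
            "bb-base": (dna.k_bond, dna.r0["bb-base"]),
            "base-hb": (dna.k_bond, dna.r0["base-hb"]),
            "ca-ca": (PROTEIN_BOND_K, PROTEIN_BOND_R0),
        }
        bi, bj, bk, br = [], [], [], []
        for i, j, cls in top.bonds:
            k, r0 = bond_const[cls]
            bi.append(i)
            bj.append(j)
            bk.append(k)
            br.append(r0)
        ai, aj, ak, akc, ac0 = [], [], [], [], []
        for i, j, k, cls in top.angles:
            ai.append(i)
            aj.append(j)
            ak.append(k)
            akc.append(dna.k_angle[cls])
            ac0.append(np.cos(np.deg2rad(dna.theta0[cls])))

        si, sj, ssig, sdlt = [], [], [], []
        for i, j, spi, spj in top.stacking_pairs():
            sig, dlt = dna.stack_params(spi, spj)
            si.append(i)
            sj.append(j)
            ssig.append(sig)
            sdlt.append(dlt)
        hi, hj, hsig, hdlt, hrc = [], [], [], [], []
        for i, j, spi, spj in top.hbond_pairs():
            sig, dlt, rc = dna.hb_params(spi, spj)
            hi.append(i)
            hj.append(j)
            hsig.append(sig)
            hdlt.append(dlt)
            hrc.append(rc)
        wi, wj = [], []
        for i, j in top.excluded_pairs():
            wi.append(i)
            wj.append(j)
        if dna.wca_backbone:
            # optional literal-rule extension: WCA on backbone-involving
            # DNA pairs as well
            bonded = top.bonded_pairs()
            dna_beads = [b for b in top.beads if b.kind in ("backbone", "base")]
            for a, b in itertools.combinations(dna_beads, 2):
                if a.kind == "base" and b.kind == "base":
                    continue
                key = (min(a.index, b.index), max(a.index, b.index))
                if key not in bonded:
                    wi.append(key[0])
                    wj.append(key[1])
        weps = [dna.eps_ex] * len(wi)
        wsig = [dna.sigma_ex] * len(wi)

        bonded = top.bonded_pairs()
        di, dj, dqq = [], [], []
        charged = [b for b in top.beads if b.charge != 0.0]
        for a, b in itertools.combinations(charged, 2):
            key = (min(a.index, b.index), max(a.index, b.index))
            if key not in bonded:
                di.append(key[0])
                dj.append(key[1])
                dqq.append(a.charge * b.charge)

        pi, pj, psig, plam, peps = [], [], [], [], []
        aa_beads = [b for b in top.beads if b.kind == "aa"]
        if aa_beads:
            others = [b for b in top.beads if b.kind in ("backbone", "base")]
            for a, b in itertools.chain(itertools.combinations(aa_beads, 2),
                                        itertools.product(aa_beads, others)):
                key = (min(a.index, b.index), max(a.index, b.index))
                if key in bonded:
                    continue
                sig, lam, eps = self.hps.pair_params(a.kind, a.species,
                                                     b.kind, b.species)
                if eps == 0.0:
                    continue
                pi.append(key[0])
                pj.append(key[1])
                psig.append(sig)
                plam.append(lam)
                peps.append(eps)

        ii = np.int64
        ff = np.float64
        self.arrays = (
            np.array(bi, ii), np.array(bj, ii), np.array(bk, ff), np.array(br, ff),
            np.array(ai, ii), np.array(aj, ii), np.array(ak, ii),
            np.array(akc, ff), np.array(ac0, ff),
            np.array(si, ii), np.array(sj, ii), np.array(ssig, ff),
            np.array(sdlt, ff), np.full(len(si), dna.r_stack, ff),
            np.array(hi, ii), np.array(hj, ii), np.array(hsig, ff),
            np.array(hdlt, ff), np.array(hrc, ff),
            np.array(wi, ii), np.array(wj, ii), np.array(weps, ff),
            np.array(wsig, ff),
            np.array(di, ii), np.array(dj, ii), np.array(dqq, ff),
            ff(self.elec.prefactor), ff(self.elec.kappa), ff(self.elec.cutoff),
            np.array(pi, ii), np.array(pj, ii), np.array(psig, ff),
            np.array(plam, ff), np.array(peps, ff), ff(self.hps.cutoff),
        )
        # all interacting pair indices, for overlap detection
        self._pairs_i = np.concatenate([self.arrays[0], self.arrays[9],
                                        self.arrays[14], self.arrays[19],
                                        self.arrays[23], self.arrays[29]])
        self._pairs_j = np.concatenate([self.arrays[1], self.arrays[10],
                                        self.arrays[15], self.arrays[20],
                                        self.arrays[24], self.arrays[30]])

    # ------------------------------------------------------------------
    def _coords(self, coords) -> tuple[np.ndarray, np.ndarray]:
        if isinstance(coords, CoordinateSet):
            return np.ascontiguousarray(coords.positions, float), \
                np.asarray(coords.box, float)
        return np.ascontiguousarray(coords, float), np.zeros(3)

    def energy(self, coords, box=None) -> EnergyReport:
        """Evaluate all energy terms and forces for a configuration.

        ``coords`` is a :class:`CoordinateSet` or a bare (N, 3) array
        (then ``box`` may be given separately; 0 disables periodicity).
        Overlapping interacting beads (r = 0) are rejected.
        """
        pos, b = self._coords(coords)
        if box is not None:
            b = np.asarray(box, float) * np.ones(3)
        if pos.shape != (self.topology.n_beads, 3):
            raise ValueError("coordinate shape does not match topology")
        if self._pairs_i.size:
            d = pos[self._pairs_i] - pos[self._pairs_j]
            if np.any(b > 0):
                d -= b * np.rint(d / np.where(b > 0, b, np.inf))
            r2 = (d ** 2).sum(axis=1)
            imin = int(np.argmin(r2))
            if r2[imin] < 1e-12:
                raise ValueError(
                    "overlapping beads at r = 0: pair "
                    f"({int(self._pairs_i[imin])}, {int(self._pairs_j[imin])})")
        f = np.zeros_like(pos)
        e = _kernels.forces_energy(pos, b, *self.arrays, f)
        return EnergyReport(*e, forces=f)
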