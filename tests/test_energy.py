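import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from cgdna.energy import (TWO_16, u_cosine_sq_angle, u_debye_huckel,
                          u_harmonic_bond, u_hps, u_hps_pair, u_lj1210,
                          u_wca)
from cgdna.forcefield import ForceField
from cgdna.geometry import build_bdna_coordinates
from cgdna.parameters import (DnaParameterSet, ElectrostaticsContext,
                              HpsParameterSet)
from cgdna.topology import (build_dna_topology, build_protein_topology,
                            combine)


class TestClosedForms:
    def test_bond(self):
        assert u_harmonic_bond(5.5) == 0.0
        assert u_harmonic_bond(6.5, k=50.0, r0=5.5) == pytest.approx(50.0)
        d = 0.3
        assert u_harmonic_bond(5.5 + d) == pytest.approx(u_harmonic_bond(5.5 - d))
        with pytest.raises(ValueError):
            u_harmonic_bond(-1.0)

    def test_angle(self):
        assert u_cosine_sq_angle(180.0, k=40.0) == pytest.approx(0.0)
        assert u_cosine_sq_angle(90.0, k=40.0) == pytest.approx(40.0)
        assert u_cosine_sq_angle(90.0, k=80.0) == pytest.approx(80.0)

    def test_lj1210_minimum_at_sigma(self):
        # A-A stacking: well depth exactly -delta at r = sigma
        assert u_lj1210(3.6, 3.6, 9.7, 6.2) == pytest.approx(-9.7)
        res = minimize_scalar(lambda r: u_lj1210(r, 3.6, 9.7, 6.2),
                              bounds=(3.0, 6.0), method="bounded")
        assert res.x == pytest.approx(3.6, abs=1e-5)
        assert res.fun == pytest.approx(-9.7, abs=1e-8)

    def test_lj1210_cutoff_and_monotonicity(self):
        assert u_lj1210(6.2, 3.6, 9.7, 6.2) == 0.0
        assert u_lj1210(100.0, 3.6, 9.7, 6.2) == 0.0
        r = np.linspace(3.6, 6.19, 200)
        u = u_lj1210(r, 3.6, 9.7, 6.2)
        assert np.all(np.diff(u) > 0)          # rises monotonically past sigma
        # truncation is small at the cutoff (documented plain truncation;
        # the printed cutoffs leave <= 5% of the well depth)
        assert abs(u_lj1210(6.1999, 3.6, 9.7, 6.2)) < 5e-2 * 9.7
        assert abs(u_lj1210(9.4999, 6.0, 2.7, 9.5)) < 5e-2 * 2.7

    def test_wca(self):
        assert u_wca(5.5) == pytest.approx(4.0)          # r = sigma -> eps
        assert u_wca(TWO_16 * 5.5 - 1e-12) == pytest.approx(0.0, abs=1e-9)
        assert u_wca(7.0) == 0.0
        r = np.linspace(4.0, 8.0, 100)
        assert np.all(u_wca(r) >= 0.0)

    def test_debye_huckel(self):
        ctx = ElectrostaticsContext(kappa=10.0)
        assert u_debye_huckel(0.0, -1.0, 5.0, ctx) == 0.0
        # two unit charges at r = kappa
        assert u_debye_huckel(-1.0, -1.0, 10.0, ctx) == pytest.approx(
            332.06 / 80.0 * np.exp(-1.0) / 10.0, rel=1e-12)
        assert u_debye_huckel(-1.0, -1.0, 10.0, ctx) == pytest.approx(
            0.1527, abs=5e-4)
        assert u_debye_huckel(-1.0, -1.0, 36.0, ctx) == 0.0   # > 3.5 kappa

    def test_hps_lambda_limits(self):
        sig, eps = 6.0, 0.2
        rmin = TWO_16 * sig
        # lambda = 0: zero at the split point and beyond (purely repulsive)
        assert u_hps(rmin, sig, 0.0, eps) == pytest.approx(0.0, abs=1e-12)
        r = np.linspace(rmin, 20.0, 50)
        assert np.allclose(u_hps(r, sig, 0.0, eps), 0.0)
        assert np.all(u_hps(np.linspace(4.0, rmin, 50), sig, 0.0, eps) >= 0)
        # lambda = 1: plain LJ, continuous at the split
        below = u_hps(rmin - 1e-9, sig, 1.0, eps)
        above = u_hps(rmin + 1e-9, sig, 1.0, eps)
        assert below == pytest.approx(above, abs=1e-6)
        assert u_hps(rmin, sig, 1.0, eps) == pytest.approx(-eps, rel=1e-9)

    def test_hps_dummy_pair_zero(self):
        h = HpsParameterSet.urry()
        r = np.linspace(1.0, 30.0, 20)
        assert np.allclose(u_hps_pair("aa", "K", "hb", "a", r, h), 0.0)


# ---------------------------------------------------------------------------
# force-field assembly
# ---------------------------------------------------------------------------

def _mixed_system():
    dna = build_dna_topology("GCGTCATACAGTGC", "three_bead", duplex=True)
    top = combine(dna, build_protein_topology("KRDEGSTAVLKK"))
    ff = ForceField(top, hps_params=HpsParameterSet.urry())
    c = build_bdna_coordinates(dna)
    rng = np.random.default_rng(7)
    pos = np.zeros((top.n_beads, 3))
    pos[:c.positions.shape[0]] = c.positions
    # protein chain laid alongside the duplex
    start = c.positions.mean(axis=0) + np.array([12.0, 0.0, -20.0])
    for k in range(top.n_beads - c.positions.shape[0]):
        pos[c.positions.shape[0] + k] = start + np.array([0.0, 0.0, 3.8 * k])
    pos += 0.25 * rng.standard_normal(pos.shape)
    return top, ff, pos


class TestForcesAndInvariance:
    def test_numeric_gradient_total(self):
        """Analytic forces equal the negative numeric gradient to 1e-5
        relative on a jittered protein-DNA configuration (all terms
        active)."""
        top, ff, pos = _mixed_system()
        rep = ff.energy(pos, box=300.0)
        assert all(abs(v) > 0 for v in
                   (rep.bond, rep.angle, rep.stacking, rep.hbond,
                    rep.electrostatics, rep.hps))
        rng = np.random.default_rng(3)
        h = 1e-5
        for _ in range(20):
            i = int(rng.integers(0, top.n_beads))
            d = int(rng.integers(0, 3))
            p = pos.copy()
            p[i, d] += h
            ep = ff.energy(p, box=300.0).total
            p[i, d] -= 2 * h
            em = ff.energy(p, box=300.0).total
            fnum = -(ep - em) / (2 * h)
            scale = max(1.0, abs(rep.forces[i, d]))
            assert abs(fnum - rep.forces[i, d]) / scale < 1e-5

    def test_numeric_gradient_wca(self):
        """The excluded-volume term alone also matches its gradient
        (engaged by compressing a duplex)."""
        top = build_dna_topology("ATGC", "two_bead", duplex=True)
        ff = ForceField(top)
        c = build_bdna_coordinates(top)
        pos = c.positions * 0.85 + 0.15 * c.positions.mean(axis=0)
        rep = ff.energy(pos)
        assert rep.excluded > 0
        h = 1e-5
        rng = np.random.default_rng(5)
        for _ in range(8):
            i = int(rng.integers(0, top.n_beads))
            d = int(rng.integers(0, 3))
            p = pos.copy()
            p[i, d] += h
            ep = ff.energy(p).total
            p[i, d] -= 2 * h
            em = ff.energy(p).total
            assert -(ep - em) / (2 * h) == pytest.approx(
                rep.forces[i, d], rel=1e-5, abs=1e-6)

    def test_translation_rotation_invariance(self):
        top, ff, pos = _mixed_system()
        e0 = ff.energy(pos).total          # no PBC
        e_t = ff.energy(pos + np.array([3.0, -7.0, 11.0])).total
        th = 0.7
        rot = np.array([[np.cos(th), -np.sin(th), 0],
                        [np.sin(th), np.cos(th), 0], [0, 0, 1.0]])
        e_r = ff.energy(pos @ rot.T).total
        assert e_t == pytest.approx(e0, rel=1e-12)
        assert e_r == pytest.approx(e0, rel=1e-10)

    def test_net_force_and_torque_vanish(self):
        top, ff, pos = _mixed_system()
        rep = ff.energy(pos)               # vacuum, no PBC wrap
        assert np.allclose(rep.forces.sum(axis=0), 0.0, atol=1e-9)
        torque = np.cross(pos - pos.mean(axis=0), rep.forces).sum(axis=0)
        assert np.allclose(torque, 0.0, atol=1e-7)

    def test_total_is_sum_of_terms(self):
        top, ff, pos = _mixed_system()
        rep = ff.energy(pos)
        assert rep.total == pytest.approx(
            rep.bond + rep.angle + rep.stacking + rep.hbond + rep.excluded
            + rep.electrostatics + rep.hps)

    def test_distant_strands_interact_only_through_nothing(self):
        """Strands separated beyond every cutoff have zero interstrand
        energy: total equals the sum of isolated single strands."""
        top = build_dna_topology("GCGTCATACAGTGC", "two_bead", duplex=True)
        ff = ForceField(top)
        c = build_bdna_coordinates(top)
        pos = c.positions.copy()
        chain2 = [b.index for b in top.beads if b.chain == 1]
        pos[chain2] += np.array([120.0, 0.0, 0.0])   # > all cutoffs (35 A DH)
        rep = ff.energy(pos)
        assert rep.hbond == pytest.approx(0.0, abs=1e-12)
        # compare with two isolated strands
        single = build_dna_topology("GCGTCATACAGTGC", "two_bead")
        sf = ForceField(single)
        c1 = [b.index for b in top.beads if b.chain == 0]
        e1 = sf.energy(pos[c1]).total
        e2 = sf.energy(pos[chain2]).total
        assert rep.total == pytest.approx(e1 + e2, rel=1e-9)

    def test_overlap_rejected_with_pair_identity(self):
        top = build_dna_topology("AT", "two_bead", duplex=True)
        ff = ForceField(top)
        c = build_bdna_coordinates(top)
        pos = c.positions.copy()
        bases = [b.index for b in top.beads if b.kind == "base"]
        pos[bases[1]] = pos[bases[0]]
        with pytest.raises(ValueError, match="overlapping"):
            ff.energy(pos)

    def test_pair_lists_disjoint(self, duplex3, ff3):
        """Mutual exclusivity: the stacking/hbond/excluded pair lists of
        the bound force field never share a pair."""
        def pairs(i_arr, j_arr):
            return {(min(a, b), max(a, b)) for a, b in zip(i_arr, j_arr)}
        st = pairs(ff3.arrays[9], ff3.arrays[10])
        hb = pairs(ff3.arrays[14], ff3.arrays[15])
        ex = pairs(ff3.arrays[19], ff3.arrays[20])
        assert not (st & hb) and not (st & ex) and not (hb & ex)

    def test_fixture_energetics(self, duplex2, duplex3):
        """Ideal fixture: bonded strain below 1 kcal/mol per residue and
        a negative hydrogen-bonding term for both variants."""
        for top in (duplex2, duplex3):
            ff = ForceField(top)
            rep = ff.energy(build_bdna_coordinates(top))
            n_res = 2 * top.n_bp
            assert (rep.bond + rep.angle) / n_res < 1.0
            assert rep.hbond < 0.0

    def test_wca_backbone_switch_adds_pairs(self):
        top = build_dna_topology("ACGT", "two_bead", duplex=True)
        n_off = len(ForceField(top).arrays[19])
        n_on = len(ForceField(
            top, DnaParameterSet(wca_backbone=True)).arrays[19])
        assert n_on > n_off
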