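"""Hybridization classification, melting thermodynamics, and helical
structure observables."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from cgdna.analysis import (classify_hybridized, contact_map, groove_widths,
                            heat_capacity, helical_parameters, melting_curve)
from cgdna.geometry import build_bdna_coordinates
from cgdna.topology import build_dna_topology
from cgdna.units import KB


class TestHybridization:
    def test_displaced_strands_are_melted(self, duplex2, coords2):
        pos = coords2.positions.copy()
        chain2 = [b.index for b in duplex2.beads if b.chain == 1]
        pos[chain2] += 100.0
        rec = classify_hybridized(pos, duplex2)
        assert not rec.hybridized
        assert rec.engaged == (0, 0)

    def test_half_engaged_boundary_inclusive(self, duplex3, coords3):
        """Exactly half of the sites engaged still counts as hybridized
        ('at least half'); one fewer does not."""
        pos = coords3.positions.copy()
        sites2 = duplex3.hb_sites(1)
        pos[sites2[:7]] += 500.0           # 7 of 14 partners removed
        rec = classify_hybridized(pos, duplex3)
        assert rec.engaged[0] == 7
        assert rec.strand_hybridized[0]
        pos[sites2[7]] += 500.0            # 6 of 14 -> melted
        rec = classify_hybridized(pos, duplex3)
        assert rec.engaged[0] == 6
        assert not rec.strand_hybridized[0]

    def test_requires_duplex(self):
        t = build_dna_topology("ACGT", "two_bead")
        with pytest.raises(ValueError, match="duplex"):
            classify_hybridized(np.zeros((8, 3)), t)


class TestMelting:
    def test_step_function_tm_midpoint(self):
        temps = np.arange(300.0, 361.0, 10.0)
        melted = [np.zeros(10) if t < 330 else np.ones(10) for t in temps]
        curve = melting_curve(temps, melted)
        assert 320.0 < curve.tm < 330.0
        assert np.all((curve.fraction_melted >= 0)
                      & (curve.fraction_melted <= 1))

    def test_constant_energy_gives_zero_cv(self):
        temps = np.array([300.0, 320.0, 340.0])
        cvc = heat_capacity(temps, [np.full(100, -50.0) for _ in temps])
        assert np.allclose(cvc.cv, 0.0)

    def test_two_state_oracle(self):
        """Exact samples of a two-state system (energy gap dE,
        degeneracy g): the fraction-based Tm matches dE/(kB ln g) and
        the Cv-based Tm matches the closed-form Cv maximum, within 3
        sigma of the block errors."""
        d_e, ln_g = 20.9, 30.0
        t_star = d_e / (KB * ln_g)                       # ~350.6 K

        def p_ex(t):
            return 1.0 / (1.0 + np.exp(d_e / (KB * t) - ln_g))

        def cv_exact(t):
            p = p_ex(t)
            return d_e ** 2 * p * (1 - p) / (KB * t * t)

        t_cv_star = minimize_scalar(lambda t: -cv_exact(t),
                                    bounds=(250, 450), method="bounded").x
        temps = np.linspace(250.0, 450.0, 26)
        rng = np.random.default_rng(2024)
        melted, energies = [], []
        for t in temps:
            m = rng.random(4000) < p_ex(t)               # exact sampling
            melted.append(m.astype(float))
            energies.append(d_e * m)
        curve = melting_curve(temps, melted)
        cvc = heat_capacity(temps, energies)
        assert abs(curve.tm - t_star) < max(3 * curve.tm_err, 2.0)
        assert abs(cvc.tm - t_cv_star) < max(3 * cvc.tm_err,
                                             np.diff(temps)[0])
        # the two Tm definitions agree within mutual uncertainty + the
        # intrinsic two-state offset between them
        offset = abs(t_star - t_cv_star)
        assert abs(curve.tm - cvc.tm) < 3 * (curve.tm_err + cvc.tm_err) \
            + offset + np.diff(temps)[0]

    def test_needs_two_temperatures(self):
        with pytest.raises(ValueError):
            melting_curve([300.0], [np.ones(5)])


@pytest.fixture(scope="module")
def top32():
    return build_dna_topology("ATACAAAGGTGCGAGGTTTCTATGCTCCCACG",
                              "two_bead", duplex=True)


@pytest.fixture(scope="module")
def groove_system(top32):
    return top32, build_bdna_coordinates(top32, preset="relaxed")


class TestHelicalParameters:

    def test_ideal_fixture_recovery(self, top32):
        """The analyser recovers the construction parameters of the
        ideal helix exactly: rise 3.4, 10 bp/turn, width = 2 x backbone
        radius."""
        c = build_bdna_coordinates(top32)
        rep = helical_parameters(c.positions, top32)
        assert rep.base_rise == pytest.approx(3.4, abs=0.01)
        assert rep.bp_per_turn == pytest.approx(10.0, abs=0.05)
        rp = np.sqrt(5.5 ** 2 - 3.4 ** 2) / (2 * np.sin(np.pi / 10))
        assert rep.helical_width == pytest.approx(2 * rp, abs=0.05)

    def test_twist_override(self, top32):
        c = build_bdna_coordinates(top32, twist=32.7)
        rep = helical_parameters(c.positions, top32)
        assert rep.bp_per_turn == pytest.approx(360.0 / 32.7, abs=0.05)

    def test_rigid_motion_invariance(self, top32):
        c = build_bdna_coordinates(top32)
        th = 1.1
        rot = np.array([[1, 0, 0],
                        [0, np.cos(th), -np.sin(th)],
                        [0, np.sin(th), np.cos(th)]])
        moved = c.positions @ rot.T + np.array([11.0, -3.0, 7.0])
        a = helical_parameters(c.positions, top32)
        b = helical_parameters(moved, top32)
        assert a.base_rise == pytest.approx(b.base_rise, abs=1e-9)
        assert a.bp_per_turn == pytest.approx(b.bp_per_turn, abs=1e-9)
        assert a.helical_width == pytest.approx(b.helical_width, abs=1e-9)

    def test_melted_frames_excluded_and_counted(self, top32):
        c = build_bdna_coordinates(top32)
        melted = c.positions.copy()
        chain2 = [b.index for b in top32.beads if b.chain == 1]
        melted[chain2] += 200.0
        frames = np.stack([c.positions, melted, c.positions])
        rep = helical_parameters(frames, top32)
        assert rep.n_frames == 2
        assert rep.n_melted_excluded == 1

    def test_minimum_size(self):
        t = build_dna_topology("ACGTACGTACGT", "two_bead", duplex=True)
        c = build_bdna_coordinates(t)
        with pytest.raises(ValueError, match="14"):
            helical_parameters(c.positions, t)


class TestGrooveWidths:
    def test_rigid_fixture_constant_widths(self, groove_system):
        top, c = groove_system
        frames = np.stack([c.positions] * 4)
        minor, major = groove_widths(frames, top, step_index=19)
        assert minor[1] < 0.05 and major[1] < 0.05     # SD over frames
        # printed convention: the minor-groove number is the larger one
        assert minor[0] >= major[0]

    def test_rigid_motion_invariance(self, groove_system):
        top, c = groove_system
        rot = np.array([[0.0, -1, 0], [1, 0, 0], [0, 0, 1.0]])
        a = groove_widths(c.positions, top, 19)
        b = groove_widths(c.positions @ rot.T + 5.0, top, 19)
        assert a[0][0] == pytest.approx(b[0][0], abs=1e-9)
        assert a[1][0] == pytest.approx(b[1][0], abs=1e-9)

    def test_step_near_terminus_rejected(self, groove_system):
        top, c = groove_system
        with pytest.raises(ValueError, match="terminus"):
            groove_widths(c.positions, top, step_index=2)
        with pytest.raises(ValueError, match="terminus"):
            groove_widths(c.positions, top, step_index=31)


class TestContacts:
    def test_three_frame_enumeration(self):
        # two single-bead groups in contact in 2 of 3 frames
        frames = np.zeros((3, 2, 3))
        frames[0, 1, 0] = 3.0
        frames[1, 1, 0] = 50.0
        frames[2, 1, 0] = 4.0
        cm = contact_map(frames, [[0]], [[1]], cutoff=5.0)
        assert cm.probability[0, 0] == pytest.approx(2.0 / 3.0)

    def test_separated_and_frozen(self):
        frames = np.zeros((2, 4, 3))
        frames[:, 2:, 0] = 100.0
        cm = contact_map(frames, [[0, 1]], [[2, 3]], cutoff=6.0)
        assert cm.probability[0, 0] == 0.0
        cm2 = contact_map(frames, [[0]], [[1]], cutoff=6.0)
        assert cm2.probability[0, 0] == 1.0

    def test_default_sigma_rule_and_validation(self):
        frames = np.zeros((1, 2, 3))
        frames[0, 1, 0] = 8.0       # 1.5 * 5.5 = 8.25 cutoff
        cm = contact_map(frames, [[0]], [[1]])
        assert cm.probability[0, 0] == 1.0
        assert cm.metadata["factor"] == 1.5
        with pytest.raises(ValueError):
            contact_map(frames, [], [[1]])
        with pytest.raises(ValueError):
            contact_map(frames, [[0]], [[]])
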