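"""Statistical oracles for the Langevin integrator, replica exchange,
and umbrella sampling, checked against closed-form equilibrium
distributions at 3-sigma tolerances."""

import numpy as np
import pytest

from cgdna.forcefield import ForceField
from cgdna.geometry import build_bdna_coordinates
from cgdna.sampler import (LangevinSettings, ReplicaLadder, SimulationBlowupError,
                           SimulationState, UmbrellaWindow, run_langevin,
                           run_remd, run_umbrella)
from cgdna.topology import build_dna_topology, build_protein_topology, combine
from cgdna.units import KB, ENERGY_TO_MVSQ

BOND_K, BOND_R0 = 10.0, 3.8     # protein spring


def _bond_system():
    """Two glycine beads joined by one harmonic bond, nothing else."""
    top = build_protein_topology("GG")
    ff = ForceField(top)
    state = SimulationState(np.array([[0.0, 0, 0], [BOND_R0, 0, 0]]))
    return top, ff, state


def _bond_moments(temperature):
    """Exact moments of the bond length under p(r) ~ r^2 e^{-beta K (r-r0)^2}."""
    beta = 1.0 / (KB * temperature)
    r = np.linspace(BOND_R0 - 2.0, BOND_R0 + 2.0, 20001)
    w = r ** 2 * np.exp(-beta * BOND_K * (r - BOND_R0) ** 2)
    w /= np.trapezoid(w, r)
    m1 = np.trapezoid(w * r, r)
    m2 = np.trapezoid(w * r ** 2, r)
    return m1, m2 - m1 ** 2


def _bond_lengths(frames):
    return np.linalg.norm(frames[:, 1] - frames[:, 0], axis=1)


def test_free_bead_equipartition():
    """A single free bead thermalises to <E_kin> = 3/2 kT within 5%."""
    top = build_protein_topology("G")
    ff = ForceField(top)
    state = SimulationState(np.zeros((1, 3)))
    st = LangevinSettings(temperature=300.0, tau_ps=0.2, seed=42, stride=10)
    traj = run_langevin(state, ff, st, 200000, save_frames=False)
    mean_ekin = traj.ekin.mean()
    assert mean_ekin == pytest.approx(1.5 * KB * 300.0, rel=0.05)
    # equivalently, the velocity variance over the run matches kT/m
    v2_mean = 2.0 * mean_ekin * ENERGY_TO_MVSQ / (3.0 * top.beads[0].mass)
    assert v2_mean == pytest.approx(
        KB * 300.0 * ENERGY_TO_MVSQ / top.beads[0].mass, rel=0.05)


def test_bond_length_boltzmann_distribution():
    """Bond-length statistics match the Jacobian-weighted Boltzmann
    distribution of U = K (r - r0)^2 within 3 sigma."""
    _, ff, state = _bond_system()
    st = LangevinSettings(temperature=300.0, tau_ps=0.2, seed=7, stride=20)
    traj = run_langevin(state, ff, st, 400000, save_frames=True)
    r = _bond_lengths(traj.frames[100:])
    m1, var = _bond_moments(300.0)
    neff = len(r) / 4.0                       # conservative correlation factor
    se_mean = np.sqrt(var / neff)
    assert abs(r.mean() - m1) < 3 * se_mean
    se_var = var * np.sqrt(2.0 / neff)
    assert abs(r.var() - var) < 3 * se_var


def test_nve_energy_conservation():
    """Thermostat off, dt = 1 fs: total-energy drift below 1e-3
    kcal/mol per step over 1e4 steps on the ideal duplex."""
    top = build_dna_topology("GCGTCATACAGTGC", "two_bead", duplex=True)
    ff = ForceField(top)
    state = SimulationState.from_coords(build_bdna_coordinates(top))
    st = LangevinSettings(temperature=290.0, dt_fs=1.0, seed=11, stride=100)
    traj = run_langevin(state, ff, st, 10000, save_frames=False,
                        thermostat=False)
    etot = traj.epot + traj.ekin
    drift = abs(etot[-1] - etot[0]) / 10000
    assert drift < 1e-3


def test_bitwise_determinism():
    _, ff, s1 = _bond_system()
    _, _, s2 = _bond_system()
    st = LangevinSettings(temperature=300.0, seed=99, stride=50)
    t1 = run_langevin(s1, ff, st, 20000, save_frames=True)
    t2 = run_langevin(s2, ff, st, 20000, save_frames=True)
    assert np.array_equal(t1.epot, t2.epot)
    assert np.array_equal(t1.frames, t2.frames)
    s3 = _bond_system()[2]
    t3 = run_langevin(s3, ff, LangevinSettings(temperature=300.0, seed=100,
                                               stride=50), 20000)
    assert not np.array_equal(t1.epot, t3.epot)


def test_thermostat_invariance():
    """The mean bond length is insensitive to the damping time tau
    (1, 10, 100 ps) within sampling error."""
    means, ses = [], []
    for tau in (1.0, 10.0, 100.0):
        _, ff, state = _bond_system()
        st = LangevinSettings(temperature=300.0, tau_ps=tau, seed=13,
                              stride=50)
        traj = run_langevin(state, ff, st, 600000, save_frames=True)
        r = _bond_lengths(traj.frames[50:])
        means.append(r.mean())
        neff = max(10.0, len(r) * 10.0 / (1.0 + tau * 100.0 / 50.0))
        ses.append(r.std() / np.sqrt(neff))
    m_exact = _bond_moments(300.0)[0]
    for m, s in zip(means, ses):
        assert abs(m - m_exact) < 3.5 * s


def test_blowup_names_step():
    top = build_dna_topology("GCGTCATACAGTGC", "two_bead", duplex=True)
    ff = ForceField(top)
    state = SimulationState.from_coords(build_bdna_coordinates(top))
    st = LangevinSettings(temperature=300.0, dt_fs=500.0, seed=1, stride=10)
    with pytest.raises(SimulationBlowupError, match="step"):
        run_langevin(state, ff, st, 5000)


class TestREMD:
    def test_equal_temperatures_always_accept(self):
        _, ff, state = _bond_system()
        ladder = ReplicaLadder([300.0, 300.0], swap_interval=50)
        st = LangevinSettings(seed=5, stride=50)
        res = run_remd(ladder, ff, state, st, 10000)
        assert res.swap_attempts[0] > 0
        assert res.acceptance_ratio[0] == pytest.approx(1.0)

    def test_harmonic_ladder_variance_matches_closed_form(self):
        """Per-temperature bond-length variance on a 4-temperature
        ladder equals the Boltzmann value within 3 sigma."""
        _, ff, state = _bond_system()
        temps = [250.0, 300.0, 360.0, 430.0]
        ladder = ReplicaLadder(temps, swap_interval=100)
        st = LangevinSettings(seed=17, tau_ps=0.5, stride=100)
        res = run_remd(ladder, ff, state, st, 300000, save_frames=True)
        for t, temp in enumerate(temps):
            r = np.array([_bond_lengths(f[None])[0] for f in res.frames[t]])
            r = r[len(r) // 5:]
            var_exact = _bond_moments(temp)[1]
            neff = len(r) / 2.0
            assert abs(r.var() - var_exact) < 3 * var_exact * np.sqrt(2 / neff)

    def test_stationary_energy_matches_single_temperature(self):
        """Consequence of detailed balance: the REMD slot ensembles are
        indistinguishable from independent single-T runs (two-state-like
        bonded toy, mean energy within 3 sigma)."""
        _, ff, state = _bond_system()
        temps = [280.0, 400.0]
        ladder = ReplicaLadder(temps, swap_interval=100)
        res = run_remd(ladder, ff, state, LangevinSettings(seed=23, tau_ps=0.5,
                                                           stride=100),
                       300000, save_frames=False)
        for t, temp in enumerate(temps):
            e = res.energies[t][5:]
            # exact <U> for U = K dr^2 with r^2 Jacobian, by quadrature
            beta = 1.0 / (KB * temp)
            r = np.linspace(BOND_R0 - 2, BOND_R0 + 2, 20001)
            w = r ** 2 * np.exp(-beta * BOND_K * (r - BOND_R0) ** 2)
            u = BOND_K * (r - BOND_R0) ** 2
            u_exact = np.trapezoid(w * u, r) / np.trapezoid(w, r)
            u_var = np.trapezoid(w * u ** 2, r) / np.trapezoid(w, r) - u_exact ** 2
            neff = len(e) / 2.0
            assert abs(e.mean() - u_exact) < 3 * np.sqrt(u_var / neff)

    def test_swap_acceptance_matches_independent_sampling(self):
        """Measured swap acceptance equals <min(1, e^{dBeta dE})> under
        independent equilibrium ensembles (Monte-Carlo oracle)."""
        _, ff, state = _bond_system()
        temps = [280.0, 400.0]
        res = run_remd(ReplicaLadder(temps, swap_interval=100), ff, state,
                       LangevinSettings(seed=31, tau_ps=0.5, stride=100),
                       400000, save_frames=False)
        # oracle: exact sampling of U at each T via inverse-CDF
        rng = np.random.default_rng(0)
        r = np.linspace(BOND_R0 - 2, BOND_R0 + 2, 40001)
        es = []
        for temp in temps:
            beta = 1.0 / (KB * temp)
            w = r ** 2 * np.exp(-beta * BOND_K * (r - BOND_R0) ** 2)
            cdf = np.cumsum(w)
            cdf /= cdf[-1]
            rs = np.interp(rng.random(200000), cdf, r)
            es.append(BOND_K * (rs - BOND_R0) ** 2)
        db = 1.0 / (KB * temps[0]) - 1.0 / (KB * temps[1])
        acc = np.minimum(1.0, np.exp(db * (es[0] - es[1])))
        pred, spred = acc.mean(), acc.std() / np.sqrt(acc.size)
        n_att = res.swap_attempts[0]
        meas = res.acceptance_ratio[0]
        se = np.sqrt(pred * (1 - pred) / (n_att / 2.0)) + 3 * spred
        assert abs(meas - pred) < 3 * se

    def test_replica_random_walk_visits_extremes(self):
        """Ergodicity smoke test: every replica visits both ladder ends."""
        _, ff, state = _bond_system()
        temps = [300.0, 330.0, 365.0, 400.0]
        res = run_remd(ReplicaLadder(temps, swap_interval=50), ff, state,
                       LangevinSettings(seed=37, tau_ps=0.5, stride=50),
                       200000, save_frames=False)
        bottom = set(res.replica_id[0].tolist())
        top_ = set(res.replica_id[-1].tolist())
        assert bottom == set(range(4))
        assert top_ == set(range(4))

    def test_ladder_validation(self):
        with pytest.raises(ValueError):
            ReplicaLadder([300.0])
        with pytest.raises(ValueError):
            ReplicaLadder([350.0, 300.0])


class TestUmbrella:
    @staticmethod
    def _two_free_beads():
        # two single-residue chains: no nonbonded interaction (G neutral,
        # lambda mixing still applies but they start far apart)
        top = combine(build_protein_topology("G"), build_protein_topology("G"))
        ff = ForceField(top)
        state = SimulationState(np.array([[0.0, 0, 0], [30.0, 0, 0]]),
                                box=np.zeros(3))
        return top, ff, state

    def test_bias_only_distance_distribution(self):
        """With no other interactions the COM distance follows the
        Jacobian-weighted Boltzmann distribution of the bias within
        3 sigma (window far beyond the HPS cutoff... the two beads are
        kept ~30 A apart where their pair energy is ~0)."""
        _, ff, state = self._two_free_beads()
        k, d0, temp = 0.5975, 30.0, 300.0
        res = run_umbrella([UmbrellaWindow(d0, k)], ff, state,
                           LangevinSettings(temperature=temp, tau_ps=0.5,
                                            seed=3, stride=20),
                           400000, group_a=[0], group_b=[1])
        d = res.series[0][200:]
        beta = 1.0 / (KB * temp)
        r = np.linspace(d0 - 8, d0 + 8, 20001)
        w = r ** 2 * np.exp(-beta * k * (r - d0) ** 2)
        w /= np.trapezoid(w, r)
        m1 = np.trapezoid(w * r, r)
        var = np.trapezoid(w * r ** 2, r) - m1 ** 2
        neff = len(d) / 4.0
        assert abs(d.mean() - m1) < 3 * np.sqrt(var / neff)
        assert abs(d.var() - var) < 3 * var * np.sqrt(2 / neff)
        # mean restraint energy is kT-scale
        mean_bias = (k * (d - d0) ** 2).mean()
        assert 0.2 * KB * temp < mean_bias < 2.0 * KB * temp

    def test_adjacent_window_overlap(self):
        """Stacked windows with the standard spring constant produce
        overlapping distance histograms.  For bias-dominated point
        particles the window width is sigma = sqrt(kT/2k) ~ 0.7 A, so
        the ladder spacing here is 2.5 A; real binding systems have
        broader intrinsic distributions and tolerate wider ladders."""
        _, ff, state = self._two_free_beads()
        wins = [UmbrellaWindow(c, 0.5975) for c in (27.5, 30.0, 32.5)]
        res = run_umbrella(wins, ff, state,
                           LangevinSettings(temperature=300.0, tau_ps=0.5,
                                            seed=9, stride=50),
                           120000, group_a=[0], group_b=[1],
                           equil_steps=10000)
        for a, b in zip(res.series, res.series[1:]):
            assert a.max() > b.min()          # shared support

    def test_group_validation(self):
        _, ff, state = self._two_free_beads()
        with pytest.raises(ValueError):
            run_umbrella([UmbrellaWindow(10.0)], ff, state,
                         LangevinSettings(), 100, group_a=[], group_b=[1])
        with pytest.raises(ValueError):
            run_umbrella([UmbrellaWindow(10.0)], ff, state,
                         LangevinSettings(), 100, group_a=[0], group_b=[0])
        with pytest.raises(ValueError):
            UmbrellaWindow(10.0, k=-1.0)
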