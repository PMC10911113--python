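"""Ensemble generation: Langevin NVT dynamics, temperature replica
exchange, and harmonic COM-COM umbrella sampling.

The integrator is a BAOAB-split Langevin scheme, which is stable at the
model's standard 10 fs timestep with the stiff K = 50 kcal/(mol A^2)
bonds.  All randomness flows from a single integer seed through
``numpy.random.Generator`` streams, so identical seeds give bitwise
identical trajectories.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .forcefield import ForceField
from .geometry import CoordinateSet
from .units import KB, FS, ENERGY_TO_MVSQ

_EMPTY = np.empty(0, np.int64)


class SimulationBlowupError(RuntimeError):
    """Numeric blow-up during integration (names the failing step)."""


@dataclass
class LangevinSettings:
    """Langevin NVT settings.

    ``dt_fs``: timestep in fs (default 10); ``tau_ps``: thermostat
    damping time in ps (friction = 1/tau); ``stride``: steps between
    samples.
    """

    temperature: float = 300.0
    dt_fs: float = 10.0
    tau_ps: float = 10.0
    seed: int = 0
    stride: int = 100

    def __post_init__(self):
        if self.dt_fs <= 0 or self.tau_ps <= 0:
            raise ValueError("dt and tau must be positive")


@dataclass
class SimulationState:
    """Coordinates (A), velocities (A/ps) and box of one replica."""

    positions: np.ndarray
    velocities: np.ndarray | None = None
    box: np.ndarray = field(default_factory=lambda: np.zeros(3))

    @classmethod
    def from_coords(cls, coords: CoordinateSet) -> "SimulationState":
        return cls(coords.positions.copy(), None, np.asarray(coords.box, float))

    def copy(self) -> "SimulationState":
        v = None if self.velocities is None else self.velocities.copy()
        return SimulationState(self.positions.copy(), v, self.box.copy())


@dataclass
class Trajectory:
    """Sampled frames and per-sample energies of one run."""

    frames: np.ndarray          # (S, N, 3); empty if save_frames=False
    epot: np.ndarray            # (S,) potential energy incl. restraint
    ekin: np.ndarray            # (S,)
    cv: np.ndarray              # (S,) restraint COM distance (0 if none)
    dt_sample_ps: float
    temperature: float
    seed: int

    @property
    def n_samples(self) -> int:
        return self.epot.shape[0]

    def kinetic_temperature(self, n_dof: int) -> np.ndarray:
        """Instantaneous kinetic temperature estimator, K."""
        return 2.0 * self.ekin / (n_dof * KB)


def maxwell_velocities(masses: np.ndarray, temperature: float,
                       rng: np.random.Generator) -> np.ndarray:
    """Maxwell-Boltzmann velocities (A/ps) at the given temperature."""
    sig = np.sqrt(KB * temperature * ENERGY_TO_MVSQ / masses)
    return rng.standard_normal((masses.size, 3)) * sig[:, None]


def run_langevin(state: SimulationState, ff: ForceField,
                 settings: LangevinSettings, n_steps: int,
                 save_frames: bool = True, thermostat: bool = True,
                 restraint: tuple | None = None) -> Trajectory:
    """Integrate Langevin dynamics in place on ``state``.

    Parameters
    ----------
    restraint:
        Optional ``(group_a, group_b, k_u, d0)`` harmonic COM-COM
        restraint, k_u in kcal/(mol A^2) with U = k_u (d - d0)^2.
    thermostat:
        ``False`` runs plain velocity-Verlet (NVE), useful for energy
        conservation checks.

    Returns the sampled :class:`Trajectory`; raises
    :class:`SimulationBlowupError` naming the step on numeric failure.
    """
    rng = np.random.default_rng(settings.seed)
    masses = ff.masses
    if state.velocities is None:
        state.velocities = maxwell_velocities(masses, settings.temperature, rng)
    pos = np.ascontiguousarray(state.positions, float)
    vel = np.ascontiguousarray(state.velocities, float)

    stride = max(1, int(settings.stride))
    n_samples = n_steps // stride
    shape = (n_samples if save_frames else 0, pos.shape[0], 3)
    out_pos = np.zeros(shape)
    out_epot = np.zeros(n_samples)
    out_ekin = np.zeros(n_samples)
    out_cv = np.zeros(n_samples)

    if restraint is None:
        ga, gb, ku, d0 = _EMPTY, _EMPTY, 0.0, 0.0
    else:
        ga = np.asarray(restraint[0], np.int64)
        gb = np.asarray(restraint[1], np.int64)
        if ga.size == 0 or gb.size == 0:
            raise ValueError("restraint groups must be non-empty")
        ku, d0 = float(restraint[2]), float(restraint[3])

    gamma = 1.0 / settings.tau_ps if thermostat else 0.0
    status = _kernels.baoab_run(
        pos, vel, masses, state.box, *ff.arrays,
        settings.dt_fs * FS, gamma, KB * settings.temperature,
        int(n_steps), stride, rng, ga, gb, ku, d0,
        out_pos, out_epot, out_ekin, out_cv, save_frames)
    if status >= 0:
        raise SimulationBlowupError(
            f"integration blew up at step {int(status)} "
            f"(non-finite coordinates or displacement > 3 A per step)")
    state.positions, state.velocities = pos, vel
    return Trajectory(out_pos, out_epot, out_ekin, out_cv,
                      settings.dt_fs * FS * stride,
                      settings.temperature, settings.seed)


def minimize_energy(state: SimulationState, ff: ForceField,
                    n_steps: int = 500, max_disp: float = 0.2,
                    restraint: tuple | None = None) -> float:
    """Steepest-descent energy minimization (overlap removal).

    Moves along the force direction with a displacement cap of
    ``max_disp`` A per step, backtracking when the energy rises.
    Returns the final potential energy.
    """
    from . import _kernels

    pos = state.positions
    box = state.box

    def eval_at(p):
        rep = ff.energy(p, box=box)
        f = rep.forces
        e = rep.total
        if restraint is not None:
            ga = np.asarray(restraint[0], np.int64)
            gb = np.asarray(restraint[1], np.int64)
            er, _ = _kernels.restraint_energy_forces(
                p, ff.masses, ga, gb, float(restraint[2]),
                float(restraint[3]), f)
            e += er
        return e, f

    alpha = max_disp
    e, f = eval_at(pos)
    for _ in range(n_steps):
        fmax = np.abs(f).max()
        if fmax < 1e-4:
            break
        trial = pos + np.clip(alpha * f / fmax, -max_disp, max_disp)
        e_t, f_t = eval_at(trial)
        if e_t < e:
            pos, e, f = trial, e_t, f_t
            alpha = min(alpha * 1.2, max_disp)
        else:
            alpha *= 0.5
            if alpha < 1e-6:
                break
    state.positions = pos
    return float(e)


# ---------------------------------------------------------------------------
# replica exchange
# ---------------------------------------------------------------------------

@dataclass
class ReplicaLadder:
    """Ordered temperature ladder for parallel tempering."""

    temperatures: np.ndarray
    swap_interval: int = 100

    def __post_init__(self):
        self.temperatures = np.asarray(self.temperatures, float)
        if self.temperatures.size < 2:
            raise ValueError("need at least 2 replicas")
        if np.any(np.diff(self.temperatures) < 0):
            raise ValueError("temperatures must be non-decreasing")


@dataclass
class REMDResult:
    """Per-temperature ensembles and swap statistics.

    ``energies[t]``/``frames[t]``/``replica_id[t]`` hold the samples
    collected at ladder temperature index t (configuration bookkeeping:
    swaps exchange configurations between temperature slots, with
    velocity rescaling by sqrt(T_new/T_old)).
    """

    temperatures: np.ndarray
    energies: list
    frames: list
    replica_id: list
    swap_attempts: np.ndarray
    swap_accepts: np.ndarray
    states: list

    @property
    def acceptance_ratio(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return np.where(self.swap_attempts > 0,
                            self.swap_accepts / self.swap_attempts, np.nan)


def run_remd(ladder: ReplicaLadder, ff: ForceField, state: SimulationState,
             settings: LangevinSettings, n_steps: int,
             save_frames: bool = False) -> REMDResult:
    """Temperature replica-exchange Langevin dynamics.

    Each ladder slot starts from a copy of ``state``; neighbour swaps
    are attempted every ``ladder.swap_interval`` steps (alternating
    even/odd neighbour pairs) and accepted with the Metropolis
    probability min(1, exp[(beta_i - beta_j)(E_i - E_j)]).
    """
    temps = ladder.temperatures
    n_rep = temps.size
    rng = np.random.default_rng(np.random.SeedSequence([settings.seed, 2**20]))
    states = []
    for r in range(n_rep):
        s = state.copy()
        srng = np.random.default_rng(np.random.SeedSequence([settings.seed, r]))
        s.velocities = maxwell_velocities(ff.masses, temps[r], srng)
        states.append(s)
    replica_of_slot = list(range(n_rep))

    energies = [[] for _ in range(n_rep)]
    frames = [[] for _ in range(n_rep)]
    rep_ids = [[] for _ in range(n_rep)]
    attempts = np.zeros(n_rep - 1)
    accepts = np.zeros(n_rep - 1)

    interval = int(ladder.swap_interval)
    n_rounds = int(n_steps) // interval
    for rnd in range(n_rounds):
        cur_e = np.zeros(n_rep)
        for r in range(n_rep):
            st = LangevinSettings(temperature=float(temps[r]),
                                  dt_fs=settings.dt_fs, tau_ps=settings.tau_ps,
                                  seed=int(np.random.SeedSequence(
                                      [settings.seed, 1000 + r, rnd]).generate_state(1)[0] >> 1),
                                  stride=interval)
            traj = run_remd_segment(states[r], ff, st, interval)
            cur_e[r] = traj.epot[-1]
            energies[r].append(cur_e[r])
            rep_ids[r].append(replica_of_slot[r])
            if save_frames:
                frames[r].append(states[r].positions.copy())
        # alternate even/odd neighbour pairs
        for r in range(rnd % 2, n_rep - 1, 2):
            attempts[r] += 1
            bi = 1.0 / (KB * temps[r])
            bj = 1.0 / (KB * temps[r + 1])
            delta = (bi - bj) * (cur_e[r] - cur_e[r + 1])
            if np.log(rng.random()) < min(0.0, delta):
                accepts[r] += 1
                states[r], states[r + 1] = states[r + 1], states[r]
                scale_up = np.sqrt(temps[r + 1] / temps[r])
                states[r].velocities *= 1.0 / scale_up
                states[r + 1].velocities *= scale_up
                replica_of_slot[r], replica_of_slot[r + 1] = \
                    replica_of_slot[r + 1], replica_of_slot[r]
                cur_e[r], cur_e[r + 1] = cur_e[r + 1], cur_e[r]

    return REMDResult(temps, [np.array(e) for e in energies],
                      [np.array(f) for f in frames],
                      [np.array(r) for r in rep_ids],
                      attempts, accepts, states)


def run_remd_segment(state: SimulationState, ff: ForceField,
                     settings: LangevinSettings, n_steps: int) -> Trajectory:
    """One between-swaps segment (thin wrapper over run_langevin)."""
    return run_langevin(state, ff, settings, n_steps, save_frames=False)


# ---------------------------------------------------------------------------
# umbrella sampling
# ---------------------------------------------------------------------------

@dataclass
class UmbrellaWindow:
    """One harmonic COM-COM umbrella window: U = k (d - center)^2."""

    center: float
    k: float = 0.5975    # kcal/(mol A^2)

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError("umbrella spring constant must be positive")


@dataclass
class UmbrellaResult:
    windows: list
    series: list          # per window, COM-distance samples (A)
    energies: list        # per window, potential energy samples
    temperature: float


def run_umbrella(windows: list, ff: ForceField, state: SimulationState,
                 settings: LangevinSettings, n_steps: int,
                 group_a, group_b, equil_steps: int = 0) -> UmbrellaResult:
    """Serial umbrella sampling over COM-COM distance windows.

    ``group_a``/``group_b`` are disjoint bead-index groups; the COM is
    mass-weighted.  Windows are visited from the largest centre inward
    (an approach trajectory): each starts from the previous window's
    final state with group B rigidly translated to the new centre,
    followed by a short steepest-descent minimization to remove any
    overlaps and ``equil_steps`` of discarded equilibration.
    """
    ga = np.asarray(group_a, np.int64)
    gb = np.asarray(group_b, np.int64)
    if ga.size == 0 or gb.size == 0:
        raise ValueError("umbrella groups must be non-empty")
    if set(ga.tolist()) & set(gb.tolist()):
        raise ValueError("umbrella groups must be disjoint")
    m = ff.masses
    order = sorted(range(len(windows)), key=lambda i: -windows[i].center)
    series = [None] * len(windows)
    energies = [None] * len(windows)
    cur = state.copy()
    for iw in order:
        win = windows[iw]
        com_a = np.average(cur.positions[ga], axis=0, weights=m[ga])
        com_b = np.average(cur.positions[gb], axis=0, weights=m[gb])
        sep = com_b - com_a
        d = np.linalg.norm(sep)
        u = sep / d if d > 1e-9 else np.array([1.0, 0.0, 0.0])
        cur.positions[gb] += (win.center - d) * u
        restraint = (ga, gb, win.k, win.center)
        minimize_energy(cur, ff, n_steps=200, restraint=restraint)
        cur.velocities = None          # rethermalise after the shift
        st = LangevinSettings(temperature=settings.temperature,
                              dt_fs=settings.dt_fs, tau_ps=settings.tau_ps,
                              seed=int(np.random.SeedSequence(
                                  [settings.seed, 3000 + iw]).generate_state(1)[0] >> 1),
                              stride=settings.stride)
        if equil_steps:
            run_langevin(cur, ff, st, equil_steps, save_frames=False,
                         restraint=restraint)
        traj = run_langevin(cur, ff, st, n_steps, save_frames=False,
                            restraint=restraint)
        series[iw] = traj.cv.copy()
        energies[iw] = traj.epot.copy()
    idx = sorted(range(len(windows)), key=lambda i: windows[i].center)
    return UmbrellaResult([windows[i] for i in idx],
                          [series[i] for i in idx],
                          [energies[i] for i in idx], settings.temperature)
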