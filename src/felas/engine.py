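"""Langevin (NVT) dynamics of sticker-spacer bead-spring chains.

The engine integrates underdamped Langevin dynamics with a BAOAB
velocity-Verlet splitting (friction/noise applied as an exact
Ornstein-Uhlenbeck half-kick between the two drift half-steps).  With zero
friction the scheme reduces to plain velocity Verlet, which the NVE energy
drift tests exploit.  Reduced LJ units throughout; the timestep default is
0.001 tau and the friction default 0.1 m/tau.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .forcefield import ForceField
from .landscape import StickerPattern

__all__ = [
    "Topology",
    "SystemState",
    "Trajectory",
    "StressSample",
    "StressSeries",
    "SimulationConfig",
    "compute_forces",
    "virial_stress",
    "langevin_step",
    "initialize_chains",
    "run_simulation",
]


class SimulationInstabilityError(RuntimeError):
    pass


@dataclass
class Topology:
    """Linear chains of equal length; bead types index into a pattern."""

    n_chains: int
    chain_length: int
    bead_type: np.ndarray  # (N,) int, residue identity i % chain_length
    chain_id: np.ndarray   # (N,) int

    @classmethod
    def linear(cls, n_chains: int, chain_length: int) -> "Topology":
        n = n_chains * chain_length
        bead_type = np.tile(np.arange(chain_length), n_chains)
        chain_id = np.repeat(np.arange(n_chains), chain_length)
        return cls(n_chains, chain_length, bead_type.astype(np.int64),
                   chain_id.astype(np.int64))

    @property
    def n_beads(self) -> int:
        return self.n_chains * self.chain_length

    @property
    def bonds(self) -> np.ndarray:
        i = np.arange(self.n_beads - 1)
        keep = self.chain_id[i] == self.chain_id[i + 1]
        return np.column_stack([i[keep], i[keep] + 1])

    @property
    def angles(self) -> np.ndarray:
        b = np.arange(1, self.n_beads - 1)
        keep = (self.chain_id[b - 1] == self.chain_id[b]) & (
            self.chain_id[b] == self.chain_id[b + 1]
        )
        b = b[keep]
        return np.column_stack([b - 1, b, b + 1])


@dataclass
class SystemState:
    """Positions are stored unwrapped; wrapped views are derived on demand."""

    positions: np.ndarray    # (N,3) unwrapped, sigma
    velocities: np.ndarray   # (N,3), sigma/tau
    box: np.ndarray          # (3,), sigma
    time: float = 0.0

    @property
    def wrapped(self) -> np.ndarray:
        return self.positions - self.box * np.floor(self.positions / self.box)

    @property
    def kinetic_energy(self) -> float:
        return 0.5 * float(np.sum(self.velocities ** 2))

    @property
    def temperature(self) -> float:
        n = self.positions.shape[0]
        return 2.0 * self.kinetic_energy / (3.0 * n)


@dataclass
class Trajectory:
    """Frames of unwrapped coordinates plus the topology that produced them."""

    times: np.ndarray         # (F,)
    positions: np.ndarray     # (F, N, 3) unwrapped
    box: np.ndarray           # (3,)
    topology: Topology
    pattern: StickerPattern | None = None

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    def wrapped(self, frame: int) -> np.ndarray:
        p = self.positions[frame]
        return p - self.box * np.floor(p / self.box)


@dataclass
class StressSample:
    time: float
    sigma_xy: float
    sigma_yz: float
    sigma_xz: float
    n_xy: float
    n_yz: float
    n_xz: float


@dataclass
class StressSeries:
    """Uniformly sampled off-diagonal stresses and normal-stress differences."""

    times: np.ndarray
    data: np.ndarray          # (S, 6): sxy, syz, sxz, nxy, nyz, nxz
    volume: float
    temperature: float

    COLUMNS = ("sigma_xy", "sigma_yz", "sigma_xz", "n_xy", "n_yz", "n_xz")

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise ValueError("sampling times must be strictly increasing")

    @property
    def dt(self) -> float:
        return float(self.times[1] - self.times[0])

    def component(self, name: str) -> np.ndarray:
        return self.data[:, self.COLUMNS.index(name)]


def _kernel_args(ff: ForceField):
    if ff.pair_eps is None:
        raise ValueError("force field has no pair interaction matrix")
    return (
        np.ascontiguousarray(ff.pair_eps.eps, dtype=np.float64),
        ff.fene_k, ff.fene_r0, ff.angle_k, ff.angle_theta0, ff.lj_cutoff,
    )


def compute_forces(state: SystemState, ff: ForceField, topology: Topology):
    """Forces, potential energy and virial tensor of a configuration."""
    eps, fene_k, fene_r0, angle_k, theta0, rc = _kernel_args(ff)
    x = np.ascontiguousarray(state.positions, dtype=np.float64)
    n = x.shape[0]
    nb_i = np.empty(max(n * (n - 1) // 2, 1), dtype=np.int64)
    nb_j = np.empty_like(nb_i)
    n_pairs = _kernels.build_neighbors(
        x, state.box.astype(np.float64), rc * rc, topology.chain_id, nb_i, nb_j
    )
    forces = np.zeros_like(x)
    virial = np.zeros((3, 3))
    pe, status = _kernels.compute_forces(
        x, state.box.astype(np.float64), topology.bead_type, eps,
        topology.chain_id, nb_i, nb_j, n_pairs,
        fene_k, fene_r0, angle_k, theta0, rc, forces, virial,
    )
    if status != 0:
        raise SimulationInstabilityError(
            "FENE bond reached maximum extension R0"
        )
    if not np.all(np.isfinite(forces)):
        raise SimulationInstabilityError("non-finite force encountered")
    return forces, pe, virial


def virial_stress(state: SystemState, ff: ForceField, topology: Topology) -> StressSample:
    """Instantaneous stress sigma_ab = (sum m v_a v_b + sum r_ab f_ab) / V."""
    _, _, virial = compute_forces(state, ff, topology)
    v = state.velocities
    kin = ff.mass * v.T @ v
    volume = float(np.prod(state.box))
    s = (kin + virial) / volume
    return StressSample(
        time=state.time,
        sigma_xy=s[0, 1], sigma_yz=s[1, 2], sigma_xz=s[0, 2],
        n_xy=s[0, 0] - s[1, 1], n_yz=s[1, 1] - s[2, 2], n_xz=s[0, 0] - s[2, 2],
    )


def langevin_step(
    state: SystemState,
    ff: ForceField,
    topology: Topology,
    dt: float = 0.001,
    gamma: float = 0.1,
    T: float = 1.0,
    rng: np.random.Generator | int | None = None,
    forces: np.ndarray | None = None,
) -> tuple[SystemState, np.ndarray]:
    """One BAOAB step; returns the updated state and the new forces.

    Passing the previous step's forces avoids one force evaluation.  The
    noise is drawn from ``rng`` (a Generator or a seed), so repeated calls
    with the same seed and inputs are bit-identical.
    """
    if T <= 0:
        raise ValueError("temperature must be positive")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    if forces is None:
        forces, _, _ = compute_forces(state, ff, topology)
    m = ff.mass
    v = state.velocities + 0.5 * dt * forces / m
    x = state.positions + 0.5 * dt * v
    if gamma > 0:
        c1 = np.exp(-gamma * dt / m)
        c2 = np.sqrt(ff.kB * T * (1.0 - c1 * c1) / m)
        v = c1 * v + c2 * rng.standard_normal(v.shape)
    x = x + 0.5 * dt * v
    new = SystemState(positions=x, velocities=v, box=state.box,
                      time=state.time + dt)
    new_forces, _, _ = compute_forces(new, ff, topology)
    new.velocities = v + 0.5 * dt * new_forces / m
    return new, new_forces


def initialize_chains(
    topology: Topology,
    box: np.ndarray,
    seed: int = 0,
    bond_length: float = 0.97,
    x_fraction: float = 1.0,
) -> SystemState:
    """Place chains as self-avoiding-ish random walks inside the box.

    Each chain starts at a uniform random point and grows with bond length
    ``bond_length`` and a bending bias around the equilibrium angle; local
    overlaps are left to the force-capped relaxation stage.  With
    ``x_fraction`` < 1 chains start inside the central slab of that width
    along x (dense-slab initialization for coexistence runs).
    """
    from scipy.spatial import cKDTree

    rng = np.random.default_rng(seed)
    box = np.asarray(box, dtype=float)
    n = topology.n_beads
    pos = np.empty((n, 3))
    lo = np.array([0.5 * box[0] * (1 - x_fraction), 0.0, 0.0])
    span = np.array([box[0] * x_fraction, box[1], box[2]])
    min_sep = 0.85
    placed_tree = None
    idx = 0
    for _ in range(topology.n_chains):
        for _attempt in range(60):
            start = lo + rng.random(3) * span
            if placed_tree is None or not placed_tree.query_ball_point(
                start % box, min_sep
            ):
                break
        direction = rng.standard_normal(3)
        direction /= np.linalg.norm(direction)
        pos[idx] = start
        for b in range(1, topology.chain_length):
            prev = pos[idx + b - 1]
            best = None
            for _attempt in range(30):
                step = direction + 0.6 * rng.standard_normal(3)
                step /= np.linalg.norm(step)
                cand = prev + bond_length * step
                clash = False
                if placed_tree is not None and placed_tree.query_ball_point(
                    cand % box, min_sep
                ):
                    clash = True
                # self-avoidance against this chain's earlier beads
                if not clash and b > 1:
                    d = pos[idx : idx + b - 1] - cand
                    d -= box * np.round(d / box)
                    if np.any(np.sum(d * d, axis=1) < min_sep * min_sep):
                        clash = True
                best = (cand, step)
                if not clash:
                    break
            cand, step = best
            pos[idx + b] = cand
            direction = step
        idx += topology.chain_length
        placed_tree = cKDTree(pos[:idx] % box, boxsize=box)
    vel = np.zeros((n, 3))
    return SystemState(positions=pos, velocities=vel, box=box, time=0.0)


@dataclass
class SimulationConfig:
    """Everything needed to run one production simulation."""

    pattern: StickerPattern
    n_chains: int = 20
    box: tuple[float, float, float] = (15.0, 15.0, 15.0)
    temperature: float = 1.0
    dt: float = 0.001
    gamma: float = 0.1
    n_steps: int = 10_000
    relax_steps: int = 2_000
    traj_stride: int = 100
    stress_stride: int = 10
    seed: int = 0
    skin: float = 0.4
    slab_init_fraction: float = 1.0
    force_field: ForceField | None = None

    def make_force_field(self) -> ForceField:
        if self.force_field is not None:
            if self.force_field.pair_eps is None:
                raise ValueError("configured force field lacks pair_eps")
            return self.force_field
        return ForceField.for_pattern(self.pattern)


def _run_kernel(state, ff, topology, dt, gamma, T, n_steps, seed, skin,
                force_cap, traj_stride, stress_stride):
    eps, fene_k, fene_r0, angle_k, theta0, rc = _kernel_args(ff)
    x = np.ascontiguousarray(state.positions, dtype=np.float64)
    v = np.ascontiguousarray(state.velocities, dtype=np.float64)
    box = state.box.astype(np.float64)
    n = x.shape[0]
    # generous neighbor capacity: dense LJ has ~80 neighbors within rc+skin
    cap = max(200 * n, 2000)
    nb_i = np.empty(cap, dtype=np.int64)
    nb_j = np.empty_like(nb_i)
    x_ref = np.empty_like(x)
    forces = np.zeros_like(x)
    virial = np.zeros((3, 3))
    nf = n_steps // traj_stride if traj_stride > 0 else 0
    ns = n_steps // stress_stride if stress_stride > 0 else 0
    traj_times = np.zeros(max(nf, 1))
    traj_pos = np.zeros((max(nf, 1), n, 3))
    stress_out = np.zeros((max(ns, 1), 7))
    log_out = np.zeros((max(ns, 1), 4))
    status, n_frames, n_stress = _kernels.run_langevin(
        x, v, box, topology.bead_type, eps, topology.chain_id,
        fene_k, fene_r0, angle_k, theta0, rc,
        dt, gamma, T, ff.mass, n_steps, seed, skin, force_cap,
        traj_stride, stress_stride, state.time,
        traj_times, traj_pos, stress_out, log_out,
        nb_i, nb_j, x_ref, forces, virial,
    )
    if status == 1:
        raise SimulationInstabilityError("FENE bond overextension during run")
    if status == 2:
        raise SimulationInstabilityError("neighbor list capacity exceeded")
    if status == 3:
        raise SimulationInstabilityError("non-finite coordinates during run")
    state.positions = x
    state.velocities = v
    state.time += n_steps * dt
    return (traj_times[:n_frames], traj_pos[:n_frames],
            stress_out[:n_stress], log_out[:n_stress])


def run_simulation(config: SimulationConfig):
    """Initialize, relax with capped forces, then run production.

    Returns (trajectory, stress_series, log) where log is a DataFrame-ready
    array of (time, kinetic, potential, instantaneous T) rows.
    """
    topo = Topology.linear(config.n_chains, config.pattern.n_residues)
    ff = config.make_force_field()
    box = np.asarray(config.box, dtype=float)
    state = initialize_chains(
        topo, box, seed=config.seed, x_fraction=config.slab_init_fraction
    )
    if config.relax_steps > 0:
        # two-stage push-off: strongly damped tight cap, then a looser cap,
        # so production can start from an overlap-free configuration
        _run_kernel(
            state, ff, topo, config.dt * 0.25, max(config.gamma, 2.0),
            config.temperature, config.relax_steps, config.seed + 2,
            config.skin, 30.0, 0, 0,
        )
        _run_kernel(
            state, ff, topo, config.dt * 0.5, max(config.gamma, 1.0),
            config.temperature, config.relax_steps, config.seed + 4,
            config.skin, 200.0, 0, 0,
        )
    # velocities re-drawn from Maxwell-Boltzmann at the target T
    rng = np.random.default_rng(config.seed + 1)
    state.velocities = rng.standard_normal((topo.n_beads, 3)) * np.sqrt(
        config.temperature / ff.mass
    )
    traj_times, traj_pos, stress, log = _run_kernel(
        state, ff, topo, config.dt, config.gamma, config.temperature,
        config.n_steps, config.seed + 3, config.skin, 0.0,
        config.traj_stride, config.stress_stride,
    )
    trajectory = Trajectory(
        times=traj_times, positions=traj_pos, box=box, topology=topo,
        pattern=config.pattern,
    )
    series = StressSeries(
        times=stress[:, 0], data=stress[:, 1:7],
        volume=float(np.prod(box)), temperature=config.temperature,
    )
    return trajectory, series, log
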