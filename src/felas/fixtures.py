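"""Deterministic synthetic-data generators with exactly known ground truth.

Each generator isolates a single observable so the analysis modules can be
validated without running any polymer simulation: Brownian walkers (MSD,
van Hove), worm-like chains (tangent correlations), Ornstein-Uhlenbeck
stress (multi-tau correlator, Green-Kubo), two-phase slabs and synthetic
binodals (phase equilibrium), and cluster fields (clustering/shape).
They do not emulate the full condensate physics.
"""

from __future__ import annotations

import numpy as np

from .engine import StressSeries, Topology, Trajectory
from .phase import CoexistencePoint

__all__ = [
    "gen_brownian",
    "gen_wlc",
    "gen_ou_stress",
    "gen_maxwell_fluid_stress",
    "gen_two_phase_slab",
    "gen_binodal",
    "gen_cluster_field",
]


def gen_brownian(
    n: int = 100,
    d0: float = 0.5,
    dt: float = 0.1,
    steps: int = 200,
    seed: int = 0,
    box_length: float = 1e6,
) -> Trajectory:
    """Independent 3-D Brownian walkers: increments N(0, 2 d0 dt) per axis.

    Ground truth: <dr^2(t)> = 6 d0 t, alpha = 1, Gaussian van Hove with
    W(t) = 4 d0 t.
    """
    if d0 <= 0:
        raise ValueError("diffusivity must be positive")
    rng = np.random.default_rng(seed)
    incr = rng.standard_normal((steps, n, 3)) * np.sqrt(2.0 * d0 * dt)
    pos = np.concatenate([np.zeros((1, n, 3)), np.cumsum(incr, axis=0)])
    topo = Topology.linear(n, 1)
    return Trajectory(
        times=np.arange(steps + 1) * dt, positions=pos,
        box=np.full(3, box_length), topology=topo,
    )


def gen_wlc(
    n_chains: int = 200,
    n_beads: int = 100,
    lp: float = 4.2,
    bond_length: float = 1.0,
    seed: int = 0,
    box_length: float = 1e6,
) -> Trajectory:
    """Worm-like chains with P(theta) ~ exp(kappa cos theta) sin theta.

    For a discrete chain <t_i . t_{i+s}> = <cos theta>^s with
    <cos theta> = coth(kappa) - 1/kappa (the Langevin function), so kappa
    is solved numerically from exp(-b/lp) = L(kappa) and the sampled chains
    decay with exactly the requested persistence length.  Single frame;
    lp -> infinity gives rods, lp -> 0 a freely jointed chain.
    """
    if lp <= 0:
        raise ValueError("persistence length must be positive")
    from scipy.optimize import brentq

    rng = np.random.default_rng(seed)
    target = np.exp(-bond_length / lp)

    def langevin(k):
        return 1.0 / np.tanh(k) - 1.0 / k

    if target < 1e-6:
        kappa = 0.0
    elif target > 1.0 - 1e-7:
        kappa = 1.0 / (1.0 - target)  # stiff limit: L(k) ~ 1 - 1/k
    else:
        kappa = brentq(lambda k: langevin(k) - target, 1e-8, 1e8)
    n = n_chains * n_beads
    pos = np.empty((n, 3))
    idx = 0
    for _ in range(n_chains):
        t = rng.standard_normal(3)
        t /= np.linalg.norm(t)
        pos[idx] = rng.random(3) * box_length * 1e-3
        for b in range(1, n_beads):
            # sample cos(theta) from the exponential-tilted distribution
            u = rng.random()
            if kappa > 1e-8:
                ct = 1.0 + np.log(u + (1.0 - u) * np.exp(-2.0 * kappa)) / kappa
            else:
                ct = 2.0 * u - 1.0
            ct = min(1.0, max(-1.0, ct))
            st = np.sqrt(1.0 - ct * ct)
            phi = 2.0 * np.pi * rng.random()
            # orthonormal frame around current tangent
            a = np.array([1.0, 0.0, 0.0])
            if abs(t[0]) > 0.9:
                a = np.array([0.0, 1.0, 0.0])
            e1 = np.cross(t, a)
            e1 /= np.linalg.norm(e1)
            e2 = np.cross(t, e1)
            t = ct * t + st * (np.cos(phi) * e1 + np.sin(phi) * e2)
            t /= np.linalg.norm(t)
            pos[idx + b] = pos[idx + b - 1] + bond_length * t
        idx += n_beads
    topo = Topology.linear(n_chains, n_beads)
    return Trajectory(
        times=np.zeros(1), positions=pos[None],
        box=np.full(3, box_length), topology=topo,
    )


def gen_ou_stress(
    tau_ou: float = 5.0,
    variance: float = 1.0,
    dt: float = 0.1,
    steps: int = 20000,
    seed: int = 0,
    volume: float = 1000.0,
    temperature: float = 1.0,
    n_components: int = 6,
) -> StressSeries:
    """Six independent OU processes with autocovariance variance*exp(-t/tau).

    Uses the exact discretization, so lag-0 equals ``variance`` and the
    correlation time is exactly ``tau_ou`` in expectation.
    """
    if tau_ou <= dt:
        raise ValueError("tau_ou must exceed the sampling interval")
    rng = np.random.default_rng(seed)
    a = np.exp(-dt / tau_ou)
    s = np.sqrt(variance * (1.0 - a * a))
    data = np.empty((steps, n_components))
    x = rng.standard_normal(n_components) * np.sqrt(variance)
    for i in range(steps):
        x = a * x + s * rng.standard_normal(n_components)
        data[i] = x
    return StressSeries(
        times=np.arange(1, steps + 1) * dt, data=data,
        volume=volume, temperature=temperature,
    )


def gen_maxwell_fluid_stress(
    modes: list[tuple[float, float]],
    dt: float = 0.05,
    steps: int = 50000,
    seed: int = 0,
    volume: float = 1000.0,
    temperature: float = 1.0,
) -> StressSeries:
    """Stress whose Green-Kubo G(t) is the given Maxwell spectrum.

    Per mode, the three off-diagonal channels are independent OU processes
    with variance v = G_i kT / V, and the normal-stress differences are
    built from three independent diagonal OU processes with variance 2v
    each, so every difference has autocovariance 4v e^{-t/tau}.  The
    five-channel estimator then returns
    V/(5 kT) * (3 v + (1/6) * 3 * 4 v) e^{-t/tau} = G_i e^{-t/tau}.
    """
    rng = np.random.default_rng(seed)

    def ou(tau, var, n_series):
        a = np.exp(-dt / tau)
        s = np.sqrt(var * (1.0 - a * a))
        x = rng.standard_normal(n_series) * np.sqrt(var)
        out = np.empty((steps, n_series))
        for i in range(steps):
            x = a * x + s * rng.standard_normal(n_series)
            out[i] = x
        return out

    kT = temperature
    data = np.zeros((steps, 6))
    for g, tau in modes:
        v_off = g * kT / volume  # per-channel variance so V/(5kT)*5*c = G
        off = ou(tau, v_off, 3)
        data[:, 0:3] += off
        # three independent diagonals of variance 2v -> C_N = 4v per channel
        diag = ou(tau, 2.0 * v_off, 3)
        data[:, 3] += diag[:, 0] - diag[:, 1]
        data[:, 4] += diag[:, 1] - diag[:, 2]
        data[:, 5] += diag[:, 0] - diag[:, 2]
    return StressSeries(
        times=np.arange(1, steps + 1) * dt, data=data,
        volume=volume, temperature=temperature,
    )


def gen_two_phase_slab(
    rho_l: float = 0.7,
    rho_v: float = 0.05,
    box: tuple[float, float, float] = (60.0, 10.0, 10.0),
    slab_width: float = 20.0,
    interface_width: float = 1.5,
    n_frames: int = 5,
    seed: int = 0,
) -> Trajectory:
    """Ideal-gas particles drawn from a tanh two-plateau density profile.

    Ground truth plateau densities are exactly (rho_l, rho_v) up to
    counting noise; the slab is centred in the box.
    """
    if rho_l <= rho_v:
        raise ValueError("need rho_l > rho_v")
    box = np.asarray(box, dtype=float)
    rng = np.random.default_rng(seed)
    lx = box[0]
    area = box[1] * box[2]
    x_grid = np.linspace(0, lx, 2000)
    prof = rho_v + 0.5 * (rho_l - rho_v) * (
        np.tanh((x_grid - (lx - slab_width) / 2) / interface_width)
        - np.tanh((x_grid - (lx + slab_width) / 2) / interface_width)
    )
    n_mean = np.trapezoid(prof, x_grid) * area
    cdf = np.cumsum(prof)
    cdf /= cdf[-1]
    n = int(round(n_mean))
    frames = []
    for _ in range(n_frames):
        x = np.interp(rng.random(n), cdf, x_grid)
        yz = rng.random((n, 2)) * box[1:]
        frames.append(np.column_stack([x, yz]))
    pos = np.stack(frames)
    topo = Topology.linear(n, 1)
    return Trajectory(
        times=np.arange(n_frames, dtype=float), positions=pos,
        box=box, topology=topo,
    )


def gen_binodal(
    tc: float = 2.0,
    rho_c: float = 0.3,
    a_slope: float = 0.1,
    delta_rho0: float = 1.0,
    beta: float = 0.325,
    temperatures: np.ndarray | None = None,
    noise: float = 0.0,
    seed: int = 0,
) -> list[CoexistencePoint]:
    """Coexistence points generated from the rectilinear-diameter + scaling
    law; with ``noise`` > 0, multiplicative Gaussian noise on both densities."""
    if temperatures is None:
        temperatures = np.linspace(1.2, 1.9, 8)
    rng = np.random.default_rng(seed)
    pts = []
    for T in temperatures:
        if T >= tc:
            raise ValueError("temperatures must lie below tc")
        mid = rho_c + a_slope * (tc - T)
        half = 0.5 * delta_rho0 * (1.0 - T / tc) ** beta
        rl = mid + half
        rv = max(mid - half, 0.0)
        if noise > 0:
            rl *= 1.0 + noise * rng.standard_normal()
            rv *= 1.0 + noise * rng.standard_normal()
            rv = max(rv, 0.0)
        pts.append(CoexistencePoint(T=float(T), rho_liquid=float(rl),
                                    rho_vapor=float(rv)))
    return pts


def gen_cluster_field(
    n_clusters: int = 5,
    cluster_size: int = 20,
    cluster_radius: float = 1.0,
    box_length: float = 40.0,
    seed: int = 0,
    elongation: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Well-separated Gaussian blobs; returns (positions, box).

    Blob centres sit on a jittered lattice with spacing >> radius so
    single-linkage at a few radii recovers exactly ``n_clusters`` clusters
    of exactly ``cluster_size`` beads.  ``elongation`` > 1 stretches blobs
    along x to exercise shape metrics.
    """
    rng = np.random.default_rng(seed)
    per_side = int(np.ceil(n_clusters ** (1 / 3)))
    spacing = box_length / per_side
    if spacing < 8 * cluster_radius * max(elongation, 1.0):
        raise ValueError("box too small for well-separated clusters")
    centers = []
    for i in range(per_side):
        for j in range(per_side):
            for k in range(per_side):
                if len(centers) < n_clusters:
                    centers.append((np.array([i, j, k]) + 0.5) * spacing)
    pos = []
    for c in centers:
        blob = rng.standard_normal((cluster_size, 3)) * (cluster_radius / 3.0)
        blob[:, 0] *= elongation
        pos.append(c + blob)
    return np.vstack(pos), np.full(3, box_length)
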