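"""End-to-end orchestration: pattern -> simulate -> analyze -> report.

Two preset scales are provided.  The ``desk`` preset (short chains, small
boxes, 1e5-scale step counts) runs a full pipeline in minutes on one CPU
and is what the test suite exercises; the ``production`` preset encodes the
publication-scale study conditions (chains of 200 residues, cubic box of
edge 50 sigma, slab boxes elongated to 250 sigma, beta = 0.325) and is
meant for cluster hardware.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .engine import SimulationConfig, StressSeries, Trajectory, run_simulation
from .landscape import StickerPattern, build_variant
from .phase import (CoexistencePoint, CriticalFit, FitConvergenceError,
                    ISING_BETA, density_profile, fit_coexistence,
                    fit_critical_point)
from .rheology import (classify_viscoelastic, fit_maxwell, green_kubo_modulus,
                       inv_loss_tangent, moduli_from_spectrum, viscosity)

__all__ = [
    "ExperimentConfig",
    "PRESETS",
    "workflow_phase_diagram",
    "workflow_rheology",
    "workflow_descriptor_table",
]

PRESETS = {
    "desk": dict(
        n_residues=50, n_chains=16, box_edge=12.0, slab_factor=5.0,
        n_steps=200_000, relax_steps=4_000, dt=0.005,
        traj_stride=1_000, stress_stride=5,
    ),
    "production": dict(
        n_residues=200, n_chains=250, box_edge=50.0, slab_factor=5.0,
        n_steps=100_000_000, relax_steps=1_000_000, dt=0.001,
        traj_stride=10_000, stress_stride=5,
    ),
}


@dataclass
class ExperimentConfig:
    """Serializable description of one experiment (pattern + system + run)."""

    variant: str = "P"
    period_k: int = 25
    n_residues: int = 50
    threshold: float = 0.1
    n_chains: int = 16
    box_edge: float = 12.0
    slab_factor: float = 5.0
    temperature: float = 1.0
    temperatures: tuple[float, ...] = ()
    dt: float = 0.005
    gamma: float = 0.1
    n_steps: int = 200_000
    relax_steps: int = 4_000
    traj_stride: int = 1_000
    stress_stride: int = 5
    seed: int = 0
    preset: str = "desk"

    @classmethod
    def from_preset(cls, preset: str = "desk", **overrides) -> "ExperimentConfig":
        if preset not in PRESETS:
            raise ValueError(f"unknown preset {preset!r}")
        kwargs = dict(PRESETS[preset])
        kwargs.update(overrides)
        return cls(preset=preset, **kwargs)

    def pattern(self) -> StickerPattern:
        return build_variant(self.variant, self.period_k, self.n_residues,
                             self.threshold, self.seed)

    def to_yaml(self) -> str:
        return yaml.safe_dump(dataclasses.asdict(self), sort_keys=True)

    @classmethod
    def from_yaml(cls, text: str) -> "ExperimentConfig":
        d = yaml.safe_load(text)
        if "temperatures" in d and d["temperatures"] is not None:
            d["temperatures"] = tuple(d["temperatures"])
        return cls(**d)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:12]

    def simulation_config(self, slab: bool = False,
                          temperature: float | None = None) -> SimulationConfig:
        e = self.box_edge
        box = (e * self.slab_factor, e, e) if slab else (e, e, e)
        return SimulationConfig(
            pattern=self.pattern(),
            n_chains=self.n_chains,
            box=box,
            temperature=self.temperature if temperature is None else temperature,
            dt=self.dt, gamma=self.gamma,
            n_steps=self.n_steps, relax_steps=self.relax_steps,
            traj_stride=self.traj_stride, stress_stride=self.stress_stride,
            seed=self.seed,
            slab_init_fraction=1.0 / self.slab_factor if slab else 1.0,
        )


def workflow_phase_diagram(
    config: ExperimentConfig,
    points: list[CoexistencePoint] | None = None,
    equil_fraction: float = 0.5,
    n_bins: int = 60,
    n_replicas: int = 1,
) -> tuple[CriticalFit, list[CoexistencePoint]]:
    """Slab runs over the temperature ladder -> binodal -> critical fit.

    Each temperature runs ``n_replicas`` independent slabs (seeds derived
    from the base seed) whose recentred density profiles are averaged
    before the interface fit -- small slabs fragment or drift in single
    runs, and profile averaging is the cheapest way to stabilize the
    plateau estimates.  With ``points`` supplied the simulation stage is
    skipped and only the fitting pipeline runs (used for validation
    against synthetic binodals).
    """
    if points is None:
        if len(config.temperatures) < 3:
            raise ValueError("temperature ladder needs at least 3 entries")
        points = []
        for i, T in enumerate(sorted(config.temperatures)):
            densities = []
            prof = None
            for rep in range(n_replicas):
                sim = config.simulation_config(slab=True, temperature=T)
                sim.seed = config.seed + 101 * i + 7919 * rep
                traj, _, _ = run_simulation(sim)
                first = int(equil_fraction * traj.n_frames)
                prof = density_profile(
                    traj, axis=0, n_bins=n_bins,
                    frames=slice(first, None), temperature=T,
                )
                densities.append(prof.density)
            prof.density = np.mean(densities, axis=0)
            try:
                points.append(fit_coexistence(prof))
            except FitConvergenceError:
                continue  # single-phase at this T; excluded from the fit
    if len(points) < 3:
        raise ValueError("fewer than 3 usable coexistence points")
    fit = fit_critical_point(points, beta=ISING_BETA)
    return fit, points


def workflow_rheology(
    config: ExperimentConfig,
    equil_fraction: float = 0.25,
    n_modes: int = 12,
    omega_ref: float | None = None,
) -> dict:
    """Bulk run -> Green-Kubo G(t) -> Maxwell spectrum -> moduli, eta, class.

    Returns a dict with the trajectory, stress series, modulus, spectrum,
    moduli curves, viscosity result, inverse loss tangent at ``omega_ref``
    (default: the inverse of a fifth of the observation window), and the
    'maxwell' / 'kelvin-voigt' classification.
    """
    traj, stress, log = run_simulation(config.simulation_config(slab=False))
    n0 = int(equil_fraction * len(stress.times))
    trimmed = StressSeries(
        times=stress.times[n0:], data=stress.data[n0:],
        volume=stress.volume, temperature=stress.temperature,
    )
    modulus = green_kubo_modulus(trimmed)
    spectrum = fit_maxwell(modulus, n_modes=n_modes)
    t_max = modulus.times[-1]
    omega = np.geomspace(0.1 / t_max, 10.0 / modulus.times[modulus.times > 0][0], 200)
    curves = moduli_from_spectrum(spectrum, omega)
    if omega_ref is None:
        omega_ref = 5.0 / t_max
    curves.inv_loss_tangent = inv_loss_tangent(curves, omega_ref)
    eta = viscosity(modulus=modulus, spectrum=spectrum)
    label = classify_viscoelastic(modulus, spectrum)
    return dict(
        trajectory=traj, stress=trimmed, log=log, modulus=modulus,
        spectrum=spectrum, moduli=curves, eta=eta,
        inv_loss_tangent=curves.inv_loss_tangent,
        omega_ref=omega_ref, classification=label,
    )


def workflow_descriptor_table(
    entries: list[tuple[str, float, float]]
) -> tuple[pd.DataFrame, str]:
    """Tabulate (label, x_descriptor, 1/tan delta) and flag the trend.

    The trend flag is 'increasing' when 1/tan delta is non-decreasing in
    the descriptor (elasticity grows with patterning periodicity),
    'decreasing' for the opposite, 'none' otherwise or with < 2 entries.
    """
    df = pd.DataFrame(entries, columns=["label", "x_descriptor", "inv_tan_delta"])
    df = df.sort_values("x_descriptor").reset_index(drop=True)
    if len(df) < 2:
        return df, "none"
    d = np.diff(df["inv_tan_delta"].to_numpy())
    if np.all(d >= 0):
        trend = "increasing"
    elif np.all(d <= 0):
        trend = "decreasing"
    else:
        trend = "none"
    return df, trend


def run_manifest(config: ExperimentConfig, results: dict) -> str:
    """JSON provenance record: config hash, seed, and scalar results."""
    scalars = {
        k: v for k, v in results.items()
        if isinstance(v, (int, float, str, bool))
    }
    return json.dumps(
        {"config_hash": config.config_hash, "seed": config.seed,
         "config": yaml.safe_load(config.to_yaml()), "results": scalars},
        indent=2, default=str,
    )
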