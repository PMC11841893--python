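"""Bead-spring force field: FENE bonds, harmonic angles, shifted LJ / WCA pairs.

Reduced Lennard-Jones units throughout: sigma = epsilon = m = kB = 1 and
tau = sqrt(m sigma^2 / epsilon).  Scalar reference implementations here are
the ground truth; the simulation engine's vectorized kernels are tested
against them.

Pair interactions:

* sticker-sticker (eps_ij > 0): 12-6 LJ with well depth eps_ij,
  force-shifted so both U and F go continuously to zero at the cutoff r_c
  (U_fs(r) = U(r) - U(r_c) - (r - r_c) U'(r_c)); default r_c = 2.5 sigma.
* any pairing involving a spacer (eps_ij = 0): WCA repulsion with unit well
  depth, truncated and shifted at 2^(1/6) sigma.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .landscape import PairInteractionMatrix, StickerPattern, pair_matrix

__all__ = [
    "ForceField",
    "fene_energy",
    "fene_force",
    "angle_energy",
    "pair_energy",
    "pair_force",
    "WCA_CUTOFF",
]

WCA_CUTOFF = 2.0 ** (1.0 / 6.0)


class BondOverextensionError(RuntimeError):
    """A FENE bond reached its maximum extension R0."""


@dataclass
class ForceField:
    """Parameter bundle for the four interaction terms.

    ``angle_k`` is not fixed by the model definition; the default 2.0
    epsilon/rad^2 gives semi-flexible chains with persistence length of a
    few sigma, consistent with the worm-like-chain behaviour of random
    sequences.
    """

    fene_k: float = 20.0          # epsilon / sigma^2
    fene_r0: float = 1.5          # sigma
    angle_k: float = 2.0          # epsilon / rad^2
    angle_theta0_deg: float = 150.0
    lj_cutoff: float = 2.5        # sigma, attractive pairs
    wca_cutoff: float = WCA_CUTOFF
    sigma: float = 1.0
    mass: float = 1.0
    kB: float = 1.0
    pair_eps: PairInteractionMatrix | None = None

    @property
    def angle_theta0(self) -> float:
        return np.deg2rad(self.angle_theta0_deg)

    @classmethod
    def for_pattern(cls, pattern: StickerPattern, **kwargs) -> "ForceField":
        return cls(pair_eps=pair_matrix(pattern), **kwargs)


def fene_energy(r: float, k: float = 20.0, r0: float = 1.5) -> float:
    """U_FENE(r) = -1/2 k R0^2 ln(1 - r^2/R0^2); diverges as r -> R0."""
    if r < 0:
        raise ValueError("bond length must be non-negative")
    if r >= r0:
        raise BondOverextensionError(
            f"bond length {r:.6f} reached maximum extension R0={r0}"
        )
    return -0.5 * k * r0 * r0 * np.log(1.0 - (r / r0) ** 2)


def fene_force(r: float, k: float = 20.0, r0: float = 1.5) -> float:
    """Magnitude of the restoring force k r / (1 - r^2/R0^2), toward r = 0."""
    if r >= r0:
        raise BondOverextensionError(
            f"bond length {r:.6f} reached maximum extension R0={r0}"
        )
    return k * r / (1.0 - (r / r0) ** 2)


def angle_energy(theta: float, k_theta: float = 2.0, theta0: float | None = None) -> float:
    """Harmonic bending U = K_theta (theta - theta0)^2, theta0 in radians."""
    if theta0 is None:
        theta0 = np.deg2rad(150.0)
    return k_theta * (theta - theta0) ** 2


def _lj(r: float, eps: float) -> tuple[float, float]:
    """Plain 12-6 LJ energy and dU/dr."""
    sr6 = (1.0 / r) ** 6
    u = 4.0 * eps * (sr6 * sr6 - sr6)
    dudr = 4.0 * eps * (-12.0 * sr6 * sr6 + 6.0 * sr6) / r
    return u, dudr


def pair_energy(r: float, eps_ij: float, rc: float = 2.5) -> float:
    """Non-bonded pair energy; see module docstring for the two branches."""
    if r <= 0:
        raise ValueError("pair distance must be positive (bead overlap)")
    if eps_ij > 0.0:
        if r >= rc:
            return 0.0
        u, _ = _lj(r, eps_ij)
        uc, duc = _lj(rc, eps_ij)
        return u - uc - (r - rc) * duc
    if r >= WCA_CUTOFF:
        return 0.0
    u, _ = _lj(r, 1.0)
    return u + 1.0  # shift so U(2^(1/6)) = 0


def pair_force(r: float, eps_ij: float, rc: float = 2.5) -> float:
    """-dU/dr of :func:`pair_energy` (positive = repulsive)."""
    if r <= 0:
        raise ValueError("pair distance must be positive (bead overlap)")
    if eps_ij > 0.0:
        if r >= rc:
            return 0.0
        _, dudr = _lj(r, eps_ij)
        _, duc = _lj(rc, eps_ij)
        return -(dudr - duc)
    if r >= WCA_CUTOFF:
        return 0.0
    _, dudr = _lj(r, 1.0)
    return -dudr
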