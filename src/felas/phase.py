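"""Slab-method phase coexistence and critical-point extrapolation.

A condensed slab coexisting with vapor in an elongated box yields a density
profile rho(x) with two plateaus.  Each temperature gives one coexistence
point (T, rho_l, rho_v); the critical point is extrapolated with the law of
rectilinear diameters together with the Ising-universality scaling of the
order parameter,

    (rho_l + rho_v)/2 = rho_c + A (T_c - T)
    rho_l - rho_v     = drho0 (1 - T/T_c)^beta,   beta = 0.325 (fixed)

fitted jointly by least squares.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit, least_squares

from .engine import Trajectory

__all__ = [
    "DensityProfile",
    "CoexistencePoint",
    "CriticalFit",
    "density_profile",
    "fit_coexistence",
    "fit_critical_point",
    "ISING_BETA",
]

ISING_BETA = 0.325


class FitConvergenceError(RuntimeError):
    pass


@dataclass
class DensityProfile:
    bin_centers: np.ndarray   # sigma, along the slab axis
    density: np.ndarray       # beads / sigma^3
    temperature: float = np.nan


@dataclass
class CoexistencePoint:
    T: float
    rho_liquid: float
    rho_vapor: float

    def __post_init__(self) -> None:
        if not self.rho_liquid > self.rho_vapor >= 0:
            raise ValueError("need rho_liquid > rho_vapor >= 0")


@dataclass
class CriticalFit:
    Tc: float
    rho_c: float
    A: float
    delta_rho0: float
    beta: float = ISING_BETA
    stderr: dict | None = None

    def binodal(self, T: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Model (rho_v, rho_l) at temperatures T below Tc."""
        T = np.asarray(T, dtype=float)
        mid = self.rho_c + self.A * (self.Tc - T)
        half = 0.5 * self.delta_rho0 * np.clip(1 - T / self.Tc, 0, None) ** self.beta
        return mid - half, mid + half


def density_profile(
    trajectory: Trajectory,
    axis: int = 0,
    n_bins: int = 50,
    frames: slice | np.ndarray | None = None,
    temperature: float = np.nan,
    recenter: bool = True,
) -> DensityProfile:
    """Time-averaged number-density profile along the elongated axis.

    Each frame is recentred so the periodic center of mass along the axis
    sits at the box center (circular-mean recentring), which keeps a
    drifting slab's plateaus sharp under time averaging.
    """
    if frames is None:
        frames = slice(None)
    pos = trajectory.positions[frames]
    if pos.shape[0] == 0:
        raise ValueError("empty frame selection")
    box = trajectory.box
    L = box[axis]
    area = float(np.prod(np.delete(box, axis)))
    bin_width = L / n_bins
    edges = np.linspace(0.0, L, n_bins + 1)
    hist = np.zeros(n_bins)
    for f in range(pos.shape[0]):
        xw = pos[f, :, axis] % L
        if recenter:
            ang = xw * (2 * np.pi / L)
            com = np.arctan2(np.sin(ang).mean(), np.cos(ang).mean()) * L / (2 * np.pi)
            xw = (xw - com + L / 2.0) % L
        hist += np.histogram(xw, bins=edges)[0]
    rho = hist / (pos.shape[0] * area * bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return DensityProfile(bin_centers=centers, density=rho, temperature=temperature)


def _tanh_profile(x, rho_l, rho_v, x0, w, d):
    return 0.5 * (rho_l + rho_v) - 0.5 * (rho_l - rho_v) * np.tanh(
        (np.abs(x - x0) - w) / d
    )


def fit_coexistence(profile: DensityProfile) -> CoexistencePoint:
    """Fit the symmetric tanh interface form and return plateau densities."""
    x = profile.bin_centers
    rho = profile.density
    lo, hi = np.percentile(rho, [10, 90])
    peak = float(rho.max())
    if hi - lo < 0.05 * max(hi, 1e-12) or hi <= 0:
        raise FitConvergenceError("profile has no distinguishable plateaus")
    x0_guess = float(x[np.argmax(rho)])
    span = x[-1] - x[0]
    # slab half-width guess from the region above the mid density
    mid = 0.5 * (hi + lo)
    w_guess = max(0.5 * np.sum(rho > mid) * (x[1] - x[0]), span / 50.0)
    p0 = [hi, max(lo, 1e-6), x0_guess, w_guess, span / 40.0]
    try:
        # rho_l bounded near the observed maximum so a narrow slab cannot
        # drive the plateau estimate above anything actually sampled
        popt, _ = curve_fit(
            _tanh_profile, x, rho, p0=p0,
            bounds=([0.5 * hi, 0, x[0], 0, 1e-6],
                    [1.1 * peak, hi, x[-1], span, span]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        raise FitConvergenceError(f"interface fit failed: {exc}") from exc
    rho_l, rho_v = popt[0], popt[1]
    if rho_l <= rho_v:
        raise FitConvergenceError("fit collapsed: no liquid/vapor contrast")
    return CoexistencePoint(T=profile.temperature, rho_liquid=float(rho_l),
                            rho_vapor=float(rho_v))


def fit_critical_point(
    points: list[CoexistencePoint],
    beta: float = ISING_BETA,
    weights: np.ndarray | None = None,
) -> CriticalFit:
    """Joint least-squares fit of diameter and order-parameter relations.

    Parameters (Tc, rho_c, A, drho0) are fitted simultaneously to the
    rectilinear-diameter line and the scaling of rho_l - rho_v; ``beta``
    stays frozen unless overridden.  Needs at least 3 points below Tc.
    """
    if len(points) < 3:
        raise ValueError("need at least 3 coexistence points")
    pts = sorted(points, key=lambda p: p.T)
    T = np.array([p.T for p in pts])
    mid = np.array([0.5 * (p.rho_liquid + p.rho_vapor) for p in pts])
    dif = np.array([p.rho_liquid - p.rho_vapor for p in pts])
    if weights is None:
        w = np.ones_like(T)
    else:
        w = np.asarray(weights, dtype=float)

    def residuals(p):
        Tc, rho_c, A, drho0 = p
        red = 1.0 - T / Tc
        red = np.where(red > 0, red, 1e-12)
        r1 = (mid - (rho_c + A * (Tc - T))) * w
        r2 = (dif - drho0 * red ** beta) * w
        return np.concatenate([r1, r2])

    Tc0 = T.max() * 1.1
    p0 = [Tc0, mid.min(), max((mid[0] - mid[-1]) / (T[-1] - T[0] + 1e-12), 1e-3),
          dif.max()]
    # Tc is only resolvable near the ladder: cap the extrapolation at
    # 1.5x the highest fitted temperature (ladders are expected to bracket
    # the critical region, as in standard slab practice)
    sol = least_squares(residuals, p0,
                        bounds=([T.max() * 1.0001, 0, -np.inf, 0],
                                [T.max() * 1.5, np.inf, np.inf, np.inf]))
    if not sol.success:
        raise FitConvergenceError("critical-point fit did not converge")
    Tc, rho_c, A, drho0 = sol.x
    # asymptotic parameter uncertainties from the Jacobian
    stderr = None
    try:
        jtj = sol.jac.T @ sol.jac
        dof = max(len(sol.fun) - 4, 1)
        cov = np.linalg.inv(jtj) * 2 * sol.cost / dof
        se = np.sqrt(np.diag(cov))
        stderr = {"Tc": se[0], "rho_c": se[1], "A": se[2], "delta_rho0": se[3]}
    except np.linalg.LinAlgError:
        pass
    return CriticalFit(Tc=float(Tc), rho_c=float(rho_c), A=float(A),
                       delta_rho0=float(drho0), beta=beta, stderr=stderr)
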