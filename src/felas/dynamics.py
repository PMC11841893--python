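"""Time-dependent observables: MSD, self-van Hove, contact autocorrelation.

MSD follows <dr^2(t)> = D t^alpha with the exponent fitted on a log-log
window; simple diffusion gives alpha = 1, condensate beads subdiffuse.
The self-van Hove G_s(r, t) is the distribution of displacement magnitudes
over lag t; for Gaussian dynamics G_s ∝ exp(-r^2 / W(t)) with W(t) = 4 D t
for free 3-D diffusion (per-axis variance W/2, so <r^2> = 3 W / 2).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import cKDTree
from scipy.stats import chi, linregress

from .engine import Trajectory

__all__ = [
    "MsdCurve",
    "VanHoveSet",
    "msd",
    "fit_msd_exponent",
    "van_hove_self",
    "contact_autocorrelation",
]


@dataclass
class MsdCurve:
    lag_times: np.ndarray
    msd: np.ndarray
    selection: str = "all"
    alpha_fit: float = np.nan
    d_fit: float = np.nan
    fit_window: tuple[float, float] | None = None


@dataclass
class VanHoveSet:
    lag_times: np.ndarray
    r_grid: np.ndarray
    gs: np.ndarray                 # (n_lags, n_bins) density of |dr|
    gaussian_widths: np.ndarray    # W(t) per lag
    gaussian_ok: np.ndarray        # bool per lag
    tail_excess: np.ndarray | None = None


def _positions(trajectory, selection):
    if isinstance(trajectory, Trajectory):
        pos = trajectory.positions
        times = trajectory.times
    else:
        pos, times = trajectory
    pos = np.asarray(pos, dtype=float)
    if selection is not None:
        pos = pos[:, selection]
    return pos, np.asarray(times, dtype=float)


def _msd_fft(pos: np.ndarray) -> np.ndarray:
    """Multi-origin MSD via the FFT autocorrelation identity, all lags."""
    f, n, _ = pos.shape
    nfft = 1 << (2 * f - 1).bit_length()
    msd_out = np.zeros(f)
    s2 = np.sum(pos ** 2, axis=2)             # (F, N)
    # S1 recursion and S2 from FFT, per particle, vectorized over particles
    fts = np.fft.rfft(pos, n=nfft, axis=0)
    acf = np.fft.irfft(np.sum(fts * fts.conj(), axis=2), n=nfft, axis=0)[:f]
    counts = f - np.arange(f)
    sq = s2.sum(axis=0)
    s1 = np.empty((f, n))
    running = 2.0 * sq
    s1[0] = running
    for m in range(1, f):
        running -= s2[m - 1] + s2[f - m]
        s1[m] = running
    msd_per = (s1 - 2.0 * acf.real) / counts[:, None]
    return msd_per.mean(axis=1)


def msd(
    trajectory,
    selection: np.ndarray | None = None,
    multi_origin: bool = True,
    log_base: float = 1.2,
    selection_label: str = "all",
) -> MsdCurve:
    """Particle-averaged mean squared displacement on a log-spaced lag grid.

    Requires unwrapped coordinates.  With ``multi_origin`` every frame is a
    time origin (FFT algorithm); otherwise displacements are measured from
    the first frame only.
    """
    pos, times = _positions(trajectory, selection)
    f = pos.shape[0]
    if f < 2:
        raise ValueError("need at least two frames")
    if multi_origin:
        full = _msd_fft(pos)
    else:
        d = pos - pos[0]
        full = np.sum(d * d, axis=2).mean(axis=1)
    # log-spaced subset of integer lags
    lags = [0]
    lag = 1
    while lag < f:
        lags.append(int(lag))
        lag = max(lag + 1, int(np.ceil(lag * log_base)))
    lags = np.unique(lags)
    dt = times[1] - times[0]
    return MsdCurve(
        lag_times=lags * dt, msd=full[lags], selection=selection_label
    )


def fit_msd_exponent(
    curve: MsdCurve, window: tuple[float, float]
) -> tuple[float, float]:
    """Log-log least-squares slope alpha of the MSD over a lag-time window.

    Also stores (alpha, D) on the curve; returns (alpha, stderr).
    """
    t = curve.lag_times
    m = curve.msd
    sel = (t >= window[0]) & (t <= window[1]) & (t > 0) & (m > 0)
    if sel.sum() < 5:
        raise ValueError("need at least 5 positive points inside the window")
    res = linregress(np.log(t[sel]), np.log(m[sel]))
    curve.alpha_fit = float(res.slope)
    curve.d_fit = float(np.exp(res.intercept))
    curve.fit_window = window
    return float(res.slope), float(res.stderr)


def van_hove_self(
    trajectory,
    selection: np.ndarray | None = None,
    lags: np.ndarray | None = None,
    r_grid: np.ndarray | None = None,
    tail_factor: float = 2.0,
    tail_tolerance: float = 3.0,
) -> VanHoveSet:
    """Self-part of the van Hove function at the requested integer lags.

    ``gs[l]`` is the probability density of the displacement magnitude
    (so it integrates to 1 over the r grid; the angular 4 pi r^2 factor is
    already absorbed).  Each lag gets a Gaussian width from the second
    moment, W = (2/3) <r^2>, and a Gaussianity verdict: the observed tail
    mass beyond ``tail_factor`` times the rms displacement must not exceed
    ``tail_tolerance`` times the Gaussian expectation.
    """
    pos, times = _positions(trajectory, selection)
    f = pos.shape[0]
    if lags is None:
        lags = np.unique(np.geomspace(1, f - 1, 8).astype(int))
    lags = np.asarray(lags, dtype=int)
    if lags.size == 0:
        raise ValueError("empty lag selection")
    dt = times[1] - times[0] if f > 1 else 1.0

    all_disp = []
    for lag in lags:
        d = pos[lag:] - pos[:-lag] if lag > 0 else np.zeros_like(pos)
        all_disp.append(np.linalg.norm(d.reshape(-1, 3), axis=1))
    if r_grid is None:
        r_hi = max(float(np.percentile(all_disp[-1], 99.9)) * 1.5, 1e-6)
        r_grid = np.linspace(0, r_hi, 120)

    n_bins = len(r_grid) - 1
    gs = np.zeros((len(lags), n_bins))
    widths = np.zeros(len(lags))
    ok = np.zeros(len(lags), dtype=bool)
    excess = np.zeros(len(lags))
    # chi distribution with 3 dof: |dr|/sigma_1d for Gaussian displacements
    for li, disp in enumerate(all_disp):
        hist, edges = np.histogram(disp, bins=r_grid, density=True)
        gs[li] = hist
        mean_sq = float(np.mean(disp ** 2))
        widths[li] = 2.0 * mean_sq / 3.0  # W: per-axis variance W/2
        sigma1d = np.sqrt(mean_sq / 3.0) if mean_sq > 0 else 0.0
        if sigma1d == 0.0:
            ok[li] = True
            continue
        r_star = tail_factor * np.sqrt(mean_sq)
        expected = chi.sf(r_star / sigma1d, df=3)
        observed = float(np.mean(disp > r_star))
        excess[li] = observed / expected if expected > 0 else np.inf
        ok[li] = observed <= tail_tolerance * expected + 1e-12
    return VanHoveSet(
        lag_times=lags * dt, r_grid=r_grid, gs=gs,
        gaussian_widths=widths, gaussian_ok=ok, tail_excess=excess,
    )


def contact_autocorrelation(
    trajectory,
    cutoff: float = 1.5,
    selection: np.ndarray | None = None,
    box: np.ndarray | None = None,
    max_lag: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """C(t) = <h_ij(0) h_ij(t)> / <h_ij(0)> over selected-bead pairs.

    h_ij is the contact indicator at ``cutoff`` (minimum image); every frame
    serves as a time origin.  Pairs never in contact contribute nothing
    (they drop out of both numerator and denominator).
    """
    if isinstance(trajectory, Trajectory):
        pos = trajectory.positions
        box = trajectory.box
        times = trajectory.times
    else:
        pos, times = trajectory
        if box is None:
            raise ValueError("box required for raw-array input")
    pos = np.asarray(pos, dtype=float)
    box = np.asarray(box, dtype=float)
    if selection is not None:
        pos = pos[:, selection]
    f, n, _ = pos.shape
    if f < 2:
        raise ValueError("need at least two frames")
    if max_lag is None:
        max_lag = f - 1

    # indicator matrix over pairs that are ever in contact
    pair_index: dict[tuple[int, int], int] = {}
    frame_pairs = []
    for t in range(f):
        r = pos[t] % box
        tree = cKDTree(r, boxsize=box)
        pr = tree.query_pairs(cutoff)
        frame_pairs.append(pr)
        for p in pr:
            if p not in pair_index:
                pair_index[p] = len(pair_index)
    if not pair_index:
        raise ValueError("no contacts found at any frame")
    h = np.zeros((f, len(pair_index)), dtype=bool)
    for t, pr in enumerate(frame_pairs):
        for p in pr:
            h[t, pair_index[p]] = True

    dt = times[1] - times[0] if f > 1 else 1.0
    lags = np.arange(max_lag + 1)
    c = np.empty(len(lags))
    for i, lag in enumerate(lags):
        h0 = h[: f - lag]
        ht = h[lag:]
        denom = h0.sum()
        c[i] = (h0 & ht).sum() / denom if denom > 0 else np.nan
    return lags * dt, c
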