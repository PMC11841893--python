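"""Static structure of condensates: S(q), g(r), contacts, chain stiffness,
PBC-aware sticker clustering and gyration-tensor shape metrics.

Shape conventions: for a cluster with gyration tensor Q (second moment of
member coordinates about the cluster COM), the traceless part is
Qhat = Q - (TrQ/3) I and

    Delta = (3/2) Tr(Qhat^2) / (TrQ)^2          asphericity, 2*Delta in [0, 2]
    Xi    = 4 Det(Qhat) / ((2/3) Tr(Qhat^2))^{3/2}   in [-1, 1]

A rigid rod gives 2*Delta = 2, Xi = +1 (prolate); a uniform disk gives
Xi = -1 (oblate); an isotropic cloud gives Delta = 0.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree
from scipy.stats import linregress

from .engine import Trajectory

__all__ = [
    "StructureFactorCurve",
    "ClusterShape",
    "ClusterCensus",
    "structure_factor",
    "radial_distribution",
    "contact_map",
    "tangent_correlation",
    "persistence_length_fit",
    "find_clusters",
    "shape_metrics",
    "gyration_tensor",
    "density_sweep_census",
]


@dataclass
class StructureFactorCurve:
    q: np.ndarray
    s_of_q: np.ndarray
    selection: str = "all"


@dataclass
class ClusterShape:
    members: np.ndarray
    gyration_tensor: np.ndarray
    principal: np.ndarray      # eigenvalues of Q, ascending (R^g_ii components)
    rg: float
    delta: float
    xi: float
    percolated: bool = False


@dataclass
class ClusterCensus:
    n_clusters: int
    mean_occupancy: float
    percolated: bool
    rg_histogram: tuple[np.ndarray, np.ndarray] | None = None


def _frames_array(trajectory, frames):
    if isinstance(trajectory, Trajectory):
        pos = trajectory.positions
        box = trajectory.box
    else:
        pos, box = trajectory
        pos = np.asarray(pos, dtype=float)
        if pos.ndim == 2:
            pos = pos[None]
        box = np.asarray(box, dtype=float)
    if frames is not None:
        pos = pos[frames]
    return pos, box


def structure_factor(
    trajectory,
    selection: np.ndarray | None = None,
    q_max: float = 6.0,
    n_bins: int | None = None,
    frames=None,
    selection_label: str = "all",
) -> StructureFactorCurve:
    """Frame-averaged S(q) = <|sum_j exp(i q.r_j)|^2>/N on the reciprocal
    lattice q = 2 pi (nx, ny, nz)/L, spherically binned by |q|."""
    pos, box = _frames_array(trajectory, frames)
    if pos.shape[0] < 1:
        raise ValueError("need at least one frame")
    q_min = 2 * np.pi / np.max(box)
    if q_max < q_min:
        raise ValueError("q_max below the smallest lattice wavevector 2*pi/L")
    n_max = np.floor(q_max * box / (2 * np.pi)).astype(int)
    grids = [np.arange(-m, m + 1) for m in n_max]
    nx, ny, nz = np.meshgrid(*grids, indexing="ij")
    qvecs = 2 * np.pi * np.column_stack(
        [nx.ravel() / box[0], ny.ravel() / box[1], nz.ravel() / box[2]]
    )
    qnorm = np.linalg.norm(qvecs, axis=1)
    keep = (qnorm > 1e-12) & (qnorm <= q_max)
    qvecs, qnorm = qvecs[keep], qnorm[keep]

    if selection is None:
        selection = np.arange(pos.shape[1])
    nsel = len(selection)
    if nsel == 0:
        raise ValueError("empty selection")
    s_accum = np.zeros(qvecs.shape[0])
    for f in range(pos.shape[0]):
        r = pos[f, selection]
        phases = r @ qvecs.T
        amp = np.exp(1j * phases).sum(axis=0)
        s_accum += (amp * amp.conj()).real / nsel
    s_accum /= pos.shape[0]

    if n_bins is None:
        n_bins = max(int(q_max / (2 * np.pi / np.max(box))), 10)
    edges = np.linspace(0, q_max, n_bins + 1)
    which = np.digitize(qnorm, edges) - 1
    q_out, s_out = [], []
    for b in range(n_bins):
        m = which == b
        if m.any():
            q_out.append(qnorm[m].mean())
            s_out.append(s_accum[m].mean())
    return StructureFactorCurve(
        q=np.array(q_out), s_of_q=np.array(s_out), selection=selection_label
    )


def radial_distribution(
    trajectory,
    selection: np.ndarray | None = None,
    r_max: float = 5.0,
    dr: float = 0.05,
    frames=None,
) -> tuple[np.ndarray, np.ndarray]:
    """Pair distribution g(r) with ideal-gas shell normalization under PBC."""
    pos, box = _frames_array(trajectory, frames)
    if r_max > np.min(box) / 2:
        raise ValueError("r_max exceeds half the smallest box length")
    if selection is None:
        selection = np.arange(pos.shape[1])
    n = len(selection)
    edges = np.arange(0.0, r_max + dr, dr)
    hist = np.zeros(len(edges) - 1)
    volume = float(np.prod(box))
    for f in range(pos.shape[0]):
        r = pos[f, selection] % box
        tree = cKDTree(r, boxsize=box)
        pairs = tree.query_pairs(r_max, output_type="ndarray")
        if len(pairs):
            d = r[pairs[:, 0]] - r[pairs[:, 1]]
            d -= box * np.round(d / box)
            hist += np.histogram(np.linalg.norm(d, axis=1), bins=edges)[0]
    shell = 4.0 / 3.0 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
    ideal = 0.5 * n * (n - 1) / volume * shell * pos.shape[0]
    centers = 0.5 * (edges[1:] + edges[:-1])
    with np.errstate(invalid="ignore", divide="ignore"):
        g = np.where(ideal > 0, hist / ideal, 0.0)
    return centers, g


def contact_map(
    trajectory: Trajectory,
    cutoff: float = 2.0,
    frames=None,
) -> np.ndarray:
    """Average number of residue-residue contacts per chain per frame.

    Bead pairs (any chains) closer than ``cutoff`` under minimum image are
    binned by their residue indices (i, j); the symmetric matrix is
    normalized by n_frames * n_chains, so the bonded super-diagonal sits
    near one.
    """
    pos = trajectory.positions if frames is None else trajectory.positions[frames]
    box = trajectory.box
    topo = trajectory.topology
    np_res = topo.chain_length
    counts = np.zeros((np_res, np_res))
    for f in range(pos.shape[0]):
        r = pos[f] % box
        tree = cKDTree(r, boxsize=box)
        pairs = tree.query_pairs(cutoff, output_type="ndarray")
        if len(pairs) == 0:
            continue
        ri = topo.bead_type[pairs[:, 0]]
        rj = topo.bead_type[pairs[:, 1]]
        np.add.at(counts, (ri, rj), 1.0)
        np.add.at(counts, (rj, ri), 1.0)
    return counts / (pos.shape[0] * topo.n_chains)


def tangent_correlation(
    trajectory: Trajectory,
    grouping: str = "all",
    frames=None,
    max_lag: int | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """<t_i . t_{i+s}> vs contour separation s (bonds), chain/frame averaged.

    ``grouping`` restricts the *first* bond of each pair by the stickiness
    class of its starting bead: "all", "sticker" or "spacer" (requires the
    trajectory to carry its pattern).
    """
    pos = trajectory.positions if frames is None else trajectory.positions[frames]
    topo = trajectory.topology
    nb = topo.chain_length - 1  # bonds per chain
    if nb < 2:
        raise ValueError("chains must have length >= 3")
    if max_lag is None:
        max_lag = nb - 1
    mask = np.ones(nb, dtype=bool)
    if grouping != "all":
        if trajectory.pattern is None:
            raise ValueError("grouping by stickiness needs a pattern")
        sticker = trajectory.pattern.is_sticker[:nb]
        mask = sticker if grouping == "sticker" else ~sticker
    corr = np.zeros(max_lag + 1)
    norm = np.zeros(max_lag + 1)
    for f in range(pos.shape[0]):
        p = pos[f].reshape(topo.n_chains, topo.chain_length, 3)
        bonds = p[:, 1:] - p[:, :-1]
        t = bonds / np.linalg.norm(bonds, axis=2, keepdims=True)
        for s in range(max_lag + 1):
            if s == 0:
                dots = np.einsum("cbk,cbk->cb", t, t)[:, mask]
            else:
                dots = np.einsum("cbk,cbk->cb", t[:, :-s], t[:, s:])[:, mask[:nb - s]]
            corr[s] += dots.sum()
            norm[s] += dots.size
    return np.arange(max_lag + 1), corr / np.maximum(norm, 1)


def persistence_length_fit(
    s: np.ndarray,
    correlation: np.ndarray,
    window: tuple[int, int] | None = None,
    mean_bond_length: float = 1.0,
) -> tuple[float, float, float]:
    """Persistence length from the log-linear decay of <t.t>(s).

    Returns (lp in sigma, stderr, R^2).  Non-positive correlations inside
    the window are dropped with a warning-by-shrink; fewer than 4 usable
    points is an error.  A low R^2 signals non-exponential (e.g. folded-
    domain, anti-correlated) decay and the caller should treat lp as
    unreliable.
    """
    s = np.asarray(s, dtype=float)
    c = np.asarray(correlation, dtype=float)
    if window is not None:
        m = (s >= window[0]) & (s <= window[1])
        s, c = s[m], c[m]
    pos_mask = c > 0
    s, c = s[pos_mask], c[pos_mask]
    if len(s) < 4:
        raise ValueError("fewer than 4 positive-correlation points to fit")
    res = linregress(s, np.log(c))
    if res.slope >= 0:
        raise ValueError("correlation does not decay; no persistence length")
    lp = -1.0 / res.slope * mean_bond_length
    stderr = res.stderr / res.slope ** 2 * mean_bond_length
    return float(lp), float(stderr), float(res.rvalue ** 2)


def gyration_tensor(points: np.ndarray) -> np.ndarray:
    """Second-moment tensor Q = <(r - com)(r - com)^T> of a point cloud."""
    r = np.asarray(points, dtype=float)
    d = r - r.mean(axis=0)
    return d.T @ d / len(r)


def shape_metrics(points_or_q: np.ndarray) -> tuple[float, float, np.ndarray]:
    """(Delta, Xi, principal components) from points or a 3x3 tensor.

    A (3, 3) input is read as a gyration tensor only if it is symmetric;
    otherwise it is three points.
    """
    q = np.asarray(points_or_q, dtype=float)
    if q.shape != (3, 3) or not np.allclose(q, q.T, rtol=1e-10, atol=1e-12):
        q = gyration_tensor(q)
    tr = np.trace(q)
    if tr <= 0:
        raise ValueError("degenerate cluster: zero gyration tensor trace")
    qhat = q - tr / 3.0 * np.eye(3)
    tr_qhat2 = float(np.sum(qhat * qhat))
    delta = 1.5 * tr_qhat2 / tr ** 2
    if tr_qhat2 > 1e-300:
        xi = 4.0 * float(np.linalg.det(qhat)) / ((2.0 / 3.0) * tr_qhat2) ** 1.5
    else:
        xi = 0.0
    principal = np.sort(np.linalg.eigvalsh(q))
    return float(delta), float(np.clip(xi, -1.0, 1.0)), principal


def _unwrap_cluster(wrapped: np.ndarray, members: np.ndarray,
                    adjacency: dict, box: np.ndarray) -> tuple[np.ndarray, bool]:
    """Minimum-image BFS unwrap of one cluster; detects percolation when a
    member is reachable with two inconsistent periodic images."""
    unw = {}
    seed = members[0]
    unw[seed] = wrapped[seed].copy()
    stack = [seed]
    percolated = False
    while stack:
        i = stack.pop()
        for j in adjacency.get(i, ()):
            d = wrapped[j] - wrapped[i]
            d -= box * np.round(d / box)
            cand = unw[i] + d
            if j in unw:
                if not np.allclose(cand, unw[j], atol=1e-6):
                    percolated = True
            else:
                unw[j] = cand
                stack.append(j)
    coords = np.array([unw[i] for i in members])
    return coords, percolated


def find_clusters(
    frame: np.ndarray,
    box: np.ndarray,
    selection: np.ndarray | None = None,
    cutoff: float = 1.5,
    rg_bins: int = 20,
) -> tuple[ClusterCensus, list[ClusterShape]]:
    """Single-linkage clusters of the selected beads under minimum image.

    Per-cluster gyration tensors are computed on BFS-unwrapped coordinates;
    clusters connecting to their own periodic image are flagged percolated
    (their shape metrics are still reported but not meaningful).
    """
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    pos = np.asarray(frame, dtype=float)
    box = np.asarray(box, dtype=float)
    if selection is None:
        selection = np.arange(pos.shape[0])
    sel_pos = pos[selection] % box
    n = len(sel_pos)
    tree = cKDTree(sel_pos, boxsize=box)
    pairs = tree.query_pairs(cutoff, output_type="ndarray")
    if len(pairs):
        graph = coo_matrix(
            (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1])), shape=(n, n)
        )
        n_comp, labels = connected_components(graph, directed=False)
    else:
        n_comp, labels = n, np.arange(n)
    adjacency: dict[int, list[int]] = {}
    for a, b in pairs:
        adjacency.setdefault(int(a), []).append(int(b))
        adjacency.setdefault(int(b), []).append(int(a))

    shapes: list[ClusterShape] = []
    any_perc = False
    occupancies = []
    rgs = []
    for c in range(n_comp):
        members = np.flatnonzero(labels == c)
        occupancies.append(len(members))
        if len(members) < 2:
            continue
        coords, perc = _unwrap_cluster(sel_pos, members, adjacency, box)
        any_perc = any_perc or perc
        q = gyration_tensor(coords)
        rg = float(np.sqrt(np.trace(q)))
        rgs.append(rg)
        try:
            delta, xi, principal = shape_metrics(q)
        except ValueError:
            delta, xi, principal = np.nan, np.nan, np.zeros(3)
        shapes.append(
            ClusterShape(
                members=selection[members], gyration_tensor=q,
                principal=principal, rg=rg, delta=delta, xi=xi,
                percolated=perc,
            )
        )
    hist = None
    if rgs:
        hist = np.histogram(rgs, bins=rg_bins)
    census = ClusterCensus(
        n_clusters=n_comp,
        mean_occupancy=float(np.mean(occupancies)) if occupancies else 0.0,
        percolated=any_perc,
        rg_histogram=hist,
    )
    return census, shapes


def density_sweep_census(
    frames_by_density: dict[float, list[tuple[np.ndarray, np.ndarray]]],
    selection: np.ndarray | None = None,
    cutoff: float = 1.5,
    min_size: int = 2,
    aspect_threshold: float = 6.0,
) -> pd.DataFrame:
    """Cluster census across a density sweep.

    ``frames_by_density`` maps number density rho to a list of (frame
    positions, box) tuples.  Returns per-density means and standard errors
    of the cluster count n_c, mean occupancy n_d and the sorted principal
    gyration components, plus a sphere-to-elongated transition flag: mean
    largest principal component exceeding ``aspect_threshold`` times the
    mean smallest one (finite clusters always split somewhat through
    eigenvalue ordering, so the threshold sits well above the isotropic
    small-sample baseline of ~2-3).
    """
    rows = []
    for rho in sorted(frames_by_density):
        ncs, nds, p_lo, p_hi, perc = [], [], [], [], []
        for frame, box in frames_by_density[rho]:
            census, shapes = find_clusters(frame, box, selection, cutoff)
            sized = [s for s in shapes if len(s.members) >= min_size]
            ncs.append(len(sized))
            if sized:
                nds.append(np.mean([len(s.members) for s in sized]))
                p_lo.extend(s.principal[0] for s in sized if not s.percolated)
                p_hi.extend(s.principal[2] for s in sized if not s.percolated)
            perc.append(census.percolated)

        def mse(v):
            v = np.asarray(v, dtype=float)
            if v.size == 0:
                return np.nan, np.nan
            if v.size == 1:
                return float(v.mean()), np.nan
            return float(v.mean()), float(v.std(ddof=1) / np.sqrt(v.size))

        nc_m, nc_s = mse(ncs)
        nd_m, nd_s = mse(nds)
        lo_m, lo_s = mse(p_lo)
        hi_m, hi_s = mse(p_hi)
        split = False
        if np.isfinite(lo_m) and np.isfinite(hi_m) and lo_m > 0:
            split = hi_m > aspect_threshold * lo_m
        rows.append(
            dict(rho=rho, n_c=nc_m, n_c_sem=nc_s, n_d=nd_m, n_d_sem=nd_s,
                 principal_min=lo_m, principal_max=hi_m,
                 elongated=bool(split), percolated=bool(np.any(perc)))
        )
    return pd.DataFrame(rows)
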