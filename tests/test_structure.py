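"""Static structure: S(q), g(r), contacts, stiffness, clusters, shapes."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from felas.engine import Topology, Trajectory
from felas.fixtures import gen_cluster_field, gen_wlc
from felas.structure import (
    contact_map,
    density_sweep_census,
    find_clusters,
    gyration_tensor,
    persistence_length_fit,
    radial_distribution,
    shape_metrics,
    structure_factor,
    tangent_correlation,
)


def _single_frame_traj(pos, box_len, n_chains=None, chain_length=None):
    n = pos.shape[0]
    if chain_length is None:
        chain_length = 1 if n_chains is None else n // n_chains
    n_chains = n // chain_length
    return Trajectory(times=np.zeros(1), positions=pos[None],
                      box=np.full(3, float(box_len)),
                      topology=Topology.linear(n_chains, chain_length))


class TestStructureFactor:
    def test_matches_bruteforce_double_sum(self, rng):
        n, L = 60, 8.0
        pos = rng.random((n, 3)) * L
        traj = _single_frame_traj(pos, L)
        curve = structure_factor(traj, q_max=4.0, n_bins=8)
        # brute force over the same lattice vectors, same binning
        m = int(np.floor(4.0 * L / (2 * np.pi)))
        qs, ss = [], []
        for nx in range(-m, m + 1):
            for ny in range(-m, m + 1):
                for nz in range(-m, m + 1):
                    q = 2 * np.pi * np.array([nx, ny, nz]) / L
                    qn = np.linalg.norm(q)
                    if qn < 1e-12 or qn > 4.0:
                        continue
                    amp = np.exp(1j * pos @ q).sum()
                    qs.append(qn)
                    ss.append(abs(amp) ** 2 / n)
        edges = np.linspace(0, 4.0, 9)
        which = np.digitize(qs, edges) - 1
        q_out, s_out = [], []
        for b in range(8):
            mask = which == b
            if mask.any():
                q_out.append(np.mean(np.array(qs)[mask]))
                s_out.append(np.mean(np.array(ss)[mask]))
        np.testing.assert_allclose(curve.q, q_out, rtol=1e-10)
        np.testing.assert_allclose(curve.s_of_q, s_out, rtol=1e-10)

    def test_ideal_gas_plateau_near_one(self, rng):
        n, L = 800, 12.0
        pos = rng.random((10, n, 3)) * L
        traj = Trajectory(times=np.arange(10.0), positions=pos,
                          box=np.full(3, L), topology=Topology.linear(n, 1))
        curve = structure_factor(traj, q_max=5.0)
        high = curve.q > 2.0
        assert np.abs(curve.s_of_q[high].mean() - 1.0) < 0.05

    def test_two_particles_orientation_averaged_form(self):
        """S(q) = 1 + sin(qd)/(qd) after averaging over orientations."""
        L, d = 30.0, 2.0
        rng = np.random.default_rng(3)
        frames = []
        for _ in range(600):
            u = rng.standard_normal(3)
            u /= np.linalg.norm(u)
            c = rng.random(3) * L
            frames.append(np.stack([c - 0.5 * d * u, c + 0.5 * d * u]))
        traj = Trajectory(times=np.arange(len(frames), dtype=float),
                          positions=np.stack(frames), box=np.full(3, L),
                          topology=Topology.linear(2, 1))
        curve = structure_factor(traj, q_max=3.0, n_bins=10)
        expected = 1 + np.sin(curve.q * d) / (curve.q * d)
        np.testing.assert_allclose(curve.s_of_q, expected, atol=0.12)

    def test_cubic_lattice_bragg_peak(self):
        a, m = 2.0, 5
        g = np.arange(m) * a
        pos = np.array(np.meshgrid(g, g, g)).reshape(3, -1).T
        traj = _single_frame_traj(pos, m * a)
        curve = structure_factor(traj, q_max=3.5, n_bins=40)
        peak_q = curve.q[np.argmax(curve.s_of_q)]
        assert peak_q == pytest.approx(2 * np.pi / a, rel=0.05)

    def test_qmax_below_lattice_spacing_rejected(self):
        traj = _single_frame_traj(np.zeros((2, 3)) + 1.0, 10.0)
        with pytest.raises(ValueError):
            structure_factor(traj, q_max=0.1)


class TestRadialDistribution:
    def test_matches_bruteforce_histogram(self, rng):
        n, L = 100, 10.0
        pos = rng.random((n, 3)) * L
        traj = _single_frame_traj(pos, L)
        r, g = radial_distribution(traj, r_max=4.0, dr=0.2)
        edges = np.arange(0, 4.2, 0.2)
        hist = np.zeros(len(edges) - 1)
        for i in range(n):
            for j in range(i + 1, n):
                d = pos[i] - pos[j]
                d -= L * np.round(d / L)
                rr = np.linalg.norm(d)
                if rr < 4.0:
                    hist += np.histogram([rr], bins=edges)[0]
        shell = 4 / 3 * np.pi * (edges[1:] ** 3 - edges[:-1] ** 3)
        ideal = 0.5 * n * (n - 1) / L ** 3 * shell
        np.testing.assert_allclose(g, hist / ideal, rtol=1e-10)

    def test_ideal_gas_unity_and_rmax_guard(self, rng):
        n, L = 3000, 15.0
        pos = rng.random((4, n, 3)) * L
        traj = Trajectory(times=np.arange(4.0), positions=pos,
                          box=np.full(3, L), topology=Topology.linear(n, 1))
        r, g = radial_distribution(traj, r_max=6.0, dr=0.5)
        assert np.allclose(g[r > 1.0], 1.0, atol=0.05)
        with pytest.raises(ValueError):
            radial_distribution(traj, r_max=9.0)

    def test_hard_core_exclusion_zone(self):
        # two particles held at contact distance: nothing below it
        pos = np.array([[5.0, 5, 5], [6.2, 5, 5]])
        traj = _single_frame_traj(pos, 12.0)
        r, g = radial_distribution(traj, r_max=5.0, dr=0.1)
        assert np.all(g[r < 1.1] == 0)


class TestContactMap:
    def test_bonded_neighbors_always_in_contact(self):
        traj = gen_wlc(n_chains=4, n_beads=12, lp=3.0, seed=0)
        cm = contact_map(traj, cutoff=2.0)
        sup = np.diag(cm, k=1)
        assert np.all(sup >= 1.0 - 1e-12)

    def test_straight_separated_chains_have_no_long_range_contacts(self):
        length, n_chains = 12, 3
        pos = np.zeros((n_chains * length, 3))
        for c in range(n_chains):
            for b in range(length):
                pos[c * length + b] = [b * 1.0, c * 10.0, 0.0]
        traj = _single_frame_traj(pos + 1.0, 60.0, n_chains=n_chains)
        cm = contact_map(traj, cutoff=2.0)
        off = np.triu(cm, k=3)
        assert np.all(off == 0)

    def test_matches_bruteforce(self, rng):
        traj = gen_wlc(n_chains=2, n_beads=20, lp=1.5, seed=4)
        cm = contact_map(traj, cutoff=2.0)
        pos = traj.positions[0]
        topo = traj.topology
        ref = np.zeros((20, 20))
        box = traj.box
        n = pos.shape[0]
        for i in range(n):
            for j in range(i + 1, n):
                d = pos[i] - pos[j]
                d -= box * np.round(d / box)
                if np.linalg.norm(d) < 2.0:
                    ri, rj = topo.bead_type[i], topo.bead_type[j]
                    ref[ri, rj] += 1
                    ref[rj, ri] += 1
        np.testing.assert_allclose(cm, ref / 2.0, rtol=1e-12)


class TestTangentCorrelation:
    def test_rigid_rod_fully_correlated(self):
        pos = np.column_stack([np.arange(20.0), np.zeros(20), np.zeros(20)])
        traj = _single_frame_traj(pos + 5.0, 100.0, n_chains=1)
        s, c = tangent_correlation(traj)
        np.testing.assert_allclose(c, 1.0, atol=1e-12)

    def test_freely_jointed_chain_decorrelates(self):
        traj = gen_wlc(n_chains=100, n_beads=40, lp=1e-6, seed=2)
        s, c = tangent_correlation(traj)
        assert abs(c[1]) < 0.05 and abs(c[5]) < 0.05

    def test_wlc_sampler_persistence_length_recovered(self):
        traj = gen_wlc(n_chains=400, n_beads=100, lp=4.2, seed=8)
        s, c = tangent_correlation(traj)
        lp, err, r2 = persistence_length_fit(s[1:13], c[1:13])
        assert lp == pytest.approx(4.2, rel=0.05)
        assert r2 > 0.99


class TestPersistenceFit:
    def test_exact_exponential_roundtrip(self):
        s = np.arange(20)
        c = np.exp(-s / 5.0)
        lp, err, r2 = persistence_length_fit(s, c)
        assert lp == pytest.approx(5.0, abs=1e-6)
        assert r2 == pytest.approx(1.0)

    def test_oscillatory_folded_signal_flagged_by_low_r2(self):
        s = np.arange(30)
        c = np.exp(-s / 8.0) * (0.6 + 0.4 * np.cos(1.5 * s))
        lp, err, r2 = persistence_length_fit(s, c)
        assert r2 < 0.9

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            persistence_length_fit(np.arange(2), np.exp(-np.arange(2) / 3))


class TestClusters:
    def test_two_separated_blobs(self):
        pos, box = gen_cluster_field(n_clusters=2, cluster_size=15,
                                     box_length=40.0, seed=0)
        census, shapes = find_clusters(pos, box, cutoff=2.0)
        assert census.n_clusters == 2
        assert sorted(len(s.members) for s in shapes) == [15, 15]
        assert not census.percolated

    def test_line_spanning_box_percolates(self):
        L = 20.0
        n = 25
        pos = np.column_stack([np.arange(n) * (L / n),
                               np.full(n, 3.0), np.full(n, 3.0)])
        census, shapes = find_clusters(pos, np.full(3, L), cutoff=1.0)
        assert census.n_clusters == 1
        assert census.percolated

    def test_matches_bruteforce_connected_components(self, rng):
        n, L, cutoff = 300, 12.0, 1.2
        pos = rng.random((n, 3)) * L
        census, _ = find_clusters(pos, np.full(3, L), cutoff=cutoff)
        # O(N^2) union-find
        parent = list(range(n))

        def find(i):
            while parent[i] != i:
                parent[i] = parent[parent[i]]
                i = parent[i]
            return i

        for i in range(n):
            for j in range(i + 1, n):
                d = pos[i] - pos[j]
                d -= L * np.round(d / L)
                if np.linalg.norm(d) < cutoff:
                    parent[find(i)] = find(j)
        n_ref = len({find(i) for i in range(n)})
        assert census.n_clusters == n_ref

    def test_input_order_invariance(self, rng):
        pos, box = gen_cluster_field(n_clusters=4, cluster_size=10, seed=3)
        perm = rng.permutation(pos.shape[0])
        c1, _ = find_clusters(pos, box, cutoff=2.0)
        c2, _ = find_clusters(pos[perm], box, cutoff=2.0)
        assert c1.n_clusters == c2.n_clusters
        assert c1.mean_occupancy == pytest.approx(c2.mean_occupancy)


class TestShapeMetrics:
    def test_rod_limit(self):
        pos = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
        delta, xi, principal = shape_metrics(pos)
        assert 2 * delta == pytest.approx(2.0, abs=1e-12)
        assert xi == pytest.approx(1.0, abs=1e-12)
        assert principal[0] == pytest.approx(0.0, abs=1e-12)

    def test_isotropic_octahedron_is_spherical(self):
        pos = np.array([[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0],
                        [0, 0, 1], [0, 0, -1]], dtype=float)
        delta, xi, _ = shape_metrics(pos)
        assert delta == pytest.approx(0.0, abs=1e-12)

    def test_uniform_ring_is_oblate(self):
        t = np.linspace(0, 2 * np.pi, 200, endpoint=False)
        pos = np.column_stack([np.cos(t), np.sin(t), np.zeros_like(t)])
        delta, xi, _ = shape_metrics(pos)
        assert xi == pytest.approx(-1.0, abs=1e-9)

    def test_rotation_translation_invariance(self, rng):
        pos = rng.standard_normal((50, 3)) * [3.0, 1.0, 0.5]
        d0, x0, p0 = shape_metrics(pos)
        from scipy.spatial.transform import Rotation

        R = Rotation.random(random_state=7).as_matrix()
        pos2 = pos @ R.T + np.array([5.0, -2.0, 9.0])
        d1, x1, p1 = shape_metrics(pos2)
        assert d1 == pytest.approx(d0, rel=1e-10)
        assert x1 == pytest.approx(x0, rel=1e-10)
        np.testing.assert_allclose(p1, p0, rtol=1e-10)

    @given(st.integers(min_value=0, max_value=10_000))
    @settings(max_examples=100, deadline=None)
    def test_bounds_on_random_point_clouds(self, seed):
        rng = np.random.default_rng(seed)
        pos = rng.standard_normal((rng.integers(3, 30), 3))
        delta, xi, _ = shape_metrics(pos)
        assert -1e-12 <= 2 * delta <= 2 + 1e-12
        assert -1 - 1e-9 <= xi <= 1 + 1e-9

    def test_coincident_points_rejected(self):
        with pytest.raises(ValueError):
            shape_metrics(np.zeros((5, 3)))


class TestDensitySweep:
    def test_cluster_count_scales_with_density(self):
        frames = {}
        for rho_label, n_c in [(0.1, 2), (0.2, 4), (0.3, 6)]:
            pos, box = gen_cluster_field(n_clusters=n_c, cluster_size=12,
                                         box_length=60.0, seed=int(n_c))
            frames[rho_label] = [(pos, box)]
        df = density_sweep_census(frames, cutoff=2.0)
        assert list(df["n_c"]) == [2, 4, 6]
        assert not df["elongated"].any()

    def test_elongated_blobs_detected(self):
        pos, box = gen_cluster_field(n_clusters=4, cluster_size=60,
                                     cluster_radius=1.0, box_length=100.0,
                                     seed=5, elongation=6.0)
        df = density_sweep_census({0.2: [(pos, box)]}, cutoff=2.5)
        assert bool(df["elongated"].iloc[0])

    def test_percolated_slab_reported(self):
        L = 20.0
        xs = np.arange(0, L, 0.8)
        ys = np.arange(0, L, 0.8)
        g = np.array(np.meshgrid(xs, ys)).reshape(2, -1).T
        pos = np.column_stack([g, np.full(len(g), 10.0)])
        df = density_sweep_census({0.5: [(pos, np.full(3, L))]}, cutoff=1.0)
        assert bool(df["percolated"].iloc[0])
        assert df["n_c"].iloc[0] == 1
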