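import numpy as np
import pytest

from sqdimer import (
    AtomRecord,
    ClusterSet,
    DyeParameters,
    Frame,
    Trajectory,
    filter_clusters,
    gromos_cluster,
    gromos_summary,
    histogram2d,
    pairwise_rmsd,
    time_series_summary,
)
from sqdimer.clustering import Cluster
from sqdimer.synthetic import ConformerSpec, GeneratorConfig, generate_dimer_trajectory


def _traj_from_coords(per_frame_coords):
    arr = np.asarray(per_frame_coords, dtype=float)
    n_atoms = arr.shape[1]
    atoms = [AtomRecord(i, f"C{i}", "C", 12.0, 1) for i in range(n_atoms)]
    return Trajectory(atoms, [Frame(k, 0.1 * k, arr[k]) for k in range(arr.shape[0])])


class TestPairwiseRMSD:
    def test_identical_frames_zero(self):
        coords = np.random.default_rng(1).normal(size=(3, 3))
        traj = _traj_from_coords([coords, coords])
        for superpose in (True, False):
            m = pairwise_rmsd(traj, [0, 1, 2], superpose=superpose)
            assert m[0, 1] == pytest.approx(0.0, abs=1e-10)

    def test_pure_translation(self):
        coords = np.random.default_rng(2).normal(size=(4, 3))
        traj = _traj_from_coords([coords, coords + np.array([1.0, 1.0, 1.0])])
        assert pairwise_rmsd(traj, range(4), superpose=True)[0, 1] == pytest.approx(
            0.0, abs=1e-10
        )
        assert pairwise_rmsd(traj, range(4), superpose=False)[0, 1] == pytest.approx(
            np.sqrt(3.0)
        )

    def test_pure_rotation_removed_by_superposition(self):
        from scipy.spatial.transform import Rotation

        rng = np.random.default_rng(3)
        coords = rng.normal(size=(6, 3))
        rot = Rotation.random(rng=rng)
        traj = _traj_from_coords([coords, rot.apply(coords)])
        # cancellation in |X|^2 + |Y|^2 - 2 tr(Sigma) leaves ~1e-7 nm residue
        assert pairwise_rmsd(traj, range(6), superpose=True)[0, 1] == pytest.approx(
            0.0, abs=1e-6
        )

    def test_two_atom_hand_arithmetic(self):
        # one atom displaced 0.1 nm -> rmsd = sqrt(0.01 / 2), no superposition
        a = np.array([[0.0, 0, 0], [1.0, 0, 0]])
        b = np.array([[0.0, 0, 0], [1.1, 0, 0]])
        traj = _traj_from_coords([a, b])
        assert pairwise_rmsd(traj, [0, 1], superpose=False)[0, 1] == pytest.approx(
            np.sqrt(0.01 / 2), rel=1e-12
        )

    def test_symmetry_and_zero_diagonal(self):
        rng = np.random.default_rng(4)
        traj = _traj_from_coords(rng.normal(size=(5, 4, 3)))
        m = pairwise_rmsd(traj, range(4), superpose=True)
        np.testing.assert_allclose(m, m.T)
        np.testing.assert_allclose(np.diag(m), 0.0, atol=1e-12)

    def test_empty_selection_rejected(self):
        traj = _traj_from_coords(np.zeros((2, 2, 3)))
        with pytest.raises(ValueError, match="empty"):
            pairwise_rmsd(traj, [])


def _greedy_oracle(m, cutoff):
    """Direct re-statement of the greedy procedure, set-based."""
    n = m.shape[0]
    remaining = set(range(n))
    clusters = []
    while remaining:
        best, best_members = None, None
        for i in sorted(remaining):  # lowest index wins ties
            members = {j for j in remaining if m[i, j] <= cutoff} | {i}
            if best is None or len(members) > len(best_members):
                best, best_members = i, members
        clusters.append((best, frozenset(best_members)))
        remaining -= best_members
    return clusters


class TestGromosCluster:
    def test_single_cluster_when_all_close(self):
        m = np.full((5, 5), 0.01)
        np.fill_diagonal(m, 0.0)
        cs = gromos_cluster(m, cutoff=0.05)
        assert len(cs) == 1
        assert cs.clusters[0].fraction == 1.0

    def test_planted_split_exact_sizes(self):
        # frames 0-5 and 6-9 form tight groups far apart
        n = 10
        m = np.full((n, n), 1.0)
        for grp in (range(6), range(6, 10)):
            for i in grp:
                for j in grp:
                    m[i, j] = 0.0
        cs = gromos_cluster(m, cutoff=0.05)
        assert sorted(len(c.member_frames) for c in cs.clusters) == [4, 6]

    def test_matches_brute_force_on_random_small_matrices(self):
        rng = np.random.default_rng(6)
        for _ in range(30):
            n = 6
            d = rng.uniform(0, 0.1, size=(n, n))
            m = (d + d.T) / 2
            np.fill_diagonal(m, 0.0)
            cs = gromos_cluster(m, cutoff=0.05)
            oracle = _greedy_oracle(m, 0.05)
            assert [(c.center_frame, c.member_frames) for c in cs.clusters] == [
                (c, frozenset(mem)) for c, mem in oracle
            ]

    def test_tie_broken_to_lowest_frame_index(self):
        # two disjoint pairs: both candidate centres have 2 neighbours
        m = np.full((4, 4), 1.0)
        m[0, 1] = m[1, 0] = 0.0
        m[2, 3] = m[3, 2] = 0.0
        np.fill_diagonal(m, 0.0)
        cs = gromos_cluster(m, cutoff=0.05)
        assert cs.clusters[0].center_frame == 0

    def test_partition_property(self):
        rng = np.random.default_rng(8)
        d = rng.uniform(0, 0.15, size=(20, 20))
        m = (d + d.T) / 2
        np.fill_diagonal(m, 0.0)
        cs = gromos_cluster(m, cutoff=0.05)
        all_members = [f for c in cs.clusters for f in c.member_frames]
        assert sorted(all_members) == list(range(20))  # disjoint and exhaustive
        assert sum(c.fraction for c in cs.clusters) == pytest.approx(1.0)


class TestFilterClusters:
    def _cs(self, fractions, n=100):
        clusters = []
        start = 0
        for f in fractions:
            size = int(round(f * n))
            members = frozenset(range(start, start + size))
            clusters.append(Cluster(center_frame=start, member_frames=members,
                                    fraction=f))
            start += size
        return ClusterSet(clusters=clusters, n_frames_total=n)

    def test_small_cluster_discarded(self):
        cs = filter_clusters(self._cs([0.96, 0.04]))
        assert len(cs) == 1
        assert cs.discarded_fraction == pytest.approx(0.04)

    def test_single_full_cluster_retained(self):
        assert len(filter_clusters(self._cs([1.0]))) == 1

    def test_boundary_is_strictly_greater(self):
        cs = filter_clusters(self._cs([0.5, 0.3, 0.15, 0.05]))
        assert len(cs) == 3  # 0.05 is not > 0.05

    def test_all_discarded_raises_with_advice(self):
        with pytest.raises(ValueError, match="cutoff"):
            filter_clusters(self._cs([0.04] * 25))


class TestTimeSeriesSummary:
    def test_constant_series(self):
        assert time_series_summary([3.5] * 10) == (3.5, 0.0)

    def test_two_point_population_sd(self):
        mean, sd = time_series_summary([0.0, 1.0])
        assert mean == pytest.approx(0.5)
        assert sd == pytest.approx(0.5)  # population, not sample

    def test_against_two_pass_computation(self):
        rng = np.random.default_rng(10)
        v = rng.normal(2.0, 3.0, size=1000)
        mean, sd = time_series_summary(v)
        mu = sum(v) / len(v)
        var = sum((x - mu) ** 2 for x in v) / len(v)
        assert mean == pytest.approx(mu, abs=1e-12)
        assert sd == pytest.approx(np.sqrt(var), abs=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            time_series_summary([])


class TestGromosSummary:
    def test_identical_frames_single_cluster(self, noiseless_aa, dye_params):
        traj, rmap, sel, _ = noiseless_aa
        m = pairwise_rmsd(traj, list(range(traj.n_atoms)))
        cs = filter_clusters(gromos_cluster(m, 0.05))
        summary, table = gromos_summary(cs, traj, sel, dye_params, "dye_m", "dye_n")
        assert len(cs) == 1
        mean_ksq, sd_ksq = summary.stats["kappa_sq"]
        assert mean_ksq == pytest.approx(1.0, abs=1e-12)
        assert sd_ksq == 0.0
        assert summary.stats["R"][0] == pytest.approx(0.6, abs=1e-12)

    def test_mirrored_packing_clusters_cancel_kappa_prime(self, dye_params):
        # equal AA and AB blocks -> two clusters with kappa' = +1 and -1
        cfg = GeneratorConfig(
            n_frames=40, seed=19, sd_R=0.0, orientation_jitter=0.0,
            packing="AA",
            conformer_switch=ConformerSpec(fraction=0.5, mean_R=0.6, packing="AB"),
        )
        traj, rmap, sel, _ = generate_dimer_trajectory(cfg)
        m = pairwise_rmsd(traj, list(range(traj.n_atoms)))
        cs = filter_clusters(gromos_cluster(m, 0.05))
        summary, _ = gromos_summary(cs, traj, sel, dye_params, "dye_m", "dye_n")
        assert len(cs) == 2
        assert summary.stats["kappa_prime"][0] == pytest.approx(0.0, abs=1e-9)

    def test_planted_conformers_recover_generator_couplings(self, dye_params):
        from sqdimer import CouplingParameters, extended_dipole_coupling, extract_extended_dipole

        cfg = GeneratorConfig(
            n_frames=200, seed=29, sd_R=0.01, orientation_jitter=2.0,
            conformer_switch=ConformerSpec(fraction=0.4, mean_R=0.9),
        )
        traj, rmap, sel, _ = generate_dimer_trajectory(cfg)
        m = pairwise_rmsd(traj, list(range(traj.n_atoms)))
        cs = filter_clusters(gromos_cluster(m, 0.05))
        _, table = gromos_summary(cs, traj, sel, dye_params, "dye_m", "dye_n")
        # noiseless reference J for each planted separation
        noiseless = {}
        for mean_R in (0.6, 0.9):
            ref_cfg = GeneratorConfig(n_frames=1, seed=1, sd_R=0.0,
                                      orientation_jitter=0.0, mean_R=mean_R)
            t, _, s, _ = generate_dimer_trajectory(ref_cfg)
            dm = extract_extended_dipole(t.frames[0], s, dye_params, "dye_m")
            dn = extract_extended_dipole(t.frames[0], s, dye_params, "dye_n")
            noiseless[mean_R] = extended_dipole_coupling(dm, dn).J_mn
        got = sorted(table["J_mn"])
        want = sorted(noiseless.values())
        for g, w in zip(got, want):
            assert g == pytest.approx(w, rel=0.15)  # sampling tolerance


class TestHistogram2D:
    def test_all_points_one_bin(self):
        h = histogram2d(np.full(40, 0.5), np.full(40, 0.5), bins=4)
        assert h.counts.sum() == 40
        assert (h.counts > 0).sum() == 1

    def test_uniform_grid_known_counts(self):
        # 3x2 grid of points, one per bin
        x = np.repeat([0.5, 1.5, 2.5], 2)
        y = np.tile([0.5, 1.5], 3)
        h = histogram2d(x, y, bins=(np.arange(4.0), np.arange(3.0)))
        np.testing.assert_array_equal(h.counts, np.ones((3, 2)))

    def test_marginals_match_1d_histograms(self):
        rng = np.random.default_rng(12)
        x, y = rng.normal(size=(2, 500))
        edges = (np.linspace(-4, 4, 11), np.linspace(-4, 4, 9))
        h = histogram2d(x, y, bins=edges)
        np.testing.assert_array_equal(h.counts.sum(axis=1), np.histogram(x, edges[0])[0])
        np.testing.assert_array_equal(h.counts.sum(axis=0), np.histogram(y, edges[1])[0])
        assert h.counts.sum() == 500

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValueError, match="lengths"):
            histogram2d([1, 2, 3], [1, 2])
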