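"""Cluster-mass permutation test: stat maps, clustering, null calibration."""

import itertools

import numpy as np
import pytest
from scipy import stats

import p300battery as pb
from p300battery.cmpt import (
    AdjacencyGraph,
    _max_cluster_mass,
    montage_positions,
)


def flood_fill_clusters(tmap, threshold, adjacency):
    """Independent oracle: exhaustive BFS over supra-threshold points."""
    nbrs = adjacency.neighbor_lists
    out = []
    for sign in (1, -1):
        mask = tmap * sign > threshold
        seen = set()
        for c0, t0 in zip(*np.nonzero(mask)):
            if (c0, t0) in seen:
                continue
            stack, members = [(c0, t0)], []
            seen.add((c0, t0))
            while stack:
                c, t = stack.pop()
                members.append((c, t))
                cands = [(c, t - 1), (c, t + 1)] + [(n, t) for n in nbrs[c]]
                for cn, tn in cands:
                    if (0 <= tn < tmap.shape[1] and mask[cn, tn]
                            and (cn, tn) not in seen):
                        seen.add((cn, tn))
                        stack.append((cn, tn))
            out.append((frozenset(members),
                        float(sum(tmap[c, t] for c, t in members))))
    return out


class TestAdjacency:
    def test_montage_geometry(self, adjacency):
        assert adjacency.neighbors("CZ") == {"FCZ", "CPZ"}
        assert "CPZ" in adjacency.neighbors("PZ")

    def test_symmetric_irreflexive(self, adjacency):
        m = adjacency.matrix
        assert (m == m.T).all() and not m.diagonal().any()

    def test_tiny_threshold_isolates_electrodes(self):
        with pytest.raises(ValueError, match="isolated"):
            pb.build_adjacency(threshold=0.05)

    def test_positions_cover_montage(self):
        pos = montage_positions()
        assert set(pos) == set(pb.CHANNELS)


class TestStatMaps:
    def test_group_null_is_zero(self):
        a = np.random.default_rng(0).normal(size=(5, 16, 20))
        t = pb.stat_map_group(a, a.copy())
        assert np.abs(t).max() == 0

    def test_group_shift_gives_positive_t(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(8, 16, 20))
        t = pb.stat_map_group(a + 2.0, a)
        assert (t > 0).all()

    def test_group_matches_scipy_paired_t(self):
        rng = np.random.default_rng(2)
        a = rng.normal(size=(14, 4, 6))
        b = rng.normal(size=(14, 4, 6))
        mine = pb.stat_map_group(a, b)
        ref = stats.ttest_rel(a, b, axis=0).statistic
        np.testing.assert_allclose(mine, ref, rtol=1e-10)

    def test_single_matches_scipy_pooled_t(self):
        rng = np.random.default_rng(3)
        a = rng.normal(size=(10, 4, 6))
        b = rng.normal(size=(30, 4, 6))
        mine = pb.stat_map_single(a, b)
        ref = stats.ttest_ind(a, b, axis=0, equal_var=True).statistic
        np.testing.assert_allclose(mine, ref, rtol=1e-10)

    def test_single_detects_injected_effect(self):
        rng = np.random.default_rng(4)
        a = rng.normal(size=(60, 16, 50))
        b = rng.normal(size=(200, 16, 50))
        a[:, 5, 20:30] += 1.5
        t = pb.stat_map_single(a, b)
        assert t[5, 20:30].min() > 3

    def test_too_few_epochs_rejected(self):
        with pytest.raises(ValueError):
            pb.stat_map_single(np.zeros((1, 2, 2)), np.zeros((5, 2, 2)))


class TestClusterFormation:
    def test_subthreshold_map_gives_no_clusters(self, adjacency):
        clusters = pb.form_clusters(np.zeros((16, 10)), 2.0, adjacency)
        assert clusters == []

    def test_singleton_cluster(self, adjacency):
        tmap = np.zeros((16, 10))
        tmap[9, 4] = 5.0  # T7 has neighbors only spatially far away
        clusters = pb.form_clusters(tmap, 2.0, adjacency)
        assert len(clusters) == 1
        assert clusters[0].mass == pytest.approx(5.0)
        assert clusters[0].members() == {(9, 4)}

    def test_matches_flood_fill_oracle_on_random_maps(self, adjacency):
        rng = np.random.default_rng(5)
        for _ in range(10):
            tmap = rng.normal(0, 2.0, size=(16, 15))
            mine = {frozenset(c.members()): c.mass
                    for c in pb.form_clusters(tmap, 2.0, adjacency)}
            oracle = dict(flood_fill_clusters(tmap, 2.0, adjacency))
            assert mine.keys() == oracle.keys()
            for members, mass in oracle.items():
                assert mine[members] == pytest.approx(mass)
            assert _max_cluster_mass(tmap, 2.0, adjacency) == pytest.approx(
                max((abs(v) for v in oracle.values()), default=0.0))

    def test_temporal_and_spatial_connectivity(self, adjacency):
        tmap = np.zeros((16, 10))
        cz, fcz, cpz = (pb.CHANNELS.index(c) for c in ("CZ", "FCZ", "CPZ"))
        tmap[cz, 3:6] = 3.0  # temporal run
        tmap[fcz, 5] = 3.0   # spatial neighbor at same sample
        tmap[cpz, 8] = 3.0   # disconnected in time
        clusters = pb.form_clusters(tmap, 2.0, adjacency)
        sizes = sorted(c.size for c in clusters)
        assert sizes == [1, 4]


class TestPermutationTest:
    def test_exact_enumeration_matches_oracle(self, adjacency):
        rng = np.random.default_rng(6)
        a = rng.normal(size=(3, 16, 6))
        a[:, 11, 2:5] += 2.5
        b = rng.normal(size=(3, 16, 6))
        res = pb.permutation_test(a, b, level="single", n_perm=100,
                                  exact=True, rng=0, adjacency=adjacency)
        x = np.concatenate([a, b])
        null = []
        for pick in itertools.combinations(range(6), 3):
            sel = np.zeros(6, bool)
            sel[list(pick)] = True
            t = pb.stat_map_single(x[sel], x[~sel])
            null.append(max((abs(m) for _, m in
                             flood_fill_clusters(t, res.threshold, adjacency)),
                            default=0.0))
        obs = abs(res.clusters[0].mass)
        expect = np.mean([m >= obs - 1e-12 for m in null])
        assert res.p_value == pytest.approx(expect)
        assert res.n_perm == 20

    def test_group_exact_enumeration_is_sign_flips(self, adjacency):
        rng = np.random.default_rng(7)
        a = rng.normal(size=(4, 16, 6)) + 1.0
        b = rng.normal(size=(4, 16, 6))
        res = pb.permutation_test(a, b, level="group", n_perm=100, exact=True,
                                  rng=0, adjacency=adjacency)
        assert res.n_perm == 16  # 2^4 sign patterns
        assert 0 < res.p_value <= 1

    def test_strong_effect_saturates_p(self, adjacency):
        rng = np.random.default_rng(8)
        a = rng.normal(size=(30, 16, 40)) + 0.02
        b = rng.normal(size=(90, 16, 40))
        a[:, [5, 11, 12], :] += 4.0
        res = pb.permutation_test(a, b, level="single", n_perm=200, rng=1,
                                  adjacency=adjacency)
        assert res.p_value == pytest.approx(1 / 201)
        assert res.selected_region is not None

    def test_swap_symmetry(self, adjacency):
        rng = np.random.default_rng(9)
        a = rng.normal(size=(20, 16, 30))
        b = rng.normal(size=(60, 16, 30))
        a[:, 11, 10:20] += 1.0
        r1 = pb.permutation_test(a, b, level="single", n_perm=300, rng=5,
                                 adjacency=adjacency)
        r2 = pb.permutation_test(b, a, level="single", n_perm=300, rng=5,
                                 adjacency=adjacency)
        assert r1.p_value == r2.p_value
        assert r1.clusters[0].sign == -r2.clusters[0].sign
        assert abs(r1.clusters[0].mass) == pytest.approx(
            abs(r2.clusters[0].mass))

    def test_channel_relabeling_invariance(self, adjacency):
        # permuting channels (with a consistently permuted adjacency)
        # leaves the p-value unchanged
        rng = np.random.default_rng(10)
        a = rng.normal(size=(15, 16, 20))
        b = rng.normal(size=(45, 16, 20))
        a[:, 11, 5:15] += 1.2
        perm = rng.permutation(16)
        adj2 = AdjacencyGraph(
            tuple(pb.CHANNELS[i] for i in perm),
            adjacency.matrix[np.ix_(perm, perm)], adjacency.threshold)
        r1 = pb.permutation_test(a, b, level="single", n_perm=200, rng=3,
                                 adjacency=adjacency)
        r2 = pb.permutation_test(a[:, perm], b[:, perm], level="single",
                                 n_perm=200, rng=3, adjacency=adj2)
        assert r1.p_value == r2.p_value

    def test_determinism_under_seed(self, adjacency):
        rng = np.random.default_rng(11)
        a = rng.normal(size=(12, 16, 20)) + 0.3
        b = rng.normal(size=(36, 16, 20))
        r1 = pb.permutation_test(a, b, n_perm=200, rng=42, adjacency=adjacency)
        r2 = pb.permutation_test(a, b, n_perm=200, rng=42, adjacency=adjacency)
        assert r1.p_value == r2.p_value
        np.testing.assert_array_equal(r1.null_max, r2.null_max)

    def test_small_space_warns(self, adjacency):
        a = np.random.default_rng(12).normal(size=(2, 16, 5)) + 3.0
        b = np.random.default_rng(13).normal(size=(2, 16, 5))
        with pytest.warns(UserWarning, match="distinct permutations"):
            pb.permutation_test(a, b, level="single", n_perm=100,
                                rng=0, adjacency=adjacency)

    def test_amplitude_monotonicity(self, adjacency):
        # larger injected effects never increase mean p (averaged over seeds)
        rng = np.random.default_rng(14)
        mean_ps = []
        for amp in (0.0, 0.6, 1.2):
            ps = []
            for seed in range(5):
                r = np.random.default_rng(100 * seed + 17)
                a = r.normal(size=(20, 16, 30))
                b = r.normal(size=(60, 16, 30))
                a[:, [11, 12, 5], 10:20] += amp
                ps.append(pb.permutation_test(a, b, n_perm=150, rng=seed,
                                              adjacency=adjacency).p_value)
            mean_ps.append(np.mean(ps))
        assert mean_ps[0] >= mean_ps[1] >= mean_ps[2]

    def test_agrees_with_mne_cluster_test(self, adjacency):
        # same data, same threshold: cluster membership of the winning
        # cluster and a saturated p from both implementations
        mne = pytest.importorskip("mne")
        from scipy import sparse

        rng = np.random.default_rng(15)
        a = rng.normal(size=(30, 16, 40))
        b = rng.normal(size=(90, 16, 40))
        a[:, [11, 12], 10:25] += 2.0
        res = pb.permutation_test(a, b, level="single", n_perm=500, rng=2,
                                  adjacency=adjacency)

        def stat_fun(x, y):
            return pb.stat_map_single(
                x.reshape(len(x), 40, 16).transpose(0, 2, 1),
                y.reshape(len(y), 40, 16).transpose(0, 2, 1)).T.ravel()

        t_obs, clusters, pvals, _ = mne.stats.permutation_cluster_test(
            [a.transpose(0, 2, 1), b.transpose(0, 2, 1)],
            threshold=res.threshold, n_permutations=500, tail=0,
            stat_fun=stat_fun, adjacency=sparse.coo_matrix(adjacency.matrix),
            n_jobs=1, seed=2, out_type="mask", verbose="error")
        best = int(np.argmin(pvals))
        mne_members = {(c, t) for t, c in zip(*np.nonzero(
            clusters[best].reshape(40, 16)))}
        assert mne_members == res.clusters[0].members()
        assert pvals.min() <= 0.01 and res.p_value <= 0.01
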