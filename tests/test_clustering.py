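import itertools

import numpy as np
import pytest
from scipy.cluster.hierarchy import cophenet
from scipy.spatial.distance import squareform
from sklearn.metrics import adjusted_rand_score

from foldspace.clustering import (
    average_linkage_tree,
    medoids,
    optimal_partition,
    separation_stats,
    tree_to_newick,
)
from foldspace.synthetic_data import LatentConfig, generate_latent_dataset


def naive_upgma(D):
    """O(n^3) unweighted average linkage; returns the cophenetic matrix.

    Clusters merge at the unweighted mean of all cross-pair distances of
    the ORIGINAL matrix; ties break on the smallest (i, j) of the current
    cluster indices.
    """
    n = D.shape[0]
    clusters = {i: [i] for i in range(n)}
    coph = np.zeros((n, n))
    heights = []
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for a, b in itertools.combinations(keys, 2):
            h = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or h < best[0] - 1e-15:
                best = (h, a, b)
        h, a, b = best
        heights.append(h)
        for i in clusters[a]:
            for j in clusters[b]:
                coph[i, j] = coph[j, i] = h
        clusters[a] = clusters[a] + clusters[b]
        del clusters[b]
    return coph, heights


def naive_minimal_partition(D, threshold):
    """Exhaustive scan over horizontal tree cuts using the naive UPGMA tree.

    Rebuilds the merge sequence independently and, for k = 1..n, forms the
    partition obtained by undoing the last k-1 merges; returns the labels
    of the minimal k whose intra-cluster distances are all < threshold.
    """
    n = D.shape[0]
    clusters = {i: frozenset([i]) for i in range(n)}
    states = [list(clusters.values())]
    while len(clusters) > 1:
        keys = sorted(clusters)
        best = None
        for a, b in itertools.combinations(keys, 2):
            h = np.mean([D[i, j] for i in clusters[a] for j in clusters[b]])
            if best is None or h < best[0] - 1e-15:
                best = (h, a, b)
        _, a, b = best
        clusters[a] = frozenset(clusters[a] | clusters[b])
        del clusters[b]
        states.append(list(clusters.values()))
    # states[m] has n-m clusters; scan k = 1..n
    for k in range(1, n + 1):
        part = states[n - k]
        ok = all(
            D[i, j] < threshold for cl in part for i in cl for j in cl if i < j
        )
        if ok:
            labels = np.empty(n, dtype=int)
            for c, cl in enumerate(sorted(part, key=min)):
                for i in cl:
                    labels[i] = c
            return k, labels
    raise AssertionError


def random_distance_matrix(rng, n):
    x = rng.uniform(0, 1, (n, n))
    D = (x + x.T) / 2
    np.fill_diagonal(D, 0)
    return D


class TestAverageLinkageTree:
    def test_two_points(self):
        D = np.array([[0.0, 0.3], [0.3, 0.0]])
        Z = average_linkage_tree(D)
        assert Z.shape == (1, 4)
        assert Z[0, 2] == pytest.approx(0.3)

    def test_ultrametric_recovers_generating_heights(self):
        # tree: (a,b) at 0.2; (c,d) at 0.3; root at 0.8
        D = np.array(
            [
                [0.0, 0.2, 0.8, 0.8],
                [0.2, 0.0, 0.8, 0.8],
                [0.8, 0.8, 0.0, 0.3],
                [0.8, 0.8, 0.3, 0.0],
            ]
        )
        Z = average_linkage_tree(D)
        assert sorted(Z[:, 2]) == pytest.approx([0.2, 0.3, 0.8])
        coph = squareform(cophenet(Z))
        np.testing.assert_allclose(coph, D, atol=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_naive_oracle_n8(self, seed):
        rng = np.random.default_rng(seed)
        D = random_distance_matrix(rng, 8)
        Z = average_linkage_tree(D)
        coph_naive, heights = naive_upgma(D)
        np.testing.assert_allclose(squareform(cophenet(Z)), coph_naive, atol=1e-10)
        np.testing.assert_allclose(np.sort(Z[:, 2]), np.sort(heights), atol=1e-10)

    def test_heights_non_decreasing(self, rng):
        D = random_distance_matrix(rng, 10)
        Z = average_linkage_tree(D)
        assert np.all(np.diff(Z[:, 2]) >= -1e-12)

    def test_validation_errors(self):
        with pytest.raises(ValueError):
            average_linkage_tree(np.array([[0.0, 0.5], [0.4, 0.0]]))
        with pytest.raises(ValueError):
            average_linkage_tree(np.array([[0.0, -0.1], [-0.1, 0.0]]))


class TestOptimalPartition:
    def test_all_close_single_cluster(self):
        D = random_distance_matrix(np.random.default_rng(0), 6) * 0.5
        part = optimal_partition(average_linkage_tree(D), D, 0.6)
        assert part.n_clusters == 1
        assert part.max_intra < 0.6

    def test_all_far_singletons(self):
        D = 0.7 + random_distance_matrix(np.random.default_rng(0), 5) * 0.2
        np.fill_diagonal(D, 0)
        part = optimal_partition(average_linkage_tree(D), D, 0.6)
        assert part.n_clusters == 5
        assert part.max_intra == 0.0

    def test_two_planted_blobs(self):
        rng = np.random.default_rng(3)
        n = 8
        D = np.zeros((n, n))
        for i, j in itertools.combinations(range(n), 2):
            same = (i < 4) == (j < 4)
            D[i, j] = D[j, i] = rng.uniform(0.05, 0.2) if same else rng.uniform(0.8, 0.95)
        part = optimal_partition(average_linkage_tree(D), D, 0.6)
        assert part.n_clusters == 2
        labels = [part.labels[str(i)] for i in range(n)]
        assert len(set(labels[:4])) == 1 and len(set(labels[4:])) == 1
        assert labels[0] != labels[4]

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_cut_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(4, 11))
        D = random_distance_matrix(rng, n)
        threshold = float(rng.uniform(0.3, 0.8))
        part = optimal_partition(average_linkage_tree(D), D, threshold)
        k_oracle, labels_oracle = naive_minimal_partition(D, threshold)
        assert part.n_clusters == k_oracle
        mine = [part.labels[str(i)] for i in range(n)]
        assert adjusted_rand_score(mine, labels_oracle) == 1.0 or k_oracle == n

    def test_minimality_cut_one_less_violates(self, rng):
        from scipy.cluster.hierarchy import cut_tree

        D = random_distance_matrix(rng, 9)
        Z = average_linkage_tree(D)
        part = optimal_partition(Z, D, 0.5)
        k = part.n_clusters
        if k > 1:
            raw = cut_tree(Z, n_clusters=k - 1).ravel()
            worst = max(
                D[np.ix_(np.flatnonzero(raw == c), np.flatnonzero(raw == c))].max()
                for c in np.unique(raw)
            )
            assert worst >= 0.5


class TestMedoids:
    def test_singleton_is_its_own_medoid(self):
        D = np.array([[0.0, 0.9], [0.9, 0.0]])
        labels = {"a": 1, "b": 2}
        assert medoids(labels, D, ["a", "b"]) == ["a", "b"]

    def test_three_member_hand_example(self):
        # sums: a: 0.1+0.2=0.3, b: 0.1+0.4=0.5, c: 0.2+0.4=0.6 -> medoid a
        D = np.array([[0.0, 0.1, 0.2], [0.1, 0.0, 0.4], [0.2, 0.4, 0.0]])
        labels = {"a": 1, "b": 1, "c": 1}
        assert medoids(labels, D, ["a", "b", "c"]) == ["a"]

    def test_symmetric_tie_lexicographic(self):
        D = np.full((3, 3), 0.3)
        np.fill_diagonal(D, 0)
        labels = {"z": 1, "m": 1, "a": 1}
        assert medoids(labels, D, ["z", "m", "a"]) == ["a"]

    @pytest.mark.parametrize("seed", range(3))
    def test_brute_force_optimality(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        D = random_distance_matrix(rng, n)
        ids = [f"d{i:02d}" for i in range(n)]
        part = optimal_partition(average_linkage_tree(D), D, 0.55, ids)
        for c in range(1, part.n_clusters + 1):
            members = sorted(i for i, lab in part.labels.items() if lab == c)
            rows = [ids.index(m) for m in members]
            sums = {
                m: sum(D[ids.index(m), r] for r in rows) for m in members
            }
            best = min(sums.values())
            assert sums[part.medoid_ids[c - 1]] == pytest.approx(best)


class TestSeparationStats:
    def test_well_separated_blobs(self):
        D = np.array(
            [
                [0.0, 0.1, 0.9, 0.9],
                [0.1, 0.0, 0.9, 0.9],
                [0.9, 0.9, 0.0, 0.1],
                [0.9, 0.9, 0.1, 0.0],
            ]
        )
        ids = ["a", "b", "c", "d"]
        part = optimal_partition(average_linkage_tree(D), D, 0.6, ids)
        stats = separation_stats(part, D, ids)
        assert stats.count == 0 and stats.fraction == 0.0

    def test_single_cluster_zero_denominator(self):
        D = np.full((3, 3), 0.2)
        np.fill_diagonal(D, 0)
        ids = ["a", "b", "c"]
        part = optimal_partition(average_linkage_tree(D), D, 0.6, ids)
        stats = separation_stats(part, D, ids)
        assert part.n_clusters == 1
        assert stats == (0, 0.0, 0)

    def test_planted_cross_pairs_counted(self):
        # two far blobs with exactly 3 cross pairs pulled below 0.4
        D = np.zeros((6, 6))
        for i, j in itertools.combinations(range(6), 2):
            same = (i < 3) == (j < 3)
            D[i, j] = D[j, i] = 0.1 if same else 0.9
        for i, j in [(0, 3), (1, 4), (2, 5)]:
            D[i, j] = D[j, i] = 0.35
        ids = list("abcdef")
        part = optimal_partition(average_linkage_tree(D), D, 0.6, ids)
        assert part.n_clusters == 2
        stats = separation_stats(part, D, ids)
        assert stats.count == 3
        assert stats.fraction == pytest.approx(3 / 9)


@pytest.mark.parametrize("n_families", [3, 5, 8])
def test_planted_family_recovery(n_families):
    """Families with within < 0.4 and between >= 0.7 are recovered exactly."""
    cfg = LatentConfig(
        n_families=n_families, members_per_family=6, within_sd=0.08,
        center_scale=1.6, seed=5 + n_families,
    )
    ds = generate_latent_dataset(cfg)
    fam = np.array([ds.family_of[i] for i in ds.ids])
    iu = np.triu_indices(len(ds.ids), 1)
    same = fam[iu[0]] == fam[iu[1]]
    # construction guard: the planted geometry satisfies the premise
    assert ds.D[iu][same].max() < 0.4
    assert ds.D[iu][~same].min() >= 0.7
    part = optimal_partition(average_linkage_tree(ds.D), ds.D, 0.6, ds.ids)
    assert part.n_clusters == n_families
    found = [part.labels[i] for i in ds.ids]
    assert adjusted_rand_score(fam, found) == 1.0


def test_newick_export_parses():
    import io

    from Bio import Phylo

    D = random_distance_matrix(np.random.default_rng(2), 6)
    Z = average_linkage_tree(D)
    ids = [f"t{i}" for i in range(6)]
    nwk = tree_to_newick(Z, ids)
    tree = Phylo.read(io.StringIO(nwk), "newick")
    assert sorted(t.name for t in tree.get_terminals()) == ids
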