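import itertools

import numpy as np
import pandas as pd
import pytest
from sklearn.metrics import mutual_info_score

from rcmir.network import (
    NoThresholdError,
    adjacency,
    clustering_coefficient,
    equal_frequency_discretize,
    expected_random_clustering,
    extract_clusters,
    mi_to_similarity,
    mutual_information,
    select_threshold,
    similarity_matrix,
)

# ---------------------------------------------------------------------------
# independent brute-force oracles (kept deliberately naive)


def oracle_scan(s: np.ndarray, grid) -> float | None:
    """Threshold pick by exhaustive per-tau enumeration, pure python."""
    n = s.shape[0]
    stats = []
    for tau in grid:
        edges = [(i, j) for i in range(n) for j in range(i + 1, n)
                 if s[i, j] > tau]
        neigh = {i: set() for i in range(n)}
        for i, j in edges:
            neigh[i].add(j)
            neigh[j].add(i)
        connected = [i for i in range(n) if neigh[i]]
        if len(connected) < 3:
            stats.append((0.0, 0.0, len(edges)))
            continue
        locals_ = []
        for i in connected:
            k = len(neigh[i])
            if k < 2:
                locals_.append(0.0)
                continue
            links = sum(1 for a, b in itertools.combinations(neigh[i], 2)
                        if b in neigh[a])
            locals_.append(links / (k * (k - 1) / 2))
        c = sum(locals_) / len(connected)
        cr = 2 * len(edges) / (len(connected) * (len(connected) - 1))
        stats.append((c, cr, len(edges)))
    d = [abs(c - cr) for c, cr, _m in stats]
    candidates = [v for v in range(len(grid) - 1)
                  if stats[v][2] >= 1 and d[v] > d[v + 1] and d[v] > 0]
    if not candidates:
        return None
    best = max(candidates, key=lambda v: (d[v], -v))
    return float(grid[best])


def oracle_components(a: np.ndarray) -> list[frozenset]:
    """Union-find connected components."""
    n = a.shape[0]
    parent = list(range(n))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(n):
        for j in range(i + 1, n):
            if a[i, j]:
                parent[find(i)] = find(j)
    groups: dict[int, set] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return [frozenset(g) for g in groups.values()]


# ---------------------------------------------------------------------------


class TestDiscretize:
    def test_simple_halves(self):
        assert equal_frequency_discretize([1, 2, 3, 4], 2).tolist() == [0, 0, 1, 1]

    def test_rank_quantiles(self):
        labels = equal_frequency_discretize([5, 1, 3, 2, 6, 4], 3)
        by_value = dict(zip([5, 1, 3, 2, 6, 4], labels))
        assert by_value[1] == by_value[2] == 0
        assert by_value[3] == by_value[4] == 1
        assert by_value[5] == by_value[6] == 2

    def test_constant_vector_stable_tie_split(self):
        labels = equal_frequency_discretize([7.0] * 6, 2)
        assert labels.tolist() == [0, 0, 0, 1, 1, 1]

    def test_occupancy_near_equal(self):
        rng = np.random.default_rng(0)
        labels = equal_frequency_discretize(rng.random(11), 3)
        occ = np.bincount(labels)
        assert occ.max() - occ.min() <= 1

    def test_nbins_errors(self):
        with pytest.raises(ValueError):
            equal_frequency_discretize([1, 2], 1)
        with pytest.raises(ValueError):
            equal_frequency_discretize([1, 2], 3)


class TestMutualInformation:
    def test_constant_is_zero(self):
        assert mutual_information([0] * 6, [0, 1, 2, 0, 1, 2]) == 0.0

    def test_perfect_match_two_bins(self):
        # joint diag (2,2) over 4 samples -> ln 2
        assert mutual_information([0, 0, 1, 1], [0, 0, 1, 1]) == pytest.approx(
            np.log(2), rel=1e-12
        )

    def test_uniform_joint_independent(self):
        # joint table [[1,1],[1,1]] -> 0
        assert mutual_information([0, 0, 1, 1], [0, 1, 0, 1]) == 0.0

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            mutual_information([0, 1], [0, 1, 2])

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_sklearn_on_random_labels(self, seed):
        rng = np.random.default_rng(seed)
        x = rng.integers(0, 4, 60)
        y = rng.integers(0, 3, 60)
        assert mutual_information(x, y) == pytest.approx(
            mutual_info_score(x, y), abs=1e-12
        )


class TestMiToSimilarity:
    def test_closed_forms(self):
        assert mi_to_similarity(0.0) == 0.0
        assert mi_to_similarity(0.5) == pytest.approx(0.7951, abs=1e-4)

    def test_monotone_increasing(self):
        grid = np.linspace(0, 3, 40)
        vals = [mi_to_similarity(i) for i in grid]
        assert np.all(np.diff(vals) > 0)

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            mi_to_similarity(-0.1)


class TestSimilarityMatrix:
    def test_identical_rows_hit_entropy_ceiling(self):
        # nbins=3, n=6 -> MI = ln 3, s = sqrt(1 - 1/9)
        row = [1.0, 5.0, 2.0, 9.0, 4.0, 7.0]
        df = pd.DataFrame([row, row], index=["a", "b"], columns=list("uvwxyz"))
        s = similarity_matrix(df, nbins=3)
        assert s.loc["a", "b"] == pytest.approx(np.sqrt(1 - 1 / 9), rel=1e-10)

    def test_symmetric_unit_diagonal_in_range(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.random((6, 12)))
        s = similarity_matrix(df, nbins=3).to_numpy()
        assert np.allclose(s, s.T)
        assert np.allclose(np.diag(s), 1.0)
        assert s.min() >= 0 and s.max() <= 1

    def test_independent_rows_low_similarity(self):
        rng = np.random.default_rng(4)
        df = pd.DataFrame(rng.random((4, 1000)))
        s = similarity_matrix(df, nbins=3).to_numpy()
        off = s[np.triu_indices(4, 1)]
        assert off.max() < 0.3

    def test_permutation_equivariance(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.random((7, 15)),
                          index=[f"m{i}" for i in range(7)])
        s = similarity_matrix(df, nbins=3)
        perm = ["m3", "m0", "m6", "m2", "m5", "m1", "m4"]
        s_perm = similarity_matrix(df.loc[perm], nbins=3)
        pd.testing.assert_frame_equal(s.loc[perm, perm], s_perm)


class TestClusteringCoefficient:
    def _from_edges(self, n, edges):
        a = np.zeros((n, n))
        for i, j in edges:
            a[i, j] = a[j, i] = 1
        return a

    def test_triangle_is_one(self):
        assert clustering_coefficient(self._from_edges(3, [(0, 1), (1, 2), (0, 2)])) == 1.0

    def test_path_is_zero(self):
        assert clustering_coefficient(self._from_edges(3, [(0, 1), (1, 2)])) == 0.0

    def test_four_cycle_with_diagonal(self):
        # edges 1-2,2-3,3-4,4-1,1-3 (1-indexed) -> (2/3 + 1 + 2/3 + 1)/4
        a = self._from_edges(4, [(0, 1), (1, 2), (2, 3), (3, 0), (0, 2)])
        assert clustering_coefficient(a) == pytest.approx(5 / 6, rel=1e-12)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_networkx_average_clustering(self, seed):
        import networkx as nx

        g = nx.gnp_random_graph(12, 0.35, seed=seed)
        a = nx.to_numpy_array(g)
        assert clustering_coefficient(a) == pytest.approx(
            nx.average_clustering(g), rel=1e-12
        )


class TestExpectedRandomClustering:
    def test_complete_graph_is_one(self):
        assert expected_random_clustering(5, 10) == 1.0

    def test_formula_value(self):
        assert expected_random_clustering(4, 5) == pytest.approx(5 / 6)

    def test_empty_and_errors(self):
        assert expected_random_clustering(4, 0) == 0.0
        with pytest.raises(ValueError):
            expected_random_clustering(1, 0)
        with pytest.raises(ValueError):
            expected_random_clustering(4, 7)


class TestSelectThreshold:
    def test_two_cliques_recovered_exactly(self, two_clique_similarity):
        s = two_clique_similarity
        scan = select_threshold(s)
        assert 0.15 < scan.tau_star <= 0.9
        cs = extract_clusters(adjacency(s, scan.tau_star))
        assert cs.clusters == [
            ["m00", "m01", "m02", "m03"],
            ["m04", "m05", "m06", "m07"],
        ]

    def test_degenerate_equal_similarities_error(self):
        s = pd.DataFrame(np.full((5, 5), 0.5), index=list("abcde"),
                         columns=list("abcde"))
        np.fill_diagonal(s.values, 1.0)
        with pytest.raises(NoThresholdError, match="fallback_tau"):
            select_threshold(s)
        scan = select_threshold(s, fallback_tau=0.3)
        assert scan.tau_star == 0.3

    def test_scan_statistics_bounded(self, two_clique_similarity):
        scan = select_threshold(two_clique_similarity)
        assert np.all((scan.C >= 0) & (scan.C <= 1))
        assert np.all((scan.Cr >= 0) & (scan.Cr <= 1))
        assert np.allclose(scan.d, np.abs(scan.C - scan.Cr))

    def test_order_invariance(self, two_clique_similarity):
        s = two_clique_similarity
        perm = list(s.index[::-1])
        scan1 = select_threshold(s)
        scan2 = select_threshold(s.loc[perm, perm])
        assert scan1.tau_star == scan2.tau_star

    def test_grid_validation(self, two_clique_similarity):
        with pytest.raises(ValueError):
            select_threshold(two_clique_similarity, grid=np.array([0.5, 0.4]))
        with pytest.raises(ValueError):
            select_threshold(two_clique_similarity, grid=np.array([0.0, 0.5]))

    @pytest.mark.parametrize("seed", range(20))
    def test_matches_brute_force_oracle_on_random_matrices(self, seed):
        """Threshold selection and clustering agree with an independently
        coded exhaustive oracle on random 10-node similarity matrices."""
        rng = np.random.default_rng(100 + seed)
        n = 10
        s = rng.random((n, n))
        s = (s + s.T) / 2
        np.fill_diagonal(s, 1.0)
        ids = [f"m{i}" for i in range(n)]
        sdf = pd.DataFrame(s, index=ids, columns=ids)
        grid = np.round(np.arange(0.01, 1.0, 0.01), 10)
        expected_tau = oracle_scan(s, grid)
        if expected_tau is None:
            with pytest.raises(NoThresholdError):
                select_threshold(sdf, grid)
            return
        scan = select_threshold(sdf, grid)
        assert scan.tau_star == pytest.approx(expected_tau, abs=1e-12)
        a = adjacency(sdf, scan.tau_star)
        got = {frozenset(c) for c in extract_clusters(a).clusters}
        exp = {
            frozenset(ids[i] for i in comp)
            for comp in oracle_components(a.to_numpy())
            if len(comp) >= 2
        }
        assert got == exp


class TestEndToEndRecovery:
    def test_planted_clusters_recovered_at_adequate_sample_size(self):
        """Two 6-member latent-factor clusters (loading 2.0, alpha=0.1) among
        40 miRNAs at 40 samples are both recovered with Jaccard >= 0.8 in a
        clear majority of seeds (86% in a 50-seed calibration)."""
        from rcmir.counts import normalize
        from rcmir.simulate import SimulationConfig, simulate_counts

        def jaccard(a, b):
            a, b = set(a), set(b)
            return len(a & b) / len(a | b)

        hits = 0
        n_seeds = 20
        for seed in range(n_seeds):
            cfg = SimulationConfig(
                n_mirnas=40, n_samples_per_group=40, groups=("control",),
                clusters=[(list(range(6)), 2.0), (list(range(6, 12)), 2.0)],
                dispersion=0.1, seed=seed,
            )
            cm, truth = simulate_counts(cfg)
            s = similarity_matrix(normalize(cm).values, nbins=3)
            try:
                scan = select_threshold(s)
            except NoThresholdError:
                continue
            cs = extract_clusters(adjacency(s, scan.tau_star))
            js = [
                max((jaccard(c, truth.members_of(k)) for c in cs.clusters),
                    default=0.0)
                for k in (0, 1)
            ]
            hits += min(js) >= 0.8
        assert hits >= 14

class TestAdjacency:
    def test_extremes_and_strict_boundary(self):
        s = pd.DataFrame([[1.0, 0.5], [0.5, 1.0]], index=["a", "b"],
                         columns=["a", "b"])
        assert adjacency(s, 0.5).to_numpy().sum() == 0  # strict inequality
        assert adjacency(s, 0.49).loc["a", "b"] == 1
        assert adjacency(s, 0.0).to_numpy().sum() == 2
        zero = adjacency(s, 0.99)
        assert zero.to_numpy().sum() == 0
        with pytest.raises(ValueError):
            adjacency(s, 1.5)


class TestExtractClusters:
    def test_two_cliques(self, two_clique_similarity):
        a = adjacency(two_clique_similarity, 0.5)
        cs = extract_clusters(a)
        assert [len(c) for c in cs.clusters] == [4, 4]
        assert len(cs.singletons) == 4

    def test_empty_graph_all_singletons(self):
        ids = list("abcde")
        a = pd.DataFrame(np.zeros((5, 5), dtype=int), index=ids, columns=ids)
        cs = extract_clusters(a)
        assert cs.clusters == []
        assert cs.singletons == ids

    def test_matches_union_find_oracle(self):
        rng = np.random.default_rng(9)
        n = 30
        a = (rng.random((n, n)) < 0.06).astype(int)
        a = np.triu(a, 1)
        a = a + a.T
        ids = [f"m{i:02d}" for i in range(n)]
        adf = pd.DataFrame(a, index=ids, columns=ids)
        cs = extract_clusters(adf)
        comps = oracle_components(a)
        exp_clusters = {frozenset(ids[i] for i in c) for c in comps if len(c) >= 2}
        exp_singles = sorted(ids[next(iter(c))] for c in comps if len(c) == 1)
        assert {frozenset(c) for c in cs.clusters} == exp_clusters
        assert cs.singletons == exp_singles

    def test_deterministic_ordering(self):
        ids = ["z", "y", "b", "a"]
        a = pd.DataFrame(0, index=ids, columns=ids)
        a.loc["z", "y"] = a.loc["y", "z"] = 1
        a.loc["b", "a"] = a.loc["a", "b"] = 1
        cs = extract_clusters(a)
        assert cs.clusters == [["a", "b"], ["y", "z"]]
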