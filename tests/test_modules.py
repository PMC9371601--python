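import itertools

import numpy as np
import pytest

from regentc import core
from regentc.modules import (
    MODULE_LABELS,
    ClusterAssignment,
    adjusted_rand_index,
    assign_early_cluster,
    clara_cluster,
    decompose_modules,
    export_heatmap_table,
    order_clusters_by_peak,
    pam,
    pam_exhaustive,
)

from conftest import make_matrix


class TestDecomposeModules:
    def test_seven_cell_example(self):
        out = decompose_modules(sucrose={"a", "b", "c"}, posterior={"b", "c", "d"}, anterior={"c", "e"})
        assert out == {
            "c": "general",
            "b": "OA_specific",
            "a": "sucrose_specific",
            "d": "posterior_specific",
            "e": "anterior_specific",
        }

    def test_disjoint_sets_single_paradigm_modules(self):
        out = decompose_modules({"a"}, {"b"}, {"c"})
        assert out == {
            "a": "sucrose_specific",
            "b": "anterior_specific",
            "c": "posterior_specific",
        }

    def test_identical_sets_all_general(self):
        s = {"x", "y"}
        out = decompose_modules(s, s, s)
        assert set(out.values()) == {"general"}

    def test_partition_property_random_sets(self):
        rng = np.random.default_rng(0)
        universe = [f"g{i}" for i in range(40)]
        for _ in range(50):
            S, A, P = (
                {g for g in universe if rng.random() < 0.4} for _ in range(3)
            )
            out = decompose_modules(S, A, P)
            assert set(out) == S | A | P
            # oracle: membership pattern determines the label uniquely
            for gene, label in out.items():
                pattern = (gene in S, gene in A, gene in P)
                expected = {
                    (True, True, True): "general",
                    (True, False, True): "OA_specific",
                    (False, True, True): "bisection_specific",
                    (True, False, False): "sucrose_specific",
                    (True, True, False): None,  # S and A only: not a stated cell
                    (False, False, True): "posterior_specific",
                    (False, True, False): "anterior_specific",
                }[pattern]
                if expected is not None:
                    assert label == expected

    def test_sucrose_and_anterior_only_goes_to_sucrose_specific(self):
        # the seventh Venn cell (S and A without P) has no named module; it is
        # folded into sucrose_specific by the if-cascade order
        out = decompose_modules({"x"}, {"x"}, set())
        assert out == {"x": "sucrose_specific"}


class TestAssignEarlyCluster:
    def _matrix(self, rows):
        return make_matrix(rows, times=[0, 30, 90, 240])

    def test_peak_at_30_included(self):
        m = self._matrix([[0.0, 5.0, 3.0, 1.0]])
        assert assign_early_cluster(m) == {"g0"}

    def test_peak_at_240_excluded(self):
        m = self._matrix([[0.0, 1.0, 3.0, 5.0]])
        assert assign_early_cluster(m) == set()

    def test_tie_broken_toward_inclusion(self):
        m = self._matrix([[0.0, 5.0, 3.0, 5.0]])
        assert assign_early_cluster(m) == {"g0"}

    def test_pre_onset_peak_ignored(self):
        m = self._matrix([[9.0, 1.0, 3.0, 2.0]])
        assert assign_early_cluster(m) == set()

    def test_missing_30min_column_rejected(self):
        m = make_matrix([[0.0, 5.0, 3.0]], times=[0, 60, 120])
        with pytest.raises(ValueError, match="30"):
            assign_early_cluster(m)


class TestPam:
    def test_k_equals_n_zero_cost(self):
        rng = np.random.default_rng(1)
        X = rng.random((5, 3))
        dist = np.linalg.norm(X[:, None] - X[None, :], axis=2)
        medoids, cost = pam(dist, 5)
        assert medoids == [0, 1, 2, 3, 4]
        assert cost == 0.0

    def test_matches_exhaustive_on_small_instances(self):
        rng = np.random.default_rng(2)
        for trial in range(25):
            n = int(rng.integers(4, 9))
            k = int(rng.integers(2, min(n, 4) + 1))
            X = rng.random((n, 2)) * 10
            dist = np.linalg.norm(X[:, None] - X[None, :], axis=2)
            _, cost = pam(dist, k)
            _, best_cost = pam_exhaustive(dist, k)
            assert cost == pytest.approx(best_cost, abs=1e-9)


class TestClara:
    def _planted(self, seed=0, n_per=15, sep=50.0):
        rng = np.random.default_rng(seed)
        a = rng.normal(0.0, 1.0, (n_per, 4))
        b = rng.normal(sep, 1.0, (n_per, 4))
        values = np.vstack([a, b])
        m = make_matrix(values, times=[0, 30, 60, 90], scale="zscore")
        truth = {f"g{i}": int(i >= n_per) for i in range(2 * n_per)}
        return m, truth

    def test_two_separated_archetypes_perfect_recovery(self):
        m, truth = self._planted()
        assignment = clara_cluster(m, k=2, seed=0)
        assert adjusted_rand_index(assignment.cluster_of, truth) == 1.0

    def test_small_n_equals_exhaustive_pam(self):
        rng = np.random.default_rng(3)
        for trial in range(10):
            n = int(rng.integers(5, 9))
            values = rng.random((n, 3))
            m = make_matrix(values, times=[0, 30, 60], scale="zscore")
            dist = np.linalg.norm(values[:, None] - values[None, :], axis=2)
            assignment = clara_cluster(m, k=3, seed=trial)
            medoid_idx = sorted(
                m.gene_ids.index(g) for g in assignment.medoid_genes.values()
            )
            from regentc.modules import _assignment_cost

            _, cost = _assignment_cost(dist, medoid_idx)
            _, best = pam_exhaustive(dist, 3)
            assert cost == pytest.approx(best, abs=1e-9)

    def test_cost_nonincreasing_in_subsamples(self):
        rng = np.random.default_rng(4)
        values = rng.random((120, 5))
        m = make_matrix(values, times=[0, 30, 60, 90, 120], scale="zscore")
        dist = np.linalg.norm(values[:, None] - values[None, :], axis=2)
        from regentc.modules import _assignment_cost

        costs = []
        for ns in (1, 3, 6):
            assignment = clara_cluster(m, k=3, n_subsamples=ns, subsample_size=20, seed=9)
            medoid_idx = [m.gene_ids.index(g) for g in assignment.medoid_genes.values()]
            costs.append(_assignment_cost(dist, medoid_idx)[1])
        assert costs[0] >= costs[1] - 1e-9 >= costs[2] - 2e-9

    def test_k_larger_than_n_rejected(self):
        m = make_matrix(np.random.default_rng(0).random((3, 4)), scale="zscore")
        with pytest.raises(ValueError, match="k="):
            clara_cluster(m, k=5)

    def test_deterministic_under_seed(self):
        m, _ = self._planted(seed=5, n_per=30)
        a1 = clara_cluster(m, k=2, subsample_size=20, seed=7)
        a2 = clara_cluster(m, k=2, subsample_size=20, seed=7)
        assert a1.cluster_of == a2.cluster_of

    def test_indices_start_at_two(self):
        m, _ = self._planted()
        assignment = clara_cluster(m, k=2, seed=0)
        assert set(assignment.cluster_of.values()) == {2, 3}


class TestOrderClustersByPeak:
    def _profiles(self):
        # g0 peaks at 90, g1 peaks at 300
        return make_matrix(
            [[0.0, 5.0, 1.0, 0.0], [0.0, 1.0, 2.0, 6.0]], times=[0, 90, 180, 300]
        )

    def test_orders_by_peak_time(self):
        profiles = self._profiles()
        assignment = ClusterAssignment({"g0": 3, "g1": 2})
        ordered = order_clusters_by_peak(assignment, profiles)
        assert ordered.cluster_of == {"g0": 2, "g1": 3}

    def test_membership_preserved(self):
        profiles = self._profiles()
        assignment = ClusterAssignment({"g0": 3, "g1": 2})
        ordered = order_clusters_by_peak(assignment, profiles)
        assert set(ordered.cluster_of) == set(assignment.cluster_of)
        assert sorted(ordered.cluster_of.values()) == sorted(
            assignment.cluster_of.values()
        )

    def test_idempotent(self):
        profiles = self._profiles()
        assignment = ClusterAssignment({"g0": 3, "g1": 2})
        once = order_clusters_by_peak(assignment, profiles)
        twice = order_clusters_by_peak(once, profiles)
        assert once.cluster_of == twice.cluster_of

    def test_cluster_one_untouched(self):
        profiles = self._profiles()
        assignment = ClusterAssignment({"g0": 1, "g1": 2})
        ordered = order_clusters_by_peak(assignment, profiles)
        assert ordered.cluster_of["g0"] == 1


class TestAdjustedRandIndex:
    def test_identical_partitions(self):
        labels = {"a": 1, "b": 1, "c": 2}
        assert adjusted_rand_index(labels, labels) == 1.0

    def test_label_permutation_invariant(self):
        a = {"a": 1, "b": 1, "c": 2, "d": 2}
        b = {"a": 9, "b": 9, "c": 4, "d": 4}
        assert adjusted_rand_index(a, b) == 1.0

    def test_mismatched_gene_sets_rejected(self):
        with pytest.raises(ValueError, match="different gene sets"):
            adjusted_rand_index({"a": 1}, {"b": 1})

    def test_matches_pair_counting_oracle(self):
        def ari_pairs(la, lb):
            genes = sorted(la)
            same_a = same_b = same_both = 0
            n_pairs = 0
            for g1, g2 in itertools.combinations(genes, 2):
                n_pairs += 1
                sa = la[g1] == la[g2]
                sb = lb[g1] == lb[g2]
                same_a += sa
                same_b += sb
                same_both += sa and sb
            expected = same_a * same_b / n_pairs
            max_index = (same_a + same_b) / 2
            if max_index == expected:
                return 1.0
            return (same_both - expected) / (max_index - expected)

        rng = np.random.default_rng(8)
        for _ in range(30):
            genes = [f"g{i}" for i in range(10)]
            la = {g: int(rng.integers(0, 3)) for g in genes}
            lb = {g: int(rng.integers(0, 3)) for g in genes}
            assert adjusted_rand_index(la, lb) == pytest.approx(ari_pairs(la, lb), abs=1e-12)


class TestExportHeatmapTable:
    def test_rows_grouped_by_cluster_and_round_trip(self, tmp_path):
        rng = np.random.default_rng(9)
        values = rng.random((10, 5))
        m = core.zscore_rows(make_matrix(values, scale="log"))
        assignment = ClusterAssignment({f"g{i}": (i % 5) + 1 for i in range(10)})
        path = tmp_path / "heatmap.tsv"
        export_heatmap_table(m, assignment, path)

        import pandas as pd

        back = pd.read_csv(path, sep="\t", index_col=0)
        clusters = back["cluster"].tolist()
        assert clusters == sorted(clusters)
        for gene in back.index:
            np.testing.assert_allclose(
                back.loc[gene].drop("cluster").to_numpy(), m.row(gene), rtol=1e-12
            )

    def test_requires_zscore_scale(self, tmp_path):
        m = make_matrix([[1.0, 2.0]], scale="log")
        with pytest.raises(ValueError, match="z-scored"):
            export_heatmap_table(m, ClusterAssignment({"g0": 1}), tmp_path / "x.tsv")


class TestSyntheticClusterRecovery:
    def test_per_module_ari(self, averaged_sim):
        cfg, averaged, _, truth = averaged_sim
        from regentc.pipeline import CLUSTERING_PARADIGM

        for module in MODULE_LABELS:
            genes = sorted(truth.module_genes(module))
            profiles = averaged.subset_paradigm(CLUSTERING_PARADIGM[module]).subset_genes(genes)
            try:
                early = assign_early_cluster(profiles)
                k = 4
            except ValueError:
                early = set()
                k = 5
            rest = [g for g in genes if g not in early]
            cluster_of = {g: 1 for g in early}
            assignment = clara_cluster(core.zscore_rows(profiles.subset_genes(rest)), k=k, seed=0)
            assignment = order_clusters_by_peak(assignment, profiles.subset_genes(rest))
            cluster_of.update(assignment.cluster_of)
            ari = adjusted_rand_index(cluster_of, {g: truth.cluster[g] for g in genes})
            assert ari >= 0.8, f"{module}: ARI {ari:.3f}"
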