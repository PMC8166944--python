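"""Log transform, distances, Ward.D2 clustering, leaf sorting, grouping."""

import numpy as np
import pytest

from caninemsk.synergy import (
    SynergyDendrogram,
    cut_longest_branches,
    distance_matrix,
    extract_synergies,
    log_activation,
    sort_leaves_minimal,
    to_newick,
    ward2_cluster,
)
from caninemsk.synthetic import (
    PlantedSynergySpec,
    make_archetype_activations,
    make_planted_activations,
)


def _adjusted_rand(a, b) -> float:
    """Adjusted Rand index from the pair-counting contingency table."""
    a = np.asarray(a)
    b = np.asarray(b)
    n = a.size
    cats_a, cats_b = np.unique(a), np.unique(b)
    table = np.array([[(np.sum((a == ca) & (b == cb))) for cb in cats_b] for ca in cats_a])
    comb = lambda x: x * (x - 1) / 2.0
    sum_ij = comb(table).sum()
    sum_a = comb(table.sum(axis=1)).sum()
    sum_b = comb(table.sum(axis=0)).sum()
    expected = sum_a * sum_b / comb(n)
    max_index = 0.5 * (sum_a + sum_b)
    if max_index == expected:
        return 1.0
    return float((sum_ij - expected) / (max_index - expected))


class TestLogActivation:
    @pytest.mark.parametrize("a,expected", [(1.0, 0.0), (0.25, -2.0), (0.0, -10.0)])
    def test_examples(self, a, expected):
        assert log_activation(np.array([[a]]))[0, 0] == expected

    def test_floor_must_be_positive(self):
        with pytest.raises(ValueError):
            log_activation(np.zeros((2, 2)), floor=0.0)


class TestDistanceMatrix:
    def test_identical_rows_zero(self):
        X = np.tile(np.linspace(0, 1, 10), (3, 1))
        assert np.allclose(distance_matrix(X), 0.0)

    def test_three_four_five(self):
        D = distance_matrix(np.array([[0.0, 0.0], [3.0, 4.0]]))
        assert D[0, 1] == pytest.approx(5.0)

    def test_matches_brute_force_double_loop(self, rng):
        X = rng.normal(size=(6, 50))
        D = distance_matrix(X)
        for i in range(6):
            for j in range(6):
                want = np.sqrt(np.sum((X[i] - X[j]) ** 2))
                assert abs(D[i, j] - want) <= 1e-12

    def test_missing_values_rejected(self):
        X = np.zeros((3, 4))
        X[1, 2] = np.nan
        with pytest.raises(ValueError):
            distance_matrix(X)


def _lance_williams_ward2(D):
    """Brute-force Ward.D2 agglomeration: squared-distance update,
    square-root heights.  Returns the merge list [(i, j, height, size)]
    with scipy-style new-cluster ids."""
    n = D.shape[0]
    d2 = D.astype(float) ** 2
    active = {i: (i, 1) for i in range(n)}  # slot -> (cluster id, size)
    dist = {}
    for i in range(n):
        for j in range(i + 1, n):
            dist[(i, j)] = d2[i, j]
    merges = []
    next_id = n
    slots = list(range(n))
    while len(slots) > 1:
        best = min(
            ((dist[tuple(sorted((p, q)))], p, q) for k, p in enumerate(slots)
             for q in slots[k + 1:]),
        )
        _, p, q = best
        key = tuple(sorted((p, q)))
        h = np.sqrt(dist[key])
        (id_p, n_p), (id_q, n_q) = active[p], active[q]
        merges.append((min(id_p, id_q), max(id_p, id_q), h, n_p + n_q))
        for r in slots:
            if r in (p, q):
                continue
            n_r = active[r][1]
            t = n_p + n_q + n_r
            d_new = (
                (n_p + n_r) * dist[tuple(sorted((p, r)))]
                + (n_q + n_r) * dist[tuple(sorted((q, r)))]
                - n_r * dist[key]
            ) / t
            dist[tuple(sorted((p, r)))] = d_new
        active[p] = (next_id, n_p + n_q)
        next_id += 1
        slots.remove(q)
    return merges


class TestWard2:
    def test_two_identical_pairs_merge_at_zero(self):
        X = np.array([[0.0, 0.0], [0.0, 0.0], [5.0, 5.0], [5.0, 5.0]])
        tree = ward2_cluster(distance_matrix(X))
        assert tree.linkage[0, 2] == pytest.approx(0.0, abs=1e-12)
        assert tree.linkage[1, 2] == pytest.approx(0.0, abs=1e-12)

    def test_singleton_merge_height_is_euclidean_distance(self):
        """Under ward.D2, two singletons merge at their plain distance."""
        D = distance_matrix(np.array([[0.0, 0.0], [3.0, 4.0]]))
        tree = ward2_cluster(D)
        assert tree.linkage[0, 2] == pytest.approx(5.0)

    def test_matches_lance_williams_oracle_on_5_points(self, rng):
        for _ in range(10):
            X = rng.normal(size=(5, 7))
            D = distance_matrix(X)
            tree = ward2_cluster(D)
            oracle = _lance_williams_ward2(D)
            for row, (i, j, h, size) in zip(tree.linkage, oracle):
                assert {int(row[0]), int(row[1])} == {i, j}
                assert row[2] == pytest.approx(h, abs=1e-10)
                assert int(row[3]) == size

    def test_translation_invariance(self, rng):
        X = rng.normal(size=(6, 20))
        t1 = ward2_cluster(distance_matrix(X))
        t2 = ward2_cluster(distance_matrix(X + 7.3))
        assert np.allclose(t1.linkage, t2.linkage)

    def test_heights_nondecreasing(self, rng):
        X = rng.normal(size=(12, 30))
        tree = ward2_cluster(distance_matrix(X))
        assert np.all(np.diff(tree.linkage[:, 2]) >= -1e-12)

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError):
            ward2_cluster(np.zeros((1, 1)))


class TestSortLeavesMinimal:
    def test_lower_subtree_first(self):
        # leaves 0,1 merge at 1.0; leaves 2,3 at 0.5; root joins them
        Z = np.array([[0.0, 1.0, 1.0, 2], [2.0, 3.0, 0.5, 2], [4.0, 5.0, 3.0, 4]])
        tree = SynergyDendrogram(linkage=Z, labels=list("abcd"))
        assert sort_leaves_minimal(tree) == [2, 3, 0, 1]

    def test_tie_preserves_input_order(self):
        Z = np.array([[0.0, 1.0, 1.0, 2], [2.0, 3.0, 1.0, 2], [4.0, 5.0, 3.0, 4]])
        tree = SynergyDendrogram(linkage=Z, labels=list("abcd"))
        assert sort_leaves_minimal(tree) == [0, 1, 2, 3]

    def test_min_first_property_on_random_trees(self, rng):
        for _ in range(5):
            X = rng.normal(size=(10, 8))
            tree = ward2_cluster(distance_matrix(X))
            order = sort_leaves_minimal(tree)
            assert sorted(order) == list(range(10))
            pos = {leaf: k for k, leaf in enumerate(order)}
            for node in range(10, 2 * 10 - 1):
                left, right = tree.children(node)
                hl, hr = tree.node_height(left), tree.node_height(right)
                first = min(tree.leaves_under(left), key=pos.get)
                second = min(tree.leaves_under(right), key=pos.get)
                if pos[first] > pos[second]:
                    assert hr <= hl  # placed-first subtree has the lower height


class TestCutLongestBranches:
    def test_three_planted_clusters_zero_noise(self):
        X = np.vstack([
            np.tile([0.0, 0.0], (4, 1)),
            np.tile([10.0, 0.0], (4, 1)),
            np.tile([5.0, 8.66], (4, 1)),  # near-equilateral cluster centres
        ])
        tree = ward2_cluster(distance_matrix(X))
        groups = cut_longest_branches(tree, level="main")
        truth = np.repeat([0, 1, 2], 4)
        assert _adjusted_rand(truth, groups.main) == 1.0
        assert len(groups.group_nodes) == 3

    def test_all_identical_rows_single_group(self):
        X = np.tile([1.0, 2.0, 3.0], (5, 1))
        tree = ward2_cluster(distance_matrix(X))
        groups = cut_longest_branches(tree, level="sub")
        assert len(set(groups.main)) == 1

    def test_planted_three_by_two_recovery(self):
        A, main, sub = make_planted_activations(PlantedSynergySpec(sigma=0.05, seed=1))
        tree, groups = extract_synergies(A)
        assert _adjusted_rand(main, groups.main) == 1.0
        assert _adjusted_rand(sub, groups.sub) == 1.0
        assert len(groups.group_nodes) == 3

    def test_bad_level_rejected(self):
        X = np.random.default_rng(0).normal(size=(4, 4))
        tree = ward2_cluster(distance_matrix(X))
        with pytest.raises(ValueError):
            cut_longest_branches(tree, level="extra")


class TestPipelineProperties:
    def test_permutation_invariance(self, rng):
        A, main, sub = make_planted_activations(PlantedSynergySpec(sigma=0.05, seed=3))
        perm = rng.permutation(A.shape[0])
        _, g1 = extract_synergies(A)
        _, g2 = extract_synergies(A[perm])
        assert _adjusted_rand(g1.main[perm], g2.main) == 1.0
        assert _adjusted_rand(g1.sub[perm], g2.sub) == 1.0

    def test_recovery_rate_and_graceful_degradation(self):
        """>= 0.95 perfect recovery at sigma 0.05; mean ARI decays with noise."""
        means = []
        for sigma, n_seeds in ((0.05, 100), (0.2, 25), (0.5, 25)):
            aris = []
            for seed in range(n_seeds):
                A, main, _ = make_planted_activations(
                    PlantedSynergySpec(sigma=sigma, seed=seed)
                )
                _, groups = extract_synergies(A)
                aris.append(_adjusted_rand(main, groups.main))
            if sigma == 0.05:
                assert np.mean(np.array(aris) == 1.0) >= 0.95
            means.append(np.mean(aris))
        assert means[0] > means[1] > means[2]

    def test_stance_and_swing_archetypes_separate(self):
        """Stance-dominated and swing-dominated muscles land in different
        main groups."""
        A, names, _ = make_archetype_activations()
        _, groups = extract_synergies(A, labels=names)
        ext = [k for k, n in enumerate(names) if n.startswith("stance_extensor")]
        pro = [k for k, n in enumerate(names) if n.startswith("swing_protractor")]
        assert set(groups.main[ext]).isdisjoint(set(groups.main[pro]))


class TestNewickExport:
    def test_parseable_and_complete(self):
        import dendropy

        A, _, _ = make_planted_activations(PlantedSynergySpec(sigma=0.05, seed=0))
        labels = [f"mus_{i}" for i in range(A.shape[0])]
        tree, _ = extract_synergies(A, labels=labels)
        newick = to_newick(tree)
        parsed = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
        taxa = {leaf.taxon.label for leaf in parsed.leaf_node_iter()}
        assert taxa == set(labels)

    def test_branch_lengths_telescope_to_root_height(self):
        A, _, _ = make_planted_activations(PlantedSynergySpec(sigma=0.05, seed=0))
        tree, _ = extract_synergies(A)
        import dendropy

        parsed = dendropy.Tree.get(data=to_newick(tree), schema="newick")
        root_h = tree.node_height(tree.root)
        # distance from root to any leaf telescopes to the root height
        depths = parsed.calc_node_root_distances(return_leaf_distances_only=True)
        assert np.allclose(depths, root_h, atol=1e-6)
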