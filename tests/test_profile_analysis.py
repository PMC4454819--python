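"""Ward clustering, two-cluster cut, Newick export and the gain-ratio tree."""

import itertools

import numpy as np
import pytest

from ezmetric import (
    EZScore,
    ValidationError,
    build_profile,
    build_tree,
    cross_validate,
    cut_two,
    profile_matrix,
    to_newick,
    ward_cluster,
)
from ezmetric.assay_io import SURFACE_GROUPS


def prof(material, pairs):
    return build_profile([EZScore(material, c, s, 10) for c, s in pairs])


GRID = [1.0, 5.0, 25.0, 125.0]


class TestProfileMatrix:
    def test_complete_grid(self):
        profiles = [prof(m, [(c, 0.1 * i) for c in GRID]) for i, m in enumerate("abc")]
        M = profile_matrix(profiles, GRID)
        assert M.shape == (3, 4)
        assert M.loc["b"].tolist() == [0.1] * 4

    def test_missing_cell_error_policy(self):
        profiles = [prof("a", [(c, 0.1) for c in GRID[:3]])]
        with pytest.raises(ValidationError, match="125"):
            profile_matrix(profiles, GRID)

    def test_missing_cell_zero_policy_warns(self):
        profiles = [prof("a", [(c, 0.1) for c in GRID[:3]])]
        with pytest.warns(UserWarning, match="filling"):
            M = profile_matrix(profiles, GRID, policy="zero")
        assert M.loc["a", 125.0] == 0.0

    def test_interior_gap_interpolates_in_log(self):
        profiles = [prof("a", [(1.0, 0.1), (25.0, 0.5), (125.0, 0.9)])]
        M = profile_matrix(profiles, GRID, policy="interpolate")
        # 5 ppm is halfway between 1 and 25 in log space
        assert M.loc["a", 5.0] == pytest.approx(0.3)

    def test_default_grid_is_union(self):
        profiles = [prof("a", [(1.0, 0.1), (5.0, 0.2)]), prof("b", [(1.0, 0.0), (5.0, 0.1)])]
        M = profile_matrix(profiles)
        assert list(M.columns) == [1.0, 5.0]


def brute_force_ward_merges(X):
    """Greedy Ward oracle computing each merge cost from raw coordinates.

    At every step, for every pair of clusters, the increase in within-cluster
    sum of squares of the merged cluster is computed from scratch; the
    cheapest pair merges.  Returns the sequence of (members, cost) merges.
    """

    def sse(idx):
        pts = X[list(idx)]
        return float(((pts - pts.mean(axis=0)) ** 2).sum())

    clusters = [frozenset([i]) for i in range(len(X))]
    merges = []
    while len(clusters) > 1:
        best = None
        for a, b in itertools.combinations(range(len(clusters)), 2):
            cost = sse(clusters[a] | clusters[b]) - sse(clusters[a]) - sse(clusters[b])
            key = (cost, tuple(sorted((min(clusters[a]), min(clusters[b])))))
            if best is None or key < best[0]:
                best = (key, a, b)
        (cost, _), a, b = best
        merged = clusters[a] | clusters[b]
        merges.append((merged, cost))
        clusters = [c for k, c in enumerate(clusters) if k not in (a, b)] + [merged]
    return merges


def collect_merges(node, acc):
    if not node.is_leaf:
        acc.append((frozenset(int(m) for m in node.members), node.height))
        for child in node.children:
            collect_merges(child, acc)
    return acc


class TestWardCluster:
    def test_identical_rows_merge_at_zero(self):
        X = np.array([[1.0, 2.0], [1.0, 2.0], [5.0, 5.0]])
        root = ward_cluster(X)
        first = min(collect_merges(root, []), key=lambda m: m[1])
        assert first == (frozenset({0, 1}), 0.0)

    def test_two_tight_pairs_split_at_top(self):
        X = np.array([[0.0, 0.0], [0.1, 0.0], [10.0, 10.0], [10.1, 10.0]])
        root = ward_cluster(X)
        top_members = {frozenset(int(m) for m in c.members) for c in root.children}
        assert top_members == {frozenset({0, 1}), frozenset({2, 3})}

    def test_matches_brute_force_oracle_small_n(self, rng):
        """Merge sequence and costs equal the exhaustive greedy Ward optimum."""
        for _ in range(15):
            n = int(rng.integers(3, 7))
            X = rng.normal(size=(n, 3))
            root = ward_cluster(X)
            mine = sorted(collect_merges(root, []), key=lambda m: m[1])
            oracle = sorted(brute_force_ward_merges(X), key=lambda m: m[1])
            for (m_members, m_cost), (o_members, o_cost) in zip(mine, oracle):
                assert m_members == o_members
                assert m_cost == pytest.approx(o_cost)

    def test_heights_match_scipy_ward(self, rng):
        """Independent cross-check: SciPy Ward heights h satisfy cost = h^2/2."""
        from scipy.cluster.hierarchy import linkage

        X = rng.normal(size=(12, 5))
        heights = sorted(h for _, h in collect_merges(ward_cluster(X), []))
        ref = sorted(linkage(X, method="ward")[:, 2] ** 2 / 2)
        assert np.allclose(heights, ref)

    def test_heights_monotone_along_root_paths(self, rng):
        X = rng.normal(size=(10, 4))

        def check(node):
            for child in node.children:
                assert child.height <= node.height + 1e-12
                check(child)

        check(ward_cluster(X))

    def test_row_order_invariance(self, rng):
        X = rng.normal(size=(8, 3))
        labels = [f"m{i}" for i in range(8)]
        root = ward_cluster(X, labels=labels)
        perm = rng.permutation(8)
        root_p = ward_cluster(X[perm], labels=[labels[i] for i in perm])

        def collect_str(node, acc):
            if not node.is_leaf:
                acc.append((node.members, round(node.height, 9)))
                for c in node.children:
                    collect_str(c, acc)
            return acc

        assert set(collect_str(root, [])) == set(collect_str(root_p, []))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValidationError):
            ward_cluster(np.array([[1.0, np.nan], [0.0, 0.0]]))


class TestCutTwoAndNewick:
    def make_root(self):
        X = np.array([[0.0, 0.0], [0.2, 0.1], [5.0, 5.0], [5.2, 5.1]])
        return ward_cluster(X, labels=["low1", "low2", "high1", "high2"])

    def test_higher_mean_sumez_labeled_b(self):
        root = self.make_root()
        sumez = {"low1": 0.4, "low2": 0.6, "high1": 3.0, "high2": 3.2}
        assign = cut_two(root, sumez)
        assert assign.members("B") == {"high1", "high2"}
        assert assign.summaries["B"]["mean"] == pytest.approx(3.1)
        assert assign.summaries["A"]["max"] == pytest.approx(0.6)

    def test_equal_means_tie_warns(self):
        root = self.make_root()
        sumez = dict.fromkeys(["low1", "low2", "high1", "high2"], 1.0)
        with pytest.warns(UserWarning, match="equal mean"):
            assign = cut_two(root, sumez)
        assert assign.labels["high1"] != assign.labels["low1"]

    def test_leaf_root_rejected(self):
        from ezmetric.profile_analysis import DendrogramNode

        with pytest.raises(ValidationError):
            cut_two(DendrogramNode(frozenset({"a"}), 0.0), {"a": 1.0})

    def test_newick_round_trips_through_dendropy(self):
        import dendropy

        root = self.make_root()
        tree = dendropy.Tree.get(data=to_newick(root), schema="newick")
        assert sorted(l.taxon.label for l in tree.leaf_node_iter()) == [
            "high1",
            "high2",
            "low1",
            "low2",
        ]
        # root-to-leaf distance equals the root merge cost (leaf heights are 0)
        depths = [l.distance_from_root() for l in tree.leaf_node_iter()]
        assert max(depths) == pytest.approx(root.height)


def rule_labels(features):
    """B iff any surface group present — exactly representable by the tree."""
    return {
        m: ("B" if any(groups.values()) else "A") for m, groups in features.items()
    }


def panel_features(rng, n=40):
    feats = {}
    for i in range(n):
        groups = {g: False for g in SURFACE_GROUPS}
        if rng.random() < 0.5:
            groups[SURFACE_GROUPS[rng.integers(4)]] = True
        feats[f"m{i:02d}"] = groups
    return feats


class TestBuildTree:
    def test_pure_labels_single_leaf(self):
        feats = {"a": dict.fromkeys(SURFACE_GROUPS, False), "b": dict.fromkeys(SURFACE_GROUPS, True)}
        tree = build_tree(feats, {"a": "A", "b": "A"})
        assert tree.is_leaf and tree.label == "A"

    def test_perfectly_separating_feature_becomes_root(self, rng):
        """A single fully informative feature maximizes the gain ratio."""
        feats = {}
        labels = {}
        for i in range(20):
            groups = {g: bool(rng.integers(2)) for g in SURFACE_GROUPS}
            groups["phosphate"] = i % 2 == 0
            feats[f"m{i}"] = groups
            labels[f"m{i}"] = "B" if groups["phosphate"] else "A"
        tree = build_tree(feats, labels)
        assert tree.feature == "phosphate"
        assert tree.branch_true.label == "B"
        assert tree.branch_false.label == "A"

    def test_any_of_four_rule_fits_exactly(self, rng):
        feats = panel_features(rng)
        labels = rule_labels(feats)
        tree = build_tree(feats, labels)
        for m, groups in feats.items():
            assert tree.predict(groups) == labels[m]

    def test_depth_never_exceeds_feature_count(self, rng):
        for _ in range(10):
            feats = {
                f"m{i}": {g: bool(rng.integers(2)) for g in SURFACE_GROUPS}
                for i in range(16)
            }
            labels = {m: ("A" if rng.random() < 0.5 else "B") for m in feats}
            assert build_tree(feats, labels).depth() <= 4

    def test_majority_tie_goes_to_a(self):
        feats = {
            "a": dict.fromkeys(SURFACE_GROUPS, False),
            "b": dict.fromkeys(SURFACE_GROUPS, False),
        }
        tree = build_tree(feats, {"a": "A", "b": "B"})
        assert tree.is_leaf and tree.label == "A"


class TestCrossValidate:
    def test_loo_perfect_on_consistent_rule(self, rng):
        feats = panel_features(rng)
        result = cross_validate(feats, rule_labels(feats), scheme="loo")
        assert result.accuracy == 1.0
        assert result.misclassified == ()

    def test_random_labels_near_majority_fraction(self, rng):
        feats = panel_features(rng, n=200)
        labels = {m: ("A" if rng.random() < 0.5 else "B") for m in feats}
        majority = max(
            sum(1 for v in labels.values() if v == lab) for lab in "AB"
        ) / len(labels)
        result = cross_validate(feats, labels, scheme="kfold", k=10, seed=3)
        assert abs(result.accuracy - majority) <= 0.1

    def test_kfold_deterministic_in_seed(self, rng):
        feats = panel_features(rng, n=60)
        labels = rule_labels(feats)
        noisy = dict(labels)
        for m in list(noisy)[::7]:
            noisy[m] = "A" if noisy[m] == "B" else "B"
        r1 = cross_validate(feats, noisy, scheme="kfold", k=10, seed=11)
        r2 = cross_validate(feats, noisy, scheme="kfold", k=10, seed=11)
        assert (r1.accuracy, r1.misclassified) == (r2.accuracy, r2.misclassified)

    def test_accuracy_consistent_with_misclassified(self, rng):
        feats = panel_features(rng, n=30)
        labels = rule_labels(feats)
        noisy = dict(labels)
        flip = sorted(noisy)[::5]
        for m in flip:
            noisy[m] = "A" if noisy[m] == "B" else "B"
        result = cross_validate(feats, noisy, scheme="loo")
        assert result.accuracy == pytest.approx(1 - len(result.misclassified) / 30)

    def test_kfold_needs_enough_rows(self, rng):
        feats = panel_features(rng, n=5)
        with pytest.raises(ValidationError):
            cross_validate(feats, rule_labels(feats), scheme="kfold", k=10)
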