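"""Covariates, Kruskal-Wallis and CART."""

import itertools

import numpy as np
import pytest
from shapely.geometry import Point

from ehacube.drivers import (euclidean_distance_map, fit_cart,
                             kruskal_wallis, predict_cart,
                             slope_from_elevation, category_summaries)
from ehacube.io import GridTransform

import pandas as pd


def transform_for(rows, cell=1000.0):
    return GridTransform(0.0, rows * cell, cell)


class TestDistanceMap:
    def test_coincident_feature_gives_zero(self):
        t = transform_for(4)
        feats = [Point(t.centroid(1, 2)[0], t.centroid(1, 2)[1])]
        d = euclidean_distance_map(t, (4, 4), feats)
        assert d[1, 2] == 0.0

    def test_matches_bruteforce_from_corner_feature(self):
        t = transform_for(6)
        fx, fy = 0.0, 6000.0  # grid's top-left corner
        d = euclidean_distance_map(t, (6, 6), [Point(fx, fy)])
        for r in range(6):
            for c in range(6):
                cx, cy = t.centroid(r, c)
                assert d[r, c] == pytest.approx(np.hypot(cx - fx, cy - fy))

    def test_two_features_elementwise_min(self):
        t = transform_for(5)
        a, b = Point(0, 0), Point(5000, 5000)
        d_both = euclidean_distance_map(t, (5, 5), [a, b])
        d_a = euclidean_distance_map(t, (5, 5), [a])
        d_b = euclidean_distance_map(t, (5, 5), [b])
        np.testing.assert_allclose(d_both, np.minimum(d_a, d_b))

    def test_adding_feature_never_increases_distance(self):
        rng = np.random.default_rng(4)
        t = transform_for(8)
        feats = [Point(x, y) for x, y in rng.uniform(0, 8000, size=(3, 2))]
        d3 = euclidean_distance_map(t, (8, 8), feats)
        d4 = euclidean_distance_map(t, (8, 8),
                                    feats + [Point(4000, 4000)])
        assert (d4 <= d3 + 1e-9).all()

    def test_empty_feature_set_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            euclidean_distance_map(transform_for(4), (4, 4), [])


class TestSlope:
    def test_constant_elevation_zero_slope(self):
        assert (slope_from_elevation(np.full((5, 5), 123.0), 30.0) == 0).all()

    def test_inclined_plane_45_degrees(self):
        x = np.arange(8, dtype=float)
        z = np.tile(x, (8, 1))  # z = x, 1 m cells
        slope = slope_from_elevation(z, 1.0)
        np.testing.assert_allclose(slope[1:-1, 1:-1], 45.0, atol=1e-9)

    def test_rotation_leaves_magnitude_unchanged(self):
        x = np.arange(8, dtype=float)
        zx = np.tile(x, (8, 1))
        zy = zx.T.copy()
        sx = slope_from_elevation(zx, 1.0)
        sy = slope_from_elevation(zy, 1.0)
        np.testing.assert_allclose(sx[1:-1, 1:-1], sy[1:-1, 1:-1], atol=1e-9)

    def test_tiny_grid_rejected(self):
        with pytest.raises(ValueError):
            slope_from_elevation(np.zeros((2, 5)), 1.0)


class TestSummaries:
    def test_hand_computed_fixture(self):
        from test_overlay import make_map
        names = np.array([["persistent", "persistent", "sporadic"],
                          ["sporadic", "sporadic", "none"]], dtype=object)
        cmap = make_map(names)
        cov = np.array([[1.0, 3.0, 10.0],
                        [20.0, 30.0, 99.0]])
        table = category_summaries(cmap, {"footprint": cov})
        pers = table[table.category == "persistent"].iloc[0]
        assert pers["mean"] == pytest.approx(2.0)
        assert pers["sem"] == pytest.approx(np.std([1, 3], ddof=1) / np.sqrt(2))
        assert pers["n"] == 2
        spor = table[table.category == "sporadic"].iloc[0]
        assert spor["mean"] == pytest.approx(20.0)
        assert spor["n"] == 3
        assert "none" not in set(table.category)

    def test_single_member_category_sem_zero(self):
        from test_overlay import make_map
        names = np.array([["new", "none"], ["none", "none"]], dtype=object)
        cmap = make_map(names)
        table = category_summaries(cmap, {"elev": np.ones((2, 2))})
        row = table.iloc[0]
        assert row["sem"] == 0.0 and row["n"] == 1

    def test_constant_covariate_sem_zero(self):
        from test_overlay import make_map
        names = np.array([["new", "new"], ["sporadic", "sporadic"]],
                         dtype=object)
        cmap = make_map(names)
        table = category_summaries(cmap, {"c": np.full((2, 2), 5.0)})
        assert (table["sem"] == 0).all()


class TestKruskalWallis:
    def test_identical_groups(self):
        res = kruskal_wallis([[2.0, 2.0], [2.0, 2.0]])
        assert res.H == 0.0 and res.p == 1.0

    def test_textbook_fixture_exact_rank_arithmetic(self):
        # {1,2,3} vs {4,5,6}: R1=6, R2=15, no ties
        # H = 12/(6*7) * (36/3 + 225/3) - 21 = 27/7
        res = kruskal_wallis([[1, 2, 3], [4, 5, 6]])
        assert res.H == pytest.approx(27 / 7, abs=1e-12)
        assert res.H == pytest.approx(3.857, abs=1e-3)
        assert res.df == 1

    def test_matches_scipy_with_ties(self):
        from scipy.stats import kruskal
        rng = np.random.default_rng(11)
        groups = [np.round(rng.normal(size=n), 1) for n in (8, 12, 9)]
        res = kruskal_wallis(groups)
        H, p = kruskal(*groups)
        assert res.H == pytest.approx(H, rel=1e-12)
        assert res.p == pytest.approx(p, rel=1e-12)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(2)
        groups = [rng.normal(size=7), rng.normal(size=9)]
        a = kruskal_wallis(groups)
        b = kruskal_wallis([np.exp(g) for g in groups])
        assert a.H == pytest.approx(b.H, rel=1e-12)

    def test_chi_square_p_close_to_permutation_null(self):
        """Permutation check of the chi-square approximation on a small
        fixture (10,000 shuffles)."""
        rng = np.random.default_rng(8)
        g1 = [3.1, 4.2, 5.0, 6.3, 7.7, 2.2]
        g2 = [5.5, 6.1, 8.2, 9.0, 7.1, 8.8]
        obs = kruskal_wallis([g1, g2])
        pooled = np.array(g1 + g2)
        count = 0
        n_perm = 10_000
        for _ in range(n_perm):
            rng.shuffle(pooled)
            h = kruskal_wallis([pooled[:6], pooled[6:]]).H
            if h >= obs.H - 1e-12:
                count += 1
        p_perm = count / n_perm
        se = np.sqrt(max(p_perm * (1 - p_perm), 1e-6) / n_perm)
        assert abs(obs.p - p_perm) <= max(4 * se, 0.02)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0, 2.0]])
        with pytest.raises(ValueError):
            kruskal_wallis([[1.0], []])


def cart_bruteforce_root(X, y, criterion="gini"):
    """Exhaustive enumeration of all (feature, midpoint) root splits,
    returning the impurity-minimising pair with the implementation's
    tie-break (lowest feature, lowest threshold)."""
    n, d = X.shape
    classes = np.unique(y)
    best = None
    for j, thr in itertools.chain.from_iterable(
            (((j, t) for t in (np.unique(X[:, j])[:-1]
                               + np.unique(X[:, j])[1:]) / 2)
             for j in range(d))):
        left = X[:, j] < thr
        if left.sum() == 0 or (~left).sum() == 0:
            continue
        w = 0.0
        for side in (left, ~left):
            counts = np.array([(y[side] == c).sum() for c in classes],
                              dtype=float)
            p = counts / counts.sum()
            if criterion == "gini":
                imp = 1 - (p ** 2).sum()
            else:
                q = p[p > 0]
                imp = -(q * np.log(q)).sum()
            w += side.sum() / n * imp
        if best is None or w < best[0] - 1e-12:
            best = (w, j, thr)
    return best


class TestCart:
    def test_perfectly_separable_1d(self):
        X = np.array([[1.0], [2.0], [3.0], [11.0], [12.0], [13.0]])
        y = np.array(["a", "a", "a", "b", "b", "b"])
        tree = fit_cart(X, y, min_leaf=1)
        assert not tree.root.is_leaf
        assert 3.0 < tree.root.threshold < 11.0
        assert tree.root.left.impurity == 0.0
        assert tree.root.right.impurity == 0.0

    @pytest.mark.parametrize("criterion", ["gini", "cross_entropy"])
    def test_root_split_matches_bruteforce(self, criterion):
        X = np.array([[2.0, 7.0], [3.0, 1.0], [5.0, 9.0],
                      [6.0, 2.0], [8.0, 8.0], [9.0, 3.0]])
        y = np.array(["u", "u", "v", "u", "v", "v"])
        tree = fit_cart(X, y, min_leaf=1, criterion=criterion)
        _, j, thr = cart_bruteforce_root(X, y, criterion)
        assert tree.root.feature == j
        assert tree.root.threshold == pytest.approx(thr)

    def test_random_fixtures_root_matches_bruteforce(self):
        rng = np.random.default_rng(6)
        for _ in range(20):
            X = np.round(rng.uniform(0, 10, size=(12, 2)), 1)
            y = rng.choice(["a", "b"], size=12)
            if len(np.unique(y)) < 2:
                continue
            tree = fit_cart(X, y, min_leaf=1)
            brute = cart_bruteforce_root(X, y)
            if tree.root.is_leaf:
                continue  # no impurity-reducing split existed
            assert tree.root.feature == brute[1]
            assert tree.root.threshold == pytest.approx(brute[2])

    def test_planted_threshold_rule_recovered(self):
        """Labels generated by 'footprint >= 12 -> consecutive, else
        historical' with 5% label noise, n=2,000: the fitted root threshold
        falls within ±0.5 of 12."""
        rng = np.random.default_rng(42)
        n = 2000
        footprint = rng.uniform(0, 24, size=n)
        elevation = rng.uniform(0, 500, size=n)
        labels = np.where(footprint >= 12, "consecutive", "historical")
        flip = rng.random(n) < 0.05
        labels[flip] = np.where(labels[flip] == "consecutive",
                                "historical", "consecutive")
        X = np.column_stack([footprint, elevation])
        tree = fit_cart(X, labels, feature_names=["footprint", "elevation"])
        assert tree.feature_names[tree.root.feature] == "footprint"
        assert abs(tree.root.threshold - 12.0) <= 0.5
        # independent cross-check against scikit-learn's CART
        from sklearn.tree import DecisionTreeClassifier
        sk = DecisionTreeClassifier(max_depth=1, random_state=0).fit(X, labels)
        assert abs(tree.root.threshold - sk.tree_.threshold[0]) <= 0.5

    def test_first_two_split_variables_follow_generating_rule(self):
        """When the planted category depends on footprint and slope only,
        the tree's first two levels split on those variables, not on the
        noise distances."""
        rng = np.random.default_rng(9)
        n = 1500
        footprint = rng.uniform(0, 20, n)
        slope = rng.uniform(0, 10, n)
        dist = rng.uniform(0, 30000, n)  # irrelevant
        labels = np.where(footprint >= 10,
                          np.where(slope >= 4, "consecutive", "sporadic"),
                          "historical")
        X = np.column_stack([dist, footprint, slope])
        tree = fit_cart(X, labels,
                        feature_names=["dist", "footprint", "slope"],
                        min_leaf=0.02)
        used = {tree.feature_names[tree.root.feature]}
        for child in (tree.root.left, tree.root.right):
            if not child.is_leaf:
                used.add(tree.feature_names[child.feature])
        assert used <= {"footprint", "slope"}
        assert "footprint" in used and "slope" in used

    def test_single_label_yields_single_leaf(self):
        X = np.array([[1.0], [2.0], [3.0]])
        tree = fit_cart(X, np.array(["a", "a", "a"]))
        assert tree.root.is_leaf
        assert tree.root.prediction == "a"
        assert predict_cart(tree, [99.0]) == ("a", 100.0)

    def test_leaf_percentages_sum_to_100(self):
        rng = np.random.default_rng(14)
        X = rng.uniform(size=(200, 3))
        y = rng.choice(["a", "b", "c"], size=200)
        tree = fit_cart(X, y, max_depth=4, min_leaf=0.05)
        total = sum(leaf.pct_of_data for leaf in tree.leaves())
        assert total == pytest.approx(100.0, abs=1e-9)

    def test_impurity_nonincreasing_on_paths(self):
        rng = np.random.default_rng(15)
        X = rng.uniform(size=(300, 2))
        y = (X[:, 0] + 0.2 * rng.normal(size=300) > 0.5).astype(str)
        tree = fit_cart(X, y, max_depth=5, min_leaf=0.02)

        def walk(node):
            if node.is_leaf:
                return
            child_w = (node.left.pct_of_data * node.left.impurity
                       + node.right.pct_of_data * node.right.impurity) \
                / node.pct_of_data
            assert child_w <= node.impurity + 1e-12
            walk(node.left)
            walk(node.right)

        walk(tree.root)

    def test_threshold_tie_goes_right(self):
        X = np.array([[0.0], [2.0], [4.0], [6.0]])
        y = np.array(["a", "a", "b", "b"])
        tree = fit_cart(X, y, min_leaf=1)
        thr = tree.root.threshold  # 3.0, midpoint of 2 and 4
        label_at_thr, _ = predict_cart(tree, [thr])
        assert label_at_thr == "b"  # value == threshold goes right

    def test_prediction_reproduces_training_partition(self):
        rng = np.random.default_rng(19)
        X = rng.uniform(size=(100, 2))
        y = np.where(X[:, 0] < 0.5, "a", "b")
        tree = fit_cart(X, y, min_leaf=1)
        preds = [predict_cart(tree, row)[0] for row in X]
        assert (np.array(preds) == y).all()

    def test_missing_covariate_rejected(self):
        X = np.array([[1.0, 5.0], [2.0, 6.0], [3.0, 7.0], [4.0, 8.0]])
        y = np.array(["a", "a", "b", "b"])
        tree = fit_cart(X, y, min_leaf=1)
        with pytest.raises(ValueError, match="missing covariate"):
            predict_cart(tree, [1.0])
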