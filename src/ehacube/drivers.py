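"""Driver attribution: covariates, per-category summaries, Kruskal-Wallis
tests and CART decision trees.

The sampling unit throughout is one analysis location (bin) of the
category map. Covariates are topographic (elevation, Horn slope) and
anthropogenic (human footprint index, Euclidean distance to the nearest
oil-palm / wood-fiber plantation feature).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy.stats import chi2, rankdata

from ehacube.classify import CATEGORIES, CATEGORY_CODES, CategoryMap
from ehacube.io import GridTransform, geometry_list


def euclidean_distance_map(transform: GridTransform, shape: tuple[int, int],
                           feature_set) -> np.ndarray:
    """Straight-line distance (m) from every cell centroid to the nearest
    feature (point, line or polygon boundary/interior per shapely
    semantics). Rejects an empty feature set — the distance is undefined.
    """
    geoms = geometry_list(feature_set)
    if len(geoms) == 0:
        raise ValueError("feature_set is empty; distance undefined")
    rows, cols = shape
    rr, cc = np.mgrid[0:rows, 0:cols]
    x, y = transform.centroid(rr, cc)
    pts = shapely.points(np.column_stack([x.ravel(), y.ravel()]))
    d = np.min([shapely.distance(pts, g) for g in geoms], axis=0)
    return d.reshape(shape)


def slope_from_elevation(elevation: np.ndarray, cell_size: float) -> np.ndarray:
    """Terrain slope in degrees by Horn's 3x3 finite differences.

    Edge cells use clamped (edge-replicated) windows. For a plane of
    gradient g the interior slope is atan(g): z = x at 1 m cells gives 45°.
    """
    z = np.asarray(elevation, dtype=float)
    if z.ndim != 2 or min(z.shape) < 3:
        raise ValueError("elevation grid must be at least 3x3")
    zp = np.pad(z, 1, mode="edge")
    nw, n_, ne = zp[:-2, :-2], zp[:-2, 1:-1], zp[:-2, 2:]
    w_, e_ = zp[1:-1, :-2], zp[1:-1, 2:]
    sw, s_, se = zp[2:, :-2], zp[2:, 1:-1], zp[2:, 2:]
    dzdx = ((ne + 2 * e_ + se) - (nw + 2 * w_ + sw)) / (8 * cell_size)
    dzdy = ((sw + 2 * s_ + se) - (nw + 2 * n_ + ne)) / (8 * cell_size)
    return np.degrees(np.arctan(np.hypot(dzdx, dzdy)))


def aggregate_to_bins(pixel_grid: np.ndarray, factor: int) -> np.ndarray:
    """Block-mean a pixel-resolution covariate onto the bin grid (partial
    edge blocks average their available pixels)."""
    rows, cols = pixel_grid.shape
    brows, bcols = -(-rows // factor), -(-cols // factor)
    padded = np.full((brows * factor, bcols * factor), np.nan)
    padded[:rows, :cols] = pixel_grid
    blocks = padded.reshape(brows, factor, bcols, factor)
    return np.nanmean(blocks, axis=(1, 3))


def category_summaries(category_map: CategoryMap,
                       covariates: dict[str, np.ndarray]) -> pd.DataFrame:
    """Mean ± SEM of each covariate per hotspot category.

    One row per (category, covariate) with mean, sem (sd/sqrt(n), 0 when
    n = 1) and n over the category's member locations; categories with no
    members are omitted, as is the none class.
    """
    rows = []
    cat = category_map.category
    for name in CATEGORIES:
        member = cat == CATEGORY_CODES[name]
        n = int(member.sum())
        if n == 0:
            continue
        for cov_name, grid in covariates.items():
            vals = np.asarray(grid, dtype=float)[member]
            vals = vals[np.isfinite(vals)]
            m = vals.mean() if vals.size else np.nan
            sem = vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else 0.0
            rows.append({"category": name, "covariate": cov_name,
                         "mean": m, "sem": sem, "n": int(vals.size)})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class KWResult:
    """Kruskal-Wallis rank test result (tie-corrected H, chi-square p)."""

    H: float
    df: int
    p: float


def kruskal_wallis(groups) -> KWResult:
    """Tie-corrected Kruskal-Wallis H over k groups.

    H = [12/(N(N+1)) * sum R_j^2/n_j - 3(N+1)] / (1 - sum(t^3-t)/(N^3-N));
    p from chi-square with k-1 degrees of freedom. All-identical pooled
    values give H = 0, p = 1 (no variation to rank).
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(g.size == 0 for g in groups):
        raise ValueError("every group needs at least one value")
    pooled = np.concatenate(groups)
    N = pooled.size
    if N < 3:
        raise ValueError("need at least 3 values in total")
    df = len(groups) - 1
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - ((tie_counts ** 3 - tie_counts).sum()
                        / (N ** 3 - N))
    if correction == 0:  # every value identical
        return KWResult(H=0.0, df=df, p=1.0)
    ranks = rankdata(pooled)
    H = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + g.size]
        H += r.sum() ** 2 / g.size
        start += g.size
    H = (12.0 / (N * (N + 1)) * H - 3 * (N + 1)) / correction
    return KWResult(H=float(H), df=df, p=float(chi2.sf(H, df)))


def kruskal_wallis_by_category(category_map: CategoryMap,
                               covariates: dict[str, np.ndarray]) -> pd.DataFrame:
    """Per-covariate Kruskal-Wallis test across category groups
    (variable, H, df, p); categories with no members drop out."""
    cat = category_map.category
    rows = []
    for cov_name, grid in covariates.items():
        grid = np.asarray(grid, dtype=float)
        groups = []
        for name in CATEGORIES:
            vals = grid[cat == CATEGORY_CODES[name]]
            vals = vals[np.isfinite(vals)]
            if vals.size:
                groups.append(vals)
        if len(groups) < 2:
            continue
        res = kruskal_wallis(groups)
        rows.append({"variable": cov_name, "H": res.H, "df": res.df,
                     "p": res.p})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CART

@dataclass
class TreeNode:
    feature: int | None = None          # None for leaves
    threshold: float | None = None      # go left iff value < threshold
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    prediction: str | None = None
    class_counts: dict = field(default_factory=dict)
    pct_of_data: float = 0.0
    impurity: float = 0.0

    @property
    def is_leaf(self) -> bool:
        return self.feature is None


@dataclass
class DecisionTree:
    """A fitted CART classifier: binary splits minimising Gini or
    cross-entropy impurity, with per-leaf class distributions and the
    percentage of the training data reaching each leaf."""

    root: TreeNode
    feature_names: list[str]
    criterion: str

    def leaves(self) -> list[TreeNode]:
        out, stack = [], [self.root]
        while stack:
            node = stack.pop()
            if node.is_leaf:
                out.append(node)
            else:
                stack.extend([node.left, node.right])
        return out

    def to_dict(self) -> dict:
        def rec(node: TreeNode) -> dict:
            if node.is_leaf:
                return {"leaf": True, "prediction": node.prediction,
                        "class_counts": node.class_counts,
                        "pct_of_data": node.pct_of_data}
            return {"leaf": False,
                    "feature": self.feature_names[node.feature],
                    "threshold": node.threshold,
                    "left": rec(node.left), "right": rec(node.right)}
        return {"criterion": self.criterion, "tree": rec(self.root)}

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)

    def render(self) -> str:
        """Indented-text rendering with per-leaf percentages."""
        lines = []

        def rec(node: TreeNode, indent: int, prefix: str) -> None:
            pad = "  " * indent
            if node.is_leaf:
                lines.append(f"{pad}{prefix}-> {node.prediction} "
                             f"({node.pct_of_data:.1f}% of data)")
            else:
                fname = self.feature_names[node.feature]
                lines.append(f"{pad}{prefix}{fname} < {node.threshold:g}?")
                rec(node.left, indent + 1, "yes: ")
                rec(node.right, indent + 1, "no:  ")

        rec(self.root, 0, "")
        return "\n".join(lines)


def _impurity(counts: np.ndarray, criterion: str) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts / n
    if criterion == "gini":
        return float(1.0 - (p ** 2).sum())
    p = p[p > 0]
    return float(-(p * np.log(p)).sum())


def _best_split(X: np.ndarray, y: np.ndarray, n_classes: int,
                min_leaf: int, criterion: str):
    """Exhaustive search over features x midpoint thresholds for the split
    minimising the weighted child impurity. Ties break toward the lowest
    feature index, then the lowest threshold."""
    n, d = X.shape
    best = None  # (weighted_impurity, feature, threshold)
    for j in range(d):
        order = np.argsort(X[:, j], kind="stable")
        xs, ys = X[order, j], y[order]
        uniq = np.unique(xs)
        if uniq.size < 2:
            continue
        thresholds = (uniq[:-1] + uniq[1:]) / 2.0
        left_counts = np.zeros(n_classes)
        total_counts = np.bincount(ys, minlength=n_classes).astype(float)
        idx = 0
        for thr in thresholds:
            while idx < n and xs[idx] < thr:
                left_counts[ys[idx]] += 1
                idx += 1
            nl = int(left_counts.sum())
            nr = n - nl
            if nl < min_leaf or nr < min_leaf:
                continue
            right_counts = total_counts - left_counts
            w = (nl * _impurity(left_counts, criterion)
                 + nr * _impurity(right_counts, criterion)) / n
            if best is None or w < best[0] - 1e-12:
                best = (w, j, float(thr))
    return best


def fit_cart(features, labels, feature_names=None, max_depth: int = 4,
             min_leaf: float = 0.05, criterion: str = "gini") -> DecisionTree:
    """Greedy recursive binary partitioning (CART) on category labels.

    ``min_leaf`` is the minimum samples per leaf, as a fraction of the
    training set when < 1 or an absolute count otherwise. Splitting stops
    at ``max_depth``, when a child would fall under ``min_leaf``, or when
    no split reduces impurity. Single-label input yields a single-leaf
    tree. Thresholds are midpoints of sorted unique feature values; the
    descent rule is "left iff value < threshold".
    """
    if criterion not in ("gini", "cross_entropy"):
        raise ValueError("criterion must be 'gini' or 'cross_entropy'")
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D (samples x covariates) array")
    if not np.isfinite(X).all():
        raise ValueError("features must be finite")
    labels = np.asarray(labels)
    n, d = X.shape
    if labels.shape[0] != n:
        raise ValueError("labels length must match features")
    feature_names = list(feature_names) if feature_names is not None \
        else [f"x{j}" for j in range(d)]
    classes, y = np.unique(labels, return_inverse=True)
    min_leaf_n = max(1, int(np.ceil(min_leaf * n))) if min_leaf < 1 \
        else int(min_leaf)

    def make_leaf(idx: np.ndarray) -> TreeNode:
        counts = np.bincount(y[idx], minlength=len(classes))
        pred = classes[int(counts.argmax())]
        return TreeNode(prediction=str(pred),
                        class_counts={str(c): int(k) for c, k
                                      in zip(classes, counts) if k},
                        pct_of_data=100.0 * idx.size / n,
                        impurity=_impurity(counts.astype(float), criterion))

    def build(idx: np.ndarray, depth: int) -> TreeNode:
        counts = np.bincount(y[idx], minlength=len(classes)).astype(float)
        node_imp = _impurity(counts, criterion)
        if depth >= max_depth or node_imp == 0.0 or idx.size < 2 * min_leaf_n:
            return make_leaf(idx)
        split = _best_split(X[idx], y[idx], len(classes), min_leaf_n,
                            criterion)
        if split is None or split[0] >= node_imp - 1e-12:  # no impurity gain
            return make_leaf(idx)
        w, j, thr = split
        go_left = X[idx, j] < thr
        node = make_leaf(idx)  # keep distribution/percentage at the node too
        node.feature, node.threshold, node.prediction = j, thr, None
        node.left = build(idx[go_left], depth + 1)
        node.right = build(idx[~go_left], depth + 1)
        return node

    root = build(np.arange(n), 0)
    return DecisionTree(root=root, feature_names=feature_names,
                        criterion=criterion)


def predict_cart(tree: DecisionTree, feature_vector) -> tuple[str, float]:
    """Root-to-leaf descent: left iff value < threshold (ties go right).

    Returns the predicted category and the leaf's share of the training
    data. The vector must cover every covariate the tree splits on.
    """
    x = np.asarray(feature_vector, dtype=float)
    if x.size < len(tree.feature_names):
        missing = tree.feature_names[x.size:]
        raise ValueError(f"feature vector missing covariate(s) {missing}")
    node = tree.root
    while not node.is_leaf:
        if not np.isfinite(x[node.feature]):
            raise ValueError(
                f"feature vector missing covariate "
                f"{tree.feature_names[node.feature]!r}")
        node = node.left if x[node.feature] < node.threshold else node.right
    return node.prediction, node.pct_of_data
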