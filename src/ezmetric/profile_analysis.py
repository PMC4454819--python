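"""Concentration-profile clustering and surface-chemistry classification.

Materials are compared through their EZ-score concentration profiles: rows of
a materials x concentration-grid matrix.  Agglomerative clustering with
Ward's minimum-variance criterion on Euclidean distances groups materials
with similar profiles; the two top-level clusters are labeled A/B with B the
cluster of higher mean sumEZ (the more toxic group).  A gain-ratio decision
tree then tests how well four surface functional groups (TMAT, phosphate,
phosphatidylcholine, amine) predict cluster membership, evaluated under
leave-one-out or stratified k-fold cross-validation.

Ward clustering is implemented directly over cluster sizes and centroids:
the merge cost of clusters *i*, *j* is the increase in within-cluster sum of
squares, ``n_i n_j / (n_i + n_j) * ||mu_i - mu_j||^2``, and at every step the
cheapest merge is taken, breaking ties on the smallest original row-index
pair.  Dendrogram heights are these merge costs (squared-Euclidean scale);
other conventions (e.g. SciPy's combined-distance heights) differ by a
monotone transform, so the two-cluster cut is convention-independent.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .assay_io import SURFACE_GROUPS
from .errors import ValidationError
from .ez_scoring import ConcentrationProfile, SumEZ

__all__ = [
    "DendrogramNode",
    "ClusterAssignment",
    "TreeNode",
    "CVResult",
    "profile_matrix",
    "ward_cluster",
    "cut_two",
    "to_newick",
    "build_tree",
    "cross_validate",
]


@dataclass(frozen=True)
class DendrogramNode:
    """Binary dendrogram node; leaves have height 0 and a single member."""

    members: frozenset[str]
    height: float
    children: tuple["DendrogramNode", ...] = ()

    def __post_init__(self) -> None:
        if self.children:
            if len(self.children) != 2:
                raise ValidationError("dendrogram nodes have 0 or 2 children")
            union = self.children[0].members | self.children[1].members
            if union != self.members:
                raise ValidationError("node members must be the union of child members")
        elif len(self.members) != 1 or self.height != 0:
            raise ValidationError("a leaf has exactly one member and height 0")

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> list[str]:
        """Member ids in dendrogram (left-to-right) order."""
        if self.is_leaf:
            return [next(iter(self.members))]
        return self.children[0].leaves() + self.children[1].leaves()


@dataclass(frozen=True)
class ClusterAssignment:
    """Two-cluster labeling; B is the cluster with the larger mean sumEZ."""

    labels: Mapping[str, str]
    summaries: Mapping[str, Mapping[str, float]]

    def members(self, label: str) -> frozenset[str]:
        return frozenset(m for m, lab in self.labels.items() if lab == label)


def profile_matrix(
    profiles: Iterable[ConcentrationProfile],
    grid: Sequence[float] | None = None,
    *,
    policy: str = "error",
) -> pd.DataFrame:
    """Align profiles on a common concentration grid (materials x grid).

    ``grid`` defaults to the union of all treatment concentrations.  Cells a
    profile does not cover are handled per ``policy``: ``"error"`` raises,
    ``"zero"`` fills 0 with a warning, ``"interpolate"`` fills interior gaps
    linearly in log10 concentration (edge gaps still raise).
    """
    profiles = list(profiles)
    if not profiles:
        raise ValidationError("no profiles given")
    if policy not in ("error", "zero", "interpolate"):
        raise ValidationError(f"unknown fill policy {policy!r}")
    if grid is None:
        grid = sorted({c for p in profiles for c in (pt.concentration for pt in p.treatment_points)})
    grid = [float(g) for g in grid]
    if any(g <= 0 for g in grid):
        raise ValidationError("grid concentrations must be positive")
    rows = {}
    for prof in profiles:
        have = {pt.concentration: pt.score for pt in prof.points}
        row = np.full(len(grid), np.nan)
        for k, g in enumerate(grid):
            for conc, score in have.items():
                if math.isclose(conc, g, rel_tol=1e-9):
                    row[k] = score
                    break
        missing = np.isnan(row)
        if missing.any():
            if policy == "error":
                raise ValidationError(
                    f"profile {prof.material_id} missing grid concentration(s) "
                    f"{[grid[k] for k in np.flatnonzero(missing)]}"
                )
            if policy == "zero":
                warnings.warn(
                    f"profile {prof.material_id}: filling {int(missing.sum())} "
                    "missing cell(s) with 0",
                    stacklevel=2,
                )
                row[missing] = 0.0
            else:
                logg = np.log10(grid)
                known = ~missing
                if not (known[0] and known[-1]):
                    raise ValidationError(
                        f"profile {prof.material_id}: cannot interpolate an edge gap"
                    )
                row = np.interp(logg, logg[known], row[known])
        rows[prof.material_id] = row
    if any(not np.isfinite(r).all() for r in rows.values()):
        raise ValidationError("non-finite profile values")
    return pd.DataFrame.from_dict(rows, orient="index", columns=grid)


def _ward_cost(n_i: int, n_j: int, mu_i: np.ndarray, mu_j: np.ndarray) -> float:
    d = mu_i - mu_j
    return n_i * n_j / (n_i + n_j) * float(d @ d)


def ward_cluster(matrix: pd.DataFrame | np.ndarray, labels: Sequence[str] | None = None) -> DendrogramNode:
    """Agglomerate profile rows under Ward's minimum-variance criterion.

    Heights are the per-merge increase in within-cluster sum of squares
    (guaranteed non-decreasing along any root path); ties break on the
    smallest pair of original row indices.
    """
    if isinstance(matrix, pd.DataFrame):
        labels = [str(x) for x in matrix.index]
        X = matrix.to_numpy(dtype=float)
    else:
        X = np.asarray(matrix, dtype=float)
        labels = [str(i) for i in range(X.shape[0])] if labels is None else list(labels)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValidationError("need a 2-D matrix with at least 2 rows")
    if len(labels) != X.shape[0]:
        raise ValidationError("label count does not match row count")
    if len(set(labels)) != len(labels):
        raise ValidationError("duplicate row labels")
    if not np.isfinite(X).all():
        raise ValidationError("matrix contains non-finite entries")

    # active clusters: (node, size, centroid, smallest original row index)
    active: list[tuple[DendrogramNode, int, np.ndarray, int]] = [
        (DendrogramNode(frozenset({lab}), 0.0), 1, X[i].copy(), i)
        for i, lab in enumerate(labels)
    ]
    while len(active) > 1:
        best = None
        for a in range(len(active)):
            for b in range(a + 1, len(active)):
                cost = _ward_cost(active[a][1], active[b][1], active[a][2], active[b][2])
                tie = tuple(sorted((active[a][3], active[b][3])))
                key = (cost, tie)
                if best is None or key < best[0]:
                    best = (key, a, b)
        (cost, _), a, b = best
        node_a, n_a, mu_a, idx_a = active[a]
        node_b, n_b, mu_b, idx_b = active[b]
        left, right = ((node_a, node_b) if idx_a < idx_b else (node_b, node_a))
        merged = DendrogramNode(
            members=node_a.members | node_b.members,
            height=cost,
            children=(left, right),
        )
        mu = (n_a * mu_a + n_b * mu_b) / (n_a + n_b)
        active = [c for k, c in enumerate(active) if k not in (a, b)]
        active.append((merged, n_a + n_b, mu, min(idx_a, idx_b)))
    return active[0][0]


def _summary(values: np.ndarray) -> dict[str, float]:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    return {
        "n": int(values.size),
        "min": float(values.min()),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "mean": float(values.mean()),
        "max": float(values.max()),
    }


def cut_two(
    root: DendrogramNode,
    sumez: Mapping[str, "SumEZ | float"],
) -> ClusterAssignment:
    """Cut the dendrogram at its root into clusters A and B.

    The two child subtrees are the clusters; the one with the larger mean
    sumEZ is labeled B (the more toxic cluster).  Per-cluster sumEZ box
    summaries (min, quartiles, mean, max) are returned alongside.  With equal
    means, B goes to the cluster containing the lexicographically smallest
    id, with a warning.
    """
    if root.is_leaf:
        raise ValidationError("cannot cut a single-leaf dendrogram")

    def value(m: str) -> float:
        v = sumez[m]
        return v.value if isinstance(v, SumEZ) else float(v)

    groups = [sorted(child.members) for child in root.children]
    means = [float(np.mean([value(m) for m in g])) for g in groups]
    if means[0] == means[1]:
        warnings.warn("equal mean sumEZ in both clusters; labeling B by smallest id", stacklevel=2)
        b_index = 0 if min(groups[0]) < min(groups[1]) else 1
    else:
        b_index = int(np.argmax(means))
    labels = {}
    summaries = {}
    for k, group in enumerate(groups):
        lab = "B" if k == b_index else "A"
        for m in group:
            labels[m] = lab
        summaries[lab] = _summary(np.array([value(m) for m in group]))
    return ClusterAssignment(labels=labels, summaries=summaries)


def _quote_newick(name: str) -> str:
    if any(c in name for c in " ():;,'[]"):
        return "'" + name.replace("'", "''") + "'"
    return name


def to_newick(root: DendrogramNode) -> str:
    """Serialize a dendrogram as Newick; branch lengths are height differences."""

    def render(node: DendrogramNode, parent_height: float) -> str:
        length = parent_height - node.height
        if node.is_leaf:
            return f"{_quote_newick(next(iter(node.members)))}:{length:g}"
        inner = ",".join(render(c, node.height) for c in node.children)
        return f"({inner}):{length:g}"

    if root.is_leaf:
        return f"{_quote_newick(next(iter(root.members)))}:0;"
    inner = ",".join(render(c, root.height) for c in root.children)
    return f"({inner});"


# ---------------------------------------------------------------------------
# Gain-ratio decision tree on the four surface-group features
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class TreeNode:
    """Decision-tree node: a split on one boolean feature, or a labeled leaf."""

    label: str | None = None
    counts: Mapping[str, int] | None = None
    feature: str | None = None
    branch_false: "TreeNode | None" = None
    branch_true: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def predict(self, features: Mapping[str, bool]) -> str:
        node = self
        while not node.is_leaf:
            node = node.branch_true if features[node.feature] else node.branch_false
        return node.label

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(self.branch_false.depth(), self.branch_true.depth())


@dataclass(frozen=True)
class CVResult:
    """Cross-validated classification outcome."""

    scheme: str
    accuracy: float
    misclassified: tuple[str, ...]
    seed: int | None = None


def _entropy(labels: Sequence[str]) -> float:
    n = len(labels)
    if n == 0:
        return 0.0
    h = 0.0
    for count in pd.Series(labels).value_counts():
        p = count / n
        h -= p * math.log2(p)
    return h


def _majority(labels: Sequence[str]) -> str:
    counts = pd.Series(labels).value_counts()
    top = counts.max()
    # ties resolve to the alphabetically first label (A before B)
    return sorted(lab for lab, c in counts.items() if c == top)[0]


def _as_feature_frame(features: Mapping[str, Mapping[str, bool]] | pd.DataFrame) -> pd.DataFrame:
    if isinstance(features, pd.DataFrame):
        df = features.astype(bool)
    else:
        df = pd.DataFrame.from_dict(features, orient="index").astype(bool)
    missing = [g for g in SURFACE_GROUPS if g not in df.columns]
    if missing:
        raise ValidationError(f"feature table missing surface group(s): {missing}")
    df = df[list(SURFACE_GROUPS)]
    df.index = df.index.astype(str)
    return df


def build_tree(
    features: Mapping[str, Mapping[str, bool]] | pd.DataFrame,
    labels: Mapping[str, str],
) -> TreeNode:
    """Induce a gain-ratio (C4.5-style) decision tree on binary features.

    At each node the split maximizing the gain ratio (information gain over
    split information) among unused features with strictly positive gain is
    taken; induction stops at pure nodes or when no informative split exists,
    and leaves take the majority label (ties to A).  No pruning is applied:
    with four binary features the hypothesis space is tiny.
    """
    df = _as_feature_frame(features)
    y = [labels[m] for m in df.index]

    def grow(idx: np.ndarray, available: tuple[str, ...]) -> TreeNode:
        sub_y = [y[i] for i in idx]
        counts = dict(pd.Series(sub_y).value_counts())
        base = _entropy(sub_y)
        if base == 0.0 or not available:
            return TreeNode(label=_majority(sub_y), counts=counts)
        n = len(idx)
        best = None
        for feat in available:
            mask = df[feat].to_numpy()[idx]
            n_true = int(mask.sum())
            if n_true == 0 or n_true == n:
                continue
            y_true = [sub_y[k] for k in range(n) if mask[k]]
            y_false = [sub_y[k] for k in range(n) if not mask[k]]
            gain = base - (len(y_true) / n) * _entropy(y_true) - (len(y_false) / n) * _entropy(y_false)
            if gain <= 1e-12:
                continue
            p = n_true / n
            split_info = -(p * math.log2(p) + (1 - p) * math.log2(1 - p))
            ratio = gain / split_info
            if best is None or ratio > best[0] + 1e-12:
                best = (ratio, feat, mask)
        if best is None:
            return TreeNode(label=_majority(sub_y), counts=counts)
        _, feat, mask = best
        remaining = tuple(f for f in available if f != feat)
        return TreeNode(
            feature=feat,
            counts=counts,
            branch_true=grow(idx[mask], remaining),
            branch_false=grow(idx[~mask], remaining),
        )

    if len(df) < 1:
        raise ValidationError("no training materials")
    return grow(np.arange(len(df)), tuple(SURFACE_GROUPS))


def cross_validate(
    features: Mapping[str, Mapping[str, bool]] | pd.DataFrame,
    labels: Mapping[str, str],
    *,
    scheme: str = "loo",
    k: int = 10,
    seed: int = 0,
) -> CVResult:
    """Cross-validate the surface-group tree classifier.

    ``scheme="loo"`` (default) is deterministic leave-one-out; ``"kfold"``
    uses stratified folds shuffled from ``seed``.  Folds whose training split
    contains a single class are trained as a majority leaf.
    """
    df = _as_feature_frame(features)
    ids = [str(m) for m in df.index]
    y = np.array([labels[m] for m in df.index])
    n = len(ids)
    if scheme == "loo":
        folds = [([j for j in range(n) if j != i], [i]) for i in range(n)]
        seed_out = None
    elif scheme == "kfold":
        if n < k:
            raise ValidationError(f"need n >= k for {k}-fold CV, got n = {n}")
        from sklearn.model_selection import StratifiedKFold

        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
        folds = [(list(tr), list(te)) for tr, te in skf.split(np.zeros(n), y)]
        seed_out = seed
    else:
        raise ValidationError(f"unknown CV scheme {scheme!r}")

    misclassified = []
    for train_idx, test_idx in folds:
        train_df = df.iloc[train_idx]
        train_labels = {ids[i]: y[i] for i in train_idx}
        tree = build_tree(train_df, train_labels)
        for i in test_idx:
            if tree.predict(df.iloc[i].to_dict()) != y[i]:
                misclassified.append(ids[i])
    accuracy = 1.0 - len(misclassified) / n
    return CVResult(
        scheme=f"kfold({k})" if scheme == "kfold" else "leave_one_out",
        accuracy=accuracy,
        misclassified=tuple(sorted(misclassified)),
        seed=seed_out,
    )
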