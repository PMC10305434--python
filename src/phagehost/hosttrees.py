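"""Per-genus binary decision trees (CART, Gini) with an impurity-split
stopping rule.

One tree is trained per bacterial host genus on the phage cluster-count
matrix; a node is split only while its weighted Gini impurity is
strictly greater than ``min_impurity_split`` (default 0.03).  Because
most genera are rare, positives are up-weighted by default so the two
classes carry equal total weight; without this the root impurity of a
rare genus sits below the split threshold and the tree degenerates to a
constant-negative leaf.  Prediction over the whole suite is multi-label:
every genus whose tree answers positive is an admissible host.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_formats import HostLabelTable


@dataclass
class TreeNode:
    """Internal node (feature/threshold/children) or leaf (positive_fraction)."""

    impurity: float
    n_samples: int
    feature: int | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    positive_fraction: float | None = None

    @property
    def is_leaf(self) -> bool:
        return self.left is None

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(self.left.depth(), self.right.depth())

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        return self.left.leaves() + self.right.leaves()


def gini(labels, weights=None) -> float:
    """Weighted Gini impurity 1 - p0^2 - p1^2 of binary labels."""
    y = np.asarray(labels)
    if y.size == 0:
        raise ValueError("gini of empty label set")
    w = np.ones(y.size) if weights is None else np.asarray(weights, dtype=float)
    if np.any(w <= 0):
        raise ValueError("weights must be positive")
    total = w.sum()
    p1 = w[y == 1].sum() / total
    return float(1.0 - p1**2 - (1.0 - p1) ** 2)


def best_split(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray,
    feature_ids: list[int],
) -> tuple[int, float, float] | None:
    """Exhaustive search for the split maximizing weighted impurity decrease.

    Thresholds are midpoints between consecutive distinct sorted values;
    ties break toward the smallest feature id, then smallest threshold.
    Returns (feature_id, threshold, decrease) or None when every feature
    is constant.  A zero-decrease split is still returned: Gini never
    increases under a split, and accepting ties lets patterns like XOR
    be solved by a later level (both children are always non-empty, so
    recursion terminates).
    """
    n = y.size
    if n < 2:
        return None
    total_w = weights.sum()
    parent = gini(y, weights)
    best: tuple[float, int, float] | None = None  # (-decrease, fid, thr) minimized
    for col, fid in enumerate(feature_ids):
        values = X[:, col]
        order = np.argsort(values, kind="stable")
        v = values[order]
        w = weights[order]
        wy = w * (y[order] == 1)
        cum_w = np.cumsum(w)
        cum_wy = np.cumsum(wy)
        # candidate boundaries: between consecutive distinct values
        distinct = np.nonzero(v[1:] != v[:-1])[0]  # split after index i
        for i in distinct:
            wl = cum_w[i]
            wr = total_w - wl
            p1l = cum_wy[i] / wl
            p1r = (cum_wy[-1] - cum_wy[i]) / wr
            gl = 1.0 - p1l**2 - (1.0 - p1l) ** 2
            gr = 1.0 - p1r**2 - (1.0 - p1r) ** 2
            decrease = parent - (wl * gl + wr * gr) / total_w
            thr = float((v[i] + v[i + 1]) / 2.0)
            key = (-decrease, fid, thr)
            if best is None or key < best:
                best = key
    if best is None:
        return None
    return best[1], best[2], max(0.0, -best[0])


def train_tree(
    X,
    y,
    min_impurity_split: float = 0.03,
    balanced: bool = True,
    feature_ids: list[int] | None = None,
) -> TreeNode:
    """Recursive CART on an integer feature matrix with binary labels.

    A node becomes a leaf iff its weighted impurity is <= the split
    threshold (only nodes with impurity strictly greater than it are
    divided), it is pure, or no split decreases impurity.  With
    ``balanced`` the positive class is up-weighted to equal total weight.
    There is no depth limit; the search and tie-breaking are exhaustive
    and deterministic.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    if X.ndim != 2 or X.shape[0] != y.size:
        raise ValueError(f"X has {X.shape[0]} rows but y has {y.size} labels")
    if feature_ids is None:
        feature_ids = list(range(X.shape[1]))
    n_pos = int((y == 1).sum())
    weights = np.ones(y.size, dtype=float)
    if balanced and 0 < n_pos < y.size:
        weights[y == 1] = (y.size - n_pos) / n_pos

    def grow(idx: np.ndarray) -> TreeNode:
        sub_y, sub_w = y[idx], weights[idx]
        imp = gini(sub_y, sub_w)
        pf = float(sub_w[sub_y == 1].sum() / sub_w.sum())
        if imp <= min_impurity_split:
            return TreeNode(impurity=imp, n_samples=idx.size, positive_fraction=pf)
        split = best_split(X[idx], sub_y, sub_w, feature_ids)
        if split is None:
            return TreeNode(impurity=imp, n_samples=idx.size, positive_fraction=pf)
        fid, thr, _ = split
        col = feature_ids.index(fid)
        go_left = X[idx, col] <= thr
        return TreeNode(
            impurity=imp,
            n_samples=idx.size,
            feature=fid,
            threshold=thr,
            left=grow(idx[go_left]),
            right=grow(idx[~go_left]),
        )

    return grow(np.arange(y.size))


@dataclass
class HostTreeSuite:
    """One trained tree per genus plus the column ids the trees index."""

    trees: dict[str, TreeNode]
    columns: list[int]
    config: dict = field(default_factory=dict)


def train_suite(
    matrix: pd.DataFrame,
    labels: HostLabelTable,
    genera: list[str] | set[str],
    min_impurity_split: float = 0.03,
    balanced: bool = True,
) -> HostTreeSuite:
    """Train one binary tree per genus: y_i = 1 iff the genus is among
    phage i's admissible hosts."""
    columns = list(matrix.columns)
    X = matrix.to_numpy(dtype=float)
    trees: dict[str, TreeNode] = {}
    for genus in sorted(genera):
        y = np.array([1 if genus in labels.genera_of(pid) else 0 for pid in matrix.index])
        if y.sum() == 0:
            warnings.warn(f"genus {genus}: no positive training phages; constant-negative tree", stacklevel=2)
            trees[genus] = TreeNode(impurity=0.0, n_samples=y.size, positive_fraction=0.0)
            continue
        trees[genus] = train_tree(
            X, y, min_impurity_split=min_impurity_split, balanced=balanced, feature_ids=columns
        )
    return HostTreeSuite(
        trees=trees,
        columns=columns,
        config={"min_impurity_split": min_impurity_split, "balanced": balanced},
    )


def _route(node: TreeNode, values: dict[int, float]) -> TreeNode:
    while not node.is_leaf:
        node = node.left if values[node.feature] <= node.threshold else node.right
    return node


def predict_hosts(
    vector: pd.Series,
    suite: HostTreeSuite,
    decision_threshold: float = 0.5,
) -> set[str]:
    """All genera whose tree routes the vector to a positive leaf.

    The result may be empty (no admissible host found) or contain
    several genera (a less-specific phage).
    """
    if list(vector.index) != list(suite.columns):
        raise ValueError(
            f"vector has {len(vector)} features but the suite expects "
            f"{len(suite.columns)} (column ids must match)"
        )
    values = {c: float(vector[c]) for c in suite.columns}
    out: set[str] = set()
    for genus, root in suite.trees.items():
        leaf = _route(root, values)
        if leaf.positive_fraction > decision_threshold:
            out.add(genus)
    return out


def predict_matrix(
    matrix: pd.DataFrame,
    suite: HostTreeSuite,
    decision_threshold: float = 0.5,
) -> dict[str, set[str]]:
    return {
        pid: predict_hosts(matrix.loc[pid], suite, decision_threshold)
        for pid in matrix.index
    }


def export_tree_dot(tree: TreeNode, genus: str, cluster_db=None) -> str:
    """Render a trained tree as Graphviz DOT text.

    Internal nodes name the gene cluster they test (plus its annotation
    when the cluster database carries one); leaves show the weighted
    positive fraction.
    """
    annotations: dict[int, str] = {}
    if cluster_db is not None:
        annotations = {
            c.cluster_id: c.annotation for c in cluster_db.clusters if c.annotation
        }
    lines = [f'digraph "{genus}" {{', "  node [shape=box];"]
    counter = [0]

    def emit(node: TreeNode) -> int:
        nid = counter[0]
        counter[0] += 1
        if node.is_leaf:
            cls = "positive" if node.positive_fraction > 0.5 else "negative"
            label = (
                f"{cls}\\npositive_fraction = {node.positive_fraction:.3f}"
                f"\\nn = {node.n_samples}\\nimpurity = {node.impurity:.3f}"
            )
            lines.append(f'  n{nid} [label="{label}"];')
            return nid
        label = (
            f"cluster {node.feature} <= {node.threshold:g}"
            f"\\nimpurity = {node.impurity:.3f}\\nn = {node.n_samples}"
        )
        if node.feature in annotations:
            label += f"\\n{annotations[node.feature]}"
        lines.append(f'  n{nid} [label="{label}"];')
        left_id = emit(node.left)
        right_id = emit(node.right)
        lines.append(f'  n{nid} -> n{left_id} [label="true"];')
        lines.append(f'  n{nid} -> n{right_id} [label="false"];')
        return nid

    emit(tree)
    lines.append("}")
    return "\n".join(lines) + "\n"
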