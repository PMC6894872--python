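"""Classification-tree characterization of extrapolation in covariate space.

Once prediction locations carry a binary extrapolation index, a classification
tree fitted with the index as the response reveals which covariate regions the
model has not adequately sampled — e.g. "shoreline above t1 and elevation
above t2" — guiding future sampling rather than merely flagging points.

The tree is plain greedy CART: at each node the (variable, threshold) pair
maximizing the decrease in Gini impurity is chosen among midpoints of sorted
unique values; recursion stops at ``max_depth``, ``min_leaf``, or purity.
Numeric covariates only.  Routing is strict: values below the threshold go
left, values at or above it go right.  Ties are broken by column order, then
by the smaller threshold, so fits are deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from mvextrap._errors import DataError, DimensionError

LABELS = {0: "prediction", 1: "extrapolation"}


@dataclass
class TreeNode:
    """One node of the binary partition.

    ``counts`` is (n_prediction, n_extrapolation) of training records reaching
    the node; ``node_fraction`` their share of the training set.  Leaves have
    ``split_variable`` None.
    """

    counts: tuple[int, int]
    node_fraction: float
    majority_label: str
    split_variable: str | None = None
    split_threshold: float | None = None
    impurity_decrease: float = 0.0
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None

    @property
    def is_leaf(self) -> bool:
        return self.split_variable is None


def _gini(n0: float, n1: float) -> float:
    tot = n0 + n1
    if tot <= 0:
        return 0.0
    p0 = n0 / tot
    return 1.0 - p0 * p0 - (1.0 - p0) * (1.0 - p0)


def _weighted_counts(y: np.ndarray, w: np.ndarray) -> tuple[float, float]:
    return float(w[y == 0].sum()), float(w[y == 1].sum())


def _best_split(
    X: np.ndarray, y: np.ndarray, w: np.ndarray, min_leaf: int
) -> tuple[int, float, float] | None:
    """Best (column, threshold, weighted impurity decrease), or None if no valid split."""
    n, q = X.shape
    n0, n1 = _weighted_counts(y, w)
    parent = (n0 + n1) * _gini(n0, n1)
    best = None
    for j in range(q):
        order = np.argsort(X[:, j], kind="stable")
        xs = X[order, j]
        ys = y[order]
        ws = w[order]
        # cumulative weighted class counts left of each boundary
        c1 = np.cumsum(ws * ys)
        c0 = np.cumsum(ws * (1 - ys))
        total1 = c1[-1]
        total0 = c0[-1]
        for i in range(n - 1):
            if xs[i] == xs[i + 1]:
                continue
            if (i + 1) < min_leaf or (n - i - 1) < min_leaf:
                continue
            l0, l1 = c0[i], c1[i]
            r0, r1 = total0 - l0, total1 - l1
            dec = parent - (l0 + l1) * _gini(l0, l1) - (r0 + r1) * _gini(r0, r1)
            thr = 0.5 * (xs[i] + xs[i + 1])
            if best is None or dec > best[2] + 1e-15:
                best = (j, thr, dec)
            # ties: keep the earlier column / smaller threshold (loop order does this)
    if best is None or best[2] <= 1e-12:
        return None
    return best


def fit_tree(
    covariates: np.ndarray,
    index: np.ndarray,
    max_depth: int = 4,
    min_leaf: int = 5,
    class_weight: dict[int, float] | str | None = None,
    column_names: Sequence[str] | None = None,
) -> TreeNode:
    """Greedy binary recursive partitioning of the extrapolation index.

    ``class_weight`` may be None (unweighted), a {0: w0, 1: w1} mapping, or
    ``"balanced"`` for inverse-frequency weights (useful because
    extrapolations are typically rare).  An all-one-class input yields a
    single leaf.
    """
    X = np.atleast_2d(np.asarray(covariates, dtype=float))
    y = np.asarray(index).astype(int).ravel()
    if X.shape[0] != y.shape[0]:
        raise DimensionError("covariates and index must have equal length")
    if not np.all(np.isfinite(X)):
        raise DataError("covariates may not contain missing entries")
    if not np.isin(y, (0, 1)).all():
        raise DataError("index must be binary 0/1")
    names = list(column_names) if column_names is not None else [
        f"x{j + 1}" for j in range(X.shape[1])
    ]
    if len(names) != X.shape[1]:
        raise DimensionError("column_names length does not match covariate columns")

    if class_weight == "balanced":
        n = y.size
        counts = np.bincount(y, minlength=2)
        cw = {c: (n / (2.0 * counts[c]) if counts[c] else 0.0) for c in (0, 1)}
    elif class_weight is None:
        cw = {0: 1.0, 1: 1.0}
    else:
        cw = {0: float(class_weight.get(0, 1.0)), 1: float(class_weight.get(1, 1.0))}
    w = np.where(y == 1, cw[1], cw[0]).astype(float)
    n_total = y.size

    def build(rows: np.ndarray, depth: int) -> TreeNode:
        yr = y[rows]
        wr = w[rows]
        n0 = int((yr == 0).sum())
        n1 = int((yr == 1).sum())
        w0, w1 = _weighted_counts(yr, wr)
        majority = LABELS[1] if w1 > w0 else LABELS[0]
        node = TreeNode(
            counts=(n0, n1),
            node_fraction=rows.size / n_total,
            majority_label=majority,
        )
        if depth >= max_depth or n0 == 0 or n1 == 0 or rows.size < 2 * min_leaf:
            return node
        found = _best_split(X[rows], yr, wr, min_leaf)
        if found is None:
            return node
        j, thr, dec = found
        go_left = X[rows, j] < thr
        node.split_variable = names[j]
        node.split_threshold = float(thr)
        node.impurity_decrease = float(dec)
        node.left = build(rows[go_left], depth + 1)
        node.right = build(rows[~go_left], depth + 1)
        return node

    return build(np.arange(n_total), 0)


def predict_tree(tree: TreeNode, x) -> tuple[str, list[str]]:
    """Route a covariate vector (mapping or array-aligned) down the tree.

    Returns the leaf's majority label and the decision path.  Values strictly
    below a threshold go left; values at the threshold go right.
    """
    path: list[str] = []
    node = tree
    while not node.is_leaf:
        var = node.split_variable
        if isinstance(x, dict):
            if var not in x:
                raise DataError(f"split variable {var!r} missing from input")
            val = float(x[var])
        else:
            val = float(_lookup(x, var, tree))
        if val < node.split_threshold:
            path.append(f"{var} < {node.split_threshold:g}")
            node = node.left
        else:
            path.append(f"{var} >= {node.split_threshold:g}")
            node = node.right
    return node.majority_label, path


def _collect_names(tree: TreeNode, out: list[str]) -> None:
    if tree.is_leaf:
        return
    if tree.split_variable not in out:
        out.append(tree.split_variable)
    _collect_names(tree.left, out)
    _collect_names(tree.right, out)


def _lookup(x, var: str, tree: TreeNode) -> float:
    # array input: positions follow the default x1..xq naming
    x = np.asarray(x, dtype=float).ravel()
    if var.startswith("x") and var[1:].isdigit():
        j = int(var[1:]) - 1
        if j >= x.size:
            raise DataError(f"split variable {var!r} missing from input")
        return x[j]
    raise DataError(
        f"split variable {var!r} requires a mapping input (named covariates)"
    )


def tree_summary(tree: TreeNode) -> list[tuple[str, float]]:
    """Split variables ranked by total Gini impurity decrease across their splits."""
    totals: dict[str, float] = {}

    def walk(node: TreeNode) -> None:
        if node.is_leaf:
            return
        totals[node.split_variable] = totals.get(node.split_variable, 0.0) + node.impurity_decrease
        walk(node.left)
        walk(node.right)

    walk(tree)
    return sorted(totals.items(), key=lambda kv: (-kv[1], kv[0]))


def render_tree(tree: TreeNode, indent: str = "") -> str:
    """Indented plain-text rendering with per-node counts, percentages, majority."""
    n0, n1 = tree.counts
    tot = max(n0 + n1, 1)
    line = (
        f"{indent}[{tree.majority_label}] extrap={n1} pred={n0} "
        f"({100 * n1 / tot:.1f}% / {100 * n0 / tot:.1f}%) "
        f"records={100 * tree.node_fraction:.1f}%"
    )
    if tree.is_leaf:
        return line + "  <leaf>"
    line += f"  split: {tree.split_variable} < {tree.split_threshold:g}"
    return "\n".join(
        [line, render_tree(tree.left, indent + "  "), render_tree(tree.right, indent + "  ")]
    )
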