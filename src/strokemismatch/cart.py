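"""Classification tree over presentation variables, split by Gini impurity.

A small, deterministic CART used to examine which presentation variables
(contraindications, mismatch eligibility/volume, NIHSS) drive the treatment
decision.  Greedy recursive partitioning: at each node every variable (in a
fixed order) and every midpoint between sorted distinct values is scored by
the decrease in Gini diversity index; ties break to the earlier variable,
then the lower threshold.  There is no pruning — the tree is descriptive.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: class labels, in fixed order; ties in a leaf resolve to the first label
CLASS_LABELS = ("supportive", "thrombolysis")


def gini_impurity(labels: Sequence) -> float:
    """Gini diversity index 1 - sum_c p_c^2 of a label multiset."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("gini_impurity of an empty label list is undefined")
    _, counts = np.unique(labels, return_counts=True)
    p = counts / labels.size
    return float(1.0 - np.sum(p**2))


@dataclass
class CartNode:
    """A tree node; leaves have ``label`` set and no split."""

    n_samples: int
    impurity: float
    class_counts: dict
    label: Optional[str] = None
    split_variable: Optional[str] = None
    split_threshold: Optional[float] = None
    left: Optional["CartNode"] = None   # samples with value <= threshold
    right: Optional["CartNode"] = None  # samples with value > threshold

    @property
    def is_leaf(self) -> bool:
        return self.split_variable is None

    def predict_one(self, row: dict) -> str:
        node = self
        while not node.is_leaf:
            v = row[node.split_variable]
            node = node.left if v <= node.split_threshold else node.right
        return node.label

    def to_dict(self) -> dict:
        d = {
            "n_samples": self.n_samples,
            "impurity": self.impurity,
            "class_counts": dict(self.class_counts),
        }
        if self.is_leaf:
            d["label"] = self.label
        else:
            d["split_variable"] = self.split_variable
            d["split_threshold"] = self.split_threshold
            d["left"] = self.left.to_dict()
            d["right"] = self.right.to_dict()
        return d

    def render(self, indent: int = 0) -> str:
        """Plain-text rendering of the tree for reports."""
        pad = "  " * indent
        head = f"{pad}[n={self.n_samples}, gini={self.impurity:.3f}]"
        if self.is_leaf:
            return f"{head} -> {self.label}\n"
        out = f"{head} {self.split_variable} <= {self.split_threshold:g}?\n"
        out += self.left.render(indent + 1)
        out += self.right.render(indent + 1)
        return out


def _majority(y: np.ndarray) -> tuple[str, dict]:
    counts = {c: int(np.sum(y == c)) for c in CLASS_LABELS}
    # ties resolve to the first label in CLASS_LABELS
    label = max(CLASS_LABELS, key=lambda c: counts[c] if counts[c] else -1)
    best = max(counts.values())
    for c in CLASS_LABELS:
        if counts[c] == best:
            label = c
            break
    return label, counts


def _best_split(
    X: pd.DataFrame, y: np.ndarray, feature_order: Sequence[str], min_leaf: int
) -> Optional[tuple[str, float, float]]:
    """(variable, threshold, impurity_decrease) of the best admissible split,
    or None.  Tie-break: earlier variable in ``feature_order``, then lower
    threshold (strictly better decreases are required to displace the best)."""
    n = y.size
    parent = gini_impurity(y)
    best: Optional[tuple[str, float, float]] = None
    for var in feature_order:
        values = X[var].to_numpy(dtype=float)
        order = np.argsort(values, kind="stable")
        v_sorted = values[order]
        y_sorted = y[order]
        distinct = np.nonzero(np.diff(v_sorted) > 0)[0]
        for i in distinct:
            thr = (v_sorted[i] + v_sorted[i + 1]) / 2.0
            n_left = i + 1
            n_right = n - n_left
            if n_left < min_leaf or n_right < min_leaf:
                continue
            g = (
                n_left / n * gini_impurity(y_sorted[:n_left])
                + n_right / n * gini_impurity(y_sorted[n_left:])
            )
            decrease = parent - g
            if decrease <= 1e-12:
                continue
            if best is None or decrease > best[2] + 1e-12:
                best = (var, thr, decrease)
    return best


def fit_cart(
    features: pd.DataFrame,
    treated: Sequence[bool],
    min_leaf: int = 5,
    max_depth: int = 4,
    feature_order: Optional[Sequence[str]] = None,
) -> CartNode:
    """Fit the classification tree.

    Parameters
    ----------
    features:
        One row per patient; numeric columns (booleans are treated as 0/1).
        Missing values are an error — imputation is out of scope.
    treated:
        Per-patient thrombolysis flag (the class to explain).
    min_leaf:
        Minimum samples in each child of an accepted split.
    max_depth:
        Maximum tree depth (root = depth 0).
    feature_order:
        Tie-breaking order over variables; defaults to column order.
    """
    X = features.copy()
    if X.isna().any().any():
        bad = list(X.columns[X.isna().any()])
        raise ValueError(f"missing feature values in columns {bad}; imputation is out of scope")
    for c in X.columns:
        X[c] = X[c].astype(float)
    y = np.asarray(
        [CLASS_LABELS[1] if t else CLASS_LABELS[0] for t in treated], dtype=object
    )
    if y.size != len(X):
        raise ValueError("features and labels have different lengths")
    if y.size < 2 * min_leaf:
        raise ValueError(f"need at least {2 * min_leaf} samples for min_leaf={min_leaf}")
    order = list(feature_order) if feature_order is not None else list(X.columns)

    def _grow(X_node: pd.DataFrame, y_node: np.ndarray, depth: int) -> CartNode:
        label, counts = _majority(y_node)
        node = CartNode(
            n_samples=int(y_node.size),
            impurity=gini_impurity(y_node),
            class_counts=counts,
            label=label,
        )
        if depth >= max_depth or node.impurity == 0.0:
            return node
        split = _best_split(X_node, y_node, order, min_leaf)
        if split is None:
            return node
        var, thr, _ = split
        go_left = X_node[var].to_numpy(dtype=float) <= thr
        node.split_variable = var
        node.split_threshold = float(thr)
        node.label = None
        node.left = _grow(X_node[go_left], y_node[go_left], depth + 1)
        node.right = _grow(X_node[~go_left], y_node[~go_left], depth + 1)
        return node

    return _grow(X, y, 0)
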