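"""Stage 1: gain-ratio decision-tree induction and path-to-rule conversion.

The tree is induced top-down in the C4.5 style: candidate tests are binary
threshold splits at midpoints between consecutive distinct sorted values
for numeric features, and multiway equality splits for categorical ones;
the test maximising the gain ratio (information gain divided by the split
information) is chosen among tests with positive gain.  Recursion stops on
node purity, the minimum leaf size, the depth cap, or when no candidate
has positive gain.  No error-based pruning is performed — in this pipeline
the subsequent rule-selection stage plays the generalisation role.

Each root-to-leaf path becomes one crisp rule; the leaf's count of
correctly classified training items becomes the rule's weight (an
``equal`` mode assigning weight 1 to every rule is also available).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Mapping

import numpy as np

from fuzzydx.crisp import CrispPredicate, CrispRule, CrispRuleBase
from fuzzydx.dataset import Dataset, FeatureSpec

__all__ = ["TreeNode", "induce_tree", "tree_to_rules", "dump_tree"]

_EPS = 1e-12


@dataclass
class TreeNode:
    """One node of the induced tree.

    Leaves carry ``class_value``, ``n_items`` and ``n_correct``; internal
    nodes carry the split (``feature`` plus either a numeric ``threshold``
    with ``left``/``right`` children for ``<= t`` / ``> t``, or a
    ``children`` mapping category -> subtree) and the majority class at the
    node (used for unseen categories at prediction time).
    """

    class_value: str
    n_items: int
    n_correct: int
    feature: str | None = None
    threshold: float | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    children: dict[str, "TreeNode"] | None = None

    @property
    def is_leaf(self) -> bool:
        return self.feature is None

    def predict(self, item: Mapping) -> str:
        node = self
        while not node.is_leaf:
            if node.threshold is not None:
                node = node.left if item[node.feature] <= node.threshold else node.right  # type: ignore[operator]
            else:
                child = (node.children or {}).get(str(item[node.feature]))
                if child is None:  # unseen category: fall back to node majority
                    return node.class_value
                node = child
        return node.class_value

    def leaves(self) -> list["TreeNode"]:
        if self.is_leaf:
            return [self]
        out = []
        if self.threshold is not None:
            out += self.left.leaves() + self.right.leaves()  # type: ignore[union-attr]
        else:
            for child in (self.children or {}).values():
                out += child.leaves()
        return out


def _entropy(counts: np.ndarray) -> float:
    n = counts.sum()
    if n == 0:
        return 0.0
    p = counts[counts > 0] / n
    return float(-(p * np.log2(p)).sum())


def _class_counts(labels: np.ndarray, classes: tuple[str, ...]) -> np.ndarray:
    return np.array([(labels == c).sum() for c in classes])


@dataclass
class _Split:
    feature: str
    gain_ratio: float
    threshold: float | None = None  # numeric split
    partitions: dict[str, np.ndarray] | None = None  # categorical split
    left_idx: np.ndarray | None = None
    right_idx: np.ndarray | None = None


def _best_numeric_split(
    values: np.ndarray, labels: np.ndarray, classes: tuple[str, ...], min_leaf: int
) -> tuple[float, float] | None:
    """Best (threshold, gain_ratio) for one numeric feature, or None."""
    order = np.argsort(values, kind="stable")
    v = values[order]
    y = labels[order]
    n = v.size
    parent_counts = _class_counts(y, classes)
    parent_h = _entropy(parent_counts)
    # cumulative class counts after each position
    onehot = np.stack([(y == c) for c in classes], axis=1).astype(int)
    cum = np.cumsum(onehot, axis=0)  # (n, M)
    best: tuple[float, float] | None = None
    # candidate cut after position i (0-based) wherever the value changes
    change = np.flatnonzero(v[1:] > v[:-1])
    for i in change:
        n_left = i + 1
        n_right = n - n_left
        if n_left < min_leaf or n_right < min_leaf:
            continue
        left_counts = cum[i]
        right_counts = parent_counts - left_counts
        h = (n_left * _entropy(left_counts) + n_right * _entropy(right_counts)) / n
        gain = parent_h - h
        if gain <= _EPS:
            continue
        split_info = _entropy(np.array([n_left, n_right]))
        if split_info <= _EPS:
            continue
        ratio = gain / split_info
        thr = (v[i] + v[i + 1]) / 2.0
        if best is None or ratio > best[1] + _EPS:
            best = (thr, ratio)
    return best


def _best_categorical_split(
    values: np.ndarray, labels: np.ndarray, classes: tuple[str, ...], min_leaf: int
) -> tuple[dict[str, np.ndarray], float] | None:
    cats = list(dict.fromkeys(values))
    if len(cats) < 2:
        return None
    parts = {c: np.flatnonzero(values == c) for c in cats}
    if any(idx.size < min_leaf for idx in parts.values()):
        return None
    n = values.size
    parent_h = _entropy(_class_counts(labels, classes))
    h = sum(idx.size * _entropy(_class_counts(labels[idx], classes)) for idx in parts.values()) / n
    gain = parent_h - h
    if gain <= _EPS:
        return None
    split_info = _entropy(np.array([idx.size for idx in parts.values()]))
    if split_info <= _EPS:
        return None
    return parts, gain / split_info


def _majority(labels: np.ndarray, classes: tuple[str, ...], global_counts: np.ndarray) -> str:
    counts = _class_counts(labels, classes)
    top = counts.max()
    tied = [classes[i] for i in np.flatnonzero(counts == top)]
    if len(tied) == 1:
        return tied[0]
    # ties: globally most frequent class, then lexicographic
    g = {classes[i]: global_counts[i] for i in range(len(classes))}
    return sorted(tied, key=lambda c: (-g[c], c))[0]


def induce_tree(
    ds: Dataset, min_leaf: int = 2, max_depth: int | None = None
) -> TreeNode:
    """Greedy top-down induction by gain ratio.

    Parameters
    ----------
    ds
        Training dataset (non-empty; a single-class dataset yields a lone
        leaf).
    min_leaf
        Minimum number of items per branch of any split.
    max_depth
        Depth cap; ``None`` means unbounded.
    """
    if ds.n_items == 0:
        raise ValueError("cannot induce a tree from an empty dataset")
    classes = ds.classes
    labels = ds.labels
    global_counts = _class_counts(labels, classes)
    columns = {
        f.name: (
            ds.items[f.name].to_numpy(dtype=float)
            if f.kind == "numeric"
            else ds.items[f.name].astype(str).to_numpy()
        )
        for f in ds.features
    }
    kinds = {f.name: f.kind for f in ds.features}

    def build(idx: np.ndarray, depth: int) -> TreeNode:
        y = labels[idx]
        cls = _majority(y, classes, global_counts)
        node = TreeNode(class_value=cls, n_items=idx.size, n_correct=int((y == cls).sum()))
        if np.unique(y).size == 1:
            return node
        if max_depth is not None and depth >= max_depth:
            return node
        if idx.size < 2 * min_leaf:
            return node
        best: _Split | None = None
        for f in ds.features:
            col = columns[f.name][idx]
            if kinds[f.name] == "numeric":
                res = _best_numeric_split(col, y, classes, min_leaf)
                if res is not None:
                    thr, ratio = res
                    if best is None or ratio > best.gain_ratio + _EPS:
                        best = _Split(f.name, ratio, threshold=thr)
            else:
                res = _best_categorical_split(col, y, classes, min_leaf)
                if res is not None:
                    parts, ratio = res
                    if best is None or ratio > best.gain_ratio + _EPS:
                        best = _Split(f.name, ratio, partitions=parts)
        if best is None:
            return node
        node.feature = best.feature
        if best.threshold is not None:
            node.threshold = best.threshold
            col = columns[best.feature][idx]
            node.left = build(idx[col <= best.threshold], depth + 1)
            node.right = build(idx[col > best.threshold], depth + 1)
        else:
            node.children = {
                cat: build(idx[sub], depth + 1)
                for cat, sub in best.partitions.items()  # type: ignore[union-attr]
            }
        return node

    return build(np.arange(ds.n_items), 0)


def tree_to_rules(
    tree: TreeNode,
    classes: tuple[str, ...],
    weight_mode: Literal["coverage", "equal"] = "coverage",
) -> CrispRuleBase:
    """One crisp rule per leaf: the conjunction of path tests implies the
    leaf class, weighted by the leaf's correctly-classified count (or 1.0
    in ``equal`` mode).  Rules are grouped by class in declaration order
    and sorted by descending weight within each class.
    """
    collected: list[CrispRule] = []

    def walk(node: TreeNode, path: tuple[CrispPredicate, ...]) -> None:
        if node.is_leaf:
            weight = float(node.n_correct) if weight_mode == "coverage" else 1.0
            collected.append(CrispRule(path, node.class_value, weight))
            return
        if node.threshold is not None:
            walk(node.left, path + (CrispPredicate(node.feature, "<=", node.threshold),))  # type: ignore[arg-type]
            walk(node.right, path + (CrispPredicate(node.feature, ">", node.threshold),))  # type: ignore[arg-type]
        else:
            for cat, child in (node.children or {}).items():
                walk(child, path + (CrispPredicate(node.feature, "==", cat),))  # type: ignore[arg-type]

    walk(tree, ())
    ordered: list[CrispRule] = []
    for cls in classes:
        cls_rules = [r for r in collected if r.consequent == cls]
        cls_rules.sort(key=lambda r: -r.weight)
        ordered.extend(cls_rules)
    return CrispRuleBase(ordered, classes)


def dump_tree(node: TreeNode, indent: int = 0) -> str:
    """Indented text rendering of the tree for inspection."""
    pad = "|   " * indent
    if node.is_leaf:
        return f"{pad}-> {node.class_value} ({node.n_correct}/{node.n_items})"
    lines = []
    if node.threshold is not None:
        lines.append(f"{pad}{node.feature} <= {node.threshold:g}")
        lines.append(dump_tree(node.left, indent + 1))  # type: ignore[arg-type]
        lines.append(f"{pad}{node.feature} > {node.threshold:g}")
        lines.append(dump_tree(node.right, indent + 1))  # type: ignore[arg-type]
    else:
        for cat, child in (node.children or {}).items():
            lines.append(f"{pad}{node.feature} == {cat}")
            lines.append(dump_tree(child, indent + 1))
    return "\n".join(lines)
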