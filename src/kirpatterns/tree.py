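"""Information-gain (ID3) decision tree over binary attributes.

Serves as the tree comparator for the rule-mining analysis: greedy
top-down induction splitting on the attribute of maximal Shannon
information gain, with deterministic tie-breaks (lexicographic
attribute order; majority-tie leaves default to class 0) and optional
reduced-error pruning on a held-out fraction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .cohort import Cohort, GenotypeRecord
from .exceptions import KirPatternsError


def entropy(class_counts: tuple[int, int]) -> float:
    """Shannon entropy in bits of a two-class count pair."""
    n0, n1 = class_counts
    if n0 < 0 or n1 < 0 or n0 + n1 == 0:
        raise ValueError(f"invalid class counts {class_counts}")
    total = n0 + n1
    h = 0.0
    for k in (n0, n1):
        if k:
            p = k / total
            h -= p * math.log2(p)
    return h


@dataclass
class TreeNode:
    """Internal node (``split_attribute`` + two children) or leaf
    (``leaf_class`` with its support and purity)."""

    split_attribute: str | None = None
    children: dict[int, "TreeNode"] = field(default_factory=dict)
    leaf_class: int | None = None
    support: int = 0
    purity: float = 1.0

    @property
    def is_leaf(self) -> bool:
        return self.split_attribute is None

    def depth(self) -> int:
        if self.is_leaf:
            return 0
        return 1 + max(child.depth() for child in self.children.values())

    def to_dict(self) -> dict:
        if self.is_leaf:
            return {
                "leaf": True, "class": self.leaf_class,
                "support": self.support, "purity": self.purity,
            }
        return {
            "leaf": False, "attribute": self.split_attribute,
            "children": {str(v): c.to_dict() for v, c in sorted(self.children.items())},
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), sort_keys=True, **kwargs)

    def render(self, indent: str = "") -> str:
        """Indented ``attribute = v: class (support)`` text layout."""
        if self.is_leaf:
            return f"{indent}class {self.leaf_class} ({self.support})"
        lines = []
        for value, child in sorted(self.children.items()):
            head = f"{indent}{self.split_attribute} = {value}:"
            if child.is_leaf:
                lines.append(f"{head} {child.leaf_class} ({child.support})")
            else:
                lines.append(head)
                lines.append(child.render(indent + "  "))
        return "\n".join(lines)


def _counts(labels: np.ndarray) -> tuple[int, int]:
    n1 = int(labels.sum())
    return (len(labels) - n1, n1)


def information_gain(cohort: Cohort, attribute: str) -> float:
    """Parent class entropy minus the split-weighted child entropies."""
    if attribute not in cohort.genes:
        raise KeyError(f"unknown attribute {attribute!r}")
    labels = cohort.class_labels()
    values = cohort.gene_matrix()[:, cohort.genes.index(attribute)]
    return _gain(values.astype(bool), labels)


def _gain(mask_present: np.ndarray, labels: np.ndarray) -> float:
    parent = entropy(_counts(labels))
    n = len(labels)
    child_sum = 0.0
    for branch in (mask_present, ~mask_present):
        if branch.any():
            child_sum += branch.sum() / n * entropy(_counts(labels[branch]))
    return parent - child_sum


def _majority(labels: np.ndarray) -> tuple[int, float]:
    n0, n1 = _counts(labels)
    cls = 0 if n0 >= n1 else 1  # ties -> healthy, the conservative call
    return cls, max(n0, n1) / (n0 + n1)


def _grow(
    mat: np.ndarray,
    labels: np.ndarray,
    attrs: list[str],
    all_attrs: tuple[str, ...],
    used: frozenset[str],
    depth: int,
    max_depth: int | None,
    min_leaf: int,
) -> TreeNode:
    cls, purity = _majority(labels)
    leaf = TreeNode(leaf_class=cls, support=len(labels), purity=purity)
    if (
        purity == 1.0
        or len(labels) < min_leaf
        or (max_depth is not None and depth >= max_depth)
    ):
        return leaf
    best_attr, best_gain = None, 0.0
    for attr in attrs:  # attrs lexicographically sorted -> deterministic ties
        if attr in used:
            continue
        col = mat[:, all_attrs.index(attr)].astype(bool)
        g = _gain(col, labels)
        if g > best_gain + 1e-12:
            best_attr, best_gain = attr, g
    if best_attr is None:
        return leaf
    col = mat[:, all_attrs.index(best_attr)].astype(bool)
    node = TreeNode(split_attribute=best_attr, support=len(labels))
    for value, branch in ((0, ~col), (1, col)):
        if branch.any():
            node.children[value] = _grow(
                mat[branch], labels[branch], attrs, all_attrs,
                used | {best_attr}, depth + 1, max_depth, min_leaf,
            )
        else:
            node.children[value] = TreeNode(
                leaf_class=cls, support=0, purity=purity
            )
    return node


def _prune_reduced_error(
    node: TreeNode, mat: np.ndarray, labels: np.ndarray, all_attrs: tuple[str, ...]
) -> TreeNode:
    if node.is_leaf or len(labels) == 0:
        return node
    col = mat[:, all_attrs.index(node.split_attribute)].astype(bool)
    for value, branch in ((0, ~col), (1, col)):
        node.children[value] = _prune_reduced_error(
            node.children[value], mat[branch], labels[branch], all_attrs
        )
    preds = np.array(
        [_follow(node, dict(zip(all_attrs, row))) for row in mat], dtype=int
    )
    subtree_errors = int((preds != labels).sum())
    cls, purity = _majority(labels)
    leaf_errors = int((labels != cls).sum())
    if leaf_errors <= subtree_errors:
        return TreeNode(leaf_class=cls, support=node.support, purity=purity)
    return node


def build_tree(
    cohort: Cohort,
    max_depth: int | None = None,
    min_leaf: int = 1,
    prune: bool = False,
    prune_fraction: float = 0.25,
    seed: int = 0,
) -> TreeNode:
    """Greedy ID3 induction on a cohort.

    A node becomes a leaf when pure, when no attribute yields positive
    gain, at the depth cap, or below ``min_leaf`` support; leaf class
    is the majority (ties to class 0).  With ``prune=True`` the cohort
    is split (seeded) into grow/validation parts and subtrees that do
    not beat their majority leaf on the validation part are collapsed.
    """
    mat = cohort.gene_matrix()
    labels = cohort.class_labels().astype(int)
    attrs = sorted(cohort.genes)
    if prune and len(cohort) >= 8:
        rng = np.random.default_rng(seed)
        idx = rng.permutation(len(cohort))
        n_val = max(1, int(round(prune_fraction * len(cohort))))
        val, grow_idx = idx[:n_val], idx[n_val:]
        root = _grow(
            mat[grow_idx], labels[grow_idx], attrs, cohort.genes,
            frozenset(), 0, max_depth, min_leaf,
        )
        return _prune_reduced_error(root, mat[val], labels[val], cohort.genes)
    return _grow(mat, labels, attrs, cohort.genes, frozenset(), 0, max_depth, min_leaf)


def _follow(node: TreeNode, values: Mapping[str, int]) -> int:
    while not node.is_leaf:
        attr = node.split_attribute
        if attr not in values:
            raise KeyError(f"record lacks attribute {attr!r} tested by the tree")
        node = node.children[int(values[attr])]
    return node.leaf_class


def predict(tree: TreeNode, record: GenotypeRecord | Mapping[str, int]) -> int:
    """Follow the path of attribute tests to a leaf class."""
    values = record.gene_presence if isinstance(record, GenotypeRecord) else record
    return _follow(tree, values)
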