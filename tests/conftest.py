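"""Shared fixtures: small hand-built trees and random-instance helpers."""

from __future__ import annotations

import numpy as np
import pytest

from thermopath.core_io import AMINO_ACIDS, AnnotatedTree, SpeciesInfo, TreeNode


def _preorder(node):
    yield node
    for child in node.children:
        yield from _preorder(child)


def build_tree(newick_like: TreeNode, phenotypes: dict[str, str] | None = None,
               labels: dict[tuple[str, str], str] | None = None) -> AnnotatedTree:
    """Wrap a TreeNode topology into an AnnotatedTree with background labels
    by default."""
    leaves = [n.name for n in _preorder(newick_like) if n.is_leaf]
    meta = {
        name: SpeciesInfo(
            (phenotypes or {}).get(name, "mesophile"),
            30.0,
        )
        for name in leaves
    }
    branch_labels = {}
    for node in _preorder(newick_like):
        for child in node.children:
            branch_labels[(node.name, child.name)] = "background"
    if labels:
        branch_labels.update(labels)
    return AnnotatedTree(newick_like, branch_labels, meta)


def node(name: str, *children: TreeNode, length: float = 1.0) -> TreeNode:
    n = TreeNode(name, length)
    for child in children:
        n.add_child(child)
    return n


def random_binary_tree(n_leaves: int, rng: np.random.Generator) -> AnnotatedTree:
    """Random rooted binary topology with background-labeled branches."""
    names = [f"L{i}" for i in range(n_leaves)]
    root = TreeNode("")
    root.add_child(TreeNode(names[0]))
    root.add_child(TreeNode(names[1]))
    for name in names[2:]:
        edges = [(p, c) for p in _preorder(root) for c in p.children]
        parent, child = edges[rng.integers(len(edges))]
        mid = TreeNode("")
        parent.children[parent.children.index(child)] = mid
        mid.parent = parent
        mid.add_child(child)
        mid.add_child(TreeNode(name))
    counter = 0
    for n in _preorder(root):
        if not n.is_leaf:
            counter += 1
            n.name = f"N{counter}"
    return build_tree(root)


def random_column(tree: AnnotatedTree, rng: np.random.Generator,
                  n_states: int = 4, p_missing: float = 0.1) -> dict[str, str]:
    """Random leaf states drawn from a small residue pool, with occasional
    missing data."""
    pool = rng.choice(20, size=n_states, replace=False)
    states = {}
    for leaf in tree.leaf_names():
        if rng.random() < p_missing:
            states[leaf] = "-"
        else:
            states[leaf] = AMINO_ACIDS[int(pool[rng.integers(len(pool))])]
    return states


@pytest.fixture
def five_leaf_tree() -> AnnotatedTree:
    """(((A,B),C),(D,E)) with unit branch lengths."""
    return build_tree(
        node(
            "root",
            node("P", node("Q", node("A"), node("B")), node("C")),
            node("R", node("D"), node("E")),
        )
    )


@pytest.fixture
def four_leaf_tree() -> AnnotatedTree:
    """(((A,B),C),D)."""
    return build_tree(
        node(
            "root",
            node("P", node("Q", node("A"), node("B")), node("C")),
            node("D"),
        )
    )
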