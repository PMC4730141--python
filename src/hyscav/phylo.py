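"""Rooted-tree helpers on top of dendropy.

Internal nodes receive stable labels ``N<postorder index>`` so that
ancestral sequences, cavity tables and lineage records can refer to the
same node across modules and across runs.  Leaf nodes keep their taxon
labels.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterator, List, Tuple

import dendropy


def read_tree(path: str | Path) -> dendropy.Tree:
    tree = dendropy.Tree.get(path=str(path), schema="newick", preserve_underscores=True)
    label_internal_nodes(tree)
    return tree


def write_tree(tree: dendropy.Tree, path: str | Path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True, unquoted_underscores=True)


def tree_from_newick(newick: str) -> dendropy.Tree:
    tree = dendropy.Tree.get(data=newick, schema="newick", preserve_underscores=True)
    label_internal_nodes(tree)
    return tree


def label_internal_nodes(tree: dendropy.Tree, force: bool = False) -> dendropy.Tree:
    """Assign post-order labels N0, N1, ... to unlabeled internal nodes."""
    idx = 0
    for node in tree.postorder_node_iter():
        if node.is_leaf():
            idx += 1
            continue
        if force or not node.label:
            node.label = f"N{idx}"
        idx += 1
    return tree

def node_name(node: dendropy.Node) -> str:
    if node.is_leaf():
        if node.taxon is None:
            raise ValueError("leaf without taxon label")
        return node.taxon.label
    if not node.label:
        raise ValueError("internal node without label; call label_internal_nodes first")
    return node.label


def leaf_names(tree: dendropy.Tree) -> List[str]:
    return [node_name(leaf) for leaf in tree.leaf_node_iter()]


def iter_branches(tree: dendropy.Tree) -> Iterator[Tuple[dendropy.Node, dendropy.Node]]:
    """Yield (parent, child) pairs for every branch of the rooted tree."""
    for node in tree.preorder_node_iter():
        for child in node.child_nodes():
            yield node, child


def total_tree_length(tree: dendropy.Tree) -> float:
    return sum((e.length or 0.0) for e in tree.preorder_edge_iter() if e.head_node.parent_node)


def scale_tree_length(tree: dendropy.Tree, target: float) -> dendropy.Tree:
    """Rescale all branch lengths so they sum to ``target``."""
    current = total_tree_length(tree)
    if current <= 0:
        if target > 0:
            raise ValueError("cannot scale a zero-length tree to positive length")
        return tree
    factor = target / current
    for edge in tree.preorder_edge_iter():
        if edge.head_node.parent_node is not None and edge.length is not None:
            edge.length *= factor
    return tree
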